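"""Learn the per-strategy word vocabularies and inspect the WCSS elbows.

Pools all subjects' segment descriptors per windowing strategy, clusters them
with PAM K-medoids over the candidate vocabulary sizes, and writes each
strategy's vocabulary (medoids + standardization + WCSS curve) as JSON plus a
combined WCSS-curve table for plotting.
"""

import argparse
from pathlib import Path

import pandas as pd

from wristbow import pipeline, synth


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--days", type=int, default=2)
    parser.add_argument("--out", type=Path, default=Path("results/vocab"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    preset = pipeline.desk_preset()
    cfg = preset.cohort_config(master_seed=args.seed)
    cfg.days = args.days
    sessions = synth.generate_cohort(cfg)
    descriptors = pipeline.cohort_descriptors(sessions, preset.windows_s)
    vocabs = pipeline.build_vocabularies(descriptors, preset, seed=args.seed)

    curves = []
    for w in sorted(vocabs):
        v = vocabs[w]
        v.to_json(args.out / f"vocabulary_{w:g}s.json")
        for k, wcss in v.wcss_curve:
            curves.append({"window_s": w, "k": k, "wcss": wcss, "chosen": k == v.k})
    pd.DataFrame(curves).to_csv(args.out / "wcss_curves.csv", index=False)

    chosen = {f"{w:g} s": vocabs[w].k for w in sorted(vocabs)}
    print("elbow-selected vocabulary sizes per windowing strategy:")
    for name, k in chosen.items():
        print(f"  {name:>8}: k = {k}")
    print(f"combined document length: {sum(v.k for v in vocabs.values())} words")
    print(f"wrote vocabularies and WCSS curves to {args.out}/")


if __name__ == "__main__":
    main()
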