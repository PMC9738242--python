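"""Seeded synthetic wrist-accelerometry cohorts.

The generator emulates week-long passive wrist recordings from two groups —
healthy elderly (HE) and Parkinson's disease (PD) — carrying the statistical
structure the downstream analysis assumes:

* a fixed per-subject gravity orientation (unit vector with a small random
  tilt), so features must behave under arbitrary device orientation;
* alternating activity/rest bouts with exponential-like durations, driven by a
  two-state Markov process; movement inside active bouts is low-pass-filtered
  Gaussian noise scaled per bout and per day;
* a PD group with globally reduced movement amplitude (``activity_scale`` < 1)
  and 4-6 Hz tremor-band oscillation during a fraction of rest bouts;
* day-to-day variability in overall movement intensity (a per-day lognormal
  multiplier), so short observation windows identify subjects less reliably
  than full weeks;
* white sensor noise and clipping at the device range (default +/- 8 g).

Effect sizes are configurable down to zero (null cohorts).  All randomness is
driven by numpy SeedSequence streams: identical (config, seed) gives
bit-identical cohorts, and the layout / movement / tremor / noise streams are
independent so that, e.g., changing the tremor amplitude does not reshuffle
the bout structure.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy import signal as sp_signal

GRAVITY_G = 1.0
DEVICE_RANGE_G = 8.0

#: Activity repertoire: each active bout is one "activity type" with its own
#: spectral bandwidth (Hz) and intensity multiplier (slow large-amplitude
#: tasks up to brisk high-frequency ones).  Subjects differ strongly in how
#: often they do each type (a Dirichlet mixture), which makes week-level
#: descriptor means vary between subjects for reasons unrelated to disease.
ACTIVITY_TYPE_CUTOFF_HZ: tuple[float, ...] = (1.0, 2.0, 3.5, 5.5)
ACTIVITY_TYPE_INTENSITY: tuple[float, ...] = (0.5, 1.0, 1.6, 2.4)
#: Cohort sizes of the default two-group design (healthy elderly / PD).
DEFAULT_N_HE = 32
DEFAULT_N_PD = 28


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class SubjectProfile:
    """Movement phenotype of one simulated subject.

    Parameters
    ----------
    group : "HE" or "PD".
    tremor_rate : probability that a given rest bout contains a tremor episode.
    tremor_freq_hz : tremor oscillation frequency (Hz); PD rest tremor sits in
        the 4-6 Hz band.
    tremor_amp_g : tremor amplitude (g).
    activity_scale : multiplicative movement-intensity factor; < 1 models the
        globally reduced movement amplitude of PD (bradykinesia).
    bout_mean_s, rest_mean_s : mean duration (s) of active and rest bouts.
    burst_sd_g : base SD (g) of in-bout movement before scaling.
    burst_amp_sd : SD of the per-bout lognormal amplitude factor (heavy-tailed
        bout-to-bout intensity variation).
    activity_type_alpha : Dirichlet concentration of the subject's mixture
        over the activity repertoire; small values give strongly personal,
        disease-unrelated activity profiles.
    rest_movement_frac : residual movement during rest, as a fraction of the
        active-bout SD (small fidgeting; keeps rest windows non-constant).
    noise_sd_g : white sensor-noise SD (g).
    day_var_sd : SD of the per-day lognormal activity multiplier.
    tilt_sd_rad : SD of the per-subject gravity tilt angle.
    """

    group: str
    tremor_rate: float = 0.0
    tremor_freq_hz: float = 5.0
    tremor_amp_g: float = 0.0
    activity_scale: float = 1.0
    bout_mean_s: float = 60.0
    rest_mean_s: float = 90.0
    burst_sd_g: float = 0.25
    burst_amp_sd: float = 0.3
    activity_type_alpha: float = 0.6
    rest_movement_frac: float = 0.05
    noise_sd_g: float = 0.02
    day_var_sd: float = 0.3
    tilt_sd_rad: float = 0.15

    def __post_init__(self) -> None:
        if self.group not in ("HE", "PD"):
            raise ConfigError(f"group must be 'HE' or 'PD', got {self.group!r}")
        if not 0.0 <= self.tremor_rate <= 1.0:
            raise ConfigError("tremor_rate must be a probability")
        if self.tremor_amp_g < 0 or self.noise_sd_g < 0 or self.burst_sd_g < 0:
            raise ConfigError("amplitudes must be non-negative")
        if self.activity_scale < 0:
            raise ConfigError("activity_scale must be non-negative")
        if self.bout_mean_s <= 0 or self.rest_mean_s <= 0:
            raise ConfigError("bout durations must be positive")


#: Default healthy-elderly phenotype: low-amplitude oscillatory episodes
#: during rest (physiological tremor / fidgeting) at a rate comparable to the
#: PD group, so episode *rate* alone does not separate the groups.
HE_PROFILE = SubjectProfile(group="HE", tremor_rate=0.3, tremor_amp_g=0.035)

#: Default PD phenotype: rest-bout oscillation episodes of ~3x higher
#: amplitude (pathological 4-6 Hz rest tremor) plus a modest global movement
#: reduction (bradykinesia).  Between-subject amplitude/rate/activity
#: heterogeneity makes the groups overlap subject-for-subject: classification
#: should be good but far from saturated, as in real wrist-accelerometry
#: cohorts.
PD_PROFILE = SubjectProfile(
    group="PD",
    tremor_rate=0.35,
    tremor_freq_hz=5.0,
    tremor_amp_g=0.10,
    activity_scale=0.9,
)


@dataclass(frozen=True)
class RecordingSession:
    """One subject's tri-axial recording plus metadata.

    ``samples`` is an (N, 3) float32 array of accelerations in g, device axes
    x, y, z; N = round(fs_hz * duration_s).
    """

    subject_id: str
    group: str
    fs_hz: float
    duration_s: float
    samples: np.ndarray
    seed: int

    def truncated(self, duration_s: float) -> "RecordingSession":
        """The first ``duration_s`` seconds of the recording (for day-wise analyses)."""
        n = int(round(self.fs_hz * duration_s))
        if n > self.samples.shape[0]:
            raise ValueError("cannot truncate beyond recorded duration")
        return dataclasses.replace(
            self, duration_s=duration_s, samples=self.samples[:n]
        )


@dataclass(frozen=True)
class Bout:
    """One activity/rest bout: sample interval [start, stop), activity flag,
    and whether a tremor episode was placed in it."""

    start: int
    stop: int
    active: bool
    tremor: bool


@dataclass
class CohortConfig:
    """A two-group cohort design.

    Between-subject heterogeneity: each subject's ``activity_scale`` and
    ``tremor_amp_g`` are multiplied by lognormal factors, the tremor episode
    rate is jittered uniformly within +/- ``subject_rate_jitter`` (clipped to
    [0, 1]), and the tremor frequency is jittered uniformly within
    +/- ``tremor_freq_jitter_hz`` (clipped to the 4-6 Hz band).
    """

    n_he: int = DEFAULT_N_HE
    n_pd: int = DEFAULT_N_PD
    days: int = 7
    day_len_s: float = 1800.0
    fs_hz: float = 32.0
    he_profile: SubjectProfile = HE_PROFILE
    pd_profile: SubjectProfile = PD_PROFILE
    subject_scale_sd: float = 0.3
    subject_amp_sd: float = 0.5
    subject_rate_jitter: float = 0.12
    subject_noise_sd: float = 0.0
    subject_rest_frac_sd: float = 0.0
    tremor_freq_jitter_hz: float = 0.8
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_he < 0 or self.n_pd < 0:
            raise ConfigError("cohort sizes must be non-negative")
        if not 1 <= self.days <= 7:
            raise ConfigError("days must be in 1..7")
        if self.day_len_s <= 0 or self.fs_hz <= 0:
            raise ConfigError("day_len_s and fs_hz must be positive")


def null_cohort_config(**overrides) -> CohortConfig:
    """A zero-effect cohort: the PD group gets the HE phenotype (label only)."""
    cfg = CohortConfig(**overrides)
    cfg.pd_profile = dataclasses.replace(cfg.he_profile, group="PD")
    return cfg


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _gravity_vector(rng: np.random.Generator, tilt_sd_rad: float) -> np.ndarray:
    theta = abs(rng.normal(0.0, tilt_sd_rad))
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return np.array(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )


def _bout_layout(
    rng: np.random.Generator, n_samples: int, fs_hz: float, profile: SubjectProfile
) -> list[Bout]:
    """Alternating active/rest bouts with exponential durations covering the record."""
    p_active = profile.bout_mean_s / (profile.bout_mean_s + profile.rest_mean_s)
    active = bool(rng.random() < p_active)
    bouts: list[Bout] = []
    pos = 0
    while pos < n_samples:
        mean = profile.bout_mean_s if active else profile.rest_mean_s
        dur = max(1, int(round(rng.exponential(mean) * fs_hz)))
        stop = min(pos + dur, n_samples)
        tremor = (not active) and bool(rng.random() < profile.tremor_rate)
        bouts.append(Bout(pos, stop, active, tremor))
        pos = stop
        active = not active
    return bouts


def _movement(
    rng: np.random.Generator,
    bouts: list[Bout],
    n_samples: int,
    fs_hz: float,
    profile: SubjectProfile,
    day_mult: np.ndarray,
    samples_per_day: int,
) -> np.ndarray:
    """Band-limited stochastic movement under a bout envelope.

    Each active bout is one activity type from the subject's personal
    repertoire mixture; types differ in spectral bandwidth and intensity, so
    the subject's long-run descriptor means depend heavily on lifestyle (the
    type mixture), not only on disease parameters.
    """
    n_types = len(ACTIVITY_TYPE_CUTOFF_HZ)
    type_mixture = rng.dirichlet(np.full(n_types, profile.activity_type_alpha))

    envelope = np.full(n_samples, profile.rest_movement_frac)
    bout_type = np.zeros(n_samples, dtype=np.int8)
    for b in bouts:
        if b.active:
            t = int(rng.choice(n_types, p=type_mixture))
            bout_type[b.start : b.stop] = t
            envelope[b.start : b.stop] = ACTIVITY_TYPE_INTENSITY[t] * rng.lognormal(
                0.0, profile.burst_amp_sd
            )
    day_idx = np.minimum(np.arange(n_samples) // samples_per_day, day_mult.size - 1)
    envelope *= day_mult[day_idx]

    white = rng.standard_normal((n_samples, 3))
    movement = np.empty((n_samples, 3))
    for t, cutoff_nominal in enumerate(ACTIVITY_TYPE_CUTOFF_HZ):
        cutoff = min(cutoff_nominal, 0.45 * fs_hz)
        sos = sp_signal.butter(4, cutoff, btype="low", fs=fs_hz, output="sos")
        filtered = sp_signal.sosfilt(sos, white, axis=0)
        # compensate the variance lost to low-pass filtering so burst_sd_g is
        # the approximate in-bout SD of each axis regardless of type
        gain = float(np.sqrt(2.0 * cutoff / fs_hz))
        sel = bout_type == t
        movement[sel] = filtered[sel] / gain
    return movement * (profile.burst_sd_g * profile.activity_scale) * envelope[:, None]


def _tremor(
    rng: np.random.Generator,
    bouts: list[Bout],
    n_samples: int,
    fs_hz: float,
    profile: SubjectProfile,
) -> np.ndarray:
    """Sinusoidal 4-6 Hz oscillation during flagged rest bouts."""
    out = np.zeros((n_samples, 3))
    # phases/directions are drawn even at zero amplitude, so amplitude changes
    # alone do not reshuffle any other draws
    t_all = np.arange(n_samples) / fs_hz
    am_sos = sp_signal.butter(2, min(0.5, 0.4 * fs_hz), btype="low", fs=fs_hz, output="sos")
    for b in bouts:
        if not b.tremor:
            continue
        phase = rng.uniform(0.0, 2.0 * np.pi)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        t = t_all[b.start : b.stop]
        wave = np.sin(2.0 * np.pi * profile.tremor_freq_hz * t + phase)
        # tremor waxes and wanes: slow lognormal amplitude modulation
        slow = sp_signal.sosfilt(am_sos, rng.standard_normal(t.size))
        sd = slow.std()
        env = np.exp(0.6 * slow / sd) if sd > 0 else np.ones_like(slow)
        env /= env.mean()
        out[b.start : b.stop] += (
            profile.tremor_amp_g * (wave * env)[:, None] * direction
        )
    return out


def generate_subject(
    profile: SubjectProfile,
    days: int,
    day_len_s: float,
    fs_hz: float,
    seed: int,
    subject_id: str = "S00",
    return_details: bool = False,
):
    """Synthesize one subject's recording.

    Signal = gravity + bout-structured movement + rest-bout tremor + white
    noise, clipped to the device range.  Deterministic given ``seed``.

    With ``return_details=True`` also returns the bout layout (a list of
    :class:`Bout`), for tests that need to locate rest/tremor intervals.
    """
    if days <= 0 or day_len_s <= 0 or fs_hz <= 0:
        raise ConfigError("days, day_len_s and fs_hz must be positive")
    samples_per_day = int(round(day_len_s * fs_hz))
    n = samples_per_day * days
    duration_s = n / fs_hz

    streams = np.random.SeedSequence(seed).spawn(5)
    orient_rng, layout_rng, move_rng, tremor_rng, noise_rng = (
        np.random.default_rng(s) for s in streams
    )

    g_vec = _gravity_vector(orient_rng, profile.tilt_sd_rad)
    bouts = _bout_layout(layout_rng, n, fs_hz, profile)
    day_mult = np.exp(move_rng.normal(0.0, profile.day_var_sd, size=days))
    movement = _movement(
        move_rng, bouts, n, fs_hz, profile, day_mult, samples_per_day
    )
    tremor = _tremor(tremor_rng, bouts, n, fs_hz, profile)
    noise = (
        noise_rng.standard_normal((n, 3)) * profile.noise_sd_g
        if profile.noise_sd_g > 0
        else 0.0
    )

    samples = GRAVITY_G * g_vec[None, :] + movement + tremor + noise
    np.clip(samples, -DEVICE_RANGE_G, DEVICE_RANGE_G, out=samples)
    session = RecordingSession(
        subject_id=subject_id,
        group=profile.group,
        fs_hz=fs_hz,
        duration_s=duration_s,
        samples=samples.astype(np.float32),
        seed=seed,
    )
    if return_details:
        return session, bouts
    return session


def _subject_seed(master_seed: int, index: int) -> int:
    return int(
        np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31)
    )


def _jitter_profile(
    profile: SubjectProfile, config: CohortConfig, rng: np.random.Generator
) -> SubjectProfile:
    scale = profile.activity_scale * float(
        np.exp(rng.normal(0.0, config.subject_scale_sd))
    )
    amp = profile.tremor_amp_g * float(np.exp(rng.normal(0.0, config.subject_amp_sd)))
    rate = float(
        np.clip(
            profile.tremor_rate
            + rng.uniform(-config.subject_rate_jitter, config.subject_rate_jitter),
            0.0,
            1.0,
        )
    )
    freq = profile.tremor_freq_hz + float(
        rng.uniform(-config.tremor_freq_jitter_hz, config.tremor_freq_jitter_hz)
    )
    freq = float(np.clip(freq, 4.0, 6.0))
    noise = profile.noise_sd_g * float(np.exp(rng.normal(0.0, config.subject_noise_sd)))
    rest_frac = profile.rest_movement_frac * float(
        np.exp(rng.normal(0.0, config.subject_rest_frac_sd))
    )
    return dataclasses.replace(
        profile,
        activity_scale=scale,
        tremor_amp_g=amp,
        tremor_rate=rate,
        tremor_freq_hz=freq,
        noise_sd_g=noise,
        rest_movement_frac=rest_frac,
    )


def generate_cohort(config: CohortConfig) -> list[RecordingSession]:
    """All sessions of a cohort; per-subject seeds derived from the master seed."""
    return list(iter_cohort(config))


def iter_cohort(config: CohortConfig) -> Iterator[RecordingSession]:
    """Sessions generated one at a time (memory-friendly for large cohorts)."""
    plan = [("HE", config.he_profile, i) for i in range(config.n_he)] + [
        ("PD", config.pd_profile, i) for i in range(config.n_pd)
    ]
    for index, (group, base_profile, within) in enumerate(plan):
        jitter_rng = np.random.default_rng(
            np.random.SeedSequence([config.master_seed, index, 1])
        )
        profile = _jitter_profile(base_profile, config, jitter_rng)
        yield generate_subject(
            profile,
            config.days,
            config.day_len_s,
            config.fs_hz,
            seed=_subject_seed(config.master_seed, index),
            subject_id=f"{group}{within:03d}",
        )
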