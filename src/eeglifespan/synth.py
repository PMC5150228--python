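"""Synthetic EEG cohort generation with known age/sex spectral trends.

The generator produces seeded cohorts of 4-channel raw sessions whose
population statistics are known by construction: a 1/f aperiodic
background, a Gaussian alpha bump whose center frequency declines
linearly (optionally quadratically) with age, higher overall power in
females, higher power at temporoparietal than frontal channels, and
occasional high-amplitude artifact bursts with ground-truth bookkeeping.

Two generation paths share the same trend model:

* :func:`render_session` synthesizes raw time series by inverse Fourier
  transform of the target spectrum with uniformly random phases, for
  end-to-end pipeline tests.
* :func:`simulate_user_features` draws user-level spectral features
  (log band powers, alpha peaks) directly from the generative
  coefficients, for large-cohort statistical work where rendering
  hundreds of thousands of seconds of signal would be pointless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .session_io import CHANNELS, RawSession, SubjectProfile, write_session_csv

CENTER_AGE = 42.0
ALPHA_LO, ALPHA_HI = 8.0, 13.0
EPOCH_LEN = 256  # artifact-scoring window, samples

# Reference age-decade composition of a large consumer-EEG cohort
# (counts per decade: male, female), used for the default age/sex mix.
_AGE_DECADES = (
    ((18, 19), 48, 17),
    ((20, 29), 854, 324),
    ((30, 39), 1227, 419),
    ((40, 49), 1059, 359),
    ((50, 59), 708, 344),
    ((60, 69), 400, 166),
    ((70, 79), 77, 20),
    ((80, 88), 6, 1),
)
DEFAULT_P_FEMALE = 1650 / 6029


def default_age_weights(age_range: tuple[int, int] = (18, 88)) -> dict[int, float]:
    """Per-age sampling weights from the reference decade composition.

    Counts in each decade are spread uniformly over the decade's years and
    restricted to ``age_range``.
    """
    lo, hi = age_range
    weights: dict[int, float] = {}
    for (a0, a1), m, f in _AGE_DECADES:
        per_year = (m + f) / (a1 - a0 + 1)
        for age in range(a0, a1 + 1):
            if lo <= age <= hi:
                weights[age] = per_year
    if not weights:
        raise ValueError(f"age_range {age_range} has no overlap with 18-88")
    return weights


@dataclass(frozen=True)
class CohortConfig:
    """Who is in the cohort and how much data each member records."""

    n_users: int = 100
    age_range: tuple[int, int] = (18, 88)
    p_female: float = DEFAULT_P_FEMALE
    age_weights: dict[int, float] | None = None
    sessions_per_user: tuple[int, int] = (1, 3)
    session_duration: float = 60.0  # seconds
    sampling_rate: float = 220.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_users < 0:
            raise ValueError("n_users must be >= 0")
        lo, hi = self.age_range
        if not (18 <= lo <= hi):
            raise ValueError(f"need 18 <= min age <= max age, got {self.age_range}")
        if not (0.0 <= self.p_female <= 1.0):
            raise ValueError("p_female must be a probability")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        s_lo, s_hi = self.sessions_per_user
        if not (1 <= s_lo <= s_hi):
            raise ValueError("sessions_per_user must be an increasing range from >= 1")


# Generative per-band log10-power coefficients on centered age:
# (intercept, age, age^2, sex, age*sex, age^2*sex), sex coded male=0/female=1.
# Defaults describe a temporoparietal reference channel of a lifespan
# consumer cohort; channel gain and noise are applied on top.
DEFAULT_LOGPOWER_COEFFS: dict[str, tuple[float, ...]] = {
    "delta": (0.74835, -0.00418, 0.00014, 0.00111, 0.00013, -0.00000),
    "theta": (0.31149, -0.00262, 0.00009, -0.00430, 0.00087, 0.00010),
    "alpha": (0.47046, 0.00024, -0.00002, -0.00498, 0.00052, 0.00013),
    "beta": (0.28957, 0.00216, 0.00000, 0.08575, 0.00011, 0.00007),
}

# Fraction of users with a detectable alpha peak, per channel: clearly
# higher at temporoparietal than frontal sites.
DEFAULT_PEAK_DETECT_PROB: dict[str, float] = {
    "TP9": 5374 / 6029,
    "TP10": 5379 / 6029,
    "AF7": 3085 / 6029,
    "AF8": 2806 / 6029,
}


@dataclass(frozen=True)
class SpectralTrendModel:
    """Generative spectral model: 1/f background + age-trending alpha bump.

    The target one-sided spectrum of a subject of age ``a`` (years) and
    sex ``s`` at channel ``c`` is

        S(f) = gain_c * 10^(s * sex_power_offset)
               * [ scale / f^beta  +  plateau(f)
                   + A * exp(-(f - mu(a))^2 / (2 w^2)) ]

    with alpha center mu(a) = intercept + slope*(a-42) + quad*(a-42)^2,
    constrained to lie inside the 8-13 Hz alpha band for every age in the
    cohort range.
    """

    background_scale: float = 24.0  # µV²/Hz at 1 Hz
    background_exponent: float = 1.0
    band_plateaus: dict[str, float] = field(default_factory=dict)  # added µV² per bin
    alpha_center_intercept: float = 9.54145  # Hz at age 42
    alpha_center_slope: float = -0.01891  # Hz / year
    alpha_center_quad: float = 0.0  # Hz / year²
    alpha_bump_height: float = 18.0  # µV²/Hz
    alpha_bump_width: float = 1.2  # Hz (Gaussian sigma)
    logpower_coeffs: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_LOGPOWER_COEFFS)
    )
    sex_power_offset: float = 0.05  # log10 units, added for females
    channel_gains: dict[str, float] = field(
        default_factory=lambda: {"TP9": 1.0, "AF7": 0.45, "AF8": 0.45, "TP10": 1.05}
    )
    # feature-level simulator noise (within-age variability)
    alpha_peak_noise_sd: float = 0.9  # Hz
    logpower_noise_sd: float = 0.35  # log10 units
    peak_detect_prob: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PEAK_DETECT_PROB)
    )

    def __post_init__(self) -> None:
        if self.alpha_bump_width <= 0:
            raise ValueError("alpha_bump_width must be positive")
        for name, val in (
            ("background_scale", self.background_scale),
            ("alpha_bump_height", self.alpha_bump_height),
        ):
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.band_plateaus.values()):
            raise ValueError("band plateaus must be >= 0")
        if any(g < 0 for g in self.channel_gains.values()):
            raise ValueError("channel gains must be >= 0")

    def alpha_center(self, age: float) -> float:
        """Alpha bump center frequency (Hz) for a subject of this age."""
        a = age - CENTER_AGE
        return (
            self.alpha_center_intercept
            + self.alpha_center_slope * a
            + self.alpha_center_quad * a * a
        )

    def validate_age_range(self, age_range: tuple[int, int]) -> None:
        ages = np.arange(age_range[0], age_range[1] + 1)
        centers = np.array([self.alpha_center(a) for a in ages])
        if centers.min() < ALPHA_LO or centers.max() > ALPHA_HI:
            bad = int(ages[np.argmax((centers < ALPHA_LO) | (centers > ALPHA_HI))])
            raise ValueError(
                f"alpha center {self.alpha_center(bad):.3f} Hz at age {bad} leaves "
                f"the {ALPHA_LO:g}-{ALPHA_HI:g} Hz band"
            )

    def logpower_predictor(self, band: str, age: float, sex: int) -> float:
        """Generative linear predictor of log10 band power (reference channel)."""
        b = self.logpower_coeffs[band]
        a = age - CENTER_AGE
        return b[0] + b[1] * a + b[2] * a * a + sex * (b[3] + b[4] * a + b[5] * a * a)


@dataclass(frozen=True)
class ArtifactModel:
    """Bernoulli per-epoch high-amplitude burst injection."""

    epoch_rate: float = 0.05  # probability a 256-sample window carries a burst
    burst_amplitude: float = 150.0  # µV
    burst_shape: str = "sinusoid"  # step | spike | sinusoid

    def __post_init__(self) -> None:
        if not (0.0 <= self.epoch_rate <= 1.0):
            raise ValueError("epoch_rate must be a probability")
        if self.burst_amplitude < 0:
            raise ValueError("burst_amplitude must be >= 0")
        if self.burst_shape not in ("step", "spike", "sinusoid"):
            raise ValueError(f"unknown burst_shape {self.burst_shape!r}")


def sample_cohort(config: CohortConfig) -> list[SubjectProfile]:
    """Draw a cohort of subject profiles.

    Ages follow ``config.age_weights`` (default: the reference decade
    composition), sexes are i.i.d. Bernoulli(p_female), mains frequency is
    a fair 50/60 split, and per-user session counts are uniform over
    ``sessions_per_user``. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    weights = config.age_weights or default_age_weights(config.age_range)
    ages_pool = np.array(sorted(weights), dtype=int)
    lo, hi = config.age_range
    if ages_pool.min() < lo or ages_pool.max() > hi:
        raise ValueError("age_weights contain ages outside age_range")
    p = np.array([weights[a] for a in ages_pool], dtype=float)
    if (p < 0).any() or p.sum() <= 0:
        raise ValueError("age_weights must be non-negative and sum > 0")
    p = p / p.sum()

    profiles = []
    width = max(4, len(str(max(config.n_users, 1))))
    for i in range(config.n_users):
        age = int(rng.choice(ages_pool, p=p))
        sex = int(rng.random() < config.p_female)
        line_freq = int(rng.choice((50, 60)))
        s_lo, s_hi = config.sessions_per_user
        n_sessions = int(rng.integers(s_lo, s_hi + 1))
        profiles.append(
            SubjectProfile(
                user_id=f"u{i:0{width}d}",
                age=age,
                sex=sex,
                line_freq=line_freq,
                n_sessions=n_sessions,
            )
        )
    return profiles


def target_psd_function(profile: SubjectProfile, trend: SpectralTrendModel, channel: str):
    """Continuous target spectrum S(f) in µV² per 1-Hz bin, as a callable."""
    if channel not in CHANNELS:
        raise ValueError(f"channel must be one of {CHANNELS}, got {channel!r}")
    center = trend.alpha_center(profile.age)
    if not (ALPHA_LO <= center <= ALPHA_HI):
        raise ValueError(
            f"alpha center {center:.3f} Hz for age {profile.age} is outside "
            f"{ALPHA_LO:g}-{ALPHA_HI:g} Hz"
        )
    gain = trend.channel_gains.get(channel, 1.0) * 10.0 ** (
        profile.sex * trend.sex_power_offset
    )
    from .spectral import BANDS  # local import to avoid a cycle at import time

    def psd(f: np.ndarray) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        out = np.zeros_like(f)
        pos = f >= 1.0
        if trend.background_scale > 0:
            out[pos] = trend.background_scale / f[pos] ** trend.background_exponent
        for band, plateau in trend.band_plateaus.items():
            lo, hi = BANDS[band]
            out[(f >= lo) & (f <= hi)] += plateau
        if trend.alpha_bump_height > 0:
            out += trend.alpha_bump_height * np.exp(
                -0.5 * ((f - center) / trend.alpha_bump_width) ** 2
            )
        return gain * out

    return psd


def target_psd(
    profile: SubjectProfile,
    trend: SpectralTrendModel,
    channel: str,
    freqs: np.ndarray | None = None,
) -> np.ndarray:
    """Target spectrum evaluated on the integer 0..110 Hz grid (µV²/bin)."""
    if freqs is None:
        freqs = np.arange(111, dtype=float)
    return target_psd_function(profile, trend, channel)(np.asarray(freqs, dtype=float))


def render_session(
    profile: SubjectProfile,
    trend: SpectralTrendModel,
    artifact_model: ArtifactModel | None,
    duration: float,
    seed: int,
    fs: float = 220.0,
    task: str = "NFB",
    order: int = 1,
) -> RawSession:
    """Synthesize one raw session from the target spectrum.

    Each channel is an independent phase-randomized realization: the
    amplitude at discrete frequency f_k is sqrt(2 S(f_k) df) with uniform
    random phase, so the expected periodogram matches the target spectrum
    and the time-domain mean square equals its integral (Parseval).
    Artifact bursts are added to a Bernoulli subset of 256-sample windows
    on all four channels; contaminated window indices are recorded on the
    returned session as ground truth.
    """
    if duration < 10:
        raise ValueError("duration must be >= 10 s")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    df = fs / n

    samples = np.zeros((len(CHANNELS), n))
    for i, ch in enumerate(CHANNELS):
        s = target_psd_function(profile, trend, ch)(freqs)
        amp = np.sqrt(2.0 * s * df)
        amp[0] = 0.0
        if n % 2 == 0:
            amp[-1] = 0.0
        phases = rng.uniform(0.0, 2.0 * np.pi, size=amp.size)
        spectrum = (n / 2.0) * amp * np.exp(1j * phases)
        samples[i] = np.fft.irfft(spectrum, n=n)

    truth = np.empty(0, dtype=int)
    if artifact_model is not None and artifact_model.epoch_rate > 0:
        n_win = n // EPOCH_LEN
        contaminated = rng.random(n_win) < artifact_model.epoch_rate
        truth = np.flatnonzero(contaminated)
        a = artifact_model.burst_amplitude
        t = np.arange(EPOCH_LEN) / fs
        for w in truth:
            sl = slice(w * EPOCH_LEN, (w + 1) * EPOCH_LEN)
            if artifact_model.burst_shape == "step":
                burst = np.full(EPOCH_LEN, a)
            elif artifact_model.burst_shape == "spike":
                burst = np.zeros(EPOCH_LEN)
                burst[EPOCH_LEN // 2] = a
            else:  # sinusoid inside the passband, so it survives filtering
                burst = a * np.sin(2.0 * np.pi * 10.0 * t)
            samples[:, sl] += burst

    return RawSession(
        samples=samples,
        fs=fs,
        task=task,
        order=order,
        line_freq=profile.line_freq,
        user=profile,
        artifact_truth=truth,
    )


def generate_cohort(
    config: CohortConfig,
    trend: SpectralTrendModel | None = None,
    artifact_model: ArtifactModel | None = None,
    tasks: tuple[str, ...] = ("CAL", "NFB"),
) -> list[RawSession]:
    """Sample profiles and render every (user, order, task) recording."""
    trend = trend or SpectralTrendModel()
    trend.validate_age_range(config.age_range)
    profiles = sample_cohort(config)
    rng = np.random.default_rng(config.seed)
    sessions = []
    for profile in profiles:
        for order in range(1, profile.n_sessions + 1):
            for task in tasks:
                seed = int(rng.integers(0, 2**31 - 1))
                sessions.append(
                    render_session(
                        profile,
                        trend,
                        artifact_model,
                        duration=config.session_duration,
                        seed=seed,
                        fs=config.sampling_rate,
                        task=task,
                        order=order,
                    )
                )
    return sessions


def write_cohort(
    sessions: list[RawSession],
    manifest_path: str | Path,
    data_dir: str | Path,
    decimals: int = 4,
) -> pd.DataFrame:
    """Write session CSVs plus a manifest; returns the manifest frame.

    Paths in the manifest are relative to the manifest's directory, so a
    cohort directory is relocatable as a unit.
    """
    manifest_path = Path(manifest_path)
    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in sessions:
        rel = Path(data_dir.name) / f"{s.session_id}.csv"
        write_session_csv(s, manifest_path.parent / rel, decimals=decimals)
        rows.append(
            {
                "user_id": s.user.user_id,
                "session_id": s.session_id,
                "order": s.order,
                "task": s.task,
                "age": s.user.age,
                "sex": s.user.sex,
                "line_freq": s.line_freq,
                "path": str(rel),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest_path.parent.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(manifest_path, index=False)
    return manifest


def simulate_user_features(
    profiles: list[SubjectProfile],
    trend: SpectralTrendModel | None = None,
    seed: int = 0,
    tasks: tuple[str, ...] = ("NFB",),
    quantize: bool = False,
) -> pd.DataFrame:
    """Draw user-level spectral features directly from the trend model.

    Returns one row per user x task with the same column schema the
    measurement pipeline produces: ``log_<band>_<channel>`` log10 band
    powers, ``alpha_peak_<channel>`` (NaN where no peak was detectable),
    and frontal/temporoparietal alpha asymmetries.

    Log band powers are the generative linear predictor plus a channel
    gain offset and i.i.d. Gaussian noise. Alpha peaks are the trend
    center plus Gaussian within-age scatter; whether a channel yields a
    peak at all is an independent Bernoulli draw with the configured
    per-channel detection probability, so the observed peaks are an
    unbiased sample of the population trend. With ``quantize=True`` the
    peaks are additionally rounded to the 1-Hz analysis grid and
    censored to the 8-13 Hz band, mimicking the measurement chain (this
    censoring biases edge-adjacent ages upward, exactly as it would in
    measured data).
    """
    trend = trend or SpectralTrendModel()
    rng = np.random.default_rng(seed)
    bands = list(trend.logpower_coeffs)
    rows = []
    for profile in profiles:
        for task in tasks:
            row: dict[str, object] = {
                "user_id": profile.user_id,
                "task": task,
                "age": profile.age,
                "sex": profile.sex,
            }
            for ch in CHANNELS:
                gain_offset = np.log10(trend.channel_gains.get(ch, 1.0))
                for band in bands:
                    # sex_power_offset scales whole spectra in the renderer;
                    # applied here too so both generation paths agree
                    mu = (
                        trend.logpower_predictor(band, profile.age, profile.sex)
                        + profile.sex * trend.sex_power_offset
                    )
                    row[f"log_{band}_{ch}"] = (
                        mu + gain_offset + rng.normal(0.0, trend.logpower_noise_sd)
                    )
                peak = trend.alpha_center(profile.age) + rng.normal(
                    0.0, trend.alpha_peak_noise_sd
                )
                detected = rng.random() < trend.peak_detect_prob.get(ch, 1.0)
                if quantize:
                    peak = float(np.rint(peak))
                    detected = detected and ALPHA_LO <= peak <= ALPHA_HI
                row[f"alpha_peak_{ch}"] = peak if detected else np.nan
            for ch in CHANNELS:
                # delta/theta/alpha/beta partition 0-30 Hz, so total power
                # is the sum of the component band powers
                row[f"log_total_{ch}"] = float(
                    np.log10(sum(10.0 ** row[f"log_{b}_{ch}"] for b in bands))
                )
            row["alpha_asym_frontal"] = row["log_alpha_AF8"] - row["log_alpha_AF7"]
            row["alpha_asym_temporoparietal"] = (
                row["log_alpha_TP10"] - row["log_alpha_TP9"]
            )
            rows.append(row)
    return pd.DataFrame(rows)


def null_interaction_trend(**overrides) -> SpectralTrendModel:
    """Trend model whose sex-by-age interaction coefficients are all zero.

    Convenience for calibration studies of the conditional by-sex refit.
    """
    coeffs = {
        band: (b[0], b[1], b[2], b[3], 0.0, 0.0)
        for band, b in DEFAULT_LOGPOWER_COEFFS.items()
    }
    return replace(SpectralTrendModel(logpower_coeffs=coeffs), **overrides)
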