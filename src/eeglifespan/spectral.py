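"""Power spectra and derived per-user features.

Spectra are plain averaged periodograms over rectangular, non-overlapping
220-sample windows tiled across the concatenated clean samples. At a
220 Hz sampling rate this puts the discrete Fourier bins exactly on the
integer 0..110 Hz grid, giving the 1-Hz resolution the band definitions
assume without any interpolation. The spectrum is scaled so that the sum
over all bins equals the mean squared amplitude of the analyzed samples
(Parseval), i.e. each bin holds the signal power (µV²) it carries.

Derived measures per channel: summed band power for the canonical bands,
its log10, the alpha peak frequency (argmax over 8-13 Hz, reported only
when it is a strict local maximum against its 1-Hz neighbors on the full
grid; absent otherwise), and right-minus-left log10 alpha asymmetry for
the frontal (AF8-AF7) and temporoparietal (TP10-TP9) pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import VERDICT_CLEAN, CleanSession
from .session_io import CHANNELS

logger = logging.getLogger(__name__)

#: Canonical frequency bands, Hz, inclusive integer bins.
BANDS: dict[str, tuple[int, int]] = {
    "delta": (0, 2),
    "theta": (3, 7),
    "alpha": (8, 13),
    "beta": (14, 30),
    "lower_alpha": (8, 10),
    "upper_alpha": (11, 13),
    "total": (0, 30),
}

ALPHA_RANGE = (8, 13)
WINDOW_LEN = 220  # samples: exact 1-Hz bins at fs = 220
MAX_FREQ = 110


class FeatureAbsent(ValueError):
    """A feature could not be computed; the message says why."""


@dataclass
class PowerSpectrum:
    """Per-channel power at integer frequencies 0..110 Hz (µV² per bin)."""

    power: np.ndarray  # (4, 111)
    n_windows: int
    freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.freqs is None:
            self.freqs = np.arange(self.power.shape[-1], dtype=float)

    def channel(self, name: str) -> np.ndarray:
        return self.power[CHANNELS.index(name)]


def periodogram_1hz(window: np.ndarray) -> np.ndarray:
    """Power per 1-Hz bin of one 220-sample window (rectangular taper).

    Scaled so that ``sum(bins) == mean(window**2)`` exactly.
    """
    window = np.asarray(window, dtype=float)
    n = window.shape[-1]
    spec = np.fft.rfft(window, axis=-1)
    p = np.abs(spec) ** 2 / n**2
    p[..., 1:-1] *= 2.0  # one-sided: double everything but DC and Nyquist
    if n % 2 == 1:
        p[..., -1] *= 2.0
    return p


def compute_psd(
    clean: CleanSession, window_len: int = WINDOW_LEN, min_epochs: int = 10
) -> PowerSpectrum:
    """Averaged periodogram of a clean session on the 1-Hz grid.

    Windows are tiled over the concatenation of the kept epochs; the
    trailing remainder shorter than one window is discarded.
    """
    if clean.verdict != VERDICT_CLEAN:
        raise FeatureAbsent(
            f"session {clean.session.session_id}: verdict {clean.verdict}"
        )
    if clean.n_kept < min_epochs:
        raise FeatureAbsent(
            f"session {clean.session.session_id}: only {clean.n_kept} clean epochs "
            f"(need {min_epochs})"
        )
    x = clean.clean_samples()
    n_win = x.shape[-1] // window_len
    if n_win == 0:
        raise FeatureAbsent(
            f"session {clean.session.session_id}: fewer than {window_len} clean samples"
        )
    x = x[:, : n_win * window_len].reshape(len(CHANNELS), n_win, window_len)
    power = periodogram_1hz(x).mean(axis=1)
    return PowerSpectrum(power=power, n_windows=n_win)


def band_power(psd: np.ndarray, band: str | tuple[int, int]) -> float:
    """Summed power over the band's inclusive integer bins (µV²)."""
    lo, hi = BANDS[band] if isinstance(band, str) else band
    if not (0 <= lo <= hi <= MAX_FREQ):
        raise ValueError(f"band ({lo}, {hi}) outside 0..{MAX_FREQ} Hz")
    psd = np.asarray(psd, dtype=float)
    return float(psd[lo : hi + 1].sum())


def log_band_power(psd: np.ndarray, band: str | tuple[int, int]) -> float:
    """log10 of summed band power; NaN (feature absent) for zero power."""
    p = band_power(psd, band)
    if p <= 0:
        logger.info("zero power in band %s: log band power absent", band)
        return float("nan")
    return float(np.log10(p))


def alpha_peak(psd: np.ndarray) -> float | None:
    """Peak alpha frequency, or None when no clear peak exists.

    The candidate is the (lowest, on ties) argmax over the 8-13 Hz bins;
    it is reported only if it strictly exceeds both 1-Hz neighbors on the
    full grid, so a monotonically decreasing background yields no peak.
    """
    psd = np.asarray(psd, dtype=float)
    lo, hi = ALPHA_RANGE
    band = psd[lo : hi + 1]
    m = lo + int(np.argmax(band))  # np.argmax takes the first (lowest) maximum
    if psd[m] > psd[m - 1] and psd[m] > psd[m + 1]:
        return float(m)
    return None


def alpha_asymmetry(log_alpha_right: float, log_alpha_left: float) -> float:
    """Right-minus-left difference of log10 alpha power."""
    return float(log_alpha_right) - float(log_alpha_left)


def session_features(clean: CleanSession, psd: PowerSpectrum | None = None) -> dict:
    """All derived measures for one clean session, as a flat mapping."""
    psd = psd or compute_psd(clean)
    feats: dict[str, float] = {}
    for i, ch in enumerate(CHANNELS):
        spec = psd.power[i]
        for band in BANDS:
            feats[f"log_{band}_{ch}"] = log_band_power(spec, band)
        pk = alpha_peak(spec)
        feats[f"alpha_peak_{ch}"] = float("nan") if pk is None else pk
    feats["alpha_asym_frontal"] = alpha_asymmetry(
        feats["log_alpha_AF8"], feats["log_alpha_AF7"]
    )
    feats["alpha_asym_temporoparietal"] = alpha_asymmetry(
        feats["log_alpha_TP10"], feats["log_alpha_TP9"]
    )
    return feats


def average_user_features(session_feats: list[dict]) -> dict:
    """Average per-session features into one user x task record.

    Log band powers and asymmetries are averaged arithmetically (i.e. on
    the log scale). Alpha peaks are averaged over the sessions in which a
    peak was present; ``n_peak_<channel>`` records how many that was.
    """
    if not session_feats:
        raise FeatureAbsent("no clean sessions to average")
    out: dict[str, float] = {"n_sessions": float(len(session_feats))}
    keys = session_feats[0].keys()
    for key in keys:
        vals = np.array([f[key] for f in session_feats], dtype=float)
        present = ~np.isnan(vals)
        if key.startswith("alpha_peak_"):
            ch = key.removeprefix("alpha_peak_")
            out[f"n_peak_{ch}"] = float(present.sum())
            out[key] = float(vals[present].mean()) if present.any() else float("nan")
        else:
            out[key] = float(vals[present].mean()) if present.any() else float("nan")
    return out


def compute_user_features(clean_sessions: list[CleanSession]) -> pd.DataFrame:
    """One row per user x task, averaged over that user's clean sessions.

    Sessions that fail the spectral preconditions are skipped with a log
    message; users with no usable session for a task are absent from that
    task's rows.
    """
    groups: dict[tuple[str, str], list[CleanSession]] = {}
    meta: dict[str, tuple[int, int]] = {}
    for c in clean_sessions:
        key = (c.session.user.user_id, c.session.task)
        groups.setdefault(key, []).append(c)
        meta[c.session.user.user_id] = (c.session.user.age, c.session.user.sex)
    rows = []
    for (user_id, task), sessions in sorted(groups.items()):
        feats = []
        for c in sorted(sessions, key=lambda c: c.session.order):
            try:
                feats.append(session_features(c))
            except FeatureAbsent as exc:
                logger.info("skipping session: %s", exc)
        if not feats:
            logger.info("user %s has no usable %s sessions", user_id, task)
            continue
        age, sex = meta[user_id]
        rows.append(
            {"user_id": user_id, "task": task, "age": age, "sex": sex}
            | average_user_features(feats)
        )
    return pd.DataFrame(rows)
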