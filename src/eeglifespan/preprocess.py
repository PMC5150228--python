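"""Artifact-gated cleaning of raw sessions.

The chain: mains notch (50/60 Hz by region), 2-36 Hz bandpass, division
into consecutive 256-sample epochs, rejection of any epoch whose mean
squared amplitude strictly exceeds 275 µV² on any channel, exclusion of
sessions with a rejection fraction strictly above 10% on any channel
(exclusion applies to the whole CAL/NFB pair of the same recording
order), and a cap of the first five clean sessions per user per task.

Epoch "overall power" is the mean of squared samples (µV²), which is
duration-invariant. An epoch rejected on any one channel is dropped from
all channels so that the retained data stay time-aligned across
channels; the per-channel rejection fractions are nonetheless tracked
separately because the session verdict is per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .session_io import CHANNELS, RawSession

VERDICT_CLEAN = "clean"
VERDICT_REJECTED = "rejected_artifacts"
VERDICT_TOO_SHORT = "too_short"


@dataclass(frozen=True)
class PreprocessConfig:
    bandpass: tuple[float, float] = (2.0, 36.0)  # Hz
    epoch_len: int = 256  # samples
    power_threshold: float = 275.0  # µV², strict >
    max_reject_frac: float = 0.10  # per channel, strict >
    max_sessions_per_user: int = 5
    filter_order: int = 5  # Butterworth, applied zero-phase
    notch_q: float = 30.0
    min_clean_epochs: int = 10  # fewer kept epochs -> too_short

    def __post_init__(self) -> None:
        lo, hi = self.bandpass
        if not (0 < lo < hi):
            raise ValueError(f"need 0 < low < high bandpass edges, got {self.bandpass}")
        if self.epoch_len <= 0:
            raise ValueError("epoch_len must be positive")
        if self.power_threshold <= 0:
            raise ValueError("power_threshold must be positive")
        if not (0.0 <= self.max_reject_frac <= 1.0):
            raise ValueError("max_reject_frac must be in [0, 1]")


@dataclass
class CleanSession:
    """Filtered session plus epoch bookkeeping and the QC verdict."""

    session: RawSession
    filtered: np.ndarray  # (4, n)
    epoch_len: int
    epoch_powers: np.ndarray  # (n_epochs, 4) µV²
    keep_mask: np.ndarray  # (n_epochs,) bool, joint across channels
    reject_frac: np.ndarray  # (4,) per-channel rejection fraction
    verdict: str

    @property
    def n_epochs(self) -> int:
        return self.keep_mask.size

    @property
    def n_kept(self) -> int:
        return int(self.keep_mask.sum())

    def clean_samples(self) -> np.ndarray:
        """Concatenated kept-epoch samples, shape (4, n_kept * epoch_len)."""
        n_ep = self.n_epochs
        x = self.filtered[:, : n_ep * self.epoch_len]
        x = x.reshape(len(CHANNELS), n_ep, self.epoch_len)
        return x[:, self.keep_mask, :].reshape(len(CHANNELS), -1)


def notch(samples: np.ndarray, fs: float, line_freq: int | None, q: float = 30.0) -> np.ndarray:
    """Zero-phase mains notch. A missing line frequency is an error."""
    if line_freq is None:
        raise ValueError("line_freq is required for the mains notch (50 or 60 Hz)")
    if line_freq not in (50, 60):
        raise ValueError(f"line_freq must be 50 or 60, got {line_freq}")
    b, a = signal.iirnotch(line_freq, Q=q, fs=fs)
    return signal.filtfilt(b, a, np.asarray(samples, dtype=float), axis=-1)


def bandpass(
    samples: np.ndarray,
    fs: float,
    band: tuple[float, float] = (2.0, 36.0),
    order: int = 5,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass (default 2-36 Hz)."""
    if fs <= 2 * band[1]:
        raise ValueError(f"sampling rate {fs} Hz too low for bandpass {band}")
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(samples, dtype=float), axis=-1)


def n_epochs(n_samples: int, epoch_len: int = 256) -> int:
    """Consecutive non-overlapping epochs; trailing remainder discarded."""
    return n_samples // epoch_len


def epoch_power(samples: np.ndarray, epoch_len: int = 256) -> np.ndarray:
    """Mean squared amplitude per epoch per channel, shape (n_epochs, 4)."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    n_ep = n_epochs(samples.shape[-1], epoch_len)
    x = samples[:, : n_ep * epoch_len].reshape(samples.shape[0], n_ep, epoch_len)
    return np.mean(x * x, axis=-1).T


def reject_epochs(powers: np.ndarray, threshold: float = 275.0):
    """Apply the strict power threshold.

    Returns ``(keep_mask, reject_frac)``: the joint keep mask (an epoch
    exceeding the threshold on any channel is dropped everywhere) and the
    per-channel rejection fractions used by the session verdict.
    """
    powers = np.atleast_2d(np.asarray(powers, dtype=float))
    exceed = powers > threshold  # strict: power exactly at threshold is kept
    keep = ~exceed.any(axis=1)
    frac = exceed.mean(axis=0) if powers.shape[0] else np.zeros(powers.shape[1])
    return keep, frac


def session_verdict(reject_frac: np.ndarray, max_reject_frac: float = 0.10) -> str:
    """Clean unless any channel's rejection fraction strictly exceeds the cap."""
    return VERDICT_REJECTED if np.any(np.asarray(reject_frac) > max_reject_frac) else VERDICT_CLEAN


def preprocess_session(raw: RawSession, config: PreprocessConfig | None = None) -> CleanSession:
    """Run the full cleaning chain on one raw session."""
    config = config or PreprocessConfig()
    filtered = notch(raw.samples, raw.fs, raw.line_freq, q=config.notch_q)
    filtered = bandpass(filtered, raw.fs, config.bandpass, order=config.filter_order)
    n_ep = n_epochs(filtered.shape[-1], config.epoch_len)
    if n_ep == 0:
        return CleanSession(
            session=raw,
            filtered=filtered,
            epoch_len=config.epoch_len,
            epoch_powers=np.empty((0, len(CHANNELS))),
            keep_mask=np.empty(0, dtype=bool),
            reject_frac=np.zeros(len(CHANNELS)),
            verdict=VERDICT_TOO_SHORT,
        )
    powers = epoch_power(filtered, config.epoch_len)
    keep, frac = reject_epochs(powers, config.power_threshold)
    verdict = session_verdict(frac, config.max_reject_frac)
    if verdict == VERDICT_CLEAN and keep.sum() < config.min_clean_epochs:
        verdict = VERDICT_TOO_SHORT
    return CleanSession(
        session=raw,
        filtered=filtered,
        epoch_len=config.epoch_len,
        epoch_powers=powers,
        keep_mask=keep,
        reject_frac=frac,
        verdict=verdict,
    )


def apply_pair_exclusion(cleaned: list[CleanSession]) -> list[CleanSession]:
    """Propagate rejection across CAL/NFB pairs of the same recording order.

    If either member of a (user_id, order) pair is not clean, both are
    excluded, mirroring whole-session exclusion of paired recordings.
    """
    bad_pairs = {
        (c.session.user.user_id, c.session.order)
        for c in cleaned
        if c.verdict != VERDICT_CLEAN
    }
    for c in cleaned:
        key = (c.session.user.user_id, c.session.order)
        if c.verdict == VERDICT_CLEAN and key in bad_pairs:
            c.verdict = VERDICT_REJECTED
    return cleaned


def cap_sessions(
    cleaned: list[CleanSession], max_sessions: int = 5
) -> list[CleanSession]:
    """Keep the first ``max_sessions`` clean sessions per user per task.

    The cap counts clean sessions in recording order: a user whose clean
    sessions are the 2nd, 5th and 7th recordings keeps all three.
    """
    kept: list[CleanSession] = []
    counts: dict[tuple[str, str], int] = {}
    for c in sorted(cleaned, key=lambda c: (c.session.user.user_id, c.session.order)):
        if c.verdict != VERDICT_CLEAN:
            continue
        key = (c.session.user.user_id, c.session.task)
        if counts.get(key, 0) < max_sessions:
            counts[key] = counts.get(key, 0) + 1
            kept.append(c)
    return kept


@dataclass
class PreprocessReport:
    """Session accounting for one preprocessing run."""

    qc: pd.DataFrame  # one row per session: verdict, rejection fractions
    n_sessions_in: int = 0
    n_clean: int = 0
    n_retained: int = 0  # after the per-user cap
    n_users_in: int = 0
    n_users_retained: int = 0

    @property
    def rejection_pct(self) -> float:
        """Percent of input sessions excluded by the artifact gate."""
        if self.n_sessions_in == 0:
            return 0.0
        return 100.0 * (1.0 - self.n_clean / self.n_sessions_in)

    @property
    def mean_retained_per_user(self) -> float:
        if self.n_users_retained == 0:
            return 0.0
        return self.n_retained / self.n_users_retained


def preprocess_cohort(
    raw_sessions: list[RawSession], config: PreprocessConfig | None = None
) -> tuple[list[CleanSession], PreprocessReport]:
    """Clean every session, apply pair exclusion and the per-user cap."""
    config = config or PreprocessConfig()
    cleaned = [preprocess_session(r, config) for r in raw_sessions]
    cleaned = apply_pair_exclusion(cleaned)
    retained = cap_sessions(cleaned, config.max_sessions_per_user)
    retained_ids = {c.session.session_id for c in retained}
    qc = pd.DataFrame(
        {
            "user_id": [c.session.user.user_id for c in cleaned],
            "session_id": [c.session.session_id for c in cleaned],
            "order": [c.session.order for c in cleaned],
            "task": [c.session.task for c in cleaned],
            "verdict": [c.verdict for c in cleaned],
            "retained": [c.session.session_id in retained_ids for c in cleaned],
            "n_epochs": [c.n_epochs for c in cleaned],
            "n_kept": [c.n_kept for c in cleaned],
        }
        | {
            f"reject_frac_{ch}": [float(c.reject_frac[i]) for c in cleaned]
            for i, ch in enumerate(CHANNELS)
        }
    )
    report = PreprocessReport(
        qc=qc,
        n_sessions_in=len(cleaned),
        n_clean=sum(c.verdict == VERDICT_CLEAN for c in cleaned),
        n_retained=len(retained),
        n_users_in=len({c.session.user.user_id for c in cleaned}),
        n_users_retained=len({c.session.user.user_id for c in retained}),
    )
    return retained, report
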