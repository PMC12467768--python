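"""Epoch container and the preprocessing / trial-exclusion contracts.

Epochs are stimulus-locked multichannel voltage segments (default −0.5 to
1.0 s at 500 Hz).  Preprocessing applies, in order: average reference,
zero-phase band-pass (0.1–40 Hz), baseline subtraction (mean over −400 to
−100 ms), and rejection of epochs whose amplitude exceeds ±80 units on any
retained channel.  Behavioral exclusions drop trials with responses faster
than 0.2 s or slower than 5 s, multiple key presses, or premature responses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from mne.filter import filter_data

__all__ = ["EpochSet", "PreprocessConfig", "preprocess", "exclude_trials"]


@dataclass
class EpochSet:
    """Trials x channels x time voltage array with per-trial metadata."""

    data: np.ndarray  # (n_trials, n_channels, n_times)
    times: np.ndarray  # seconds relative to stimulus onset, strictly increasing
    ch_names: list[str]
    metadata: pd.DataFrame  # one row per trial

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, times)")
        n, c, t = self.data.shape
        if len(self.times) != t:
            raise ValueError("times length must match data")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.ch_names) != c:
            raise ValueError("ch_names length must match data")
        if len(self.metadata) != n:
            raise ValueError("metadata rows must match trials")
        self.metadata = self.metadata.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def sfreq(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))

    def select(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = mask
        else:
            idx = np.flatnonzero(mask)
        return EpochSet(
            data=self.data[idx],
            times=self.times,
            ch_names=list(self.ch_names),
            metadata=self.metadata.iloc[idx],
        )

    def crop(self, tmin: float, tmax: float) -> "EpochSet":
        keep = (self.times >= tmin) & (self.times <= tmax)
        return EpochSet(
            data=self.data[:, :, keep],
            times=self.times[keep],
            ch_names=list(self.ch_names),
            metadata=self.metadata,
        )

    def decimate(self, factor: int) -> "EpochSet":
        """Keep every ``factor``-th sample (apply after low-pass filtering)."""
        return EpochSet(
            data=self.data[:, :, ::factor],
            times=self.times[::factor],
            ch_names=list(self.ch_names),
            metadata=self.metadata,
        )

    def save(self, directory: str | Path, stem: str = "epochs") -> None:
        """Array file + JSON sidecar (channels, times, trial metadata)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.save(directory / f"{stem}_data.npy", self.data)
        sidecar = {
            "times": self.times.tolist(),
            "ch_names": self.ch_names,
            "metadata": self.metadata.to_dict(orient="list"),
        }
        with open(directory / f"{stem}.json", "w") as fh:
            json.dump(sidecar, fh)

    @classmethod
    def load(cls, directory: str | Path, stem: str = "epochs") -> "EpochSet":
        directory = Path(directory)
        data = np.load(directory / f"{stem}_data.npy")
        with open(directory / f"{stem}.json") as fh:
            sidecar = json.load(fh)
        return cls(
            data=data,
            times=np.asarray(sidecar["times"]),
            ch_names=sidecar["ch_names"],
            metadata=pd.DataFrame(sidecar["metadata"]),
        )

    def to_mne(self):
        """Export to an :class:`mne.EpochsArray` (EEG channel types)."""
        import mne

        info = mne.create_info(self.ch_names, sfreq=self.sfreq, ch_types="eeg")
        return mne.EpochsArray(
            self.data, info, tmin=float(self.times[0]), metadata=self.metadata,
            verbose="error",
        )


@dataclass
class PreprocessConfig:
    l_freq: float = 0.1
    h_freq: float = 40.0
    baseline: tuple[float, float] = (-0.4, -0.1)
    reject_amplitude: float = 80.0
    average_reference: bool = True


def preprocess(
    epochs: EpochSet, config: PreprocessConfig | None = None
) -> tuple[EpochSet, pd.DataFrame]:
    """Average reference, band-pass, baseline-correct, and reject epochs.

    Returns the cleaned :class:`EpochSet` and a kept-trial log with one row
    per input trial (``kept`` flag and ``reason``).  Raises when every trial
    is rejected.
    """
    cfg = config or PreprocessConfig()
    data = epochs.data.copy()
    if cfg.average_reference:
        data -= data.mean(axis=1, keepdims=True)
    sfreq = epochs.sfreq
    n, c, t = data.shape
    data = filter_data(
        data.reshape(n * c, t), sfreq, cfg.l_freq, cfg.h_freq, verbose="error"
    ).reshape(n, c, t)
    bmask = (epochs.times >= cfg.baseline[0]) & (epochs.times <= cfg.baseline[1])
    if not bmask.any():
        raise ValueError("baseline window outside epoch times")
    data -= data[:, :, bmask].mean(axis=2, keepdims=True)
    peak = np.abs(data).max(axis=(1, 2))
    kept = peak <= cfg.reject_amplitude
    log = pd.DataFrame(
        {
            "trial": np.arange(n),
            "kept": kept,
            "peak_amplitude": peak,
            "reason": np.where(kept, "", "amplitude"),
        }
    )
    if not kept.any():
        raise ValueError("all trials rejected by the amplitude criterion")
    clean = EpochSet(
        data=data[kept],
        times=epochs.times,
        ch_names=list(epochs.ch_names),
        metadata=epochs.metadata.iloc[np.flatnonzero(kept)],
    )
    return clean, log


def exclude_trials(
    behavior: pd.DataFrame,
    rt_min: float = 0.2,
    rt_max: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop trials with out-of-range RTs, multiple presses, or premature responses.

    Expects columns ``rt`` (seconds) and optionally ``n_keypresses`` and
    ``premature``.  Returns (filtered table, per-row log of reasons).
    """
    if "rt" not in behavior.columns:
        raise ValueError("behavior table needs an 'rt' column")
    reasons = pd.Series("", index=behavior.index, dtype=object)
    bad = behavior.rt < rt_min
    reasons[bad] = "fast_rt"
    slow = (behavior.rt > rt_max) & (reasons == "")
    reasons[slow] = "slow_rt"
    if "n_keypresses" in behavior.columns:
        multi = (behavior.n_keypresses > 1) & (reasons == "")
        reasons[multi] = "multiple_keypresses"
    if "premature" in behavior.columns:
        prem = behavior.premature.astype(bool) & (reasons == "")
        reasons[prem] = "premature"
    log = pd.DataFrame({"reason": reasons, "excluded": reasons != ""})
    return behavior[reasons == ""].copy(), log
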