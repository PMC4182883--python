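"""Artifact screening, baseline correction, filtering and balanced trial labelling.

The cleaning chain mirrors a conventional ERP pipeline: a coarse technical
screen at +/-500 uV, blink/eye-movement removal by ICA upstream (out of scope
here - the pipeline accepts post-ICA epochs), a strict +/-200 uV screen,
baseline correction over the 100 ms pre-stimulus window, a 50 Hz notch, and -
for the ERP-component path only - a 30 Hz low-pass.  Decoding runs on the
non-low-passed data.

``label_and_balance`` attaches 3-level rating-increment labels to retained
trials and draws an equal-count random subset per increment, so decoding
accuracy cannot be driven by class-frequency biases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .core_io import EpochsArray, RatingTable
from .errors import ParticipantExcluded, ValidationError

logger = logging.getLogger("erpdecode")


@dataclass
class ScreenReport:
    """Per-trial amplitude extrema and pass/fail decisions."""

    threshold_uv: float
    trial_max: np.ndarray
    trial_min: np.ndarray
    passed: np.ndarray  # boolean per trial

    @property
    def retained_indices(self) -> np.ndarray:
        return np.nonzero(self.passed)[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"trial": np.arange(len(self.passed)),
                             "max_uv": self.trial_max, "min_uv": self.trial_min,
                             "passed": self.passed})


def screen_artifacts(epochs: EpochsArray, threshold_uv: float) -> ScreenReport:
    """Flag trials whose amplitude exceeds ``threshold_uv`` on any channel/sample."""
    if threshold_uv <= 0:
        raise ValidationError("threshold must be > 0")
    tmax = epochs.data.max(axis=(1, 2))
    tmin = epochs.data.min(axis=(1, 2))
    passed = np.maximum(np.abs(tmax), np.abs(tmin)) <= threshold_uv
    logger.info("screen at +/-%g uV: %d/%d trials retained", threshold_uv,
                passed.sum(), len(passed))
    return ScreenReport(threshold_uv, tmax, tmin, passed)


def two_stage_screen(epochs: EpochsArray, technical_uv: float = 500.0,
                     strict_uv: float = 200.0) -> tuple[ScreenReport, ScreenReport]:
    """The technical (+/-500 uV) then strict (+/-200 uV) screens.

    The strict pass set is a subset of the technical pass set by construction.
    """
    return screen_artifacts(epochs, technical_uv), screen_artifacts(epochs, strict_uv)


def baseline_correct(epochs: EpochsArray,
                     window_ms: tuple[float, float] = (-100.0, 0.0)) -> EpochsArray:
    """Subtract each trial/channel's mean over the pre-stimulus baseline window."""
    sl = epochs.sample_slice(*window_ms)
    if sl.stop <= sl.start:
        raise ValidationError("empty baseline window")
    out = epochs.copy()
    out.data -= out.data[:, :, sl].mean(axis=2, keepdims=True)
    return out


def filter_epochs(epochs: EpochsArray, kind: str, notch_q: float = 35.0,
                  lowpass_order: int = 4) -> EpochsArray:
    """Zero-phase filtering: ``"notch50"`` (line noise) or ``"lowpass30"``.

    Filters are applied bidirectionally (filtfilt), so component latencies are
    not shifted.  The 30 Hz low-pass belongs only on the ERP-component path;
    decoding uses unfiltered (apart from the notch) CSD epochs.
    """
    nyq = epochs.fs / 2.0
    if kind == "notch50":
        if 50.0 >= nyq:
            raise ValidationError("notch frequency at or above Nyquist")
        b, a = signal.iirnotch(50.0, notch_q, fs=epochs.fs)
    elif kind == "lowpass30":
        if 30.0 >= nyq:
            raise ValidationError("low-pass cutoff at or above Nyquist")
        b, a = signal.butter(lowpass_order, 30.0, btype="low", fs=epochs.fs)
    else:
        raise ValidationError(f"unknown filter kind {kind!r}")
    out = epochs.copy()
    out.data = signal.filtfilt(b, a, out.data, axis=2)
    return out


@dataclass
class LabeledTrials:
    """Rating-increment labels for one dimension plus a balanced trial subset."""

    dimension: str
    labels: np.ndarray          # increment (1/2/3) per candidate trial
    trial_indices: np.ndarray   # epoch indices the labels refer to
    counts: dict[int, int]
    balanced_indices: np.ndarray  # epoch indices, equal count per increment
    seed: int

    @property
    def balanced_labels(self) -> np.ndarray:
        lookup = dict(zip(self.trial_indices.tolist(), self.labels.tolist()))
        return np.array([lookup[i] for i in self.balanced_indices])


def label_and_balance(trial_meta: pd.DataFrame, ratings: RatingTable,
                      participant_id: str, dimension: str, seed: int = 0,
                      min_trials: int = 16) -> LabeledTrials:
    """Label retained trials by rating increment and draw a balanced subset.

    The balanced subset holds, for every increment present, exactly the
    minimum per-increment count, sampled without replacement with ``seed``.
    A dimension with fewer than 2 distinct increments, or with fewer than
    ``min_trials`` trials in some increment, excludes the participant for that
    dimension (mirroring the exclusion of raters who used only extreme values).
    """
    inc_by_image = ratings.increments_for(participant_id, dimension)
    retained = trial_meta.index[trial_meta["retained"]].to_numpy()
    image_ids = trial_meta.loc[retained, "image_id"]
    try:
        labels = inc_by_image.loc[image_ids].to_numpy()
    except KeyError as exc:
        raise ValidationError(f"trial references unrated image: {exc}") from None
    values, counts = np.unique(labels, return_counts=True)
    if len(values) < 2:
        raise ParticipantExcluded(
            f"{participant_id}/{dimension}: only {len(values)} distinct rating "
            "increment(s); no variability to decode")
    if counts.min() < min_trials:
        raise ParticipantExcluded(
            f"{participant_id}/{dimension}: smallest increment has "
            f"{counts.min()} trials (< {min_trials})")
    n_per = int(counts.min())
    rng = np.random.default_rng(seed)
    picked = []
    for v in values:
        pool = retained[labels == v]
        picked.append(rng.choice(pool, size=n_per, replace=False))
    balanced = np.sort(np.concatenate(picked))
    logger.info("%s/%s: counts %s -> balanced %d per increment (seed=%d)",
                participant_id, dimension, dict(zip(values.tolist(),
                                                    counts.tolist())), n_per, seed)
    return LabeledTrials(dimension, labels, retained,
                         dict(zip(values.tolist(), counts.tolist())),
                         balanced, seed)
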