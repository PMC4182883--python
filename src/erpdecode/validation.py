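"""Statistical validation harnesses for the decoding pipeline.

Two simulation studies characterize the pipeline as a statistical procedure:

* **Null calibration** - with no rating-dependent signal, the window-wise
  paired test (empirical vs shuffled-label SVR) should reject at the nominal
  rate.  Many small null sessions are simulated and the achieved rejection
  rate is measured.
* **Effect recovery** - with a signal planted at a known window and channel
  group, group decoding should reach significance at the overlapping windows
  (and localize there), and channel-wise temporal decoding should peak at the
  planted channels.

Both run scaled-down designs (fewer participants/trials/windows and a reduced
montage) so that hundreds of simulated sessions are affordable on one CPU;
the simulated conditions are stated in each function's parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import EpochsArray, PipelineConfig, builtin_montage
from .decoding import (channel_group_stats, channel_temporal_decode,
                       group_stats, make_window_grid, sliding_window_decode)
from .preprocessing import LabeledTrials
from .synthetic_data import _pink_noise, _raised_cosine

logger = logging.getLogger("erpdecode")

#: Posterior/parietal sub-montage used by the scaled-down simulations.
SMALL_MONTAGE_CHANNELS = ("O1", "Oz", "O2", "PO7", "PO3", "PO4", "PO8", "Pz")


def _balanced_labels(rng: np.random.Generator, trials_per_class: int) -> np.ndarray:
    labels = np.repeat([1, 2, 3], trials_per_class)
    rng.shuffle(labels)
    return labels


def _simulated_participant(rng: np.random.Generator, labels: np.ndarray,
                           n_channels: int, n_samples: int, fs: float,
                           slope: float, effect_window_ms, effect_channels,
                           noise_rms: float = 1.0) -> EpochsArray:
    """Minimal synthetic epochs: pink noise + optional planted increment effect."""
    n_trials = len(labels)
    data = noise_rms * _pink_noise(rng, n_trials, n_channels, n_samples, fs, 1.0)
    times = np.arange(n_samples) / fs * 1000.0
    if slope != 0.0:
        env = _raised_cosine(times, effect_window_ms)
        w = np.zeros(n_channels)
        w[list(effect_channels)] = 1.0
        data += (slope * (labels - 2.0))[:, None, None] * w[None, :, None] \
            * env[None, None, :]
    labels_mont = builtin_montage().labels[:n_channels] \
        if n_channels > len(SMALL_MONTAGE_CHANNELS) \
        else SMALL_MONTAGE_CHANNELS[:n_channels]
    meta = pd.DataFrame({"image_id": np.arange(n_trials) % 24 + 1,
                         "block": 1, "jitter_s": 4, "retained": True})
    return EpochsArray("sim", data, fs, 0.0, tuple(labels_mont), meta, "uV")


def _labeled(labels: np.ndarray, dimension: str = "time_reference",
             seed: int = 0) -> LabeledTrials:
    idx = np.arange(len(labels))
    vals, counts = np.unique(labels, return_counts=True)
    return LabeledTrials(dimension, labels, idx,
                         dict(zip(vals.tolist(), counts.tolist())), idx, seed)


@dataclass
class CalibrationResult:
    rejection_rate: float
    n_tests: int
    n_rejections: int
    alpha: float


def null_rejection_rate(n_simulations: int = 500, n_participants: int = 8,
                        n_windows: int = 5, folds: int = 5,
                        repetitions: int = 2, trials_per_class: int = 8,
                        n_channels: int = 8, fs: float = 256.0,
                        alpha: float = 0.05, seed: int = 0) -> CalibrationResult:
    """Window-wise rejection rate of the group test under the global null.

    Each simulation draws ``n_participants`` pure-noise sessions, runs the
    full sliding-window empirical + shuffled-label decoding and the paired
    group test per window, and counts windows with p < alpha.  Under the null
    the rate should sit at alpha.
    """
    rng = np.random.default_rng(seed)
    cfg = PipelineConfig(folds=folds, repetitions=repetitions)
    span_hi = 40.0 + (n_windows - 1) * 20.0
    grid = make_window_grid(fs, 40.0, 20.0, (0.0, span_hi), t_start_ms=0.0)
    n_samples = int(np.ceil(span_hi / 1000.0 * fs)) + 1
    rejections = 0
    total = 0
    for _sim in range(n_simulations):
        results = []
        for p in range(n_participants):
            labels = _balanced_labels(rng, trials_per_class)
            epochs = _simulated_participant(rng, labels, n_channels, n_samples,
                                            fs, 0.0, None, ())
            epochs.participant_id = f"sim{p:02d}"
            part_seed = int(rng.integers(2 ** 31))
            results.append(sliding_window_decode(epochs, _labeled(labels),
                                                 grid, cfg, seed=part_seed))
        stats = group_stats(results, alpha=alpha)
        rejections += int((stats.windows["p"] < alpha).sum())
        total += len(stats.windows)
    logger.info("null calibration: %d/%d windows rejected (%.3f)",
                rejections, total, rejections / total)
    return CalibrationResult(rejections / total, total, rejections, alpha)


@dataclass
class RecoveryResult:
    detection_rate: float       # fraction of seeds significant at planted windows
    localization_rate: float    # ... with the best window within +/- 1 of planted
    false_positive_rate: float  # significant windows far from the planted one
    channel_hit_rate: float     # channel map peaks at a planted channel
    planted_center_ms: float
    recovered_centers_ms: list


def effect_recovery(n_seeds: int = 10, n_participants: int = 6,
                    n_windows: int = 7, folds: int = 5, repetitions: int = 2,
                    trials_per_class: int = 8, n_channels: int = 8,
                    fs: float = 256.0, slope: float = 2.0,
                    noise_rms: float = 1.0, alpha: float = 0.05,
                    seed: int = 0) -> RecoveryResult:
    """Detection and localization of a planted effect.

    The effect (raised-cosine envelope, ``slope`` uV per increment step,
    default 2x the noise RMS) occupies the window centred on the grid's
    middle window and the first two channels of the reduced montage.  For
    each seed the group analysis must reach significance at a window
    overlapping the planted one; localization requires the minimum-p window
    within one step of the planted centre; the channel-wise map must peak at
    a planted channel.
    """
    rng = np.random.default_rng(seed)
    cfg = PipelineConfig(folds=folds, repetitions=repetitions)
    span_hi = 40.0 + (n_windows - 1) * 20.0
    grid = make_window_grid(fs, 40.0, 20.0, (0.0, span_hi), t_start_ms=0.0)
    n_samples = int(np.ceil(span_hi / 1000.0 * fs)) + 1
    mid = n_windows // 2
    planted = grid.windows[mid]
    effect_channels = (0, 1)
    detected = localized = 0
    channel_hits = 0
    far_fp = 0
    far_total = 0
    recovered = []
    for _s in range(n_seeds):
        results = []
        chan_results = []
        for p in range(n_participants):
            labels = _balanced_labels(rng, trials_per_class)
            epochs = _simulated_participant(
                rng, labels, n_channels, n_samples, fs, slope,
                (planted.start_ms, planted.end_ms), effect_channels, noise_rms)
            epochs.participant_id = f"sim{p:02d}"
            part_seed = int(rng.integers(2 ** 31))
            lab = _labeled(labels)
            results.append(sliding_window_decode(epochs, lab, grid, cfg,
                                                 seed=part_seed))
            chan_results.append(channel_temporal_decode(
                epochs, lab, (planted.start_ms, planted.end_ms), cfg,
                seed=part_seed + 1))
        stats = group_stats(results, alpha=alpha)
        pvals = stats.windows["p"].to_numpy()
        centers = stats.windows["center_ms"].to_numpy()
        overlap = np.abs(centers - planted.center_ms) < grid.length_ms - 1e-9
        sig = pvals < alpha
        if (sig & overlap).any():
            detected += 1
        best = centers[int(np.argmin(pvals))]
        recovered.append(float(best))
        if sig.any() and abs(best - planted.center_ms) <= grid.step_ms + 1e-9:
            localized += 1
        far = np.abs(centers - planted.center_ms) > grid.length_ms + 1e-9
        far_fp += int((sig & far).sum())
        far_total += int(far.sum())
        cmap = channel_group_stats(chan_results)
        if int(cmap["mean_z_empirical"].sub(cmap["mean_z_null"]).idxmax()) \
                in effect_channels:
            channel_hits += 1
    logger.info("recovery: detected %d/%d, localized %d/%d, channel hits %d/%d",
                detected, n_seeds, localized, n_seeds, channel_hits, n_seeds)
    return RecoveryResult(detected / n_seeds, localized / n_seeds,
                          far_fp / max(far_total, 1), channel_hits / n_seeds,
                          planted.center_ms, recovered)
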