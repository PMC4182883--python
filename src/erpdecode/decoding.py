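"""Sliding-window support-vector regression decoding with a shuffled-label null.

The core analysis asks, for every short post-stimulus time window, whether the
spatio-temporal pattern of CSD amplitudes across all channels predicts the
trial's 3-level rating increment.  Per window:

* features are every channel x sample amplitude in the window (64 channels x
  20 samples = 1280 features at the defaults);
* a linear epsilon-SVR (LIBSVM; C = 0.1, epsilon = 0.1) is trained and tested
  in a 10-fold cross-validation, the whole CV repeated 10 times with freshly
  drawn folds (100 analyses); each analysis yields the Pearson correlation
  between predicted and true increments on the held-out fold;
* correlations are Fisher-Z transformed and averaged;
* the identical machinery is rerun with labels randomly permuted afresh for
  every analysis, giving a matched empirical null per window.

Group inference is a paired t-test (empirical vs null, one-sided by default)
per window across participants, plus period-aggregate tests over the full
span and its two halves.  A channel-wise variant decodes from each channel's
samples alone over a union of significant windows, mapping where predictive
signal sits on the scalp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVR

from .core_io import EpochsArray, PipelineConfig
from .errors import ValidationError
from .preprocessing import LabeledTrials

logger = logging.getLogger("erpdecode")


# ---------------------------------------------------------------------------
# Fisher Z
# ---------------------------------------------------------------------------

_R_CLIP = 1.0 - 1e-12


def fisher_z(r) -> float | np.ndarray:
    """atanh of a correlation, with r clipped just inside +/-1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValidationError("|r| must be <= 1")
    out = np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))
    return float(out) if out.ndim == 0 else out


def inverse_fisher_z(z) -> float | np.ndarray:
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Window grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Window:
    start_ms: float
    end_ms: float
    start_sample: int
    n_samples: int

    @property
    def center_ms(self) -> float:
        return (self.start_ms + self.end_ms) / 2.0


@dataclass(frozen=True)
class WindowGrid:
    """Sliding analysis windows over the post-stimulus span.

    Windows are ``length_ms`` long, advance by ``step_ms`` and hold
    ``floor(length_ms / 1000 * fs)`` samples each (20 at 40 ms / 512 Hz).
    """

    fs: float
    length_ms: float
    step_ms: float
    span_ms: tuple[float, float]
    windows: tuple[Window, ...]

    @property
    def centers_ms(self) -> np.ndarray:
        return np.array([w.center_ms for w in self.windows])


def make_window_grid(fs: float, length_ms: float = 40.0, step_ms: float = 20.0,
                     span_ms: tuple[float, float] = (0.0, 440.0),
                     t_start_ms: float = -100.0) -> WindowGrid:
    """Build the sliding-window grid; the first window starts at span start."""
    lo, hi = span_ms
    if hi - lo < length_ms:
        raise ValidationError(f"span {span_ms} shorter than window {length_ms} ms")
    n_per = int(np.floor(length_ms / 1000.0 * fs))
    if n_per < 1:
        raise ValidationError("window shorter than one sample period")
    windows = []
    start = lo
    while start + length_ms <= hi + 1e-9:
        s0 = int(round((start - t_start_ms) * fs / 1000.0))
        windows.append(Window(start, start + length_ms, s0, n_per))
        start += step_ms
    return WindowGrid(fs, length_ms, step_ms, (lo, hi), tuple(windows))


def vectorize_window(epochs: EpochsArray, window: Window) -> np.ndarray:
    """Trials x features matrix for one window; channel-major feature order
    (all of channel 0's samples, then channel 1's, ...)."""
    s0, n = window.start_sample, window.n_samples
    if s0 < 0 or s0 + n > epochs.n_samples:
        raise ValidationError(f"window samples [{s0}, {s0 + n}) outside epoch")
    block = epochs.data[:, :, s0:s0 + n]
    return block.reshape(epochs.n_trials, epochs.n_channels * n)


# ---------------------------------------------------------------------------
# Cross-validated SVR
# ---------------------------------------------------------------------------

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r; defined as 0 when either side has zero variance (a constant
    prediction carries no label information)."""
    sa, sb = a.std(), b.std()
    scale_a = max(1.0, float(np.abs(a).max()))
    scale_b = max(1.0, float(np.abs(b).max()))
    if sa <= 1e-10 * scale_a or sb <= 1e-10 * scale_b:
        return 0.0
    r = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
    return max(-1.0, min(1.0, r))


def run_svr_cv(features: np.ndarray, labels: np.ndarray, cfg: PipelineConfig,
               rng: np.random.Generator, shuffle_labels: bool = False
               ) -> tuple[list[float], float]:
    """Repeated k-fold cross-validated epsilon-SVR.

    Per repetition the trials are randomly partitioned into ``cfg.folds``
    equal bins; each bin serves once as the test set.  Each analysis (fold x
    repetition) returns the Pearson correlation between the SVR's continuous
    predictions and the true labels on the held-out bin.  With
    ``shuffle_labels`` a fresh random permutation of the labels is drawn for
    every analysis (the shuffled-label empirical null).

    Returns (per-analysis r values, mean Fisher-Z r).
    """
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    n = len(y)
    if n < cfg.folds:
        raise ValidationError(f"{n} trials cannot fill {cfg.folds} folds")
    rs: list[float] = []
    for _rep in range(cfg.repetitions):
        order = rng.permutation(n)
        bins = np.array_split(order, cfg.folds)
        for test_idx in bins:
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            y_run = rng.permutation(y) if shuffle_labels else y
            x_train, y_train = x[train_mask], y_run[train_mask]
            x_test, y_test = x[test_idx], y_run[test_idx]
            if cfg.scale_features:
                mu = x_train.mean(axis=0)
                sd = x_train.std(axis=0)
                sd[sd == 0] = 1.0
                x_train = (x_train - mu) / sd
                x_test = (x_test - mu) / sd
            model = SVR(kernel="linear", C=cfg.svr_c, epsilon=cfg.svr_epsilon)
            model.fit(x_train, y_train)
            pred = model.predict(x_test)
            rs.append(_pearson(pred, y_test))
    return rs, float(np.mean(fisher_z(np.array(rs))))


# ---------------------------------------------------------------------------
# Sliding-window decoding (per participant)
# ---------------------------------------------------------------------------

@dataclass
class WindowResult:
    """One participant x window: empirical and null mean Fisher-Z correlations."""

    participant_id: str
    center_ms: float
    z_empirical: float
    z_null: float
    r_empirical: list[float] = field(repr=False, default_factory=list)
    r_null: list[float] = field(repr=False, default_factory=list)


@dataclass
class ParticipantDecoding:
    """All window results for one participant and dimension."""

    participant_id: str
    dimension: str
    grid: WindowGrid
    windows: list[WindowResult]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"participant_id": w.participant_id,
                              "center_ms": w.center_ms,
                              "z_empirical": w.z_empirical,
                              "z_null": w.z_null} for w in self.windows])


def sliding_window_decode(epochs: EpochsArray, labeled: LabeledTrials,
                          grid: WindowGrid, cfg: PipelineConfig,
                          seed: int = 0) -> ParticipantDecoding:
    """Run the windowed SVR (empirical + shuffled-label null) for one participant.

    The balanced trial subset is fixed once, before windowing, so every window
    sees the same trials.  Everything random (fold partitions and label
    shuffles, drawn independently per analysis and window) descends from
    ``seed``.
    """
    sub = epochs.select_trials(labeled.balanced_indices)
    y = labeled.balanced_labels
    rng = np.random.default_rng(seed)
    results = []
    for window in grid.windows:
        x = vectorize_window(sub, window)
        r_emp, z_emp = run_svr_cv(x, y, cfg, rng)
        r_null, z_null = run_svr_cv(x, y, cfg, rng, shuffle_labels=True)
        results.append(WindowResult(epochs.participant_id, window.center_ms,
                                    z_emp, z_null, r_emp, r_null))
    logger.info("decoded %s/%s over %d windows (seed=%d)", epochs.participant_id,
                labeled.dimension, len(grid.windows), seed)
    return ParticipantDecoding(epochs.participant_id, labeled.dimension, grid,
                               results)


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

FIRST_HALF_MS = (20.0, 200.0)
SECOND_HALF_MS = (220.0, 400.0)


def _paired_t(emp: np.ndarray, null: np.ndarray, one_sided: bool) -> tuple[float, float]:
    d = emp - null
    if np.allclose(d.std(ddof=1), 0):
        return 0.0, 1.0
    t, p = stats.ttest_rel(emp, null)
    if one_sided:
        p = p / 2.0 if t > 0 else 1.0 - p / 2.0
    return float(t), float(p)


@dataclass
class GroupDecodingStats:
    """Window-wise and period-aggregate group tests (empirical vs null)."""

    dimension: str
    windows: pd.DataFrame   # center_ms, mean_z_emp, mean_z_null, t, df, p
    periods: pd.DataFrame   # period, t, df, p
    alpha: float

    def significant_centers(self) -> np.ndarray:
        return self.windows.loc[self.windows["p"] < self.alpha,
                                "center_ms"].to_numpy()

    def summary(self) -> str:
        lines = [f"Group decoding: {self.dimension} "
                 f"(n = {int(self.windows['df'].iloc[0]) + 1} participants)",
                 "=" * 64,
                 self.windows.to_string(index=False, float_format="%.4f"), "",
                 "Period aggregates:",
                 self.periods.to_string(index=False, float_format="%.4f")]
        return "\n".join(lines)


def group_stats(results: list[ParticipantDecoding], alpha: float = 0.05,
                one_sided: bool = True,
                first_half_ms: tuple[float, float] = FIRST_HALF_MS,
                second_half_ms: tuple[float, float] = SECOND_HALF_MS
                ) -> GroupDecodingStats:
    """Paired t-tests per window and per aggregation period across participants."""
    if len(results) < 3:
        raise ValidationError("need >= 3 participants for group statistics")
    centers = results[0].grid.centers_ms
    for r in results[1:]:
        if not np.array_equal(r.grid.centers_ms, centers):
            raise ValidationError("participants decoded on different window grids")
    emp = np.array([[w.z_empirical for w in r.windows] for r in results])
    null = np.array([[w.z_null for w in r.windows] for r in results])
    n = len(results)
    rows = []
    for j, c in enumerate(centers):
        t, p = _paired_t(emp[:, j], null[:, j], one_sided)
        rows.append({"center_ms": c, "mean_z_empirical": emp[:, j].mean(),
                     "mean_z_null": null[:, j].mean(), "t": t, "df": n - 1, "p": p})
    windows = pd.DataFrame(rows)

    period_rows = []
    periods = [("full", (centers.min(), centers.max())),
               ("first_half", first_half_ms), ("second_half", second_half_ms)]
    for name, (lo, hi) in periods:
        mask = (centers >= lo - 1e-9) & (centers <= hi + 1e-9)
        if not mask.any():
            continue
        t, p = _paired_t(emp[:, mask].mean(axis=1), null[:, mask].mean(axis=1),
                         one_sided)
        period_rows.append({"period": name, "centers_lo_ms": lo,
                            "centers_hi_ms": hi, "n_windows": int(mask.sum()),
                            "t": t, "df": n - 1, "p": p})
    dim = results[0].dimension
    return GroupDecodingStats(dim, windows, pd.DataFrame(period_rows), alpha)


# ---------------------------------------------------------------------------
# Channel-wise temporal decoding
# ---------------------------------------------------------------------------

def union_extent(grid: WindowGrid, centers_ms) -> tuple[float, float]:
    """Time extent covered by the union of the windows with the given centers."""
    selected = [w for w in grid.windows
                if any(abs(w.center_ms - c) < 1e-9 for c in centers_ms)]
    if not selected:
        raise ValidationError(f"no grid windows with centers {centers_ms}")
    return (min(w.start_ms for w in selected), max(w.end_ms for w in selected))


def temporal_samples(epochs: EpochsArray, extent_ms: tuple[float, float]) -> slice:
    """Inclusive sample range for a channel-wise temporal decoding period:
    floor(duration * fs / 1000) + 1 samples from the nearest sample of the
    period start (31 samples for 80-140 ms at 512 Hz)."""
    lo, hi = extent_ms
    if hi <= lo:
        raise ValidationError("empty temporal-decoding extent")
    s0 = epochs.time_index(lo)
    n = int(np.floor((hi - lo) * epochs.fs / 1000.0)) + 1
    if s0 + n > epochs.n_samples:
        raise ValidationError("temporal-decoding extent outside epoch")
    return slice(s0, s0 + n)


@dataclass
class ChannelDecodingResult:
    """Per-channel mean Fisher-Z correlations for one participant."""

    participant_id: str
    dimension: str
    extent_ms: tuple[float, float]
    channel_labels: tuple[str, ...]
    z_empirical: np.ndarray
    z_null: np.ndarray


def channel_temporal_decode(epochs: EpochsArray, labeled: LabeledTrials,
                            extent_ms: tuple[float, float], cfg: PipelineConfig,
                            seed: int = 0) -> ChannelDecodingResult:
    """Decode from each channel separately using its samples over ``extent_ms``."""
    sub = epochs.select_trials(labeled.balanced_indices)
    y = labeled.balanced_labels
    sl = temporal_samples(sub, extent_ms)
    rng = np.random.default_rng(seed)
    z_emp = np.empty(sub.n_channels)
    z_null = np.empty(sub.n_channels)
    for ch in range(sub.n_channels):
        x = sub.data[:, ch, sl]
        _, z_emp[ch] = run_svr_cv(x, y, cfg, rng)
        _, z_null[ch] = run_svr_cv(x, y, cfg, rng, shuffle_labels=True)
    return ChannelDecodingResult(epochs.participant_id, labeled.dimension,
                                 extent_ms, sub.channel_labels, z_emp, z_null)


def channel_group_stats(results: list[ChannelDecodingResult],
                        one_sided: bool = True) -> pd.DataFrame:
    """Per-channel paired t (empirical vs null) across participants."""
    if len(results) < 3:
        raise ValidationError("need >= 3 participants for group statistics")
    labels = results[0].channel_labels
    emp = np.array([r.z_empirical for r in results])
    null = np.array([r.z_null for r in results])
    rows = []
    for ch, lab in enumerate(labels):
        t, p = _paired_t(emp[:, ch], null[:, ch], one_sided)
        rows.append({"channel": lab, "mean_z_empirical": emp[:, ch].mean(),
                     "mean_z_null": null[:, ch].mean(), "t": t,
                     "df": len(results) - 1, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model-style front end
# ---------------------------------------------------------------------------

class SlidingWindowDecoder:
    """Model object: sliding-window SVR decoding for one participant.

    Parameters
    ----------
    epochs : EpochsArray
        CSD-transformed epochs (not 30 Hz low-passed).
    labeled : LabeledTrials
        Balanced rating-increment labels for the decoded dimension.
    cfg : PipelineConfig, optional
    grid : WindowGrid, optional
        Defaults to the config's window/step/span on the epochs' clock.
    """

    def __init__(self, epochs: EpochsArray, labeled: LabeledTrials,
                 cfg: PipelineConfig | None = None,
                 grid: WindowGrid | None = None):
        self.epochs = epochs
        self.labeled = labeled
        self.cfg = cfg or PipelineConfig()
        self.grid = grid or make_window_grid(
            epochs.fs, self.cfg.window_ms, self.cfg.step_ms, self.cfg.span_ms,
            epochs.t_start_ms)

    def fit(self, seed: int = 0) -> ParticipantDecoding:
        return sliding_window_decode(self.epochs, self.labeled, self.grid,
                                     self.cfg, seed=seed)


class GroupDecoding:
    """Group-level model over per-participant decoding results."""

    def __init__(self, results: list[ParticipantDecoding],
                 alpha: float = 0.05, one_sided: bool = True):
        self.results = results
        self.alpha = alpha
        self.one_sided = one_sided

    def fit(self) -> GroupDecodingStats:
        return group_stats(self.results, self.alpha, self.one_sided)
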