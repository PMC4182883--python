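"""Conventional ERP-component analysis on CSD-transformed epochs.

Per participant and rating increment, average waveforms are computed and four
components quantified: N1 (most negative peak at FCz, 50-150 ms), N2 (most
negative peak at Pz, 150-300 ms), P3 (most positive peak at Pz, 300-700 ms)
and the early posterior negativity (EPN; mean amplitude 280-320 ms, averaged
over O1/P9/PO7 on the left and O2/PO8/P10 on the right).  Peak components
yield amplitude and latency; the EPN yields a per-hemisphere mean, analysed
with rating increment x laterality repeated-measures ANOVA.

The ANOVA machinery is a fully-within-subjects one- or two-way decomposition
with Greenhouse-Geisser (GG) correction.  Sphericity is checked per effect
with Mauchly's test on the effect's contrast-projected covariance; when it
rejects at alpha = .05 the GG-corrected p-value is adopted (both raw and
corrected p are always reported).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import DEFAULT_COMPONENTS, EPN_LEFT, EPN_RIGHT, EpochsArray
from .errors import ValidationError

logger = logging.getLogger("erpdecode")


# ---------------------------------------------------------------------------
# Averaging and component measurement
# ---------------------------------------------------------------------------

def average_by_condition(epochs: EpochsArray, labels: np.ndarray,
                         conditions=None) -> dict[int, np.ndarray]:
    """Mean waveform (channels x samples) per condition label.

    ``labels`` holds one condition value per trial in ``epochs``.  An
    explicitly requested condition with no trials raises, naming it.
    """
    labels = np.asarray(labels)
    if len(labels) != epochs.n_trials:
        raise ValidationError(f"{len(labels)} labels for {epochs.n_trials} trials")
    conditions = sorted(set(labels.tolist())) if conditions is None else conditions
    out = {}
    for cond in conditions:
        mask = labels == cond
        if not mask.any():
            raise ValidationError(f"no trials in condition {cond!r}")
        out[cond] = epochs.data[mask].mean(axis=0)
    return out


def detect_peak(waveform: np.ndarray, times_ms: np.ndarray,
                window_ms: tuple[float, float],
                polarity: str) -> tuple[float, float]:
    """Extremum of the stated polarity within the inclusive window.

    Returns (amplitude, latency_ms); ties break to the earliest sample.
    """
    waveform = np.asarray(waveform, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    i0 = int(np.argmin(np.abs(times_ms - window_ms[0])))
    i1 = int(np.argmin(np.abs(times_ms - window_ms[1])))
    if i1 < i0:
        raise ValidationError("empty peak window")
    seg = waveform[i0:i1 + 1]
    if np.isnan(seg).any():
        raise ValidationError("NaNs inside the peak-detection window")
    if polarity == "neg":
        k = int(np.argmin(seg))
    elif polarity == "pos":
        k = int(np.argmax(seg))
    else:
        raise ValidationError(f"polarity must be 'neg' or 'pos', got {polarity!r}")
    return float(seg[k]), float(times_ms[i0 + k])


def epn_mean(waveforms: dict[int, np.ndarray], channel_labels,
             times_ms: np.ndarray,
             window_ms: tuple[float, float] = (280.0, 320.0)) -> pd.DataFrame:
    """Per condition x hemisphere mean amplitude in the EPN window.

    Averages over the inclusive 280-320 ms samples and over each hemisphere's
    three occipito-parietal electrodes.
    """
    channel_labels = list(channel_labels)
    for ch in EPN_LEFT + EPN_RIGHT:
        if ch not in channel_labels:
            raise ValidationError(f"EPN electrode {ch!r} missing")
    times_ms = np.asarray(times_ms, dtype=float)
    i0 = int(np.argmin(np.abs(times_ms - window_ms[0])))
    i1 = int(np.argmin(np.abs(times_ms - window_ms[1])))
    rows = []
    for cond, wf in waveforms.items():
        for hemi, chans in (("left", EPN_LEFT), ("right", EPN_RIGHT)):
            idx = [channel_labels.index(c) for c in chans]
            rows.append((cond, hemi, float(wf[idx, i0:i1 + 1].mean())))
    return pd.DataFrame(rows, columns=["condition", "hemisphere", "amplitude"])


def measure_components(epochs: EpochsArray, labels: np.ndarray,
                       components=DEFAULT_COMPONENTS) -> pd.DataFrame:
    """Quantify every configured component per condition for one participant."""
    waveforms = average_by_condition(epochs, labels)
    times = epochs.times
    rows = []
    for comp in components:
        if comp.measure == "mean":  # EPN-style hemispheric mean
            table = epn_mean(waveforms, epochs.channel_labels, times,
                             comp.window_ms)
            for _, r in table.iterrows():
                rows.append((epochs.participant_id, r["condition"], comp.name,
                             r["hemisphere"], r["amplitude"], np.nan))
        else:
            polarity = "neg" if comp.measure == "peak_neg" else "pos"
            for cond, wf in waveforms.items():
                ch = epochs.channel_index(comp.electrodes[0])
                amp, lat = detect_peak(wf[ch], times, comp.window_ms, polarity)
                rows.append((epochs.participant_id, cond, comp.name,
                             None, amp, lat))
    return pd.DataFrame(rows, columns=["participant", "condition", "component",
                                       "hemisphere", "amplitude", "latency_ms"])


# ---------------------------------------------------------------------------
# Sphericity and repeated-measures ANOVA
# ---------------------------------------------------------------------------

def gg_epsilon(condition_covariance: np.ndarray) -> float:
    """Box's Greenhouse-Geisser epsilon-hat from a k x k condition covariance.

    Double-centers the covariance and returns
    (sum of diagonal)^2 / ((k - 1) * sum of squared entries),
    clipped to [1 / (k - 1), 1].
    """
    s = np.asarray(condition_covariance, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1] or s.shape[0] < 2:
        raise ValidationError("covariance must be k x k with k >= 2")
    k = s.shape[0]
    row = s.mean(axis=1, keepdims=True)
    col = s.mean(axis=0, keepdims=True)
    centered = s - row - col + s.mean()
    denom = (k - 1) * np.sum(centered ** 2)
    if denom <= 0:
        return 1.0
    eps = np.trace(centered) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _helmert_contrasts(k: int) -> np.ndarray:
    """Orthonormal contrast matrix (k x (k-1)) spanning deviations from the mean."""
    c = np.zeros((k, k - 1))
    for j in range(1, k):
        c[:j, j - 1] = 1.0 / j
        c[j, j - 1] = -1.0
        c[:, j - 1] /= np.linalg.norm(c[:, j - 1])
    return c


def mauchly_test(scores: np.ndarray) -> tuple[float, float]:
    """Mauchly's sphericity test on within-subject scores (subjects x k levels).

    Returns (W, p).  For k = 2 sphericity holds trivially (W = 1, p = 1).
    """
    y = np.asarray(scores, dtype=float)
    n, k = y.shape
    if k < 3 or n <= k - 1:
        return 1.0, 1.0
    c = _helmert_contrasts(k)
    t = c.T @ np.cov(y, rowvar=False) @ c
    q = k - 1
    eig = np.linalg.eigvalsh(t)
    if np.any(eig <= 0):
        return 0.0, 0.0
    w = float(np.prod(eig) / (np.mean(eig) ** q))
    df = q * (q + 1) // 2 - 1
    chi2 = -(n - 1 - (2 * q ** 2 + q + 2) / (6.0 * q)) * np.log(max(w, 1e-300))
    p = float(stats.chi2.sf(chi2, df))
    return w, p


@dataclass
class AnovaResult:
    """One within-subjects effect from a repeated-measures ANOVA."""

    effect: str
    F: float
    df_num: float
    df_den: float
    epsilon: float
    p_uncorrected: float
    p_gg: float
    correction_applied: bool
    sphericity_p: float
    degenerate: bool = False

    @property
    def p(self) -> float:
        return self.p_gg if self.correction_applied else self.p_uncorrected

    @property
    def df_num_reported(self) -> float:
        return self.df_num * self.epsilon if self.correction_applied else self.df_num

    @property
    def df_den_reported(self) -> float:
        return self.df_den * self.epsilon if self.correction_applied else self.df_den


def _effect_result(name: str, ss_eff: float, df_eff: int, ss_err: float,
                   df_err: int, scores: np.ndarray) -> AnovaResult:
    """Assemble one effect's F-test with GG handling from its error term and
    the subject x level score matrix used for sphericity/epsilon."""
    if ss_err <= 1e-24:
        degenerate = ss_eff <= 1e-24
        f = 0.0 if degenerate else np.inf
        p = 1.0 if degenerate else 0.0
        return AnovaResult(name, f, df_eff, df_err, 1.0, p, p, False, 1.0,
                           degenerate=degenerate)
    f = (ss_eff / df_eff) / (ss_err / df_err)
    p_unc = float(stats.f.sf(f, df_eff, df_err))
    if scores.shape[1] >= 3:
        eps = gg_epsilon(np.cov(scores, rowvar=False))
        _, spher_p = mauchly_test(scores)
    else:
        eps, spher_p = 1.0, 1.0
    p_gg = float(stats.f.sf(f, df_eff * eps, df_err * eps))
    applied = spher_p < 0.05 and eps < 1.0
    return AnovaResult(name, float(f), df_eff, df_err, eps, p_unc, p_gg,
                       applied, spher_p)


def rm_anova(measures: pd.DataFrame, dv: str, subject: str,
             within: list[str]) -> list[AnovaResult]:
    """One- or two-way fully-within-subjects ANOVA.

    ``measures`` is long-format with one observation per subject x cell; a
    missing cell raises, listing the offenders.  With two factors the model
    includes both main effects and their interaction, each tested against its
    own subject-by-effect error term.
    """
    if not 1 <= len(within) <= 2:
        raise ValidationError("within must name 1 or 2 factors")
    levels = [sorted(measures[f].unique().tolist()) for f in within]
    subjects = sorted(measures[subject].unique().tolist())
    cells = list(itertools.product(subjects, *levels))
    grouped = measures.groupby([subject] + within)[dv]
    sizes = grouped.size()
    missing = [c for c in cells if c not in sizes.index or sizes[c] == 0]
    if missing:
        raise ValidationError(f"incomplete within-subject design; missing cells: "
                              f"{missing[:10]}")
    mean_table = grouped.mean()
    n = len(subjects)

    if len(within) == 1:
        a = len(levels[0])
        y = np.array([[mean_table[(s, i)] for i in levels[0]] for s in subjects])
        grand = y.mean()
        ss_a = n * np.sum((y.mean(axis=0) - grand) ** 2)
        ss_s = a * np.sum((y.mean(axis=1) - grand) ** 2)
        ss_err = np.sum((y - y.mean(axis=0) - y.mean(axis=1)[:, None] + grand) ** 2)
        return [_effect_result(within[0], ss_a, a - 1, ss_err, (a - 1) * (n - 1), y)]

    a, b = len(levels[0]), len(levels[1])
    y = np.array([[[mean_table[(s, i, j)] for j in levels[1]]
                   for i in levels[0]] for s in subjects])  # n x a x b
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)
    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_sa = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_sb = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    resid = (y - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
             + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :]
             - grand)
    ss_sab = np.sum(resid ** 2)

    # subject x level score matrices for sphericity of each effect
    inter_scores = (y - m_sa[:, :, None] - m_sb[:, None, :]
                    + m_s[:, None, None]).reshape(n, a * b)
    results = [
        _effect_result(within[0], ss_a, a - 1, ss_sa, (a - 1) * (n - 1), m_sa),
        _effect_result(within[1], ss_b, b - 1, ss_sb, (b - 1) * (n - 1), m_sb),
        _effect_result(f"{within[0]} x {within[1]}", ss_ab, (a - 1) * (b - 1),
                       ss_sab, (a - 1) * (b - 1) * (n - 1), inter_scores),
    ]
    return results


def anova_frame(results: list[AnovaResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "effect": r.effect, "F": r.F, "df_num": r.df_num_reported,
        "df_den": r.df_den_reported, "epsilon": r.epsilon,
        "p_uncorrected": r.p_uncorrected, "p_gg": r.p_gg, "p": r.p,
        "gg_applied": r.correction_applied, "sphericity_p": r.sphericity_p,
        "degenerate": r.degenerate} for r in results])


# ---------------------------------------------------------------------------
# Model-style wrapper over the full conventional analysis
# ---------------------------------------------------------------------------

class ErpComponentModel:
    """Component quantification + group ANOVA over a set of participants.

    Parameters
    ----------
    data : dict mapping participant id -> (EpochsArray, labels)
        CSD-transformed (and low-pass filtered) epochs plus the per-trial
        rating-increment labels for the analysed dimension.
    components : sequence of ComponentWindow
    """

    def __init__(self, data: dict[str, tuple[EpochsArray, np.ndarray]],
                 components=DEFAULT_COMPONENTS):
        if not data:
            raise ValidationError("no participants supplied")
        self.data = data
        self.components = components

    def fit(self) -> "ErpComponentResults":
        frames = [measure_components(ep, lab, self.components)
                  for ep, lab in self.data.values()]
        measures = pd.concat(frames, ignore_index=True)
        anovas: dict[str, pd.DataFrame] = {}
        for comp in self.components:
            sub = measures[measures["component"] == comp.name]
            if comp.measure == "mean":
                res = rm_anova(sub, "amplitude", "participant",
                               ["condition", "hemisphere"])
                anovas[f"{comp.name} amplitude"] = anova_frame(res)
            else:
                for dv in ("amplitude", "latency_ms"):
                    res = rm_anova(sub, dv, "participant", ["condition"])
                    anovas[f"{comp.name} {dv}"] = anova_frame(res)
        return ErpComponentResults(measures, anovas)


class ErpComponentResults:
    """Fitted component measures and their repeated-measures ANOVA tables."""

    def __init__(self, measures: pd.DataFrame, anovas: dict[str, pd.DataFrame]):
        self.measures = measures
        self.anovas = anovas

    def condition_means(self) -> pd.DataFrame:
        keys = ["component", "condition", "hemisphere"]
        g = self.measures.groupby(keys, dropna=False)
        out = g.agg(amplitude_mean=("amplitude", "mean"),
                    amplitude_se=("amplitude", "sem"),
                    latency_mean=("latency_ms", "mean"),
                    latency_se=("latency_ms", "sem"))
        return out.reset_index()

    def summary(self) -> str:
        lines = ["ERP component analysis", "=" * 60,
                 self.condition_means().to_string(index=False), ""]
        for name, table in self.anovas.items():
            lines.append(name)
            lines.append(table[["effect", "F", "df_num", "df_den", "p",
                                "gg_applied"]].to_string(index=False))
            lines.append("")
        return "\n".join(lines)
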