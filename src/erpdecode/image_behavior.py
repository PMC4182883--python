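"""Control analyses: low-level image features vs ratings, and foreground-task
behavior.

Eleven low-level features are computed per stimulus image: the R, G and B
channel means, their three pairwise ratios, the mean of the three channel
means, the mean/median/standard deviation of pixel luminance (Rec. 601:
0.299 R + 0.587 G + 0.114 B) and the mean spatial frequency (the
amplitude-weighted mean radial frequency of the 2-D Fourier spectrum, DC
excluded, in cycles/pixel).  Correlation and multiple-regression analyses
check that the rating dimensions are not explained by these features, and the
foreground-task analysis checks that ratings are unrelated to task accuracy
per image.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core_io import RatingTable
from .decoding import fisher_z
from .errors import ValidationError
from .synthetic_data import IMAGE_FEATURES, TrialSchedule

logger = logging.getLogger("erpdecode")

LUMA_WEIGHTS = (0.299, 0.587, 0.114)  # Rec. 601


# ---------------------------------------------------------------------------
# Image features
# ---------------------------------------------------------------------------

def mean_spatial_frequency(gray: np.ndarray) -> tuple[float, bool]:
    """Amplitude-weighted mean radial frequency (cycles/pixel) of a grayscale
    image, DC excluded.

    Returns (value, flagged); a constant image has no non-DC energy and is
    reported as (0.0, True).
    """
    gray = np.asarray(gray, dtype=float)
    if not np.all(np.isfinite(gray)):
        raise ValidationError("image contains non-finite values")
    spec = np.abs(np.fft.fft2(gray))
    fy = np.fft.fftfreq(gray.shape[0])
    fx = np.fft.fftfreq(gray.shape[1])
    radius = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    spec[0, 0] = 0.0
    total = spec.sum()
    if total == 0:
        return 0.0, True
    return float((spec * radius).sum() / total), False


def compute_image_features(rgb: np.ndarray) -> pd.Series:
    """The 11 low-level features of one RGB image (H x W x 3, 0-255).

    Channel ratios divide channel means; a zero denominator yields NaN (the
    feature is flagged undefined rather than fabricated).
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValidationError(f"expected H x W x 3 RGB image, got {rgb.shape}")
    r_mean, g_mean, b_mean = (rgb[..., i].mean() for i in range(3))

    def ratio(num, den):
        return num / den if den != 0 else np.nan

    lum = (LUMA_WEIGHTS[0] * rgb[..., 0] + LUMA_WEIGHTS[1] * rgb[..., 1]
           + LUMA_WEIGHTS[2] * rgb[..., 2])
    msf, _ = mean_spatial_frequency(lum)
    values = {
        "R": r_mean, "G": g_mean, "B": b_mean,
        "R_G": ratio(r_mean, g_mean), "R_B": ratio(r_mean, b_mean),
        "G_B": ratio(g_mean, b_mean),
        "RGB_mean": (r_mean + g_mean + b_mean) / 3.0,
        "lum_mean": float(lum.mean()), "lum_median": float(np.median(lum)),
        "lum_sd": float(lum.std()), "spatial_freq": msf,
    }
    return pd.Series(values, index=list(IMAGE_FEATURES))


def image_feature_table(images) -> pd.DataFrame:
    """Feature table for a list of RGB images, indexed by 1-based image id."""
    rows = [compute_image_features(img) for img in images]
    df = pd.DataFrame(rows)
    df.index = pd.RangeIndex(1, len(images) + 1, name="image_id")
    return df


# ---------------------------------------------------------------------------
# Feature / rating correlations and regression
# ---------------------------------------------------------------------------

def correlate_features_ratings(features: pd.DataFrame, ratings: RatingTable,
                               dimension: str) -> pd.DataFrame:
    """Per-feature correlation with ratings along two routes.

    The mean-rating route correlates each feature with the across-participant
    mean combined rating per image (Pearson r, p).  The individual route
    correlates each participant's own ratings with the feature, Fisher-Z
    transforms the per-participant r's and reports their mean and standard
    error.  A zero-variance feature is left NaN (flagged undefined).
    """
    comb = ratings.combined()
    comb = comb[comb["dimension"] == dimension]
    if features.index.name != "image_id":
        raise ValidationError("feature table must be indexed by image_id")
    mean_rating = comb.groupby("image_id")["combined"].mean()
    if len(mean_rating) < 3:
        raise ValidationError("need >= 3 images")
    common = features.index.intersection(mean_rating.index)
    rows = []
    for feat in features.columns:
        fvals = features.loc[common, feat].to_numpy()
        if np.isnan(fvals).any() or np.std(fvals) == 0:
            rows.append({"feature": feat, "r_mean_ratings": np.nan,
                         "p_mean_ratings": np.nan, "mean_z_individual": np.nan,
                         "se_z_individual": np.nan, "undefined": True})
            continue
        r, p = stats.pearsonr(fvals, mean_rating.loc[common].to_numpy())
        zs = []
        for pid, grp in comb.groupby("participant_id"):
            ind = grp.set_index("image_id")["combined"].loc[common].to_numpy()
            if np.std(ind) == 0:
                continue
            zs.append(fisher_z(stats.pearsonr(fvals, ind)[0]))
        zs = np.asarray(zs)
        rows.append({"feature": feat, "r_mean_ratings": float(r),
                     "p_mean_ratings": float(p),
                     "mean_z_individual": float(zs.mean()),
                     "se_z_individual": float(zs.std(ddof=1) / np.sqrt(len(zs)))
                     if len(zs) > 1 else np.nan,
                     "undefined": False})
    return pd.DataFrame(rows)


def regress_ratings_on_features(features: pd.DataFrame, mean_ratings: pd.Series,
                                prune_collinear: bool = False):
    """OLS of the mean rating per image on all (or rank-pruned) features.

    Returns (adjusted R^2, F, df_num, df_den, p).  With all 11 predictors and
    24 images the overall test is F(11, 12).
    """
    common = features.index.intersection(mean_ratings.index)
    x = features.loc[common].copy()
    y = mean_ratings.loc[common].to_numpy(dtype=float)
    if prune_collinear:
        keep, dropped = [], []
        for col in x.columns:
            trial = x[keep + [col]].to_numpy()
            if np.linalg.matrix_rank(np.column_stack([np.ones(len(x)), trial])) \
                    == trial.shape[1] + 1:
                keep.append(col)
            else:
                dropped.append(col)
        if dropped:
            logger.info("pruned collinear features: %s", dropped)
        x = x[keep]
    if len(common) <= x.shape[1]:
        raise ValidationError(f"{len(common)} images cannot support "
                              f"{x.shape[1]} predictors")
    design = sm.add_constant(x.to_numpy(dtype=float))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        corr = np.corrcoef(x.to_numpy(dtype=float), rowvar=False)
        np.fill_diagonal(corr, 0)
        bad = [x.columns[i] for i in np.unique(np.argwhere(np.abs(corr) > 0.999))]
        raise ValidationError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(y, design).fit()
    return (float(fit.rsquared_adj), float(fit.fvalue),
            int(fit.df_model), int(fit.df_resid), float(fit.f_pvalue))


# ---------------------------------------------------------------------------
# Foreground task
# ---------------------------------------------------------------------------

def foreground_accuracy(log: pd.DataFrame, schedule: TrialSchedule,
                        ratings: RatingTable | None = None,
                        window_ms: float = 400.0) -> dict:
    """Accuracy and response times for the box-monitoring foreground task.

    A response is correct when it matches the opening's side and falls within
    the 400 ms open period.  Returns per-participant accuracy and RT summary,
    per-image accuracy, and (when ratings are supplied) each participant's
    Pearson correlation between per-image accuracy and each rating dimension.
    """
    for col in ("participant_id", "trial", "opening_side", "response_side", "rt_ms"):
        if col not in log.columns:
            raise ValidationError(f"behavior log missing column {col!r}")
    scheduled = set(schedule.df["trial_index"].tolist())
    stray = set(log["trial"]) - scheduled
    if stray:
        logger.warning("responses outside scheduled trials counted as errors: %s",
                       sorted(stray)[:5])
    log = log.copy()
    log["correct"] = ((log["response_side"] == log["opening_side"])
                      & (log["rt_ms"] > 0) & (log["rt_ms"] <= window_ms)
                      & log["trial"].isin(scheduled))
    image_of_trial = schedule.df.set_index("trial_index")["image_id"]
    log["image_id"] = log["trial"].map(image_of_trial)

    per_participant = log.groupby("participant_id").agg(
        accuracy=("correct", "mean"),
        rt_mean_ms=("rt_ms", lambda s: s[log.loc[s.index, "correct"]].mean()),
        rt_sd_ms=("rt_ms", lambda s: s[log.loc[s.index, "correct"]].std()),
    ).reset_index()
    per_image = (log.groupby(["participant_id", "image_id"])["correct"]
                 .mean().rename("accuracy").reset_index())

    correlations = None
    if ratings is not None:
        comb = ratings.combined()
        rows = []
        for (pid, dim), grp in comb.groupby(["participant_id", "dimension"]):
            acc = per_image[per_image["participant_id"] == pid].set_index(
                "image_id")["accuracy"]
            rat = grp.set_index("image_id")["combined"]
            common = acc.index.intersection(rat.index)
            if len(common) < 3 or rat.loc[common].std() == 0 \
                    or acc.loc[common].std() == 0:
                continue
            r, p = stats.pearsonr(acc.loc[common], rat.loc[common])
            rows.append({"participant_id": pid, "dimension": dim,
                         "r": float(r), "p": float(p)})
        correlations = pd.DataFrame(rows)
    return {"per_participant": per_participant, "per_image": per_image,
            "rating_correlations": correlations}
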