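"""Synthetic experiment generator: designs, ratings, EEG epochs and stimuli.

No raw data ship with this package, so every downstream stage is exercised on
synthetic sessions that reproduce the structure of the experiment: 24 images x
3 repetitions x 6 blocks (432 trials) with 3/4/5 s inter-trial jitter in exact
25/50/25 proportions; two 1-9 rating dimensions per image with a controllable
between-dimension correlation; multichannel epochs built from a shared ERP
template, a rating-increment-dependent spatio-temporal effect, spatially
correlated 1/f noise, 50 Hz line noise, stereotyped frontal blinks and
planted extreme-amplitude artifact trials; and RGB stimulus images with a
planted low-level-feature / rating correlation.

The generator's defaults are the study conditions; effect sizes and noise
levels are exercise parameters (the original recordings' spectra are unknown),
chosen so that a realistic decoding analysis neither trivially succeeds nor
trivially fails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import (DIMENSIONS, ElectrodeMontage, EpochsArray, RatingTable,
                      builtin_montage)
from .errors import ConfigurationError, ValidationError

logger = logging.getLogger("erpdecode")


# ---------------------------------------------------------------------------
# Trial schedule
# ---------------------------------------------------------------------------

@dataclass
class TrialSchedule:
    """Ordered trials of one session: (trial_index, block, image_id, jitter_s)."""

    df: pd.DataFrame

    def __post_init__(self):
        for col in ("trial_index", "block", "image_id", "jitter_s"):
            if col not in self.df.columns:
                raise ValidationError(f"schedule missing column {col!r}")

    @property
    def n_trials(self) -> int:
        return len(self.df)

    def jitter_counts(self) -> pd.Series:
        return self.df["jitter_s"].value_counts().sort_index()


def generate_design(n_images: int = 24, reps_per_block: int = 3,
                    n_blocks: int = 6, jitter_probs=(0.25, 0.5, 0.25),
                    jitter_values=(3, 4, 5), seed: int = 0) -> TrialSchedule:
    """A randomized session: each image ``reps_per_block`` times per block, with
    an exact (deterministic multiset, shuffled) jitter composition.

    Defaults give 24 images x 3 reps x 6 blocks = 432 trials, 72 per block,
    and jitters 3/4/5 s at exactly 25/50/25% of the session (108/216/108).
    """
    if len(jitter_probs) != len(jitter_values):
        raise ConfigurationError("jitter_probs and jitter_values length mismatch")
    if abs(sum(jitter_probs) - 1.0) > 1e-9:
        raise ConfigurationError("jitter_probs must sum to 1")
    if reps_per_block < 1 or int(reps_per_block) != reps_per_block:
        raise ConfigurationError("reps_per_block must be a positive integer")
    n_total = n_images * reps_per_block * n_blocks
    counts = [p * n_total for p in jitter_probs]
    if any(abs(c - round(c)) > 1e-9 for c in counts):
        raise ConfigurationError(
            f"jitter_probs {jitter_probs} do not yield integer counts at "
            f"{n_total} trials")
    rng = np.random.default_rng(seed)
    # exact jitter multiset for the session, shuffled
    jitters = np.repeat(jitter_values, [int(round(c)) for c in counts])
    rng.shuffle(jitters)
    rows = []
    for block in range(1, n_blocks + 1):
        images = np.repeat(np.arange(1, n_images + 1), reps_per_block)
        rng.shuffle(images)
        rows.append(images)
    images = np.concatenate(rows)
    blocks = np.repeat(np.arange(1, n_blocks + 1), n_images * reps_per_block)
    df = pd.DataFrame({"trial_index": np.arange(n_total), "block": blocks,
                       "image_id": images, "jitter_s": jitters})
    logger.info("generated design: %d trials, seed=%d", n_total, seed)
    return TrialSchedule(df)


# ---------------------------------------------------------------------------
# Ratings
# ---------------------------------------------------------------------------

def discretize_to_scale(latent: np.ndarray, n_levels: int = 9) -> np.ndarray:
    """Rank-based mapping of a latent variable onto an integer 1..n_levels scale.

    Equal-count bins over the ranks: order-preserving, and with >= n_levels
    items every level of the scale is used at least once.
    """
    latent = np.asarray(latent, dtype=float)
    order = np.argsort(latent, kind="stable")
    ranks = np.empty(len(latent), dtype=int)
    ranks[order] = np.arange(len(latent))
    return (ranks * n_levels // len(latent) + 1).astype(int)


def generate_ratings(n_participants: int, n_images: int = 24, rho: float = 0.0,
                     seed: int = 0, participant_agreement: float = 0.5,
                     presentation_noise: float = 0.3) -> RatingTable:
    """Two-dimension 1-9 ratings (two presentations each) for every participant.

    Latent (arousal, time-reference) values are bivariate Gaussian with
    correlation ``rho``; a fraction ``participant_agreement`` of latent
    variance is an image-level effect shared by all participants, the rest is
    idiosyncratic.  Latents are rank-discretized to 1-9, and each of the two
    presentations perturbs the combined rating by +/-1 with probability
    ``presentation_noise``.
    """
    if abs(rho) > 1:
        raise ValidationError("|rho| must be <= 1")
    if n_images < 3:
        raise ValidationError("need >= 3 images to form 3 rating increments")
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(2))
    # Image-level component shared by all participants.  Its two rows are set
    # to the target correlation EXACTLY (standardize, orthogonalize,
    # recombine): the shared part would otherwise drag every participant's
    # sample correlation toward its own sampling error rather than rho.
    u = rng.standard_normal((2, n_images))
    u = (u - u.mean(axis=1, keepdims=True)) / u.std(axis=1, keepdims=True)
    v1 = u[1] - (u[0] @ u[1] / (u[0] @ u[0])) * u[0]
    sd = v1.std()
    v1 = v1 / (sd if sd > 0 else 1.0)
    image_part = np.vstack([u[0], rho * u[0] + np.sqrt(max(0.0, 1 - rho ** 2)) * v1])
    a = float(np.clip(participant_agreement, 0.0, 1.0))
    rows = []
    for p in range(1, n_participants + 1):
        pid = f"S{p:02d}"
        personal = chol @ rng.standard_normal((2, n_images))
        latent = np.sqrt(a) * image_part + np.sqrt(1 - a) * personal
        for d, dim in enumerate(DIMENSIONS):
            base = discretize_to_scale(latent[d])
            for img in range(n_images):
                for pres in (1, 2):
                    shift = rng.choice([-1, 0, 1],
                                       p=[presentation_noise / 2,
                                          1 - presentation_noise,
                                          presentation_noise / 2])
                    raw = int(np.clip(base[img] + shift, 1, 9))
                    rows.append((pid, img + 1, dim, pres, raw))
    df = pd.DataFrame(rows, columns=list(RatingTable.COLUMNS))
    return RatingTable(df)


# ---------------------------------------------------------------------------
# Epochs
# ---------------------------------------------------------------------------

@dataclass
class EffectSpec:
    """A rating-increment-dependent signal planted in a channel/time window.

    Per trial the effect adds ``slope_uv * (increment - 2)`` microvolts at the
    peak of a raised-cosine envelope over ``window_ms``, spatially weighted by
    a Gaussian falloff (scale ``spatial_sigma`` radians of arc) around the
    target channels; weights are normalized to max 1.
    """

    dimension: str = "time_reference"
    channels: tuple[str, ...] = ("PO8", "PO7", "O1", "O2")
    window_ms: tuple[float, float] = (160.0, 200.0)
    slope_uv: float = 1.0
    spatial_sigma: float = 0.6
    weights: np.ndarray | None = None  # explicit per-montage-channel weights

    def __post_init__(self):
        if not np.isfinite(self.slope_uv):
            raise ValidationError("slope must be finite")
        if self.dimension not in DIMENSIONS:
            raise ValidationError(f"unknown dimension {self.dimension!r}")

    def channel_weights(self, montage: ElectrodeMontage) -> np.ndarray:
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (len(montage.labels),):
                raise ValidationError("explicit weights must match montage size")
        else:
            targets = np.array([montage.position(c) for c in self.channels])
            cos = np.clip(montage.positions @ targets.T, -1, 1)
            angle = np.arccos(cos)  # channels x targets, radians
            w = np.exp(-(angle.min(axis=1) / self.spatial_sigma) ** 2)
        m = np.abs(w).max()
        return w / m if m > 0 else w


@dataclass
class NoiseSpec:
    """Background activity and artifact model for synthetic epochs."""

    pink_exponent: float = 1.0      # 1/f^exponent amplitude spectrum
    rms_uv: float = 10.0            # per-channel noise RMS
    line_freq_hz: float = 50.0
    line_amp_uv: float = 2.0
    channel_corr_length: float = 1.0  # radians of arc on the sphere
    blink_rate: float = 0.1         # expected blinks per trial
    blink_amp_uv: float = 80.0
    extreme_fraction: float = 0.0   # fraction of trials with planted artifacts
    extreme_amp_uv: float = 300.0

    def __post_init__(self):
        for name in ("rms_uv", "line_amp_uv", "blink_rate", "blink_amp_uv",
                     "extreme_fraction", "extreme_amp_uv", "pink_exponent",
                     "channel_corr_length"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


def _raised_cosine(times_ms: np.ndarray, window_ms) -> np.ndarray:
    t0, t1 = window_ms
    env = np.zeros_like(times_ms)
    inside = (times_ms >= t0) & (times_ms <= t1)
    env[inside] = 0.5 * (1 - np.cos(2 * np.pi * (times_ms[inside] - t0) / (t1 - t0)))
    return env


def _gaussian_weights(montage: ElectrodeMontage, center_label: str,
                      sigma: float) -> np.ndarray:
    center = montage.position(center_label)
    angle = np.arccos(np.clip(montage.positions @ center, -1, 1))
    return np.exp(-(angle / sigma) ** 2)


def erp_template(montage: ElectrodeMontage, times_ms: np.ndarray,
                 scale: float = 1.0) -> np.ndarray:
    """Deterministic shared ERP waveform (channels x samples, uV).

    A fronto-central negativity near 110 ms, a parietal negativity near 220 ms
    and a broad parietal positivity peaking around 400 ms - generic visual ERP
    morphology, identical for every trial and rating increment.
    """
    comps = [("FCz", 110.0, 25.0, -4.0, 0.8),
             ("Pz", 220.0, 35.0, -2.5, 0.8),
             ("Pz", 400.0, 120.0, 5.0, 1.0)]
    out = np.zeros((len(montage.labels), len(times_ms)))
    for label, peak_ms, width_ms, amp, sigma in comps:
        w = _gaussian_weights(montage, label, sigma)
        bump = amp * np.exp(-0.5 * ((times_ms - peak_ms) / width_ms) ** 2)
        bump[times_ms < 0] = 0.0
        out += np.outer(w, bump)
    return scale * out


def _pink_noise(rng: np.random.Generator, n_trials: int, n_channels: int,
                n_samples: int, fs: float, exponent: float) -> np.ndarray:
    """Independent 1/f^exponent noise per trial/channel, unit RMS."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0
    spec = (rng.standard_normal((n_trials, n_channels, len(freqs)))
            + 1j * rng.standard_normal((n_trials, n_channels, len(freqs))))
    noise = np.fft.irfft(spec * shaping, n=n_samples, axis=-1)
    rms = noise.std(axis=-1, keepdims=True)
    rms[rms == 0] = 1.0
    return noise / rms


def generate_epochs(schedule: TrialSchedule, ratings: RatingTable,
                    effects: list[EffectSpec], noise: NoiseSpec,
                    participant_id: str, fs: float = 512.0,
                    t_start_ms: float = -100.0, t_end_ms: float = 700.0,
                    montage: ElectrodeMontage | None = None,
                    template_scale: float = 1.0,
                    seed: int = 0) -> EpochsArray:
    """Simulate one participant's epochs for ``schedule``.

    Per trial: shared ERP template + sum over ``effects`` of
    envelope(t) * weights(ch) * slope * (increment(image, dimension) - 2)
    + spatially correlated pink noise + line noise + blinks; a deterministic
    subset of round(extreme_fraction * n_trials) trials additionally receives
    a planted artifact exceeding +/-200 uV.
    """
    montage = montage or builtin_montage()
    rng = np.random.default_rng(seed)
    n_trials = schedule.n_trials
    n_ch = len(montage.labels)
    n_samples = int(round((t_end_ms - t_start_ms) / 1000.0 * fs))
    times = t_start_ms + np.arange(n_samples) / fs * 1000.0

    data = np.zeros((n_trials, n_ch, n_samples))
    data += erp_template(montage, times, template_scale)[None, :, :]

    # planted rating-dependent effects
    image_ids = schedule.df["image_id"].to_numpy()
    for eff in effects:
        if not (t_start_ms <= eff.window_ms[0] < eff.window_ms[1] <= t_end_ms):
            raise ValidationError(f"effect window {eff.window_ms} outside epoch")
        inc = ratings.increments_for(participant_id, eff.dimension)
        try:
            trial_inc = inc.loc[image_ids].to_numpy()
        except KeyError as exc:
            raise ValidationError(
                f"schedule references images without ratings: {exc}") from None
        env = _raised_cosine(times, eff.window_ms)
        w = eff.channel_weights(montage)
        contrast = eff.slope_uv * (trial_inc - 2.0)
        data += contrast[:, None, None] * w[None, :, None] * env[None, None, :]

    # spatially correlated pink noise
    if noise.rms_uv > 0:
        white = _pink_noise(rng, n_trials, n_ch, n_samples, fs, noise.pink_exponent)
        if noise.channel_corr_length > 0:
            # squared-exponential kernel of chordal distance (positive definite
            # on the sphere, unlike the geodesic version)
            chord = np.linalg.norm(montage.positions[:, None, :]
                                   - montage.positions[None, :, :], axis=-1)
            k = np.exp(-(chord / noise.channel_corr_length) ** 2)
            chol = np.linalg.cholesky(k + 1e-9 * np.eye(n_ch))
            # renormalize rows so per-channel RMS stays at rms_uv
            chol = chol / np.linalg.norm(chol, axis=1, keepdims=True)
            white = np.einsum("ij,tjs->tis", chol, white)
        data += noise.rms_uv * white

    if noise.line_amp_uv > 0:
        phase = rng.uniform(0, 2 * np.pi, n_trials)
        line = np.sin(2 * np.pi * noise.line_freq_hz * (times / 1000.0)[None, :]
                      + phase[:, None])
        data += noise.line_amp_uv * line[:, None, :]

    if noise.blink_rate > 0 and noise.blink_amp_uv > 0:
        blink_w = _gaussian_weights(montage, "Fpz", 0.5)
        width_ms = 300.0
        n_blinks = rng.poisson(noise.blink_rate, n_trials)
        for t in np.nonzero(n_blinks)[0]:
            for _ in range(n_blinks[t]):
                center = rng.uniform(times[0], times[-1])
                shape = np.clip(np.cos(np.pi * (times - center) / width_ms), 0, None) ** 2
                shape[np.abs(times - center) > width_ms / 2] = 0.0
                data[t] += noise.blink_amp_uv * np.outer(blink_w, shape)

    artifact_trials = np.array([], dtype=int)
    if noise.extreme_fraction > 0:
        n_extreme = int(round(noise.extreme_fraction * n_trials))
        artifact_trials = rng.choice(n_trials, size=n_extreme, replace=False)
        for t in artifact_trials:
            ch = rng.integers(n_ch)
            s0 = rng.integers(0, max(1, n_samples - 8))
            sign = rng.choice([-1.0, 1.0])
            data[t, ch, s0:s0 + 8] = sign * noise.extreme_amp_uv

    meta = pd.DataFrame({
        "image_id": schedule.df["image_id"].to_numpy(),
        "block": schedule.df["block"].to_numpy(),
        "jitter_s": schedule.df["jitter_s"].to_numpy(),
        "retained": True,
        "planted_artifact": np.isin(np.arange(n_trials), artifact_trials),
    })
    logger.info("generated epochs for %s: %d trials, %d artifacts, seed=%d",
                participant_id, n_trials, len(artifact_trials), seed)
    return EpochsArray(participant_id, data, fs, t_start_ms,
                       tuple(montage.labels), meta, "uV")


# ---------------------------------------------------------------------------
# Stimulus images
# ---------------------------------------------------------------------------

IMAGE_FEATURES = ("R", "G", "B", "R_G", "R_B", "G_B", "RGB_mean",
                  "lum_mean", "lum_median", "lum_sd", "spatial_freq")


def generate_images(n: int = 24, planted_feature: str = "lum_mean",
                    r_target: float = 0.0, seed: int = 0,
                    size: tuple[int, int] = (384, 512)):
    """Random RGB stimulus images whose ``planted_feature`` correlates with the
    returned image-level scores at roughly ``r_target``.

    Returns ``(images, scores)`` where ``images`` is a list of uint8 arrays of
    shape ``size + (3,)`` (default 384 x 512, i.e. 512 x 384 pixels) and
    ``scores`` is an ``n``-vector of rating-like values.
    """
    if abs(r_target) > 1:
        raise ValidationError("|r_target| must be <= 1")
    if planted_feature not in IMAGE_FEATURES:
        raise ValidationError(f"unknown feature {planted_feature!r}; "
                              f"one of {IMAGE_FEATURES}")
    rng = np.random.default_rng(seed)
    h, w = size
    z = rng.standard_normal(n)
    e = rng.standard_normal(n)
    f = r_target * z + np.sqrt(max(0.0, 1 - r_target ** 2)) * e  # feature driver
    scores = 5.0 + 1.5 * z
    images = []
    for i in range(n):
        img = rng.integers(60, 196, size=(h, w, 3)).astype(float)
        d = 40.0 * f[i]
        if planted_feature in ("R", "G", "B"):
            img[..., "RGB".index(planted_feature)] += d
        elif planted_feature in ("R_G", "R_B", "G_B"):
            num = "RGB".index(planted_feature[0])
            den = "RGB".index(planted_feature[2])
            img[..., num] += d / 2
            img[..., den] -= d / 2
        elif planted_feature in ("RGB_mean", "lum_mean", "lum_median"):
            img += d
        elif planted_feature == "lum_sd":
            img = 128 + (img - 128) * (1.0 + 0.4 * f[i])
        elif planted_feature == "spatial_freq":
            from scipy.ndimage import uniform_filter
            k = int(np.clip(6 - 2.5 * f[i], 1, 12))
            img = uniform_filter(img, size=(k, k, 1))
        images.append(np.clip(img, 0, 255).astype(np.uint8))
    return images, scores


# ---------------------------------------------------------------------------
# Foreground-task behavior
# ---------------------------------------------------------------------------

def generate_behavior_log(schedule: TrialSchedule, participant_id: str,
                          accuracy: float = 0.716, rt_mean_ms: float = 316.0,
                          rt_sd_ms: float = 20.0, seed: int = 0) -> pd.DataFrame:
    """Simulated responses to the box-opening foreground task.

    Each 3.2 s image presentation alternates 400 ms closed / 400 ms open
    (starting closed), giving 4 openings per trial.  Responses are correct
    (matching side, within the 400 ms open period) with probability
    ``accuracy``; errors respond on the wrong side.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for trial in schedule.df["trial_index"]:
        for opening in range(4):
            side = rng.choice(["L", "R"])
            rt = float(np.clip(rng.normal(rt_mean_ms, rt_sd_ms), 1.0, 400.0))
            if rng.uniform() < accuracy:
                resp = side
            else:
                resp = "L" if side == "R" else "R"
            rows.append((participant_id, int(trial), opening, side, resp, rt))
    return pd.DataFrame(rows, columns=["participant_id", "trial", "opening",
                                       "opening_side", "response_side", "rt_ms"])


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def visual_angle(extent_cm: float, distance_cm: float = 50.0) -> float:
    """Visual angle in degrees subtended by ``extent_cm`` at ``distance_cm``."""
    if extent_cm <= 0 or distance_cm <= 0:
        raise ValidationError("extent and distance must be positive")
    return float(np.degrees(2.0 * np.arctan(extent_cm / (2.0 * distance_cm))))
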