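"""Shared domain types, container I/O, montage geometry and the rating-increment mapping.

The pipeline operates on three core containers:

``EpochsArray``
    Stimulus-locked multichannel EEG epochs (trials x channels x samples) with a
    millisecond time axis, sampling rate and per-trial metadata.  Stored on disk
    as a raw binary payload (``<name>.dat``) plus a JSON sidecar (``<name>.json``)
    so that round trips are bit-exact and self-describing.
``ElectrodeMontage``
    The 64-channel 10-10 montage on an idealized unit sphere (Cz at the apex),
    which supplies the geometry for the spherical-spline current source density
    transform.
``RatingTable``
    Post-experiment 1-9 ratings of each image on two dimensions (arousal and
    time reference), each collected twice; the two presentations are combined
    and discretized into three rating increments which serve as the decoding
    labels.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ShapeError, ValidationError

logger = logging.getLogger("erpdecode")

#: The two rated stimulus dimensions.
DIMENSIONS = ("arousal", "time_reference")

#: Left / right occipito-parietal electrode sets over which the early posterior
#: negativity (EPN) is averaged.
EPN_LEFT = ("O1", "P9", "PO7")
EPN_RIGHT = ("O2", "PO8", "P10")


# ---------------------------------------------------------------------------
# Rating increments
# ---------------------------------------------------------------------------

def bin_rating(raw: int, *, participant_id: str | None = None,
               image_id: int | None = None) -> int:
    """Map a raw 1-9 rating onto its 3-level rating increment.

    1-3 -> 1 (low arousal / present), 4-5 -> 2 (medium / intermediate),
    6-9 -> 3 (high arousal / future).

    Raises :class:`ValidationError` (naming the participant/image when known)
    for anything outside the integer range 1-9.
    """
    if not float(raw).is_integer() or not 1 <= int(raw) <= 9:
        who = ""
        if participant_id is not None or image_id is not None:
            who = f" (participant={participant_id!r}, image={image_id!r})"
        raise ValidationError(f"rating {raw!r} outside integer range 1-9{who}")
    raw = int(raw)
    if raw <= 3:
        return 1
    if raw <= 5:
        return 2
    return 3


def combine_presentations(r1: int, r2: int, **ctx) -> int:
    """Combine the two rating presentations of an image into one 1-9 value.

    The combination rule is the arithmetic mean rounded half-up, which is
    deterministic, order-free and unbiased between the two presentations.
    """
    for r in (r1, r2):
        if not float(r).is_integer() or not 1 <= int(r) <= 9:
            raise ValidationError(f"rating {r!r} outside integer range 1-9")
    combined = int(np.floor((int(r1) + int(r2)) / 2.0 + 0.5))
    return min(9, max(1, combined))


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

#: The 64 scalp channels, in recording order.
CHANNELS_64 = (
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P9", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P10",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
)


@dataclass(frozen=True)
class ElectrodeMontage:
    """Labeled electrode positions on an idealized unit sphere.

    ``positions[i]`` is the unit 3-vector of ``labels[i]`` in a right-handed
    frame with +x to the right ear, +y to the nasion and +z through the vertex
    (Cz).  ``head_radius`` (cm) scales the sphere when physical units are
    needed (the CSD transform divides by its square).
    """

    labels: tuple[str, ...]
    positions: np.ndarray
    head_radius: float = 10.0

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.labels), 3):
            raise ShapeError(f"positions shape {pos.shape} != ({len(self.labels)}, 3)")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValidationError("montage positions must have unit norm")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("duplicate channel labels in montage")
        object.__setattr__(self, "positions", pos)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(f"channel {label!r} not in montage") from None

    def position(self, label: str) -> np.ndarray:
        return self.positions[self.index(label)]

    def subset(self, labels: Sequence[str]) -> "ElectrodeMontage":
        idx = [self.index(l) for l in labels]
        return ElectrodeMontage(tuple(labels), self.positions[idx], self.head_radius)

    def cosine_distances(self) -> np.ndarray:
        """Pairwise cosines of inter-electrode angles, clipped to [-1, 1]."""
        c = self.positions @ self.positions.T
        return np.clip(c, -1.0, 1.0)


def _sph(azimuth_deg: float, elevation_deg: float) -> np.ndarray:
    az = np.deg2rad(azimuth_deg)
    el = np.deg2rad(elevation_deg)
    return np.array([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)])


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` about unit ``axis`` by ``angle`` radians."""
    return (v * np.cos(angle)
            + np.cross(axis, v) * np.sin(angle)
            + axis * np.dot(axis, v) * (1 - np.cos(angle)))


def _arc_point(a: np.ndarray, m: np.ndarray, frac: float) -> np.ndarray:
    """Point a fraction ``frac`` of the way from ``a`` to ``m`` along the
    (generally non-great) circle through ``a``, ``m`` and the mirror image of
    ``a`` across the sagittal plane."""
    b = a * np.array([-1.0, 1.0, 1.0])
    n = np.cross(m - a, b - a)
    n = n / np.linalg.norm(n)
    centre = np.dot(n, a) * n
    u, v = a - centre, m - centre
    ang = np.arctan2(np.linalg.norm(np.cross(u, v)), np.dot(u, v))
    for sign in (1.0, -1.0):
        p = centre + _rotate(u, n, sign * ang)
        if np.linalg.norm(p - m) < 1e-9:
            p = centre + _rotate(u, n, sign * frac * ang)
            return p / np.linalg.norm(p)
    raise RuntimeError("arc interpolation failed")  # pragma: no cover


def _build_positions() -> dict[str, np.ndarray]:
    pos: dict[str, np.ndarray] = {}
    # Equatorial (10%) ring, 18 degrees apart, front = azimuth 90.
    ring = ["Fpz", "Fp1", "AF7", "F7", "FT7", "T7", "TP7", "P7", "PO7", "O1",
            "Oz", "O2", "PO8", "P8", "TP8", "T8", "FT8", "F8", "AF8", "Fp2"]
    ring_az = {}
    for i, lab in enumerate(ring):
        ring_az[lab] = (90 + 18 * i) % 360
        pos[lab] = _sph(ring_az[lab], 0.0)
    # Midline and coronal chains: 22.5 degrees per 10% step up from the equator.
    for lab, az, el in [("AFz", 90, 22.5), ("Fz", 90, 45.0), ("FCz", 90, 67.5),
                        ("CPz", 270, 67.5), ("Pz", 270, 45.0), ("POz", 270, 22.5),
                        ("C5", 180, 22.5), ("C3", 180, 45.0), ("C1", 180, 67.5),
                        ("C2", 0, 67.5), ("C4", 0, 45.0), ("C6", 0, 22.5)]:
        pos[lab] = _sph(az, el)
    pos["Cz"] = np.array([0.0, 0.0, 1.0])
    # Interior rows: equal-arc subdivision of the circle through the row anchors.
    rows = [
        ("AF7", "AFz", ["AF3"]), ("AF8", "AFz", ["AF4"]),
        ("F7", "Fz", ["F5", "F3", "F1"]), ("F8", "Fz", ["F6", "F4", "F2"]),
        ("FT7", "FCz", ["FC5", "FC3", "FC1"]), ("FT8", "FCz", ["FC6", "FC4", "FC2"]),
        ("TP7", "CPz", ["CP5", "CP3", "CP1"]), ("TP8", "CPz", ["CP6", "CP4", "CP2"]),
        ("P7", "Pz", ["P5", "P3", "P1"]), ("P8", "Pz", ["P6", "P4", "P2"]),
        ("PO7", "POz", ["PO3"]), ("PO8", "POz", ["PO4"]),
    ]
    for outer, inner, between in rows:
        steps = len(between) + 1
        for k, lab in enumerate(between, start=1):
            pos[lab] = _arc_point(pos[outer], pos[inner], k / steps)
    # Sites 10% below the equator.
    pos["P9"] = _sph(ring_az["P7"], -22.5)
    pos["P10"] = _sph(ring_az["P8"], -22.5)
    pos["Iz"] = _sph(270, -22.5)
    return pos


def builtin_montage(head_radius: float = 10.0) -> ElectrodeMontage:
    """The 64-channel 10-10 montage on an idealized unit sphere.

    Cz sits exactly at the apex (0, 0, 1); the equator passes through Fpz, T8,
    Oz and T7; each 10% step of the 10-10 system subtends 22.5 degrees, and
    interior electrodes (e.g. F3) lie on equal-arc subdivisions of the circle
    through their row's anchors (F7 - Fz - F8).
    """
    table = _build_positions()
    positions = np.array([table[l] for l in CHANNELS_64])
    return ElectrodeMontage(CHANNELS_64, positions, head_radius)


# ---------------------------------------------------------------------------
# Epochs
# ---------------------------------------------------------------------------

TRIAL_META_COLUMNS = ("image_id", "block", "jitter_s", "retained")


@dataclass
class EpochsArray:
    """Stimulus-locked EEG epochs: trials x channels x samples.

    ``t_start_ms`` is the time of sample 0 relative to stimulus onset
    (negative = baseline).  Sample ``k`` maps to ``t_start_ms + k / fs * 1000``
    ms.  ``units`` is ``"uV"`` for scalp potential and ``"uV/cm^2"`` after the
    CSD transform.
    """

    participant_id: str
    data: np.ndarray
    fs: float
    t_start_ms: float
    channel_labels: tuple[str, ...]
    trial_meta: pd.DataFrame
    units: str = "uV"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 3:
            raise ShapeError(f"epochs data must be 3-D, got shape {self.data.shape}")
        if self.data.shape[1] != len(self.channel_labels):
            raise ShapeError(
                f"{self.data.shape[1]} channels in payload but "
                f"{len(self.channel_labels)} channel labels")
        if len(self.trial_meta) != self.data.shape[0]:
            raise ShapeError(
                f"{len(self.trial_meta)} trial_meta rows for {self.data.shape[0]} trials")
        for col in TRIAL_META_COLUMNS:
            if col not in self.trial_meta.columns:
                raise ValidationError(f"trial_meta missing column {col!r}")

    # -- geometry of the time axis -------------------------------------------------

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Time of each sample in ms relative to stimulus onset."""
        return self.t_start_ms + np.arange(self.n_samples) / self.fs * 1000.0

    def time_index(self, t_ms: float) -> int:
        """Index of the sample nearest to ``t_ms``."""
        idx = int(round((t_ms - self.t_start_ms) * self.fs / 1000.0))
        if not 0 <= idx < self.n_samples:
            raise ValidationError(f"time {t_ms} ms outside epoch "
                                  f"[{self.t_start_ms}, {self.times[-1]:.1f}] ms")
        return idx

    def sample_slice(self, start_ms: float, end_ms: float,
                     inclusive: bool = False) -> slice:
        """Samples covering [start_ms, end_ms), or inclusive of both endpoints'
        nearest samples when ``inclusive`` is set."""
        if end_ms <= start_ms:
            raise ValidationError("empty time window")
        i0 = self.time_index(start_ms)
        i1 = self.time_index(end_ms)
        return slice(i0, i1 + 1 if inclusive else i1)

    # -- convenience ----------------------------------------------------------------

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise ValidationError(f"channel {label!r} not in epochs") from None

    def copy(self) -> "EpochsArray":
        return EpochsArray(self.participant_id, self.data.copy(), self.fs,
                           self.t_start_ms, self.channel_labels,
                           self.trial_meta.copy(), self.units)

    def select_trials(self, idx: Iterable[int]) -> "EpochsArray":
        idx = np.asarray(list(idx), dtype=int)
        return EpochsArray(self.participant_id, self.data[idx], self.fs,
                           self.t_start_ms, self.channel_labels,
                           self.trial_meta.iloc[idx].reset_index(drop=True),
                           self.units)


_SIDE_CAR_REQUIRED = ("fs", "t_start_ms", "channel_labels", "trial_meta", "units",
                      "participant_id", "shape", "dtype")


def save_epochs(epochs: EpochsArray, path: str | Path) -> None:
    """Write the epochs container: raw binary payload + JSON sidecar."""
    base = Path(path).with_suffix("")
    epochs.data.astype(np.float64).tofile(base.with_suffix(".dat"))
    sidecar = {
        "participant_id": epochs.participant_id,
        "fs": epochs.fs,
        "t_start_ms": epochs.t_start_ms,
        "channel_labels": list(epochs.channel_labels),
        "units": epochs.units,
        "shape": list(epochs.data.shape),
        "dtype": "float64",
        "trial_meta": epochs.trial_meta.to_dict(orient="list"),
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar))
    logger.info("wrote epochs %s (%d trials)", base, epochs.n_trials)


def load_epochs(path: str | Path) -> EpochsArray:
    """Read the epochs container written by :func:`save_epochs`."""
    base = Path(path).with_suffix("")
    sidecar_path = base.with_suffix(".json")
    payload_path = base.with_suffix(".dat")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    if not payload_path.exists():
        raise FormatError(f"missing payload {payload_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in _SIDE_CAR_REQUIRED:
        if key not in sidecar:
            raise FormatError(f"sidecar missing required key {key!r}")
    shape = tuple(sidecar["shape"])
    data = np.fromfile(payload_path, dtype=sidecar["dtype"])
    if data.size != int(np.prod(shape)):
        raise FormatError(f"payload has {data.size} values, sidecar shape {shape}")
    data = data.reshape(shape)
    meta = pd.DataFrame(sidecar["trial_meta"])
    return EpochsArray(sidecar["participant_id"], data, sidecar["fs"],
                       sidecar["t_start_ms"], tuple(sidecar["channel_labels"]),
                       meta, sidecar["units"])


# ---------------------------------------------------------------------------
# Ratings
# ---------------------------------------------------------------------------

class RatingTable:
    """Long-format table of raw ratings: one row per participant x image x
    dimension x presentation, ``raw`` in 1-9.

    ``combined()`` collapses the two presentations (mean, round half-up) and
    appends the 3-level increment used as the decoding label.
    """

    COLUMNS = ("participant_id", "image_id", "dimension", "presentation", "raw")

    def __init__(self, df: pd.DataFrame):
        for col in self.COLUMNS:
            if col not in df.columns:
                raise ValidationError(f"rating table missing column {col!r}")
        bad = df[~df["raw"].astype(float).apply(float.is_integer)
                 | (df["raw"] < 1) | (df["raw"] > 9)]
        if len(bad):
            row = bad.iloc[0]
            raise ValidationError(
                f"rating {row['raw']!r} outside 1-9 for participant "
                f"{row['participant_id']!r}, image {row['image_id']!r}")
        unknown = set(df["dimension"]) - set(DIMENSIONS)
        if unknown:
            raise ValidationError(f"unknown rating dimensions {sorted(unknown)}")
        self.df = df.reset_index(drop=True).copy()
        self.df["raw"] = self.df["raw"].astype(int)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RatingTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    def combined(self) -> pd.DataFrame:
        """Per participant x image x dimension: combined 1-9 rating + increment."""
        rows = []
        for (pid, img, dim), grp in self.df.groupby(
                ["participant_id", "image_id", "dimension"], sort=True):
            raws = list(grp.sort_values("presentation")["raw"])
            if len(raws) == 1:
                comb = raws[0]
            else:
                comb = combine_presentations(raws[0], raws[1])
            rows.append((pid, img, dim, comb,
                         bin_rating(comb, participant_id=pid, image_id=img)))
        return pd.DataFrame(rows, columns=["participant_id", "image_id", "dimension",
                                           "combined", "increment"])

    def increments_for(self, participant_id, dimension: str) -> pd.Series:
        comb = self.combined()
        sel = comb[(comb["participant_id"] == participant_id)
                   & (comb["dimension"] == dimension)]
        return sel.set_index("image_id")["increment"]

    def usable(self, participant_id, dimension: str) -> bool:
        """A participant x dimension is usable only with >= 2 distinct increments."""
        return self.increments_for(participant_id, dimension).nunique() >= 2

    def participants(self) -> list:
        return sorted(self.df["participant_id"].unique())


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ComponentWindow:
    """One ERP component definition: where and how it is measured."""
    name: str
    electrodes: tuple[str, ...]
    window_ms: tuple[float, float]
    measure: str  # peak_neg | peak_pos | mean


DEFAULT_COMPONENTS = (
    ComponentWindow("N1", ("FCz",), (50.0, 150.0), "peak_neg"),
    ComponentWindow("N2", ("Pz",), (150.0, 300.0), "peak_neg"),
    ComponentWindow("P3", ("Pz",), (300.0, 700.0), "peak_pos"),
    ComponentWindow("EPN", EPN_LEFT + EPN_RIGHT, (280.0, 320.0), "mean"),
)


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the defaults used throughout."""

    # artifact screening (uV)
    technical_threshold_uv: float = 500.0
    strict_threshold_uv: float = 200.0
    # CSD (spherical spline)
    csd_m: int = 4
    csd_lambda: float = 1e-5
    csd_n_legendre: int = 50
    head_radius_cm: float = 10.0
    # ERP analysis
    components: tuple[ComponentWindow, ...] = DEFAULT_COMPONENTS
    baseline_ms: tuple[float, float] = (-100.0, 0.0)
    # decoding
    window_ms: float = 40.0
    step_ms: float = 20.0
    span_ms: tuple[float, float] = (0.0, 440.0)
    svr_c: float = 0.1
    svr_epsilon: float = 0.1
    folds: int = 10
    repetitions: int = 10
    scale_features: bool = True
    min_trials: int = 16
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")
        if self.repetitions < 1:
            raise ValidationError("repetitions must be >= 1")
        if self.svr_c <= 0:
            raise ValidationError("C must be > 0")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import tomllib
        raw = tomllib.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, value in raw.items():
            if key not in known:
                raise ValidationError(f"unknown config key {key!r}")
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
        kwargs.update(overrides)
        return cls(**kwargs)

    def replace(self, **changes) -> "PipelineConfig":
        return dataclasses.replace(self, **changes)
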