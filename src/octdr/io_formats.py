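"""On-disk conventions for OCT volumes, layer label maps, features and config.

A macular OCT acquisition is handled as an ordered stack of ``K`` grayscale
B-scans (cross-sectional images).  Stacks travel as multi-page TIFF (primary),
NIfTI-1, or a directory of numerically ordered PNG/TIFF slices.  Gray values
are quantized to ``Q`` levels on read; layer label maps use integer codes
0 (background: vitreous/choroid) and 1..12 for the retinal layers from the
nerve fiber layer (NFL, innermost) to the retinal pigment epithelium (RPE).
Per-layer texture descriptors travel as a flat CSV feature table.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import (
    ConfigError,
    FeatureSchemaError,
    LabelValueError,
    MissingPathError,
    ShapeMismatchError,
    UnsupportedFormatError,
)

N_LAYERS = 12

#: Short anatomical names for layers 1..12, inner to outer.
LAYER_NAMES = (
    "NFL", "GCL", "IPL", "INL", "OPL", "ONL",
    "ELM", "MZ", "EZ", "OPR", "IZ", "RPE",
)

FEATURE_DECILE_COLUMNS = tuple(f"d{p}" for p in range(10, 100, 10))
FEATURE_COLUMNS = ("subject_id", "class", "layer") + FEATURE_DECILE_COLUMNS

_SLICE_EXTENSIONS = {".png", ".tif", ".tiff"}


@dataclass
class BScanVolume:
    """Ordered stack of K quantized grayscale B-scans for one eye.

    ``scans`` is a ``K x H x W`` integer array with values in ``[0, Q-1]``.
    Scan index follows anatomical order; the foveal mid scan sits at
    ``floor(K/2)``.  ``voxel_spacing`` ``(dy, dx, dz)`` is carried as
    metadata only and never interpreted.
    """

    scans: np.ndarray
    q_levels: int
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_id: str = ""
    eye: str = "unknown"

    def __post_init__(self) -> None:
        self.scans = np.asarray(self.scans)
        if self.scans.ndim != 3 or self.scans.shape[0] < 1:
            raise ShapeMismatchError(
                f"scans must be a K x H x W stack with K >= 1, got shape "
                f"{self.scans.shape}"
            )
        if not np.issubdtype(self.scans.dtype, np.integer):
            raise ValueError("scans must hold integer gray levels")
        if self.q_levels < 2:
            raise ValueError(f"q_levels must be >= 2, got {self.q_levels}")
        lo, hi = int(self.scans.min()), int(self.scans.max())
        if lo < 0 or hi >= self.q_levels:
            from .errors import GrayLevelError

            raise GrayLevelError(
                f"gray values [{lo}, {hi}] outside [0, {self.q_levels - 1}]"
            )
        if self.eye not in ("left", "right", "unknown"):
            raise ValueError(f"eye must be left/right/unknown, got {self.eye!r}")

    @property
    def n_scans(self) -> int:
        return self.scans.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.scans.shape

    @property
    def mid_index(self) -> int:
        """Index of the foveal mid scan (floor(K/2); 2 for K=5)."""
        return self.scans.shape[0] // 2


@dataclass
class LayerLabelMap:
    """Per-pixel retinal layer labels aligned to a :class:`BScanVolume`.

    0 = background (vitreous above / choroid below), 1..12 = NFL..RPE.
    """

    labels: np.ndarray
    n_layers: int = N_LAYERS

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ShapeMismatchError(
                f"labels must be K x H x W, got shape {self.labels.shape}"
            )
        _validate_labels(self.labels, self.n_layers)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


def _validate_labels(arr: np.ndarray, n_layers: int = N_LAYERS) -> None:
    if not np.issubdtype(arr.dtype, np.integer):
        raise LabelValueError("label maps must be integer-valued")
    lo, hi = int(arr.min()), int(arr.max())
    if lo < 0 or hi > n_layers:
        bad = lo if lo < 0 else hi
        raise LabelValueError(
            f"label value {bad} outside the valid set {{0..{n_layers}}}"
        )


def quantize_stack(raw: np.ndarray, q_levels: int) -> np.ndarray:
    """Quantize a raw gray stack to ``q_levels`` uniform bins.

    Integer input already confined to ``[0, q_levels-1]`` passes through
    unchanged, which makes volume round trips exact.  Otherwise the input
    dynamic range ``[min, max]`` is binned uniformly; a constant stack maps
    to all zeros.  The mapping is monotone by construction.
    """
    raw = np.asarray(raw)
    if q_levels < 2:
        raise ValueError(f"q_levels must be >= 2, got {q_levels}")
    if np.issubdtype(raw.dtype, np.integer):
        lo, hi = int(raw.min()), int(raw.max())
        if 0 <= lo and hi < q_levels:
            return raw.astype(np.int32)
    lo = float(raw.min())
    hi = float(raw.max())
    if hi == lo:
        return np.zeros(raw.shape, dtype=np.int32)
    q = np.floor((raw.astype(np.float64) - lo) / (hi - lo) * q_levels)
    return np.clip(q, 0, q_levels - 1).astype(np.int32)


def _numeric_sort_key(p: Path) -> tuple:
    nums = re.findall(r"\d+", p.stem)
    return (int(nums[-1]) if nums else -1, p.name)


def _load_stack(path: Path) -> np.ndarray:
    """Load a raw (unquantized) K x H x W integer/float stack from disk."""
    path = Path(path)
    if not path.exists():
        raise MissingPathError(f"input path does not exist: {path}")
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in _SLICE_EXTENSIONS),
            key=_numeric_sort_key,
        )
        if not files:
            raise UnsupportedFormatError(f"no PNG/TIFF slices in directory {path}")
        slices = [np.asarray(iio.imread(p)) for p in files]
        shapes = {s.shape for s in slices}
        if len(shapes) > 1:
            raise ShapeMismatchError(
                f"slice shapes differ in {path}: {sorted(shapes)}"
            )
        return np.stack(slices, axis=0)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj)
        if arr.ndim == 2:
            arr = arr[..., None]
        if arr.ndim != 3:
            raise ShapeMismatchError(f"NIfTI must be 2D/3D, got shape {arr.shape}")
        # convention: last NIfTI axis is the scan index
        return np.moveaxis(arr, -1, 0)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ShapeMismatchError(f"TIFF must be 2D/3D, got shape {arr.shape}")
        return arr
    raise UnsupportedFormatError(
        f"unsupported volume container: {path} (expected .tif/.tiff, "
        f".nii/.nii.gz, or a slice directory)"
    )


def read_volume(
    path,
    q_levels: int,
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    subject_id: str = "",
    eye: str = "unknown",
) -> BScanVolume:
    """Read a B-scan stack and quantize it to ``q_levels`` gray levels."""
    raw = _load_stack(Path(path))
    scans = quantize_stack(raw, q_levels)
    return BScanVolume(
        scans=scans,
        q_levels=q_levels,
        voxel_spacing=voxel_spacing,
        subject_id=subject_id or Path(path).stem.split(".")[0],
        eye=eye,
    )


def _write_stack(arr: np.ndarray, path: Path, max_value: int) -> None:
    dtype = np.uint8 if max_value < 256 else np.uint16
    out = arr.astype(dtype)
    suffixes = "".join(path.suffixes).lower()
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out, photometric="minisblack")
    elif suffixes.endswith((".nii", ".nii.gz")):
        img = nib.Nifti1Image(np.moveaxis(out, 0, -1), affine=np.eye(4))
        nib.save(img, str(path))
    elif path.suffix == "":
        path.mkdir(parents=True, exist_ok=True)
        for k in range(out.shape[0]):
            iio.imwrite(path / f"slice_{k:03d}.png", out[k])
    else:
        raise UnsupportedFormatError(
            f"unsupported output container: {path} (use .tif/.tiff, "
            f".nii/.nii.gz, or an extension-less directory path)"
        )


def write_volume(volume: BScanVolume, path) -> None:
    """Write a volume losslessly; ``read_volume`` with the same Q round-trips."""
    path = Path(path)
    if path.suffix and not path.parent.exists():
        raise MissingPathError(f"parent directory does not exist: {path.parent}")
    _write_stack(volume.scans, path, volume.q_levels - 1)


def read_labelmap(path) -> LayerLabelMap:
    raw = _load_stack(Path(path))
    if not np.issubdtype(raw.dtype, np.integer):
        raise LabelValueError(f"label map at {path} is not integer-valued")
    _validate_labels(raw)
    return LayerLabelMap(labels=raw.astype(np.int32))


def write_labelmap(labelmap: LayerLabelMap, path) -> None:
    path = Path(path)
    if path.suffix and not path.parent.exists():
        raise MissingPathError(f"parent directory does not exist: {path.parent}")
    _write_stack(labelmap.labels, path, labelmap.n_layers)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def validate_features(table: pd.DataFrame, warn_monotone: bool = True) -> pd.DataFrame:
    """Check the feature-table schema; warn on non-monotone decile rows."""
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise FeatureSchemaError(f"feature table missing columns: {missing}")
    table = table.loc[:, list(FEATURE_COLUMNS)]
    if warn_monotone and len(table):
        dec = table.loc[:, list(FEATURE_DECILE_COLUMNS)].to_numpy(float)
        bad = np.where(np.any(np.diff(dec, axis=1) < -1e-12, axis=1))[0]
        for i in bad:
            warnings.warn(
                f"non-monotone decile row {table.index[i]} "
                f"(subject {table.iloc[i]['subject_id']}, "
                f"layer {table.iloc[i]['layer']})",
                stacklevel=3,
            )
    return table


def write_features(table: pd.DataFrame, path) -> None:
    table = validate_features(table)
    table.to_csv(path, index=False, float_format="%.17g")


def read_features(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise MissingPathError(f"feature table does not exist: {path}")
    table = pd.read_csv(path)
    return validate_features(table)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

def _merge_dataclass(instance, overrides: dict):
    """Replace dataclass fields from a dict, coercing lists to tuples."""
    if not overrides:
        return instance
    valid = {f.name: f for f in dataclasses.fields(instance)}
    updates = {}
    for key, value in overrides.items():
        if key not in valid:
            raise ConfigError(
                f"unknown config key {key!r} for {type(instance).__name__}"
            )
        current = getattr(instance, key)
        if isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            value = _merge_dataclass(current, value)
        updates[key] = value
    return dataclasses.replace(instance, **updates)


@dataclass
class RunConfig:
    """Whole-pipeline configuration: one object, one YAML file.

    Sections mirror the pipeline stages; each stage owns its dataclass
    (see :mod:`octdr.mgrf`, :mod:`octdr.propagation`, :mod:`octdr.classify`,
    :mod:`octdr.phantom`).
    """

    q_levels: int = 32
    mgrf: "object" = None
    propagation: "object" = None
    ann: "object" = None
    evaluation: "object" = None
    phantom: "object" = None

    def __post_init__(self) -> None:
        # deferred imports: stage modules import io_formats themselves
        from .classify import AnnConfig, EvalConfig
        from .mgrf import MgrfConfig
        from .phantom import PhantomParams
        from .propagation import PropagationConfig

        if self.q_levels < 2:
            raise ConfigError("q_levels must be >= 2")
        if self.mgrf is None:
            self.mgrf = MgrfConfig()
        if self.propagation is None:
            self.propagation = PropagationConfig()
        if self.ann is None:
            self.ann = AnnConfig()
        if self.evaluation is None:
            self.evaluation = EvalConfig()
        if self.phantom is None:
            self.phantom = PhantomParams()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise MissingPathError(f"config file does not exist: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping, got {type(data)}")
        base = cls()
        try:
            return _merge_dataclass(base, data)
        except TypeError as exc:  # bad field types surfaced by dataclass ctor
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
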