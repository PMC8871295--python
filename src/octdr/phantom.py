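"""Synthetic layered-retina phantoms for end-to-end pipeline testing.

Clinical OCT cohorts of this kind are private, so the package ships a
generator that emulates their geometry and the statistical contrast the
feature chain is built to detect: each phantom eye is a stack of K B-scans
holding 12 stacked retinal layers between dark vitreous and choroid, with a
foveal depression strongest in the mid scan, speckle-like gray texture per
layer, and a disease effect ("DR") expressed purely in the *second-order*
spatial statistics of a configurable subset of layers (default OPL and ONL,
layers 5-6) while first-order gray histograms are rank-matched between
classes.  A first-order classifier therefore has nothing to learn from;
discriminating the classes requires exactly the co-occurrence structure the
Gibbs-energy features measure.

The disease effect is a change of spatial correlation lengths (and their
anisotropy) of the layer texture; effect sizes are free parameters of the
phantom, not claims about retinal biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import GeometryError
from .io_formats import (
    BScanVolume,
    LayerLabelMap,
    N_LAYERS,
    write_labelmap,
    write_volume,
)

CLASSES = ("healthy", "DR")

#: Relative layer thickness weights, NFL..RPE (normalized to the retina band).
_DEFAULT_THICKNESS = (1.2, 0.9, 0.9, 0.8, 0.8, 1.5, 0.5, 0.5, 0.5, 0.6, 0.6, 1.0)

#: Mean reflectivity per layer, alternating bright/dark bands as in OCT.
_DEFAULT_MEANS = (0.75, 0.35, 0.62, 0.28, 0.58, 0.22,
                  0.68, 0.40, 0.64, 0.34, 0.70, 0.55)


@dataclass
class PhantomParams:
    """Geometry, texture and class-contrast parameters of the phantom."""

    height: int = 128
    width: int = 256
    n_scans: int = 5
    q_levels: int = 32
    # geometry (pixels / fractions of image height)
    margin_top_frac: float = 0.12
    retina_frac: float = 0.70
    thickness_fracs: tuple[float, ...] = _DEFAULT_THICKNESS
    boundary_wave_amp: float = 1.2
    boundary_wave_cycles: float = 1.5
    fovea_depth: float = 16.0
    fovea_width: float = 22.0
    fovea_scan_decay: float = 0.4  # dip weight = max(0, 1 - decay*|k - mid|)
    # texture
    layer_means: tuple[float, ...] = _DEFAULT_MEANS
    layer_std: float = 0.055
    background_mean: float = 0.08
    background_std: float = 0.02
    speckle_contrast: float = 0.15
    healthy_corr: tuple[float, float] = (1.0, 2.5)   # (rows, cols)
    dr_corr: tuple[float, float] = (3.5, 0.7)
    affected_layers: tuple[int, ...] = (5, 6)
    histogram_matching: bool = True

    def __post_init__(self) -> None:
        if len(self.thickness_fracs) != N_LAYERS:
            raise GeometryError("need 12 thickness fractions")
        if any(t <= 0 for t in self.thickness_fracs):
            raise GeometryError("thickness fractions must be positive")
        if not 0 < self.retina_frac < 1 or not 0 <= self.margin_top_frac < 1:
            raise GeometryError("retina band must fit inside the image")
        if self.margin_top_frac + self.retina_frac >= 1:
            raise GeometryError("retina band + top margin exceed image height")
        if min(self.healthy_corr + self.dr_corr) <= 0:
            raise GeometryError("correlation lengths must be positive")
        bad = set(self.affected_layers) - set(range(1, N_LAYERS + 1))
        if bad:
            raise GeometryError(f"affected_layers outside 1..12: {sorted(bad)}")

    @property
    def mid_index(self) -> int:
        return self.n_scans // 2

    def corr_for(self, class_label: str, layer: int) -> tuple[float, float]:
        if class_label == "DR" and layer in self.affected_layers:
            return self.dr_corr
        return self.healthy_corr


def _dip_weights(params: PhantomParams) -> np.ndarray:
    k = np.arange(params.n_scans)
    return np.maximum(0.0, 1.0 - params.fovea_scan_decay * np.abs(k - params.mid_index))


def generate_layer_geometry(
    params: PhantomParams, scan_index: int, seed: int
) -> np.ndarray:
    """13 non-crossing boundary rows (13 x W), vitreous side first.

    Boundaries carry a smooth low-frequency wave (shared by all scans of a
    volume, so inter-scan geometry differs only through the fovea) plus a
    Gaussian foveal dip that pushes the inner boundaries outward, thinning
    the inner layers near the central column; the dip is strongest at the
    mid scan and decays toward the outer scans.
    """
    if not 0 <= scan_index < params.n_scans:
        raise ValueError(f"scan_index {scan_index} outside [0, {params.n_scans})")
    H, W = params.height, params.width
    rng = np.random.default_rng([seed, 0xB0])  # volume-level geometry stream
    top = params.margin_top_frac * H
    band = params.retina_frac * H
    fr = np.asarray(params.thickness_fracs, dtype=np.float64)
    cum = np.concatenate([[0.0], np.cumsum(fr)]) / fr.sum()
    base = top + band * cum  # 13 flat boundary rows

    cols = np.arange(W)
    phases = rng.uniform(0, 2 * np.pi, size=13)
    # one shared wave shape per volume keeps boundaries parallel enough
    # never to cross under the amplitude/thickness defaults
    wave = params.boundary_wave_amp * np.sin(
        2 * np.pi * params.boundary_wave_cycles * cols / W + phases[:, None]
    )

    dip_w = _dip_weights(params)[scan_index]
    dip_col = np.exp(-0.5 * ((cols - W / 2) / params.fovea_width) ** 2)
    j = np.arange(13)
    dip_j = np.maximum(0.0, 1.0 - j / 5.0)  # inner boundaries move, outer fixed
    dip = params.fovea_depth * dip_w * dip_j[:, None] * dip_col[None, :]

    bounds = base[:, None] + wave + dip
    if np.any(np.diff(bounds, axis=0) < 1.0):
        raise GeometryError(
            "layer boundaries would cross (dip depth / wave amplitude too "
            "large for the configured thicknesses)"
        )
    if bounds.min() < 0 or bounds.max() > H - 1:
        raise GeometryError("boundaries leave the image")
    return bounds


def _labels_from_boundaries(bounds: np.ndarray, H: int) -> np.ndarray:
    rows = np.arange(H)[:, None]
    labels = np.zeros((H, bounds.shape[1]), dtype=np.int32)
    for l in range(1, N_LAYERS + 1):
        inside = (rows >= bounds[l - 1][None, :]) & (rows < bounds[l][None, :])
        labels[inside] = l
    return labels


def _correlated_field(
    shape: tuple[int, int], corr: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean unit-variance stationary field with the given correlation
    lengths (Gaussian-smoothed white noise, renormalized)."""
    white = rng.standard_normal(shape)
    fld = gaussian_filter(white, sigma=corr, mode="reflect")
    sd = fld.std()
    return fld / sd if sd > 0 else fld


def synthesize_layer_texture(
    class_label: str,
    layer: int,
    region_mask: np.ndarray,
    params: PhantomParams,
    seed: int,
) -> np.ndarray:
    """Gray values (float, nominally in [0, 1]) for the masked region.

    The field is correlated speckle: smoothed Gaussian noise with the
    class/layer correlation lengths, modulated by a multiplicative speckle
    term.  With histogram matching on, DR values on affected layers are
    rank-mapped onto an equally sized healthy-marginal sample, so the two
    classes share first-order statistics while keeping their own spatial
    arrangement.
    """
    if class_label not in CLASSES:
        raise ValueError(f"class must be one of {CLASSES}, got {class_label!r}")
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError("region mask is empty")
    rng = np.random.default_rng(seed)
    shape = region_mask.shape
    mean = params.layer_means[layer - 1]
    std = params.layer_std

    corr = params.corr_for(class_label, layer)
    fld = _correlated_field(shape, corr, rng)
    speckle = _correlated_field(shape, (0.8, 0.8), rng)
    values = (mean + std * fld) * (1.0 + params.speckle_contrast * speckle * std / max(mean, 1e-9))
    out = values[region_mask]

    matched = (
        params.histogram_matching
        and class_label == "DR"
        and layer in params.affected_layers
    )
    if matched:
        # reference draw from the healthy marginal, same pixel count
        ref_fld = _correlated_field(shape, params.healthy_corr, rng)
        ref_spk = _correlated_field(shape, (0.8, 0.8), rng)
        ref = (mean + std * ref_fld) * (
            1.0 + params.speckle_contrast * ref_spk * std / max(mean, 1e-9)
        )
        ref_sorted = np.sort(ref[region_mask])
        ranks = np.argsort(np.argsort(out, kind="stable"), kind="stable")
        out = ref_sorted[ranks]
    return out


def generate_phantom_volume(
    class_label: str, params: PhantomParams, seed: int
) -> tuple[BScanVolume, LayerLabelMap]:
    """One phantom eye: quantized B-scan stack plus ground-truth labels.

    Gray values are quantized on the fixed [0, 1] range (not per-volume
    min/max) so histograms are comparable across a cohort.  Texture streams
    are seeded per (scan, layer), geometry per volume: the same
    (class, params, seed) always reproduces the volume bit for bit.
    """
    if class_label not in CLASSES:
        raise ValueError(f"class must be one of {CLASSES}, got {class_label!r}")
    K, H, W = params.n_scans, params.height, params.width
    scans = np.zeros((K, H, W), dtype=np.int32)
    labels = np.zeros((K, H, W), dtype=np.int32)
    for k in range(K):
        bounds = generate_layer_geometry(params, k, seed)
        lab = _labels_from_boundaries(bounds, H)
        bg_rng = np.random.default_rng([seed, k, 0])
        values = params.background_mean + params.background_std * _correlated_field(
            (H, W), (1.0, 1.0), bg_rng
        )
        for layer in range(1, N_LAYERS + 1):
            mask = lab == layer
            if not mask.any():
                continue
            values[mask] = synthesize_layer_texture(
                class_label, layer, mask, params, seed=_texture_seed(seed, k, layer)
            )
        q = np.floor(np.clip(values, 0.0, 1.0 - 1e-12) * params.q_levels)
        scans[k] = q.astype(np.int32)
        labels[k] = lab
    volume = BScanVolume(
        scans=scans, q_levels=params.q_levels,
        subject_id=f"{class_label}_{seed}", eye="unknown",
    )
    return volume, LayerLabelMap(labels=labels)


def _texture_seed(seed: int, scan: int, layer: int) -> list[int]:
    return [seed, scan, layer]


def generate_cohort(
    n_healthy: int,
    n_dr: int,
    params: PhantomParams,
    seed: int,
    out_dir,
) -> pd.DataFrame:
    """Write a phantom cohort to disk and return its manifest.

    Subject ``i`` (healthy first, then DR) is generated with seed
    ``seed + i``; the manifest CSV records subject_id, class, paths and the
    per-subject seed, and regenerating with the same arguments reproduces
    every file.
    """
    if n_healthy < 0 or n_dr < 0:
        raise ValueError("cohort counts must be >= 0")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    class_plan = [("healthy", i) for i in range(n_healthy)]
    class_plan += [("DR", i) for i in range(n_dr)]
    for idx, (cls, within) in enumerate(class_plan):
        subj_seed = seed + idx
        subject_id = f"{'h' if cls == 'healthy' else 'd'}{within:03d}"
        volume, labelmap = generate_phantom_volume(cls, params, subj_seed)
        volume.subject_id = subject_id
        vol_path = out_dir / f"{subject_id}_volume.tif"
        lab_path = out_dir / f"{subject_id}_labels.tif"
        write_volume(volume, vol_path)
        write_labelmap(labelmap, lab_path)
        rows.append(
            {
                "subject_id": subject_id,
                "class": cls,
                "volume_path": str(vol_path),
                "labelmap_path": str(lab_path),
                "seed": subj_seed,
            }
        )
    manifest = pd.DataFrame(
        rows, columns=["subject_id", "class", "volume_path", "labelmap_path", "seed"]
    )
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
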