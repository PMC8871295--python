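"""Second-order Markov-Gibbs random field (MGRF) texture features per layer.

Each B-scan is treated as a realisation of a pairwise MGRF over a
translation-invariant neighborhood system of gray-level co-occurrence
offsets.  For a retinal layer ``l`` and offset ``i`` the model is summarised
by the scaled co-occurrence matrix ``F_i`` (an empirical joint distribution
of gray pairs), its marginal ``f_i``, and the analytical maximum-likelihood
Gibbs potentials

    V_i(q, s) = rho_i * (F_i(q, s) - f_i(q) * f_i(s)),

which vanish exactly when gray levels at the two clique ends are
independent.  Texture is summarised two ways:

* a per-layer, per-offset scalar Gibbs energy
  ``E = sum_{q,s} F(q,s) * (F(q,s) - f(q) f(s))`` (diagnostic), and
* a per-pixel Gibbs energy map — each pixel accumulates the potentials of
  all its in-layer cliques — whose nine deciles E(10)..E(90) form the
  layer's feature vector fed to the classifier.

Co-occurrence statistics are tallied per scan and averaged over the scans
in which the layer appears, so one model describes the layer across the
whole volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyLayerError, GrayLevelError, ShapeMismatchError
from .io_formats import (
    FEATURE_DECILE_COLUMNS,
    BScanVolume,
    LayerLabelMap,
    N_LAYERS,
)

#: The default in-plane neighborhood: the 8 unit and diagonal offsets
#: (delta_row, delta_col).
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (1, -1), (-1, -1), (-1, 1),
)

#: Optional through-plane offsets (delta_scan, delta_row, delta_col).
INTERSLICE_OFFSETS: tuple[tuple[int, int, int], ...] = ((1, 0, 0), (-1, 0, 0))

DECILE_PERCENTS = tuple(range(10, 100, 10))


@dataclass(frozen=True)
class NeighborhoodSystem:
    """Ordered set of clique offsets; optionally extended across scans."""

    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    include_interslice: bool = False

    def __post_init__(self) -> None:
        offs = tuple(tuple(int(v) for v in o) for o in self.offsets)
        if any(o == (0, 0) for o in offs):
            raise ValueError("neighborhood may not contain the (0, 0) offset")
        if len(set(offs)) != len(offs):
            raise ValueError("neighborhood offsets must be distinct")
        object.__setattr__(self, "offsets", offs)

    @property
    def offsets3d(self) -> tuple[tuple[int, int, int], ...]:
        """All offsets as (delta_scan, delta_row, delta_col) triples."""
        planar = tuple((0, dr, dc) for dr, dc in self.offsets)
        return planar + (INTERSLICE_OFFSETS if self.include_interslice else ())


@dataclass
class MgrfConfig:
    """Feature-extraction knobs for the MGRF stage."""

    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    include_interslice: bool = False
    rho: float = 1.0
    marginal_convention: str = "standard"  # or "printed"
    per_scan: bool = False  # concatenate per-scan deciles instead of pooling
    on_empty: str = "raise"  # or "nan"

    def neighborhood(self) -> NeighborhoodSystem:
        return NeighborhoodSystem(self.offsets, self.include_interslice)


@dataclass
class CooccurrenceModel:
    """Per-layer co-occurrence statistics and Gibbs potentials, per offset."""

    layer: int
    offsets: tuple[tuple[int, ...], ...]
    F: np.ndarray          # n_offsets x Q x Q, each page sums to 1
    f: np.ndarray          # n_offsets x Q
    V: np.ndarray          # n_offsets x Q x Q
    rho: np.ndarray        # n_offsets
    pair_counts: np.ndarray  # n_offsets, cliques tallied

    @property
    def q_levels(self) -> int:
        return self.F.shape[1]

    def layer_energies(self) -> np.ndarray:
        """Per-offset scalar Gibbs energies for this layer."""
        return np.array([layer_energy(Fi, fi) for Fi, fi in zip(self.F, self.f)])


@dataclass
class EnergyMap:
    """Per-pixel Gibbs energies on the pixels of one layer across a volume."""

    layer: int
    values: np.ndarray        # flat array, one entry per layer pixel
    indices: tuple[np.ndarray, np.ndarray, np.ndarray]  # (scan, row, col)
    shape: tuple[int, int, int]

    @property
    def count(self) -> int:
        return self.values.size

    def to_dense(self, fill: float = np.nan) -> np.ndarray:
        dense = np.full(self.shape, fill, dtype=np.float64)
        dense[self.indices] = self.values
        return dense


@dataclass
class LayerDescriptor:
    """Nine-decile summary E(10)..E(90) of a layer's Gibbs-energy CDF."""

    layer: int
    deciles: np.ndarray

    def __post_init__(self) -> None:
        self.deciles = np.asarray(self.deciles, dtype=np.float64)
        if self.deciles.shape != (9,):
            raise ValueError(f"expected 9 deciles, got {self.deciles.shape}")


# ---------------------------------------------------------------------------
# Co-occurrence tallies
# ---------------------------------------------------------------------------

def _check_gray(scan: np.ndarray, q_levels: int) -> np.ndarray:
    scan = np.asarray(scan)
    if scan.min() < 0 or scan.max() >= q_levels:
        raise GrayLevelError(
            f"gray values [{int(scan.min())}, {int(scan.max())}] outside "
            f"[0, {q_levels - 1}]"
        )
    return scan


def cooccurrence_counts(
    scan: np.ndarray, mask: np.ndarray, offset: tuple[int, int], q_levels: int
) -> np.ndarray:
    """Integer co-occurrence tally: pairs (g(v), g(v+offset)) with both
    endpoints in-image and in-mask."""
    scan = _check_gray(scan, q_levels)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != scan.shape:
        raise ShapeMismatchError(
            f"mask shape {mask.shape} != scan shape {scan.shape}"
        )
    dr, dc = offset
    H, W = scan.shape
    r0, r1 = max(0, -dr), H - max(0, dr)
    c0, c1 = max(0, -dc), W - max(0, dc)
    counts = np.zeros((q_levels, q_levels), dtype=np.int64)
    if r0 >= r1 or c0 >= c1:
        return counts
    src = (slice(r0, r1), slice(c0, c1))
    dst = (slice(r0 + dr, r1 + dr), slice(c0 + dc, c1 + dc))
    valid = mask[src] & mask[dst]
    a = scan[src][valid]
    b = scan[dst][valid]
    np.add.at(counts, (a, b), 1)
    return counts


def cooccurrence(
    scan: np.ndarray, mask: np.ndarray, offset: tuple[int, int], q_levels: int
) -> tuple[np.ndarray, int]:
    """Normalized co-occurrence matrix F and the number of cliques tallied.

    With no qualifying pair the zero matrix and count 0 are returned.
    """
    counts = cooccurrence_counts(scan, mask, offset, q_levels)
    n = int(counts.sum())
    if n == 0:
        return np.zeros_like(counts, dtype=np.float64), 0
    return counts / n, n


def marginal(F: np.ndarray, convention: str = "standard") -> np.ndarray:
    """Gray-level marginal of a co-occurrence matrix.

    ``standard`` (default): row sums, a true probability distribution —
    the convention under which the potentials vanish for independent gray
    levels.  ``printed`` keeps an extra 1/Q factor (the marginal then sums
    to 1/Q); exposed for auditability only.
    """
    F = np.asarray(F, dtype=np.float64)
    f = F.sum(axis=1)
    if convention == "printed":
        return f / F.shape[0]
    if convention != "standard":
        raise ValueError(f"unknown marginal convention {convention!r}")
    return f


def potentials(F: np.ndarray, f: np.ndarray, rho: float = 1.0) -> np.ndarray:
    """Analytical ML Gibbs potentials V(q,s) = rho * (F(q,s) - f(q) f(s))."""
    F = np.asarray(F, dtype=np.float64)
    f = np.asarray(f, dtype=np.float64)
    return rho * (F - np.outer(f, f))


def layer_energy(F: np.ndarray, f: np.ndarray) -> float:
    """Scalar layer Gibbs energy: sum of F(q,s) * (F(q,s) - f(q) f(s))."""
    F = np.asarray(F, dtype=np.float64)
    f = np.asarray(f, dtype=np.float64)
    return float(np.sum(F * (F - np.outer(f, f))))


def _interslice_cooccurrence(
    scans: np.ndarray,
    layer_mask: np.ndarray,
    offset: tuple[int, int, int],
    q_levels: int,
) -> tuple[np.ndarray, int]:
    """Through-plane tally over the whole volume, normalized once."""
    ds, dr, dc = offset
    K = scans.shape[0]
    counts = np.zeros((q_levels, q_levels), dtype=np.int64)
    for k in range(K):
        k2 = k + ds
        if not 0 <= k2 < K:
            continue
        a2d, b2d = scans[k], scans[k2]
        H, W = a2d.shape
        r0, r1 = max(0, -dr), H - max(0, dr)
        c0, c1 = max(0, -dc), W - max(0, dc)
        if r0 >= r1 or c0 >= c1:
            continue
        src = (slice(r0, r1), slice(c0, c1))
        dst = (slice(r0 + dr, r1 + dr), slice(c0 + dc, c1 + dc))
        valid = layer_mask[k][src] & layer_mask[k2][dst]
        np.add.at(counts, (a2d[src][valid], b2d[dst][valid]), 1)
    n = int(counts.sum())
    if n == 0:
        return np.zeros_like(counts, dtype=np.float64), 0
    return counts / n, n


def pooled_layer_cooccurrence(
    volume: BScanVolume,
    labels: LayerLabelMap,
    layer: int,
    nbhd: NeighborhoodSystem | None = None,
    rho: float | Sequence[float] = 1.0,
    convention: str = "standard",
) -> CooccurrenceModel:
    """Build the layer's MGRF model pooled across B-scans.

    Per in-plane offset, each scan containing the layer contributes its own
    normalized co-occurrence matrix; the pooled ``F_i`` is their unweighted
    mean.  Through-plane offsets (if enabled) are tallied volume-wide.
    """
    nbhd = nbhd or NeighborhoodSystem()
    if labels.shape != volume.shape:
        raise ShapeMismatchError(
            f"label shape {labels.shape} != volume shape {volume.shape}"
        )
    if not 1 <= layer <= labels.n_layers:
        raise ValueError(f"layer must be in 1..{labels.n_layers}, got {layer}")
    Q = volume.q_levels
    layer_mask = labels.labels == layer
    present = [k for k in range(volume.n_scans) if layer_mask[k].any()]
    if not present:
        raise EmptyLayerError(f"layer {layer} absent from every scan")

    offsets3d = nbhd.offsets3d
    rho_arr = np.broadcast_to(np.asarray(rho, dtype=np.float64), (len(offsets3d),)).copy()
    F_all = np.zeros((len(offsets3d), Q, Q))
    counts_all = np.zeros(len(offsets3d), dtype=np.int64)
    for i, off in enumerate(offsets3d):
        ds, dr, dc = off
        if ds == 0:
            mats, total = [], 0
            for k in present:
                Fk, nk = cooccurrence(volume.scans[k], layer_mask[k], (dr, dc), Q)
                mats.append(Fk)
                total += nk
            F_all[i] = np.mean(mats, axis=0)
            counts_all[i] = total
        else:
            F_all[i], counts_all[i] = _interslice_cooccurrence(
                volume.scans, layer_mask, off, Q
            )
    f_all = np.stack([marginal(F, convention) for F in F_all])
    V_all = np.stack(
        [potentials(F, f, r) for F, f, r in zip(F_all, f_all, rho_arr)]
    )
    return CooccurrenceModel(
        layer=layer,
        offsets=offsets3d,
        F=F_all,
        f=f_all,
        V=V_all,
        rho=rho_arr,
        pair_counts=counts_all,
    )


# ---------------------------------------------------------------------------
# Per-pixel energies and descriptors
# ---------------------------------------------------------------------------

def pixel_energies(
    volume: BScanVolume,
    labels: LayerLabelMap,
    layer: int,
    model: CooccurrenceModel,
    normalize: bool = False,
) -> EnergyMap:
    """Gibbs energy of every pixel in the layer.

    A pixel's energy is the sum of ``V_i(g(v), g(v+offset))`` over all
    offsets whose far endpoint lies in-image and in the same layer.  Pixels
    with no in-layer neighbor get energy 0.  ``normalize=True`` divides by
    the number of contributing cliques instead (off by default: the Gibbs
    energy of a pixel is the plain sum of its clique potentials).
    """
    if model.layer != layer:
        raise ValueError(f"model built for layer {model.layer}, not {layer}")
    K, H, W = volume.shape
    scans = volume.scans
    layer_mask = labels.labels == layer
    energy = np.zeros((K, H, W), dtype=np.float64)
    nclique = np.zeros((K, H, W), dtype=np.int64)
    for i, (ds, dr, dc) in enumerate(model.offsets):
        Vi = model.V[i]
        for k in range(K):
            k2 = k + ds
            if not 0 <= k2 < K:
                continue
            r0, r1 = max(0, -dr), H - max(0, dr)
            c0, c1 = max(0, -dc), W - max(0, dc)
            if r0 >= r1 or c0 >= c1:
                continue
            src = (slice(r0, r1), slice(c0, c1))
            dst = (slice(r0 + dr, r1 + dr), slice(c0 + dc, c1 + dc))
            valid = layer_mask[k][src] & layer_mask[k2][dst]
            contrib = np.where(valid, Vi[scans[k][src], scans[k2][dst]], 0.0)
            energy[k][src] += contrib
            nclique[k][src] += valid
    if normalize:
        with np.errstate(invalid="ignore"):
            energy = np.where(nclique > 0, energy / np.maximum(nclique, 1), 0.0)
    idx = np.nonzero(layer_mask)
    return EnergyMap(layer=layer, values=energy[idx], indices=idx, shape=(K, H, W))


def decile_descriptor(energies: EnergyMap) -> LayerDescriptor:
    """Nine deciles of the energy CDF, linear interpolation between order
    statistics (inclusive endpoints)."""
    if energies.count == 0:
        raise EmptyLayerError(f"layer {energies.layer} has no pixels")
    dec = np.percentile(energies.values, DECILE_PERCENTS, method="linear")
    return LayerDescriptor(layer=energies.layer, deciles=dec)


def extract_volume_features(
    volume: BScanVolume,
    labels: LayerLabelMap,
    config: MgrfConfig | None = None,
    class_label: str = "",
) -> pd.DataFrame:
    """Full per-volume feature table: 12 layers x 9 Gibbs-energy deciles.

    Default pools co-occurrence statistics over scans (one row per layer).
    ``config.per_scan`` instead emits one row per (layer, scan) with deciles
    of that scan's energies under the pooled potentials, giving a
    9*K-dimensional descriptor per layer after concatenation.
    """
    config = config or MgrfConfig()
    nbhd = config.neighborhood()
    rows = []
    empty: list[int] = []
    for layer in range(1, labels.n_layers + 1):
        try:
            model = pooled_layer_cooccurrence(
                volume, labels, layer, nbhd, config.rho, config.marginal_convention
            )
            emap = pixel_energies(volume, labels, layer, model)
        except EmptyLayerError:
            if config.on_empty == "nan":
                if config.per_scan:
                    for k in range(volume.n_scans):
                        rows.append(_feature_row(volume, class_label, layer,
                                                 np.full(9, np.nan), scan=k))
                else:
                    rows.append(_feature_row(volume, class_label, layer,
                                             np.full(9, np.nan)))
                continue
            empty.append(layer)
            continue
        if config.per_scan:
            for k in range(volume.n_scans):
                in_scan = emap.indices[0] == k
                vals = emap.values[in_scan]
                dec = (np.percentile(vals, DECILE_PERCENTS, method="linear")
                       if vals.size else np.full(9, np.nan))
                rows.append(_feature_row(volume, class_label, layer, dec, scan=k))
        else:
            desc = decile_descriptor(emap)
            rows.append(_feature_row(volume, class_label, layer, desc.deciles))
    if empty:
        raise EmptyLayerError(f"layers with no pixels: {empty}")
    return pd.DataFrame(rows)


def _feature_row(volume, class_label, layer, deciles, scan=None) -> dict:
    row = {"subject_id": volume.subject_id, "class": class_label, "layer": layer}
    if scan is not None:
        row["scan"] = scan
    row.update(dict(zip(FEATURE_DECILE_COLUMNS, np.asarray(deciles, float))))
    return row
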