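"""Shape-prior propagation of a labeled mid B-scan through the volume.

The macular mid scan crosses the fovea and serves as a patient-specific
atlas: its 12-layer segmentation is carried outward scan by scan.  Each hop
(1) densely registers the unlabeled target scan to its already-labeled
neighbor, (2) for every target pixel v looks at a window around the
corresponding reference pixel v', keeps the window pixels whose gray level
lies within a threshold tau of g(v), expanding the window when none
qualify, and (3) assigns the label with the highest incidence among the
qualifying pixels (the intensity-conditioned label posterior).

Two deterministic rules close the procedure:

* center-match shortcut — when g(v') equals g(v) exactly (gray levels are
  quantized, so exact agreement is common between neighboring scans), the
  correspondence is trusted and v takes v''s label outright.  This makes
  propagation over identical scans an exact fixed point for any label map.
* tie/fallback — posterior ties prefer the label of v', then the smaller
  label index; if window expansion exhausts the maximum size without a
  qualifying pixel, v falls back to the label of v' with confidence 0.

Background (label 0) participates in the vote like any retinal layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.registration import optical_flow_ilk, optical_flow_tvl1

from .errors import ConfigError, ShapeMismatchError
from .io_formats import BScanVolume, LayerLabelMap, N_LAYERS


@dataclass
class PropagationConfig:
    """Windowed-voting and registration parameters for label propagation."""

    tau: int = 2                       # gray-level threshold, quantized units
    initial_window: tuple[int, int] = (11, 11)
    expand_step: int = 4               # growth per side per expansion
    max_window: tuple[int, int] = (31, 31)
    method: str = "ilk"                # dense registration: "ilk" or "tvl1"
    radius: int = 15                   # ilk window radius
    num_warp: int = 5
    prefilter: bool = True

    def __post_init__(self) -> None:
        for w in (self.initial_window, self.max_window):
            if w[0] % 2 == 0 or w[1] % 2 == 0:
                raise ConfigError(f"windows must be odd-sized, got {w}")
        if (self.initial_window[0] > self.max_window[0]
                or self.initial_window[1] > self.max_window[1]):
            raise ConfigError("initial window exceeds max window")
        if self.tau < 0:
            raise ConfigError("tau must be >= 0")
        if self.expand_step <= 0:
            raise ConfigError("expand_step must be positive")
        if self.method not in ("ilk", "tvl1"):
            raise ConfigError(f"unknown registration method {self.method!r}")


def register_nonrigid(
    moving: np.ndarray, fixed: np.ndarray, config: PropagationConfig | None = None
) -> np.ndarray:
    """Dense displacement field mapping moving-scan to fixed-scan coordinates.

    Returns a ``2 x H x W`` array ``d`` such that the content at ``v`` in
    the moving scan corresponds to ``v + d[:, v]`` in the fixed scan.
    Identical inputs give a (near-)zero field; constant inputs give a zero
    field (no gradient signal, regularization dominates).
    """
    config = config or PropagationConfig()
    moving = np.asarray(moving, dtype=np.float64)
    fixed = np.asarray(fixed, dtype=np.float64)
    if moving.shape != fixed.shape:
        raise ShapeMismatchError(
            f"moving shape {moving.shape} != fixed shape {fixed.shape}"
        )
    if np.ptp(moving) == 0 and np.ptp(fixed) == 0:
        return np.zeros((2,) + moving.shape)
    if config.method == "ilk":
        flow = optical_flow_ilk(
            moving, fixed, radius=config.radius, num_warp=config.num_warp,
            prefilter=config.prefilter,
        )
    else:
        flow = optical_flow_tvl1(moving, fixed, num_warp=config.num_warp,
                                 prefilter=config.prefilter)
    return np.nan_to_num(np.asarray(flow), nan=0.0, posinf=0.0, neginf=0.0)


def _window_offsets(half_r: int, half_c: int) -> np.ndarray:
    dr, dc = np.meshgrid(
        np.arange(-half_r, half_r + 1), np.arange(-half_c, half_c + 1),
        indexing="ij",
    )
    return np.stack([dr.ravel(), dc.ravel()], axis=1)


def _window_schedule(config: PropagationConfig) -> list[tuple[int, int]]:
    sizes = [config.initial_window]
    while sizes[-1] != config.max_window:
        nr = min(sizes[-1][0] + 2 * config.expand_step, config.max_window[0])
        nc = min(sizes[-1][1] + 2 * config.expand_step, config.max_window[1])
        sizes.append((nr, nc))
    return sizes


def propagate_step(
    target_scan: np.ndarray,
    ref_scan: np.ndarray,
    ref_labels: np.ndarray,
    config: PropagationConfig | None = None,
    displacement: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Label one scan from its labeled neighbor; returns (labels, confidence).

    Confidence is the posterior (incidence fraction) of the assigned label
    among the qualifying window pixels; 0 on the exhaustion fallback.
    """
    config = config or PropagationConfig()
    target_scan = np.asarray(target_scan)
    ref_scan = np.asarray(ref_scan)
    ref_labels = np.asarray(ref_labels)
    if not (target_scan.shape == ref_scan.shape == ref_labels.shape):
        raise ShapeMismatchError("target, reference and labels must share a shape")
    H, W = target_scan.shape
    n_labels = N_LAYERS + 1

    if displacement is None:
        displacement = register_nonrigid(target_scan, ref_scan, config)
    rows, cols = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    vr = np.clip(np.rint(rows + displacement[0]), 0, H - 1).astype(np.intp)
    vc = np.clip(np.rint(cols + displacement[1]), 0, W - 1).astype(np.intp)

    center_gray = ref_scan[vr, vc]
    center_label = ref_labels[vr, vc]
    exact = center_gray == target_scan

    tgt_flat = target_scan.ravel()
    vr_flat, vc_flat = vr.ravel(), vc.ravel()
    n_pix = H * W
    votes = np.zeros(n_labels * n_pix, dtype=np.int64)
    pix_idx = np.arange(n_pix)

    prev_half: tuple[int, int] | None = None
    for size in _window_schedule(config):
        half = (size[0] // 2, size[1] // 2)
        offs = _window_offsets(*half)
        if prev_half is None:
            new = offs
            sel = pix_idx
        else:
            # ring: offsets of the grown window outside the previous one;
            # only pixels with zero qualifiers so far need the expansion
            ring = (np.abs(offs[:, 0]) > prev_half[0]) | (
                np.abs(offs[:, 1]) > prev_half[1]
            )
            new = offs[ring]
            unresolved = votes.reshape(n_labels, n_pix).sum(axis=0) == 0
            if not unresolved.any():
                break
            sel = pix_idx[unresolved]
        for dr, dc in new:
            nr = vr_flat[sel] + dr
            nc = vc_flat[sel] + dc
            inb = (nr >= 0) & (nr < H) & (nc >= 0) & (nc < W)
            if not inb.any():
                continue
            s = sel[inb]
            nri, nci = nr[inb], nc[inb]
            qual = np.abs(ref_scan[nri, nci].astype(np.int64)
                          - tgt_flat[s].astype(np.int64)) <= config.tau
            if not qual.any():
                continue
            lab = ref_labels[nri[qual], nci[qual]]
            votes += np.bincount(
                lab.astype(np.int64) * n_pix + s[qual],
                minlength=n_labels * n_pix,
            )
        prev_half = half

    votes2 = votes.reshape(n_labels, n_pix)
    totals = votes2.sum(axis=0)
    max_votes = votes2.max(axis=0)

    center_flat = center_label.ravel().astype(np.intp)
    center_votes = votes2[center_flat, pix_idx]
    # argmax with ties broken toward the label of v', then smallest index
    arg = votes2.argmax(axis=0)
    tie_to_center = center_votes == max_votes
    chosen = np.where(tie_to_center, center_flat, arg)
    # center-match shortcut overrides the vote
    chosen = np.where(exact.ravel(), center_flat, chosen)

    with np.errstate(invalid="ignore", divide="ignore"):
        conf = np.where(totals > 0,
                        votes2[chosen, pix_idx] / np.maximum(totals, 1), 0.0)
    # exhaustion fallback: no qualifying pixel anywhere up to max window
    exhausted = totals == 0
    chosen = np.where(exhausted, center_flat, chosen)
    conf = np.where(exhausted, 0.0, conf)

    return (chosen.reshape(H, W).astype(ref_labels.dtype),
            conf.reshape(H, W))


def propagate_volume(
    volume: BScanVolume,
    mid_labels: np.ndarray,
    config: PropagationConfig | None = None,
    return_confidence: bool = False,
):
    """Propagate the mid-scan segmentation to the whole stack.

    The mid scan keeps its labels verbatim; scans on either side are
    labeled outward, each from its already-labeled neighbor.
    """
    config = config or PropagationConfig()
    mid_labels = np.asarray(mid_labels)
    K, H, W = volume.shape
    if mid_labels.shape != (H, W):
        raise ShapeMismatchError(
            f"mid labels shape {mid_labels.shape} != scan shape {(H, W)}"
        )
    labels = np.zeros((K, H, W), dtype=np.int32)
    conf = np.ones((K, H, W), dtype=np.float64)
    mid = volume.mid_index
    labels[mid] = mid_labels
    for i in range(mid - 1, -1, -1):
        labels[i], conf[i] = propagate_step(
            volume.scans[i], volume.scans[i + 1], labels[i + 1], config
        )
    for i in range(mid + 1, K):
        labels[i], conf[i] = propagate_step(
            volume.scans[i], volume.scans[i - 1], labels[i - 1], config
        )
    result = LayerLabelMap(labels=labels)
    if return_confidence:
        return result, conf
    return result
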