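import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octdr import mgrf
from octdr.errors import EmptyLayerError, GrayLevelError
from octdr.io_formats import BScanVolume, LayerLabelMap
from octdr.mgrf import (
    DEFAULT_OFFSETS,
    CooccurrenceModel,
    MgrfConfig,
    NeighborhoodSystem,
    cooccurrence,
    cooccurrence_counts,
    decile_descriptor,
    extract_volume_features,
    layer_energy,
    marginal,
    pixel_energies,
    pooled_layer_cooccurrence,
    potentials,
)


def brute_force_counts(scan, mask, offset, q):
    """Independent double-loop tally of in-mask, in-image gray pairs."""
    dr, dc = offset
    H, W = scan.shape
    counts = np.zeros((q, q), dtype=np.int64)
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W and mask[r, c] and mask[r2, c2]:
                counts[scan[r, c], scan[r2, c2]] += 1
    return counts


def test_cooccurrence_matches_bruteforce_on_random_masks():
    """Vectorized tally equals the double-loop oracle exactly, all offsets."""
    rng = np.random.default_rng(42)
    for _ in range(50):
        scan = rng.integers(0, 8, size=(16, 16))
        mask = rng.random((16, 16)) < 0.7
        for off in DEFAULT_OFFSETS:
            expected = brute_force_counts(scan, mask, off, 8)
            got = cooccurrence_counts(scan, mask, off, 8)
            np.testing.assert_array_equal(got, expected)


def test_cooccurrence_edge_cases():
    # constant image: all mass at (0, 0)
    F, n = cooccurrence(np.zeros((4, 4), int), np.ones((4, 4), bool), (0, 1), 2)
    assert F[0, 0] == 1.0 and F.sum() == 1.0 and n == 12
    # empty mask
    F, n = cooccurrence(np.zeros((4, 4), int), np.zeros((4, 4), bool), (0, 1), 2)
    assert n == 0 and np.all(F == 0)
    # out-of-range gray level
    with pytest.raises(GrayLevelError):
        cooccurrence(np.full((2, 2), 5), np.ones((2, 2), bool), (0, 1), 4)


def test_worked_two_by_two_example():
    """Hand-enumerated 2x2 image: F, marginal, potentials and energy."""
    scan = np.array([[0, 1], [1, 0]])
    mask = np.ones((2, 2), bool)
    F, n = cooccurrence(scan, mask, (0, 1), 2)
    assert n == 2
    np.testing.assert_allclose(F, [[0, 0.5], [0.5, 0]])
    f = marginal(F)
    np.testing.assert_allclose(f, [0.5, 0.5])
    V = potentials(F, f, rho=1.0)
    np.testing.assert_allclose(V, [[-0.25, 0.25], [0.25, -0.25]])
    np.testing.assert_allclose(potentials(F, f, rho=2.0), 2 * V)
    assert layer_energy(F, f) == pytest.approx(0.25)


def test_marginal_conventions_and_product_structure(rng):
    u = rng.random(8)
    u /= u.sum()
    F = np.outer(u, u)
    np.testing.assert_allclose(marginal(F), u)
    np.testing.assert_allclose(marginal(F, "printed"), u / 8)
    # identity/Q: perfectly correlated uniform
    np.testing.assert_allclose(marginal(np.eye(4) / 4), np.full(4, 0.25))
    # independence: zero potentials, zero energy
    np.testing.assert_allclose(potentials(F, u), 0, atol=1e-15)
    assert layer_energy(F, u) == pytest.approx(0.0, abs=1e-15)


def test_energy_invariant_under_gray_relabeling(rng):
    """Permuting the gray scale permutes the terms of the energy sum."""
    F = rng.random((6, 6))
    F /= F.sum()
    f = marginal(F)
    perm = rng.permutation(6)
    Fp = F[np.ix_(perm, perm)]
    assert layer_energy(Fp, marginal(Fp)) == pytest.approx(layer_energy(F, f))


def test_offset_reversal_transposes_cooccurrence(rng):
    scan = rng.integers(0, 8, size=(32, 32))
    mask = np.ones((32, 32), bool)
    for dr, dc in [(0, 1), (1, 0), (1, 1), (1, -1)]:
        F1, _ = cooccurrence(scan, mask, (dr, dc), 8)
        F2, _ = cooccurrence(scan, mask, (-dr, -dc), 8)
        np.testing.assert_array_equal(F2, F1.T)


def test_translation_invariance(rng):
    """Shifting content and mask together leaves interior tallies unchanged."""
    scan = rng.integers(0, 8, size=(20, 20))
    mask = np.zeros((20, 20), bool)
    mask[4:14, 4:14] = True
    shifted_scan = np.roll(scan, (3, 2), axis=(0, 1))
    shifted_mask = np.roll(mask, (3, 2), axis=(0, 1))
    for off in DEFAULT_OFFSETS:
        a = cooccurrence_counts(scan, mask, off, 8)
        b = cooccurrence_counts(shifted_scan, shifted_mask, off, 8)
        np.testing.assert_array_equal(a, b)


def _flat_volume(scan, k=3, layer=1):
    scans = np.stack([scan] * k)
    labels = np.full(scans.shape, layer, dtype=np.int32)
    vol = BScanVolume(scans=scans.astype(np.int32), q_levels=int(scan.max()) + 1)
    return vol, LayerLabelMap(labels=labels)


def test_pooled_cooccurrence_identical_scans_equals_single_scan(rng):
    scan = rng.integers(0, 8, size=(12, 12))
    vol, labels = _flat_volume(scan, k=3)
    model = pooled_layer_cooccurrence(vol, labels, 1)
    single, _ = cooccurrence(scan, np.ones_like(scan, bool), (0, 1), 8)
    np.testing.assert_allclose(model.F[0], single)
    # normalization invariant
    assert np.allclose(model.F.sum(axis=(1, 2)), 1.0, atol=1e-9)
    assert np.allclose(model.f.sum(axis=1), 1.0, atol=1e-9)


def test_pooled_checkerboard_horizontal_offset():
    board = np.indices((4, 4)).sum(axis=0) % 2
    vol, labels = _flat_volume(board, k=2)
    model = pooled_layer_cooccurrence(vol, labels, 1)
    F = model.F[0]  # offset (0, 1)
    np.testing.assert_allclose(F, [[0, 0.5], [0.5, 0]])


def test_pooled_empty_layer_raises(rng):
    vol, labels = _flat_volume(rng.integers(0, 4, size=(6, 6)))
    with pytest.raises(EmptyLayerError, match="7"):
        pooled_layer_cooccurrence(vol, labels, 7)


def test_independence_limit_bounds_potentials():
    """On a large i.i.d. uniform scan every potential entry is tiny."""
    rng = np.random.default_rng(7)
    scan = rng.integers(0, 8, size=(512, 512))
    mask = np.ones_like(scan, bool)
    worst = 0.0
    for off in DEFAULT_OFFSETS:
        F, _ = cooccurrence(scan, mask, off, 8)
        f = marginal(F)
        worst = max(worst, np.abs(F - np.outer(f, f)).max())
    assert worst <= 5e-3


def test_pixel_energies_hand_cases():
    # zero potentials -> zero energies everywhere
    scan = np.array([[0, 1, 0]])
    labels = np.ones((1, 1, 3), np.int32)
    vol = BScanVolume(scans=scan[None].astype(np.int32), q_levels=2)
    lmap = LayerLabelMap(labels=labels)
    model = CooccurrenceModel(
        layer=1,
        offsets=((0, 0, 1), (0, 0, -1)),
        F=np.zeros((2, 2, 2)),
        f=np.zeros((2, 2)),
        V=np.zeros((2, 2, 2)),
        rho=np.ones(2),
        pair_counts=np.zeros(2, int),
    )
    emap = pixel_energies(vol, lmap, 1, model)
    np.testing.assert_allclose(emap.values, 0.0)
    # hand-computed V from the 2x2 example; 3-pixel layer [0,1,0]:
    # center pixel has two in-layer cliques, both V(1,0)=0.25 -> 0.5
    V = np.array([[-0.25, 0.25], [0.25, -0.25]])
    model.V = np.stack([V, V])
    emap = pixel_energies(vol, lmap, 1, model)
    dense = emap.to_dense()
    assert dense[0, 0, 1] == pytest.approx(0.5)
    # edge pixels: one clique each, V(0,1)=0.25
    assert dense[0, 0, 0] == pytest.approx(0.25)
    # single-pixel layer has no in-layer neighbors -> energy 0
    lone = LayerLabelMap(labels=np.array([[[1, 0, 0]]], np.int32))
    emap = pixel_energies(vol, lone, 1, model)
    np.testing.assert_allclose(emap.values, [0.0])


def _energy_map(values):
    values = np.asarray(values, float)
    idx = (np.zeros(values.size, int), np.zeros(values.size, int),
           np.arange(values.size))
    return mgrf.EnergyMap(layer=1, values=values, indices=idx,
                          shape=(1, 1, values.size))


def sort_interpolate_percentile(values, p):
    """Brute-force linear interpolation between closest order statistics."""
    v = np.sort(np.asarray(values, float))
    h = (len(v) - 1) * p / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def test_deciles_match_sort_interpolate_oracle():
    values = np.arange(1, 101)[np.random.default_rng(3).permutation(100)]
    desc = decile_descriptor(_energy_map(values))
    expected = [sort_interpolate_percentile(values, p) for p in range(10, 100, 10)]
    np.testing.assert_allclose(desc.deciles, expected)
    # constant map -> all deciles equal
    np.testing.assert_allclose(decile_descriptor(_energy_map(np.full(5, 3.3))).deciles, 3.3)
    # translation equivariance
    shifted = decile_descriptor(_energy_map(values + 2.5))
    np.testing.assert_allclose(shifted.deciles, desc.deciles + 2.5)
    with pytest.raises(EmptyLayerError):
        decile_descriptor(_energy_map(np.array([])))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40))
def test_decile_monotonicity_property(values):
    desc = decile_descriptor(_energy_map(np.array(values)))
    assert np.all(np.diff(desc.deciles) >= -1e-12)


def test_extract_features_schema_and_determinism(healthy_volume):
    vol, labels = healthy_volume
    t1 = extract_volume_features(vol, labels, class_label="healthy")
    t2 = extract_volume_features(vol, labels, class_label="healthy")
    assert len(t1) == 12
    dec = t1[[f"d{p}" for p in range(10, 100, 10)]].to_numpy()
    assert np.isfinite(dec).all()
    assert np.all(np.diff(dec, axis=1) >= -1e-12)
    pd.testing.assert_frame_equal(t1, t2)


def test_extract_features_per_scan_mode(healthy_volume):
    vol, labels = healthy_volume
    t = extract_volume_features(vol, labels, MgrfConfig(per_scan=True))
    assert len(t) == 12 * vol.n_scans
    assert set(t["scan"]) == set(range(vol.n_scans))


def test_extract_features_iid_noise_deciles_near_zero():
    """Independence limit through the full feature chain: on an i.i.d.
    uniform volume every Gibbs-energy decile is close to zero."""
    rng = np.random.default_rng(11)
    K, H, W = 2, 128, 128  # >= 2048 pixels per layer
    scans = rng.integers(0, 8, size=(K, H, W), dtype=np.int32)
    labels = np.zeros((K, H, W), np.int32)
    for l in range(1, 13):  # 12 horizontal bands of 10 rows; remainder joins 12
        labels[:, (l - 1) * 10:(l * 10) + (0 if l < 12 else H), :] = l
    vol = BScanVolume(scans=scans, q_levels=8)
    t = extract_volume_features(vol, LayerLabelMap(labels=labels))
    dec = t[[f"d{p}" for p in range(10, 100, 10)]].to_numpy()
    assert np.abs(dec).max() <= 0.05


def test_extract_features_reports_empty_layers(healthy_volume):
    vol, labels = healthy_volume
    only_one = LayerLabelMap(labels=(labels.labels == 1).astype(np.int32))
    with pytest.raises(EmptyLayerError, match=r"\[2"):
        extract_volume_features(vol, only_one)
    t = extract_volume_features(vol, only_one, MgrfConfig(on_empty="nan"))
    assert len(t) == 12
    assert t[t.layer == 2]["d50"].isna().all()


def test_interslice_offsets_extend_neighborhood(healthy_volume):
    vol, labels = healthy_volume
    nb = NeighborhoodSystem(include_interslice=True)
    assert len(nb.offsets3d) == 10
    model = pooled_layer_cooccurrence(vol, labels, 6, nb)
    assert model.F.shape[0] == 10
    assert np.allclose(model.F.sum(axis=(1, 2)), 1.0, atol=1e-9)
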