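"""Clustering, ordination and climate-vector fitting against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from varzea.betadiv import dissimilarity_matrix
from varzea.structure import (
    cut_and_match,
    decorrelate_variables,
    fit_climate_vectors,
    nmds,
    pcoa,
    rotate_to_reference,
    select_k,
    stress1,
    ward_cluster,
)


def euclidean_dm(points, ids=None):
    pts = np.asarray(points, dtype=float)
    ids = ids or [f"p{i}" for i in range(len(pts))]
    return DistanceMatrix(squareform(pdist(pts)), ids=ids)


def two_block_dm(n1=4, n2=4, within=0.1, between=0.9):
    n = n1 + n2
    D = np.full((n, n), between)
    D[:n1, :n1] = within
    D[n1:, n1:] = within
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D, ids=[f"s{i}" for i in range(n)])


# ---------------------------------------------------------------------------
# Ward clustering


def test_ward_recovers_two_blocks():
    d = two_block_dm()
    tree = ward_cluster(d)
    match = cut_and_match(tree, 2, pd.Series(["x"] * 4 + ["y"] * 4, index=d.ids))
    assert match.mismatch_overall == 0.0


def test_ward_matches_hand_lance_williams_recursion():
    """4-site merge heights equal the hand-run ward recursion on squared input."""
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(4, 2))
    D = squareform(pdist(pts))
    tree = ward_cluster(DistanceMatrix(D, ids=list("abcd")))

    # hand recursion (Lance-Williams, ward on squared dissimilarities)
    clusters = {i: [i] for i in range(4)}
    d2 = {frozenset((i, j)): D[i, j] ** 2 for i in range(4) for j in range(i + 1, 4)}
    heights = []
    next_id = 4
    while len(clusters) > 1:
        (ci, cj), h2 = min(
            ((pair, d2[frozenset(pair)]) for pair in itertools.combinations(clusters, 2)),
            key=lambda kv: kv[1],
        )
        heights.append(np.sqrt(h2))
        ni, nj = len(clusters[ci]), len(clusters[cj])
        merged = clusters.pop(ci) + clusters.pop(cj)
        for ck in list(clusters):
            nk = len(clusters[ck])
            d2[frozenset((next_id, ck))] = (
                (ni + nk) * d2[frozenset((ci, ck))]
                + (nj + nk) * d2[frozenset((cj, ck))]
                - nk * h2
            ) / (ni + nj + nk)
        clusters[next_id] = merged
        next_id += 1
    np.testing.assert_allclose(tree.Z[:, 2], heights, atol=1e-10)


def test_ward_invariant_to_site_permutation():
    d = two_block_dm(3, 5)
    labels = pd.Series(["x"] * 3 + ["y"] * 5, index=d.ids)
    perm = np.random.default_rng(0).permutation(8)
    ids_p = [d.ids[i] for i in perm]
    d_p = DistanceMatrix(d.data[np.ix_(perm, perm)], ids=ids_p)
    m1 = cut_and_match(ward_cluster(d), 2, labels)
    m2 = cut_and_match(ward_cluster(d_p), 2, labels)
    assert m1.mismatch_overall == m2.mismatch_overall
    a1 = m1.assignments.set_index("site_id")["cluster_label"]
    a2 = m2.assignments.set_index("site_id")["cluster_label"]
    assert (a1.sort_index() == a2.sort_index()).all()


def test_ward_variant_d_differs_but_same_blocks():
    d = two_block_dm()
    td = ward_cluster(d, variant="D")
    match = cut_and_match(td, 2, pd.Series(["x"] * 4 + ["y"] * 4, index=d.ids))
    assert match.mismatch_overall == 0.0


def test_ward_rejects_asymmetric_input():
    with pytest.raises(Exception):
        bad = np.array([[0, 1.0], [0.5, 0]])
        ward_cluster(DistanceMatrix(bad, ids=["a", "b"]))


def test_cut_and_match_trivial_cases():
    d = two_block_dm()
    tree = ward_cluster(d)
    labels = pd.Series(["x"] * 4 + ["y"] * 4, index=d.ids)
    # k = n: every cluster a singleton, mismatch 0
    assert cut_and_match(tree, 8, labels).mismatch_overall == 0.0
    # identical labels: mismatch 0 for any k
    same = pd.Series(["z"] * 8, index=d.ids)
    for k in (2, 3, 5):
        assert cut_and_match(tree, k, same).mismatch_overall == 0.0
    with pytest.raises(ValueError):
        cut_and_match(tree, 9, labels)


def test_cut_and_match_mismatch_accounting():
    d = two_block_dm()
    labels = pd.Series(["x"] * 4 + ["y"] * 3 + ["x"], index=d.ids)  # one stray
    m = cut_and_match(ward_cluster(d), 2, labels)
    assert m.mismatch_overall == pytest.approx(1 / 8)
    assert m.mismatch_per_label["x"] == pytest.approx(1 / 5)
    assert m.contingency.to_numpy().sum() == 8


def test_select_k_finds_true_group_count(small_dataset):
    d = dissimilarity_matrix(small_dataset.community, "forbes")
    tree = ward_cluster(d)
    labels = small_dataset.metadata.biome_of()
    best, path = select_k(tree, labels, range(2, 7))
    assert best == 3
    assert path[best] == path.max()


def test_select_k_tie_returns_smallest():
    d = two_block_dm()
    same = pd.Series(["z"] * 8, index=d.ids)
    best, path = select_k(ward_cluster(d), same, range(2, 6))
    assert best == 2  # score flat (all zero) -> smallest k


def test_low_overlap_biomes_cluster_cleanly(small_dataset):
    d = dissimilarity_matrix(small_dataset.community, "forbes")
    tree = ward_cluster(d)
    m = cut_and_match(tree, 3, small_dataset.metadata.biome_of())
    assert m.mismatch_overall < 0.10


# ---------------------------------------------------------------------------
# PCoA


def test_pcoa_recovers_planar_configuration():
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(5, 2))
    res = pcoa(euclidean_dm(pts))
    pos = res.eigenvalues > 1e-8
    assert pos.sum() == 2
    # congruence up to rotation/reflection: compare distance matrices
    rec = res.coordinates.to_numpy()[:, :2]
    assert np.max(np.abs(pdist(rec) - pdist(pts))) < 1e-8


def test_pcoa_three_point_hand_eigendecomposition():
    D = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.5], [2.0, 1.5, 0.0]])
    res = pcoa(DistanceMatrix(D, ids=list("abc")))
    A = -0.5 * D**2
    J = np.eye(3) - np.ones((3, 3)) / 3
    hand = np.sort(np.linalg.eigvalsh(J @ A @ J))[::-1]
    np.testing.assert_allclose(res.eigenvalues, hand, atol=1e-12)


def test_pcoa_proportions_over_positive_eigenvalues(small_dataset):
    d = dissimilarity_matrix(small_dataset.community, "forbes")
    res = pcoa(d)
    lam = res.eigenvalues
    assert lam.min() < 0  # non-Euclidean metric yields negative eigenvalues, reported
    manual = np.where(lam > 0, lam, 0.0) / lam[lam > 0].sum()
    np.testing.assert_allclose(res.proportion_explained, manual)
    assert res.proportion_explained.sum() <= 1.0 + 1e-12


def test_pcoa_agrees_with_skbio(small_dataset):
    from skbio.stats.ordination import pcoa as skbio_pcoa

    d = dissimilarity_matrix(small_dataset.community, "forbes")
    ours = pcoa(d)
    ref = skbio_pcoa(d, number_of_dimensions=3)
    np.testing.assert_allclose(
        np.sort(ours.eigenvalues)[::-1][:3], ref.eigvals.values[:3], rtol=1e-8
    )
    for axis in range(2):
        r = np.corrcoef(
            ours.coordinates.iloc[:, axis], ref.samples.iloc[:, axis]
        )[0, 1]
        assert abs(r) > 1 - 1e-8


# ---------------------------------------------------------------------------
# NMDS


def _pava(values, weights):
    """Hand pool-adjacent-violators: weighted LS non-decreasing fit."""
    blocks = [[v * w, w] for v, w in zip(values, weights)]
    merged = True
    while merged:
        merged = False
        out = []
        for b in blocks:
            if out and out[-1][0] / out[-1][1] > b[0] / b[1]:
                out[-1][0] += b[0]
                out[-1][1] += b[1]
                merged = True
            else:
                out.append(list(b))
        blocks = out
    fits = []
    for s, w in blocks:
        fits.append(s / w)
    return fits, [w for _, w in blocks]


def independent_stress1(D, coords):
    """Stress-1 with tied dissimilarities pooled (secondary tie treatment)."""
    dis = squareform(D, checks=False)
    dist = pdist(coords)
    # one block per unique dissimilarity value, weighted by its multiplicity
    uniq = np.unique(dis)
    means = [dist[dis == u].mean() for u in uniq]
    weights = [int(np.sum(dis == u)) for u in uniq]
    fits, ws = _pava(means, weights)
    per_uniq = np.empty(len(uniq))
    idx = 0
    for f, w in zip(fits, ws):
        used = 0
        while used < w:
            per_uniq[idx] = f
            used += weights[idx]
            idx += 1
    dhat = per_uniq[np.searchsorted(uniq, dis)]
    return np.sqrt(np.sum((dist - dhat) ** 2) / np.sum(dist**2))


def test_nmds_perfect_planar_configuration_has_tiny_stress():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(12, 2))
    res = nmds(euclidean_dm(pts), seed=0, n_starts=4)
    assert res.stress < 0.01


def test_nmds_stress_matches_independent_recomputation(small_dataset):
    d = dissimilarity_matrix(small_dataset.community, "forbes")
    res = nmds(d, seed=1, n_starts=3)
    s_ind = independent_stress1(d.data, res.coordinates.to_numpy())
    assert res.stress == pytest.approx(s_ind, abs=1e-10)


def test_nmds_deterministic_given_seed():
    rng = np.random.default_rng(4)
    d = euclidean_dm(rng.normal(size=(9, 3)))
    a = nmds(d, seed=11, n_starts=3)
    b = nmds(d, seed=11, n_starts=3)
    pd.testing.assert_frame_equal(a.coordinates, b.coordinates)
    assert a.stress == b.stress


def test_nmds_requires_seed():
    with pytest.raises(ValueError):
        nmds(two_block_dm(), seed=None)


# ---------------------------------------------------------------------------
# rotation


def test_rotation_to_own_axis_is_identity():
    rng = np.random.default_rng(6)
    res = pcoa(euclidean_dm(rng.normal(size=(7, 2))))
    rot = rotate_to_reference(res, res.coordinates["axis_1"])
    np.testing.assert_allclose(
        rot.coordinates.to_numpy()[:, 0], res.coordinates.to_numpy()[:, 0], atol=1e-10
    )


def test_rotation_recovers_rotated_plane():
    rng = np.random.default_rng(7)
    pts = rng.normal(size=(10, 2))
    theta = np.pi / 2
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    ids = [f"p{i}" for i in range(10)]
    rotated = pd.DataFrame(pts @ R.T, index=ids, columns=["axis_1", "axis_2"])
    from varzea.structure import OrdinationResult

    res = OrdinationResult(coordinates=rotated, method="nmds")
    ref = pd.Series(pts[:, 0], index=ids)
    back = rotate_to_reference(res, ref)
    r = np.corrcoef(back.coordinates["axis_1"], pts[:, 0])[0, 1]
    assert abs(abs(r) - 1) < 1e-10


def test_rotation_preserves_distances_and_beats_grid_search():
    rng = np.random.default_rng(8)
    pts = rng.normal(size=(15, 2))
    ids = [f"p{i}" for i in range(15)]
    from varzea.structure import OrdinationResult

    res = OrdinationResult(
        coordinates=pd.DataFrame(pts, index=ids, columns=["axis_1", "axis_2"]),
        method="nmds",
    )
    ref = pd.Series(rng.normal(size=15), index=ids)
    rot = rotate_to_reference(res, ref)
    # rigid: distances unchanged
    assert np.max(np.abs(pdist(rot.coordinates.to_numpy()) - pdist(pts))) < 1e-10
    # optimal: no grid angle correlates better
    best = max(
        abs(
            np.corrcoef(
                pts @ np.array([np.cos(t), np.sin(t)]), ref.to_numpy()
            )[0, 1]
        )
        for t in np.linspace(0, 2 * np.pi, 721)
    )
    achieved = abs(np.corrcoef(rot.coordinates["axis_1"], ref.to_numpy())[0, 1])
    assert achieved >= best - 1e-6


# ---------------------------------------------------------------------------
# collinearity filter and fitted vectors


def test_decorrelate_drops_duplicate_and_keeps_orthogonal():
    rng = np.random.default_rng(9)
    x = rng.normal(size=60)
    z = rng.normal(size=60)
    df = pd.DataFrame({"a": x, "b": x * 2.0, "c": z})
    retained, dropped = decorrelate_variables(df)
    assert retained == ["a", "c"]
    assert dropped == {"b": "a"}


def test_decorrelate_matches_brute_force_pair_check(rng):
    n = 80
    base = rng.normal(size=n)
    df = pd.DataFrame(
        {
            "v1": base,
            "v2": base + 0.2 * rng.normal(size=n),          # ~r=0.98 with v1
            "v3": rng.normal(size=n),
            "v4": 0.5 * base + rng.normal(size=n),          # moderate r
        }
    )
    retained, dropped = decorrelate_variables(df, threshold=0.7)
    kept = []
    for var in df.columns:
        if all(abs(np.corrcoef(df[var], df[k])[0, 1]) <= 0.7 for k in kept):
            kept.append(var)
    assert retained == kept


def test_decorrelate_excludes_constant_variable(caplog):
    df = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0, 4.0]})
    with caplog.at_level("WARNING"):
        retained, _ = decorrelate_variables(df)
    assert retained == ["b"]


def test_vector_fit_along_axis_one():
    rng = np.random.default_rng(10)
    res = pcoa(euclidean_dm(rng.normal(size=(12, 2))))
    climate = pd.DataFrame(
        {"v": 3.0 * res.coordinates["axis_1"] + 1.0}, index=res.ids
    )
    vec = fit_climate_vectors(res, climate, n_perm=99, seed=0)[0]
    assert vec.r2 == pytest.approx(1.0, abs=1e-10)
    assert abs(vec.direction[0]) == pytest.approx(1.0, abs=1e-6)
    assert abs(vec.direction[1]) < 1e-6


def test_exact_permutation_p_matches_enumeration():
    rng = np.random.default_rng(11)
    pts = rng.normal(size=(6, 2))
    res = pcoa(euclidean_dm(pts))
    v = rng.normal(size=6)
    climate = pd.DataFrame({"v": v}, index=res.ids)
    vec = fit_climate_vectors(res, climate, n_perm="exact")[0]
    # independent enumeration of all 720 permutations
    coords = res.coordinates.to_numpy()[:, :2]
    Xc = coords - coords.mean(axis=0)

    def r2_of(vp):
        vc = (vp - vp.mean()) / vp.std()
        beta, *_ = np.linalg.lstsq(Xc, vc, rcond=None)
        fitted = Xc @ beta
        return np.sum(fitted**2) / np.sum(vc**2)

    obs = r2_of(v)
    count = sum(
        r2_of(np.array(p)) >= obs - 1e-12 for p in itertools.permutations(v)
    )
    assert vec.n_permutations == 720
    assert vec.p_value == pytest.approx(count / 720)


def test_vector_fit_type_one_error_rate():
    """Noise variables rejected at ~alpha under the permutation test."""
    rng = np.random.default_rng(12)
    res = pcoa(euclidean_dm(rng.normal(size=(20, 2))))
    rejections = 0
    n_vars = 120
    for i in range(n_vars):
        climate = pd.DataFrame({"v": rng.normal(size=20)}, index=res.ids)
        vec = fit_climate_vectors(res, climate, n_perm=99, seed=1000 + i)[0]
        rejections += vec.p_value < 0.05
    assert rejections / n_vars < 0.12  # ~5% expected, generous binomial slack
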