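"""Evidence accumulation core: vote counting, combination, extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster import hierarchy

from pneac import ensemble as ev
from conftest import brute_force_average_link, brute_force_pair_counts


# ------------------------------------------------------------ k sampling

@pytest.mark.parametrize(
    "n, lo, hi",
    [(100, 5, 10), (600, 13, 24), (4, 2, 2), (16, 2, 4)],
)
def test_k_range_bounds(n, lo, hi):
    assert ev.k_range(n) == (lo, hi)


def test_sample_k_covers_range(rng):
    draws = {ev.sample_k(100, rng) for _ in range(500)}
    assert draws == set(range(5, 11))


def test_sample_k_rejects_degenerate():
    with pytest.raises(ValueError):
        ev.sample_k(3, np.random.default_rng(0))


# ---------------------------------------------------- partition ensembles

def test_ensemble_is_reproducible_and_k_in_range():
    X = np.random.default_rng(7).normal(size=(60, 2))
    a = ev.generate_partition_ensemble(X, 10, np.random.default_rng(42))
    b = ev.generate_partition_ensemble(X, 10, np.random.default_rng(42))
    for pa, pb in zip(a, b):
        np.testing.assert_array_equal(pa, pb)
    lo, hi = ev.k_range(60)
    for p in a:
        k = p.max() + 1
        assert lo <= k <= hi
        assert set(p) == set(range(k))  # contiguous labels, no empty cluster


def test_separated_pairs_recovered():
    X = np.array([[0.0, 0], [0.1, 0], [10, 10], [10.1, 10]])
    (p,) = ev.generate_partition_ensemble(
        X, 1, np.random.default_rng(0), k_bounds=(2, 2))
    assert p[0] == p[1] and p[2] == p[3] and p[0] != p[2]


def test_nan_features_rejected():
    X = np.ones((10, 2))
    X[3, 1] = np.nan
    with pytest.raises(ValueError, match="NaN"):
        ev.generate_partition_ensemble(X, 1, np.random.default_rng(0))


# ------------------------------------------------------- evidence matrices

def test_positive_evidence_worked_examples():
    G = ev.accumulate_positive([[0, 0, 1]]).values
    np.testing.assert_array_equal(G, [[1, 1, 0], [1, 1, 0], [0, 0, 1]])
    G = ev.accumulate_positive([[0, 0, 1], [0, 1, 1]]).values
    assert G[0, 1] == G[1, 2] == 0.5 and G[0, 2] == 0.0
    G = ev.accumulate_positive([[0, 0, 0], [0, 0, 0]]).values
    np.testing.assert_array_equal(G, np.ones((3, 3)))


def test_negative_evidence_worked_examples():
    G = ev.accumulate_negative([[0, 0, 1]]).values
    assert G[0, 1] == 0 and G[0, 2] == -1 and G[1, 2] == -1
    np.testing.assert_array_equal(
        ev.accumulate_negative([[0, 0, 0]]).values, np.zeros((3, 3)))
    G = ev.accumulate_negative([[0, 0, 1], [0, 1, 0]]).values
    assert G[0, 1] == -0.5 and G[0, 2] == -0.5 and G[1, 2] == -1.0


@settings(max_examples=30, deadline=None)
@given(st.data())
def test_vote_counting_matches_brute_force(data):
    n = data.draw(st.integers(4, 30))
    m = data.draw(st.integers(1, 20))
    seed = data.draw(st.integers(0, 10_000))
    rng = np.random.default_rng(seed)
    parts = [rng.integers(0, data.draw(st.integers(1, 6)), size=n) for _ in range(m)]
    np.testing.assert_array_equal(
        ev.co_occurrence_counts(parts), brute_force_pair_counts(parts, same=True))
    np.testing.assert_array_equal(
        ev.separation_counts(parts), brute_force_pair_counts(parts, same=False))


def test_evidence_invariants(rng):
    parts = [rng.integers(0, 4, size=25) for _ in range(8)]
    Gp = ev.accumulate_positive(parts).values
    Gn = ev.accumulate_negative(parts).values
    np.testing.assert_allclose(Gp, Gp.T)
    np.testing.assert_allclose(Gn, Gn.T)
    np.testing.assert_allclose(np.diag(Gp), 1.0)
    np.testing.assert_allclose(np.diag(Gn), 0.0)
    assert Gp.min() >= 0 and Gp.max() <= 1
    assert Gn.min() >= -1 and Gn.max() <= 0
    G = ev.combine_evidence(ev.co_occurrence_counts(parts), len(parts),
                            ev.separation_counts(parts), len(parts)).values
    assert G.min() >= -1 and G.max() <= 1


def test_combine_evidence_cases():
    pos = np.array([[2, 2], [2, 2]])
    # both positive partitions co-assign, one negative separates: 2/2 - 1/1 = 0
    neg = np.array([[0, 1], [1, 0]])
    G = ev.combine_evidence(pos, 2, neg, 1).values
    assert G[0, 1] == 0.0
    # no negative part: reduces to normalized positive matrix
    np.testing.assert_array_equal(ev.combine_evidence(pos, 2).values, pos / 2)
    np.testing.assert_array_equal(
        ev.combine_evidence(np.zeros((2, 2)), 1, np.zeros((2, 2)), 1).values,
        np.zeros((2, 2)))
    with pytest.raises(ValueError, match="shape"):
        ev.combine_evidence(pos, 2, np.zeros((3, 3)), 1)


# ----------------------------------------------------------- dissimilarity

def test_dissimilarity_modes():
    G = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.1], [0.2, 0.1, 1.0]])
    D = ev.evidence_to_dissimilarity(G, mode="rows")
    expected01 = np.linalg.norm(G[0] - G[1])
    assert D[0, 1] == pytest.approx(expected01)
    assert np.allclose(np.diag(D), 0) and np.allclose(D, D.T)
    S = ev.evidence_to_dissimilarity(G, mode="shift")
    assert S[0, 1] == pytest.approx(1.0 - 0.5)
    # all-ones evidence -> zero dissimilarity in both modes
    ones = np.ones((4, 4))
    for mode in ("rows", "shift"):
        assert np.allclose(ev.evidence_to_dissimilarity(ones, mode=mode), 0)
    with pytest.raises(ValueError, match="symmetric"):
        ev.evidence_to_dissimilarity(np.array([[0, 1.0], [0.5, 0]]))


def test_identical_rows_are_at_distance_zero():
    G = np.array([[0.5, 0.5, 0.1], [0.5, 0.5, 0.1], [0.1, 0.1, 0.9]])
    D = ev.evidence_to_dissimilarity(G, mode="rows")
    assert D[0, 1] == 0.0


# ----------------------------------------------------------- average link

def _random_dissimilarity(rng, n):
    A = rng.uniform(0.1, 1.0, size=(n, n))
    D = (A + A.T) / 2
    np.fill_diagonal(D, 0)
    return D


def test_two_elements_single_merge():
    D = np.array([[0.0, 0.7], [0.7, 0.0]])
    Z = ev.average_link(D)
    assert Z.shape == (1, 4) and Z[0, 2] == pytest.approx(0.7)


def test_average_link_matches_brute_force(rng):
    for _ in range(25):
        n = int(rng.integers(5, 13))
        D = _random_dissimilarity(rng, n)
        Z = ev.average_link(D)
        heights, merged = brute_force_average_link(D)
        np.testing.assert_allclose(Z[:, 2], heights, atol=1e-10)
        # same clusters formed at each step (ties would be the only excuse)
        scipy_sets = _merge_sets(Z, n)
        assert scipy_sets == merged


def _merge_sets(Z, n):
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for t, (a, b, _, _) in enumerate(Z):
        s = members[int(a)] | members[int(b)]
        members[n + t] = s
        out.append(s)
    return out


def test_block_structure_merges_last(rng):
    D = np.full((6, 6), 0.1)
    D[:3, 3:] = D[3:, :3] = 1.0
    np.fill_diagonal(D, 0)
    Z = ev.average_link(D)
    assert Z[-1, 2] == pytest.approx(1.0)
    assert Z[-1, 2] > Z[:-1, 2].max()


def test_average_link_rejects_negative_entries():
    D = np.array([[0.0, -0.1], [-0.1, 0.0]])
    with pytest.raises(ValueError, match="non-negative"):
        ev.average_link(D)


# ------------------------------------------------------------------- cuts

def test_cut_k_extremes(rng):
    D = _random_dissimilarity(rng, 8)
    Z = ev.average_link(D)
    assert np.unique(ev.cut_k(Z, 1)).size == 1
    assert np.unique(ev.cut_k(Z, 8)).size == 8
    with pytest.raises(ValueError):
        ev.cut_k(Z, 9)


def test_cut_k_matches_threshold_cut(rng):
    D = _random_dissimilarity(rng, 6)
    Z = ev.average_link(D)
    labels = ev.cut_k(Z, 3)
    # oracle: cut by a height threshold between merges n-k and n-k+1
    thresh = (Z[2, 2] + Z[3, 2]) / 2
    oracle = ev.relabel(hierarchy.fcluster(Z, t=thresh, criterion="distance"))
    assert _same_partition(labels, oracle)


def _same_partition(a, b):
    return len(set(zip(a, b))) == len(set(a)) == len(set(b))


# --------------------------------------------------------------- lifetime

def test_lifetime_worked_example():
    # merge heights chosen so L2=0.31, L3=0.23, L4=0.02
    heights = [0.05, 0.07, 0.30, 0.61]
    Z = _chain_linkage(heights)
    k, lifetimes = ev.lifetime_select(Z)
    assert k == 2
    assert lifetimes[2] == pytest.approx(0.31)
    assert lifetimes[3] == pytest.approx(0.23)
    assert lifetimes[4] == pytest.approx(0.02)


def _chain_linkage(heights):
    n = len(heights) + 1
    Z = np.zeros((n - 1, 4))
    prev = 0
    for t, h in enumerate(heights):
        Z[t] = [prev, t + 1, h, t + 2]
        prev = n + t
    return Z


def test_lifetime_tie_breaks_to_smallest_k():
    Z = _chain_linkage([0.5, 0.5, 0.5, 0.5])
    k, lifetimes = ev.lifetime_select(Z)
    assert k == 2
    assert all(v == 0 for v in lifetimes.values())


def test_lifetime_on_two_gaussian_blobs(rng):
    X = np.vstack([rng.normal(0, 0.2, (30, 2)), rng.normal(5, 0.2, (30, 2))])
    parts = ev.generate_partition_ensemble(X, 50, rng)
    G = ev.accumulate_positive(parts)
    Z = ev.average_link(ev.evidence_to_dissimilarity(G, mode="rows"))
    k, _ = ev.lifetime_select(Z)
    assert k == 2


# ------------------------------------------------------------- properties

def test_single_partition_roundtrip(rng):
    """One positive partition -> shift dissimilarity -> cut at its k
    recovers the partition exactly."""
    labels = ev.relabel(rng.integers(0, 4, size=20))
    G = ev.accumulate_positive([labels])
    D = ev.evidence_to_dissimilarity(G, mode="shift")
    Z = ev.average_link(D)
    recovered = ev.cut_k(Z, labels.max() + 1)
    assert _same_partition(labels, recovered)


def test_permutation_equivariance(rng):
    parts = [rng.integers(0, 3, size=15) for _ in range(6)]
    perm = rng.permutation(15)
    Gp = ev.accumulate_positive(parts).values
    Gp_perm = ev.accumulate_positive([p[perm] for p in parts]).values
    np.testing.assert_array_equal(Gp_perm, Gp[np.ix_(perm, perm)])
    Gn = ev.accumulate_negative(parts).values
    Gn_perm = ev.accumulate_negative([p[perm] for p in parts]).values
    np.testing.assert_array_equal(Gn_perm, Gn[np.ix_(perm, perm)])
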