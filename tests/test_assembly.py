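"""Unit and property tests for betaMNTD, nulls, RC_bray and classification."""

import io
from itertools import combinations, permutations

import numpy as np
import pandas as pd
import pytest
import skbio
from hypothesis import given, settings
from hypothesis import strategies as st

import cryoassembly as ca
from cryoassembly.assembly import (
    PROCESSES,
    DegenerateNullError,
    NullDistribution,
    _align_distance,
)
from cryoassembly.signal import patristic_matrix

from conftest import brute_force_bmntd, rc_exact


# ---------------------------------------------------------------------------
# Bray-Curtis


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ([3, 1, 4], [3, 1, 4], 0.0),  # identity
        ([5, 0, 0], [0, 2, 3], 1.0),  # disjoint supports
        ([6, 0, 2], [2, 2, 4], 0.5),  # hand evaluation of the formula
    ],
)
def test_bray_curtis_known_values(a, b, expected):
    assert ca.bray_curtis(a, b) == pytest.approx(expected, abs=1e-12)


def test_bray_curtis_rejects_double_zero():
    with pytest.raises(ValueError):
        ca.bray_curtis([0, 0], [0, 0])


@settings(deadline=None, derandomize=True)
@given(
    st.lists(st.integers(min_value=0, max_value=50), min_size=3, max_size=8),
    st.lists(st.integers(min_value=0, max_value=50), min_size=3, max_size=8),
)
def test_bray_curtis_symmetric_and_bounded(a, b):
    n = min(len(a), len(b))
    a, b = a[:n], b[:n]
    if sum(a) + sum(b) == 0:
        return
    d = ca.bray_curtis(a, b)
    assert 0.0 <= d <= 1.0
    assert d == pytest.approx(ca.bray_curtis(b, a), abs=1e-15)


# ---------------------------------------------------------------------------
# betaMNTD


def test_bmntd_identical_support_is_zero(five_taxon_tree):
    comm = pd.DataFrame(
        [[3, 1, 2, 0, 0], [7, 2, 5, 0, 0]], index=["X", "Y"], columns=list("ABCDE")
    )
    assert ca.bmntd(comm, ("X", "Y"), five_taxon_tree) == 0.0


def test_bmntd_single_taxon_pair_is_patristic_distance(cherry_tree):
    comm = pd.DataFrame(
        [[4, 0, 0], [0, 0, 9]], index=["X", "Y"], columns=list("ABC")
    )
    # d(A, C) = 0.3 + 0.2 + 0.9 = 1.4
    assert ca.bmntd(comm, ("X", "Y"), cherry_tree) == pytest.approx(1.4)


@pytest.mark.parametrize("weighted", [True, False])
def test_bmntd_matches_brute_force_oracle(weighted):
    rng = np.random.default_rng(11)
    for rep in range(50):
        n = int(rng.integers(3, 11))
        tree = ca.simulate_tree(n, seed=int(rng.integers(2**31)))
        dist = patristic_matrix(tree)
        counts = rng.integers(0, 6, size=(2, n))
        for row in counts:  # both samples must be nonzero
            if row.sum() == 0:
                row[rng.integers(n)] = 1
        comm = pd.DataFrame(counts, index=["X", "Y"], columns=dist.index)
        got = ca.bmntd(comm, ("X", "Y"), tree, abundance_weighted=weighted)
        want = brute_force_bmntd(comm, ("X", "Y"), dist, weighted=weighted)
        assert got == pytest.approx(want, abs=1e-12)
        assert got == pytest.approx(
            ca.bmntd(comm, ("Y", "X"), tree, abundance_weighted=weighted), abs=1e-12
        )
        assert got >= 0.0


def test_bmntd_unknown_taxon_is_named(five_taxon_tree):
    comm = pd.DataFrame([[1, 2], [2, 1]], index=["X", "Y"], columns=["A", "ZZZ"])
    with pytest.raises(KeyError, match="ZZZ"):
        ca.bmntd(comm, ("X", "Y"), five_taxon_tree)


# ---------------------------------------------------------------------------
# tip-shuffle null and betaNTI


def test_null_two_taxon_tree_takes_two_values():
    tree = skbio.TreeNode.read(io.StringIO("(A:0.4,B:0.6);"))
    comm = pd.DataFrame([[3, 0], [0, 5]], index=["X", "Y"], columns=["A", "B"])
    nulls = ca.null_bmntd(comm, tree, n_reps=200, seed=0)
    values = set(np.round(nulls[("X", "Y")].values, 12))
    assert values <= {0.0, 1.0}  # either the swap (d=1.0) or identity (d... )
    # identity permutation keeps each single-taxon sample on its own tip: d(A,B)=1
    assert values == {1.0}


def test_null_seed_determinism(five_taxon_tree, toy_table):
    a = ca.null_bmntd(toy_table, five_taxon_tree, n_reps=50, seed=42)
    b = ca.null_bmntd(toy_table, five_taxon_tree, n_reps=50, seed=42)
    for pair in a:
        assert np.array_equal(a[pair].values, b[pair].values)


def test_null_mean_matches_exhaustive_permutation_expectation():
    """999-rep null mean agrees with the exact all-permutations expectation."""
    tree = ca.simulate_tree(6, seed=3)
    dist = patristic_matrix(tree)
    rng = np.random.default_rng(5)
    counts = rng.integers(0, 5, size=(2, 6))
    counts[0, 0] = max(counts[0, 0], 1)
    counts[1, 3] = max(counts[1, 3], 1)
    comm = pd.DataFrame(counts, index=["X", "Y"], columns=dist.index)

    exact = []
    d = dist.to_numpy()
    from cryoassembly.assembly import _bmntd_from_indices, _sample_support

    sup = _sample_support(comm, True)
    (ia, wa), (ib, wb) = sup["X"], sup["Y"]
    for perm in permutations(range(6)):
        p = np.array(perm)
        exact.append(_bmntd_from_indices(d[np.ix_(p, p)], ia, wa, ib, wb))
    exact_mean = np.mean(exact)

    null = ca.null_bmntd(comm, tree, n_reps=999, seed=7)[("X", "Y")]
    se = null.sd / np.sqrt(len(null))
    assert abs(null.mean - exact_mean) < 3 * se


def test_bnti_definition_and_degenerate_null():
    null = NullDistribution(np.array([1.0, 2.0, 3.0]))
    assert ca.bnti(null.mean, null) == 0.0
    assert ca.bnti(null.mean + 2 * null.sd, null) == pytest.approx(2.0)
    flat = NullDistribution(np.zeros(10))
    with pytest.raises(DegenerateNullError):
        ca.bnti(0.5, flat)


def test_bnti_invariant_under_branch_rescaling(five_taxon_tree, toy_table):
    dist = patristic_matrix(five_taxon_tree)
    obs = ca.bmntd(toy_table, ("S1", "S2"), five_taxon_tree)
    null = ca.null_bmntd(toy_table, dist, n_reps=199, seed=1)[("S1", "S2")]
    z = ca.bnti(obs, null)
    c = 3.7
    null_scaled = ca.null_bmntd(toy_table, dist * c, n_reps=199, seed=1)[("S1", "S2")]
    z_scaled = ca.bnti(obs * c, null_scaled)
    assert abs(z - z_scaled) < 1e-9


# ---------------------------------------------------------------------------
# Raup-Crick


def test_rc_bray_bounds_and_symmetry(five_taxon_tree):
    rng = np.random.default_rng(2)
    comm = pd.DataFrame(
        rng.integers(0, 20, size=(4, 5)), columns=list("ABCDE"),
        index=["S1", "S2", "S3", "S4"],
    )
    comm[comm.sum(axis=1) == 0] = 1
    rc_ab = ca.raup_crick_bray(comm, ("S1", "S2"), n_reps=199, seed=5)
    rc_ba = ca.raup_crick_bray(comm, ("S2", "S1"), n_reps=199, seed=5)
    assert -1.0 <= rc_ab <= 1.0
    assert rc_ab == rc_ba  # per-pair stream keyed by the sorted names


def test_rc_bray_matches_exhaustive_enumeration():
    """Monte-Carlo RC within 3 standard errors of the exact enumeration."""
    comm = pd.DataFrame(
        [[2, 1, 0], [0, 2, 2], [1, 1, 1]],
        index=["S1", "S2", "S3"],
        columns=["A", "B", "C"],
    )
    exact = rc_exact(comm, ("S1", "S2"))
    n_reps = 999
    got = ca.raup_crick_bray(comm, ("S1", "S2"), n_reps=n_reps, seed=3)
    u = (exact + 1.0) / 2.0
    se = 2.0 * np.sqrt(max(u * (1 - u), 1e-6) / n_reps)
    assert abs(got - exact) < 3 * se


def test_rc_extremes():
    # S1/S2 disjoint: observed BC=1 beats nearly every null (null samples of
    # richness 3 from 6 occupied taxa usually overlap), so RC approaches +1.
    comm = pd.DataFrame(
        [
            [10, 10, 10, 0, 0, 0],
            [0, 0, 0, 10, 10, 10],
            [5, 5, 5, 5, 5, 5],
            [8, 2, 10, 4, 6, 0],
        ],
        index=["S1", "S2", "S3", "S4"],
        columns=list("ABCDEF"),
    )
    rc = ca.raup_crick_bray(comm, ("S1", "S2"), n_reps=499, seed=9)
    assert rc > 0.5
    # near-identical abundant pair: observed BC below nearly every null
    comm2 = pd.DataFrame(
        [[10, 10, 10, 10], [11, 9, 10, 10], [30, 0, 5, 0], [0, 25, 0, 10]],
        index=["S1", "S2", "S3", "S4"],
        columns=list("ABCD"),
    )
    rc2 = ca.raup_crick_bray(comm2, ("S1", "S2"), n_reps=499, seed=9)
    assert rc2 < -0.9


# ---------------------------------------------------------------------------
# classification and profiles


@pytest.mark.parametrize(
    "z, rc, expected",
    [
        (-3.0, None, "homogeneous_selection"),
        (3.0, None, "heterogeneous_selection"),
        (0.5, 0.99, "dispersal_limitation_drift"),
        (1.0, 0.2, "drift_alone"),
        (-1.5, -0.99, "homogenizing_dispersal"),
        # boundary convention: thresholds fall to the stochastic side
        (-2.0, 0.0, "drift_alone"),
        (2.0, 0.96, "dispersal_limitation_drift"),
        (0.0, 0.95, "drift_alone"),
        (0.0, -0.95, "drift_alone"),
    ],
)
def test_classify_process(z, rc, expected):
    assert ca.classify_process(z, rc) == expected


def test_classify_requires_rc_in_stochastic_band():
    with pytest.raises(ValueError):
        ca.classify_process(0.0, None)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(
    st.floats(min_value=-10, max_value=10, allow_nan=False),
    st.floats(min_value=-1, max_value=1, allow_nan=False),
)
def test_classifier_covers_the_plane(z, rc):
    assert ca.classify_process(z, rc) in PROCESSES


def _record(a, b, process):
    return ca.PairwiseAssembly(a, b, 1.0, 1.0, 0.5, 0.0, 0.0, process)


def test_process_profile_counts():
    recs = [
        _record("a", "b", "homogeneous_selection"),
        _record("a", "c", "homogeneous_selection"),
        _record("b", "c", "dispersal_limitation_drift"),
        _record("c", "d", "drift_alone"),
    ]
    prof = ca.process_profile(recs)
    assert prof.fractions["homogeneous_selection"] == 0.5
    assert prof.fractions["dispersal_limitation_drift"] == 0.25
    assert prof.fractions["drift_alone"] == 0.25
    assert prof.fractions["heterogeneous_selection"] == 0.0
    assert sum(prof.fractions.values()) == pytest.approx(1.0, abs=1e-9)
    assert prof.n_comparisons == 4


def test_process_profile_within_group_and_empty_subset():
    recs = [_record("a", "b", "drift_alone"), _record("a", "c", "drift_alone")]
    groups = {"a": "g1", "b": "g1", "c": "g2"}
    prof = ca.process_profile(recs, "within-group", groups=groups)
    assert prof.n_comparisons == 1
    with pytest.raises(ValueError):
        ca.process_profile(recs, subset=lambda r: False)


def test_all_vs_all_26_samples_gives_325_comparisons():
    samples = [f"s{i}" for i in range(26)]
    recs = [_record(a, b, "drift_alone") for a, b in combinations(samples, 2)]
    assert ca.process_profile(recs).n_comparisons == 325
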