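"""Tests for the synthetic community / phylogeny / respiration generators."""

import io
import math

import numpy as np
import pandas as pd
import pytest
import skbio

import cryoassembly as ca
from cryoassembly import synthetic as syn


# ---------------------------------------------------------------------------
# trees


def test_simulate_tree_tip_count_and_positive_lengths():
    tree = ca.simulate_tree(8, seed=1)
    tips = list(tree.tips())
    assert len(tips) == 8
    assert len(list(tree.non_tips(include_self=True))) == 7
    assert len({t.name for t in tips}) == 8
    assert all(n.length > 0 for n in tree.preorder(include_self=False))


def test_simulate_tree_two_taxa_distance_is_terminal_branch_sum():
    tree = ca.simulate_tree(2, seed=4)
    a, b = tree.tips()
    dm = tree.tip_tip_distances()
    assert dm[a.name, b.name] == pytest.approx(a.length + b.length)


def test_simulate_tree_seed_determinism_byte_identical():
    s1 = io.StringIO()
    s2 = io.StringIO()
    ca.simulate_tree(50, seed=7).write(s1)
    ca.simulate_tree(50, seed=7).write(s2)
    assert s1.getvalue() == s2.getvalue()


def test_simulate_tree_rejects_tiny():
    with pytest.raises(ValueError):
        ca.simulate_tree(1)


def test_structured_tree_geometry():
    tree = ca.simulate_structured_tree(50, seed=3)
    tips = list(tree.tips())
    assert len(tips) == 50
    assert all(n.length > 0 for n in tree.preorder(include_self=False))
    # radiations are shallow relative to stems: nearest neighbour distance is
    # a small fraction of the typical distance
    dm = tree.tip_tip_distances().data
    np.fill_diagonal(dm, np.inf)
    assert np.median(dm.min(axis=1)) < 0.1 * np.median(dm[np.isfinite(dm)])


def test_phylo_guilds_group_close_relatives():
    tree = ca.simulate_structured_tree(50, seed=3)
    guilds = ca.phylo_guilds(tree)
    # tips labelled c<clade>_<member>: guild assignment must match clades
    clades = pd.Series({t: t.split("_")[0] for t in guilds.index})
    assert guilds.groupby(clades).nunique().max() == 1


# ---------------------------------------------------------------------------
# Brownian traits


def test_bm_trait_near_root_value_at_tiny_sigma():
    tree = ca.simulate_tree(10, seed=2)
    traits = ca.evolve_trait_bm(tree, bm_sigma=1e-9, root_value=5.0, seed=0)
    assert np.allclose(traits, 5.0, atol=1e-6)
    with pytest.raises(ValueError):
        ca.evolve_trait_bm(tree, bm_sigma=0.0)


def test_bm_variance_identity_monte_carlo():
    """Tip variance over replicates ~ bm_sigma^2 * root-to-tip depth (15%)."""
    tree = ca.simulate_tree(6, seed=9)
    tip = next(tree.tips())
    depth = sum(a.length or 0.0 for a in tip.ancestors()) + tip.length
    sigma = 0.8
    vals = np.array(
        [ca.evolve_trait_bm(tree, sigma, seed=i)[tip.name] for i in range(500)]
    )
    assert vals.var(ddof=1) == pytest.approx(sigma**2 * depth, rel=0.15)


def test_bm_zero_length_cherry_gets_identical_traits():
    tree = skbio.TreeNode.read(io.StringIO("((A:0,B:0):1.0,C:1.0);"))
    traits = ca.evolve_trait_bm(tree, 1.0, seed=5)
    assert traits["A"] == traits["B"]


# ---------------------------------------------------------------------------
# assembly regimes


def _tree_and_trait(n=20, seed=0):
    tree = ca.simulate_tree(n, seed=seed)
    trait = ca.evolve_trait_bm(tree, 1.0, seed=seed + 1)
    return tree, (trait - trait.mean()) / trait.std(ddof=0)


def test_selection_flat_filter_is_uniform():
    tree, trait = _tree_and_trait()
    comm = ca.assemble_selection(
        tree, trait, 0.0, 30, 2000, math.inf, seed=1, drift_concentration=math.inf
    )
    counts = comm.sum(axis=0)
    expected = 30 * 2000 / 20
    assert (abs(counts - expected) / expected < 0.1).all()


def test_selection_narrow_filter_concentrates_on_nearest_taxon():
    tree, trait = _tree_and_trait()
    env = trait.iloc[3]
    comm = ca.assemble_selection(
        tree, trait, env, 5, 500, 1e-4, seed=1, drift_concentration=math.inf
    )
    assert (comm[trait.index[3]] == 500).all()


def test_selection_two_environments_separate_in_bray_curtis():
    tree, trait = _tree_and_trait(50, seed=4)
    low = ca.assemble_selection(tree, trait, -3.0, 6, 1000, 0.5, seed=2, sample_prefix="L")
    high = ca.assemble_selection(tree, trait, 3.0, 6, 1000, 0.5, seed=3, sample_prefix="H")
    within = [
        ca.bray_curtis(low.iloc[i], low.iloc[j])
        for i in range(6)
        for j in range(i + 1, 6)
    ]
    between = [ca.bray_curtis(low.iloc[i], high.iloc[j]) for i in range(6) for j in range(6)]
    assert np.mean(between) > np.mean(within)


def test_row_sums_conserved_across_generators():
    tree, trait = _tree_and_trait()
    meta = ca.lognormal_metacommunity(trait.index, seed=0)
    tables = [
        ca.assemble_selection(tree, trait, 0.0, 4, 300, 0.5, seed=1),
        ca.assemble_neutral_drift(tree, meta, 4, 300, 50.0, seed=2),
        ca.assemble_dispersal_limited(tree, 4, 300, 0.4, seed=3),
        ca.assemble_guild_selection(tree, trait, 0.0, 4, 300, seed=4),
    ]
    for t in tables:
        assert (t.sum(axis=1) == 300).all()
        assert (t.to_numpy() >= 0).all()


def test_neutral_drift_mean_counts_match_metacommunity():
    """Mean count of each taxon ~ community_size * relative abundance (10%)."""
    tree, _ = _tree_and_trait()
    meta = pd.Series(
        np.arange(1, 21, dtype=float), index=[t.name for t in tree.tips()]
    )
    rel = meta / meta.sum()
    tables = [
        ca.assemble_neutral_drift(tree, meta, 1, 1000, 200.0, seed=i)
        for i in range(200)
    ]
    mean_counts = pd.concat(tables).mean(axis=0)
    expected = 1000 * rel
    frequent = expected > 20
    assert (
        (mean_counts[frequent] - expected[frequent]).abs() / expected[frequent] < 0.1
    ).all()


def test_neutral_drift_unperturbed_large_sample_converges():
    tree, _ = _tree_and_trait()
    meta = pd.Series(
        np.arange(1, 21, dtype=float), index=[t.name for t in tree.tips()]
    )
    comm = ca.assemble_neutral_drift(tree, meta, 1, 200_000, math.inf, seed=0)
    rel_obs = comm.iloc[0] / comm.iloc[0].sum()
    assert np.allclose(rel_obs, meta / meta.sum(), atol=0.005)


def test_neutral_drift_seed_determinism():
    tree, _ = _tree_and_trait()
    meta = ca.lognormal_metacommunity([t.name for t in tree.tips()], seed=1)
    a = ca.assemble_neutral_drift(tree, meta, 3, 100, 50.0, seed=9)
    b = ca.assemble_neutral_drift(tree, meta, 3, 100, 50.0, seed=9)
    assert a.equals(b)


def test_dispersal_pool_bound_and_divergence():
    tree, _ = _tree_and_trait(50, seed=6)
    limited = ca.assemble_dispersal_limited(tree, 10, 500, 0.2, seed=1)
    assert ((limited > 0).sum(axis=1) <= math.ceil(0.2 * 50)).all()
    # mean pairwise BC under pool_fraction=0.2 exceeds pool_fraction=1
    def mean_bc(table):
        n = table.shape[0]
        return np.mean(
            [
                ca.bray_curtis(table.iloc[i], table.iloc[j])
                for i in range(n)
                for j in range(i + 1, n)
            ]
        )

    diffs = []
    for rep in range(20):
        lim = ca.assemble_dispersal_limited(tree, 6, 500, 0.2, seed=100 + rep)
        full = ca.assemble_dispersal_limited(tree, 6, 500, 1.0, seed=200 + rep)
        diffs.append(mean_bc(lim) - mean_bc(full))
    assert np.mean(diffs) > 0


def test_dispersal_full_pool_reduces_to_uniform_neutral_drift():
    """pool_fraction=1 matches drift from a uniform metacommunity in moments."""
    tree, _ = _tree_and_trait()
    uniform = pd.Series(1.0, index=[t.name for t in tree.tips()])
    a = pd.concat(
        [
            ca.assemble_dispersal_limited(tree, 1, 400, 1.0, seed=i)
            for i in range(150)
        ]
    )
    b = pd.concat(
        [
            ca.assemble_neutral_drift(tree, uniform, 1, 400, math.inf, seed=1000 + i)
            for i in range(150)
        ]
    )
    assert np.allclose(a.mean(axis=0), b.mean(axis=0), rtol=0, atol=3.0)
    assert abs(a.to_numpy().std() - b.to_numpy().std()) < 1.0


def test_homogenizing_dispersal_conservation_and_zero_swap():
    template = pd.Series([50, 30, 15, 5, 0], index=list("ABCDE"))
    frozen = ca.assemble_homogenizing_dispersal(template, 5, 0.0, seed=1)
    assert (frozen == template).all().all()
    swapped = ca.assemble_homogenizing_dispersal(template, 5, 0.02, seed=1)
    assert (swapped.sum(axis=1) == template.sum()).all()
    bc = [
        ca.bray_curtis(swapped.iloc[i], swapped.iloc[j])
        for i in range(5)
        for j in range(i + 1, 5)
    ]
    assert max(bc) < 0.1


# ---------------------------------------------------------------------------
# respiration and full experiment


def test_respiration_zero_noise_recovers_q10_exactly():
    series = ca.simulate_respiration(2.0, 2.0, days=[1, 5, 30], measurement_noise_cv=0)
    pair = ca.RatePair(k15=series["rate_15c"].iloc[0], k4=series["rate_4c"].iloc[0])
    assert ca.q10(pair) == pytest.approx(2.0, abs=1e-12)
    flat = ca.simulate_respiration(1.5, 1.0, days=[0, 1], measurement_noise_cv=0)
    assert np.allclose(flat["rate_4c"], flat["rate_15c"])


def test_respiration_noisy_median_recovery():
    """Median recovered Q10 over 200 noisy replicates within 5% of the truth."""
    q10s = []
    for i in range(200):
        s = ca.simulate_respiration(1.0, 2.5, days=range(10), measurement_noise_cv=0.1, seed=i)
        q10s.append(
            ca.q10(ca.RatePair(k15=s["rate_15c"].mean(), k4=s["rate_4c"].mean()))
        )
    assert np.median(q10s) == pytest.approx(2.5, rel=0.05)


def test_five_process_dataset_structure():
    data = ca.five_process_dataset(ca.SimulationConfig(seed=0))
    comm = data["community"]
    assert (comm.sum(axis=1) == 200).all()
    assert set(data["groups"].values()) == {"selL", "selH", "hom", "dis", "dri"}
    assert comm.shape[0] == 40
    # combined table drops nothing but empty taxa
    assert (comm.sum(axis=0) > 0).all()
    # determinism
    data2 = ca.five_process_dataset(ca.SimulationConfig(seed=0))
    assert comm.equals(data2["community"])
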