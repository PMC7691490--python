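"""Synthetic communities assembled under known ecological processes.

Every inference stage in this package can be exercised by parameter recovery
on data whose generating process is known. The generators here map one-to-one
onto the five assembly processes of the null-model framework:

* selection (shared or divergent environments): Gaussian trait filtering of a
  Brownian-motion-evolved niche trait,
* drift alone: Dirichlet-multinomial sampling from a fixed metacommunity,
* dispersal limitation: each sample draws only from its own random taxon pool,
* homogenizing dispersal: near-copies of a single template community.

Plus a birth-death phylogeny simulator and a two-temperature soil-respiration
series for Q10 recovery.
"""

from __future__ import annotations

import io
import math
import random
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
import skbio
from dendropy.simulate import treesim

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "simulate_structured_tree",
    "phylo_guilds",
    "evolve_trait_bm",
    "assemble_guild_selection",
    "assemble_selection",
    "assemble_neutral_drift",
    "assemble_dispersal_limited",
    "assemble_homogenizing_dispersal",
    "lognormal_metacommunity",
    "simulate_respiration",
    "five_process_dataset",
    "depth_profile_metadata",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a full synthetic community-assembly experiment.

    Defaults give a 50-taxon tree with 16S-like two-level structure (shallow
    terminal radiations on long deep stems), 8 samples per assembly regime and
    200 individuals per sample — a miniature of a rarefied amplicon table in
    which most taxa are absent from most samples — a unit-variance Brownian
    niche trait, a selection filter half as wide as the trait spread, a 60%
    reachable taxon pool with strong local drift under dispersal limitation,
    and moderate Dirichlet drift (concentration 50) for the drift-alone
    regime.
    """

    n_taxa: int = 50
    n_samples_per_group: int = 8
    community_size: int = 200
    birth_rate: float = 1.0
    death_rate: float = 0.0
    bm_sigma: float = 1.0
    filter_width: float = 0.5
    pool_fraction: float = 0.6
    noise_level: float = 50.0
    seed: int = 0
    # tree geometry (see simulate_structured_tree)
    clade_size: float = 3.0         # mean tips per terminal radiation
    clade_height: float = 0.02      # radiation depth as fraction of tree height
    stem_concentration: float = 5.0  # >1 pushes backbone splits toward the root
    # selection-regime knobs (see assemble_guild_selection)
    n_guilds_selected: int = 6      # niches per environment
    keep_prob: float = 0.45         # per-member lottery retention within a guild
    swap_fraction: float = 0.02     # homogenizing-dispersal resampling rate
    dispersal_noise: float = 15.0   # local-drift concentration in isolated pools
    metacommunity_sigma: float = 1.5  # lognormal species-abundance spread

    def __post_init__(self):
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.n_samples_per_group < 1 or self.community_size < 1:
            raise ValueError("sample and community sizes must be positive")
        for name in ("birth_rate", "bm_sigma", "filter_width", "noise_level"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.death_rate < 0:
            raise ValueError("death_rate must be nonnegative")
        if not 0 < self.pool_fraction <= 1:
            raise ValueError("pool_fraction must be in (0, 1]")
        if not 0 < self.keep_prob <= 1:
            raise ValueError("keep_prob must be in (0, 1]")


# ---------------------------------------------------------------------------
# phylogeny and traits


def simulate_tree(
    n_taxa: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    seed: int | None = None,
    jitter_sigma: float = 0.0,
) -> skbio.TreeNode:
    """Simulate a rooted binary birth-death tree with ``n_taxa`` extant tips.

    The birth-death process is stopped at the last birth event, which leaves
    the newest cherry with zero-length branches; every terminal edge is then
    extended by one further exponential waiting time so all branch lengths are
    strictly positive and the tree stays ultrametric. ``jitter_sigma > 0``
    multiplies every edge by independent lognormal noise, breaking
    ultrametricity for robustness checks.

    Tips are labelled ``t1 .. t<n_taxa>``.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if birth_rate <= 0 or death_rate < 0:
        raise ValueError("birth_rate must be > 0 and death_rate >= 0")
    rng = random.Random(seed)
    dtree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=death_rate,
        num_extant_tips=n_taxa,
        rng=rng,
    )
    extension = rng.expovariate(n_taxa * (birth_rate + death_rate))
    for leaf in dtree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extension
    for i, leaf in enumerate(dtree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"t{i}"
    if jitter_sigma > 0:
        for edge in dtree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= rng.lognormvariate(0.0, jitter_sigma)
    newick = dtree.as_string(schema="newick", suppress_rooting=True)
    tree = skbio.TreeNode.read(io.StringIO(newick))
    tree.length = None  # drop the simulator's root-edge remnant
    return tree


def _max_depth(tree: skbio.TreeNode) -> float:
    return max(
        sum(a.length or 0.0 for a in t.ancestors()) + (t.length or 0.0)
        for t in tree.tips()
    )


def _rescale_height(tree: skbio.TreeNode, target: float) -> skbio.TreeNode:
    f = target / _max_depth(tree)
    for nd in tree.preorder(include_self=False):
        nd.length *= f
    return tree


def _concentrate_stems(tree: skbio.TreeNode, exponent: float) -> skbio.TreeNode:
    """Remap node depths d -> h*(d/h)**exponent; exponent > 1 deepens splits."""
    depths = {}
    for nd in tree.preorder(include_self=True):
        depths[id(nd)] = (
            0.0 if nd.parent is None else depths[id(nd.parent)] + nd.length
        )
    h = _max_depth(tree)
    for nd in tree.preorder(include_self=False):
        nd.length = h * (
            (depths[id(nd)] / h) ** exponent
            - (depths[id(nd.parent)] / h) ** exponent
        )
    return tree


def simulate_structured_tree(
    n_taxa: int,
    clade_size: float = 3.0,
    clade_height: float = 0.02,
    stem_concentration: float = 5.0,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    seed: int | None = None,
) -> skbio.TreeNode:
    """Two-level phylogeny: shallow terminal radiations on long deep stems.

    Microbial (16S) gene trees are strongly hierarchical: within-genus
    distances are a few percent of between-phylum distances. A single
    birth-death tree at a few dozen tips does not reproduce that geometry, so
    this generator builds it explicitly: a birth-death backbone whose splits
    are pushed toward the root (depths remapped by ``stem_concentration`` > 1),
    carrying birth-death radiations of mean size ``clade_size`` whose height is
    ``clade_height`` of the total (ultrametric, height 1). Tips are labelled
    ``c<clade>_<member>``.
    """
    if n_taxa < 4:
        raise ValueError("n_taxa must be >= 4")
    if not 0 < clade_height < 0.5:
        raise ValueError("clade_height must be in (0, 0.5)")
    rng = np.random.default_rng(seed)
    sizes: list[int] = []
    left = n_taxa
    while left > 0:
        s = min(max(2, int(round(rng.normal(clade_size, 1.0)))), left)
        if left - s == 1:
            s += 1  # avoid a trailing singleton radiation
        sizes.append(s)
        left -= s
    seeds = [int(x) for x in rng.integers(0, 2**31, size=len(sizes) + 1)]
    backbone = simulate_tree(len(sizes), birth_rate, death_rate, seed=seeds[0])
    _concentrate_stems(backbone, stem_concentration)
    _rescale_height(backbone, 1.0 - clade_height)
    for ci, (tip, size) in enumerate(zip(list(backbone.tips()), sizes), start=1):
        sub = simulate_tree(size, birth_rate, death_rate, seed=seeds[ci])
        _rescale_height(sub, clade_height)
        for j, st in enumerate(sub.tips(), start=1):
            st.name = f"c{ci}_{j}"
        sub.length = tip.length
        parent = tip.parent
        parent.remove(tip)
        parent.append(sub)
    return backbone


def phylo_guilds(tree: skbio.TreeNode, radius: float = 0.1) -> pd.Series:
    """Cluster tips into guilds of close relatives (average linkage, patristic).

    A guild is a set of tips whose average patristic distance is below
    ``radius`` — the ecologically interchangeable close relatives among which
    lottery drift operates in the selection generator.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    dm = tree.tip_tip_distances()
    labels = list(dm.ids)
    Z = linkage(squareform(dm.data, checks=False), method="average")
    return pd.Series(fcluster(Z, t=radius, criterion="distance"), index=labels)


def assemble_guild_selection(
    tree: skbio.TreeNode,
    traits: pd.Series,
    env_value: float,
    n_samples: int,
    community_size: int,
    filter_width: float = 0.5,
    seed: int | None = None,
    sample_prefix: str = "S",
    n_guilds: int = 3,
    keep_prob: float = 0.45,
    guild_radius: float = 0.1,
    min_guild_size: int = 3,
    guild_ids=None,
) -> pd.DataFrame:
    """Selection acting on guilds, with lottery drift among guild members.

    The environment at ``env_value`` offers ``n_guilds`` niches, filled by the
    guilds (clusters of close relatives, see :func:`phylo_guilds`) whose mean
    trait is closest to it. Guild-level abundances are set deterministically by
    a Gaussian filter on the guild mean traits (width adapted upward to the
    spread of the selected guild means so no niche collapses); within each
    guild, member identity is a lottery — every member is retained
    independently with probability ``keep_prob`` (at least one survives) and
    the guild's share is split evenly among survivors.

    This separation — selection between guilds, neutral lottery within — is
    what makes repeated samples from one environment phylogenetically
    clustered yet compositionally distinct, the signature of homogeneous
    selection. Taxon-level Gaussian filtering alone cannot produce it at small
    taxon counts: samples either share all dominant taxa (turnover carries no
    weight) or turn over in trait-marginal taxa that are phylogenetically
    scattered.
    """
    if filter_width <= 0:
        raise ValueError("filter_width must be strictly positive")
    if not 0 < keep_prob <= 1:
        raise ValueError("keep_prob must be in (0, 1]")
    guilds = phylo_guilds(tree, guild_radius)
    traits = traits.loc[guilds.index]
    stats = traits.groupby(guilds).agg(["mean", "count"])
    if guild_ids is not None:
        chosen_ids = list(guild_ids)
    else:
        cand = stats[stats["count"] >= min_guild_size]
        if len(cand) < n_guilds:  # relax on very small or unstructured trees
            cand = stats
        chosen_ids = list(
            (cand["mean"] - env_value).abs().nsmallest(min(n_guilds, len(cand))).index
        )
    sel_means = stats.loc[chosen_ids, "mean"]
    width = max(filter_width, float(sel_means.std(ddof=0)) or filter_width)
    gw = np.exp(-0.5 * ((sel_means - env_value) / width) ** 2)
    gw = gw / gw.sum()
    rng = np.random.default_rng(seed)
    taxa = list(guilds.index)
    rows = np.zeros((n_samples, len(taxa)), dtype=int)
    gvals = guilds.to_numpy()
    for i in range(n_samples):
        p = np.zeros(len(taxa))
        for g, share in gw.items():
            idx = np.flatnonzero(gvals == g)
            keep = idx[rng.random(idx.size) < keep_prob]
            if keep.size == 0:
                keep = idx[[rng.integers(idx.size)]]
            p[keep] = share / keep.size
        rows[i] = rng.multinomial(community_size, p / p.sum())
    return pd.DataFrame(
        rows,
        index=[f"{sample_prefix}{i + 1}" for i in range(n_samples)],
        columns=taxa,
    )


def evolve_trait_bm(
    tree: skbio.TreeNode,
    bm_sigma: float,
    root_value: float = 0.0,
    seed: int | None = None,
) -> pd.Series:
    """Evolve one continuous niche trait along the tree by Brownian motion.

    Each branch adds a Normal(0, bm_sigma * sqrt(branch length)) increment, so
    a tip's trait variance equals ``bm_sigma**2`` times its root-to-tip depth
    and covariances follow shared branch lengths — the phylogenetic signal the
    correlogram stage is designed to detect.
    """
    if bm_sigma <= 0:
        raise ValueError("bm_sigma must be strictly positive")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree): root_value}
    for node in tree.preorder(include_self=False):
        bl = node.length
        if bl is None:
            raise ValueError("tree has a branch without a length")
        step = rng.normal(0.0, bm_sigma * math.sqrt(bl)) if bl > 0 else 0.0
        values[id(node)] = values[id(node.parent)] + step
    tips = list(tree.tips())
    return pd.Series(
        [values[id(t)] for t in tips], index=[t.name for t in tips], name="trait"
    )


# ---------------------------------------------------------------------------
# community assembly regimes


def _multinomial_table(
    rng: np.random.Generator,
    probs: np.ndarray,
    taxa,
    n_samples: int,
    community_size: int,
    prefix: str,
) -> pd.DataFrame:
    counts = rng.multinomial(community_size, probs, size=n_samples)
    return pd.DataFrame(
        counts,
        index=[f"{prefix}{i + 1}" for i in range(n_samples)],
        columns=list(taxa),
        dtype=int,
    )


def assemble_selection(
    tree: skbio.TreeNode,
    traits: pd.Series,
    env_value: float,
    n_samples: int,
    community_size: int,
    filter_width: float,
    seed: int | None = None,
    sample_prefix: str = "S",
    drift_concentration: float = 10.0,
) -> pd.DataFrame:
    """Communities filtered by a Gaussian selection kernel around ``env_value``.

    Taxon sampling probability is proportional to
    ``exp(-(trait - env_value)**2 / (2 * filter_width**2))``. A shared
    ``env_value`` across samples realizes homogeneous selection; divergent
    values across groups realize heterogeneous selection. ``filter_width`` of
    ``inf`` gives the flat (neutral) limit.

    ``drift_concentration`` perturbs each sample's probabilities with a
    Dirichlet draw around the filter weights (selection still acting through
    the expectation). Selected communities need this residual compositional
    drift to show less-than-chance phylogenetic turnover: with identical
    sampling probabilities every sample holds the same taxa, shared taxa
    contribute zero to nearest-taxon turnover, and the filter leaves no
    detectable imprint. ``inf`` disables the perturbation (pure multinomial).
    """
    if filter_width <= 0:
        raise ValueError("filter_width must be strictly positive")
    if drift_concentration <= 0:
        raise ValueError("drift_concentration must be strictly positive")
    tip_names = {t.name for t in tree.tips()}
    missing = tip_names - set(traits.index)
    if missing:
        raise ValueError(f"traits missing for tips: {sorted(missing)}")
    traits = traits.loc[[t.name for t in tree.tips()]]
    rng = np.random.default_rng(seed)
    if math.isinf(filter_width):
        logw = np.zeros(len(traits))
    else:
        z = (traits.to_numpy() - env_value) / filter_width
        logw = -0.5 * z**2
    w = np.exp(logw - logw.max())
    w = w / w.sum()
    rows = np.zeros((n_samples, w.size), dtype=int)
    for i in range(n_samples):
        if math.isinf(drift_concentration):
            p = w
        else:
            p = rng.dirichlet(np.maximum(drift_concentration * w, 1e-12))
        rows[i] = rng.multinomial(community_size, p)
    return pd.DataFrame(
        rows,
        index=[f"{sample_prefix}{i + 1}" for i in range(n_samples)],
        columns=list(traits.index),
    )


def assemble_neutral_drift(
    tree: skbio.TreeNode,
    metacommunity_abundances: pd.Series | np.ndarray,
    n_samples: int,
    community_size: int,
    noise_level: float = 100.0,
    seed: int | None = None,
    sample_prefix: str = "S",
) -> pd.DataFrame:
    """Drift-only communities: Dirichlet-multinomial draws from a metacommunity.

    Each sample's composition is a Dirichlet perturbation of the metacommunity
    relative abundances with concentration ``noise_level`` (larger = weaker
    drift; ``inf`` disables the perturbation), then ``community_size``
    individuals are drawn multinomially. Neither the tree topology nor any
    trait enters: turnover is pure chance.
    """
    meta = np.asarray(metacommunity_abundances, dtype=float)
    if np.any(meta < 0) or meta.sum() == 0:
        raise ValueError("metacommunity abundances must be nonnegative, not all zero")
    if isinstance(metacommunity_abundances, pd.Series):
        taxa = list(metacommunity_abundances.index)
    else:
        taxa = [t.name for t in tree.tips()]
        if len(taxa) != meta.size:
            raise ValueError("metacommunity length does not match tree tips")
    rel = meta / meta.sum()
    rng = np.random.default_rng(seed)
    rows = np.zeros((n_samples, meta.size), dtype=int)
    nz = np.flatnonzero(rel)
    for i in range(n_samples):
        if math.isinf(noise_level):
            p = rel[nz]
        else:
            p = rng.dirichlet(noise_level * rel[nz])
        rows[i, nz] = rng.multinomial(community_size, p)
    return pd.DataFrame(
        rows, index=[f"{sample_prefix}{i + 1}" for i in range(n_samples)], columns=taxa
    )


def assemble_dispersal_limited(
    tree: skbio.TreeNode,
    n_samples: int,
    community_size: int,
    pool_fraction: float,
    seed: int | None = None,
    sample_prefix: str = "S",
    noise_level: float = math.inf,
) -> pd.DataFrame:
    """Dispersal-limited communities: each sample sees only a random taxon pool.

    Every sample independently draws its own subset of
    ``ceil(pool_fraction * n_taxa)`` taxa and fills ``community_size``
    individuals over that subset — uniformly by default, or with local drift
    when ``noise_level`` is finite (Dirichlet concentration ``noise_level /
    pool_size`` per member; small values give the strong dominance of isolated
    communities drifting independently). ``pool_fraction = 1`` reduces to
    neutral sampling from a uniform metacommunity with the same concentration.
    """
    if not 0 < pool_fraction <= 1:
        raise ValueError("pool_fraction must be in (0, 1]")
    if noise_level <= 0:
        raise ValueError("noise_level must be strictly positive")
    taxa = [t.name for t in tree.tips()]
    n_taxa = len(taxa)
    pool_size = math.ceil(pool_fraction * n_taxa)
    rng = np.random.default_rng(seed)
    rows = np.zeros((n_samples, n_taxa), dtype=int)
    for i in range(n_samples):
        pool = rng.choice(n_taxa, size=pool_size, replace=False)
        if math.isinf(noise_level):
            p = np.full(pool_size, 1.0 / pool_size)
        else:
            p = rng.dirichlet(np.full(pool_size, noise_level / pool_size))
        rows[i, pool] = rng.multinomial(community_size, p)
    return pd.DataFrame(
        rows, index=[f"{sample_prefix}{i + 1}" for i in range(n_samples)], columns=taxa
    )


def assemble_homogenizing_dispersal(
    template_sample: pd.Series,
    n_samples: int,
    swap_fraction: float = 0.02,
    seed: int | None = None,
    sample_prefix: str = "S",
) -> pd.DataFrame:
    """Near-copies of one template community (mass-effects regime).

    Each sample removes ``round(swap_fraction * total)`` individuals uniformly
    without replacement and replaces them with individuals drawn from the
    template's relative abundances, conserving the total count. Pairwise
    dissimilarity is therefore far below any neutral expectation.
    """
    if swap_fraction < 0 or swap_fraction > 1:
        raise ValueError("swap_fraction must be in [0, 1]")
    template = template_sample.to_numpy(dtype=int)
    if np.any(template < 0) or template.sum() == 0:
        raise ValueError("template must be nonnegative with positive total")
    total = int(template.sum())
    n_swap = round(swap_fraction * total)
    rel = template / total
    rng = np.random.default_rng(seed)
    rows = np.zeros((n_samples, template.size), dtype=int)
    for i in range(n_samples):
        removed = rng.multivariate_hypergeometric(template, n_swap)
        rows[i] = template - removed + rng.multinomial(n_swap, rel)
    return pd.DataFrame(
        rows,
        index=[f"{sample_prefix}{i + 1}" for i in range(n_samples)],
        columns=list(template_sample.index),
    )


def lognormal_metacommunity(
    taxa, sigma: float = 1.5, seed: int | None = None
) -> pd.Series:
    """Lognormal species-abundance distribution over ``taxa`` (sums to 1)."""
    taxa = list(taxa)
    rng = np.random.default_rng(seed)
    w = rng.lognormal(0.0, sigma, size=len(taxa))
    return pd.Series(w / w.sum(), index=taxa, name="metacommunity")


# ---------------------------------------------------------------------------
# respiration


def simulate_respiration(
    base_rate_4c: float,
    q10_true: float,
    days,
    measurement_noise_cv: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Paired 4C / 15C respiration-rate series for Q10 recovery.

    The 15C rate is ``base_rate_4c * q10_true**1.1`` (an 11-degree step on the
    Q10 scale) times multiplicative lognormal noise with coefficient of
    variation ``measurement_noise_cv`` (mean-one noise; zero CV disables it).
    Returns a frame with columns ``day``, ``rate_4c``, ``rate_15c``.
    """
    if base_rate_4c <= 0 or q10_true <= 0:
        raise ValueError("base_rate_4c and q10_true must be strictly positive")
    if measurement_noise_cv < 0:
        raise ValueError("measurement_noise_cv must be nonnegative")
    days = np.asarray(list(days), dtype=float)
    rng = np.random.default_rng(seed)
    k15 = base_rate_4c * q10_true ** ((15.0 - 4.0) / 10.0)

    def noisy(mean_rate: float) -> np.ndarray:
        if measurement_noise_cv == 0:
            return np.full(days.size, mean_rate)
        s = math.sqrt(math.log(1.0 + measurement_noise_cv**2))
        return mean_rate * rng.lognormal(-0.5 * s**2, s, size=days.size)

    return pd.DataFrame(
        {"day": days, "rate_4c": noisy(base_rate_4c), "rate_15c": noisy(k15)}
    )


# ---------------------------------------------------------------------------
# full experiment and metadata


def depth_profile_metadata(
    samples, seed: int | None = None, n_depths: int = 4
) -> pd.DataFrame:
    """Abiotic metadata emulating an organic permafrost depth profile.

    Samples are spread over ``n_depths`` strata (10 cm steps). Along the
    profile, gravimetric water content and %C decline, pH rises from strongly
    acidic toward ~5, %N fluctuates mildly and C:N declines — the qualitative
    shape of organic active-layer-to-permafrost cores.
    """
    samples = list(samples)
    rng = np.random.default_rng(seed)
    rows = []
    for i, s in enumerate(samples):
        d = i % n_depths  # stratum index, shallow -> deep
        frac = d / max(n_depths - 1, 1)
        gwc = 400.0 - 250.0 * frac + rng.normal(0, 20)
        ph = 3.9 + 1.2 * frac + rng.normal(0, 0.1)
        pc = 46.0 - 20.0 * frac + rng.normal(0, 2)
        pn = 1.4 + rng.normal(0, 0.3)
        rows.append(
            {
                "sample": s,
                "group": f"{10 + 10 * d}-{20 + 10 * d} cm",
                "gwc": max(gwc, 50.0),
                "ph": min(max(ph, 3.0), 8.0),
                "percent_c": max(pc, 5.0),
                "percent_n": max(pn, 0.2),
            }
        )
    meta = pd.DataFrame(rows).set_index("sample")
    meta["cn_ratio"] = meta["percent_c"] / meta["percent_n"]
    return meta


def _balanced_deep_split(
    tree: skbio.TreeNode, guilds: pd.Series, max_rel_depth: float = 0.3
) -> set:
    """Tips on one side of the deep bipartition that best balances guild counts.

    Considers internal nodes whose depth is within ``max_rel_depth`` of the
    tree height and returns the tip set under the node that splits the guilds
    most evenly (the root bipartition can be arbitrarily lopsided).
    """
    n_guilds = guilds.nunique()
    height = _max_depth(tree)
    best, best_balance = None, -1
    depths = {id(tree): 0.0}
    for nd in tree.preorder(include_self=False):
        depths[id(nd)] = depths[id(nd.parent)] + (nd.length or 0.0)
        if nd.is_tip() or depths[id(nd)] > max_rel_depth * height:
            continue
        under = {t.name for t in nd.tips()}
        g_under = guilds[guilds.index.isin(under)].nunique()
        balance = min(g_under, n_guilds - g_under)
        if balance > best_balance:
            best, best_balance = under, balance
    return best if best is not None else {t.name for t in tree.children[0].tips()}


def five_process_dataset(config: SimulationConfig) -> dict:
    """One synthetic experiment per assembly process, on a shared phylogeny.

    Builds a structured (two-level) tree, evolves a Brownian niche trait
    (standardized to zero mean, unit variance across tips), and assembles one
    sample group per regime, all combined into a single community table — the
    shape of a real survey, where one rarefied table spanning the whole tree
    is analysed at once and pairs are compared within and between groups:

    * ``selL`` / ``selH``: guild selection at the two ends of the niche axis
      (the environments are the means of the 3 lowest / highest guild mean
      traits). Within-group pairs are the homogeneous-selection condition,
      between-group pairs the heterogeneous one.
    * ``hom``: near-copies of a lognormal-metacommunity template
      (homogenizing dispersal).
    * ``dis``: pool-restricted samples (dispersal limitation + drift).
    * ``dri``: Dirichlet-multinomial samples from the lognormal metacommunity
      (drift alone).

    Returns a dict with ``tree``, ``trait``, ``community`` (combined table),
    ``groups`` (sample -> regime label), per-regime tables, and the
    metacommunity. The lognormal metacommunity is used for the stochastic
    regimes because a near-uniform one would put every taxon in every sample,
    making nearest-taxon turnover identically zero.
    """
    c = config
    root = np.random.SeedSequence(c.seed)
    seeds = [int(s) for s in root.generate_state(8) % (2**31)]
    tree = simulate_structured_tree(
        c.n_taxa, c.clade_size, c.clade_height, c.stem_concentration,
        c.birth_rate, c.death_rate, seed=seeds[0],
    )
    trait = evolve_trait_bm(tree, c.bm_sigma, seed=seeds[1])
    trait = (trait - trait.mean()) / trait.std(ddof=0)

    guilds = phylo_guilds(tree)
    stats = trait.groupby(guilds).agg(["mean", "count"])

    # Heterogeneous selection is detectable by phylogenetic turnover only when
    # environmental divergence aligns with deep lineages, so the two
    # environments are anchored in the two deep halves of the tree (the root
    # bipartition): each favours the most extreme-trait guilds of its half,
    # making every cross-environment path pass through the root.
    half_a = _balanced_deep_split(tree, guilds)
    side = pd.Series(
        [1 if t in half_a else 2 for t in guilds.index], index=guilds.index
    )
    guild_side = side.groupby(guilds).first()  # guilds are clades: one side each

    def pick(side_id: int, lowest: bool) -> list:
        cand = stats[(guild_side == side_id) & (stats["count"] >= 3)]
        if len(cand) < 2:
            cand = stats[guild_side == side_id]
        k = min(c.n_guilds_selected, len(cand))
        means = cand["mean"].sort_values()
        return list(means.index[:k] if lowest else means.index[-k:])

    # the half holding the lower-trait extreme hosts the low environment
    mins = stats["mean"].groupby(guild_side).min()
    low_side = int(mins.idxmin())
    high_side = 1 if low_side == 2 else 2
    low_ids = pick(low_side, lowest=True)
    high_ids = pick(high_side, lowest=False)
    env_low = float(stats.loc[low_ids, "mean"].mean())
    env_high = float(stats.loc[high_ids, "mean"].mean())

    low = assemble_guild_selection(
        tree, trait, env_low, c.n_samples_per_group, c.community_size,
        c.filter_width, seed=seeds[2], sample_prefix="selL",
        keep_prob=c.keep_prob, guild_ids=low_ids,
    )
    high = assemble_guild_selection(
        tree, trait, env_high, c.n_samples_per_group, c.community_size,
        c.filter_width, seed=seeds[3], sample_prefix="selH",
        keep_prob=c.keep_prob, guild_ids=high_ids,
    )

    meta = lognormal_metacommunity(
        [t.name for t in tree.tips()], c.metacommunity_sigma, seed=seeds[4]
    )
    rng = np.random.default_rng(seeds[5])
    template = pd.Series(
        rng.multinomial(c.community_size, meta.to_numpy()), index=meta.index
    )
    homogenizing = assemble_homogenizing_dispersal(
        template, c.n_samples_per_group, c.swap_fraction, seed=seeds[5],
        sample_prefix="hom",
    )
    dispersal = assemble_dispersal_limited(
        tree, c.n_samples_per_group, c.community_size, c.pool_fraction,
        seed=seeds[6], sample_prefix="dis", noise_level=c.dispersal_noise,
    )
    drift = assemble_neutral_drift(
        tree, meta, c.n_samples_per_group, c.community_size, c.noise_level,
        seed=seeds[7], sample_prefix="dri",
    )
    community = (
        pd.concat([low, high, homogenizing, dispersal, drift])
        .fillna(0)
        .astype(int)
    )
    community = community.loc[:, community.sum(axis=0) > 0]
    groups = {}
    for s in community.index:
        for label in ("selL", "selH", "hom", "dis", "dri"):
            if s.startswith(label):
                groups[s] = label
    return {
        "tree": tree,
        "trait": trait,
        "community": community,
        "groups": groups,
        "env_values": {"selL": env_low, "selH": env_high},
        "selection_low": low,
        "selection_high": high,
        "homogenizing": homogenizing,
        "dispersal": dispersal,
        "drift": drift,
        "metacommunity": meta,
    }
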