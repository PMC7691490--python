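"""Null-model inference of community assembly processes.

Implements the phylogenetic-turnover framework used to partition microbial
community assembly into deterministic and stochastic processes:

* beta-mean-nearest-taxon distance (betaMNTD) between sample pairs,
* a tip-shuffle null model (default 999 iterations) giving betaNTI,
* abundance-based Raup-Crick nulls on Bray-Curtis (RC_bray),
* the five-way process classification
  (homogeneous selection | heterogeneous selection | homogenizing dispersal |
  dispersal limitation + drift | drift alone),
* relative process contributions over sets of pairwise comparisons.

Sample pairs with |betaNTI| > 2 reflect less / more phylogenetic turnover than
chance (homogeneous / heterogeneous selection); the interior band is split by
RC_bray at +-0.95. Values exactly at a threshold fall to the stochastic /
interior side (|betaNTI| = 2 proceeds to the RC test; |RC_bray| = 0.95 is
drift alone): the conservative-toward-stochasticity boundary convention.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import skbio

__all__ = [
    "PROCESSES",
    "NullDistribution",
    "PairwiseAssembly",
    "ProcessProfile",
    "DegenerateNullError",
    "bray_curtis",
    "bmntd",
    "null_bmntd",
    "bnti",
    "raup_crick_bray",
    "classify_process",
    "process_profile",
    "assembly_analysis",
]

#: Process labels in Table-style order: deterministic first, then stochastic.
PROCESSES = (
    "homogeneous_selection",
    "heterogeneous_selection",
    "homogenizing_dispersal",
    "dispersal_limitation_drift",
    "drift_alone",
)

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95
#: absolute tolerance when counting Bray-Curtis ties in the RC null
RC_TIE_TOL = 1e-12


class DegenerateNullError(ValueError):
    """Raised when a null distribution has zero spread (betaNTI undefined)."""


@dataclass(frozen=True)
class NullDistribution:
    """A Monte-Carlo null distribution of betaMNTD values for one sample pair."""

    values: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PairwiseAssembly:
    """Per sample-pair assembly inference record."""

    sample_a: str
    sample_b: str
    bmntd_obs: float
    null_mean: float
    null_sd: float
    bnti: float
    rc_bray: float | None
    process: str


@dataclass(frozen=True)
class ProcessProfile:
    """Relative contribution of each assembly process over a comparison set."""

    fractions: Mapping[str, float]
    n_comparisons: int
    subset_label: str = "all"

    def __post_init__(self):
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"process fractions sum to {total}, expected 1")


# ---------------------------------------------------------------------------
# dissimilarities


def bray_curtis(counts_a: Sequence[float], counts_b: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min(a,b)) / (sum(a)+sum(b))."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must have the same length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be nonnegative")
    total = a.sum() + b.sum()
    if total == 0:
        raise ValueError("Bray-Curtis undefined: both vectors are all-zero")
    return float(1.0 - 2.0 * np.minimum(a, b).sum() / total)


def _check_table(comm: pd.DataFrame) -> None:
    if (comm.values < 0).any():
        raise ValueError("community table contains negative counts")


def _align_distance(comm: pd.DataFrame, dm) -> np.ndarray:
    """Tip-tip distance submatrix in the table's taxon order.

    ``dm`` may be a skbio DistanceMatrix, a labelled DataFrame or a tree.
    Raises a named error for any table taxon absent from the tree.
    """
    if isinstance(dm, skbio.TreeNode):
        dm = dm.tip_tip_distances()
    if isinstance(dm, skbio.DistanceMatrix):
        dm = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    missing = [t for t in comm.columns if t not in dm.index]
    if missing:
        raise KeyError(f"taxa absent from the tree: {missing}")
    return dm.loc[comm.columns, comm.columns].to_numpy(dtype=float)


def _bmntd_from_indices(
    dist: np.ndarray,
    idx_a: np.ndarray,
    w_a: np.ndarray,
    idx_b: np.ndarray,
    w_b: np.ndarray,
) -> float:
    """betaMNTD for one pair given nonzero-taxon indices and weights."""
    sub = dist[np.ix_(idx_a, idx_b)]
    return 0.5 * (w_a @ sub.min(axis=1) + w_b @ sub.min(axis=0))


def _sample_support(
    comm: pd.DataFrame, abundance_weighted: bool
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Map sample -> (nonzero taxon indices, weights summing to 1)."""
    counts = comm.to_numpy(dtype=float)
    out = {}
    for i, sample in enumerate(comm.index):
        row = counts[i]
        idx = np.flatnonzero(row)
        if idx.size == 0:
            raise ValueError(f"sample {sample!r} has no nonzero taxa")
        if abundance_weighted:
            w = row[idx] / row[idx].sum()
        else:
            w = np.full(idx.size, 1.0 / idx.size)
        out[sample] = (idx, w)
    return out


def bmntd(
    comm: pd.DataFrame,
    pair: tuple[str, str],
    tree,
    abundance_weighted: bool = True,
) -> float:
    """beta-mean-nearest-taxon distance between two samples.

    For each taxon in one sample, takes the patristic distance to its closest
    relative present in the other sample, averages with relative-abundance
    weights (or 1/richness if unweighted), and symmetrizes:

        betaMNTD = 0.5 * [ sum_i f_iA d(i, B) + sum_j f_jB d(j, A) ]

    Parameters
    ----------
    comm : DataFrame
        samples x taxa counts; taxa must be tree tips.
    pair : (str, str)
        The two sample identifiers.
    tree : skbio.TreeNode, skbio.DistanceMatrix or labelled DataFrame
        Phylogeny, or a precomputed patristic matrix.
    abundance_weighted : bool
        Weight by relative abundance (default) or by presence.
    """
    _check_table(comm)
    dist = _align_distance(comm, tree)
    support = _sample_support(comm.loc[list(pair)], abundance_weighted)
    (idx_a, w_a), (idx_b, w_b) = support[pair[0]], support[pair[1]]
    return float(_bmntd_from_indices(dist, idx_a, w_a, idx_b, w_b))


def null_bmntd(
    comm: pd.DataFrame,
    tree,
    n_reps: int = 999,
    seed: int | np.random.Generator | None = None,
    abundance_weighted: bool = True,
    pairs: Iterable[tuple[str, str]] | None = None,
) -> dict[tuple[str, str], NullDistribution]:
    """Tip-shuffle null distributions of betaMNTD for every sample pair.

    Each iteration draws ONE random permutation of the assignment between tip
    labels and the taxa present in the table, shared across all pairs, and
    recomputes betaMNTD for every pair under that permutation. Returns a
    mapping ``(sample_a, sample_b) -> NullDistribution`` of length ``n_reps``.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    _check_table(comm)
    if comm.shape[1] < 2:
        raise ValueError("need at least 2 distinct taxa to shuffle tips")
    rng = np.random.default_rng(seed)
    dist = _align_distance(comm, tree)
    support = _sample_support(comm, abundance_weighted)
    if pairs is None:
        pairs = list(combinations(comm.index, 2))
    else:
        pairs = [tuple(p) for p in pairs]
    n_taxa = dist.shape[0]
    out = {p: np.empty(n_reps) for p in pairs}
    for rep in range(n_reps):
        perm = rng.permutation(n_taxa)
        d_perm = dist[np.ix_(perm, perm)]
        for p in pairs:
            (ia, wa), (ib, wb) = support[p[0]], support[p[1]]
            out[p][rep] = _bmntd_from_indices(d_perm, ia, wa, ib, wb)
    return {p: NullDistribution(v) for p, v in out.items()}


def bnti(bmntd_obs: float, null: NullDistribution) -> float:
    """beta-nearest-taxon index: (observed - null mean) / null sd."""
    sd = null.sd
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateNullError(
            "null betaMNTD distribution has zero spread; betaNTI is undefined "
            "(tiny tree or identical taxon supports)"
        )
    return float((bmntd_obs - null.mean) / sd)


# ---------------------------------------------------------------------------
# Raup-Crick (Bray-Curtis) null


def _weighted_subset(rng: np.random.Generator, weights: np.ndarray, k: int) -> np.ndarray:
    """k distinct indices, successively drawn with prob proportional to weights."""
    return rng.choice(weights.size, size=k, replace=False, p=weights / weights.sum())


def _null_sample(
    rng: np.random.Generator,
    occupancy: np.ndarray,
    rel_abund: np.ndarray,
    richness: int,
    total: int,
    n_taxa: int,
) -> np.ndarray:
    """One null community: identity by occupancy, filling by abundance.

    Draws ``richness`` distinct taxa with probability proportional to the
    number of samples each taxon occupies, gives each one individual, then
    allocates the remaining individuals multinomially with probability
    proportional to metacommunity relative abundance among the drawn taxa.
    """
    chosen = _weighted_subset(rng, occupancy, richness)
    counts = np.zeros(n_taxa)
    counts[chosen] = 1.0
    remaining = total - richness
    if remaining > 0:
        p = rel_abund[chosen]
        psum = p.sum()
        if psum <= 0:  # all drawn taxa vanishingly rare: fill uniformly
            p = np.full(richness, 1.0 / richness)
        else:
            p = p / psum
        counts[chosen] += rng.multinomial(remaining, p)
    return counts


def _pair_rng(seed, sample_a: str, sample_b: str) -> np.random.Generator:
    """Stable per-pair stream keyed by the sorted sample names."""
    key = "\x1f".join(sorted((str(sample_a), str(sample_b))))
    pair_entropy = zlib.crc32(key.encode())
    root = seed if isinstance(seed, (int, np.integer)) else 0
    return np.random.default_rng(np.random.SeedSequence([int(root), pair_entropy]))


def raup_crick_bray(
    comm: pd.DataFrame,
    pair: tuple[str, str],
    n_reps: int = 999,
    seed: int | None = None,
) -> float:
    """Abundance-based Raup-Crick metric on Bray-Curtis, in [-1, 1].

    Each of ``n_reps`` iterations reassembles both samples from the
    metacommunity (all samples in ``comm``) preserving each sample's observed
    richness and total individual count, and compares the null Bray-Curtis to
    the observed one. RC_bray = 2*[(#null < obs) + 0.5*(#null = obs)]/n - 1:
    +1 means the pair is more dissimilar than any null expectation
    (dispersal limitation + drift), -1 less dissimilar (homogenizing
    dispersal), ~0 consistent with drift alone.
    """
    _check_table(comm)
    counts = comm.to_numpy(dtype=float)
    occupancy = (counts > 0).sum(axis=0).astype(float)
    totals = counts.sum(axis=0)
    rel_abund = totals / totals.sum()
    n_taxa = counts.shape[1]

    # canonical sample order so RC(a, b) == RC(b, a) exactly
    ordered = sorted(pair, key=str)
    rows = comm.loc[ordered].to_numpy(dtype=float)
    obs = bray_curtis(rows[0], rows[1])
    n_pool = int((occupancy > 0).sum())
    rng = _pair_rng(seed, *pair)

    below = 0.0
    for _ in range(n_reps):
        nulls = []
        for row in rows:
            richness = int((row > 0).sum())
            if richness == 0:
                raise ValueError("RC_bray requires both samples to be nonzero")
            if richness > n_pool:
                raise ValueError(
                    f"sample richness {richness} exceeds the {n_pool} taxa "
                    "with nonzero metacommunity occupancy"
                )
            nulls.append(
                _null_sample(rng, occupancy, rel_abund, richness, int(row.sum()), n_taxa)
            )
        null_bc = bray_curtis(nulls[0], nulls[1])
        if null_bc < obs - RC_TIE_TOL:
            below += 1.0
        elif abs(null_bc - obs) <= RC_TIE_TOL:
            below += 0.5
    return float(2.0 * below / n_reps - 1.0)


# ---------------------------------------------------------------------------
# classification and profiles


def classify_process(bnti_value: float, rc_bray: float | None = None) -> str:
    """Assign a sample pair to one of the five assembly processes.

    betaNTI < -2 -> homogeneous selection; betaNTI > 2 -> heterogeneous
    selection; otherwise RC_bray < -0.95 -> homogenizing dispersal,
    RC_bray > 0.95 -> dispersal limitation + drift, else drift alone.
    Threshold values fall to the interior (stochastic) side.
    """
    if bnti_value < -BNTI_THRESHOLD:
        return "homogeneous_selection"
    if bnti_value > BNTI_THRESHOLD:
        return "heterogeneous_selection"
    if rc_bray is None:
        raise ValueError("rc_bray is required when |betaNTI| <= 2")
    if rc_bray < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    if rc_bray > RC_THRESHOLD:
        return "dispersal_limitation_drift"
    return "drift_alone"


def process_profile(
    results: Iterable[PairwiseAssembly],
    subset: str | Callable[[PairwiseAssembly], bool] = "all",
    groups: Mapping[str, str] | None = None,
    subset_label: str | None = None,
) -> ProcessProfile:
    """Fraction of pairwise comparisons assigned to each process.

    ``subset`` is ``"all"``, ``"within-group"`` (requires ``groups`` mapping
    sample -> group label; keeps pairs whose samples share a label), or a
    predicate on PairwiseAssembly records.
    """
    results = list(results)
    if subset == "all":
        selected = results
        label = subset_label or "all"
    elif subset == "within-group":
        if groups is None:
            raise ValueError("within-group subsetting requires a groups mapping")
        selected = [r for r in results if groups[r.sample_a] == groups[r.sample_b]]
        label = subset_label or "within-group"
    elif callable(subset):
        selected = [r for r in results if subset(r)]
        label = subset_label or "custom"
    else:
        raise ValueError(f"unknown subset rule: {subset!r}")
    if not selected:
        raise ValueError("subset selects no pairwise comparisons")
    n = len(selected)
    fractions = {p: sum(r.process == p for r in selected) / n for p in PROCESSES}
    return ProcessProfile(fractions=fractions, n_comparisons=n, subset_label=label)


def assembly_analysis(
    comm: pd.DataFrame,
    tree,
    n_reps: int = 999,
    rc_reps: int | None = None,
    seed: int | None = None,
    abundance_weighted: bool = True,
    pairs: Iterable[tuple[str, str]] | None = None,
) -> list[PairwiseAssembly]:
    """Full per-pair inference: betaMNTD, null, betaNTI, RC_bray, process.

    RC_bray is computed only for pairs whose |betaNTI| does not exceed the
    selection threshold. ``rc_reps`` defaults to ``n_reps``. ``pairs``
    restricts the comparisons (default: all sample pairs); the tip-shuffle
    pool and the RC metacommunity are always the full table.
    """
    _check_table(comm)
    if rc_reps is None:
        rc_reps = n_reps
    dist = _align_distance(comm, tree)
    dist_df = pd.DataFrame(dist, index=comm.columns, columns=comm.columns)
    support = _sample_support(comm, abundance_weighted)
    pairs = (
        list(combinations(comm.index, 2))
        if pairs is None
        else [tuple(p) for p in pairs]
    )
    nulls = null_bmntd(
        comm, dist_df, n_reps=n_reps, seed=seed,
        abundance_weighted=abundance_weighted, pairs=pairs,
    )
    records = []
    for a, b in pairs:
        (ia, wa), (ib, wb) = support[a], support[b]
        obs = float(_bmntd_from_indices(dist, ia, wa, ib, wb))
        null = nulls[(a, b)]
        if null.sd == 0 and abs(obs - null.mean) <= 1e-12:
            # identical taxon supports: betaMNTD is permutation-invariant, the
            # pair carries no phylogenetic information; no deviation from the
            # null, so fall through to the Raup-Crick test
            z = 0.0
        else:
            z = bnti(obs, null)
        rc = None
        if abs(z) <= BNTI_THRESHOLD:
            rc = raup_crick_bray(comm, (a, b), n_reps=rc_reps, seed=seed)
        records.append(
            PairwiseAssembly(
                sample_a=str(a),
                sample_b=str(b),
                bmntd_obs=obs,
                null_mean=null.mean,
                null_sd=null.sd,
                bnti=z,
                rc_bray=rc,
                process=classify_process(z, rc),
            )
        )
    return records


def results_frame(results: Iterable[PairwiseAssembly]) -> pd.DataFrame:
    """Long-format table of PairwiseAssembly records (one row per pair)."""
    return pd.DataFrame(
        [
            {
                "sample_a": r.sample_a,
                "sample_b": r.sample_b,
                "bmntd": r.bmntd_obs,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "bnti": r.bnti,
                "rc_bray": np.nan if r.rc_bray is None else r.rc_bray,
                "process": r.process,
            }
            for r in results
        ]
    )
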