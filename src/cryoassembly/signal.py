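"""Phylogenetic-signal testing via niche optima and Mantel correlograms.

Null-model inference from phylogenetic turnover is only interpretable when
closely related taxa are ecologically similar (phylogenetic signal at short
phylogenetic distances). This module estimates each taxon's environmental
optimum as the abundance-weighted mean of an abiotic variable over the samples
where it occurs, builds between-taxon optima distance matrices (Manhattan per
variable, or Euclidean over log-transformed optima for the combined test), and
correlates them with patristic distance in a Mantel correlogram: fifty
equal-width phylogenetic distance classes, permutation p-values and a
progressive Holm correction.

Sign convention: the raw Mantel correlation between an ecological *distance*
matrix and a within-class indicator is negated, so POSITIVE plotted values
mean taxa in that distance class are ecologically MORE similar than chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio

__all__ = [
    "CorrelogramResult",
    "niche_optima",
    "optima_distance",
    "combined_optima_distance",
    "patristic_matrix",
    "mantel_correlogram",
    "correlogram_frame",
]

#: abiotic variables evaluated by default, as column names of the metadata
DEFAULT_VARIABLES = ("gwc", "ph", "percent_n", "percent_c", "cn_ratio")


@dataclass(frozen=True)
class CorrelogramResult:
    """Mantel statistics for one phylogenetic distance class."""

    class_index: int
    class_midpoint: float
    n_pairs: int
    mantel_r: float
    p_raw: float
    p_corrected: float
    significant: bool
    testable: bool = True


def niche_optima(
    comm: pd.DataFrame, env: pd.DataFrame, variable: str | None = None
) -> pd.Series | pd.DataFrame:
    """Abundance-weighted mean environment (niche optimum) per taxon.

    optimum_i = sum_s count_is * env_s / sum_s count_is. A convex combination
    of sample values, so each optimum lies within the variable's observed
    range. Taxa with zero total abundance are excluded (with a warning).

    With ``variable=None`` returns a DataFrame over every numeric metadata
    column; otherwise a Series for that one variable.
    """
    missing = [s for s in comm.index if s not in env.index]
    if missing:
        raise KeyError(f"samples missing from the metadata: {missing}")
    counts = comm.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    present = totals > 0
    if not present.all():
        import warnings

        dropped = list(comm.columns[~present])
        warnings.warn(
            f"excluding {len(dropped)} taxa with zero total abundance: "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            stacklevel=2,
        )
    cols = (
        [variable]
        if variable is not None
        else list(env.select_dtypes("number").columns)
    )
    envv = env.loc[comm.index, cols].to_numpy(dtype=float)
    if not np.isfinite(envv).all():
        raise ValueError("environmental variables must be finite")
    opt = (counts[:, present].T @ envv) / totals[present, None]
    out = pd.DataFrame(opt, index=comm.columns[present], columns=cols)
    return out[variable] if variable is not None else out


def optima_distance(optima: pd.Series) -> pd.DataFrame:
    """Between-taxon Manhattan distance on a single variable's optima.

    On one variable this is simply |opt_i - opt_j|: symmetric, zero diagonal.
    """
    v = optima.to_numpy(dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("optima must be finite")
    d = np.abs(v[:, None] - v[None, :])
    return pd.DataFrame(d, index=optima.index, columns=optima.index)


def combined_optima_distance(
    optima: pd.DataFrame, log_base: float = 10.0, shift: bool = True
) -> pd.DataFrame:
    """Euclidean distance over log-transformed optima of all variables.

    Each variable's optima are log-transformed (base 10 by default) before the
    Euclidean distance across variables is taken, so no single variable's
    units dominate. Variables containing nonpositive optima are shifted by
    ``min + 1 unit in the log base`` to be strictly positive when ``shift`` is
    true, otherwise they raise.
    """
    x = optima.to_numpy(dtype=float).copy()
    for j, col in enumerate(optima.columns):
        mn = x[:, j].min()
        if mn <= 0:
            if not shift:
                raise ValueError(
                    f"variable {col!r} has nonpositive optima; enable shift"
                )
            x[:, j] = x[:, j] - mn + 1.0
    logx = np.log(x) / np.log(log_base)
    diff = logx[:, None, :] - logx[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    return pd.DataFrame(d, index=optima.index, columns=optima.index)


def patristic_matrix(tree: skbio.TreeNode) -> pd.DataFrame:
    """Tip-to-tip patristic distance matrix (sum of branch lengths on paths)."""
    for node in tree.preorder(include_self=False):
        if node.length is None:
            raise ValueError(f"branch above {node.name!r} has no length")
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)


# ---------------------------------------------------------------------------
# Mantel correlogram


def _condensed(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def _holm_progressive(p_raw: np.ndarray, testable: np.ndarray) -> np.ndarray:
    """Progressive Holm correction: class k is corrected over classes 1..k.

    Untestable classes are skipped and do not inflate the correction count.
    Returns corrected p-values (NaN where untestable).
    """
    out = np.full(p_raw.shape, np.nan)
    seen: list[float] = []
    for k in range(p_raw.size):
        if not testable[k]:
            continue
        seen.append(p_raw[k])
        m = len(seen)
        order = np.argsort(seen, kind="stable")
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * seen[idx])
            adj[idx] = min(running, 1.0)
        out[k] = adj[-1]  # corrected value of the newest (k-th) class
    return out


def mantel_correlogram(
    d_eco: pd.DataFrame,
    d_phylo: pd.DataFrame,
    n_classes: int = 50,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
) -> list[CorrelogramResult]:
    """Mantel correlogram of ecological vs phylogenetic distance.

    Phylogenetic distances are binned into ``n_classes`` equal-width classes
    over [0, max]. For class k a binary within-class indicator matrix is
    built; the Mantel statistic is the Pearson correlation between the
    ecological distances and that indicator over all off-diagonal pairs,
    negated so that positive r means within-class pairs are more similar than
    chance. Two-sided permutation p-values come from ``n_perm`` simultaneous
    row+column permutations of ``d_eco`` (taxon relabelling), and class k's
    p-value is Holm-corrected over classes 1..k (progressive). Classes with
    fewer than 2 member pairs (or with all pairs) are untestable and excluded
    from the correction.
    """
    if list(d_eco.index) != list(d_phylo.index):
        common = [t for t in d_phylo.index if t in d_eco.index]
        if len(common) < 3:
            raise ValueError("matrices share fewer than 3 taxa")
        d_eco = d_eco.loc[common, common]
        d_phylo = d_phylo.loc[common, common]
    eco = d_eco.to_numpy(dtype=float)
    phy = d_phylo.to_numpy(dtype=float)
    for name, m in (("ecological", eco), ("phylogenetic", phy)):
        if not np.allclose(m, m.T):
            raise ValueError(f"{name} distance matrix is not symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError(f"{name} distance matrix has nonzero diagonal")
    n = eco.shape[0]
    rng = np.random.default_rng(seed)

    phy_c = _condensed(phy)
    eco_c = _condensed(eco)
    npairs = phy_c.size

    edges = np.linspace(0.0, phy_c.max(), n_classes + 1)
    # right-inclusive last bin so the maximum lands in class n_classes
    which = np.clip(np.digitize(phy_c, edges[1:-1], right=False), 0, n_classes - 1)
    midpoints = 0.5 * (edges[:-1] + edges[1:])

    # class-membership indicator columns, centered, for vectorized Pearson r
    members = np.zeros((npairs, n_classes))
    members[np.arange(npairs), which] = 1.0
    counts = members.sum(axis=0).astype(int)
    testable = (counts >= 2) & (counts <= npairs - 2)
    m_c = members - members.mean(axis=0, keepdims=True)
    m_norm = np.linalg.norm(m_c, axis=0)
    m_norm[m_norm == 0] = np.nan

    def class_r(vec: np.ndarray) -> np.ndarray:
        v = vec - vec.mean()
        denom = np.linalg.norm(v) * m_norm
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (v @ m_c) / denom
        return -r  # positive = within-class ecological similarity

    r_obs = class_r(eco_c)

    iu = np.triu_indices(n, k=1)
    exceed = np.zeros(n_classes)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        eco_p = eco[np.ix_(perm, perm)][iu]
        exceed += np.abs(class_r(eco_p)) >= np.abs(r_obs) - 1e-15
    p_raw = (exceed + 1.0) / (n_perm + 1.0)
    p_raw[~testable] = np.nan
    p_corr = _holm_progressive(p_raw, testable)

    results = []
    for k in range(n_classes):
        ok = bool(testable[k]) and np.isfinite(r_obs[k])
        results.append(
            CorrelogramResult(
                class_index=k + 1,
                class_midpoint=float(midpoints[k]),
                n_pairs=int(counts[k]),
                mantel_r=float(r_obs[k]) if ok else float("nan"),
                p_raw=float(p_raw[k]) if ok else float("nan"),
                p_corrected=float(p_corr[k]) if ok else float("nan"),
                significant=bool(ok and p_corr[k] <= alpha),
                testable=ok,
            )
        )
    return results


def short_distance_signal(
    results: list[CorrelogramResult], fraction: float = 0.25
) -> bool:
    """Whether the correlogram shows significant positive r at short distances.

    True if any testable class whose midpoint lies within ``fraction`` of the
    largest class midpoint is significant (after the progressive correction)
    with positive Mantel r — the qualitative signature of phylogenetically
    conserved niches.
    """
    testable = [r for r in results if r.testable]
    if not testable:
        return False
    cutoff = fraction * max(r.class_midpoint for r in testable)
    return any(
        r.significant and r.mantel_r > 0
        for r in testable
        if r.class_midpoint <= cutoff
    )


def correlogram_frame(results: list[CorrelogramResult]) -> pd.DataFrame:
    """Correlogram results as a tidy table (one row per distance class)."""
    return pd.DataFrame(
        [
            {
                "class": r.class_index,
                "midpoint": r.class_midpoint,
                "n_pairs": r.n_pairs,
                "mantel_r": r.mantel_r,
                "p_raw": r.p_raw,
                "p_corrected": r.p_corrected,
                "significant": r.significant,
                "testable": r.testable,
            }
            for r in results
        ]
    )


def plot_correlogram(results: list[CorrelogramResult], ax=None, title: str = ""):
    """Plot a correlogram: filled markers are significant classes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    xs = [r.class_midpoint for r in results if r.testable]
    ys = [r.mantel_r for r in results if r.testable]
    sig = [r.significant for r in results if r.testable]
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.plot(xs, ys, "-", color="0.3", lw=1)
    for x, y, s in zip(xs, ys, sig):
        ax.plot(x, y, "o", mfc="black" if s else "white", mec="black", ms=5)
    ax.set_xlabel("phylogenetic distance class midpoint")
    ax.set_ylabel("Mantel r")
    if title:
        ax.set_title(title)
    return ax
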