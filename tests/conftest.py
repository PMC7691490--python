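import io

import numpy as np
import pandas as pd
import pytest
import skbio


@pytest.fixture
def cherry_tree():
    """((A:0.3,B:0.5):0.2,C:0.9); — hand-checkable three-tip tree."""
    return skbio.TreeNode.read(io.StringIO("((A:0.3,B:0.5):0.2,C:0.9);"))


@pytest.fixture
def five_taxon_tree():
    return skbio.TreeNode.read(
        io.StringIO("(((A:0.1,B:0.2):0.3,(C:0.15,D:0.25):0.2):0.1,E:0.7);")
    )


@pytest.fixture
def toy_table():
    """Two samples over five taxa with partial support overlap."""
    return pd.DataFrame(
        [[5, 3, 0, 2, 0], [0, 4, 6, 0, 1]],
        index=["S1", "S2"],
        columns=list("ABCDE"),
    )


def brute_force_bmntd(comm, pair, dist_df, weighted=True):
    """Independent oracle: explicit loops over taxa, explicit minimization."""
    total = 0.0
    for a, b in (pair, pair[::-1]):
        row_a = comm.loc[a]
        row_b = comm.loc[b]
        present_a = [t for t in comm.columns if row_a[t] > 0]
        present_b = [t for t in comm.columns if row_b[t] > 0]
        acc = 0.0
        for t in present_a:
            nearest = min(dist_df.loc[t, u] for u in present_b)
            w = row_a[t] / row_a.sum() if weighted else 1.0 / len(present_a)
            acc += w * nearest
        total += acc
    return 0.5 * total


def naive_patristic(tree):
    """Path-walk oracle: distance via explicit paths to the root."""
    tips = list(tree.tips())

    def path_to_root(tip):
        nodes, d = [], {}
        node, acc = tip, 0.0
        while node is not None:
            d[id(node)] = acc
            nodes.append(node)
            acc += node.length or 0.0
            node = node.parent
        return nodes, d

    out = pd.DataFrame(0.0, index=[t.name for t in tips], columns=[t.name for t in tips])
    for i, ti in enumerate(tips):
        nodes_i, di = path_to_root(ti)
        ids_i = {id(n) for n in nodes_i}
        for tj in tips[i + 1:]:
            node, up = tj, 0.0
            while id(node) not in ids_i:
                up += node.length or 0.0
                node = node.parent
            dist = up + di[id(node)]
            out.loc[ti.name, tj.name] = dist
            out.loc[tj.name, ti.name] = dist
    return out


def rc_exact(comm, pair, tie_tol=1e-12):
    """Exhaustive Raup-Crick expectation for tiny tables.

    Enumerates every null assembly of both samples (taxon subsets drawn
    successively without replacement with probability proportional to
    occupancy, then all multinomial allocations of the remaining individuals
    weighted by metacommunity relative abundance) and returns the exact
    RC_bray value 2*[P(null < obs) + 0.5*P(null = obs)] - 1.
    """
    from itertools import permutations

    from cryoassembly.assembly import bray_curtis

    counts = comm.to_numpy(dtype=float)
    occupancy = (counts > 0).sum(axis=0).astype(float)
    totals = counts.sum(axis=0)
    rel = totals / totals.sum()
    n_taxa = counts.shape[1]

    def subset_prob(subset):
        # sum over orderings of the without-replacement draw probabilities
        p = 0.0
        for order in permutations(subset):
            q, remaining = 1.0, occupancy.sum()
            for idx in order:
                q *= occupancy[idx] / remaining
                remaining -= occupancy[idx]
            p += q
        return p

    def allocations(remaining, k):
        if k == 1:
            yield (remaining,)
            return
        for first in range(remaining + 1):
            for rest in allocations(remaining - first, k - 1):
                yield (first,) + rest

    def null_distribution(row):
        from itertools import combinations
        from math import factorial

        richness = int((row > 0).sum())
        total = int(row.sum())
        occupied = [i for i in range(n_taxa) if occupancy[i] > 0]
        for subset in combinations(occupied, richness):
            ps = subset_prob(subset)
            p_vec = rel[list(subset)]
            p_vec = (
                p_vec / p_vec.sum()
                if p_vec.sum() > 0
                else np.full(richness, 1.0 / richness)
            )
            rem = total - richness
            for alloc in allocations(rem, richness):
                mult = factorial(rem)
                for a in alloc:
                    mult //= factorial(a)
                pa = mult * np.prod(p_vec ** np.array(alloc))
                vec = np.zeros(n_taxa)
                vec[list(subset)] = 1 + np.array(alloc)
                yield ps * pa, vec

    rows = comm.loc[list(pair)].to_numpy(dtype=float)
    obs = bray_curtis(rows[0], rows[1])
    below = 0.0
    for p1, v1 in null_distribution(rows[0]):
        for p2, v2 in null_distribution(rows[1]):
            bc = bray_curtis(v1, v2)
            if bc < obs - tie_tol:
                below += p1 * p2
            elif abs(bc - obs) <= tie_tol:
                below += 0.5 * p1 * p2
    return 2.0 * below - 1.0
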