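"""End-to-end parameter-recovery experiments on synthetic data.

These routines wire the generators to the inference stages and measure how
often each known assembly process is recovered — the package's analysis-level
validation surface. They are used by the test suite and by the reproduction
script, and are handy for sensitivity analyses.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from . import assembly as _assembly
from . import signal as _signal
from . import synthetic as _synthetic
from .flux import RatePair, q10

__all__ = [
    "five_process_recovery",
    "null_calibration",
    "bnti_rescaling_difference",
    "signal_replication_rate",
    "signal_false_positive_rate",
    "q10_recovery_error",
]


def five_process_recovery(
    config: _synthetic.SimulationConfig | None = None,
    n_reps: int = 999,
    seed: int | None = None,
) -> dict[str, float]:
    """Classify all regime pairs of one synthetic experiment.

    Runs the full inference (tip-shuffle nulls + RC_bray, ``n_reps``
    iterations) on the combined five-regime community table and returns the
    fraction of pairs recovered for each condition:

    * ``homogeneous_selection``: within-group selection pairs with that label;
    * ``heterogeneous_selection``: between-environment selection pairs;
    * ``homogenizing_dispersal``: within-regime pairs of the template copies;
    * ``dispersal_majority``: dispersal_limitation_drift fraction among the
      dispersal regime's stochastic (|betaNTI| <= 2) pairs;
    * ``drift_band``: drift-regime pairs inside the stochastic betaNTI band.
    """
    if config is None:
        config = _synthetic.SimulationConfig(seed=0 if seed is None else int(seed))
    data = _synthetic.five_process_dataset(config)
    comm, groups, tree = data["community"], data["groups"], data["tree"]
    by: dict[str, list[str]] = {}
    for s, g in groups.items():
        by.setdefault(g, []).append(s)
    pairs = {g: list(combinations(ss, 2)) for g, ss in by.items()}
    pairs["between"] = [(a, b) for a in by["selL"] for b in by["selH"]]
    all_pairs = [p for ps in pairs.values() for p in ps]
    records = _assembly.assembly_analysis(
        comm, tree, n_reps=n_reps, seed=config.seed if seed is None else seed,
        pairs=all_pairs,
    )
    rec = {(r.sample_a, r.sample_b): r for r in records}

    def frac(plist, label):
        return float(np.mean([rec[p].process == label for p in plist]))

    within_sel = pairs["selL"] + pairs["selH"]
    dis_stochastic = [
        p for p in pairs["dis"] if abs(rec[p].bnti) <= _assembly.BNTI_THRESHOLD
    ]
    return {
        "homogeneous_selection": frac(within_sel, "homogeneous_selection"),
        "heterogeneous_selection": frac(pairs["between"], "heterogeneous_selection"),
        "homogenizing_dispersal": frac(pairs["hom"], "homogenizing_dispersal"),
        "dispersal_majority": (
            frac(dis_stochastic, "dispersal_limitation_drift")
            if dis_stochastic
            else 0.0
        ),
        "drift_band": float(
            np.mean([abs(rec[p].bnti) < _assembly.BNTI_THRESHOLD for p in pairs["dri"]])
        ),
        "n_pairs": float(len(all_pairs)),
    }


def _calibration_table(seed: int):
    """Small drift community with varying taxon supports, plus its distances."""
    root = np.random.SeedSequence(seed)
    ss = [int(s) for s in root.generate_state(4) % (2**31)]
    tree = _synthetic.simulate_structured_tree(32, seed=ss[0])
    meta = _synthetic.lognormal_metacommunity(
        [t.name for t in tree.tips()], 1.5, seed=ss[1]
    )
    comm = _synthetic.assemble_neutral_drift(tree, meta, 4, 100, 50.0, seed=ss[2])
    comm = comm.loc[:, comm.sum(axis=0) > 0]
    return comm, tree, ss[3]


def null_calibration(
    n_obs: int = 200, n_reps: int = 999, seed: int = 0
) -> tuple[float, float]:
    """betaNTI of observations drawn from the null itself.

    Builds one tip-shuffle null distribution, draws ``n_obs`` further shuffled
    betaMNTD values as pseudo-observations, and returns the (mean, sd) of
    their betaNTI. A calibrated null gives mean ~ 0 and sd ~ 1.
    """
    comm, tree, sub = _calibration_table(seed)
    from .assembly import (
        NullDistribution,
        _align_distance,
        _bmntd_from_indices,
        _sample_support,
    )

    dist = _align_distance(comm, tree)
    sup = _sample_support(comm, True)
    rng = np.random.default_rng(sub)
    n = comm.shape[1]
    # pool betaNTI over every sample pair so the estimate does not hinge on
    # one pair's null shape (permutation nulls are skewed at small taxon counts)
    pairs = list(combinations(comm.index, 2))
    per_pair = max(1, n_obs // len(pairs))
    z_all = []
    for a, b in pairs:
        (ia, wa), (ib, wb) = sup[a], sup[b]
        null = NullDistribution(
            np.array(
                [
                    _bmntd_from_indices(dist[np.ix_(p, p)], ia, wa, ib, wb)
                    for p in (rng.permutation(n) for _ in range(n_reps))
                ]
            )
        )
        obs = np.array(
            [
                _bmntd_from_indices(dist[np.ix_(p, p)], ia, wa, ib, wb)
                for p in (rng.permutation(n) for _ in range(per_pair))
            ]
        )
        z_all.append((obs - null.mean) / null.sd)
    z = np.concatenate(z_all)
    return float(z.mean()), float(z.std(ddof=1))


def bnti_rescaling_difference(scale: float = 3.7, seed: int = 0) -> float:
    """|betaNTI difference| under uniform branch-length rescaling (should be ~0)."""
    comm, tree, sub = _calibration_table(seed)
    dist = _signal.patristic_matrix(tree).loc[comm.columns, comm.columns]
    pair = (comm.index[0], comm.index[1])
    obs = _assembly.bmntd(comm, pair, dist)
    null = _assembly.null_bmntd(comm, dist, n_reps=299, seed=sub, pairs=[pair])[pair]
    z = _assembly.bnti(obs, null)
    null_s = _assembly.null_bmntd(
        comm, dist * scale, n_reps=299, seed=sub, pairs=[pair]
    )[pair]
    z_s = _assembly.bnti(obs * scale, null_s)
    return abs(z - z_s)


def _gradient_dataset(seed: int, n_taxa: int = 100, n_samples: int = 20):
    """Niche optima estimated from selection communities along a gradient."""
    import warnings

    root = np.random.SeedSequence(seed)
    ss = [int(s) for s in root.generate_state(4) % (2**31)]
    tree = _synthetic.simulate_tree(n_taxa, seed=ss[0])
    trait = _synthetic.evolve_trait_bm(tree, 1.0, seed=ss[1])
    trait = (trait - trait.mean()) / trait.std(ddof=0)
    env = np.linspace(-2.0, 2.0, n_samples)
    tables = [
        _synthetic.assemble_selection(
            tree, trait, e, 1, 1000, 0.5, seed=ss[2] + i,
            sample_prefix=f"g{i}_", drift_concentration=10.0,
        )
        for i, e in enumerate(env)
    ]
    comm = pd.concat(tables)
    meta = pd.DataFrame({"env": env}, index=comm.index)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        optima = _signal.niche_optima(comm, meta, "env")
    d_phy = _signal.patristic_matrix(tree).loc[optima.index, optima.index]
    return optima, d_phy, ss[3]


def signal_replication_rate(
    n_runs: int = 50, n_perm: int = 999, seed: int = 0
) -> float:
    """Fraction of seeded runs showing short-distance phylogenetic signal.

    Each run evolves a Brownian niche trait on a fresh 100-tip tree, assembles
    selection communities along an environmental gradient, estimates
    abundance-weighted niche optima, and tests whether the Mantel correlogram
    shows a significant positive class at short phylogenetic distance.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_runs):
        optima, d_phy, sub = _gradient_dataset(int(rng.integers(2**31)))
        res = _signal.mantel_correlogram(
            _signal.optima_distance(optima), d_phy, n_perm=n_perm, seed=sub
        )
        hits += _signal.short_distance_signal(res)
    return hits / n_runs


def signal_false_positive_rate(
    n_runs: int = 100, n_perm: int = 999, alpha: float = 0.05, seed: int = 0
) -> float:
    """First-class rejection rate when optima are shuffled across taxa."""
    optima, d_phy, sub = _gradient_dataset(seed)
    rng = np.random.default_rng(sub)
    hits = 0
    for _ in range(n_runs):
        shuffled = pd.Series(rng.permutation(optima.to_numpy()), index=optima.index)
        res = _signal.mantel_correlogram(
            _signal.optima_distance(shuffled), d_phy, n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        )
        first = next((r for r in res if r.testable), None)
        hits += bool(first is not None and first.p_raw <= alpha)
    return hits / n_runs


def q10_recovery_error(
    q10_true: float = 2.5,
    noise_cv: float = 0.1,
    n_replicates: int = 200,
    seed: int = 0,
) -> float:
    """Relative error of the median recovered Q10 over noisy replicates."""
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(n_replicates):
        s = _synthetic.simulate_respiration(
            1.0, q10_true, days=range(10), measurement_noise_cv=noise_cv,
            seed=int(rng.integers(2**31)),
        )
        values.append(q10(RatePair(k15=s["rate_15c"].mean(), k4=s["rate_4c"].mean())))
    return abs(float(np.median(values)) - q10_true) / q10_true
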