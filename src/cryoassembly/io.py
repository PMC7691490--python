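"""Readers, writers, rarefaction and pipeline orchestration.

Formats are deliberately plain: newick trees, tab-separated count tables
(samples as rows, taxa as columns, header row and index column), tab-separated
metadata keyed by sample. Rarefaction subsamples each sample's individuals
without replacement (multivariate hypergeometric) to a fixed depth; samples
below the depth are dropped and reported, mirroring how rarefied amplicon
tables are prepared upstream of assembly analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

from . import assembly as _assembly
from . import signal as _signal

__all__ = [
    "RunConfig",
    "read_tree",
    "write_tree",
    "read_table",
    "write_table",
    "read_metadata",
    "rarefy",
    "run_pipeline",
]


def read_tree(path) -> skbio.TreeNode:
    """Read a rooted newick tree; require unique tips and branch lengths."""
    tree = skbio.TreeNode.read(str(path), format="newick")
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        dupes = sorted({t for t in tips if tips.count(t) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    for node in tree.preorder(include_self=False):
        if node.length is None:
            raise ValueError(
                f"branch above {node.name or 'an internal node'} has no length"
            )
    if len(tree.children) > 2:
        raise ValueError("tree appears unrooted (root has more than two children)")
    return tree


def write_tree(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_table(path) -> pd.DataFrame:
    """Read a samples x taxa TSV count table with integer entries."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError("duplicate sample or taxon identifiers in count table")
    values = df.to_numpy()
    if not np.isfinite(values.astype(float)).all():
        raise ValueError("count table contains non-finite entries")
    if not np.allclose(values.astype(float) % 1, 0):
        raise ValueError("count table contains non-integer entries")
    if (values.astype(float) < 0).any():
        raise ValueError("count table contains negative entries")
    return df.astype(int)


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_metadata(path, samples=None) -> pd.DataFrame:
    """Read sample metadata TSV; optionally check coverage of given samples."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample identifiers in metadata")
    if samples is not None:
        missing = [s for s in samples if s not in meta.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
    return meta


def check_taxa_against_tree(table: pd.DataFrame, tree: skbio.TreeNode) -> None:
    tips = {t.name for t in tree.tips()}
    missing = [t for t in table.columns if t not in tips]
    if missing:
        raise ValueError(f"taxa absent from the tree: {missing}")


def rarefy(
    comm: pd.DataFrame,
    depth: int,
    seed: int | None = None,
    with_replacement: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Rarefy each sample to exactly ``depth`` individuals.

    Subsampling is uniform WITHOUT replacement over each sample's individuals
    (multivariate hypergeometric), the behaviour of standard amplicon
    pipelines; ``with_replacement=True`` switches to multinomial resampling.
    Samples whose total is below ``depth`` are dropped; taxa left with all-zero
    columns are removed. Returns ``(rarefied table, dropped sample ids)``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = comm.sum(axis=1)
    dropped = list(comm.index[totals < depth])
    kept = comm.loc[totals >= depth]
    if kept.empty:
        raise ValueError(f"all samples fall below rarefaction depth {depth}")
    rows = []
    for _, row in kept.iterrows():
        counts = row.to_numpy(dtype=np.int64)
        if counts.sum() == depth:
            rows.append(counts)
        elif with_replacement:
            rows.append(rng.multinomial(depth, counts / counts.sum()))
        else:
            rows.append(rng.multivariate_hypergeometric(counts, depth))
    out = pd.DataFrame(np.vstack(rows), index=kept.index, columns=kept.columns)
    out = out.loc[:, out.sum(axis=0) > 0]
    return out, dropped


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class RunConfig:
    """Configuration for one reproducible pipeline run."""

    tree: str | None = None
    table: str | None = None
    metadata: str | None = None
    out_dir: str = "cryoassembly_out"
    stage: str = "assembly"  # assembly | signal
    rarefaction_depth: int = 2500
    group_column: str = "group"
    reps: int = 999
    seed: int = 0
    abundance_weighted: bool = True
    signal_variables: tuple[str, ...] = _signal.DEFAULT_VARIABLES
    n_classes: int = 50
    subset: str = "all"  # all | within-group

    def __post_init__(self):
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be >= 1")
        if self.reps < 2:
            raise ValueError("reps must be >= 2")
        if self.stage not in ("assembly", "signal"):
            raise ValueError(f"unknown stage: {self.stage!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Rarefy, run the configured stage, and write versioned outputs.

    Writes the rarefied table, stage outputs and a machine-readable
    ``manifest.json`` recording the seed, rarefaction depth, dropped samples
    and the conventions in force (boundary rules, log shifts). Outputs are a
    pure function of (inputs, config, seed).
    """
    for name in ("tree", "table"):
        if getattr(config, name) is None:
            raise ValueError(f"config is missing the {name} path for this stage")
    tree = read_tree(config.tree)
    comm = read_table(config.table)
    check_taxa_against_tree(comm, tree)
    meta = None
    if config.metadata is not None:
        meta = read_metadata(config.metadata, samples=comm.index)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rare, dropped = rarefy(comm, config.rarefaction_depth, seed=config.seed)
    write_table(rare, out / "rarefied_table.tsv")

    manifest = {
        "stage": config.stage,
        "seed": config.seed,
        "reps": config.reps,
        "rarefaction_depth": config.rarefaction_depth,
        "rarefaction": "without replacement (multivariate hypergeometric)",
        "dropped_samples": dropped,
        "n_samples": int(rare.shape[0]),
        "n_taxa": int(rare.shape[1]),
        "boundary_convention": "threshold values fall to the stochastic side",
        "outputs": ["rarefied_table.tsv"],
    }
    results: dict = {"rarefied": rare, "dropped": dropped}

    if config.stage == "assembly":
        records = _assembly.assembly_analysis(
            rare,
            tree,
            n_reps=config.reps,
            seed=config.seed,
            abundance_weighted=config.abundance_weighted,
        )
        frame = _assembly.results_frame(records)
        frame.to_csv(out / "pairwise_assembly.tsv", sep="\t", index=False)
        manifest["outputs"].append("pairwise_assembly.tsv")
        profiles = [_assembly.process_profile(records, "all")]
        if meta is not None and config.group_column in meta.columns:
            groups = meta.loc[rare.index, config.group_column].to_dict()
            for g in sorted(set(groups.values())):
                pairs = [
                    r
                    for r in records
                    if groups[r.sample_a] == g and groups[r.sample_b] == g
                ]
                if pairs:
                    profiles.append(
                        _assembly.process_profile(pairs, "all", subset_label=str(g))
                    )
                else:
                    manifest.setdefault("untestable_groups", []).append(str(g))
        prof_frame = pd.DataFrame(
            [
                {"subset": p.subset_label, "n_comparisons": p.n_comparisons}
                | dict(p.fractions)
                for p in profiles
            ]
        )
        prof_frame.to_csv(out / "process_profiles.tsv", sep="\t", index=False)
        manifest["outputs"].append("process_profiles.tsv")
        results |= {"pairwise": records, "profiles": profiles}

    elif config.stage == "signal":
        if meta is None:
            raise ValueError("the signal stage requires a metadata table")
        optima = _signal.niche_optima(rare, meta)
        dphy = _signal.patristic_matrix(tree).loc[optima.index, optima.index]
        tables = {}
        for var in config.signal_variables:
            if var == "combined":
                deco = _signal.combined_optima_distance(optima)
            else:
                deco = _signal.optima_distance(optima[var])
            res = _signal.mantel_correlogram(
                deco, dphy, n_classes=config.n_classes,
                n_perm=config.reps, seed=config.seed,
            )
            frame = _signal.correlogram_frame(res)
            frame.to_csv(out / f"correlogram_{var}.tsv", sep="\t", index=False)
            manifest["outputs"].append(f"correlogram_{var}.tsv")
            tables[var] = res
        manifest["log_transform"] = (
            "combined optima: log10 with additive shift to min+1 when nonpositive"
        )
        results |= {"correlograms": tables, "optima": optima}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results
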