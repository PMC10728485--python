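"""Response-gene selection from per-cluster differential expression.

Each (cluster, treatment timepoint) is contrasted against the control
subset of the same cluster.  The DE engine is pluggable: the built-in
engine aggregates raw counts into replicate-level pseudobulks and runs
a Welch t-test on log-CPM with Benjamini-Hochberg adjustment per
contrast; results from an external engine (e.g. a negative-binomial
GLM run in R) can be supplied as a CSV table instead.

A gene qualifies as a response gene when at least one of its records is
simultaneously significant and strongly fold-changed; its summary
p-value is the minimum adjusted p over all its records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from stimflow.io_core import CLUSTER_COL, REPLICATE_COL, TIME_COL, ExpressionDataset, TimepointDesign

DE_COLUMNS = ["gene", "cluster", "timepoint", "adj_p", "log_fc"]


@dataclass
class DEResult:
    """Records of (gene, cluster, timepoint, adj_p, log_fc)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"DE table missing columns {missing}")
        self.table = self.table[DE_COLUMNS].reset_index(drop=True)
        p = self.table["adj_p"]
        if ((p < 0) | (p > 1)).any():
            raise ValueError("adjusted p-values must lie in [0, 1]")
        if self.table.duplicated(["gene", "cluster", "timepoint"]).any():
            raise ValueError("duplicate (gene, cluster, timepoint) records")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ResponseGeneSet:
    """Selected genes sorted by ascending minimum adjusted p-value."""

    table: pd.DataFrame  # columns: gene, min_adj_p, max_abs_lfc
    alpha: float
    min_lfc: float

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()

    def __len__(self) -> int:
        return len(self.table)


def _cpm(counts: np.ndarray) -> np.ndarray:
    totals = counts.sum(axis=1, keepdims=True)
    return counts / np.maximum(totals, 1e-300) * 1e6


def run_de(
    dataset: ExpressionDataset | None,
    engine: str = "builtin_pseudobulk",
    table_path: str | None = None,
    design: TimepointDesign | None = None,
    cluster_col: str = CLUSTER_COL,
    replicate_col: str = REPLICATE_COL,
    time_col: str = TIME_COL,
) -> DEResult:
    """Differential expression per (cluster, treatment timepoint) vs control.

    ``builtin_pseudobulk`` sums raw counts per (replicate, cluster,
    timepoint), computes log2 fold change on mean CPM + 1, runs a
    two-sided Welch t-test on log2(CPM + 1) per gene, and BH-adjusts
    p-values within each contrast.  Contrasts with fewer than two
    replicates on either side are skipped with a warning.

    ``external_table`` simply loads a DE CSV (columns ``gene, cluster,
    timepoint, adj_p, log_fc``) produced by any external engine.
    """
    if engine == "external_table":
        if table_path is None:
            raise ValueError("external_table engine requires table_path")
        return DEResult(pd.read_csv(table_path, dtype={"gene": str}))
    if engine != "builtin_pseudobulk":
        raise ValueError(f"unknown engine {engine!r}")
    if dataset is None:
        raise ValueError("builtin_pseudobulk requires a dataset")
    if dataset.state != "raw":
        raise ValueError("builtin_pseudobulk expects raw counts")
    if design is None:
        raise ValueError("builtin_pseudobulk requires a TimepointDesign")

    meta = dataset.cell_meta
    X = dataset.dense()
    control_label = design.labels[0]
    records: list[pd.DataFrame] = []
    for cluster in sorted(meta[cluster_col].unique(), key=str):
        in_cluster = (meta[cluster_col] == cluster).to_numpy()
        # pseudobulk: one count vector per (timepoint, replicate)
        bulks: dict[str, list[np.ndarray]] = {}
        for tp in design.labels:
            sel = in_cluster & (meta[time_col].astype(str) == tp).to_numpy()
            reps = []
            for rep in sorted(meta.loc[sel, replicate_col].unique(), key=str):
                rows = sel & (meta[replicate_col] == rep).to_numpy()
                reps.append(X[rows].sum(axis=0))
            bulks[tp] = reps
        ctrl = bulks.get(control_label, [])
        if len(ctrl) < 2:
            warnings.warn(
                f"cluster {cluster!r}: fewer than 2 control replicates; skipped",
                stacklevel=2,
            )
            continue
        ctrl_cpm = _cpm(np.vstack(ctrl))
        ctrl_log = np.log2(ctrl_cpm + 1.0)
        for tp in design.labels[1:]:
            trt = bulks.get(tp, [])
            if len(trt) < 2:
                warnings.warn(
                    f"contrast ({cluster!r}, {tp!r}): fewer than 2 treatment "
                    "replicates; skipped",
                    stacklevel=2,
                )
                continue
            trt_cpm = _cpm(np.vstack(trt))
            trt_log = np.log2(trt_cpm + 1.0)
            log_fc = np.log2(trt_cpm.mean(axis=0) + 1.0) - np.log2(
                ctrl_cpm.mean(axis=0) + 1.0
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                _, pvals = stats.ttest_ind(trt_log, ctrl_log, equal_var=False, axis=0)
            pvals = np.nan_to_num(np.asarray(pvals), nan=1.0)
            adj_p = multipletests(pvals, method="fdr_bh")[1]
            records.append(
                pd.DataFrame(
                    {
                        "gene": dataset.gene_names,
                        "cluster": cluster,
                        "timepoint": tp,
                        "adj_p": adj_p,
                        "log_fc": log_fc,
                    }
                )
            )
    if not records:
        raise ValueError("no testable contrasts (need >= 2 replicates per side)")
    return DEResult(pd.concat(records, ignore_index=True))


def select_response_genes(
    de: DEResult, alpha: float = 0.05, min_lfc: float = 1.0
) -> ResponseGeneSet:
    """Keep genes significant and fold-changed in at least one contrast.

    A gene qualifies if any of its records has adjusted p <= ``alpha``
    and |log_fc| > ``min_lfc``.  Each kept gene is summarized by its
    minimum adjusted p-value over ALL its records and its maximum
    |log_fc|; the result is sorted ascending by that minimum p (ties by
    larger max |log_fc|, then gene name).
    """
    if len(de) == 0:
        raise ValueError("empty DE result")
    t = de.table
    hit = (t["adj_p"] <= alpha) & (t["log_fc"].abs() > min_lfc)
    qualifying = set(t.loc[hit, "gene"])
    sub = t[t["gene"].isin(qualifying)]
    summary = (
        sub.groupby("gene")
        .agg(min_adj_p=("adj_p", "min"), max_abs_lfc=("log_fc", lambda s: s.abs().max()))
        .reset_index()
    )
    summary = summary.sort_values(
        ["min_adj_p", "max_abs_lfc", "gene"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return ResponseGeneSet(table=summary, alpha=alpha, min_lfc=min_lfc)


def top_k_response_genes(gene_set: ResponseGeneSet, k: int = 500) -> ResponseGeneSet:
    """First ``k`` genes by minimum adjusted p.

    Ties at the boundary are broken by larger max |log_fc|, then by
    lexicographic gene name (the set is already sorted with those
    keys).  ``k`` larger than the set returns everything.
    """
    return ResponseGeneSet(
        table=gene_set.table.head(k).reset_index(drop=True),
        alpha=gene_set.alpha,
        min_lfc=gene_set.min_lfc,
    )
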