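"""Count-matrix QC, pseudo-bulk differential expression, and lamin A vs
lamin C splice-junction classification.

QC applies the thresholds used for the rod scRNA-seq data: genes detected
in fewer than 3 cells are dropped, then cells with fewer than 200 or more
than 2500 detected genes, or more than 18% mitochondrial counts, are
excluded.  Differential expression is a deliberately simple pseudo-bulk
estimator: library-size (CPM) normalization, a pseudocounted log2 ratio of
group means, and a negative-binomial Wald test with method-of-moments
dispersion — an approximation to a full shrinkage-based NB GLM, adequate
for planted-effect recovery at the fold-changes of interest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Genes x units (cells or samples) of raw integer counts."""

    counts: pd.DataFrame  # index: gene names, columns: unit ids
    unit_meta: pd.DataFrame | None = None  # index: unit ids; e.g. group, replicate

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("gene names must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.unit_meta is not None:
            self.unit_meta = self.unit_meta.loc[self.counts.columns]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_units(self) -> int:
        return self.counts.shape[1]

    def cpm(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=0)
        return self.counts.divide(totals, axis=1) * 1e6

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, unit_meta: pd.DataFrame | None = None) -> "CountMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0), unit_meta)

    def to_mtx(self, prefix) -> None:
        """Write MatrixMarket triplet plus gene / unit name sidecars."""
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(str(prefix) + ".mtx", csr_matrix(self.counts.to_numpy()))
        pd.Series(self.counts.index).to_csv(str(prefix) + ".genes.tsv", sep="\t", index=False, header=False)
        pd.Series(self.counts.columns).to_csv(str(prefix) + ".units.tsv", sep="\t", index=False, header=False)

    @classmethod
    def from_mtx(cls, prefix, unit_meta: pd.DataFrame | None = None) -> "CountMatrix":
        from scipy.io import mmread

        mat = np.asarray(mmread(str(prefix) + ".mtx").todense())
        genes = pd.read_csv(str(prefix) + ".genes.tsv", sep="\t", header=None)[0]
        units = pd.read_csv(str(prefix) + ".units.tsv", sep="\t", header=None)[0]
        return cls(pd.DataFrame(mat, index=genes, columns=units), unit_meta)


@dataclass
class QCThresholds:
    min_genes_per_cell: int = 200
    max_genes_per_cell: int = 2500
    max_mito_fraction: float = 0.18
    min_cells_per_gene: int = 3

    def __post_init__(self) -> None:
        if self.min_genes_per_cell >= self.max_genes_per_cell:
            raise ValueError("min_genes_per_cell must be < max_genes_per_cell")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in [0, 1]")


@dataclass
class IsoformModelSet:
    """Diagnostic and shared splice junctions for two isoforms (LA / LC)."""

    diagnostic: dict[str, list[tuple[str, int, int]]]  # isoform -> [(chrom, donor, acceptor)]
    shared: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        sets = {iso: {tuple(j) for j in js} for iso, js in self.diagnostic.items()}
        names = list(sets)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if sets[names[i]] & sets[names[j]]:
                    raise ValueError("diagnostic junction sets must be disjoint")
        self.diagnostic = {iso: [tuple(j) for j in js] for iso, js in self.diagnostic.items()}
        self.shared = [tuple(j) for j in self.shared]

    @classmethod
    def from_json(cls, path) -> "IsoformModelSet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            diagnostic={k: [tuple(j) for j in v] for k, v in payload["diagnostic"].items()},
            shared=[tuple(j) for j in payload.get("shared", [])],
        )

    @classmethod
    def packaged_lmna(cls) -> "IsoformModelSet":
        """The packaged schematic Lmna model (synthetic coordinates)."""
        from importlib.resources import files

        path = files("tetherscope.data").joinpath("lmna_isoforms_synthetic.json")
        with path.open() as fh:
            payload = json.load(fh)
        return cls(
            diagnostic={k: [tuple(j) for j in v] for k, v in payload["diagnostic"].items()},
            shared=[tuple(j) for j in payload.get("shared", [])],
        )


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------


def qc_filter(
    matrix: CountMatrix,
    thresholds: QCThresholds | None = None,
    mito_prefix: str = "mt-",
) -> tuple[CountMatrix, dict]:
    """Apply the QC thresholds; returns the filtered matrix and a report.

    Order of operations: (1) genes detected in fewer than
    ``min_cells_per_gene`` cells are removed; (2) cells failing any of the
    three cell rules are removed, with the mitochondrial fraction computed
    on totals *before* gene removal.
    """
    thresholds = thresholds or QCThresholds()
    counts = matrix.counts
    if counts.size == 0:
        raise ValueError("empty count matrix")

    detected = counts > 0
    # cell metrics on the pre-filter matrix
    mito = counts.index.str.startswith(mito_prefix)
    total_per_cell = counts.sum(axis=0)
    mito_frac = counts.loc[mito].sum(axis=0) / total_per_cell.replace(0, np.nan)
    mito_frac = mito_frac.fillna(0.0)

    gene_keep = detected.sum(axis=1) >= thresholds.min_cells_per_gene
    genes_removed = int((~gene_keep).sum())
    counts_g = counts.loc[gene_keep]

    genes_per_cell = (counts_g > 0).sum(axis=0)
    fail_low = genes_per_cell < thresholds.min_genes_per_cell
    fail_high = genes_per_cell > thresholds.max_genes_per_cell
    fail_mito = mito_frac > thresholds.max_mito_fraction
    cell_keep = ~(fail_low | fail_high | fail_mito)
    if not cell_keep.any():
        raise ValueError("no cells survive QC")

    filtered = CountMatrix(
        counts_g.loc[:, cell_keep].copy(),
        matrix.unit_meta.loc[cell_keep[cell_keep].index] if matrix.unit_meta is not None else None,
    )
    report = {
        "genes_removed_min_cells": genes_removed,
        "cells_removed_low_genes": int(fail_low.sum()),
        "cells_removed_high_genes": int(fail_high.sum()),
        "cells_removed_mito": int(fail_mito.sum()),
        "cells_removed_total": int((~cell_keep).sum()),
        "genes_kept": int(gene_keep.sum()),
        "cells_kept": int(cell_keep.sum()),
        "thresholds": thresholds.__dict__,
        "mito_prefix": mito_prefix,
        "order": "genes-first; mito fraction on pre-filter totals",
    }
    return filtered, report


# ---------------------------------------------------------------------------
# Pseudo-bulk differential expression
# ---------------------------------------------------------------------------


def pseudobulk_lfc(
    matrix: CountMatrix,
    groups: pd.Series | dict,
    case: str,
    control: str,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Pseudo-bulk log2 fold-change (case vs control) with an NB Wald test.

    CPM-normalizes each unit, then per gene computes
    ``log2((mean_CPM_case + pc) / (mean_CPM_control + pc))``.  The p-value
    comes from a Wald z on the log2 ratio with a delta-method standard
    error under a negative-binomial mean-variance relationship; per-gene
    dispersion is method-of-moments, floored at 0.01.  BH adjustment across
    genes.  Genes with zero counts in both groups get LFC 0 and p 1.
    """
    groups = pd.Series(groups)
    case_units = groups.index[groups == case]
    ctrl_units = groups.index[groups == control]
    if len(case_units) < 2 or len(ctrl_units) < 2:
        raise ValueError("need >= 2 units per group")
    cpm = matrix.cpm()
    for name, units in (("case", case_units), ("control", ctrl_units)):
        if matrix.counts[units].to_numpy().sum() == 0:
            raise ValueError(f"{name} group has zero total counts")

    a, b = cpm[case_units].to_numpy(), cpm[ctrl_units].to_numpy()
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    lfc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))

    # method-of-moments NB dispersion pooled across groups, floored
    pooled_mean = np.concatenate([a, b], axis=1).mean(axis=1)
    within_var = (a.var(axis=1, ddof=1) * (a.shape[1] - 1) + b.var(axis=1, ddof=1) * (b.shape[1] - 1)) / (
        a.shape[1] + b.shape[1] - 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (within_var - pooled_mean) / pooled_mean**2
    disp = np.where(np.isfinite(disp), disp, 0.01)
    disp = np.maximum(disp, 0.01)

    # delta-method variance of log2(mean + pc) under Var(X) = mu + disp*mu^2
    def _var_log2_mean(mu: np.ndarray, n: int) -> np.ndarray:
        var_mean = (mu + disp * mu**2) / n
        return var_mean / ((mu + pseudocount) ** 2 * np.log(2) ** 2)

    se = np.sqrt(_var_log2_mean(mean_a, a.shape[1]) + _var_log2_mean(mean_b, b.shape[1]))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))

    both_zero = (mean_a == 0) & (mean_b == 0)
    lfc[both_zero] = 0.0
    pvals[both_zero] = 1.0

    padj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2_fc": lfc,
            "p_value": pvals,
            "p_adj": padj,
            "mean_cpm_case": mean_a,
            "mean_cpm_control": mean_b,
        },
        index=matrix.counts.index,
    )


# ---------------------------------------------------------------------------
# Splice-junction classification (lamin A vs lamin C)
# ---------------------------------------------------------------------------


def classify_junctions(
    junctions: pd.DataFrame, models: IsoformModelSet
) -> dict:
    """Estimate the lamin A fraction from diagnostic splice-junction reads.

    ``junctions`` has columns chrom, donor, acceptor, count.  Reads at
    junctions shared between the isoforms are excluded from the ratio.
    ``alpha_la`` = LA-diagnostic / (LA-diagnostic + LC-diagnostic), with an
    exact (Clopper-Pearson) binomial 95% CI.  With zero diagnostic reads
    the estimate is undefined and flagged, not an error.
    """
    lookup = {}
    for iso, js in models.diagnostic.items():
        for j in js:
            lookup[tuple(j)] = iso
    per_iso = {iso: 0 for iso in models.diagnostic}
    shared_set = {tuple(j) for j in models.shared}
    shared_count = 0
    for _, row in junctions.iterrows():
        key = (row["chrom"], int(row["donor"]), int(row["acceptor"]))
        if key in lookup:
            per_iso[lookup[key]] += int(row["count"])
        elif key in shared_set:
            shared_count += int(row["count"])

    n_la, n_lc = per_iso.get("LA", 0), per_iso.get("LC", 0)
    n = n_la + n_lc
    result = {
        "diagnostic_counts": per_iso,
        "shared_count": shared_count,
        "n_diagnostic": n,
    }
    if n == 0:
        result.update({"alpha_la": None, "ci_95": None, "flag": "no diagnostic reads"})
        return result
    lo, hi = proportion_confint(n_la, n, alpha=0.05, method="beta")
    result.update({"alpha_la": n_la / n, "ci_95": (float(lo), float(hi)), "flag": None})
    return result


# ---------------------------------------------------------------------------
# Gene-set expression summary
# ---------------------------------------------------------------------------


def gene_set_expression_summary(
    matrix: CountMatrix,
    gene_set: list[str],
    groups: pd.Series | dict,
    case: str,
    control: str,
) -> dict:
    """Per-group CPM summary for a gene set plus a paired location test.

    Gene-level group means are compared with a Wilcoxon signed-rank test
    for a systematic shift of the set as a whole.
    """
    groups = pd.Series(groups)
    present = [g for g in gene_set if g in matrix.counts.index]
    if not present:
        raise ValueError("gene_set does not intersect the matrix genes")
    cpm = matrix.cpm().loc[present]
    mean_case = cpm[groups.index[groups == case]].mean(axis=1)
    mean_ctrl = cpm[groups.index[groups == control]].mean(axis=1)
    diffs = (mean_case - mean_ctrl).to_numpy()
    if np.allclose(diffs, 0.0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(diffs, zero_method="zsplit").pvalue)
    return {
        "n_genes": len(present),
        "median_shift_cpm": float(np.median(diffs)),
        "wilcoxon_p": p,
        "per_gene": pd.DataFrame(
            {"mean_cpm_case": mean_case, "mean_cpm_control": mean_ctrl}
        ),
    }
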