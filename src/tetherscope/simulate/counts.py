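"""Negative-binomial count matrices with planted fold-changes.

Supports testing of the QC filter and the pseudo-bulk differential
expression estimator: per-gene baseline means are drawn from a log-normal,
counts are negative-binomial with a common dispersion, library sizes vary
around ``library_size_mean``, and selected genes are shifted by a known
log2 fold-change in a designated group.  Mitochondrial genes are named
with the mouse ``mt-`` prefix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..expression import CountMatrix


@dataclass
class CountSimSpec:
    n_genes: int = 2000
    group_sizes: dict[str, int] = field(default_factory=lambda: {"control": 5, "case": 5})
    de_genes: dict[str, float] = field(default_factory=dict)  # gene name -> log2 FC in de_group
    de_group: str = "case"
    nb_dispersion: float = 0.1
    library_size_mean: float = 200_000.0
    mito_gene_count: int = 13
    mito_fraction: float = 0.05  # share of the expression budget on mt- genes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not self.group_sizes:
            raise ValueError("group_sizes must be non-empty")
        if self.de_genes and self.de_group not in self.group_sizes:
            raise ValueError(f"de_group {self.de_group!r} not among groups")
        if self.mito_gene_count > self.n_genes:
            raise ValueError("mito_gene_count exceeds n_genes")


def _gene_names(spec: CountSimSpec) -> list[str]:
    names = [f"mt-gene{i:03d}" for i in range(spec.mito_gene_count)]
    names += [f"gene{i:05d}" for i in range(spec.n_genes - spec.mito_gene_count)]
    return names


def generate_count_matrix(spec: CountSimSpec) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate the matrix; returns it with a per-gene truth table.

    Truth columns: gene, base_mean, planted_log2fc (0 for non-DE genes).
    Counts for unit j of gene g are NB with mean
    ``lib_j * rel_expr_g * 2**lfc_g`` (the shift applied only in the DE
    group) and variance ``mu + dispersion * mu**2``.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec)
    unknown = set(spec.de_genes) - set(genes)
    if unknown:
        raise ValueError(f"de_genes not in the simulated gene set: {sorted(unknown)[:5]}")

    # relative expression: log-normal, mito genes scaled to the requested share
    rel = rng.lognormal(mean=0.0, sigma=1.0, size=spec.n_genes)
    is_mito = np.array([g.startswith("mt-") for g in genes])
    if is_mito.any() and 0 < spec.mito_fraction < 1:
        scale = (spec.mito_fraction / (1.0 - spec.mito_fraction)) * (
            rel[~is_mito].sum() / rel[is_mito].sum()
        )
        rel[is_mito] *= scale
    rel = rel / rel.sum()

    lfc = pd.Series(0.0, index=genes)
    for g, v in spec.de_genes.items():
        lfc[g] = v

    columns, group_labels = [], []
    for group in sorted(spec.group_sizes):
        for i in range(spec.group_sizes[group]):
            columns.append(f"{group}_{i:03d}")
            group_labels.append(group)

    counts = np.zeros((spec.n_genes, len(columns)), dtype=int)
    disp = spec.nb_dispersion
    for j, (unit, group) in enumerate(zip(columns, group_labels)):
        lib = rng.normal(spec.library_size_mean, 0.1 * spec.library_size_mean)
        lib = max(lib, 0.2 * spec.library_size_mean)
        mu = lib * rel
        if group == spec.de_group:
            mu = mu * np.power(2.0, lfc.to_numpy())
        # NB via gamma-Poisson: shape r = 1/disp, scale mu*disp
        lam = rng.gamma(shape=1.0 / disp, scale=mu * disp)
        counts[:, j] = rng.poisson(lam)

    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=columns),
        unit_meta=pd.DataFrame({"group": group_labels}, index=columns),
    )
    truth = pd.DataFrame(
        {"gene": genes, "base_rel_expr": rel, "planted_log2fc": lfc.to_numpy()}
    )
    return matrix, truth
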