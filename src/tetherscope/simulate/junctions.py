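"""Simulated splice-junction read tables for isoform discrimination.

Reads are assigned to the lamin A isoform with probability ``alpha_la``
and to lamin C otherwise; a configurable fraction of reads falls on
junctions shared by both isoforms and is therefore uninformative for the
LA:LC ratio.  Within an isoform, reads distribute uniformly over its
junctions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..expression import IsoformModelSet


def generate_junctions(
    n_reads: int,
    alpha_la: float,
    models: IsoformModelSet | None = None,
    seed: int = 0,
    shared_read_fraction: float = 0.3,
) -> pd.DataFrame:
    """Simulate a junction count table (columns chrom, donor, acceptor,
    count).  ``n_reads = 0`` yields an empty table.

    Diagnostic reads split LA : LC as ``alpha_la : 1 - alpha_la``; shared
    junctions receive ``shared_read_fraction`` of all reads regardless of
    isoform.
    """
    if not 0.0 <= alpha_la <= 1.0:
        raise ValueError("alpha_la must lie in [0, 1]")
    models = models or IsoformModelSet.packaged_lmna()
    for iso, js in models.diagnostic.items():
        if not js:
            raise ValueError(f"isoform {iso!r} has no diagnostic junction")
    rng = np.random.default_rng(seed)

    counts: dict[tuple, int] = {}
    all_junctions = (
        [(j, "LA") for j in models.diagnostic.get("LA", [])]
        + [(j, "LC") for j in models.diagnostic.get("LC", [])]
        + [(j, "shared") for j in models.shared]
    )
    for j, _ in all_junctions:
        counts[tuple(j)] = 0

    if n_reads > 0:
        n_shared = rng.binomial(n_reads, shared_read_fraction) if models.shared else 0
        n_diag = n_reads - n_shared
        n_la = rng.binomial(n_diag, alpha_la)
        n_lc = n_diag - n_la
        for n, pool in (
            (n_la, models.diagnostic.get("LA", [])),
            (n_lc, models.diagnostic.get("LC", [])),
            (n_shared, models.shared),
        ):
            if n > 0 and pool:
                assignment = rng.integers(len(pool), size=n)
                for idx in assignment:
                    counts[tuple(pool[idx])] += 1

    rows = [
        {"chrom": chrom, "donor": donor, "acceptor": acceptor, "count": c}
        for (chrom, donor, acceptor), c in sorted(counts.items())
    ]
    df = pd.DataFrame(rows, columns=["chrom", "donor", "acceptor", "count"])
    return df if n_reads > 0 else df.iloc[0:0]
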