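"""Peak-set intersection, summit-centered signal matrices, K-means
extraction of the tethering-specific cluster, gene-proximal annotation,
and A/B compartment overlap.

The central analysis: accessibility peaks called in rods whose
heterochromatin has been tethered at the nuclear envelope (by lamin A or
the lamin B receptor) are compared against control rods.  Peaks whose
signal is elevated only in tethered samples form the tethering-specific
cluster; those peaks are then annotated against genes using a promoter
window running 5 kb upstream to 1 kb downstream of the TSS, and assigned
to Hi-C A/B compartments by their summit position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from sklearn.cluster import KMeans

from .genomics_io import CompartmentTrack, GeneModel, Peak, PeakSet, SignalTrack

PROXIMAL_UPSTREAM_BP = 5000
PROXIMAL_DOWNSTREAM_BP = 1000


# ---------------------------------------------------------------------------
# Peak-set intersection (upset logic)
# ---------------------------------------------------------------------------


def merge_membership(peaksets: list[PeakSet]) -> pd.DataFrame:
    """Partition the union of all peaks into maximal merged regions
    (single-linkage: overlapping or book-ended intervals chain together,
    matching the covered-basepair runs of the union) and record which
    samples contribute to each region.

    Returns a frame with columns chrom, start, end plus one boolean column
    per sample.  Order-invariant in the input list.
    """
    if len(peaksets) < 2:
        raise ValueError("need at least 2 peak sets")
    samples = [ps.sample for ps in peaksets]
    if len(set(samples)) != len(samples):
        raise ValueError("sample names must be unique")

    events = []  # (chrom, start, end, sample)
    for ps in peaksets:
        for p in ps.peaks:
            events.append((p.chrom, p.start, p.end, ps.sample))
    events.sort(key=lambda e: (e[0], e[1], e[2]))

    rows = []
    cur = None  # [chrom, start, end, set(samples)]
    for chrom, start, end, sample in events:
        if cur is not None and chrom == cur[0] and start <= cur[2]:
            cur[2] = max(cur[2], end)
            cur[3].add(sample)
        else:
            if cur is not None:
                rows.append(cur)
            cur = [chrom, start, end, {sample}]
    if cur is not None:
        rows.append(cur)

    out = pd.DataFrame(
        [{"chrom": c, "start": s, "end": e} for c, s, e, _ in rows]
    )
    for name in sorted(samples):
        out[name] = [name in members for _, _, _, members in rows]
    return out


def upset_counts(membership: pd.DataFrame) -> pd.Series:
    """Counts of merged regions per exclusive membership combination.

    Keys are '&'-joined sorted sample names; the counts sum to the number
    of merged regions.
    """
    sample_cols = [c for c in membership.columns if c not in ("chrom", "start", "end")]
    combos = membership[sample_cols].apply(
        lambda row: "&".join(sorted(c for c in sample_cols if row[c])), axis=1
    )
    return combos.value_counts().sort_index()


# ---------------------------------------------------------------------------
# Summit-centered signal matrices
# ---------------------------------------------------------------------------


@dataclass
class SignalMatrix:
    sample: str
    peak_keys: list[tuple]
    values: np.ndarray  # peaks x bins
    flank_bp: int
    bin_bp: int
    normalization: str


def summit_matrix(
    peaks: list[Peak],
    track: SignalTrack,
    flank_bp: int = 1000,
    bin_bp: int = 50,
    sample: str = "",
    normalize: str = "cpm",
) -> SignalMatrix:
    """Mean coverage per bin in [summit - flank, summit + flank) around every
    peak summit.  Bins beyond the chromosome ends are zero-filled.

    ``normalize='cpm'`` scales values to counts-per-million of the track's
    total raw signal; ``'raw'`` leaves them untouched.
    """
    if flank_bp % bin_bp != 0:
        raise ValueError("flank_bp must be a multiple of bin_bp")
    n_bins = 2 * flank_bp // bin_bp
    values = np.zeros((len(peaks), n_bins))
    for i, p in enumerate(peaks):
        if p.chrom not in track.data:
            raise KeyError(f"unknown chromosome {p.chrom!r} in signal track")
        arr = track.data[p.chrom]
        window = np.zeros(2 * flank_bp)
        lo, hi = p.summit - flank_bp, p.summit + flank_bp
        src_lo, src_hi = max(lo, 0), min(hi, len(arr))
        if src_hi > src_lo:
            window[src_lo - lo : src_hi - lo] = arr[src_lo:src_hi]
        values[i] = window.reshape(n_bins, bin_bp).mean(axis=1)
    norm_tag = track.normalization
    if normalize == "cpm":
        total = track.total()
        if total > 0:
            values *= 1e6 / total
        norm_tag = "cpm"
    return SignalMatrix(
        sample=sample,
        peak_keys=[p.key for p in peaks],
        values=values,
        flank_bp=flank_bp,
        bin_bp=bin_bp,
        normalization=norm_tag,
    )


# ---------------------------------------------------------------------------
# K-means isolation of the tethering-specific cluster
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    k: int
    seed: int
    labels: pd.Series  # index: peak name/key order as supplied
    cluster_sample_means: pd.DataFrame  # clusters x samples
    tethering_cluster_id: int  # cluster with the largest tethered-control gap
    tethering_cluster_ids: list[int]  # all clusters with a comparable gap
    tethering_score: float  # mean(tethered) - mean(control) of the top cluster

    @property
    def tethering_mask(self) -> np.ndarray:
        """Boolean membership of the tethering-specific peak set (the union
        of all clusters elevated in tethered samples)."""
        return self.labels.isin(self.tethering_cluster_ids).to_numpy()


def cluster_peaks(
    matrices: dict[str, SignalMatrix],
    roles: dict[str, str],
    k: int = 3,
    seed: int = 0,
) -> ClusterResult:
    """K-means on concatenated per-sample summit matrices (log2(x+1)
    features) and designation of the tethering-specific cluster.

    The primary tethering cluster maximizes mean(tethered sample blocks) -
    mean(control sample blocks) over cluster members;
    ``tethering_cluster_ids`` additionally lists every cluster whose gap is
    at least half the maximum, so that a planted signal split across
    near-duplicate clusters (k larger than the number of real patterns) is
    still captured as one peak set.  Rows are re-sorted by peak key before
    initialization, so labels are stable under permutation of the input
    peak order at a fixed seed.
    """
    samples = sorted(matrices)
    keys = matrices[samples[0]].peak_keys
    for s in samples[1:]:
        if matrices[s].peak_keys != keys:
            raise ValueError("all matrices must share the same peak rows")
    n = len(keys)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of peaks ({n})")

    feats = np.hstack([np.log2(matrices[s].values + 1.0) for s in samples])
    order = np.argsort(np.array([str(key) for key in keys]))
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    sorted_labels = km.fit_predict(feats[order])
    labels = np.empty(n, dtype=int)
    labels[order] = sorted_labels

    tethered = [s for s in samples if roles.get(s, "control").startswith("tethered")]
    control = [s for s in samples if not roles.get(s, "control").startswith("tethered")]
    if not tethered or not control:
        raise ValueError("roles must include both tethered and control samples")

    block_means = {}
    for s in samples:
        vals = np.log2(matrices[s].values + 1.0).mean(axis=1)
        block_means[s] = np.array([vals[labels == c].mean() for c in range(k)])
    cluster_sample_means = pd.DataFrame(block_means, index=range(k))
    diff = cluster_sample_means[tethered].mean(axis=1) - cluster_sample_means[control].mean(axis=1)
    tether_id = int(diff.idxmax())
    score = float(diff.max())
    if score < 1e-6:
        warnings.warn(
            "no cluster shows elevated signal in tethered samples; "
            "tethering_cluster_id is arbitrary",
            RuntimeWarning,
            stacklevel=2,
        )
        tether_ids = [tether_id]
    else:
        tether_ids = sorted(int(c) for c in diff.index[diff >= 0.5 * score])
    return ClusterResult(
        k=k,
        seed=seed,
        labels=pd.Series(labels, index=pd.Index([str(key) for key in keys], name="peak")),
        cluster_sample_means=cluster_sample_means,
        tethering_cluster_id=tether_id,
        tethering_cluster_ids=tether_ids,
        tethering_score=score,
    )


# ---------------------------------------------------------------------------
# Gene-proximal annotation
# ---------------------------------------------------------------------------


def gene_window(
    gene: GeneModel,
    upstream_bp: int = PROXIMAL_UPSTREAM_BP,
    downstream_bp: int = PROXIMAL_DOWNSTREAM_BP,
    anchor: str = "tss",
) -> tuple[int, int]:
    """Strand-aware proximal window, 0-based half-open.

    With the default TSS anchor on the + strand the window covers bases
    [tss - upstream, tss + downstream); on the - strand it is mirrored so
    that upstream extends toward larger coordinates.  ``anchor='body'``
    extends the whole gene body instead.
    """
    if anchor == "body":
        if gene.strand == "+":
            return max(0, gene.start - upstream_bp), gene.end + downstream_bp
        return max(0, gene.start - downstream_bp), gene.end + upstream_bp
    t = gene.tss
    if gene.strand == "+":
        return max(0, t - upstream_bp), t + downstream_bp
    # '-' strand: upstream means larger coordinates; half-open mirror of the
    # + strand window so the same strand-relative offsets are proximal
    return max(0, t - downstream_bp + 1), t + upstream_bp + 1


def annotate_proximal(
    peaks: list[Peak],
    genes: list[GeneModel],
    upstream_bp: int = PROXIMAL_UPSTREAM_BP,
    downstream_bp: int = PROXIMAL_DOWNSTREAM_BP,
    anchor: str = "tss",
) -> pd.DataFrame:
    """Classify peaks as promoter-proximal or distal.

    A peak is proximal when its interval overlaps (>= 1 bp) the proximal
    window of any gene.  The nearest gene is chosen by |summit - tss|
    (ties broken by lexicographic gene id).  Returns one record per peak
    with columns peak, category, gene, distance_to_tss (signed,
    strand-relative: positive = downstream of the TSS).
    """
    if not genes:
        raise ValueError("genes must be non-empty")
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        lo, hi = gene_window(g, upstream_bp, downstream_bp, anchor)
        if hi > lo:
            trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g)

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    rows = []
    for p in peaks:
        hits = trees[p.chrom].overlap(p.start, p.end) if p.chrom in trees else set()
        proximal = bool(hits)
        candidates = [iv.data for iv in hits] if proximal else by_chrom.get(p.chrom, [])
        gene_id, signed_dist = None, None
        if candidates:
            best = min(candidates, key=lambda g: (abs(p.summit - g.tss), g.gene_id))
            gene_id = best.gene_id
            raw = p.summit - best.tss
            signed_dist = int(raw if best.strand == "+" else -raw)
        rows.append(
            {
                "peak": p.name,
                "category": "proximal" if proximal else "distal",
                "gene": gene_id,
                "distance_to_tss": signed_dist,
            }
        )
    return pd.DataFrame(rows)


def proximal_gene_set(annotation: pd.DataFrame) -> list[str]:
    """Unique gene ids associated with proximal peaks (for GO tools)."""
    mask = annotation["category"] == "proximal"
    return sorted(annotation.loc[mask, "gene"].dropna().unique())


# ---------------------------------------------------------------------------
# A/B compartment overlap
# ---------------------------------------------------------------------------


def compartment_fraction(
    peaks: list[Peak], compartments: CompartmentTrack
) -> dict[str, float]:
    """Fraction of peaks whose summit falls in A, B, or no compartment."""
    df = compartments.intervals
    counts = {"A": 0, "B": 0, "unassigned": 0}
    by_chrom = {c: g.sort_values("start") for c, g in df.groupby("chrom")}
    for p in peaks:
        sub = by_chrom.get(p.chrom)
        label = "unassigned"
        if sub is not None:
            idx = np.searchsorted(sub["start"].to_numpy(), p.summit, side="right") - 1
            if idx >= 0 and p.summit < sub["end"].iloc[idx]:
                label = sub["label"].iloc[idx]
        counts[label] += 1
    n = max(1, len(peaks))
    return {k: v / n for k, v in counts.items()}
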