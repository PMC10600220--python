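"""Toy genome with planted tethering-specific accessibility peaks.

Emulates the structure of a multi-sample ATAC-seq comparison: every sample
shares a common set of accessible peaks, while a planted subset carries
called peaks and elevated coverage only in "tethered" samples.  Genes,
alternating A/B compartment blocks, and a configurable fraction of
tether-specific peaks planted inside the promoter-proximal window
(5 kb upstream to 1 kb downstream of a TSS, strand-aware) give every
downstream annotation step a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..accessibility import PROXIMAL_DOWNSTREAM_BP, PROXIMAL_UPSTREAM_BP, gene_window
from ..genomics_io import (
    CompartmentTrack,
    GeneModel,
    Peak,
    PeakSet,
    SignalTrack,
    write_bedgraph,
    write_compartments,
    write_gff_genes,
    write_narrowpeak,
)

BASELINE_COVERAGE = 1.0


@dataclass
class ToyGenomeSpec:
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 2_000_000})
    n_genes: int = 60
    n_shared_peaks: int = 100
    n_tether_specific_peaks: int = 50
    samples: dict[str, str] = field(
        default_factory=lambda: {
            "control": "control",
            "la": "tethered_LA",
            "lbr": "tethered_Lbr",
        }
    )  # sample name -> role
    peak_width_bp: int = 400
    signal_amplitude: float = 20.0
    compartment_block_bp: int = 100_000
    frac_proximal_planted: float = 0.10
    frac_a_planted: float = 0.90  # tether-specific summits placed in A blocks
    gene_length_bp: tuple[int, int] = (2000, 8000)
    seed: int = 0

    def __post_init__(self) -> None:
        roles = set(self.samples.values())
        if not any(r == "control" for r in roles) or not any(
            r.startswith("tethered") for r in roles
        ):
            raise ValueError("samples must include >= 1 control and >= 1 tethered role")
        if not 0.0 <= self.frac_proximal_planted <= 1.0:
            raise ValueError("frac_proximal_planted must lie in [0, 1]")
        if not 0.0 <= self.frac_a_planted <= 1.0:
            raise ValueError("frac_a_planted must lie in [0, 1]")


@dataclass
class ToyGenome:
    spec: ToyGenomeSpec
    genes: list[GeneModel]
    peaksets: dict[str, PeakSet]  # per sample, called peaks
    tracks: dict[str, SignalTrack]  # per sample, coverage
    compartments: CompartmentTrack
    truth: pd.DataFrame  # per planted peak: class, proximal, compartment

    def write(self, outdir) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        write_gff_genes(self.genes, outdir / "genes.gff3")
        paths["genes"] = str(outdir / "genes.gff3")
        for sample, ps in self.peaksets.items():
            p = outdir / f"{sample}.narrowPeak"
            write_narrowpeak(ps, p)
            paths[f"peaks_{sample}"] = str(p)
        for sample, track in self.tracks.items():
            p = outdir / f"{sample}.bedGraph"
            write_bedgraph(track, p)
            paths[f"coverage_{sample}"] = str(p)
        write_compartments(self.compartments, outdir / "compartments.bed")
        paths["compartments"] = str(outdir / "compartments.bed")
        self.truth.to_csv(outdir / "peak_truth.tsv", sep="\t", index=False)
        paths["truth"] = str(outdir / "peak_truth.tsv")
        return paths


def _alternating_compartments(spec: ToyGenomeSpec) -> CompartmentTrack:
    rows = []
    for chrom, length in sorted(spec.chrom_lengths.items()):
        pos, i = 0, 0
        while pos < length:
            end = min(pos + spec.compartment_block_bp, length)
            rows.append(
                {"chrom": chrom, "start": pos, "end": end, "label": "A" if i % 2 == 0 else "B"}
            )
            pos, i = end, i + 1
    return CompartmentTrack(intervals=pd.DataFrame(rows))


def _compartment_of(comp: CompartmentTrack, chrom: str, pos: int) -> str:
    df = comp.intervals
    sub = df[df["chrom"] == chrom]
    hit = sub[(sub["start"] <= pos) & (pos < sub["end"])]
    return hit["label"].iloc[0] if len(hit) else "unassigned"


def _plant_bump(arr: np.ndarray, start: int, end: int, summit: int, amplitude: float) -> None:
    """Coverage bump over [start, end): half amplitude at the edges rising
    linearly to the full amplitude at the summit (strict maximum there)."""
    pos = np.arange(start, end)
    half_span = np.maximum(summit - start, end - 1 - summit)
    tri = 1.0 - np.abs(pos - summit) / max(1, half_span)
    arr[start:end] += amplitude * (0.5 + 0.5 * np.clip(tri, 0.0, 1.0))


def generate_toy_genome(spec: ToyGenomeSpec) -> ToyGenome:
    """Build the toy genome in memory; ``ToyGenome.write`` emits the files."""
    rng = np.random.default_rng(spec.seed)
    chroms = sorted(spec.chrom_lengths)
    lengths = spec.chrom_lengths

    # --- genes, non-overlapping, uniform strand -----------------------------
    genes: list[GeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def _fits(chrom: str, lo: int, hi: int, registry) -> bool:
        return all(hi <= s or lo >= e for s, e in registry[chrom])

    attempts = 0
    while len(genes) < spec.n_genes:
        attempts += 1
        if attempts > 100 * spec.n_genes:
            raise ValueError("could not place genes within chromosome bounds")
        chrom = chroms[rng.integers(len(chroms))]
        glen = int(rng.integers(*spec.gene_length_bp))
        margin = PROXIMAL_UPSTREAM_BP + PROXIMAL_DOWNSTREAM_BP
        if lengths[chrom] <= glen + 2 * margin:
            raise ValueError("chromosome too short for genes and their windows")
        start = int(rng.integers(margin, lengths[chrom] - glen - margin))
        strand = "+" if rng.uniform() < 0.5 else "-"
        cand = GeneModel(f"gene{len(genes):04d}", chrom, strand, start, start + glen)
        # keep promoter windows and bodies of distinct genes disjoint so
        # planted proximal/distal labels are unambiguous
        wlo, whi = gene_window(cand)
        lo, hi = min(wlo, cand.start) - 500, max(whi, cand.end) + 500
        if _fits(chrom, lo, hi, occupied):
            genes.append(cand)
            occupied[chrom].append((lo, hi))

    windows = [(g.chrom, *gene_window(g)) for g in genes]

    # --- peak placement ------------------------------------------------------
    peak_registry: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    min_gap = 2200  # keep flanks used by summit matrices from overlapping

    def _in_any_window(chrom: str, lo: int, hi: int) -> bool:
        return any(c == chrom and lo < we and ws < hi for c, ws, we in windows)

    def _block_label(chrom: str, pos: int) -> str:
        return "A" if (pos // spec.compartment_block_bp) % 2 == 0 else "B"

    def _place_peak(name: str, want_proximal: bool | None, want_a: bool | None = None) -> Peak:
        w = spec.peak_width_bp
        for _ in range(5000):
            if want_proximal:
                g = genes[rng.integers(len(genes))]
                ws, we = gene_window(g)
                start = int(rng.integers(ws, we - w)) if we - w > ws else ws
                chrom = g.chrom
            else:
                chrom = chroms[rng.integers(len(chroms))]
                start = int(rng.integers(min_gap, lengths[chrom] - w - min_gap))
            end = start + w
            if end > lengths[chrom]:
                continue
            if want_proximal is False and _in_any_window(chrom, start, end):
                continue
            if not _fits(chrom, start - min_gap, end + min_gap, peak_registry):
                continue
            peak_registry[chrom].append((start - min_gap, end + min_gap))
            # summit off-center within the central half of the peak
            summit = start + w // 2 + int(rng.integers(-w // 8, w // 8 + 1))
            if want_a is not None and (_block_label(chrom, summit) == "A") != want_a:
                peak_registry[chrom].pop()
                continue
            return Peak(chrom, start, end, summit, name, spec.signal_amplitude)
        raise ValueError("could not place peak without overflowing chromosome bounds")

    shared = [_place_peak(f"shared{i:04d}", None) for i in range(spec.n_shared_peaks)]
    n_prox = int(round(spec.frac_proximal_planted * spec.n_tether_specific_peaks))
    tether = []
    for i in range(spec.n_tether_specific_peaks):
        proximal = i < n_prox
        # compartment bias applies to the freely placed (distal) peaks;
        # proximal peaks are anchored to gene promoters instead
        want_a = None if proximal else bool(rng.uniform() < spec.frac_a_planted)
        tether.append(_place_peak(f"tether{i:04d}", want_proximal=proximal, want_a=want_a))

    # --- per-sample peak calls and coverage ----------------------------------
    peaksets, tracks = {}, {}
    for sample, role in spec.samples.items():
        tethered = role.startswith("tethered")
        plist = shared + tether if tethered else list(shared)
        peaksets[sample] = PeakSet(sample=sample, peaks=plist, role=role)
        data = {c: np.full(lengths[c], BASELINE_COVERAGE) for c in chroms}
        for p in shared:
            _plant_bump(data[p.chrom], p.start, p.end, p.summit, spec.signal_amplitude)
        if tethered:
            for p in tether:
                _plant_bump(data[p.chrom], p.start, p.end, p.summit, spec.signal_amplitude)
        tracks[sample] = SignalTrack(data=data)

    compartments = _alternating_compartments(spec)

    rows = []
    for p in shared + tether:
        prox = _in_any_window(p.chrom, p.start, p.end)
        rows.append(
            {
                "peak": p.name,
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "summit": p.summit,
                "peak_class": "tether_specific" if p.name.startswith("tether") else "shared",
                "placement": "proximal" if prox else "distal",
                "compartment": _compartment_of(compartments, p.chrom, p.summit),
            }
        )
    truth = pd.DataFrame(rows)
    return ToyGenome(
        spec=spec,
        genes=genes,
        peaksets=peaksets,
        tracks=tracks,
        compartments=compartments,
        truth=truth,
    )
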