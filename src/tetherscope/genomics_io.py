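"""Readers and writers for the genomic text formats the pipeline consumes.

All interval containers use 0-based half-open coordinates (the BED /
narrowPeak convention); GFF3 is converted on the way in and out (1-based,
closed).  narrowPeak round trips losslessly: column 10 is the summit
offset from the interval start, and an offset of -1 maps to the interval
midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    summit: int  # absolute bp
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if not self.start <= self.summit < self.end:
            raise ValueError(f"summit {self.summit} outside {self.start}-{self.end}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.name)


@dataclass
class PeakSet:
    sample: str
    peaks: list[Peak]
    role: str = "control"  # control / tethered_LA / tethered_Lbr / reference

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end))

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class SignalTrack:
    """Per-chromosome per-basepair coverage arrays."""

    data: dict[str, np.ndarray]
    normalization: str = "raw"

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    def chrom_length(self, chrom: str) -> int:
        return len(self.data[chrom])


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open
    end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError("invalid gene interval")

    @property
    def tss(self) -> int:
        """Strand-resolved transcription start site (0-based)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class CompartmentTrack:
    """Non-overlapping A/B compartment intervals."""

    intervals: pd.DataFrame  # columns: chrom, start, end, label

    def __post_init__(self) -> None:
        df = self.intervals.sort_values(["chrom", "start"]).reset_index(drop=True)
        bad = ~df["label"].isin(["A", "B"])
        if bad.any():
            raise ValueError(f"compartment labels must be A or B, got {df.loc[bad, 'label'].unique()}")
        prev_end = df.groupby("chrom")["end"].shift()
        if ((df["start"] - prev_end) < 0).any():
            raise ValueError("compartment intervals overlap")
        self.intervals = df


class FormatError(ValueError):
    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


# ---------------------------------------------------------------------------
# narrowPeak
# ---------------------------------------------------------------------------


def read_narrowpeak(path, sample: str | None = None, role: str = "control") -> PeakSet:
    peaks = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise FormatError(path, ln, f"expected 10 columns, got {len(fields)}")
            try:
                chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                score = float(fields[4])
                offset = int(fields[9])
            except ValueError as exc:
                raise FormatError(path, ln, str(exc)) from exc
            summit = start + offset if offset >= 0 else (start + end) // 2
            try:
                peaks.append(Peak(chrom, start, end, summit, name, score))
            except ValueError as exc:
                raise FormatError(path, ln, str(exc)) from exc
    name = sample if sample is not None else str(path)
    return PeakSet(sample=name, peaks=peaks, role=role)


def write_narrowpeak(peakset: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for p in peakset.peaks:
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        p.name,
                        f"{p.score:g}",
                        ".",
                        f"{p.score:g}",
                        "-1",
                        "-1",
                        str(p.summit - p.start),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def read_bedgraph(path, chrom_lengths: dict[str, int] | None = None) -> SignalTrack:
    """Read a bedGraph into dense per-basepair arrays.

    Intended for the compact toy genomes this package simulates; arrays are
    sized to ``chrom_lengths`` when given, else to the maximum end seen.
    """
    spans: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(path, ln, f"expected 4 columns, got {len(fields)}")
            try:
                chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise FormatError(path, ln, str(exc)) from exc
            if not 0 <= start < end:
                raise FormatError(path, ln, f"invalid span {start}-{end}")
            spans.setdefault(chrom, []).append((start, end, value))
    data = {}
    for chrom, items in spans.items():
        length = (
            chrom_lengths[chrom] if chrom_lengths is not None else max(e for _, e, _ in items)
        )
        arr = np.zeros(length)
        for start, end, value in items:
            arr[start:end] = value
        data[chrom] = arr
    return SignalTrack(data=data)


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write a dense track as run-length-encoded bedGraph (zeros skipped)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# GFF3 genes
# ---------------------------------------------------------------------------


def read_gff_genes(path) -> list[GeneModel]:
    """Parse ``gene`` features from a GFF3 file into 0-based GeneModels."""
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(path, ln, f"expected 9 columns, got {len(fields)}")
            if fields[2] != "gene":
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise FormatError(path, ln, str(exc)) from exc
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", attrs.get("gene_id", f"gene_at_{path}:{ln}"))
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=fields[0],
                    strand=fields[6],
                    start=start1 - 1,  # GFF is 1-based closed
                    end=end1,
                )
            )
    return genes


def write_gff_genes(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        "tetherscope",
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Compartment BED
# ---------------------------------------------------------------------------


def read_compartments(path) -> CompartmentTrack:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(path, ln, "compartment BED needs >= 4 columns")
            try:
                rows.append(
                    {
                        "chrom": fields[0],
                        "start": int(fields[1]),
                        "end": int(fields[2]),
                        "label": fields[3],
                    }
                )
            except ValueError as exc:
                raise FormatError(path, ln, str(exc)) from exc
    return CompartmentTrack(intervals=pd.DataFrame(rows))


def write_compartments(track: CompartmentTrack, path) -> None:
    track.intervals[["chrom", "start", "end", "label"]].to_csv(
        path, sep="\t", header=False, index=False
    )
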