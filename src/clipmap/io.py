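"""File input/output and the crosslink-track container.

All genomic coordinates are 0-based, half-open in memory; on disk we use the
native convention of each format (GTF 1-based inclusive, BED/bedGraph 0-based
half-open).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STRANDS = ("+", "-")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Read a genome FASTA into a dict of upper-case sequences."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# Crosslink tracks

class CrosslinkTrack:
    """Strand-specific per-nucleotide crosslink-event counts.

    Counts are held as dense integer arrays per (chromosome, strand); the
    genomes this package works with are small enough that a dense
    representation is both simpler and faster than a sparse one.

    Parameters
    ----------
    chrom_lengths:
        Mapping chromosome name -> length in nt.
    label:
        Replicate name, or ``"merged"`` for the replicate sum.
    """

    def __init__(self, chrom_lengths: dict[str, int], label: str = "track"):
        self.chrom_lengths = dict(chrom_lengths)
        self.label = label
        self.data: dict[tuple[str, str], np.ndarray] = {
            (c, s): np.zeros(n, dtype=np.int64)
            for c, n in self.chrom_lengths.items()
            for s in STRANDS
        }

    def counts(self, chrom: str, strand: str) -> np.ndarray:
        return self.data[(chrom, strand)]

    def window(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        """Counts over [start, end); positions outside the chromosome are 0."""
        n = self.chrom_lengths[chrom]
        out = np.zeros(end - start, dtype=np.int64)
        lo, hi = max(start, 0), min(end, n)
        if hi > lo:
            out[lo - start : hi - start] = self.data[(chrom, strand)][lo:hi]
        return out

    def add(self, other: "CrosslinkTrack") -> None:
        for key, arr in other.data.items():
            self.data[key] += arr

    @staticmethod
    def merge(tracks: list["CrosslinkTrack"], label: str = "merged") -> "CrosslinkTrack":
        """Positionwise sum of replicate tracks."""
        merged = CrosslinkTrack(tracks[0].chrom_lengths, label=label)
        for t in tracks:
            merged.add(t)
        return merged

    # -- bedGraph -----------------------------------------------------------

    def to_bedgraph(self, outdir, prefix: str | None = None) -> list[Path]:
        """Write one bedGraph per strand (zero runs omitted)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        prefix = prefix or self.label
        paths = []
        for strand, tag in (("+", "plus"), ("-", "minus")):
            path = outdir / f"{prefix}.{tag}.bedgraph"
            with open(path, "w") as fh:
                for chrom in sorted(self.chrom_lengths):
                    arr = self.data[(chrom, strand)]
                    if not arr.any():
                        continue
                    # run-length encode constant stretches
                    change = np.flatnonzero(np.diff(arr)) + 1
                    starts = np.concatenate(([0], change))
                    ends = np.concatenate((change, [len(arr)]))
                    for s, e in zip(starts, ends):
                        v = arr[s]
                        if v:
                            fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")
            paths.append(path)
        return paths

    @staticmethod
    def from_bedgraph(plus_path, minus_path, chrom_lengths: dict[str, int],
                      label: str = "track") -> "CrosslinkTrack":
        track = CrosslinkTrack(chrom_lengths, label=label)
        for path, strand in ((plus_path, "+"), (minus_path, "-")):
            if path is None or not os.path.exists(path) or os.path.getsize(path) == 0:
                continue
            df = pd.read_csv(path, sep="\t", header=None,
                             names=["chrom", "start", "end", "value"])
            for row in df.itertuples(index=False):
                track.data[(row.chrom, strand)][row.start:row.end] += int(row.value)
        return track


def read_track_dir(trackdir, chrom_lengths: dict[str, int]) -> tuple[list[CrosslinkTrack], CrosslinkTrack]:
    """Load all ``<name>.{plus,minus}.bedgraph`` pairs from a directory.

    Returns (replicate tracks, merged track); a pre-existing ``merged`` pair
    is used if present, otherwise replicates are summed.
    """
    trackdir = Path(trackdir)
    names = sorted({p.name.rsplit(".", 2)[0] for p in trackdir.glob("*.bedgraph")})
    reps, merged = [], None
    for name in names:
        track = CrosslinkTrack.from_bedgraph(
            trackdir / f"{name}.plus.bedgraph", trackdir / f"{name}.minus.bedgraph",
            chrom_lengths, label=name)
        if name == "merged":
            merged = track
        else:
            reps.append(track)
    if merged is None:
        merged = CrosslinkTrack.merge(reps)
    return reps, merged


# ---------------------------------------------------------------------------
# Significant sites / binding sites (BED)

SITE_COLUMNS = ["chrom", "pos", "strand", "score"]


def write_sites_bed(sites: pd.DataFrame, path) -> None:
    """Single-nucleotide significant sites as BED6 with the caller score."""
    df = sites.reset_index(drop=True)
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["pos"],
        "end": df["pos"] + 1,
        "name": [f"site_{i}" for i in range(len(df))],
        "score": df["score"],
        "strand": df["strand"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_sites_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"])
    return pd.DataFrame({
        "chrom": df["chrom"], "pos": df["start"],
        "strand": df["strand"], "score": df["score"].astype(float),
    })


def write_binding_sites(bsites: pd.DataFrame, prefix) -> tuple[Path, Path]:
    """BED6 (score = round(strength*100)) plus a companion TSV with details."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bed_path = prefix.with_suffix(".bed")
    tsv_path = prefix.with_suffix(".tsv")
    df = bsites.reset_index(drop=True)
    bed = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start"],
        "end": df["end"],
        "name": df["site_id"],
        "score": np.round(df["strength"] * 100).astype(int),
        "strand": df["strand"],
    })
    bed.to_csv(bed_path, sep="\t", header=False, index=False)
    df.to_csv(tsv_path, sep="\t", index=False)
    return bed_path, tsv_path


def read_binding_sites(tsv_path) -> pd.DataFrame:
    return pd.read_csv(tsv_path, sep="\t")


# ---------------------------------------------------------------------------
# FASTQ

def read_fastq(path):
    """Yield (id, sequence, qualities) tuples from a FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq), list(rec.letter_annotations["phred_quality"])


def write_fastq(records, path) -> None:
    """Write (id, sequence, qualities) tuples to FASTQ (Phred+33)."""
    recs = []
    for rid, seq, quals in records:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = list(quals)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")
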