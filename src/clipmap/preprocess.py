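"""iCLIP read preprocessing.

Implements the read-level rules of the experimental protocol: the first 9 nt
of each read are a barcode block laid out as

    [random 3 nt][sample barcode 4 nt][random 2 nt]

The random positions form the unique molecular identifier (UMI) used for
duplicate removal after alignment; the sample barcode identifies the
replicate.  Reads are

1. dropped when the barcode block is unreliable (more than one sample-barcode
   position with Phred quality < 20, or any random-barcode position < 17),
2. demultiplexed on the 4-nt sample barcode with zero mismatches,
3. stripped of the barcode block (which is moved into the read name),
4. trimmed of 3' sequencing-adapter remnants (>= 1 nt overlap, one mismatch
   allowed per 10 nt of overlap),
5. discarded when shorter than 15 nt after trimming.

Deduplication operates on aligned-read stubs: within each group sharing
(chromosome, strand, 5'-end position) exactly one read per distinct random
barcode is kept — identical UMIs are technical (PCR) duplicates, distinct
UMIs are independent molecules.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as cio

DEFAULT_ADAPTER = "AGATCGGAAGAGCGGTTCAG"

# 0-based slices of the 9-nt barcode block
RANDOM_SLICES = ((0, 3), (7, 9))
SAMPLE_SLICE = (3, 7)
BARCODE_LEN = 9


@dataclass
class BarcodeScheme:
    """Barcode layout and the sample-barcode table."""

    barcodes: dict[str, str]
    random_slices: tuple[tuple[int, int], ...] = RANDOM_SLICES
    sample_slice: tuple[int, int] = SAMPLE_SLICE

    def __post_init__(self):
        lengths = {len(b) for b in self.barcodes.values()}
        if len(self.barcodes) != len(set(self.barcodes.values())):
            raise ValueError("sample barcodes must be unique")
        width = self.sample_slice[1] - self.sample_slice[0]
        if lengths and lengths != {width}:
            raise ValueError(f"all sample barcodes must have length {width}")

    @classmethod
    def from_tsv(cls, path) -> "BarcodeScheme":
        df = pd.read_csv(path, sep="\t", header=None, names=["sample", "barcode"])
        return cls(dict(zip(df["sample"], df["barcode"].str.upper())))


@dataclass
class ReadRecord:
    identifier: str
    sequence: str
    qualities: list[int]

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and quality lengths differ")


@dataclass
class AlignedReadStub:
    """Minimal aligned read: 5'-end position plus the random barcode."""

    chrom: str
    strand: str
    position: int  # 0-based genomic position of the read 5' end
    barcode: str

    def __post_init__(self):
        if self.position < 0:
            raise ValueError("position must be >= 0")


class MalformedReadError(ValueError):
    pass


def random_barcode(read: ReadRecord, scheme: BarcodeScheme | None = None) -> str:
    scheme = scheme or BarcodeScheme({})
    return "".join(read.sequence[a:b] for a, b in scheme.random_slices)


def filter_barcode_quality(read: ReadRecord, scheme: BarcodeScheme) -> tuple[bool, str | None]:
    """Return (keep, reason).  reason is None when the read is kept.

    Drop when more than one sample-barcode position has Q < 20, or any
    random-barcode position has Q < 17.
    """
    if len(read.sequence) < BARCODE_LEN:
        raise MalformedReadError(f"read {read.identifier!r} shorter than {BARCODE_LEN} nt")
    a, b = scheme.sample_slice
    n_low_sample = sum(q < 20 for q in read.qualities[a:b])
    if n_low_sample > 1:
        return False, "sample_barcode_quality"
    for a, b in scheme.random_slices:
        if any(q < 17 for q in read.qualities[a:b]):
            return False, "random_barcode_quality"
    return True, None


def demultiplex(reads, scheme: BarcodeScheme) -> dict[str, list[ReadRecord]]:
    """Split reads by sample barcode (no mismatches); trim the 9-nt barcode
    block off the left end and append it to the read name.

    Reads whose 4-mer matches no table entry go into ``"undetermined"``.
    """
    by_barcode = {v: k for k, v in scheme.barcodes.items()}
    bins: dict[str, list[ReadRecord]] = OrderedDict(
        (name, []) for name in list(scheme.barcodes) + ["undetermined"])
    a, b = scheme.sample_slice
    for read in reads:
        if len(read.sequence) < BARCODE_LEN:
            raise MalformedReadError(f"read {read.identifier!r} shorter than {BARCODE_LEN} nt")
        barcode_block = read.sequence[:BARCODE_LEN]
        sample = by_barcode.get(read.sequence[a:b], "undetermined")
        bins[sample].append(ReadRecord(
            identifier=f"{read.identifier}_{barcode_block}",
            sequence=read.sequence[BARCODE_LEN:],
            qualities=read.qualities[BARCODE_LEN:],
        ))
    return bins


def trim_adapter(read: ReadRecord, adapter: str = DEFAULT_ADAPTER) -> ReadRecord:
    """Remove a 3' adapter remnant.

    The longest suffix of the read matching a prefix of the adapter with at
    most floor(overlap/10) mismatches is removed; minimum overlap 1 nt.  Ties
    cannot occur because overlaps are scanned from longest to shortest.
    """
    seq = read.sequence
    max_l = min(len(seq), len(adapter))
    for length in range(max_l, 0, -1):
        suffix = seq[-length:]
        budget = length // 10
        mism = sum(x != y for x, y in zip(suffix, adapter[:length]))
        if mism <= budget:
            return ReadRecord(read.identifier, seq[:-length], read.qualities[:-length])
    return read


def length_filter(read: ReadRecord, min_len: int = 15) -> bool:
    """Keep reads of at least ``min_len`` nt after trimming."""
    return len(read.sequence) >= min_len


def dedup_random_barcode(stubs) -> list[AlignedReadStub]:
    """Keep one representative per (chrom, strand, 5' position, barcode).

    The first stub seen for each key is retained, so the operation is
    idempotent and order-stable.
    """
    seen: set[tuple] = set()
    kept = []
    for stub in stubs:
        key = (stub.chrom, stub.strand, stub.position, stub.barcode)
        if key not in seen:
            seen.add(key)
            kept.append(stub)
    return kept


def preprocess_reads(reads, scheme: BarcodeScheme,
                     adapter: str = DEFAULT_ADAPTER, min_len: int = 15):
    """Run quality filter -> demultiplex -> adapter trim -> length filter.

    Returns (per-sample surviving reads, summary counts DataFrame).
    """
    reads = list(reads)
    kept_quality = []
    n_drop_quality = 0
    for read in reads:
        keep, _ = filter_barcode_quality(read, scheme)
        if keep:
            kept_quality.append(read)
        else:
            n_drop_quality += 1
    bins = demultiplex(kept_quality, scheme)
    out: dict[str, list[ReadRecord]] = {}
    n_short = 0
    for sample, sample_reads in bins.items():
        survivors = []
        for read in sample_reads:
            trimmed = trim_adapter(read, adapter)
            if length_filter(trimmed, min_len):
                survivors.append(trimmed)
            else:
                n_short += 1
        out[sample] = survivors
    summary = pd.DataFrame([
        {"stage": "input", "reads": len(reads)},
        {"stage": "barcode_quality", "reads": len(kept_quality)},
        {"stage": "length_filter", "reads": sum(len(v) for v in out.values())},
        *({"stage": f"sample:{s}", "reads": len(v)} for s, v in out.items()),
    ])
    return out, summary


def preprocess_fastq(fastq_path, barcode_tsv, outdir,
                     adapter: str = DEFAULT_ADAPTER, min_len: int = 15) -> pd.DataFrame:
    """File-level entry point: FASTQ in, per-sample FASTQ + summary TSV out."""
    scheme = BarcodeScheme.from_tsv(barcode_tsv)
    reads = [ReadRecord(rid, seq, quals) for rid, seq, quals in cio.read_fastq(fastq_path)]
    out, summary = preprocess_reads(reads, scheme, adapter=adapter, min_len=min_len)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sample, sample_reads in out.items():
        cio.write_fastq(((r.identifier, r.sequence, r.qualities) for r in sample_reads),
                        outdir / f"{sample}.fastq")
    summary.to_csv(outdir / "preprocess_summary.tsv", sep="\t", index=False)
    return summary
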