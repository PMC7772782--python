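"""Gene and transcript-region assignment of binding sites.

Annotation handling follows the GENCODE dialect: genes carry ``gene_type``
and ``level`` attributes, transcripts carry ``transcript_support_level``.
Genes with level > 2 and transcripts with support level > 3 (or a
non-numeric support level) are removed on load.

Region assignment is strand-matched and two-staged: a binding site must
overlap exactly one retained gene ("unique gene" rule; sites overlapping
two or more genes are ambiguous and excluded), and within that gene the
transcript-region label (intron, CDS, 3'UTR, 5'UTR) is decided by a
majority vote over the gene's transcripts with ties broken by the fixed
hierarchy intron > CDS > 3'UTR > 5'UTR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pyranges as pr
from intervaltree import IntervalTree

# hierarchy order: lower index wins ties
REGION_HIERARCHY = ["intron", "CDS", "3UTR", "5UTR", "exonic"]
_RANK = {label: i for i, label in enumerate(REGION_HIERARCHY)}


@dataclass
class TranscriptAnnotation:
    """Filtered gene models with derived transcript regions.

    ``genes``: gene_id, chrom, start, end, strand, gene_type, level
    ``transcripts``: transcript_id, gene_id, tsl
    ``exons``: transcript_id, start, end
    ``cds``: transcript_id, start, end
    All coordinates 0-based half-open.
    """

    genes: pd.DataFrame
    transcripts: pd.DataFrame
    exons: pd.DataFrame
    cds: pd.DataFrame
    _regions: pd.DataFrame | None = field(default=None, repr=False)

    def regions(self) -> pd.DataFrame:
        """Per-transcript region intervals (transcript_id, label, start, end).

        Introns are the gaps between exons; exonic stretches are split into
        CDS / 5'UTR / 3'UTR by the CDS span (strand-aware).  Transcripts
        without CDS records yield plain ``exonic`` intervals.
        """
        if self._regions is not None:
            return self._regions
        tx_strand = self.transcripts.merge(
            self.genes[["gene_id", "strand"]], on="gene_id")
        strand_of = dict(zip(tx_strand["transcript_id"], tx_strand["strand"]))
        cds_span = {
            tid: (g["start"].min(), g["end"].max())
            for tid, g in self.cds.groupby("transcript_id")
        }
        rows = []
        for tid, ex in self.exons.groupby("transcript_id"):
            ex = ex.sort_values("start")
            starts = ex["start"].to_numpy(int)
            ends = ex["end"].to_numpy(int)
            for intron_start, intron_end in zip(ends[:-1], starts[1:]):
                if intron_end > intron_start:
                    rows.append((tid, "intron", intron_start, intron_end))
            span = cds_span.get(tid)
            strand = strand_of[tid]
            for s, e in zip(starts, ends):
                if span is None:
                    rows.append((tid, "exonic", s, e))
                    continue
                lo, hi = span
                if s < min(lo, e):
                    left_end = min(lo, e)
                    label = "5UTR" if strand == "+" else "3UTR"
                    rows.append((tid, label, s, left_end))
                cs, ce = max(s, lo), min(e, hi)
                if ce > cs:
                    rows.append((tid, "CDS", cs, ce))
                if e > max(hi, s):
                    right_start = max(hi, s)
                    label = "3UTR" if strand == "+" else "5UTR"
                    rows.append((tid, label, right_start, e))
        self._regions = pd.DataFrame(rows, columns=["transcript_id", "label", "start", "end"])
        return self._regions


def _numeric(series: pd.Series) -> pd.Series:
    return pd.to_numeric(series, errors="coerce")


def load_annotation(gtf_path, max_gene_level: int = 2, max_tsl: int = 3) -> TranscriptAnnotation:
    """Load a GENCODE-style GTF and apply the support filters."""
    df = pr.read_gtf(str(gtf_path)).df
    df = df.rename(columns={"Chromosome": "chrom", "Start": "start", "End": "end",
                            "Strand": "strand", "Feature": "feature"})
    for col in ("level", "transcript_support_level", "gene_type"):
        if col not in df.columns:
            df[col] = np.nan
    genes = df[df["feature"] == "gene"].copy()
    genes["level"] = _numeric(genes["level"])
    genes = genes[genes["level"] <= max_gene_level]
    genes = genes[["gene_id", "chrom", "start", "end", "strand", "gene_type", "level"]]

    tx = df[df["feature"] == "transcript"].copy()
    tx["tsl"] = _numeric(tx["transcript_support_level"])
    tx = tx[tx["tsl"].notna() & (tx["tsl"] <= max_tsl)]
    tx = tx[tx["gene_id"].isin(genes["gene_id"])]
    tx = tx[["transcript_id", "gene_id", "tsl"]]

    keep_tx = set(tx["transcript_id"])
    exons = df[(df["feature"] == "exon") & df["transcript_id"].isin(keep_tx)]
    cds = df[(df["feature"] == "CDS") & df["transcript_id"].isin(keep_tx)]
    return TranscriptAnnotation(
        genes=genes.reset_index(drop=True),
        transcripts=tx.reset_index(drop=True),
        exons=exons[["transcript_id", "start", "end"]].reset_index(drop=True),
        cds=cds[["transcript_id", "start", "end"]].reset_index(drop=True),
    )


def write_gtf(ann: TranscriptAnnotation, path, source: str = "clipmap") -> None:
    """Write the annotation back out as GENCODE-dialect GTF (1-based)."""
    gene_meta = ann.genes.set_index("gene_id")
    tx_meta = ann.transcripts.set_index("transcript_id")

    def attrs(**kw) -> str:
        return " ".join(f'{k} "{v}";' for k, v in kw.items())

    with open(path, "w") as fh:
        fh.write("##description: clipmap annotation\n")
        for g in ann.genes.itertuples(index=False):
            fh.write("\t".join(map(str, [
                g.chrom, source, "gene", g.start + 1, g.end, ".", g.strand, ".",
                attrs(gene_id=g.gene_id, gene_type=g.gene_type,
                      gene_name=g.gene_id, level=int(g.level)),
            ])) + "\n")
            gene_tx = ann.transcripts[ann.transcripts["gene_id"] == g.gene_id]
            for t in gene_tx.itertuples(index=False):
                tx_exons = ann.exons[ann.exons["transcript_id"] == t.transcript_id]
                tx_cds = ann.cds[ann.cds["transcript_id"] == t.transcript_id]
                common = dict(gene_id=g.gene_id, transcript_id=t.transcript_id,
                              gene_type=g.gene_type, level=int(g.level),
                              transcript_support_level=int(t.tsl))
                fh.write("\t".join(map(str, [
                    g.chrom, source, "transcript",
                    tx_exons["start"].min() + 1, tx_exons["end"].max(),
                    ".", g.strand, ".", attrs(**common)])) + "\n")
                for feature, feat_df in (("exon", tx_exons), ("CDS", tx_cds)):
                    for r in feat_df.sort_values("start").itertuples(index=False):
                        fh.write("\t".join(map(str, [
                            g.chrom, source, feature, r.start + 1, r.end,
                            ".", g.strand, ".", attrs(**common)])) + "\n")


def _gene_trees(genes: pd.DataFrame) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in genes.itertuples(index=False):
        trees.setdefault((g.chrom, g.strand), IntervalTree()).addi(
            g.start, g.end, g.gene_id)
    return trees


def remove_overlapping_genes(genes: pd.DataFrame) -> pd.DataFrame:
    """Drop genes whose span overlaps another gene on the same strand."""
    trees = _gene_trees(genes)
    drop = set()
    for g in genes.itertuples(index=False):
        hits = trees[(g.chrom, g.strand)].overlap(g.start, g.end)
        if sum(1 for h in hits if h.data != g.gene_id) > 0:
            drop.add(g.gene_id)
    return genes[~genes["gene_id"].isin(drop)].reset_index(drop=True)


def assign_unique_gene(bsites: pd.DataFrame, ann: TranscriptAnnotation,
                       overlap_removal: str = "gene") -> pd.DataFrame:
    """Attach a ``gene_id`` to every binding site.

    A site overlapping exactly one retained gene (same strand) gets that
    gene; >= 2 genes -> ``"ambiguous"``; none -> ``"none"``.  With
    ``overlap_removal="gene"`` (default), genes overlapping another retained
    gene on the same strand are removed before assignment; ``"none"``
    disables the pre-filter so that overlap resolves via ambiguity only.
    """
    if overlap_removal not in ("gene", "none"):
        raise ValueError("overlap_removal must be 'gene' or 'none'")
    genes = ann.genes
    if overlap_removal == "gene":
        genes = remove_overlapping_genes(genes)
    trees = _gene_trees(genes)
    biotype = dict(zip(genes["gene_id"], genes["gene_type"]))
    out = bsites.reset_index(drop=True).copy()
    assigned, types = [], []
    for s in out.itertuples(index=False):
        tree = trees.get((s.chrom, s.strand))
        hits = sorted(h.data for h in tree.overlap(s.start, s.end)) if tree else []
        if len(hits) == 1:
            assigned.append(hits[0])
            types.append(biotype[hits[0]])
        elif len(hits) == 0:
            assigned.append("none")
            types.append(None)
        else:
            assigned.append("ambiguous")
            types.append(None)
    out["gene_id"] = assigned
    out["gene_type"] = types
    return out


def assign_region(site_start: int, site_end: int, gene_id: str,
                  ann: TranscriptAnnotation,
                  regions: pd.DataFrame | None = None,
                  coding_gene: bool = True) -> tuple[str | None, dict[str, int]]:
    """Majority-vote region label for one site within its unique gene.

    Each retained transcript of the gene casts one vote: the hierarchically
    highest label among the transcript's region intervals overlapping the
    site.  In coding genes, transcripts without CDS records vote only when
    the overlap is intronic.  Returns (label, votes); label is None when no
    transcript overlaps the site.
    """
    regions = ann.regions() if regions is None else regions
    tids = ann.transcripts.loc[ann.transcripts["gene_id"] == gene_id, "transcript_id"]
    has_cds = set(ann.cds["transcript_id"])
    votes: dict[str, int] = {}
    for tid in tids:
        tr = regions[regions["transcript_id"] == tid]
        hit = tr[(tr["start"] < site_end) & (tr["end"] > site_start)]
        if hit.empty:
            continue
        labels = set(hit["label"])
        if coding_gene and tid not in has_cds:
            # CDS-absent transcript of a coding gene: only intron votes count
            labels &= {"intron"}
            if not labels:
                continue
        label = min(labels, key=_RANK.__getitem__)
        votes[label] = votes.get(label, 0) + 1
    if not votes:
        return None, votes
    top = max(votes.values())
    winner = min((lab for lab, n in votes.items() if n == top), key=_RANK.__getitem__)
    return winner, votes


def assign_regions(assigned_sites: pd.DataFrame, ann: TranscriptAnnotation,
                   protein_coding_only: bool = True) -> pd.DataFrame:
    """Region labels for all uniquely assigned sites.

    With ``protein_coding_only`` (the default analysis path) sites in
    non-coding genes are dropped; otherwise their exonic overlaps are
    labelled ``exonic``.
    """
    regions = ann.regions()
    region_by_tx = {tid: g for tid, g in regions.groupby("transcript_id")}
    biotypes = dict(zip(ann.genes["gene_id"], ann.genes["gene_type"]))
    keep = assigned_sites[~assigned_sites["gene_id"].isin(["ambiguous", "none"])]
    if protein_coding_only:
        keep = keep[keep["gene_type"] == "protein_coding"]
    rows = []
    for s in keep.itertuples(index=False):
        coding = biotypes.get(s.gene_id) == "protein_coding"
        tids = ann.transcripts.loc[ann.transcripts["gene_id"] == s.gene_id, "transcript_id"]
        sub = pd.concat([region_by_tx[t] for t in tids if t in region_by_tx]) \
            if len(tids) else regions.iloc[:0]
        label, votes = assign_region(s.start, s.end, s.gene_id, ann,
                                     regions=sub, coding_gene=coding)
        if label is None:
            continue
        rows.append({"site_id": s.site_id, "gene_id": s.gene_id,
                     "region": label, "votes": votes})
    return pd.DataFrame(rows, columns=["site_id", "gene_id", "region", "votes"])


def region_enrichment(region_assignments: pd.DataFrame,
                      ann: TranscriptAnnotation) -> pd.DataFrame:
    """Length-normalized site density per region type (sites per kb).

    The denominator sums the lengths of each region type over the bound
    transcripts (transcripts of genes carrying at least one assigned site).
    """
    bound_genes = set(region_assignments["gene_id"])
    bound_tx = set(ann.transcripts.loc[ann.transcripts["gene_id"].isin(bound_genes),
                                       "transcript_id"])
    regions = ann.regions()
    regions = regions[regions["transcript_id"].isin(bound_tx)]
    lengths = (regions["end"] - regions["start"]).groupby(regions["label"]).sum()
    counts = region_assignments["region"].value_counts()
    rows = []
    for label in REGION_HIERARCHY:
        total_nt = int(lengths.get(label, 0))
        n = int(counts.get(label, 0))
        if total_nt == 0 and n == 0:
            continue
        density = 1000.0 * n / total_nt if total_nt else np.nan
        rows.append({"region": label, "n_sites": n, "total_nt": total_nt,
                     "sites_per_kb": density})
    return pd.DataFrame(rows)


def gene_type_distribution(assigned_sites: pd.DataFrame) -> pd.Series:
    """Fraction of uniquely assigned sites per gene biotype (sums to 1)."""
    unique = assigned_sites[~assigned_sites["gene_id"].isin(["ambiguous", "none"])]
    if len(unique) == 0:
        return pd.Series(dtype=float)
    return unique["gene_type"].value_counts(normalize=True)
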