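"""Annotation loading/filtering, unique-gene assignment, region voting and
length-normalized enrichment."""

import numpy as np
import pandas as pd
import pytest

from clipmap.annotation import (
    TranscriptAnnotation, assign_region, assign_regions, assign_unique_gene,
    gene_type_distribution, load_annotation, region_enrichment,
    remove_overlapping_genes, write_gtf,
)
from clipmap.synthetic import SyntheticConfig, generate_genome_and_annotation


def build_annotation(genes, transcripts, exons, cds):
    return TranscriptAnnotation(
        genes=pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end",
                                           "strand", "gene_type", "level"]),
        transcripts=pd.DataFrame(transcripts, columns=["transcript_id", "gene_id", "tsl"]),
        exons=pd.DataFrame(exons, columns=["transcript_id", "start", "end"]),
        cds=pd.DataFrame(cds, columns=["transcript_id", "start", "end"]),
    )


@pytest.fixture
def two_tx_gene():
    """One + strand gene, two transcripts with different structures."""
    return build_annotation(
        genes=[("G1", "chr1", 0, 1000, "+", "protein_coding", 2)],
        transcripts=[("T1", "G1", 1), ("T2", "G1", 1)],
        exons=[("T1", 0, 200), ("T1", 400, 700), ("T1", 800, 1000),
               ("T2", 0, 200), ("T2", 800, 1000)],
        cds=[("T1", 100, 200), ("T1", 400, 700), ("T1", 800, 900),
             ("T2", 100, 200), ("T2", 800, 900)],
    )


class TestRegionDerivation:
    def test_regions_partition_transcript_span(self, two_tx_gene):
        regions = two_tx_gene.regions()
        t1 = regions[regions["transcript_id"] == "T1"].sort_values("start")
        # contiguous tiling from transcript start to end
        assert t1["start"].iloc[0] == 0 and t1["end"].iloc[-1] == 1000
        assert (t1["start"].iloc[1:].to_numpy() == t1["end"].iloc[:-1].to_numpy()).all()
        labels = dict(zip(zip(t1["start"], t1["end"]), t1["label"]))
        assert labels[(0, 100)] == "5UTR"
        assert labels[(200, 400)] == "intron"
        assert labels[(400, 700)] == "CDS"
        assert labels[(900, 1000)] == "3UTR"

    def test_minus_strand_utr_orientation(self):
        ann = build_annotation(
            genes=[("G1", "chr1", 0, 300, "-", "protein_coding", 2)],
            transcripts=[("T1", "G1", 1)],
            exons=[("T1", 0, 300)],
            cds=[("T1", 50, 250)],
        )
        regions = ann.regions()
        labels = dict(zip(zip(regions["start"], regions["end"]), regions["label"]))
        # genomic-left UTR is the 3'UTR on the minus strand
        assert labels[(0, 50)] == "3UTR"
        assert labels[(250, 300)] == "5UTR"

    def test_intron_set_is_exon_complement(self, small_dataset):
        ds = small_dataset
        regions = ds.annotation.regions()
        for tid, ex in ds.annotation.exons.groupby("transcript_id"):
            ex = ex.sort_values("start")
            expected = [(e, s) for e, s in zip(ex["end"].iloc[:-1], ex["start"].iloc[1:])]
            got = regions[(regions["transcript_id"] == tid)
                          & (regions["label"] == "intron")].sort_values("start")
            assert list(zip(got["start"], got["end"])) == expected


class TestLoadFilters:
    def test_gtf_round_trip_and_support_filters(self, tmp_path, small_dataset):
        gtf = tmp_path / "ann.gtf"
        write_gtf(small_dataset.annotation, gtf)
        loaded = load_annotation(gtf)
        assert set(loaded.genes["gene_id"]) == set(small_dataset.annotation.genes["gene_id"])
        assert len(loaded.exons) == len(small_dataset.annotation.exons)
        pd.testing.assert_frame_equal(
            loaded.regions().sort_values(["transcript_id", "start"]).reset_index(drop=True),
            small_dataset.annotation.regions().sort_values(
                ["transcript_id", "start"]).reset_index(drop=True))

    def test_level_and_tsl_filters(self, tmp_path):
        lines = ["##test"]
        for gid, level, tsl in (("GA", 2, 1), ("GB", 3, 1), ("GC", 2, 4), ("GD", 2, "NA")):
            attrs_g = f'gene_id "{gid}"; gene_type "protein_coding"; level {level};'
            attrs_t = attrs_g + f' transcript_id "{gid}.1"; transcript_support_level "{tsl}";'
            lines.append(f"chr1\tx\tgene\t1\t100\t.\t+\t.\t{attrs_g}")
            lines.append(f"chr1\tx\ttranscript\t1\t100\t.\t+\t.\t{attrs_t}")
            lines.append(f"chr1\tx\texon\t1\t100\t.\t+\t.\t{attrs_t}")
        path = tmp_path / "t.gtf"
        path.write_text("\n".join(lines) + "\n")
        ann = load_annotation(path)
        assert set(ann.genes["gene_id"]) == {"GA", "GC", "GD"}  # gene level <= 2
        assert set(ann.transcripts["transcript_id"]) == {"GA.1"}  # TSL <= 3, numeric


class TestUniqueGene:
    def _sites(self, coords, strand="+"):
        return pd.DataFrame([{"site_id": f"s{i}", "chrom": "chr1", "start": a,
                              "end": b, "strand": strand}
                             for i, (a, b) in enumerate(coords)])

    def test_single_gene_assigned_two_genes_ambiguous(self):
        ann = build_annotation(
            genes=[("G1", "chr1", 0, 500, "+", "protein_coding", 2),
                   ("G2", "chr1", 1000, 1500, "+", "protein_coding", 2)],
            transcripts=[("T1", "G1", 1), ("T2", "G2", 1)],
            exons=[("T1", 0, 500), ("T2", 1000, 1500)], cds=[],
        )
        out = assign_unique_gene(self._sites([(10, 19), (600, 609)]), ann)
        assert list(out["gene_id"]) == ["G1", "none"]

    def test_overlapping_genes_removed_by_default(self):
        ann = build_annotation(
            genes=[("G1", "chr1", 0, 500, "+", "protein_coding", 2),
                   ("G2", "chr1", 400, 900, "+", "protein_coding", 2),
                   ("G3", "chr1", 2000, 2500, "+", "protein_coding", 2)],
            transcripts=[], exons=[], cds=[],
        )
        kept = remove_overlapping_genes(ann.genes)
        assert list(kept["gene_id"]) == ["G3"]
        out = assign_unique_gene(self._sites([(450, 459), (2100, 2109)]), ann)
        assert list(out["gene_id"]) == ["none", "G3"]
        out2 = assign_unique_gene(self._sites([(450, 459)]), ann, overlap_removal="none")
        assert list(out2["gene_id"]) == ["ambiguous"]

    def test_strand_matching(self):
        ann = build_annotation(
            genes=[("G1", "chr1", 0, 500, "+", "protein_coding", 2)],
            transcripts=[], exons=[], cds=[],
        )
        out = assign_unique_gene(self._sites([(10, 19)], strand="-"), ann)
        assert list(out["gene_id"]) == ["none"]

    def test_exclusion_matches_bruteforce_all_pairs(self):
        rng = np.random.default_rng(5)
        genes = []
        for i in range(30):
            start = int(rng.integers(0, 5000))
            genes.append((f"G{i}", "chr1", start, start + int(rng.integers(100, 800)),
                          "+", "protein_coding", 2))
        ann = build_annotation(genes, [], [], [])
        sites = self._sites([(int(p), int(p) + 9)
                             for p in rng.integers(0, 6000, size=50)])
        out = assign_unique_gene(sites, ann, overlap_removal="none")
        for site, got in zip(sites.itertuples(index=False), out["gene_id"]):
            hits = [g[0] for g in genes if g[2] < site.end and g[3] > site.start]
            expect = hits[0] if len(hits) == 1 else ("none" if not hits else "ambiguous")
            assert got == expect


class TestRegionVote:
    def test_majority_then_hierarchy(self, two_tx_gene):
        # site in T1's intron (200..400) which T2 also spans as intron
        label, votes = assign_region(250, 259, "G1", two_tx_gene)
        assert label == "intron" and votes == {"intron": 2}
        # site in 450..459: CDS in T1, intron in T2 -> tie broken to intron
        label, votes = assign_region(450, 459, "G1", two_tx_gene)
        assert votes == {"CDS": 1, "intron": 1} and label == "intron"
        # 3'UTR vs 5'UTR tie prefers 3'UTR
        ann = build_annotation(
            genes=[("G1", "chr1", 0, 200, "+", "protein_coding", 2)],
            transcripts=[("T1", "G1", 1), ("T2", "G1", 1)],
            exons=[("T1", 0, 200), ("T2", 0, 200)],
            cds=[("T1", 0, 100), ("T2", 150, 200)],
        )
        label, votes = assign_region(120, 129, "G1", ann)
        assert votes == {"3UTR": 1, "5UTR": 1} and label == "3UTR"

    def test_majority_beats_hierarchy(self):
        ann = build_annotation(
            genes=[("G1", "chr1", 0, 300, "+", "protein_coding", 2)],
            transcripts=[("T1", "G1", 1), ("T2", "G1", 1), ("T3", "G1", 1)],
            exons=[("T1", 0, 300), ("T2", 0, 300), ("T3", 0, 100), ("T3", 200, 300)],
            cds=[("T1", 0, 300), ("T2", 0, 300), ("T3", 0, 100), ("T3", 200, 300)],
        )
        label, votes = assign_region(120, 129, "G1", ann)
        assert votes == {"CDS": 2, "intron": 1} and label == "CDS"


class TestEnrichmentAndBiotypes:
    def test_density_arithmetic(self):
        ann = build_annotation(
            genes=[("G1", "chr1", 0, 1000, "+", "protein_coding", 2)],
            transcripts=[("T1", "G1", 1)],
            exons=[("T1", 0, 1000)], cds=[("T1", 0, 1000)],
        )
        assignments = pd.DataFrame({"site_id": [f"s{i}" for i in range(10)],
                                    "gene_id": "G1", "region": "CDS",
                                    "votes": [{}] * 10})
        dens = region_enrichment(assignments, ann)
        cds = dens[dens["region"] == "CDS"].iloc[0]
        assert cds["sites_per_kb"] == pytest.approx(10.0)

    def test_gene_type_distribution_recovers_planted_split(self):
        sites = pd.DataFrame({
            "site_id": [f"s{i}" for i in range(10)],
            "gene_id": [f"G{i}" for i in range(10)],
            "gene_type": ["protein_coding"] * 8 + ["lncRNA"] * 2,
        })
        frac = gene_type_distribution(sites)
        assert frac["protein_coding"] == pytest.approx(0.8)
        assert frac["lncRNA"] == pytest.approx(0.2)

    def test_empty_site_set(self):
        assert gene_type_distribution(pd.DataFrame(
            {"site_id": [], "gene_id": [], "gene_type": []})).empty


def test_region_assignment_unique_and_deterministic(small_dataset):
    ds = small_dataset
    from clipmap.binding_sites import call_binding_sites
    bsites = call_binding_sites(ds.sites, ds.replicate_tracks, ds.merged_track)
    assigned = assign_unique_gene(bsites, ds.annotation)
    first = assign_regions(assigned, ds.annotation)
    second = assign_regions(assigned, ds.annotation)
    pd.testing.assert_frame_equal(first, second)
    assert first["site_id"].is_unique
    assert set(first["region"]) <= {"intron", "CDS", "3UTR", "5UTR"}
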