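"""Synthetic iCLIP / RNA-seq data generator.

Generates small genomes with multi-exon gene models, plants GAA-repeat
motifs, simulates per-replicate crosslink-event tracks with negative-
binomial noise, emits significant sites via a surrogate caller, and builds
a cassette-exon table with paired control/knockdown PSI values — the
statistical structure every downstream stage of the pipeline assumes.

Study conditions emulated:

* binding is driven by runs of consecutive GAA triplets; crosslink pile-ups
  over planted runs peak towards the run's 3' end;
* genes fall into three classes: ``down`` (exon of decreased inclusion upon
  knockdown, GAA runs planted in the alternative-exon body), ``up``
  (increased inclusion, runs planted in the flanking constitutive exons)
  and ``neutral`` (unregulated; occasional intronic runs);
* exonic crosslink rates scale with the exon's control inclusion level, so
  highly included exons show more events (the coverage bias that motivates
  PSI-matched backgrounds);
* PSI values are beta-distributed around event means with a shared
  per-replicate-pair offset (paired design, 5 pairs); the FDR column comes
  from a paired t-test with Benjamini-Hochberg correction over all events.

The surrogate caller is a deliberately simple stand-in for an HMM-based
peak caller, used only on synthetic runs: a position is significant when
its merged count exceeds the per-gene ``background_quantile`` count
quantile, and its score is the merged count.  It is not equivalent to the
real caller; it merely produces scored single-nucleotide sites with the
right qualitative structure (score increases with local enrichment).

All generators are deterministic in ``seed``; sub-streams are derived per
component and per replicate so outputs are stable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import TranscriptAnnotation
from .io import CrosslinkTrack
from .preprocess import BarcodeScheme, ReadRecord, DEFAULT_ADAPTER
from .splicing_events import RMATS_SE_COLUMNS

PLACEMENT_CLASSES = ("exon_body_down", "flanking_exon_up", "neutral")

CATALOG_COLUMNS = ["gene_id", "chrom", "strand", "start", "end",
                   "n_triplets", "placement_class"]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic dataset.

    Ranges are inclusive on both ends.  Rates are per nucleotide per
    replicate; ``dispersion`` is the negative-binomial size parameter
    (smaller = more overdispersed).
    """

    n_genes: int = 400
    exons_per_gene: tuple[int, int] = (3, 5)
    exon_len: tuple[int, int] = (80, 160)
    intron_len: tuple[int, int] = (150, 400)
    intergenic_len: tuple[int, int] = (200, 500)
    cds_margin: int = 30          # UTR width inside the first/last exon
    n_replicates: int = 4
    motif_repeat_range: tuple[int, int] = (2, 5)
    background_rate: float = 0.05
    enrichment_factor: float = 16.0
    dispersion: float = 2.0
    ce_fraction_down: float = 0.15
    ce_fraction_up: float = 0.08
    dpsi_effect: float = 0.2
    exon_runs_down: int = 4       # GAA runs planted in a down-regulated exon body
    flank_runs_up: int = 3        # GAA runs per flanking exon of up-regulated events
    neutral_run_prob: float = 0.7
    noncoding_fraction: float = 0.0
    psi_concentration: float = 100.0
    pair_sd: float = 0.2          # logit-scale SD of the shared per-pair offset
    n_psi_replicates: int = 5
    junction_read_mean: float = 60.0
    junction_read_dispersion: float = 8.0
    background_quantile: float = 0.99
    surrogate_min_count: int = 2
    seed: int = 0

    def validate(self) -> None:
        for name in ("background_rate", "enrichment_factor", "dispersion",
                     "psi_concentration", "junction_read_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("exons_per_gene", "exon_len", "intron_len",
                     "intergenic_len", "motif_repeat_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"{name} range empty or non-positive")
        if not (0 <= self.ce_fraction_down <= 1 and 0 <= self.ce_fraction_up <= 1):
            raise ValueError("regulated fractions must lie in [0,1]")
        if self.ce_fraction_down + self.ce_fraction_up > 1:
            raise ValueError("regulated fractions must sum to <= 1")
        if self.exons_per_gene[0] < 3:
            raise ValueError("genes need >= 3 exons for cassette-exon events")
        if self.exon_len[0] < 2 * self.cds_margin + 10:
            raise ValueError("exons too short for the CDS margin")


def _rng(config_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config_seed), *key]))


# ---------------------------------------------------------------------------
# genome & annotation


def generate_genome_and_annotation(config: SyntheticConfig
                                   ) -> tuple[dict[str, str], TranscriptAnnotation]:
    """Random genome plus one multi-exon transcript per gene.

    Genes alternate between two chromosomes and random strands, with a CDS
    spanning from ``cds_margin`` inside the first exon to ``cds_margin``
    before the end of the last exon (so internal exons are fully coding).
    """
    config.validate()
    rng = _rng(config.seed, 0)
    if config.n_genes == 0:
        empty = TranscriptAnnotation(
            genes=pd.DataFrame(columns=["gene_id", "chrom", "start", "end",
                                        "strand", "gene_type", "level"]),
            transcripts=pd.DataFrame(columns=["transcript_id", "gene_id", "tsl"]),
            exons=pd.DataFrame(columns=["transcript_id", "start", "end"]),
            cds=pd.DataFrame(columns=["transcript_id", "start", "end"]),
        )
        return {}, empty
    chroms = ["chrA", "chrB"]
    cursors = {c: rng.integers(*config.intergenic_len, endpoint=True) for c in chroms}
    genes, transcripts, exons, cds = [], [], [], []
    for i in range(config.n_genes):
        gid = f"G{i:04d}"
        chrom = chroms[i % len(chroms)]
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(*config.exons_per_gene, endpoint=True))
        ex_lens = rng.integers(*config.exon_len, size=n_ex, endpoint=True)
        in_lens = rng.integers(*config.intron_len, size=n_ex - 1, endpoint=True)
        start = int(cursors[chrom])
        pos = start
        gene_exons = []
        for j in range(n_ex):
            gene_exons.append((pos, pos + int(ex_lens[j])))
            pos += int(ex_lens[j])
            if j < n_ex - 1:
                pos += int(in_lens[j])
        end = pos
        cursors[chrom] = end + int(rng.integers(*config.intergenic_len, endpoint=True))
        coding = rng.random() >= config.noncoding_fraction
        gene_type = "protein_coding" if coding else "lncRNA"
        tid = f"{gid}.1"
        genes.append((gid, chrom, start, end, strand, gene_type, 2))
        transcripts.append((tid, gid, 1))
        for s, e in gene_exons:
            exons.append((tid, s, e))
        if coding:
            cds_lo = gene_exons[0][0] + config.cds_margin
            cds_hi = gene_exons[-1][1] - config.cds_margin
            for s, e in gene_exons:
                cs, ce = max(s, cds_lo), min(e, cds_hi)
                if ce > cs:
                    cds.append((tid, cs, ce))
    ann = TranscriptAnnotation(
        genes=pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end",
                                           "strand", "gene_type", "level"]),
        transcripts=pd.DataFrame(transcripts, columns=["transcript_id", "gene_id", "tsl"]),
        exons=pd.DataFrame(exons, columns=["transcript_id", "start", "end"]),
        cds=pd.DataFrame(cds, columns=["transcript_id", "start", "end"]),
    )
    genome = {}
    for chrom in chroms:
        length = int(cursors[chrom]) + 100
        genome[chrom] = "".join(rng.choice(list("ACGT"), size=length))
    return genome, ann


def transcript_exons(ann: TranscriptAnnotation, gene_id: str) -> list[tuple[int, int]]:
    """Exon intervals of the gene's transcript, in transcript orientation."""
    tid = ann.transcripts.loc[ann.transcripts["gene_id"] == gene_id,
                              "transcript_id"].iloc[0]
    ex = ann.exons[ann.exons["transcript_id"] == tid].sort_values("start")
    pairs = list(zip(ex["start"], ex["end"]))
    strand = ann.genes.loc[ann.genes["gene_id"] == gene_id, "strand"].iloc[0]
    return pairs if strand == "+" else pairs[::-1]


def make_gene_plans(ann: TranscriptAnnotation, config: SyntheticConfig) -> pd.DataFrame:
    """Assign each coding gene a regulation class and a base inclusion level.

    Down-regulated exons start highly included (control PSI 0.55-0.9), up-
    regulated ones lowly included (0.1-0.45), neutral events anywhere in
    0.1-0.9.  The alternative exon is the middle exon of the transcript.
    """
    rng = _rng(config.seed, 1)
    coding = ann.genes[ann.genes["gene_type"] == "protein_coding"]
    gene_ids = coding["gene_id"].to_numpy()
    n = len(gene_ids)
    n_down = int(round(config.ce_fraction_down * n))
    n_up = int(round(config.ce_fraction_up * n))
    order = rng.permutation(n)
    klass = np.full(n, "neutral", dtype=object)
    klass[order[:n_down]] = "down"
    klass[order[n_down:n_down + n_up]] = "up"
    psi0 = np.empty(n)
    for i, k in enumerate(klass):
        if k == "down":
            psi0[i] = rng.uniform(0.55, 0.9)
        elif k == "up":
            psi0[i] = rng.uniform(0.1, 0.45)
        else:
            psi0[i] = rng.uniform(0.1, 0.9)
    rows = []
    for gid, k, p in zip(gene_ids, klass, psi0):
        ex = transcript_exons(ann, gid)
        g = coding[coding["gene_id"] == gid].iloc[0]
        rows.append({"gene_id": gid, "klass": k, "psi0": float(p),
                     "alt_idx": len(ex) // 2, "chrom": g["chrom"],
                     "strand": g["strand"]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# motif planting


def plant_motifs(genome: dict[str, str], ann: TranscriptAnnotation,
                 plans: pd.DataFrame, config: SyntheticConfig,
                 max_tries: int = 100) -> tuple[dict[str, str], pd.DataFrame]:
    """Write runs of consecutive GAA triplets into the genome.

    Runs are placed (strand-aware, so the transcript reads GAA...GAA) in
    the alternative-exon body for down-regulated genes, in the two flanking
    exons for up-regulated genes, and occasionally in an intron of neutral
    genes.  Placement respects the CDS span and a 5-nt margin from splice
    sites; a colliding draw is retried up to ``max_tries`` times, then the
    run is skipped.
    """
    rng = _rng(config.seed, 2)
    buffers = {c: bytearray(s, "ascii") for c, s in genome.items()}
    cds_span = {}
    for tid, g in ann.cds.groupby("transcript_id"):
        gid = ann.transcripts.loc[ann.transcripts["transcript_id"] == tid,
                                  "gene_id"].iloc[0]
        cds_span[gid] = (int(g["start"].min()), int(g["end"].max()))
    catalog = []

    def place_runs(plan, interval: tuple[int, int], n_runs: int,
                   placement_class: str, occupied: list[tuple[int, int]]):
        margin = 5
        lo, hi = interval
        lo, hi = lo + margin, hi - margin
        for _ in range(n_runs):
            n_trip = int(rng.integers(*config.motif_repeat_range, endpoint=True))
            run_len = 3 * n_trip
            if hi - lo < run_len:
                continue
            for _ in range(max_tries):
                p = int(rng.integers(lo, hi - run_len, endpoint=True))
                if all(p + run_len + 1 <= s or p >= e + 1 for s, e in occupied):
                    break
            else:
                continue
            occupied.append((p, p + run_len))
            motif = "GAA" * n_trip if plan.strand == "+" else "TTC" * n_trip
            buffers[plan.chrom][p:p + run_len] = motif.encode()
            catalog.append({"gene_id": plan.gene_id, "chrom": plan.chrom,
                            "strand": plan.strand, "start": p, "end": p + run_len,
                            "n_triplets": n_trip, "placement_class": placement_class})

    for plan in plans.itertuples(index=False):
        exons = transcript_exons(ann, plan.gene_id)
        span = cds_span.get(plan.gene_id)

        def coding_part(ex):
            if span is None:
                return ex
            return (max(ex[0], span[0]), min(ex[1], span[1]))

        occupied: list[tuple[int, int]] = []
        if plan.klass == "down":
            place_runs(plan, coding_part(exons[plan.alt_idx]),
                       config.exon_runs_down, "exon_body_down", occupied)
        elif plan.klass == "up":
            for flank in (plan.alt_idx - 1, plan.alt_idx + 1):
                place_runs(plan, coding_part(exons[flank]),
                           config.flank_runs_up, "flanking_exon_up", occupied)
        else:
            if rng.random() < config.neutral_run_prob and len(exons) >= 2:
                ex_sorted = sorted(exons)
                i = int(rng.integers(0, len(ex_sorted) - 1))
                intron = (ex_sorted[i][1], ex_sorted[i + 1][0])
                place_runs(plan, intron, 1, "neutral", occupied)
    genome2 = {c: b.decode() for c, b in buffers.items()}
    return genome2, pd.DataFrame(catalog, columns=CATALOG_COLUMNS)


# ---------------------------------------------------------------------------
# crosslink tracks & surrogate caller


def _negative_binomial(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_crosslink_data(ann: TranscriptAnnotation, catalog: pd.DataFrame,
                            plans: pd.DataFrame, config: SyntheticConfig,
                            chrom_lengths: dict[str, int]
                            ) -> tuple[list[CrosslinkTrack], pd.DataFrame, CrosslinkTrack]:
    """Per-replicate crosslink tracks, significant sites and the merge.

    The per-nucleotide rate is ``background_rate`` across each gene, scaled
    on exons by the inclusion level (alternative exon: its control PSI,
    constitutive exons: 0.95) and multiplied by ``enrichment_factor`` over
    planted runs with a linear ramp peaking at the run's transcript 3' end.
    Counts are negative-binomial per replicate; the merge is their sum.
    """
    rate = {(c, s): np.zeros(n, dtype=float)
            for c, n in chrom_lengths.items() for s in ("+", "-")}
    plan_by_gene = {p.gene_id: p for p in plans.itertuples(index=False)}
    for g in ann.genes.itertuples(index=False):
        arr = rate[(g.chrom, g.strand)]
        arr[g.start:g.end] = config.background_rate
        plan = plan_by_gene.get(g.gene_id)
        exons = transcript_exons(ann, g.gene_id)
        for idx, (s, e) in enumerate(exons):
            psi = 0.95
            if plan is not None and idx == plan.alt_idx:
                psi = plan.psi0
            arr[s:e] = config.background_rate * (0.4 + 1.2 * psi)
    for run in catalog.itertuples(index=False):
        arr = rate[(run.chrom, run.strand)]
        ramp = np.linspace(0.5, 1.0, run.end - run.start)
        if run.strand == "-":
            ramp = ramp[::-1]  # transcript 3' end is the genomic left end
        arr[run.start:run.end] = arr[run.start:run.end] * config.enrichment_factor * ramp

    replicates = []
    for r in range(config.n_replicates):
        rng = _rng(config.seed, 3, r)
        track = CrosslinkTrack(chrom_lengths, label=f"rep{r + 1}")
        for key, mu in rate.items():
            nz = mu > 0
            counts = np.zeros(len(mu), dtype=np.int64)
            counts[nz] = _negative_binomial(rng, mu[nz], config.dispersion)
            track.data[key] = counts
        replicates.append(track)
    merged = CrosslinkTrack.merge(replicates)

    site_rows = []
    for g in ann.genes.itertuples(index=False):
        counts = merged.counts(g.chrom, g.strand)[g.start:g.end]
        threshold = np.quantile(counts, config.background_quantile)
        sig = np.flatnonzero((counts > threshold)
                             & (counts >= config.surrogate_min_count))
        for offset in sig:
            site_rows.append((g.chrom, g.start + int(offset), g.strand,
                              float(counts[offset])))
    sites = pd.DataFrame(site_rows, columns=["chrom", "pos", "strand", "score"])
    return replicates, sites, merged


# ---------------------------------------------------------------------------
# cassette-exon table


def _logit(p):
    return np.log(p / (1 - p))


def _sigmoid(x):
    return 1 / (1 + np.exp(-x))


def simulate_ce_table(ann: TranscriptAnnotation, plans: pd.DataFrame,
                      config: SyntheticConfig) -> pd.DataFrame:
    """rMATS SE-dialect cassette-exon table (sample 1 = control, 2 = KD).

    Per event, paired control/KD PSI replicates are beta-distributed around
    the event mean with a shared per-pair logit offset; regulated events
    shift the KD mean by at least ``dpsi_effect`` in the planted direction.
    FDR is Benjamini-Hochberg over paired t-test p-values of all events.
    """
    rng = _rng(config.seed, 4)
    kappa = config.psi_concentration
    rows = []
    pvals = []
    for plan in plans.itertuples(index=False):
        exons = transcript_exons(ann, plan.gene_id)
        up, alt, down = (exons[plan.alt_idx - 1], exons[plan.alt_idx],
                         exons[plan.alt_idx + 1])
        if plan.klass == "down":
            delta = -config.dpsi_effect * (1 + abs(rng.normal(0, 0.1)))
        elif plan.klass == "up":
            delta = config.dpsi_effect * (1 + abs(rng.normal(0, 0.1)))
        else:
            delta = 0.0
        m_ctl = np.clip(plan.psi0, 0.02, 0.98)
        m_kd = np.clip(plan.psi0 + delta, 0.02, 0.98)
        psi_ctl, psi_kd = [], []
        ijc1, sjc1, ijc2, sjc2 = [], [], [], []
        for _ in range(config.n_psi_replicates):
            offset = rng.normal(0, config.pair_sd)
            mc = _sigmoid(_logit(m_ctl) + offset)
            mk = _sigmoid(_logit(m_kd) + offset)
            pc = rng.beta(mc * kappa, (1 - mc) * kappa)
            pk = rng.beta(mk * kappa, (1 - mk) * kappa)
            psi_ctl.append(pc)
            psi_kd.append(pk)
            for psi, ijc, sjc in ((pc, ijc1, sjc1), (pk, ijc2, sjc2)):
                total = int(_negative_binomial(
                    rng, np.array([config.junction_read_mean]),
                    config.junction_read_dispersion)[0])
                inc = int(rng.binomial(total, psi)) if total else 0
                ijc.append(inc)
                sjc.append(total - inc)
        t_res = stats.ttest_rel(psi_kd, psi_ctl)
        pvals.append(float(t_res.pvalue) if np.isfinite(t_res.pvalue) else 1.0)
        rows.append({
            "GeneID": plan.gene_id, "geneSymbol": plan.gene_id,
            "chr": plan.chrom, "strand": plan.strand,
            "exonStart_0base": alt[0], "exonEnd": alt[1],
            "upstreamES": up[0], "upstreamEE": up[1],
            "downstreamES": down[0], "downstreamEE": down[1],
            "IJC_SAMPLE_1": ",".join(map(str, ijc1)),
            "SJC_SAMPLE_1": ",".join(map(str, sjc1)),
            "IJC_SAMPLE_2": ",".join(map(str, ijc2)),
            "SJC_SAMPLE_2": ",".join(map(str, sjc2)),
            "IncFormLen": alt[1] - alt[0] + 98, "SkipFormLen": 98,
            "IncLevel1": ",".join(f"{p:.4f}" for p in psi_ctl),
            "IncLevel2": ",".join(f"{p:.4f}" for p in psi_kd),
            "IncLevelDifference": round(float(np.mean(psi_ctl) - np.mean(psi_kd)), 4),
        })
    fdr = multipletests(pvals, method="fdr_bh")[1]
    table = pd.DataFrame(rows)
    table.insert(0, "ID", np.arange(len(table)))
    table["PValue"] = pvals
    table["FDR"] = fdr
    return table[RMATS_SE_COLUMNS]


# ---------------------------------------------------------------------------
# raw reads


def simulate_iclip_reads(scheme: BarcodeScheme, n_reads: int, seed: int = 0,
                         insert_len: tuple[int, int] = (20, 40),
                         adapter_fraction: float = 0.3,
                         adapter: str = DEFAULT_ADAPTER,
                         base_quality: int = 35
                         ) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Raw iCLIP reads with the 9-nt barcode layout.

    Layout: [random 3 nt][sample 4 nt][random 2 nt][insert][optional
    adapter prefix].  Returns the reads plus a ground-truth table (sample,
    random barcode, insert length, adapter length) for checking the
    preprocessing stages.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 5]))
    samples = sorted(scheme.barcodes)
    reads, truth = [], []
    for i in range(n_reads):
        sample = samples[int(rng.integers(len(samples)))]
        rand5 = "".join(rng.choice(list("ACGT"), size=5))
        insert_n = int(rng.integers(*insert_len, endpoint=True))
        insert = "".join(rng.choice(list("ACGT"), size=insert_n))
        adapter_n = 0
        if rng.random() < adapter_fraction:
            adapter_n = int(rng.integers(1, len(adapter), endpoint=True))
        seq = (rand5[:3] + scheme.barcodes[sample] + rand5[3:]
               + insert + adapter[:adapter_n])
        reads.append(ReadRecord(f"read{i:06d}", seq, [base_quality] * len(seq)))
        truth.append({"read_id": f"read{i:06d}", "sample": sample,
                      "random_barcode": rand5, "insert_len": insert_n,
                      "adapter_len": adapter_n})
    return reads, pd.DataFrame(truth, columns=["read_id", "sample", "random_barcode",
                                               "insert_len", "adapter_len"])


# ---------------------------------------------------------------------------
# motif-strength fixture


def simulate_motif_strength_sites(n: int = 5000, a: float = 3.0, b: float = 0.5,
                                  noise_sd: float = 0.5, seed: int = 1,
                                  n_slots: int = 7, window: int = 49
                                  ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Synthetic binding sites with a planted strength ~ GAA-count relation.

    Each site's 49-nt window carries ``n_slots`` fixed 5-nt slots, ``k`` of
    which (k uniform in 0..n_slots) hold a C-guarded GAA triplet and the
    rest a neutral filler, on a GAA-scrubbed random background — so the
    window contains exactly k GAA triplets while the UUC background is
    independent of k.  Site strength is ``a + b*k`` plus Gaussian noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 6]))
    block = window + 12
    chrom_parts, rows = [], []
    for i in range(n):
        k = int(rng.integers(0, n_slots, endpoint=True))
        bg = "".join(rng.choice(list("ACGT"), size=window))
        while "GAA" in bg:
            bg = bg.replace("GAA", "CAA", 1)
        win = list(bg)
        slots = rng.permutation(n_slots)[:k]
        for s in range(n_slots):
            start = 2 + 6 * s
            content = "CGAAC" if s in slots else "CCGCC"
            win[start:start + 5] = content
        win = "".join(win)
        strength = a + b * k + rng.normal(0, noise_sd)
        pad_left, pad_right = 6, block - window - 6
        chrom_parts.append("C" * pad_left + win + "C" * pad_right)
        center = i * block + pad_left + window // 2
        rows.append({"site_id": f"MS{i:05d}", "chrom": "chrM", "start": center - 4,
                     "end": center + 5, "strand": "+", "center": center,
                     "score": float(2 ** strength), "strength": float(strength),
                     "n_significant_positions": 2, "region": "CDS",
                     "true_n_gaa": k})
    genome = {"chrM": "".join(chrom_parts)}
    return pd.DataFrame(rows), genome


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SimulatedDataset:
    config: SyntheticConfig
    genome: dict[str, str]
    annotation: TranscriptAnnotation
    plans: pd.DataFrame
    catalog: pd.DataFrame
    replicate_tracks: list[CrosslinkTrack]
    merged_track: CrosslinkTrack
    sites: pd.DataFrame
    ce_table: pd.DataFrame

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def simulate_dataset(config: SyntheticConfig | None = None) -> SimulatedDataset:
    """Run the full generator chain for one configuration."""
    config = config or SyntheticConfig()
    genome, ann = generate_genome_and_annotation(config)
    plans = make_gene_plans(ann, config)
    genome, catalog = plant_motifs(genome, ann, plans, config)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    reps, sites, merged = simulate_crosslink_data(ann, catalog, plans, config,
                                                  chrom_lengths)
    ce_table = simulate_ce_table(ann, plans, config)
    return SimulatedDataset(config, genome, ann, plans, catalog,
                            reps, merged, sites, ce_table)


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    """Write the dataset in its on-disk formats (FASTA, GTF, bedGraph, BED,
    TSV) under ``outdir``."""
    from pathlib import Path
    from . import io as cio
    from .annotation import write_gtf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cio.write_fasta(ds.genome, outdir / "genome.fa")
    write_gtf(ds.annotation, outdir / "annotation.gtf")
    trackdir = outdir / "tracks"
    for track in ds.replicate_tracks:
        track.to_bedgraph(trackdir)
    ds.merged_track.to_bedgraph(trackdir, prefix="merged")
    cio.write_sites_bed(ds.sites, outdir / "significant_sites.bed")
    ds.ce_table.to_csv(outdir / "cassette_exons.tsv", sep="\t", index=False)
    ds.catalog.to_csv(outdir / "planted_sites.tsv", sep="\t", index=False)
    ds.plans.to_csv(outdir / "gene_plans.tsv", sep="\t", index=False)
    with open(outdir / "chrom_lengths.tsv", "w") as fh:
        for c, n in ds.chrom_lengths.items():
            fh.write(f"{c}\t{n}\n")
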