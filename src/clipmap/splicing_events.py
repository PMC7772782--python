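"""Cassette-exon event tables: filtering and binding-site overlap.

Events come in the rMATS skipped-exon (SE) dialect.  Sample 1 is the
control condition, sample 2 the knockdown (KD); per-replicate PSI values
are comma-separated in ``IncLevel1`` / ``IncLevel2``.  dPSI is defined as
KD minus control, so exons losing inclusion upon KD have dPSI < 0.

Upstream/downstream exons are stored in transcript orientation: on the
minus strand the upstream exon is the genomically rightmost of the three.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

RMATS_SE_COLUMNS = [
    "ID", "GeneID", "geneSymbol", "chr", "strand",
    "exonStart_0base", "exonEnd", "upstreamES", "upstreamEE",
    "downstreamES", "downstreamEE",
    "IJC_SAMPLE_1", "SJC_SAMPLE_1", "IJC_SAMPLE_2", "SJC_SAMPLE_2",
    "IncFormLen", "SkipFormLen", "PValue", "FDR",
    "IncLevel1", "IncLevel2", "IncLevelDifference",
]

EVENT_COLUMNS = [
    "event_id", "gene_id", "chrom", "strand",
    "exon_start", "exon_end", "up_start", "up_end", "down_start", "down_end",
    "psi_ctl", "psi_kd", "psi_ctl_mean", "psi_kd_mean", "dpsi",
    "fdr", "pvalue", "jc_reps", "jc_mean",
]


@dataclass
class RegulatedSets:
    """Partition of measured events into down / up / unchanged."""

    down: pd.DataFrame   # decreased inclusion upon KD (dPSI < 0)
    up: pd.DataFrame     # increased inclusion upon KD (dPSI > 0)
    unchanged: pd.DataFrame

    @property
    def n_regulated(self) -> int:
        return len(self.down) + len(self.up)


def _parse_psi(value) -> list[float]:
    return [float(x) for x in str(value).split(",") if x not in ("", "NA")]


def _parse_counts(value) -> list[int]:
    return [int(x) for x in str(value).split(",") if x not in ("", "NA")]


def read_ce_table(path) -> pd.DataFrame:
    """Read an rMATS SE table into the internal event frame.

    Malformed rows (PSI outside [0,1], FDR outside [0,1], or unordered exon
    coordinates) are rejected with a warning listing their row numbers.
    """
    raw = pd.read_csv(path, sep="\t")
    missing = [c for c in RMATS_SE_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"missing rMATS SE columns: {missing}")
    rows, bad = [], []
    for i, r in raw.iterrows():
        try:
            psi_ctl = _parse_psi(r["IncLevel1"])
            psi_kd = _parse_psi(r["IncLevel2"])
            ijc1, sjc1 = _parse_counts(r["IJC_SAMPLE_1"]), _parse_counts(r["SJC_SAMPLE_1"])
            ijc2, sjc2 = _parse_counts(r["IJC_SAMPLE_2"]), _parse_counts(r["SJC_SAMPLE_2"])
            fdr = float(r["FDR"])
            if not all(0.0 <= p <= 1.0 for p in psi_ctl + psi_kd):
                raise ValueError("PSI outside [0,1]")
            if not 0.0 <= fdr <= 1.0:
                raise ValueError("FDR outside [0,1]")
            up = (int(r["upstreamES"]), int(r["upstreamEE"]))
            alt = (int(r["exonStart_0base"]), int(r["exonEnd"]))
            down = (int(r["downstreamES"]), int(r["downstreamEE"]))
            strand = str(r["strand"])
            order = (up, alt, down) if strand == "+" else (down, alt, up)
            if not (order[0][1] <= order[1][0] and order[1][1] <= order[2][0]):
                raise ValueError("exons not ordered")
            per_rep = [a + b + c + d for a, b, c, d in zip(ijc1, sjc1, ijc2, sjc2)]
            rows.append({
                "event_id": str(r["ID"]), "gene_id": r["GeneID"], "chrom": r["chr"],
                "strand": strand,
                "exon_start": alt[0], "exon_end": alt[1],
                "up_start": up[0], "up_end": up[1],
                "down_start": down[0], "down_end": down[1],
                "psi_ctl": psi_ctl, "psi_kd": psi_kd,
                "psi_ctl_mean": float(np.mean(psi_ctl)),
                "psi_kd_mean": float(np.mean(psi_kd)),
                "dpsi": float(np.mean(psi_kd) - np.mean(psi_ctl)),
                "fdr": fdr, "pvalue": float(r["PValue"]),
                "jc_reps": per_rep, "jc_mean": float(np.mean(per_rep)),
            })
        except (ValueError, TypeError) as exc:
            bad.append((i + 2, str(exc)))  # +2: header line and 1-based numbering
    if bad:
        listing = "; ".join(f"line {n}: {msg}" for n, msg in bad)
        warnings.warn(f"rejected {len(bad)} malformed row(s): {listing}")
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def filter_significant_events(events: pd.DataFrame, fdr: float = 0.05,
                              min_abs_dpsi: float = 0.05,
                              min_log2_jc: float = 5.0,
                              log2_before_mean: bool = False) -> RegulatedSets:
    """Partition events by FDR, |dPSI| and junction-read support.

    Significant iff FDR < ``fdr`` AND |dPSI| > ``min_abs_dpsi`` AND
    log2(mean over replicates of the per-replicate junction-read sums)
    > ``min_log2_jc``.  With ``log2_before_mean`` the mean is instead taken
    over per-replicate log2 sums.  All thresholds are strict, and the sign
    of dPSI routes significant events to the down (negative) or up
    (positive) set.
    """
    ev = events.reset_index(drop=True)
    if log2_before_mean:
        jc_stat = np.array([
            np.mean([np.log2(max(x, 1)) for x in reps]) for reps in ev["jc_reps"]
        ])
    else:
        jc_stat = np.log2(np.maximum(ev["jc_mean"].to_numpy(float), 1e-9))
    sig = (ev["fdr"] < fdr) & (ev["dpsi"].abs() > min_abs_dpsi) & (jc_stat > min_log2_jc)
    down = ev[sig & (ev["dpsi"] < 0)]
    up = ev[sig & (ev["dpsi"] > 0)]
    unchanged = ev[~ev.index.isin(down.index.union(up.index))]
    return RegulatedSets(down.reset_index(drop=True), up.reset_index(drop=True),
                         unchanged.reset_index(drop=True))


def as_region_window(event) -> tuple[int, int]:
    """Genomic window of the alternatively spliced region.

    Runs from 100 nt before the upstream exon's 5' splice site to 100 nt
    past the downstream exon's 3' splice site (transcript orientation).
    """
    if event.strand == "+":
        return event.up_end - 100, event.down_start + 100
    return event.down_end - 100, event.up_start + 100


def as_region_overlap(events: pd.DataFrame, bsites: pd.DataFrame,
                      flank: int = 100) -> pd.DataFrame:
    """Attach binding sites inside each event's alternatively spliced region.

    Returns the events with ``n_sites``, ``site_ids`` and
    ``max_site_strength`` columns; strand-matched interval overlap.
    """
    out = events.reset_index(drop=True).copy()
    n_sites, ids, strengths = [], [], []
    for ev in out.itertuples(index=False):
        if ev.strand == "+":
            lo, hi = ev.up_end - flank, ev.down_start + flank
        else:
            lo, hi = ev.down_end - flank, ev.up_start + flank
        hit = bsites[(bsites["chrom"] == ev.chrom) & (bsites["strand"] == ev.strand)
                     & (bsites["start"] < hi) & (bsites["end"] > lo)]
        n_sites.append(len(hit))
        ids.append(list(hit["site_id"]))
        strengths.append(float(hit["strength"].max()) if len(hit) else np.nan)
    out["n_sites"] = n_sites
    out["site_ids"] = ids
    out["max_site_strength"] = strengths
    return out


def percent_inclusion(molarity_long: float, molarity_short: float) -> float:
    """RT-PCR percent inclusion from amplicon molarities.

    ``100 * long / (long + short)``; the longer amplicon is the
    exon-inclusion isoform.
    """
    if molarity_long < 0 or molarity_short < 0:
        raise ValueError("molarities must be non-negative")
    total = molarity_long + molarity_short
    if total == 0:
        raise ValueError("at least one molarity must be positive")
    return 100.0 * molarity_long / total


def intersect_gene_list(sets: RegulatedSets, gene_list) -> dict[str, pd.DataFrame]:
    """Events from each regulated set whose gene is in ``gene_list``."""
    wanted = set(gene_list)
    return {
        name: df[df["gene_id"].isin(wanted)].reset_index(drop=True)
        for name, df in (("down", sets.down), ("up", sets.up),
                         ("unchanged", sets.unchanged))
    }
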