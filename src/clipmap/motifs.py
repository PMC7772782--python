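"""Pentamer and triplet analytics around binding sites.

Sequences are always handled in transcript orientation (minus-strand sites
are reverse-complemented), in the DNA alphabet internally; use
:func:`to_rna` for presentation.  Pentamer statistics compare the 9-nt
binding site against its 20-nt flanks, positional profiles tally pentamer
starts over a 201-nt window around the site center, and the triplet
analytics relate GAA / UUC content in a 49-nt window to binding-site
strength (log2 peak-caller score).
"""

from __future__ import annotations

import itertools
import re

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

BASES = "ACGT"
PENTAMERS = ["".join(p) for p in itertools.product(BASES, repeat=5)]
_BASE_CODE = {ord(b): i for i, b in enumerate(BASES)}
_COMP = str.maketrans("ACGTN", "TGCAN")


def to_rna(kmer: str) -> str:
    return kmer.replace("T", "U")


def to_dna(kmer: str) -> str:
    return kmer.replace("U", "T")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def fetch_oriented(genome: dict[str, str], chrom: str, strand: str,
                   start: int, end: int) -> str:
    """Genomic [start, end) in transcript orientation, N-padded at edges."""
    ref = genome[chrom]
    lo, hi = max(start, 0), min(end, len(ref))
    seq = "N" * (lo - start) + ref[lo:hi] + "N" * (end - hi)
    return _revcomp(seq) if strand == "-" else seq


def centered_seq(genome, chrom, strand, center: int, left: int, right: int) -> str:
    """Sequence covering transcript offsets -left..+right around ``center``."""
    if strand == "+":
        return fetch_oriented(genome, chrom, strand, center - left, center + right + 1)
    return fetch_oriented(genome, chrom, strand, center - right, center + left + 1)


def _encode(seq: str) -> np.ndarray:
    """Base codes A,C,G,T -> 0..3; anything else -> -1."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(len(arr), -1, dtype=np.int64)
    for byte, code in _BASE_CODE.items():
        out[arr == byte] = code
    return out


def _pentamer_counts(seq: str) -> np.ndarray:
    """Overlapping pentamer occurrence counts (length-1024 vector)."""
    codes = _encode(seq)
    n = len(codes) - 4
    if n <= 0:
        return np.zeros(1024, dtype=np.int64)
    idx = sum(codes[k:k + n] * 4 ** (4 - k) for k in range(5))
    valid = np.ones(n, dtype=bool)
    for k in range(5):
        valid &= codes[k:k + n] >= 0
    return np.bincount(idx[valid], minlength=1024)


def sample_sites(bsites: pd.DataFrame, per_region_n: int = 5000,
                 seed: int = 0) -> pd.DataFrame:
    """Uniform sample without replacement of up to ``per_region_n`` sites per
    region class (all sites when a region has fewer)."""
    rng = np.random.default_rng(seed)
    parts = []
    for region, group in sorted(bsites.groupby("region"), key=lambda kv: kv[0]):
        if len(group) <= per_region_n:
            parts.append(group)
        else:
            take = rng.choice(len(group), size=per_region_n, replace=False)
            parts.append(group.iloc[np.sort(take)])
    return pd.concat(parts).reset_index(drop=True) if parts else bsites.iloc[:0]


def pentamer_window_counts(bsites: pd.DataFrame, genome: dict[str, str],
                           flank: int = 20) -> pd.DataFrame:
    """Mean overlapping-pentamer counts in the binding site and its flanks.

    Returns a 1024-row frame indexed by pentamer with columns ``site``
    (the 9-nt window itself), ``upstream`` and ``downstream`` (20-nt flanks
    in transcript orientation).
    """
    sums = {w: np.zeros(1024, dtype=float) for w in ("site", "upstream", "downstream")}
    n = len(bsites)
    for s in bsites.itertuples(index=False):
        if s.strand == "+":
            windows = {
                "site": (s.start, s.end),
                "upstream": (s.start - flank, s.start),
                "downstream": (s.end, s.end + flank),
            }
        else:
            windows = {
                "site": (s.start, s.end),
                "upstream": (s.end, s.end + flank),
                "downstream": (s.start - flank, s.start),
            }
        for name, (a, b) in windows.items():
            sums[name] += _pentamer_counts(fetch_oriented(genome, s.chrom, s.strand, a, b))
    data = {name: vec / n if n else vec for name, vec in sums.items()}
    return pd.DataFrame(data, index=pd.Index(PENTAMERS, name="pentamer"))


def positional_profiles(bsites: pd.DataFrame, genome: dict[str, str],
                        window: int = 201) -> pd.DataFrame:
    """Fraction of sites with each pentamer starting at each offset.

    Offsets run -(window//2)..+(window//2) relative to the site center
    (summit), in transcript orientation.  At any offset fully covered by
    A/C/G/T sequence in every site, the 1,024 fractions sum to 1.
    """
    half = window // 2
    n = len(bsites)
    counts = np.zeros((1024, window), dtype=float)
    if n:
        seqs = [centered_seq(genome, s.chrom, s.strand, s.center, half, half + 4)
                for s in bsites.itertuples(index=False)]
        codes = np.stack([_encode(seq) for seq in seqs])
        idx = sum(codes[:, k:k + window] * 4 ** (4 - k) for k in range(5))
        valid = np.ones((n, window), dtype=bool)
        for k in range(5):
            valid &= codes[:, k:k + window] >= 0
        for j in range(window):
            col = idx[valid[:, j], j]
            counts[:, j] = np.bincount(col, minlength=1024)
        counts /= n
    offsets = np.arange(-half, window - half)
    return pd.DataFrame(counts, index=pd.Index(PENTAMERS, name="pentamer"),
                        columns=offsets)


def cluster_profiles(profiles: pd.DataFrame, site_freq: pd.Series,
                     k: int = 3, top_n: int = 300, seed: int = 0) -> pd.DataFrame:
    """k-means clustering of the positional profiles of the ``top_n``
    pentamers ranked by in-site frequency.

    Returns pentamer, in-site frequency and cluster id, ordered by
    decreasing frequency within cluster.
    """
    ranked = site_freq.sort_values(ascending=False, kind="stable").index[:top_n]
    mat = profiles.loc[ranked].to_numpy()
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(mat)
    out = pd.DataFrame({"pentamer": ranked, "site_freq": site_freq.loc[ranked].to_numpy(),
                        "cluster": labels})
    return out.sort_values(["cluster", "site_freq"],
                           ascending=[True, False]).reset_index(drop=True)


def count_triplet(seq: str, triplet: str) -> int:
    """Non-overlapping occurrences, maximal placements left to right."""
    return seq.count(to_dna(triplet))


def max_run_length(seq: str, triplet: str, gap: int) -> int:
    """Longest chain of triplet occurrences separated by exactly ``gap`` nt."""
    t = to_dna(triplet)
    positions = [m.start() for m in re.finditer(f"(?={re.escape(t)})", seq)]
    best = 0
    for start_pos in positions:
        length, pos = 1, start_pos
        while pos + 3 + gap in positions:
            pos += 3 + gap
            length += 1
        best = max(best, length)
    return best


def triplet_strength_analysis(bsites: pd.DataFrame, genome: dict[str, str],
                              window: int = 49, triplets: tuple[str, ...] = ("GAA", "UUC"),
                              max_category: int = 7,
                              max_n_fraction: float = 0.2) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Triplet counts in a window around each site center versus strength.

    Returns (per-site table, per-stratum summary).  The summary gives
    quartiles of strength per triplet count, with counts capped at
    ``max_category``+ as one category.  Sites whose window contains more
    than ``max_n_fraction`` N are excluded.
    """
    half = window // 2
    rows = []
    for s in bsites.itertuples(index=False):
        seq = centered_seq(genome, s.chrom, s.strand, s.center, half, window - half - 1)
        if seq.count("N") > max_n_fraction * len(seq):
            continue
        row = {"site_id": s.site_id, "strength": s.strength}
        for t in triplets:
            row[f"n_{t}"] = count_triplet(seq, t)
            for g in (0, 1, 2):
                row[f"run_{t}_gap{g}"] = max_run_length(seq, t, g)
        rows.append(row)
    table = pd.DataFrame(rows)
    summaries = []
    for t in triplets:
        col = table[f"n_{t}"].clip(upper=max_category)
        for cat, group in table.groupby(col):
            label = f"{max_category}+" if cat == max_category else str(int(cat))
            q1, med, q3 = np.percentile(group["strength"], [25, 50, 75])
            summaries.append({"triplet": t, "n_triplets": label, "n_sites": len(group),
                              "q25": q1, "median": med, "q75": q3})
    return table, pd.DataFrame(summaries)


RUN_CLASSES = ("0-1", ">=2_direct", ">=2_gap1", ">=2_gap2")


def consecutive_run_analysis(bsites: pd.DataFrame, genome: dict[str, str],
                             window: int = 49, triplet: str = "GAA",
                             allowed_gaps: tuple[int, ...] = (0, 1, 2)) -> pd.DataFrame:
    """Classify each site by its maximal chain of triplet repeats.

    Classes: ``0-1`` (no chain of two), ``>=2_direct`` (two or more in
    direct sequence), ``>=2_gap1`` / ``>=2_gap2`` (two or more separated by
    exactly 1 or 2 nt).  A site satisfying several is classed by the
    smallest gap.
    """
    half = window // 2
    rows = []
    for s in bsites.itertuples(index=False):
        seq = centered_seq(genome, s.chrom, s.strand, s.center, half, window - half - 1)
        runs = {g: max_run_length(seq, triplet, g) for g in allowed_gaps}
        cls = "0-1"
        for g in sorted(allowed_gaps):
            if runs[g] >= 2:
                cls = f">=2_direct" if g == 0 else f">=2_gap{g}"
                break
        row = {"site_id": s.site_id, "run_class": cls}
        row.update({f"run_gap{g}": n for g, n in runs.items()})
        rows.append(row)
    return pd.DataFrame(rows)
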