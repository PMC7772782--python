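"""Independent brute-force reference implementations used only by tests.

These re-implement the pipeline rules with naive scans and explicit loops,
deliberately sharing no code with the package (beyond numpy's standard
quantile primitive).
"""

from __future__ import annotations

import numpy as np


def oracle_binding_sites(site_list, merged, chrom_lengths, rep_counts,
                         drop_fraction=0.05, max_distance=8, min_region=3,
                         width=9, min_sig=2, min_support=3, quantile=0.20):
    """Full binding-site pipeline by brute force.

    site_list: [(chrom, pos, strand, score)]
    merged / rep_counts[r]: dict[(chrom, strand)] -> list[int] per-position counts
    Returns the retained sites as a set of (chrom, strand, start, end, center).
    """
    # 1. drop the lowest-scoring fraction (ties at the cutoff kept)
    scores = [s[3] for s in site_list]
    if not scores:
        return set()
    cutoff = np.quantile(scores, drop_fraction)
    kept = [s for s in site_list if s[3] >= cutoff]

    # 2. cluster sites closer than max_distance, drop narrow regions
    by_key = {}
    for chrom, pos, strand, score in kept:
        by_key.setdefault((chrom, strand), []).append(pos)
    regions = []
    for key in sorted(by_key):
        positions = sorted(by_key[key])
        cluster = [positions[0]]
        for p in positions[1:]:
            if p - cluster[-1] < max_distance:
                cluster.append(p)
            else:
                regions.append((key, cluster))
                cluster = [p]
        regions.append((key, cluster))
    regions = [(key, c) for key, c in regions if c[-1] - c[0] + 1 >= min_region]

    # 3./4. summit-centered 9-nt windows with the min-sig placement rule
    sig_by_key = {}
    for chrom, pos, strand, score in kept:
        sig_by_key.setdefault((chrom, strand), set()).add(pos)

    def n_sig(key, start, end):
        return sum(1 for p in sig_by_key.get(key, ()) if start <= p < end)

    def summit_of(key, candidates):
        chrom, strand = key
        counts = merged[key]
        best = max(counts[p] for p in candidates)
        at_best = [p for p in candidates if counts[p] == best]
        return min(at_best) if strand == "+" else max(at_best)

    windows = []  # (key, start, end, center)
    placed_by_key = {}

    def ok(key, start, end):
        chrom, _ = key
        if start < 0 or end > chrom_lengths[chrom]:
            return False
        return all(end <= s or start >= e for s, e, _ in placed_by_key.get(key, []))

    half = width // 2
    for key, cluster in regions:
        counts = merged[key]
        region_start, region_end = cluster[0], cluster[-1] + 1
        region_width = region_end - region_start
        if region_width <= width:
            candidates = [p for p in range(region_start, region_end) if counts[p] > 0]
            if not candidates:
                continue
            summit = summit_of(key, candidates)
            if region_width == width:
                start, end = region_start, region_end
            else:
                start, end = summit - half, summit + half + 1
            if ok(key, start, end) and n_sig(key, start, end) >= min_sig:
                placed_by_key.setdefault(key, []).append((start, end, summit))
        else:
            remaining = {p for p in range(region_start, region_end) if counts[p] > 0}
            while remaining:
                summit = summit_of(key, remaining)
                start, end = summit - half, summit + half + 1
                if ok(key, start, end) and n_sig(key, start, end) >= min_sig:
                    placed_by_key.setdefault(key, []).append((start, end, summit))
                    remaining -= set(range(start, end))
                else:
                    remaining.discard(summit)
    for key, placed in placed_by_key.items():
        for start, end, summit in placed:
            windows.append((key[0], key[1], start, end, summit))

    # 5. reproducibility: per-replicate 20%-quantile threshold on window sums
    if not windows:
        return set()
    support = {w: 0 for w in windows}
    for r in rep_counts:
        sums = {}
        for w in windows:
            chrom, strand, start, end, _ = w
            sums[w] = sum(r[(chrom, strand)][p] for p in range(start, end))
        threshold = np.quantile(list(sums.values()), quantile)
        for w in windows:
            if sums[w] >= threshold:
                support[w] += 1
    return {w for w in windows if support[w] >= min_support}


def oracle_pentamer_counts(seq: str) -> dict[str, int]:
    """Count every overlapping 5-mer made of A/C/G/T."""
    out = {}
    for i in range(len(seq) - 4):
        kmer = seq[i:i + 5]
        if all(c in "ACGT" for c in kmer):
            out[kmer] = out.get(kmer, 0) + 1
    return out


def oracle_run_class(seq: str, triplet: str = "GAA") -> str:
    """Maximal-repeat class of a window by explicit position chaining."""
    hits = [i for i in range(len(seq) - 2) if seq[i:i + 3] == triplet]
    for gap in (0, 1, 2):
        for start in hits:
            n, pos = 1, start
            while pos + 3 + gap in hits:
                n += 1
                pos += 3 + gap
            if n >= 2:
                return ">=2_direct" if gap == 0 else f">=2_gap{gap}"
    return "0-1"


def oracle_bh(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
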