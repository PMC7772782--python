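"""Binding-site definition from scored single-nucleotide crosslink sites.

The procedure turns a set of single-nucleotide significant crosslink sites
(each carrying a peak-caller score) plus per-replicate crosslink-event tracks
into equal-sized, reproducible binding sites:

1. drop the sites with the 5% lowest scores;
2. cluster remaining sites closer than 8 nt into regions, discard regions
   narrower than 3 nt;
3. convert every region into 9-nt windows centered on crosslink-event peak
   summits — short regions are extended symmetrically around their summit,
   long regions are split iteratively, placing a window at the current
   global summit and masking it before searching again;
4. require at least two significant positions per window;
5. keep only windows supported by at least three of four replicates, where a
   replicate supports a window when its summed events reach the replicate's
   20%-quantile threshold over all windows.

Windows never overlap on the same strand and always contain their summit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CrosslinkTrack

logger = logging.getLogger(__name__)

BINDING_SITE_COLUMNS = [
    "site_id", "chrom", "start", "end", "strand",
    "center", "score", "strength", "n_significant_positions",
]


@dataclass
class Region:
    chrom: str
    strand: str
    start: int
    end: int  # half-open

    @property
    def width(self) -> int:
        return self.end - self.start


def filter_low_scores(sites: pd.DataFrame, drop_fraction: float = 0.05) -> pd.DataFrame:
    """Remove the sites with the lowest ``drop_fraction`` of scores.

    The cutoff is the empirical (linear-interpolation) quantile of all
    scores; sites whose score equals the cutoff are kept, so a degenerate
    input with all-equal scores loses nothing.
    """
    if len(sites) == 0:
        return sites.copy()
    cutoff = np.quantile(sites["score"].to_numpy(float), drop_fraction)
    return sites[sites["score"] >= cutoff].reset_index(drop=True)


def cluster_sites(sites: pd.DataFrame, max_distance: int = 8, min_width: int = 3) -> list[Region]:
    """Cluster significant sites closer than ``max_distance`` nt into regions.

    Consecutive sites on the same chromosome/strand with positional distance
    < max_distance join one region spanning first..last site; regions
    narrower than ``min_width`` nt are discarded.
    """
    regions: list[Region] = []
    for (chrom, strand), group in sites.groupby(["chrom", "strand"], sort=True):
        pos = np.sort(group["pos"].to_numpy(int))
        if len(pos) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) >= max_distance) + 1
        for chunk in np.split(pos, breaks):
            region = Region(chrom, strand, int(chunk[0]), int(chunk[-1]) + 1)
            if region.width >= min_width:
                regions.append(region)
    return regions


def _argmax_summit(counts: np.ndarray, positions: np.ndarray, strand: str) -> int:
    """Peak summit among candidate positions; ties go to the 5'-most
    position in transcript orientation (leftmost on +, rightmost on -)."""
    best = counts.max()
    at_best = positions[counts == best]
    return int(at_best.min() if strand == "+" else at_best.max())


def define_binding_sites(regions: list[Region], merged_track: CrosslinkTrack,
                         sites: pd.DataFrame, width: int = 9,
                         min_sig: int = 2) -> pd.DataFrame:
    """Convert candidate regions into equal-sized summit-centered windows.

    Regions are processed per (chromosome, strand) in coordinate order.  A
    window is placeable only if it lies within chromosome bounds, does not
    overlap an already-placed window on the same strand, and covers at least
    ``min_sig`` significant positions; windows that would run off the
    chromosome are dropped with a warning rather than clipped.
    """
    half = width // 2
    sig_index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for key, g in sites.groupby(["chrom", "strand"], sort=False):
        order = np.argsort(g["pos"].to_numpy(int))
        sig_index[key] = (g["pos"].to_numpy(int)[order],
                          g["score"].to_numpy(float)[order])

    def sig_slice(chrom, strand, start, end):
        entry = sig_index.get((chrom, strand))
        if entry is None:
            return np.array([], dtype=int), np.array([], dtype=float)
        pos, scores = entry
        lo, hi = np.searchsorted(pos, (start, end))
        return pos[lo:hi], scores[lo:hi]

    def n_sig_in(chrom, strand, start, end) -> int:
        return len(sig_slice(chrom, strand, start, end)[0])

    out_rows = []
    by_key: dict[tuple[str, str], list[Region]] = {}
    for region in regions:
        by_key.setdefault((region.chrom, region.strand), []).append(region)

    for (chrom, strand), key_regions in sorted(by_key.items()):
        chrom_len = merged_track.chrom_lengths[chrom]
        placed_ends: list[tuple[int, int]] = []  # windows placed on this strand

        def placeable(start: int, end: int) -> bool:
            if start < 0 or end > chrom_len:
                return False
            return all(end <= s or start >= e for s, e in placed_ends)

        for region in sorted(key_regions, key=lambda r: r.start):
            counts = merged_track.counts(chrom, strand)[region.start:region.end]
            positions = np.arange(region.start, region.end)
            if region.width <= width:
                if counts.max() <= 0:
                    logger.warning("region %s:%d-%d(%s) has no crosslink events; dropped",
                                   chrom, region.start, region.end, strand)
                    continue
                summit = _argmax_summit(counts, positions, strand)
                if region.width == width:
                    start, end = region.start, region.end
                else:
                    start, end = summit - half, summit + half + 1
                if start < 0 or end > chrom_len:
                    logger.warning("window around summit %s:%d(%s) runs off the "
                                   "chromosome; dropped", chrom, summit, strand)
                    continue
                if n_sig_in(chrom, strand, start, end) < min_sig:
                    continue
                if not placeable(start, end):
                    logger.warning("extended window %s:%d-%d(%s) overlaps a placed "
                                   "site; dropped", chrom, start, end, strand)
                    continue
                placed_ends.append((start, end))
                out_rows.append((chrom, strand, start, end, summit))
            else:
                # iterative splitting: place at the global summit, mask, repeat
                active = counts > 0
                while active.any():
                    summit = _argmax_summit(counts[active], positions[active], strand)
                    start, end = summit - half, summit + half + 1
                    if placeable(start, end) and n_sig_in(chrom, strand, start, end) >= min_sig:
                        placed_ends.append((start, end))
                        out_rows.append((chrom, strand, start, end, summit))
                        # mask the window's positions from further consideration
                        lo = max(start, region.start)
                        hi = min(end, region.end)
                        active[lo - region.start:hi - region.start] = False
                    else:
                        active[summit - region.start] = False

    rows = []
    for i, (chrom, strand, start, end, summit) in enumerate(out_rows):
        in_win, window_scores = sig_slice(chrom, strand, start, end)
        score = float(window_scores.max())
        rows.append({
            "site_id": f"BS{i:06d}", "chrom": chrom, "start": start, "end": end,
            "strand": strand, "center": summit, "score": score,
            "strength": float(np.log2(score)),
            "n_significant_positions": len(in_win),
        })
    df = pd.DataFrame(rows, columns=BINDING_SITE_COLUMNS)
    return df.sort_values(["chrom", "strand", "start"]).reset_index(drop=True)


def reproducibility_filter(bsites: pd.DataFrame, replicate_tracks: list[CrosslinkTrack],
                           min_support: int = 3, quantile: float = 0.20,
                           inclusive: bool = True) -> pd.DataFrame:
    """Keep binding sites supported by >= ``min_support`` replicates.

    For each replicate the support threshold is the ``quantile`` quantile of
    that replicate's summed events over all binding sites; a site is
    supported when its summed events reach the threshold (``>=`` by default;
    strict ``>`` with ``inclusive=False``).

    The returned frame gains per-replicate count columns and ``n_support``.
    """
    if len(replicate_tracks) < min_support:
        raise ValueError("need at least min_support replicate tracks")
    df = bsites.reset_index(drop=True).copy()
    if len(df) == 0:
        df["n_support"] = pd.Series(dtype=int)
        return df
    support = np.zeros(len(df), dtype=int)
    for track in replicate_tracks:
        sums = np.array([
            int(track.counts(r.chrom, r.strand)[r.start:r.end].sum())
            for r in df.itertuples(index=False)
        ])
        threshold = np.quantile(sums, quantile)
        supported = sums >= threshold if inclusive else sums > threshold
        support += supported.astype(int)
        df[f"events_{track.label}"] = sums
    df["n_support"] = support
    return df[df["n_support"] >= min_support].reset_index(drop=True)


def site_strength(score: float) -> float:
    """Binding-site strength: log2 of the peak-caller score."""
    if score <= 0:
        raise ValueError("site score must be positive")
    return float(np.log2(score))


def call_binding_sites(sites: pd.DataFrame, replicate_tracks: list[CrosslinkTrack],
                       merged_track: CrosslinkTrack | None = None,
                       drop_fraction: float = 0.05, max_distance: int = 8,
                       width: int = 9, min_sig: int = 2,
                       min_support: int = 3, quantile: float = 0.20) -> pd.DataFrame:
    """Full pipeline: score filter -> clustering -> windows -> reproducibility."""
    if merged_track is None:
        merged_track = CrosslinkTrack.merge(replicate_tracks)
    kept = filter_low_scores(sites, drop_fraction)
    regions = cluster_sites(kept, max_distance=max_distance)
    bsites = define_binding_sites(regions, merged_track, kept, width=width, min_sig=min_sig)
    return reproducibility_filter(bsites, replicate_tracks,
                                  min_support=min_support, quantile=quantile)
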