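"""From mapped reads to clonal-filtered, shift-adjusted, normalized occupancy.

The chain mirrors standard MNase-seq practice: PCR-clonal read stacks are
truncated with a Poisson test on identical 5'-end counts, every read is
shifted toward its 3' end by half the (cross-correlation-estimated)
fragment size so that its adjusted position sits on the nucleosome dyad,
occupancy is the count of adjusted positions within half a nucleosome of
each base pair, and samples are made comparable by genome-wide quantile
normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import OccupancyTrack, ReadSet

__all__ = [
    "OccupancyConfig",
    "AdjustedReads",
    "FragmentSizeError",
    "remove_clonal_reads",
    "estimate_fragment_size",
    "adjust_reads",
    "compute_coverage",
    "quantile_normalize",
]

log = logging.getLogger(__name__)

DEFAULT_FOOTPRINT_HALF_WIDTH = 73  # half a nucleosome


class FragmentSizeError(ValueError):
    """Fragment size cannot be estimated from the given reads."""


@dataclass(frozen=True)
class OccupancyConfig:
    clonal_pvalue_cutoff: float = 1e-10
    fragment_size_override: int | None = None
    normalization: str = "quantile"  # "quantile" | "none"
    footprint_half_width: int = DEFAULT_FOOTPRINT_HALF_WIDTH

    def validate(self) -> list[str]:
        errors = []
        if not 0.0 < self.clonal_pvalue_cutoff < 1.0:
            errors.append("clonal_pvalue_cutoff must be in (0, 1)")
        if self.fragment_size_override is not None and self.fragment_size_override <= 0:
            errors.append("fragment_size_override must be > 0")
        if self.normalization not in ("quantile", "none"):
            errors.append("normalization must be 'quantile' or 'none'")
        if self.footprint_half_width < 0:
            errors.append("footprint_half_width must be >= 0")
        return errors


@dataclass
class AdjustedReads:
    """Dyad-adjusted 1-bp read positions, sorted per chromosome."""

    positions: dict[str, np.ndarray]

    def __len__(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    def in_window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Positions on chrom within [start, end)."""
        pos = self.positions.get(chrom)
        if pos is None:
            return np.empty(0, dtype=np.int64)
        lo, hi = np.searchsorted(pos, [start, end])
        return pos[lo:hi]


def _five_prime(reads: ReadSet) -> pd.DataFrame:
    """5'-end position of every read: start for '+', end-1 for '-'.

    Paired fragments carry strand '+', so their 5' end is the fragment start.
    """
    df = reads.df
    fivep = np.where(df["strand"].to_numpy() == "+",
                     df["start"].to_numpy(), df["end"].to_numpy() - 1)
    return pd.DataFrame(
        {"chrom": df["chrom"], "pos": fivep, "strand": df["strand"]}
    )


def clonal_max_copies(lam: float, cutoff: float) -> int:
    """Largest k with P(X >= k | Poisson(lam)) >= cutoff (at least 1)."""
    k = 1
    # P(X >= k) = sf(k - 1); strictly decreasing in k
    while stats.poisson.sf(k, lam) >= cutoff:
        k += 1
        if k > 10_000_000:  # pragma: no cover - defensive
            raise RuntimeError("clonal copy bound did not converge")
    return max(k, 1) if stats.poisson.sf(0, lam) >= cutoff else 0


def remove_clonal_reads(reads: ReadSet, chrom_sizes: dict[str, int],
                        cutoff: float = 1e-10) -> tuple[ReadSet, dict]:
    """Truncate stacks of reads sharing (chrom, 5' end, strand).

    With lam the genome-wide mean 5'-end count per position, a stack is cut
    to the largest k whose Poisson upper-tail probability P(X >= k) is still
    at least ``cutoff``; anything above k is treated as PCR-clonal.
    """
    genome = sum(chrom_sizes.values())
    if genome <= 0:
        raise ValueError("empty genome: chromosome sizes sum to zero")
    report = {"n_input": len(reads), "n_removed": 0, "lam": 0.0, "max_copies": None}
    if len(reads) == 0:
        return reads, report
    lam = len(reads) / genome
    kmax = clonal_max_copies(lam, cutoff)
    report["lam"] = lam
    report["max_copies"] = kmax
    fivep = _five_prime(reads)
    rank = fivep.groupby(["chrom", "pos", "strand"], sort=False).cumcount()
    keep = (rank < kmax).to_numpy()
    report["n_removed"] = int((~keep).sum())
    if report["n_removed"]:
        log.info("clonal filter removed %d of %d reads (lam=%.4g, max %d/stack)",
                 report["n_removed"], len(reads), lam, kmax)
    out = ReadSet(reads.df.loc[keep].reset_index(drop=True), paired=reads.paired)
    return out, report


def estimate_fragment_size(reads: ReadSet, chrom_sizes: dict[str, int],
                           lag_range: tuple[int, int] = (100, 250)) -> int:
    """Strand cross-correlation estimate of the fragment size.

    Correlates the '+'-strand 5'-end count vector against the '-'-strand
    read *end* coordinates over lags in ``lag_range``; for fragments of
    length L the two pile up exactly L apart.  Ties break toward the
    smaller lag.  Paired fragments carry their own length, so for a paired
    read set this returns the median observed fragment length.
    """
    if reads.paired:
        if len(reads) == 0:
            raise FragmentSizeError("empty paired read set")
        return int(np.median(reads.df["end"] - reads.df["start"]))
    df = reads.df
    plus = df[df["strand"] == "+"]
    minus = df[df["strand"] == "-"]
    if len(plus) < 100 or len(minus) < 100:
        raise FragmentSizeError(
            f"too few reads per strand ({len(plus)} '+', {len(minus)} '-') for "
            "cross-correlation; supply fragment_size_override"
        )
    lo, hi = lag_range
    score = np.zeros(hi - lo + 1)
    for chrom, size in chrom_sizes.items():
        p = plus[plus["chrom"] == chrom]
        m = minus[minus["chrom"] == chrom]
        if len(p) == 0 or len(m) == 0:
            continue
        pv = np.bincount(p["start"].to_numpy(), minlength=size)[:size]
        mv = np.bincount(np.minimum(m["end"].to_numpy(), size - 1),
                         minlength=size)[:size]
        for i, lag in enumerate(range(lo, hi + 1)):
            score[i] += float(pv[: size - lag] @ mv[lag:])
    best = int(np.argmax(score))  # argmax returns the first (smallest) tie
    return lo + best


def adjust_reads(reads: ReadSet, fragment_size: int,
                 chrom_sizes: dict[str, int]) -> AdjustedReads:
    """Shift each read toward its 3' end by half the fragment size.

    '+' reads map to start + fragment_size//2, '-' reads to
    (end - 1) - fragment_size//2; paired fragments map to their midpoint.
    Positions falling outside the chromosome are clipped to its bounds.
    """
    if fragment_size <= 0:
        raise ValueError("fragment_size must be > 0")
    df = reads.df
    if reads.paired:
        pos = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
    else:
        half = fragment_size // 2
        pos = np.where(df["strand"].to_numpy() == "+",
                       df["start"].to_numpy() + half,
                       df["end"].to_numpy() - 1 - half)
    positions = {}
    chrom_arr = df["chrom"].to_numpy()
    n_clipped = 0
    for chrom, size in chrom_sizes.items():
        p = pos[chrom_arr == chrom]
        clipped = np.clip(p, 0, size - 1)
        n_clipped += int((clipped != p).sum())
        positions[chrom] = np.sort(clipped).astype(np.int64)
    if n_clipped:
        log.info("clipped %d adjusted positions to chromosome bounds", n_clipped)
    return AdjustedReads(positions)


def compute_coverage(adjusted: AdjustedReads, chrom_sizes: dict[str, int],
                     half_width: int = DEFAULT_FOOTPRINT_HALF_WIDTH,
                     sample: str = "sample") -> OccupancyTrack:
    """Occupancy(p) = number of adjusted positions within [p-w, p+w].

    Each adjusted read therefore contributes a (2w+1)-bp footprint centred
    on its dyad-proximal position; w=0 degenerates to the raw positional
    histogram.
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    values = {}
    for chrom, size in chrom_sizes.items():
        pos = adjusted.positions.get(chrom, np.empty(0, dtype=np.int64))
        hist = np.bincount(pos, minlength=size)[:size]
        cs = np.concatenate(([0], np.cumsum(hist)))
        p = np.arange(size)
        occ = cs[np.minimum(p + half_width + 1, size)] - cs[np.maximum(p - half_width, 0)]
        values[chrom] = occ.astype(float)
    return OccupancyTrack(values, sample=sample, normalized="raw")


def quantile_normalize(tracks: list[OccupancyTrack],
                       ties: str = "stable") -> list[OccupancyTrack]:
    """Quantile-normalize the genome-wide value vectors of all samples.

    The reference distribution is the rank-wise mean of the samples' sorted
    vectors, computed over the concatenated all-chromosome vector.  With
    ``ties="stable"`` (default) equal values within a sample are ranked by
    genome position, so every output shares the reference multiset exactly;
    with ``ties="average"`` tied values receive the mean of the reference
    values their rank range spans (the classical convention, at the cost of
    exact multiset equality between samples).
    """
    if len(tracks) < 2:
        raise ValueError("quantile normalization needs at least two tracks")
    if ties not in ("stable", "average"):
        raise ValueError("ties must be 'stable' or 'average'")
    sizes = tracks[0].chrom_sizes
    for t in tracks[1:]:
        if t.chrom_sizes != sizes:
            raise ValueError("tracks cover different chromosomes/lengths")
    flats = [t.concatenated() for t in tracks]
    orders = [np.argsort(v, kind="stable") for v in flats]
    reference = np.mean([v[o] for v, o in zip(flats, orders)], axis=0)
    out = []
    for track, v, o in zip(tracks, flats, orders):
        normalized = np.empty_like(reference)
        normalized[o] = reference
        if ties == "average":
            sv = v[o]
            boundaries = np.concatenate(
                ([0], np.flatnonzero(np.diff(sv)) + 1, [len(sv)])
            )
            means = np.add.reduceat(reference, boundaries[:-1])
            counts = np.diff(boundaries)
            means = means / counts
            normalized[o] = np.repeat(means, counts)
        values = {}
        offset = 0
        for chrom, size in sizes.items():
            values[chrom] = normalized[offset:offset + size].copy()
            offset += size
        out.append(OccupancyTrack(values, sample=track.sample,
                                  normalized="quantile"))
    return out
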