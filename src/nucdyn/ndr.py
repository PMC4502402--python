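"""Nucleosome-depleted-region (NDR) length at TSS/TTS anchors and the
cross-condition change per gene.

The NDR at an anchor is the longest maximal run of base pairs whose
occupancy is strictly below a genome-derived threshold (genome mean minus
population SD) and whose anchor-proximal border lies closer than
``max_anchor_offset`` bp to the anchor.  A positive per-gene delta
(wt minus mut) means the region shrank in the mutant; the 10% genes with
the strongest shrink/expansion form the extreme deciles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenomeAnnotation, OccupancyTrack

__all__ = [
    "NDRConfig",
    "NDRCall",
    "genome_threshold",
    "threshold_runs",
    "call_ndr",
    "ndr_table",
    "delta_ndr",
    "select_deciles",
]


@dataclass(frozen=True)
class NDRConfig:
    max_anchor_offset: int = 65
    inclusive_offset: bool = False  # "closer than 65 bp" read strictly

    def validate(self) -> list[str]:
        return [] if self.max_anchor_offset >= 0 else [
            "max_anchor_offset must be >= 0"
        ]


@dataclass(frozen=True)
class NDRCall:
    gene_id: str
    anchor: str        # "tss" | "tts"
    condition: str
    chrom: str
    start: int         # 0 when no qualifying segment
    end: int
    length: int

    @property
    def segment(self) -> tuple[int, int]:
        return (self.start, self.end)


def genome_threshold(track: OccupancyTrack) -> float:
    """mean(occupancy) - population SD over every genome position."""
    values = track.concatenated()
    if values.size == 0:
        raise ValueError("empty genome: no occupancy values")
    threshold = float(values.mean() - values.std(ddof=0))
    if threshold <= 0:
        warnings.warn(
            f"NDR threshold {threshold:.4g} <= 0: no position can fall below "
            "it, all NDR lengths will be 0", stacklevel=2)
    return threshold


def threshold_runs(values: np.ndarray, threshold: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Maximal runs of consecutive positions strictly below threshold.

    Returns (starts, ends) as half-open intervals.
    """
    below = values < threshold
    if not below.any():
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    d = np.diff(below.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if below[0]:
        starts = np.concatenate(([0], starts))
    if below[-1]:
        ends = np.concatenate((ends, [len(values)]))
    return starts.astype(np.int64), ends.astype(np.int64)


def _anchor_distance(start: int, end: int, anchor: int) -> int:
    """Distance from the anchor to the run's nearest border (0 if inside)."""
    if start <= anchor < end:
        return 0
    if anchor < start:
        return start - anchor
    return anchor - (end - 1)


def _best_run(starts, ends, anchor: int, config: NDRConfig):
    best = None  # (length, distance, start, end); longest, then nearest border
    for s, e in zip(starts, ends):
        d = _anchor_distance(int(s), int(e), anchor)
        qualifies = d <= config.max_anchor_offset if config.inclusive_offset \
            else d < config.max_anchor_offset
        if not qualifies:
            continue
        length = int(e - s)
        key = (-length, d)
        if best is None or key < (-best[0], best[1]):
            best = (length, d, int(s), int(e))
    return best


def call_ndr(track: OccupancyTrack, annotation: GenomeAnnotation,
             gene_id: str, anchor: str = "tss",
             threshold: float | None = None,
             config: NDRConfig = NDRConfig()) -> NDRCall:
    """NDR call for one gene at one anchor; length 0 when nothing qualifies.

    Ties on length break toward the segment whose proximal border is
    nearest the anchor.
    """
    if threshold is None:
        threshold = genome_threshold(track)
    chrom, pos, _strand = annotation.anchor(gene_id, anchor)
    starts, ends = threshold_runs(track.values[chrom], threshold)
    best = _best_run(starts, ends, pos, config)
    if best is None:
        return NDRCall(gene_id, anchor, track.sample, chrom, 0, 0, 0)
    length, _d, s, e = best
    return NDRCall(gene_id, anchor, track.sample, chrom, s, e, length)


def ndr_table(track: OccupancyTrack, annotation: GenomeAnnotation,
              anchor: str = "tss", threshold: float | None = None,
              config: NDRConfig = NDRConfig()) -> pd.DataFrame:
    """NDR calls for every gene (sub-threshold runs computed once per chrom)."""
    if threshold is None:
        threshold = genome_threshold(track)
    runs = {chrom: threshold_runs(v, threshold)
            for chrom, v in track.values.items()}
    rows = []
    for gid in annotation.genes.index:
        chrom, pos, _strand = annotation.anchor(gid, anchor)
        best = _best_run(*runs[chrom], pos, config)
        if best is None:
            rows.append((gid, chrom, 0, 0, 0))
        else:
            length, _d, s, e = best
            rows.append((gid, chrom, s, e, length))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "length"]
    ).set_index("gene_id")


def delta_ndr(calls_wt: pd.DataFrame, calls_mut: pd.DataFrame) -> pd.DataFrame:
    """Per-gene table (ndr_wt, ndr_mut, delta = ndr_wt - ndr_mut).

    Positive delta = the region shrank in the mutant.  Genes without a
    qualifying segment in a condition contribute length 0 there.
    """
    if set(calls_wt.index) != set(calls_mut.index):
        raise ValueError("gene universes differ between conditions")
    df = pd.DataFrame({
        "ndr_wt": calls_wt["length"],
        "ndr_mut": calls_mut.loc[calls_wt.index, "length"],
    })
    df["delta"] = df["ndr_wt"] - df["ndr_mut"]
    return df


def select_deciles(delta_table: pd.DataFrame, fraction: float = 0.10
                   ) -> tuple[list[str], list[str]]:
    """The genes whose NDR shrinks/expands the most between conditions.

    Returns (shrink_set, expand_set), each of ceil(fraction * n) genes;
    ties on delta break lexicographically on gene id for determinism.
    """
    if len(delta_table) == 0:
        raise ValueError("empty delta table")
    if not 0.0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    k = math.ceil(fraction * len(delta_table))
    # opposite lexicographic tie-breaks keep the two sets disjoint even when
    # every delta is identical
    shrink = delta_table.sort_index(ascending=True).sort_values(
        "delta", ascending=False, kind="stable")
    expand = delta_table.sort_index(ascending=False).sort_values(
        "delta", ascending=True, kind="stable")
    return list(shrink.index[:k]), list(expand.index[:k])
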