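"""Strand-aware meta-gene aggregation of occupancy, average −1 nucleosome
localization, and positional profiling of the dynamic-nucleosome percentage.

Offsets are in gene orientation: negative offsets are upstream of the
anchor, positive offsets point into the gene body, for both strands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .io import GenomeAnnotation, OccupancyTrack

__all__ = [
    "MetaProfile",
    "MetageneError",
    "align_profiles",
    "minus_one_position",
    "minus_one_shift",
    "per_gene_minus_one",
    "call_offsets",
    "dynamic_fraction_profile",
]


class MetageneError(ValueError):
    pass


@dataclass
class MetaProfile:
    """Mean occupancy per strand-aware offset around an anchor."""

    anchor: str
    offsets: np.ndarray      # -window .. +window inclusive
    mean: np.ndarray         # NaN where no gene contributes
    n_genes: np.ndarray
    sample: str = "sample"

    @property
    def window(self) -> int:
        return int(self.offsets[-1])


def align_profiles(track: OccupancyTrack, annotation: GenomeAnnotation,
                   anchor: str = "tss", window: int = 1000,
                   gene_ids=None) -> MetaProfile:
    """Average the occupancy over genes aligned at their TSS or TTS.

    Each gene contributes its occupancy over [anchor-window, anchor+window],
    reversed for "-"-strand genes so positive offsets point into the gene
    body; out-of-chromosome positions are dropped from both the sum and the
    per-offset gene count.
    """
    if window <= 0:
        raise MetageneError("window must be > 0")
    ids = list(gene_ids) if gene_ids is not None else list(annotation.genes.index)
    if not ids:
        raise MetageneError("no genes to aggregate")
    width = 2 * window + 1
    total = np.zeros(width)
    count = np.zeros(width, dtype=np.int64)
    for gid in ids:
        chrom, pos, strand = annotation.anchor(gid, anchor)
        values = track.values[chrom]
        lo, hi = pos - window, pos + window + 1
        clip_lo, clip_hi = max(lo, 0), min(hi, len(values))
        if clip_lo >= clip_hi:
            continue
        segment = values[clip_lo:clip_hi]
        out_lo = clip_lo - lo
        out_hi = out_lo + (clip_hi - clip_lo)
        if strand == "-":
            segment = segment[::-1]
            out_lo, out_hi = width - out_hi, width - out_lo
        total[out_lo:out_hi] += segment
        count[out_lo:out_hi] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return MetaProfile(anchor=anchor, offsets=np.arange(-window, window + 1),
                       mean=mean, n_genes=count, sample=track.sample)


def minus_one_position(profile: MetaProfile, smooth: int = 31,
                       mode: str = "nearest",
                       min_prominence: float = 0.15) -> float:
    """Distance (bp, positive upstream) from the anchor to the average −1
    nucleosome midpoint.

    The profile is smoothed with a ``smooth``-bp moving average and local
    maxima at negative offsets with prominence of at least
    ``min_prominence`` times the upstream dynamic range are candidate
    nucleosome peaks.  ``mode="nearest"`` (default) returns the candidate
    closest to the anchor — the first nucleosome upstream of the NDR, i.e.
    the −1 by definition; ``mode="max"`` returns the highest upstream
    maximum instead.  Raises MetageneError("no upstream peak") when the
    upstream profile is flat or monotone.
    """
    from scipy.signal import find_peaks

    upstream = profile.offsets < 0
    y = profile.mean.copy()
    y[~np.isfinite(y)] = 0.0
    if smooth > 1:
        y = uniform_filter1d(y, size=smooth, mode="nearest")
    yu = y[upstream]
    if len(yu) < 3:
        raise MetageneError("no upstream peak")
    span = float(yu.max() - yu.min())
    if span == 0:
        raise MetageneError("no upstream peak")
    candidates, _props = find_peaks(yu, prominence=min_prominence * span)
    if len(candidates) == 0:
        raise MetageneError("no upstream peak")
    if mode == "nearest":
        best = candidates[-1]  # offsets ascend toward 0: last = nearest anchor
    elif mode == "max":
        best = candidates[np.argmax(yu[candidates])]
    else:
        raise ValueError("mode must be 'nearest' or 'max'")
    return float(-profile.offsets[upstream][best])


def minus_one_shift(profile_ref: MetaProfile, profile_alt: MetaProfile,
                    smooth: int = 31) -> float:
    """How far the average −1 nucleosome moved toward the anchor (positive =
    closer to the anchor in the second profile)."""
    return minus_one_position(profile_ref, smooth) - \
        minus_one_position(profile_alt, smooth)


def per_gene_minus_one(calls: pd.DataFrame, annotation: GenomeAnnotation,
                       max_distance: int = 400,
                       gene_ids=None) -> pd.Series:
    """Per-gene distance (bp, positive upstream) from the TSS to the nearest
    called nucleosome summit upstream of it.

    The per-gene median of these distances is an alternative estimate of
    the average −1 nucleosome position that is robust to gene-to-gene NDR
    width variation (which smears the −1 peak of an averaged profile) and
    to genes whose −1 is called in one condition only.  Genes without an
    upstream summit within ``max_distance`` are NaN.
    """
    ids = list(gene_ids) if gene_ids is not None else list(annotation.genes.index)
    by_chrom = {chrom: np.sort(sub["summit"].to_numpy())
                for chrom, sub in calls.groupby("chrom")}
    out = pd.Series(np.nan, index=pd.Index(ids, name="gene_id"))
    for gid in ids:
        chrom, pos, strand = annotation.anchor(gid, "tss")
        summits = by_chrom.get(chrom)
        if summits is None or len(summits) == 0:
            continue
        if strand == "+":
            lo, hi = np.searchsorted(summits, [pos - max_distance, pos])
            if hi > lo:
                out[gid] = pos - summits[hi - 1]
        else:
            lo, hi = np.searchsorted(summits, [pos + 1, pos + max_distance + 1])
            if hi > lo:
                out[gid] = summits[lo] - pos
    return out


def call_offsets(calls: pd.DataFrame, annotation: GenomeAnnotation,
                 anchor: str = "tss") -> pd.DataFrame:
    """Strand-aware offset of every call summit to its nearest gene anchor.

    Ties between two equidistant genes break toward the lexicographically
    smaller gene id.  Returns a copy of ``calls`` with ``gene_id`` and
    ``offset`` columns (negative = upstream of the anchor).
    """
    anchors = {}
    genes = annotation.genes
    for chrom in annotation.chrom_sizes:
        sub = genes[genes["chrom"] == chrom].copy()
        sub["_pos"] = sub[anchor]
        sub["_id"] = sub.index
        sub = sub.sort_values(["_pos", "_id"], kind="stable")
        anchors[chrom] = (sub["_pos"].to_numpy(), sub.index.to_numpy(),
                          sub["strand"].to_numpy())
    gene_ids = []
    offsets = []
    for row in calls.itertuples(index=False):
        pos, ids, strands = anchors[row.chrom]
        if len(pos) == 0:
            gene_ids.append(None)
            offsets.append(np.nan)
            continue
        j = np.searchsorted(pos, row.summit)
        best = None
        for cand in (j - 1, j, j + 1):
            if 0 <= cand < len(pos):
                d = abs(int(row.summit) - int(pos[cand]))
                key = (d, str(ids[cand]))
                if best is None or key < best[0]:
                    best = (key, cand)
        cand = best[1]
        sign = 1 if strands[cand] == "+" else -1
        gene_ids.append(ids[cand])
        offsets.append(sign * (int(row.summit) - int(pos[cand])))
    out = calls.copy()
    out["gene_id"] = gene_ids
    out["offset"] = offsets
    return out


def dynamic_fraction_profile(dynamics: pd.DataFrame, all_calls: pd.DataFrame,
                             annotation: GenomeAnnotation, anchor: str = "tss",
                             bin_size: int = 50, window: int = 1000
                             ) -> tuple[pd.DataFrame, float]:
    """Percentage of dynamic nucleosomes per bin of distance to the anchor.

    Each reference-condition call lands in the bin of its summit's
    strand-aware offset to the nearest anchor; a call is dynamic when it
    participates in a retained dynamics record (``call_wt`` index).  Bins
    without calls report NaN (undefined, not 0).  The second return value
    is the genome-wide dynamic percentage (the horizontal reference line).
    """
    if window % bin_size != 0:
        raise ValueError("bin_size must divide window")
    if len(all_calls) == 0:
        raise ValueError("no calls")
    if len(dynamics) and "call_wt" in dynamics.columns:
        sub = dynamics[dynamics["dynamic"]] if "dynamic" in dynamics.columns \
            else dynamics
        dynamic_ids = set(sub.loc[sub["call_wt"] >= 0, "call_wt"].astype(int))
    else:
        dynamic_ids = set()
    ann = call_offsets(all_calls, annotation, anchor)
    edges = np.arange(-window, window + bin_size, bin_size)
    n = np.zeros(len(edges) - 1, dtype=np.int64)
    k = np.zeros(len(edges) - 1, dtype=np.int64)
    for idx, off in zip(ann.index, ann["offset"]):
        if not np.isfinite(off) or off < -window or off >= window:
            continue
        b = int((off + window) // bin_size)
        n[b] += 1
        if idx in dynamic_ids:
            k[b] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n > 0, 100.0 * k / np.maximum(n, 1), np.nan)
    table = pd.DataFrame({
        "bin_start": edges[:-1], "bin_end": edges[1:],
        "n_calls": n, "n_dynamic": k, "percent_dynamic": pct,
    })
    genome_avg = 100.0 * len(dynamic_ids.intersection(all_calls.index)) / len(all_calls)
    return table, genome_avg


def plot_profiles(profiles: list[MetaProfile], path, labels=None) -> None:
    """Save a simple occupancy meta-profile figure (one line per profile)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for i, profile in enumerate(profiles):
        label = labels[i] if labels else profile.sample
        ax.plot(profile.offsets, profile.mean, label=label)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel(f"distance to {profiles[0].anchor.upper()} (bp)")
    ax.set_ylabel("mean occupancy")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
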