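"""Nucleosome calling, per-bp Poisson differential signal, and classification
of dynamic nucleosomes into occupancy change, position shift and fuzziness
change at a nucleosome-level FDR.

Nucleosomes are called per condition as occupancy local maxima (greedy
highest-first, minimum summit spacing of one nucleosome width).  The
differential signal between two quantile-normalized tracks is a two-sided
Poisson test at every base pair; each matched wt/mut nucleosome pair takes
the minimum per-bp p-value over its union span, and Benjamini-Hochberg is
applied across nucleosomes so the FDR cutoff is well-defined at the
nucleosome level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import find_peaks
from statsmodels.stats.multitest import multipletests

from .io import GenomeAnnotation, OccupancyTrack
from .occupancy import AdjustedReads, DEFAULT_FOOTPRINT_HALF_WIDTH

__all__ = [
    "DynamicsConfig",
    "call_nucleosomes",
    "differential_signal",
    "bh_fdr",
    "match_and_classify",
    "dynamic_fraction",
]

NUCLEOSOME_WIDTH = 147

CALL_COLUMNS = ["chrom", "summit", "start", "end", "summit_occupancy",
                "fuzziness", "n_reads"]

DYNAMICS_COLUMNS = ["chrom", "summit_wt", "summit_mut", "start", "end",
                    "category", "direction", "occupancy_fold", "delta_summit",
                    "fuzziness_ratio", "p_value", "fdr", "call_wt", "call_mut"]


@dataclass(frozen=True)
class DynamicsConfig:
    fdr_cutoff: float = 0.005
    min_shift: int = 10
    min_occupancy_fold: float = 1.5
    min_fuzziness_ratio: float = 1.3
    match_max_distance: int = 100
    pseudocount: float = 0.5
    summit_spacing: int = NUCLEOSOME_WIDTH

    def validate(self) -> list[str]:
        errors = []
        if not 0.0 < self.fdr_cutoff < 1.0:
            errors.append("fdr_cutoff must be in (0, 1)")
        for name in ("min_shift", "min_occupancy_fold", "min_fuzziness_ratio",
                     "match_max_distance", "pseudocount", "summit_spacing"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be > 0")
        return errors


def call_nucleosomes(track: OccupancyTrack,
                     adjusted: AdjustedReads | None = None,
                     spacing: int = NUCLEOSOME_WIDTH,
                     half_width: int = DEFAULT_FOOTPRINT_HALF_WIDTH,
                     ) -> pd.DataFrame:
    """Call nucleosome positions from an occupancy track.

    Summits are occupancy local maxima above the genome mean, accepted
    greedily highest-first with a minimum spacing of one nucleosome width;
    plateau maxima take the plateau midpoint.  The span is summit +/- one
    half nucleosome, clipped at the midpoint to each neighbouring summit
    and at the chromosome ends.  Fuzziness is the SD of the adjusted read
    positions falling inside the span (NaN without reads).
    """
    mean = track.genome_mean()
    rows = []
    for chrom, values in track.values.items():
        if len(values) == 0 or not np.any(values > mean):
            continue
        summits, _props = find_peaks(values, height=np.nextafter(mean, np.inf),
                                     distance=spacing, plateau_size=0)
        if len(summits) == 0:
            continue
        summits = np.sort(summits)
        left_mid = np.empty(len(summits), dtype=np.int64)
        right_mid = np.empty(len(summits), dtype=np.int64)
        left_mid[0] = 0
        left_mid[1:] = (summits[:-1] + summits[1:]) // 2
        right_mid[-1] = len(values)
        right_mid[:-1] = (summits[:-1] + summits[1:] + 1) // 2
        starts = np.maximum(summits - half_width, left_mid)
        ends = np.minimum(summits + half_width + 1, right_mid)
        for s, a, b in zip(summits, starts, ends):
            if adjusted is not None:
                pos = adjusted.in_window(chrom, int(a), int(b))
                n = len(pos)
                fuzz = float(np.std(pos)) if n else float("nan")
            else:
                n, fuzz = 0, float("nan")
            rows.append((chrom, int(s), int(a), int(b), float(values[s]),
                         fuzz, n))
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def differential_signal(track_a: OccupancyTrack, track_b: OccupancyTrack,
                        pseudocount: float = 0.5) -> dict[str, np.ndarray]:
    """Two-sided per-bp Poisson p-value of track B's occupancy given track A's.

    At each base pair, with a = max(value_a, pseudocount) as the Poisson
    rate and b = round(value_b) as the observation,
    p = min(1, 2 * min(P(X >= b), P(X <= b))).
    """
    if track_a.chrom_sizes != track_b.chrom_sizes:
        raise ValueError("tracks cover different chromosomes/lengths")
    pvals = {}
    for chrom in track_a.values:
        a = np.maximum(track_a.values[chrom], pseudocount)
        b = np.rint(track_b.values[chrom])
        upper = stats.poisson.sf(b - 1, a)  # P(X >= b)
        lower = stats.poisson.cdf(b, a)     # P(X <= b)
        pvals[chrom] = np.minimum(1.0, 2.0 * np.minimum(upper, lower))
    return pvals


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _greedy_match(summits_a: np.ndarray, summits_b: np.ndarray,
                  max_distance: int) -> list[tuple[int, int]]:
    """Greedy nearest-summit matching; each summit used at most once."""
    pairs = []
    j0 = 0
    for i, s in enumerate(summits_a):
        j0 = np.searchsorted(summits_b, s - max_distance)
        for j in range(j0, len(summits_b)):
            d = int(summits_b[j]) - int(s)
            if d > max_distance:
                break
            pairs.append((abs(d), i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for _d, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((i, j))
    return matches


def _record_pvalues(df: pd.DataFrame, adjusted_wt: AdjustedReads,
                    adjusted_mut: AdjustedReads) -> np.ndarray:
    """Calibrated per-record p-value from the reads in the union span.

    Combines (Bonferroni over the three effect axes) an exact conditional
    binomial test on the read counts (occupancy), a Welch t-test on the
    read positions (position shift) and a variance-ratio F-test on the
    read positions (fuzziness).  Unmatched records use the binomial test
    alone.  Unlike a Poisson test that conditions on one sample's observed
    occupancy as if it were the true rate, these tests acknowledge the
    sampling noise of both conditions and keep the null FDR controlled.
    """
    n_a, n_b = len(adjusted_wt), len(adjusted_mut)
    if n_a + n_b == 0:
        return np.ones(len(df))
    q = n_b / (n_a + n_b)
    out = np.ones(len(df))
    for k, row in enumerate(df.itertuples(index=False)):
        pos_a = adjusted_wt.in_window(row.chrom, int(row.start), int(row.end))
        pos_b = adjusted_mut.in_window(row.chrom, int(row.start), int(row.end))
        na, nb = len(pos_a), len(pos_b)
        if na + nb == 0:
            continue
        p_occ = stats.binomtest(nb, na + nb, q).pvalue
        if row.call_wt < 0 or row.call_mut < 0:
            out[k] = p_occ
            continue
        p_pos = p_fuzz = 1.0
        if na >= 2 and nb >= 2:
            t = stats.ttest_ind(pos_a, pos_b, equal_var=False)
            if np.isfinite(t.pvalue):
                p_pos = float(t.pvalue)
            va, vb = np.var(pos_a, ddof=1), np.var(pos_b, ddof=1)
            if va > 0 and vb > 0:
                fr = vb / va
                p_fuzz = 2.0 * min(stats.f.sf(fr, nb - 1, na - 1),
                                   stats.f.cdf(fr, nb - 1, na - 1))
        out[k] = min(1.0, 3.0 * min(p_occ, p_pos, p_fuzz))
    return out


def match_and_classify(calls_wt: pd.DataFrame, calls_mut: pd.DataFrame,
                       pvals: dict[str, np.ndarray],
                       config: DynamicsConfig = DynamicsConfig(),
                       adjusted_wt: AdjustedReads | None = None,
                       adjusted_mut: AdjustedReads | None = None,
                       track_wt: OccupancyTrack | None = None,
                       track_mut: OccupancyTrack | None = None,
                       full: bool = False) -> pd.DataFrame:
    """Pair nucleosome calls across conditions and classify the dynamic ones.

    Nearest-summit greedy matching within ``match_max_distance``.  Each
    record carries ``min_bp_p``, the minimum per-bp Poisson differential p
    over its union span; when the adjusted reads are supplied the
    ``p_value`` that feeds the FDR is the calibrated two-sample combination
    of occupancy/position/fuzziness tests on the span reads (see
    ``_record_pvalues``), otherwise ``min_bp_p`` is used.  Categories fire
    when the effect size passes its threshold (occupancy fold,
    |Delta summit|, fuzziness ratio); when several fire the reported
    category follows the fixed dominance order occupancy > shift >
    fuzziness.  Unmatched calls are occupancy changes (loss when only wt
    called, gain when only mut).  Records are retained when the
    BH-adjusted FDR over all candidate records is below ``fdr_cutoff`` and
    at least one category fires; ``full=True`` returns every candidate
    with its ``dynamic`` flag instead.

    ``call_wt``/``call_mut`` columns carry the row index of the paired call
    in the input tables (-1 when absent).
    """
    records = []
    chroms = sorted(set(calls_wt["chrom"]).union(calls_mut["chrom"]))
    for chrom in chroms:
        sub_a = calls_wt[calls_wt["chrom"] == chrom]
        sub_b = calls_mut[calls_mut["chrom"] == chrom]
        sa = sub_a["summit"].to_numpy()
        sb = sub_b["summit"].to_numpy()
        matches = _greedy_match(sa, sb, config.match_max_distance)
        used_a = {i for i, _ in matches}
        used_b = {j for _, j in matches}
        for i, j in matches:
            ra, rb = sub_a.iloc[i], sub_b.iloc[j]
            records.append(_pair_record(chrom, ra, rb, config))
        for i in range(len(sub_a)):
            if i not in used_a:
                records.append(_unmatched_record(
                    chrom, sub_a.iloc[i], "loss", track_mut, config))
        for j in range(len(sub_b)):
            if j not in used_b:
                records.append(_unmatched_record(
                    chrom, sub_b.iloc[j], "gain", track_wt, config))
    if not records:
        return pd.DataFrame(columns=DYNAMICS_COLUMNS + ["min_bp_p"]
                            + (["dynamic"] if full else []))
    df = pd.DataFrame(records, columns=DYNAMICS_COLUMNS[:10] + ["call_wt", "call_mut"])
    # min per-bp differential p over the union span (reported per record)
    min_bp = np.ones(len(df))
    for k, row in enumerate(df.itertuples(index=False)):
        arr = pvals[row.chrom][int(row.start):int(row.end)]
        if len(arr):
            min_bp[k] = float(arr.min())
    df["min_bp_p"] = min_bp
    if adjusted_wt is not None and adjusted_mut is not None:
        df["p_value"] = _record_pvalues(df, adjusted_wt, adjusted_mut)
    else:
        df["p_value"] = min_bp
    df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    df = df[DYNAMICS_COLUMNS + ["min_bp_p"]]
    dynamic = (df["fdr"] < config.fdr_cutoff) & (df["category"] != "")
    if full:
        df = df.copy()
        df["dynamic"] = dynamic
        return df.reset_index(drop=True)
    return df[dynamic].reset_index(drop=True)


def _pair_record(chrom, ra, rb, config: DynamicsConfig):
    eps = config.pseudocount
    fold_raw = max(float(rb["summit_occupancy"]), eps) / max(
        float(ra["summit_occupancy"]), eps)
    fold = max(fold_raw, 1.0 / fold_raw)
    delta = int(rb["summit"]) - int(ra["summit"])
    fa, fb = float(ra["fuzziness"]), float(rb["fuzziness"])
    if np.isnan(fa) or np.isnan(fb) or fa <= 0 or fb <= 0:
        fuzz_ratio = float("nan")
    else:
        r = fb / fa
        fuzz_ratio = max(r, 1.0 / r)
    categories = []
    if fold >= config.min_occupancy_fold:
        categories.append("occupancy_change")
    if abs(delta) >= config.min_shift:
        categories.append("position_shift")
    if np.isfinite(fuzz_ratio) and fuzz_ratio >= config.min_fuzziness_ratio:
        categories.append("fuzziness_change")
    category = categories[0] if categories else ""
    if category == "occupancy_change":
        direction = "gain" if fold_raw > 1 else "loss"
    elif category == "position_shift":
        direction = "downstream" if delta > 0 else "upstream"
    elif category == "fuzziness_change":
        direction = "fuzzier" if fb > fa else "sharper"
    else:
        direction = ""
    start = int(min(ra["start"], rb["start"]))
    end = int(max(ra["end"], rb["end"]))
    return (chrom, int(ra["summit"]), int(rb["summit"]), start, end, category,
            direction, float(fold), delta, fuzz_ratio,
            int(ra.name), int(rb.name))


def _unmatched_record(chrom, row, direction, other_track, config: DynamicsConfig):
    eps = config.pseudocount
    own = max(float(row["summit_occupancy"]), eps)
    if other_track is not None:
        other = max(float(other_track.values[chrom][int(row["summit"])]), eps)
    else:
        other = eps
    fold = max(own, other) / min(own, other)
    start, end = int(row["start"]), int(row["end"])
    summit = int(row["summit"])
    if direction == "loss":
        summit_wt, summit_mut = summit, -1
        call_wt, call_mut = int(row.name), -1
    else:
        summit_wt, summit_mut = -1, summit
        call_wt, call_mut = -1, int(row.name)
    return (chrom, summit_wt, summit_mut, start, end, "occupancy_change",
            direction, float(fold), 0, float("nan"), call_wt, call_mut)


def dynamic_fraction(dynamics: pd.DataFrame, all_calls: pd.DataFrame) -> float:
    """|dynamic records| / |reference-condition calls|."""
    if len(all_calls) == 0:
        raise ValueError("no reference-condition calls: fraction undefined")
    if "dynamic" in dynamics.columns:
        n = int(dynamics["dynamic"].sum())
    else:
        n = len(dynamics)
    return n / len(all_calls)
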