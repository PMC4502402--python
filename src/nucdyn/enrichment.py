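"""Fisher's exact tests for promoter enrichment of dynamic nucleosomes and
for overlaps between gene sets.

The promoter window follows the analysis this pipeline reproduces:
−350 bp to +50 bp around the TSS, strand-resolved, boundaries inclusive.
Two-sided p-values use the probability-mass rule (sum of hypergeometric
probabilities of tables, at fixed margins, no more probable than the
observed one) — the convention of mainstream statistics environments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenomeAnnotation
from .metagene import call_offsets

__all__ = [
    "PromoterWindow",
    "EnrichmentResult",
    "EnrichmentError",
    "fisher_2x2",
    "promoter_enrichment",
    "overlap_enrichment",
]


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class PromoterWindow:
    """Strand-resolved window around the TSS: [-upstream, +downstream]."""

    upstream: int = 350
    downstream: int = 50
    inclusive: bool = True

    def validate(self) -> list[str]:
        errors = []
        if self.upstream < 0:
            errors.append("upstream must be >= 0")
        if self.downstream < 0:
            errors.append("downstream must be >= 0")
        return errors

    def contains(self, offset: float) -> bool:
        if self.inclusive:
            return -self.upstream <= offset <= self.downstream
        return -self.upstream < offset < self.downstream


@dataclass(frozen=True)
class EnrichmentResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    label: str = ""

    def as_dict(self) -> dict:
        (a, b), (c, d) = self.table
        return {"a": a, "b": b, "c": c, "d": d,
                "odds_ratio": self.odds_ratio, "p_value": self.p_value,
                "label": self.label}


def _sample_odds_ratio(a, b, c, d, haldane: bool) -> float:
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    num, den = a * d, b * c
    if den == 0:
        return float("inf") if num > 0 else float("nan")
    return num / den


def fisher_2x2(table, haldane: bool = False, label: str = "") -> EnrichmentResult:
    """Two-sided Fisher's exact test on a 2x2 table [[a, b], [c, d]].

    The odds ratio is the sample OR (a*d)/(b*c), reported as inf (or NaN
    when doubly degenerate) at zero cells unless ``haldane`` adds 0.5 to
    every cell.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise EnrichmentError("table must be 2x2")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        if np.any(arr != np.floor(arr)) or np.any(arr < 0):
            raise EnrichmentError("counts must be non-negative integers")
        arr = arr.astype(np.int64)
    (a, b), (c, d) = arr.tolist()
    _or_, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(
        table=((int(a), int(b)), (int(c), int(d))),
        odds_ratio=_sample_odds_ratio(a, b, c, d, haldane),
        p_value=float(p),
        label=label,
    )


def promoter_enrichment(dynamics: pd.DataFrame, all_calls: pd.DataFrame,
                        annotation: GenomeAnnotation,
                        window: PromoterWindow = PromoterWindow(),
                        haldane: bool = False) -> EnrichmentResult:
    """Are dynamic nucleosomes enriched in the promoter window around TSSs?

    The 2x2 table is (dynamic in-window, dynamic outside; non-dynamic
    in-window, non-dynamic outside) over all reference-condition calls,
    where in-window means the summit's strand-aware offset to its nearest
    TSS lies within the promoter window.
    """
    if len(all_calls) == 0:
        raise EnrichmentError("empty call set")
    if len(dynamics) and "dynamic" in dynamics.columns:
        dynamics = dynamics[dynamics["dynamic"]]
    if len(dynamics) == 0:
        raise EnrichmentError("no dynamic nucleosomes: enrichment undefined")
    dynamic_ids = set(dynamics.loc[dynamics["call_wt"] >= 0, "call_wt"].astype(int))
    ann = call_offsets(all_calls, annotation, anchor="tss")
    in_window = ann["offset"].map(window.contains)
    is_dynamic = ann.index.isin(dynamic_ids)
    a = int((is_dynamic & in_window).sum())
    b = int((is_dynamic & ~in_window).sum())
    c = int((~is_dynamic & in_window).sum())
    d = int((~is_dynamic & ~in_window).sum())
    if (a + c) == 0 or (b + d) == 0:
        raise EnrichmentError(
            "degenerate promoter window: every call falls on one side")
    if (a + b) == 0:
        raise EnrichmentError("no dynamic calls with a mapped offset")
    return fisher_2x2([[a, b], [c, d]], haldane=haldane,
                      label="promoter_enrichment")


def overlap_enrichment(set_a, set_b, universe, haldane: bool = False,
                       label: str = "overlap") -> EnrichmentResult:
    """Fisher's exact test of the overlap between two gene sets.

    Table: (|A∩B|, |A\\B|; |B\\A|, |universe \\ (A∪B)|).
    """
    sa, sb, u = set(set_a), set(set_b), set(universe)
    if not sa <= u:
        raise EnrichmentError(f"{len(sa - u)} elements of set A outside universe")
    if not sb <= u:
        raise EnrichmentError(f"{len(sb - u)} elements of set B outside universe")
    a = len(sa & sb)
    b = len(sa - sb)
    c = len(sb - sa)
    d = len(u - (sa | sb))
    return fisher_2x2([[a, b], [c, d]], haldane=haldane, label=label)
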