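"""Associate event breakpoints with transposable-element annotations.

Provides interval overlap of breakpoint windows with element spans, tallies of
recombination-partner family pairs, and a per-element hotspot enrichment test
(one-sided binomial against uniform element usage).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .event_caller import EventCall
from .genome_model import DiploidGenome, TyElement

__all__ = [
    "BreakpointAnnotation",
    "associate",
    "association_summary",
    "partner_tally",
    "hotspot_test",
]


@dataclass
class BreakpointAnnotation:
    """Overlap of one breakpoint interval with element annotations."""

    event_id: str
    call_class: str
    interval: tuple[int, int]
    chromosome: str
    overlapping_ids: list[str] = field(default_factory=list)
    overlapping_families: list[str] = field(default_factory=list)

    @property
    def has_ty(self) -> bool:
        return bool(self.overlapping_ids)


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    # closed intervals; any shared base counts
    return a_start <= b_end and b_start <= a_end


def associate(
    events: list[EventCall], genome: DiploidGenome
) -> list[BreakpointAnnotation]:
    """Annotate every breakpoint interval with overlapping elements."""
    by_chrom: dict[str, list[TyElement]] = {}
    for ty in genome.ty_elements:
        by_chrom.setdefault(ty.chromosome, []).append(ty)

    out: list[BreakpointAnnotation] = []
    for ev in events:
        for interval in ev.breakpoints:
            lo, hi = int(interval[0]), int(interval[1])
            hits = [
                ty
                for ty in by_chrom.get(ev.chromosome, [])
                if _overlaps(lo, hi, ty.start, ty.end)
            ]
            out.append(
                BreakpointAnnotation(
                    event_id=ev.id,
                    call_class=ev.call_class,
                    interval=(lo, hi),
                    chromosome=ev.chromosome,
                    overlapping_ids=[t.id for t in hits],
                    overlapping_families=[t.family for t in hits],
                )
            )
    return out


def association_summary(annotations: list[BreakpointAnnotation]) -> pd.DataFrame:
    """Fraction of breakpoints with an element, per event class group."""
    groups = {
        "dosage": {"I-DEL", "I-DUP", "T-DEL", "T-DUP", "CIRCLE", "ISO"},
        "loh": {"I-LOH", "T-LOH"},
    }
    rows = []
    for name, classes in groups.items():
        subset = [a for a in annotations if a.call_class in classes]
        n = len(subset)
        k = sum(a.has_ty for a in subset)
        rows.append(
            {
                "group": name,
                "n_breakpoints": n,
                "n_with_element": k,
                "fraction": k / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def partner_tally(pairs: list[tuple[str, str]]) -> Counter:
    """Symmetric tally of recombination-partner family pairs.

    Family labels are normalized so that e.g. ('Ty2', 'Ty1') and
    ('Ty1', 'Ty2') land in the same cell.
    """
    normalize = {"solo_delta": "delta", "truncated_Ty1": "Ty1"}
    tally: Counter = Counter()
    for a, b in pairs:
        a = normalize.get(a, a)
        b = normalize.get(b, b)
        tally[tuple(sorted((a, b)))] += 1
    return tally


def hotspot_test(
    event_counts: dict[str, int],
    n_elements: int,
    total_events: int,
    correction: str = "bonferroni",
) -> dict[str, float]:
    """Per-element enrichment p-values against uniform usage.

    For an element observed in ``k`` of ``total_events`` element-involvements
    the one-sided p-value is ``P(X >= k)`` with
    ``X ~ Binomial(total_events, 1/n_elements)``, optionally Bonferroni
    multiplied by the number of elements and capped at 1.
    """
    if correction not in {"bonferroni", "none"}:
        raise ValueError(f"unknown correction {correction!r}")
    if n_elements <= 0 or total_events < 0:
        raise ValueError("need n_elements > 0 and total_events >= 0")
    p0 = 1.0 / n_elements
    out: dict[str, float] = {}
    for element, k in event_counts.items():
        if k > total_events:
            raise ValueError(
                f"{element}: count {k} exceeds total events {total_events}"
            )
        p = float(stats.binom.sf(k - 1, total_events, p0))  # P(X >= k)
        if correction == "bonferroni":
            p = min(1.0, p * n_elements)
        out[element] = p
    return out
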