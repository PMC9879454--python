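"""Classify genomic alterations from per-SNP allele read depth.

The caller normalizes allele counts to a ratio of coverage (RC), smooths and
thresholds the RC series of each parental class into dosage states (0, 1, 2
copies), merges the two per-class segmentations into event regions, and maps
region signatures to the event taxonomy: reciprocal dosage changes are LOH
(terminal or interstitial), non-reciprocal ones are deletions/duplications,
whole-chromosome signatures are monosomy/trisomy/uniparental disomy, and
paired terminal signatures on one chromosome are circles or isochromosomes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_model import ChromosomeDef, DiploidGenome

logger = logging.getLogger(__name__)

__all__ = [
    "CallerParams",
    "EventCall",
    "HaploidPcrPattern",
    "compute_rc",
    "segment_profile",
    "classify_chromosome",
    "call_events",
    "pair_translocations",
    "breakpoint_interval",
    "classify_haploid_isolate",
    "write_events",
    "read_events",
]

CALL_CLASSES = (
    "I-LOH", "T-LOH", "I-DEL", "I-DUP", "T-DEL", "T-DUP",
    "CIRCLE", "ISO", "MONOSOMY", "TRISOMY", "UPD",
)


@dataclass(frozen=True)
class CallerParams:
    """Tuning parameters for segmentation and classification."""

    smoothing_window: int = 11  # SNPs, odd
    t_low: float = 0.25  # RC below -> 0 copies
    t_high: float = 0.75  # RC at/above -> 2 copies
    min_segment_snps: int = 5
    min_segment_bp: int = 10_000
    terminal_margin: int = 30_000  # bp from a chromosome end counted terminal
    breakpoint_window: int = 20_000  # bp, window width around dosage transitions

    def __post_init__(self) -> None:
        if not (0 < self.t_low < self.t_high < 1.25):
            raise ValueError("require 0 < t_low < t_high < 1.25")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing window must be odd and >= 1")


@dataclass
class EventCall:
    """One classified alteration with its breakpoint interval(s)."""

    id: str
    call_class: str
    chromosome: str
    lost: str | None = None  # parental class at reduced/zero dosage
    gained: str | None = None  # parental class at elevated dosage
    breakpoints: list[tuple[int, int]] = field(default_factory=list)
    paired_with: str | None = None
    span: tuple[int, int] | None = None  # affected SNP span (positions)

    def __post_init__(self) -> None:
        if self.call_class not in CALL_CLASSES:
            raise ValueError(f"unknown call class {self.call_class!r}")

    @property
    def reciprocal(self) -> bool:
        """LOH-type calls change both parental dosages; DEL/DUP do not."""
        return self.call_class in {"I-LOH", "T-LOH", "UPD"}


# ---------------------------------------------------------------------------
# ratio of coverage


def compute_rc(table: pd.DataFrame) -> pd.DataFrame:
    """Fill the normalized ratio-of-coverage column.

    RC of a row is its read count divided by the genome mean total site
    coverage (the per-site sum of both parental counts averaged over all
    sites), so an unaltered heterozygous allele sits near 0.5 and a
    duplicated single allele near 1.0.
    """
    if len(table) == 0:
        raise ValueError("empty dosage table")
    site_totals = table.groupby(["chromosome", "position"], sort=False)[
        "read_count"
    ].sum()
    mean_site_coverage = float(site_totals.mean())
    if mean_site_coverage == 0:
        raise ValueError("zero mean site coverage")
    out = table.copy()
    out["RC"] = out["read_count"] / mean_site_coverage
    return out


# ---------------------------------------------------------------------------
# segmentation


def _rolling_median(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(x) == 0:
        return x.astype(float)
    return (
        pd.Series(x)
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )


def _states_from_rc(rc: np.ndarray, params: CallerParams) -> np.ndarray:
    smoothed = _rolling_median(rc, params.smoothing_window)
    states = np.ones(len(smoothed), dtype=np.int8)
    states[smoothed < params.t_low] = 0
    states[smoothed >= params.t_high] = 2
    return states


def _runs(states: np.ndarray) -> list[list[int]]:
    """Maximal same-state runs as mutable [state, start_idx, end_idx]."""
    runs: list[list[int]] = []
    for i, s in enumerate(states):
        if runs and runs[-1][0] == s:
            runs[-1][2] = i
        else:
            runs.append([int(s), i, i])
    return runs


def segment_profile(
    positions: np.ndarray, rc: np.ndarray, params: CallerParams
) -> list[tuple[int, int, int]]:
    """Smooth, threshold and denoise one RC series into dosage-state runs.

    Returns ``(state, start_idx, end_idx)`` tuples over the sorted SNP index.
    Runs shorter than the minimum support (in SNPs or bp) are absorbed into
    the larger neighbor; a chromosome with fewer SNPs than the smoothing
    window collapses to a single majority-state segment.
    """
    positions = np.asarray(positions)
    rc = np.asarray(rc, dtype=float)
    if np.any(np.diff(positions) < 0):
        raise ValueError("SNP positions must be sorted")
    if len(positions) == 0:
        return []
    if len(positions) < params.smoothing_window:
        states = _states_from_rc(rc, CallerParams(
            smoothing_window=1, t_low=params.t_low, t_high=params.t_high))
        majority = int(np.argmax(np.bincount(states, minlength=3)))
        logger.debug("short chromosome (%d SNPs): majority state %d",
                     len(positions), majority)
        return [(majority, 0, len(positions) - 1)]

    states = _states_from_rc(rc, params)
    runs = _runs(states)

    def too_small(run) -> bool:
        _, i0, i1 = run
        n = i1 - i0 + 1
        bp = int(positions[i1] - positions[i0])
        return n < params.min_segment_snps or bp < params.min_segment_bp

    changed = True
    while changed and len(runs) > 1:
        changed = False
        # absorb the smallest offending run into its bigger neighbor
        small = [i for i, r in enumerate(runs) if too_small(r)]
        if not small:
            break
        i = min(small, key=lambda j: runs[j][2] - runs[j][1])
        left = runs[i - 1] if i > 0 else None
        right = runs[i + 1] if i + 1 < len(runs) else None
        if left is None:
            runs[i][0] = right[0]
        elif right is None:
            runs[i][0] = left[0]
        else:
            bigger = left if (left[2] - left[1]) >= (right[2] - right[1]) else right
            runs[i][0] = bigger[0]
        # re-merge equal-state neighbors
        merged: list[list[int]] = []
        for r in runs:
            if merged and merged[-1][0] == r[0]:
                merged[-1][2] = r[2]
            else:
                merged.append(r)
        runs = merged
        changed = True
    _refine_boundaries(runs, rc, params)
    return [(r[0], r[1], r[2]) for r in runs]


_STATE_LEVELS = {0: 0.0, 1: 0.5, 2: 1.0}


def _refine_boundaries(runs, rc: np.ndarray, params: CallerParams) -> None:
    """Re-place each run boundary by a raw-RC step fit.

    Median smoothing can drag a transition one or two SNPs into the flanking
    run; the least-squares step fit against the ideal levels of the two
    adjacent states restores the exact edge.
    """
    reach = params.smoothing_window
    for left, right in zip(runs, runs[1:]):
        lvl_a = _STATE_LEVELS[left[0]]
        lvl_b = _STATE_LEVELS[right[0]]
        lo = max(left[1] + 1, right[1] - reach)
        hi = min(right[2], left[2] + reach + 1)
        best_s, best_cost = right[1], None
        for s in range(lo, hi + 1):
            cost = float(
                ((rc[lo - 1 : s] - lvl_a) ** 2).sum()
                + ((rc[s : hi + 1] - lvl_b) ** 2).sum()
            )
            if best_cost is None or cost < best_cost:
                best_s, best_cost = s, cost
        left[2] = best_s - 1
        right[1] = best_s


# ---------------------------------------------------------------------------
# classification


def _pair_regions(w_states: np.ndarray, y_states: np.ndarray):
    """Maximal runs of identical (w, y) state pairs."""
    pairs = list(zip(w_states.tolist(), y_states.tolist()))
    regions = []
    for i, p in enumerate(pairs):
        if regions and regions[-1][0] == p:
            regions[-1][2] = i
        else:
            regions.append([p, i, i])
    return regions


_SIGNATURES = {
    (0, 2): ("LOH", "W", "Y"),
    (2, 0): ("LOH", "Y", "W"),
    (0, 1): ("DEL", "W", None),
    (1, 0): ("DEL", "Y", None),
    (2, 1): ("DUP", None, "W"),
    (1, 2): ("DUP", None, "Y"),
}

_WHOLE_CHROM = {
    (0, 1): ("MONOSOMY", "W", None),
    (1, 0): ("MONOSOMY", "Y", None),
    (2, 1): ("TRISOMY", None, "W"),
    (1, 2): ("TRISOMY", None, "Y"),
    (0, 2): ("UPD", "W", "Y"),
    (2, 0): ("UPD", "Y", "W"),
}


def _consolidate_boundaries(
    w_states: np.ndarray, y_states: np.ndarray, tol: int = 2
) -> None:
    """Align nearly coincident transitions of the two parental series.

    Reciprocal events move both parental dosages at the same SNP; a
    transition into or out of zero copies is noise-free (a zero-copy allele
    draws zero reads), so a nearby transition of the other class that does
    not involve zero is snapped onto it.
    """

    def boundaries(states):
        return [int(j) for j in np.flatnonzero(np.diff(states)) + 1]

    for a, b in ((y_states, w_states), (w_states, y_states)):
        for j in boundaries(a):
            if 0 in (a[j - 1], a[j]):
                continue
            for j2 in boundaries(b):
                if j2 != j and abs(j2 - j) <= tol and 0 in (b[j2 - 1], b[j2]):
                    if j2 > j:
                        a[j : j2] = a[j - 1]
                    else:
                        a[j2 : j] = a[j]
                    break


def _expand_states(runs, n) -> np.ndarray:
    states = np.ones(n, dtype=np.int8)
    for s, i0, i1 in runs:
        states[i0 : i1 + 1] = s
    return states


def classify_chromosome(
    segments_w: list[tuple[int, int, int]],
    segments_y: list[tuple[int, int, int]],
    positions: np.ndarray,
    chromosome: ChromosomeDef,
    params: CallerParams,
    id_prefix: str = "",
) -> list[EventCall]:
    """Map per-class dosage segmentations of one chromosome to event calls.

    Whole-chromosome signatures (monosomy/trisomy/UPD) suppress segment-level
    calls; paired terminal deletions on one homolog become a circle and a
    terminal deletion/duplication pair on opposite arms an isochromosome.
    """
    n = len(positions)
    if n == 0:
        return []
    for runs in (segments_w, segments_y):
        covered = sorted((i0, i1) for _, i0, i1 in runs)
        if not covered or covered[0][0] != 0 or covered[-1][1] != n - 1:
            raise ValueError("segments do not cover the chromosome")
        for (a, b), (c, d) in zip(covered, covered[1:]):
            if c != b + 1:
                raise ValueError("segments do not cover the chromosome")
    w_states = _expand_states(segments_w, n)
    y_states = _expand_states(segments_y, n)
    _consolidate_boundaries(w_states, y_states)
    regions = _pair_regions(w_states, y_states)

    # whole-chromosome precedence
    if len(regions) == 1 and tuple(regions[0][0]) in _WHOLE_CHROM:
        cls, lost, gained = _WHOLE_CHROM[tuple(regions[0][0])]
        return [
            EventCall(
                id=f"{id_prefix}{chromosome.name}-1",
                call_class=cls,
                chromosome=chromosome.name,
                lost=lost,
                gained=gained,
                span=(int(positions[0]), int(positions[-1])),
            )
        ]

    provisional = []
    for pair, i0, i1 in regions:
        pair = tuple(pair)
        if pair == (1, 1):
            continue
        if pair not in _SIGNATURES:
            logger.debug(
                "%s: unclassified dosage signature %s over [%d, %d]",
                chromosome.name, pair, positions[i0], positions[i1],
            )
            continue
        kind, lost, gained = _SIGNATURES[pair]
        terminal_left = i0 == 0 or positions[i0] <= params.terminal_margin
        terminal_right = (
            i1 == n - 1 or positions[i1] >= chromosome.length - params.terminal_margin
        )
        provisional.append(
            {
                "kind": kind,
                "lost": lost,
                "gained": gained,
                "i0": i0,
                "i1": i1,
                "terminal": terminal_left or terminal_right,
                "left_end": terminal_left and i0 == 0,
                "right_end": terminal_right and i1 == n - 1,
            }
        )

    calls: list[EventCall] = []
    used = [False] * len(provisional)
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"{id_prefix}{chromosome.name}-{counter}"

    def edge_window(last_idx: int, first_idx: int) -> tuple[int, int]:
        mid = (int(positions[last_idx]) + int(positions[first_idx])) / 2.0
        half = params.breakpoint_window / 2.0
        lo = max(1, int(round(mid - half)))
        hi = min(chromosome.length, int(round(mid + half)))
        return lo, hi

    def region_windows(p) -> list[tuple[int, int]]:
        wins = []
        if not p["left_end"]:
            wins.append(edge_window(p["i0"] - 1, p["i0"]))
        if not p["right_end"]:
            wins.append(edge_window(p["i1"], p["i1"] + 1))
        return wins

    # circle: terminal deletions of the same homolog at both chromosome ends
    for a in range(len(provisional)):
        for b in range(a + 1, len(provisional)):
            pa, pb = provisional[a], provisional[b]
            if used[a] or used[b]:
                continue
            if (
                pa["kind"] == pb["kind"] == "DEL"
                and pa["lost"] == pb["lost"]
                and {pa["left_end"], pb["left_end"]} == {True, False}
                and {pa["right_end"], pb["right_end"]} == {True, False}
            ):
                used[a] = used[b] = True
                calls.append(
                    EventCall(
                        id=new_id(),
                        call_class="CIRCLE",
                        chromosome=chromosome.name,
                        lost=pa["lost"],
                        breakpoints=region_windows(pa) + region_windows(pb),
                        span=(int(positions[0]), int(positions[-1])),
                    )
                )

    # isochromosome: terminal DEL on one end, terminal DUP on the other,
    # same homolog affected (lost class deleted, same class duplicated)
    for a in range(len(provisional)):
        for b in range(len(provisional)):
            pa, pb = provisional[a], provisional[b]
            if a == b or used[a] or used[b]:
                continue
            if (
                pa["kind"] == "DEL"
                and pb["kind"] == "DUP"
                and pa["lost"] == pb["gained"]
                and pa["left_end"] != pb["left_end"]
                and (pa["left_end"] or pb["left_end"])
                and (pa["right_end"] or pb["right_end"])
            ):
                used[a] = used[b] = True
                calls.append(
                    EventCall(
                        id=new_id(),
                        call_class="ISO",
                        chromosome=chromosome.name,
                        lost=pa["lost"],
                        gained=pb["gained"],
                        breakpoints=region_windows(pa) + region_windows(pb),
                        span=(int(positions[0]), int(positions[-1])),
                    )
                )

    for p, was_used in zip(provisional, used):
        if was_used:
            continue
        terminal = p["left_end"] or p["right_end"]
        if p["kind"] == "LOH":
            cls = "T-LOH" if terminal else "I-LOH"
        elif p["kind"] == "DEL":
            cls = "T-DEL" if terminal else "I-DEL"
        else:
            cls = "T-DUP" if terminal else "I-DUP"
        if cls == "I-LOH":
            # breakpoint = region between flanking heterozygous SNPs
            lo = int(positions[p["i0"] - 1]) if p["i0"] > 0 else 1
            hi = (
                int(positions[p["i1"] + 1])
                if p["i1"] < n - 1
                else chromosome.length
            )
            breakpoints = [(lo, hi)]
        else:
            breakpoints = region_windows(p)
        calls.append(
            EventCall(
                id=new_id(),
                call_class=cls,
                chromosome=chromosome.name,
                lost=p["lost"],
                gained=p["gained"],
                breakpoints=breakpoints,
                span=(int(positions[p["i0"]]), int(positions[p["i1"]])),
            )
        )
    return calls


def call_events(
    table: pd.DataFrame,
    genome: DiploidGenome,
    params: CallerParams | None = None,
    isolate_id: str = "",
) -> list[EventCall]:
    """Full pipeline: RC normalization, segmentation, classification, pairing."""
    params = params or CallerParams()
    table = compute_rc(table)
    prefix = f"{isolate_id}:" if isolate_id else ""
    calls: list[EventCall] = []
    for chrom in genome.chromosomes:
        sub = table[table["chromosome"] == chrom.name]
        if len(sub) == 0:
            continue
        wide = sub.pivot_table(
            index="position", columns="parental_class", values="RC", sort=True
        )
        positions = wide.index.to_numpy()
        seg_w = segment_profile(positions, wide["W"].to_numpy(), params)
        seg_y = segment_profile(positions, wide["Y"].to_numpy(), params)
        calls.extend(
            classify_chromosome(seg_w, seg_y, positions, chrom, params, prefix)
        )
    return pair_translocations(calls)


def pair_translocations(calls: list[EventCall]) -> list[EventCall]:
    """Greedily pair terminal deletions with terminal duplications.

    A terminal deletion and a terminal duplication on different chromosomes in
    the same isolate are the two dosage footprints of one unbalanced
    translocation.  Ties break by chromosome order then coordinate.
    """
    order = {c.id: i for i, c in enumerate(calls)}
    dels = sorted(
        (c for c in calls if c.call_class == "T-DEL" and c.paired_with is None),
        key=lambda c: order[c.id],
    )
    dups = sorted(
        (c for c in calls if c.call_class == "T-DUP" and c.paired_with is None),
        key=lambda c: order[c.id],
    )
    for d in dels:
        for u in dups:
            if u.paired_with is None and u.chromosome != d.chromosome:
                d.paired_with = u.id
                u.paired_with = d.id
                break
    return calls


def breakpoint_interval(
    call: EventCall,
    snp_positions: np.ndarray,
    params: CallerParams,
    chromosome_length: int | None = None,
) -> list[tuple[int, int]]:
    """Recompute breakpoint interval(s) for a call from the raw SNP map.

    Interstitial LOH gets the full region between the flanking heterozygous
    SNPs; every other transition gets a fixed-width window centered at the
    midpoint between the last unaltered and first altered SNP, clipped to the
    chromosome.
    """
    if call.span is None:
        return list(call.breakpoints)
    pos = np.asarray(snp_positions)
    lo_idx = int(np.searchsorted(pos, call.span[0], "left"))
    hi_idx = int(np.searchsorted(pos, call.span[1], "right")) - 1
    length = chromosome_length or int(pos[-1])

    def window(last_idx, first_idx):
        if last_idx < 0:
            logger.debug("altered region at chromosome start; window clipped")
            mid = float(pos[first_idx])
        else:
            mid = (float(pos[last_idx]) + float(pos[first_idx])) / 2.0
        half = params.breakpoint_window / 2.0
        return max(1, int(round(mid - half))), min(length, int(round(mid + half)))

    if call.call_class == "I-LOH":
        left = int(pos[lo_idx - 1]) if lo_idx > 0 else 1
        right = int(pos[hi_idx + 1]) if hi_idx < len(pos) - 1 else length
        return [(left, right)]
    out = []
    if lo_idx > 0:
        out.append(window(lo_idx - 1, lo_idx))
    if hi_idx < len(pos) - 1:
        out.append(window(hi_idx, hi_idx + 1))
    return out


# ---------------------------------------------------------------------------
# caller resolution


def visible_expected_calls(truth_event, genome: DiploidGenome,
                           params: CallerParams | None = None):
    """Expected calls of a truth event that are resolvable at these parameters.

    Median smoothing erodes roughly half a window from each side of an
    interior altered run before the minimum-support filter applies, so a
    dosage-altered span is counted visible only when it contains at least
    ``smoothing_window // 2 + min_segment_snps`` SNPs whose interior
    (window-trimmed) positions still span ``min_segment_bp``.  Calls built
    from several spans (circles, isochromosomes) need every span visible.
    """
    params = params or CallerParams()
    trim = params.smoothing_window // 2
    min_snps = trim + params.min_segment_snps

    def span_visible(chromosome: str, lo: int, hi: int) -> bool:
        pos = genome.snp_positions(chromosome)
        i0 = int(np.searchsorted(pos, lo, "left"))
        i1 = int(np.searchsorted(pos, hi, "right"))
        n = i1 - i0
        if n < min_snps:
            return False
        inner = pos[i0 + trim // 2 : i1 - (trim - trim // 2)]
        return len(inner) >= 2 and int(inner[-1] - inner[0]) >= params.min_segment_bp

    def flanks_visible(cls: str, chromosome: str, spans) -> bool:
        # The interstitial/terminal/whole-chromosome distinctions also need
        # the *unaltered* remainder to be resolvable, else the caller merges
        # it into the event (I- collapses to T-, T- to a whole-chromosome
        # signature, a circle to a single terminal deletion).
        length = genome.chromosome(chromosome).length
        if cls in {"MONOSOMY", "TRISOMY", "UPD"}:
            return True
        if cls in {"CIRCLE", "ISO"}:
            (lo1, hi1), (lo2, hi2) = sorted(spans)
            return span_visible(chromosome, hi1 + 1, lo2 - 1)
        (lo, hi) = spans[0]
        flanks = []
        if cls.startswith("I-"):
            flanks = [(1, lo - 1), (hi + 1, length)]
        elif lo > 1:
            flanks = [(1, lo - 1)]
        else:
            flanks = [(hi + 1, length)]
        return all(span_visible(chromosome, a, b) for a, b in flanks if b >= a)

    out = []
    for (cls, chromosome), spans in zip(
        truth_event.expected_calls, truth_event.call_spans
    ):
        if all(span_visible(chromosome, lo, hi) for lo, hi in spans) and \
                flanks_visible(cls, chromosome, spans):
            out.append((cls, chromosome))
    return out


# ---------------------------------------------------------------------------
# haploid PCR classification


@dataclass(frozen=True)
class HaploidPcrPattern:
    """Presence/size category of the four diagnostic PCR products."""

    left_junction: str
    right_junction: str
    across_element: str
    marker_internal: str

    _ALLOWED = {"absent", "present_parental_size", "present_shorter"}

    def __post_init__(self) -> None:
        for name in ("left_junction", "right_junction", "across_element",
                     "marker_internal"):
            if getattr(self, name) not in self._ALLOWED:
                raise ValueError(f"bad value for {name}: {getattr(self, name)!r}")


def classify_haploid_isolate(pattern: HaploidPcrPattern) -> str:
    """Sort a marker-loss isolate into PCR class 1-4 (or 'unclassified').

    Class 1: all products at parental size (marker point change).
    Class 2: the across-element product shortened to solo-LTR size (pop-out).
    Class 3: junctions and element intact but the marker-internal product
    absent (conversion without crossover).
    Class 4: both junction products present individually but no across-element
    product (conversion with a crossover rearranging the flank).
    """
    parental = "present_parental_size"
    if pattern.across_element == "present_shorter":
        return "2"
    if (
        pattern.left_junction == parental
        and pattern.right_junction == parental
        and pattern.across_element == parental
        and pattern.marker_internal == parental
    ):
        return "1"
    if (
        pattern.left_junction == parental
        and pattern.right_junction == parental
        and pattern.across_element == parental
        and pattern.marker_internal == "absent"
    ):
        return "3"
    if (
        pattern.left_junction == parental
        and pattern.right_junction == parental
        and pattern.across_element == "absent"
    ):
        return "4"
    return "unclassified"


# ---------------------------------------------------------------------------
# serialization


def write_events(calls: list[EventCall], path: str | Path) -> None:
    payload = [
        {
            "id": c.id,
            "class": c.call_class,
            "chromosome": c.chromosome,
            "lost": c.lost,
            "gained": c.gained,
            "breakpoints": [list(b) for b in c.breakpoints],
            "paired_with": c.paired_with,
            "span": list(c.span) if c.span else None,
        }
        for c in calls
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_events(path: str | Path) -> list[EventCall]:
    payload = json.loads(Path(path).read_text())
    return [
        EventCall(
            id=rec["id"],
            call_class=rec["class"],
            chromosome=rec["chromosome"],
            lost=rec.get("lost"),
            gained=rec.get("gained"),
            breakpoints=[tuple(b) for b in rec.get("breakpoints", [])],
            paired_with=rec.get("paired_with"),
            span=tuple(rec["span"]) if rec.get("span") else None,
        )
        for rec in payload
    ]
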