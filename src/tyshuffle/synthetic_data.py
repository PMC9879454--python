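"""Karyotype rearrangement simulator and synthetic signal generation.

A :class:`Karyotype` holds the derived chromosome molecules of one isolate as
ordered segments of parental material.  Mechanism operations (`apply_*`)
rewrite molecules and return :class:`TruthEvent` records carrying the dosage
signature each mechanism is expected to leave.  Signal synthesis turns the
per-SNP copy-number profile into noisy allele read counts, produces read-by-SNP
call matrices over hybrid elements, and simulates fluctuation assays.
"""

from __future__ import annotations

import copy as _copy
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_model import (
    SOLO_DELTA_LENGTH,
    ChromosomeDef,
    DiploidGenome,
    TyElement,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Segment",
    "DerivedChromosome",
    "Karyotype",
    "TruthEvent",
    "SimParams",
    "TyReadMatrix",
    "FluctuationExperiment",
    "baseline_karyotype",
    "apply_ssa_popout",
    "apply_unequal_xover",
    "apply_intrachromatid_circle",
    "apply_isochromosome",
    "apply_inversion",
    "apply_translocation",
    "apply_allelic_event",
    "apply_aneuploidy",
    "simulate_isolate",
    "copy_number_profile",
    "synthesize_snp_counts",
    "synthesize_ty_reads",
    "simulate_fluctuation",
    "read_counts_table",
    "write_counts_table",
    "write_truth",
    "read_truth",
]

MECHANISMS = (
    "SSA_popout",
    "conversion_noncrossover",
    "unequal_xover_del",
    "unequal_xover_dup",
    "intrachromatid_circle",
    "sister_dicentric",
    "isochromosome",
    "inversion",
    "reciprocal_translocation_balanced",
    "reciprocal_translocation_unbalanced",
    "BIR_translocation",
    "allelic_crossover",
    "allelic_BIR",
    "allelic_conversion",
    "monosomy",
    "trisomy",
    "UPD",
)


@dataclass(frozen=True)
class Segment:
    """A stretch of parental material inside a derived molecule (1-based incl.)."""

    homolog: str  # W | Y
    chromosome: str
    start: int
    end: int
    orientation: str = "forward"  # forward | reverse

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"segment end {self.end} <= start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class DerivedChromosome:
    """An ordered list of parental segments forming one molecule."""

    name: str
    segments: list[Segment]
    circular: bool = False

    def centromere_count(self, genome: DiploidGenome) -> int:
        n = 0
        for seg in self.segments:
            cen = genome.chromosome(seg.chromosome).centromere_mid
            if seg.start <= cen <= seg.end:
                n += 1
        return n


@dataclass
class TruthEvent:
    """Ground-truth record for one simulated mechanism.

    ``expected_calls`` expands the dosage signature into the per-chromosome
    calls the event caller should emit ("silent" events expand to nothing);
    ``call_spans`` lists, parallel to ``expected_calls``, the dosage-altered
    interval(s) behind each expected call, and ``true_breakpoints`` lists
    (chromosome, position) pairs for breakpoint-window checks.
    """

    mechanism: str
    participants: list[str]
    expected_call_class: str
    expected_calls: list[tuple[str, str]] = field(default_factory=list)
    call_spans: list[list[tuple[int, int]]] = field(default_factory=list)
    true_breakpoints: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")


@dataclass
class SimParams:
    """Knobs for isolate and signal simulation."""

    mechanism_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_WEIGHTS)
    )
    conversion_tract_mean: float = 2_000.0  # geometric mean tract length, bp
    mean_depth: float = 40.0  # mean total coverage per SNP site
    depth_noise: str = "poisson"  # poisson | negative_binomial
    nb_dispersion: float = 10.0  # NB size parameter when depth_noise=nb
    miscall_rate: float = 0.05  # per-call error in Ty read matrices
    ty2_partner_prob: float = 5.0 / 124.0  # observed non-Ty1 partner fraction
    allow_chromosome_reuse: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.mechanism_weights.values()):
            raise ValueError("mechanism weights must be >= 0")
        if sum(self.mechanism_weights.values()) <= 0:
            raise ValueError("mechanism weights must sum to > 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not (0 <= self.miscall_rate < 0.5):
            raise ValueError("miscall_rate must be in [0, 0.5)")


# Weights loosely follow the observed per-isolate event composition in
# transiently induced diploids (deletions/duplications, one circle,
# translocations, and allelic I-/T-LOH dominating).
_DEFAULT_WEIGHTS = {
    "unequal_xover_del": 12.0,
    "unequal_xover_dup": 4.0,
    "intrachromatid_circle": 1.0,
    "isochromosome": 1.0,
    "inversion": 1.0,
    "reciprocal_translocation_unbalanced": 10.0,
    "reciprocal_translocation_balanced": 2.0,
    "SSA_popout": 2.0,
    "allelic_conversion": 9.0,
    "allelic_crossover": 9.0,
    "allelic_BIR": 4.0,
    "monosomy": 2.0,
    "trisomy": 0.5,
    "UPD": 0.5,
}


@dataclass
class Karyotype:
    """Derived molecules of one isolate plus provenance genome."""

    genome: DiploidGenome
    molecules: list[DerivedChromosome]
    popped_elements: set[str] = field(default_factory=set)

    def copy(self) -> "Karyotype":
        return Karyotype(
            genome=self.genome,
            molecules=_copy.deepcopy(self.molecules),
            popped_elements=set(self.popped_elements),
        )

    # -- molecule bookkeeping -------------------------------------------

    def find_molecule(self, homolog: str, chromosome: str, start: int, end: int):
        """Locate the molecule/segment containing a parental interval.

        Only forward-orientation segments are searched: mechanism operations
        target loci that have not been reoriented by a previous event.
        Returns ``(mol_index, seg_index)`` or ``None``.
        """
        for mi, mol in enumerate(self.molecules):
            for si, seg in enumerate(mol.segments):
                if (
                    seg.homolog == homolog
                    and seg.chromosome == chromosome
                    and seg.orientation == "forward"
                    and seg.start <= start
                    and end <= seg.end
                ):
                    return mi, si
        return None

    def homolog_molecule(self, homolog: str, chromosome: str) -> int | None:
        """Index of the intact single-segment molecule for a homolog, if any."""
        for mi, mol in enumerate(self.molecules):
            if (
                len(mol.segments) == 1
                and not mol.circular
                and mol.segments[0].homolog == homolog
                and mol.segments[0].chromosome == chromosome
                and mol.segments[0].orientation == "forward"
            ):
                return mi
        return None

    def validate(self) -> None:
        """Every retained molecule must carry exactly one centromere."""
        for mol in self.molecules:
            n = mol.centromere_count(self.genome)
            if n != 1:
                kind = "acentric" if n == 0 else "dicentric"
                raise ValueError(f"molecule {mol.name} is {kind} ({n} centromeres)")

    def adjacencies(self) -> set[tuple]:
        """Set of novel junctions (segment-boundary signatures) across molecules."""
        out = set()
        for mol in self.molecules:
            for a, b in zip(mol.segments, mol.segments[1:]):
                out.add(
                    (
                        (a.homolog, a.chromosome, a.end if a.orientation == "forward" else a.start),
                        (b.homolog, b.chromosome, b.start if b.orientation == "forward" else b.end),
                    )
                )
        return out


def baseline_karyotype(genome: DiploidGenome) -> Karyotype:
    """Unrearranged diploid: one full-length molecule per homolog per chromosome."""
    molecules = []
    for chrom in genome.chromosomes:
        for homolog in ("W", "Y"):
            molecules.append(
                DerivedChromosome(
                    name=f"{chrom.name}_{homolog}",
                    segments=[Segment(homolog, chrom.name, 1, chrom.length)],
                )
            )
    return Karyotype(genome=genome, molecules=molecules)


# ---------------------------------------------------------------------------
# segment surgery primitives


def _cut(segments: list[Segment], homolog: str, chromosome: str, pos: int):
    """Split a segment list at parental position ``pos`` (pos stays left)."""
    for i, seg in enumerate(segments):
        if (
            seg.homolog == homolog
            and seg.chromosome == chromosome
            and seg.orientation == "forward"
            and seg.start <= pos < seg.end
        ):
            left = segments[:i] + [replace(seg, end=pos)]
            right = [replace(seg, start=pos + 1)] + segments[i + 1 :]
            return left, right
    raise ValueError(f"no forward segment of {homolog}/{chromosome} contains {pos}")


def _reverse(segments: list[Segment]) -> list[Segment]:
    flip = {"forward": "reverse", "reverse": "forward"}
    return [replace(s, orientation=flip[s.orientation]) for s in reversed(segments)]


def _element_breakpoint(ty: TyElement, genome: DiploidGenome) -> int:
    """Within-element recombination point: the cut site if inside, else midpoint."""
    p = ty.start + genome.dsb_offset
    if not (ty.start <= p < ty.end):
        p = (ty.start + ty.end) // 2
    return p


def _require_same_molecule(k: Karyotype, ty_a: TyElement, ty_b: TyElement) -> int:
    la = k.find_molecule(ty_a.homolog, ty_a.chromosome, ty_a.start, ty_a.end)
    lb = k.find_molecule(ty_b.homolog, ty_b.chromosome, ty_b.start, ty_b.end)
    if la is None or lb is None or la[0] != lb[0]:
        raise ValueError("both elements must lie on one molecule")
    return la[0]


# ---------------------------------------------------------------------------
# mechanism operations (each returns (new_karyotype, TruthEvent))


def apply_ssa_popout(k: Karyotype, ty: TyElement):
    """Replace a full element by one 330-bp solo LTR (dosage-silent)."""
    if ty.family == "solo_delta":
        raise ValueError(f"{ty.id} is already a solo delta")
    if ty.id in k.popped_elements:
        raise ValueError(f"{ty.id} already popped out")
    loc = k.find_molecule(ty.homolog, ty.chromosome, ty.start, ty.end)
    if loc is None:
        raise ValueError(f"{ty.id} not present on any molecule")
    k2 = k.copy()
    mol = k2.molecules[loc[0]]
    left, rest = _cut(mol.segments, ty.homolog, ty.chromosome, ty.start + SOLO_DELTA_LENGTH - 1)
    _, right = _cut(rest, ty.homolog, ty.chromosome, ty.end)
    mol.segments = _merge_adjacent(left + right)
    k2.popped_elements.add(ty.id)
    event = TruthEvent(
        mechanism="SSA_popout",
        participants=[ty.id],
        expected_call_class="silent",
    )
    return k2, event


def apply_unequal_xover(k: Karyotype, ty_a: TyElement, ty_b: TyElement, keep: str):
    """Unequal crossover between direct repeats: interstitial del or dup."""
    if keep not in {"del", "dup"}:
        raise ValueError("keep must be 'del' or 'dup'")
    if ty_a.orientation != ty_b.orientation:
        raise ValueError("elements must be in direct orientation (see apply_inversion)")
    if ty_a.homolog != ty_b.homolog or ty_a.chromosome != ty_b.chromosome:
        raise ValueError("elements must be on the same homolog and chromosome")
    if ty_a.start > ty_b.start:
        ty_a, ty_b = ty_b, ty_a
    if ty_a.end >= ty_b.start:
        raise ValueError("elements overlap")
    mi = _require_same_molecule(k, ty_a, ty_b)

    genome = k.genome
    pa = _element_breakpoint(ty_a, genome)
    pb = _element_breakpoint(ty_b, genome)
    k2 = k.copy()
    mol = k2.molecules[mi]
    left, rest = _cut(mol.segments, ty_a.homolog, ty_a.chromosome, pa)
    mid, right = _cut(rest, ty_a.homolog, ty_a.chromosome, pb)
    if keep == "del":
        mol.segments = _merge_adjacent(left + right)
        call = "I-DEL"
    else:
        mol.segments = _merge_adjacent(left + mid + mid + right)
        call = "I-DUP"
    n_snps = genome.count_snps_between(ty_a.chromosome, pa + 1, pb)
    expected = call if n_snps > 0 else "silent"
    event = TruthEvent(
        mechanism=f"unequal_xover_{keep}",
        participants=[ty_a.id, ty_b.id],
        expected_call_class=expected,
        expected_calls=[(call, ty_a.chromosome)] if expected != "silent" else [],
        call_spans=[[(pa + 1, pb)]] if expected != "silent" else [],
        true_breakpoints=[(ty_a.chromosome, pa), (ty_a.chromosome, pb)],
    )
    return k2, event


def apply_intrachromatid_circle(k: Karyotype, ty_a: TyElement, ty_b: TyElement):
    """Intrachromatid crossover across the centromere: retain the circle."""
    if ty_a.homolog != ty_b.homolog or ty_a.chromosome != ty_b.chromosome:
        raise ValueError("elements must be on the same homolog and chromosome")
    genome = k.genome
    chrom = genome.chromosome(ty_a.chromosome)
    if ty_a.arm(chrom) == ty_b.arm(chrom):
        raise ValueError("elements must be on opposite arms")
    if ty_a.orientation != ty_b.orientation:
        raise ValueError("circle formation requires directly oriented elements")
    if ty_a.start > ty_b.start:
        ty_a, ty_b = ty_b, ty_a
    mi = _require_same_molecule(k, ty_a, ty_b)

    pa = _element_breakpoint(ty_a, genome)
    pb = _element_breakpoint(ty_b, genome)
    k2 = k.copy()
    mol = k2.molecules[mi]
    _, rest = _cut(mol.segments, ty_a.homolog, ty_a.chromosome, pa)
    mid, _ = _cut(rest, ty_a.homolog, ty_a.chromosome, pb)
    mol.segments = _merge_adjacent(mid)
    mol.circular = True
    event = TruthEvent(
        mechanism="intrachromatid_circle",
        participants=[ty_a.id, ty_b.id],
        expected_call_class="CIRCLE",
        expected_calls=[("CIRCLE", ty_a.chromosome)],
        call_spans=[[(1, pa), (pb + 1, chrom.length)]],
        true_breakpoints=[(ty_a.chromosome, pa), (ty_a.chromosome, pb)],
    )
    return k2, event


def apply_isochromosome(k: Karyotype, ty_left: TyElement, ty_right: TyElement):
    """Inverted-repeat exchange across the centromere: mirror one arm.

    The retained product duplicates material distal to the left-arm element
    and loses material distal to the right-arm element.
    """
    if ty_left.homolog != ty_right.homolog or ty_left.chromosome != ty_right.chromosome:
        raise ValueError("elements must be on the same homolog and chromosome")
    genome = k.genome
    chrom = genome.chromosome(ty_left.chromosome)
    if ty_left.arm(chrom) == ty_right.arm(chrom):
        raise ValueError("elements must be on opposite arms")
    if ty_left.orientation == ty_right.orientation:
        raise ValueError("isochromosome formation requires inverted elements")
    if ty_left.start > ty_right.start:
        ty_left, ty_right = ty_right, ty_left
    mi = _require_same_molecule(k, ty_left, ty_right)

    pa = _element_breakpoint(ty_left, genome)
    pb = _element_breakpoint(ty_right, genome)
    k2 = k.copy()
    mol = k2.molecules[mi]
    left_of_b, _ = _cut(mol.segments, ty_left.homolog, ty_left.chromosome, pb)
    left_of_a, _ = _cut(mol.segments, ty_left.homolog, ty_left.chromosome, pa)
    mol.segments = left_of_b + _reverse(left_of_a)
    event = TruthEvent(
        mechanism="isochromosome",
        participants=[ty_left.id, ty_right.id],
        expected_call_class="ISO",
        expected_calls=[("ISO", ty_left.chromosome)],
        call_spans=[[(1, pa), (pb + 1, chrom.length)]],
        true_breakpoints=[
            (ty_left.chromosome, pa),
            (ty_left.chromosome, pb),
        ],
    )
    return k2, event


def apply_inversion(k: Karyotype, ty_a: TyElement, ty_b: TyElement):
    """Exchange between inverted repeats on one arm: dosage-silent inversion."""
    if ty_a.homolog != ty_b.homolog or ty_a.chromosome != ty_b.chromosome:
        raise ValueError("elements must be on the same homolog and chromosome")
    if ty_a.orientation == ty_b.orientation:
        raise ValueError("inversion requires elements in inverted orientation")
    genome = k.genome
    chrom = genome.chromosome(ty_a.chromosome)
    if ty_a.arm(chrom) != ty_b.arm(chrom):
        raise ValueError("elements must be on the same arm (see apply_isochromosome)")
    if ty_a.start > ty_b.start:
        ty_a, ty_b = ty_b, ty_a
    pa = _element_breakpoint(ty_a, genome)
    pb = _element_breakpoint(ty_b, genome)
    k2 = k.copy()
    try:
        mi = _require_same_molecule(k, ty_a, ty_b)
        mol = k2.molecules[mi]
        left, rest = _cut(mol.segments, ty_a.homolog, ty_a.chromosome, pa)
        mid, right = _cut(rest, ty_a.homolog, ty_a.chromosome, pb)
        mol.segments = left + _reverse(mid) + right
    except ValueError:
        # a second exchange between the same (now hybrid) elements reverts
        # the previously inverted middle: locate and flip it back
        mol = _find_inverted_middle(k2, ty_a, pa, pb)
        if mol is None:
            raise
    event = TruthEvent(
        mechanism="inversion",
        participants=[ty_a.id, ty_b.id],
        expected_call_class="silent",
        true_breakpoints=[(ty_a.chromosome, pa), (ty_a.chromosome, pb)],
    )
    return k2, event


def apply_translocation(
    k: Karyotype,
    ty_a: TyElement,
    ty_b: TyElement,
    segregation: str = "unbalanced",
    keep: str | None = None,
):
    """Exchange between elements on non-homologous chromosomes.

    ``balanced``: both recombinant molecules replace the participating
    homolog molecules (dosage-silent).  ``unbalanced``: one recombinant
    replaces the broken homolog of ``ty_b``'s chromosome while both homologs
    of ``ty_a``'s chromosome stay intact, yielding a terminal duplication on
    ``ty_a``'s chromosome and a terminal deletion on ``ty_b``'s chromosome.
    Monocentric products require both elements on the same arm side.
    """
    if segregation not in {"balanced", "unbalanced"}:
        raise ValueError("segregation must be 'balanced' or 'unbalanced'")
    if ty_a.chromosome == ty_b.chromosome:
        raise ValueError(
            "elements on the same chromosome: use allelic/intrachromosomal operations"
        )
    genome = k.genome
    ca = genome.chromosome(ty_a.chromosome)
    cb = genome.chromosome(ty_b.chromosome)
    if ty_a.arm(ca) != ty_b.arm(cb):
        raise ValueError("opposite arm sides would produce dicentric/acentric products")

    la = k.find_molecule(ty_a.homolog, ty_a.chromosome, ty_a.start, ty_a.end)
    lb = k.find_molecule(ty_b.homolog, ty_b.chromosome, ty_b.start, ty_b.end)
    if la is None or lb is None:
        raise ValueError("both elements must be present on molecules")
    pa = _element_breakpoint(ty_a, genome)
    pb = _element_breakpoint(ty_b, genome)

    k2 = k.copy()
    mol_a = k2.molecules[la[0]]
    mol_b = k2.molecules[lb[0]]
    a_left, a_right = _cut(mol_a.segments, ty_a.homolog, ty_a.chromosome, pa)
    b_left, b_right = _cut(mol_b.segments, ty_b.homolog, ty_b.chromosome, pb)

    if segregation == "balanced":
        mol_a.segments = _merge_adjacent(a_left + b_right)
        mol_b.segments = _merge_adjacent(b_left + a_right)
        mol_a.name = f"t({ty_a.chromosome};{ty_b.chromosome})"
        mol_b.name = f"t({ty_b.chromosome};{ty_a.chromosome})"
        event = TruthEvent(
            mechanism="reciprocal_translocation_balanced",
            participants=[ty_a.id, ty_b.id],
            expected_call_class="silent",
            true_breakpoints=[(ty_a.chromosome, pa), (ty_b.chromosome, pb)],
        )
        return k2, event

    # unbalanced: the recombinant keeps ty_b's proximal part plus ty_a's
    # distal part; ty_a's own molecule is untouched (sister chromatid).
    if ty_a.arm(ca) == "R":
        mol_b.segments = _merge_adjacent(b_left + a_right)
        dup_span = (pa + 1, ca.length)
        del_span = (pb + 1, cb.length)
    else:
        mol_b.segments = _merge_adjacent(a_left + b_right)
        dup_span = (1, pa)
        del_span = (1, pb)
    mol_b.name = f"t({ty_b.chromosome};{ty_a.chromosome})"
    event = TruthEvent(
        mechanism="reciprocal_translocation_unbalanced",
        participants=[ty_a.id, ty_b.id],
        expected_call_class="T-DUP+T-DEL",
        expected_calls=[("T-DUP", ty_a.chromosome), ("T-DEL", ty_b.chromosome)],
        call_spans=[[dup_span], [del_span]],
        true_breakpoints=[(ty_a.chromosome, pa), (ty_b.chromosome, pb)],
    )
    return k2, event


def apply_allelic_event(
    k: Karyotype,
    chromosome: str,
    position: int,
    kind: str,
    tract_len: int | None = None,
    lost_homolog: str = "W",
):
    """Allelic recombination between homologs.

    ``crossover``/``BIR``: from ``position`` to the telomere on that arm, the
    lost homolog is replaced by a copy of the other (terminal LOH, dosage
    conserved).  ``conversion``: an interstitial tract of ``tract_len`` bp is
    homozygosed (interstitial LOH); a tract running past the telomere is
    clipped and relabeled terminal.
    """
    if kind not in {"crossover", "BIR", "conversion"}:
        raise ValueError(f"unknown allelic kind {kind!r}")
    if lost_homolog not in {"W", "Y"}:
        raise ValueError("lost_homolog must be 'W' or 'Y'")
    genome = k.genome
    chrom = genome.chromosome(chromosome)
    if not (1 < position < chrom.length):
        raise ValueError("position must be inside the chromosome")
    other = "Y" if lost_homolog == "W" else "W"

    mi = k.homolog_molecule(lost_homolog, chromosome)
    if mi is None:
        raise ValueError(f"no intact {lost_homolog} homolog of {chromosome}")
    mechanism = {"crossover": "allelic_crossover", "BIR": "allelic_BIR",
                 "conversion": "allelic_conversion"}[kind]
    k2 = k.copy()
    mol = k2.molecules[mi]

    if kind in {"crossover", "BIR"}:
        to_right = position > chrom.centromere_mid
        if to_right:
            left, _ = _cut(mol.segments, lost_homolog, chromosome, position)
            mol.segments = _merge_adjacent(
                left + [Segment(other, chromosome, position + 1, chrom.length)]
            )
        else:
            _, right = _cut(mol.segments, lost_homolog, chromosome, position)
            mol.segments = _merge_adjacent(
                [Segment(other, chromosome, 1, position)] + right
            )
        span = (position + 1, chrom.length) if to_right else (1, position)
        event = TruthEvent(
            mechanism=mechanism,
            participants=[f"{chromosome}:{position}"],
            expected_call_class="T-LOH",
            expected_calls=[("T-LOH", chromosome)],
            call_spans=[[span]],
            true_breakpoints=[(chromosome, position)],
        )
        return k2, event

    if tract_len is None or tract_len <= 0:
        raise ValueError("conversion requires tract_len > 0")
    end = position + tract_len - 1
    call = "I-LOH"
    breakpoints = [(chromosome, position), (chromosome, end)]
    if end >= chrom.length:
        logger.warning(
            "conversion tract at %s:%d clipped at telomere; relabeled T-LOH",
            chromosome, position,
        )
        end = chrom.length
        call = "T-LOH"
        breakpoints = [(chromosome, position)]
        left, _ = _cut(mol.segments, lost_homolog, chromosome, position - 1)
        mol.segments = _merge_adjacent(
            left + [Segment(other, chromosome, position, chrom.length)]
        )
    else:
        left, rest = _cut(mol.segments, lost_homolog, chromosome, position - 1)
        _, right = _cut(rest, lost_homolog, chromosome, end)
        mol.segments = _merge_adjacent(
            left + [Segment(other, chromosome, position, end)] + right
        )
    n_snps = genome.count_snps_between(chromosome, position, end)
    event = TruthEvent(
        mechanism=mechanism,
        participants=[f"{chromosome}:{position}-{end}"],
        expected_call_class=call if n_snps > 0 else "silent",
        expected_calls=[(call, chromosome)] if n_snps > 0 else [],
        call_spans=[[(position, end)]] if n_snps > 0 else [],
        true_breakpoints=breakpoints,
    )
    return k2, event


def apply_aneuploidy(k: Karyotype, chromosome: str, kind: str, which_homolog: str = "W"):
    """Whole-chromosome loss, gain, or uniparental disomy."""
    if kind not in {"monosomy", "trisomy", "UPD"}:
        raise ValueError(f"unknown aneuploidy kind {kind!r}")
    if which_homolog not in {"W", "Y"}:
        raise ValueError("which_homolog must be 'W' or 'Y'")
    other = "Y" if which_homolog == "W" else "W"
    k2 = k.copy()
    whole = [[(1, k.genome.chromosome(chromosome).length)]]

    if kind == "monosomy":
        mi = k2.homolog_molecule(which_homolog, chromosome)
        if mi is None:
            raise ValueError(
                f"no intact {which_homolog} homolog of {chromosome} to lose"
            )
        del k2.molecules[mi]
        event = TruthEvent(
            "monosomy", [f"{chromosome}_{which_homolog}"], "MONOSOMY",
            expected_calls=[("MONOSOMY", chromosome)], call_spans=whole,
        )
    elif kind == "trisomy":
        mi = k2.homolog_molecule(which_homolog, chromosome)
        if mi is None:
            raise ValueError(f"no intact {which_homolog} homolog of {chromosome}")
        mol = k2.molecules[mi]
        k2.molecules.append(
            DerivedChromosome(mol.name + "+", _copy.deepcopy(mol.segments))
        )
        event = TruthEvent(
            "trisomy", [f"{chromosome}_{which_homolog}"], "TRISOMY",
            expected_calls=[("TRISOMY", chromosome)], call_spans=whole,
        )
    else:  # UPD: keep which_homolog, replace the other with its copy
        mi_lost = k2.homolog_molecule(other, chromosome)
        mi_kept = k2.homolog_molecule(which_homolog, chromosome)
        if mi_lost is None or mi_kept is None:
            raise ValueError(f"UPD requires both intact homologs of {chromosome}")
        kept = k2.molecules[mi_kept]
        k2.molecules[mi_lost] = DerivedChromosome(
            kept.name + "'", _copy.deepcopy(kept.segments)
        )
        event = TruthEvent(
            "UPD", [f"{chromosome}_keep_{which_homolog}"], "UPD",
            expected_calls=[("UPD", chromosome)], call_spans=whole,
        )
    return k2, event


def _find_inverted_middle(k: Karyotype, ty_a: TyElement, pa: int, pb: int):
    """Revert a previously inverted middle [pa+1, pb]; None if not found."""
    for mol in k.molecules:
        for i, seg in enumerate(mol.segments):
            if (
                seg.homolog == ty_a.homolog
                and seg.chromosome == ty_a.chromosome
                and seg.orientation == "reverse"
                and seg.start == pa + 1
                and seg.end == pb
            ):
                mol.segments[i : i + 1] = _reverse([seg])
                mol.segments = _merge_adjacent(mol.segments)
                return mol
    return None


def _merge_adjacent(segments: list[Segment]) -> list[Segment]:
    """Fuse abutting same-homolog same-orientation segments."""
    out: list[Segment] = []
    for seg in segments:
        if (
            out
            and out[-1].homolog == seg.homolog
            and out[-1].chromosome == seg.chromosome
            and out[-1].orientation == seg.orientation == "forward"
            and out[-1].end + 1 == seg.start
        ):
            out[-1] = replace(out[-1], end=seg.end)
        else:
            out.append(seg)
    return out


# ---------------------------------------------------------------------------
# isolate composition


def _eligible_ty_pool(k: Karyotype, rng: np.random.Generator, params: SimParams):
    """Draw an element pool: cut-target Ty1 with prob 1-eps, else Ty2."""
    genome = k.genome
    if rng.random() < params.ty2_partner_prob:
        pool = [t for t in genome.ty_elements if t.family == "Ty2"]
    else:
        pool = [t for t in genome.ty_elements if t.has_cas9_target]
    return [t for t in pool if t.id not in k.popped_elements]


def simulate_isolate(
    genome: DiploidGenome,
    params: SimParams,
    n_events: int,
    rng: np.random.Generator | None = None,
):
    """Compose ``n_events`` random mechanisms into one isolate karyotype.

    Mechanisms are drawn by weight; participants are drawn uniformly from the
    eligible elements/positions (bounded retries, then the draw is skipped
    with a log message).  By default each chromosome hosts at most one event
    so truth labels stay well defined.
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    k = baseline_karyotype(genome)
    truth: list[TruthEvent] = []
    used_chroms: set[str] = set()
    names = list(params.mechanism_weights)
    weights = np.array([params.mechanism_weights[n] for n in names], dtype=float)
    weights /= weights.sum()

    produced = 0
    attempts = 0
    max_attempts = 60 * max(n_events, 1)
    while produced < n_events and attempts < max_attempts:
        attempts += 1
        mechanism = names[int(rng.choice(len(names), p=weights))]
        try:
            k2, event = _draw_event(k, mechanism, rng, params, used_chroms)
        except ValueError:
            continue
        k = k2
        truth.append(event)
        produced += 1
        if not params.allow_chromosome_reuse:
            used_chroms.update(_event_chromosomes(event, genome))
    if produced < n_events:
        logger.warning("only %d of %d events placed (eligibility exhausted)",
                       produced, n_events)
    return k, truth


def _event_chromosomes(event: TruthEvent, genome: DiploidGenome) -> set[str]:
    chroms = {c for _, c in event.expected_calls}
    chroms.update({c for c, _ in event.true_breakpoints})
    for p in event.participants:
        token = p.split(":")[0].split("_")[0]
        if token in {c.name for c in genome.chromosomes}:
            chroms.add(token)
        else:  # element id convention: H-<chrom><arm>-...
            parts = p.split("-")
            if len(parts) >= 2 and parts[1][:-1] in {c.name for c in genome.chromosomes}:
                chroms.add(parts[1][:-1])
    return chroms


def _pick(rng: np.random.Generator, items: list):
    if not items:
        raise ValueError("empty pool")
    return items[int(rng.integers(0, len(items)))]


def _draw_event(k, mechanism, rng, params, used_chroms):
    genome = k.genome
    chrom_ok = lambda name: params.allow_chromosome_reuse or name not in used_chroms

    if mechanism == "SSA_popout":
        pool = [t for t in _eligible_ty_pool(k, rng, params)
                if t.family in {"Ty1", "Ty2"} and chrom_ok(t.chromosome)]
        ty = _pick(rng, pool)
        return apply_ssa_popout(k, ty)

    if mechanism in {"unequal_xover_del", "unequal_xover_dup"}:
        keep = mechanism.rsplit("_", 1)[1]
        pool = [t for t in _eligible_ty_pool(k, rng, params) if chrom_ok(t.chromosome)]
        pairs = []
        for i, a in enumerate(pool):
            chrom = genome.chromosome(a.chromosome)
            for b in pool[i + 1 :]:
                if (
                    a.homolog == b.homolog
                    and a.chromosome == b.chromosome
                    and a.orientation == b.orientation
                    and a.arm(chrom) == b.arm(chrom)
                    and max(a.start, b.start) > min(a.end, b.end)
                ):
                    pairs.append((a, b))
        a, b = _pick(rng, pairs)
        return apply_unequal_xover(k, a, b, keep=keep)

    if mechanism in {"intrachromatid_circle", "isochromosome", "inversion"}:
        pool = [t for t in _eligible_ty_pool(k, rng, params) if chrom_ok(t.chromosome)]
        pairs = []
        for i, a in enumerate(pool):
            chrom = genome.chromosome(a.chromosome)
            for b in pool[i + 1 :]:
                if a.homolog != b.homolog or a.chromosome != b.chromosome:
                    continue
                same_arm = a.arm(chrom) == b.arm(chrom)
                same_ori = a.orientation == b.orientation
                if mechanism == "intrachromatid_circle" and not same_arm and same_ori:
                    pairs.append((a, b))
                elif mechanism == "isochromosome" and not same_arm and not same_ori:
                    pairs.append((a, b))
                elif mechanism == "inversion" and same_arm and not same_ori:
                    pairs.append((a, b))
        a, b = _pick(rng, pairs)
        if mechanism == "intrachromatid_circle":
            return apply_intrachromatid_circle(k, a, b)
        if mechanism == "isochromosome":
            a, b = (a, b) if a.start < b.start else (b, a)
            return apply_isochromosome(k, a, b)
        return apply_inversion(k, a, b)

    if mechanism in {
        "reciprocal_translocation_balanced",
        "reciprocal_translocation_unbalanced",
    }:
        segregation = mechanism.rsplit("_", 1)[1]
        pool = [t for t in _eligible_ty_pool(k, rng, params) if chrom_ok(t.chromosome)]
        pairs = []
        for i, a in enumerate(pool):
            ca = genome.chromosome(a.chromosome)
            for b in pool[i + 1 :]:
                if a.chromosome == b.chromosome:
                    continue
                if a.arm(ca) == b.arm(genome.chromosome(b.chromosome)):
                    pairs.append((a, b))
        a, b = _pick(rng, pairs)
        return apply_translocation(k, a, b, segregation=segregation)

    if mechanism in {"allelic_crossover", "allelic_BIR", "allelic_conversion"}:
        kind = mechanism.split("_", 1)[1]
        chroms = [c for c in genome.chromosomes if chrom_ok(c.name)]
        chrom = _pick(rng, chroms)
        pos_arr = genome.snp_positions(chrom.name)
        if len(pos_arr) < 12:
            raise ValueError("too few SNPs")
        lost = "W" if rng.random() < 0.5 else "Y"
        if kind == "conversion":
            tract = max(
                1, int(rng.geometric(1.0 / params.conversion_tract_mean))
            )
            idx = int(rng.integers(6, len(pos_arr) - 6))
            position = int(pos_arr[idx]) - 1
            return apply_allelic_event(
                k, chrom.name, position, "conversion", tract_len=tract,
                lost_homolog=lost,
            )
        idx = int(rng.integers(6, len(pos_arr) - 6))
        position = int(pos_arr[idx]) + 1
        return apply_allelic_event(k, chrom.name, position, kind, lost_homolog=lost)

    if mechanism in {"monosomy", "trisomy", "UPD"}:
        chroms = [c for c in genome.chromosomes if chrom_ok(c.name)]
        chrom = _pick(rng, chroms)
        homolog = "W" if rng.random() < 0.5 else "Y"
        return apply_aneuploidy(k, chrom.name, mechanism, which_homolog=homolog)

    raise ValueError(f"mechanism {mechanism!r} not simulated")


# ---------------------------------------------------------------------------
# signal synthesis


def copy_number_profile(k: Karyotype) -> pd.DataFrame:
    """Integer per-SNP copies of each parental allele by interval arithmetic.

    Returns a frame with columns ``chromosome, position, W_copies, Y_copies``
    sorted by chromosome order then position.
    """
    genome = k.genome
    frames = []
    for chrom in genome.chromosomes:
        pos = genome.snp_positions(chrom.name)
        w = np.zeros(len(pos), dtype=np.int64)
        y = np.zeros(len(pos), dtype=np.int64)
        for mol in k.molecules:
            for seg in mol.segments:
                if seg.chromosome != chrom.name:
                    continue
                lo = np.searchsorted(pos, seg.start, "left")
                hi = np.searchsorted(pos, seg.end, "right")
                (w if seg.homolog == "W" else y)[lo:hi] += 1
        frames.append(
            pd.DataFrame(
                {
                    "chromosome": chrom.name,
                    "position": pos,
                    "W_copies": w,
                    "Y_copies": y,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def synthesize_snp_counts(
    profile: pd.DataFrame,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw allele read counts from the copy-number profile.

    Counts for an allele at copy number ``c`` are Poisson with mean
    ``mean_depth/2 * c`` (or negative-binomial with the configured
    dispersion).  Output is long-form: one row per (site, parental class).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    depth_per_copy = params.mean_depth / 2.0

    rows = []
    for allele, col in (("W", "W_copies"), ("Y", "Y_copies")):
        mean = depth_per_copy * profile[col].to_numpy(dtype=float)
        if params.depth_noise == "poisson":
            counts = rng.poisson(mean)
        elif params.depth_noise == "negative_binomial":
            size = params.nb_dispersion
            counts = np.where(
                mean > 0,
                rng.negative_binomial(size, size / (size + np.maximum(mean, 1e-12))),
                0,
            )
        else:
            raise ValueError(f"unknown depth noise model {params.depth_noise!r}")
        rows.append(
            pd.DataFrame(
                {
                    "chromosome": profile["chromosome"],
                    "position": profile["position"],
                    "parental_class": allele,
                    "read_count": counts,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    table = table.sort_values(
        ["chromosome", "position", "parental_class"], kind="stable"
    ).reset_index(drop=True)
    return table


@dataclass
class TyReadMatrix:
    """Long-read x diagnostic-SNP call matrix over a hybrid element."""

    positions: np.ndarray  # strictly increasing offsets within the element, bp
    calls: np.ndarray  # (n_reads, n_snps) array of 'A' | 'B' | '.'
    dsb_offset: int
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype="<U1")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.calls.ndim != 2 or self.calls.shape[1] != len(self.positions):
            raise ValueError("calls shape inconsistent with positions")
        if np.any((self.calls != ".").sum(axis=1) == 0):
            raise ValueError("every read needs at least one non-missing call")


def synthesize_ty_reads(
    snp_positions,
    true_tract: tuple[int, int] | None,
    dsb_offset: int,
    n_reads: int,
    miscall: float = 0.0,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> TyReadMatrix:
    """Emulate long reads across a hybrid element.

    SNPs inside ``true_tract`` (inclusive interval of donor-derived offsets)
    come from parent B, the rest from parent A; each call is flipped with
    probability ``miscall`` and dropped with probability ``missing_rate``.
    """
    positions = np.asarray(sorted(snp_positions), dtype=np.int64)
    rng = np.random.default_rng(seed)
    if true_tract is None:
        truth = np.full(len(positions), "A")
    else:
        lo, hi = true_tract
        truth = np.where((positions >= lo) & (positions <= hi), "B", "A")
    flip = {"A": "B", "B": "A"}
    calls = np.empty((n_reads, len(positions)), dtype="<U1")
    for r in range(n_reads):
        while True:
            row = np.array(
                [flip[t] if rng.random() < miscall else t for t in truth], dtype="<U1"
            )
            if missing_rate > 0:
                row[rng.random(len(row)) < missing_rate] = "."
            if (row != ".").sum() > 0:
                break
        calls[r] = row
    return TyReadMatrix(positions=positions, calls=calls, dsb_offset=dsb_offset)


@dataclass
class FluctuationExperiment:
    """Mutant counts from parallel cultures of a fluctuation assay."""

    counts: np.ndarray  # per-culture mutant counts
    n_final: int  # cells per culture at plating

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("mutant counts must be >= 0")
        if self.n_final <= 0:
            raise ValueError("n_final must be > 0")

    @property
    def median_count(self) -> float:
        return float(np.median(self.counts))


def simulate_fluctuation(
    rate_per_division: float,
    n_final: int,
    n_cultures: int,
    seed: int = 0,
) -> FluctuationExperiment:
    """Grow cultures 1 -> ``n_final`` by synchronous doublings.

    At each division a wild-type cell yields one mutant daughter with
    probability ``rate_per_division``; mutant lineages expand clonally.
    ``n_final`` is rounded up to the next power of two if necessary.
    """
    if rate_per_division < 0:
        raise ValueError("rate must be >= 0")
    generations = math.ceil(math.log2(n_final)) if n_final > 1 else 0
    n_t = 2**generations
    if n_t != n_final:
        logger.warning("n_final %d rounded up to 2^%d = %d", n_final, generations, n_t)
    rng = np.random.default_rng(seed)
    n_wt = np.ones(n_cultures, dtype=np.int64)
    n_mut = np.zeros(n_cultures, dtype=np.int64)
    for _ in range(generations):
        new_mut = rng.binomial(n_wt, rate_per_division)
        n_mut = 2 * n_mut + new_mut
        n_wt = 2 * n_wt - new_mut
    return FluctuationExperiment(counts=n_mut, n_final=n_t)


# ---------------------------------------------------------------------------
# serialization


def write_counts_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False,
                 columns=["chromosome", "position", "parental_class", "read_count"])


def read_counts_table(path: str | Path) -> pd.DataFrame:
    try:
        table = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ValueError(f"cannot parse counts table {path}: {exc}") from exc
    required = {"chromosome", "position", "parental_class", "read_count"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = table["read_count"] < 0
    if bad.any():
        line = int(table.index[bad][0]) + 2
        raise ValueError(f"{path} line {line}: negative read count")
    return table


def write_truth(truth: list[TruthEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mechanism\tparticipants\texpected_call_class\t"
                 "expected_calls\tcall_spans\ttrue_breakpoints\n")
        for t in truth:
            fh.write(
                f"{t.mechanism}\t{','.join(t.participants)}\t{t.expected_call_class}\t"
                f"{json.dumps(t.expected_calls)}\t{json.dumps(t.call_spans)}\t"
                f"{json.dumps(t.true_breakpoints)}\n"
            )


def read_truth(path: str | Path) -> list[TruthEvent]:
    out = []
    df = pd.read_csv(path, sep="\t")
    for _, row in df.iterrows():
        participants = str(row["participants"]).split(",") if row["participants"] else []
        out.append(
            TruthEvent(
                mechanism=row["mechanism"],
                participants=participants,
                expected_call_class=row["expected_call_class"],
                expected_calls=[tuple(x) for x in json.loads(row["expected_calls"])],
                call_spans=[
                    [tuple(span) for span in spans]
                    for spans in json.loads(row["call_spans"])
                ],
                true_breakpoints=[tuple(x) for x in json.loads(row["true_breakpoints"])],
            )
        )
    return out


def write_karyotype(k: Karyotype, path: str | Path) -> None:
    payload = {
        "molecules": [
            {
                "name": m.name,
                "circular": m.circular,
                "segments": [
                    {
                        "homolog": s.homolog,
                        "chromosome": s.chromosome,
                        "start": s.start,
                        "end": s.end,
                        "orientation": s.orientation,
                    }
                    for s in m.segments
                ],
            }
            for m in k.molecules
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))
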