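"""Hybrid diploid genome model: chromosomes, heterozygous SNPs and Ty annotations.

The model emulates a diploid formed by crossing two sequence-diverged haploids
(parental classes ``W`` and ``Y``).  The two parental chromosome sets differ in
their transposable-element complement (by default 37 Ty1 + 15 Ty2 on the W
homologs versus 17 Ty1 + 9 Ty2 on the Y homologs) and are heterozygous for a
dense map of single-nucleotide polymorphisms placed outside element spans.

Coordinates are 1-based inclusive internally; BED output is 0-based half-open.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChromosomeDef",
    "TyElement",
    "SnpDef",
    "DiploidGenome",
    "GenomeFormatError",
    "default_hybrid_genome",
    "read_genome",
    "write_genome",
    "CHROMOSOME_NAMES",
]

#: Roman-numeral chromosome labels in karyotype order.
CHROMOSOME_NAMES = (
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII",
    "IX", "X", "XI", "XII", "XIII", "XIV", "XV", "XVI",
)

# (length, cen_start, cen_end) per chromosome, proportioned like the
# S. cerevisiae reference karyotype (~12 Mb per haploid set).
_REFERENCE_KARYOTYPE = {
    "I": (230_218, 151_465, 151_582),
    "II": (813_184, 238_207, 238_323),
    "III": (316_620, 114_385, 114_501),
    "IV": (1_531_933, 449_711, 449_821),
    "V": (576_874, 151_987, 152_104),
    "VI": (270_161, 148_510, 148_627),
    "VII": (1_090_940, 496_920, 497_038),
    "VIII": (562_643, 105_586, 105_703),
    "IX": (439_888, 355_629, 355_745),
    "X": (745_751, 436_307, 436_425),
    "XI": (666_816, 440_129, 440_246),
    "XII": (1_078_177, 150_828, 150_947),
    "XIII": (924_431, 268_031, 268_149),
    "XIV": (784_333, 628_758, 628_875),
    "XV": (1_091_291, 326_584, 326_702),
    "XVI": (948_066, 555_957, 556_073),
}

SOLO_DELTA_LENGTH = 330  # long terminal repeat length, bp
FULL_TY_LENGTH_RANGE = (5_900, 6_300)  # full-length element span, bp
DEFAULT_DSB_OFFSET = 2_180  # cut-site offset from the 5' end of the 5' LTR

_BASES = ("A", "C", "G", "T")


class GenomeFormatError(ValueError):
    """Raised when an on-disk genome file violates the model invariants."""


@dataclass(frozen=True)
class ChromosomeDef:
    """A chromosome with its centromere interval (1-based inclusive)."""

    name: str
    length: int
    centromere_start: int
    centromere_end: int

    def __post_init__(self) -> None:
        if not (0 < self.centromere_start < self.centromere_end <= self.length):
            raise ValueError(
                f"chromosome {self.name}: centromere "
                f"[{self.centromere_start}, {self.centromere_end}] "
                f"inconsistent with length {self.length}"
            )

    @property
    def centromere_mid(self) -> int:
        return (self.centromere_start + self.centromere_end) // 2


@dataclass(frozen=True)
class TyElement:
    """A transposable element (or solo LTR) on one parental homolog."""

    id: str
    family: str  # Ty1 | Ty2 | solo_delta | truncated_Ty1
    orientation: str  # Watson | Crick
    homolog: str  # W | Y
    chromosome: str
    start: int
    end: int
    has_cas9_target: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"element {self.id}: end {self.end} <= start {self.start}")
        if self.family not in {"Ty1", "Ty2", "solo_delta", "truncated_Ty1"}:
            raise ValueError(f"element {self.id}: unknown family {self.family!r}")
        if self.orientation not in {"Watson", "Crick"}:
            raise ValueError(f"element {self.id}: bad orientation {self.orientation!r}")
        if self.homolog not in {"W", "Y"}:
            raise ValueError(f"element {self.id}: bad homolog {self.homolog!r}")
        if self.has_cas9_target and self.family not in {"Ty1", "truncated_Ty1"}:
            raise ValueError(
                f"element {self.id}: cas9 target only valid on Ty1/truncated_Ty1"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def arm(self, chrom: ChromosomeDef) -> str:
        """Chromosome arm: 'L' if left of the centromere, else 'R'."""
        return "L" if self.end < chrom.centromere_start else "R"


@dataclass(frozen=True)
class SnpDef:
    """A heterozygous single-nucleotide polymorphism."""

    chromosome: str
    position: int
    w_allele: str
    y_allele: str

    def __post_init__(self) -> None:
        if self.w_allele == self.y_allele:
            raise ValueError(
                f"SNP {self.chromosome}:{self.position}: alleles must differ"
            )


@dataclass
class DiploidGenome:
    """The full hybrid diploid model consumed by the simulator and callers."""

    chromosomes: list[ChromosomeDef]
    snps: list[SnpDef]
    ty_elements: list[TyElement]
    dsb_offset: int = DEFAULT_DSB_OFFSET

    _chrom_index: dict[str, ChromosomeDef] = field(
        default=None, repr=False, compare=False
    )
    _snp_positions: dict[str, np.ndarray] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        self._chrom_index = {c.name: c for c in self.chromosomes}
        for snp in self.snps:
            chrom = self._chrom_index.get(snp.chromosome)
            if chrom is None:
                raise ValueError(f"SNP references unknown chromosome {snp.chromosome}")
            if not (1 <= snp.position <= chrom.length):
                raise ValueError(
                    f"SNP {snp.chromosome}:{snp.position} outside chromosome"
                )
        for ty in self.ty_elements:
            chrom = self._chrom_index.get(ty.chromosome)
            if chrom is None:
                raise ValueError(f"element {ty.id} on unknown chromosome {ty.chromosome}")
            if ty.end > chrom.length:
                raise ValueError(f"element {ty.id} extends past chromosome end")
        self._snp_positions = None

    # -- lookups ---------------------------------------------------------

    def chromosome(self, name: str) -> ChromosomeDef:
        try:
            return self._chrom_index[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def snp_positions(self, chromosome: str) -> np.ndarray:
        """Sorted SNP positions on a chromosome (cached)."""
        if self._snp_positions is None:
            by_chrom: dict[str, list[int]] = {c.name: [] for c in self.chromosomes}
            for snp in self.snps:
                by_chrom[snp.chromosome].append(snp.position)
            self._snp_positions = {
                name: np.asarray(sorted(pos), dtype=np.int64)
                for name, pos in by_chrom.items()
            }
        return self._snp_positions[chromosome]

    def elements_on(self, homolog: str, chromosome: str | None = None) -> list[TyElement]:
        return [
            t
            for t in self.ty_elements
            if t.homolog == homolog
            and (chromosome is None or t.chromosome == chromosome)
        ]

    def count_snps_between(self, chromosome: str, start: int, end: int) -> int:
        """Number of SNPs with ``start <= pos <= end`` on a chromosome."""
        pos = self.snp_positions(chromosome)
        return int(np.searchsorted(pos, end, "right") - np.searchsorted(pos, start, "left"))


# ---------------------------------------------------------------------------
# construction


def _scaled_karyotype(profile: str) -> list[ChromosomeDef]:
    chroms = []
    for name in CHROMOSOME_NAMES:
        length, cs, ce = _REFERENCE_KARYOTYPE[name]
        if profile == "mini":
            # compress into 100-500 kb while keeping relative proportions
            new_len = max(100_000, min(500_000, round(length / 3)))
            scale = new_len / length
            cs = max(2, round(cs * scale))
            ce = max(cs + 1, round(ce * scale))
            length = new_len
        chroms.append(ChromosomeDef(name, length, cs, ce))
    return chroms


def _place_elements(
    rng: np.random.Generator,
    chroms: Sequence[ChromosomeDef],
    homolog: str,
    n_ty1: int,
    n_ty2: int,
) -> list[TyElement]:
    """Place full-length elements uniformly outside centromeres, non-overlapping."""
    lengths = np.array([c.length for c in chroms], dtype=float)
    placed: dict[str, list[tuple[int, int]]] = {c.name: [] for c in chroms}
    out: list[TyElement] = []
    counters: dict[tuple[str, str], int] = {}
    margin = 5_000  # stay clear of telomeres

    families = ["Ty1"] * n_ty1 + ["Ty2"] * n_ty2
    for fam in families:
        span = int(rng.integers(*FULL_TY_LENGTH_RANGE))
        for _ in range(10_000):
            ci = int(rng.choice(len(chroms), p=lengths / lengths.sum()))
            chrom = chroms[ci]
            lo, hi = margin, chrom.length - span - margin
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            end = start + span - 1
            if start <= chrom.centromere_end and end >= chrom.centromere_start - 1:
                continue  # keep elements off the centromere
            if any(start <= e and end >= s for s, e in placed[chrom.name]):
                continue
            break
        else:  # pragma: no cover - placement virtually never fails
            raise RuntimeError("could not place element")
        placed[chrom.name].append((start, end))
        orientation = "Watson" if rng.random() < 0.5 else "Crick"
        arm = "L" if end < chrom.centromere_start else "R"
        key = (chrom.name + arm, fam)
        counters[key] = counters.get(key, 0) + 1
        ident = (
            f"{homolog}-{chrom.name}{arm}-"
            f"{'W' if orientation == 'Watson' else 'C'}{fam}-{counters[key]}"
        )
        out.append(
            TyElement(
                id=ident,
                family=fam,
                orientation=orientation,
                homolog=homolog,
                chromosome=chrom.name,
                start=start,
                end=end,
                has_cas9_target=(fam == "Ty1"),
            )
        )
    return out


def default_hybrid_genome(
    seed: int,
    n_snps: int = 55_000,
    profile: str = "full",
    w_ty1: int = 37,
    w_ty2: int = 15,
    y_ty1: int = 17,
    y_ty2: int = 9,
) -> DiploidGenome:
    """Build the default hybrid diploid genome.

    Parameters
    ----------
    seed
        Seed for all placement randomness; the result is deterministic per seed.
    n_snps
        Number of heterozygous SNPs placed quasi-uniformly outside element spans.
    profile
        ``"full"`` for reference-scale chromosomes (~12 Mb haploid), ``"mini"``
        for a compressed 16-chromosome test genome (100-500 kb each).
    """
    if n_snps < 0:
        raise ValueError(f"n_snps must be >= 0, got {n_snps}")
    if profile not in {"full", "mini"}:
        raise ValueError(f"unknown profile {profile!r}")
    rng = np.random.default_rng(seed)
    chroms = _scaled_karyotype(profile)

    elements = _place_elements(rng, chroms, "W", w_ty1, w_ty2)
    elements += _place_elements(rng, chroms, "Y", y_ty1, y_ty2)

    # SNPs: quasi-uniform across the genome, rejected from element spans
    # (on either homolog) so dosage signal is never confounded by element copy.
    spans: dict[str, list[tuple[int, int]]] = {c.name: [] for c in chroms}
    for ty in elements:
        spans[ty.chromosome].append((ty.start, ty.end))

    lengths = np.array([c.length for c in chroms], dtype=float)
    total = lengths.sum()
    snps: list[SnpDef] = []
    for ci, chrom in enumerate(chroms):
        quota = int(round(n_snps * chrom.length / total))
        if ci == len(chroms) - 1:
            quota = n_snps - len(snps)
        taken: set[int] = set()
        chrom_spans = sorted(spans[chrom.name])
        while len(taken) < quota:
            need = quota - len(taken)
            cand = rng.integers(1, chrom.length + 1, size=max(2 * need, 16))
            for p in cand:
                p = int(p)
                if p in taken:
                    continue
                if any(s <= p <= e for s, e in chrom_spans):
                    continue
                taken.add(p)
                if len(taken) == quota:
                    break
        for p in sorted(taken):
            w = _BASES[rng.integers(0, 4)]
            y = _BASES[(rng.integers(1, 4) + _BASES.index(w)) % 4]
            snps.append(SnpDef(chrom.name, p, w, y))

    return DiploidGenome(chromosomes=chroms, snps=snps, ty_elements=elements)


# ---------------------------------------------------------------------------
# serialization
#
# chromosomes.tsv : name  length  cen_start  cen_end
# ty.bed          : chrom  start0  end  id  score  strand  homolog  family
# snps.tsv        : chrom  pos  w_allele  y_allele


def write_genome(genome: DiploidGenome, directory: str | Path) -> None:
    """Write a genome to ``chromosomes.tsv``, ``ty.bed`` and ``snps.tsv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    with open(directory / "chromosomes.tsv", "w") as fh:
        fh.write("name\tlength\tcen_start\tcen_end\n")
        for c in genome.chromosomes:
            fh.write(f"{c.name}\t{c.length}\t{c.centromere_start}\t{c.centromere_end}\n")

    with open(directory / "ty.bed", "w") as fh:
        for t in genome.ty_elements:
            strand = "+" if t.orientation == "Watson" else "-"
            # internal 1-based inclusive -> BED 0-based half-open
            fh.write(
                f"{t.chromosome}\t{t.start - 1}\t{t.end}\t{t.id}\t0\t{strand}"
                f"\t{t.homolog}\t{t.family}\n"
            )

    with open(directory / "snps.tsv", "w") as fh:
        fh.write(f"#dsb_offset={genome.dsb_offset}\n")
        fh.write("chrom\tpos\tw_allele\ty_allele\n")
        for s in genome.snps:
            fh.write(f"{s.chromosome}\t{s.position}\t{s.w_allele}\t{s.y_allele}\n")


def read_genome(directory: str | Path) -> DiploidGenome:
    """Read a genome written by :func:`write_genome`; inverse on all fields."""
    directory = Path(directory)

    chroms: list[ChromosomeDef] = []
    chrom_path = directory / "chromosomes.tsv"
    df = pd.read_csv(chrom_path, sep="\t")
    for i, row in df.iterrows():
        try:
            chroms.append(
                ChromosomeDef(
                    str(row["name"]), int(row["length"]),
                    int(row["cen_start"]), int(row["cen_end"]),
                )
            )
        except (ValueError, KeyError) as exc:
            raise GenomeFormatError(f"{chrom_path} line {i + 2}: {exc}") from exc
    known = {c.name for c in chroms}

    elements: list[TyElement] = []
    seen_spans: dict[tuple[str, str], list[tuple[int, int]]] = {}
    bed_path = directory / "ty.bed"
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise GenomeFormatError(f"{bed_path} line {lineno}: expected 8 columns")
            chrom, start0, end, ident, _score, strand, homolog, family = parts[:8]
            try:
                start0, end = int(start0), int(end)
            except ValueError:
                raise GenomeFormatError(
                    f"{bed_path} line {lineno}: malformed coordinates"
                ) from None
            if chrom not in known:
                raise GenomeFormatError(
                    f"{bed_path} line {lineno}: unknown chromosome {chrom!r}"
                )
            if end <= start0:
                raise GenomeFormatError(
                    f"{bed_path} line {lineno}: end {end} <= start {start0}"
                )
            start = start0 + 1  # BED -> 1-based inclusive
            key = (homolog, chrom)
            for s, e in seen_spans.get(key, []):
                if start <= e and end >= s:
                    raise GenomeFormatError(
                        f"{bed_path} line {lineno}: overlapping element span on "
                        f"homolog {homolog} {chrom}"
                    )
            seen_spans.setdefault(key, []).append((start, end))
            try:
                elements.append(
                    TyElement(
                        id=ident,
                        family=family,
                        orientation="Watson" if strand == "+" else "Crick",
                        homolog=homolog,
                        chromosome=chrom,
                        start=start,
                        end=end,
                        has_cas9_target=(family in {"Ty1", "truncated_Ty1"}),
                    )
                )
            except ValueError as exc:
                raise GenomeFormatError(f"{bed_path} line {lineno}: {exc}") from exc

    snp_path = directory / "snps.tsv"
    dsb_offset = DEFAULT_DSB_OFFSET
    with open(snp_path) as fh:
        text = fh.read()
    lines = text.splitlines()
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            body_start += 1
            if line.startswith("#dsb_offset="):
                dsb_offset = int(line.split("=", 1)[1])
        else:
            break
    sdf = pd.read_csv(io.StringIO("\n".join(lines[body_start:])), sep="\t")
    snps: list[SnpDef] = []
    for i, row in sdf.iterrows():
        chrom = str(row["chrom"])
        if chrom not in known:
            raise GenomeFormatError(
                f"{snp_path} line {i + body_start + 2}: unknown chromosome {chrom!r}"
            )
        try:
            snps.append(
                SnpDef(chrom, int(row["pos"]), str(row["w_allele"]), str(row["y_allele"]))
            )
        except ValueError as exc:
            raise GenomeFormatError(
                f"{snp_path} line {i + body_start + 2}: {exc}"
            ) from exc

    try:
        return DiploidGenome(
            chromosomes=chroms, snps=snps, ty_elements=elements, dsb_offset=dsb_offset
        )
    except ValueError as exc:
        raise GenomeFormatError(str(exc)) from exc
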