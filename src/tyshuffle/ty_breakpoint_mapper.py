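"""Map recombination breakpoints inside hybrid elements from long-read evidence.

Each diagnostic SNP column of a read-by-SNP call matrix is assigned to the
parent supported by at least a threshold fraction (default two-thirds) of the
non-missing calls; the donor conversion tract is the run of minority-parent
assignments nearest the cut site, and its sidedness relative to the cut site
suggests the repair mechanism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .synthetic_data import TyReadMatrix

__all__ = [
    "SnpAssignment",
    "TractCall",
    "vote_snps",
    "find_tract",
    "classify_mechanism",
    "write_tract",
    "read_ty_matrix",
    "write_ty_matrix",
]

DEFAULT_THRESHOLD = 2.0 / 3.0


@dataclass(frozen=True)
class SnpAssignment:
    """Per-column parent assignment with its support fraction."""

    position: int
    call: str  # 'A' | 'B' | 'ambiguous'
    support: float


@dataclass
class TractCall:
    """Donor conversion tract and derived mechanism label."""

    transitions: list[tuple[int, int]] = field(default_factory=list)
    tract_span: tuple[int, int] | None = None
    sidedness: str = "none"  # one_sided | two_sided | none
    mechanism: str = "indeterminate"  # BIR_like | DSBR_like | indeterminate


def vote_snps(
    matrix: TyReadMatrix, threshold: float = DEFAULT_THRESHOLD
) -> list[SnpAssignment]:
    """Assign each diagnostic SNP by majority vote over non-missing calls.

    A column is assigned to the parent whose fraction of non-missing calls is
    at least ``threshold`` (closed inequality); otherwise it is ambiguous.  A
    column with no non-missing call is ambiguous with support 0.
    """
    if matrix.calls.shape[0] == 0:
        raise ValueError("empty read matrix")
    out: list[SnpAssignment] = []
    for j, pos in enumerate(matrix.positions):
        col = matrix.calls[:, j]
        n_a = int((col == "A").sum())
        n_b = int((col == "B").sum())
        total = n_a + n_b
        if total == 0:
            out.append(SnpAssignment(int(pos), "ambiguous", 0.0))
            continue
        if n_a >= n_b:
            parent, support = "A", n_a / total
        else:
            parent, support = "B", n_b / total
        if support >= threshold:
            out.append(SnpAssignment(int(pos), parent, support))
        else:
            out.append(SnpAssignment(int(pos), "ambiguous", support))
    return out


def find_tract(assignments: list[SnpAssignment], dsb_offset: int) -> TractCall:
    """Locate the donor tract and the parent-switch transition intervals.

    The donor tract is the maximal run of minority-parent assignments nearest
    the cut site; ambiguous columns are transparent (they neither break nor
    extend runs).  Transition intervals are the gaps between the last SNP of
    one parent run and the first SNP of the next.
    """
    assigned = [a for a in assignments if a.call in {"A", "B"}]
    if not assigned:
        return TractCall()

    # collapse into runs of same-parent assignments (ambiguous skipped)
    runs: list[list[SnpAssignment]] = []
    for a in assigned:
        if runs and runs[-1][-1].call == a.call:
            runs[-1].append(a)
        else:
            runs.append([a])

    transitions = [
        (runs[i][-1].position, runs[i + 1][0].position)
        for i in range(len(runs) - 1)
    ]
    if len(runs) == 1:
        return TractCall(transitions=[], tract_span=None, sidedness="none")

    n_a = sum(len(r) for r in runs if r[0].call == "A")
    n_b = sum(len(r) for r in runs if r[0].call == "B")
    minority = "B" if n_b <= n_a else "A"
    minority_runs = [r for r in runs if r[0].call == minority]

    def distance(run: list[SnpAssignment]) -> int:
        lo, hi = run[0].position, run[-1].position
        if lo <= dsb_offset <= hi:
            return 0
        return min(abs(lo - dsb_offset), abs(hi - dsb_offset))

    tract = min(minority_runs, key=distance)
    span = (tract[0].position, tract[-1].position)
    if span[0] < dsb_offset < span[1]:
        sidedness = "two_sided"
    else:
        sidedness = "one_sided"
    call = TractCall(
        transitions=transitions, tract_span=span, sidedness=sidedness
    )
    call.mechanism = classify_mechanism(call)
    return call


def classify_mechanism(tract: TractCall) -> str:
    """Suggestive repair-pathway label from tract sidedness.

    A conversion tract on both sides of the cut fits double-strand break
    repair; a one-sided tract fits break-induced replication (with the caveat
    that early mismatch correction during strand invasion can mimic either).
    """
    if tract.sidedness == "two_sided":
        return "DSBR_like"
    if tract.sidedness == "one_sided":
        return "BIR_like"
    return "indeterminate"


# ---------------------------------------------------------------------------
# serialization
#
# tymatrix.tsv: first line "#dsb_offset=<bp>", header of SNP offsets, then one
# row per read of calls in {A, B, .}.


def write_ty_matrix(matrix: TyReadMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#dsb_offset={matrix.dsb_offset}\n")
        fh.write("\t".join(str(int(p)) for p in matrix.positions) + "\n")
        for row in matrix.calls:
            fh.write("\t".join(row) + "\n")


def read_ty_matrix(path: str | Path) -> TyReadMatrix:
    lines = Path(path).read_text().splitlines()
    dsb_offset = 0
    body = []
    for line in lines:
        if line.startswith("#dsb_offset="):
            dsb_offset = int(line.split("=", 1)[1])
        elif line.strip():
            body.append(line)
    if not body:
        raise ValueError(f"{path}: no matrix content")
    positions = [int(x) for x in body[0].split("\t")]
    calls = [line.split("\t") for line in body[1:]]
    return TyReadMatrix(
        positions=np.array(positions), calls=np.array(calls), dsb_offset=dsb_offset
    )


def write_tract(
    assignments: list[SnpAssignment], tract: TractCall, path: str | Path
) -> None:
    payload = {
        "assignments": [
            {"position": a.position, "call": a.call, "support": a.support}
            for a in assignments
        ],
        "transitions": [list(t) for t in tract.transitions],
        "tract_span": list(tract.tract_span) if tract.tract_span else None,
        "sidedness": tract.sidedness,
        "mechanism": tract.mechanism,
    }
    Path(path).write_text(json.dumps(payload, indent=1))
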