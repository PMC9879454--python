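"""Per-division event-rate estimation.

Implements the Lea-Coulson method of the median for fluctuation assays,
simple per-isolate event-rate arithmetic, per-base-pair mutation rates, and
fold-change reporting at a fixed number of significant figures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from scipy.optimize import brentq

from .synthetic_data import FluctuationExperiment

__all__ = [
    "RateReport",
    "lea_coulson_m",
    "lea_coulson_median_rate",
    "per_division_rate",
    "mutation_rate_per_bp",
    "fold_change",
    "round_sigfigs",
]

# Lea-Coulson median relation: median/m - ln(m) - 1.24 = 0
_LEA_COULSON_CONST = 1.24


@dataclass(frozen=True)
class RateReport:
    """A rate with its provenance and an optional fold over a reference."""

    rate: float
    numerator: str
    denominator: str
    fold_vs_reference: float | None = None
    below_resolution: bool = False

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")


def lea_coulson_m(median_count: float) -> float:
    """Solve the Lea-Coulson median equation for the expected mutation number m."""
    if median_count < 0:
        raise ValueError("median count must be >= 0")
    if median_count == 0:
        return 0.0

    def f(m: float) -> float:
        return median_count / m - math.log(m) - _LEA_COULSON_CONST

    lo, hi = 1e-12, 1.0
    while f(hi) > 0:  # f is decreasing in m
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover
            raise RuntimeError("failed to bracket root")
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def lea_coulson_median_rate(experiment: FluctuationExperiment) -> RateReport:
    """Per-division mutation rate by the method of the median.

    ``rate = m / N_t`` with m solving ``median/m - ln(m) - 1.24 = 0``.  An
    all-zero median yields rate 0 flagged as below the assay resolution.
    """
    if len(experiment.counts) == 0:
        raise ValueError("need at least one culture")
    median = experiment.median_count
    if median == 0:
        return RateReport(
            rate=0.0,
            numerator="median mutant count 0",
            denominator=f"N_t={experiment.n_final}",
            below_resolution=True,
        )
    m = lea_coulson_m(median)
    return RateReport(
        rate=m / experiment.n_final,
        numerator=f"m={m:.6g} (median {median:g})",
        denominator=f"N_t={experiment.n_final}",
    )


def per_division_rate(n_events: int, n_isolates: int) -> float:
    """Events per cell division assuming one relevant division per isolate."""
    if n_isolates <= 0:
        raise ValueError("n_isolates must be > 0")
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    return n_events / n_isolates

def mutation_rate_per_bp(n_mutations: int, n_isolates: int, genome_bp: float) -> float:
    """Mutations per base pair per division over a cohort of isolates."""
    if genome_bp <= 0:
        raise ValueError("genome_bp must be > 0")
    return per_division_rate(n_mutations, n_isolates) / genome_bp


def round_sigfigs(x: float, sigfigs: int = 2) -> float:
    """Round half-up to a number of significant figures."""
    if x == 0:
        return 0.0
    # pre-round to 12 significant digits so binary float dust (e.g. a ratio
    # landing at 22.499999999999996) does not defeat half-up rounding
    d = Decimal(f"{float(x):.12g}")
    shift = sigfigs - 1 - math.floor(math.log10(abs(x)))
    quantum = Decimal(1).scaleb(-shift)
    return float(d.quantize(quantum, rounding=ROUND_HALF_UP))


def fold_change(rate: float, reference: float, sigfigs: int = 2) -> float:
    """Rate over reference, rounded to ``sigfigs`` significant figures."""
    if reference <= 0:
        raise ValueError("reference rate must be > 0")
    return round_sigfigs(rate / reference, sigfigs)
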