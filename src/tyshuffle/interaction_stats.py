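"""Cohort-level statistics on event tallies.

Expected intra-/inter-chromosomal proportions by exhaustive element-pair
enumeration, Pearson goodness-of-fit, Fisher's exact test (two-sided,
probability-mass convention), a 1-df region over-representation chi-square
with optional Yates correction, and exact two-sided binomial bias tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome_model import DiploidGenome

__all__ = [
    "PairEnumeration",
    "enumerate_pairs",
    "gof_chisq",
    "fisher_2x2",
    "region_chisq",
    "binomial_bias",
]


@dataclass(frozen=True)
class PairEnumeration:
    """Counts and proportions of detectable element pairs by geometry."""

    n_intra: int
    n_inter: int

    @property
    def proportions(self) -> tuple[float, float]:
        total = self.n_intra + self.n_inter
        return self.n_intra / total, self.n_inter / total


def enumerate_pairs(genome: DiploidGenome) -> PairEnumeration:
    """Enumerate detectable Ty1-Ty1 pairs.

    A pair on the same homolog molecule is intrachromosomal-detectable when an
    exchange between the elements changes gene dosage over at least one SNP
    (at least one SNP strictly between the element spans).  A pair on
    non-homologous chromosomes is always interchromosomal-detectable (an
    unbalanced translocation changes terminal dosage).  Pairs on homologous
    chromosomes are allelic and excluded.
    """
    ty1 = [t for t in genome.ty_elements if t.family == "Ty1"]
    if len(ty1) < 2:
        raise ValueError("need at least two Ty1 elements")
    n_intra = n_inter = 0
    for i, a in enumerate(ty1):
        for b in ty1[i + 1 :]:
            if a.chromosome == b.chromosome:
                if a.homolog != b.homolog:
                    continue  # allelic
                lo = min(a.end, b.end) + 1
                hi = max(a.start, b.start) - 1
                if hi >= lo and genome.count_snps_between(a.chromosome, lo, hi) > 0:
                    n_intra += 1
            else:
                n_inter += 1
    if n_intra + n_inter == 0:
        raise ValueError("no detectable pairs")
    return PairEnumeration(n_intra=n_intra, n_inter=n_inter)


def gof_chisq(observed, expected_proportions) -> tuple[float, int, float]:
    """Pearson goodness-of-fit against expected proportions.

    Proportions are renormalized, so scaling them by a constant is harmless.
    Returns ``(statistic, df, upper-tail p)``.
    """
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.shape != props.shape:
        raise ValueError("observed and expected shapes differ")
    props = props / props.sum()
    expected = props * obs.sum()
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    p = float(stats.chi2.sf(statistic, df))
    return statistic, df, p


def fisher_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Uses the probability-mass convention: the p-value sums the probabilities
    of all tables (with the observed margins) whose point probability does
    not exceed that of the observed table.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(p)


def region_chisq(
    n_in: int, n_out: int, expected_fraction: float, continuity: bool = True
) -> tuple[float, float]:
    """1-df chi-square for counts inside/outside a genomic region.

    Compares ``(n_in, n_out)`` against ``N*f`` and ``N*(1-f)``; the Yates
    continuity correction subtracts 0.5 from each absolute deviation.
    """
    if n_in < 0 or n_out < 0:
        raise ValueError("counts must be >= 0")
    if not (0 < expected_fraction < 1):
        raise ValueError("expected_fraction must be in (0, 1)")
    total = n_in + n_out
    expected = np.array([total * expected_fraction, total * (1 - expected_fraction)])
    observed = np.array([n_in, n_out], dtype=float)
    dev = np.abs(observed - expected)
    if continuity:
        dev = np.maximum(dev - 0.5, 0.0)
    statistic = float((dev**2 / expected).sum())
    p = float(stats.chi2.sf(statistic, 1))
    return statistic, p


def binomial_bias(a: int, b: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial test of ``a`` successes in ``a + b`` trials."""
    if a < 0 or b < 0:
        raise ValueError("counts must be >= 0")
    return float(stats.binomtest(a, a + b, p0, alternative="two-sided").pvalue)
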