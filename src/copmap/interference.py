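"""Interference, heterochiasmy and crossover-pathway statistics.

The coefficient of coincidence (CoC) for an interval pair (i, j) is the
observed frequency of gametes with a crossover in both intervals divided by
the product of the single-interval frequencies.  CoC is ~1 without
interference and < 1 when a crossover inhibits nearby doubles; the CoC
curve (mean CoC against inter-interval distance) recovers toward 1 with
distance.  Each chromosome is split into K = 10 equal intervals and
presence/absence per gamete is scored per interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from copmap.io import FocusTable, PopulationCalls
from copmap.layout import GenomeLayout


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of printed summary values;
    Python's round() would round half to even)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CoCMatrix:
    """Coefficient-of-coincidence matrix of one chromosome."""

    chromosome: str
    k: int
    n_gametes: int
    marginal: np.ndarray        # x_i, fraction of gametes with >=1 CO in interval i
    joint: np.ndarray           # x_ij (k x k)
    coc: np.ndarray             # x_ij / (x_i * x_j); NaN where undefined

    def distance_curve(self) -> np.ndarray:
        """Mean CoC over defined pairs at each inter-interval distance d=1..k-1."""
        out = np.full(self.k - 1, np.nan)
        for d in range(1, self.k):
            vals = [
                self.coc[i, i + d]
                for i in range(self.k - d)
                if np.isfinite(self.coc[i, i + d])
            ]
            if vals:
                out[d - 1] = float(np.mean(vals))
        return out


def _presence_matrix(pop: PopulationCalls, chrom: str, length: int, k: int) -> np.ndarray:
    bounds = np.linspace(0, length, k + 1)
    index = {s: i for i, s in enumerate(pop.sample_ids)}
    present = np.zeros((pop.n_gametes, k), dtype=bool)
    for call in pop.calls:
        if call.chromosome != chrom:
            continue
        interval = min(int(np.searchsorted(bounds, call.midpoint, side="right")) - 1, k - 1)
        present[index[call.sample_id], interval] = True
    return present


def coc(pop: PopulationCalls, layout: GenomeLayout, k: int = 10,
        skip_excluded: bool = True) -> list[CoCMatrix]:
    """Per-chromosome CoC matrices over ``k`` equal-length intervals.

    Chromosomes in the layout's excluded-for-interference set are skipped
    (structural rearrangements would bias the statistic).  Pairs with a
    zero marginal are undefined (NaN), never zero-filled.
    """
    if k < 2:
        raise ValueError("need at least 2 intervals")
    out = []
    for chrom, length in layout.chromosomes:
        if skip_excluded and chrom in layout.excluded_for_interference:
            continue
        present = _presence_matrix(pop, chrom, length, k)
        x = present.mean(axis=0)
        joint = (present.astype(float).T @ present.astype(float)) / pop.n_gametes
        expected = np.outer(x, x)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(expected > 0, joint / expected, np.nan)
        np.fill_diagonal(c, np.nan)
        out.append(CoCMatrix(chrom, k, pop.n_gametes, x, joint, c))
    return out


def coc_curve(matrices: list[CoCMatrix]) -> np.ndarray:
    """Genome CoC curve: distance curves averaged over chromosomes
    (each chromosome weighted by its gamete count; identical within one
    population, so effectively a plain mean over defined chromosomes)."""
    if not matrices:
        raise ValueError("no CoC matrices to summarize")
    curves = np.array([m.distance_curve() for m in matrices])
    weights = np.array([m.n_gametes for m in matrices], dtype=float)
    out = np.full(curves.shape[1], np.nan)
    for d in range(curves.shape[1]):
        ok = np.isfinite(curves[:, d])
        if ok.any():
            out[d] = float(np.average(curves[ok, d], weights=weights[ok]))
    return out


def heterochiasmy(female: PopulationCalls, male: PopulationCalls) -> tuple[float, float]:
    """Female/male ratio of mean crossovers per gamete, with the p value of
    a two-sided Mann-Whitney test on the per-gamete counts."""
    f = female.counts_per_gamete()
    m = male.counts_per_gamete()
    ratio = float(f.mean() / m.mean())
    p = float(stats.mannwhitneyu(f, m, alternative="two-sided").pvalue)
    return ratio, p


def ratio_female_male(female_mean: float, male_mean: float) -> float:
    """Heterochiasmy ratio from summary means, at printed precision (2 d.p.)."""
    if male_mean <= 0:
        raise ValueError("male mean must be positive")
    return round_half_away(female_mean / male_mean, 2)


@dataclass
class ClassDecomposition:
    """Split of total genetic crossovers into class I and class II.

    One cytological chiasma (an MLH1/HEI10 co-focus marks a class I one)
    is transmitted to a gamete with probability 1/2, so the expected class I
    crossovers per gamete equal half the mean focus count per meiocyte; the
    excess of the genetic mean over that is the class II estimate.  The
    estimate may come out negative from sampling noise; it is reported
    as-is, never clamped.
    """

    genotype_label: str
    sex: str
    genetic_mean: float
    foci_mean: float
    expected_class1: float
    class2_estimate: float


def decompose_classes(genetic_mean: float, foci: FocusTable) -> ClassDecomposition:
    if len(foci.counts) == 0:
        raise ValueError("empty focus table")
    foci_mean = foci.mean
    expected = foci_mean / 2.0
    class2 = genetic_mean - expected
    if class2 < 0:
        import warnings

        warnings.warn(
            f"negative class II estimate ({class2:.2f}): sampling noise or "
            "unmarked chiasmata", stacklevel=2,
        )
    return ClassDecomposition(
        foci.genotype_label, foci.sex, genetic_mean, foci_mean, expected, class2
    )


def additive_prediction(wt_mean: float, single_means: list[float]) -> float:
    """Predicted mutant-combination mean under additivity: the wild-type
    count plus the gain of each single mutant over wild type."""
    if wt_mean < 0 or any(s < 0 for s in single_means):
        raise ValueError("means must be >= 0")
    return wt_mean + sum(s - wt_mean for s in single_means)


def fold_change(mut_mean: float, wt_mean: float) -> float:
    """Mutant/wild-type fold change at printed precision (1 d.p.)."""
    if wt_mean <= 0:
        raise ValueError("wild-type mean must be positive")
    return round_half_away(mut_mean / wt_mean, 1)
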