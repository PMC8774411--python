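"""Validation statistics for a candidate recessive lethal variant.

Covers the whole downstream evidence chain: the homozygote-deficiency
test (observed vs expected homozygotes of the haplotype), the exact
2x2 association between haplotype status and variant genotype,
Hardy-Weinberg and Mendelian-segregation chi-squares, allele/carrier
frequency, an exact rank-sum test for small phenotype groups (with
midranks for ties), the attributable fraction of juvenile mortality,
and the status-vs-genotype concordance audit.

P-value machinery rides on scipy where scipy implements the exact
definition used here (Poisson/binomial lower tails, the probability-mass
two-sided Fisher rule, the chi-square survival function); the exact
rank-sum distribution is computed by dynamic programming over doubled
midranks because a tie-aware exact enumeration is not available
upstream.  No multiple-testing adjustment is applied anywhere.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .io_formats import HET, HOM_ALT, HOM_REF, MISSING, MatingRecord

logger = logging.getLogger("recleth")


def percent_half_up(x: float) -> int:
    """Round a proportion to the nearest integer percent, halves up."""
    return int(math.floor(x * 100.0 + 0.5))


# ---------------------------------------------------------------------------
# homozygote deficiency
# ---------------------------------------------------------------------------


@dataclass
class DeficiencyResult:
    observed: int
    expected: float
    deficit: float  # (E - O) / E
    p_value: float
    model: str

    def __post_init__(self):
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p_value must lie in (0, 1]")


def deficiency_test(
    observed: int,
    expected: float,
    model: str = "poisson",
    n_trials: int | None = None,
    p_hom: float | None = None,
) -> DeficiencyResult:
    """Lower-tail test of a shortfall of observed homozygotes.

    Under ``model="poisson"`` the number of homozygotes is X ~ Poisson(E)
    and the p-value is P(X <= O).  Under ``model="binomial"`` supply
    ``n_trials`` and ``p_hom``; the p-value is the exact binomial lower
    tail P(X <= O) for X ~ Bin(n_trials, p_hom).  The deficit is
    D = (E - O)/E, the fraction of expected homozygotes that are missing.
    """
    if observed < 0:
        raise ValueError("observed must be >= 0")
    if expected <= 0:
        raise ValueError("expected must be > 0")
    if model == "poisson":
        p = float(sps.poisson.cdf(observed, expected))
    elif model == "binomial":
        if n_trials is None or p_hom is None:
            raise ValueError("binomial model needs n_trials and p_hom")
        p = float(sps.binom.cdf(observed, n_trials, p_hom))
    else:
        raise ValueError(f"unknown model {model!r}")
    return DeficiencyResult(observed, expected, (expected - observed) / expected, p, model)


# ---------------------------------------------------------------------------
# 2x2 exact association
# ---------------------------------------------------------------------------


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Two-sidedness by the probability-mass rule: the sum of hypergeometric
    probabilities (margins fixed) of every table at most as probable as
    the observed one.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer cells")
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


@dataclass
class ContingencyTable:
    """Labelled counts of haplotype status x variant genotype."""

    row_labels: list
    col_labels: list
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


# ---------------------------------------------------------------------------
# Hardy-Weinberg and allele frequency
# ---------------------------------------------------------------------------


@dataclass
class HWEResult:
    n: int
    observed: tuple  # (n_AA, n_Aa, n_aa)
    q_hat: float
    expected: tuple
    chi2: float
    df: int
    p_value: float


def hwe_chisq(counts) -> HWEResult:
    """Pearson chi-square against Hardy-Weinberg proportions.

    The allele frequency q is estimated from the same counts; expectations
    are n(1-q)^2, 2nq(1-q), nq^2; df = 1 (one estimated parameter), no
    continuity correction.  A monomorphic sample gives chi2 = 0, p = 1
    with a warning.
    """
    n_aa_, n_ab, n_bb = (int(c) for c in counts)
    n = n_aa_ + n_ab + n_bb
    if n <= 0:
        raise ValueError("need at least one genotyped individual")
    q = (n_ab + 2 * n_bb) / (2 * n)
    expected = (n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q**2)
    if q in (0.0, 1.0):
        logger.warning("monomorphic sample: HWE test degenerate")
        return HWEResult(n, (n_aa_, n_ab, n_bb), q, expected, 0.0, 1, 1.0)
    chi2 = sum(
        (o - e) ** 2 / e for o, e in zip((n_aa_, n_ab, n_bb), expected) if e > 0
    )
    p = float(sps.chi2.sf(chi2, df=1))
    return HWEResult(n, (n_aa_, n_ab, n_bb), q, expected, float(chi2), 1, p)


@dataclass
class AlleleFrequencyResult:
    n: int
    q_hat: float
    carrier_frequency: float
    q_percent: int
    carrier_percent: int


def allele_frequency(counts) -> AlleleFrequencyResult:
    """Alternate-allele frequency and any-copy carrier frequency from genotype counts."""
    n_aa_, n_ab, n_bb = (int(c) for c in counts)
    n = n_aa_ + n_ab + n_bb
    if n <= 0:
        raise ValueError("need at least one genotyped individual")
    q = (n_ab + 2 * n_bb) / (2 * n)
    carrier = (n_ab + n_bb) / n
    return AlleleFrequencyResult(n, q, carrier, percent_half_up(q), percent_half_up(carrier))


# ---------------------------------------------------------------------------
# Mendelian segregation
# ---------------------------------------------------------------------------

#: offspring genotype distribution (hom_ref, het, hom_alt) by parental pair
MENDELIAN = {
    frozenset([(HOM_REF, HOM_REF)]): (1.0, 0.0, 0.0),
    frozenset([(HOM_ALT, HOM_ALT)]): (0.0, 0.0, 1.0),
    frozenset([(HET, HET)]): (0.25, 0.5, 0.25),
    frozenset([(HOM_REF, HET), (HET, HOM_REF)]): (0.5, 0.5, 0.0),
    frozenset([(HOM_ALT, HET), (HET, HOM_ALT)]): (0.0, 0.5, 0.5),
    frozenset([(HOM_REF, HOM_ALT), (HOM_ALT, HOM_REF)]): (0.0, 1.0, 0.0),
}


def mendelian_probs(sire: str, dam: str) -> tuple:
    for key, probs in MENDELIAN.items():
        if (sire, dam) in key:
            return probs
    raise ValueError(f"unknown parental genotype pair ({sire}, {dam})")


@dataclass
class SegregationResult:
    observed: tuple  # pooled (hom_ref, het, hom_alt)
    expected: tuple
    chi2: float
    df: int
    p_value: float
    n_offspring: int
    n_mendelian_errors: int
    mendelian_errors: list = field(default_factory=list)


def segregation_test(matings: list, df_mode: str = "classes") -> SegregationResult:
    """Pooled observed vs Mendelian-expected offspring genotype counts.

    Expected counts accumulate each genotyped lamb's per-mating Mendelian
    class probabilities.  Offspring whose genotype is impossible given the
    parents are flagged as Mendelian errors and excluded (logged).
    ``df_mode="classes"`` uses df = (#classes with nonzero expectation) - 1;
    ``df_mode="hwe"`` uses df = 1, matching a Hardy-Weinberg-style test on
    the pooled counts.
    """
    if df_mode not in ("classes", "hwe"):
        raise ValueError(f"unknown df_mode {df_mode!r}")
    observed = np.zeros(3)
    expected = np.zeros(3)
    errors = []
    idx = {HOM_REF: 0, HET: 1, HOM_ALT: 2}
    for m in matings:
        probs = mendelian_probs(m.sire_genotype, m.dam_genotype)
        for lamb in m.offspring:
            if lamb.genotype == MISSING:
                continue
            k = idx[lamb.genotype]
            if probs[k] == 0.0:
                errors.append((m.mating_id, lamb.lamb_id, lamb.genotype))
                logger.warning(
                    "Mendelian error: lamb %s genotype %s impossible from %s x %s",
                    lamb.lamb_id, lamb.genotype, m.sire_genotype, m.dam_genotype,
                )
                continue
            observed[k] += 1
            expected += np.asarray(probs)
    n = int(observed.sum())
    if n == 0:
        raise ValueError("no genotyped offspring")
    nonzero = expected > 0
    chi2 = float(((observed[nonzero] - expected[nonzero]) ** 2 / expected[nonzero]).sum())
    df = 1 if df_mode == "hwe" else max(1, int(nonzero.sum()) - 1)
    p = float(sps.chi2.sf(chi2, df=df))
    return SegregationResult(
        tuple(observed.astype(int)), tuple(expected), chi2, df, p, n,
        len(errors), errors,
    )


# ---------------------------------------------------------------------------
# simple rates
# ---------------------------------------------------------------------------


@dataclass
class RateResult:
    successes: int
    trials: int
    proportion: float
    percent: int


def rate(successes: int, trials: int) -> RateResult:
    """Proportion with half-up nearest-percent rounding (e.g. AI success 11/17 -> 65%)."""
    if trials <= 0:
        raise ValueError("trials must be > 0")
    if not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials")
    p = successes / trials
    return RateResult(successes, trials, p, percent_half_up(p))


# ---------------------------------------------------------------------------
# exact rank-sum (Wilcoxon / Mann-Whitney) for small groups
# ---------------------------------------------------------------------------


def wilcoxon_exact(group_a, group_b) -> float:
    """Two-sided exact rank-sum p-value with midranks for ties.

    Enumerates the permutation distribution of the group-A rank sum over
    all C(n_a + n_b, n_a) label assignments by dynamic programming on
    doubled midranks (doubling makes midranks integral).  Two-sided p is
    2 x min(lower tail, upper tail), capped at 1.  Exact mode is limited
    to n_a + n_b <= 25.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    if n > 25:
        raise ValueError("exact mode is limited to n_a + n_b <= 25")
    ranks = sps.rankdata(np.concatenate([a, b]))
    dr = np.rint(2 * ranks).astype(np.int64)  # doubled midranks are integers
    w_obs = int(dr[:n_a].sum())
    total = int(dr.sum())
    # counts[k, s] = number of size-k subsets with doubled-rank sum s
    counts = np.zeros((n_a + 1, total + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in dr:
        # RHS evaluated before assignment: the overlapping slices must not cascade
        counts[1:, r:] = counts[1:, r:] + counts[:-1, : total + 1 - r]
    dist = counts[n_a]
    n_subsets = dist.sum()
    p_low = dist[: w_obs + 1].sum() / n_subsets
    p_high = dist[w_obs:].sum() / n_subsets
    return float(min(1.0, 2.0 * min(p_low, p_high)))


# ---------------------------------------------------------------------------
# attributable mortality
# ---------------------------------------------------------------------------

ROUND_DENOMINATORS = (10, 20, 25, 50, 100)


@dataclass
class MortalityEstimate:
    q: float
    m: float
    fraction_of_deaths: float
    as_percent: int
    as_one_in_n: int


def attributable_mortality(q: float, m: float, denominators=ROUND_DENOMINATORS) -> MortalityEstimate:
    """Share of juvenile deaths attributable to the recessive lethal.

    Assumes Hardy-Weinberg conception frequencies and full juvenile
    lethality of homozygotes: a fraction q^2 of conceptions dies of the
    variant, out of an overall juvenile mortality rate m, so the
    attributable fraction is q^2 / m.  ``as_one_in_n`` reports it as
    "1 in N" with N the nearest round denominator.
    """
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    if not 0 < m <= 1:
        raise ValueError("m must lie in (0, 1]")
    if q * q > m:
        raise ValueError("q^2 > m violates the attribution model")
    frac = q * q / m
    inv = 1.0 / frac
    one_in_n = min(denominators, key=lambda d: (abs(inv - d), d))
    return MortalityEstimate(q, m, frac, percent_half_up(frac), one_in_n)


# ---------------------------------------------------------------------------
# status-vs-genotype concordance audit
# ---------------------------------------------------------------------------

#: expected variant genotype for each haplotype status
EXPECTED_GENOTYPE = {
    "non_carrier": HOM_REF,
    "carrier_het": HET,
    "carrier_hom": HOM_ALT,
}


@dataclass
class AuditResult:
    n: int
    n_discordant: int
    status_noncarrier_genotype_het: int
    status_carrier_genotype_homref: int
    other_discordant: int
    n_missing: int
    discordant_ids: list = field(default_factory=list)


def concordance_audit(cohort: dict) -> AuditResult:
    """Count animals whose haplotype status and variant genotype disagree.

    ``cohort`` maps sample_id -> (haplotype_status, genotype).  The
    expected mapping is non_carrier<->hom_ref, carrier_het<->het,
    carrier_hom<->hom_alt.  The two discordance classes of interest are
    broken out: non-carriers that carry the variant (recombination-
    shortened haplotypes) and haplotype carriers without it (array
    genotyping/phasing error).  Unknown statuses and missing genotypes
    are counted separately, not as discordant.
    """
    n = n_disc = n_missing = cls1 = cls2 = other = 0
    ids = []
    for sample_id, (status, genotype) in cohort.items():
        n += 1
        if status not in EXPECTED_GENOTYPE or genotype == MISSING:
            n_missing += 1
            continue
        if genotype not in (HOM_REF, HET, HOM_ALT):
            raise ValueError(f"invalid genotype {genotype!r} for {sample_id}")
        if genotype == EXPECTED_GENOTYPE[status]:
            continue
        n_disc += 1
        ids.append(sample_id)
        if status == "non_carrier" and genotype == HET:
            cls1 += 1
        elif status in ("carrier_het", "carrier_hom") and genotype == HOM_REF:
            cls2 += 1
        else:
            other += 1
    return AuditResult(n, n_disc, cls1, cls2, other, n_missing, ids)
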