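"""Validation statistics against independent high-precision / enumeration oracles."""

import itertools
import math
from decimal import Decimal, getcontext
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from recleth import (
    MatingRecord,
    PhenotypeRecord,
    allele_frequency,
    attributable_mortality,
    concordance_audit,
    deficiency_test,
    fisher_exact_2x2,
    hwe_chisq,
    mendelian_probs,
    percent_half_up,
    rate,
    segregation_test,
    wilcoxon_exact,
)
from recleth.syndata import (
    SWISS_LACAUNE_COUNTS,
    cohort_as_samples,
    cohort_association_table,
    cohort_genotype_counts,
)

# ---------------------------------------------------------------------------
# homozygote deficiency (Poisson lower tail)
# ---------------------------------------------------------------------------


def poisson_lower_tail_decimal(observed, expected, precision=80):
    """Arbitrary-precision term-by-term summation of the Poisson lower tail."""
    getcontext().prec = precision
    lam = Decimal(str(expected))
    total = Decimal(0)
    term = (-lam).exp()
    for k in range(observed + 1):
        if k > 0:
            term = term * lam / k
        total += term
    return float(total)


def test_deficiency_reproduces_published_screen():
    r = deficiency_test(3, 72.0)
    assert r.deficit == pytest.approx((72 - 3) / 72)
    assert percent_half_up(r.deficit) == 96
    assert r.p_value == pytest.approx(3.5e-27, rel=0.05)
    assert r.p_value == pytest.approx(poisson_lower_tail_decimal(3, 72.0), rel=1e-10)


def test_deficiency_no_deficit_case():
    r = deficiency_test(10, 10.0)
    assert r.deficit == 0.0
    assert r.p_value > 0.5


@pytest.mark.parametrize("seed", range(6))
def test_poisson_tail_matches_high_precision_summation(seed):
    rng = np.random.default_rng(seed)
    for _ in range(10):
        o = int(rng.integers(0, 31))
        e = float(np.round(rng.uniform(0.1, 200.0), 3))
        got = deficiency_test(o, e).p_value
        want = poisson_lower_tail_decimal(o, e)
        assert got == pytest.approx(want, rel=1e-6)  # >= 6 significant digits


def test_poisson_tail_monotone_in_expectation():
    ps = [deficiency_test(5, e).p_value for e in (1.0, 5.0, 20.0, 80.0, 160.0)]
    assert all(a > b for a, b in zip(ps, ps[1:]))


def test_deficiency_binomial_model():
    r = deficiency_test(3, 72.0, model="binomial", n_trials=10_000, p_hom=0.0072)
    want = sum(
        math.comb(10_000, k) * 0.0072**k * (1 - 0.0072) ** (10_000 - k) for k in range(4)
    )
    assert r.p_value == pytest.approx(want, rel=1e-9)


def test_deficiency_input_validation():
    with pytest.raises(ValueError):
        deficiency_test(3, 0.0)
    with pytest.raises(ValueError):
        deficiency_test(-1, 5.0)


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------


def fisher_two_sided_enumeration(table):
    """Exhaustive hypergeometric enumeration with exact rational arithmetic."""
    (a, b), (c, d) = table
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    def prob(x):
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1))
    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs)
    return float(total)


def test_fisher_on_cohort_association_is_extreme():
    table = cohort_association_table()
    assert table.tolist() == [[2540, 3], [9, 399]]
    assert fisher_exact_2x2(table) <= 1e-4


def test_fisher_balanced_unit_table():
    assert fisher_exact_2x2([[1, 0], [0, 1]]) == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(8))
def test_fisher_matches_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    for _ in range(25):
        cells = rng.multinomial(int(rng.integers(4, 41)), [0.25] * 4)
        table = [[int(cells[0]), int(cells[1])], [int(cells[2]), int(cells[3])]]
        got = fisher_exact_2x2(table)
        want = fisher_two_sided_enumeration(table)
        assert 0.0 < got <= 1.0
        assert got == pytest.approx(want, rel=1e-6, abs=1e-12)


def test_fisher_rejects_negative_cells():
    with pytest.raises(ValueError):
        fisher_exact_2x2([[1, -1], [0, 2]])


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------


def test_hwe_on_atrisk_offspring():
    r = hwe_chisq((5, 6, 5))
    assert r.q_hat == 0.5
    assert r.expected == (4.0, 8.0, 4.0)
    assert r.chi2 == pytest.approx(1.0)
    assert round(r.p_value, 3) == 0.317


def test_hwe_departure_in_genotyped_cohort():
    r = hwe_chisq(cohort_genotype_counts())
    assert r.p_value < 0.001


def test_hwe_exact_proportions_give_chi2_zero():
    r = hwe_chisq((25, 50, 25))
    assert r.chi2 == pytest.approx(0.0) and r.p_value == pytest.approx(1.0)


def test_hwe_expected_counts_sum_to_n():
    rng = np.random.default_rng(1)
    for _ in range(20):
        counts = tuple(int(x) for x in rng.integers(0, 500, size=3))
        if sum(counts) == 0:
            continue
        r = hwe_chisq(counts)
        assert sum(r.expected) == pytest.approx(r.n)
        assert r.chi2 >= 0.0


def test_hwe_monomorphic_and_empty():
    r = hwe_chisq((10, 0, 0))
    assert r.chi2 == 0.0 and r.p_value == 1.0
    with pytest.raises(ValueError):
        hwe_chisq((0, 0, 0))


# ---------------------------------------------------------------------------
# allele / carrier frequency
# ---------------------------------------------------------------------------


def test_allele_frequency_of_genotyped_cohort():
    r = allele_frequency(cohort_genotype_counts())
    assert r.q_hat == pytest.approx(410 / 5904)
    assert r.q_percent == 7


def test_allele_frequency_degenerate_and_diversity_panel():
    assert allele_frequency((50, 0, 0)).q_hat == 0.0
    r = allele_frequency(SWISS_LACAUNE_COUNTS)
    assert r.carrier_frequency == pytest.approx(10 / 37)
    with pytest.raises(ValueError):
        allele_frequency((0, 0, 0))


# ---------------------------------------------------------------------------
# Mendelian segregation
# ---------------------------------------------------------------------------


def _mating(i, sire, dam, genotypes):
    return MatingRecord(
        f"M{i}", sire, dam, True, True,
        [PhenotypeRecord(f"M{i}L{j}", "F", g) for j, g in enumerate(genotypes)],
    )


def test_segregation_het_by_het_expected_quarters():
    offspring = ["hom_ref"] * 5 + ["het"] * 6 + ["hom_alt"] * 5
    matings = [_mating(i, "het", "het", [g]) for i, g in enumerate(offspring)]
    r = segregation_test(matings, df_mode="hwe")
    assert r.observed == (5, 6, 5)
    assert r.expected == pytest.approx((4.0, 8.0, 4.0))
    assert r.chi2 == pytest.approx(1.0)
    assert round(r.p_value, 3) == 0.317


def test_segregation_backcross_classes():
    matings = [_mating(0, "het", "hom_ref", ["hom_ref", "het"])]
    r = segregation_test(matings)
    assert r.expected == pytest.approx((1.0, 1.0, 0.0))
    assert r.df == 1  # only two possible classes


def test_segregation_flags_impossible_offspring():
    matings = [_mating(0, "hom_ref", "het", ["hom_alt", "het"])]
    r = segregation_test(matings)
    assert r.n_mendelian_errors == 1
    assert r.observed == (0, 1, 0)


def test_segregation_large_simulation_consistency():
    rng = np.random.default_rng(5)
    genotypes = np.array(["hom_ref", "het", "hom_alt"])[
        rng.choice(3, size=10_000, p=[0.25, 0.5, 0.25])
    ]
    matings = [_mating(0, "het", "het", list(genotypes))]
    r = segregation_test(matings)
    for o, e in zip(r.observed, r.expected):
        assert abs(o - e) < 3 * math.sqrt(e)
    assert r.p_value > 1e-4


def test_mendelian_probs_table():
    assert mendelian_probs("het", "het") == (0.25, 0.5, 0.25)
    assert mendelian_probs("hom_ref", "hom_alt") == (0.0, 1.0, 0.0)
    assert mendelian_probs("het", "hom_ref") == (0.5, 0.5, 0.0)


# ---------------------------------------------------------------------------
# rates
# ---------------------------------------------------------------------------


def test_ai_success_rate_rounding():
    r = rate(11, 17)
    assert r.proportion == pytest.approx(11 / 17)
    assert r.percent == 65
    assert rate(0, 10).percent == 0
    assert rate(1, 8).percent == 13  # 12.5 rounds half-up
    with pytest.raises(ValueError):
        rate(1, 0)
    with pytest.raises(ValueError):
        rate(5, 4)


# ---------------------------------------------------------------------------
# exact rank-sum
# ---------------------------------------------------------------------------


def wilcoxon_enumeration_oracle(a, b):
    """Full enumeration over label assignments, midranks for ties."""
    from scipy.stats import rankdata

    values = list(a) + list(b)
    n_a = len(a)
    ranks = rankdata(values)
    w_obs = sum(ranks[:n_a])
    sums = [sum(ranks[i] for i in comb) for comb in itertools.combinations(range(len(values)), n_a)]
    n = len(sums)
    eps = 1e-9
    p_low = sum(s <= w_obs + eps for s in sums) / n
    p_high = sum(s >= w_obs - eps for s in sums) / n
    return min(1.0, 2.0 * min(p_low, p_high))


def test_wilcoxon_simple_separation():
    assert wilcoxon_exact([1, 2], [3, 4]) == pytest.approx(1 / 3)


def test_wilcoxon_identical_groups():
    assert wilcoxon_exact([5, 5, 5], [5, 5]) == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(8))
def test_wilcoxon_matches_full_enumeration(seed):
    rng = np.random.default_rng(seed)
    n_a, n_b = int(rng.integers(2, 6)), int(rng.integers(2, 6))
    # integer values force ties regularly
    a = list(rng.integers(0, 6, size=n_a))
    b = list(rng.integers(0, 6, size=n_b))
    assert wilcoxon_exact(a, b) == pytest.approx(wilcoxon_enumeration_oracle(a, b))


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    hst.lists(hst.integers(0, 8), min_size=2, max_size=5),
    hst.lists(hst.integers(0, 8), min_size=2, max_size=5),
)
def test_wilcoxon_property_matches_enumeration(a, b):
    """Exact rank-sum p equals full enumeration for arbitrary tied data."""
    assert wilcoxon_exact(a, b) == pytest.approx(wilcoxon_enumeration_oracle(a, b))


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    hst.integers(0, 400), hst.integers(0, 400), hst.integers(0, 400)
)
def test_hwe_invariants_hold_for_arbitrary_counts(n_aa, n_ab, n_bb):
    """Expected counts sum to n; chi2 is zero iff counts sit at HWE proportions."""
    if n_aa + n_ab + n_bb == 0:
        return
    r = hwe_chisq((n_aa, n_ab, n_bb))
    assert sum(r.expected) == pytest.approx(r.n)
    assert r.chi2 >= 0.0
    at_hwe = all(o == pytest.approx(e) for o, e in zip(r.observed, r.expected))
    assert (r.chi2 == pytest.approx(0.0, abs=1e-12)) == at_hwe


def test_wilcoxon_input_limits():
    with pytest.raises(ValueError):
        wilcoxon_exact([], [1.0])
    with pytest.raises(ValueError):
        wilcoxon_exact(list(range(20)), list(range(10)))


# ---------------------------------------------------------------------------
# attributable mortality
# ---------------------------------------------------------------------------


def test_attributable_mortality_headline_estimate():
    r = attributable_mortality(0.06, 0.15)
    assert r.fraction_of_deaths == pytest.approx(0.024)
    assert r.as_percent == 2
    assert r.as_one_in_n == 50


def test_attributable_mortality_scaling_and_validation():
    assert attributable_mortality(0.1, 0.2).fraction_of_deaths == pytest.approx(0.05)
    assert attributable_mortality(0.001, 0.15).fraction_of_deaths < 1e-5
    with pytest.raises(ValueError):
        attributable_mortality(0.5, 0.1)  # q^2 > m
    with pytest.raises(ValueError):
        attributable_mortality(0.0, 0.1)


# ---------------------------------------------------------------------------
# concordance audit
# ---------------------------------------------------------------------------


def test_audit_of_genotyped_cohort():
    r = concordance_audit(cohort_as_samples())
    assert r.n == 2952
    assert r.n_discordant == 12
    assert r.status_noncarrier_genotype_het == 9
    assert r.status_carrier_genotype_homref == 3
    assert r.other_discordant == 0


def test_audit_perfect_cohort_and_missing_handling():
    cohort = {
        "a": ("non_carrier", "hom_ref"),
        "b": ("carrier_het", "het"),
        "c": ("carrier_hom", "hom_alt"),
        "d": ("unknown", "het"),
        "e": ("carrier_het", "missing"),
    }
    r = concordance_audit(cohort)
    assert r.n_discordant == 0
    assert r.n_missing == 2


def test_audit_recovers_injected_errors():
    rng = np.random.default_rng(4)
    cohort = {}
    injected = 0
    for i in range(2000):
        status, geno = ("non_carrier", "hom_ref") if rng.random() < 0.85 else ("carrier_het", "het")
        if rng.random() < 0.01:
            injected += 1
            geno = "het" if geno == "hom_ref" else "hom_ref"
        cohort[f"s{i}"] = (status, geno)
    r = concordance_audit(cohort)
    assert r.n_discordant == injected
    assert r.status_noncarrier_genotype_het + r.status_carrier_genotype_homref == injected
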