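import itertools
import math

import numpy as np
import pytest
from scipy.stats import chi2

from dupepi.genotypes import MISSING, GenotypeMatrix
from dupepi.popgen_stats import (
    _rarefied_allele_count,
    diversity_summary,
    filter_missing,
    fisher_combine,
    hwe_exact_test,
    ld_exact_test,
    rarefaction_sizes,
)
from dupepi.synthetic_data import SimulationConfig, simulate_ssr_dataset

from conftest import make_matrix


# ----------------------------------------------------------------------
# filtering
# ----------------------------------------------------------------------
def grid_matrix(n_ind, n_loci, missing_cells=()):
    cells = [[(100, 105) for _ in range(n_loci)] for _ in range(n_ind)]
    for i, j in missing_cells:
        cells[i][j] = None
    return make_matrix(cells)


def test_filter_strict_inequality_on_locus():
    # locus 0: 2/18 = 11.1% missing -> removed; locus 1: exactly 10% kept
    gm = grid_matrix(20, 3, missing_cells=[(0, 0), (1, 0), (0, 1), (1, 1)])
    # make locus 1 exactly 10%: 2/20
    out, report = filter_missing(gm, locus_threshold=0.10)
    assert report.loci_removed == []  # 2/20 = 10% exactly -> kept
    gm2 = grid_matrix(18, 2, missing_cells=[(0, 0), (1, 0)])
    out2, report2 = filter_missing(gm2)
    assert report2.loci_removed == ["L1"]  # 2/18 = 11.1% > 10%
    assert out2.loci == ["L2"]


def test_filter_individuals_after_loci():
    # individual 0 is missing at the to-be-removed locus only: survives
    gm = grid_matrix(18, 10, missing_cells=[(i, 0) for i in range(3)] + [(0, j) for j in range(1, 4)])
    out, report = filter_missing(gm)
    assert report.loci_removed == ["L1"]
    assert report.individuals_removed == ["ind1"]  # 3/9 = 33% on reduced set
    assert out.n_individuals == 17


def test_filter_identity_without_missing():
    gm = grid_matrix(5, 4)
    out, report = filter_missing(gm)
    assert report.loci_removed == [] and report.individuals_removed == []
    assert np.array_equal(out.data, gm.data)


def test_filter_empty_result_is_error():
    gm = grid_matrix(4, 2, missing_cells=[(i, j) for i in range(4) for j in range(2)][:-1])
    with pytest.raises(ValueError):
        filter_missing(gm)


# ----------------------------------------------------------------------
# HWE exact test
# ----------------------------------------------------------------------
def test_hwe_monomorphic_p_one():
    gm = make_matrix([[(100, 100)]] * 6)
    res = hwe_exact_test(gm, "L1", "pop1", n_perm=10, seed=0)
    assert res.p_value == 1.0 and res.degenerate


def exact_hwe_p_all_het_n5():
    """Full enumeration oracle: n=5 individuals, allele counts (5, 5).

    Tables: (nAA, nAB, nBB) in {(0,5,0), (1,3,1), (2,1,2)} with
    conditional probabilities from Levene's formula.
    """
    def table_prob(naa, nab, nbb):
        n = naa + nab + nbb
        return (
            math.factorial(n)
            * 2**nab
            * math.factorial(5) * math.factorial(5)
            / (math.factorial(naa) * math.factorial(nab) * math.factorial(nbb))
            / math.factorial(2 * n)
        )

    tables = [(0, 5, 0), (1, 3, 1), (2, 1, 2)]
    probs = {t: table_prob(*t) for t in tables}
    assert abs(sum(probs.values()) - 1.0) < 1e-12
    obs = probs[(0, 5, 0)]
    return sum(p for p in probs.values() if p <= obs + 1e-15)


def test_hwe_mc_converges_to_enumeration():
    gm = make_matrix([[(100, 105)]] * 5)  # all heterozygotes
    oracle = exact_hwe_p_all_het_n5()
    res = hwe_exact_test(gm, "L1", "pop1", n_perm=20_000, seed=3)
    # MC error ~ sqrt(p(1-p)/n_perm) ~ 0.003
    assert res.p_value == pytest.approx(oracle, abs=0.02)


def test_hwe_seed_reproducible():
    gm = make_matrix([[(100, 105)], [(100, 100)], [(105, 105)], [(100, 105)]])
    r1 = hwe_exact_test(gm, "L1", "pop1", n_perm=500, seed=42)
    r2 = hwe_exact_test(gm, "L1", "pop1", n_perm=500, seed=42)
    assert r1.p_value == r2.p_value


def test_hwe_too_few_individuals():
    gm = make_matrix([[(100, 105)]])
    with pytest.raises(ValueError, match="typed individuals"):
        hwe_exact_test(gm, "L1", "pop1")


# ----------------------------------------------------------------------
# LD exact test
# ----------------------------------------------------------------------
def _ld_matrix(seed, correlated):
    rng = np.random.default_rng(seed)
    n = 50
    g1 = rng.integers(0, 3, size=n)  # genotype codes 0,1,2 at a biallelic locus
    g2 = g1 if correlated else rng.integers(0, 3, size=n)
    geno = {0: (100, 100), 1: (100, 105), 2: (105, 105)}
    cells = [[geno[g1[i]], geno[g2[i]]] for i in range(n)]
    return make_matrix(cells)


def test_ld_self_pair_significant():
    gm = _ld_matrix(1, correlated=True)
    res = ld_exact_test(gm, "L1", "L2", n_perm=500, seed=0)
    assert res.p_value < 0.01


def test_ld_independent_loci_not_significant_on_average():
    ps = []
    for seed in range(20):
        gm = _ld_matrix(seed, correlated=False)
        ps.append(ld_exact_test(gm, "L1", "L2", n_perm=200, seed=seed).p_value)
    # roughly uniform: mean near 0.5, not clustered near 0
    assert np.mean(ps) > 0.25


def test_fisher_combine_closed_forms():
    x2, df, p = fisher_combine([0.05, 0.05])
    assert x2 == pytest.approx(11.983, abs=1e-3)
    assert df == 4
    assert p == pytest.approx(chi2.sf(11.98293, 4), abs=1e-6)
    assert p == pytest.approx(0.0175, abs=1e-3)


def test_fisher_single_p_identity():
    _, _, p = fisher_combine([0.3])
    assert p == pytest.approx(0.3, abs=1e-12)


def test_fisher_all_ones():
    x2, _, p = fisher_combine([1.0, 1.0, 1.0])
    assert x2 == 0.0 and p == 1.0


def test_fisher_zero_clamped():
    x2, _, p = fisher_combine([0.0, 0.5])
    assert math.isfinite(x2) and 0.0 <= p <= 1.0


# ----------------------------------------------------------------------
# rarefaction
# ----------------------------------------------------------------------
def enumeration_rarefied(counts, g):
    """Oracle: average allele count over all subsamples of size g."""
    pool = list(
        itertools.chain.from_iterable([a] * c for a, c in enumerate(counts))
    )
    subsets = list(itertools.combinations(range(len(pool)), g))
    return np.mean([len({pool[i] for i in sub}) for sub in subsets])


def test_rarefaction_small_case_vs_enumeration():
    counts = np.array([3, 1])
    expected = enumeration_rarefied([3, 1], 2)  # over all C(4,2) subsamples
    assert _rarefied_allele_count(counts, 2) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("counts", [[4, 2, 2], [5, 1], [2, 2, 2, 2]])
def test_rarefaction_vs_enumeration_all_g(counts):
    counts = np.array(counts)
    n = counts.sum()
    for g in range(1, n + 1):
        assert _rarefied_allele_count(counts, g) == pytest.approx(
            enumeration_rarefied(list(counts), g), abs=1e-10
        )


def test_rarefaction_full_sample_equals_observed():
    counts = np.array([3, 2, 1])
    assert _rarefied_allele_count(counts, 6) == 3.0


def test_rarefaction_monotone_in_g():
    counts = np.array([5, 3, 2])
    vals = [_rarefied_allele_count(counts, g) for g in range(1, 11)]
    assert all(b >= a for a, b in zip(vals, vals[1:]))


# ----------------------------------------------------------------------
# diversity summary
# ----------------------------------------------------------------------
def test_unbiased_he_closed_form():
    # one locus, five individuals, allele freqs (0.5, 0.5)
    gm = make_matrix(
        [[(100, 105)], [(100, 105)], [(100, 105)], [(100, 100)], [(105, 105)]]
    )
    s = diversity_summary(gm, "pop1", n_bootstrap=10, seed=0)
    assert s.h_e == pytest.approx((10 / 9) * 0.5, abs=1e-12)


def test_fixed_locus_contributes_zero():
    gm = make_matrix([[(100, 100), (200, 205)]] * 6)
    s = diversity_summary(gm, "pop1", n_bootstrap=10, seed=0)
    # locus 1 contributes H_O = H_E = 0; averages are half the locus-2 values
    assert s.h_o == pytest.approx(0.5)


def test_fis_undefined_when_monomorphic():
    gm = make_matrix([[(100, 100)]] * 5)
    s = diversity_summary(gm, "pop1", n_bootstrap=10, seed=0)
    assert math.isnan(s.f_is)


def test_bootstrap_reproducible_and_ordered():
    cfg = SimulationConfig(n_populations=2, f_is=0.3, missing_rate=0.0, seed=30)
    _, gm = simulate_ssr_dataset(cfg)
    s1 = diversity_summary(gm, "P01", n_bootstrap=200, seed=5)
    s2 = diversity_summary(gm, "P01", n_bootstrap=200, seed=5)
    assert s1.f_is_ci95 == s2.f_is_ci95
    assert s1.f_is_ci95[0] <= s1.f_is_ci95[1]


def test_rarefaction_sizes_are_min_across_pops():
    gm = make_matrix(
        [[(100, 105)], [(100, 100)], [(105, 105)], [None], [(100, 105)]],
        populations=["p1", "p1", "p2", "p2", "p2"],
    )
    assert rarefaction_sizes(gm) == {"L1": 4}  # p1: 4 copies, p2: 4 copies


def test_he_invariant_under_relabeling():
    gm1 = make_matrix([[(100, 105)], [(100, 100)], [(105, 105)]])
    gm2 = make_matrix([[(300, 900)], [(300, 300)], [(900, 900)]])
    s1 = diversity_summary(gm1, "pop1", n_bootstrap=10, seed=0)
    s2 = diversity_summary(gm2, "pop1", n_bootstrap=10, seed=0)
    assert s1.h_e == s2.h_e and s1.h_o == s2.h_o
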