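"""Missing-data filtering, exact tests and per-population diversity summaries.

Hardy-Weinberg and linkage tests are seeded Monte Carlo exact tests;
diversity summaries report observed/unbiased-expected heterozygosity,
rarefied allelic richness and a multilocus F_IS (ratio of means) with
a percentile bootstrap CI over individuals.
"""

from __future__ import annotations

import logging
import math
import sys
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger("dupepi")


# ----------------------------------------------------------------------
# filtering
# ----------------------------------------------------------------------
@dataclass
class FilterReport:
    loci_removed: list[str]
    individuals_removed: list[str]
    locus_threshold: float
    individual_threshold: float


def filter_missing(
    gm: GenotypeMatrix,
    locus_threshold: float = 0.10,
    individual_threshold: float = 0.20,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop loci then individuals with too much missing data.

    Loci strictly above ``locus_threshold`` missing are removed first;
    individuals strictly above ``individual_threshold`` are then judged
    on the reduced locus set.
    """
    miss = gm.missing_mask()
    locus_frac = miss.mean(axis=0)
    keep_loci = np.nonzero(locus_frac <= locus_threshold)[0]
    dropped_loci = [gm.loci[j] for j in np.nonzero(locus_frac > locus_threshold)[0]]
    if keep_loci.size == 0:
        raise ValueError("no loci survive the missing-data filter")
    reduced = miss[:, keep_loci]
    ind_frac = reduced.mean(axis=1)
    keep_ind = np.nonzero(ind_frac <= individual_threshold)[0]
    dropped_ind = [gm.individuals[i] for i in np.nonzero(ind_frac > individual_threshold)[0]]
    if keep_ind.size == 0:
        raise ValueError("no individuals survive the missing-data filter")
    out = gm.subset(keep_ind, keep_loci)
    return out, FilterReport(
        loci_removed=dropped_loci,
        individuals_removed=dropped_ind,
        locus_threshold=locus_threshold,
        individual_threshold=individual_threshold,
    )


# ----------------------------------------------------------------------
# exact tests
# ----------------------------------------------------------------------
@dataclass
class TestResult:
    unit: str
    statistic: float
    p_value: float
    n_permutations: int
    method: str
    degenerate: bool = False


def _genotype_log_prob(pairs: np.ndarray, n_alleles: int) -> float:
    """Log conditional probability of a genotype table given allele counts.

    Levene's formula: P = n! 2^h prod(n_a!) / ((2n)! prod(n_gg!)); the
    terms fixed by the allele counts cancel in comparisons, so only
    h*ln2 - sum(ln n_gg!) is returned.
    """
    codes = pairs[:, 0] * n_alleles + pairs[:, 1]
    counts = np.bincount(codes, minlength=n_alleles * n_alleles)
    h = int((pairs[:, 0] != pairs[:, 1]).sum())
    return h * math.log(2.0) - float(gammaln(counts + 1.0).sum())


def hwe_exact_test(
    gm: GenotypeMatrix,
    locus: str,
    population: str,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """Monte Carlo exact test of Hardy-Weinberg proportions.

    The statistic is the conditional probability of the genotype table
    given the allele counts; the null distribution is generated by
    re-pairing the observed gene copies at random.  The p-value is the
    fraction of shuffled tables at most as probable as the observed
    one, with the (count+1)/(n_perm+1) correction.
    """
    unit = f"{locus}@{population}"
    j = gm.locus_index(locus)
    rows = gm.population_index(population)
    cells = gm.data[rows, j, :]
    cells = cells[(cells != MISSING).all(axis=1)]
    if cells.shape[0] < 2:
        raise ValueError(f"{unit}: need at least 2 typed individuals")
    labels = np.unique(cells)
    if labels.size == 1:
        return TestResult(unit, math.nan, 1.0, 0, "hwe_exact_mc", degenerate=True)
    lut = np.searchsorted(labels, cells)
    n_alleles = labels.size
    obs = _genotype_log_prob(lut, n_alleles)

    rng = np.random.default_rng(seed)
    flat = lut.ravel()
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(flat)
        pairs = np.sort(perm.reshape(-1, 2), axis=1)
        if _genotype_log_prob(pairs, n_alleles) <= obs + 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return TestResult(unit, obs, p, n_perm, "hwe_exact_mc")


def _g_statistic(table: np.ndarray) -> float:
    """Log-likelihood-ratio G for independence in a contingency table."""
    n = table.sum()
    if n == 0:
        return 0.0
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows * cols / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / expected), 0.0)
    return float(2.0 * terms.sum())


def ld_exact_test(
    gm: GenotypeMatrix,
    locus_a: str,
    locus_b: str,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """Permutation test of genotypic linkage disequilibrium.

    Within each population the two-locus genotype contingency table is
    scored with the G statistic and one locus's single-locus genotypes
    are permuted among individuals; per-population p-values are combined
    with Fisher's method.
    """
    ja, jb = gm.locus_index(locus_a), gm.locus_index(locus_b)
    rng = np.random.default_rng(seed)
    pop_ps = []
    g_total = 0.0
    for pop in gm.population_ids():
        rows = gm.population_index(pop)
        ga = gm.data[rows, ja, :]
        gb = gm.data[rows, jb, :]
        typed = (ga != MISSING).all(axis=1) & (gb != MISSING).all(axis=1)
        ga, gb = ga[typed], gb[typed]
        if ga.shape[0] < 2:
            continue
        codes_a = _genotype_codes(ga)
        codes_b = _genotype_codes(gb)
        na, nb = codes_a.max() + 1, codes_b.max() + 1
        if na < 2 or nb < 2:
            continue  # monomorphic in this population: no information
        table = np.zeros((na, nb))
        np.add.at(table, (codes_a, codes_b), 1.0)
        g_obs = _g_statistic(table)
        g_total += g_obs
        count = 0
        for _ in range(n_perm):
            perm_b = rng.permutation(codes_b)
            t = np.zeros((na, nb))
            np.add.at(t, (codes_a, perm_b), 1.0)
            if _g_statistic(t) >= g_obs - 1e-12:
                count += 1
        pop_ps.append((count + 1) / (n_perm + 1))
    unit = f"{locus_a}x{locus_b}"
    if not pop_ps:
        return TestResult(unit, math.nan, 1.0, 0, "ld_exact_mc", degenerate=True)
    _, _, p = fisher_combine(pop_ps)
    return TestResult(unit, g_total, p, n_perm, "ld_exact_mc")


def _genotype_codes(pairs: np.ndarray) -> np.ndarray:
    """Dense integer codes of single-locus genotypes (unordered pairs)."""
    key = pairs[:, 0].astype(np.int64) * 1_000_000 + pairs[:, 1]
    _, codes = np.unique(key, return_inverse=True)
    return codes


def fisher_combine(p_values: list[float]) -> tuple[float, int, float]:
    """Fisher's combined probability: X2 = -2 sum ln p, df = 2k."""
    if not p_values:
        raise ValueError("no p-values to combine")
    ps = np.asarray(p_values, dtype=float)
    if (ps < 0).any() or (ps > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (ps == 0).any():
        logger.warning("fisher_combine: clamping zero p-value(s) to machine minimum")
        ps = np.maximum(ps, sys.float_info.min)
    x2 = float(-2.0 * np.log(ps).sum())
    df = 2 * len(ps)
    return x2, df, float(chi2.sf(x2, df))


# ----------------------------------------------------------------------
# diversity summaries
# ----------------------------------------------------------------------
@dataclass
class DiversitySummary:
    population_id: str
    n_genotyped: int
    pct_missing: float
    n_alleles_observed: int
    pct_total_alleles: float
    allelic_richness: float
    h_o: float
    h_e: float
    f_is: float
    f_is_ci95: tuple[float, float]


def _rarefied_allele_count(counts: np.ndarray, g: int) -> float:
    """Expected allele count in a subsample of g gene copies.

    E[A(g)] = sum_a [1 - C(N - N_a, g) / C(N, g)] with N = sum counts.
    Exact integer combinatorics; g may not exceed N.
    """
    n_tot = int(counts.sum())
    if g > n_tot:
        raise ValueError("rarefaction size exceeds available gene copies")
    denom = math.comb(n_tot, g)
    return float(
        sum(1.0 - math.comb(n_tot - int(c), g) / denom for c in counts if c > 0)
    )


def _per_locus_stats(
    cells: np.ndarray,
) -> tuple[float, float, np.ndarray, int]:
    """(H_O, unbiased H_E, allele counts, typed individuals) for one locus."""
    typed = cells[(cells != MISSING).all(axis=1)]
    n = typed.shape[0]
    if n == 0:
        return math.nan, math.nan, np.array([], dtype=int), 0
    h_o = float((typed[:, 0] != typed[:, 1]).mean())
    alleles = typed.ravel()
    _, counts = np.unique(alleles, return_counts=True)
    c = counts.sum()
    p = counts / c
    h_e = (c / (c - 1)) * (1.0 - float((p**2).sum())) if c > 1 else math.nan
    return h_o, h_e, counts, n


def rarefaction_sizes(gm: GenotypeMatrix) -> dict[str, int]:
    """Per-locus rarefaction size: minimum typed gene copies across populations."""
    sizes = {}
    pops = gm.population_ids()
    for j, locus in enumerate(gm.loci):
        per_pop = []
        for pop in pops:
            rows = gm.population_index(pop)
            cells = gm.data[rows, j, :]
            per_pop.append(int((cells != MISSING).all(axis=1).sum()) * 2)
        sizes[locus] = min(per_pop)
    return sizes


def diversity_summary(
    gm: GenotypeMatrix,
    population: str,
    rarefaction_g: dict[str, int] | None = None,
    n_bootstrap: int = 1000,
    seed: int | None = None,
) -> DiversitySummary:
    """Per-population diversity summary across loci.

    H_E uses the small-sample-unbiased estimator; allelic richness is
    rarefied to ``rarefaction_g`` gene copies per locus (default: the
    minimum typed count across populations, so populations are
    comparable); F_IS = 1 - mean(H_O)/mean(H_E) with a percentile
    bootstrap CI over individuals.
    """
    if rarefaction_g is None:
        rarefaction_g = rarefaction_sizes(gm)
    rows = gm.population_index(population)
    sub = gm.data[rows]
    n_loci = gm.n_loci

    total_alleles = {
        locus: len(gm.allele_counts(locus)) for locus in gm.loci
    }

    h_o_loc, h_e_loc, rich_loc, pct_loc = [], [], [], []
    n_obs_alleles = 0
    for j, locus in enumerate(gm.loci):
        h_o, h_e, counts, n_typed = _per_locus_stats(sub[:, j, :])
        if n_typed == 0:
            continue
        h_o_loc.append(h_o)
        h_e_loc.append(h_e)
        n_obs_alleles += counts.size
        if total_alleles[locus] > 0:
            pct_loc.append(counts.size / total_alleles[locus])
        g = min(rarefaction_g[locus], int(counts.sum()))
        if g >= 1:
            rich_loc.append(_rarefied_allele_count(counts, g))

    miss = (sub == MISSING).all(axis=2)
    n_genotyped = int((~miss).any(axis=1).sum())
    pct_missing = float(miss.mean()) * 100.0

    mean_h_o = float(np.nanmean(h_o_loc)) if h_o_loc else math.nan
    mean_h_e = float(np.nanmean(h_e_loc)) if h_e_loc else math.nan
    f_is = _f_is_from_cells(sub, n_loci)
    if math.isnan(f_is):
        logger.warning("population %s: F_IS undefined (no expected heterozygosity)", population)
        ci = (math.nan, math.nan)
    else:
        ci = _bootstrap_f_is(sub, n_loci, n_bootstrap, seed)
    return DiversitySummary(
        population_id=population,
        n_genotyped=n_genotyped,
        pct_missing=pct_missing,
        n_alleles_observed=n_obs_alleles,
        pct_total_alleles=float(np.mean(pct_loc)) * 100.0 if pct_loc else math.nan,
        allelic_richness=float(np.mean(rich_loc)) if rich_loc else math.nan,
        h_o=mean_h_o,
        h_e=mean_h_e,
        f_is=f_is,
        f_is_ci95=ci,
    )


def _f_is_from_cells(sub: np.ndarray, n_loci: int) -> float:
    """Multilocus F_IS = 1 - mean(H_O)/mean(H_E) over loci with data."""
    h_o_list, h_e_list = [], []
    for j in range(n_loci):
        h_o, h_e, _, n_typed = _per_locus_stats(sub[:, j, :])
        if n_typed and not math.isnan(h_e):
            h_o_list.append(h_o)
            h_e_list.append(h_e)
    if not h_e_list:
        return math.nan
    mean_h_e = float(np.mean(h_e_list))
    if mean_h_e == 0.0:
        return math.nan
    return 1.0 - float(np.mean(h_o_list)) / mean_h_e


def _bootstrap_f_is(
    sub: np.ndarray, n_loci: int, n_bootstrap: int, seed: int | None
) -> tuple[float, float]:
    """Percentile 95% CI for F_IS, resampling individuals with replacement."""
    rng = np.random.default_rng(seed)
    n = sub.shape[0]
    stats = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        stats[b] = _f_is_from_cells(sub[idx], n_loci)
    stats = stats[~np.isnan(stats)]
    if stats.size == 0:
        return (math.nan, math.nan)
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return (float(lo), float(hi))
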