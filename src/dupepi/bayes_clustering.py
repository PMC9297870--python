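"""Simplified admixture-model Gibbs sampler, run alignment and Evanno ΔK.

The sampler is a desk-scale stand-in for full structure-style MCMC:
cluster allele frequencies P and individual admixture proportions Q
get Dirichlet full-conditional updates, allele-origin indicators Z are
sampled per gene copy, missing alleles are skipped, and the model
evidence proxy is mean(lnL) - var(lnL)/2 over post-burn-in sweeps.
Label switching across runs is resolved by permutation search
maximizing the G' similarity (exhaustive for K <= 8, greedy beyond).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger("dupepi")


@dataclass
class ClusterRunResult:
    K: int
    Q: np.ndarray  # (n_individuals, K) posterior-mean admixture
    log_likelihood_trace: np.ndarray
    L_estimate: float
    seed: int | None
    burn_in: int
    n_sweeps: int

    def __post_init__(self) -> None:
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("Q rows must sum to 1")
        if not math.isfinite(self.L_estimate):
            raise ValueError("L_estimate must be finite")


def _encode_observations(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Flatten typed gene copies to (ind_idx, locus_idx, allele_idx) arrays."""
    ind_idx, loc_idx, all_idx = [], [], []
    n_alleles = np.zeros(gm.n_loci, dtype=int)
    for j in range(gm.n_loci):
        cells = gm.data[:, j, :]
        labels = np.unique(cells[cells != MISSING])
        n_alleles[j] = max(labels.size, 1)
        lut = {int(lab): k for k, lab in enumerate(labels)}
        for i in range(gm.n_individuals):
            for c in (0, 1):
                a = cells[i, c]
                if a != MISSING:
                    ind_idx.append(i)
                    loc_idx.append(j)
                    all_idx.append(lut[int(a)])
    return (
        np.asarray(ind_idx),
        np.asarray(loc_idx),
        np.asarray(all_idx),
        n_alleles,
    )


def run_admixture(
    gm: GenotypeMatrix,
    K: int,
    burn_in: int = 5_000,
    n_sweeps: int = 20_000,
    alpha: float = 1.0,
    lam: float = 1.0,
    seed: int | None = None,
    init_by_population: bool = False,
) -> ClusterRunResult:
    """One Gibbs run of the admixture model at a fixed K.

    ``n_sweeps`` counts post-burn-in sweeps (the recorded run length).
    ``init_by_population`` seeds Q from population labels — a weak
    substitute for location-aware priors, off by default.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > gm.n_individuals:
        raise ValueError("K exceeds the number of individuals")
    rng = np.random.default_rng(seed)
    ind_idx, loc_idx, all_idx, n_alleles = _encode_observations(gm)
    n_obs = ind_idx.size
    n_ind, n_loci = gm.n_individuals, gm.n_loci
    a_max = int(n_alleles.max())
    valid = np.zeros((n_loci, a_max), dtype=bool)
    for j in range(n_loci):
        valid[j, : n_alleles[j]] = True

    if init_by_population and K > 1:
        pops = gm.population_ids()
        q = np.full((n_ind, K), 0.1 / max(K - 1, 1))
        for i, p in enumerate(gm.populations):
            q[i, pops.index(p) % K] = 0.9
        q /= q.sum(axis=1, keepdims=True)
    else:
        q = rng.dirichlet(np.full(K, alpha), size=n_ind)
    p = np.full((K, n_loci, a_max), 1.0 / a_max)
    for k in range(K):
        for j in range(n_loci):
            p[k, j, : n_alleles[j]] = rng.dirichlet(np.full(n_alleles[j], lam))
            p[k, j, n_alleles[j]:] = 0.0

    total = burn_in + n_sweeps
    trace = np.empty(total)
    q_accum = np.zeros((n_ind, K))
    lnl_post = np.empty(n_sweeps)

    for sweep in range(total):
        # z | q, p  — per gene copy
        w = q[ind_idx, :] * p[:, loc_idx, all_idx].T  # (n_obs, K)
        row_sum = w.sum(axis=1)
        trace[sweep] = float(np.log(row_sum).sum())
        if K == 1:
            z = np.zeros(n_obs, dtype=int)
        else:
            cdf = np.cumsum(w, axis=1)
            u = rng.random(n_obs) * row_sum
            z = (u[:, None] > cdf).sum(axis=1)
            np.minimum(z, K - 1, out=z)

        # q | z  — Dirichlet(alpha + per-individual origin counts)
        counts_q = np.zeros((n_ind, K))
        np.add.at(counts_q, (ind_idx, z), 1.0)
        g = rng.gamma(alpha + counts_q)
        q = g / g.sum(axis=1, keepdims=True)

        # p | z  — Dirichlet(lambda + per-cluster allele counts)
        counts_p = np.zeros((K, n_loci, a_max))
        np.add.at(counts_p, (z, loc_idx, all_idx), 1.0)
        g = rng.gamma(lam + counts_p) * valid[None, :, :]
        g_sum = g.sum(axis=2, keepdims=True)
        g_sum[g_sum == 0] = 1.0
        p = g / g_sum

        if sweep >= burn_in:
            q_accum += q
            lnl_post[sweep - burn_in] = trace[sweep]

    q_mean = q_accum / n_sweeps
    q_mean /= q_mean.sum(axis=1, keepdims=True)
    l_est = float(lnl_post.mean() - lnl_post.var() / 2.0)
    return ClusterRunResult(
        K=K,
        Q=q_mean,
        log_likelihood_trace=trace,
        L_estimate=l_est,
        seed=seed,
        burn_in=burn_in,
        n_sweeps=n_sweeps,
    )


# ----------------------------------------------------------------------
# label alignment across runs
# ----------------------------------------------------------------------
def _similarity(qa: np.ndarray, qb: np.ndarray) -> float:
    """G' = 1 - ||Qa - Qb||_F / sqrt(2n)."""
    n = qa.shape[0]
    return 1.0 - float(np.linalg.norm(qa - qb)) / math.sqrt(2.0 * n)


def _best_permutation(reference: np.ndarray, q: np.ndarray) -> tuple[int, ...]:
    k = q.shape[1]
    if k <= 8:
        best, best_sim = None, -np.inf
        for perm in itertools.permutations(range(k)):
            sim = _similarity(reference, q[:, perm])
            if sim > best_sim:
                best, best_sim = perm, sim
        assert best is not None
        return best
    # greedy for large K: columns matched by descending correlation
    taken: set[int] = set()
    perm = [0] * k
    scores = reference.T @ q  # (k_ref, k)
    for ref_col in np.argsort(-scores.max(axis=1)):
        col = int(
            max(
                (c for c in range(k) if c not in taken),
                key=lambda c: scores[ref_col, c],
            )
        )
        perm[ref_col] = col
        taken.add(col)
    return tuple(perm)


def align_runs(runs: list[ClusterRunResult]) -> np.ndarray:
    """Align cluster labels across runs and return the mean Q matrix.

    The first run is the reference; each subsequent run is permuted to
    maximize G' similarity with the running mean of aligned runs.
    """
    if not runs:
        raise ValueError("no runs to align")
    ks = {r.K for r in runs}
    if len(ks) > 1:
        raise ValueError(f"runs have differing K: {sorted(ks)}")
    aligned = [runs[0].Q]
    for run in runs[1:]:
        reference = np.mean(aligned, axis=0)
        perm = _best_permutation(reference, run.Q)
        aligned.append(run.Q[:, perm])
    return np.mean(aligned, axis=0)


# ----------------------------------------------------------------------
# Evanno ΔK
# ----------------------------------------------------------------------
@dataclass
class EvannoRow:
    K: int
    n_runs: int
    mean_L: float
    sd_L: float
    L_prime: float | None
    L_double_prime_abs: float | None
    delta_K: float | None


def evanno(runs: list[ClusterRunResult]) -> list[EvannoRow]:
    """Evanno table over a contiguous K range.

    L'(K) = mean_L(K) - mean_L(K-1); |L''(K)| = |L'(K+1) - L'(K)|;
    ΔK = |L''(K)| / sd_L(K).  ΔK is undefined at the endpoints and
    infinite (with a warning) when sd_L is zero.
    """
    by_k: dict[int, list[float]] = {}
    for r in runs:
        by_k.setdefault(r.K, []).append(r.L_estimate)
    ks = sorted(by_k)
    if len(ks) < 3:
        raise ValueError("Evanno needs at least 3 consecutive K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError(f"K values must be contiguous, got {ks}")
    if any(len(v) < 2 for v in by_k.values()):
        raise ValueError("Evanno needs at least 2 runs per K")
    mean_l = {k: float(np.mean(by_k[k])) for k in ks}
    sd_l = {k: float(np.std(by_k[k], ddof=1)) for k in ks}
    l_prime = {k: mean_l[k] - mean_l[k - 1] for k in ks[1:]}
    out = []
    for k in ks:
        lp = l_prime.get(k)
        if k == ks[0] or k == ks[-1]:
            ldp, dk = None, None
        else:
            ldp = abs(l_prime[k + 1] - l_prime[k])
            if sd_l[k] == 0.0:
                logger.warning("evanno: sd_L = 0 at K=%d, ΔK infinite", k)
                dk = math.inf
            else:
                dk = ldp / sd_l[k]
        out.append(
            EvannoRow(
                K=k,
                n_runs=len(by_k[k]),
                mean_L=mean_l[k],
                sd_L=sd_l[k],
                L_prime=lp,
                L_double_prime_abs=ldp,
                delta_K=dk,
            )
        )
    return out


def best_k(rows: list[EvannoRow]) -> int:
    """K with the largest ΔK among interior rows."""
    interior = [r for r in rows if r.delta_K is not None]
    if not interior:
        raise ValueError("no interior K with a defined ΔK")
    return max(interior, key=lambda r: r.delta_K).K
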