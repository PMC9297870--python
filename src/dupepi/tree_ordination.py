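"""Prevosti distances, neighbour-joining with locus bootstrap, and PCA.

Distances are computed between populations from per-locus allele
frequencies (missing data handled by per-locus renormalization over
typed copies).  Neighbour joining follows the Saitou-Nei Q-criterion
with deterministic tie-breaking and negative branch lengths clamped to
zero.  Bootstrap supports resample loci with replacement.
"""

from __future__ import annotations

import logging

import numpy as np

from .genotypes import MISSING, AlleleFreqTable, GenotypeMatrix, allele_frequencies
from .trees import TreeNode

logger = logging.getLogger("dupepi")


# ----------------------------------------------------------------------
# Prevosti distance
# ----------------------------------------------------------------------
def _per_locus_contributions(
    f: AlleleFreqTable,
) -> tuple[np.ndarray, np.ndarray]:
    """(L, P, P) per-locus summed |p_x - p_y| and (L, P) typed indicators."""
    n_pop = len(f.populations)
    n_loci = len(f.loci)
    diff = np.zeros((n_loci, n_pop, n_pop))
    typed = np.zeros((n_loci, n_pop), dtype=bool)
    for j in range(n_loci):
        fr = f.freqs[j]
        typed[j] = f.copies[j] > 0
        diff[j] = np.abs(fr[:, None, :] - fr[None, :, :]).sum(axis=2)
    return diff, typed


def _distance_matrix_from_contributions(
    diff: np.ndarray, typed: np.ndarray, locus_idx: np.ndarray
) -> np.ndarray:
    both = typed[locus_idx][:, :, None] & typed[locus_idx][:, None, :]
    n_shared = both.sum(axis=0)
    if (n_shared == 0).any():
        raise ValueError("population pair with no shared typed locus")
    total = (diff[locus_idx] * both).sum(axis=0)
    d = total / (2.0 * n_shared)
    np.fill_diagonal(d, 0.0)
    return d


def prevosti_distance_matrix(f: AlleleFreqTable) -> np.ndarray:
    """Pairwise Prevosti distance: (1/2L) sum over loci/alleles of |p_x - p_y|."""
    diff, typed = _per_locus_contributions(f)
    return _distance_matrix_from_contributions(
        diff, typed, np.arange(len(f.loci))
    )


def prevosti_distance(f: AlleleFreqTable, x: str, y: str) -> float:
    """Prevosti distance between two populations (in [0, 1])."""
    ix, iy = f.populations.index(x), f.populations.index(y)
    return float(prevosti_distance_matrix(f)[ix, iy])


# ----------------------------------------------------------------------
# neighbour joining
# ----------------------------------------------------------------------
def neighbor_joining(d: np.ndarray, labels: list[str]) -> TreeNode:
    """Saitou-Nei neighbour joining on a symmetric distance matrix.

    Ties in the Q-criterion are broken by the lowest (row, column) pair
    in the current node ordering; negative branch lengths are clamped
    to zero.  Returns an unrooted tree represented with a trifurcating
    root.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    nodes = [TreeNode(name=lab) for lab in labels]
    active = list(range(n))
    dm = d.copy()

    while len(active) > 3:
        m = len(active)
        sub = dm[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # argmin scans row-major: first occurrence = lowest index pair
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        a, b = active[i], active[j]
        parent = TreeNode(children=[nodes[a], nodes[b]])
        nodes[a].length = li
        nodes[b].length = lj
        nodes.append(parent)
        new_idx = len(nodes) - 1
        # distances from the new node to every other active node
        new_row = np.zeros(new_idx)
        for k in active:
            if k in (a, b):
                continue
            new_row[k] = 0.5 * (dm[a, k] + dm[b, k] - dij)
        dm = np.pad(dm, ((0, 1), (0, 1)))
        dm[new_idx, :new_idx] = new_row
        dm[:new_idx, new_idx] = new_row
        active = [k for k in active if k not in (a, b)] + [new_idx]

    a, b, c = active
    dab, dac, dbc = dm[a, b], dm[a, c], dm[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    nodes[a].length = max(la, 0.0)
    nodes[b].length = max(lb, 0.0)
    nodes[c].length = max(lc, 0.0)
    return root


def bootstrap_tree(
    f: AlleleFreqTable, n_reps: int = 1000, seed: int | None = None
) -> TreeNode:
    """NJ tree on the full data with locus-bootstrap support percentages.

    Loci are resampled with replacement; the support of each internal
    bipartition of the main tree is the percentage of replicate trees
    containing it.
    """
    n_loci = len(f.loci)
    diff, typed = _per_locus_contributions(f)
    all_loci = np.arange(n_loci)
    main = neighbor_joining(
        _distance_matrix_from_contributions(diff, typed, all_loci), f.populations
    )
    if n_loci == 1:
        logger.warning("bootstrap over a single locus: supports are trivially 100")
    parts = main.bipartitions()
    hits = {p: 0 for p in parts}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        sample = rng.integers(0, n_loci, size=n_loci)
        rep_d = _distance_matrix_from_contributions(diff, typed, sample)
        rep_tree = neighbor_joining(rep_d, f.populations)
        for p in rep_tree.bipartitions():
            if p in hits:
                hits[p] += 1
    for p, h in hits.items():
        node = main.find_clade(p)
        if node is not None:
            node.support = 100.0 * h / n_reps
    return main


# ----------------------------------------------------------------------
# PCA
# ----------------------------------------------------------------------
def allele_count_matrix(gm: GenotypeMatrix) -> tuple[np.ndarray, list[str]]:
    """Individuals x allele-dosage matrix (0/1/2; NaN where untyped)."""
    cols: list[str] = []
    blocks: list[np.ndarray] = []
    for j, locus in enumerate(gm.loci):
        cells = gm.data[:, j, :]
        labels = np.unique(cells[cells != MISSING])
        miss = (cells == MISSING).all(axis=1)
        for lab in labels:
            dose = (cells == lab).sum(axis=1).astype(float)
            dose[miss] = np.nan
            blocks.append(dose)
            cols.append(f"{locus}.{int(lab)}")
    return np.column_stack(blocks), cols


def pca_individuals(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """PCA of individual allele dosages.

    Missing cells are imputed with the column mean; columns are
    centered but not scaled.  Returns (coordinates, percent variance
    per axis); percentages sum to 100 over all axes.
    """
    if gm.n_individuals < 2:
        raise ValueError("PCA needs at least 2 individuals")
    x, _ = allele_count_matrix(gm)
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    idx = np.where(np.isnan(x))
    x[idx] = col_mean[idx[1]]
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    coords = u * s
    var = s**2
    total = var.sum()
    pct = 100.0 * var / total if total > 0 else np.zeros_like(var)
    return coords, pct
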