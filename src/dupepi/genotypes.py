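"""Core genotype containers shared across the SSR analysis stack.

A :class:`GenotypeMatrix` stores two integer allele labels per
individual x locus cell (``MISSING`` for untyped cells) and is the
substrate of every downstream population-genetic computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel allele code for an untyped cell.
MISSING: int = -1


@dataclass
class GenotypeMatrix:
    """Individuals x loci matrix of unordered diploid allele-label pairs.

    Parameters
    ----------
    individuals
        Individual identifiers, one per row.
    populations
        Population identifier of each individual (parallel to
        ``individuals``).
    loci
        Locus identifiers, one per column.
    data
        Integer array of shape ``(n_individuals, n_loci, 2)``.  Allele
        labels are non-negative integers; ``MISSING`` marks untyped
        cells.  Pairs are stored sorted so homozygotes are identical
        pairs and unordered comparisons are cheap.
    """

    individuals: list[str]
    populations: list[str]
    loci: list[str]
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int64)
        n_ind, n_loc = len(self.individuals), len(self.loci)
        if self.data.shape != (n_ind, n_loc, 2):
            raise ValueError(
                f"data shape {self.data.shape} does not match "
                f"({n_ind}, {n_loc}, 2)"
            )
        if len(self.populations) != n_ind:
            raise ValueError("populations must be parallel to individuals")
        # normalize: a missing half-call contaminates the whole cell,
        # and pairs are kept sorted
        half_missing = (self.data == MISSING).any(axis=2)
        self.data[half_missing] = MISSING
        self.data = np.sort(self.data, axis=2)

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci) array, True where untyped."""
        return (self.data == MISSING).all(axis=2)

    def population_index(self, population: str) -> np.ndarray:
        idx = np.asarray(
            [i for i, p in enumerate(self.populations) if p == population]
        )
        if idx.size == 0:
            raise KeyError(f"unknown population {population!r}")
        return idx

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def population_ids(self) -> list[str]:
        """Unique population identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def subset(
        self,
        individual_idx: np.ndarray | list[int] | None = None,
        locus_idx: np.ndarray | list[int] | None = None,
    ) -> "GenotypeMatrix":
        ii = np.arange(self.n_individuals) if individual_idx is None else np.asarray(individual_idx)
        li = np.arange(self.n_loci) if locus_idx is None else np.asarray(locus_idx)
        return GenotypeMatrix(
            individuals=[self.individuals[i] for i in ii],
            populations=[self.populations[i] for i in ii],
            loci=[self.loci[j] for j in li],
            data=self.data[np.ix_(ii, li)].copy(),
        )

    def allele_counts(self, locus: str, population: str | None = None) -> dict[int, int]:
        """Counts of each allele label at ``locus`` (optionally one population)."""
        j = self.locus_index(locus)
        rows = (
            np.arange(self.n_individuals)
            if population is None
            else self.population_index(population)
        )
        alleles = self.data[rows, j, :].ravel()
        alleles = alleles[alleles != MISSING]
        labels, counts = np.unique(alleles, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


@dataclass
class AlleleFreqTable:
    """Per-population allele frequencies, one block per locus.

    ``freqs[j]`` is an ``(n_populations, n_alleles_j)`` matrix of
    frequencies over the allele labels ``alleles[j]``; rows of typed
    populations sum to one (missing data excluded by per-locus
    renormalization).  ``copies[j]`` holds the typed gene-copy count
    per population, so zero-copy populations are distinguishable from
    monomorphic ones.
    """

    populations: list[str]
    loci: list[str]
    alleles: list[np.ndarray]
    freqs: list[np.ndarray]
    copies: list[np.ndarray]

    def frequency(self, population: str, locus: str, allele: int) -> float:
        p = self.populations.index(population)
        j = self.loci.index(locus)
        hits = np.nonzero(self.alleles[j] == allele)[0]
        return float(self.freqs[j][p, hits[0]]) if hits.size else 0.0


def allele_frequencies(gm: GenotypeMatrix) -> AlleleFreqTable:
    """Tabulate per-population allele frequencies from a genotype matrix."""
    pops = gm.population_ids()
    pop_rows = [gm.population_index(p) for p in pops]
    alleles: list[np.ndarray] = []
    freqs: list[np.ndarray] = []
    copies: list[np.ndarray] = []
    for j in range(gm.n_loci):
        col = gm.data[:, j, :]
        observed = np.unique(col[col != MISSING])
        alleles.append(observed)
        f = np.zeros((len(pops), observed.size))
        c = np.zeros(len(pops))
        for p, rows in enumerate(pop_rows):
            a = col[rows].ravel()
            a = a[a != MISSING]
            c[p] = a.size
            if a.size:
                counts = np.array([(a == lab).sum() for lab in observed], dtype=float)
                f[p] = counts / a.size
        freqs.append(f)
        copies.append(c)
    return AlleleFreqTable(
        populations=pops, loci=list(gm.loci), alleles=alleles, freqs=freqs, copies=copies
    )
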