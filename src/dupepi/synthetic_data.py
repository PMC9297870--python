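"""Synthetic qPCR panels and SSR datasets with known ground truth.

The generator produces (a) copy-number states and Ct panels for the
four duplication genotype classes, inverting the comparative-Ct
transform so that noiseless panels round-trip exactly; and (b) SSR
genotypes under an island model: ancestral allele frequencies per
locus are Dirichlet(1,...,1), population frequencies follow the
Balding-Nichols parameterization at a chosen F_ST, and genotypes are
drawn with an inbreeding coefficient F_IS (probability F_IS of an
autozygous draw).  Everything is reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .io_formats import REGIONS, FragmentTable, PanelTable, PopulationMetadata

GENOTYPE_CLASSES = ("A", "B", "C", "S")

#: MGE copies per haploid genome in the susceptible baseline.
SUSCEPTIBLE_MGE_RANGE = (4.0, 6.0)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic-data generator.

    Defaults mirror the survey design being emulated: ~tens of
    populations of 9-18 individuals, 10 pentanucleotide SSR loci,
    weak structure, moderate inbreeding.
    """

    n_populations: int = 6
    individuals_per_population: tuple[int, int] = (9, 18)
    n_loci: int = 10
    motif_length: int = 5
    f_st: float = 0.05
    f_is: float = 0.2
    missing_rate: float = 0.02
    region_genotype_mix: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "Central Great Plains": {"A": 0.7, "B": 0.1, "C": 0.0, "S": 0.2},
            "Northern Plains": {"A": 0.0, "B": 0.7, "C": 0.2, "S": 0.1},
            "Pacific Northwest": {"A": 0.0, "B": 0.0, "C": 0.7, "S": 0.3},
        }
    )
    ct_noise_sd: float = 0.15
    size_noise_sd: float = 0.3
    n_alleles_range: tuple[int, int] = (4, 8)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.f_st < 1.0):
            raise ValueError("f_st must lie in (0, 1)")
        if not (0.0 <= self.f_is < 1.0):
            raise ValueError("f_is must lie in [0, 1)")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must be a probability")
        for region, mix in self.region_genotype_mix.items():
            if any(v < 0 for v in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"genotype mix for {region!r} must be a distribution")


@dataclass
class TrueState:
    """Ground truth for one simulated individual's qPCR block."""

    individual_id: str
    population_id: str
    genotype: str
    epsps_cn: float
    type1_cn: float
    type2_cn: float
    mge_cn: float


# ----------------------------------------------------------------------
# copy numbers and Ct panels
# ----------------------------------------------------------------------
def simulate_copy_numbers(
    genotype: str, rng: np.random.Generator
) -> tuple[float, float, float, float]:
    """Draw (epsps, type1, type2, mge) copies for one genotype class.

    Class S has exactly one EPSPS copy and no repeat markers; classes
    B and C lack both repeat markers; class A always has type I above
    type II.  MGE in classes C and S stays in the susceptible baseline
    range.
    """
    u = rng.uniform
    if genotype == "A":
        e = u(4.0, 12.0)
        t1 = e * u(0.9, 1.3)
        t2 = e * u(0.3, 0.5)
        mge = 2.0 * e + u(*SUSCEPTIBLE_MGE_RANGE)
    elif genotype == "B":
        e = u(4.0, 30.0)
        t1 = t2 = 0.0
        mge = 1.5 * e + u(*SUSCEPTIBLE_MGE_RANGE)
    elif genotype == "C":
        e = u(2.0, 8.0)
        t1 = t2 = 0.0
        mge = u(*SUSCEPTIBLE_MGE_RANGE)
    elif genotype == "S":
        e = 1.0
        t1 = t2 = 0.0
        mge = u(*SUSCEPTIBLE_MGE_RANGE)
    else:
        raise ValueError(f"unknown genotype class {genotype!r}")
    return e, t1, t2, mge


def copy_numbers_to_ct(
    states: list[TrueState],
    ct_noise_sd: float = 0.15,
    n_replicates: int = 1,
    rng: np.random.Generator | None = None,
) -> PanelTable:
    """Invert the comparative-Ct transform: true copies -> Ct panel.

    Per individual, the reference Ct is Normal(22, 0.5); a marker with
    c > 0 true copies gets Ct = Ct_ref - log2(c) plus replicate noise;
    c = 0 yields a no-amplification row.
    """
    rng = rng or np.random.default_rng()
    rows = []
    for st in states:
        ct_als = rng.normal(22.0, 0.5)
        markers = {
            "EPSPS": st.epsps_cn,
            "TypeI": st.type1_cn,
            "TypeII": st.type2_cn,
            "MGE": st.mge_cn,
        }
        for rep in range(1, n_replicates + 1):
            rows.append((st.individual_id, st.population_id, "ALS", ct_als, rep))
            for marker, c in markers.items():
                if c <= 0:
                    ct = np.nan
                else:
                    ct = ct_als - np.log2(c) + (
                        rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                    )
                rows.append((st.individual_id, st.population_id, marker, ct, rep))
    df = pd.DataFrame(
        rows, columns=["individual", "population", "marker", "ct", "replicate"]
    )
    return PanelTable(df)


def simulate_panel_dataset(
    cfg: SimulationConfig, seed: int | None = None, n_replicates: int = 1
) -> tuple[PanelTable, list[TrueState], PopulationMetadata]:
    """Simulate a full survey panel: metadata, truth and Ct table.

    Populations are assigned round-robin to the regions present in the
    genotype mix; individuals draw their class from the regional mix.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    regions = [r for r in REGIONS if r in cfg.region_genotype_mix]
    states: list[TrueState] = []
    meta_rows = []
    lo, hi = cfg.individuals_per_population
    for p in range(cfg.n_populations):
        region = regions[p % len(regions)]
        pop_id = f"P{p + 1:02d}"
        meta_rows.append((pop_id, region, np.nan, np.nan, "R"))
        mix = cfg.region_genotype_mix[region]
        probs = np.array([mix.get(g, 0.0) for g in GENOTYPE_CLASSES])
        n_ind = int(rng.integers(lo, hi + 1))
        classes = rng.choice(len(GENOTYPE_CLASSES), size=n_ind, p=probs)
        for i, ci in enumerate(classes):
            g = GENOTYPE_CLASSES[ci]
            e, t1, t2, mge = simulate_copy_numbers(g, rng)
            states.append(
                TrueState(
                    individual_id=f"{pop_id}_{i + 1:03d}",
                    population_id=pop_id,
                    genotype=g,
                    epsps_cn=e,
                    type1_cn=t1,
                    type2_cn=t2,
                    mge_cn=mge,
                )
            )
    panel = copy_numbers_to_ct(
        states, ct_noise_sd=cfg.ct_noise_sd, n_replicates=n_replicates, rng=rng
    )
    meta = PopulationMetadata(
        pd.DataFrame(
            meta_rows,
            columns=["population", "region", "latitude", "longitude", "resistance_status"],
        )
    )
    return panel, states, meta


# ----------------------------------------------------------------------
# SSR genotypes
# ----------------------------------------------------------------------
def _balding_nichols_freqs(
    ancestral: np.ndarray, f_st: float, n_populations: int, rng: np.random.Generator
) -> np.ndarray:
    """Population frequencies around an ancestral vector at a given F_ST.

    Dirichlet with concentration p * (1 - F) / F — the multi-allele
    Balding-Nichols parameterization; F -> 0 recovers the ancestral
    frequencies.
    """
    conc = ancestral * (1.0 - f_st) / f_st
    gamma = rng.gamma(np.broadcast_to(conc, (n_populations, conc.size)))
    # guard against all-zero draws at tiny concentrations
    gamma = np.where(gamma.sum(axis=1, keepdims=True) == 0, ancestral, gamma)
    return gamma / gamma.sum(axis=1, keepdims=True)


def simulate_ssr_dataset(
    cfg: SimulationConfig, seed: int | None = None
) -> tuple[FragmentTable, GenotypeMatrix]:
    """Simulate fragment sizes plus the true binned genotype matrix.

    Allele labels of the truth matrix are exact integer fragment sizes
    ``locus_offset + motif * repeat_count`` so binned calls are directly
    comparable.  Fragment sizes add Normal(0, size_noise_sd) bp noise;
    cells go missing i.i.d. at ``missing_rate``.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_pop, n_loci, m = cfg.n_populations, cfg.n_loci, cfg.motif_length
    lo, hi = cfg.individuals_per_population
    pop_sizes = rng.integers(lo, hi + 1, size=n_pop)
    pop_ids = [f"P{p + 1:02d}" for p in range(n_pop)]

    individuals: list[str] = []
    populations: list[str] = []
    for pop_id, n_ind in zip(pop_ids, pop_sizes):
        for i in range(int(n_ind)):
            individuals.append(f"{pop_id}_{i + 1:03d}")
            populations.append(pop_id)
    n_total = len(individuals)
    pop_of = np.repeat(np.arange(n_pop), pop_sizes)

    data = np.full((n_total, n_loci, 2), MISSING, dtype=np.int64)
    frag_rows = []
    for j in range(n_loci):
        n_alleles = int(rng.integers(cfg.n_alleles_range[0], cfg.n_alleles_range[1] + 1))
        base_repeat = int(rng.integers(8, 20))
        locus_offset = int(rng.integers(100, 350))
        labels = np.array(
            [locus_offset + m * (base_repeat + a) for a in range(n_alleles)]
        )
        ancestral = rng.dirichlet(np.ones(n_alleles))
        pop_freqs = _balding_nichols_freqs(ancestral, cfg.f_st, n_pop, rng)

        # inbreeding: with prob f_is the two gene copies are identical by descent
        auto = rng.random(n_total) < cfg.f_is
        cum = np.cumsum(pop_freqs, axis=1)

        def draw() -> np.ndarray:
            # categorical draw per individual from its population's frequencies
            u = rng.random(n_total)[:, None]
            return np.minimum((u > cum[pop_of]).sum(axis=1), n_alleles - 1)
        a1 = draw()
        a2 = np.where(auto, a1, draw())
        alleles = np.sort(np.stack([a1, a2], axis=1), axis=1)
        typed = rng.random(n_total) >= cfg.missing_rate
        data[typed, j, 0] = labels[alleles[typed, 0]]
        data[typed, j, 1] = labels[alleles[typed, 1]]

        sizes = labels[alleles].astype(float)
        if cfg.size_noise_sd > 0:
            sizes = sizes + rng.normal(0.0, cfg.size_noise_sd, size=sizes.shape)
        for i in range(n_total):
            if typed[i]:
                frag_rows.append(
                    (individuals[i], populations[i], f"SSR{j + 1}", sizes[i, 0], sizes[i, 1])
                )
            else:
                frag_rows.append(
                    (individuals[i], populations[i], f"SSR{j + 1}", np.nan, np.nan)
                )

    frag = FragmentTable(
        pd.DataFrame(
            frag_rows, columns=["individual", "population", "locus", "size1", "size2"]
        )
    )
    loci = [f"SSR{j + 1}" for j in range(n_loci)]
    truth = GenotypeMatrix(individuals, populations, loci, data)
    return frag, truth
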