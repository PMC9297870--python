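"""Rule-based duplication-genotype classification (A/B/C/S).

The decision cascade, applied to a copy-number profile:

1. EPSPS copy number at or below the increase threshold -> S.
2. Otherwise both repeat markers present (type I and type II > 0) -> A.
3. Otherwise MGE at or above the increase threshold -> B.
4. Otherwise -> C.

Repeat-marker presence takes precedence over the MGE rule, and
single-copy individuals are decided first regardless of MGE, so
high-MGE susceptibles stay S.  Profiles violating the expected
co-occurrence patterns are classified by the cascade but carry QC
flags rather than being rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .io_formats import PopulationMetadata
from .qpcr_quant import CopyNumberProfile

GENOTYPES = ("A", "B", "C", "S")

#: QC flag names
DISCORDANT_REPEATS = "discordant_repeat_markers"
ATYPICAL_LOW_MGE_A = "atypical_low_MGE_A"
HIGH_MGE_SUSCEPTIBLE = "high_MGE_susceptible"


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds (defaults are the published values)."""

    epsps_increased: float = 1.4
    mge_increased: float = 10.0
    repeat_present: float = 0.0

    def __post_init__(self) -> None:
        if self.epsps_increased <= 0 or self.mge_increased <= 0:
            raise ValueError("thresholds must be positive")
        if self.repeat_present < 0:
            raise ValueError("repeat_present must be non-negative")


@dataclass(frozen=True)
class DuplicationCall:
    individual_id: str
    population_id: str
    genotype: str
    flags: frozenset[str] = frozenset()


@dataclass
class PopulationGenotypeSummary:
    """Per-population marker means/SEs and genotype proportions."""

    population_id: str
    region: str
    n: int
    means: dict[str, float]
    ses: dict[str, float]  # NaN when n == 1
    proportions: dict[str, float]  # keys A, B, C, S; sums to 1

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"genotype proportions sum to {total}, not 1")


@dataclass
class RegionSummary:
    region: str
    n: int
    proportions: dict[str, float]
    present: frozenset[str] = field(default_factory=frozenset)


def classify(profile: CopyNumberProfile, thresholds: Thresholds = Thresholds()) -> DuplicationCall:
    """Assign a duplication genotype to one copy-number profile."""
    e, t1, t2, mge = (
        profile.epsps_cn,
        profile.type1_cn,
        profile.type2_cn,
        profile.mge_cn,
    )
    if min(e, t1, t2, mge) < 0:
        raise ValueError("copy numbers must be non-negative")
    th = thresholds
    t1_present = t1 > th.repeat_present
    t2_present = t2 > th.repeat_present
    flags: set[str] = set()
    if t1_present != t2_present:
        flags.add(DISCORDANT_REPEATS)

    if e <= th.epsps_increased:
        genotype = "S"
        if mge >= th.mge_increased:
            flags.add(HIGH_MGE_SUSCEPTIBLE)
    elif t1_present and t2_present:
        genotype = "A"
        if mge < th.mge_increased:
            flags.add(ATYPICAL_LOW_MGE_A)
    elif mge >= th.mge_increased:
        genotype = "B"
    else:
        genotype = "C"
    return DuplicationCall(
        individual_id=profile.individual_id,
        population_id=profile.population_id,
        genotype=genotype,
        flags=frozenset(flags),
    )


def summarize_population(
    profiles: list[CopyNumberProfile],
    calls: list[DuplicationCall],
    meta: PopulationMetadata,
) -> list[PopulationGenotypeSummary]:
    """Aggregate calls and profiles into per-population summaries.

    Means are arithmetic; SE uses the n-1 denominator and is NaN for
    n = 1; proportions are genotype call frequencies.
    """
    by_pop: dict[str, tuple[list[CopyNumberProfile], list[DuplicationCall]]] = {}
    call_by_ind = {c.individual_id: c for c in calls}
    for p in profiles:
        by_pop.setdefault(p.population_id, ([], []))
        by_pop[p.population_id][0].append(p)
        by_pop[p.population_id][1].append(call_by_ind[p.individual_id])

    out = []
    for pop, (profs, pop_calls) in by_pop.items():
        if pop not in meta:
            raise KeyError(f"population {pop!r} absent from metadata")
        n = len(profs)
        means, ses = {}, {}
        for marker in ("EPSPS", "TypeI", "TypeII", "MGE"):
            vals = [p.marker(marker) for p in profs]
            mean = sum(vals) / n
            means[marker] = mean
            if n == 1:
                ses[marker] = math.nan
            else:
                var = sum((v - mean) ** 2 for v in vals) / (n - 1)
                ses[marker] = math.sqrt(var / n)
        proportions = {
            g: sum(c.genotype == g for c in pop_calls) / n for g in GENOTYPES
        }
        out.append(
            PopulationGenotypeSummary(
                population_id=pop,
                region=meta.region_of(pop),
                n=n,
                means=means,
                ses=ses,
                proportions=proportions,
            )
        )
    return out


def summarize_region(
    summaries: list[PopulationGenotypeSummary],
) -> list[RegionSummary]:
    """Pool population summaries into per-region proportions (n-weighted)."""
    by_region: dict[str, list[PopulationGenotypeSummary]] = {}
    for s in summaries:
        by_region.setdefault(s.region, []).append(s)
    out = []
    for region, group in by_region.items():
        n_total = sum(s.n for s in group)
        pooled = {
            g: sum(s.n * s.proportions[g] for s in group) / n_total for g in GENOTYPES
        }
        present = frozenset(g for g in GENOTYPES if pooled[g] > 0)
        out.append(
            RegionSummary(region=region, n=n_total, proportions=pooled, present=present)
        )
    return out
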