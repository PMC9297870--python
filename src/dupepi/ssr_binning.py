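"""Fragment-size allele binning onto a fixed-motif ladder.

Raw capillary sizes at a microsatellite locus are fit to a ladder of
rungs ``offset + k * motif``: the offset is chosen on a grid over
[0, motif) to minimize the total squared residual, each size is
assigned to its nearest rung, and sizes further than ``tolerance``
from any rung are flagged off-ladder.  Rungs are fixed-width at exact
motif spacing — a deliberate simplification that is adequate when
adjacent alleles differ by a full motif (e.g. 5 bp for
pentanucleotide loci).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeMatrix
from .io_formats import FragmentTable

logger = logging.getLogger("dupepi")

DEFAULT_GRID_STEP = 0.1
DEFAULT_TOLERANCE = 1.0


@dataclass
class AlleleBinMap:
    """Fitted ladder for one locus.

    ``bins`` maps repeat index k -> (integer bp label, member count).
    Labels are ``round(offset + k * motif)`` and strictly increase
    with k.
    """

    locus_id: str
    offset: float
    motif: int
    tolerance: float
    bins: dict[int, tuple[int, int]]

    def label_of(self, size: float) -> int:
        """Bin label for a size; MISSING when off-ladder."""
        k = int(round((size - self.offset) / self.motif))
        rung = self.offset + k * self.motif
        if abs(size - rung) > self.tolerance:
            return MISSING
        return int(round(rung))


def fit_bins(
    sizes: list[float],
    motif: int,
    grid_step: float = DEFAULT_GRID_STEP,
    tolerance: float = DEFAULT_TOLERANCE,
    locus_id: str = "",
) -> AlleleBinMap:
    """Fit a ladder to observed fragment sizes at one locus.

    The offset grid covers [0, motif) at ``grid_step``; the objective
    is the summed squared distance of each size to its nearest rung.
    """
    s = np.asarray([x for x in sizes if np.isfinite(x)], dtype=float)
    if s.size == 0:
        raise ValueError(f"locus {locus_id!r}: no sizes to bin")
    if motif < 2:
        raise ValueError("motif must be at least 2 bp")
    offsets = np.arange(0.0, motif, grid_step)
    # residual of size x to nearest rung of ladder with offset o is the
    # centered remainder of (x - o) mod motif
    rem = np.mod(s[None, :] - offsets[:, None] + motif / 2.0, motif) - motif / 2.0
    best = int(np.argmin((rem**2).sum(axis=1)))
    offset = float(offsets[best])

    k = np.round((s - offset) / motif).astype(int)
    resid = s - (offset + k * motif)
    on_ladder = np.abs(resid) <= tolerance
    if not on_ladder.any():
        raise ValueError(f"locus {locus_id!r}: all sizes off-ladder at tolerance {tolerance}")
    n_off = int((~on_ladder).sum())
    if n_off:
        logger.warning("locus %s: %d off-ladder size(s) set missing", locus_id, n_off)
    bins: dict[int, tuple[int, int]] = {}
    for ki in sorted(set(k[on_ladder].tolist())):
        label = int(round(offset + ki * motif))
        bins[ki] = (label, int((k[on_ladder] == ki).sum()))
    return AlleleBinMap(
        locus_id=locus_id, offset=offset, motif=motif, tolerance=tolerance, bins=bins
    )


def fit_all_bins(
    frag: FragmentTable,
    motif: int,
    grid_step: float = DEFAULT_GRID_STEP,
    tolerance: float = DEFAULT_TOLERANCE,
) -> dict[str, AlleleBinMap]:
    """Fit a bin map for every locus of a fragment table."""
    maps = {}
    for locus, block in frag.df.groupby("locus", sort=False):
        sizes = np.concatenate(
            [block["size1"].dropna().to_numpy(), block["size2"].dropna().to_numpy()]
        )
        maps[str(locus)] = fit_bins(
            list(sizes), motif, grid_step=grid_step, tolerance=tolerance, locus_id=str(locus)
        )
    return maps


def build_genotype_matrix(
    frag: FragmentTable,
    bin_maps: dict[str, AlleleBinMap],
    single_peak: str = "homozygote",
) -> GenotypeMatrix:
    """Bin every fragment-table cell into a genotype matrix.

    ``single_peak`` controls cells with exactly one present size:
    "homozygote" (default fragment-analysis convention) duplicates the
    present allele, "missing" drops the cell.
    """
    if single_peak not in ("homozygote", "missing"):
        raise ValueError("single_peak must be 'homozygote' or 'missing'")
    df = frag.df
    for locus in df["locus"].unique():
        if str(locus) not in bin_maps:
            raise KeyError(f"no bin map for locus {locus!r}")
    individuals: list[str] = []
    populations: list[str] = []
    for ind, pop in zip(df["individual"], df["population"]):
        if ind not in individuals:
            individuals.append(str(ind))
            populations.append(str(pop))
    loci = [str(x) for x in dict.fromkeys(df["locus"])]
    ind_ix = {v: k for k, v in enumerate(individuals)}
    loc_ix = {v: k for k, v in enumerate(loci)}
    data = np.full((len(individuals), len(loci), 2), MISSING, dtype=np.int64)
    for row in df.itertuples(index=False):
        i, j = ind_ix[str(row.individual)], loc_ix[str(row.locus)]
        bm = bin_maps[str(row.locus)]
        labels = []
        for size in (row.size1, row.size2):
            if size is None or not np.isfinite(size):
                labels.append(MISSING)
            else:
                labels.append(bm.label_of(float(size)))
        a, b = labels
        if a == MISSING and b == MISSING:
            continue
        if a == MISSING or b == MISSING:
            present = a if a != MISSING else b
            if single_peak == "homozygote":
                data[i, j] = (present, present)
            # else stays MISSING
        else:
            data[i, j] = (a, b)
    return GenotypeMatrix(individuals, populations, loci, data)
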