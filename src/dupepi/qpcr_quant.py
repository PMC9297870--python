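"""Relative copy-number quantification from qPCR Ct values.

Copies per haploid genome are obtained by the comparative-Ct method
against the single-copy reference marker (ALS), assuming perfect
doubling per cycle: copies = 2^(Ct_reference - Ct_target).  Technical
replicates are averaged on the Ct scale before transformation.  An
optional calibrator with known copy number rescales estimates
(comparative ΔΔCt); by default raw ΔCt values are returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .io_formats import PanelTable, is_no_amp

TARGET_MARKERS = ("EPSPS", "TypeI", "TypeII", "MGE")


@dataclass(frozen=True)
class CopyNumberProfile:
    """Relative marker copies of one individual (haploid-genome scale).

    Non-amplifying markers are exactly 0 — a definite absence, not a
    missing value, because the genotype cascade tests ``> 0``.
    """

    individual_id: str
    population_id: str
    epsps_cn: float
    type1_cn: float
    type2_cn: float
    mge_cn: float

    def __post_init__(self) -> None:
        for f in (self.epsps_cn, self.type1_cn, self.type2_cn, self.mge_cn):
            if not math.isfinite(f) or f < 0:
                raise ValueError("copy numbers must be finite and non-negative")

    def marker(self, name: str) -> float:
        return {
            "EPSPS": self.epsps_cn,
            "TypeI": self.type1_cn,
            "TypeII": self.type2_cn,
            "MGE": self.mge_cn,
        }[name]


def delta_ct(ct_target: float, ct_reference: float) -> float:
    """Relative copies of a target marker vs the reference.

    A non-amplifying target maps to exactly 0 copies.  A non-amplifying
    reference invalidates the run and raises.
    """
    if is_no_amp(ct_reference) or not math.isfinite(ct_reference):
        raise ValueError("reference Ct did not amplify: run invalid")
    if is_no_amp(ct_target):
        return 0.0
    return 2.0 ** (ct_reference - ct_target)


def _mean_ct(values: list[float]) -> float:
    """Average replicate Ct values; all-NO_AMP collapses to NO_AMP."""
    finite = [v for v in values if not is_no_amp(v)]
    if not finite:
        return math.nan
    return sum(finite) / len(finite)


def quantify_panel(
    panel: PanelTable,
    calibration: dict[str, tuple[str, float]] | None = None,
) -> list[CopyNumberProfile]:
    """Quantify every individual of a panel.

    Parameters
    ----------
    panel
        Ct table with an ALS row per (individual, replicate) block.
    calibration
        Optional per-marker calibrator: ``{marker: (individual_id, known_copies)}``.
        Estimates for that marker are rescaled by
        ``known_copies / calibrator_estimate`` (ΔΔCt).  Without it raw
        ΔCt values are returned.
    """
    df = panel.df
    profiles: dict[str, dict[str, float]] = {}
    pops: dict[str, str] = {}
    for ind, block in df.groupby("individual", sort=False):
        pops[ind] = block["population"].iloc[0]
        ct_by_marker = {
            m: _mean_ct(list(sub["ct"])) for m, sub in block.groupby("marker")
        }
        ref = ct_by_marker.get("ALS", math.nan)
        if is_no_amp(ref):
            raise ValueError(f"individual {ind!r}: ALS reference did not amplify")
        est = {
            m: delta_ct(ct_by_marker.get(m, math.nan), ref) for m in TARGET_MARKERS
        }
        profiles[ind] = est

    if calibration:
        for marker, (cal_id, known) in calibration.items():
            if cal_id not in profiles:
                raise ValueError(f"calibrator individual {cal_id!r} absent from panel")
            cal_est = profiles[cal_id][marker]
            if cal_est == 0 and known > 0:
                raise ValueError(
                    f"calibrator estimate for {marker} is 0 but known copies {known} > 0"
                )
            if known > 0:
                factor = known / cal_est
                for est in profiles.values():
                    est[marker] *= factor

    return [
        CopyNumberProfile(
            individual_id=ind,
            population_id=pops[ind],
            epsps_cn=est["EPSPS"],
            type1_cn=est["TypeI"],
            type2_cn=est["TypeII"],
            mge_cn=est["MGE"],
        )
        for ind, est in profiles.items()
    ]
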