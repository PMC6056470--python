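"""In-situ morphometry: compartment densities, thymopoietic indices,
stereological whole-organ totals, and the histology/flow reconciliation.

The central quantities:

* compartment TEC density — detected nuclei per 10^4 um^2 of cortex or
  medulla;
* thymopoietic index (TI) — thymocytes per TEC, the per-TEC lymphopoietic
  load; by flow cytometry it equals CD45+EpCAM- events over CD45-EpCAM+
  events, and is the inverse of the TEC fraction in the profile;
* stereological extrapolation — areal densities divided by an effective
  section thickness (physical thickness plus mean nuclear diameter, the
  Abercrombie overcount correction) give volumetric densities, which times
  compartment volumes (area fractions x organ volume from displacement)
  give whole-organ TEC totals;
* reconciliation — the ratio of the flow-cytometric to the histological TI
  is the factor by which enzymatic dissociation under-recovers TECs, and
  rescales flow-based TEC counts to whole-organ estimates.

All ratio operations are scale-invariant: multiplying every count by k
changes no TI, ratio or fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detect import SpotSet
from .imgen import CORTEX, MEDULLA, TissueScenario
from .segment import AreaFractions, CompartmentMask

__all__ = [
    "DensityEstimate", "TIResult", "StereologyResult", "ReconciliationReport",
    "compartment_density", "ctec_mtec_ratio", "thymopoietic_index",
    "ti_from_tec_fraction", "whole_organ_ti", "extrapolate_total_tecs",
    "reconcile", "fold_change",
]

UL_TO_UM3 = 1e9  # 1 ul = 1e9 um^3

_COMPARTMENT_LABELS = {"cortex": CORTEX, "medulla": MEDULLA}


@dataclass
class DensityEstimate:
    """TEC count over compartment area, reported per 10^4 um^2."""

    compartment: str
    tec_count: int
    area_um2: float
    density_per_1e4um2: float

    @classmethod
    def from_counts(cls, compartment: str, tec_count: int,
                    area_um2: float) -> "DensityEstimate":
        if area_um2 <= 0:
            raise ValueError(f"{compartment} area is zero; density undefined")
        return cls(compartment=compartment, tec_count=int(tec_count),
                   area_um2=float(area_um2),
                   density_per_1e4um2=tec_count / area_um2 * 1e4)


@dataclass
class TIResult:
    """Thymopoietic index: thymocytes per TEC for a given scope."""

    scope: str  # cortex | medulla | whole | flow
    thymocyte_count: float
    tec_count: float
    ti: float


@dataclass
class StereologyResult:
    cortical_volumetric_density_per_um3: float
    medullary_volumetric_density_per_um3: float
    effective_thickness_um: float
    organ_volume_ul: float
    cortical_total: float
    medullary_total: float
    total_tec_estimate: float


@dataclass
class ReconciliationReport:
    """Flow-vs-histology reconciliation of TEC numbers.

    ``correction_factor = ti_flow / ti_hist`` is the factor by which
    dissociation-based counting underestimates TECs (assuming thymocytes are
    recovered completely); ``corrected_total = flow_tec_count x factor``.
    ``recovery_rate`` is measured directly when an in-situ TEC count is
    supplied, else derived as ``ti_hist / ti_flow`` under the equal-thymocyte-
    recovery assumption (recorded in ``assumptions``).
    """

    ti_hist: float
    ti_flow: float
    correction_factor: float
    flow_tec_count: float
    corrected_total: float
    recovery_rate: float
    recovery_rate_in_range: bool
    assumptions: list[str] = field(default_factory=list)

    def summary(self, sig: int = 2) -> dict:
        """Rounded to the reporting precision (2 significant figures)."""
        def r(x: float) -> float:
            if x == 0 or not np.isfinite(x):
                return x
            from math import floor, log10
            return round(x, -int(floor(log10(abs(x)))) + (sig - 1))
        return {"ti_hist": r(self.ti_hist), "ti_flow": r(self.ti_flow),
                "correction_factor": r(self.correction_factor),
                "corrected_total": r(self.corrected_total),
                "recovery_rate": r(self.recovery_rate)}


def compartment_density(spots: SpotSet, mask: CompartmentMask,
                        compartment: str, guard_um: float = 0.0,
                        ) -> DensityEstimate:
    """Count spots whose centroid pixel carries ``compartment``'s label and
    divide by the compartment area.

    ``guard_um`` > 0 applies a stereological guard zone: counting is
    restricted to the compartment core further than ``guard_um`` from any
    boundary, and the core area is used as denominator.  For a uniformly
    distributed population this is unbiased while excluding the
    boundary band where segmentation errors concentrate.
    """
    if compartment not in _COMPARTMENT_LABELS:
        raise ValueError(f"compartment must be one of {list(_COMPARTMENT_LABELS)}")
    lab = _COMPARTMENT_LABELS[compartment]
    psz = mask.pixel_size_xy
    region = mask.labels == lab
    if guard_um > 0.0:
        from scipy import ndimage as _ndi
        # pad with background so the image border also counts as a boundary
        padded = np.pad(region, 1)
        dist = _ndi.distance_transform_edt(padded, sampling=psz)[1:-1, 1:-1]
        region = dist > guard_um
    area = float(np.count_nonzero(region)) * psz ** 2
    if area <= 0:
        raise ValueError(f"{compartment} has zero area in this mask"
                         + (f" after a {guard_um} um guard zone" if guard_um
                            else ""))
    ny, nx = mask.labels.shape
    count = 0
    for xy in spots.coords_um:
        ix = min(max(int(xy[0] / psz), 0), nx - 1)
        iy = min(max(int(xy[1] / psz), 0), ny - 1)
        if region[iy, ix]:
            count += 1
    return DensityEstimate.from_counts(compartment, count, area)


def ctec_mtec_ratio(cortex: DensityEstimate, medulla: DensityEstimate,
                    fractions: AreaFractions | tuple[float, float]) -> float:
    """Cortical-to-medullary TEC number ratio,
    (density_c x fraction_c) / (density_m x fraction_m).

    Accepts an :class:`AreaFractions` or a plain ``(f_cortex, f_medulla)``
    tuple.  A zero medullary term yields ``inf`` (flagged by the caller's
    degenerate handling rather than an exception, matching the area-ratio
    convention)."""
    if isinstance(fractions, AreaFractions):
        fc, fm = fractions.cortex_fraction, fractions.medulla_fraction
    else:
        fc, fm = fractions
    num = cortex.density_per_1e4um2 * fc
    den = medulla.density_per_1e4um2 * fm
    if den == 0.0:
        return float("inf")
    return num / den


def thymopoietic_index(thymocyte_count: float, tec_count: float,
                       scope: str = "whole") -> TIResult:
    """TI = thymocytes / TECs."""
    if tec_count <= 0:
        raise ValueError("tec_count must be > 0")
    if thymocyte_count < 0:
        raise ValueError("thymocyte_count must be >= 0")
    return TIResult(scope=scope, thymocyte_count=float(thymocyte_count),
                    tec_count=float(tec_count),
                    ti=float(thymocyte_count) / float(tec_count))


def ti_from_tec_fraction(tec_fraction: float, exclusive: bool = False,
                         scope: str = "flow") -> TIResult:
    """TI from the TEC fraction of a flow profile.

    The index is the inverse of the TEC fraction (a 0.1% TEC fraction is a TI
    of 1,000).  With ``exclusive=True`` the numerator excludes the TECs
    themselves, giving (1 - f)/f; the two forms agree to O(f).
    """
    if not 0.0 < tec_fraction <= 1.0:
        raise ValueError("tec_fraction must lie in (0, 1]")
    ti = (1.0 - tec_fraction) / tec_fraction if exclusive else 1.0 / tec_fraction
    return TIResult(scope=scope, thymocyte_count=ti, tec_count=1.0, ti=ti)


def whole_organ_ti(cortex_ti: TIResult, medulla_ti: TIResult,
                   tec_weights: tuple[float, float]) -> TIResult:
    """Whole-organ TI reconstructed from compartment TIs weighted by the
    proportions of cortical and medullary TECs.

    Equals (sum_i w_i thy_i) / (sum_i w_i tec_i) for per-TEC-normalized
    compartment counts, i.e. the TEC-weighted mean of the compartment TIs.
    """
    wc, wm = tec_weights
    if wc < 0 or wm < 0 or wc + wm <= 0:
        raise ValueError("tec_weights must be >= 0 and sum to > 0")
    ti = (wc * cortex_ti.ti + wm * medulla_ti.ti) / (wc + wm)
    thy = wc * cortex_ti.ti + wm * medulla_ti.ti
    return TIResult(scope="whole", thymocyte_count=thy, tec_count=wc + wm,
                    ti=ti)


def extrapolate_total_tecs(cortex: DensityEstimate, medulla: DensityEstimate,
                           fractions: AreaFractions | tuple[float, float],
                           scenario: TissueScenario,
                           correction: str = "abercrombie",
                           nuclear_diameter_cortex: float | None = None,
                           nuclear_diameter_medulla: float | None = None,
                           ) -> StereologyResult:
    """Whole-organ TEC totals from section densities.

    Areal density / effective thickness gives the volumetric density, where
    effective thickness = section thickness + mean nuclear diameter
    (``correction="abercrombie"``, the default: a nucleus is counted in every
    section its profile touches) or the bare section thickness
    (``correction="none"``, for sensitivity analysis).  Compartment totals are
    volumetric density x area fraction x organ volume; per-compartment
    nuclear diameters may be overridden (medullary TEC nuclei are larger).
    """
    if scenario.organ_volume is None or scenario.organ_volume <= 0:
        raise ValueError("scenario.organ_volume must be set and > 0")
    if correction not in ("abercrombie", "none"):
        raise ValueError("correction must be 'abercrombie' or 'none'")
    if isinstance(fractions, AreaFractions):
        fc, fm = fractions.cortex_fraction, fractions.medulla_fraction
    else:
        fc, fm = fractions
    d_c = (nuclear_diameter_cortex if nuclear_diameter_cortex is not None
           else scenario.mean_nuclear_diameter)
    d_m = (nuclear_diameter_medulla if nuclear_diameter_medulla is not None
           else scenario.mean_nuclear_diameter)
    if correction == "none":
        d_c = d_m = 0.0
    t_c = scenario.section_thickness + d_c
    t_m = scenario.section_thickness + d_m
    vol_um3 = scenario.organ_volume * UL_TO_UM3
    dens_c = cortex.density_per_1e4um2 / 1e4 / t_c  # per um^3
    dens_m = medulla.density_per_1e4um2 / 1e4 / t_m
    total_c = dens_c * fc * vol_um3
    total_m = dens_m * fm * vol_um3
    return StereologyResult(
        cortical_volumetric_density_per_um3=dens_c,
        medullary_volumetric_density_per_um3=dens_m,
        effective_thickness_um=t_c,
        organ_volume_ul=scenario.organ_volume,
        cortical_total=total_c, medullary_total=total_m,
        total_tec_estimate=total_c + total_m)


def reconcile(ti_hist: float, ti_flow: float, flow_tec_count: float,
              insitu_tec_count: float | None = None) -> ReconciliationReport:
    """Reconcile flow-cytometric with histological TEC enumeration.

    correction_factor = ti_flow / ti_hist;
    corrected_total = flow_tec_count x correction_factor (exact identity);
    recovery_rate = flow/in-situ counts when the latter is given, else
    ti_hist / ti_flow (equal thymocyte recovery assumed).
    """
    if ti_hist <= 0 or ti_flow <= 0:
        raise ValueError("TIs must be > 0")
    if flow_tec_count < 0:
        raise ValueError("flow_tec_count must be >= 0")
    factor = ti_flow / ti_hist
    corrected = flow_tec_count * factor
    assumptions = []
    if insitu_tec_count is not None:
        if insitu_tec_count <= 0:
            raise ValueError("insitu_tec_count must be > 0 when given")
        recovery = flow_tec_count / insitu_tec_count
    else:
        recovery = ti_hist / ti_flow
        assumptions.append(
            "recovery_rate derived from TI ratio assuming equal thymocyte "
            "recovery across preparations")
    return ReconciliationReport(
        ti_hist=float(ti_hist), ti_flow=float(ti_flow),
        correction_factor=factor, flow_tec_count=float(flow_tec_count),
        corrected_total=corrected, recovery_rate=recovery,
        recovery_rate_in_range=bool(0.0 <= recovery <= 1.0),
        assumptions=assumptions)


def fold_change(a: float, b: float) -> float:
    """Ratio a/b (e.g. TI at P10 over TI at P0)."""
    if b == 0:
        raise ZeroDivisionError("fold_change denominator is zero")
    return a / b
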