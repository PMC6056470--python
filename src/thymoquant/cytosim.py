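"""Enzymatic-dissociation and flow-cytometry simulation.

Models the chain that turns a thymus into a flow profile: class-specific
survival of enzymatic digestion (binomial thinning), log-normal marker
intensities (CD45, EpCAM, Ly51, UEA1) per surviving cell, fixed-threshold
quadrant gating, and composition-weighted bulk expression for whole-organ vs
purified-TEC RNA comparisons.

Four classes are modelled: thymocytes (CD45+EpCAM-), outer and inner
cortical TECs (CD45-EpCAM+Ly51+; split only to carry the regional
Cxcl12-vs-Ccl25 expression logic), and medullary TECs (CD45-EpCAM+UEA1+).
Survival defaults are calibrated so the default P10 scenario reproduces the
order-of-magnitude flow-vs-histology discrepancy (weighted TEC recovery
~ 0.075, thymocytes ~ 1.0), with cortical TECs lost preferentially.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imgen import TissueScenario, make_scenario
from .morpho import extrapolate_total_tecs, DensityEstimate

__all__ = [
    "ClassSpec", "PopulationSpec", "FlowEventTable", "GateResult",
    "ExpressionSpec", "dissociate", "gate", "bulk_expression",
    "ratio_fold_change", "recovery_timeline", "default_population",
    "default_expression", "ablation_recovery_timeline_specs",
]

MARKERS = ("CD45", "EpCAM", "Ly51", "UEA1")
TEC_CLASSES = ("cTEC_outer", "cTEC_inner", "mTEC")
ALL_CLASSES = ("thymocyte",) + TEC_CLASSES

GENES = ("Foxn1", "Cxcl12", "Ccl25", "Psmb11", "Prss16", "Dll4", "Epcam")

# log10 intensity model: negative and positive populations one decade apart
NEG_LOG_MEAN = 2.0
POS_LOG_MEAN = 3.0
DEFAULT_LOG_SD = 0.15

_POSITIVE_MARKERS = {
    "thymocyte": {"CD45"},
    "cTEC_outer": {"EpCAM", "Ly51"},
    "cTEC_inner": {"EpCAM", "Ly51"},
    "mTEC": {"EpCAM", "UEA1"},
}


def _default_markers(cls: str, log_sd: float) -> dict[str, tuple[float, float]]:
    pos = _POSITIVE_MARKERS[cls]
    return {m: (POS_LOG_MEAN if m in pos else NEG_LOG_MEAN, log_sd)
            for m in MARKERS}


@dataclass
class ClassSpec:
    """One cell class: true count, digestion survival probability, and
    per-marker log10-normal intensity parameters (mean, sd)."""

    count: int
    survival: float
    markers: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if not 0.0 <= self.survival <= 1.0:
            raise ValueError("survival must lie in [0, 1]")
        for m, (mu, sd) in self.markers.items():
            if sd <= 0:
                raise ValueError(f"marker {m}: sd must be > 0")


@dataclass
class PopulationSpec:
    """True composition of a thymus entering the dissociation protocol."""

    classes: dict[str, ClassSpec]

    def __post_init__(self) -> None:
        unknown = set(self.classes) - set(ALL_CLASSES)
        if unknown:
            raise ValueError(f"unknown classes {unknown}; valid: {ALL_CLASSES}")

    @property
    def true_tec_count(self) -> int:
        return sum(c.count for n, c in self.classes.items() if n != "thymocyte")

    @property
    def true_thymocyte_count(self) -> int:
        c = self.classes.get("thymocyte")
        return c.count if c else 0

    @property
    def ti_true(self) -> float:
        return self.true_thymocyte_count / self.true_tec_count

    @property
    def weighted_tec_survival(self) -> float:
        num = sum(c.count * c.survival for n, c in self.classes.items()
                  if n != "thymocyte")
        return num / self.true_tec_count

    def scaled(self, factor: float) -> "PopulationSpec":
        """Same composition with every count multiplied by ``factor``
        (all gated ratios are scale-invariant)."""
        return PopulationSpec(classes={
            n: ClassSpec(count=int(round(c.count * factor)),
                         survival=c.survival, markers=dict(c.markers))
            for n, c in self.classes.items()})

    def to_dict(self) -> dict:
        return {n: {"count": c.count, "survival": c.survival,
                    "markers": {m: list(v) for m, v in c.markers.items()}}
                for n, c in self.classes.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationSpec":
        return cls(classes={
            n: ClassSpec(count=int(v["count"]), survival=float(v["survival"]),
                         markers={m: tuple(mv) for m, mv in
                                  v["markers"].items()})
            for n, v in d.items()})


def default_population(age_label: str = "P10", scale: float = 0.01,
                       log_sd: float = DEFAULT_LOG_SD,
                       survival: dict[str, float] | None = None,
                       ) -> PopulationSpec:
    """Population spec for a preset stage.

    TEC totals come from the stage's stereology (preset densities, area
    fractions, organ volume); thymocytes from the stage's reference
    compartment TIs weighted by TEC proportions.  ``scale`` multiplies all
    counts (default 1:100 of the real organ; gated quantities are ratios and
    therefore scale-free).  Survival defaults: thymocytes 1.0, cortical TECs
    0.045, medullary TECs 0.105 (preferential cortical loss; weighted TEC
    recovery ~ 0.075 at P10).
    """
    scn = make_scenario(age_label)
    fc = scn.cortex_area_fraction
    # densities built directly (count/area bookkeeping not needed here)
    cortex = DensityEstimate("cortex", 0, 1.0, scn.cortical_tec_density)
    medulla = DensityEstimate("medulla", 0, 1.0, scn.medullary_tec_density)
    ster = extrapolate_total_tecs(cortex, medulla, (fc, 1.0 - fc), scn)
    n_ctec = ster.cortical_total
    n_mtec = ster.medullary_total
    if scn.cortical_ti is None or scn.medullary_ti is None:
        raise ValueError(f"preset {age_label} lacks reference TIs")
    n_thy = scn.cortical_ti * n_ctec + scn.medullary_ti * n_mtec
    surv = {"thymocyte": 1.0, "cTEC_outer": 0.045, "cTEC_inner": 0.045,
            "mTEC": 0.105}
    if survival:
        surv.update(survival)
    counts = {"thymocyte": n_thy * scale,
              "cTEC_outer": n_ctec / 2 * scale,
              "cTEC_inner": n_ctec / 2 * scale,
              "mTEC": n_mtec * scale}
    return PopulationSpec(classes={
        n: ClassSpec(count=int(round(counts[n])), survival=surv[n],
                     markers=_default_markers(n, log_sd))
        for n in ALL_CLASSES})


@dataclass
class FlowEventTable:
    """One row per surviving cell: marker intensities (linear units) plus the
    hidden true class (synthetic mode)."""

    events: pd.DataFrame
    survivors: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.events)

    def to_csv(self, path, include_truth: bool = True) -> None:
        df = self.events if include_truth else self.events[list(MARKERS)]
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FlowEventTable":
        df = pd.read_csv(path)
        missing = set(MARKERS) - set(df.columns)
        if missing:
            raise ValueError(f"event table missing marker columns {missing}")
        surv = (df["true_class"].value_counts().to_dict()
                if "true_class" in df.columns else {})
        return cls(events=df, survivors=surv)


def dissociate(spec: PopulationSpec, seed: int = 0) -> FlowEventTable:
    """Simulate enzymatic digestion and staining.

    Survivors are binomial draws per class; each survivor's marker
    intensities are drawn log-normally from its class distributions.
    Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    frames = []
    survivors: dict[str, int] = {}
    for name in ALL_CLASSES:
        cls = spec.classes.get(name)
        if cls is None:
            continue
        n = int(rng.binomial(cls.count, cls.survival)) if cls.count else 0
        survivors[name] = n
        if n == 0:
            continue
        data = {}
        for m in MARKERS:
            mu, sd = cls.markers[m]
            data[m] = 10.0 ** rng.normal(mu, sd, size=n)
        data["true_class"] = np.full(n, name, dtype=object)
        frames.append(pd.DataFrame(data))
    if frames:
        events = pd.concat(frames, ignore_index=True)
    else:
        events = pd.DataFrame({m: pd.Series(dtype=float) for m in MARKERS}
                              | {"true_class": pd.Series(dtype=object)})
    return FlowEventTable(events=events, survivors=survivors)


@dataclass
class GateResult:
    thymocyte_count: int          # CD45+ EpCAM-
    tec_count: int                # CD45- EpCAM+
    ly51_pos_count: int           # Ly51+ UEA1- among TECs
    uea1_pos_count: int           # Ly51- UEA1+ among TECs
    thymocyte_fraction: float
    tec_fraction: float
    ly51_fraction_of_tecs: float
    uea1_fraction_of_tecs: float
    ly51_uea1_ratio: float
    ti_flow: float
    thresholds: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def default_thresholds() -> dict[str, float]:
    """Quadrant thresholds at the geometric midpoint of the negative and
    positive class means (10^2.5 with the default one-decade separation)."""
    mid = 10.0 ** ((NEG_LOG_MEAN + POS_LOG_MEAN) / 2.0)
    return {m: mid for m in MARKERS}


def gate(events: FlowEventTable, thresholds: dict[str, float] | None = None,
         ) -> GateResult:
    """Fixed-threshold quadrant gating.

    Thymocytes: CD45 >= t, EpCAM < t.  TECs: CD45 < t, EpCAM >= t.  Among
    TECs, Ly51+UEA1- vs Ly51-UEA1+.  ti_flow = thymocytes / TECs; a zero TEC
    gate flags the result and yields inf ratios.
    """
    thr = dict(default_thresholds())
    if thresholds:
        thr.update(thresholds)
    df = events.events
    n = len(df)
    cd45 = df["CD45"].to_numpy() >= thr["CD45"] if n else np.empty(0, bool)
    epcam = df["EpCAM"].to_numpy() >= thr["EpCAM"] if n else np.empty(0, bool)
    thy = cd45 & ~epcam
    tec = ~cd45 & epcam
    ly51 = df["Ly51"].to_numpy() >= thr["Ly51"] if n else np.empty(0, bool)
    uea1 = df["UEA1"].to_numpy() >= thr["UEA1"] if n else np.empty(0, bool)
    ly51_pos = tec & ly51 & ~uea1
    uea1_pos = tec & ~ly51 & uea1
    n_thy, n_tec = int(thy.sum()), int(tec.sum())
    n_ly51, n_uea1 = int(ly51_pos.sum()), int(uea1_pos.sum())
    flags = []
    if n_tec == 0:
        flags.append("zero TEC gate; ratios undefined")
    ti_flow = n_thy / n_tec if n_tec else float("inf")
    ratio = (n_ly51 / n_uea1 if n_uea1 else
             (float("inf") if n_ly51 else float("nan")))
    if n_uea1 == 0:
        flags.append("zero UEA1+ gate; Ly51/UEA1 ratio flagged")
    return GateResult(
        thymocyte_count=n_thy, tec_count=n_tec,
        ly51_pos_count=n_ly51, uea1_pos_count=n_uea1,
        thymocyte_fraction=n_thy / n if n else 0.0,
        tec_fraction=n_tec / n if n else 0.0,
        ly51_fraction_of_tecs=n_ly51 / n_tec if n_tec else 0.0,
        uea1_fraction_of_tecs=n_uea1 / n_tec if n_tec else 0.0,
        ly51_uea1_ratio=ratio, ti_flow=ti_flow, thresholds=thr, flags=flags)


@dataclass
class ExpressionSpec:
    """Per-cell expression level per gene and class (arbitrary units).

    Epcam must be positive in every TEC class and zero in thymocytes (it is
    the qPCR normalizer for epithelial content).
    """

    levels: dict[str, dict[str, float]]  # gene -> class -> per-cell level

    def __post_init__(self) -> None:
        for g, per_class in self.levels.items():
            for cls, v in per_class.items():
                if v < 0:
                    raise ValueError(f"{g}/{cls}: level must be >= 0")
        ep = self.levels.get("Epcam")
        if ep is not None:
            if ep.get("thymocyte", 0.0) != 0.0:
                raise ValueError("Epcam must be 0 in thymocytes")
            for cls in TEC_CLASSES:
                if cls in ep and ep[cls] <= 0.0:
                    raise ValueError("Epcam must be > 0 in all TEC classes")

    def level(self, gene: str, cls: str) -> float:
        return self.levels.get(gene, {}).get(cls, 0.0)


def default_expression() -> ExpressionSpec:
    """Regional expression logic: Cxcl12 cortical with an outer-cortex bias;
    Ccl25 cortical throughout with a trace in the medulla; Psmb11/Prss16
    strictly cortical; Foxn1/Dll4/Epcam pan-TEC; thymocytes express none."""
    z = {"thymocyte": 0.0}
    return ExpressionSpec(levels={
        "Foxn1":  z | {"cTEC_outer": 2.0, "cTEC_inner": 2.0, "mTEC": 2.0},
        "Cxcl12": z | {"cTEC_outer": 5.0, "cTEC_inner": 1.0, "mTEC": 0.0},
        "Ccl25":  z | {"cTEC_outer": 3.0, "cTEC_inner": 3.0, "mTEC": 0.3},
        "Psmb11": z | {"cTEC_outer": 2.0, "cTEC_inner": 2.0, "mTEC": 0.0},
        "Prss16": z | {"cTEC_outer": 1.5, "cTEC_inner": 1.5, "mTEC": 0.0},
        "Dll4":   z | {"cTEC_outer": 1.0, "cTEC_inner": 1.0, "mTEC": 1.0},
        "Epcam":  z | {"cTEC_outer": 1.0, "cTEC_inner": 1.0, "mTEC": 1.0},
    })


def bulk_expression(spec: PopulationSpec, expr: ExpressionSpec,
                    source: str = "whole_organ") -> dict[str, float]:
    """Composition-weighted bulk expression per gene.

    level(g) = sum over classes of count x per-cell level.  ``whole_organ``
    uses the true counts of every class; ``purified_TEC`` uses the expected
    post-survival counts of the TEC classes only (the sorted CD45-EpCAM+
    fraction).  Exact expectation — linear in counts, no sampling.
    """
    if source not in ("whole_organ", "purified_TEC"):
        raise ValueError("source must be 'whole_organ' or 'purified_TEC'")
    out: dict[str, float] = {}
    for g in GENES:
        total = 0.0
        for name, cls in spec.classes.items():
            if source == "purified_TEC":
                if name == "thymocyte":
                    continue
                weight = cls.count * cls.survival
            else:
                weight = cls.count
            total += weight * expr.level(g, name)
        out[g] = total
    return out


def ratio_fold_change(bulk_whole: dict[str, float],
                      bulk_purified: dict[str, float],
                      gene_a: str, gene_b: str) -> float:
    """Fold change of the a/b expression ratio, whole organ over purified
    TECs.  Equals 1 whenever the two genes are confined to the same classes
    (any class-uniform loss cancels in the ratio)."""
    for name, bulk in (("whole_organ", bulk_whole),
                       ("purified_TEC", bulk_purified)):
        if bulk.get(gene_b, 0.0) == 0.0:
            raise ZeroDivisionError(
                f"{gene_b} has zero expression in {name}; ratio undefined")
        if bulk.get(gene_a) is None:
            raise KeyError(f"{gene_a} missing from {name} table")
    return ((bulk_whole[gene_a] / bulk_whole[gene_b])
            / (bulk_purified[gene_a] / bulk_purified[gene_b]))


def recovery_timeline(specs: list[PopulationSpec], seed: int = 0,
                      labels: list[str] | None = None) -> pd.DataFrame:
    """Dissociate + gate an ordered series of population specs (e.g. an
    ablation-recovery time course) and tabulate the flow metrics.

    Returns a tidy frame with one row per time point: gated counts, the
    Ly51+/UEA1+ ratio and ti_flow, plus the true TI for reference.
    """
    if len(specs) < 2:
        raise ValueError("need at least two time points")
    if labels is None:
        labels = [f"t{i}" for i in range(len(specs))]
    rows = []
    rng = np.random.default_rng(seed)
    for label, spec in zip(labels, specs):
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        res = gate(dissociate(spec, seed=sub_seed))
        rows.append({
            "time": label,
            "thymocytes_gated": res.thymocyte_count,
            "tecs_gated": res.tec_count,
            "ly51_pos": res.ly51_pos_count,
            "uea1_pos": res.uea1_pos_count,
            "ly51_uea1_ratio": res.ly51_uea1_ratio,
            "ti_flow": res.ti_flow,
            "ti_true": spec.ti_true,
        })
    return pd.DataFrame(rows)


def ablation_recovery_timeline_specs(n_timepoints: int = 5,
                                     ablated: bool = True,
                                     scale: float = 0.01) -> list[PopulationSpec]:
    """Population series emulating recovery after subtotal ablation of
    cortical-type TECs during embryogenesis.

    In the ablated series the medullary compartment re-emerges from a nearly
    absent state while cortical TEC numbers stay flat, so the Ly51+/UEA1+
    ratio starts abnormally high and falls towards the control value; the
    control series shows the milder developmental decline.
    """
    base = default_population("P0", scale=scale)
    specs = []
    for k in range(n_timepoints):
        t = k / (n_timepoints - 1)
        f = dict(base.classes)
        if ablated:
            ctec_f = 0.4          # reduced by embryonic ablation, flat
            mtec_f = 0.02 + 0.98 * t   # mTECs emerge during recovery
            thy_f = 0.3 + 0.7 * t
        else:
            ctec_f = 1.0
            mtec_f = 0.5 + 0.5 * t
            thy_f = 0.6 + 0.4 * t
        classes = {
            "thymocyte": ClassSpec(int(f["thymocyte"].count * thy_f),
                                   f["thymocyte"].survival,
                                   dict(f["thymocyte"].markers)),
            "cTEC_outer": ClassSpec(int(f["cTEC_outer"].count * ctec_f),
                                    f["cTEC_outer"].survival,
                                    dict(f["cTEC_outer"].markers)),
            "cTEC_inner": ClassSpec(int(f["cTEC_inner"].count * ctec_f),
                                    f["cTEC_inner"].survival,
                                    dict(f["cTEC_inner"].markers)),
            "mTEC": ClassSpec(int(f["mTEC"].count * mtec_f),
                              f["mTEC"].survival, dict(f["mTEC"].markers)),
        }
        specs.append(PopulationSpec(classes=classes))
    return specs
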