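"""End-to-end reproduction runs.

``run_reproduction`` executes the whole chain for one developmental stage:
synthetic sections -> spot detection -> compartment segmentation ->
densities, area fractions and stereology -> reconstructed histological TI,
and in parallel the dissociation simulation -> gating -> flow TI, finally
reconciling the two.  All randomness flows from one master seed through
named substreams, so reports are byte-identical for a fixed configuration
regardless of stage-internal call order.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import numpy as np

from . import cytosim, detect, imgen, morpho, segment

__all__ = ["default_config", "run_reproduction", "substream_seed",
           "measure_sections", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def substream_seed(master_seed: int, name: str) -> int:
    """Stable named substream: one master seed, one independent child per
    stage name."""
    ss = np.random.SeedSequence([int(master_seed) % (2 ** 31),
                                 zlib.crc32(name.encode()) % (2 ** 31)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def default_config(age: str = "P10", seed: int = 0) -> dict:
    return {
        "age": age,
        "seed": int(seed),
        "field_size": [800.0, 800.0],
        # enough sections that the sparse postnatal cortical/medullary TEC
        # counts (~30 nuclei per compartment and section) average out
        "n_sections": 12,
        "guard_um": 25.0,  # boundary-exclusion zone for density estimates
        "detect": {"expected_diameter": 6.0, "threshold": 0.2},
        "segment": {"window": segment.DEFAULT_WINDOW_UM},
        "cytosim": {"scale": 0.01},
        # printed 4-week flow-cytometric TEC count; the reconciliation input
        "reconcile": {"flow_tec_count": 1.12e5},
    }


def measure_sections(scenario: imgen.TissueScenario, field_size, n_sections: int,
                     seed: int, detect_params: dict | None = None,
                     segment_params: dict | None = None,
                     guard_um: float = 25.0) -> dict:
    """Render, count and segment ``n_sections`` sections; pool counts and
    areas into per-compartment density estimates and area fractions.

    Densities use a ``guard_um`` boundary-exclusion zone (unbiased for the
    uniform within-compartment distribution, robust to segmentation-boundary
    error); area fractions use the full label areas.
    """
    detect_params = detect_params or {}
    segment_params = segment_params or {}
    counts = {"cortex": 0, "medulla": 0}
    core_areas = {"cortex": 0.0, "medulla": 0.0}
    full_areas = {"cortex": 0.0, "medulla": 0.0}
    per_section = []
    for k in range(n_sections):
        img, _truth = imgen.render_section(
            scenario, field_size=tuple(field_size),
            seed=substream_seed(seed, f"section-{k}"))
        spots = detect.detect_spots_2d(img, **detect_params)
        mask = segment.segment_compartments(img, **segment_params)
        row = {"section": k, "spots": spots.count}
        for comp in ("cortex", "medulla"):
            try:
                de = morpho.compartment_density(spots, mask, comp,
                                                guard_um=guard_um)
            except ValueError:
                continue
            counts[comp] += de.tec_count
            core_areas[comp] += de.area_um2
            full_areas[comp] += mask.areas_um2[comp]
            row[f"{comp}_count"] = de.tec_count
            row[f"{comp}_core_area_um2"] = de.area_um2
            row[f"{comp}_area_um2"] = mask.areas_um2[comp]
        per_section.append(row)
    if core_areas["cortex"] <= 0 or core_areas["medulla"] <= 0:
        raise StageError("segment", "a compartment was never found across "
                                    f"{n_sections} sections")
    cortex = morpho.DensityEstimate.from_counts("cortex", counts["cortex"],
                                                core_areas["cortex"])
    medulla = morpho.DensityEstimate.from_counts("medulla", counts["medulla"],
                                                 core_areas["medulla"])
    tissue = full_areas["cortex"] + full_areas["medulla"]
    fractions = (full_areas["cortex"] / tissue, full_areas["medulla"] / tissue)
    return {"cortex": cortex, "medulla": medulla, "fractions": fractions,
            "per_section": per_section}


def run_reproduction(config: dict, out_dir: str | Path | None = None) -> dict:
    """Run the full reproduction chain for one configuration.

    Returns (and optionally writes, as JSON + Markdown) a report containing
    the reconstructed histological TI, the simulated flow TI, the correction
    factor, the corrected whole-organ TEC count, and per-stage provenance.
    Idempotent for a fixed config.
    """
    cfg = default_config(config.get("age", "P10"), config.get("seed", 0))
    for key, val in config.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    seed = int(cfg["seed"])

    try:
        scenario = imgen.make_scenario(cfg["age"])
    except ValueError as e:
        raise StageError("imgen", str(e)) from e

    # --- histology side -------------------------------------------------
    try:
        meas = measure_sections(scenario, cfg["field_size"],
                                int(cfg["n_sections"]), seed,
                                cfg.get("detect"), cfg.get("segment"),
                                guard_um=float(cfg.get("guard_um", 25.0)))
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001 - stage-named rethrow
        raise StageError("histology", str(e)) from e
    cortex, medulla = meas["cortex"], meas["medulla"]
    fractions = meas["fractions"]
    cm_ratio = morpho.ctec_mtec_ratio(cortex, medulla, fractions)
    ster = morpho.extrapolate_total_tecs(cortex, medulla, fractions, scenario)
    if scenario.cortical_ti is None or scenario.medullary_ti is None:
        raise StageError("morpho", f"preset {cfg['age']} lacks reference TIs")
    ti_hist = morpho.whole_organ_ti(
        morpho.TIResult("cortex", scenario.cortical_ti, 1.0,
                        scenario.cortical_ti),
        morpho.TIResult("medulla", scenario.medullary_ti, 1.0,
                        scenario.medullary_ti),
        tec_weights=(ster.cortical_total, ster.medullary_total)).ti

    # --- flow side ------------------------------------------------------
    try:
        pop = cytosim.default_population(cfg["age"],
                                         scale=cfg["cytosim"]["scale"])
        events = cytosim.dissociate(pop, seed=substream_seed(seed, "dissociate"))
        gated = cytosim.gate(events)
    except Exception as e:  # noqa: BLE001
        raise StageError("cytosim", str(e)) from e
    if not np.isfinite(gated.ti_flow):
        raise StageError("cytosim", "flow TI undefined (zero TEC gate)")

    # --- reconciliation -------------------------------------------------
    rec = morpho.reconcile(ti_hist, gated.ti_flow,
                           cfg["reconcile"]["flow_tec_count"])

    report = {
        "config": cfg,
        "histology": {
            "cortical_density_per_1e4um2": cortex.density_per_1e4um2,
            "medullary_density_per_1e4um2": medulla.density_per_1e4um2,
            "cortex_fraction": fractions[0],
            "medulla_fraction": fractions[1],
            "ctec_mtec_ratio": cm_ratio,
            "total_tec_estimate_insitu": ster.total_tec_estimate,
            "cortical_total": ster.cortical_total,
            "medullary_total": ster.medullary_total,
            "effective_thickness_um": ster.effective_thickness_um,
            "ti_hist": ti_hist,
            "per_section": meas["per_section"],
        },
        "flow": {
            "events": int(len(events)),
            "thymocytes_gated": gated.thymocyte_count,
            "tecs_gated": gated.tec_count,
            "ly51_uea1_ratio": gated.ly51_uea1_ratio,
            "ti_flow": gated.ti_flow,
            "weighted_tec_survival": pop.weighted_tec_survival,
        },
        "reconciliation": {
            "ti_hist": rec.ti_hist,
            "ti_flow": rec.ti_flow,
            "correction_factor": rec.correction_factor,
            "flow_tec_count": rec.flow_tec_count,
            "corrected_total": rec.corrected_total,
            "recovery_rate": rec.recovery_rate,
            "summary_2sf": rec.summary(),
        },
        "provenance": {
            "master_seed": seed,
            "substreams": {"sections": [substream_seed(seed, f"section-{k}")
                                        for k in range(int(cfg["n_sections"]))],
                           "dissociate": substream_seed(seed, "dissociate")},
        },
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=float))
        (out / "report.md").write_text(_report_markdown(report))
    return report


def _report_markdown(report: dict) -> str:
    h, f, r = (report["histology"], report["flow"], report["reconciliation"])
    cfg = report["config"]
    lines = [
        f"# Reproduction report — {cfg['age']} (seed {cfg['seed']})",
        "",
        "## Histology (in situ)",
        f"- cortical TEC density: {h['cortical_density_per_1e4um2']:.2f} "
        "per 10^4 um^2",
        f"- medullary TEC density: {h['medullary_density_per_1e4um2']:.2f} "
        "per 10^4 um^2",
        f"- cortex / medulla area fractions: {h['cortex_fraction']:.3f} / "
        f"{h['medulla_fraction']:.3f}",
        f"- cTEC/mTEC ratio: {h['ctec_mtec_ratio']:.2f}",
        f"- whole-organ TEC estimate (stereology): "
        f"{h['total_tec_estimate_insitu']:.3g}",
        f"- reconstructed histological TI: {h['ti_hist']:.1f}",
        "",
        "## Flow cytometry (simulated dissociation)",
        f"- events: {f['events']}, gated thymocytes: {f['thymocytes_gated']}, "
        f"gated TECs: {f['tecs_gated']}",
        f"- Ly51+/UEA1+ ratio: {f['ly51_uea1_ratio']:.2f}",
        f"- flow TI: {f['ti_flow']:.0f}",
        "",
        "## Reconciliation",
        f"- correction factor (ti_flow / ti_hist): {r['correction_factor']:.1f}",
        f"- corrected whole-organ TEC count: {r['corrected_total']:.3g}",
        f"- implied TEC recovery rate: {r['recovery_rate']:.3f}",
        "",
    ]
    return "\n".join(lines)
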