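"""Dissociation/flow simulation: survival draws, gating accuracy against the
hidden classes, the Gaussian-overlap misclassification oracle, expression
mixtures and their cancellation identities, and the survival<->TI link."""

import numpy as np
import pytest
from scipy.stats import norm

import thymoquant as tq
from thymoquant.cytosim import MARKERS, default_thresholds


def _sep_markers(positive, sd=0.15):
    return {m: (3.0 if m in positive else 2.0, sd) for m in MARKERS}


def _spec(counts, survival, sd=0.05):  # tight sd: gating exact by design
    classes = {}
    pos = {"thymocyte": {"CD45"}, "cTEC_outer": {"EpCAM", "Ly51"},
           "cTEC_inner": {"EpCAM", "Ly51"}, "mTEC": {"EpCAM", "UEA1"}}
    for name, n in counts.items():
        classes[name] = tq.ClassSpec(count=n, survival=survival.get(name, 1.0),
                                     markers=_sep_markers(pos[name], sd))
    return tq.PopulationSpec(classes=classes)


class TestDissociate:
    def test_full_survival_keeps_every_cell(self):
        spec = _spec({"thymocyte": 500, "cTEC_outer": 40, "mTEC": 30}, {})
        ev = tq.dissociate(spec, seed=1)
        assert len(ev) == 570
        assert ev.survivors == {"thymocyte": 500, "cTEC_outer": 40,
                                "mTEC": 30}

    def test_zero_tec_survival_leaves_only_thymocytes(self):
        spec = _spec({"thymocyte": 200, "cTEC_outer": 50, "mTEC": 50},
                     {"cTEC_outer": 0.0, "mTEC": 0.0})
        ev = tq.dissociate(spec, seed=2)
        assert set(ev.events["true_class"]) == {"thymocyte"}

    def test_survivor_count_within_binomial_bounds(self):
        n, p = 10 ** 6, 0.5
        spec = _spec({"thymocyte": n}, {"thymocyte": p})
        ev = tq.dissociate(spec, seed=3)
        half_width = 3.29 * np.sqrt(n * p * (1 - p))  # 99.9% interval
        assert abs(len(ev) - n * p) < half_width

    def test_deterministic_under_seed(self):
        spec = _spec({"thymocyte": 100, "mTEC": 50}, {"mTEC": 0.4})
        a = tq.dissociate(spec, seed=9).events
        b = tq.dissociate(spec, seed=9).events
        assert a.equals(b)

    def test_intensities_positive(self):
        spec = _spec({"thymocyte": 100, "mTEC": 100}, {})
        ev = tq.dissociate(spec, seed=0).events
        assert (ev[list(MARKERS)] > 0).all().all()


class TestGate:
    def test_separated_classes_gated_exactly(self):
        spec = _spec({"thymocyte": 2000, "cTEC_outer": 150, "cTEC_inner": 150,
                      "mTEC": 200}, {})
        ev = tq.dissociate(spec, seed=4)
        res = tq.gate(ev)
        assert res.thymocyte_count == 2000
        assert res.tec_count == 500
        assert res.ly51_pos_count == 300
        assert res.uea1_pos_count == 200
        assert res.ly51_uea1_ratio == pytest.approx(1.5)
        assert res.ti_flow == pytest.approx(4.0)

    def test_tec_fraction_of_0p1_percent_gives_ti_1000(self):
        spec = _spec({"thymocyte": 100_000, "mTEC": 100}, {})
        res = tq.gate(tq.dissociate(spec, seed=5))
        assert res.ti_flow == pytest.approx(1000.0)
        assert res.tec_fraction == pytest.approx(100 / 100_100)

    def test_zero_tecs_flagged(self):
        spec = _spec({"thymocyte": 100}, {})
        res = tq.gate(tq.dissociate(spec, seed=6))
        assert res.ti_flow == float("inf")
        assert any("zero TEC" in f for f in res.flags)

    def test_misclassification_matches_gaussian_overlap_oracle(self):
        """With a 1-sd mean separation on EpCAM, the fraction of TECs
        falling below a midpoint threshold follows the normal tail."""
        n = 40_000
        sd = 0.2
        spec = tq.PopulationSpec(classes={
            "mTEC": tq.ClassSpec(count=n, survival=1.0, markers={
                "CD45": (2.0, sd), "EpCAM": (2.2, sd),  # 1 sd above negatives
                "Ly51": (2.0, sd), "UEA1": (3.0, sd)}),
        })
        ev = tq.dissociate(spec, seed=7)
        thr = default_thresholds() | {"EpCAM": 10.0 ** 2.1}  # midpoint
        res = tq.gate(ev, thresholds=thr)
        missed = 1.0 - res.tec_count / n
        expected = norm.cdf(-0.5)  # 0.3085
        mc_sd = np.sqrt(expected * (1 - expected) / n)
        assert abs(missed - expected) < 3 * mc_sd


class TestBulkExpression:
    def test_single_class_level_is_count_times_percell(self):
        spec = _spec({"mTEC": 250}, {})
        expr = tq.default_expression()
        whole = tq.bulk_expression(spec, expr, "whole_organ")
        assert whole["Foxn1"] == pytest.approx(250 * 2.0)
        assert whole["Psmb11"] == 0.0

    def test_thymocytes_do_not_change_tec_exclusive_genes(self):
        expr = tq.default_expression()
        a = tq.bulk_expression(_spec({"mTEC": 100}, {}), expr, "whole_organ")
        b = tq.bulk_expression(_spec({"mTEC": 100, "thymocyte": 10 ** 6}, {}),
                               expr, "whole_organ")
        for gene in ("Foxn1", "Cxcl12", "Epcam"):
            assert a[gene] == b[gene]

    def test_two_class_mixture_matches_hand_sum(self):
        spec = _spec({"cTEC_outer": 30, "mTEC": 70}, {})
        expr = tq.default_expression()
        whole = tq.bulk_expression(spec, expr, "whole_organ")
        assert whole["Cxcl12"] == pytest.approx(30 * 5.0 + 70 * 0.0)
        assert whole["Ccl25"] == pytest.approx(30 * 3.0 + 70 * 0.3)

    def test_linearity_in_counts(self):
        expr = tq.default_expression()
        a = tq.bulk_expression(_spec({"cTEC_outer": 10, "mTEC": 20}, {}),
                               expr, "whole_organ")
        b = tq.bulk_expression(_spec({"cTEC_outer": 30, "mTEC": 60}, {}),
                               expr, "whole_organ")
        for gene, val in a.items():
            assert b[gene] == pytest.approx(3 * val)

    def test_purified_uses_post_survival_tec_counts(self):
        spec = _spec({"thymocyte": 1000, "cTEC_outer": 100, "mTEC": 100},
                     {"cTEC_outer": 0.1, "mTEC": 0.5})
        expr = tq.default_expression()
        pur = tq.bulk_expression(spec, expr, "purified_TEC")
        assert pur["Foxn1"] == pytest.approx((100 * 0.1 + 100 * 0.5) * 2.0)


class TestRatioFoldChange:
    def test_uniform_survival_cancels_for_any_gene_pair(self):
        spec = _spec({"cTEC_outer": 100, "cTEC_inner": 100, "mTEC": 100},
                     {"cTEC_outer": 0.2, "cTEC_inner": 0.2, "mTEC": 0.2})
        expr = tq.default_expression()
        whole = tq.bulk_expression(spec, expr, "whole_organ")
        pur = tq.bulk_expression(spec, expr, "purified_TEC")
        for a, b in [("Cxcl12", "Foxn1"), ("Ccl25", "Epcam"),
                     ("Psmb11", "Dll4")]:
            assert tq.ratio_fold_change(whole, pur, a, b) == pytest.approx(1.0)

    def test_colocalized_gene_pairs_cancel_regardless_of_survival(self):
        """Two strictly cortical genes keep their ratio through any
        class-asymmetric loss (the Psmb11/Prss16 observation)."""
        spec = _spec({"cTEC_outer": 120, "cTEC_inner": 80, "mTEC": 300},
                     {"cTEC_outer": 0.03, "cTEC_inner": 0.03, "mTEC": 0.6})
        expr = tq.default_expression()
        whole = tq.bulk_expression(spec, expr, "whole_organ")
        pur = tq.bulk_expression(spec, expr, "purified_TEC")
        assert tq.ratio_fold_change(whole, pur, "Psmb11",
                                    "Prss16") == pytest.approx(1.0)

    def test_cortical_over_pantec_closed_form(self):
        """Equal counts, unit expression: fold = (s_c + s_m) / (2 s_c)."""
        s_c, s_m = 0.05, 0.5
        spec = tq.PopulationSpec(classes={
            "cTEC_outer": tq.ClassSpec(1000, s_c, _sep_markers({"EpCAM"})),
            "mTEC": tq.ClassSpec(1000, s_m, _sep_markers({"EpCAM"})),
        })
        expr = tq.ExpressionSpec(levels={
            "Psmb11": {"cTEC_outer": 1.0, "mTEC": 0.0},
            "Foxn1": {"cTEC_outer": 1.0, "mTEC": 1.0}})
        whole = tq.bulk_expression(spec, expr, "whole_organ")
        pur = tq.bulk_expression(spec, expr, "purified_TEC")
        fold = tq.ratio_fold_change(whole, pur, "Psmb11", "Foxn1")
        assert fold == pytest.approx((s_c + s_m) / (2 * s_c))  # 5.5

    def test_zero_denominator_gene_raises(self):
        spec = _spec({"mTEC": 10}, {})
        expr = tq.default_expression()
        whole = tq.bulk_expression(spec, expr, "whole_organ")
        pur = tq.bulk_expression(spec, expr, "purified_TEC")
        with pytest.raises(ZeroDivisionError):
            tq.ratio_fold_change(whole, pur, "Foxn1", "Psmb11")


class TestRecoveryTimeline:
    def test_static_specs_give_flat_trajectories(self):
        spec = _spec({"thymocyte": 3000, "cTEC_outer": 200, "cTEC_inner": 200,
                      "mTEC": 100}, {})  # survival 1: no sampling noise
        tl = tq.recovery_timeline([spec, spec, spec], seed=0)
        assert tl["ti_flow"].nunique() == 1
        assert tl["ly51_uea1_ratio"].nunique() == 1

    def test_emerging_mtecs_drive_ratio_down(self):
        from thymoquant.cytosim import ablation_recovery_timeline_specs
        specs = ablation_recovery_timeline_specs(n_timepoints=4)
        ratios = np.zeros(4)
        for seed in range(8):
            tl = tq.recovery_timeline(specs, seed=seed)
            ratios += tl["ly51_uea1_ratio"].to_numpy()
        ratios /= 8
        assert (np.diff(ratios) < 0).all()

    def test_requires_two_timepoints(self):
        with pytest.raises(ValueError):
            tq.recovery_timeline([_spec({"mTEC": 10}, {})])


class TestSurvivalTiIdentity:
    def test_ti_flow_over_ti_true_equals_survival_ratio(self):
        """ti_flow / ti_true = s_thymocyte / s_TEC-weighted within
        Monte-Carlo error (ties the simulator to the reconciliation)."""
        pop = tq.default_population("P10", scale=0.01)
        expected = 1.0 / pop.weighted_tec_survival
        ratios = []
        for seed in range(6):
            res = tq.gate(tq.dissociate(pop, seed=seed))
            ratios.append(res.ti_flow / pop.ti_true)
        mean = np.mean(ratios)
        # dominant noise: binomial TEC survivor count (~450 events)
        n_tec = pop.true_tec_count * pop.weighted_tec_survival
        mc_sd = expected / np.sqrt(n_tec) / np.sqrt(len(ratios))
        assert abs(mean - expected) < 4 * mc_sd

    def test_preferential_ctec_loss_depresses_gated_ratio(self):
        """Gated Ly51+/UEA1+ never exceeds the true cTEC/mTEC ratio when
        cortical survival is lower."""
        pop = tq.default_population("P10", scale=0.01)
        true_ratio = ((pop.classes["cTEC_outer"].count
                       + pop.classes["cTEC_inner"].count)
                      / pop.classes["mTEC"].count)
        for seed in range(20):
            res = tq.gate(tq.dissociate(pop, seed=seed))
            assert res.ly51_uea1_ratio <= true_ratio
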