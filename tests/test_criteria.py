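"""Logistic criterion transforms, aggregation algebra, triple evaluation."""

import numpy as np
import pytest

import acoforms as af
from acoforms.criteria import (
    FormEvaluation,
    default_profile,
    evaluate_triple,
    phi_diff,
    phi_dtf,
    phi_fit,
    phi_prec,
    phi_rel,
)
from acoforms.dtf import DtfResult
from acoforms.irt import CurveSet
from acoforms.model_fit import FitIndices


class TestLogitPhi:
    def test_inflection_point_is_half(self):
        assert af.logit_phi(0.97, 0.97, 100, "maximize") == pytest.approx(0.5, abs=1e-12)
        assert af.logit_phi(202.0, 202.0, 0.025, "minimize") == pytest.approx(0.5, abs=1e-12)

    def test_direct_evaluations(self):
        assert af.logit_phi(0.98, 0.97, 100, "maximize") == pytest.approx(
            1 / (1 + np.exp(-1)), abs=1e-10
        )
        assert af.logit_phi(0.03, 0.02, 100, "minimize") == pytest.approx(
            1 - 1 / (1 + np.exp(-1)), abs=1e-10
        )

    def test_monotone_directions(self):
        lo, hi = af.logit_phi(0.5, 0.63, 100, "maximize"), af.logit_phi(0.7, 0.63, 100, "maximize")
        assert lo < 0.5 < hi
        lo, hi = af.logit_phi(0.01, 0.02, 100, "minimize"), af.logit_phi(0.05, 0.02, 100, "minimize")
        assert lo > 0.5 > hi

    def test_numerically_stable_for_extreme_arguments(self):
        for x in (-1e2, 1e2):
            v = af.logit_phi(x, 0.0, 100.0, "maximize")
            assert 0.0 <= v <= 1.0 and np.isfinite(v)

    def test_invalid_slope_or_direction(self):
        with pytest.raises(ValueError):
            af.logit_phi(0.5, 0.5, -1.0, "maximize")
        with pytest.raises(ValueError):
            af.logit_phi(0.5, 0.5, 1.0, "sideways")


@pytest.fixture(scope="module")
def profile():
    return default_profile()


class TestComponentPheromones:

    def test_fit_weighting(self, profile):
        # phi_cfi=1, phi_rmsea=1 -> 1; phi_cfi=0.5, phi_rmsea=1 -> 0.625
        hi_cfi, lo_rmsea = 2.0, -1.0  # saturate the logistics
        assert phi_fit(hi_cfi, lo_rmsea, profile) == pytest.approx(1.0, abs=1e-10)
        val = (3 * 0.5 + 1 * 1.0) / 4
        assert phi_fit(0.97, lo_rmsea, profile) == pytest.approx(val, abs=1e-10)

    def test_reliability_inflection_and_step(self, profile):
        assert phi_rel(0.63, profile) == pytest.approx(0.5, abs=1e-12)
        assert phi_rel(0.64, profile) == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-6)

    def test_curve_inflections(self, profile):
        assert phi_diff(202.0, profile) == pytest.approx(0.5, abs=1e-12)
        assert phi_prec(62.0, profile) == pytest.approx(0.5, abs=1e-12)
        assert phi_diff(0.0, profile) == pytest.approx(1 / (1 + np.exp(-5.05)), abs=1e-10)

    def test_dtf_inflection_and_zero(self, profile):
        assert phi_dtf(0.13, 0.29, profile) == pytest.approx(0.5, abs=1e-12)
        expected = (1 / (1 + np.exp(-25 * 0.13)) + 1 / (1 + np.exp(-25 * 0.29))) / 2
        assert phi_dtf(0.0, 0.0, profile) == pytest.approx(expected, abs=1e-10)

    def test_sdtf_uses_magnitude(self, profile):
        assert phi_dtf(-0.3, 0.0, profile) == phi_dtf(0.3, 0.0, profile)

    def test_overall_weighted_mean(self):
        comps = dict(zip("abcde", [1.0, 0.0, 1.0, 0.0, 1.0]))
        assert af.phi_overall(comps) == pytest.approx(0.6)
        comps = dict(zip("abcde", [1.0, 0.0, 0.0, 0.0, 0.0]))
        w = dict(zip("abcde", [2.0, 1.0, 1.0, 1.0, 1.0]))
        assert af.phi_overall(comps, w) == pytest.approx(2 / 6)

    def test_unknown_weight_name_rejected(self):
        with pytest.raises(KeyError):
            af.phi_overall({"a": 0.5}, {"b": 1.0})


def _form_eval(item_ids, cfi, rmsea, rel, sdtf, udtf):
    form = af.CalibratedForm(item_ids, np.ones(len(item_ids)),
                             np.zeros(len(item_ids)), -1.0, True, 600)
    fit = FitIndices(m2=10, df=8, rmsea=rmsea, cfi=cfi, n_persons=600)
    return FormEvaluation(form=form, fit=fit, reliability=rel,
                         dtf=DtfResult(sdtf=sdtf, udtf=abs(sdtf) + udtf))


class TestEvaluateTriple:

    def _curves(self, profile, offsets, kind):
        grid = profile.grid()
        base = np.linspace(0.0, 4.0, grid.n_nodes)
        return CurveSet(grid, [base + o for o in offsets], kind)

    def test_decisive_rules_and_manual_composition(self, profile):
        """Full evaluation must equal a step-by-step manual composition."""
        evs = [
            _form_eval(["a1", "a2"], 0.99, 0.020, 0.70, -0.30, 0.02),
            _form_eval(["b1", "b2"], 0.98, 0.031, 0.66, 0.10, 0.00),
            _form_eval(["c1", "c2"], 0.95, 0.024, 0.63, 0.05, 0.01),
        ]
        tcc = self._curves(profile, [0.0, 0.1, 0.2], "tcc")
        tif = self._curves(profile, [0.0, 0.0, 0.3], "tif")
        out = evaluate_triple(evs, tcc, tif, profile)
        assert out.raw["cfi_min"] == 0.95
        assert out.raw["rmsea_max"] == 0.031
        assert out.raw["rel_min"] == 0.63
        assert out.raw["sdtf_max"] == -0.30  # max-magnitude rule keeps the sign
        tcc_sqsum = af.curve_sqsum(tcc)
        tif_sqsum = af.curve_sqsum(tif)
        manual = np.mean([
            phi_fit(0.95, 0.031, profile),
            phi_rel(0.63, profile),
            phi_diff(tcc_sqsum, profile),
            phi_prec(tif_sqsum, profile),
            phi_dtf(-0.30, out.raw["udtf_max"], profile),
        ])
        assert out.phi_overall == pytest.approx(manual, abs=1e-12)
        assert min(out.components.values()) <= out.phi_overall <= max(out.components.values())

    def test_identical_curves_maximize_matching_components(self, profile):
        evs = [_form_eval([f"{c}1"], 0.99, 0.01, 0.7, 0.0, 0.0) for c in "abc"]
        tcc = self._curves(profile, [0.0, 0.0, 0.0], "tcc")
        tif = self._curves(profile, [0.0, 0.0, 0.0], "tif")
        out = evaluate_triple(evs, tcc, tif, profile)
        assert out.components["difficulty"] == pytest.approx(phi_diff(0.0, profile))
        assert out.components["precision"] == pytest.approx(phi_prec(0.0, profile))

    def test_failed_form_collapses_to_zero(self, profile):
        evs = [_form_eval([f"{c}1"], 0.99, 0.01, 0.7, 0.0, 0.0) for c in "abc"]
        evs[1].form.converged = False
        out = evaluate_triple(
            evs,
            self._curves(profile, [0, 0, 0], "tcc"),
            self._curves(profile, [0, 0, 0], "tif"),
            profile,
        )
        assert out.failed and out.phi_overall == 0.0

    def test_wrong_form_count_rejected(self, profile):
        evs = [_form_eval(["a1"], 0.99, 0.01, 0.7, 0.0, 0.0)] * 2
        with pytest.raises(ValueError):
            evaluate_triple(evs, self._curves(profile, [0, 0], "tcc"),
                            self._curves(profile, [0, 0], "tif"), profile)

    def test_phi_strictly_inside_unit_interval(self, profile):
        evs = [
            _form_eval([f"{c}1"], 0.5, 0.3, 0.1, 2.0, 1.0) for c in "abc"
        ]  # terrible forms
        out = evaluate_triple(
            evs,
            self._curves(profile, [0, 5, 10], "tcc"),
            self._curves(profile, [0, 3, 6], "tif"),
            profile,
        )
        assert not out.failed
        assert 0.0 < out.phi_overall < 1.0
        assert all(0.0 < v < 1.0 for v in out.components.values())


class TestProfile:
    def test_round_trip_preserves_phi(self):
        prof = default_profile()
        prof2 = af.CriterionProfile.from_dict(prof.to_dict())
        for x in (0.5, 0.63, 0.9):
            assert phi_rel(x, prof) == phi_rel(x, prof2)
        for s in (0.0, 100.0, 202.0, 500.0):
            assert phi_diff(s, prof) == phi_diff(s, prof2)
        assert prof2.n_forms == prof.n_forms
        assert prof2.grid_spec == prof.grid_spec

    def test_with_thresholds_replaces_only_named(self):
        prof = default_profile()
        prof2 = prof.with_thresholds({"reliability": 0.55})
        assert prof2.criteria["reliability"].threshold == 0.55
        assert prof2.criteria["cfi"].threshold == 0.97
        with pytest.raises(KeyError):
            prof.with_thresholds({"nope": 1.0})

    def test_grid_required_with_curve_criteria(self):
        d = default_profile().to_dict()
        d["grid_spec"] = None
        with pytest.raises(ValueError, match="grid_spec"):
            af.CriterionProfile.from_dict(d)

    def test_without_dtf_profile(self):
        prof = default_profile(with_dtf=False)
        assert not prof.has_dtf
        assert "dtf" not in prof.component_weights


def test_evaluation_serializes_per_form_fit_details(small_data):
    """End-to-end evaluation carries per-form m2/df/rmsea/cfi/reliability/DTF."""
    from acoforms.criteria import evaluate_forms

    prof = default_profile()
    sets = [small_data.item_ids[i::3][:4] for i in range(3)]
    ev = evaluate_forms(small_data, sets, prof)
    d = ev.to_dict()
    assert len(d["per_form"]) == 3
    for rec in d["per_form"]:
        assert set(rec) >= {"item_ids", "m2", "df", "rmsea", "cfi", "n",
                            "reliability", "sdtf", "udtf"}
        assert rec["df"] == 2  # 4-item 2PL
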