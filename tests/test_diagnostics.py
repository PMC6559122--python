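"""Modification indices, residual diagnostics, and the amendment search."""

import numpy as np
import pytest

import fusionval as fv
from fusionval.diagnostics import (
    AmendmentPolicy,
    amend_search,
    modification_indices,
    scale_residual_diagnostic,
    standardized_residuals,
    weight_diagnostics,
)
from fusionval.model import ModelSpecError, add_amendment, declare_model
from fusionval.synthetic import mini_scenario, sample_cov, true_sigma


@pytest.fixture(scope="module")
def bypass_fit():
    """Baseline fit to data whose true model has an i1 -> d2 bypass.

    N = 4000 so the single replicate identifies the planted locus sharply;
    rate-level behaviour at N = 1000 is covered by the replication tests.
    """
    sc = mini_scenario("bypass", n_obs=4000, seed=3)
    sigma = true_sigma(sc)
    labels = [v.name for v in sc.spec.variables]
    mom = sample_cov(sigma, 4000, 31, labels=labels)
    model = fv.build_baseline(sc.spec, mom)
    return sc, fv.fit(model, mom)


class TestModificationIndices:
    def test_already_free_candidates_are_excluded_with_notice(self, mini_fit):
        cands = [fv.PathSpec("S", "d1", klass="scale_effect")]
        out = modification_indices(mini_fit, cands)
        assert len(out) == 1
        assert not np.isfinite(out[0].mi)
        assert "already free" in out[0].note

    def test_omitted_bypass_attains_maximum_mi(self, bypass_fit):
        sc, res = bypass_fit
        mis = modification_indices(res, fv.candidate_set(sc.spec))
        top = mis[0]
        assert (top.locus.source, top.locus.target) == ("i1", "d2")
        assert top.epc > 0  # the omitted true effect is positive

    def test_mi_matches_refit_chi_square_drop(self, bypass_fit):
        sc, res = bypass_fit
        mis = modification_indices(res, fv.candidate_set(sc.spec))
        checked = 0
        for m in mis:
            if not np.isfinite(m.mi) or m.mi <= 5:
                continue
            refit = fv.fit(add_amendment(res.model, m.locus), res.moments)
            drop = res.chi_square - refit.chi_square
            assert m.mi == pytest.approx(drop, rel=0.15)
            checked += 1
        assert checked >= 2

    def test_detection_rate_across_replications(self):
        # the planted bypass should win the MI race in nearly all replicates
        sc = mini_scenario("bypass", n_obs=1000, seed=11)
        rep = fv.recovery_experiment(sc, reps=200)
        assert rep.mi_detection_rate >= 0.9
        assert rep.rejection_rate >= 0.8

    def test_single_item_weight_is_unidentifiable(self):
        cfg = {
            "scale": {"name": "S", "items": ["i1"]},
            "variables": [
                {"name": "i1", "role": "scale_item", "error_fraction": 0.0},
                {"name": "d", "role": "downstream", "error_fraction": 0.0},
                {"name": "c", "role": "control", "error_fraction": 0.0},
            ],
            "paths": [{"source": "S", "target": "d"}, {"source": "c", "target": "d"}],
        }
        spec = declare_model(cfg)
        rng = np.random.default_rng(2)
        a = rng.standard_normal((3, 6))
        mom = fv.SampleMoments(["i1", "d", "c"], a @ a.T / 6 + 0.2 * np.eye(3), 300)
        res = fv.fit(fv.build_baseline(spec, mom), mom)
        out = weight_diagnostics(res)
        assert all(not np.isfinite(m.mi) for m in out)
        assert any("unidentified" in m.note for m in out)


class TestStandardizedResiduals:
    def test_saturated_model_residuals_vanish(self):
        cfg = {
            "scale": {"name": "S", "items": ["i1"]},
            "variables": [
                {"name": "i1", "role": "scale_item"},
                {"name": "d", "role": "downstream"},
                {"name": "c", "role": "control"},
            ],
            "paths": [{"source": "S", "target": "d"}, {"source": "c", "target": "d"}],
        }
        spec = declare_model(cfg)
        mom = fv.SampleMoments(
            ["i1", "d", "c"],
            np.array([[1.0, 0.3, 0.2], [0.3, 1.0, 0.25], [0.2, 0.25, 1.0]]),
            200,
        )
        res = fv.fit(fv.build_baseline(spec, mom), mom)
        assert res.chi_square == pytest.approx(0.0, abs=1e-6)
        assert np.abs(standardized_residuals(res, mom)).max() < 1e-3

    def test_item_block_is_essentially_zero_after_any_fit(self, bypass_fit):
        # the free true-score covariances reproduce the item moments even
        # under misspecification elsewhere
        sc, res = bypass_fit
        sr = standardized_residuals(res, res.moments)
        items = [res.model.obs_names.index(i) for i in sc.spec.items]
        assert np.abs(sr[np.ix_(items, items)]).max() < 0.1

    def test_magnitudes_invariant_to_variable_reordering(self, mini_true):
        sc, sigma, labels = mini_true
        mom = sample_cov(sigma, 600, 37, labels=labels)
        res1 = fv.fit(fv.build_baseline(sc.spec, mom), mom)
        sr1 = standardized_residuals(res1, mom)
        mom2 = mom.reorder(list(reversed(labels)))
        res2 = fv.fit(fv.build_baseline(sc.spec, mom2), mom2)
        sr2 = standardized_residuals(res2, mom2)
        # model variable order is identical; compare against the same layout
        assert np.allclose(np.abs(sr1), np.abs(sr2), atol=1e-6)


class TestScaleResidualDiagnostic:
    def test_small_under_fusion_true_data(self, mini_true):
        sc, sigma, labels = mini_true
        below = 0
        for r in range(20):
            mom = sample_cov(sigma, 1000, 400 + r, labels=labels)
            res = fv.fit(fv.build_baseline(sc.spec, mom), mom)
            if scale_residual_diagnostic(res).mi < 3.84:
                below += 1
        assert below >= 18  # >= 90% of replications

    def test_large_and_positive_under_genuine_extra_cause(self):
        sc = mini_scenario("extra_cause", n_obs=1000, seed=2)
        sigma = true_sigma(sc)
        labels = [v.name for v in sc.spec.variables]
        hits = 0
        for r in range(20):
            mom = sample_cov(sigma, 1000, 500 + r, labels=labels)
            res = fv.fit(fv.build_baseline(sc.spec, mom), mom)
            d = scale_residual_diagnostic(res)
            if d.mi > 3.84 and d.epc > 0:
                hits += 1
        assert hits >= 18

    def test_error_when_residual_already_free(self, mini_true):
        sc, sigma, labels = mini_true
        mom = fv.SampleMoments(labels, sigma, 1000)
        model = fv.build_baseline(sc.spec, mom)
        model = add_amendment(model, fv.PathSpec("S", "S", klass="scale_residual"))
        res = fv.fit(model, mom)
        with pytest.raises(ModelSpecError, match="already free"):
            scale_residual_diagnostic(res)


class TestWeightDiagnostics:
    def test_equal_weight_world_leaves_weights_unquestioned(self, mini_fit):
        out = weight_diagnostics(mini_fit)
        assert all(m.mi < 3.84 for m in out if np.isfinite(m.mi))

    def test_doubled_item_weight_attains_maximum_weight_mi(self):
        sc = mini_scenario("weighted", n_obs=1000, seed=2)
        sigma = true_sigma(sc)
        labels = [v.name for v in sc.spec.variables]
        mom = sample_cov(sigma, 1000, 61, labels=labels)
        res = fv.fit(fv.build_baseline(sc.spec, mom), mom)
        out = [m for m in weight_diagnostics(res) if np.isfinite(m.mi)]
        top = max(out, key=lambda m: m.mi)
        assert top.locus.source == "i1"
        assert top.epc > 0  # the world fuses i1 more strongly than 1/3


class TestAmendSearch:
    def test_zero_max_additions_returns_baseline(self, bypass_fit):
        sc, res = bypass_fit
        trace = amend_search(res, policy=AmendmentPolicy(max_additions=0))
        assert trace.steps == []
        assert trace.final is res

    def test_fusion_true_data_triggers_no_amendments(self, mini_true):
        sc, sigma, labels = mini_true
        clean = 0
        for r in range(30):
            mom = sample_cov(sigma, 1000, 600 + r, labels=labels)
            res = fv.fit(fv.build_baseline(sc.spec, mom), mom)
            trace = amend_search(res)
            if not trace.steps:
                clean += 1
        assert clean >= 27  # >= 90% of replications

    def test_search_recovers_the_planted_bypass(self, bypass_fit):
        sc, res = bypass_fit
        trace = amend_search(res)
        assert trace.status in ("resolved", "baseline_ok")
        freed = {(s.locus.source, s.locus.target) for s in trace.steps}
        assert ("i1", "d2") in freed
        # monotone improvement at each step
        for s in trace.steps:
            assert s.chi2_after <= s.chi2_before + 1e-9
            assert s.df_after == s.df_before - 1

    def test_trace_is_deterministic(self, bypass_fit):
        sc, res = bypass_fit
        t1 = amend_search(res)
        t2 = amend_search(res)
        assert [(s.locus.source, s.locus.target) for s in t1.steps] == [
            (s.locus.source, s.locus.target) for s in t2.steps
        ]
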