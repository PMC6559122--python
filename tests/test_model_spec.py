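"""Declarative spec handling, matrix translation, and df bookkeeping."""

import numpy as np
import pytest

import fusionval as fv
from fusionval import leadership as ld
from fusionval.model import ModelSpecError, declare_model, fixed_error_variance
from fusionval.synthetic import mini_config

from conftest import toy_two_item_config


class TestDeclareModel:
    def test_average_scale_weights_are_exact_reciprocals(self):
        spec = ld.alberta_spec()
        assert spec.scale.weights == pytest.approx([1 / 6] * 6)
        assert sum(spec.scale.weights) == pytest.approx(1.0)

        mini = declare_model(mini_config())
        assert mini.scale.weights == pytest.approx([1 / 3] * 3)

    def test_single_item_scale_is_a_valid_degenerate_spec(self):
        cfg = toy_two_item_config()
        cfg["scale"]["items"] = ["i1"]
        cfg["variables"] = [v for v in cfg["variables"] if v["name"] != "i2"]
        spec = declare_model(cfg)
        assert spec.scale.weights == [1.0]

    def test_unknown_variable_in_path_rejected(self):
        cfg = toy_two_item_config()
        cfg["paths"].append({"source": "S", "target": "nonexistent"})
        with pytest.raises(ModelSpecError, match="undeclared"):
            declare_model(cfg)

    def test_weight_count_must_match_item_count(self):
        cfg = toy_two_item_config()
        cfg["scale"]["weights"] = [0.5]
        with pytest.raises(ModelSpecError, match="weights"):
            declare_model(cfg)

    def test_baseline_rejects_scale_confronting_paths(self):
        cfg = toy_two_item_config()
        cfg["paths"].append({"source": "i1", "target": "d"})  # item bypass
        with pytest.raises(ModelSpecError, match="item_bypass"):
            declare_model(cfg)
        cfg = toy_two_item_config()
        cfg["paths"].append({"source": "d", "target": "S"})  # cause of scale
        with pytest.raises(ModelSpecError, match="cause_of_scale"):
            declare_model(cfg)

    def test_no_downstream_variables_is_inestimable(self):
        cfg = toy_two_item_config()
        cfg["variables"] = [v for v in cfg["variables"] if v["name"] != "d"]
        cfg["paths"] = []
        with pytest.raises(ModelSpecError, match="downstream"):
            declare_model(cfg)

    def test_serialization_round_trip_is_identity(self, alberta_moments):
        spec = ld.alberta_spec()
        spec2 = declare_model(spec.to_config())
        assert spec2.to_config() == spec.to_config()
        m1 = fv.build_baseline(spec, alberta_moments)
        m2 = fv.build_baseline(spec2, alberta_moments)
        assert [f.name for f in m1.free] == [f.name for f in m2.free]
        assert np.array_equal(m1.beta_fixed, m2.beta_fixed)
        assert np.array_equal(m1.psi_fixed, m2.psi_fixed)


class TestFixedErrorVariance:
    @pytest.mark.parametrize(
        "fraction,variance,expected",
        [(0.05, 1.20, 0.06), (0.0, 3.7, 0.0), (0.01, 0.25, 0.0025)],
    )
    def test_fraction_of_sample_variance(self, fraction, variance, expected):
        assert fixed_error_variance(fraction, variance) == pytest.approx(expected)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            fixed_error_variance(0.05, -1.0)


class TestMatrixTranslation:
    def test_items_are_perfectly_measured_latents(self, alberta_moments):
        model = fv.build_baseline(ld.alberta_spec(), alberta_moments)
        assert np.all(model.theta_matrix == 0.0)
        for it in ld.ITEMS:
            i = model.obs_names.index(it)
            assert model.lambda_matrix[i, model.index[it]] == 1.0
            # fixed unit true-score effect and 5% error variance in Psi
            assert model.beta_fixed[model.index[it], model.index[f"{it}(TS)"]] == 1.0
            assert model.psi_fixed[model.index[it], model.index[it]] == pytest.approx(
                0.05 * alberta_moments.variance(it)
            )

    def test_scale_row_carries_fixed_weights_and_zero_residual(self, alberta_moments):
        model = fv.build_baseline(ld.alberta_spec(), alberta_moments)
        s = model.index["Leadership"]
        for it in ld.ITEMS:
            assert model.beta_fixed[s, model.index[it]] == pytest.approx(1 / 6)
        assert model.psi_fixed[s, s] == 0.0
        free_keys = model.free_locus_keys()
        assert ("Psi", s, s) not in free_keys

    def test_baseline_frees_no_scale_confronting_loci(self, alberta_moments):
        model = fv.build_baseline(ld.alberta_spec(), alberta_moments)
        for f in model.free:
            assert f.klass not in ("item_bypass", "cause_of_scale")


class TestDegreesOfFreedom:
    def test_leadership_df_bookkeeping(self, alberta_moments):
        base = fv.build_baseline(ld.alberta_spec(), alberta_moments)
        assert fv.degrees_of_freedom(base) == 67
        amended = base
        for p in ld.alberta_amendments():
            amended = fv.add_amendment(amended, p)
        assert fv.degrees_of_freedom(amended) == 61
        manitoba = fv.build_baseline(ld.manitoba_spec(), alberta_moments)
        assert fv.degrees_of_freedom(manitoba) == 68

    def test_each_freed_locus_costs_one_df(self, alberta_moments):
        model = fv.build_baseline(ld.alberta_spec(), alberta_moments)
        df = fv.degrees_of_freedom(model)
        for k, p in enumerate(ld.alberta_amendments(), start=1):
            model = fv.add_amendment(model, p)
            assert fv.degrees_of_freedom(model) == df - k

    def test_saturated_model_has_zero_df(self):
        cfg = {
            "scale": {"name": "S", "items": ["i1"]},
            "variables": [
                {"name": "i1", "role": "scale_item"},
                {"name": "d", "role": "downstream"},
                {"name": "c", "role": "control"},
            ],
            "paths": [
                {"source": "S", "target": "d"},
                {"source": "c", "target": "d"},
            ],
        }
        spec = declare_model(cfg)
        mom = fv.SampleMoments(
            ["i1", "d", "c"],
            np.array([[1.0, 0.3, 0.2], [0.3, 1.0, 0.25], [0.2, 0.25, 1.0]]),
            100,
        )
        model = fv.build_baseline(spec, mom)
        assert fv.degrees_of_freedom(model) == 0


class TestAmendments:
    def test_add_then_drop_restores_original_pattern(self, alberta_moments):
        model = fv.build_baseline(ld.alberta_spec(), alberta_moments)
        path = ld.alberta_amendments()[0]
        restored = fv.drop_amendment(fv.add_amendment(model, path), path)
        assert [f.name for f in restored.free] == [f.name for f in model.free]
        assert np.array_equal(restored.beta_fixed, model.beta_fixed)
        assert np.array_equal(restored.psi_fixed, model.psi_fixed)

    def test_freeing_an_already_free_locus_rejected(self, alberta_moments):
        model = fv.build_baseline(ld.alberta_spec(), alberta_moments)
        with pytest.raises(ModelSpecError, match="already free"):
            fv.add_amendment(model, fv.PathSpec("Leadership", "Supportive"))

    def test_loop_closing_amendment_is_flagged(self, alberta_moments):
        model = fv.build_baseline(ld.alberta_spec(), alberta_moments)
        amended = fv.add_amendment(
            model, fv.PathSpec("Extra", "Leadership", klass="cause_of_scale")
        )
        assert any("closes a causal loop" in w for w in amended.warnings)

    def test_cause_of_scale_redefines_the_scale(self, alberta_moments):
        model = fv.build_baseline(ld.alberta_spec(), alberta_moments)
        assert not model.redefined
        amended = fv.add_amendment(
            model, fv.PathSpec("Staff", "Leadership", klass="cause_of_scale")
        )
        assert amended.redefined
        assert amended.report_scale_name == "New-Leadership"


class TestCandidateSet:
    def test_leadership_candidate_enumeration(self):
        spec = ld.alberta_spec()
        cands = fv.candidate_set(spec)
        bypass = [c for c in cands if c.klass == "item_bypass"]
        causes = [c for c in cands if c.klass == "cause_of_scale"]
        weights = [c for c in cands if c.klass == "item_weight"]
        residual = [c for c in cands if c.klass == "scale_residual"]
        assert len(bypass) == 6 * 7 == 42
        assert len(causes) == 6 + 7  # controls + downstream into the scale
        assert len(weights) == 6
        assert len(residual) == 1

    def test_minimal_enumeration_and_ordering(self):
        cfg = toy_two_item_config()
        cfg["scale"]["items"] = ["i1"]
        cfg["variables"] = [v for v in cfg["variables"] if v["name"] != "i2"]
        spec = declare_model(cfg)
        cands = fv.candidate_set(spec)
        assert [c.klass for c in cands if c.klass == "item_bypass"] == ["item_bypass"]
        keys = [(c.source, c.target) for c in cands]
        assert keys == sorted(keys)

    def test_loci_already_in_spec_are_excluded(self):
        cfg = mini_config()
        cfg["baseline"] = False
        cfg["paths"].append({"source": "i1", "target": "d2", "klass": "item_bypass"})
        spec = declare_model(cfg)
        keys = {c.locus_key() for c in fv.candidate_set(spec)}
        assert ("i1", "d2") not in keys
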