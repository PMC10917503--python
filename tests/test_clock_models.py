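import numpy as np
import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

from phytoclock import (
    LightProtocol,
    ParameterSet,
    Release,
    SplitCoupling,
    derive_K11,
    evaluate_light,
    get_variant,
    parameters_for_variant,
    rhs,
)
from phytoclock.clock_models import (
    StateShapeError,
    _PARAM_DIR,
    split_parameter_names,
)


class TestEvaluateLight:
    def test_light_phase_is_one(self):
        assert evaluate_light(LightProtocol(), 6.0) == pytest.approx(1.0, abs=1e-9)

    def test_dark_phase_is_zero(self):
        assert evaluate_light(LightProtocol(), 18.0) == pytest.approx(0.0, abs=1e-9)

    def test_constant_light_after_release(self):
        # 30 h into free run lands mid-subjective-night, yet light stays on
        assert evaluate_light(LightProtocol(), 8 * 24 + 30.0) == 1.0

    def test_constant_dark_release(self):
        proto = LightProtocol(release=Release.CONSTANT_DARK)
        assert evaluate_light(proto, proto.release_time_h + 6.0) == 0.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            evaluate_light(LightProtocol(), -1.0)

    def test_square_wave_when_twilight_zero(self):
        proto = LightProtocol(twilight_h=0.0)
        t = np.array([0.0, 11.999, 12.0, 23.999, 24.0])
        np.testing.assert_array_equal(
            evaluate_light(proto, t), [1.0, 1.0, 0.0, 0.0, 1.0]
        )

    def test_twilight_is_sigmoidal_and_bounded(self):
        proto = LightProtocol()
        t = np.linspace(0, 48, 4801)
        L = evaluate_light(proto, t)
        assert np.all(L >= 0.0) and np.all(L <= 1.0)
        # halfway point at the dusk edge
        assert evaluate_light(proto, 12.0) == pytest.approx(0.5, abs=1e-9)

    def test_validation(self):
        with pytest.raises(ValueError):
            LightProtocol(photoperiod_light_h=25.0)
        with pytest.raises(ValueError):
            LightProtocol(free_run_days=0)
        with pytest.raises(ValueError):
            LightProtocol(twilight_h=6.0)


class TestDeriveK11:
    def test_arithmetic_mean(self):
        assert derive_K11(2.0, 4.0) == 3.0

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_identity_under_equal_arguments(self, K):
        assert derive_K11(K, K) == pytest.approx(K)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            derive_K11(0.0, 1.0)
        with pytest.raises(ValueError):
            derive_K11(1.0, -2.0)

    def test_base_table_value(self, base_params):
        # oracle: direct arithmetic on the bundled table, read independently
        with open(_PARAM_DIR / "base.yaml") as fh:
            raw = yaml.safe_load(fh)
        expected = (raw["K4"] + raw["K5"]) / 2.0
        assert derive_K11(base_params["K4"], base_params["K5"]) == expected
        m2 = parameters_for_variant("MODEL2", base_params)
        assert m2["K11"] == expected


class TestStructure:
    def test_state_counts(self):
        assert get_variant("BASE").n_states == 9
        for name in ("MODEL1", "MODEL2", "MODEL3"):
            assert get_variant(name).n_states == 11

    def test_split_variants_have_distinct_p9_p7_labels(self):
        for name in ("MODEL1", "MODEL2", "MODEL3"):
            comps = get_variant(name).component_names
            for label in ("P9_m", "P9_p", "P7_m", "P7_p"):
                assert label in comps
            assert "P97_m" not in comps

    def test_base_has_merged_pair(self):
        comps = get_variant("BASE").component_names
        assert "P97_m" in comps and "P97_p" in comps
        assert "P9_m" not in comps

    def test_unknown_variant(self):
        with pytest.raises(KeyError):
            get_variant("MODEL4")

    def test_rhs_shape_mismatch(self, base_params):
        params = parameters_for_variant("MODEL1", base_params)
        with pytest.raises(StateShapeError):
            rhs("MODEL1", np.zeros(9), 0.0, params, LightProtocol())

    def test_rhs_output_lengths(self, base_params):
        proto = LightProtocol()
        d = rhs("BASE", np.full(9, 0.2), 3.0, base_params, proto)
        assert d.shape == (9,)
        m1 = parameters_for_variant("MODEL1", base_params)
        d = rhs("MODEL1", np.full(11, 0.2), 3.0, m1, proto)
        assert d.shape == (11,)


class TestRhsExamples:
    def test_decay_and_translation_terms(self, base_params):
        # only P9 mRNA present, no transcription: d[P9]m = -k2*m0, d[P9]p = p2*m0
        m0 = 0.7
        variant = get_variant("MODEL2")
        params = parameters_for_variant("MODEL2", base_params).replace(
            v2A_p9=0.0, v2L_p9=0.0, v2A_p7=0.0, v2L_p7=0.0
        )
        state = np.zeros(11)
        state[variant.index("P9_m")] = m0
        d = rhs(variant, state, 5.0, params, LightProtocol())
        assert d[variant.index("P9_m")] == pytest.approx(-params["k2_p9"] * m0)
        assert d[variant.index("P9_p")] == pytest.approx(params["p2_p9"] * m0)

    def test_basal_transcription_at_origin_in_dark(self, base_params):
        # all Hill denominators are 1 at the origin; light term vanishes in dark
        variant = get_variant("MODEL2")
        params = parameters_for_variant("MODEL2", base_params)
        d = rhs(variant, np.zeros(11), 18.0, params, LightProtocol())
        assert d[variant.index("P9_m")] == pytest.approx(params["v2A_p9"])
        assert d[variant.index("P7_m")] == pytest.approx(params["v2A_p7"])

    def test_model1_vs_model2_differ_only_in_p9_mrna(self, base_params):
        variant = get_variant("MODEL1")
        p1 = parameters_for_variant("MODEL1", base_params)
        p2 = parameters_for_variant("MODEL2", base_params)
        rng = np.random.default_rng(0)
        state = rng.uniform(0.1, 2.0, size=11)
        proto = LightProtocol()
        d1 = rhs("MODEL1", state, 30.0, p1, proto)
        d2 = rhs("MODEL2", state, 30.0, p2, proto)
        i_p9m = variant.index("P9_m")
        for i in range(11):
            if i == i_p9m:
                continue
            assert d1[i] == pytest.approx(d2[i], rel=1e-12)
        # the K11 term joins the shared denominator additively
        CLp = state[variant.index("CL_p")]
        P51p = state[variant.index("P51_p")]
        ELp = state[variant.index("EL_p")]
        m = state[i_p9m]
        den1 = 1 + (P51p / p1["K4"]) ** 2 + (ELp / p1["K5"]) ** 2
        den2 = den1 + (CLp / p2["K11"]) ** 2
        prod1 = d1[i_p9m] + p1["k2_p9"] * m
        prod2 = d2[i_p9m] + p2["k2_p9"] * m
        assert prod2 == pytest.approx(prod1 * den1 / den2, rel=1e-12)

    def test_model2_factor_reduces_to_K11_hill_at_clean_state(self, base_params):
        # with P51p = ELp = 0 the productions differ exactly by 1/(1+(CLp/K11)^2)
        variant = get_variant("MODEL1")
        p1 = parameters_for_variant("MODEL1", base_params)
        p2 = parameters_for_variant("MODEL2", base_params)
        state = np.zeros(11)
        state[variant.index("CL_p")] = 1.7
        state[variant.index("P9_m")] = 0.4
        i = variant.index("P9_m")
        d1 = rhs("MODEL1", state, 30.0, p1, LightProtocol())
        d2 = rhs("MODEL2", state, 30.0, p2, LightProtocol())
        prod1 = d1[i] + p1["k2_p9"] * 0.4
        prod2 = d2[i] + p2["k2_p9"] * 0.4
        assert prod2 == pytest.approx(
            prod1 / (1 + (1.7 / p2["K11"]) ** 2), rel=1e-12
        )

    def test_model2_reduces_to_model1_as_K11_grows(self, base_params):
        p1 = parameters_for_variant("MODEL1", base_params)
        p2 = parameters_for_variant("MODEL2", base_params, K11=1e12)
        rng = np.random.default_rng(1)
        state = rng.uniform(0.1, 2.0, size=11)
        d1 = rhs("MODEL1", state, 7.0, p1, LightProtocol())
        d2 = rhs("MODEL2", state, 7.0, p2, LightProtocol())
        np.testing.assert_allclose(d1, d2, rtol=1e-12, atol=1e-15)

    def test_model3_has_cl_autoregulation_and_p7_repression(self, base_params):
        variant = get_variant("MODEL3")
        p1 = parameters_for_variant("MODEL1", base_params)
        p3 = parameters_for_variant("MODEL3", base_params, K_auto=0.5)
        rng = np.random.default_rng(2)
        state = rng.uniform(0.1, 2.0, size=11)
        d1 = rhs("MODEL1", state, 7.0, p1, LightProtocol())
        d3 = rhs("MODEL3", state, 7.0, p3, LightProtocol())
        # CL, P9 and P7 mRNA productions are all reduced relative to MODEL1
        for comp in ("CL_m", "P9_m", "P7_m"):
            assert d3[variant.index(comp)] < d1[variant.index(comp)]


class TestParameterSet:
    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ParameterSet({"v1": -1.0})

    def test_zero_hill_constant_rejected(self):
        with pytest.raises(ValueError):
            ParameterSet({"K1": 0.0})

    def test_replace_is_pure(self, base_params):
        modified = base_params.replace(v4=0.0)
        assert modified["v4"] == 0.0
        assert base_params["v4"] > 0
        with pytest.raises(KeyError):
            base_params.replace(nope=1.0)

    def test_variant_files_complete(self, base_params):
        for name in ("BASE", "MODEL1", "MODEL2", "MODEL3"):
            variant = get_variant(name)
            ps = ParameterSet.from_yaml(
                _PARAM_DIR / f"{name.lower()}.yaml", variant=name
            )
            ps.require(split_parameter_names(variant))

    def test_sum_halved_halves_only_transcription(self, base_params):
        m1 = parameters_for_variant("MODEL1", base_params,
                                    coupling=SplitCoupling.SUM_HALVED)
        full = parameters_for_variant("MODEL1", base_params,
                                      coupling=SplitCoupling.INDEPENDENT_FULL)
        for copy in ("p9", "p7"):
            assert m1[f"v2A_{copy}"] == base_params["v2A"] / 2
            assert full[f"v2A_{copy}"] == base_params["v2A"]
            assert m1[f"k2_{copy}"] == base_params["k2"]
            assert m1[f"d2L_{copy}"] == base_params["d2L"]


@settings(max_examples=5, deadline=None)
@given(st.integers(min_value=0, max_value=2**32 - 1))
def test_nonnegativity_of_trajectories(seed):
    """Random positive parameter sets keep states >= -tolerance."""
    from phytoclock import run_simulation

    base = parameters_for_variant("BASE")
    rng = np.random.default_rng(seed)
    scaled = {k: v * rng.uniform(0.5, 2.0) for k, v in base.to_dict().items()}
    params = ParameterSet(scaled, variant="BASE")
    proto = LightProtocol(entrain_days=2, free_run_days=1)
    from phytoclock import SolverOptions

    traj = run_simulation(
        "BASE", params, protocol=proto,
        solver=SolverOptions(rtol=1e-6, atol=1e-9), sampling_step_h=0.5,
    )
    assert traj.states.min() >= -1e-6
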