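"""Detection model structure, per-history probabilities, and the likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dosabund import (
    DetectionModelSpec,
    GroupRecord,
    SurveyDataset,
    build_design,
    history_probability,
    inverse_link,
    negative_log_likelihood,
    predict_detection,
)
from dosabund.detection import group_probabilities, nll_and_gradient


@pytest.fixture
def mixed_dataset():
    return SurveyDataset(
        [
            GroupRecord(group_id="a", detected_obs1=1, detected_obs2=0, size_best=3,
                        forest=1, pct_conceal=0.2, pct_snow=0.9, moving=0),
            GroupRecord(group_id="b", collared=1, size_best=5, forest=0,
                        pct_conceal=0.5, pct_snow=0.4, moving=1, size_source="telemetry"),
            GroupRecord(group_id="c", detected_obs1=1, detected_obs2=1, collared=1,
                        size_best=2, forest=1, pct_conceal=0.1, pct_snow=0.3, moving=0),
            GroupRecord(group_id="d", detected_obs1=0, detected_obs2=1, size_best=12,
                        forest=0, pct_conceal=0.7, pct_snow=0.5, moving=1),
        ]
    )


class TestSpec:
    def test_parameter_count_tracks_enabled_terms(self):
        spec = DetectionModelSpec(type_effect=True, recapture_effect=True,
                                  covariates=("ln_size", "forest"))
        assert spec.coef_names() == ["b_obs1", "b_obs2", "b_type", "b_recap",
                                     "b_ln_size", "b_forest"]
        assert spec.n_parameters == 6
        assert DetectionModelSpec(observer_effect=False).coef_names() == ["b0"]

    def test_default_label_follows_field_convention(self):
        spec = DetectionModelSpec(recapture_effect=True, covariates=("ln_size",))
        assert spec.label == "observer + recapture + groupsize"

    def test_unknown_covariate_rejected(self):
        with pytest.raises(ValueError, match="unknown covariate"):
            DetectionModelSpec(covariates=("elevation",))

    def test_dict_round_trip(self):
        spec = DetectionModelSpec(type_effect=True, covariates=("forest",), label="m3")
        assert DetectionModelSpec.from_dict(spec.to_dict()) == spec


class TestBuildDesign:
    def test_two_groups_observer_only_gives_four_rows(self):
        ds = SurveyDataset(
            [GroupRecord(group_id="a", detected_obs1=1, size_best=2),
             GroupRecord(group_id="b", detected_obs2=1, size_best=4)]
        )
        design = build_design(ds, DetectionModelSpec())
        long = design.to_frame()
        assert len(long) == 4
        assert set(long.columns) == {"group_id", "observer", "b_obs1", "b_obs2"}

    def test_singleton_group_has_zero_ln_size(self):
        ds = SurveyDataset([GroupRecord(group_id="a", detected_obs1=1, size_best=1)])
        design = build_design(ds, DetectionModelSpec(covariates=("ln_size",)))
        assert design.X1[0, design.coef_names.index("b_ln_size")] == 0.0

    def test_missing_covariate_raises(self):
        ds = SurveyDataset([GroupRecord(group_id="a", detected_obs1=1, size_best=2)])
        with pytest.raises(ValueError, match="forest"):
            build_design(ds, DetectionModelSpec(covariates=("forest",)))


class TestInverseLink:
    def test_logistic_values(self):
        assert inverse_link(0.0) == 0.5
        assert inverse_link(np.log(4)) == pytest.approx(0.8, abs=1e-12)
        assert inverse_link(800.0) == 1.0
        assert inverse_link(-800.0) == 0.0


class TestHistoryProbability:
    def test_uncollared_conditional(self):
        # P(1,1)/p* = 0.25 / 0.75
        assert history_probability(0.5, 0.5, 0.5, (1, 1), collared=False) == pytest.approx(1 / 3)

    def test_collared_all_zero_unconditional(self):
        assert history_probability(0.5, 0.5, 0.5, (0, 0), collared=True) == pytest.approx(0.25)

    def test_recapture_probability_applies_after_obs1_detection(self):
        assert history_probability(0.5, 0.5, 0.8, (1, 0), collared=True) == pytest.approx(0.10)

    def test_uncollared_all_zero_rejected(self):
        with pytest.raises(ValueError, match="unobservable"):
            history_probability(0.5, 0.5, 0.5, (0, 0), collared=False)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="p1"):
            history_probability(1.5, 0.5, 0.5, (1, 1), collared=False)


_NORMALIZATION_DESIGN = []


def _normalization_design():
    if not _NORMALIZATION_DESIGN:
        ds = SurveyDataset(
            [
                GroupRecord(group_id="a", detected_obs1=1, detected_obs2=0,
                            size_best=3, forest=1),
                GroupRecord(group_id="b", collared=1, size_best=5, forest=0,
                            size_source="telemetry"),
                GroupRecord(group_id="c", detected_obs1=1, detected_obs2=1,
                            collared=1, size_best=2, forest=1),
            ]
        )
        spec = DetectionModelSpec(type_effect=True, recapture_effect=True,
                                  covariates=("ln_size", "forest"))
        _NORMALIZATION_DESIGN.append(build_design(ds, spec))
    return _NORMALIZATION_DESIGN[0]


class TestNegativeLogLikelihood:
    def test_single_uncollared_both_seen_at_zero_beta(self):
        ds = SurveyDataset([GroupRecord(group_id="u", detected_obs1=1, detected_obs2=1,
                                        size_best=1)])
        design = build_design(ds, DetectionModelSpec())
        assert negative_log_likelihood(np.zeros(2), design) == pytest.approx(np.log(3))

    def test_single_collared_missed_at_zero_beta(self):
        ds = SurveyDataset([GroupRecord(group_id="c", collared=1, size_best=2,
                                        size_source="telemetry")])
        design = build_design(ds, DetectionModelSpec())
        assert negative_log_likelihood(np.zeros(2), design) == pytest.approx(np.log(4))

    def test_non_finite_beta_rejected(self, mixed_dataset):
        design = build_design(mixed_dataset, DetectionModelSpec())
        with pytest.raises(ValueError, match="non-finite"):
            negative_log_likelihood(np.array([np.nan, 0.0]), design)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-4, 4), min_size=6, max_size=6))
    def test_per_group_probabilities_normalize(self, beta_list):
        """Admissible histories sum to 1 per group, for any coefficients."""
        design = _normalization_design()
        beta = np.asarray(beta_list)
        p1, p2i, p2r = group_probabilities(beta, design)
        for i in range(design.n_groups):
            coll = bool(design.collared[i])
            hists = [(0, 0), (0, 1), (1, 0), (1, 1)] if coll else [(0, 1), (1, 0), (1, 1)]
            total = sum(history_probability(p1[i], p2i[i], p2r[i], h, coll) for h in hists)
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_type_coefficient_zero_reduces_to_observer_only(self, mixed_dataset):
        base = build_design(mixed_dataset, DetectionModelSpec())
        typed = build_design(mixed_dataset, DetectionModelSpec(type_effect=True))
        beta = np.array([0.4, -0.3])
        assert negative_log_likelihood(np.append(beta, 0.0), typed) == pytest.approx(
            negative_log_likelihood(beta, base), abs=1e-12
        )

    def test_recapture_off_means_shared_observer2_probability(self, mixed_dataset):
        design = build_design(mixed_dataset, DetectionModelSpec())
        _, p2i, p2r = group_probabilities(np.array([0.7, -0.2]), design)
        assert np.array_equal(p2i, p2r)

    def test_analytic_gradient_matches_finite_differences(self, mixed_dataset):
        spec = DetectionModelSpec(type_effect=True, recapture_effect=True,
                                  covariates=("ln_size", "forest", "pct_snow"))
        design = build_design(mixed_dataset, spec)
        rng = np.random.default_rng(3)
        for _ in range(3):
            beta = rng.normal(0, 1, len(design.coef_names))
            _, grad = nll_and_gradient(beta, design)
            fd = np.array(
                [
                    (negative_log_likelihood(beta + 1e-6 * e, design)
                     - negative_log_likelihood(beta - 1e-6 * e, design)) / 2e-6
                    for e in np.eye(beta.size)
                ]
            )
            np.testing.assert_allclose(grad, fd, atol=5e-8)


class TestPredictDetection:
    SPEC = DetectionModelSpec(covariates=("ln_size", "forest"))

    def test_positive_size_effect_gives_monotone_curve(self):
        beta = {"b_obs1": -0.5, "b_obs2": -0.2, "b_ln_size": 0.8, "b_forest": -1.0}
        curve = predict_detection(beta, self.SPEC, sizes=np.arange(1, 30))
        assert (np.diff(curve["p_obs1"]) > 0).all()
        assert (np.diff(curve["p_obs2"]) > 0).all()

    def test_negative_forest_effect_lowers_whole_curve(self):
        beta = {"b_obs1": 0.0, "b_obs2": 0.0, "b_ln_size": 0.5, "b_forest": -1.2}
        open_curve = predict_detection(beta, self.SPEC, sizes=np.arange(1, 30), forest=0)
        forested = predict_detection(beta, self.SPEC, sizes=np.arange(1, 30), forest=1)
        assert (forested["p_obs1"] < open_curve["p_obs1"]).all()

    def test_all_zero_coefficients_give_half(self):
        curve = predict_detection({}, DetectionModelSpec(), sizes=[1, 5, 10])
        assert (curve["p_obs1"] == 0.5).all()
        assert (curve["p_obs2"] == 0.5).all()

    def test_sizes_below_one_rejected(self):
        with pytest.raises(ValueError, match="sizes"):
            predict_detection({}, self.SPEC, sizes=[0.5])
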