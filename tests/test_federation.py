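"""Site messages and pooling: exact moment pooling, Fisher correlation
pooling, Newton message additivity, and the privacy audit."""

import json

import numpy as np
import pandas as pd
import pytest

from conftest import make_site
from fedrad import (
    SiteDataset,
    pooled_correlation,
    pooled_moments,
    site_correlation,
    site_moments,
    site_newton_step,
)
from fedrad.federation import CorrelationMessage
from fedrad.simulate import GeneratorConfig, generate_federation, inject_missingness


class TestSiteMoments:
    def test_hand_arithmetic(self):
        m = site_moments(make_site([[1.0], [3.0]]))
        assert m.mean[0] == 2.0
        assert m.sum_sq_dev[0] == 2.0

    def test_symmetric_sample_has_zero_skewness(self):
        m = site_moments(make_site([[-1.0], [0.0], [1.0]]))
        assert m.skewness[0] == pytest.approx(0.0, abs=1e-12)

    def test_outlier_skewness_closed_form(self):
        # nine zeros and one 100: m2 = 900, m3 = 72000, g1 = 72000/27000 = 8/3
        m = site_moments(make_site([[0.0]] * 9 + [[100.0]]))
        assert m.skewness[0] == pytest.approx(8.0 / 3.0, rel=1e-12)

    def test_too_few_values_flags_skewness_undefined(self):
        site = make_site([[1.0], [2.0], [np.nan], [np.nan]])
        m = site_moments(site)
        assert m.n_per_feature[0] == 2
        assert np.isnan(m.skewness[0])


class TestPooledMoments:
    def test_two_site_hand_example(self):
        pm = pooled_moments(
            [site_moments(make_site([[1.0], [3.0]])), site_moments(make_site([[5.0], [7.0]]))]
        )
        assert pm.mean[0] == pytest.approx(4.0)
        assert pm.sd[0] ** 2 == pytest.approx(20.0 / 3.0)

    def test_single_site_identity(self):
        m = site_moments(make_site([[1.0], [2.0], [5.0]]))
        pm = pooled_moments([m])
        assert pm.mean[0] == pytest.approx(m.mean[0])
        assert pm.sd[0] ** 2 == pytest.approx(m.sum_sq_dev[0] / 2)

    def test_two_identical_sites_keep_common_mean(self):
        m = site_moments(make_site([[2.0], [4.0]]))
        pm = pooled_moments([m, m])
        assert pm.mean[0] == pytest.approx(3.0)

    def test_matches_concatenated_data_exactly(self):
        """Oracle: pooled formulas vs pandas on the concatenated rows."""
        rng = np.random.default_rng(0)
        sites = []
        for k, n in enumerate([37, 113, 64]):
            x = rng.normal(size=(n, 5)) * rng.uniform(0.5, 3, 5) + rng.normal(0, 2, 5)
            site = make_site(x, site_id=f"s{k}")
            site = inject_missingness(site, site.feature_ids[:2], 0.15, seed=k)
            sites.append(site)
        pm = pooled_moments([site_moments(s) for s in sites])
        concat = pd.concat([s.features for s in sites])
        np.testing.assert_allclose(pm.mean, concat.mean().to_numpy(), rtol=1e-12)
        np.testing.assert_allclose(pm.sd, concat.std(ddof=1).to_numpy(), rtol=1e-12)
        np.testing.assert_allclose(
            pm.missing_fraction, concat.isna().mean().to_numpy(), rtol=1e-12
        )


class TestPooledCorrelation:
    def test_single_site_identity(self):
        rng = np.random.default_rng(1)
        site = make_site(rng.normal(size=(50, 4)))
        msg = site_correlation(site)
        pooled = pooled_correlation([msg])
        np.testing.assert_allclose(pooled.to_numpy(), msg.corr, atol=1e-9)

    def test_identical_correlations_are_a_fixed_point(self):
        corr = np.array([[1.0, 0.7], [0.7, 1.0]])
        msgs = [
            CorrelationMessage(site_id=s, feature_ids=["a", "b"], corr=corr, n=50)
            for s in "xy"
        ]
        pooled = pooled_correlation(msgs)
        assert pooled.iloc[0, 1] == pytest.approx(0.7, abs=1e-9)

    def test_equal_weight_average_on_z_scale(self):
        msgs = [
            CorrelationMessage("x", ["a", "b"], np.array([[1.0, 0.5], [0.5, 1.0]]), n=50),
            CorrelationMessage("y", ["a", "b"], np.array([[1.0, 0.0], [0.0, 1.0]]), n=50),
        ]
        pooled = pooled_correlation(msgs)
        assert pooled.iloc[0, 1] == pytest.approx(np.tanh(np.arctanh(0.5) / 2))

    def test_tiny_site_excluded_with_warning(self):
        good = CorrelationMessage("x", ["a", "b"], np.array([[1.0, 0.4], [0.4, 1.0]]), n=50)
        tiny = CorrelationMessage("y", ["a", "b"], np.array([[1.0, -0.9], [-0.9, 1.0]]), n=3)
        with pytest.warns(UserWarning, match="excluded"):
            pooled = pooled_correlation([good, tiny])
        assert pooled.iloc[0, 1] == pytest.approx(0.4, abs=1e-9)

    def test_close_to_pooled_data_correlation_for_homogeneous_sites(self):
        cfg = GeneratorConfig(
            num_sites=4, patients_per_site=[200] * 4, num_clusters=3,
            features_per_cluster=4, within_cluster_corr=0.7, seed=21,
        )
        sites = generate_federation(cfg)
        pooled = pooled_correlation([site_correlation(s) for s in sites]).to_numpy()
        concat = pd.concat([s.features for s in sites]).corr().to_numpy()
        assert np.max(np.abs(pooled - concat)) < 0.05


class TestNewtonMessages:
    def test_null_beta_closed_form(self):
        rng = np.random.default_rng(2)
        site = make_site(rng.normal(size=(40, 2)), outcome=rng.integers(0, 2, 40))
        msg = site_newton_step(site, site.feature_ids, np.zeros(3))
        assert msg.log_likelihood == pytest.approx(-40 * np.log(2))

    def test_gradient_hand_example(self):
        site = make_site([[1.0], [-1.0]], outcome=[1, 0])
        msg = site_newton_step(site, ["f0"], np.zeros(2))
        np.testing.assert_allclose(msg.gradient, [0.0, 1.0])

    def test_additivity_over_row_partitions(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(90, 3))
        y = rng.integers(0, 2, 90)
        beta = rng.normal(size=4)
        whole = site_newton_step(make_site(x, y), ["f0", "f1", "f2"], beta)
        parts = [
            site_newton_step(make_site(x[a:b], y[a:b]), ["f0", "f1", "f2"], beta)
            for a, b in [(0, 20), (20, 55), (55, 90)]
        ]
        np.testing.assert_allclose(
            sum(p.gradient for p in parts), whole.gradient, rtol=1e-12
        )
        np.testing.assert_allclose(
            sum(p.hessian for p in parts), whole.hessian, rtol=1e-12
        )
        assert sum(p.log_likelihood for p in parts) == pytest.approx(
            whole.log_likelihood, rel=1e-12
        )

    def test_rows_with_missing_entries_dropped(self):
        site = make_site([[1.0], [np.nan], [2.0]], outcome=[1, 0, np.nan])
        msg = site_newton_step(site, ["f0"], np.zeros(2))
        assert msg.n == 1


def test_privacy_audit_payload_size_independent_of_cohort_size():
    """No serialized message array may have a patient-indexed axis."""
    from fedrad.selection import cluster_features, site_cluster_votes

    cfg_small = GeneratorConfig(num_sites=1, patients_per_site=[40], num_clusters=2,
                                features_per_cluster=3, seed=5,
                                true_coefficients={"c01_f01": 1.0})
    cfg_large = GeneratorConfig(num_sites=1, patients_per_site=[400], num_clusters=2,
                                features_per_cluster=3, seed=6,
                                true_coefficients={"c01_f01": 1.0})
    payload_shapes = {}
    for tag, cfg in [("small", cfg_small), ("large", cfg_large)]:
        site = generate_federation(cfg)[0]
        corr_msg = site_correlation(site)
        clusters = cluster_features(pd.DataFrame(
            corr_msg.corr, index=site.feature_ids, columns=site.feature_ids))
        messages = [
            site_moments(site),
            corr_msg,
            site_cluster_votes(site, clusters),
            site_newton_step(site, site.feature_ids, np.zeros(7)),
        ]
        shapes = []
        for m in messages:
            payload = json.loads(json.dumps(m.payload()))

            def dims(obj):
                if isinstance(obj, list):
                    return [len(obj)] + (dims(obj[0]) if obj and isinstance(obj[0], list) else [])
                return []

            shapes.append({k: dims(v) for k, v in payload.items() if isinstance(v, list)})
            n = payload.get("n", cfg.patients_per_site[0])
            for k, d in shapes[-1].items():
                assert cfg.patients_per_site[0] not in d, f"{k} leaks a patient axis"
        payload_shapes[tag] = shapes
    assert payload_shapes["small"] == payload_shapes["large"]
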