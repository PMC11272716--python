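"""Multiscale bootstrap: scale-wise recovery counts, the (v, c) probit fit
producing AU/BP/SI, archive queries and the sklearn estimator wrapper."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from grouprax.bootstrap import (
    DEFAULT_SCALES,
    MultiscaleBootstrapClustering,
    cluster_frequency,
    fit_au,
    multiscale_bootstrap,
)


def two_blob_profile(n_features=60, sep=50.0, seed=0) -> pd.DataFrame:
    """Six objects in two blobs separated by `sep` x the within-blob spread."""
    rng = np.random.default_rng(seed)
    centre = rng.normal(size=n_features)
    cols = {}
    for i in range(3):
        cols[f"A{i}"] = centre + 0.1 * rng.normal(size=n_features)
    for i in range(3):
        cols[f"B{i}"] = centre + sep + 0.1 * rng.normal(size=n_features)
    return pd.DataFrame(cols)


class TestFitAU:
    def test_recovers_model_parameters_exactly(self):
        # counts generated noiselessly from the probit model, v=1, c=0.2
        v, c, B = 1.0, 0.2, 10000
        counts = {
            r: int(round(B * (1 - norm.cdf(v * np.sqrt(r) + c / np.sqrt(r)))))
            for r in DEFAULT_SCALES
        }
        s = fit_au(counts, B)
        assert s.v == pytest.approx(1.0, abs=0.02)
        assert s.c == pytest.approx(0.2, abs=0.02)
        assert s.au == pytest.approx(1 - norm.cdf(0.8), abs=1e-3)  # 0.2119
        assert s.bp == pytest.approx(1 - norm.cdf(1.2), abs=1e-3)

    def test_zero_curvature_makes_au_equal_bp(self):
        B = 10000
        counts = {
            r: int(round(B * (1 - norm.cdf(1.0 * np.sqrt(r))))) for r in DEFAULT_SCALES
        }
        s = fit_au(counts, B)
        assert abs(s.c) < 0.02
        assert s.au == pytest.approx(s.bp, abs=5e-3)

    def test_always_recovered_is_degenerate_full_support(self):
        counts = {r: 1000 for r in DEFAULT_SCALES}
        s = fit_au(counts, 1000)
        assert s.au == 1.0 and s.bp == 1.0 and s.si == 1.0
        assert "degenerate" in s.flags

    def test_never_recovered_is_degenerate_zero_support(self):
        counts = {r: 0 for r in DEFAULT_SCALES}
        s = fit_au(counts, 1000)
        assert s.au == 0.0 and "degenerate" in s.flags

    def test_si_between_zero_and_one_and_below_au_for_supported(self):
        # strongly supported cluster: recovery ~97% everywhere
        B = 10000
        counts = {
            r: int(round(B * (1 - norm.cdf(-2.0 * np.sqrt(r) + 0.3 / np.sqrt(r)))))
            for r in DEFAULT_SCALES
        }
        s = fit_au(counts, B)
        assert 0.0 <= s.si <= 1.0
        assert s.si <= s.au
        assert s.au > 0.95

    def test_au_at_least_bp_under_positive_v_and_c(self):
        B = 10000
        counts = {
            r: int(round(B * (1 - norm.cdf(0.5 * np.sqrt(r) + 0.4 / np.sqrt(r)))))
            for r in DEFAULT_SCALES
        }
        s = fit_au(counts, B)
        assert s.v > 0 and s.c > 0
        assert s.au >= s.bp

    def test_single_informative_scale_reports_degenerate_limit(self):
        counts = {r: 1000 for r in DEFAULT_SCALES}
        counts[1.0] = 999  # one lone failure carries no curvature information
        s = fit_au(counts, 1000)
        assert s.au == 1.0 and "degenerate" in s.flags


class TestMultiscaleBootstrap:
    def test_separated_blobs_get_full_support(self):
        res = multiscale_bootstrap(two_blob_profile(), n_boot=200, seed=1)
        for members in (["A0", "A1", "A2"], ["B0", "B1", "B2"]):
            sup = res.support_for(members)
            assert sup is not None
            assert sup.bp_raw(1.0) == pytest.approx(1.0, abs=0.02)
            assert sup.au >= 0.99

    def test_noise_profile_supports_spread_below_one(self):
        rng = np.random.default_rng(4)
        prof = pd.DataFrame(rng.normal(size=(40, 8)))
        res = multiscale_bootstrap(prof, n_boot=100, seed=2)
        aus = [s.au for s in res.supports if "root" not in s.flags]
        assert min(aus) < 0.9  # nothing is systematically certain

    def test_same_seed_reproduces_counts_exactly(self):
        prof = two_blob_profile(seed=3)
        a = multiscale_bootstrap(prof, n_boot=100, seed=42)
        b = multiscale_bootstrap(prof, n_boot=100, seed=42)
        for sa, sb in zip(a.supports, b.supports):
            assert sa.counts == sb.counts

    def test_root_always_recovered(self):
        res = multiscale_bootstrap(two_blob_profile(), n_boot=50, seed=0)
        root = [s for s in res.supports if "root" in s.flags]
        assert len(root) == 1
        assert all(v == 50 for v in root[0].counts.values())

    def test_fitted_bp_tracks_raw_recovery_fraction(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=(50, 6)) + 1.2 * rng.normal(size=(1, 6))
        res = multiscale_bootstrap(pd.DataFrame(base), n_boot=400, seed=5)
        for s in res.supports:
            if "degenerate" in s.flags or "root" in s.flags:
                continue
            raw = s.bp_raw(1.0)
            mc_se = np.sqrt(max(raw * (1 - raw), 1e-6) / 400)
            assert abs(s.bp - raw) <= max(3 * mc_se, 0.05)

    def test_tiny_feature_count_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            multiscale_bootstrap(pd.DataFrame(np.ones((5, 4))), n_boot=10, seed=0)


class TestClusterFrequency:
    def test_consistent_with_recorded_counts_and_root(self):
        res = multiscale_bootstrap(
            two_blob_profile(), n_boot=100, seed=7, keep_archive=True
        )
        for s in res.supports:
            assert cluster_frequency(s.mask, res, scale=1.0) == s.counts[1.0]
        assert cluster_frequency(list(res.dendrogram.leaves), res, scale=1.0) == 100

    def test_blob_mixing_cluster_never_seen(self):
        res = multiscale_bootstrap(
            two_blob_profile(), n_boot=100, seed=7, keep_archive=True
        )
        assert cluster_frequency(["A0", "B0"], res, scale=1.0) == 0

    def test_archive_required(self):
        res = multiscale_bootstrap(two_blob_profile(), n_boot=20, seed=0)
        with pytest.raises(ValueError, match="keep_archive"):
            cluster_frequency(["A0", "A1"], res)


class TestEstimator:
    def test_fit_sets_sklearn_attributes(self):
        X = two_blob_profile().to_numpy().T  # objects x features
        est = MultiscaleBootstrapClustering(n_boot=50, random_state=0, n_clusters=2)
        est.fit(X)
        assert est.labels_.shape == (6,)
        assert len(set(est.labels_)) == 2
        # blob membership respected
        assert len({est.labels_[i] for i in range(3)}) == 1
        assert est.dendrogram_.n_leaves == 6

    def test_get_set_params_roundtrip(self):
        est = MultiscaleBootstrapClustering(n_boot=77)
        params = est.get_params()
        assert params["n_boot"] == 77
        est.set_params(n_boot=33)
        assert est.n_boot == 33
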