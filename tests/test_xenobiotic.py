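"""ppm mass matching, fold-change tiering and dose-correlation scoring."""

import warnings

import numpy as np
import pandas as pd
import pytest

from grouprax.matrix import FeatureMatrix
from grouprax.xenobiotic import (
    PROTON_MASS,
    MassTarget,
    control_fold_filter,
    dose_correlation,
    match_mz,
    xeno_scan,
)


TARGET = MassTarget(substance="S1", label="parent", neutral_mass=349.1427)
THEO = 349.1427 + PROTON_MASS


class TestMatchMz:
    def test_within_and_outside_tolerance(self):
        # observed 350.1512 sits ~3.5 ppm above the protonated mass
        hits5 = match_mz({"f": 350.1512}, [TARGET], ppm_tol=5)
        assert len(hits5) == 1
        assert hits5[0].ppm_error == pytest.approx(
            (350.1512 - THEO) / THEO * 1e6
        )
        assert 1 < abs(hits5[0].ppm_error) < 5
        assert match_mz({"f": 350.1512}, [TARGET], ppm_tol=1) == []

    def test_exact_mass_gives_zero_ppm(self):
        hits = match_mz({"f": THEO}, [TARGET], ppm_tol=5)
        assert hits[0].ppm_error == 0.0

    def test_empty_target_list_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            assert match_mz({"f": 100.0}, [], ppm_tol=5) == []

    def test_widening_tolerance_never_loses_hits(self):
        rng = np.random.default_rng(0)
        mz = {f"f{i}": float(m) for i, m in enumerate(rng.uniform(340, 360, 50))}
        prev: set = set()
        for tol in (1, 2, 5, 20, 100):
            got = {h.feature_id for h in match_mz(mz, [TARGET], ppm_tol=tol)}
            assert prev <= got
            prev = got

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            MassTarget("X", "parent", -1.0)


def _study_matrix():
    """One substance, 3 doses x 2 reps + 2 controls, two features."""
    meta = pd.DataFrame(
        {
            "substance": ["S1"] * 8,
            "dose_level": ["low", "low", "medium", "medium", "high", "high",
                           "control", "control"],
            "time_point": ["24h"] * 8,
            "replicate": [1, 2] * 4,
            "batch": ["b1"] * 8,
        },
        index=[f"s{i}" for i in range(8)],
    )
    vals = pd.DataFrame(
        {
            "dyefeat": [10.0, 10.0, 100.0, 100.0, 1000.0, 1000.0, 0.0, 0.0],
            "flatfeat": [10.0] * 8,
        },
        index=meta.index,
    )
    return FeatureMatrix("apolar", vals, meta)


DOSES = {"S1": {"low": 1.0, "medium": 3.16, "high": 10.0}}


class TestFoldChangeFilter:
    def _hit(self, fid):
        return match_mz({fid: THEO}, [TARGET], ppm_tol=5)[0]

    def test_strong_fold_change_confirms(self):
        fm = _study_matrix()
        vals = fm.values.copy()
        vals.loc[["s6", "s7"], "dyefeat"] = 10.0  # control mean 10, treated 370
        fm2 = FeatureMatrix("apolar", vals, fm.meta)
        hits = control_fold_filter([self._hit("dyefeat")], fm2, min_fc=10)
        assert hits[0].tier == "confirmed"

    def test_flat_feature_is_tentative(self):
        hits = control_fold_filter([self._hit("flatfeat")], _study_matrix(), min_fc=10)
        assert hits[0].tier == "tentative"
        assert hits[0].fold_change == pytest.approx(1.0)

    def test_zero_control_confirms_with_flag(self):
        hits = control_fold_filter([self._hit("dyefeat")], _study_matrix(), min_fc=10)
        assert hits[0].tier == "confirmed"
        assert "infinite_fc" in hits[0].flags


class TestDoseCorrelation:
    def _hits(self, fid="dyefeat"):
        return match_mz({fid: THEO}, [TARGET], ppm_tol=5)

    def test_perfect_monotone_increase(self):
        hits = dose_correlation(self._hits(), _study_matrix(), DOSES)
        assert hits[0].dose_corr == pytest.approx(1.0)
        assert hits[0].dose_responsive

    def test_reversed_intensities_give_minus_one(self):
        fm = _study_matrix()
        vals = fm.values.copy()
        # reverse the treated dose-response (controls excluded from the test)
        vals.loc[vals.index[:6], "dyefeat"] = vals["dyefeat"].iloc[:6][::-1].to_numpy()
        fm2 = FeatureMatrix("apolar", vals, fm.meta)
        hits = dose_correlation(self._hits(), fm2, DOSES, include_controls=False)
        assert hits[0].dose_corr == pytest.approx(-1.0)
        assert not hits[0].dose_responsive

    def test_replicate_order_within_dose_irrelevant(self):
        fm = _study_matrix()
        vals = fm.values.copy()
        vals.loc[["s0", "s1"], "dyefeat"] = [11.0, 9.0]
        a = dose_correlation(self._hits(), FeatureMatrix("apolar", vals, fm.meta), DOSES)
        vals2 = vals.copy()
        vals2.loc[["s0", "s1"], "dyefeat"] = [9.0, 11.0]
        b = dose_correlation(self._hits(), FeatureMatrix("apolar", vals2, fm.meta), DOSES)
        assert a[0].dose_corr == pytest.approx(b[0].dose_corr)

    def test_constant_intensity_flagged_zero(self):
        hits = dose_correlation(self._hits("flatfeat"), _study_matrix(), DOSES)
        assert hits[0].dose_corr == 0.0
        assert "constant_intensity" in hits[0].flags


class TestRoundTrip:
    def test_spiked_features_and_only_those_confirmed(self, default_study):
        st = default_study
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hits = xeno_scan(
                st.layers["apolar"], st.mass_targets, nominal_doses=st.nominal_doses
            )
        confirmed = {h.feature_id for h in hits if h.tier == "confirmed"}
        assert confirmed == set(st.truth.spiked_features.values())
        for h in hits:
            if h.tier == "confirmed":
                assert h.dose_corr == pytest.approx(1.0)
                assert abs(h.ppm_error) <= 5
                # independent ppm arithmetic
                assert abs(h.mz_observed - h.mz_theoretical) / h.mz_theoretical * 1e6 == (
                    pytest.approx(abs(h.ppm_error))
                )
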