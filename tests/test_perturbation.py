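"""t-statistic profiles: computation, collapse, normalisation, concatenation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grouprax.design import TreatmentGroup
from grouprax.perturbation import (
    TStatProfile,
    _group_index,
    compute_tstats,
    concatenate_layers,
    max_perturbation_collapse,
    percent_significant,
    vector_normalize,
)

from .conftest import toy_matrix


def _profile(tdict, index=None, layer="polar", p=None):
    cols = _group_index(tdict)
    t = pd.DataFrame(
        np.column_stack(list(tdict.values())),
        columns=cols,
        index=index or range(len(next(iter(tdict.values())))),
    )
    pframe = None
    if p is not None:
        pframe = pd.DataFrame(
            np.column_stack(list(p.values())), columns=cols, index=t.index
        )
    return TStatProfile(layer=layer, t=t, p=pframe)


class TestComputeTStats:
    def test_textbook_pooled_t(self):
        # treated (4,5,6) vs control (1,2,3): t = 3/sqrt(2/3) = 3.674, df = 4
        vals = np.array([[4.0], [5.0], [6.0], [1.0], [2.0], [3.0]])
        fm = toy_matrix(vals)
        prof = compute_tstats(fm)
        g = prof.groups[0]
        assert prof.t[g].iloc[0] == pytest.approx(3.6742346, abs=1e-6)
        ref = stats.ttest_ind([4, 5, 6], [1, 2, 3], equal_var=True)
        assert prof.t[g].iloc[0] == pytest.approx(ref.statistic)
        assert prof.p[g].iloc[0] == pytest.approx(ref.pvalue)

    def test_identical_groups_give_zero(self):
        vals = np.tile([[7.0, 2.0]], (6, 1))
        prof = compute_tstats(toy_matrix(vals))
        g = prof.groups[0]
        assert (prof.t[g] == 0).all()
        assert (prof.p[g] == 1).all()
        assert prof.flags[g].all()  # zero-variance features flagged

    def test_swapping_labels_negates_t(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(5, 1, size=(8, 10))
        fm = toy_matrix(vals)
        swapped = toy_matrix(np.vstack([vals[4:], vals[:4]]))
        a = compute_tstats(fm)
        b = compute_tstats(swapped)
        assert np.allclose(a.t.to_numpy(), -b.t.to_numpy())
        assert np.allclose(a.p.to_numpy(), b.p.to_numpy())

    def test_welch_option_matches_scipy(self):
        rng = np.random.default_rng(1)
        vals = np.abs(rng.normal(5, 1, size=(8, 4)))
        prof = compute_tstats(toy_matrix(vals), equal_var=False)
        g = prof.groups[0]
        ref = stats.ttest_ind(vals[:4], vals[4:], equal_var=False)
        assert np.allclose(prof.t[g], ref.statistic)
        assert np.allclose(prof.p[g], ref.pvalue)

    def test_underreplicated_group_dropped_with_warning(self, small_study):
        fm = small_study.layers["polar"]
        keep = [
            s for s in fm.sample_ids
            if not (fm.meta.loc[s, "substance"] == "DY3"
                    and fm.meta.loc[s, "dose_level"] == "low"
                    and fm.meta.loc[s, "time_point"] == "2h"
                    and fm.meta.loc[s, "replicate"] > 1)
        ]
        crippled = fm.subset_samples(keep)
        with pytest.warns(UserWarning, match="dropped"):
            prof = compute_tstats(crippled)
        assert TreatmentGroup("DY3", "low", "2h") not in prof.groups


class TestPercentSignificant:
    def test_enumerated_examples(self):
        p = {TreatmentGroup("A", "d", "t"): np.array([0.01, 0.2, 0.03, 0.5])}
        t = {TreatmentGroup("A", "d", "t"): np.zeros(4)}
        prof = _profile(t, p=p)
        assert percent_significant(prof, alpha=0.05)["percent"].iloc[0] == 50.0
        assert percent_significant(prof, alpha=1.0)["percent"].iloc[0] == 100.0
        prof_all1 = _profile(t, p={k: np.ones(4) for k in p})
        assert percent_significant(prof_all1, alpha=0.05)["percent"].iloc[0] == 0.0

    def test_collapsed_profile_has_no_pvalues(self):
        g1 = TreatmentGroup("A", "d", "t1")
        prof = _profile({g1: np.ones(3)})
        with pytest.raises(ValueError, match="no p-values"):
            percent_significant(prof)


class TestVectorNormalize:
    def test_three_four_five(self):
        g1, g2 = TreatmentGroup("A", "d", "t"), TreatmentGroup("B", "d", "t")
        prof = _profile({g1: np.array([3.0, 0.0]), g2: np.array([4.0, 0.0])})
        out = vector_normalize(prof)
        assert out.t.iloc[0].tolist() == pytest.approx([0.6, 0.8])
        assert out.t.iloc[1].tolist() == [0.0, 0.0]  # zero row stays zero
        assert out.normalised

    def test_idempotent_and_unit_norm(self):
        rng = np.random.default_rng(2)
        tdict = {
            TreatmentGroup(f"S{i}", "d", "t"): rng.normal(size=20) for i in range(4)
        }
        once = vector_normalize(_profile(tdict))
        twice = vector_normalize(once)
        assert np.allclose(once.t.to_numpy(), twice.t.to_numpy())
        norms = np.linalg.norm(once.t.to_numpy(), axis=1)
        assert np.allclose(norms, 1.0)


class TestMaxPerturbationCollapse:
    def test_signed_maximum_kept(self):
        groups = [TreatmentGroup("A", "high", t) for t in ("2h", "24h", "48h")]
        prof = _profile(dict(zip(groups, [np.array([1.0]), np.array([-2.5]), np.array([2.0])])))
        out = max_perturbation_collapse(prof)
        assert out.t.iloc[0, 0] == -2.5
        assert out.groups == [TreatmentGroup("A", "high", None)]
        assert out.p is None

    def test_single_time_point_passthrough(self):
        g = TreatmentGroup("A", "low", "2h")
        out = max_perturbation_collapse(_profile({g: np.array([1.5, -0.5])}))
        assert out.t.iloc[:, 0].tolist() == [1.5, -0.5]

    def test_full_design_collapses_to_21_columns(self, small_study):
        import warnings

        from grouprax.pipeline import preprocess_layer

        fm, _ = preprocess_layer(small_study.layers["polar"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = compute_tstats(fm, groups=small_study.design.retained_groups())
        out = max_perturbation_collapse(prof)
        assert len(out.groups) == 21


class TestConcatenateLayers:
    def test_feature_counts_add(self):
        g = [TreatmentGroup("A", "d", None), TreatmentGroup("B", "d", None)]
        a = _profile({k: np.zeros(245) for k in g}, layer="polar")
        b = _profile({k: np.zeros(183) for k in g}, layer="apolar")
        combined = concatenate_layers([a, b])
        assert combined.n_features == 428
        assert combined.layer == "combined"
        assert combined.t.index[0].startswith("polar:")

    def test_single_input_identity(self):
        a = _profile({TreatmentGroup("A", "d", None): np.ones(5)})
        assert concatenate_layers([a]) is a

    def test_mismatched_groups_named_in_error(self):
        a = _profile({TreatmentGroup("A", "d", None): np.ones(5)}, layer="polar")
        b = _profile({TreatmentGroup("B", "d", None): np.ones(5)}, layer="apolar")
        with pytest.raises(ValueError, match="B/d"):
            concatenate_layers([a, b])

    def test_stacking_order_leaves_distances_unchanged(self):
        from grouprax.hca import distance_matrix

        rng = np.random.default_rng(3)
        g = [TreatmentGroup(s, "d", None) for s in "ABC"]
        a = _profile({k: rng.normal(size=30) for k in g}, layer="polar")
        b = _profile({k: rng.normal(size=20) for k in g}, layer="apolar")
        d1 = distance_matrix(concatenate_layers([a, b])).to_numpy()
        d2 = distance_matrix(concatenate_layers([b, a])).to_numpy()
        assert np.allclose(d1, d2)
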