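"""Differential expression: filtering, moderated t, BH, ANOVA, clustering."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import lncmod as lm
from lncmod.de import fit_variance_prior, moderated_t_stats
from lncmod.types import Contrast, ExpressionStudy

from conftest import make_study, null_two_group_config


def _two_group_study(rng, n_genes=50, n_per=6, shift=None):
    x = rng.normal(7.0, 1.0, size=(n_genes, 2 * n_per))
    if shift is not None:
        x[:len(shift), n_per:] += np.asarray(shift)[:, None]
    genes = {f"G{i}": list(x[i]) for i in range(n_genes)}
    sample_ids = [f"C{i}" for i in range(n_per)] + [f"M{i}" for i in range(n_per)]
    groups = {s: ("CTR" if s.startswith("C") else "MDS-EB2")
              for s in sample_ids}
    return make_study(genes, {}, groups, sample_ids=sample_ids)


CONTRAST = Contrast("mds_vs_ctr", ("MDS-EB2",), ("CTR",))


class TestDetectionFilter:
    def test_zero_fraction_is_identity(self, small_cohort):
        study = small_cohort[0]
        out = lm.detection_filter(study, min_fraction=0.0)
        assert out.gene_ids == study.gene_ids

    def test_floor_gene_removed(self):
        study = make_study({"LOW": [0.0, 0.0, 0.0], "HI": [5.0, 6.0, 7.0]},
                           {}, {})
        out = lm.detection_filter(study, min_signal=1.0, min_fraction=0.5)
        assert out.gene_ids == ["HI"]

    def test_planted_counts(self):
        rng = np.random.default_rng(0)
        vals = {f"G{i}": list(rng.uniform(5, 10, 4)) for i in range(70)}
        vals.update({f"L{i}": [0.1, 0.2, 0.1, 0.2] for i in range(30)})
        study = make_study(vals, {}, {}, sample_ids=list("ABCD"))
        out = lm.detection_filter(study, min_signal=1.0, min_fraction=0.5)
        assert out.n_genes == 70

    def test_error_when_everything_removed(self):
        study = make_study({"G1": [1.0, 1.0]}, {}, {})
        with pytest.raises(ValueError):
            lm.detection_filter(study, min_signal=10.0, min_fraction=0.5)


class TestCollapseDuplicates:
    def _probe_study(self):
        import pandas as pd
        m = pd.DataFrame([[4.0, 1.0], [6.0, 3.0], [2.0, 2.0]],
                         index=pd.Index(["GA", "GA", "GB"], name="gene_id"),
                         columns=["S1", "S2"])
        g = pd.DataFrame({"biotype": ["PCG", "PCG", "lncRNA"],
                          "partner_id": ""},
                         index=pd.Index(["GA", "GA", "GB"], name="gene_id"))
        s = make_study({"X": [1.0, 2.0]}, {}, {},
                       sample_ids=["S1", "S2"]).samples
        return ExpressionStudy(m, g, s)

    def test_median_of_probes(self):
        out = lm.collapse_duplicates(self._probe_study())
        assert out.matrix.loc["GA", "S1"] == 5.0
        assert out.matrix.loc["GA", "S2"] == 2.0
        assert out.n_genes == 2

    def test_no_duplicates_identity(self, small_cohort):
        study = small_cohort[0]
        assert lm.collapse_duplicates(study) is study

    def test_probe_count_bookkeeping(self):
        import pandas as pd
        ids = ["A"] + ["B"] * 2 + ["C"] * 3
        m = pd.DataFrame(np.arange(12.0).reshape(6, 2),
                         index=pd.Index(ids, name="gene_id"),
                         columns=["S1", "S2"])
        g = pd.DataFrame({"biotype": "PCG", "partner_id": ""},
                         index=pd.Index(ids, name="gene_id"))
        s = make_study({"X": [1.0, 2.0]}, {}, {},
                       sample_ids=["S1", "S2"]).samples
        out = lm.collapse_duplicates(ExpressionStudy(m, g, s))
        assert out.gene_ids == ["A", "B", "C"]


class TestModeratedT:
    def test_identical_variances_are_shrinkage_fixed_point(self):
        rng = np.random.default_rng(1)
        # equal residual variance in every gene: s2_post must equal it
        base = rng.normal(size=(30, 1))
        noise = rng.normal(size=6)
        xa = base + noise[None, :3]
        xb = base + noise[None, 3:]
        st_ = moderated_t_stats(xa, xb)
        assert np.allclose(st_["s2_post"], st_["s2_g"], atol=1e-12)

    def test_d0_zero_reduces_to_ordinary_t(self):
        rng = np.random.default_rng(2)
        xa = rng.normal(size=(40, 5))
        xb = rng.normal(size=(40, 7))
        st_ = moderated_t_stats(xa, xb, d0=0.0)
        t_ref, p_ref = stats.ttest_ind(xa, xb, axis=1)
        assert np.allclose(st_["t_mod"], t_ref, atol=1e-10)
        assert np.allclose(st_["p"], p_ref, atol=1e-10)

    def test_d0_infinite_pools_completely(self):
        rng = np.random.default_rng(3)
        xa = rng.normal(size=(40, 5))
        xb = rng.normal(size=(40, 5))
        st_ = moderated_t_stats(xa, xb, d0=np.inf, s2_0=2.0)
        assert np.allclose(st_["s2_post"], 2.0)

    def test_prior_fit_recovers_hyperparameters(self):
        # variances drawn from the scaled inverse chi-square model itself
        rng = np.random.default_rng(4)
        d0_true, s2_0_true, d_g = 8.0, 1.5, 10
        s2_prior = d0_true * s2_0_true / rng.chisquare(d0_true, size=20000)
        s2 = s2_prior * rng.chisquare(d_g, size=20000) / d_g
        d0, s2_0 = fit_variance_prior(s2, d_g)
        assert abs(d0 - d0_true) / d0_true < 0.15
        assert abs(s2_0 - s2_0_true) / s2_0_true < 0.05

    def test_group_swap_negates_logfc_preserves_p(self):
        study = _two_group_study(np.random.default_rng(5))
        res = lm.moderated_t_contrast(study, CONTRAST)
        res_swap = lm.moderated_t_contrast(study, CONTRAST.swapped())
        assert np.allclose(res["logFC"], -res_swap["logFC"], atol=1e-12)
        assert np.allclose(res["p"], res_swap["p"], atol=1e-12)

    def test_null_type_one_error_quick(self):
        fracs = []
        for seed in range(10):
            study, _ = lm.simulate_study(null_two_group_config(seed=seed))
            res = lm.moderated_t_contrast(study, CONTRAST)
            fracs.append((res["p"] < 0.05).mean())
        assert 0.02 < np.mean(fracs) < 0.08


class TestBenjaminiHochberg:
    def test_hand_evaluated_step_up(self):
        q = lm.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert lm.benjamini_hochberg([0.3])[0] == pytest.approx(0.3)

    def test_equal_ps_unchanged(self):
        q = lm.benjamini_hochberg([0.05] * 10)
        assert np.allclose(q, 0.05)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=37)
        # independent evaluation of the step-up rule
        order = np.argsort(p)
        m = len(p)
        adj = np.minimum(1.0, p[order] * m / np.arange(1, m + 1))
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        expected = np.empty_like(p)
        expected[order] = adj
        assert np.allclose(lm.benjamini_hochberg(p), expected, atol=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40),
           st.randoms(use_true_random=False))
    def test_permutation_invariance(self, pvals, rnd):
        p = np.array(pvals)
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        q = lm.benjamini_hochberg(p)
        q_perm = lm.benjamini_hochberg(p[perm])
        assert np.allclose(q[perm], q_perm, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            lm.benjamini_hochberg([0.5, 1.5])


class TestSignificanceCalls:
    def test_boundary_logfc_not_significant(self):
        rng = np.random.default_rng(7)
        study = _two_group_study(rng, n_genes=40, n_per=30,
                                 shift=[1.0] * 5 + [2.5] * 5)
        res = lm.moderated_t_contrast(study, CONTRAST)
        # force a gene to sit exactly at the threshold
        res.loc["G0", "logFC"] = 1.0
        res.loc["G0", "q"] = 1e-6
        summary = lm.call_significant(res, study, CONTRAST)
        assert "G0" not in summary.significant

    def test_recovers_planted_directions(self):
        rng = np.random.default_rng(8)
        study = _two_group_study(rng, n_genes=120, n_per=20,
                                 shift=[2.0] * 20 + [-2.0] * 10)
        res = lm.moderated_t_contrast(study, CONTRAST)
        summary = lm.call_significant(res, study, CONTRAST)
        up = {g for lst in summary.up.values() for g in lst}
        down = {g for lst in summary.down.values() for g in lst}
        planted_up = {f"G{i}" for i in range(20)}
        planted_down = {f"G{i}" for i in range(20, 30)}
        recovered = len(up & planted_up) + len(down & planted_down)
        false_calls = len(up - planted_up) + len(down - planted_down)
        assert recovered >= 27
        assert false_calls <= 0.1 * max(len(up) + len(down), 1)

    def test_looser_threshold_calls_more(self):
        rng = np.random.default_rng(9)
        study = _two_group_study(rng, n_genes=80, n_per=15,
                                 shift=[0.6] * 20)
        tight = Contrast("t", ("MDS-EB2",), ("CTR",), lfc_threshold=1.0)
        loose = Contrast("l", ("MDS-EB2",), ("CTR",), lfc_threshold=0.3)
        res = lm.moderated_t_contrast(study, tight)
        n_tight = len(lm.call_significant(res, study, tight).significant)
        res_l = lm.moderated_t_contrast(study, loose)
        n_loose = len(lm.call_significant(res_l, study, loose).significant)
        assert n_loose >= n_tight


class TestAnova:
    def test_two_groups_f_equals_t_squared(self):
        study = _two_group_study(np.random.default_rng(10), n_genes=30)
        profile = lm.anova_profile(study)
        res = lm.moderated_t_contrast(study, CONTRAST, d0=0.0)
        assert np.allclose(profile.table["F"], res["t_mod"] ** 2, atol=1e-9)

    def test_null_p_uniform(self):
        pvals = []
        for seed in range(5):
            study, _ = lm.simulate_study(null_two_group_config(seed=seed))
            pvals += list(lm.anova_profile(study).table["p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_gradient_detected(self):
        rng = np.random.default_rng(11)
        n_per = 10
        groups = ["CTR", "MDS-MLD", "MDS-EB2"]
        x = rng.normal(7, 0.4, size=(20, 3 * n_per))
        x[0, n_per:2 * n_per] += 0.75
        x[0, 2 * n_per:] += 1.5
        ids = [f"{g}{i}" for g in "cme" for i in range(n_per)]
        study = make_study({f"G{i}": list(x[i]) for i in range(20)}, {},
                           {s: groups["cme".index(s[0])] for s in ids},
                           sample_ids=ids)
        profile = lm.anova_profile(study)
        assert profile.table.loc["G0", "q"] < 0.05
        assert profile.logfc_vs_ctr.loc["G0", "CTR"] == 0.0

    def test_undersized_group_excluded(self):
        study = _two_group_study(np.random.default_rng(12), n_per=4)
        study.samples.iloc[0, study.samples.columns.get_loc("group")] = \
            "AML-MRC"
        profile = lm.anova_profile(study)
        assert "AML-MRC" not in profile.groups


class TestGroupClustering:
    def _profiled_study(self, rng, offsets):
        """One gene block per profile; groups listed per offset vector."""
        n_per = 6
        group_names = list(offsets)
        ids, group_map, cols = [], {}, []
        for gi, g in enumerate(group_names):
            for i in range(n_per):
                sid = f"s{gi}_{i}"
                ids.append(sid)
                group_map[sid] = g
        x = rng.normal(0, 0.1, size=(30, len(ids)))
        for gi, g in enumerate(group_names):
            vec = offsets[g]
            sl = slice(gi * n_per, (gi + 1) * n_per)
            for b in range(3):
                x[b * 10:(b + 1) * 10, sl] += vec[b]
        return make_study({f"G{i}": list(x[i]) for i in range(30)}, {},
                          group_map, sample_ids=ids)

    def test_three_planted_profiles_recovered(self):
        rng = np.random.default_rng(13)
        offsets = {
            "CTR": (0, 0, 0), "MDS-SLD": (0, 0, 0),
            "MDS-MLD": (2, 0, 0), "MDS-RS": (2, 0, 0),
            "MDS-EB2": (0, 2, 2), "AML-MRC": (0, 2, 2)}
        study = self._profiled_study(rng, offsets)
        clusters = lm.cluster_groups(lm.anova_profile(study), n_clusters=3)
        lab = clusters.labels
        assert lab["CTR"] == lab["MDS-SLD"]
        assert lab["MDS-MLD"] == lab["MDS-RS"]
        assert lab["MDS-EB2"] == lab["AML-MRC"]
        assert len({lab["CTR"], lab["MDS-MLD"], lab["MDS-EB2"]}) == 3

    def test_identical_profiles_cocluster_at_zero_height(self):
        rng = np.random.default_rng(14)
        offsets = {"CTR": (0, 0, 0), "MDS-MLD": (3, 0, 0),
                   "MDS-RS": (3, 0, 0)}
        study = self._profiled_study(rng, offsets)
        profile = lm.anova_profile(study)
        # make two group profiles exactly identical
        profile.logfc_vs_ctr.loc[:, "MDS-RS"] = \
            profile.logfc_vs_ctr.loc[:, "MDS-MLD"]
        clusters = lm.cluster_groups(profile, n_clusters=2)
        assert clusters.labels["MDS-MLD"] == clusters.labels["MDS-RS"]
        assert clusters.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_k_equals_groups_gives_singletons(self):
        rng = np.random.default_rng(15)
        offsets = {"CTR": (0, 0, 0), "MDS-MLD": (2, 0, 0),
                   "MDS-EB2": (0, 2, 0)}
        study = self._profiled_study(rng, offsets)
        clusters = lm.cluster_groups(lm.anova_profile(study), n_clusters=3)
        assert len(set(clusters.labels.values())) == 3

    def test_requires_significant_genes(self):
        study, _ = lm.simulate_study(null_two_group_config(seed=16,
                                                           n_genes=30))
        profile = lm.anova_profile(study)
        profile.table["q"] = 1.0
        with pytest.raises(ValueError):
            lm.cluster_groups(profile)
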