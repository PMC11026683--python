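import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from capdyn import cap_stats as cs
from capdyn import synthetic_cohort as sc


# ---------------------------------------------------------------------------
# independent oracles

def bh_stepup_oracle(pvals, q):
    """Hand transcription of the BH step-up rule."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order]
    k_max = 0
    for k in range(1, n + 1):
        if ranked[k - 1] <= k * q / n:
            k_max = k
    reject = np.zeros(n, dtype=bool)
    reject[order[:k_max]] = True
    return reject


class TestBhFdr:
    def test_hand_example_keeps_all_four(self):
        p = [0.001, 0.008, 0.039, 0.041]
        reject, _ = cs.bh_fdr(p, alpha=0.05)
        # hand computation: p(4)=.041 <= 4*.05/4=.05 -> all four rejected
        assert reject.all()

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_hand_stepup_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 11)
        p = rng.uniform(size=n) ** 2
        reject, _ = cs.bh_fdr(p, alpha=0.05)
        assert np.array_equal(reject, bh_stepup_oracle(p, 0.05))

    def test_empty_input(self):
        reject, p_adj = cs.bh_fdr(np.array([]))
        assert reject.size == 0


class TestOneSampleTMap:
    def test_closed_form_t(self):
        frames = np.array([[1.0], [2.0], [3.0]])
        tmap = cs.one_sample_t_map(frames)
        assert tmap.t[0] == pytest.approx(2 * np.sqrt(3))
        assert tmap.df == 2

    def test_all_zero_voxel_nonsignificant(self):
        rng = np.random.default_rng(0)
        frames = rng.normal(size=(20, 5))
        frames[:, 2] = 0.0
        tmap = cs.one_sample_t_map(frames)
        assert not tmap.significant[2]
        assert np.isnan(tmap.t[2])

    def test_planted_voxel_significant_after_bonferroni(self):
        # amplitude 1, noise 0.5, n=150, Bonferroni over 500 voxels:
        # noncentral-t power at alpha/m is essentially 1
        rng = np.random.default_rng(1)
        frames = rng.normal(scale=0.5, size=(150, 500))
        frames[:, 0] += 1.0
        tmap = cs.one_sample_t_map(frames)
        assert tmap.sig_pos[0]
        # null voxels essentially never survive Bonferroni
        assert tmap.significant[1:].sum() <= 1

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            cs.one_sample_t_map(np.ones((2, 30)))

    def test_two_tailed_p_matches_scipy(self):
        rng = np.random.default_rng(2)
        frames = rng.normal(size=(25, 10))
        tmap = cs.one_sample_t_map(frames)
        ref = sstats.ttest_1samp(frames, 0.0)
        assert np.allclose(tmap.t, ref.statistic)
        assert np.allclose(tmap.p, ref.pvalue)


def make_subject_maps(effects=None, noise=0.0, n_per_cell=4, m=30, seed=0):
    """Synthetic subject-level maps for one CAP, with optional planted
    cell-specific additive effects: {(genotype, age): (voxels, delta)}."""
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for genotype in ("WT", "TG"):
        for age in ("4M", "6M"):
            for _ in range(n_per_cell):
                vec = rng.normal(scale=noise, size=m) if noise else np.zeros(m)
                if effects and (genotype, age) in effects:
                    voxels, delta = effects[(genotype, age)]
                    vec[voxels] += delta
                rows.append({"subject_id": f"s{i}", "genotype": genotype,
                             "age": age, "cap": 1, "map": vec})
                i += 1
    return pd.DataFrame(rows)


class TestVoxelwiseAnova:
    def test_identical_values_no_effects(self):
        maps = make_subject_maps(noise=0.0)
        res = cs.voxelwise_two_way_anova(maps, cap=1)
        assert not res.interaction_retained.any()
        assert np.all(res.p_age == 1.0)
        assert np.all(res.p_genotype == 1.0)

    def test_planted_interaction_detected_exactly(self):
        voxels = np.arange(5)
        maps = make_subject_maps(
            effects={("TG", "6M"): (voxels, 3.0)}, noise=0.0)
        res = cs.voxelwise_two_way_anova(maps, cap=1)
        assert res.interaction_retained[voxels].all()
        assert not res.interaction_retained[5:].any()

    def test_additive_effects_do_not_trigger_interaction(self):
        # genotype main effect only, strong and noiseless-plus-jitter
        voxels = np.arange(8)
        maps = make_subject_maps(
            effects={("TG", "4M"): (voxels, 2.0), ("TG", "6M"): (voxels, 2.0)},
            noise=0.05, seed=4)
        res = cs.voxelwise_two_way_anova(maps, cap=1)
        assert np.all(res.p_genotype[voxels] < 1e-4)
        assert res.interaction_retained[voxels].sum() <= 2

    def test_interaction_type_i_rate_near_nominal(self):
        # null voxels: interaction retained at about the 5% nominal rate
        hits = 0
        total = 0
        for rep in range(200):
            maps = make_subject_maps(noise=0.5, n_per_cell=6, m=5, seed=100 + rep)
            res = cs.voxelwise_two_way_anova(maps, cap=1)
            hits += res.interaction_retained.sum()
            total += 5
        rate = hits / total
        assert 0.03 <= rate <= 0.07

    def test_anova_p_matches_statsmodels_oracle(self):
        # independent route: statsmodels OLS + anova_lm per voxel
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        maps = make_subject_maps(noise=1.0, n_per_cell=5, m=3, seed=5)
        res = cs.voxelwise_two_way_anova(maps, cap=1)
        Y = np.vstack(maps["map"].to_numpy())
        for v in range(3):
            df = maps[["genotype", "age"]].copy()
            df["y"] = Y[:, v]
            full = ols("y ~ C(genotype) * C(age)", data=df).fit()
            tab = sm.stats.anova_lm(full, typ=2)
            assert res.p_interaction[v] == pytest.approx(
                tab.loc["C(genotype):C(age)", "PR(>F)"], abs=1e-10)
            add = ols("y ~ C(genotype) + C(age)", data=df).fit()
            tab2 = sm.stats.anova_lm(add, typ=2)
            assert res.p_age[v] == pytest.approx(tab2.loc["C(age)", "PR(>F)"],
                                                 abs=1e-10)
            assert res.p_genotype[v] == pytest.approx(
                tab2.loc["C(genotype)", "PR(>F)"], abs=1e-10)


class TestClusterFilter:
    def _coords(self, shape):
        return np.column_stack(np.nonzero(np.ones(shape, dtype=bool)))

    def test_nine_voxel_blob_removed(self):
        shape = (8, 8, 2)
        coords = self._coords(shape)
        mask = np.zeros(len(coords), dtype=bool)
        vol = np.zeros(shape, dtype=bool)
        vol[0:3, 0:3, 0] = True  # 9 voxels, one slice
        mask = vol[coords[:, 0], coords[:, 1], coords[:, 2]]
        out = cs.cluster_filter(mask, coords, shape, min_cluster=10)
        assert not out.any()

    def test_ten_voxel_blob_retained(self):
        shape = (8, 8, 2)
        coords = self._coords(shape)
        vol = np.zeros(shape, dtype=bool)
        vol[0:2, 0:5, 0] = True  # 10 voxels in-plane
        mask = vol[coords[:, 0], coords[:, 1], coords[:, 2]]
        out = cs.cluster_filter(mask, coords, shape, min_cluster=10)
        assert out.sum() == 10

    def test_blob_split_across_slices_removed(self):
        # 12 voxels total but only 6 per plane: in-plane rule rejects it
        shape = (8, 8, 2)
        coords = self._coords(shape)
        vol = np.zeros(shape, dtype=bool)
        vol[0:2, 0:3, 0] = True
        vol[0:2, 0:3, 1] = True
        mask = vol[coords[:, 0], coords[:, 1], coords[:, 2]]
        out = cs.cluster_filter(mask, coords, shape, min_cluster=10)
        assert not out.any()

    def test_diagonal_counts_as_connected(self):
        # 8-connectivity: diagonal chain of 10 voxels survives
        shape = (12, 12, 1)
        coords = self._coords(shape)
        vol = np.zeros(shape, dtype=bool)
        for i in range(10):
            vol[i, i, 0] = True
        mask = vol[coords[:, 0], coords[:, 1], coords[:, 2]]
        out = cs.cluster_filter(mask, coords, shape, min_cluster=10)
        assert out.sum() == 10


class TestPosthocClusterCorrect:
    def test_posthoc_only_on_eligible_voxels(self):
        shape = (6, 6, 1)
        coords = np.column_stack(np.nonzero(np.ones(shape, dtype=bool)))
        m = len(coords)
        voxels = np.arange(12)
        maps = make_subject_maps(
            effects={("TG", "6M"): (voxels, 3.0)}, noise=0.05, m=m,
            n_per_cell=5, seed=6)
        anova = cs.voxelwise_two_way_anova(maps, cap=1)
        group_sig = np.zeros(m, dtype=bool)
        group_sig[:20] = True
        out = cs.posthoc_cluster_correct(anova, maps, 1, group_sig, coords,
                                         shape, min_cluster=10)
        for age in ("4M", "6M"):
            tested = np.isfinite(out.posthoc_t[age])
            assert np.all(tested <= (anova.interaction_retained & group_sig))
        # effect at 6M on 12 in-plane voxels -> survives cluster rule at 6M
        assert out.cluster_mask["6M"].sum() >= 10
        # cluster mask is a subset of the FDR-rejected voxels
        sig = out.posthoc_p_fdr["6M"] < 0.05
        assert np.all(out.cluster_mask["6M"] <= np.nan_to_num(sig, nan=False))

    def test_no_eligible_voxels_yields_empty_result(self):
        shape = (4, 4, 1)
        coords = np.column_stack(np.nonzero(np.ones(shape, dtype=bool)))
        maps = make_subject_maps(noise=0.5, m=16, seed=7)
        anova = cs.voxelwise_two_way_anova(maps, cap=1)
        anova.interaction_retained[:] = False
        out = cs.posthoc_cluster_correct(anova, maps, 1,
                                         np.ones(16, dtype=bool), coords, shape)
        for age in ("4M", "6M"):
            assert not out.cluster_mask[age].any()


class TestTemporalMetrics:
    def test_occurrence_counting_example(self):
        occ = cs.occurrence_percentage(np.array([1, 1, 2, 3]), K=3)
        assert np.allclose(occ, [50, 25, 25])

    def test_occurrence_single_cap(self):
        occ = cs.occurrence_percentage(np.ones(10, dtype=int), K=4)
        assert np.allclose(occ, [100, 0, 0, 0])

    def test_occurrence_sums_to_hundred(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            labels = rng.integers(1, 7, size=rng.integers(1, 300))
            occ = cs.occurrence_percentage(labels, K=6)
            assert occ.sum() == pytest.approx(100.0, abs=1e-9)

    def test_occurrence_uniform_chain(self):
        chain = sc.make_markov_spec(6, 0.85)
        seq = sc.generate_state_sequence(chain, 980, seed=17)
        occ = cs.occurrence_percentage(seq, K=6)
        assert np.all(np.abs(occ - 100 / 6) < 3 * 4)  # multinomial + runs bound

    def test_duration_run_enumeration(self):
        dur = cs.mean_duration(np.array([2, 2, 1, 2]), K=2)
        assert dur[1] == pytest.approx(1.5)  # runs {2, 1}
        assert dur[0] == pytest.approx(1.0)

    def test_duration_constant_sequence(self):
        dur = cs.mean_duration(np.full(10, 3), K=3)
        assert dur[2] == 10
        assert np.isnan(dur[0]) and np.isnan(dur[1])

    def test_duration_geometric_expectation(self):
        chain = sc.make_markov_spec(6, 0.85)
        seq = sc.generate_state_sequence(chain, 100_000, seed=23)
        dur = cs.mean_duration(seq, K=6)
        assert abs(dur.mean() - 1 / (1 - 0.85)) < 0.2
        assert np.all(np.abs(dur - 1 / (1 - 0.85)) < 0.5)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            cs.occurrence_percentage(np.array([]), K=2)
        with pytest.raises(ValueError):
            cs.mean_duration(np.array([]), K=2)

    def test_metrics_table_tidy(self):
        manifest = pd.DataFrame({
            "subject_id": ["a", "b"], "genotype": ["WT", "TG"],
            "age": ["4M", "4M"], "path": ["", ""],
        })
        seqs = {"a": np.array([1, 1, 2]), "b": np.array([2, 2, 2])}
        tab = cs.temporal_metrics_table(seqs, manifest, K=2)
        assert len(tab) == 4
        a1 = tab.query("subject_id=='a' and cap==1").iloc[0]
        assert a1.occurrence_pct == pytest.approx(100 * 2 / 3)
        assert a1.duration == pytest.approx(2.0)


def make_temporal_df(effects=None, noise=0.0, n=6, seed=0, base=20.0):
    """Per-animal metric values over genotype x age, optional planted shifts."""
    rng = np.random.default_rng(seed)
    rows = []
    for genotype in ("WT", "TG"):
        for i in range(n):
            for age in ("4M", "6M"):
                val = base + rng.normal(scale=noise) if noise else base
                if effects and (genotype, age) in effects:
                    val += effects[(genotype, age)]
                rows.append({"animal_id": f"{genotype}{i}", "genotype": genotype,
                             "age": age, "cap": 1, "occurrence_pct": val,
                             "duration": val / 4})
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_identical_values_no_effects(self):
        df = make_temporal_df()
        res = cs.mixed_anova_2x2(df, dv="occurrence_pct")
        assert res["age"]["p"] == 1.0
        assert res["genotype"]["p"] == 1.0
        assert not res["interaction"]["retained"]

    def test_wt_only_age_increase_detected(self):
        df = make_temporal_df(effects={("WT", "6M"): 10.0}, noise=0.01, seed=1)
        res = cs.mixed_anova_2x2(df, dv="occurrence_pct")
        assert res["interaction"]["p"] < 1e-6
        posthocs = {d["contrast"]: d["p"] for d in res["posthocs"]}
        assert posthocs["4M-vs-6M@WT"] < 1e-6
        assert posthocs["4M-vs-6M@TG"] > 0.05

    def test_matches_pingouin_oracle(self):
        import pingouin as pg

        df = make_temporal_df(effects={("TG", "6M"): 3.0}, noise=2.0, seed=2)
        res = cs.mixed_anova_2x2(df, dv="occurrence_pct")
        aov = pg.mixed_anova(data=df, dv="occurrence_pct", within="age",
                             subject="animal_id", between="genotype")
        aov = aov.set_index("Source")
        assert res["genotype"]["p"] == pytest.approx(
            aov.loc["genotype", "p_unc"], abs=1e-8)
        assert res["age"]["p"] == pytest.approx(aov.loc["age", "p_unc"], abs=1e-8)
        assert res["interaction"]["p"] == pytest.approx(
            aov.loc["Interaction", "p_unc"], abs=1e-8)

    def test_matches_pingouin_oracle_unbalanced(self):
        import pingouin as pg

        df = make_temporal_df(noise=1.5, seed=9)
        df = df[~df.animal_id.isin(["TG0", "TG1"])]  # 6 WT vs 4 TG
        res = cs.mixed_anova_2x2(df, dv="occurrence_pct")
        aov = pg.mixed_anova(data=df, dv="occurrence_pct", within="age",
                             subject="animal_id", between="genotype"
                             ).set_index("Source")
        for ours, theirs in (("genotype", "genotype"), ("age", "age"),
                             ("interaction", "Interaction")):
            assert res[ours]["p"] == pytest.approx(aov.loc[theirs, "p_unc"],
                                                   abs=1e-8)

    def test_subject_missing_an_age_excluded(self):
        df = make_temporal_df(noise=1.0, seed=3)
        df = df.drop(df[(df.animal_id == "WT0") & (df.age == "6M")].index)
        res = cs.mixed_anova_2x2(df, dv="occurrence_pct")  # no error
        assert np.isfinite(res["age"]["p"])

    def test_interaction_type_i_rate(self):
        hits = 0
        for rep in range(200):
            df = make_temporal_df(noise=1.0, seed=500 + rep)
            res = cs.mixed_anova_2x2(df, dv="occurrence_pct")
            hits += res["interaction"]["retained"]
        assert 0.02 <= hits / 200 <= 0.09

    def test_rm_anova_temporal_table(self):
        df = make_temporal_df(effects={("WT", "6M"): 10.0}, noise=0.1, seed=4)
        out = cs.rm_anova_temporal(df)
        inter = out.query("metric=='occurrence_pct' and effect=='interaction'")
        assert inter.iloc[0].p < 1e-6
        ph = out[out.effect.str.startswith("posthoc:")]
        assert ph.p_fdr.notna().all()
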