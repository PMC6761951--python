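import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import dunn_z_brute, kruskal_brute, mwu_enum
from zwdose.dosage import (
    exclude_and_rerun,
    kruskal_dunn,
    median_ratio_bootstrap,
    mf_analysis,
    mwu,
    quartile_analysis,
    run_dosage,
    za_analysis,
)
from zwdose.normalize import group_key


def _gm(values: dict, genes=None) -> pd.DataFrame:
    out = pd.DataFrame(values)
    out.index = pd.Index(genes or [f"g{i}" for i in range(len(out))], name="gene_id")
    return out


class TestMWU:
    def test_worked_example(self):
        res = mwu([1, 2, 3], [4, 5, 6])
        assert res.u == 0.0
        assert res.p == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        res = mwu([1, 2, 2, 5], [5, 2, 1, 2], method="exact")
        assert res.p == pytest.approx(1.0)

    def test_fully_tied_data(self):
        res = mwu([3.0, 3.0, 3.0], [3.0] * 10)
        assert res.p == 1.0

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(
        st.lists(st.integers(0, 6), min_size=1, max_size=7),
        st.lists(st.integers(0, 6), min_size=1, max_size=7),
    )
    def test_exact_matches_enumeration_oracle(self, x, y):
        ours = mwu(x, y, method="exact")
        u_ref, p_ref = mwu_enum(x, y)
        assert ours.u == pytest.approx(u_ref, abs=1e-12)
        assert ours.p == pytest.approx(p_ref, abs=1e-12)

    def test_auto_switches_to_exact_below_8(self):
        x, y = [1, 5, 3], [2, 8, 9, 4]
        assert mwu(x, y, method="auto").p == mwu(x, y, method="exact").p

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            mwu([], [1.0])


class TestMedianRatioBootstrap:
    def test_degenerate_samples(self):
        est = median_ratio_bootstrap([2.0] * 10, [4.0] * 10, n_boot=200, rng=0)
        assert est.point == pytest.approx(0.5)
        assert est.ci_low == pytest.approx(0.5)
        assert est.ci_high == pytest.approx(0.5)

    def test_printed_median_ratio_arithmetic(self):
        # larva male Z median 30 vs autosomal 76 -> 0.395
        est = median_ratio_bootstrap([30.0], [76.0], n_boot=10, rng=0)
        assert est.point == pytest.approx(30 / 76)
        # adult Z: male 52 vs female 32 -> 1.625
        est = median_ratio_bootstrap([52.0], [32.0], n_boot=10, rng=0)
        assert est.point == pytest.approx(1.625)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(3)
        num, den = rng.lognormal(1, 1, 200), rng.lognormal(1.4, 1, 300)
        a = median_ratio_bootstrap(num, den, n_boot=500, rng=11)
        b = median_ratio_bootstrap(num, den, n_boot=500, rng=11)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_zero_denominator_median_errors(self):
        with pytest.raises(ValueError):
            median_ratio_bootstrap([1.0, 2.0], [0.0, 0.0, 0.0], n_boot=10, rng=0)

    def test_same_distribution_ci_covers_one(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(40):
            num = rng.lognormal(2, 1, 500)
            den = rng.lognormal(2, 1, 500)
            est = median_ratio_bootstrap(num, den, n_boot=300, rng=rng)
            hits += est.ci_low <= 1.0 <= est.ci_high
        assert hits >= 36  # >= 90%


class TestZAandMF:
    def _null_gm(self, n_z=60, n_a=400, seed=0, z_shift=1.0, m_shift=1.0):
        rng = np.random.default_rng(seed)
        genes = [f"z{i}" for i in range(n_z)] + [f"a{i}" for i in range(n_a)]
        base = rng.lognormal(2, 1, n_z + n_a)
        shift = np.concatenate([np.full(n_z, z_shift), np.ones(n_a)])
        gm = _gm(
            {
                group_key("larva", "F"): base * shift,
                group_key("larva", "M"): base * shift * m_shift,
            },
            genes,
        )
        cls = pd.Series(["Z"] * n_z + ["A"] * n_a, index=gm.index)
        return gm, cls

    def test_constant_expression_gives_unit_ratio_and_p_one(self):
        gm, cls = self._null_gm(seed=1)
        gm[:] = 7.0
        za = za_analysis(gm, cls, n_boot=100, rng=0)
        assert (za["point"] == 1.0).all()
        assert (za["p_mwu"] == 1.0).all()
        mf = mf_analysis(gm, cls, n_boot=100, rng=0)
        assert (mf["point"] == 1.0).all()
        assert (mf["p_mwu"] == 1.0).all()

    def test_planted_multiplicative_shift_recovered(self):
        for k in (0.5, 2.0):
            gm, cls = self._null_gm(n_z=300, n_a=2000, seed=2, z_shift=k)
            za = za_analysis(gm, cls, n_boot=100, rng=0)
            assert (za["point"].between(0.9 * k, 1.1 * k)).all()

    def test_mf_restricted_to_genes_expressed_in_both_sexes(self):
        gm, cls = self._null_gm(n_z=20, n_a=50, seed=3)
        gm.iloc[0, 0] = 0.0  # female-silent Z gene must drop from M:F
        mf = mf_analysis(gm, cls, n_boot=50, rng=0)
        n_z = mf.set_index("chrom_class").loc["Z", "n_genes"]
        assert n_z == 19

    def test_scale_equivariance(self):
        gm, cls = self._null_gm(seed=4, z_shift=0.6)
        a = za_analysis(gm, cls, n_boot=200, rng=7)
        b = za_analysis(gm * 1000.0, cls, n_boot=200, rng=7)
        assert np.allclose(a["point"], b["point"])
        assert np.allclose(a["ci_low"], b["ci_low"])
        assert np.allclose(a["p_mwu"], b["p_mwu"])

    def test_no_z_genes_errors(self):
        gm, cls = self._null_gm(n_z=5, n_a=50, seed=5)
        gm.loc[cls == "Z"] = 0.0
        with pytest.raises(ValueError):
            za_analysis(gm, cls, n_boot=10, rng=0)


class TestKruskalDunn:
    def test_identical_groups(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        groups = ["Z", "Z", "Z", "A1", "A1", "A1"]
        h, p, dunn = kruskal_dunn(vals, groups)
        assert h == pytest.approx(0.0, abs=1e-12)
        assert dunn["z"].abs().max() == pytest.approx(0.0, abs=1e-12)

    def test_all_tied(self):
        h, p, dunn = kruskal_dunn([5.0] * 9, ["Z"] * 3 + ["A1"] * 3 + ["A2"] * 3)
        assert (h, p) == (0.0, 1.0)
        assert (dunn["p"] == 1.0).all()

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        n_groups = data.draw(st.integers(2, 4))
        groups = []
        for _ in range(n_groups):
            groups.append(
                data.draw(st.lists(st.integers(0, 8), min_size=2, max_size=8))
            )
        vals = [float(v) for g in groups for v in g]
        labels = [
            "Z" if i == 0 else f"A{i}" for i, g in enumerate(groups) for _ in g
        ]
        if len(set(vals)) == 1:
            return
        h, _, dunn = kruskal_dunn(vals, labels)
        h_ref, _ = kruskal_brute([list(map(float, g)) for g in groups])
        assert h == pytest.approx(h_ref, abs=1e-10)
        for j, row in enumerate(dunn.itertuples(), start=1):
            z_ref = dunn_z_brute([list(map(float, g)) for g in groups], 0, j)
            assert row.z == pytest.approx(z_ref, abs=1e-10)

    def test_planted_z_deficit_detected_per_autosome(self):
        rng = np.random.default_rng(6)
        vals, labels = [], []
        for i in range(1, 11):
            vals.extend(rng.lognormal(2, 0.8, 300))
            labels.extend([f"A{i}"] * 300)
        vals.extend(rng.lognormal(2 + np.log(0.5), 0.8, 200))
        labels.extend(["Z"] * 200)
        _, p_kw, dunn = kruskal_dunn(vals, labels)
        assert p_kw < 0.001
        assert (dunn["p"] < 0.05).sum() >= 9


class TestQuartiles:
    def test_binning_rule_on_eight_genes(self):
        male = pd.Series(
            [1.0, 2, 3, 4, 5, 6, 7, 8],
            index=pd.Index([f"g{i}" for i in range(8)], name="gene_id"),
        )
        female = male * 0.5  # max = male values
        out = quartile_analysis(male, female)
        assert list(out["n_genes"]) == [2, 2, 2, 2]
        assert list(out["male_median"]) == [1.5, 3.5, 5.5, 7.5]

    def test_remainders_go_to_lower_bins(self):
        male = pd.Series(
            np.arange(1.0, 11.0),
            index=pd.Index([f"g{i}" for i in range(10)], name="gene_id"),
        )
        out = quartile_analysis(male, male.copy())
        assert list(out["n_genes"]) == [3, 3, 2, 2]

    def test_equal_sexes_give_p_one(self):
        rng = np.random.default_rng(7)
        male = pd.Series(
            rng.lognormal(2, 1, 40),
            index=pd.Index([f"g{i}" for i in range(40)], name="gene_id"),
        )
        out = quartile_analysis(male, male.copy())
        assert (out["p"] == 1.0).all()

    def test_uniform_male_shift_significant_in_all_quartiles(self):
        rng = np.random.default_rng(8)
        female = pd.Series(
            rng.lognormal(2, 0.5, 400),
            index=pd.Index([f"g{i}" for i in range(400)], name="gene_id"),
        )
        out = quartile_analysis(female * 2.0, female)
        assert (out["p"] < 0.05).all()

    def test_too_few_genes_errors(self):
        male = pd.Series([1.0] * 5, index=pd.Index([f"g{i}" for i in range(5)], name="gene_id"))
        with pytest.raises(ValueError):
            quartile_analysis(male, male)


class TestExclusionRerun:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        n_z, n_a = 200, 1500
        genes = [f"z{i}" for i in range(n_z)] + [f"a{i}" for i in range(n_a)]
        base = rng.lognormal(2, 1, n_z + n_a)
        biased = np.zeros(n_z + n_a, dtype=bool)
        biased[:60] = True  # male-biased Z genes
        male = base * np.where(biased, 4.0, 1.0)
        gm = _gm(
            {group_key("adult", "F"): base, group_key("adult", "M"): male}, genes
        )
        cls = pd.Series(["Z"] * n_z + ["A"] * n_a, index=gm.index)
        labels = pd.Series(
            np.where(biased, "male-biased", "unbiased"), index=gm.index
        )
        return gm, cls, labels

    def test_empty_exclusion_reproduces_full_run(self):
        gm, cls, _ = self._setup()
        labels = pd.Series("unbiased", index=gm.index)
        full, reduced = exclude_and_rerun(
            gm, cls, {"adult": labels}, n_boot=150, rng=3
        )
        pd.testing.assert_frame_equal(full.za, reduced.za)
        pd.testing.assert_frame_equal(full.mf, reduced.mf)
        pd.testing.assert_frame_equal(full.quartiles, reduced.quartiles)

    def test_removing_male_biased_moves_mf_toward_one(self):
        gm, cls, labels = self._setup(seed=1)
        full, reduced = exclude_and_rerun(
            gm, cls, {"adult": labels}, n_boot=100, rng=4
        )
        mf_full = full.mf.set_index("chrom_class").loc["Z", "point"]
        mf_red = reduced.mf.set_index("chrom_class").loc["Z", "point"]
        assert abs(mf_red - 1.0) < abs(mf_full - 1.0)

    def test_random_unbiased_removal_barely_moves_za(self):
        gm, cls, _ = self._setup(seed=2)
        rng = np.random.default_rng(5)
        drop = rng.choice(gm.index, size=len(gm) // 10, replace=False)
        full = run_dosage(gm, cls, n_boot=100, rng=6)
        reduced = run_dosage(
            gm, cls, n_boot=100, rng=6, exclude_by_stage={"adult": set(drop)}
        )
        delta = (full.za["point"] - reduced.za["point"]).abs().max()
        assert delta < 0.05
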