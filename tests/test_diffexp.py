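"""Differential expression, surrogate variables, MDMR and matching."""

import numpy as np
import pandas as pd
import pytest

import rintx
from rintx.diffexp import (
    DEParams,
    count_de_genes,
    differential_expression,
    estimate_surrogate_variables,
    match_subcohort,
    mdmr_variance_explained,
    ranking_concordance,
    rin_association,
)


def frame(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"{prefix}{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )


class TestSurrogates:
    def test_pure_noise_rarely_yields_surrogates(self):
        hits = 0
        for seed in range(40):
            y = frame(np.random.default_rng(seed).normal(size=(150, 30)))
            g = np.arange(30) % 2
            sv = estimate_surrogate_variables(y, g, n_perm=30, seed=seed)
            hits += sv.shape[1] > 0
        assert hits <= 4  # parallel-analysis rule operates at the 5% level

    def test_planted_batch_factor_recovered(self, rng):
        n = 40
        batch = (np.arange(n) >= n // 2).astype(float)
        y = rng.normal(size=(200, n))
        affected = rng.random(200) < 0.3
        y[affected] += 5 * 1.0 * batch[None, :] * 1.0
        g = rng.permutation(np.arange(n) % 2)
        sv = estimate_surrogate_variables(frame(y), g, n_perm=20, seed=1)
        assert sv.shape[1] >= 1
        assert abs(np.corrcoef(sv[:, 0], batch)[0, 1]) > 0.9

    def test_orthogonal_to_primary(self, rng):
        y = rng.normal(size=(100, 24))
        y[: 30] += 4 * (np.arange(24) % 3 == 0)[None, :]
        g = np.arange(24) % 2
        sv = estimate_surrogate_variables(frame(y), g, n_perm=20, seed=0)
        gc = g - g.mean()
        for j in range(sv.shape[1]):
            assert abs(np.dot(sv[:, j], gc) / np.linalg.norm(gc)) < 1e-8


class TestDifferentialExpression:
    def test_identical_groups_zero_fold_change(self, rng):
        half = rng.normal(size=(50, 10))
        y = frame(np.hstack([half, half]))
        g = np.repeat([0, 1], 10)
        res = differential_expression(y, g)
        assert res["log2_fold_change"].to_numpy() == pytest.approx(0.0, abs=1e-12)

    def test_planted_effects_bonferroni_significant(self, rng):
        y = rng.normal(0, 0.5, size=(110, 40))
        y[:10, 20:] += 2.0
        res = differential_expression(frame(y), np.repeat([0, 1], 20))
        planted = res.index[:10]
        assert (res.loc[planted, "p_bonf"] < 0.05).all()
        false = (res["p_bonf"].iloc[10:] < 0.05).sum()
        assert false <= 1
        assert count_de_genes(res, DEParams(correction="bonferroni")) == (10, 0)

    def test_fold_threshold_excludes_small_changes(self):
        res = pd.DataFrame(
            dict(log2_fold_change=[np.log2(1.2)], statistic=[3.0],
                 p=[0.01], p_bh=[0.01], p_bonf=[0.01]),
            index=["g0"],
        )
        assert count_de_genes(res, DEParams()) == (0, 0)

    def test_all_null_p_one_counts_zero(self, rng):
        res = differential_expression(frame(rng.normal(size=(20, 12))), np.arange(12) % 2)
        res[["p", "p_bh", "p_bonf"]] = 1.0
        assert count_de_genes(res) == (0, 0)

    def test_constant_gene(self):
        y = frame(np.vstack([np.ones(8), np.random.default_rng(0).normal(size=8)]))
        res = differential_expression(y, np.arange(8) % 2)
        assert res.loc["g0", "p"] == 1.0
        assert res.loc["g0", "log2_fold_change"] == 0.0

    def test_small_group_rejected(self, rng):
        with pytest.raises(ValueError):
            differential_expression(frame(rng.normal(size=(5, 6))), [1, 0, 0, 0, 0, 0])


class TestRinAssociation:
    def test_gene_equal_to_rin(self, rng):
        rin = rng.uniform(4, 9, 30)
        y = frame(np.vstack([rin, np.full(30, 2.0)]))
        res = rin_association(y, rin)
        assert res.loc["g0", "pearson_r"] == pytest.approx(1.0)
        assert not res.loc["g1", "assessable"]
        assert np.isnan(res.loc["g1", "pearson_r"])

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            rin_association(frame(rng.normal(size=(3, 5))), np.ones(4))


class TestRankingConcordance:
    def test_self_concordance(self, rng):
        res = differential_expression(frame(rng.normal(size=(30, 10))), np.arange(10) % 2)
        rho, _ = ranking_concordance(res, res)
        assert rho == pytest.approx(1.0)

    def test_single_swap_spearman(self):
        # orderings (1,2,3,4,5) vs (2,1,3,4,5): rho = 1 - 6*2/(5*24) = 0.9
        a = pd.DataFrame(dict(log2_fold_change=[1.0, 2.0, 3.0, 4.0, 5.0]),
                         index=list("abcde"))
        b = pd.DataFrame(dict(log2_fold_change=[2.0, 1.0, 3.0, 4.0, 5.0]),
                         index=list("abcde"))
        rho, _ = ranking_concordance(a, b)
        assert rho == pytest.approx(0.9)

    def test_too_few_shared_genes(self):
        a = pd.DataFrame(dict(log2_fold_change=[1.0]), index=["x"])
        with pytest.raises(ValueError):
            ranking_concordance(a, a)


class TestMdmr:
    def test_variance_fraction_bounded(self, rng):
        y = frame(rng.normal(size=(40, 16)))
        f, frac, p = mdmr_variance_explained(y, rng.normal(size=16), n_perm=30, seed=0)
        assert 0.0 <= frac <= 1.0

    def test_separated_groups_attain_minimum_p(self, rng):
        y = rng.normal(size=(60, 20))
        grp = np.repeat([0.0, 1.0], 10)
        y += 5 * grp[None, :] * (rng.random((60, 1)) < 0.5)
        f, frac, p = mdmr_variance_explained(frame(y), grp, n_perm=50, seed=1)
        assert p == pytest.approx(1 / 51)

    def test_constant_covariate_rejected(self, rng):
        with pytest.raises(ValueError):
            mdmr_variance_explained(frame(rng.normal(size=(10, 8))), np.ones(8))

    def test_region_dominates_demographics(self, small_cohort):
        _, donors, samples, matrices, _ = small_cohort
        merged = pd.concat(
            [matrices[r].to_log2().data for r in ("HIP", "TCx")], axis=1
        )
        meta = samples.set_index("sample_id").loc[merged.columns]
        donor_meta = donors.set_index("donor_id").loc[meta["donor_id"]]
        region = (meta["region"] == "HIP").astype(float).to_numpy()
        age = donor_meta["age_at_death"].to_numpy(dtype=float)
        _, frac_region, _ = mdmr_variance_explained(merged, region, n_perm=10, seed=0)
        _, frac_age, _ = mdmr_variance_explained(merged, age, n_perm=10, seed=0)
        assert frac_region > frac_age


class TestMatching:
    def test_identical_groups_fully_paired(self):
        donors = pd.DataFrame(dict(
            donor_id=[f"d{i}" for i in range(8)],
            sex=["F"] * 4 + ["M"] * 4,
            dementia=[True, False, True, False] * 2,
        ))
        samples = pd.DataFrame(dict(
            sample_id=[f"d{i}_HIP" for i in range(8)],
            donor_id=[f"d{i}" for i in range(8)],
            region="HIP", rin=[6.0] * 8,
        ))
        pairs = match_subcohort(donors, samples)
        assert len(pairs) == 4
        assert pairs.attrs["matched_rin_gap"] == pytest.approx(0.0)

    def test_matching_shrinks_rin_gap(self):
        # dementia RIN uniformly 1 lower; greedy matching should narrow the
        # gap relative to the full cohort (oracle: best attainable pairing)
        rng = np.random.default_rng(5)
        n = 10
        dementia = np.array([True] * 4 + [False] * 6)
        rin = np.where(dementia, 5.5, 6.5) + rng.normal(0, 0.4, n)
        donors = pd.DataFrame(dict(
            donor_id=[f"d{i}" for i in range(n)], sex=["F"] * n, dementia=dementia,
        ))
        samples = pd.DataFrame(dict(
            sample_id=[f"d{i}_HIP" for i in range(n)],
            donor_id=[f"d{i}" for i in range(n)], region="HIP", rin=rin,
        ))
        pairs = match_subcohort(donors, samples)
        assert len(pairs) == 4
        assert abs(pairs.attrs["matched_rin_gap"]) < abs(pairs.attrs["full_rin_gap"])
        assert len(pairs) * 2 <= 2 * min(dementia.sum(), (~dementia).sum())

    def test_single_group_stratum_warns(self):
        donors = pd.DataFrame(dict(
            donor_id=["a", "b", "c"], sex=["F", "F", "M"],
            dementia=[True, False, True],
        ))
        samples = pd.DataFrame(dict(
            sample_id=["a_H", "b_H", "c_H"], donor_id=["a", "b", "c"],
            region="HIP", rin=[6, 7, 5],
        ))
        with pytest.warns(UserWarning, match="stratum"):
            pairs = match_subcohort(donors, samples)
        assert set(pairs["stratum"]) == {"F"}
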