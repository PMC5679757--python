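"""Module detection, eigengene post-processing, trait association."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import rintx
from rintx.coexpress import (
    ModulePartition,
    NetworkParams,
    build_modules,
    me_trait_association,
    module_eigengenes,
    module_overlap_test,
    refine_modules,
    relabel_by_marker_fraction,
    topological_overlap,
)
from rintx.enrich import GeneList, hypergeom_upper_tail


def log2_frame(values):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )


@pytest.fixture(scope="module")
def block_partition(block_design):
    _, _, samples, matrices, gt = block_design
    log2m = matrices["HIP"].to_log2()
    params = NetworkParams(variable_gene_fraction=1.0, expressed_floor=0.0)
    part = build_modules(log2m, params)
    refined = refine_modules(log2m, part, params)
    return log2m, refined, gt


class TestBuildRefine:
    def test_planted_blocks_recovered(self, block_partition):
        _, part, gt = block_partition
        truth = gt["module_id"]
        labeled = truth.index[truth > 0]
        ari = adjusted_rand_score(truth.loc[labeled], part.labels.loc[labeled])
        assert ari >= 0.8

    def test_me_tracks_latent_factor(self, block_design, block_partition):
        _, _, _, _, gt = block_design
        log2m, part, _ = block_partition
        factors = gt.attrs["module_factors"]["HIP"]
        best = []
        for m, latent in factors.items():
            cors = [abs(np.corrcoef(part.eigengenes[c], latent)[0, 1])
                    for c in part.eigengenes.columns]
            best.append(max(cors))
        assert min(best) >= 0.9

    def test_labeled_genes_satisfy_kme_threshold(self, block_partition):
        _, part, _ = block_partition
        for gene, mod in part.labels.items():
            if mod == 0 or gene not in part.kme.index:
                continue
            own = part.kme.at[gene, f"M{mod}"]
            assert own >= NetworkParams().kme_threshold - 1e-9
            assert own == pytest.approx(part.kme.loc[gene].max())

    def test_all_noise_rarely_forms_modules(self):
        hits = 0
        for seed in range(10):
            y = log2_frame(np.random.default_rng(seed).normal(5, 1, size=(80, 40)))
            part = build_modules(y, NetworkParams(variable_gene_fraction=1.0))
            hits += len(part.module_ids) > 0
        assert hits <= 1

    def test_multi_region_samples_rejected(self, small_cohort):
        _, _, samples, matrices, _ = small_cohort
        merged = pd.concat(
            [matrices["HIP"].to_log2().data, matrices["TCx"].to_log2().data], axis=1
        )
        with pytest.raises(ValueError):
            build_modules(merged, NetworkParams(), samples=samples)

    def test_too_few_genes_rejected(self, rng):
        y = log2_frame(rng.normal(size=(10, 20)))
        with pytest.raises(ValueError):
            build_modules(y, NetworkParams(variable_gene_fraction=1.0))

    def test_tom_bounds(self, rng):
        x = rng.normal(size=(30, 50))
        adj = ((1 + np.corrcoef(x)) / 2) ** 6
        tom = topological_overlap(adj)
        assert tom.min() >= 0 and tom.max() <= 1 + 1e-12


class TestEigengenes:
    def test_identical_genes_give_standardized_profile(self, rng):
        v = rng.normal(size=20)
        y = log2_frame(np.tile(v, (5, 1)))
        labels = pd.Series(1, index=y.index)
        me = module_eigengenes(y, labels)["M1"]
        z = (v - v.mean()) / v.std(ddof=1)
        assert me.to_numpy() == pytest.approx(z, abs=1e-8)

    def test_single_gene_module(self, rng):
        v = rng.normal(size=15)
        y = log2_frame(v[None, :])
        me = module_eigengenes(y, pd.Series(1, index=y.index))["M1"]
        assert np.corrcoef(me, v)[0, 1] == pytest.approx(1.0)

    def test_sign_rule_positive_on_mean(self, block_partition):
        log2m, part, _ = block_partition
        for m in part.module_ids:
            genes = part.members(m)
            x = log2m.data.loc[genes].to_numpy()
            z = (x - x.mean(1, keepdims=True)) / x.std(1, ddof=1, keepdims=True)
            assert np.corrcoef(part.eigengenes[f"M{m}"], z.mean(0))[0, 1] > 0

    def test_unit_variance(self, block_partition):
        _, part, _ = block_partition
        assert part.eigengenes.std(ddof=1).to_numpy() == pytest.approx(1.0)

    def test_sample_reorder_determinism(self, rng):
        y = log2_frame(rng.normal(size=(12, 30)) + rng.normal(size=30) * 0.8)
        labels = pd.Series(1, index=y.index)
        me = module_eigengenes(y, labels)
        perm = rng.permutation(y.columns)
        me_perm = module_eigengenes(y[perm], labels)
        assert me_perm.loc[me.index[0]].to_numpy() == pytest.approx(
            me.loc[me.index[0]].to_numpy()
        )


class TestRefinement:
    def test_merge_down_to_cap(self, rng):
        # 25 tight planted blocks must merge down to the 20-module cap
        n, per = 25, 8
        factors = rng.normal(size=(n, 60))
        rows = np.repeat(factors, per, axis=0) + rng.normal(0, 0.25, (n * per, 60))
        y = log2_frame(rows)
        params = NetworkParams(variable_gene_fraction=1.0, min_module_size=5,
                               expressed_floor=-10)
        labels = pd.Series(np.repeat(np.arange(1, n + 1), per), index=y.index)
        part = ModulePartition(labels=labels)
        refined = refine_modules(y, part, params)
        assert len(refined.module_ids) == params.max_modules

    def test_gene_equal_to_me_gets_kme_one(self, block_partition):
        log2m, part, _ = block_partition
        me = part.eigengenes["M1"]
        data = log2m.data.copy()
        data.loc["clone"] = me.to_numpy()
        params = NetworkParams(variable_gene_fraction=1.0, expressed_floor=-10)
        refined = refine_modules(data, ModulePartition(labels=part.labels.reindex(data.index, fill_value=0)), params)
        mod = refined.labels.loc["clone"]
        assert mod != 0
        assert refined.kme.at["clone", f"M{mod}"] > 0.95

    def test_monotone_module_count(self, block_partition):
        log2m, part, _ = block_partition
        again = refine_modules(log2m, part,
                               NetworkParams(variable_gene_fraction=1.0, expressed_floor=0.0))
        assert len(again.module_ids) <= max(len(part.module_ids), 1)


class TestRelabel:
    def make_partition(self):
        labels = pd.Series([1] * 4 + [2] * 10 + [3] * 6,
                           index=[f"g{i}" for i in range(20)])
        return ModulePartition(labels=labels)

    def test_marker_fraction_ordering(self):
        part = self.make_partition()
        markers = GeneList("neu", genes=("g0", "g1", "g14"))  # 50% in M1, 17% in M3
        out = relabel_by_marker_fraction(part, markers)
        assert out.labels["g0"] == 1       # highest marker fraction
        assert out.labels["g14"] == 2      # M3's 1/6 beats M2's 0
        assert out.labels["g4"] == 3

    def test_no_markers_orders_by_size(self):
        part = self.make_partition()
        out = relabel_by_marker_fraction(part, GeneList("none", genes=("zz",)))
        assert out.labels["g4"] == 1       # largest module first
        assert out.labels["g14"] == 2
        assert out.labels["g0"] == 3

    def test_pure_permutation(self):
        part = self.make_partition()
        out = relabel_by_marker_fraction(part, GeneList("m", genes=("g0",)))
        for m in part.module_ids:
            genes = set(part.members(m))
            assert any(set(out.members(k)) == genes for k in out.module_ids)


class TestTraitAssociation:
    def test_trait_equal_to_me(self, block_partition, rng):
        _, part, _ = block_partition
        traits = pd.DataFrame({
            "echo": part.eigengenes["M1"],
            "noise": rng.normal(size=len(part.eigengenes)),
            "const": 1.0,
        })
        out = me_trait_association(part.eigengenes, traits).set_index(["module", "trait"])
        assert out.loc[("M1", "echo"), "r"] == pytest.approx(1.0)
        assert out.loc[("M1", "echo"), "p_corrected"] < 1e-10
        assert not out.loc[("M1", "const"), "assessable"]

    def test_planted_pathology_association(self, block_design):
        cfg, donors, samples, matrices, gt = block_design
        log2m = matrices["HIP"].to_log2()
        params = NetworkParams(variable_gene_fraction=1.0, expressed_floor=0.0)
        part = refine_modules(log2m, build_modules(log2m, params), params)
        meta = samples.set_index("sample_id").loc[log2m.sample_ids]
        traits = meta[["gfap_ihc_density", "at8_ihc_density"]].apply(np.log)
        out = me_trait_association(part.eigengenes, traits)
        best = out.loc[out["p"].idxmin()]
        # gfap tracks the inflammation latent, which drives the last module
        assert best["trait"] == "gfap_ihc_density"
        infl = gt.attrs["module_factors"]["HIP"][cfg.n_modules]
        me = part.eigengenes[best["module"]]
        assert abs(np.corrcoef(me, infl)[0, 1]) > 0.8


class TestOverlap:
    def test_exact_formula(self):
        labels_a = pd.Series([1] * 20 + [0] * 80, index=[f"g{i}" for i in range(100)])
        labels_b = pd.Series([0] * 90 + [1] * 10, index=[f"g{i}" for i in range(100)])
        # overlap 10 of (20, 10) in universe 100
        labels_b[:] = 0
        labels_b.iloc[10:20] = 1
        out = module_overlap_test(labels_a, labels_b)
        expected = hypergeom_upper_tail(100, 20, 10, 10)
        assert out["p"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_identical_partitions_minimal_p(self, block_partition):
        _, part, _ = block_partition
        out = module_overlap_test(part.labels, part.labels)
        diag = out[out["module_a"] == out["module_b"]]
        assert (diag["p"] < 1e-20).all()

    def test_empty_universe(self):
        empty = pd.Series(dtype=int)
        with pytest.raises(ValueError):
            module_overlap_test(empty, empty)
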