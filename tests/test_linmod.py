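import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from semde.linmod import (
    DesignSpec,
    bh_adjust,
    call_de,
    collapse_to_genes,
    combine_nested,
    de_analyze,
    fit_probe_model,
    fold_change,
    relevance_filter,
    select_effects,
)
from semde.synthetic import SimulationConfig, generate_expression
from semde.qc import log_median_center

from oracles import bh_oracle, ols_normal_equations

SIMPLE_SPEC = DesignSpec(categorical=("sex", "muscle"), covariates=("carcass_weight",))


def simple_meta(n_per: int = 6, seed: int = 0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(2 * n_per):
        rows.append({
            "sample_id": f"S{i}",
            "muscle": "LM" if i < n_per else "SM",
            "sex": "F" if i % 2 == 0 else "M",
            "carcass_weight": float(rng.normal(90, 5)),
        })
    return pd.DataFrame(rows)


class TestFitProbeModel:
    def test_noiseless_additive_recovery(self):
        meta = simple_meta()
        y = (2.0 + 0.5 * (meta["sex"] == "M") + 1.5 * (meta["muscle"] == "SM")
             + 0.01 * meta["carcass_weight"])
        beta, pvals, resid = fit_probe_model(y.values, meta, SIMPLE_SPEC)
        assert np.allclose(resid, 0.0, atol=1e-10)
        # columns: intercept, sex[M], muscle[SM], carcass_weight
        assert beta == pytest.approx([2.0, 0.5, 1.5, 0.01], abs=1e-8)
        assert pvals["muscle"] == 0.0

    def test_coefficients_match_normal_equations(self):
        rng = np.random.default_rng(7)
        meta = simple_meta(8, seed=7)
        y = rng.normal(size=len(meta))
        beta, _, _ = fit_probe_model(y, meta, SIMPLE_SPEC)
        X = np.column_stack([
            np.ones(len(meta)),
            (meta["sex"] == "M").astype(float),
            (meta["muscle"] == "SM").astype(float),
            meta["carcass_weight"].astype(float),
        ])
        assert beta == pytest.approx(ols_normal_equations(X, y), abs=1e-8)

    def test_null_muscle_p_uniform(self):
        """Under the null, muscle p-values over replicates are uniform (KS)."""
        rng = np.random.default_rng(123)
        meta = simple_meta(10, seed=1)
        n_rep = 1000
        Y = rng.normal(size=(len(meta), n_rep))
        vals = pd.DataFrame(Y.T, index=[f"P{i}" for i in range(n_rep)],
                            columns=meta["sample_id"])
        res = de_analyze(vals, meta, SIMPLE_SPEC, alpha_keep=1.1)
        ks = stats.kstest(res["muscle_p"].values, "uniform")
        assert ks.pvalue > 0.01


class TestSelectEffects:
    def test_all_nuisance_dropped(self):
        spec = SIMPLE_SPEC
        kept = select_effects({"sex": 0.9, "carcass_weight": 0.9, "muscle": 0.9}, spec)
        assert kept == {"muscle"}

    def test_all_kept_when_significant(self):
        kept = select_effects({"sex": 0.001, "carcass_weight": 0.001,
                               "muscle": 0.001}, SIMPLE_SPEC)
        assert kept == {"sex", "carcass_weight", "muscle"}

    def test_muscle_forced_even_if_null(self):
        kept = select_effects({"sex": 0.01, "muscle": 0.99}, SIMPLE_SPEC)
        assert "muscle" in kept

    def test_boundary_p_dropped(self):
        # retention rule is p < 0.2 strictly
        kept = select_effects({"sex": 0.2, "muscle": 0.5}, SIMPLE_SPEC)
        assert kept == {"muscle"}


class TestAdjustedMeans:
    def test_balanced_design_equals_group_means(self):
        meta = simple_meta(8, seed=2)
        spec = DesignSpec(categorical=("sex", "muscle"), covariates=())
        rng = np.random.default_rng(2)
        y = rng.normal(size=len(meta))
        vals = pd.DataFrame([y], index=["P0"], columns=meta["sample_id"])
        res = de_analyze(vals, meta, spec, alpha_keep=1.1)
        lm = y[(meta["muscle"] == "LM").values].mean()
        sm = y[(meta["muscle"] == "SM").values].mean()
        # sex is balanced within muscle -> lsmeans equal raw group means
        assert res.loc["P0", "mean_LM"] == pytest.approx(lm, abs=1e-9)
        assert res.loc["P0", "mean_SM"] == pytest.approx(sm, abs=1e-9)

    def test_muscle_only_model(self):
        meta = simple_meta(5, seed=3)
        spec = DesignSpec(categorical=("muscle",), covariates=())
        y = np.arange(10, dtype=float)
        vals = pd.DataFrame([y], index=["P0"], columns=meta["sample_id"])
        res = de_analyze(vals, meta, spec, alpha_keep=1.1)
        assert res.loc["P0", "mean_LM"] == pytest.approx(y[:5].mean())
        assert res.loc["P0", "mean_SM"] == pytest.approx(y[5:].mean())

    def test_unbalanced_matches_grid_oracle(self):
        """lsmeans equal the equal-weight average of cell predictions."""
        rng = np.random.default_rng(11)
        meta = simple_meta(7, seed=11)
        meta = meta.drop(index=[1, 2, 3]).reset_index(drop=True)  # unbalance sex
        y = rng.normal(size=len(meta))
        beta, _, _ = fit_probe_model(y, meta, SIMPLE_SPEC)
        w_mean = meta["carcass_weight"].mean()

        def predict(sex, muscle):
            return (beta[0] + beta[1] * (sex == "M")
                    + beta[2] * (muscle == "SM") + beta[3] * w_mean)

        oracle_lm = np.mean([predict(s, "LM") for s in ("F", "M")])
        oracle_sm = np.mean([predict(s, "SM") for s in ("F", "M")])
        vals = pd.DataFrame([y], index=["P0"], columns=meta["sample_id"])
        res = de_analyze(vals, meta, SIMPLE_SPEC, alpha_keep=1.1)
        assert res.loc["P0", "mean_LM"] == pytest.approx(oracle_lm, abs=1e-9)
        assert res.loc["P0", "mean_SM"] == pytest.approx(oracle_sm, abs=1e-9)


class TestBhAdjust:
    def test_worked_case(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.42]) == pytest.approx([0.42])

    def test_nan_propagated_and_excluded(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        assert out[[0, 2]] == pytest.approx(bh_oracle([0.01, 0.04]))

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_matches_direct_stepup_oracle(self, pvals):
        got = bh_adjust(pvals)
        want = bh_oracle(pvals)
        assert np.allclose(got, want, atol=1e-12)
        assert (got >= np.asarray(pvals) - 1e-15).all()
        assert (got <= 1.0).all()
        # significant-set rank order preserved
        order_in = np.argsort(pvals, kind="stable")
        assert (np.diff(got[order_in]) >= -1e-15).all()


class TestCalls:
    def test_alpha_boundary_inclusive(self):
        df = pd.DataFrame({"padj": [0.05, 0.050001]}, index=["a", "b"])
        assert list(call_de(df).index) == ["a"]

    def test_empty_input(self):
        df = pd.DataFrame({"padj": []})
        assert len(call_de(df)) == 0

    @pytest.mark.parametrize("lm, sm, fc, direction", [
        (np.log(2), 0.0, 2.0, "LM"),
        (0.0, np.log(3), 3.0, "SM"),
    ])
    def test_fold_change(self, lm, sm, fc, direction):
        got_fc, got_dir = fold_change(lm, sm)
        assert got_fc == pytest.approx(fc)
        assert got_dir == direction

    def test_fold_change_tie(self):
        fc, direction = fold_change(1.0, 1.0)
        assert fc == 1.0 and direction is None


class TestGeneCollapse:
    def _de(self, rows):
        return pd.DataFrame(rows).set_index("probe_id")

    def test_max_fc_probe_representative(self):
        de = self._de([
            {"probe_id": "p1", "fc": 2.0, "direction": "LM", "padj": 0.01},
            {"probe_id": "p2", "fc": 1.6, "direction": "LM", "padj": 0.02},
        ])
        pmap = pd.DataFrame({"probe_id": ["p1", "p2"], "gene_id": ["g", "g"]})
        calls = collapse_to_genes(de, pmap)
        assert len(calls) == 1
        assert calls.loc["g", "fc"] == 2.0
        assert calls.loc["g", "direction"] == "LM"
        assert not calls.loc["g", "conflict"]

    def test_conflicting_directions_flagged_and_excluded(self):
        de = self._de([
            {"probe_id": "p1", "fc": 2.0, "direction": "LM", "padj": 0.01},
            {"probe_id": "p2", "fc": 1.8, "direction": "SM", "padj": 0.02},
        ])
        pmap = pd.DataFrame({"probe_id": ["p1", "p2"], "gene_id": ["g", "g"]})
        calls = collapse_to_genes(de, pmap)
        assert calls.loc["g", "conflict"]
        assert len(relevance_filter(calls, min_fc=1.0)) == 0

    def test_unannotated_probe_absent(self):
        de = self._de([{"probe_id": "p1", "fc": 2.0, "direction": "LM", "padj": 0.01}])
        pmap = pd.DataFrame({"probe_id": ["other"], "gene_id": ["g"]})
        assert len(collapse_to_genes(de, pmap)) == 0


class TestRelevanceFilter:
    def _calls(self, fcs):
        return pd.DataFrame({
            "fc": fcs, "conflict": [False] * len(fcs),
            "direction": ["LM"] * len(fcs),
        }, index=[f"g{i}" for i in range(len(fcs))])

    def test_boundary_strictly_above(self):
        calls = self._calls([1.5, 1.51])
        kept = relevance_filter(calls, min_fc=1.5)
        assert list(kept.index) == ["g1"]

    def test_min_fc_one_keeps_all(self):
        calls = self._calls([1.2, 3.0])
        assert len(relevance_filter(calls, min_fc=1.0)) == 2


@pytest.fixture(scope="module")
def lownoise():
    cfg = SimulationConfig(n_animals_per_muscle=12, n_probes=200, n_genes=200,
                           prop_de=0.3, noise_sd=0.02, flag_prob=0.0, seed=5)
    matrix, meta, truth = generate_expression(cfg)
    centered = log_median_center(matrix)
    meta = combine_nested(meta)
    res = de_analyze(centered.values, meta)
    return res, meta, truth


class TestEndToEnd:
    def test_direction_recovery_confident_calls(self, lownoise):
        res, meta, truth = lownoise
        confident = res[res["padj"] <= 0.01]
        gene_dir = truth.genes["direction"]
        pmap = truth.probe_map.set_index("probe_id")["gene_id"]
        for probe in confident.index:
            true_dir = gene_dir[pmap[probe]]
            if true_dir is not None and not pd.isna(true_dir):
                assert confident.loc[probe, "direction"] == true_dir

    def test_fc_recovery_low_noise(self, lownoise):
        """Planted FCs recovered to <1% relative error at near-zero noise."""
        res, meta, truth = lownoise
        pmap = truth.probe_map.set_index("probe_id")["gene_id"]
        de_genes = truth.de_genes()
        for probe in res.index:
            gene = pmap[probe]
            if gene in de_genes.index and res.loc[probe, "padj"] <= 0.01:
                planted = de_genes.loc[gene, "fc"]
                assert abs(res.loc[probe, "fc"] - planted) / planted < 0.05

    def test_label_swap_symmetry(self, lownoise):
        res, meta, truth = lownoise
        cfg = SimulationConfig(n_animals_per_muscle=8, n_probes=60, n_genes=60,
                               prop_de=0.4, noise_sd=0.1, flag_prob=0.0, seed=6)
        matrix, meta2, _ = generate_expression(cfg)
        centered = log_median_center(matrix)
        meta2 = combine_nested(meta2)
        res_a = de_analyze(centered.values, meta2)
        swapped = meta2.copy()
        swapped["muscle"] = swapped["muscle"].map({"LM": "SM", "SM": "LM"})
        res_b = de_analyze(centered.values, swapped)
        assert np.allclose(res_a["fc"], res_b["fc"], atol=1e-9)
        flip = {"LM": "SM", "SM": "LM"}
        for p in res_a.index[res_a["direction"].notna()]:
            assert res_b.loc[p, "direction"] == flip[res_a.loc[p, "direction"]]
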