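"""Cross-validation machinery, Fisher Z, ANOVA on predictive abilities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saltgp.bayes import GibbsConfig
from saltgp.evaluation import (
    anova_pa,
    fisher_z,
    inverse_fisher_z,
    make_partitions,
    method_agreement,
    run_cv,
    summarize_cv,
)


class TestPartitions:
    def test_sizes_follow_floor_rule(self):
        parts = make_partitions(241, 0.8, n_reps=10, seed=0)
        for tr, va in parts.splits:
            assert len(tr) == 192
            assert len(va) == 49

    def test_determinism(self):
        a = make_partitions(50, 0.8, 5, seed=3)
        b = make_partitions(50, 0.8, 5, seed=3)
        for (t1, v1), (t2, v2) in zip(a.splits, b.splits):
            np.testing.assert_array_equal(t1, t2)
            np.testing.assert_array_equal(v1, v2)

    def test_union_and_disjointness(self):
        parts = make_partitions(100, 0.8, 100, seed=1)
        for tr, va in parts.splits:
            assert len(np.intersect1d(tr, va)) == 0
            np.testing.assert_array_equal(np.union1d(tr, va), np.arange(100))

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            make_partitions(50, 1.2, 5)

    def test_json_round_trip(self, tmp_path):
        import json

        parts = make_partitions(20, 0.8, 3, seed=2)
        p = tmp_path / "parts.json"
        parts.to_json(p, sample_ids=[f"g{i}" for i in range(20)])
        payload = json.loads(p.read_text())
        assert len(payload["reps"]) == 3
        assert len(payload["reps"][0]["train"]) == 16


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_printed_formula_value(self):
        assert fisher_z(0.69) == pytest.approx(
            0.5 * (np.log(1.69) - np.log(0.31)), abs=1e-12
        )
        assert fisher_z(0.69) == pytest.approx(0.8480, abs=1e-4)

    def test_inverse_identity(self):
        r = np.arange(-0.9, 0.95, 0.1)
        np.testing.assert_allclose(inverse_fisher_z(fisher_z(r)), r, atol=1e-12)

    def test_out_of_range_rejected_unless_clamped(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)
        assert np.isfinite(fisher_z(1.0, clamp=True))

    @given(st.floats(min_value=-0.999, max_value=0.999))
    @settings(max_examples=50, deadline=None)
    def test_odd_function(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    @given(st.tuples(st.floats(-0.99, 0.99), st.floats(-0.99, 0.99)))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing(self, pair):
        a, b = sorted(pair)
        if a < b:
            assert fisher_z(a) < fisher_z(b)


def _quick_cfg(seed=1):
    return GibbsConfig(n_iter=1200, burn_in=300, thin=2, seed=seed)


class TestRunCV:
    def test_high_signal_high_pa(self):
        """A noiseless genetic phenotype is predicted almost perfectly."""
        from saltgp.kernels import CenteredMatrix, linear_kernel
        from saltgp.simulate import SimulationConfig, simulate_genotypes

        # markers << individuals: the kernel is low-rank, so training
        # lines span the genetic space and masked lines are recoverable
        m, _ = simulate_genotypes(
            SimulationConfig(n_individuals=200, n_markers=50, n_chromosomes=5,
                             n_causal=20, seed=71)
        )
        k = linear_kernel(
            CenteredMatrix(m.dosage - m.dosage.mean(axis=0), m.samples)
        )
        rng = np.random.default_rng(72)
        g = rng.multivariate_normal(
            np.zeros(k.n), k.values + 1e-8 * np.eye(k.n)
        )
        pheno = pd.DataFrame({"control": g, "salt": g})
        parts = make_partitions(k.n, 0.8, 5, seed=4)
        cv = run_cv(m, pheno, parts, "GBLUP", "single", _quick_cfg(), trait="g")
        assert cv["r"].mean() > 0.9

    def test_null_signal_pa_near_zero(self, small_markers, rng):
        pheno = pd.DataFrame(
            {
                "control": rng.normal(size=small_markers.n_samples),
                "salt": rng.normal(size=small_markers.n_samples),
            }
        )
        parts = make_partitions(small_markers.n_samples, 0.8, 12, seed=5)
        cv = run_cv(small_markers, pheno, parts, "GBLUP", "single",
                    _quick_cfg(2), trait="null")
        assert abs(cv["r"].mean()) < 0.15

    def test_partitions_are_paired_across_methods(self, small_markers, rng):
        pheno = pd.DataFrame(
            {"control": rng.normal(size=small_markers.n_samples),
             "salt": rng.normal(size=small_markers.n_samples)}
        )
        parts = make_partitions(small_markers.n_samples, 0.8, 3, seed=6)
        a = run_cv(small_markers, pheno, parts, "GBLUP", "single",
                   _quick_cfg(3), trait="t")
        b = run_cv(small_markers, pheno, parts, "GBLUP", "multi",
                   _quick_cfg(3), trait="t")
        assert sorted(a["rep"].unique()) == sorted(b["rep"].unique())
        merged = a.merge(b, on=["rep", "condition"], suffixes=("_s", "_m"))
        assert len(merged) == len(a)

    def test_summarize_counts_undefined(self):
        cv = pd.DataFrame(
            {
                "rep": [0, 1, 2],
                "trait": "t",
                "condition": "control",
                "method": "GBLUP",
                "model": "single",
                "r": [0.5, np.nan, 0.7],
            }
        )
        s = summarize_cv(cv)
        assert s["n_reps"].item() == 2
        assert s["n_undefined"].item() == 1
        assert s["mean_pa"].item() == pytest.approx(0.6)


class TestAnovaPA:
    def _table(self, rng, trait_effect=0.0):
        rows = []
        for rep in range(20):
            rep_eff = rng.normal(0, 0.05)
            for trait in ("A", "B"):
                for cond in ("control", "salt"):
                    z = rng.normal(0.5, 0.1) + rep_eff
                    if trait == "B":
                        z += trait_effect
                    rows.append(
                        dict(rep=rep, trait=trait, condition=cond,
                             method="GBLUP", model="single",
                             r=np.tanh(z))
                    )
        return pd.DataFrame(rows)

    def test_trait_effect_detected(self):
        rng = np.random.default_rng(8)
        table = anova_pa(self._table(rng, trait_effect=0.4),
                         factors=("trait", "condition"))
        assert table.loc["C(trait)", "PR(>F)"] < 0.01
        assert table.loc["C(condition)", "PR(>F)"] > 0.01

    def test_constant_z_gives_zero_f(self):
        cv = pd.DataFrame(
            dict(rep=list(range(10)) * 2, trait=["A"] * 10 + ["B"] * 10,
                 condition="control", method="GBLUP", model="single", r=0.5)
        )
        table = anova_pa(cv, factors=("trait",))
        assert table.loc["C(trait)", "F"] == pytest.approx(0.0, abs=1e-20)

    def test_matches_projection_oracle(self):
        """Type-II sum of squares for a factor equals the residual-sum
        difference between the full and the reduced projection."""
        rng = np.random.default_rng(10)
        cv = self._table(rng, trait_effect=0.3).iloc[:40]
        table = anova_pa(cv, factors=("trait", "condition"), block_on_rep=False)
        z = np.arctanh(cv["r"].to_numpy())

        def proj_rss(cols):
            x = np.column_stack(cols)
            beta, *_ = np.linalg.lstsq(x, z, rcond=None)
            return np.sum((z - x @ beta) ** 2)

        ones = np.ones(len(cv))
        t = (cv["trait"] == "B").astype(float).to_numpy()
        c = (cv["condition"] == "salt").astype(float).to_numpy()
        ss_trait = proj_rss([ones, c]) - proj_rss([ones, c, t])
        assert table.loc["C(trait)", "sum_sq"] == pytest.approx(ss_trait, rel=1e-8)

    def test_single_level_factor_dropped(self):
        rng = np.random.default_rng(11)
        cv = self._table(rng)
        with pytest.warns(UserWarning, match="method"):
            anova_pa(cv, factors=("trait", "method"))


class TestMethodAgreement:
    def _table(self, values, trait="T"):
        return pd.DataFrame(
            {
                "genotype": [f"g{i}" for i in range(len(values))],
                "trait": trait,
                "predicted": values,
            }
        )

    def test_identical_tables(self):
        t = self._table([1.0, 3.0, 2.0, 5.0])
        assert method_agreement(t, t)["T"] == pytest.approx(1.0)

    def test_monotone_transform(self):
        a = self._table([1.0, 3.0, 2.0, 5.0])
        b = self._table(np.exp([1.0, 3.0, 2.0, 5.0]))
        assert method_agreement(a, b)["T"] == pytest.approx(1.0)

    def test_independent_tables_near_zero(self):
        rng = np.random.default_rng(12)
        a = self._table(rng.normal(size=500))
        b = self._table(rng.normal(size=500))
        assert abs(method_agreement(a, b)["T"]) < 0.15

    def test_no_overlap_raises(self):
        a = self._table([1.0, 2.0, 3.0])
        b = self._table([1.0, 2.0, 3.0])
        b["genotype"] = ["x1", "x2", "x3"]
        with pytest.raises(ValueError):
            method_agreement(a, b)
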