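"""Tree pruning, BM covariance, OLS/PGLS fits and the correlation suite."""

import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from gsevol.comparative import (
    bm_covariance,
    ols_fit,
    pgls_fit,
    prune_tree,
    results_to_frame,
    run_correlation_suite,
    terminal_branch_lengths,
    tip_depths,
)
from gsevol.metrics import SpeciesRecord, SpeciesTable
from gsevol.annotate import ClassProportions


def newick(s):
    return dendropy.Tree.get(data=s, schema="newick")


def star_tree(n, b=1.0):
    labels = [f"T{i}" for i in range(1, n + 1)]
    return newick("(" + ",".join(f"{l}:{b}" for l in labels) + ");")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

class TestPruneTree:
    def test_keeping_all_tips_preserves_paths(self):
        t = newick("((A:1,B:2):0.5,(C:0.3,(D:0.4,E:0.6):0.2):0.7);")
        pruned = prune_tree(t, {"A", "B", "C", "D", "E"})
        assert tip_depths(pruned) == pytest.approx(tip_depths(t))

    def test_caterpillar_subset_path_lengths_preserved(self):
        t = newick("(((((A:1,B:1):1,C:2):1,D:3):1,E:4):0);")
        before = tip_depths(t)
        pruned = prune_tree(t, {"A", "C", "E"})
        after = tip_depths(pruned)
        for tip in ("A", "C", "E"):
            assert after[tip] == pytest.approx(before[tip])
        assert set(after) == {"A", "C", "E"}

    def test_too_small_keep_set_rejected(self):
        t = newick("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError):
            prune_tree(t, {"A", "B"})

    def test_unknown_label_reported(self):
        t = newick("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError, match="XX"):
            prune_tree(t, {"A", "B", "XX"})


class TestBMCovariance:
    def test_star_tree_is_diagonal(self):
        V, labels = bm_covariance(star_tree(4, b=2.5))
        assert np.allclose(V, 2.5 * np.eye(4))

    def test_two_branch_tree(self):
        V, labels = bm_covariance(newick("(A:1.5,B:0.5,C:1.0);"))
        d = {l: V[i, i] for i, l in enumerate(labels)}
        assert d == pytest.approx({"A": 1.5, "B": 0.5, "C": 1.0})
        assert np.allclose(V - np.diag(np.diag(V)), 0)

    def test_balanced_tree_matches_path_enumeration_oracle(self):
        t = newick("((A:1,B:2):0.5,(C:0.7,D:0.4):0.8);")
        V, labels = bm_covariance(t)

        # oracle: shared path length = sum of branch lengths on the
        # intersection of root-to-tip edge paths
        pdm = {}
        paths = {}
        for leaf in t.leaf_node_iter():
            edges = []
            node = leaf
            while node is not t.seed_node:
                edges.append((id(node), node.edge.length))
                node = node.parent_node
            paths[leaf.taxon.label] = edges
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                shared = {e for e, _ in paths[a]} & {e for e, _ in paths[b]}
                pdm[(a, b)] = sum(l for e, l in paths[a] if e in shared)
                assert V[i, j] == pytest.approx(pdm[(a, b)])

    def test_symmetric_positive_semidefinite(self):
        t = newick("((A:1,B:2):0.5,(C:0.7,(D:0.4,E:0.3):0.3):0.8);")
        V, _ = bm_covariance(t)
        assert np.allclose(V, V.T)
        assert np.all(np.linalg.eigvalsh(V) > -1e-12)
        # diagonal dominates off-diagonal within each row
        assert np.all(np.diag(V)[:, None] >= V - 1e-12)

    def test_negative_branch_length_rejected(self):
        with pytest.raises(ValueError):
            bm_covariance(newick("((A:1,B:-0.5):1,C:1);"))


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

class TestOLS:
    def test_exact_line(self):
        fit = ols_fit({"x": [0.0, 1.0, 2.0]}, [1.0, 3.0, 5.0])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.df_resid == 1

    def test_slope_equals_cov_over_var(self, rng):
        for _ in range(10):
            x = rng.normal(size=25)
            y = rng.normal(size=25)
            fit = ols_fit({"x": x}, y)
            expected = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
            assert fit.slope == pytest.approx(expected, rel=1e-9)

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            ols_fit({"x": [1.0, 1.0, 1.0, 1.0]}, [1.0, 2.0, 3.0, 4.0])

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            ols_fit({"x": [1.0, 2.0]}, [1.0, 2.0])


class TestPGLS:
    def _data(self, rng, n=20):
        x = rng.uniform(0, 10, n)
        y = 0.5 * x + rng.normal(size=n)
        return x, y

    def test_identity_covariance_reduces_to_ols(self, rng):
        x, y = self._data(rng)
        f_ols = ols_fit({"x": x}, y)
        f_pgls = pgls_fit({"x": x}, y, np.eye(len(x)))
        assert f_pgls.slope == pytest.approx(f_ols.slope, abs=1e-10)
        assert f_pgls.bse["x"] == pytest.approx(f_ols.bse["x"], abs=1e-10)
        assert f_pgls.pvalues["x"] == pytest.approx(f_ols.pvalues["x"], abs=1e-10)

    def test_equal_depth_star_tree_equals_ols(self, rng):
        V, _ = bm_covariance(star_tree(15, b=3.0))
        x, y = self._data(rng, 15)
        assert pgls_fit({"x": x}, y, V).slope == pytest.approx(
            ols_fit({"x": x}, y).slope, abs=1e-10
        )

    def test_rescaling_covariance_leaves_inference_unchanged(self, rng):
        t = newick("((A:1,B:2):0.5,(C:0.7,(D:0.4,E:0.3):0.3):0.8);")
        V, _ = bm_covariance(t)
        x, y = self._data(rng, 5)
        f1 = pgls_fit({"x": x}, y, V)
        f2 = pgls_fit({"x": x}, y, 7.3 * V)
        assert f2.slope == pytest.approx(f1.slope, rel=1e-10)
        assert f2.tvalues["x"] == pytest.approx(f1.tvalues["x"], rel=1e-10)
        assert f2.pvalues["x"] == pytest.approx(f1.pvalues["x"], rel=1e-10)
        assert f2.sigma2 == pytest.approx(f1.sigma2 / 7.3, rel=1e-9)

    def test_matches_whitened_ols_oracle(self, rng):
        # contract: PGLS == OLS on L^-1-transformed data for V = L L'
        t = newick("((A:1,B:2):0.5,(C:0.7,(D:0.4,E:0.3):0.3):0.8);")
        V, _ = bm_covariance(t)
        x, y = self._data(rng, 5)
        fit = pgls_fit({"x": x}, y, V)
        L = np.linalg.cholesky(V)
        Xw = np.linalg.solve(L, np.column_stack([np.ones(5), x]))
        yw = np.linalg.solve(L, y)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        assert fit.intercept == pytest.approx(beta[0], rel=1e-9)
        assert fit.slope == pytest.approx(beta[1], rel=1e-9)

    def test_singular_covariance_rejected(self, rng):
        x, y = self._data(rng, 4)
        V = np.zeros((4, 4))
        with pytest.raises(ValueError, match="positive definite"):
            pgls_fit({"x": x}, y, V)


# ---------------------------------------------------------------------------
# the correlation suite
# ---------------------------------------------------------------------------

def _panel_table(rng, n=12, ltr_drives_gf=True):
    from gsevol.simulate import simulate_yule_tree

    tree = simulate_yule_tree(n, 1.0, rng)
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    records = []
    for sp in labels:
        ltr_pct = float(rng.uniform(5, 70))
        gf = (0.017 * ltr_pct if ltr_drives_gf else rng.uniform(0.1, 1.0)) + float(
            rng.normal(0, 0.02)
        )
        fr = {
            "tandem": float(rng.uniform(0, 0.05)),
            "LTR": ltr_pct / 100,
            "LINE": float(rng.uniform(0, 0.05)),
            "SINE": float(rng.uniform(0, 0.005)),
            "DNA": float(rng.uniform(0, 0.1)),
        }
        records.append(
            SpeciesRecord(
                species=sp,
                genome_size_mb=max(gf, 0.01) * 1691.94,
                m=int(rng.integers(0, 4)),
                n=int(rng.integers(0, 2)),
                proportions=ClassProportions(fractions=fr, total=sum(fr.values())),
                mean_insertion_myr=float(rng.uniform(0.5, 4.0)),
            )
        )
    return SpeciesTable(records=records), tree


class TestCorrelationSuite:
    def test_result_cardinality(self, rng):
        table, tree = _panel_table(rng)
        results = run_correlation_suite(table, tree)
        by_factor = {}
        for lr in results:
            by_factor.setdefault(lr.factor, []).append(lr.method)
        multiple = by_factor.pop("LTR_pct~age+insertion")
        assert multiple == ["OLS-multiple"]
        for methods in by_factor.values():
            assert sorted(methods) == ["OLS", "PGLS"]

    def test_planted_ltr_effect_detected_and_random_pf_not(self, rng):
        table, tree = _panel_table(rng, n=20, ltr_drives_gf=True)
        results = {(lr.factor, lr.method): lr.result
                   for lr in run_correlation_suite(table, tree)}
        assert results[("LTR_pct", "OLS")].pvalues["LTR_pct"] < 0.05
        assert results[("LTR_pct", "OLS")].slope == pytest.approx(0.017, abs=0.005)
        assert results[("pf", "OLS")].pvalues["pf"] > 0.05

    def test_permuting_a_factor_destroys_significance(self, rng):
        table, tree = _panel_table(rng, n=20, ltr_drives_gf=True)
        # permute LTR percentages across species
        perm = rng.permutation(len(table.records))
        fracs = [table.records[i].proportions for i in perm]
        for rec, pr in zip(table.records, fracs):
            rec.proportions = pr
        rejections = 0
        trials = 20
        for _ in range(trials):
            perm = rng.permutation(len(table.records))
            fracs = [table.records[i].proportions for i in perm]
            for rec, pr in zip(table.records, fracs):
                rec.proportions = pr
            results = {(lr.factor, lr.method): lr.result
                       for lr in run_correlation_suite(table, tree)}
            if results[("LTR_pct", "OLS")].pvalues["LTR_pct"] < 0.05:
                rejections += 1
        assert rejections <= 4  # ~5% nominal under the permutation null

    def test_results_frame_schema(self, rng):
        table, tree = _panel_table(rng)
        df = results_to_frame(run_correlation_suite(table, tree))
        assert {"factor", "method", "slope", "intercept", "se", "t", "p",
                "r_squared", "n"} <= set(df.columns)
        assert (df["n"] == len(table.records)).all()

    def test_terminal_branch_lengths_positive(self, rng):
        from gsevol.simulate import simulate_yule_tree

        tree = simulate_yule_tree(8, 1.0, rng)
        ages = terminal_branch_lengths(tree)
        assert len(ages) == 8
        assert all(v > 0 for v in ages.values())
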