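"""Probe summarisation, quantile normalisation, probe filters, moderated
differential expression, signatures, clustering and co-expression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from emtkit import expression as expr
from emtkit.synthetic import ExpressionSimSpec, generate_expression_matrix
from emtkit.types import DegenerateInputError


class TestTukeyBiweight:
    def test_single_value_passthrough(self):
        assert expr.tukey_biweight([7.3]) == 7.3

    def test_symmetric_outlier_free(self):
        assert expr.tukey_biweight([1.0, 2.0, 3.0]) == pytest.approx(2.0)

    def test_outlier_downweighted_vs_brute_force(self):
        x = np.array([1.0, 2.0, 3.0, 100.0])
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        u = (x - med) / (5.0 * mad + 1e-4)
        w = np.where(np.abs(u) < 1, (1 - u ** 2) ** 2, 0.0)
        ref = np.sum(w * x) / np.sum(w)
        est = expr.tukey_biweight(x)
        assert est == pytest.approx(ref, abs=1e-6)
        assert abs(est - 2.0) < abs(np.mean(x) - 2.0)

    @given(st.floats(-50, 50))
    def test_location_equivariance(self, shift):
        x = np.array([1.0, 2.0, 4.0, 8.0, 40.0])
        assert expr.tukey_biweight(x + shift) == pytest.approx(
            expr.tukey_biweight(x) + shift, abs=1e-9
        )

    def test_bounded_by_input_range(self, rng):
        for _ in range(20):
            x = rng.normal(0, 10, rng.integers(2, 12))
            est = expr.tukey_biweight(x)
            assert x.min() <= est <= x.max()

    def test_probeset_grouping(self):
        probes = pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0, 9.0], "s2": [4.0, 5.0, 6.0, 1.0]},
            index=["p1", "p2", "p3", "p4"],
        )
        gene_map = {"p1": "A", "p2": "A", "p3": "A", "p4": "B"}
        out = expr.summarize_probesets(probes, gene_map)
        assert out.loc["A", "s1"] == pytest.approx(2.0)
        assert out.loc["B", "s2"] == 1.0


class TestQuantileNormalize:
    def test_mean_of_order_statistics(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = expr.quantile_normalize(m)
        assert out["a"].tolist() == [2.5, 3.5, 4.5]
        assert out["b"].tolist() == [2.5, 3.5, 4.5]

    def test_identical_columns_unchanged(self):
        m = pd.DataFrame({"a": [2.0, 4.0, 8.0], "b": [2.0, 4.0, 8.0]})
        pd.testing.assert_frame_equal(expr.quantile_normalize(m), m)

    def test_floor_applied_before_normalization(self):
        m = pd.DataFrame({"a": [0.1, 2.0], "b": [1.0, 3.0]})
        out = expr.quantile_normalize(m, floor=1.0)
        assert out.min().min() >= 1.0

    def test_ties_get_mean_of_tied_targets(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = expr.quantile_normalize(m)
        # rank-walk oracle: reference = mean of sorted cols = [1.5, 2.5, 5.5];
        # the two tied 1.0s share targets 1.5 and 2.5 -> both 2.0
        assert out["a"].tolist() == [2.0, 2.0, 5.5]
        assert out["b"].tolist() == [1.5, 2.5, 5.5]

    def test_sorted_vectors_identical_and_idempotent(self, rng):
        m = pd.DataFrame(rng.lognormal(3, 1, (40, 5)))
        out = expr.quantile_normalize(m)
        cols = [np.sort(out[c].to_numpy()) for c in out]
        for c in cols[1:]:
            np.testing.assert_allclose(c, cols[0], atol=1e-12)
        pd.testing.assert_frame_equal(expr.quantile_normalize(out), out)

    def test_ranks_preserved_within_column(self, rng):
        m = pd.DataFrame(rng.normal(10, 2, (30, 4)))
        out = expr.quantile_normalize(m)
        for c in m:
            np.testing.assert_array_equal(
                m[c].rank(method="average"), out[c].rank(method="average")
            )


class TestFilterProbes:
    def fixture(self):
        """10 genes designed so the three stages retain (8, 7, 6)."""
        samples = ["c1_1", "c1_2", "c2_1", "c2_2"]
        conditions = {"c1_1": "c1", "c1_2": "c1", "c2_1": "c2", "c2_2": "c2"}
        base = {
            f"g{i}": [10.0 + i, 11.0 + i, 12.0 + i, 13.0 + i] for i in range(8)
        }
        base["g_low1"] = [1.0, 1.0, 1.0, 1.0]  # below every 20th pctile
        base["g_low2"] = [2.0, 2.0, 2.0, 2.0]
        m = pd.DataFrame(base, index=samples).T
        flags = pd.DataFrame("P", index=m.index, columns=m.columns)
        flags.loc["g0"] = "A"  # absent everywhere -> stage-2 removal
        m.loc["g1"] = [20.0, 20.0, 20.0, 20.0]  # constant -> stage-3 removal
        return m, flags, conditions

    def test_designed_stage_counts(self):
        m, flags, conditions = self.fixture()
        out, counts = expr.filter_probes(m, flags, conditions)
        assert counts == {"expression": 8, "flags": 7, "cv": 6}
        assert set(out.index) == {f"g{i}" for i in range(2, 8)}

    def test_constant_gene_removed_by_cv(self):
        m = pd.DataFrame(
            {"s1": [5.0, 5.0], "s2": [5.0, 7.0]}, index=["flat", "varies"]
        ).T
        m = m.T
        out, counts = expr.filter_probes(
            m, None, {"s1": "c1", "s2": "c1"}, band=(0.0, 100.0)
        )
        assert "flat" not in out.index and "varies" in out.index

    def test_all_absent_gene_removed_by_flags(self):
        m, flags, conditions = self.fixture()
        out, _ = expr.filter_probes(m, flags, conditions)
        assert "g0" not in out.index

    def test_unknown_flag_symbol_rejected(self):
        m, flags, conditions = self.fixture()
        flags.iloc[0, 0] = "X"
        with pytest.raises(ValueError):
            expr.filter_probes(m, flags, conditions)


class TestBHQvalues:
    def test_matches_step_up_oracle(self, rng):
        for _ in range(10):
            p = rng.random(rng.integers(5, 200))
            q = expr.bh_qvalues(p)
            n = p.size
            order = np.argsort(p)
            ref = np.empty(n)
            running = 1.0
            for rank in range(n - 1, -1, -1):
                i = order[rank]
                running = min(running, p[i] * n / (rank + 1))
                ref[i] = running
            np.testing.assert_allclose(q, ref, atol=1e-12)

    def test_monotone_in_rank(self, rng):
        p = rng.random(100)
        q = expr.bh_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestDifferentialExpression:
    def test_zero_noise_logfc_exact_and_selected(self):
        d = generate_expression_matrix(
            ExpressionSimSpec(n_genes=300, noise_sd=0.0, logfc=2.0,
                              de_fraction=0.1, anchor_rho=0.0, seed=2)
        )
        de = expr.differential_expression(
            d["matrix"], d["labels"], group_order=("epithelial", "mesenchymal")
        )
        g = d["truth"]["up_genes"][0]
        assert de.loc[g, "logFC"] == pytest.approx(2.0, abs=1e-12)
        assert bool(de.loc[g, "selected"])
        down = d["truth"]["down_genes"][0]
        assert de.loc[down, "logFC"] == pytest.approx(-2.0, abs=1e-12)

    def test_zero_variance_gene_never_divides_by_zero(self):
        m = pd.DataFrame(
            {
                "e1": [1.0, 5.0], "e2": [1.0, 5.5],
                "m1": [1.0, 9.0], "m2": [1.0, 9.5],
            },
            index=["flat", "de"],
        )
        labels = {"e1": "epi", "e2": "epi", "m1": "mes", "m2": "mes"}
        de = expr.differential_expression(m, labels, group_order=("epi", "mes"))
        assert np.isfinite(de["t"]).all()

    def test_moderated_shrinks_toward_mean_variance(self, rng):
        m = pd.DataFrame(
            rng.normal(8, 0.25, (500, 8)),
            columns=[f"e{i}" for i in range(4)] + [f"m{i}" for i in range(4)],
        )
        labels = {c: ("epi" if c.startswith("e") else "mes") for c in m}
        mod = expr.differential_expression(m, labels, group_order=("epi", "mes"))
        plain = expr.differential_expression(
            m, labels, group_order=("epi", "mes"), moderated=False
        )
        # moderation stabilises the statistic: fewer extreme |t|
        assert np.abs(mod["t"]).max() < np.abs(plain["t"]).max()

    def test_signatures_recover_injected_mesenchymal_genes(self):
        spec = ExpressionSimSpec(
            n_genes=1000, de_fraction=0.24, logfc=3.0, anchor_rho=0.0, seed=3
        )
        d = generate_expression_matrix(spec)
        de = expr.differential_expression(
            d["matrix"], d["labels"], group_order=("epithelial", "mesenchymal")
        )
        sig = expr.rank_signatures(de, k=100)
        assert set(sig["mesenchymal"]) <= set(d["truth"]["up_genes"])
        assert set(sig["epithelial"]) <= set(d["truth"]["down_genes"])
        assert "CAV1" in sig["mesenchymal"]

    def test_k_zero_gives_empty_lists(self):
        d = generate_expression_matrix(ExpressionSimSpec(n_genes=50, seed=1))
        de = expr.differential_expression(
            d["matrix"], d["labels"], group_order=("epithelial", "mesenchymal")
        )
        sig = expr.rank_signatures(de, k=0)
        assert sig["mesenchymal"] == [] and sig["epithelial"] == []


class TestHierarchicalClustering:
    def block_matrix(self, rng):
        """Two gene blocks: 'pure' on only in mesenchymal samples,
        'transition' on in mesenchymal plus half the epithelial samples."""
        epi = [f"e{i}" for i in range(8)]
        mes = [f"m{i}" for i in range(4)]
        rows = {}
        for g in range(10):
            on = {s: 10.0 for s in mes}
            off = {s: 2.0 for s in epi}
            rows[f"pure{g}"] = {**off, **on}
        for g in range(10):
            on = {s: 10.0 for s in mes + epi[:4]}
            off = {s: 2.0 for s in epi[4:]}
            rows[f"trans{g}"] = {**off, **on}
        m = pd.DataFrame(rows).T[epi + mes]
        return m + rng.normal(0, 0.2, m.shape), epi

    def test_block_model_recovered_with_labels(self, rng):
        m, epi = self.block_matrix(rng)
        out = expr.hierarchical_clustering(m, 2, epithelial_samples=epi)
        trans = set(out.index[out["label"] == "transition"])
        assert trans == {f"trans{g}" for g in range(10)}

    def test_single_cluster(self, rng):
        m, _ = self.block_matrix(rng)
        out = expr.hierarchical_clustering(m, 1)
        assert (out["cluster"] == 1).all()

    def test_gene_order_invariance(self, rng):
        m, epi = self.block_matrix(rng)
        a = expr.hierarchical_clustering(m, 2, epithelial_samples=epi)
        b = expr.hierarchical_clustering(
            m.sample(frac=1.0, random_state=7), 2, epithelial_samples=epi
        )
        assert a["label"].sort_index().equals(b["label"].sort_index())

    def test_generator_transition_genes_recovered_end_to_end(self):
        """Signature genes from a matrix with an injected transition block
        sub-cluster into the truth's transition / pure partition."""
        spec = ExpressionSimSpec(
            n_genes=600, de_fraction=0.1, logfc=2.0,
            transition_fraction=0.4, anchor_rho=0.0, seed=9,
        )
        d = generate_expression_matrix(spec)
        de = expr.differential_expression(
            d["matrix"], d["labels"], group_order=("epithelial", "mesenchymal")
        )
        sig = expr.rank_signatures(de, k=len(d["truth"]["up_genes"]))
        epi = [s for s, l in d["labels"].items() if l == "epithelial"]
        out = expr.hierarchical_clustering(
            d["matrix"].loc[sig["mesenchymal"]], 2, epithelial_samples=epi
        )
        trans = set(out.index[out["label"] == "transition"])
        assert trans == set(d["truth"]["transition_genes"])

    def test_constant_rows_dropped_with_warning(self, rng):
        m, epi = self.block_matrix(rng)
        m.loc["flat"] = 5.0
        with pytest.warns(UserWarning):
            out = expr.hierarchical_clustering(m, 2, epithelial_samples=epi)
        assert "flat" not in out.index


class TestAnchorCoexpression:
    def test_anchor_ranks_first(self):
        d = generate_expression_matrix(ExpressionSimSpec(n_genes=100, seed=4))
        co = expr.anchor_coexpression(d["matrix"], "CAV1")
        assert co.loc[0, "gene"] == "CAV1"
        assert co.loc[0, "r"] == pytest.approx(1.0)

    def test_block_recovered_null_rejected(self):
        spec = ExpressionSimSpec(
            n_genes=1050, n_epithelial=150, n_mesenchymal=150,
            anchor_block_size=50, anchor_rho=0.9, de_fraction=0.0, seed=5,
        )
        d = generate_expression_matrix(spec)
        co = expr.anchor_coexpression(d["matrix"], "CAV1", top_n=500, r_min=0.3)
        got = set(co["gene"])
        assert set(d["truth"]["anchor_block"]) <= got
        null_genes = got - set(d["truth"]["anchor_block"])
        assert len(null_genes) < 0.05 * 1000

    def test_independent_anchor_returns_nothing(self):
        spec = ExpressionSimSpec(
            n_genes=400, n_epithelial=150, n_mesenchymal=150,
            anchor_rho=0.0, de_fraction=0.0, seed=6,
        )
        d = generate_expression_matrix(spec)
        co = expr.anchor_coexpression(d["matrix"], "CAV1", r_min=0.3)
        assert len(co) == 1  # only the anchor itself

    def test_constant_anchor_signals(self):
        m = pd.DataFrame(np.ones((3, 5)), index=["a", "b", "c"])
        with pytest.raises(DegenerateInputError):
            expr.anchor_coexpression(m, "a")


class TestPCASeparation:
    def test_classes_separate_on_pc1(self):
        d = generate_expression_matrix(
            ExpressionSimSpec(n_genes=500, de_fraction=0.2, logfc=3.0, seed=7)
        )
        pcs = expr.pca_class_separation(d["matrix"], d["labels"])
        epi = pcs[pcs["label"] == "epithelial"]["PC1"]
        mes = pcs[pcs["label"] == "mesenchymal"]["PC1"]
        assert (epi.max() < mes.min()) or (mes.max() < epi.min())
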