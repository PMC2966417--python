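"""Mutual information, GPA averaging, ranking, and the four model variants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from minegs import (
    BindingMatrix,
    ExpressionDataset,
    GeneNetwork,
    gene_phenotype_association,
    mutual_information,
    rank_genes,
    run_model,
)
from minegs.partners import NFPTable


class TestMutualInformation:
    def test_perfectly_predictive_bins_give_one_bit(self):
        # 5 values in the bottom bin, 5 in the top bin, classes follow the bins
        x = np.array([0.0, 0.01, 0.02, 0.03, 0.04, 0.96, 0.97, 0.98, 0.99, 1.0])
        y = np.array([0] * 5 + [1] * 5)
        assert mutual_information(x, y, bins=10) == pytest.approx(1.0, abs=1e-12)

    def test_constant_labels_give_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert mutual_information(x, np.zeros(4)) == pytest.approx(0.0, abs=1e-12)

    def test_exactly_factorizing_joint_gives_zero(self):
        # two occupied bins x two classes with counts 1,1,1,1
        x = np.array([0.0, 0.0, 1.0, 1.0])
        y = np.array([0, 1, 0, 1])
        assert mutual_information(x, y, bins=10) == pytest.approx(0.0, abs=1e-12)

    def test_constant_x_errors(self):
        with pytest.raises(ValueError, match="constant"):
            mutual_information(np.ones(4), np.array([0, 0, 1, 1]))

    def test_max_value_lands_in_last_bin(self):
        # all 6 values distinct; max must not fall off the histogram
        x = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        mi = mutual_information(x, y, bins=10)
        assert np.isfinite(mi) and mi > 0

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(0, 2**31 - 1), st.integers(4, 40))
    def test_bounded_by_marginal_entropies(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.random(n)
        if np.ptp(x) == 0:
            return
        y = rng.integers(0, 2, size=n)
        bins = 10
        mi = mutual_information(x, y, bins=bins)
        edges = np.linspace(x.min(), x.max(), bins + 1)
        px = np.histogram(x, bins=edges)[0] / n
        hx = -np.sum(px[px > 0] * np.log2(px[px > 0]))
        py = np.array([(y == c).mean() for c in np.unique(y)])
        hy = -np.sum(py[py > 0] * np.log2(py[py > 0]))
        assert -1e-12 <= mi <= min(hx, hy) + 1e-9


class TestGPA:
    def test_mean_of_four(self):
        mi = {"g": 0.5, "p1": 0.1, "p2": 0.2, "p3": 0.3}
        table = NFPTable("diffusion", 3, {"g": [("p1", 1.0), ("p2", 2.0), ("p3", 3.0)],
                                          "p1": [], "p2": [], "p3": []})
        gpa = gene_phenotype_association(mi, table)
        assert gpa["g"] == pytest.approx(0.275)
        assert gpa["p1"] == pytest.approx(0.1)  # empty list falls back to own MI

    def test_constant_scores_are_fixed_point(self):
        mi = {g: 0.7 for g in "abcd"}
        table = NFPTable("diffusion", 2, {"a": [("b", 1.0), ("c", 1.0)],
                                          "b": [("a", 1.0)], "c": [], "d": []})
        assert all(v == pytest.approx(0.7) for v in gene_phenotype_association(mi, table).values())

    def test_unknown_partner_errors(self):
        table = NFPTable("diffusion", 1, {"a": [("ghost", 1.0)]})
        with pytest.raises(ValueError, match="ghost"):
            gene_phenotype_association({"a": 0.1}, table)

    def test_gpa_is_convex_combination(self):
        rng = np.random.default_rng(4)
        mi = {f"g{i}": float(rng.random()) for i in range(8)}
        partners = {
            g: [(p, 1.0) for p in rng.choice([x for x in mi if x != g], size=3, replace=False)]
            for g in mi
        }
        table = NFPTable("diffusion", 3, partners)
        gpa = gene_phenotype_association(mi, table)
        for g in mi:
            group = [mi[g]] + [mi[p] for p, _ in partners[g]]
            assert min(group) - 1e-12 <= gpa[g] <= max(group) + 1e-12


class TestRankGenes:
    def test_descending_with_lexicographic_ties(self):
        gpa = {"b": 0.5, "a": 0.5, "c": 0.9}
        r = rank_genes(gpa, gpa, "classic")
        assert r.order == ("c", "a", "b")
        assert r.ranks == {"c": 1, "a": 2, "b": 3}

    def test_order_invariant_to_input_order(self):
        gpa1 = {"a": 0.1, "b": 0.3, "c": 0.2}
        gpa2 = dict(reversed(list(gpa1.items())))
        assert rank_genes(gpa1, gpa1, "classic").order == rank_genes(gpa2, gpa2, "classic").order


def _module_fixture():
    """Planted two-gene module where partner MI should lift a weak member."""
    rng = np.random.default_rng(11)
    n = 30
    labels = tuple(["A"] * 15 + ["B"] * 15)
    shift = np.array([0.0] * 15 + [1.0] * 15)
    genes = ("weak", "strong1", "strong2", "noise1", "noise2")
    values = np.vstack(
        [
            0.2 * shift + 0.3 * rng.standard_normal(n),  # weak module member
            2.0 * shift + 0.3 * rng.standard_normal(n),
            2.0 * shift + 0.3 * rng.standard_normal(n),
            1.0 * shift + 0.5 * rng.standard_normal(n),  # decoy: decent MI, bad partners
            rng.standard_normal(n),
        ]
    )
    expr = ExpressionDataset(genes, tuple(f"s{j}" for j in range(n)), values, labels)
    edges = frozenset({("strong1", "weak"), ("strong2", "weak"), ("strong1", "strong2"),
                       ("noise1", "noise2"), ("noise1", "weak")})
    net = GeneNetwork(genes, edges)
    Z = np.array([[1, 1], [1, 1], [1, 1], [0, 0], [0, 0]])
    bind = BindingMatrix(genes, ("m1", "m2"), Z)
    return expr, bind, net


class TestRunModel:
    def test_classic_equals_descending_mi(self):
        expr, bind, net = _module_fixture()
        ranking, nfp = run_model(expr, bind, net, model="classic")
        assert nfp is None
        assert ranking.order == tuple(sorted(ranking.mi, key=lambda g: (-ranking.mi[g], g)))
        assert ranking.gpa == ranking.mi

    def test_negs_invariant_to_binding_permutation(self):
        expr, bind, net = _module_fixture()
        r1, _ = run_model(expr, bind, net, model="NeGS")
        shuffled = BindingMatrix(bind.gene_ids, ("m2", "m1"), bind.Z[:, [1, 0]])
        r2, _ = run_model(expr, shuffled, net, model="NeGS")
        assert r1.order == r2.order
        assert r1.gpa == r2.gpa

    def test_minegs_lifts_coordinated_weak_gene_above_classic_rank(self):
        expr, bind, net = _module_fixture()
        classic, _ = run_model(expr, bind, net, model="classic")
        minegs, nfp = run_model(expr, bind, net, model="MiNeGS", k=2)
        # weak's diffusion partners are the strong module genes, whose MI lifts it
        assert set(nfp.partner_ids("weak")) == {"strong1", "strong2"}
        assert minegs.ranks["weak"] < classic.ranks["weak"]
        # direct recomputation of the GPA value
        expected = np.mean([minegs.mi[g] for g in ("weak", "strong1", "strong2")])
        assert minegs.gpa["weak"] == pytest.approx(expected)

    def test_unknown_model_errors(self):
        expr, bind, net = _module_fixture()
        with pytest.raises(ValueError, match="unknown model"):
            run_model(expr, bind, net, model="bogus")

    def test_zero_combined_edges_leave_gene_with_mi_fallback(self):
        # bound/unbound edge pair has J=0: edge dropped, singleton falls back to MI
        rng = np.random.default_rng(5)
        n = 20
        labels = tuple(["A"] * 10 + ["B"] * 10)
        base = rng.standard_normal(n)
        values = np.vstack([base + 0.1 * rng.standard_normal(n),
                            base + 0.1 * rng.standard_normal(n),
                            base + 0.1 * rng.standard_normal(n)])
        genes = ("bound1", "bound2", "unbound")
        expr = ExpressionDataset(genes, tuple(f"s{j}" for j in range(n)), values, labels)
        net = GeneNetwork(genes, frozenset({("bound1", "bound2"), ("bound2", "unbound")}))
        bind = BindingMatrix(genes, ("m1",), np.array([[1], [1], [0]]))
        ranking, nfp = run_model(expr, bind, net, model="MiNeGS")
        assert nfp.partner_ids("unbound") == []
        assert ranking.gpa["unbound"] == pytest.approx(ranking.mi["unbound"])
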