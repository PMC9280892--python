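"""Chromosome encoding, decoding, evaluation and Gram construction."""

import itertools

import numpy as np
import pytest

import genofold as gf
from genofold.kernel_lang import (
    OPERATORS,
    TERMINALS,
    ChromosomeError,
    Gene,
    GFChromosome,
    GramMatrix,
    KernelExpression,
    gram_unit_scale,
)

from conftest import EXAMPLE_LINKS, EXAMPLE_SYMBOLS


# ---------------------------------------------------------------------------
# Parsing and validation
# ---------------------------------------------------------------------------


class TestParse:
    def test_worked_example_is_valid(self, example_chromosome):
        assert len(example_chromosome) == 7
        assert example_chromosome.genes[0].symbol == "*_s"
        assert example_chromosome.link_tokens == tuple(EXAMPLE_LINKS)

    def test_single_leaf_chromosome(self):
        ch = gf.parse_chromosome(["1"], ["x"])
        assert len(ch) == 1
        assert str(gf.decode(ch)) == "x"

    @pytest.mark.parametrize(
        "links, symbols, fragment",
        [
            (["2.3", "3", "3"], ["+_v", "x", "x"], "terminal gene 2"),
            (
                ["2.3", "4.5", "4.6", "4", "5", "6", "7"],
                ["+_v", "+_s", "+_s", "x", "x", "x", "x"],
                "referenced",
            ),
            (["2.3"], ["+_v", "x"], "link tokens"),
            (["1.2", "2", "3"], ["+_v", "x", "x"], "forward"),
            (["2.3", "2", "3"], ["x", "x", "y"], "child links"),
            (["2.3", "2", "3", "4"], ["+_v", "x", "y", "x"], "referenced"),
            (["2"], ["x"], "link to itself"),
        ],
    )
    def test_malformed_chromosomes_rejected(self, links, symbols, fragment):
        with pytest.raises(ChromosomeError, match=fragment):
            gf.parse_chromosome(links, symbols)

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ChromosomeError, match="unknown symbol"):
            gf.parse_chromosome(["1"], ["z"])

    def test_text_format_round_trip(self, example_chromosome):
        line = example_chromosome.to_text()
        assert line == (
            "links: 2.3,4.5,3,6.7,5,6,7 | symbols: *_s,-_s,x,+_v,x,y,x"
        )
        assert GFChromosome.from_text(line).to_text() == line


# ---------------------------------------------------------------------------
# Genotype <-> phenotype round trips
# ---------------------------------------------------------------------------


def all_shapes(n_leaves: int):
    """All binary tree shapes with the given number of leaves."""
    if n_leaves == 1:
        yield "leaf"
        return
    for k in range(1, n_leaves):
        for left in all_shapes(k):
            for right in all_shapes(n_leaves - k):
                yield (left, right)


def fill_shapes(shape):
    """All symbol assignments of a shape."""
    if shape == "leaf":
        for t in TERMINALS:
            yield KernelExpression(t)
        return
    left, right = shape
    for op in OPERATORS:
        for lt in fill_shapes(left):
            for rt in fill_shapes(right):
                yield KernelExpression(op, (lt, rt))


class TestRoundTrip:
    def test_worked_example_decodes_to_printed_expression(self, example_chromosome):
        expr = gf.decode(example_chromosome)
        assert str(expr) == "*_s(-_s(+_v(y, x), x), x)"

    def test_worked_example_reencodes_to_printed_links(self, example_chromosome):
        ch2 = gf.encode(gf.decode(example_chromosome))
        assert ch2 == example_chromosome
        assert ch2.link_tokens == tuple(EXAMPLE_LINKS)
        assert ch2.symbols == tuple(EXAMPLE_SYMBOLS)

    def test_exhaustive_small_trees(self):
        """decode(encode(T)) == T for every tree with <= 7 nodes."""
        count = 0
        for n_leaves in (1, 2, 3, 4):  # 7 nodes = 4 leaves + 3 operators
            for shape in all_shapes(n_leaves):
                for tree in fill_shapes(shape):
                    assert gf.decode(gf.encode(tree)) == tree
                    count += 1
        assert count == 2 + 20 + 400 + 10_000

    @staticmethod
    def _expr_strategy():
        from hypothesis import strategies as st

        leaves = st.sampled_from(TERMINALS).map(KernelExpression)
        return st.recursive(
            leaves,
            lambda children: st.tuples(
                st.sampled_from(OPERATORS), children, children
            ).map(lambda t: KernelExpression(t[0], (t[1], t[2]))),
            max_leaves=16,
        )

    def test_round_trip_property(self):
        from hypothesis import given, settings

        @given(self._expr_strategy())
        @settings(max_examples=200, deadline=None, derandomize=True)
        def check(tree):
            assert gf.decode(gf.encode(tree)) == tree

        check()

    def test_random_trees_round_trip(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            tree = gf.random_expression(5, rng=rng)
            chrom = gf.encode(tree)
            assert gf.decode(chrom) == tree
            assert gf.encode(gf.decode(chrom)) == chrom


# ---------------------------------------------------------------------------
# Evaluation semantics
# ---------------------------------------------------------------------------


class TestEvaluate:
    def test_linear_kernel_is_inner_product(self, linear_chromosome):
        expr = gf.decode(linear_chromosome)
        assert gf.evaluate(expr, [1, 2], [3, 4]) == 11.0

    def test_worked_example_hand_value(self, example_chromosome):
        # +_v(y,x) = (4,6); -_s -> (4+6)-(1+2) = 7; *_s -> 7 * (1+2) = 21
        expr = gf.decode(example_chromosome)
        assert gf.evaluate(expr, [1, 2], [3, 4]) == 21.0

    def test_zero_vector_case(self):
        expr = KernelExpression("+_s", (KernelExpression("x"), KernelExpression("x")))
        assert gf.evaluate(expr, [0, 0], [1, 1]) == 0.0

    def test_elementwise_difference_reduces_to_zero_on_equal_inputs(self):
        expr = KernelExpression("-_v", (KernelExpression("x"), KernelExpression("y")))
        assert gf.evaluate(expr, [2.5, -1.0], [2.5, -1.0]) == 0.0

    def test_overflow_is_reported_not_propagated(self, linear_chromosome):
        expr = gf.decode(linear_chromosome)
        big = np.full(3, 1e200)
        nested = KernelExpression("*_s", (expr, expr))  # (x.y)^2 ~ 1e801
        with pytest.raises(gf.InvalidKernelError):
            gf.evaluate(nested, big, big)

    def test_mismatched_dimensions_rejected(self, linear_chromosome):
        with pytest.raises(ValueError):
            gf.evaluate(gf.decode(linear_chromosome), [1, 2], [1, 2, 3])


# ---------------------------------------------------------------------------
# Gram matrices
# ---------------------------------------------------------------------------


class TestGram:
    def test_identity_rows_linear(self, linear_chromosome):
        expr = gf.decode(linear_chromosome)
        G = gf.gram(expr, np.eye(2))
        np.testing.assert_array_equal(G.values, np.eye(2))

    def test_matches_entrywise_bruteforce(self):
        rng = np.random.default_rng(7)
        A = rng.standard_normal((30, 5))
        B = rng.standard_normal((20, 5))
        for _ in range(20):
            expr = gf.random_expression(4, rng=rng)
            G = gf.gram(expr, A, B)
            brute = np.array(
                [[gf.evaluate(expr, a, b) for b in B] for a in A]
            )
            np.testing.assert_allclose(G.values, brute, atol=1e-10, rtol=1e-10)

    def test_linear_chromosome_gram_is_matrix_product(self, linear_chromosome):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((25, 6))
        G = gf.gram(gf.decode(linear_chromosome), X)
        np.testing.assert_allclose(G.values, X @ X.T, atol=1e-12)

    def test_nonfinite_entries_invalidate_matrix(self, linear_chromosome):
        expr = gf.decode(linear_chromosome)
        nested = KernelExpression("*_s", (expr, expr))
        G = gf.gram(nested, np.full((3, 2), 1e200))
        assert not G.valid

    def test_symmetrized_gram_is_symmetric_bitwise(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((15, 4))
        expr = KernelExpression("-_s", (KernelExpression("x"), KernelExpression("y")))
        G = gf.repair_gram(gf.gram(expr, X), "symmetrize")
        assert np.array_equal(G.values, G.values.T)


class TestRepair:
    def test_antisymmetric_symmetrizes_to_zero(self):
        G = GramMatrix(np.array([[0.0, 1.0], [-1.0, 0.0]]))
        R = gf.repair_gram(G, "symmetrize")
        np.testing.assert_array_equal(R.values, np.zeros((2, 2)))
        assert R.repaired and R.repair_mode == "symmetrize"

    def test_clip_zeroes_negative_eigenvalue(self):
        R = gf.repair_gram(GramMatrix(np.diag([1.0, -1.0])), "clip")
        np.testing.assert_allclose(R.values, np.diag([1.0, 0.0]), atol=1e-12)

    def test_clip_fixed_point_on_psd(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((10, 3))
        K = X @ X.T
        R = gf.repair_gram(GramMatrix(K), "clip")
        np.testing.assert_allclose(R.values, K, atol=1e-10)

    def test_clip_spectrum_and_idempotence_on_evolved_grams(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((50, 8))
        for _ in range(100):
            expr = gf.random_expression(5, rng=rng)
            G = gf.gram(expr, X)
            if not G.valid:
                continue
            R = gf.repair_gram(G, "clip")
            scale = max(1.0, np.abs(R.values).max())
            assert np.linalg.eigvalsh(R.values).min() >= -1e-8 * scale
            R2 = gf.repair_gram(R, "clip")
            np.testing.assert_allclose(
                R2.values, R.values, atol=1e-8 * scale
            )

    def test_nonsquare_rejected(self):
        with pytest.raises(ValueError):
            gf.repair_gram(GramMatrix(np.zeros((2, 3))), "clip")


class TestNormalize:
    def test_unit_diagonal_after_cosine(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((12, 4))
        G = gf.normalize_gram(GramMatrix(X @ X.T))
        np.testing.assert_allclose(np.diag(G.values), 1.0, atol=1e-12)

    def test_nonpositive_diagonal_refused(self):
        G = gf.normalize_gram(GramMatrix(np.diag([1.0, 0.0])))
        assert not G.valid

    def test_unit_scale_falls_back_on_zero_diagonal(self):
        K = np.array([[0.0, 2.0], [2.0, 0.0]])
        assert gram_unit_scale(K) == 1.0  # mean |entry| fallback


# ---------------------------------------------------------------------------
# Complexity and random generation
# ---------------------------------------------------------------------------


class TestComplexityAndRandom:
    def test_worked_example_complexity(self, example_chromosome):
        assert gf.complexity(gf.decode(example_chromosome)) == 3

    def test_leaf_complexity(self):
        assert gf.complexity(KernelExpression("x")) == 0

    def test_complexity_equals_operator_gene_count(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            tree = gf.random_expression(5, rng=rng)
            chrom = gf.encode(tree)
            n_terminals = sum(g.is_terminal for g in chrom.genes)
            assert gf.complexity(tree) == len(chrom) - n_terminals

    def test_max_depth_zero_gives_terminal(self):
        tree = gf.random_expression(0, rng=np.random.default_rng(0))
        assert tree.is_leaf

    def test_depth_bounded(self):
        rng = np.random.default_rng(2)
        assert all(
            gf.random_expression(4, rng=rng).depth <= 4 for _ in range(500)
        )

    def test_random_trees_encode_validly(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            gf.encode(gf.random_expression(4, rng=rng))  # validation in ctor

    def test_same_seed_same_tree(self):
        t1 = gf.random_expression(5, rng=np.random.default_rng(123))
        t2 = gf.random_expression(5, rng=np.random.default_rng(123))
        assert t1 == t2

    def test_empty_symbol_set_rejected(self):
        with pytest.raises(ValueError):
            gf.random_expression(3, operators=(), rng=np.random.default_rng(0))
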