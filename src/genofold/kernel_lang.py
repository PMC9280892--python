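"""The genetic-folding kernel language.

A genetic-folding (GF) chromosome is a linear array of *genes*.  Each gene
holds a symbol -- one of five binary operators (``+_v``, ``+_s``, ``-_v``,
``-_s``, ``*_s``) or one of the terminals ``x`` and ``y`` -- together with a
*link* that folds the flat array into a binary expression tree: an operator
gene stores the 1-based positions of its two children as an ``l.r`` pair,
while a terminal gene stores its own position.  The chromosome

    links:   2.3, 4.5, 3, 6.7, 5, 6, 7
    symbols: *_s, -_s, x, +_v, x,  y, x

decodes to the expression ``*_s(-_s(+_v(y, x), x), x)``.

Decoded expressions are kernel functions ``K(x, y)`` over pairs of feature
vectors.  Operators subscripted ``_v`` act elementwise (vector-valued);
operators subscripted ``_s`` reduce their operands to scalars (a vector is
reduced by summing its components) -- except ``*_s`` applied to two vectors,
which is the inner product.  The value at the root is reduced to a scalar,
so every expression defines a real-valued kernel; in particular ``*_s(x, y)``
is exactly the linear kernel.

Evolved kernels need not be symmetric or positive semidefinite, so this
module also provides Gram-matrix construction and repair (symmetrization and
eigenvalue clipping) for use with precomputed-kernel SVMs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "OPERATORS",
    "TERMINALS",
    "SYMBOLS",
    "arity",
    "Gene",
    "GFChromosome",
    "KernelExpression",
    "GramMatrix",
    "ChromosomeError",
    "InvalidKernelError",
    "parse_chromosome",
    "decode",
    "encode",
    "evaluate",
    "gram",
    "repair_gram",
    "normalize_gram",
    "complexity",
    "random_expression",
]

#: The five binary operators of the kernel language.
OPERATORS: tuple[str, ...] = ("+_v", "+_s", "-_v", "-_s", "*_s")
#: The two terminals: the pair of feature vectors a kernel compares.
TERMINALS: tuple[str, ...] = ("x", "y")
SYMBOLS: tuple[str, ...] = OPERATORS + TERMINALS


class ChromosomeError(ValueError):
    """Raised when tokens do not form a valid GF chromosome."""


class InvalidKernelError(ArithmeticError):
    """Raised when a kernel evaluation produces a non-finite value."""


def arity(symbol: str) -> int:
    """Arity of a symbol: 2 for operators, 0 for terminals."""
    if symbol in OPERATORS:
        return 2
    if symbol in TERMINALS:
        return 0
    raise ChromosomeError(f"unknown symbol {symbol!r}")


@dataclass(frozen=True)
class Gene:
    """One position of a chromosome.

    ``link`` is an ``(l, r)`` pair of child positions for an operator gene,
    or the gene's own position for a terminal gene.
    """

    position: int
    symbol: str
    link: tuple[int, int] | int

    @property
    def is_terminal(self) -> bool:
        return arity(self.symbol) == 0

    def link_token(self) -> str:
        if self.is_terminal:
            return str(self.link)
        l, r = self.link  # type: ignore[misc]
        return f"{l}.{r}"


def _validate_genes(genes: Sequence[Gene]) -> None:
    L = len(genes)
    if L < 1:
        raise ChromosomeError("a chromosome needs at least one gene")
    refs: list[int] = []
    n_ops = 0
    for i, g in enumerate(genes, start=1):
        if g.position != i:
            raise ChromosomeError(
                f"gene at index {i} carries position {g.position}"
            )
        if arity(g.symbol) == 2:
            n_ops += 1
            if not (isinstance(g.link, tuple) and len(g.link) == 2):
                raise ChromosomeError(
                    f"operator gene {i} ({g.symbol}) needs an l.r child pair"
                )
            l, r = g.link
            for child in (l, r):
                if not i < child <= L:
                    raise ChromosomeError(
                        f"gene {i} links to {child}: children must be forward "
                        f"references within 1..{L}"
                    )
            if l == r:
                raise ChromosomeError(f"gene {i} links twice to position {l}")
            refs.extend((l, r))
        else:
            if g.link != i:
                raise ChromosomeError(
                    f"terminal gene {i} ({g.symbol}) must link to itself, "
                    f"got {g.link}"
                )
    counts = Counter(refs)
    if counts.get(1, 0):
        raise ChromosomeError("the root (position 1) may not be a child")
    for pos in range(2, L + 1):
        c = counts.get(pos, 0)
        if c == 0:
            raise ChromosomeError(f"position {pos} is never referenced")
        if c > 1:
            raise ChromosomeError(f"position {pos} is referenced {c} times")
    if L - n_ops != n_ops + 1:
        raise ChromosomeError(
            f"{L - n_ops} terminals for {n_ops} operators: a binary tree "
            "needs exactly one more terminal than operators"
        )


@dataclass(frozen=True)
class GFChromosome:
    """A validated linear chromosome; gene 1 is the root of the fold."""

    genes: tuple[Gene, ...]

    def __post_init__(self) -> None:
        _validate_genes(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(g.symbol for g in self.genes)

    @property
    def link_tokens(self) -> tuple[str, ...]:
        return tuple(g.link_token() for g in self.genes)

    def to_text(self) -> str:
        """One-line round-trippable text form."""
        return (
            "links: " + ",".join(self.link_tokens)
            + " | symbols: " + ",".join(self.symbols)
        )

    @classmethod
    def from_text(cls, line: str) -> "GFChromosome":
        try:
            links_part, symbols_part = line.split("|")
            links = links_part.split(":", 1)[1].strip()
            symbols = symbols_part.split(":", 1)[1].strip()
        except (ValueError, IndexError) as exc:
            raise ChromosomeError(f"unparseable chromosome line: {line!r}") from exc
        return parse_chromosome(
            [t.strip() for t in links.split(",")],
            [s.strip() for s in symbols.split(",")],
        )


@dataclass(frozen=True)
class KernelExpression:
    """A kernel expression tree node: a symbol with 0 or 2 children."""

    symbol: str
    children: tuple["KernelExpression", ...] = ()

    def __post_init__(self) -> None:
        if len(self.children) != arity(self.symbol):
            raise ChromosomeError(
                f"symbol {self.symbol!r} takes {arity(self.symbol)} children, "
                f"got {len(self.children)}"
            )

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def complexity(self) -> int:
        """Number of operator (internal) nodes."""
        return 0 if self.is_leaf else 1 + sum(c.complexity for c in self.children)

    @property
    def depth(self) -> int:
        return 0 if self.is_leaf else 1 + max(c.depth for c in self.children)

    def __str__(self) -> str:
        if self.is_leaf:
            return self.symbol
        left, right = self.children
        return f"{self.symbol}({left}, {right})"

    def pretty(self) -> str:
        """Multi-line tree rendering for reports."""
        lines: list[str] = []

        def walk(node: "KernelExpression", prefix: str, tail: bool, root: bool) -> None:
            if root:
                lines.append(node.symbol)
                child_prefix = ""
            else:
                connector = "└── " if tail else "├── "
                lines.append(prefix + connector + node.symbol)
                child_prefix = prefix + ("    " if tail else "│   ")
            for i, child in enumerate(node.children):
                walk(child, child_prefix, i == len(node.children) - 1, False)

        walk(self, "", True, True)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Genotype <-> phenotype
# ---------------------------------------------------------------------------

def _parse_link_token(token, position: int) -> tuple[int, int] | int:
    if isinstance(token, float):
        token = format(token, "g")
    s = str(token).strip()
    if "." in s:
        parts = s.split(".")
        if len(parts) != 2 or not all(p.isdigit() for p in parts):
            raise ChromosomeError(f"malformed link token {token!r}")
        return int(parts[0]), int(parts[1])
    if not s.lstrip("-").isdigit():
        raise ChromosomeError(f"malformed link token {token!r}")
    return int(s)


def parse_chromosome(link_tokens: Sequence, symbol_tokens: Sequence[str]) -> GFChromosome:
    """Build a validated chromosome from parallel link and symbol tokens.

    Link tokens are ``"l.r"`` strings (or integers for terminals); passing
    floats works for single-digit positions but strings are preferred since
    e.g. ``6.10`` cannot survive float formatting.
    """
    if len(link_tokens) != len(symbol_tokens):
        raise ChromosomeError(
            f"{len(link_tokens)} link tokens vs {len(symbol_tokens)} symbols"
        )
    genes = []
    for pos, (ltok, sym) in enumerate(zip(link_tokens, symbol_tokens), start=1):
        link = _parse_link_token(ltok, pos)
        a = arity(sym)
        if a == 2 and not isinstance(link, tuple):
            raise ChromosomeError(
                f"gene {pos}: operator {sym!r} needs an l.r link, got {ltok!r}"
            )
        if a == 0 and isinstance(link, tuple):
            raise ChromosomeError(
                f"gene {pos}: terminal {sym!r} cannot take child links {ltok!r}"
            )
        genes.append(Gene(pos, sym, link))
    return GFChromosome(tuple(genes))


def decode(chrom: GFChromosome) -> KernelExpression:
    """Fold the linear chromosome into its expression tree."""

    def build(pos: int) -> KernelExpression:
        g = chrom.genes[pos - 1]
        if g.is_terminal:
            return KernelExpression(g.symbol)
        l, r = g.link  # type: ignore[misc]
        return KernelExpression(g.symbol, (build(l), build(r)))

    return build(1)


def encode(expr: KernelExpression) -> GFChromosome:
    """Lay an expression tree out as a chromosome in breadth-first order."""
    order: list[KernelExpression] = [expr]
    links: list[tuple[int, int] | int] = []
    i = 0
    while i < len(order):
        node = order[i]
        if node.children:
            l = len(order) + 1
            order.append(node.children[0])
            r = len(order) + 1
            order.append(node.children[1])
            links.append((l, r))
        else:
            links.append(i + 1)
        i += 1
    genes = tuple(
        Gene(pos, node.symbol, link)
        for pos, (node, link) in enumerate(zip(order, links), start=1)
    )
    return GFChromosome(genes)


def complexity(expr: KernelExpression) -> int:
    """Parsimony measure: the count of operator nodes."""
    return expr.complexity


# ---------------------------------------------------------------------------
# Evaluation semantics
# ---------------------------------------------------------------------------
#
# A node value is tagged scalar or vector.  reduce(vector) = component sum,
# reduce(scalar) = identity.  ``+_v``/``-_v`` act elementwise with scalar
# broadcast; ``+_s``/``-_s`` reduce both operands then add/subtract; ``*_s``
# is the inner product on two vectors, otherwise the product of reductions.
# The root value is reduced, so every expression is a scalar kernel.


def _reduce_val(tag: str, val):
    return float(np.sum(val)) if tag == "v" else float(val)


def _eval_node(node: KernelExpression, x: np.ndarray, y: np.ndarray):
    s = node.symbol
    if s == "x":
        return "v", x
    if s == "y":
        return "v", y
    ta, va = _eval_node(node.children[0], x, y)
    tb, vb = _eval_node(node.children[1], x, y)
    if s in ("+_v", "-_v"):
        out = va + vb if s == "+_v" else va - vb
        return ("v" if "v" in (ta, tb) else "s"), out
    ra, rb = _reduce_val(ta, va), _reduce_val(tb, vb)
    if s == "+_s":
        return "s", ra + rb
    if s == "-_s":
        return "s", ra - rb
    # *_s
    if ta == "v" and tb == "v":
        return "s", float(np.dot(va, vb))
    return "s", ra * rb


def evaluate(expr: KernelExpression, x, y) -> float:
    """Evaluate the kernel on a single pair of feature vectors.

    Raises :class:`InvalidKernelError` if the result is non-finite
    (overflow in evolved expressions is reported, never silently clamped).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape or x.size < 1:
        raise ValueError("x and y must be 1-d vectors of equal dimension >= 1")
    with np.errstate(over="ignore", invalid="ignore", under="ignore"):
        tag, val = _eval_node(expr, x, y)
        out = _reduce_val(tag, val)
    if not np.isfinite(out):
        raise InvalidKernelError(f"non-finite kernel value for {expr}")
    return out


# ---------------------------------------------------------------------------
# Gram matrices
# ---------------------------------------------------------------------------


@dataclass
class GramMatrix:
    """Pairwise kernel evaluations with symmetry/PSD-repair state."""

    values: np.ndarray
    repaired: bool = False
    repair_mode: str = "none"
    valid: bool = True

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def is_square(self) -> bool:
        return self.values.shape[0] == self.values.shape[1]


class _GramContext:
    """Precomputed O(n*m) fields shared by the closed-form Gram evaluator."""

    __slots__ = ("Sx", "Sy", "Qx", "Qy", "P", "d", "n", "m")

    def __init__(self, A: np.ndarray, B: np.ndarray):
        self.n, self.d = A.shape
        self.m = B.shape[0]
        self.Sx = A.sum(axis=1)[:, None]          # row sums of A
        self.Sy = B.sum(axis=1)[None, :]          # row sums of B
        self.Qx = np.einsum("ij,ij->i", A, A)[:, None]   # squared norms
        self.Qy = np.einsum("ij,ij->i", B, B)[None, :]
        self.P = A @ B.T                          # linear-kernel block


def _gram_reduce(tag: str, val, ctx: _GramContext):
    if tag == "s":
        return val
    a, b, c = val
    return a * ctx.Sx + b * ctx.Sy + c * ctx.d


def _gram_node(node: KernelExpression, ctx: _GramContext):
    """Evaluate a node over all sample pairs at once.

    Vector-valued nodes are affine in the two terminals, ``a*x + b*y + c``,
    with coefficient fields broadcastable over the (n, m) pair grid; this
    keeps every operation O(n*m) regardless of the feature dimension, and is
    algebraically identical to entrywise evaluation.
    """
    s = node.symbol
    if s == "x":
        return "v", (1.0, 0.0, 0.0)
    if s == "y":
        return "v", (0.0, 1.0, 0.0)
    ta, va = _gram_node(node.children[0], ctx)
    tb, vb = _gram_node(node.children[1], ctx)
    if s in ("+_v", "-_v"):
        sign = 1.0 if s == "+_v" else -1.0
        if ta == "v" and tb == "v":
            a1, b1, c1 = va
            a2, b2, c2 = vb
            return "v", (a1 + sign * a2, b1 + sign * b2, c1 + sign * c2)
        if ta == "v":
            a1, b1, c1 = va
            return "v", (a1, b1, c1 + sign * vb)
        if tb == "v":
            a2, b2, c2 = vb
            return "v", (sign * a2, sign * b2, va + sign * c2)
        return "s", va + sign * vb
    ra = _gram_reduce(ta, va, ctx)
    rb = _gram_reduce(tb, vb, ctx)
    if s == "+_s":
        return "s", ra + rb
    if s == "-_s":
        return "s", ra - rb
    # *_s
    if ta == "v" and tb == "v":
        a1, b1, c1 = va
        a2, b2, c2 = vb
        out = (
            a1 * a2 * ctx.Qx
            + b1 * b2 * ctx.Qy
            + (a1 * b2 + b1 * a2) * ctx.P
            + (a1 * c2 + a2 * c1) * ctx.Sx
            + (b1 * c2 + b2 * c1) * ctx.Sy
            + c1 * c2 * ctx.d
        )
        return "s", out
    return "s", ra * rb


def gram(expr: KernelExpression, A, B=None) -> GramMatrix:
    """Kernel matrix ``K[i, j] = K(A_i, B_j)`` (``B`` defaults to ``A``).

    Any non-finite entry marks the whole matrix invalid rather than being
    clamped: downstream fitness treats such kernels as failed genotypes.
    """
    A = np.asarray(A, dtype=float)
    B = A if B is None else np.asarray(B, dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError("A and B must be 2-d with a shared feature dimension")
    with np.errstate(over="ignore", invalid="ignore", under="ignore"):
        ctx = _GramContext(A, B)
        tag, val = _gram_node(expr, ctx)
        K = _gram_reduce(tag, val, ctx)
    K = np.broadcast_to(np.asarray(K, dtype=float), (ctx.n, ctx.m)).copy()
    return GramMatrix(K, valid=bool(np.isfinite(K).all()))


def repair_gram(G: GramMatrix, mode: str = "clip") -> GramMatrix:
    """Repair an evolved (possibly asymmetric/indefinite) square Gram matrix.

    ``symmetrize``: (G + G^T)/2.  ``clip``: symmetrize, then zero any
    negative eigenvalues.  ``clip`` first attempts a Cholesky factorization
    and skips the eigendecomposition when the matrix is already positive
    definite.
    """
    if not G.is_square:
        raise ValueError("repair requires a square Gram matrix")
    S = (G.values + G.values.T) / 2.0
    if mode == "symmetrize":
        return GramMatrix(S, repaired=True, repair_mode="symmetrize", valid=G.valid)
    if mode != "clip":
        raise ValueError(f"unknown repair mode {mode!r}")
    if G.valid:
        try:
            np.linalg.cholesky(S)
            K = S
        except np.linalg.LinAlgError:
            w, U = np.linalg.eigh(S)
            w = np.clip(w, 0.0, None)
            K = (U * w) @ U.T
            K = (K + K.T) / 2.0
    else:
        K = S
    return GramMatrix(K, repaired=True, repair_mode="clip", valid=G.valid)


def gram_unit_scale(values: np.ndarray) -> float:
    """Scale factor that brings a square Gram to unit mean |diagonal|.

    A kernel's overall scale is arbitrary (rescaling K is equivalent to
    rescaling the SVM cost C), but evolved expressions produce Grams whose
    magnitudes span many orders, which stalls the SVM solver.  Training all
    candidates at a common scale fixes the conditioning and makes the fixed
    cost C mean the same thing for every candidate.  Falls back to the mean
    |entry| when the diagonal is degenerate.
    """
    diag_scale = float(np.mean(np.abs(np.diag(values))))
    if diag_scale <= 1e-12:
        diag_scale = float(np.mean(np.abs(values)))
    return diag_scale if diag_scale > 1e-12 else 1.0


def normalize_gram(G: GramMatrix) -> GramMatrix:
    """Cosine normalization ``K'_ij = K_ij / sqrt(K_ii * K_jj)`` (square only).

    Refused -- the matrix is marked invalid -- when any diagonal entry is
    non-positive, since the normalization is then undefined.
    """
    if not G.is_square:
        raise ValueError("cosine normalization requires a square Gram matrix")
    diag = np.diag(G.values)
    if not G.valid or np.any(diag <= 0):
        return GramMatrix(G.values.copy(), G.repaired, G.repair_mode, valid=False)
    scale = np.sqrt(np.outer(diag, diag))
    return GramMatrix(G.values / scale, G.repaired, G.repair_mode, valid=True)


# ---------------------------------------------------------------------------
# Random initialization
# ---------------------------------------------------------------------------


def random_expression(
    max_depth: int,
    operators: Sequence[str] = OPERATORS,
    terminals: Sequence[str] = TERMINALS,
    rng=None,
) -> KernelExpression:
    """Draw a random expression tree of depth <= ``max_depth`` (grow method).

    Below the depth limit each node's symbol is drawn uniformly from the
    combined operator+terminal pool; at the limit a terminal is forced.
    Deterministic for a fixed seeded generator.
    """
    if not operators or not terminals:
        raise ValueError("operator and terminal sets must be nonempty")
    operators = tuple(operators)
    terminals = tuple(terminals)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    def grow(depth: int) -> KernelExpression:
        if depth <= 0:
            return KernelExpression(terminals[rng.integers(len(terminals))])
        pool = operators + terminals
        sym = pool[rng.integers(len(pool))]
        if arity(sym) == 0:
            return KernelExpression(sym)
        return KernelExpression(sym, (grow(depth - 1), grow(depth - 1)))

    return grow(max_depth)
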