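"""Maximum-likelihood protein phylogenetics under the JTT model.

The model is the empirical Jones-Taylor-Thornton (JTT) amino-acid
replacement process: a time-reversible CTMC with published exchangeabilities
S and stationary frequencies pi, rate matrix Q_ij = S_ij * pi_j normalized to
one expected substitution per site per unit time. The workflow mirrors the
classical ML protocol at desk scale: pairwise ML distances under JTT, an
NJ/BioNJ starting tree, Felsenstein-pruning log-likelihood, and per-branch
length optimization on the fixed starting topology. Branch lengths are in
expected substitutions per site.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from scipy.optimize import minimize_scalar

from ._jtt_data import (JTT_ALPHABET, JTT_EXCHANGEABILITIES_LOWER,
                        JTT_FREQUENCIES)

BRANCH_MAX = 10.0
BRANCH_MIN = 1e-6


class JttModel:
    """JTT substitution model with spectral matrix exponentials.

    P(t) = exp(Qt) is computed through the symmetric form
    B = diag(sqrt(pi)) Q diag(1/sqrt(pi)), so a single eigendecomposition
    serves every branch length.
    """

    alphabet = JTT_ALPHABET

    def __init__(self):
        n = 20
        S = np.zeros((n, n))
        for i, row in enumerate(JTT_EXCHANGEABILITIES_LOWER, start=1):
            for j, v in enumerate(row):
                S[i, j] = S[j, i] = v
        pi = np.array(JTT_FREQUENCIES)
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -(pi * np.diag(Q)).sum()
        Q /= scale
        self.pi = pi
        self.Q = Q
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        B = (B + B.T) / 2  # symmetrize against round-off
        lam, U = np.linalg.eigh(B)
        self._lam = lam
        # P(t) = D^{-1/2} U e^{lam t} U^T D^{1/2} with D = diag(pi)
        self._A = U / sq[:, None]
        self._Bt = (U * sq[:, None]).T
        self.index = {aa: i for i, aa in enumerate(self.alphabet)}

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1, tiny negative entries clamped."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        P = (self._A * np.exp(self._lam * t)) @ self._Bt
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


@dataclass
class ProteinAlignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) < 2:
            raise ValueError("alignment needs >= 2 sequences")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "ProteinAlignment":
        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(ids, rows)


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf():
            yield self
        else:
            for c, _ in self.children:
                yield from c.leaves()


@dataclass
class PhyloTree:
    """Unrooted tree stored with an arbitrary internal root (trifurcating
    for NJ output). Branch lengths in substitutions/site."""

    root: TreeNode
    log_likelihood: float | None = None

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.root.leaves()]

    def edges(self):
        """Iterate (parent, child_index) over all branches."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            for i, (child, _) in enumerate(node.children):
                yield node, i
                stack.append(child)

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                return node.name
            inner = ",".join(f"{fmt(c)}:{bl:.6f}" for c, bl in node.children)
            return f"({inner})"

        return fmt(self.root) + ";"

    def write(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick() + "\n")


# ---------------------------------------------------------------------------
# pairwise ML distances

def _pair_counts(row_i: str, row_j: str, model: JttModel) -> np.ndarray:
    """20x20 site-pattern counts under pairwise deletion of gap columns."""
    counts = np.zeros((20, 20))
    for a, b in zip(row_i, row_j):
        ia = model.index.get(a)
        ib = model.index.get(b)
        if ia is not None and ib is not None:
            counts[ia, ib] += 1
    return counts


def ml_pairwise_distance(row_i: str, row_j: str, model: JttModel) -> float:
    """ML divergence time for two aligned rows: argmax_t of
    sum_sites log(pi_a P_ab(t)), bracketed on [1e-6, 10]; saturated pairs
    return the upper bound."""
    counts = _pair_counts(row_i, row_j, model)
    if counts.sum() == 0:
        raise ValueError("no comparable (gap-free) sites between sequences")
    logpi = np.log(model.pi)

    def negloglik(t: float) -> float:
        P = model.transition_matrix(t)
        with np.errstate(divide="ignore"):
            ll = counts * (logpi[:, None] + np.log(np.maximum(P, 1e-300)))
        return -ll.sum()

    res = minimize_scalar(negloglik, bounds=(BRANCH_MIN, BRANCH_MAX),
                          method="bounded", options={"xatol": 1e-8})
    return float(min(res.x, BRANCH_MAX))


def distance_matrix(aln: ProteinAlignment, model: JttModel) -> np.ndarray:
    n = len(aln.ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = ml_pairwise_distance(aln.rows[i], aln.rows[j],
                                                     model)
    return D


# ---------------------------------------------------------------------------
# NJ / BioNJ

def build_nj(D: np.ndarray, ids: list[str], variant: str = "NJ") -> PhyloTree:
    """Agglomerative tree from a distance matrix.

    NJ follows the Saitou-Nei Q-criterion; BioNJ additionally propagates a
    variance matrix and uses variance-weighted reduction (the two agree on
    additive inputs). Negative branch lengths are clamped to zero and
    Q-criterion ties break on the smallest (i, j) index pair.
    """
    variant = variant.upper()
    if variant not in ("NJ", "BIONJ"):
        raise ValueError(f"unknown variant {variant}")
    D = np.asarray(D, dtype=float)
    n = len(ids)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    active = list(range(n))
    Dw = D.copy()
    Vw = D.copy()  # BioNJ variance estimates

    while len(active) > 3:
        m = len(active)
        r = {a: sum(Dw[a, b] for b in active if b != a) for a in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                a, b = active[ai], active[aj]
                q = (m - 2) * Dw[a, b] - r[a] - r[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        la = 0.5 * Dw[a, b] + (r[a] - r[b]) / (2 * (m - 2))
        lb = Dw[a, b] - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        new = TreeNode(children=[(nodes[a], la), (nodes[b], lb)])

        if variant == "BIONJ" and Vw[a, b] > 1e-12 and m > 3:
            others = [k for k in active if k not in (a, b)]
            lam = 0.5 + sum(Vw[b, k] - Vw[a, k] for k in others) / (
                2 * (m - 2) * Vw[a, b])
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5

        # grow matrices by one row/col for the new node
        u = Dw.shape[0]
        Dw = np.pad(Dw, ((0, 1), (0, 1)))
        Vw = np.pad(Vw, ((0, 1), (0, 1)))
        for k in active:
            if k in (a, b):
                continue
            if variant == "BIONJ":
                duk = lam * (Dw[a, k] - la) + (1 - lam) * (Dw[b, k] - lb)
                vuk = lam * Vw[a, k] + (1 - lam) * Vw[b, k] - lam * (1 - lam) * Vw[a, b]
            else:
                duk = 0.5 * (Dw[a, k] + Dw[b, k] - Dw[a, b])
                vuk = duk
            Dw[u, k] = Dw[k, u] = duk
            Vw[u, k] = Vw[k, u] = vuk
        nodes.append(new)
        active = [k for k in active if k not in (a, b)] + [u]

    a, b, c = active
    la = 0.5 * (Dw[a, b] + Dw[a, c] - Dw[b, c])
    lb = 0.5 * (Dw[a, b] + Dw[b, c] - Dw[a, c])
    lc = 0.5 * (Dw[a, c] + Dw[b, c] - Dw[a, b])
    root = TreeNode(children=[(nodes[a], max(la, 0.0)),
                              (nodes[b], max(lb, 0.0)),
                              (nodes[c], max(lc, 0.0))])
    return PhyloTree(root=root)


# ---------------------------------------------------------------------------
# likelihood

def transition_matrix(model: JttModel, t: float) -> np.ndarray:
    return model.transition_matrix(t)


def _site_patterns(aln: ProteinAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Compress columns into unique patterns; returns (patterns, counts)
    with residue indices, -1 for gap/unknown (missing data)."""
    n, L = len(aln.rows), aln.n_sites
    mat = np.full((L, n), -1, dtype=np.int8)
    # build index map once
    for j, row in enumerate(aln.rows):
        for s, ch in enumerate(row):
            mat[s, j] = _GLOBAL_INDEX.get(ch, -1)
    patterns, counts = np.unique(mat, axis=0, return_counts=True)
    return patterns, counts


_GLOBAL_INDEX = {aa: i for i, aa in enumerate(JTT_ALPHABET)}


def _partials(node: TreeNode, patterns: np.ndarray,
              leaf_col: dict[str, int], model: JttModel) -> tuple[np.ndarray, np.ndarray]:
    """Conditional likelihoods (n_patterns x 20) and per-pattern log-scalers."""
    if node.is_leaf():
        col = patterns[:, leaf_col[node.name]]
        L = np.zeros((len(patterns), 20))
        known = col >= 0
        L[known, col[known]] = 1.0
        L[~known, :] = 1.0  # gap: missing data
        return L, np.zeros(len(patterns))
    L = np.ones((len(patterns), 20))
    scaler = np.zeros(len(patterns))
    for child, bl in node.children:
        Lc, sc = _partials(child, patterns, leaf_col, model)
        P = model.transition_matrix(bl)
        L = L * (Lc @ P.T)
        scaler += sc
    m = L.max(axis=1)
    m = np.where(m > 0, m, 1.0)
    L /= m[:, None]
    scaler += np.log(m)
    return L, scaler


def prune_loglik(tree: PhyloTree, aln: ProteinAlignment,
                 model: JttModel) -> float:
    """Felsenstein-pruning log-likelihood; gaps are missing data."""
    names = set(tree.leaf_names())
    if names != set(aln.ids):
        raise ValueError("tree leaves and alignment ids differ")
    for parent, i in tree.edges():
        if parent.children[i][1] is None:
            raise ValueError("unset branch length")
    patterns, counts = _site_patterns(aln)
    leaf_col = {name: j for j, name in enumerate(aln.ids)}
    L, scaler = _partials(tree.root, patterns, leaf_col, model)
    site_ll = np.log(np.maximum(L @ model.pi, 1e-300)) + scaler
    return float((site_ll * counts).sum())


def optimize_branch_lengths(tree: PhyloTree, aln: ProteinAlignment,
                            model: JttModel, tol: float = 1e-6,
                            max_sweeps: int = 100) -> PhyloTree:
    """Round-robin per-branch bracketed maximization of the pruning
    log-likelihood on the fixed topology; monotone by construction."""
    ll = prune_loglik(tree, aln, model)
    for _ in range(max_sweeps):
        improved = ll
        for parent, i in list(tree.edges()):
            child, bl0 = parent.children[i]

            def neg(x):
                parent.children[i] = (child, float(x))
                return -prune_loglik(tree, aln, model)

            res = minimize_scalar(neg, bounds=(BRANCH_MIN, BRANCH_MAX),
                                  method="bounded", options={"xatol": 1e-6})
            if -res.fun > ll:
                parent.children[i] = (child, float(res.x))
                ll = -res.fun
            else:
                parent.children[i] = (child, bl0)
        if ll - improved < tol:
            break
    tree.log_likelihood = ll
    return tree


# ---------------------------------------------------------------------------
# simulation (for parameter-recovery checks)

def simulate_alignment(tree: PhyloTree, n_sites: int, model: JttModel,
                       rng: np.random.Generator) -> ProteinAlignment:
    """Evolve sites down the tree under the model (root states ~ pi)."""
    rows: dict[str, np.ndarray] = {}

    def descend(node: TreeNode, states: np.ndarray):
        if node.is_leaf():
            rows[node.name] = states
            return
        for child, bl in node.children:
            P = model.transition_matrix(bl)
            cum = P.cumsum(axis=1)
            u = rng.random(n_sites)
            child_states = (u[:, None] > cum[states]).sum(axis=1)
            descend(child, child_states)

    root_states = (rng.random(n_sites)[:, None] > model.pi.cumsum()[None, :]
                   ).sum(axis=1)
    descend(tree.root, root_states)
    alphabet = np.array(list(JTT_ALPHABET))
    ids = [l.name for l in tree.root.leaves()]
    return ProteinAlignment(ids, ["".join(alphabet[rows[i]]) for i in ids])


def run_ml_pipeline(aln: ProteinAlignment, variant: str = "NJ",
                    model: JttModel | None = None) -> PhyloTree:
    """Distances -> starting tree -> branch-length ML on that topology."""
    model = model or JttModel()
    D = distance_matrix(aln, model)
    tree = build_nj(D, aln.ids, variant=variant)
    return optimize_branch_lengths(tree, aln, model)
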