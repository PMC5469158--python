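"""Phylogenetic likelihoods under a reversible model with +I+G rate mixing.

The per-site likelihood of an alignment column D_i on a tree T under a
normalized generator Q, invariant-site proportion v and C discrete gamma
categories with rates rho_c (mean 1) is the standard mixture

    L_i = v * L(invariant; D_i) + (1 - v) * (1/C) * sum_c L(rho_c T, Q; D_i),

where rho_c T is T with every branch multiplied by rho_c, L(.; D_i) is
the Felsenstein pruning likelihood, and the invariant component is the
equilibrium probability of the residue the column is constant in (zero if
the column cannot be constant; all-gap columns contribute zero
log-likelihood).  The alignment log-likelihood is the weighted sum of
log L_i over the unique site patterns.

Numerical notes: partial likelihood vectors are rescaled per node and per
(category, pattern), with the log of the scale factors accumulated, so
arbitrarily many sites and taxa never underflow.  Transition matrices come
from the symmetric eigendecomposition of Q (see :mod:`mtsubst.models`).
Multifurcating trees are handled naturally by the pruning recursion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy import optimize
from scipy.special import logsumexp
from scipy.stats import gamma as gamma_dist

from .align import Alignment
from .alphabet import N_STATES
from .models import RateMatrix, SubstitutionModel
from .phylo import Node, PhyloTree

__all__ = [
    "RateHeterogeneity",
    "LikelihoodResult",
    "discretize_gamma",
    "site_likelihood",
    "alignment_loglik",
    "optimize_branch_lengths",
    "optimize_rate_model",
    "information_criteria",
    "export_site_lnl",
    "read_site_lnl",
    "PruningEngine",
]

_LOG0 = -np.inf


def discretize_gamma(alpha: float, C: int = 4) -> np.ndarray:
    """Mean rates of C equal-probability bins of a mean-1 gamma distribution.

    The gamma has shape ``alpha`` and scale ``1/alpha``; category c's rate
    is the conditional mean of the distribution within its probability
    bin, so the category rates average exactly 1.
    """
    if alpha <= 0:
        raise ValueError(f"gamma shape must be positive, got {alpha}")
    if C < 1:
        raise ValueError("need at least one category")
    if C == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.arange(C + 1) / C, alpha, scale=1.0 / alpha)
    # integral of x * pdf over a bin equals the shape-(alpha+1) CDF increment
    upper_cdf = gamma_dist.cdf(edges, alpha + 1.0, scale=1.0 / alpha)
    rho = C * np.diff(upper_cdf)
    return rho / rho.mean()


@dataclass
class RateHeterogeneity:
    """+I+G site-rate model: invariant proportion v, gamma shape alpha,
    C discrete categories with mean-1 rates rho."""

    alpha: float = 1.0
    v: float = 0.0
    C: int = 4
    rho: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if not 0.0 <= self.v <= 1.0:
            raise ValueError(f"invariant proportion must be in [0, 1], got {self.v}")
        if self.rho is None:
            self.rho = discretize_gamma(self.alpha, self.C)
        self.rho = np.asarray(self.rho, dtype=float)
        if abs(self.rho.mean() - 1.0) > 1e-10:
            raise ValueError("category rates must average 1")

    def with_params(self, alpha: float | None = None, v: float | None = None) -> "RateHeterogeneity":
        return RateHeterogeneity(
            alpha=self.alpha if alpha is None else alpha,
            v=self.v if v is None else v,
            C=self.C,
        )


@dataclass
class LikelihoodResult:
    """Total and per-site log-likelihoods with the parameters that produced them."""

    total: float
    site_loglik: np.ndarray  # alignment order, one entry per column
    params: dict

    def __post_init__(self) -> None:
        if not math.isclose(self.total, float(self.site_loglik.sum()), abs_tol=1e-6):
            raise ValueError("per-site log-likelihoods do not sum to the total")


# ---------------------------------------------------------------------------
# Pruning engine


class PruningEngine:
    """Felsenstein pruning over compressed site patterns.

    Flattens a :class:`PhyloTree` into postorder arrays and evaluates the
    +I+G mixture log-likelihood, per-edge outside vectors (for branch
    optimization and rate-matrix gradients), and per-site values.
    The tree object is referenced, not copied: changing a node's
    ``length`` and re-evaluating is the supported idiom.
    """

    def __init__(
        self,
        tree: PhyloTree,
        model: SubstitutionModel | None,
        het: RateHeterogeneity | None,
        alignment: Alignment,
        Q: RateMatrix | None = None,
    ):
        self.tree = tree
        self.model = model
        self.het = het or RateHeterogeneity(alpha=1.0, v=0.0, C=1)
        self.alignment = alignment
        if Q is None:
            if model is None:
                raise ValueError("need a model or a rate matrix")
            Q = model.rate_matrix(normalize=True)
        self.set_rate_matrix(Q)

        row_of = {name: i for i, name in enumerate(alignment.names)}
        missing = [l for l in tree.leaf_names() if l not in row_of]
        if missing:
            raise ValueError(f"tree leaves missing from alignment: {missing[:5]}")

        self.nodes: list[Node] = list(tree.postorder())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.tips = alignment.tip_indicators()  # (seqs, S, 20)
        self.leaf_row = {
            self.index[id(n)]: row_of[n.name] for n in self.nodes if n.is_leaf
        }
        _, self.weights, self.site_index = alignment.patterns()
        self.S = len(self.weights)

        # residues each column could be constant in, for the invariant class
        inv = np.ones((self.S, N_STATES))
        for n in self.nodes:
            if n.is_leaf:
                inv *= self.tips[row_of[n.name]]
        self._constant_indicator = inv
        self.invariant_prob = inv @ self.pi  # (S,)

    # -- configuration -------------------------------------------------

    def set_rate_matrix(self, Q: RateMatrix) -> None:
        self.Q = Q
        self.lam, self.A, self.B = Q.eigensystem()
        self.pi = Q.frequencies
        if getattr(self, "_constant_indicator", None) is not None:
            self.invariant_prob = self._constant_indicator @ self.pi

    def set_het(self, het: RateHeterogeneity) -> None:
        self.het = het

    def prob_matrices(self, t: float) -> np.ndarray:
        """(C, 20, 20) transition matrices for one branch under each rate."""
        if t < 0:
            raise ValueError("negative branch length")
        tau = self.het.rho * t  # (C,)
        E = np.exp(self.lam[None, :] * tau[:, None])  # (C, 20)
        P = np.einsum("ik,ck,kj->cij", self.A, E, self.B)
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P

    # -- core passes ---------------------------------------------------

    def _edge_length(self, node: Node) -> float:
        if node.length is None:
            raise ValueError(f"branch above {node.name or 'internal node'} has no length")
        return node.length

    def inside(self):
        """Postorder partials.  Returns (partials, logscale, M, Mls) where
        ``partials[i]`` is the (C, S, 20) inside vector at node i with
        accumulated log-scale ``logscale[i]`` (C, S), and ``M[i]`` is node
        i's partial propagated through its own edge (used by siblings and
        the outside pass)."""
        C = self.het.C
        partials = [None] * len(self.nodes)
        logscale = [None] * len(self.nodes)
        M = [None] * len(self.nodes)
        Mls = [None] * len(self.nodes)
        for i, node in enumerate(self.nodes):
            if node.is_leaf:
                part = np.broadcast_to(
                    self.tips[self.leaf_row[i]][None, :, :], (C, self.S, N_STATES)
                ).copy()
                ls = np.zeros((C, self.S))
            else:
                part = np.ones((C, self.S, N_STATES))
                ls = np.zeros((C, self.S))
                for ch in node.children:
                    j = self.index[id(ch)]
                    part = part * M[j]
                    ls = ls + Mls[j]
                m = part.max(axis=2)
                nz = m > 0
                part = np.where(nz[..., None], part / np.where(nz, m, 1.0)[..., None], part)
                ls = ls + np.where(nz, np.log(np.where(nz, m, 1.0)), _LOG0)
            partials[i] = part
            logscale[i] = ls
            if node.parent is not None:
                P = self.prob_matrices(self._edge_length(node))
                M[i] = np.einsum("cij,csj->csi", P, part)
                Mls[i] = ls
        return partials, logscale, M, Mls

    def _category_loglik(self, partials, logscale) -> np.ndarray:
        """(C, S) log-likelihood per gamma category and pattern."""
        root = len(self.nodes) - 1
        with np.errstate(divide="ignore"):
            return np.log(partials[root] @ self.pi) + logscale[root]

    def _mix(self, cat_loglik: np.ndarray) -> np.ndarray:
        """Fold category log-likelihoods and the invariant class into the
        per-pattern mixture log-likelihood (S,)."""
        v, C = self.het.v, self.het.C
        with np.errstate(divide="ignore"):
            lg = logsumexp(cat_loglik, axis=0) - np.log(C)
            if v == 0.0:
                return lg
            log_inv = np.where(
                self.invariant_prob > 0, np.log(np.where(self.invariant_prob > 0, self.invariant_prob, 1.0)), _LOG0
            )
            return np.logaddexp(np.log(v) + log_inv, np.log1p(-v) + lg)

    def pattern_loglik(self) -> np.ndarray:
        partials, logscale, _, _ = self.inside()
        return self._mix(self._category_loglik(partials, logscale))

    def loglik(self) -> float:
        return float(np.dot(self.weights, self.pattern_loglik()))

    def result(self) -> LikelihoodResult:
        per_pattern = self.pattern_loglik()
        per_site = per_pattern[self.site_index]
        return LikelihoodResult(
            total=float(per_site.sum()),
            site_loglik=per_site,
            params={
                "model": self.model.name if self.model is not None else "(rate matrix)",
                "alpha": self.het.alpha,
                "v": self.het.v,
                "C": self.het.C,
                "tree": self.tree.newick(),
            },
        )

    def outside(self, inside_state=None):
        """Root-ward vectors per edge: ``out[i]`` (C, S, 20) with log-scale
        ``outls[i]`` such that for the edge above node i,
        sum_jk out[i][..., j] P_jk inside[i][..., k] recovers the category
        likelihood (up to the two accumulated log-scales)."""
        partials, logscale, M, Mls = inside_state or self.inside()
        C = self.het.C
        n = len(self.nodes)
        out = [None] * n
        outls = [None] * n
        R = [None] * n
        Rls = [None] * n
        root = n - 1
        R[root] = np.broadcast_to(self.pi[None, None, :], (C, self.S, N_STATES)).copy()
        Rls[root] = np.zeros((C, self.S))
        for i in range(n - 1, -1, -1):
            node = self.nodes[i]
            if node.is_leaf:
                continue
            for ch in node.children:
                j = self.index[id(ch)]
                o = R[i].copy()
                ols = Rls[i].copy()
                for sib in node.children:
                    if sib is ch:
                        continue
                    k = self.index[id(sib)]
                    o = o * M[k]
                    ols = ols + Mls[k]
                m = o.max(axis=2)
                nz = m > 0
                o = np.where(nz[..., None], o / np.where(nz, m, 1.0)[..., None], o)
                ols = ols + np.where(nz, np.log(np.where(nz, m, 1.0)), _LOG0)
                out[j] = o
                outls[j] = ols
                if not ch.is_leaf:
                    P = self.prob_matrices(self._edge_length(ch))
                    R[j] = np.einsum("cij,csi->csj", P, o)
                    Rls[j] = ols
        return partials, logscale, out, outls

    # -- branch-length optimization ------------------------------------

    def edge_loglik_fn(self, node: Node, inside_state=None):
        """Return f(t): total mixture lnL as a function of one edge length.

        Built from fresh inside/outside vectors; exact while every other
        branch stays put."""
        partials, logscale, out, outls = self.outside(inside_state)
        j = self.index[id(node)]
        inn, innls = partials[j], logscale[j]
        o, ols = out[j], outls[j]
        base_ls = innls + ols

        def f(t: float) -> float:
            P = self.prob_matrices(t)
            tmp = np.einsum("cij,csj->csi", P, inn)
            L = np.einsum("csi,csi->cs", o, tmp)
            with np.errstate(divide="ignore"):
                cat = np.log(np.maximum(L, 0.0)) + base_ls
            return float(np.dot(self.weights, self._mix(cat)))

        return f


def site_likelihood(tree: PhyloTree, Q: RateMatrix, site: dict[str, str]) -> float:
    """Pruning likelihood of a single alignment column (no rate mixing).

    ``site`` maps every leaf name to its amino-acid symbol (ambiguity
    codes act as indicator sets).  Returns the probability, i.e. the
    equilibrium-weighted root summation of the pruning recursion.
    """
    names = tree.leaf_names()
    missing = [n for n in names if n not in site]
    if missing:
        raise ValueError(f"no residue given for leaves: {missing[:5]}")
    aln = Alignment(list(names), [site[n] for n in names])
    if len(names) == 1:
        # single leaf: probability is just the equilibrium frequency
        from .alphabet import indicator

        return float(indicator(aln.rows[0][0]) @ Q.frequencies)
    het = RateHeterogeneity(alpha=1.0, v=0.0, C=1)
    engine = PruningEngine(tree, None, het, aln, Q=Q)
    return float(np.exp(engine.pattern_loglik()[0]))


def alignment_loglik(
    tree: PhyloTree,
    model: SubstitutionModel,
    het: RateHeterogeneity | None,
    alignment: Alignment,
) -> LikelihoodResult:
    """Total and per-site +I+G log-likelihood of an alignment on a tree."""
    return PruningEngine(tree, model, het, alignment).result()


# ---------------------------------------------------------------------------
# Optimization


_MIN_BRANCH = 1e-8
_MAX_BRANCH = 20.0


def optimize_branch_lengths(
    tree: PhyloTree,
    model: SubstitutionModel,
    het: RateHeterogeneity | None,
    alignment: Alignment,
    tol: float = 1e-6,
    lnl_tol: float = 1e-4,
    max_rounds: int = 20,
) -> tuple[PhyloTree, LikelihoodResult]:
    """Coordinate-wise ML branch lengths (one Brent search per edge).

    Edges without a starting length are initialized at 0.1.  Each edge is
    optimized against fresh inside/outside vectors, so the total
    log-likelihood never decreases; rounds stop when a full sweep gains
    less than ``lnl_tol`` log-units.  Returns a new tree and the fit.
    """
    work = tree.copy()
    for node in work.edges():
        if node.length is None or node.length <= 0:
            node.length = 0.1
    engine = PruningEngine(work, model, het, alignment)
    current = engine.loglik()
    if not np.isfinite(current):
        bad = int(np.argmin(np.isfinite(engine.pattern_loglik()[engine.site_index])))
        raise ValueError(f"non-finite starting log-likelihood (first bad site: {bad})")
    for _ in range(max_rounds):
        previous = current
        for node in engine.tree.edges():
            f = engine.edge_loglik_fn(node)
            res = optimize.minimize_scalar(
                lambda t: -f(t),
                bounds=(_MIN_BRANCH, _MAX_BRANCH),
                method="bounded",
                options={"xatol": tol},
            )
            if -res.fun > f(node.length):
                node.length = float(res.x)
        current = engine.loglik()
        if current - previous < lnl_tol:
            break
    return work, engine.result()


def optimize_rate_model(
    tree: PhyloTree,
    model: SubstitutionModel,
    het0: RateHeterogeneity,
    alignment: Alignment,
    optimize_v: bool = True,
    tol: float = 1e-6,
) -> tuple[RateHeterogeneity, LikelihoodResult]:
    """Bounded joint ML of the gamma shape and invariant proportion.

    alpha is searched in [0.02, 100] (log scale), v in [0, 0.99]; the
    returned fit never undercuts the starting parameters.
    """
    engine = PruningEngine(tree, model, het0, alignment)

    def objective(x) -> float:
        alpha = float(np.exp(x[0]))
        v = float(x[1]) if optimize_v else het0.v
        engine.set_het(RateHeterogeneity(alpha=alpha, v=v, C=het0.C))
        return -engine.loglik()

    x0 = [np.log(het0.alpha), het0.v]
    bounds = [(np.log(0.02), np.log(100.0)), (0.0, 0.99)]
    if not optimize_v:
        bounds[1] = (het0.v, het0.v)
    res = optimize.minimize(
        objective, x0, method="L-BFGS-B", bounds=bounds, options={"ftol": tol, "gtol": 1e-8}
    )
    start = -objective(x0)
    best_x = res.x if -res.fun >= start else np.array(x0)
    best = RateHeterogeneity(
        alpha=float(np.exp(best_x[0])),
        v=float(best_x[1]) if optimize_v else het0.v,
        C=het0.C,
    )
    engine.set_het(best)
    return best, engine.result()


class InformationCriteria(NamedTuple):
    aic: float
    bic: float
    aic_per_site: float
    bic_per_site: float


def information_criteria(lnl: float, k: int, n_sites: int) -> InformationCriteria:
    """AIC = 2k - 2 lnL and BIC = k ln(n) - 2 lnL, absolute and per site."""
    if n_sites < 1:
        raise ValueError("n_sites must be positive")
    aic = 2.0 * k - 2.0 * lnl
    bic = k * math.log(n_sites) - 2.0 * lnl
    return InformationCriteria(aic, bic, aic / n_sites, bic / n_sites)


# ---------------------------------------------------------------------------
# Site-wise log-likelihood export (CONSEL input)


def export_site_lnl(results: list[LikelihoodResult], path: str | Path) -> None:
    """Write the site-likelihood text matrix consumed by CONSEL.

    Header line ``<n_trees> <n_sites>``, then one whitespace-separated row
    of per-site log-likelihoods per (tree, model) result.
    """
    if not results:
        raise ValueError("no results to export")
    n_sites = {len(r.site_loglik) for r in results}
    if len(n_sites) != 1:
        raise ValueError(f"results have differing site counts: {sorted(n_sites)}")
    (n,) = n_sites
    with open(path, "w") as fh:
        fh.write(f"{len(results)} {n}\n")
        for r in results:
            fh.write(" ".join(f"{x:.10g}" for x in r.site_loglik))
            fh.write("\n")


def read_site_lnl(path: str | Path) -> np.ndarray:
    """Read a site-likelihood matrix written by :func:`export_site_lnl`."""
    with open(path) as fh:
        header = fh.readline().split()
        n_rows, n_sites = int(header[0]), int(header[1])
        mat = np.loadtxt(fh, ndmin=2)
    if mat.shape != (n_rows, n_sites):
        raise ValueError(f"matrix shape {mat.shape} does not match header {(n_rows, n_sites)}")
    return mat
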