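"""Joint maximum-likelihood estimation of an amino-acid substitution matrix.

Given a collection of alignments D = {D^i}, the target function is

    LK(Q; D) = prod_i LK(T^i, Q, alpha^i, v^i; D^i),

maximized by block coordinate ascent: per-alignment parameters (branch
lengths of T^i and the +I+G parameters alpha^i, v^i) are fitted under the
current matrix, then the 190 exchangeabilities are re-estimated by direct
likelihood maximization with the per-alignment parameters held fixed, and
the two half-steps alternate until the gain per site is insignificant.
Both half-steps are conditional maximizations, so the target
log-likelihood never decreases across iterations.

The matrix step optimizes log-exchangeabilities (one reference coefficient
is pinned for identifiability; the overall scale is absorbed by the
generator normalization) with an analytic gradient: the derivative of the
log-likelihood with respect to each transition matrix P(t rho_c) is
assembled from inside/outside vectors, pulled back through the matrix
exponential with the eigendecomposition form of its Frechet derivative,
and chained through q_xy = pi_y r_xy and the expected-rate normalization.
Equilibrium frequencies are the empirical residue proportions of the
training alignments, the standard convention for empirical models.
"""

from __future__ import annotations

import io as _io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .align import Alignment, read_alignment
from .alphabet import N_STATES, encode
from .likelihood import (
    PruningEngine,
    RateHeterogeneity,
    optimize_branch_lengths,
    optimize_rate_model,
)
from .models import RateMatrix, SubstitutionModel, build_rate_matrix
from .phylo import PhyloTree, parse_newick

log = logging.getLogger(__name__)

__all__ = [
    "TrainingEntry",
    "TrainingSet",
    "EstimationTrace",
    "EmpiricalMatrixML",
    "EmpiricalMatrixResults",
    "pairwise_ml_distance",
    "initial_tree",
    "fit_alignment_params",
    "optimize_matrix",
    "estimate_model",
]

_TRIL = np.tril_indices(N_STATES, k=-1)
_MAX_DISTANCE = 10.0


# ---------------------------------------------------------------------------
# Pairwise ML distances and neighbor-joining starting trees


def pairwise_ml_distance(
    row_a: str, row_b: str, model: SubstitutionModel, Q: RateMatrix | None = None
) -> float:
    """One-dimensional ML evolutionary distance between two aligned rows.

    Maximizes sum_sites log(pi_x P(t)_{x,y}) over t in [1e-8, 10] under the
    normalized generator, so the distance is in expected substitutions per
    site.  Columns where either row is fully ambiguous are uninformative
    but still enter the likelihood (they contribute a constant).
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must be aligned (equal length)")
    if len(row_a) == 0:
        raise ValueError("empty alignment")
    Q = Q or model.rate_matrix(normalize=True)
    lam, A, B = Q.eigensystem()
    pi = Q.frequencies
    aln = Alignment(["a", "b"], [row_a, row_b])
    cols, weights, _ = aln.patterns()
    fa = np.stack([encode(c)[0] for c in cols[:, 0]])  # (S, 20)
    fb = np.stack([encode(c)[0] for c in cols[:, 1]])
    va = (fa * pi) @ A  # (S, 20) in eigenbasis
    wb = fb @ B.T
    coeff = va * wb  # L_s(t) = sum_k coeff[s, k] * exp(lam_k t)
    informative = ~(np.all(fa == 1.0, axis=1) | np.all(fb == 1.0, axis=1))
    if not informative.any():
        warnings.warn("no informative columns between sequence pair; using maximum distance")
        return _MAX_DISTANCE

    def negloglik(t: float) -> float:
        L = coeff @ np.exp(lam * t)
        if np.any(L <= 0):
            return np.inf
        return -float(np.dot(weights, np.log(L)))

    res = optimize.minimize_scalar(
        negloglik, bounds=(1e-8, _MAX_DISTANCE), method="bounded", options={"xatol": 1e-8}
    )
    return float(res.x)


def nj_tree(distances: np.ndarray, names: list[str]) -> PhyloTree:
    """Neighbor joining on a symmetric distance matrix (scikit-bio),
    with negative branch-length estimates clamped to 1e-6."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    buf = _io.StringIO()
    nj(DistanceMatrix(distances, ids=names)).write(buf)
    tree = parse_newick(buf.getvalue())
    for node in tree.edges():
        if node.length is None or node.length < 1e-6:
            node.length = 1e-6
    return tree


def initial_tree(alignment: Alignment, model: SubstitutionModel) -> PhyloTree:
    """Neighbor-joining tree from pairwise ML distances under ``model``.

    Negative NJ branch lengths are clamped to 1e-6.  For two sequences the
    single-edge tree carries the pairwise ML distance.
    """
    n = alignment.n_sequences
    if n < 2:
        raise ValueError("need at least two sequences")
    Q = model.rate_matrix(normalize=True)
    if n == 2:
        d = pairwise_ml_distance(alignment.rows[0], alignment.rows[1], model, Q)
        a, b = alignment.names
        return parse_newick(f"({a}:{d / 2:.12g},{b}:{d / 2:.12g});")
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = pairwise_ml_distance(
                alignment.rows[i], alignment.rows[j], model, Q
            )
    return nj_tree(dm, alignment.names)


# ---------------------------------------------------------------------------
# Training sets


@dataclass
class TrainingEntry:
    """One alignment with its per-alignment nuisance parameters."""

    name: str
    alignment: Alignment
    tree: PhyloTree | None = None
    het: RateHeterogeneity | None = None
    loglik: float = np.nan


@dataclass
class TrainingSet:
    """A collection of alignments sharing one substitution matrix."""

    entries: list[TrainingEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("training set is empty")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @classmethod
    def from_alignments(
        cls, alignments: list[Alignment], trees: list[PhyloTree] | None = None,
        names: list[str] | None = None,
    ) -> "TrainingSet":
        names = names or [f"aln{i:03d}" for i in range(len(alignments))]
        trees = trees or [None] * len(alignments)
        return cls([
            TrainingEntry(name=n, alignment=a, tree=t)
            for n, a, t in zip(names, alignments, trees)
        ])

    @classmethod
    def from_directory(cls, directory: str | Path) -> "TrainingSet":
        """Load every FASTA/PHYLIP alignment in a directory, pairing each
        with a same-stem ``.nwk``/``.tree`` Newick file when present."""
        directory = Path(directory)
        entries = []
        patterns = ("*.fasta", "*.fa", "*.faa", "*.fas", "*.phy", "*.phylip")
        paths = sorted(p for pat in patterns for p in directory.glob(pat))
        for path in paths:
            aln = read_alignment(path)
            tree = None
            for ext in (".nwk", ".tree", ".treefile"):
                tp = path.with_suffix(ext)
                if tp.exists():
                    tree = parse_newick(tp.read_text())
                    break
            entries.append(TrainingEntry(name=path.stem, alignment=aln, tree=tree))
        if not entries:
            raise ValueError(f"no alignments found in {directory}")
        return cls(entries)

    def empirical_frequencies(self, floor: float = 1e-6) -> np.ndarray:
        """Residue proportions over all alignments, floored and renormalized
        so every state keeps a nonzero equilibrium frequency."""
        counts = np.zeros(N_STATES)
        for entry in self.entries:
            counts += entry.alignment.residue_counts()
        if counts.sum() == 0:
            raise ValueError("training alignments contain no canonical residues")
        freqs = np.maximum(counts / counts.sum(), floor)
        return freqs / freqs.sum()


def fit_alignment_params(
    entry: TrainingEntry,
    model: SubstitutionModel,
    optimize_het: bool = True,
    het_categories: int = 4,
) -> TrainingEntry:
    """Fit the per-alignment nuisance parameters under a fixed matrix.

    Builds a starting tree if the entry has none (pairwise ML distances +
    neighbor joining), then optimizes branch lengths and, when requested,
    the +I+G parameters.  The topology is never changed.  Updates the
    entry in place and returns it; the entry log-likelihood cannot
    decrease relative to a previous fit under the same matrix.
    """
    if entry.tree is None:
        entry.tree = initial_tree(entry.alignment, model)
    if entry.het is None:
        entry.het = (
            RateHeterogeneity(alpha=1.0, v=0.1, C=het_categories)
            if optimize_het
            else RateHeterogeneity(alpha=1.0, v=0.0, C=1)
        )
    entry.tree, result = optimize_branch_lengths(entry.tree, model, entry.het, entry.alignment)
    if optimize_het:
        entry.het, result = optimize_rate_model(
            entry.tree, model, entry.het, entry.alignment
        )
        entry.tree, result = optimize_branch_lengths(
            entry.tree, model, entry.het, entry.alignment
        )
    entry.loglik = result.total
    return entry


# ---------------------------------------------------------------------------
# Matrix step: direct likelihood maximization over exchangeabilities


def _phi(lam: np.ndarray, tau: float) -> np.ndarray:
    """Divided-difference kernel of the matrix exponential's derivative:
    phi[k, l] = (exp(lam_k tau) - exp(lam_l tau)) / (lam_k - lam_l),
    with the confluent limit tau * exp(lam tau) on the diagonal."""
    x = lam * tau
    e = np.exp(x)
    diff = lam[:, None] - lam[None, :]
    close = np.abs(diff) * abs(tau) < 1e-9
    safe = np.where(close, 1.0, diff)
    phi = np.where(close, tau * np.exp((x[:, None] + x[None, :]) / 2.0), (e[:, None] - e[None, :]) / safe)
    return phi


def _grad_pull_back(G_P_by_edge, taus_by_edge, Q: RateMatrix) -> np.ndarray:
    """Pull per-edge gradients w.r.t. P(tau) back to a gradient w.r.t. Q.

    Uses P(tau) = D^-1 U exp(Lambda tau) U^T D with D = diag(sqrt pi):
    the adjoint of the exponential's derivative is elementwise
    multiplication by the divided-difference kernel in the eigenbasis.
    """
    lam, A, B = Q.eigensystem()
    d = np.sqrt(Q.frequencies)
    U = A * d[:, None]  # orthogonal factor of the symmetrized generator
    acc = np.zeros((N_STATES, N_STATES))
    for G_P, taus in zip(G_P_by_edge, taus_by_edge):
        # G_P: (C, 20, 20); taus: (C,)
        for c in range(G_P.shape[0]):
            G_X = G_P[c] * (d[None, :] / d[:, None])
            W = U.T @ G_X @ U
            acc += W * _phi(lam, taus[c])
    G_S = U @ acc @ U.T
    return G_S * (d[:, None] / d[None, :])


def _entry_loglik_and_gradQ(engine: PruningEngine) -> tuple[float, np.ndarray]:
    """Total lnL of one engine plus the gradient w.r.t. its normalized Q."""
    partials, logscale, out, outls = engine.outside()
    cat = engine._category_loglik(partials, logscale)  # (C, S)
    mix = engine._mix(cat)  # (S,)
    total = float(np.dot(engine.weights, mix))
    v, C = engine.het.v, engine.het.C
    G_P_by_edge, taus_by_edge = [], []
    for node in engine.tree.edges():
        j = engine.index[id(node)]
        with np.errstate(invalid="ignore"):
            coeff = engine.weights[None, :] * (1.0 - v) / C * np.exp(
                outls[j] + logscale[j] - mix[None, :]
            )
        coeff = np.nan_to_num(coeff, nan=0.0, posinf=0.0, neginf=0.0)
        G_P = np.einsum("cs,csi,csj->cij", coeff, out[j], partials[j])
        G_P_by_edge.append(G_P)
        taus_by_edge.append(engine.het.rho * node.length)
    G_Q = _grad_pull_back(G_P_by_edge, taus_by_edge, engine.Q)
    return total, G_Q


def _gradQ_to_grad_r(G_Q: np.ndarray, model: SubstitutionModel, mu: float) -> np.ndarray:
    """Chain a gradient w.r.t. normalized Q through q_xy = pi_y r_xy / mu."""
    pi = model.frequencies
    Qdot = build_rate_matrix(model, normalize=True).entries
    s = float(np.sum(G_Q * Qdot))
    M1 = G_Q * pi[None, :]
    dga = np.diag(G_Q)
    grad = (M1 + M1.T - np.outer(dga, pi) - np.outer(pi, dga) - 2.0 * s * np.outer(pi, pi)) / mu
    return grad[_TRIL]


def optimize_matrix(
    training: TrainingSet,
    current: SubstitutionModel,
    maxiter: int = 300,
    ftol: float = 1e-9,
) -> SubstitutionModel:
    """Re-estimate the exchangeabilities by direct likelihood maximization.

    Per-alignment trees and rate-heterogeneity parameters are held fixed
    (every entry must have been fitted).  Optimizes the 190 coefficients
    in log space with one reference pinned; frequencies are the training
    set's empirical residue proportions.  The returned model is rescaled
    to mean exchangeability 1 and never has lower target likelihood than
    the input.
    """
    for entry in training:
        if entry.tree is None or entry.het is None:
            raise ValueError(f"entry {entry.name!r} has not been fitted yet")
    pi = training.empirical_frequencies()
    r0 = np.maximum(current.lower_triangle, 1e-8)
    ref = int(np.argmax(r0))
    theta0 = np.log(r0 / r0[ref])
    free = np.ones(190, dtype=bool)
    free[ref] = False

    engines = [
        PruningEngine(e.tree, current, e.het, e.alignment) for e in training
    ]

    def unpack(theta_free: np.ndarray) -> SubstitutionModel:
        theta = np.zeros(190)
        theta[free] = theta_free
        return SubstitutionModel.from_lower_triangle("(fitting)", np.exp(theta), pi)

    def objective(theta_free: np.ndarray) -> tuple[float, np.ndarray]:
        model = unpack(theta_free)
        Q = build_rate_matrix(model, normalize=True)
        total, grad_r_acc = 0.0, np.zeros(190)
        for engine in engines:
            engine.set_rate_matrix(Q)
            lnl, G_Q = _entry_loglik_and_gradQ(engine)
            total += lnl
            grad_r_acc += _gradQ_to_grad_r(G_Q, model, Q.mu)
        grad_theta = grad_r_acc * model.lower_triangle  # log-parameterization
        return -total, -grad_theta[free]

    f0, _ = objective(theta0[free])
    res = optimize.minimize(
        objective,
        theta0[free],
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": ftol, "maxcor": 20},
    )
    if not res.success:
        log.warning("matrix optimization stopped early: %s", res.message)
    theta_best = res.x if res.fun <= f0 else theta0[free]
    fitted = unpack(theta_best)
    scale = 1.0 / fitted.lower_triangle.mean()
    return SubstitutionModel(
        name=f"{current.name}+refit",
        exchangeabilities=fitted.exchangeabilities * scale,
        frequencies=pi,
    )


def training_loglik(training: TrainingSet, model: SubstitutionModel) -> float:
    """Target-function log-likelihood of the whole set under ``model``
    with the per-entry trees and rate parameters as they stand."""
    total = 0.0
    for entry in training:
        engine = PruningEngine(entry.tree, model, entry.het, entry.alignment)
        entry.loglik = engine.loglik()
        total += entry.loglik
    return total


# ---------------------------------------------------------------------------
# The iterative estimator, statsmodels style


@dataclass
class EstimationTrace:
    """Per-iteration record of the target log-likelihood."""

    labels: list[str] = field(default_factory=list)
    loglik: list[float] = field(default_factory=list)
    models: list[SubstitutionModel] = field(default_factory=list)
    termination: str = ""

    def append(self, label: str, lnl: float, model: SubstitutionModel) -> None:
        if self.loglik and lnl < self.loglik[-1] - 1e-6:
            raise RuntimeError(
                f"target log-likelihood decreased: {self.loglik[-1]:.6f} -> {lnl:.6f}"
            )
        self.labels.append(label)
        self.loglik.append(lnl)
        self.models.append(model)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"stage": self.labels, "loglik": self.loglik})


class EmpiricalMatrixML:
    """Maximum-likelihood estimator of an empirical substitution matrix.

    Parameters
    ----------
    training : TrainingSet
        Alignments (with optional starting trees) sharing one matrix.
    initial_model : SubstitutionModel, optional
        Starting matrix; the bundled mtZoa by default (the customary
        starting point for mitochondrial data).
    optimize_het : bool
        Fit per-alignment +I+G parameters (4 gamma categories); when
        False, rates are homogeneous.
    """

    def __init__(
        self,
        training: TrainingSet,
        initial_model: SubstitutionModel | None = None,
        optimize_het: bool = True,
        het_categories: int = 4,
    ):
        if initial_model is None:
            from .matrices import load_model

            initial_model = load_model("mtZoa")
        self.training = training
        self.initial_model = initial_model
        self.optimize_het = optimize_het
        self.het_categories = het_categories

    @property
    def n_sites(self) -> int:
        return sum(e.alignment.n_sites for e in self.training)

    def fit(
        self,
        tol_per_site: float = 0.01,
        max_iter: int = 10,
        matrix_maxiter: int = 300,
    ) -> "EmpiricalMatrixResults":
        """Alternate per-alignment fits and matrix re-estimation.

        Stops when one full iteration improves the target log-likelihood
        by less than ``tol_per_site`` per alignment column, or after
        ``max_iter`` iterations.
        """
        trace = EstimationTrace()
        model = self.initial_model
        n_sites = self.n_sites
        log.info("fitting per-alignment parameters under %s", model.name)
        for entry in self.training:
            fit_alignment_params(
                entry, model, optimize_het=self.optimize_het,
                het_categories=self.het_categories,
            )
        total = training_loglik(self.training, model)
        trace.append(f"{model.name} (initial model)", total, model)
        log.info("initial target lnL = %.4f", total)

        converged = False
        for iteration in range(1, max_iter + 1):
            previous = trace.loglik[-1]
            model = optimize_matrix(self.training, model, maxiter=matrix_maxiter)
            for entry in self.training:
                fit_alignment_params(
                    entry, model, optimize_het=self.optimize_het,
                    het_categories=self.het_categories,
                )
            total = training_loglik(self.training, model)
            trace.append(f"iteration {iteration}", total, model)
            log.info("iteration %d: target lnL = %.4f", iteration, total)
            if total - previous < tol_per_site * n_sites:
                converged = True
                trace.termination = (
                    f"converged: gain {total - previous:.4f} < "
                    f"{tol_per_site:g}/site over {n_sites} sites"
                )
                break
        if not converged:
            trace.termination = f"stopped at max_iter={max_iter}"
        final = model.rescaled(1.0, name=f"{self.initial_model.name}-derived")
        return EmpiricalMatrixResults(self, final, trace, converged)


@dataclass
class EmpiricalMatrixResults:
    """Fitted matrix, its estimation trace, and reporting helpers."""

    estimator: EmpiricalMatrixML
    model: SubstitutionModel
    trace: EstimationTrace
    converged: bool

    @property
    def initial_loglik(self) -> float:
        return self.trace.loglik[0]

    @property
    def final_loglik(self) -> float:
        return self.trace.loglik[-1]

    @property
    def n_iterations(self) -> int:
        return len(self.trace.loglik) - 1

    def first_iteration_gain_fraction(self) -> float:
        """Share of the total log-likelihood gain made by iteration 1."""
        total = self.final_loglik - self.initial_loglik
        if total <= 0 or self.n_iterations < 1:
            return float("nan")
        return (self.trace.loglik[1] - self.initial_loglik) / total

    def save(self, path: str | Path) -> None:
        self.model.write(path)

    def trace_table(self) -> pd.DataFrame:
        return self.trace.as_frame()

    def summary(self) -> str:
        est = self.estimator
        lines = [
            "Empirical substitution matrix estimation",
            "=" * 56,
            f"alignments:            {len(est.training)}",
            f"total sites:           {est.n_sites}",
            f"initial model:         {est.initial_model.name}",
            f"free parameters:       208 (189 exchangeabilities + 19 frequencies)",
            f"rate heterogeneity:    "
            + (f"+I+G{est.het_categories}" if est.optimize_het else "homogeneous"),
            f"iterations:            {self.n_iterations}"
            + (" (converged)" if self.converged else " (max-iter stop)"),
            f"termination:           {self.trace.termination}",
            "",
            "target log-likelihood trace:",
        ]
        for label, lnl in zip(self.trace.labels, self.trace.loglik):
            lines.append(f"  {label:<28s} {lnl:18.4f}")
        gain = self.final_loglik - self.initial_loglik
        lines.append("")
        lines.append(f"total gain:            {gain:.4f} ({gain / est.n_sites:.4f} per site)")
        if self.n_iterations >= 1 and gain > 0:
            lines.append(
                f"first-iteration share: {100 * self.first_iteration_gain_fraction():.1f}%"
            )
        return "\n".join(lines)


def estimate_model(
    training: TrainingSet,
    initial: SubstitutionModel | None = None,
    tol_per_site: float = 0.01,
    max_iter: int = 10,
    optimize_het: bool = True,
    het_categories: int = 4,
) -> EmpiricalMatrixResults:
    """Functional front door to :class:`EmpiricalMatrixML`."""
    return EmpiricalMatrixML(
        training, initial_model=initial, optimize_het=optimize_het,
        het_categories=het_categories,
    ).fit(tol_per_site=tol_per_site, max_iter=max_iter)
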