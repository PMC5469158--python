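"""Reversible amino-acid substitution models and their rate matrices.

A model is the pair (r, pi): a symmetric matrix of exchangeability
coefficients r[x, y] and a vector of equilibrium frequencies pi.  The
instantaneous generator of the general time-reversible Markov process is

    q[x, y] = pi[y] * r[x, y]   (x != y),
    q[x, x] = -sum_{y != x} q[x, y],

optionally rescaled by the expected substitution rate
mu = sum_x pi[x] * (-q[x, x]) so that one time unit corresponds to one
expected substitution per site.  Transition probabilities P(t) = expm(Q t)
are computed through the symmetric eigendecomposition of
Pi^(1/2) Q Pi^(-1/2), which is exact for reversible generators.

Model files use the PAML ``.dat`` layout: 19 lower-triangular rows of
exchangeabilities followed by the 20 frequencies, residues in the order
A R N D C Q E G H I L K M F P S T W Y V.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .alphabet import N_STATES, RESIDUES

__all__ = [
    "SubstitutionModel",
    "RateMatrix",
    "ModelFormatError",
    "DegenerateModelError",
    "read_model",
    "write_model",
    "build_rate_matrix",
    "transition_probabilities",
    "model_correlation",
    "exchangeability_ratios",
    "gtr_free_parameters",
    "uniform_model",
]

_TRIL = np.tril_indices(N_STATES, k=-1)


class ModelFormatError(ValueError):
    """Malformed PAML .dat model file."""


class DegenerateModelError(ValueError):
    """Model cannot yield a usable rate matrix (e.g. all rates zero)."""


@dataclass
class SubstitutionModel:
    """Named exchangeability matrix plus equilibrium frequency vector.

    Parameters
    ----------
    name : str
        Model label (e.g. ``"WAG"``).
    exchangeabilities : (20, 20) ndarray
        Symmetric, non-negative, zero diagonal.  The overall scale is not
        identifiable; published models use arbitrary conventions.
    frequencies : (20,) ndarray
        Non-negative, summing to 1.
    """

    name: str
    exchangeabilities: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if r.shape != (N_STATES, N_STATES):
            raise ValueError(f"exchangeabilities must be 20x20, got {r.shape}")
        if pi.shape != (N_STATES,):
            raise ValueError(f"frequencies must have length 20, got {pi.shape}")
        if not np.allclose(r, r.T):
            raise ValueError("exchangeabilities must be symmetric")
        if np.any(np.diag(r) != 0.0):
            r = r.copy()
            np.fill_diagonal(r, 0.0)
        if np.any(r < 0):
            raise ValueError("exchangeabilities must be non-negative")
        if np.any(pi < 0):
            raise ValueError("frequencies must be non-negative")
        if abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError(f"frequencies sum to {pi.sum():.10g}, not 1")
        self.exchangeabilities = r
        self.frequencies = pi

    @property
    def lower_triangle(self) -> np.ndarray:
        """The 190 exchangeabilities below the diagonal, row by row."""
        return self.exchangeabilities[_TRIL]

    def rate_matrix(self, normalize: bool = True, weighted_mu: bool = True) -> "RateMatrix":
        return build_rate_matrix(self, normalize=normalize, weighted_mu=weighted_mu)

    def rescaled(self, factor: float, name: str | None = None) -> "SubstitutionModel":
        """Return a copy with all exchangeabilities multiplied by ``factor``."""
        if factor <= 0:
            raise ValueError("rescaling factor must be positive")
        return SubstitutionModel(
            name=name or self.name,
            exchangeabilities=self.exchangeabilities * factor,
            frequencies=self.frequencies,
        )

    @classmethod
    def from_lower_triangle(
        cls, name: str, lower: np.ndarray, frequencies: np.ndarray
    ) -> "SubstitutionModel":
        lower = np.asarray(lower, dtype=float)
        if lower.shape != (190,):
            raise ValueError(f"expected 190 coefficients, got {lower.shape}")
        r = np.zeros((N_STATES, N_STATES))
        r[_TRIL] = lower
        r = r + r.T
        return cls(name=name, exchangeabilities=r, frequencies=np.asarray(frequencies, float))

    @classmethod
    def read(cls, path: str | Path, name: str | None = None) -> "SubstitutionModel":
        return read_model(path, name=name)

    def write(self, path: str | Path) -> None:
        write_model(self, path)


@dataclass
class RateMatrix:
    """Instantaneous generator Q of a reversible substitution process."""

    entries: np.ndarray
    frequencies: np.ndarray
    mu: float
    normalized: bool
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def expected_rate(self) -> float:
        """sum_x pi[x] * (-q[x, x]); 1 for a normalized generator."""
        return float(-np.dot(self.frequencies, np.diag(self.entries)))

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Spectral factors (lam, A, B) with Q = A diag(lam) B.

        Uses the similarity S = Pi^(1/2) Q Pi^(-1/2), which is symmetric
        for a reversible generator, so ``numpy.linalg.eigh`` applies and
        P(t) = A diag(exp(lam t)) B with A = Pi^(-1/2) U, B = U^T Pi^(1/2).
        """
        if self._eig is None:
            pi = self.frequencies
            if np.any(pi <= 0):
                raise DegenerateModelError("zero equilibrium frequency; generator not irreducible")
            d = np.sqrt(pi)
            S = self.entries * (d[:, None] / d[None, :])
            S = 0.5 * (S + S.T)  # enforce exact symmetry
            lam, U = np.linalg.eigh(S)
            A = U / d[:, None]
            B = U.T * d[None, :]
            recon = (A * lam) @ B
            if not np.allclose(recon, self.entries, atol=1e-12 * max(1.0, np.abs(self.entries).max())):
                raise DegenerateModelError("eigendecomposition failed to reconstruct Q")
            self._eig = (lam, A, B)
        return self._eig

    def transition_probabilities(self, t: float) -> np.ndarray:
        return transition_probabilities(self, t)


def build_rate_matrix(
    model: SubstitutionModel, normalize: bool = True, weighted_mu: bool = True
) -> RateMatrix:
    """Construct Q from a model; optionally rescale to one substitution per time unit.

    ``weighted_mu=True`` divides by the expected rate
    mu = sum_x pi[x] * (-q[x, x]), which makes branch lengths read as
    expected substitutions per site.  ``weighted_mu=False`` divides by the
    unweighted trace -sum_x q[x, x] instead; it changes only the time
    scale, never likelihoods at re-optimized branch lengths.
    """
    pi = model.frequencies
    q = model.exchangeabilities * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = float(-np.dot(pi, np.diag(q)) if weighted_mu else -np.trace(q))
    if mu <= 0.0:
        raise DegenerateModelError(f"model {model.name!r} has zero total rate (mu={mu})")
    if normalize:
        q = q / mu
    return RateMatrix(entries=q, frequencies=pi, mu=mu, normalized=normalize)


def transition_probabilities(Q: RateMatrix, t: float) -> np.ndarray:
    """P(t) = expm(Q t) via the symmetric eigendecomposition.

    Rows sum to 1; small negative round-off entries are clipped to 0.
    """
    if t < 0:
        raise ValueError(f"branch length must be non-negative, got {t}")
    lam, A, B = Q.eigensystem()
    P = (A * np.exp(lam * t)) @ B
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


# ---------------------------------------------------------------------------
# PAML .dat input / output


def read_model(path: str | Path, name: str | None = None) -> SubstitutionModel:
    """Read a PAML ``.dat`` substitution-model file.

    Accepts the canonical layout (19 lower-triangular exchangeability rows,
    then 20 frequencies) with arbitrary blank lines and ``#``/``//``
    comment lines interleaved.  Frequencies are renormalized to sum to 1
    when within 1e-4 of it; larger deviations are format errors.
    """
    path = Path(path)
    tokens: list[tuple[float, int]] = []  # (value, line number)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].split("//", 1)[0].strip()
            if not text:
                continue
            for tok in text.split():
                try:
                    val = float(tok)
                except ValueError:
                    # trailing annotation (e.g. residue labels) ends the numeric block
                    if len(tokens) >= 210:
                        break
                    raise ModelFormatError(
                        f"{path.name}:{lineno}: non-numeric token {tok!r}"
                    ) from None
                tokens.append((val, lineno))
    if len(tokens) < 210:
        raise ModelFormatError(
            f"{path.name}: expected 190 exchangeabilities + 20 frequencies, found {len(tokens)} numbers"
        )
    values = np.array([v for v, _ in tokens[:210]])
    lower, freqs = values[:190], values[190:210]
    bad = np.nonzero(lower < 0)[0]
    if bad.size:
        lineno = tokens[int(bad[0])][1]
        raise ModelFormatError(f"{path.name}:{lineno}: negative exchangeability {lower[bad[0]]}")
    if np.any(freqs < 0):
        idx = 190 + int(np.nonzero(freqs < 0)[0][0])
        raise ModelFormatError(f"{path.name}:{tokens[idx][1]}: negative frequency")
    total = freqs.sum()
    if abs(total - 1.0) > 1e-4:
        raise ModelFormatError(
            f"{path.name}:{tokens[190][1]}: frequencies sum to {total:.6g}, not 1"
        )
    freqs = freqs / total
    return SubstitutionModel.from_lower_triangle(name or path.stem, lower, freqs)


def write_model(model: SubstitutionModel, path: str | Path) -> None:
    """Write the canonical PAML ``.dat`` layout at 12 significant digits."""
    path = Path(path)
    buf = io.StringIO()
    r = model.exchangeabilities
    for i in range(1, N_STATES):
        buf.write(" ".join(f"{r[i, j]:.12g}" for j in range(i)))
        buf.write("\n")
    buf.write("\n")
    buf.write(" ".join(f"{f:.12g}" for f in model.frequencies))
    buf.write("\n\n")
    buf.write("# " + " ".join(RESIDUES) + "\n")
    path.write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Model-to-model comparison


def model_correlation(
    a: SubstitutionModel, b: SubstitutionModel, component: str = "exchangeabilities"
) -> float:
    """Pearson correlation between two models' exchangeabilities or frequencies.

    Exchangeabilities are compared over the 190 lower-triangular
    coefficients after rescaling each model to mean coefficient 1 (a no-op
    for Pearson, applied for reproducibility of intermediate values);
    frequencies over the 20-vectors.
    """
    if component == "exchangeabilities":
        va, vb = a.lower_triangle, b.lower_triangle
        va = va / va.mean()
        vb = vb / vb.mean()
    elif component == "frequencies":
        va, vb = a.frequencies, b.frequencies
    else:
        raise ValueError(f"component must be 'exchangeabilities' or 'frequencies', got {component!r}")
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(va, vb).statistic)


def exchangeability_ratios(
    a: SubstitutionModel, b: SubstitutionModel, cap: float = 10.0
):
    """Element-wise ratio r_a / r_b over amino-acid pairs, capped for display.

    Each model is first rescaled to mean exchangeability 1 so that the
    ratios compare substitution patterns rather than the models' arbitrary
    publication scales.  Returns ``(ratios, capped, zero_denominator)``:
    a 20x20 ratio table (diagonal NaN) and two boolean flag tables.
    Ratios above ``cap`` are reported as ``cap`` with the flag set; zero
    denominators yield ``inf`` (or NaN for 0/0) with their flag set.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    ra = a.exchangeabilities / a.lower_triangle.mean()
    rb = b.exchangeabilities / b.lower_triangle.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = ra / rb
    zero_den = (rb == 0)
    np.fill_diagonal(ratios, np.nan)
    np.fill_diagonal(zero_den, False)
    capped = np.zeros_like(zero_den)
    over = np.isfinite(ratios) & (ratios > cap)
    capped |= over
    capped |= zero_den & (ra > 0)
    ratios = np.where(over, cap, ratios)
    return ratios, capped, zero_den


def gtr_free_parameters(n_states: int = N_STATES) -> int:
    """Free parameters of a general time-reversible model on ``n_states``.

    n(n-1)/2 exchangeabilities minus one for the arbitrary overall scale,
    plus n-1 free frequencies: 208 for amino acids (n=20), 8 for
    nucleotides (n=4).
    """
    if n_states < 2:
        raise ValueError("need at least two states")
    return (n_states * (n_states - 1)) // 2 - 1 + (n_states - 1)


def uniform_model(name: str = "uniform") -> SubstitutionModel:
    """All exchangeabilities 1, frequencies 1/20 (a Jukes-Cantor-like model)."""
    r = np.ones((N_STATES, N_STATES))
    np.fill_diagonal(r, 0.0)
    return SubstitutionModel(name=name, exchangeabilities=r, frequencies=np.full(N_STATES, 1 / N_STATES))
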