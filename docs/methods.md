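# Methods notes

This note records the modelling conventions, numerical choices and design
decisions behind `mtsubst`, and what the simulation-based tests do and do
not establish.

## The substitution model

We assume a stationary, time-reversible Markov process on the 20 amino
acids, identical and independent across sites (apart from the site-rate
mixture below), with generator `q_xy = π_y r_xy` for `x ≠ y` and diagonal
entries making rows sum to zero. `r` is symmetric and non-negative; its
overall scale is not identifiable and bundled/published matrices use
arbitrary conventions, so every comparison in the package either rescales
to mean coefficient 1 or is scale-invariant by construction.

**Normalization.** The generator is rescaled so that one time unit equals
one expected substitution per site, dividing by the *frequency-weighted*
expected rate μ = −Σ_x π_x q_xx. An unweighted variant (dividing by the
raw trace −Σ_x q_xx) is exposed via `build_rate_matrix(...,
weighted_mu=False)`; the two differ only in the time scale. Only the
weighted form makes branch lengths read as expected substitutions per
site, which is why it is the default. Likelihoods at re-optimized branch
lengths are identical under either convention (tested).

**Transition probabilities.** For a reversible generator,
`Π^{1/2} Q Π^{−1/2}` is symmetric, so `P(t) = e^{Qt}` is computed exactly
through `numpy.linalg.eigh`; the factorization is validated by
reconstructing Q to 1e-12 (relative) and rejected otherwise. Round-off
negatives are clipped and rows renormalized; agreement with
scaling-and-squaring (`scipy.linalg.expm`) is tested to 1e-9.

## Site-rate heterogeneity (+I+G)

The per-site likelihood is the standard mixture

    L_i = v·L(invariant; D_i) + (1−v)·(1/C)·Σ_c L(ρ_c T, Q; D_i),

with the invariant component equal to the equilibrium probability of the
residue the column is constant in (0 if the column cannot be constant;
ambiguity codes count as compatible sets, so an all-gap column contributes
exactly zero log-likelihood). Some presentations place the product over
sites inside each mixture component; that form would make whole
*alignments* entirely invariant or entirely gamma-distributed, which is
not the model any mainstream likelihood program computes. We implement
the per-site mixture and treat the product-outside presentation as a
typographical variant.

Gamma discretization uses C equal-probability bins of a mean-1 gamma
(shape α, scale 1/α) with **conditional-mean** category rates, computed
from the incremented-shape CDF identity; category means are renormalized
to average exactly 1 (absolute deviation < 1e-10). C defaults to 4. The
conditional means approach 1 only at rate ~1.27/√α, so "effectively
homogeneous" requires very large α (the degenerate-limit test uses 1e8).

## Likelihood engine

Felsenstein pruning over unique site patterns (pattern compression is
exact, not approximate, and is tested against uncompressed evaluation).
Partial-likelihood vectors are rescaled per node and per
(category, pattern) with log-scale accumulators, so deep trees and long
alignments never underflow. Multifurcations are supported (needed after
zero-length-branch collapse). Trees are unrooted; the likelihood is
invariant to the internal vertex chosen as the traversal root (tested by
re-rooting).

**Branch lengths** are optimized coordinate-wise with bounded Brent
searches on [1e-8, 20] substitutions/site; each edge is optimized against
freshly recomputed inside/outside vectors, which makes every accepted
update a guaranteed improvement; sweeps stop when a full round gains
< 1e-4 log-units. **(α, v)** are optimized jointly by L-BFGS-B with α on a
log scale in [0.02, 100] and v in [0, 0.99], never returning a fit worse
than the starting point.

## Matrix estimation

Given alignments with fitted per-alignment trees and rate parameters, the
190 exchangeabilities are re-estimated by direct maximization of the joint
log-likelihood:

- **Parameterization:** log-exchangeabilities, with the largest starting
  coefficient pinned (the scale is absorbed by generator normalization;
  pinning one reference removes the flat direction). The returned matrix
  is rescaled to mean coefficient 1.
- **Gradient:** analytic. Per edge and gamma category, the derivative of
  the log-likelihood with respect to P(tρ_c) is an outer product of
  outside and inside vectors summed over patterns; it is pulled back
  through the matrix exponential using the eigendecomposition form of the
  Fréchet-derivative adjoint (elementwise multiplication by the divided-
  difference kernel in the eigenbasis, with the confluent limit handled
  explicitly), then chained through `q_xy = π_y r_xy` and the μ
  normalization. The gradient is verified against central finite
  differences in the test suite (relative agreement ~1e-6).
- **Optimizer:** L-BFGS-B; if the optimizer ever fails to improve, the
  incoming matrix is returned, preserving monotonicity of the outer loop.
- **Frequencies:** empirical residue proportions over the training
  alignments (the standard convention for empirical matrices), floored at
  1e-6 and renormalized so the generator stays irreducible. ML frequency
  estimation is deliberately out of scope.
- **Outer loop:** alternate per-alignment fits and the matrix step until
  the gain drops below 0.01 log-units per alignment column (default) or
  `max_iter` = 10. Tree *topologies* are fixed after the initial
  neighbor-joining construction; refitting branch lengths and (α, v) each
  iteration is the self-contained stand-in for re-estimating trees with an
  external tree-search program, which this package intentionally does not
  do. With informative data the first iteration contributes nearly all of
  the gain and the loop converges in two to three iterations.

Starting trees come from neighbor joining (scikit-bio) on pairwise ML
distances, each distance a bounded one-dimensional maximization of the
two-taxon likelihood in the eigenbasis; negative NJ branch estimates are
clamped to 1e-6.

## Topology diagnostics

Bipartitions are stored canonically as the side not containing the
lexicographically smallest leaf. RF distance counts nontrivial
bipartitions unique to either tree (trivial splits are always shared).
Normalized RF divides by 2n−3. For two binary trees inferred from the
same data at RF distance d, the union of their splits exceeds the true
tree's 2n−3 splits by d/2, so at least d/2 of them are wrong, and the
worse-likelihood tree must carry at least half of those: the reported
lower bound is d/4 (with its integer ceiling). Both the bound and the
union count are verified exhaustively over all five-taxon topology pairs
and all candidate true trees.

**Branch filtering** removes zero-length branches (internal ones collapse
into polytomies, terminal ones drop the leaf) and *cuts* at branches of
length ≥ 2, yielding independent subtrees. Cutting — rather than merely
ignoring long branches — is the reading consistent with the purpose of
the preprocessing: a branch long enough to be noise carries no usable
signal between the two sides, so the sides become separate training
units. **Alignment splitting** recursively cuts the guide tree at its
most balanced edge until every part has ≤ `max_size` (default 128)
leaves; ties break on the lexicographically smallest canonical
bipartition key, making the split deterministic.

## Simulator

Sites draw an invariant flag (probability v) or a gamma category, the
root residue comes from π, and states evolve down the tree with
`P(ρ_c t)` per branch. Random topologies use sequential uniform edge
bisection (uniform over labeled topologies); branch lengths are i.i.d.
exponential (mean 0.15 by default) truncated to (0, 2) — the same window
within which training branches are considered informative. All
randomness flows from one integer seed; identical seeds give
byte-identical files.

The simulator intentionally omits several features of real mitochondrial
data: no indels (gaps appear only if present in input data), no
compositional non-stationarity, no site-specific structural constraints,
no codon-level effects of the different mitochondrial genetic codes.
Passing recovery tests therefore demonstrates correctness of the
estimation machinery under the model's own assumptions — not robustness
to their violation.

## Information criteria

`information_criteria` computes AIC = 2k − 2lnL and BIC = k·ln(n) − 2lnL
with the parameter count k supplied explicitly, because conventions
differ on whether branch lengths, rate parameters, and the (fixed,
empirical) matrix should count. The comparison workflow uses
k = (number of branch lengths) + 2 when +I+G is fitted; any other
convention can be recomputed from the reported log-likelihoods.

## Problem sizes used in tests and the acceptance script

Exact and closed-form checks run on 2–6 taxa. The matrix-recovery
experiment uses eight alignments of 16 taxa × 500 sites (4000 columns
total) simulated under WAG with homogeneous rates, estimation started
from a uniform matrix; homogeneous rates are used there to isolate
exchangeability estimation from rate-mixture estimation, which is
exercised separately (α and v recovery on 16 taxa × 5000 sites). At this
scale the recovered exchangeabilities correlate with the generating
matrix at ≈ 0.99, and the first iteration contributes ≈ 99.9% of the
log-likelihood gain.

## Known limitations

- No tree-topology search, bootstrap, or topology-test internals (only
  the CONSEL input matrix is produced).
- Frequencies are count-based, not ML-estimated.
- The expected-count (counting-based) shortcut for the matrix step is not
  implemented; the matrix step is direct likelihood maximization, which
  is exact for the target but slower on very large training sets.
- Protein models only; no codon or nucleotide models.
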