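# mtsubst

A Python toolkit for **empirical amino-acid substitution models**, aimed at
phylogenetics with mitochondrially encoded proteins. It covers the full life
cycle of such models:

- reading/writing substitution models in the PAML `.dat` layout, and bundled
  copies of the published LG, WAG, mtREV24, mtArt and mtZoa matrices;
- building and normalizing reversible rate matrices and computing transition
  probabilities `P(t) = e^{Qt}` exactly via the symmetric eigendecomposition;
- Felsenstein pruning log-likelihoods with invariant sites and discrete-gamma
  rate heterogeneity (+I+G), branch-length and rate-parameter optimization,
  AIC/BIC, and CONSEL-compatible site-likelihood export;
- **estimating new 20×20 matrices** by iterative joint maximum likelihood
  over collections of alignments (the Le–Gascuel / FastMG scheme);
- comparing models across alignment sets, and quantifying tree-topology
  disagreement with Robinson–Foulds distances and a lower bound on the
  number of incorrect bipartitions;
- simulating alignments and training sets under known parameters, and
  tree-guided splitting of large alignments into tractable pieces.

## The model

A substitution model is a pair (r, π): symmetric exchangeability
coefficients `r_xy` and equilibrium frequencies `π_x` over the 20 amino
acids. The general time-reversible generator is

    q_xy = π_y · r_xy   (x ≠ y),     q_xx = −Σ_{y≠x} q_xy ,

normalized by the expected rate μ = −Σ_x π_x q_xx so that one time unit is
one expected substitution per site. Such a model has 208 free parameters
(189 free exchangeabilities + 19 free frequencies; the nucleotide analogue
has 8). Site rates follow the +I+G mixture: a site is invariant with
probability v, otherwise its rate is one of C discrete gamma categories
(shape α, category means averaging 1).

Given alignments **D** = {Dⁱ}, each with its own tree Tⁱ and rate
parameters (αⁱ, vⁱ), a matrix is estimated by maximizing

    LK(Q; D) = Π_i LK(Tⁱ, Q, αⁱ, vⁱ; Dⁱ)

by block coordinate ascent: fit the per-alignment nuisance parameters under
the current Q, re-estimate the 190 exchangeabilities by direct gradient-based
likelihood maximization, repeat until the gain per site is insignificant.
Both half-steps are conditional maximizations, so the target log-likelihood
never decreases.

## Worked example

Simulate a small training set under WAG, then re-estimate the matrix
starting from an uninformative uniform model:

```python
from mtsubst import (load_model, uniform_model, model_correlation,
                     TrainingSet, estimate_model, simulate_training_set)

wag = load_model("WAG")
simulate_training_set(4, wag, "demo_train", seed=42, n_taxa=12, n_sites=400,
                      alpha_range=(1.0, 1.0), v=0.0, C=1)
training = TrainingSet.from_directory("demo_train")
fit = estimate_model(training, initial=uniform_model(), optimize_het=False)
print(fit.summary())
print("correlation with generating matrix (WAG):",
      round(model_correlation(fit.model, wag), 3))
```

which prints

```
Empirical substitution matrix estimation
========================================================
alignments:            4
total sites:           1600
initial model:         uniform
free parameters:       208 (189 exchangeabilities + 19 frequencies)
rate heterogeneity:    homogeneous
iterations:            2 (converged)
termination:           converged: gain 0.2844 < 0.01/site over 1600 sites

target log-likelihood trace:
  uniform (initial model)             -25929.5386
  iteration 1                         -23656.5743
  iteration 2                         -23656.2899

total gain:            2273.2487 (1.4208 per site)
first-iteration share: 100.0%

correlation with generating matrix (WAG): 0.955
```

The trace is monotone, essentially all of the gain comes from the first
iteration, and even 1600 simulated columns pin down the exchangeability
pattern to a 0.955 correlation with the generating matrix.
`fit.save("new_model.dat")` writes the result in PAML layout, usable in any
standard phylogenetics program.

The same machinery is available from the shell. Topology diagnostics, for
the classic five-taxon example (two trees at RF distance 4 and a reference
true tree):

```
$ mtsubst rfdist --trees trees.nwk --truth truth.nwk
.       T1      T2
T1      0       4
T2      4       0

pair    rf      lemma_bound     bound_ceil      incorrect_in_union
T1-T2   4       1       1       2
```

Two trees at RF distance 4 jointly carry 2 bipartitions absent from the
true tree, and the worse of the two must contain at least 1 (a quarter of
the RF distance). Other subcommands: `estimate`, `compare`, `loglik`,
`simulate`, `split` (see `mtsubst <cmd> --help`).

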