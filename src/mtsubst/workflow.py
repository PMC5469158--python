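"""Model-comparison pipeline: fit each candidate matrix to each alignment.

For every (alignment, model) pair the exchangeabilities and frequencies
are held fixed while a starting tree is built (pairwise ML distances +
neighbor joining), branch lengths are optimized, and the +I+G parameters
are fitted.  The report collects log-likelihoods, per-site information
criteria and the best-fit model per alignment, plus the per-site
log-likelihood rows needed to drive CONSEL-style topology tests.

The parameter count used for AIC/BIC covers what is actually optimized
per alignment: the branch lengths plus, with rate heterogeneity, the
gamma shape and invariant proportion.  The matrix itself is an empirical
constant and contributes no parameters; alternative conventions can be
applied by recomputing the criteria from the reported log-likelihoods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .align import Alignment
from .estimate import initial_tree
from .likelihood import (
    LikelihoodResult,
    RateHeterogeneity,
    export_site_lnl,
    information_criteria,
    optimize_branch_lengths,
    optimize_rate_model,
)
from .models import SubstitutionModel

log = logging.getLogger(__name__)

__all__ = ["ComparisonReport", "compare_models"]


@dataclass
class ComparisonReport:
    """Tidy per-(alignment, model) fit table plus derived summaries."""

    table: pd.DataFrame
    site_loglik: dict[str, dict[str, LikelihoodResult]]

    def best_fit(self) -> pd.Series:
        """Best model per alignment (row-maximum lnL; ties to the
        lexicographically first model name)."""
        def pick(group: pd.DataFrame) -> str:
            best = group[group["loglik"] == group["loglik"].max()]
            return sorted(best["model"])[0]

        return self.table.groupby("alignment", sort=True).apply(pick, include_groups=False)

    def mean_loglik_difference(self) -> pd.DataFrame:
        """Mean per-site lnL difference (row model minus column model)."""
        wide = self.table.pivot(index="alignment", columns="model", values="loglik_per_site")
        models = list(wide.columns)
        out = pd.DataFrame(0.0, index=models, columns=models)
        for a in models:
            for b in models:
                out.loc[a, b] = float((wide[a] - wide[b]).mean())
        return out

    def export_site_lnl(self, alignment_name: str, path) -> None:
        """Write the CONSEL site-likelihood matrix for one alignment,
        rows in sorted model-name order."""
        results = self.site_loglik[alignment_name]
        export_site_lnl([results[m] for m in sorted(results)], path)

    def summary(self) -> str:
        best = self.best_fit()
        lines = [
            "Model comparison",
            "=" * 48,
            f"alignments: {best.size}   models: {self.table['model'].nunique()}",
            "",
            "best-fit model per alignment:",
        ]
        for name, model in best.items():
            lines.append(f"  {name:<24s} {model}")
        lines.append("")
        lines.append("mean per-site lnL difference (row - column):")
        lines.append(self.mean_loglik_difference().round(4).to_string())
        return "\n".join(lines)


def compare_models(
    alignments: dict[str, Alignment] | list[Alignment],
    models: list[SubstitutionModel],
    optimize_het: bool = True,
    het_categories: int = 4,
) -> ComparisonReport:
    """Fit every model to every alignment with the matrix held fixed."""
    if len(models) < 1:
        raise ValueError("need at least one model")
    names = {m.name for m in models}
    if len(names) != len(models):
        raise ValueError("model names must be unique")
    if isinstance(alignments, list):
        alignments = {f"aln{i:03d}": a for i, a in enumerate(alignments)}

    rows = []
    site_loglik: dict[str, dict[str, LikelihoodResult]] = {}
    for aln_name, aln in alignments.items():
        site_loglik[aln_name] = {}
        for model in models:
            log.info("fitting %s to %s", model.name, aln_name)
            tree = initial_tree(aln, model)
            het = (
                RateHeterogeneity(alpha=1.0, v=0.1, C=het_categories)
                if optimize_het
                else RateHeterogeneity(alpha=1.0, v=0.0, C=1)
            )
            tree, result = optimize_branch_lengths(tree, model, het, aln)
            if optimize_het:
                het, result = optimize_rate_model(tree, model, het, aln)
                tree, result = optimize_branch_lengths(tree, model, het, aln)
            k = len(tree.edges()) + (2 if optimize_het else 0)
            ic = information_criteria(result.total, k, aln.n_sites)
            rows.append(
                {
                    "alignment": aln_name,
                    "model": model.name,
                    "loglik": result.total,
                    "loglik_per_site": result.total / aln.n_sites,
                    "aic_per_site": ic.aic_per_site,
                    "bic_per_site": ic.bic_per_site,
                    "alpha": het.alpha if optimize_het else np.nan,
                    "v": het.v if optimize_het else np.nan,
                    "k": k,
                    "n_sites": aln.n_sites,
                }
            )
            site_loglik[aln_name][model.name] = result
    table = pd.DataFrame(rows).sort_values(["alignment", "model"]).reset_index(drop=True)
    return ComparisonReport(table=table, site_loglik=site_loglik)
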