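"""Pruning likelihoods, rate heterogeneity, optimizers, criteria, export."""

import itertools

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import gamma as gamma_dist

from mtsubst import (
    Alignment,
    RateHeterogeneity,
    SimulationSpec,
    alignment_loglik,
    build_rate_matrix,
    discretize_gamma,
    information_criteria,
    parse_newick,
    random_tree,
    simulate_alignment,
)
from mtsubst.alphabet import INDEX, RESIDUES
from mtsubst.likelihood import (
    export_site_lnl,
    optimize_branch_lengths,
    optimize_rate_model,
    read_site_lnl,
    site_likelihood,
)


class TestDiscreteGamma:
    @pytest.mark.parametrize("alpha", [0.1, 0.5, 1.0, 3.7, 50.0])
    def test_category_rates_average_one(self, alpha):
        rho = discretize_gamma(alpha, 4)
        assert rho.mean() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(rho) > 0)

    def test_alpha_one_matches_integration_oracle(self):
        # direct numerical integration of x * pdf over each quartile bin
        alpha = 1.0
        edges = gamma_dist.ppf([0, 0.25, 0.5, 0.75, 1 - 1e-12], alpha, scale=1 / alpha)
        oracle = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            val, _ = integrate.quad(
                lambda x: x * gamma_dist.pdf(x, alpha, scale=1 / alpha), lo, hi
            )
            oracle.append(4 * val)
        rho = discretize_gamma(1.0, 4)
        assert np.allclose(rho, oracle, atol=1e-6)
        assert np.allclose(rho, [0.1369, 0.4768, 1.0000, 2.3863], atol=2e-4)

    def test_degenerate_high_alpha(self):
        # category means approach 1 at rate ~ alpha^(-1/2)
        assert np.allclose(discretize_gamma(1e6, 4), 1.0, atol=2e-3)
        assert np.allclose(discretize_gamma(1e8, 4), 1.0, atol=2e-4)

    def test_invalid_shape(self):
        with pytest.raises(ValueError):
            discretize_gamma(0.0, 4)


class TestSiteLikelihood:
    def test_single_leaf_is_equilibrium_frequency(self, wag):
        Q = build_rate_matrix(wag)
        tree = parse_newick("(a:0.0,b:0.0);")  # placeholder; single leaf below
        for aa in "AW":
            single = parse_newick(f"({aa.lower()}x);")
            assert site_likelihood(single, Q, {f"{aa.lower()}x": aa}) == pytest.approx(
                wag.frequencies[INDEX[aa]]
            )

    def test_two_leaf_closed_form(self, wag):
        Q = build_rate_matrix(wag)
        t1, t2 = 0.2, 0.35
        tree = parse_newick(f"(a:{t1},b:{t2});")
        P = Q.transition_probabilities(t1 + t2)
        for x, y in [("A", "R"), ("W", "W"), ("C", "V")]:
            expected = wag.frequencies[INDEX[x]] * P[INDEX[x], INDEX[y]]
            assert site_likelihood(tree, Q, {"a": x, "b": y}) == pytest.approx(
                expected, rel=1e-12
            )

    def test_four_taxon_exhaustive_state_oracle(self, random_model):
        Q = build_rate_matrix(random_model)
        tree = parse_newick("((a:0.1,b:0.25):0.15,c:0.3,d:0.12);")
        P = {t: Q.transition_probabilities(t) for t in [0.1, 0.25, 0.15, 0.3, 0.12]}
        pi = random_model.frequencies
        site = {"a": "A", "b": "R", "c": "N", "d": "D"}
        ia, ib, ic, id_ = (INDEX[site[k]] for k in "abcd")
        oracle = sum(
            pi[r] * P[0.15][r, u] * P[0.1][u, ia] * P[0.25][u, ib] * P[0.3][r, ic] * P[0.12][r, id_]
            for r in range(20)
            for u in range(20)
        )
        assert site_likelihood(tree, Q, site) == pytest.approx(oracle, abs=1e-12)

    def test_ambiguity_code_sums_component_likelihoods(self, wag):
        Q = build_rate_matrix(wag)
        tree = parse_newick("(a:0.2,b:0.3);")
        b_sum = site_likelihood(tree, Q, {"a": "A", "b": "N"}) + site_likelihood(
            tree, Q, {"a": "A", "b": "D"}
        )
        assert site_likelihood(tree, Q, {"a": "A", "b": "B"}) == pytest.approx(b_sum)


class TestAlignmentLoglik:
    def test_mixture_collapses_without_heterogeneity(self, wag, small_alignment):
        tree, _, aln = small_alignment
        het = RateHeterogeneity(alpha=1.0, v=0.0, C=1)
        res = alignment_loglik(tree, wag, het, aln)
        Q = build_rate_matrix(wag)
        cols, _, _ = aln.patterns()
        by_hand = 0.0
        for i in range(aln.n_sites):
            site = {n: aln.rows[j][i] for j, n in enumerate(aln.names)}
            by_hand += np.log(site_likelihood(tree, Q, site))
        assert res.total == pytest.approx(by_hand, abs=1e-8)

    def test_five_taxon_mixture_against_exhaustive_oracle(self, random_model):
        # +I+G likelihood vs. a brute-force sum over all internal states
        rng = np.random.default_rng(13)
        tree = parse_newick("((a:0.1,b:0.3):0.2,(c:0.15,d:0.25):0.1,e:0.4);")
        het = RateHeterogeneity(alpha=0.7, v=0.15, C=4)
        aln = simulate_alignment(
            SimulationSpec(tree=tree, model=random_model, het=het, n_sites=40, seed=29)
        )
        res = alignment_loglik(tree, random_model, het, aln)
        Q = build_rate_matrix(random_model)
        pi = random_model.frequencies
        total = 0.0
        for i in range(aln.n_sites):
            obs = {n: INDEX[aln.rows[j][i]] for j, n in enumerate(aln.names)}
            mix = 0.0
            if len({v for v in obs.values()}) == 1:
                mix += het.v * pi[next(iter(obs.values()))]
            for rho in het.rho:
                P = {}
                for t in [0.1, 0.3, 0.2, 0.15, 0.25, 0.4]:
                    P[t] = Q.transition_probabilities(rho * t)
                like = sum(
                    pi[r]
                    * P[0.2][r, u]
                    * P[0.1][u, obs["a"]]
                    * P[0.3][u, obs["b"]]
                    * P[0.1][r, w]
                    * P[0.15][w, obs["c"]]
                    * P[0.25][w, obs["d"]]
                    * P[0.4][r, obs["e"]]
                    for r in range(20)
                    for u in range(20)
                    for w in range(20)
                )
                mix += (1 - het.v) * like / het.C
            total += np.log(mix)
        assert res.total == pytest.approx(total, abs=1e-8)

    def test_single_sequence_frequencies_only(self, wag):
        row = "ARNDW"
        expected = sum(np.log(wag.frequencies[INDEX[c]]) for c in row)
        # via the 2-leaf tree with a zero-length twin carrying full ambiguity
        tree = parse_newick("(a:0.0,b:0.0);")
        aln = Alignment(["a", "b"], [row, "-" * len(row)])
        het = RateHeterogeneity(alpha=1.0, v=0.0, C=1)
        res = alignment_loglik(tree, wag, het, aln)
        assert res.total == pytest.approx(expected, rel=1e-10)

    def test_per_site_values_sum_to_total(self, wag, small_alignment):
        tree, het, aln = small_alignment
        res = alignment_loglik(tree, wag, het, aln)
        assert len(res.site_loglik) == aln.n_sites
        assert res.site_loglik.sum() == pytest.approx(res.total, abs=1e-6)

    def test_pattern_compression_invariance(self, wag):
        # duplicating columns multiplies pattern weights but per-site
        # values must match an uncompressed evaluation column by column
        rng = np.random.default_rng(19)
        tree = random_tree(5, rng)
        aln = simulate_alignment(SimulationSpec(tree=tree, model=wag, n_sites=30, seed=5))
        doubled = Alignment(aln.names, [r + r for r in aln.rows])
        het = RateHeterogeneity(alpha=0.9, v=0.05, C=4)
        res1 = alignment_loglik(tree, wag, het, aln)
        res2 = alignment_loglik(tree, wag, het, doubled)
        assert res2.total == pytest.approx(2 * res1.total, abs=1e-8)
        assert np.allclose(res2.site_loglik[:30], res1.site_loglik)

    def test_invariant_under_leaf_reordering(self, wag, small_alignment):
        tree, het, aln = small_alignment
        perm = list(reversed(range(aln.n_sequences)))
        shuffled = Alignment(
            [aln.names[i] for i in perm], [aln.rows[i] for i in perm]
        )
        a = alignment_loglik(tree, wag, het, aln).total
        b = alignment_loglik(tree, wag, het, shuffled).total
        assert a == pytest.approx(b, abs=1e-9)

    def test_invariant_under_rerooting(self, wag, small_alignment):
        tree, het, aln = small_alignment
        # re-expressing the same unrooted tree from a different internal
        # vertex must not change the likelihood
        import dendropy

        d = dendropy.Tree.get(data=tree.newick(), schema="newick", preserve_underscores=True)
        internal = [e for e in d.preorder_edge_iter() if e.length and e.head_node.child_nodes()]
        d.reroot_at_edge(internal[-1], length1=internal[-1].length / 2, length2=internal[-1].length / 2)
        rerooted = parse_newick(d.as_string(schema="newick").strip())
        a = alignment_loglik(tree, wag, het, aln).total
        b = alignment_loglik(rerooted, wag, het, aln).total
        assert a == pytest.approx(b, abs=1e-8)

    def test_increasing_v_cannot_help_without_constant_sites(self, wag):
        tree = parse_newick("(a:0.3,b:0.4,c:0.5);")
        aln = Alignment(["a", "b", "c"], ["AR", "RN", "ND"])  # no constant column
        het0 = RateHeterogeneity(alpha=1.0, v=0.0, C=4)
        base = alignment_loglik(tree, wag, het0, aln).total
        for v in [0.1, 0.4, 0.8]:
            worse = alignment_loglik(tree, wag, het0.with_params(v=v), aln).total
            assert worse < base

    def test_gap_only_columns_contribute_zero(self, wag):
        tree = parse_newick("(a:0.2,b:0.3,c:0.1);")
        het = RateHeterogeneity(alpha=1.0, v=0.2, C=4)
        aln1 = Alignment(["a", "b", "c"], ["AR", "AN", "AD"])
        aln2 = Alignment(["a", "b", "c"], ["AR-", "AN-", "AD-"])
        l1 = alignment_loglik(tree, wag, het, aln1).total
        l2 = alignment_loglik(tree, wag, het, aln2).total
        assert l1 == pytest.approx(l2, abs=1e-10)


class TestBranchOptimization:
    def test_recovers_simulated_lengths(self, wag):
        tree = parse_newick("((a:0.15,b:0.4):0.2,(c:0.08,d:0.3):0.12,e:0.6);")
        aln = simulate_alignment(SimulationSpec(tree=tree, model=wag, n_sites=2000, seed=37))
        het = RateHeterogeneity(alpha=1.0, v=0.0, C=1)
        start = tree.copy()
        for node in start.edges():
            node.length = 0.1
        fitted, _ = optimize_branch_lengths(start, wag, het, aln)
        true_by_split = _lengths_by_split(tree)
        fit_by_split = _lengths_by_split(fitted)
        for split, t_true in true_by_split.items():
            if t_true >= 0.05:
                assert fit_by_split[split] == pytest.approx(t_true, rel=0.15)

    def test_idempotent(self, wag, small_alignment):
        tree, het, aln = small_alignment
        once, r1 = optimize_branch_lengths(tree, wag, het, aln)
        twice, r2 = optimize_branch_lengths(once, wag, het, aln)
        assert r2.total == pytest.approx(r1.total, abs=1e-3)

    def test_monotone_improvement(self, wag, small_alignment):
        tree, het, aln = small_alignment
        start = alignment_loglik(tree, wag, het, aln).total
        _, res = optimize_branch_lengths(tree, wag, het, aln)
        assert res.total >= start - 1e-9

    def test_two_taxon_matches_closed_form_ml(self, wag):
        from mtsubst.estimate import pairwise_ml_distance

        tree = parse_newick("(a:0.2,b:0.2);")
        aln = simulate_alignment(SimulationSpec(tree=tree, model=wag, n_sites=3000, seed=41))
        het = RateHeterogeneity(alpha=1.0, v=0.0, C=1)
        fitted, _ = optimize_branch_lengths(tree, wag, het, aln)
        total = sum(n.length for n in fitted.edges())
        direct = pairwise_ml_distance(aln.rows[0], aln.rows[1], wag)
        assert total == pytest.approx(direct, abs=1e-4)

    def test_normalization_invariance_after_reoptimization(self, wag, small_alignment):
        # likelihood at re-optimized branch lengths is the same whether the
        # generator is normalized by the expected rate or by the raw trace
        tree, _, aln = small_alignment
        het = RateHeterogeneity(alpha=1.0, v=0.0, C=1)

        from mtsubst.likelihood import PruningEngine

        def fit_with(weighted_mu):
            work = tree.copy()
            Q = build_rate_matrix(wag, normalize=True, weighted_mu=weighted_mu)
            engine = PruningEngine(work, wag, het, aln, Q=Q)
            from scipy import optimize as sopt

            for _ in range(8):
                before = engine.loglik()
                for node in work.edges():
                    f = engine.edge_loglik_fn(node)
                    res = sopt.minimize_scalar(
                        lambda t: -f(t), bounds=(1e-8, 20.0), method="bounded",
                        options={"xatol": 1e-8},
                    )
                    if -res.fun > f(node.length):
                        node.length = float(res.x)
                if engine.loglik() - before < 1e-6:
                    break
            return engine.loglik()

        assert fit_with(True) == pytest.approx(fit_with(False), abs=1e-3)


def _lengths_by_split(tree):
    all_leaves = frozenset(tree.leaf_names())
    out = {}
    for node in tree.edges():
        sub = frozenset(
            n.name for n in tree.postorder() if n.is_leaf and _is_descendant(n, node)
        )
        if min(all_leaves) in sub:
            sub = all_leaves - sub
        out[sub] = node.length
    return out


def _is_descendant(leaf, ancestor):
    node = leaf
    while node is not None:
        if node is ancestor:
            return True
        node = node.parent
    return False


class TestRateModelOptimization:
    def test_recovers_simulated_alpha_and_v(self, wag):
        rng = np.random.default_rng(53)
        tree = random_tree(16, rng, branch_mean=0.2)
        het_true = RateHeterogeneity(alpha=0.5, v=0.2, C=4)
        aln = simulate_alignment(
            SimulationSpec(tree=tree, model=wag, het=het_true, n_sites=5000, seed=59)
        )
        tree_fit, _ = optimize_branch_lengths(
            tree, wag, RateHeterogeneity(alpha=1.0, v=0.1, C=4), aln
        )
        het, _ = optimize_rate_model(
            tree_fit, wag, RateHeterogeneity(alpha=1.0, v=0.1, C=4), aln
        )
        assert 0.35 <= het.alpha <= 0.7
        assert 0.1 <= het.v <= 0.3

    def test_uniform_rate_data_pushes_alpha_high(self, wag):
        rng = np.random.default_rng(61)
        tree = random_tree(8, rng, branch_mean=0.2)
        aln = simulate_alignment(SimulationSpec(tree=tree, model=wag, n_sites=1500, seed=67))
        het0 = RateHeterogeneity(alpha=1.0, v=0.0, C=4)
        het, res = optimize_rate_model(tree, wag, het0, aln, optimize_v=False)
        flat = alignment_loglik(tree, wag, RateHeterogeneity(alpha=1e6, v=0.0, C=4), aln)
        assert het.alpha > 10 or res.total - flat.total < 2.0

    def test_never_worse_than_start(self, wag, small_alignment):
        tree, het, aln = small_alignment
        start = alignment_loglik(tree, wag, het, aln).total
        _, res = optimize_rate_model(tree, wag, het, aln)
        assert res.total >= start - 1e-9


class TestInformationCriteria:
    def test_zero_case(self):
        ic = information_criteria(0.0, 0, 100)
        assert ic == (0.0, 0.0, 0.0, 0.0)

    def test_arithmetic(self):
        ic = information_criteria(-1000.0, 10, 500)
        assert ic.aic == pytest.approx(2020.0)
        assert ic.aic_per_site == pytest.approx(4.04)
        assert ic.bic == pytest.approx(10 * np.log(500) + 2000)

    def test_delta_aic_identity(self):
        a = information_criteria(-1200.0, 7, 300)
        b = information_criteria(-1180.0, 7, 300)
        assert a.aic - b.aic == pytest.approx(-2 * (-1200.0 - -1180.0))


class TestSiteLnlExport:
    def test_format_and_roundtrip(self, tmp_path, wag, small_alignment):
        tree, het, aln = small_alignment
        r1 = alignment_loglik(tree, wag, het, aln)
        r2 = alignment_loglik(tree, wag, het.with_params(v=0.0), aln)
        path = tmp_path / "sites.sitelh"
        export_site_lnl([r1, r2], path)
        header = path.read_text().splitlines()[0]
        assert header == f"2 {aln.n_sites}"
        mat = read_site_lnl(path)
        assert mat.shape == (2, aln.n_sites)
        assert mat[0].sum() == pytest.approx(r1.total, abs=1e-6)
        assert mat[1].sum() == pytest.approx(r2.total, abs=1e-6)

    def test_ragged_rows_rejected(self, tmp_path, wag, small_alignment):
        tree, het, aln = small_alignment
        r1 = alignment_loglik(tree, wag, het, aln)
        short = Alignment(aln.names, [row[:50] for row in aln.rows])
        r2 = alignment_loglik(tree, wag, het, short)
        with pytest.raises(ValueError, match="site counts"):
            export_site_lnl([r1, r2], tmp_path / "x.sitelh")
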