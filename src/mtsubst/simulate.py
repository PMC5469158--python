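"""Sequence simulation under a known (tree, matrix, alpha, v).

Every stage of the estimation and comparison machinery can be exercised
against data whose generating parameters are known: per site, an
invariant flag is drawn with probability v, otherwise one of C discrete
gamma categories; the root residue is drawn from the equilibrium
frequencies and evolved down the tree with P(rho_c * t) per branch.
All randomness flows from a single integer seed, so the same spec always
produces byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align import Alignment
from .alphabet import N_STATES, RESIDUES
from .likelihood import RateHeterogeneity
from .models import SubstitutionModel
from .phylo import Node, PhyloTree

__all__ = [
    "SimulationSpec",
    "simulate_alignment",
    "simulate_training_set",
    "random_tree",
    "pairwise_distance_check",
]


@dataclass
class SimulationSpec:
    """Everything that determines one simulated alignment."""

    tree: PhyloTree
    model: SubstitutionModel
    het: RateHeterogeneity = field(default_factory=lambda: RateHeterogeneity(alpha=1.0, v=0.0, C=1))
    n_sites: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be positive")


def random_tree(
    n_leaves: int,
    rng: np.random.Generator,
    branch_mean: float = 0.15,
    branch_range: tuple[float, float] = (0.0, 2.0),
    prefix: str = "t",
) -> PhyloTree:
    """Random unrooted binary topology by sequential leaf attachment.

    Each new leaf bisects a uniformly chosen existing edge, which makes
    every labeled topology equally likely.  Branch lengths are drawn from
    an exponential with the given mean, truncated to the open interval
    ``branch_range`` (matching the window within which training branches
    are considered informative).
    """
    if n_leaves < 3:
        raise ValueError("need at least three leaves")
    lo, hi = branch_range

    def draw_length() -> float:
        while True:
            x = float(rng.exponential(branch_mean))
            if lo < x < hi:
                return x

    names = [f"{prefix}{i}" for i in range(n_leaves)]
    root = Node()
    edges: list[Node] = []
    for name in names[:3]:
        edges.append(root.add(Node(name=name)))
    for name in names[3:]:
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        mid = Node()
        idx = parent.children.index(target)
        parent.children[idx] = mid
        mid.parent = parent
        mid.add(target)
        leaf = mid.add(Node(name=name))
        edges.extend([mid, leaf])
    # lengths are drawn only after the topology is complete, so every
    # branch is an independent truncated-exponential draw
    tree = PhyloTree(root)
    for node in tree.edges():
        node.length = draw_length()
    return tree


def simulate_alignment(spec: SimulationSpec) -> Alignment:
    """Evolve one alignment down a tree under the +I+G mixture."""
    rng = np.random.default_rng(spec.seed)
    het, n = spec.het, spec.n_sites
    Q = spec.model.rate_matrix(normalize=True)
    pi = Q.frequencies

    invariant = rng.random(n) < het.v
    category = rng.integers(het.C, size=n)
    rate = np.where(invariant, 0.0, het.rho[category])

    nodes = list(spec.tree.postorder())
    order = list(reversed(nodes))  # root first
    states: dict[int, np.ndarray] = {}
    states[id(order[0])] = rng.choice(N_STATES, size=n, p=pi)
    unique_rates = np.unique(rate)
    for node in order:
        if node.parent is None:
            continue
        parent_state = states[id(node.parent)]
        child = np.empty(n, dtype=np.int64)
        for r in unique_rates:
            mask = rate == r
            if not mask.any():
                continue
            if r == 0.0:
                child[mask] = parent_state[mask]
                continue
            cum = np.cumsum(Q.transition_probabilities(r * node.length), axis=1)
            u = rng.random(mask.sum())
            rows = cum[parent_state[mask]]
            child[mask] = np.minimum(
                (rows < u[:, None]).sum(axis=1), N_STATES - 1
            )
        states[id(node)] = child

    rows, names = [], []
    for node in nodes:
        if node.is_leaf:
            names.append(node.name)
            rows.append("".join(RESIDUES[s] for s in states[id(node)]))
    return Alignment(names, rows)


def simulate_training_set(
    n_alignments: int,
    model: SubstitutionModel,
    out_dir: str | Path,
    seed: int,
    n_taxa: int = 16,
    n_sites: int = 500,
    alpha_range: tuple[float, float] = (0.5, 2.0),
    v: float = 0.0,
    C: int = 4,
    branch_mean: float = 0.15,
) -> list[SimulationSpec]:
    """Write a directory of simulated alignments with trees and a manifest.

    Each alignment gets a fresh random topology, exponential branch
    lengths truncated to (0, 2), and its own gamma shape drawn uniformly
    from ``alpha_range``.  Files: ``aln_###.fasta``, ``aln_###.nwk`` and a
    ``manifest.tsv`` listing the generating parameters.
    """
    if n_alignments < 1:
        raise ValueError("need at least one alignment")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    specs = []
    manifest = ["name\tn_taxa\tn_sites\talpha\tv\tC\tseed\ttree_file"]
    for i in range(n_alignments):
        sub_seed = int(master.integers(2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        tree = random_tree(n_taxa, rng, branch_mean=branch_mean)
        alpha = float(rng.uniform(*alpha_range))
        spec = SimulationSpec(
            tree=tree,
            model=model,
            het=RateHeterogeneity(alpha=alpha, v=v, C=C),
            n_sites=n_sites,
            seed=sub_seed,
        )
        aln = simulate_alignment(spec)
        name = f"aln_{i:03d}"
        aln.write(out_dir / f"{name}.fasta")
        (out_dir / f"{name}.nwk").write_text(tree.newick() + "\n")
        manifest.append(
            f"{name}\t{n_taxa}\t{n_sites}\t{alpha:.6g}\t{v:g}\t{C}\t{sub_seed}\t{name}.nwk"
        )
        specs.append(spec)
    (out_dir / "manifest.tsv").write_text("\n".join(manifest) + "\n")
    return specs


def pairwise_distance_check(
    alignment: Alignment, model: SubstitutionModel
) -> float:
    """ML distance between the two rows of a two-taxon simulated alignment."""
    from .estimate import pairwise_ml_distance

    if alignment.n_sequences != 2:
        raise ValueError("pairwise check needs exactly two sequences")
    return pairwise_ml_distance(alignment.rows[0], alignment.rows[1], model)
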