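"""Codon alignment and fixture simulation.

Generates codon alignments evolved on a tree under the site-class models
(the generative mirror of the fitting machinery), random trees, and
amino-acid fixtures with planted residues for tuning-site tests. All
randomness flows through a single integer seed via numpy's PCG64
generator, so outputs are reproducible across platforms.

Sites in the beta models draw their omega from the discretized classes
(not the continuous beta) by default, so a simulation matches the fitted
likelihood exactly; ``continuous_beta=True`` draws from Beta(p, q) instead
for robustness studies. Branch evolution samples each child state from the
exact transition matrix (spectral decomposition), not by event simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import beta as beta_dist

from .codon_model import decompose_rate_matrix, get_structure
from .errors import ValidationError
from .genetic_code import STANDARD_CODE, GeneticCode
from .io_formats import CodonAlignment, Phylogeny, TreeNode
from .likelihood import mixture_rate_normalizer
from .site_models import SiteClassSpec
from .tuning_sites import ReferenceNumbering


@dataclass(frozen=True)
class SimulationTruth:
    """Per-site generating class and omega, plus everything used to simulate."""

    class_index: np.ndarray
    omega: np.ndarray
    model_name: str
    theta: dict[str, float]
    seed: int
    tree_newick: str


def simulate_tree(
    n_taxa: int,
    seed: int = 0,
    length_range: tuple[float, float] = (0.05, 0.3),
    taxon_prefix: str = "t",
) -> Phylogeny:
    """Random unrooted topology by sequential random edge attachment.

    Starts from a three-taxon star (the basal trichotomy) and repeatedly
    bisects a uniformly chosen edge to attach the next tip. Branch lengths
    are i.i.d. uniform on ``length_range``.
    """
    if n_taxa < 3:
        raise ValidationError("need at least 3 taxa for an unrooted tree")
    rng = np.random.default_rng(seed)
    labels = [f"{taxon_prefix}{i + 1}" for i in range(n_taxa)]
    root = TreeNode(children=[TreeNode(label=labels[i]) for i in range(3)])
    edges = list(root.children)  # nodes, each standing for its parent edge

    for label in labels[3:]:
        target = edges[rng.integers(len(edges))]
        # bisect the edge above `target`: splice in a new internal node
        parent = _find_parent(root, target)
        mid = TreeNode(children=[target])
        parent.children[parent.children.index(target)] = mid
        leaf = TreeNode(label=label)
        mid.children.append(leaf)
        edges.extend([mid, leaf])

    nodes = [n for n in root.postorder() if n is not root]
    lengths = rng.uniform(length_range[0], length_range[1], size=len(nodes))
    for node, ln in zip(nodes, lengths):
        node.length = float(ln)
    return Phylogeny(root)


def _find_parent(root: TreeNode, child: TreeNode) -> TreeNode:
    for node in root.postorder():
        if child in node.children:
            return node
    raise ValueError("child not in tree")


def simulate_codon_alignment(
    tree: Phylogeny,
    spec: SiteClassSpec,
    theta: dict[str, float],
    n_sites: int,
    kappa: float,
    pi: np.ndarray,
    seed: int = 0,
    code: GeneticCode = STANDARD_CODE,
    continuous_beta: bool = False,
) -> tuple[CodonAlignment, SimulationTruth]:
    """Evolve ``n_sites`` codon sites on ``tree`` under a site-class model.

    Per site a class is drawn from the model's mixture, a root codon from
    ``pi``, and each branch transition from P(t) under that class's rate
    matrix. Matrices share the mixture-average rate normalization, exactly
    as in the likelihood, so branch lengths mean the same thing in both
    directions.
    """
    if n_sites < 1:
        raise ValidationError("n_sites must be >= 1")
    spec.validate_theta(theta)
    rng = np.random.default_rng(seed)
    pi = np.asarray(pi, dtype=float)
    dist = spec.class_distribution(theta)
    mu_bar = mixture_rate_normalizer(kappa, pi, dist, code)

    class_idx = rng.choice(len(dist.proportions), size=n_sites, p=dist.proportions)
    if continuous_beta and spec.name in ("M7", "M8", "M8a"):
        k = spec.n_beta_classes
        draws = beta_dist.rvs(theta["p"], theta["q"], size=n_sites, random_state=rng)
        site_omega = np.where(class_idx < k, draws, dist.omegas[class_idx])
    else:
        site_omega = dist.omegas[class_idx]
    unique_omegas, inverse = np.unique(site_omega, return_inverse=True)

    struct = get_structure(code)
    decomps = []
    for w in unique_omegas:
        qu = struct.unscaled_rates(kappa, float(w), pi) / mu_bar
        np.fill_diagonal(qu, 0.0)
        np.fill_diagonal(qu, -qu.sum(axis=1))
        decomps.append(decompose_rate_matrix(qu, pi))

    # root states
    states = {id(tree.root): _sample_categorical(rng, np.tile(pi, (n_sites, 1)))}
    order = [n for n in _preorder(tree.root)]
    parent_of: dict[int, TreeNode] = {}
    for node in order:
        for child in node.children:
            parent_of[id(child)] = node
    for node in order:
        if node is tree.root:
            continue
        parent_states = states[id(parent_of[id(node)])]
        t = node.length
        if t is None:
            raise ValidationError("simulation requires branch lengths on every edge")
        child = np.empty(n_sites, dtype=np.int64)
        for g, dec in enumerate(decomps):
            sel = inverse == g
            if not sel.any():
                continue
            p = dec.transition_matrix(t)
            p = p / p.sum(axis=1, keepdims=True)
            child[sel] = _sample_rows(rng, p, parent_states[sel])
        states[id(node)] = child

    codons = code.sense_codons
    names, seqs = [], []
    for node in order:
        if node.is_leaf:
            names.append(node.label)
            seqs.append("".join(codons[s] for s in states[id(node)]))
    aln = CodonAlignment(taxon_names=tuple(names), sequences=tuple(seqs), code=code)
    truth = SimulationTruth(
        class_index=class_idx,
        omega=site_omega,
        model_name=spec.name,
        theta=dict(theta),
        seed=seed,
        tree_newick=tree.newick(),
    )
    return aln, truth


def _preorder(root: TreeNode):
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(reversed(node.children))


def _sample_categorical(rng, probs: np.ndarray) -> np.ndarray:
    """One draw per row of a (n, k) probability matrix."""
    cum = probs.cumsum(axis=1)
    u = rng.random(probs.shape[0]) * cum[:, -1]
    return (cum < u[:, None]).sum(axis=1)


def _sample_rows(rng, p: np.ndarray, rows: np.ndarray) -> np.ndarray:
    cum = p.cumsum(axis=1)[rows]
    u = rng.random(len(rows)) * cum[:, -1]
    return (cum < u[:, None]).sum(axis=1)


def plant_residues(
    scaffold: str,
    plants: dict[int, str],
    numbering: ReferenceNumbering,
) -> str:
    """Replace residues at reference-numbered positions of a scaffold.

    ``plants`` maps reference positions to residue letters; every position
    must be mapped (non-gap) in the scaffold's numbering, and exactly the
    planted positions change.
    """
    seq = list(scaffold)
    inverse = numbering.reference_to_query()
    for ref_pos, residue in plants.items():
        q = inverse.get(ref_pos)
        if q is None:
            raise ValidationError(f"reference position {ref_pos} is unmapped in scaffold")
        seq[q - 1] = residue
    return "".join(seq)
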