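"""Synthetic-data generators mirroring the two-organelle study design.

The study structure being emulated: two gene sets over one shared taxon
set — a gene-rich "plast" set evolving faster, and a smaller "mito" set
evolving slower but with a broader spread of per-gene rates — either
sharing one true topology or following two distinct topologies, with
partial taxon occupancy and optional clade-restricted base-composition
shifts.  Every generator is a pure function of its seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import NucAlignment
from .likelihood import GTRParams, _EigenGTR, discrete_gamma_rates
from .tree import Node, Tree, TreeError

__all__ = [
    "StudyConfig",
    "sample_tree",
    "simulate_alignment",
    "simulate_composition_shift_alignment",
    "simulate_organelle_study",
    "perturb_nni",
]

_BASES = "ACGT"


def sample_tree(n_taxa: int, seed: int, mean_branch_length: float = 0.1) -> Tree:
    """Random bifurcating tree via exchangeable coalescent-style joins.

    Branch lengths are i.i.d. exponential with the given mean; the result
    is unrooted (trifurcating base) with tips t1..tN.
    """
    if n_taxa < 4:
        raise ValueError("need >= 4 taxa")
    rng = np.random.default_rng(seed)
    lineages = [Node(label=f"t{i + 1}") for i in range(n_taxa)]
    while len(lineages) > 3:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        parent = Node()
        parent.add_child(lineages[i])
        parent.add_child(lineages[j])
        lineages = [l for k, l in enumerate(lineages) if k not in (i, j)]
        lineages.append(parent)
    root = Node()
    for l in lineages:
        root.add_child(l)
    tree = Tree(root, rooted=False)
    for node in tree.edges():
        node.length = float(rng.exponential(mean_branch_length))
    return tree


def _edge_regimes(tree: Tree, shifts) -> dict[int, int]:
    """Nearest-ancestor regime painting; regime 0 at the root."""
    shift_ids = {id(node): i + 1 for i, (node, _) in enumerate(shifts)}
    regime_of: dict[int, int] = {}

    def walk(node: Node, regime: int) -> None:
        if id(node) in shift_ids:
            regime = shift_ids[id(node)]
        regime_of[id(node)] = regime
        for c in node.children:
            walk(c, regime)

    walk(tree.root, 0)
    return regime_of


def simulate_composition_shift_alignment(
    tree_rooted: Tree,
    shifts,
    base_params: GTRParams,
    n_sites: int,
    seed: int,
) -> NucAlignment:
    """Simulate sequences with clade-restricted composition regimes.

    ``shifts`` is a list of (node, pi_new): below each shift edge the rate
    matrix is rebuilt with the new equilibrium frequencies (same
    exchangeabilities, re-normalized).  With no shifts this reduces
    exactly to stationary simulation and consumes the same random stream.
    """
    rng = np.random.default_rng(seed)
    for _, pi in shifts:
        pi = np.asarray(pi, dtype=float)
        if pi.shape != (4,) or np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("invalid shift frequency vector")
    regime_of = _edge_regimes(tree_rooted, shifts)
    regime_params = [base_params] + [
        GTRParams(
            rates=base_params.rates,
            freqs=tuple(np.asarray(pi, dtype=float) / np.asarray(pi, dtype=float).sum()),
            p_inv=base_params.p_inv,
            alpha=base_params.alpha,
            n_cat=base_params.n_cat,
        )
        for _, pi in shifts
    ]
    eigs = [_EigenGTR(p) for p in regime_params]
    cat_rates = discrete_gamma_rates(base_params.alpha, base_params.n_cat)
    m = len(cat_rates)

    # per-site rate: invariant with prob p_inv, else a gamma category
    u = rng.random(n_sites)
    site_rates = np.zeros(n_sites)
    variable = u >= base_params.p_inv
    cats = rng.integers(0, m, size=n_sites)
    site_rates[variable] = cat_rates[cats[variable]]

    pi0 = np.asarray(base_params.freqs)
    states: dict[int, np.ndarray] = {
        id(tree_rooted.root): rng.choice(4, size=n_sites, p=pi0)
    }
    seqs: dict[str, np.ndarray] = {}
    for node in tree_rooted.preorder():
        if node.parent is None:
            if node.is_tip:
                raise TreeError("degenerate single-tip tree")
            continue
        if node.length is None:
            raise TreeError("unset branch length")
        parent_states = states[id(node.parent)]
        eig = eigs[regime_of[id(node)]]
        child_states = parent_states.copy()
        for r in np.unique(site_rates[variable]) if node.length > 0 else []:
            mask = variable & (site_rates == r)
            if not mask.any():
                continue
            P = eig.pmat(node.length * r)
            P = P / P.sum(axis=1, keepdims=True)
            cum = np.cumsum(P, axis=1)
            draws = rng.random(int(mask.sum()))
            ps = parent_states[mask]
            child_states[mask] = (draws[:, None] > cum[ps]).sum(axis=1)
        states[id(node)] = child_states
        if node.is_tip:
            seqs[node.label] = child_states
    labels = tree_rooted.tip_labels()
    base_arr = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    return NucAlignment(
        labels,
        [base_arr[seqs[t]].tobytes().decode("ascii") for t in labels],
    )


def simulate_alignment(
    tree: Tree, params: GTRParams, n_sites: int, seed: int
) -> NucAlignment:
    """Stationary GTR+I+G simulation along ``tree`` (root states from pi)."""
    return simulate_composition_shift_alignment(tree, [], params, n_sites, seed)


def perturb_nni(tree: Tree, n_moves: int, seed: int) -> Tree:
    """Apply ``n_moves`` random NNI moves; RF to the input is <= 2 * n_moves."""
    from .likelihood import _apply_nni

    if n_moves < 0:
        raise ValueError("n_moves must be >= 0")
    rng = np.random.default_rng(seed)
    out = tree.copy()
    for _ in range(n_moves):
        nodes = list(out.preorder())
        edge_idx = [
            i for i, n in enumerate(nodes) if n.parent is not None and not n.is_tip
        ]
        if not edge_idx:
            break
        e = int(rng.choice(edge_idx))
        c = int(rng.integers(0, 2))
        out = _apply_nni(out, e, c)
    return out


@dataclass
class StudyConfig:
    """Configuration of a synthetic two-organelle study.

    Defaults are desk-scale: 16 taxa, 8 faster "plast" genes and 5 slower
    "mito" genes whose per-gene rate multipliers are log-normal with a
    broader sigma for mito, 500-2000 sites per gene, 90 percent taxon
    occupancy.  ``distinct_rf`` > 0 gives the mito set its own topology
    at (at least) that RF distance from the plast topology.
    """

    n_taxa: int = 16
    n_plast: int = 8
    n_mito: int = 5
    plast_rate: float = 2.0
    mito_rate: float = 1.0
    plast_sigma: float = 0.3
    mito_sigma: float = 0.8
    site_range: tuple[int, int] = (500, 2000)
    occupancy: float = 0.9
    mean_branch_length: float = 0.05
    distinct_rf: int = 0
    params: GTRParams = field(
        default_factory=lambda: GTRParams(
            rates=(1.5, 4.0, 1.2, 1.1, 5.0, 1.0),
            freqs=(0.3, 0.2, 0.2, 0.3),
            alpha=0.8,
            n_cat=4,
        )
    )
    shifts: list = field(default_factory=list)  # (tag, gene_index, clade_node_fn?, pi)
    seed: int = 0

    def __post_init__(self):
        if self.n_plast < 1 or self.n_mito < 1:
            raise ValueError("gene counts must be >= 1")
        if self.plast_rate <= 0 or self.mito_rate <= 0:
            raise ValueError("rates must be > 0")
        if not (0.0 < self.occupancy <= 1.0):
            raise ValueError("occupancy must be in (0, 1]")


@dataclass
class GeneRecord:
    name: str
    tag: str
    alignment: NucAlignment
    rate_multiplier: float
    n_sites: int
    taxa: list[str]


def _scaled(tree: Tree, factor: float) -> Tree:
    out = tree.copy()
    for node in out.edges():
        node.length = (node.length or 0.0) * factor
    return out


def simulate_organelle_study(config: StudyConfig):
    """Generate the full synthetic study.

    Returns ``(genes, true_trees, manifest)``: per-gene alignments tagged
    'plast'/'mito', the true topology per tag, and a manifest recording
    every generating truth (topologies, multipliers, site counts, dropped
    taxa, composition shifts).
    """
    from .tree_compare import rf_distance

    rng = np.random.default_rng(config.seed)
    tree_plast = sample_tree(
        config.n_taxa, int(rng.integers(2**31)), config.mean_branch_length
    )
    if config.distinct_rf > 0:
        tree_mito = None
        for _ in range(200):
            cand = perturb_nni(
                tree_plast, max(1, config.distinct_rf), int(rng.integers(2**31))
            )
            if rf_distance(tree_plast, cand) >= config.distinct_rf:
                tree_mito = cand
                break
        if tree_mito is None:
            raise RuntimeError("could not reach the requested RF distance")
        # fresh branch lengths for the second topology
        for node in tree_mito.edges():
            node.length = float(rng.exponential(config.mean_branch_length))
    else:
        tree_mito = tree_plast.copy()
    true_trees = {"plast": tree_plast, "mito": tree_mito}

    genes: list[GeneRecord] = []
    manifest: dict = {
        "seed": config.seed,
        "true_tree_plast": tree_plast.newick(),
        "true_tree_mito": tree_mito.newick(),
        "genes": {},
    }
    plan = [("plast", i) for i in range(config.n_plast)] + [
        ("mito", i) for i in range(config.n_mito)
    ]
    shift_specs = {(tag, idx): pi for tag, idx, pi in config.shifts}
    for tag, idx in plan:
        name = f"{tag}{idx + 1}"
        rate = config.plast_rate if tag == "plast" else config.mito_rate
        sigma = config.plast_sigma if tag == "plast" else config.mito_sigma
        mult = float(rng.lognormal(-0.5 * sigma**2, sigma))
        n_sites = int(rng.integers(config.site_range[0], config.site_range[1] + 1))
        gene_tree = _scaled(true_trees[tag], rate * mult)
        pi_new = shift_specs.get((tag, idx))
        if pi_new is not None:
            # plant the shift on the largest internal clade below the base
            cands = [
                n for n in gene_tree.preorder()
                if n.parent is not None and not n.is_tip
            ]
            cands.sort(key=lambda n: -len(Tree(n).tips()))
            shifts = [(cands[0], pi_new)]
        else:
            shifts = []
        aln = simulate_composition_shift_alignment(
            gene_tree, shifts, config.params, n_sites, int(rng.integers(2**31))
        )
        # occupancy dropout, re-drawn until >= 4 taxa remain
        taxa = list(aln.taxon_labels)
        for _ in range(100):
            keep = [t for t in taxa if rng.random() < config.occupancy]
            if len(keep) >= 4:
                break
        else:  # pragma: no cover - occupancy pathologically low
            keep = taxa[:4]
        aln = aln.subset_taxa(keep)
        genes.append(GeneRecord(name, tag, aln, mult, n_sites, keep))
        manifest["genes"][name] = {
            "tag": tag,
            "rate_multiplier": mult,
            "n_sites": n_sites,
            "taxa": keep,
            "shift_pi": list(pi_new) if pi_new is not None else None,
        }
    return genes, true_trees, manifest
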