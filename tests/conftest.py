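import numpy as np
import pytest

from phylocombine import GTRParams, parse_newick
from phylocombine.tree import Node, Tree


@pytest.fixture
def jc():
    return GTRParams()


@pytest.fixture
def gtr_params():
    return GTRParams(
        rates=(1.5, 4.0, 1.2, 1.1, 5.0, 1.0),
        freqs=(0.3, 0.2, 0.2, 0.3),
    )


@pytest.fixture
def quartet():
    return parse_newick("((a:0.1,b:0.1):0.05,c:0.1,d:0.1);")


def make_star(lengths: dict) -> Tree:
    root = Node()
    for label, length in lengths.items():
        root.add_child(Node(label, length))
    return Tree(root)


def random_gtr(rng) -> GTRParams:
    rates = tuple(np.exp(rng.uniform(-1.5, 1.5, 6)))
    f = rng.dirichlet([5.0] * 4)
    return GTRParams(rates=rates, freqs=tuple(f / f.sum()))


def enumeration_loglik(tree, aln, params):
    """Independent likelihood oracle: exhaustive sum over internal-state
    assignments per site, mixing invariant and gamma-category classes."""
    from itertools import product

    from scipy.linalg import expm

    from phylocombine.alignment import CODE_TO_STATES
    from phylocombine.likelihood import build_rate_matrix, discrete_gamma_rates

    Q = build_rate_matrix(params)
    pi = np.asarray(params.freqs)
    cat_rates = discrete_gamma_rates(params.alpha, params.n_cat)
    nodes = list(tree.preorder())
    internal = [n for n in nodes if not n.is_tip]
    codes = {t: aln.sequence(t) for t in tree.tip_labels()}
    from phylocombine.alignment import CHAR_TO_CODE

    pmats = [
        {id(n): expm(Q * (n.length * r)) for n in nodes if n.parent is not None}
        for r in cat_rates
    ]
    total = 0.0
    for site in range(aln.n_sites):
        site_states = {
            n: CODE_TO_STATES[CHAR_TO_CODE[codes[n.label][site]]]
            for n in nodes
            if n.is_tip
        }
        cat_liks = []
        for P in pmats:
            lik = 0.0
            for assign in product(range(4), repeat=len(internal)):
                state_of = dict(zip((id(n) for n in internal), assign))
                term = pi[state_of[id(tree.root)]]
                for n in nodes:
                    if n.parent is None:
                        continue
                    parent_state = state_of[id(n.parent)]
                    if n.is_tip:
                        term *= sum(
                            P[id(n)][parent_state, s] for s in site_states[n]
                        )
                    else:
                        term *= P[id(n)][parent_state, state_of[id(n)]]
                lik += term
            cat_liks.append(lik)
        var_part = (1.0 - params.p_inv) * np.mean(cat_liks)
        inv_part = 0.0
        if params.p_inv > 0:
            allowed = set(range(4))
            for n in nodes:
                if n.is_tip:
                    allowed &= set(site_states[n])
            inv_part = params.p_inv * sum(pi[s] for s in allowed)
        total += np.log(var_part + inv_part)
    return total


def enumerate_unrooted_topologies(labels):
    """All unrooted binary topologies on the given labels (as Trees)."""
    from phylocombine.tree import Node, Tree

    def clone(node):
        c = Node(node.label, node.length)
        for ch in node.children:
            c.add_child(clone(ch))
        return c

    base = Node()
    for lbl in labels[:3]:
        base.add_child(Node(lbl))
    trees = [Tree(base)]
    for lbl in labels[3:]:
        new_trees = []
        for t in trees:
            edges = [n for n in t.preorder() if n.parent is not None]
            for i in range(len(edges)):
                t2 = Tree(clone(t.root))
                target = [n for n in t2.preorder() if n.parent is not None][i]
                parent = target.parent
                idx = parent.children.index(target)
                mid = Node()
                mid.add_child(target)
                mid.add_child(Node(lbl))
                parent.children[idx] = mid
                mid.parent = parent
                new_trees.append(t2)
        trees = new_trees
    for t in trees:
        for n in t.edges():
            n.length = 0.1
    return trees
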