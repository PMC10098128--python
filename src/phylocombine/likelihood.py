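"""GTR+I+G likelihood on trees: pruning, optimization, search, bootstrap.

The model is the general time-reversible substitution process with a
proportion of invariant sites and discrete-gamma rate variation.  The rate
matrix is normalized to one expected substitution per site per unit branch
length; the per-site likelihood mixes the invariant class and the gamma
categories as

    L_site = p_inv * [site can be constant in x] * pi_x
             + (1 - p_inv) * (1/m) * sum_c L(site | rate_c)

Gaps and ambiguity codes are marginalized: a tip contributes partial
likelihood 1 over each state its character allows.  All randomness takes
explicit seeds; nothing touches global RNG state.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammainc, gammaincinv

from .alignment import NucAlignment
from .partitions import PartitionScheme
from .tree import Node, Tree, TreeError

__all__ = [
    "GTRParams",
    "LikelihoodResult",
    "build_rate_matrix",
    "transition_matrix",
    "discrete_gamma_rates",
    "tree_log_likelihood",
    "fit_model",
    "nni_search",
    "nni_neighbors",
    "bootstrap_support",
    "per_partition_contributions",
    "PartitionedLikelihood",
    "ALL_FREE",
    "n_free_substitution_params",
]

RATE_NAMES = ("AC", "AG", "AT", "CG", "CT", "GT")
BRANCH_MIN, BRANCH_MAX = 1e-8, 10.0

#: the full free-parameter set for GTR+I+G (10 substitution parameters)
ALL_FREE = frozenset({"branch_lengths", "exchangeabilities", "base_freqs", "alpha", "p_inv"})

# tip partial-likelihood lookup: bitmask code -> allowed-state indicator
TIP_PARTIALS = np.zeros((16, 4))
for _code in range(1, 16):
    for _i in range(4):
        if _code & (1 << _i):
            TIP_PARTIALS[_code, _i] = 1.0


@dataclass(frozen=True)
class GTRParams:
    """GTR+I+G parameters.

    ``rates`` are the six exchangeabilities (AC, AG, AT, CG, CT, GT) with
    GT normalized to 1 (5 free); ``freqs`` the stationary base frequencies
    (A, C, G, T; 3 free); ``p_inv`` the invariant-site proportion and
    ``alpha`` the gamma shape (together 2 free); ``n_cat`` the number of
    discrete gamma categories (``n_cat == 1`` disables rate variation).
    """

    rates: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    freqs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    p_inv: float = 0.0
    alpha: float = 1.0
    n_cat: int = 1

    def __post_init__(self):
        rates = np.asarray(self.rates, dtype=float)
        if rates.shape != (6,) or np.any(rates <= 0):
            raise ValueError("need 6 positive exchangeabilities")
        rates = rates / rates[5]  # GT fixed to 1
        freqs = np.asarray(self.freqs, dtype=float)
        if freqs.shape != (4,) or np.any(freqs <= 0):
            raise ValueError("need 4 positive base frequencies")
        if abs(freqs.sum() - 1.0) > 1e-8:
            raise ValueError("base frequencies must sum to 1")
        freqs = freqs / freqs.sum()
        if not (0.0 <= self.p_inv < 1.0):
            raise ValueError("p_inv must be in [0, 1)")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.n_cat < 1:
            raise ValueError("n_cat must be >= 1")
        object.__setattr__(self, "rates", tuple(rates))
        object.__setattr__(self, "freqs", tuple(freqs))

    @classmethod
    def jc(cls, n_cat: int = 1) -> "GTRParams":
        return cls()

    def rate_array(self) -> np.ndarray:
        return np.asarray(self.rates)

    def freq_array(self) -> np.ndarray:
        return np.asarray(self.freqs)


def build_rate_matrix(params: GTRParams) -> np.ndarray:
    """Normalized GTR rate matrix Q with q_ij = s_ij * pi_j (i != j).

    Rows sum to zero and the mean rate -sum_i pi_i q_ii equals 1.
    """
    s = np.zeros((4, 4))
    ac, ag, at, cg, ct, gt = params.rates
    s[0, 1] = s[1, 0] = ac
    s[0, 2] = s[2, 0] = ag
    s[0, 3] = s[3, 0] = at
    s[1, 2] = s[2, 1] = cg
    s[1, 3] = s[3, 1] = ct
    s[2, 3] = s[3, 2] = gt
    pi = params.freq_array()
    Q = s * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(pi, np.diag(Q))
    return Q / mu


def transition_matrix(Q: np.ndarray, t: float, r: float = 1.0) -> np.ndarray:
    """P(rt) = exp(Q * r * t); rows sum to 1."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    if r <= 0:
        raise ValueError("category rate must be > 0")
    return expm(Q * (r * t))


def discrete_gamma_rates(alpha: float, n_categories: int = 4) -> np.ndarray:
    """Category-mean rates of the mean-1 gamma over equal-probability bins."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if n_categories < 1:
        raise ValueError("need at least one category")
    if n_categories == 1:
        return np.array([1.0])
    probs = np.arange(1, n_categories) / n_categories
    # X ~ Gamma(shape=alpha, rate=alpha) so E[X]=1
    bounds = gammaincinv(alpha, probs) / alpha
    upper = np.concatenate([bounds, [np.inf]])
    lower = np.concatenate([[0.0], bounds])
    # E[X; a<X<b] = I(alpha+1, alpha*b) - I(alpha+1, alpha*a)
    mass = gammainc(alpha + 1, alpha * np.where(np.isinf(upper), 1e300, upper)) - gammainc(
        alpha + 1, alpha * lower
    )
    return n_categories * mass


class _EigenGTR:
    """Cached symmetric eigendecomposition of a reversible Q for fast P(t)."""

    def __init__(self, params: GTRParams):
        Q = build_rate_matrix(params)
        pi = params.freq_array()
        sq = np.sqrt(pi)
        S = (Q * sq[:, None]) / sq[None, :]  # D^{1/2} Q D^{-1/2}, symmetric
        S = 0.5 * (S + S.T)
        w, U = np.linalg.eigh(S)
        # a CTMC generator has eigenvalues <= 0; clamp numerical noise
        self.w = np.minimum(w, 0.0)
        self.left = U / sq[None, :].T  # D^{-1/2} U  (4x4)
        self.right = (U * sq[:, None]).T  # U' D^{1/2}
        self.pi = pi

    def pmat(self, t: float) -> np.ndarray:
        P = (self.left * np.exp(self.w * t)) @ self.right
        np.clip(P, 0.0, None, out=P)
        return P


class TreeLikelihood:
    """Pruning-algorithm likelihood for one alignment on one tree.

    Site patterns are compressed once at construction; the tree's branch
    lengths may be modified in place between calls.  An optional global
    ``rate_scale`` multiplies every branch length (used by the
    edge-proportional partition model).
    """

    def __init__(self, tree: Tree, aln: NucAlignment, params: GTRParams):
        self.tree = tree
        labels = tree.tip_labels()
        missing = [t for t in labels if t not in aln.taxon_labels]
        if missing:
            raise TreeError(f"tips missing from alignment: {missing}")
        rows = [aln.taxon_labels.index(t) for t in labels]
        codes = aln.codes()[rows, :]
        patterns, weights = np.unique(codes, axis=1, return_counts=True)
        self.patterns = patterns  # (n_tips, n_patterns)
        self.weights = weights.astype(float)
        self.tip_index = {t: i for i, t in enumerate(labels)}
        # constant-capable mask per state: AND of tip bitmasks
        allmask = patterns[0].copy()
        for row in patterns[1:]:
            allmask &= row
        self.const_lik_states = np.stack(
            [(allmask & (1 << i)) > 0 for i in range(4)], axis=1
        ).astype(float)  # (n_patterns, 4)
        self.set_params(params)

    def set_params(self, params: GTRParams) -> None:
        self.params = params
        self.eig = _EigenGTR(params)
        self.cat_rates = discrete_gamma_rates(params.alpha, params.n_cat)

    @property
    def n_sites(self) -> int:
        return int(self.weights.sum())

    def log_likelihood(self, rate_scale: float = 1.0) -> float:
        params = self.params
        pi = self.eig.pi
        npat = self.patterns.shape[1]
        m = len(self.cat_rates)
        log_cat = np.empty((m, npat))
        for ci, r in enumerate(self.cat_rates):
            log_cat[ci] = self._category_loglik(r * rate_scale)
        if params.p_inv > 0.0:
            inv = self.const_lik_states @ pi  # (n_patterns,)
            with np.errstate(divide="ignore"):
                log_inv = np.log(params.p_inv) + np.log(inv)
            log_var = np.log1p(-params.p_inv) - np.log(m)
            stacked = np.vstack([log_cat + log_var, log_inv[None, :]])
        else:
            stacked = log_cat - np.log(m)
        mx = stacked.max(axis=0)
        site_lnl = mx + np.log(np.exp(stacked - mx[None, :]).sum(axis=0))
        return float(np.dot(self.weights, site_lnl))

    def _category_loglik(self, rate: float) -> np.ndarray:
        """log per-pattern likelihood for one rate category."""
        npat = self.patterns.shape[1]
        logscale = np.zeros(npat)
        partial: dict[int, np.ndarray] = {}
        for node in self.tree.postorder():
            if node.is_tip:
                partial[id(node)] = TIP_PARTIALS[self.patterns[self.tip_index[node.label]]]
                continue
            F = None
            for child in node.children:
                if child.length is None:
                    raise TreeError("unset branch length")
                P = self.eig.pmat(child.length * rate)
                msg = partial.pop(id(child)) @ P.T
                F = msg if F is None else F * msg
            scale = F.max(axis=1)
            scale[scale == 0.0] = 1.0
            F /= scale[:, None]
            logscale += np.log(scale)
            partial[id(node)] = F
        root_lik = partial[id(self.tree.root)] @ self.eig.pi
        with np.errstate(divide="ignore"):
            return np.log(root_lik) + logscale


@dataclass
class LikelihoodResult:
    """Outcome of a model fit: maximized lnL, parameters, fitted tree."""

    lnL: float
    params: GTRParams
    tree: Tree
    converged: bool = True
    n_iterations: int = 0


def tree_log_likelihood(tree: Tree, aln: NucAlignment, params: GTRParams) -> float:
    """Log-likelihood of ``aln`` on ``tree`` under GTR+I+G ``params``."""
    return TreeLikelihood(tree, aln, params).log_likelihood()


def n_free_substitution_params(free, n_cat: int = 4) -> int:
    """Free substitution-parameter count for a free-set (10 for GTR+I+G)."""
    k = 0
    if "exchangeabilities" in free:
        k += 5
    if "base_freqs" in free:
        k += 3
    if "alpha" in free and n_cat > 1:
        k += 1
    if "p_inv" in free:
        k += 1
    return k


def empirical_base_freqs(aln: NucAlignment) -> np.ndarray:
    """Observed base proportions over unambiguous cells (pseudocount 1)."""
    codes = aln.codes()
    counts = np.array([(codes == (1 << i)).sum() for i in range(4)], dtype=float)
    counts += 1.0
    return counts / counts.sum()


def _pack(params: GTRParams, free) -> tuple[np.ndarray, list[tuple[float, float]]]:
    x: list[float] = []
    bounds: list[tuple[float, float]] = []
    if "exchangeabilities" in free:
        x.extend(np.clip(np.log(np.asarray(params.rates[:5])), -5.0, 5.0))
        bounds.extend([(-5.0, 5.0)] * 5)
    if "base_freqs" in free:
        f = params.freq_array()
        x.extend(np.clip(np.log(f[:3] / f[3]), -6.0, 6.0))
        bounds.extend([(-6.0, 6.0)] * 3)
    if "alpha" in free and params.n_cat > 1:
        x.append(np.log(params.alpha))
        bounds.append((np.log(0.02), np.log(100.0)))
    if "p_inv" in free:
        p = min(max(params.p_inv, 1e-6), 0.9)
        x.append(np.log(p / (1 - p)))
        bounds.append((-13.0, np.log(0.95 / 0.05)))
    return np.asarray(x), bounds


def _unpack(x: np.ndarray, params: GTRParams, free) -> GTRParams:
    i = 0
    kw: dict = {}
    if "exchangeabilities" in free:
        kw["rates"] = tuple(np.exp(x[i : i + 5])) + (1.0,)
        i += 5
    if "base_freqs" in free:
        z = np.concatenate([x[i : i + 3], [0.0]])
        e = np.exp(z - z.max())
        kw["freqs"] = tuple(e / e.sum())
        i += 3
    if "alpha" in free and params.n_cat > 1:
        kw["alpha"] = float(np.exp(x[i]))
        i += 1
    if "p_inv" in free:
        kw["p_inv"] = float(1.0 / (1.0 + np.exp(-x[i])))
        i += 1
    return replace(params, **kw)


def _optimize_substitution(
    engines: list[TreeLikelihood],
    params: GTRParams,
    free,
    scales: list[float] | None = None,
) -> tuple[GTRParams, float]:
    """Maximize the summed lnL of ``engines`` over the free subset."""
    subst_free = set(free) - {"branch_lengths"}
    if scales is None:
        scales = [1.0] * len(engines)

    def objective(x: np.ndarray) -> float:
        try:
            p = _unpack(x, params, subst_free)
        except ValueError:
            return 1e12
        total = 0.0
        for eng, sc in zip(engines, scales):
            eng.set_params(p)
            total += eng.log_likelihood(sc)
        # probabilities cannot exceed 1, so a positive lnL marks a
        # numerically broken trial point
        if not np.isfinite(total) or total > 1e-6:
            return 1e12
        return -total

    x0, bounds = _pack(params, subst_free)
    if x0.size == 0:
        total = 0.0
        for eng, sc in zip(engines, scales):
            eng.set_params(params)
            total += eng.log_likelihood(sc)
        return params, total
    f0 = objective(x0)
    res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
    if res.fun <= f0:
        best, fbest = _unpack(res.x, params, subst_free), -float(res.fun)
    else:  # keep the starting point if the line search ended worse
        best, fbest = params, -float(f0)
    for eng in engines:
        eng.set_params(best)
    return best, fbest


def _optimize_branches(
    tree: Tree,
    engines: list[TreeLikelihood],
    scales: list[float] | None = None,
    xatol: float = 1e-6,
) -> float:
    """One sweep of bounded 1-D optimization over every branch length."""
    if scales is None:
        scales = [1.0] * len(engines)

    def total() -> float:
        return sum(e.log_likelihood(s) for e, s in zip(engines, scales))

    current = total()
    for node in tree.edges():
        original = node.length

        def obj(t: float) -> float:
            node.length = t
            return -total()

        res = minimize_scalar(
            obj, bounds=(BRANCH_MIN, BRANCH_MAX), method="bounded",
            options={"xatol": xatol},
        )
        if -res.fun > current:
            node.length = float(res.x)
            current = -float(res.fun)
        else:
            node.length = original
    return current


def fit_model(
    tree: Tree,
    aln: NucAlignment,
    params0: GTRParams,
    free=ALL_FREE,
    tol: float = 1e-4,
    max_rounds: int = 100,
) -> LikelihoodResult:
    """Coordinate-ascent ML fit of branch lengths and/or model parameters.

    Branches are optimized by bounded 1-D searches, substitution
    parameters by a bounded multivariate search; rounds repeat until the
    lnL improvement drops below ``tol``.  Non-convergence is flagged on
    the result, not raised.
    """
    work = tree.copy()
    fit_branches = "branch_lengths" in free
    if fit_branches:
        for node in work.edges():
            if node.length is None:
                node.length = 0.1
    engine = TreeLikelihood(work, aln, params0)
    params = params0
    lnl = engine.log_likelihood()
    converged = False
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        prev = lnl
        params, lnl = _optimize_substitution([engine], params, free)
        if fit_branches:
            lnl = _optimize_branches(work, [engine])
        if abs(lnl - prev) < tol:
            converged = True
            break
    return LikelihoodResult(lnl, params, work, converged, rounds)


# ------------------------------------------------------------------ NNI
def nni_neighbors(tree: Tree) -> list[Tree]:
    """All nearest-neighbor-interchange neighbors of a bifurcating tree."""
    neighbors = []
    edges = []
    nodes = list(tree.preorder())
    for i, node in enumerate(nodes):
        if node.parent is not None and not node.is_tip:
            edges.append(i)
    for edge_i in edges:
        for child_j in (0, 1):
            neighbors.append(_apply_nni(tree, edge_i, child_j))
    return neighbors


def _apply_nni(tree: Tree, edge_index: int, child_index: int) -> Tree:
    """Copy ``tree`` and swap child ``child_index`` of the edge's lower node
    with the first sibling of that node."""
    work = tree.copy()
    nodes = list(work.preorder())
    v = nodes[edge_index]
    u = v.parent
    assert u is not None and not v.is_tip
    sib = next(c for c in u.children if c is not v)
    child = v.children[child_index]
    ui = u.children.index(sib)
    vi = v.children.index(child)
    u.children[ui] = child
    child.parent = u
    v.children[vi] = sib
    sib.parent = v
    for n in (u, v):
        n.support = None
    return work


def _branch_lnl(
    tree: Tree,
    aln: NucAlignment,
    params: GTRParams,
    sweeps: int = 2,
    xatol: float = 1e-5,
) -> float:
    for node in tree.edges():
        if node.length is None:
            node.length = 0.1
    engine = TreeLikelihood(tree, aln, params)
    lnl = engine.log_likelihood()
    for _ in range(sweeps):
        new = _optimize_branches(tree, [engine], xatol=xatol)
        if new - lnl < 1e-3:
            lnl = new
            break
        lnl = new
    return lnl


def nni_search(
    start_tree: Tree,
    aln: NucAlignment,
    params: GTRParams,
    return_trace: bool = False,
):
    """Greedy hill-climb over NNI moves; accepted moves strictly increase
    lnL (branch lengths re-optimized per candidate)."""
    current = start_tree.copy()
    current_lnl = _branch_lnl(current, aln, params)
    trace = [current_lnl]
    improved = True
    while improved:
        improved = False
        best_tree, best_lnl = None, current_lnl
        # candidates are scored with a single cheap branch sweep; the
        # accepted move is then refined before the next round
        for cand in nni_neighbors(current):
            lnl = _branch_lnl(cand, aln, params, sweeps=1, xatol=1e-4)
            if lnl > best_lnl + 1e-6:
                best_tree, best_lnl = cand, lnl
        if best_tree is not None:
            refined = _branch_lnl(best_tree, aln, params)
            current, current_lnl = best_tree, max(best_lnl, refined)
            trace.append(current_lnl)
            improved = True
    if return_trace:
        return current, trace
    return current


# ------------------------------------------------------------ bootstrap
def bootstrap_support(
    aln: NucAlignment,
    params: GTRParams,
    tree: Tree,
    n_reps: int = 100,
    seed: int = 0,
    search: bool = False,
) -> Tree:
    """Nonparametric bootstrap: resample sites with replacement, refit each
    replicate (branch lengths, optionally NNI search), and write the
    percent of replicates containing each bipartition onto ``tree``."""
    from .tree_compare import bipartition_set

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(n_reps):
        idx = rng.integers(0, aln.n_sites, size=aln.n_sites)
        rep = aln.subset_sites(idx)
        rep_tree = tree.copy()
        if search:
            rep_tree = nni_search(rep_tree, rep, params)
        else:
            _branch_lnl(rep_tree, rep, params)
        for split in bipartition_set(rep_tree).splits:
            counts[split] = counts.get(split, 0) + 1
    out = tree.copy()
    ref = min(out.leaf_set())
    for node in out.internal_edges():
        clade = frozenset(n.label for n in Tree(node).tips())
        if len(clade) < 2 or len(clade) > out.n_tips - 2:
            continue
        split = clade if ref not in clade else out.leaf_set() - clade
        node.support = 100.0 * counts.get(frozenset(split), 0) / n_reps
    return out


# --------------------------------------------- per-partition contributions
def per_partition_contributions(
    tree: Tree,
    aln: NucAlignment,
    scheme: PartitionScheme,
    params0: GTRParams | None = None,
    free=frozenset({"exchangeabilities", "base_freqs"}),
    tol: float = 1e-4,
    max_rounds: int = 20,
    return_params: bool = False,
):
    """Per-partition lnL contributions on a fixed tree.

    Topology and branch lengths are held fixed; each partition's
    substitution parameters are fitted independently.  The per-partition
    values sum exactly to the total lnL of the same per-partition model on
    the fixed tree.  With ``return_params`` the fitted parameters are
    returned alongside each contribution.
    """
    if params0 is None:
        params0 = GTRParams()
    out = []
    fitted = []
    for part in scheme.partitions:
        if part.indices()[-1] >= aln.n_sites:
            raise ValueError(f"partition {part.name!r} outside alignment bounds")
        sub = aln.subset_sites(part.indices())
        start = replace(params0, freqs=tuple(empirical_base_freqs(sub)))
        res = fit_model(
            tree, sub, start, free=frozenset(free) - {"branch_lengths"},
            tol=tol, max_rounds=max_rounds,
        )
        out.append(res.lnL)
        fitted.append(res.params)
    if return_params:
        return out, fitted
    return out


# --------------------------------------------- multi-partition objective
class PartitionedLikelihood:
    """Joint likelihood of several partitions sharing one tree object.

    Each partition has its own substitution parameters and (optionally) a
    branch-length multiplier; all partitions reference the same ``Tree``
    instance so branch-length moves are shared.
    """

    def __init__(
        self,
        tree: Tree,
        aln: NucAlignment,
        scheme: PartitionScheme,
        params: list[GTRParams],
    ):
        self.tree = tree
        self.engines = [
            TreeLikelihood(tree, aln.subset_sites(p.indices()), params[i])
            for i, p in enumerate(scheme.partitions)
        ]
        self.weights = np.array([p.n_sites for p in scheme.partitions], dtype=float)
        self.scales = [1.0] * len(self.engines)

    def total(self) -> float:
        return sum(e.log_likelihood(s) for e, s in zip(self.engines, self.scales))

    def per_partition(self) -> list[float]:
        return [e.log_likelihood(s) for e, s in zip(self.engines, self.scales)]

    def optimize_branches(self, xatol: float = 1e-6) -> float:
        return _optimize_branches(self.tree, self.engines, self.scales, xatol)

    def optimize_substitution(self, free) -> float:
        total = 0.0
        for i, eng in enumerate(self.engines):
            p, lnl = _optimize_substitution([eng], eng.params, free, [self.scales[i]])
            total += lnl
        return total

    def optimize_scales(self) -> float:
        """Per-partition multiplier optimization, then renormalization to
        site-weighted mean 1 (branch lengths absorb the constant)."""
        for i, eng in enumerate(self.engines):
            def obj(logm: float) -> float:
                return -eng.log_likelihood(float(np.exp(logm)))

            res = minimize_scalar(
                obj, bounds=(np.log(1e-3), np.log(1e3)), method="bounded",
                options={"xatol": 1e-6},
            )
            if -res.fun > eng.log_likelihood(self.scales[i]):
                self.scales[i] = float(np.exp(res.x))
        c = float(np.dot(self.weights, self.scales) / self.weights.sum())
        self.scales = [s / c for s in self.scales]
        for node in self.tree.edges():
            node.length = min((node.length or 0.0) * c, BRANCH_MAX)
        return self.total()
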