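"""Partition linking schemes, information criteria, and combinability.

Five ways of tying data partitions together are supported, ordered by
nesting (each is a constrained case of the next):

- ``unpartitioned``   one substitution model, one set of branch lengths;
- ``edge_equal``      per-partition substitution models, shared branch
                      lengths ("-q");
- ``edge_proportional``  shared branch lengths up to one multiplier per
                      partition, site-weighted mean 1 ("-spp");
- ``edge_unlinked``   free branch lengths per partition on a shared
                      topology ("-sp");
- ``separate_trees``  independent trees per dataset; their lnL, n and k
                      are summed before scoring.

Free parameters per entry (s substitution parameters per partition, p
partitions, T taxa): unpartitioned s + (2T-3); edge_equal sp + (2T-3);
edge_proportional sp + (2T-3) + (p-1); edge_unlinked sp + p(2T-3).
The combinability question — do two genomes support one tree or two? —
is answered by comparing AICc/BIC across these candidates.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .alignment import NucAlignment
from .likelihood import (
    ALL_FREE,
    GTRParams,
    PartitionedLikelihood,
    TreeLikelihood,
    empirical_base_freqs,
    fit_model,
    n_free_substitution_params,
    nni_search,
)
from .partitions import Partition, PartitionScheme
from .tree import Tree

__all__ = [
    "LINKING_SCHEMES",
    "FitSummary",
    "ICTriple",
    "count_free_parameters",
    "information_criteria",
    "fit_linked_scheme",
    "sum_fit_summaries",
    "combinability_rank",
    "greedy_merge_partitions",
    "cluster_mix_summary",
    "starting_tree",
]

#: linking schemes in nesting order
LINKING_SCHEMES = (
    "unpartitioned",
    "edge_equal",
    "edge_proportional",
    "edge_unlinked",
    "separate_trees",
)


@dataclass(frozen=True)
class ICTriple:
    AIC: float
    AICc: float
    BIC: float


@dataclass
class FitSummary:
    """Maximized lnL plus the bookkeeping the combinability test needs."""

    lnL: float
    k: int
    n: int
    scheme: str
    per_partition_lnL: list[float] = field(default_factory=list)
    trees: list[Tree] = field(default_factory=list)
    multipliers: list[float] | None = None
    tree_lengths: list[float] = field(default_factory=list)
    params: list[GTRParams] = field(default_factory=list)

    def ic(self) -> ICTriple:
        return information_criteria(self.lnL, self.k, self.n)


def count_free_parameters(structure, per_partition_substitution_params: int = 10) -> int:
    """Free-parameter count for a list of (scheme, n_partitions, n_taxa).

    Each partition carries ``per_partition_substitution_params`` free
    substitution parameters (10 for GTR+I+G: 5 exchangeabilities, 3 base
    frequencies, invariant proportion, gamma shape); an unrooted tree on T
    taxa carries 2T-3 edge lengths.  Multiple entries (the separate-trees
    case) are summed.
    """
    s = per_partition_substitution_params
    total = 0
    for scheme, p, t in structure:
        if p < 1:
            raise ValueError("need at least one partition")
        if t < 4:
            raise ValueError("need at least 4 taxa")
        edges = 2 * t - 3
        if scheme == "unpartitioned":
            if p != 1:
                raise ValueError("unpartitioned entries must have p == 1")
            total += s + edges
        elif scheme == "edge_equal":
            total += s * p + edges
        elif scheme == "edge_proportional":
            total += s * p + edges + (p - 1)
        elif scheme == "edge_unlinked":
            total += s * p + p * edges
        else:
            raise ValueError(f"unknown linking scheme: {scheme!r}")
    return total


def information_criteria(lnL: float, k: float, n: float) -> ICTriple:
    """AIC = 2k - 2lnL; AICc = AIC + 2k(k+1)/(n-k-1); BIC = k ln(n) - 2lnL."""
    if n <= k + 1:
        raise ValueError("AICc undefined: need n > k + 1")
    aic = 2.0 * k - 2.0 * lnL
    aicc = aic + 2.0 * k * (k + 1.0) / (n - k - 1.0)
    bic = k * math.log(n) - 2.0 * lnL
    return ICTriple(aic, aicc, bic)


def starting_tree(aln: NucAlignment, params: GTRParams | None = None) -> Tree:
    """Neighbor-joining start tree from Jukes-Cantor-corrected distances."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    from .tree import parse_newick

    codes = aln.codes()
    n = aln.n_taxa
    d = np.zeros((n, n))
    unamb = (codes == 1) | (codes == 2) | (codes == 4) | (codes == 8)
    for i in range(n):
        for j in range(i + 1, n):
            both = unamb[i] & unamb[j]
            tot = both.sum()
            if tot == 0:
                p = 0.0
            else:
                p = float(((codes[i] != codes[j]) & both).sum() / tot)
            p = min(p, 0.74)
            dist = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            d[i, j] = d[j, i] = max(dist, 1e-8)
    import io as _io

    dm = DistanceMatrix(d, ids=aln.taxon_labels)
    buf = _io.StringIO()
    nj(dm).write(buf)
    tree = parse_newick(buf.getvalue().strip())
    tree.unroot()
    for node in tree.edges():
        if node.length is None or node.length < 1e-8:
            node.length = 1e-8
    return tree


def _subst_free(free) -> frozenset:
    return frozenset(free) - {"branch_lengths"}


def _start_params(aln: NucAlignment, params0: GTRParams | None, free) -> GTRParams:
    base = params0 if params0 is not None else GTRParams(alpha=1.0, n_cat=1)
    if "base_freqs" in free:
        base = replace(base, freqs=tuple(empirical_base_freqs(aln)))
    return base


def fit_linked_scheme(
    aln: NucAlignment,
    scheme_def: PartitionScheme,
    linking: str,
    topology: Tree | None = None,
    params0: GTRParams | None = None,
    free=ALL_FREE,
    tol: float = 1e-3,
    max_rounds: int = 30,
    search: bool = False,
    init_from: "FitSummary | None" = None,
) -> FitSummary:
    """Fit one linking scheme on one alignment + partition scheme.

    ``topology`` must be supplied (or found upstream via
    :func:`starting_tree` / :func:`nni_search` when ``search`` is set).
    ``init_from`` warm-starts from a previously fitted (nested) summary so
    that lnL can only improve along the nesting order.
    For ``separate_trees`` fit each dataset separately and combine with
    :func:`sum_fit_summaries`.
    """
    if linking == "separate_trees":
        raise ValueError(
            "fit each dataset separately and combine with sum_fit_summaries"
        )
    if linking not in LINKING_SCHEMES:
        raise ValueError(f"unknown linking scheme: {linking!r}")
    n_taxa = aln.n_taxa
    s = n_free_substitution_params(
        _subst_free(free), (params0.n_cat if params0 else 1)
    )
    if topology is None:
        topology = starting_tree(aln)
    work = topology.copy()
    if work.rooted:
        work.unroot()
    for node in work.edges():
        if node.length is None:
            node.length = 0.1

    if search:
        p0 = _start_params(aln, params0, free)
        work = nni_search(work, aln, p0)

    parts = scheme_def.partitions
    p = len(parts)

    if linking == "unpartitioned":
        p0 = _start_params(aln, params0, free)
        res = fit_model(work, aln, p0, free=frozenset(free) | {"branch_lengths"},
                        tol=tol, max_rounds=max_rounds)
        k = count_free_parameters([("unpartitioned", 1, n_taxa)], s)
        tl = sum(n.length or 0.0 for n in res.tree.edges())
        return FitSummary(res.lnL, k, aln.n_sites, "unpartitioned",
                          [res.lnL], [res.tree], None, [tl], [res.params])

    if linking == "edge_unlinked":
        lnls, trees, tls, plist = [], [], [], []
        for i, part in enumerate(parts):
            sub = aln.subset_sites(part.indices())
            start_tree_i = work.copy()
            if init_from is not None and init_from.scheme == "edge_proportional":
                m = init_from.multipliers[i] if init_from.multipliers else 1.0
                src = init_from.trees[0]
                for a, b in zip(start_tree_i.preorder(), src.preorder()):
                    if b.length is not None:
                        a.length = min(b.length * m, 10.0)
            p0 = _start_params(sub, params0, free)
            if init_from is not None and i < len(init_from.params):
                p0 = init_from.params[i]
            res = fit_model(start_tree_i, sub, p0,
                            free=frozenset(free) | {"branch_lengths"},
                            tol=tol, max_rounds=max_rounds)
            lnls.append(res.lnL)
            trees.append(res.tree)
            tls.append(sum(n.length or 0.0 for n in res.tree.edges()))
            plist.append(res.params)
        k = count_free_parameters([("edge_unlinked", p, n_taxa)], s)
        return FitSummary(sum(lnls), k, aln.n_sites, "edge_unlinked",
                          lnls, trees, None, tls, plist)

    # edge_equal / edge_proportional: shared tree, coordinate ascent
    if init_from is not None and init_from.trees:
        src = init_from.trees[0]
        for a, b in zip(work.preorder(), src.preorder()):
            if b.length is not None:
                a.length = b.length
    init_params = []
    for i, part in enumerate(parts):
        sub = aln.subset_sites(part.indices())
        if init_from is not None and i < len(init_from.params):
            init_params.append(init_from.params[i])
        elif init_from is not None and len(init_from.params) == 1:
            init_params.append(init_from.params[0])
        else:
            init_params.append(_start_params(sub, params0, free))
    joint = PartitionedLikelihood(work, aln, scheme_def, init_params)
    lnl = joint.total()
    for _ in range(max_rounds):
        prev = lnl
        lnl = joint.optimize_substitution(_subst_free(free))
        if linking == "edge_proportional":
            lnl = joint.optimize_scales()
        lnl = joint.optimize_branches()
        if abs(lnl - prev) < tol:
            break
    k = count_free_parameters([(linking, p, n_taxa)], s)
    base_tl = sum(n.length or 0.0 for n in work.edges())
    if linking == "edge_proportional":
        mults = list(joint.scales)
        tls = [base_tl * m for m in mults]
    else:
        mults = None
        tls = [base_tl]
    return FitSummary(lnl, k, aln.n_sites, linking, joint.per_partition(),
                      [work], mults, tls, [e.params for e in joint.engines])


def sum_fit_summaries(fits) -> FitSummary:
    """Combine separate-tree fits by summing lnL, k and n.

    This is the separate-topology scoring rule: per-dataset maxima are
    added and the combined triple is scored as one candidate.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to combine")
    return FitSummary(
        lnL=sum(f.lnL for f in fits),
        k=sum(f.k for f in fits),
        n=sum(f.n for f in fits),
        scheme="separate_trees",
        per_partition_lnL=[x for f in fits for x in f.per_partition_lnL],
        trees=[t for f in fits for t in f.trees],
        multipliers=None,
        tree_lengths=[x for f in fits for x in f.tree_lengths],
        params=[p for f in fits for p in f.params],
    )


def combinability_rank(candidates) -> pd.DataFrame:
    """Score and rank combinability candidates.

    ``candidates`` is a list of ``(label, FitSummary)`` or
    ``(label, [FitSummary, ...])``; lists are summed (separate-trees rule)
    before scoring.  All candidates must describe the same sites (equal
    total n).  Returns a table sorted by BIC with best-by-BIC and
    best-by-AICc flags.
    """
    rows = []
    for label, fit in candidates:
        if isinstance(fit, (list, tuple)):
            fit = sum_fit_summaries(fit)
        ic = fit.ic()
        rows.append(
            {"label": label, "lnL": fit.lnL, "k": fit.k, "n": fit.n,
             "AIC": ic.AIC, "AICc": ic.AICc, "BIC": ic.BIC}
        )
    df = pd.DataFrame(rows)
    if df["n"].nunique() != 1:
        raise ValueError(
            f"candidates describe different site totals: {sorted(df['n'].unique())}"
        )
    df["best_BIC"] = df["BIC"] == df["BIC"].min()
    df["best_AICc"] = df["AICc"] == df["AICc"].min()
    df = df.sort_values(["BIC", "label"], kind="mergesort").reset_index(drop=True)
    df["rank_BIC"] = df["BIC"].rank(method="min").astype(int)
    df["rank_AICc"] = df["AICc"].rank(method="min").astype(int)
    return df


# ------------------------------------------------------------- merging
def _fit_cluster(
    tree: Tree,
    aln: NucAlignment,
    indices: np.ndarray,
    params0: GTRParams,
    free,
) -> float:
    """lnL of one cluster on a fixed tree: substitution params + a free
    branch-length multiplier."""
    sub = aln.subset_sites(indices)
    start = _start_params(sub, params0, free)
    engine = TreeLikelihood(tree, sub, start)
    from .likelihood import _optimize_substitution
    from scipy.optimize import minimize_scalar

    scale = 1.0
    lnl = engine.log_likelihood(scale)
    for _ in range(6):
        prev = lnl
        _, lnl = _optimize_substitution([engine], engine.params, _subst_free(free), [scale])

        def obj(logm: float) -> float:
            return -engine.log_likelihood(float(np.exp(logm)))

        res = minimize_scalar(obj, bounds=(np.log(1e-3), np.log(1e3)),
                              method="bounded", options={"xatol": 1e-6})
        if -res.fun > lnl:
            scale = float(np.exp(res.x))
            lnl = -float(res.fun)
        if abs(lnl - prev) < 1e-3:
            break
    return lnl


def greedy_merge_partitions(
    aln: NucAlignment,
    initial: PartitionScheme,
    topology: Tree,
    linking: str = "edge_proportional",
    criterion: str = "BIC",
    params0: GTRParams | None = None,
    free=ALL_FREE,
):
    """Greedy agglomerative partition merging under an information criterion.

    Starting from ``initial``, every candidate pair merge is scored (the
    merged cluster shares substitution parameters and one rate
    multiplier); the best strictly-improving merge is applied and the
    process repeats until no merge improves the criterion.  Branch lengths
    are re-optimized once per round, not per pair.  Ties break on the
    lexicographically smallest pair of cluster names.

    Returns ``(scheme, trace)`` where ``trace`` is a DataFrame with one
    row per accepted merge and its criterion delta (always negative).
    """
    if criterion not in ("AIC", "AICc", "BIC"):
        raise ValueError("criterion must be AIC, AICc or BIC")
    if linking != "edge_proportional":
        raise ValueError("merging is defined under the edge_proportional model")
    base = params0 if params0 is not None else GTRParams(alpha=1.0, n_cat=1)
    s = n_free_substitution_params(_subst_free(free), base.n_cat)
    n_taxa = aln.n_taxa
    n_sites = initial.n_sites

    clusters: list[Partition] = list(initial.partitions)
    tree = topology.copy()
    if tree.rooted:
        tree.unroot()
    for node in tree.edges():
        if node.length is None:
            node.length = 0.1

    def total_ic(lnls: list[float], p: int) -> float:
        k = count_free_parameters([("edge_proportional", p, n_taxa)], s)
        ic = information_criteria(sum(lnls), k, n_sites)
        return getattr(ic, criterion)

    trace_rows = []
    while True:
        p = len(clusters)
        # re-optimize shared branch lengths once per round under the
        # current scheme, then per-cluster fits on the fixed tree
        scheme = PartitionScheme(list(clusters))
        joint = PartitionedLikelihood(
            tree, aln, scheme,
            [_start_params(aln.subset_sites(c.indices()), base, free) for c in clusters],
        )
        joint.optimize_substitution(_subst_free(free))
        if p > 1:
            joint.optimize_scales()
        joint.optimize_branches()
        cluster_lnl = [
            _fit_cluster(tree, aln, c.indices(), base, free) for c in clusters
        ]
        current = total_ic(cluster_lnl, p)
        if p == 1:
            break
        best = None  # (delta, name_i, name_j, i, j, lnl_merged)
        for i in range(p):
            for j in range(i + 1, p):
                merged_idx = np.sort(
                    np.concatenate([clusters[i].indices(), clusters[j].indices()])
                )
                lnl_m = _fit_cluster(tree, aln, merged_idx, base, free)
                lnls = [
                    lnl for idx, lnl in enumerate(cluster_lnl) if idx not in (i, j)
                ] + [lnl_m]
                delta = total_ic(lnls, p - 1) - current
                key = tuple(sorted((clusters[i].name, clusters[j].name)))
                if delta < -1e-9 and (
                    best is None
                    or delta < best[0] - 1e-9
                    or (abs(delta - best[0]) <= 1e-9 and key < best[1])
                ):
                    best = (delta, key, i, j, lnl_m)
        if best is None:
            break
        delta, key, i, j, _ = best
        merged_name = "+".join(sorted([clusters[i].name, clusters[j].name]))
        ranges = clusters[i].ranges + clusters[j].ranges
        merged = Partition(merged_name, ranges)
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)]
        clusters.append(merged)
        trace_rows.append(
            {"merged": merged_name, "criterion_delta": delta,
             "n_clusters": len(clusters)}
        )
    trace = pd.DataFrame(trace_rows, columns=["merged", "criterion_delta", "n_clusters"])
    return PartitionScheme(clusters), trace


def cluster_mix_summary(scheme: PartitionScheme, origin_labels: dict) -> pd.DataFrame:
    """Per-cluster composition by dataset tag.

    Cluster members are recovered from '+'-joined merged names; every
    original partition must appear in ``origin_labels``.  The summary
    reports, per cluster, the count for each tag plus whether the cluster
    is mixed, homogeneous, or a singleton.
    """
    tags = sorted(set(origin_labels.values()))
    rows = []
    for part in scheme.partitions:
        members = part.name.split("+")
        missing = [m for m in members if m not in origin_labels]
        if missing:
            raise ValueError(f"unlabeled partitions: {missing}")
        counts = {t: 0 for t in tags}
        for m in members:
            counts[origin_labels[m]] += 1
        present = [t for t in tags if counts[t] > 0]
        rows.append(
            {"cluster": part.name, "size": len(members),
             **{f"n_{t}": counts[t] for t in tags},
             "mixed": len(present) > 1,
             "singleton_tag": present[0] if len(members) == 1 else None}
        )
    return pd.DataFrame(rows)
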