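"""Detection of base-composition shifts across a fixed rooted topology.

The model is deliberately explicit and simple: each tip's unambiguous base
counts are multinomial draws from the equilibrium frequencies of the
composition regime painted on its subtending edge.  A regime painting
assigns regime 0 to the root and introduces each further regime at one
shift edge, inherited by the whole subtended clade until overridden by a
nested shift.  Maximum-likelihood regime frequencies are pooled count
proportions; the greedy search adds the shift edge with the best
information-criterion improvement (3 free frequencies per regime) until
no addition helps.  Candidate shift edges must subtend at least
``min_clade`` tips (default 4).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import NucAlignment
from .model_select import information_criteria
from .tree import Node, Tree, TreeError

__all__ = [
    "ShiftSearchResult",
    "tip_base_counts",
    "regime_log_likelihood",
    "regime_ml_frequencies",
    "candidate_shift_edges",
    "greedy_shift_search",
    "shift_prevalence",
    "paint_regimes",
]

_SMOOTH = 0.5  # additive smoothing per base cell when a pooled count is 0


def tip_base_counts(aln: NucAlignment) -> pd.DataFrame:
    """Per-taxon A,C,G,T counts; gaps and ambiguity codes are excluded."""
    codes = aln.codes()
    data = {
        base: (codes == (1 << i)).sum(axis=1)
        for i, base in enumerate("ACGT")
    }
    df = pd.DataFrame(data, index=aln.taxon_labels)
    df["total"] = df.sum(axis=1)
    return df


def _clade_tips(node: Node) -> list[str]:
    return [n.label for n in Tree(node).tips()]


def paint_regimes(tree_rooted: Tree, shift_edges) -> dict[int, int]:
    """Map ``id(node) -> regime`` for every node.

    ``shift_edges`` is an ordered list of nodes (the child end of each
    shift edge); regime i+1 starts at shift_edges[i].  Descendants take
    the nearest-ancestor shift's regime; everything else is regime 0.
    """
    regime_of = {}
    shift_ids = {id(n): i + 1 for i, n in enumerate(shift_edges)}

    def walk(node: Node, regime: int) -> None:
        if id(node) in shift_ids:
            regime = shift_ids[id(node)]
        regime_of[id(node)] = regime
        for c in node.children:
            walk(c, regime)

    walk(tree_rooted.root, 0)
    return regime_of


def regime_ml_frequencies(
    tree_rooted: Tree, shift_edges, counts: pd.DataFrame
) -> np.ndarray:
    """(n_regimes, 4) pooled-proportion ML frequencies, smoothed when any
    pooled cell is zero."""
    regime_of = paint_regimes(tree_rooted, shift_edges)
    n_regimes = len(shift_edges) + 1
    pooled = np.zeros((n_regimes, 4))
    for tip in tree_rooted.tips():
        if tip.label not in counts.index:
            raise TreeError(f"no counts for tip {tip.label!r}")
        pooled[regime_of[id(tip)]] += counts.loc[tip.label, ["A", "C", "G", "T"]].to_numpy(
            dtype=float
        )
    if (pooled == 0).any():
        pooled = pooled + _SMOOTH
    totals = pooled.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return pooled / totals


def regime_log_likelihood(
    tree_rooted: Tree,
    shift_edges,
    counts: pd.DataFrame,
    frequencies: np.ndarray | None = None,
) -> float:
    """Multinomial lnL of tip base counts under a regime painting."""
    if frequencies is None:
        frequencies = regime_ml_frequencies(tree_rooted, shift_edges, counts)
    regime_of = paint_regimes(tree_rooted, shift_edges)
    lnl = 0.0
    logf = np.log(frequencies)
    for tip in tree_rooted.tips():
        c = counts.loc[tip.label, ["A", "C", "G", "T"]].to_numpy(dtype=float)
        lnl += float(c @ logf[regime_of[id(tip)]])
    return lnl


def candidate_shift_edges(tree_rooted: Tree, min_clade: int = 4) -> list[Node]:
    """Internal edges whose subtended clade has >= min_clade tips.

    The root itself carries no edge and is excluded.
    """
    out = []
    for node in tree_rooted.preorder():
        if node.parent is None or node.is_tip:
            continue
        if len(_clade_tips(node)) >= min_clade:
            out.append(node)
    return out


@dataclass
class ShiftSearchResult:
    shift_edges: list[Node]
    shift_clades: list[frozenset[str]]
    frequencies: np.ndarray
    lnL: float
    k: int
    n: int
    criterion: float
    null_criterion: float
    trace: list[dict] = field(default_factory=list)

    @property
    def n_shifts(self) -> int:
        return len(self.shift_edges)


def greedy_shift_search(
    tree_rooted: Tree,
    aln: NucAlignment,
    min_clade: int = 4,
    criterion: str = "BIC",
    max_shifts: int = 10,
) -> ShiftSearchResult:
    """Greedy forward search for composition-shift edges.

    Starts from the single-regime null; each round adds the candidate
    edge giving the best criterion improvement (k grows by 3 per regime;
    n is the total number of counted bases) and stops when nothing
    improves or ``max_shifts`` is reached.
    """
    if criterion not in ("AIC", "AICc", "BIC"):
        raise ValueError("criterion must be AIC, AICc or BIC")
    counts = tip_base_counts(aln)
    n = int(counts["total"].sum())

    def score(shifts) -> tuple[float, float]:
        lnl = regime_log_likelihood(tree_rooted, shifts, counts)
        k = 3 * (len(shifts) + 1)
        return lnl, getattr(information_criteria(lnl, k, n), criterion)

    shifts: list[Node] = []
    lnl, current = score(shifts)
    null_criterion = current
    trace: list[dict] = []
    candidates = candidate_shift_edges(tree_rooted, min_clade)
    while len(shifts) < max_shifts:
        best = None
        for cand in candidates:
            if any(cand is s for s in shifts):
                continue
            cand_lnl, cand_score = score(shifts + [cand])
            if cand_score < current - 1e-9 and (
                best is None or cand_score < best[1]
            ):
                best = (cand_lnl, cand_score, cand)
        if best is None:
            break
        lnl, current = best[0], best[1]
        shifts.append(best[2])
        trace.append(
            {
                "clade": ",".join(sorted(_clade_tips(best[2]))),
                "criterion": current,
                "lnL": lnl,
            }
        )
    freqs = regime_ml_frequencies(tree_rooted, shifts, counts)
    return ShiftSearchResult(
        shift_edges=shifts,
        shift_clades=[frozenset(_clade_tips(s)) for s in shifts],
        frequencies=freqs,
        lnL=lnl,
        k=3 * (len(shifts) + 1),
        n=n,
        criterion=current,
        null_criterion=null_criterion,
        trace=trace,
    )


def shift_prevalence(
    per_gene_results: dict,
    named_clades: dict,
    gene_taxa: dict,
    tags: dict | None = None,
    display_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-clade fraction of genes whose search found a shift at it.

    A named clade matches a gene's shift when the shift edge subtends
    exactly the clade restricted to the gene's taxa.  ``per_gene_results``
    maps gene -> ShiftSearchResult, ``gene_taxa`` maps gene -> taxon set,
    ``tags`` (optional) maps gene -> dataset tag for per-tag breakdown.
    """
    rows = []
    tag_values = sorted(set(tags.values())) if tags else [None]
    for clade_name, clade_taxa in named_clades.items():
        clade_taxa = frozenset(clade_taxa)
        for tag in tag_values:
            genes = [
                g for g in per_gene_results
                if tags is None or tag is None or tags[g] == tag
            ]
            if not genes:
                continue
            hits = 0
            for g in genes:
                restricted = clade_taxa & frozenset(gene_taxa[g])
                if len(restricted) < 2:
                    continue
                if any(c == restricted for c in per_gene_results[g].shift_clades):
                    hits += 1
            frac = hits / len(genes)
            rows.append(
                {
                    "clade": clade_name,
                    "tag": tag,
                    "n_genes": len(genes),
                    "n_with_shift": hits,
                    "fraction": frac,
                    "display": frac >= display_threshold,
                }
            )
    return pd.DataFrame(rows)
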