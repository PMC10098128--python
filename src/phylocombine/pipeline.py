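"""End-to-end study orchestration: from tagged gene alignments to every
result table (fits, combinability ranking, merging, RF network, conflict,
clock metrics, composition shifts)."""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .alignment import concatenate_supermatrix
from .clock import midpoint_root, root_to_tip_variance
from .compshift import greedy_shift_search
from .conflict import conflict_table, topology_conflict_edges
from .likelihood import GTRParams, nni_search
from .model_select import (
    combinability_rank,
    fit_linked_scheme,
    greedy_merge_partitions,
    cluster_mix_summary,
    starting_tree,
    sum_fit_summaries,
)
from .tree_compare import build_tree_network, fr_layout, rf_matrix

logger = logging.getLogger("phylocombine")

__all__ = ["PipelineConfig", "run_study"]


@dataclass
class PipelineConfig:
    """Knobs of the full pipeline (defaults mirror the analysis design:
    95 percent support threshold, BIC selection, minimum shift clade 4)."""

    support_threshold: float = 95.0
    criterion: str = "BIC"
    min_clade: int = 4
    seed: int = 0
    output_dir: str = "study_out"
    free: frozenset = frozenset({"exchangeabilities", "base_freqs"})
    n_cat: int = 1
    search: bool = True

    def __post_init__(self):
        if not (0.0 <= self.support_threshold <= 100.0):
            raise ValueError("support threshold must be in [0, 100]")


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def run_study(genes, config: PipelineConfig):
    """Run the whole analysis on tagged genes.

    ``genes`` is a list of objects with ``name``, ``tag`` and
    ``alignment`` attributes (e.g. ``simulate.GeneRecord``).  Writes every
    table under ``config.output_dir`` and returns a result dict.
    """
    t_start = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    results: dict = {}
    try:
        tags = sorted({g.tag for g in genes})
        if len(tags) < 2:
            raise ValueError("need at least two dataset tags")
        logger.info("stage=concatenate tags=%s genes=%d", tags, len(genes))
        per_tag = {}
        for tag in tags:
            members = [g for g in genes if g.tag == tag]
            aln, scheme = concatenate_supermatrix(
                [g.alignment for g in members], [g.name for g in members]
            )
            per_tag[tag] = (aln, scheme)
        comb_aln, comb_scheme = concatenate_supermatrix(
            [g.alignment for g in genes], [g.name for g in genes]
        )

        logger.info("stage=fit_schemes")
        params0 = GTRParams(n_cat=config.n_cat)
        fits: dict[str, dict] = {}
        for label, (aln, scheme) in {**per_tag, "comb": (comb_aln, comb_scheme)}.items():
            topo = starting_tree(aln)
            if config.search:
                topo = nni_search(topo, aln, params0)
            chain: dict = {}
            prev = None
            for linking in ("unpartitioned", "edge_equal", "edge_proportional", "edge_unlinked"):
                sdef = scheme if linking != "unpartitioned" else _single_partition(scheme)
                chain[linking] = fit_linked_scheme(
                    aln, sdef, linking, topology=topo, params0=params0,
                    free=config.free, init_from=prev,
                )
                prev = chain[linking]
            fits[label] = chain
        results["fits"] = fits

        logger.info("stage=combinability")
        candidates = [
            (f"comb_{l}", fits["comb"][l]) for l in fits["comb"]
        ]
        separate = [fits[t]["edge_proportional"] for t in tags]
        candidates.append(("separate_trees", sum_fit_summaries(separate)))
        rank = combinability_rank(candidates)
        _write(rank, out / "combinability.tsv")
        results["combinability"] = rank

        logger.info("stage=merge")
        topo_comb = fits["comb"]["edge_proportional"].trees[0]
        merged_scheme, trace = greedy_merge_partitions(
            comb_aln, comb_scheme, topo_comb, criterion=config.criterion,
            params0=params0, free=config.free,
        )
        origin = {g.name: g.tag for g in genes}
        mix = cluster_mix_summary(merged_scheme, origin)
        _write(mix, out / "cluster_mix.tsv")
        _write(trace, out / "merge_trace.tsv")
        results["merged_scheme"] = merged_scheme
        results["cluster_mix"] = mix

        logger.info("stage=rf_network")
        labeled = []
        for label, chain in fits.items():
            for linking, f in chain.items():
                for ti, t in enumerate(f.trees):
                    if linking != "edge_unlinked" or ti == 0:
                        labeled.append((f"{label}-{linking}", t))
                        break
        mat = rf_matrix([t for _, t in labeled])
        rf_df = pd.DataFrame(mat, index=[l for l, _ in labeled],
                             columns=[l for l, _ in labeled])
        rf_df.to_csv(out / "rf_matrix.tsv", sep="\t")
        net = build_tree_network(labeled)
        coords = fr_layout(net, seed=config.seed)
        edge_rows = [
            {"a": ",".join(net.nodes[u]["members"]),
             "b": ",".join(net.nodes[v]["members"]),
             "rf": d["rf"], "weight": d["weight"]}
            for u, v, d in net.edges(data=True)
        ]
        _write(pd.DataFrame(edge_rows, columns=["a", "b", "rf", "weight"]),
               out / "tree_network.tsv")
        results["rf_matrix"] = rf_df
        results["network"] = net
        results["layout"] = coords

        logger.info("stage=gene_trees")
        gene_trees = {}
        for g in genes:
            topo = starting_tree(g.alignment)
            if config.search:
                topo = nni_search(topo, g.alignment, params0)
            gene_trees[g.name] = topo

        logger.info("stage=conflict")
        reference = topo_comb
        ct = conflict_table(
            reference, list(gene_trees.values()), config.support_threshold
        )
        _write(ct, out / "conflict_table.tsv")
        results["conflict_table"] = ct
        edges_ab = topology_conflict_edges(
            fits[tags[0]]["edge_proportional"].trees[0],
            fits[tags[1]]["edge_proportional"].trees[0],
            config.support_threshold,
        )
        results["topology_conflicts"] = edges_ab

        logger.info("stage=root_to_tip")
        rtt_rows = []
        for g in genes:
            tree = gene_trees[g.name]
            rooted = midpoint_root(tree)
            rep = root_to_tip_variance(rooted)
            rtt_rows.append(
                {"gene": g.name, "tag": g.tag, "n_tips": rep.n_tips,
                 "variance": rep.variance}
            )
        rtt = pd.DataFrame(rtt_rows)
        _write(rtt, out / "root_to_tip.tsv")
        results["root_to_tip"] = rtt

        logger.info("stage=comp_shift")
        shift_rows = []
        for g in genes:
            ref_tree = midpoint_root(gene_trees[g.name])
            res = greedy_shift_search(
                ref_tree, g.alignment, min_clade=config.min_clade,
                criterion=config.criterion,
            )
            shift_rows.append(
                {"gene": g.name, "tag": g.tag, "n_tips": ref_tree.n_tips,
                 "n_shifts": res.n_shifts,
                 "shift_clades": ";".join(
                     ",".join(sorted(c)) for c in res.shift_clades
                 ),
                 "lnL": res.lnL, "criterion": res.criterion}
            )
        shifts = pd.DataFrame(shift_rows)
        _write(shifts, out / "composition_shifts.tsv")
        results["composition_shifts"] = shifts

        logger.info("done elapsed=%.1fs", time.time() - t_start)
        return results
    except Exception:
        logger.exception("pipeline stage failed; partial outputs retained")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _single_partition(scheme):
    from .partitions import Partition, PartitionScheme

    total = scheme.n_sites
    return PartitionScheme([Partition("all", [(0, total)])])
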