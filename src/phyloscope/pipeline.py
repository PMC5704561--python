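"""End-to-end orchestration: simulate/load -> cluster -> align -> merge ->
trees -> coherence -> dN/dS -> context classification -> report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import coherence, family_tree, locus_context, selection
from .cluster_align import (
    Alignment,
    Cluster,
    ClusterParams,
    ClusterSet,
    filter_columns,
    greedy_cluster,
    progressive_align,
)
from .errors import InvalidArgumentError, PhyloscopeError, UndefinedCorrelationError
from .family_tree import (
    correct_distances,
    graft,
    iterative_merge,
    midpoint_root,
    nj_tree,
    similarity_to_distance,
    upgma,
    _encode_rows,
    _p_distances,
)
from .sequence_io import GeneFeature, SequenceRecord, read_fasta, read_feature_table
from .synthetic_data import SimulationConfig, simulate, write_outputs
from .tree import PhyloTree, TreeNode

logger = logging.getLogger(__name__)

_CONFIG_KEYS = {
    "seed",
    "simulate",
    "inputs",
    "cluster",
    "rrna_cluster",
    "merge",
    "tree",
    "coherence",
    "dnds",
    "classify",
}


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: Optional[Dict] = None
    inputs: Optional[Dict[str, str]] = None
    cluster: Dict = field(default_factory=lambda: {"identity": 0.5, "coverage": 0.8})
    rrna_cluster: Dict = field(default_factory=lambda: {"identity": 0.9, "coverage": 0.9})
    merge: Dict = field(default_factory=lambda: {"ratio_threshold": 0.1})
    tree: Dict = field(default_factory=lambda: {"bootstrap": 25})
    coherence: Dict = field(
        default_factory=lambda: {"protein_sentinel": 12.0, "rrna_sentinel": 3.0}
    )
    dnds: Dict = field(default_factory=lambda: {"min_identity": 0.5, "max_identity": 0.95})
    classify: Dict = field(default_factory=lambda: {"window_genes": 10})

    @classmethod
    def from_dict(cls, raw: Dict) -> "PipelineConfig":
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls()
        for key, value in raw.items():
            default = getattr(cfg, key)
            if isinstance(default, dict) and isinstance(value, dict):
                merged = dict(default)
                unknown_sub = set(value) - set(default)
                if unknown_sub and key != "simulate":
                    raise InvalidArgumentError(
                        f"unknown keys in config block {key!r}: {sorted(unknown_sub)}"
                    )
                merged.update(value)
                setattr(cfg, key, merged)
            else:
                setattr(cfg, key, value)
        return cfg

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def _tiny_tree(aln: Alignment) -> PhyloTree:
    """Tree for clusters with fewer than 3 members."""
    if aln.n_rows == 1:
        root = TreeNode(name=aln.rows[0].id, length=None)
        tree = PhyloTree(root)
    else:
        codes = _encode_rows(aln)
        model = "nucleotide" if aln.kind in ("cds", "rrna") else "protein"
        d = correct_distances(_p_distances(codes), model)[0, 1]
        root = TreeNode()
        for rec in aln.rows:
            root.add_child(TreeNode(name=rec.id, length=d / 2.0))
        tree = PhyloTree(root)
    tree.leaf_genome = {r.id: r.genome_id for r in aln.rows}
    return tree


def build_family_trees(
    seqs: Sequence[SequenceRecord],
    params: ClusterParams,
    ratio_threshold: float = 0.1,
    bootstrap: int = 25,
    seed: int = 0,
) -> Dict:
    """Cluster, align, merge, and build per-cluster + grafted trees.

    Returns a dict with the final ClusterSet, per-cluster rooted trees,
    the grafted supertree, the UPGMA dendrogram, and the merge log.
    """
    clusters = greedy_cluster(seqs, params)
    for cluster in clusters.clusters:
        cluster.alignment = progressive_align(cluster.members)
    merged, sim, merge_log = iterative_merge(clusters, ratio_threshold)
    trees: Dict[str, PhyloTree] = {}
    for cluster in merged.clusters:
        cluster.alignment = filter_columns(cluster.alignment)
        if not cluster.alignment.column_mask.any():
            # degenerate cluster: fall back to the unfiltered columns
            cluster.alignment = filter_columns(cluster.alignment, 1.0, 0.0)
        if cluster.size >= 3:
            tree = midpoint_root(nj_tree(cluster.alignment, bootstrap=bootstrap, seed=seed))
        else:
            tree = _tiny_tree(cluster.alignment)
        trees[cluster.id] = tree
    if len(merged.clusters) >= 2:
        dist = similarity_to_distance(sim)
        dendrogram = upgma(dist, sim.ids)
        for node in dendrogram.preorder():
            if not node.is_leaf:
                node.support = 0.0  # never-aligned clusters attach with support 0
        supertree = graft(dendrogram, trees)
    else:
        dendrogram = None
        supertree = next(iter(trees.values()))
    input_ids = sorted(s.id for s in seqs)
    output_ids = sorted(supertree.leaf_names())
    if input_ids != output_ids:
        raise PhyloscopeError("grafted tree leaf census mismatch")
    return {
        "clusters": merged,
        "trees": trees,
        "supertree": supertree,
        "dendrogram": dendrogram,
        "merge_log": merge_log,
        "similarity": sim,
        "initial_cluster_count": len(clusters.clusters),
    }


def run_all(config: PipelineConfig, outdir: Optional[str] = None) -> Dict:
    """Run every stage; returns a JSON-serializable report."""
    report: Dict = {"config_digest": config.digest(), "config": config.to_dict()}
    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(
            json.dumps(config.to_dict(), indent=2, sort_keys=True, default=str) + "\n"
        )

    stage = "inputs"
    try:
        if config.simulate is not None:
            sim_kwargs = dict(config.simulate)
            sim_kwargs.setdefault("seed", config.seed)
            if "locus_mix" in sim_kwargs:
                sim_kwargs["locus_mix"] = tuple(sim_kwargs["locus_mix"])
            sim_config = SimulationConfig(**sim_kwargs)
            result = simulate(sim_config)
            if out:
                write_outputs(result, out / "simulated")
            proteins, cds, rrna, features = (
                result.proteins,
                result.cds,
                result.rrna,
                result.features,
            )
            truth = result.ground_truth
        elif config.inputs:
            proteins = read_fasta(config.inputs["proteins"], "protein")
            cds = read_fasta(config.inputs["cds"], "cds") if "cds" in config.inputs else []
            rrna = read_fasta(config.inputs["rrna"], "rrna")
            features = (
                read_feature_table(config.inputs["features"])
                if "features" in config.inputs
                else []
            )
            truth = None
        else:
            raise InvalidArgumentError("config needs either a simulate block or inputs")
        report["inputs"] = {
            "n_proteins": len(proteins),
            "n_cds": len(cds),
            "n_rrna": len(rrna),
            "n_features": len(features),
        }

        stage = "protein_trees"
        prot_build = build_family_trees(
            proteins,
            ClusterParams(config.cluster["identity"], config.cluster["coverage"]),
            ratio_threshold=config.merge["ratio_threshold"],
            bootstrap=config.tree["bootstrap"],
            seed=config.seed,
        )
        report["protein_clusters"] = {
            "initial": prot_build["initial_cluster_count"],
            "final": len(prot_build["clusters"].clusters),
            "merge_log": [
                {"step": e.step, "cluster_i": e.cluster_i, "cluster_j": e.cluster_j,
                 "ratio": round(e.ratio, 6)}
                for e in prot_build["merge_log"]
            ],
        }
        if out:
            from .sequence_io import write_newick

            write_newick(prot_build["supertree"], out / "protein_supertree.nwk")

        stage = "rrna_trees"
        rrna_build = build_family_trees(
            rrna,
            ClusterParams(
                config.rrna_cluster["identity"], config.rrna_cluster["coverage"]
            ),
            ratio_threshold=config.merge["ratio_threshold"],
            bootstrap=0,
            seed=config.seed,
        )
        report["rrna_clusters"] = {
            "initial": rrna_build["initial_cluster_count"],
            "final": len(rrna_build["clusters"].clusters),
        }

        stage = "coherence"
        pair_table = coherence.assemble_pairs(
            list(prot_build["trees"].values()),
            list(rrna_build["trees"].values()),
            protein_sentinel=config.coherence["protein_sentinel"],
            rrna_sentinel=config.coherence["rrna_sentinel"],
        )
        if out:
            coherence.write_pair_table(pair_table, out / "genome_pairs.tsv")
        try:
            rho = coherence.rank_correlation(pair_table)
        except (InvalidArgumentError, UndefinedCorrelationError) as exc:
            rho = None
            report.setdefault("warnings", []).append(f"coherence: {exc}")
        report["coherence"] = {"n_pairs": len(pair_table), "rho": rho}

        stage = "classify"
        family_ids = {p.id for p in proteins}
        classifications = locus_context.classify_all(
            features,
            family_gene_ids=family_ids if truth is not None else None,
            window_genes=config.classify["window_genes"],
        )
        counts: Dict[str, int] = {}
        for cl in classifications:
            counts[cl.category] = counts.get(cl.category, 0) + 1
        report["classification"] = {"counts": counts, "n_genes": len(classifications)}
        if truth is not None and truth.true_labels:
            truth_map = {"cas_operon": "CAS", "solo": "solo", "mge": "MGE"}
            agree = sum(
                1
                for cl in classifications
                if truth_map.get(truth.true_labels.get(cl.gene_id, "")) == cl.category
            )
            report["classification"]["truth_agreement"] = (
                agree / len(classifications) if classifications else None
            )

        stage = "dnds"
        label_map = {
            cl.gene_id: ("CAS" if cl.category == "CAS" else "solo")
            for cl in classifications
            if cl.category in ("CAS", "solo")
        }
        cds_by_id = {rec.id: rec for rec in cds}
        results = []
        if cds:
            for cluster in prot_build["clusters"].clusters:
                if cluster.size < 2:
                    continue
                if not all(r.id in cds_by_id for r in cluster.alignment.rows):
                    continue
                codon_aln = selection.backtranslate(cluster.alignment, cds)
                pairs = selection.select_pairs(
                    cluster.alignment,
                    config.dnds["min_identity"],
                    config.dnds["max_identity"],
                )
                for i, j in pairs:
                    results.append(
                        selection.ng86_pair(codon_aln.rows[i], codon_aln.rows[j])
                    )
        medians = selection.group_medians(results, label_map)
        report["dnds"] = {"n_pairs": len(results), "group_medians": medians}
        if out and results:
            selection.results_table(results).to_csv(out / "dnds.tsv", sep="\t", index=False)
    except PhyloscopeError:
        if out:
            (out / "FAILED_STAGE").write_text(stage + "\n")
        raise
    if out:
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=str) + "\n"
        )
    return report
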