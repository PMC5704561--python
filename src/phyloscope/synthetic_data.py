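"""Ground-truth simulator: species trees, gene families with transfer/
duplication/loss, codon sequences under selection, slow-evolving rRNA-like
markers, and annotated genome feature tables.

Every stage draws from a labeled substream of the master seed, so outputs
are byte-reproducible and adding a stage does not perturb the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import expm  # noqa: F401  (kept for callers wanting exact P(t))

from ._codon import CODON_TO_AA, NUCLEOTIDES, SENSE_CODONS, is_transition, translate
from ._rng import substream
from .errors import EmptyFamilyError, InvalidArgumentError
from .sequence_io import GeneFeature, SequenceRecord
from .tree import PhyloTree, TreeNode

LOCUS_CATEGORIES = ("cas_operon", "solo", "mge")


@dataclass(frozen=True)
class SimulationConfig:
    n_genomes: int = 20
    birth_rate: float = 1.0
    hgt_rate: float = 0.0
    dup_rate: float = 0.0
    loss_rate: float = 0.0
    omega: float = 0.1
    kappa: float = 2.0
    seq_len_codons: int = 150
    rrna_len: int = 800
    locus_mix: Tuple[float, float, float] = (0.5, 0.3, 0.2)
    seed: int = 0
    #: species tree is rescaled to this height (substitutions per codon site
    #: on the protein side); None keeps raw Yule branch lengths
    tree_height: Optional[float] = 1.0
    rrna_rate: float = 0.1
    #: sigma of the lognormal lineage-specific rate multipliers (mean 1);
    #: shared between the protein and rRNA markers of a lineage, 0 = strict
    #: molecular clock
    rate_var: float = 0.5

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise InvalidArgumentError("n_genomes must be >= 2")
        for name in ("birth_rate", "hgt_rate", "dup_rate", "loss_rate", "omega", "kappa"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if self.seq_len_codons < 1 or self.rrna_len < 1:
            raise InvalidArgumentError("sequence lengths must be positive")
        if self.rate_var < 0:
            raise InvalidArgumentError("rate_var must be >= 0")
        mix = self.locus_mix
        if len(mix) != 3 or any(not (0.0 <= m <= 1.0) for m in mix):
            raise InvalidArgumentError("locus_mix must be three fractions in [0,1]")
        if abs(sum(mix) - 1.0) > 1e-9:
            raise InvalidArgumentError("locus_mix must sum to 1")


@dataclass(frozen=True)
class TransferEvent:
    donor: str
    recipient: str
    time: float


@dataclass
class GroundTruth:
    species_tree: PhyloTree
    gene_trees: List[PhyloTree]
    transfer_events: List[TransferEvent]
    true_labels: Dict[str, str] = field(default_factory=dict)
    true_omega: Optional[float] = None


# ------------------------------------------------------------- species tree
def simulate_species_tree(n_genomes: int, birth_rate: float = 1.0, seed: int = 0) -> PhyloTree:
    """Ultrametric Yule (pure-birth) tree with ``n_genomes`` leaves."""
    if n_genomes < 2:
        raise InvalidArgumentError("n_genomes must be >= 2")
    if birth_rate <= 0:
        raise InvalidArgumentError("birth_rate must be > 0")
    rng = substream(seed, "species_tree")
    root = TreeNode()
    birth: Dict[int, float] = {}
    active: List[TreeNode] = []
    t = 0.0
    for _ in range(2):
        child = TreeNode()
        root.add_child(child)
        birth[id(child)] = 0.0
        active.append(child)
    while len(active) < n_genomes:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        node = active.pop(int(rng.integers(len(active))))
        node.length = t - birth[id(node)]
        for _ in range(2):
            child = TreeNode()
            node.add_child(child)
            birth[id(child)] = t
            active.append(child)
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for node in active:
        node.length = t - birth[id(node)]
    tree = PhyloTree(root, rooted=True)
    width = max(4, len(str(n_genomes)))
    for k, leaf in enumerate(tree.leaves()):
        leaf.name = f"G{k + 1:0{width}d}"
    tree.leaf_genome = {name: name for name in tree.leaf_names()}
    return tree


# --------------------------------------------------------------- gene family
def _edges_alive_at(tree: PhyloTree, t: float):
    depths = tree.depths()
    out = []
    for node in tree.preorder():
        if node is tree.root:
            continue
        top = depths[node.parent]
        bottom = depths[node]
        if top < t < bottom:
            out.append((node, top, bottom))
    # deterministic order: by smallest descendant leaf name
    def min_leaf(node: TreeNode) -> str:
        stack, best = [node], None
        while stack:
            cur = stack.pop()
            if cur.is_leaf:
                if best is None or (cur.name or "") < best:
                    best = cur.name or ""
            else:
                stack.extend(cur.children)
        return best or ""

    out.sort(key=lambda item: min_leaf(item[0]))
    return out, depths


def _spr_transfer(tree: PhyloTree, recipient: TreeNode, donor: TreeNode, t: float,
                  depths: Dict[TreeNode, float]) -> None:
    """Reattach the subtree below ``recipient`` as sister to ``donor`` at
    time ``t`` (replacement transfer)."""
    old_parent = recipient.parent
    old_parent.remove_child(recipient)
    donor_parent = donor.parent
    attach = TreeNode(length=t - depths[donor_parent], rate=donor.rate)
    donor_parent.remove_child(donor)
    donor_parent.add_child(attach)
    donor.length = depths[donor] - t
    attach.add_child(donor)
    recipient.length = depths[recipient] - t
    attach.add_child(recipient)
    tree.suppress_unifurcations()


def _min_leaf_name(node: TreeNode) -> str:
    stack, best = [node], None
    while stack:
        cur = stack.pop()
        if cur.is_leaf:
            if best is None or (cur.name or "") < best:
                best = cur.name or ""
        else:
            stack.extend(cur.children)
    return best or ""


def evolve_gene_family(
    species_tree: PhyloTree,
    hgt_rate: float = 0.0,
    dup_rate: float = 0.0,
    loss_rate: float = 0.0,
    seed: int = 0,
) -> GroundTruth:
    """Evolve a gene family on the species tree by transfer, duplication and
    loss.

    The expected number of transfers is ``hgt_rate`` per gene lineage per
    unit tree height, i.e. ``hgt_rate * total_branch_length / height`` in
    total. Each transfer prunes a random contemporaneous recipient lineage
    and regrafts it as sister to a random donor lineage at the transfer time.
    Duplication and loss are per-branch Bernoulli events.
    """
    gene_tree = species_tree.copy()
    gene_tree.leaf_genome = {name: name for name in gene_tree.leaf_names()}
    rng = substream(seed, "gene_family")
    events: List[TransferEvent] = []

    height = gene_tree.height()
    if hgt_rate > 0 and height > 0:
        # sample event times uniformly on total branch length of the original
        # tree (lineage-through-time is invariant under the SPR moves)
        depths = gene_tree.depths()
        edges = [
            (depths[n.parent], depths[n])
            for n in gene_tree.preorder()
            if n is not gene_tree.root
        ]
        total = sum(b - a for a, b in edges)
        n_events = rng.poisson(hgt_rate * total / height)
        times = []
        for _ in range(n_events):
            u = rng.uniform(0.0, total)
            for top, bottom in edges:
                span = bottom - top
                if u <= span:
                    times.append(top + u)
                    break
                u -= span
        for t in sorted(times):
            alive, depths_now = _edges_alive_at(gene_tree, t)
            if len(alive) < 2:
                continue
            ridx = int(rng.integers(len(alive)))
            recipient = alive[ridx][0]
            rest = [item for k, item in enumerate(alive) if k != ridx]
            donor = rest[int(rng.integers(len(rest)))][0]
            events.append(
                TransferEvent(
                    donor=_min_leaf_name(donor),
                    recipient=_min_leaf_name(recipient),
                    time=float(t),
                )
            )
            _spr_transfer(gene_tree, recipient, donor, t, depths_now)

    # duplications and losses: one pass over the original branches (copies
    # introduced by a duplication are not revisited)
    if dup_rate > 0 or loss_rate > 0:
        original = [n for n in gene_tree.preorder() if n is not gene_tree.root]
        lost: set = set()
        for node in original:
            anc = node.parent
            skip = False
            while anc is not None:
                if id(anc) in lost:
                    skip = True
                    break
                anc = anc.parent
            if skip or id(node) in lost:
                continue
            u = rng.uniform()
            if u < loss_rate:
                lost.add(id(node))
                node.parent.remove_child(node)
            elif u < loss_rate + dup_rate:
                parent = node.parent
                parent.remove_child(node)
                mid = TreeNode(length=0.0)
                parent.add_child(mid)
                copy_root = _copy_subtree(node)
                mid.add_child(node)
                mid.add_child(copy_root)
        gene_tree.suppress_unifurcations()

    leaves = gene_tree.leaves()
    if not leaves or (len(leaves) == 1 and gene_tree.root in leaves):
        raise EmptyFamilyError("every gene lineage was lost")

    # rename leaves to unique per-genome copy ids
    counter: Dict[str, int] = {}
    leaf_genome: Dict[str, str] = {}
    for leaf in leaves:
        genome = leaf.name or ""
        counter[genome] = counter.get(genome, 0) + 1
        leaf.name = f"{genome}|c{counter[genome]}"
        leaf_genome[leaf.name] = genome
    gene_tree.leaf_genome = leaf_genome
    return GroundTruth(
        species_tree=species_tree,
        gene_trees=[gene_tree],
        transfer_events=events,
    )


def _copy_subtree(node: TreeNode) -> TreeNode:
    dup = TreeNode(node.name, node.length, node.support, node.rate)
    for child in node.children:
        dup.add_child(_copy_subtree(child))
    return dup


# ------------------------------------------------------------ codon evolution
def _mg94_probability_factory(omega: float, kappa: float):
    """Eigendecomposition of the (symmetric, uniform-frequency) MG94/HKY
    codon rate matrix, scaled to one expected substitution per codon site
    per unit time; returns P(t)."""
    n = len(SENSE_CODONS)
    q = np.zeros((n, n))
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [k for k in range(3) if ci[k] != cj[k]]
            if len(diff) != 1:
                continue
            k = diff[0]
            rate = kappa if is_transition(ci[k], cj[k]) else 1.0
            if CODON_TO_AA[ci] != CODON_TO_AA[cj]:
                rate *= omega
            q[i, j] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -np.mean(np.diag(q))
    if mean_rate > 0:
        q /= mean_rate
    eigvals, eigvecs = np.linalg.eigh(q)

    def p_matrix(t: float) -> np.ndarray:
        p = (eigvecs * np.exp(eigvals * t)) @ eigvecs.T
        p = np.clip(p, 0.0, None)
        p /= p.sum(axis=1, keepdims=True)
        return p

    return p_matrix


def simulate_codon_sequences(
    gene_tree: PhyloTree,
    omega: float,
    kappa: float = 2.0,
    seq_len_codons: int = 150,
    seed: int = 0,
) -> Tuple[List[SequenceRecord], List[SequenceRecord]]:
    """Evolve codon sequences down the gene tree under MG94/HKY.

    Returns (CDS records, translated protein records), one per leaf. Stop
    codons are never produced; with ``omega == 0`` proteins are invariant.
    """
    if omega < 0:
        raise InvalidArgumentError("omega must be >= 0")
    if seq_len_codons < 1:
        raise InvalidArgumentError("seq_len_codons must be >= 1")
    rng = substream(seed, "codon_seq")
    p_matrix = _mg94_probability_factory(omega, kappa)
    n_codons = len(SENSE_CODONS)
    root_state = rng.integers(0, n_codons, size=seq_len_codons)
    states: Dict[int, np.ndarray] = {id(gene_tree.root): root_state}
    p_cache: Dict[float, np.ndarray] = {}
    for node in gene_tree.preorder():
        if node is gene_tree.root:
            continue
        t = (node.length or 0.0) * node.rate
        parent_state = states[id(node.parent)]
        if t <= 0:
            states[id(node)] = parent_state.copy()
            continue
        if t not in p_cache:
            p_cache[t] = p_matrix(t)
        p = p_cache[t]
        child = np.empty_like(parent_state)
        for codon in np.unique(parent_state):
            mask = parent_state == codon
            child[mask] = rng.choice(n_codons, size=int(mask.sum()), p=p[codon])
        states[id(node)] = child
    cds_records: List[SequenceRecord] = []
    protein_records: List[SequenceRecord] = []
    for leaf in gene_tree.leaves():
        codons = states[id(leaf)]
        cds = "".join(SENSE_CODONS[c] for c in codons)
        genome = gene_tree.leaf_genome.get(leaf.name or "", (leaf.name or "").split("|")[0])
        cds_records.append(SequenceRecord(leaf.name or "", genome, cds, "cds"))
        protein_records.append(SequenceRecord(leaf.name or "", genome, translate(cds), "protein"))
    return cds_records, protein_records


def simulate_rrna(
    species_tree: PhyloTree,
    rrna_len: int = 800,
    seed: int = 0,
    rate_multiplier: float = 0.1,
) -> List[SequenceRecord]:
    """Evolve one slow Jukes-Cantor marker per genome on the species tree."""
    if rrna_len < 1:
        raise InvalidArgumentError("rrna_len must be >= 1")
    rng = substream(seed, "rrna")
    nts = np.array(list(NUCLEOTIDES))
    states: Dict[int, np.ndarray] = {
        id(species_tree.root): rng.integers(0, 4, size=rrna_len)
    }
    for node in species_tree.preorder():
        if node is species_tree.root:
            continue
        t = (node.length or 0.0) * node.rate * rate_multiplier
        parent_state = states[id(node.parent)]
        p_change = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
        child = parent_state.copy()
        hit = rng.random(rrna_len) < p_change
        if hit.any():
            # substitute with one of the three other nucleotides
            shift = rng.integers(1, 4, size=int(hit.sum()))
            child[hit] = (child[hit] + shift) % 4
        states[id(node)] = child
    out = []
    for leaf in species_tree.leaves():
        seq = "".join(nts[states[id(leaf)]])
        genome = leaf.name or ""
        out.append(SequenceRecord(f"{genome}_16S", genome, seq, "rrna"))
    return out


# ------------------------------------------------------------- genome tables
_OPERON_PATTERNS = (
    ("cas4-cas1-cas2", ["cas4*", "cas1", "cas2"]),
    ("cas4/cas1-cas2", ["fusion*", "cas2"]),
    ("cas4-cas1-cas2-cas6", ["cas4*", "cas1", "cas2", "cas6"]),
    ("two-cas4", ["cas4*", "cas4+", "cas1", "cas2"]),
)
_EFFECTOR_SUBTYPES = ("I-A", "I-B", "I-C", "I-D", "II-B", "V-A")
_GENE_LEN = 900
_GENE_GAP = 100


def emit_genome_tables(
    ground_truth: GroundTruth,
    locus_mix: Sequence[float] = (0.5, 0.3, 0.2),
    seed: int = 0,
) -> Tuple[List[GeneFeature], Dict[str, str]]:
    """Place every gene copy on a synthetic contig according to ``locus_mix``.

    cas_operon placements embed the gene in an adaptation-module arrangement
    (optionally with effector genes and a CRISPR array); mge placements put
    it on a viral or plasmid contig flanked by mobile-element markers; solo
    placements surround it with unannotated genes. Fills and returns
    ``ground_truth.true_labels``.
    """
    if abs(sum(locus_mix) - 1.0) > 1e-9 or len(locus_mix) != 3:
        raise InvalidArgumentError("locus_mix must be three fractions summing to 1")
    rng = substream(seed, "locus")
    gene_tree = ground_truth.gene_trees[0]
    features: List[GeneFeature] = []
    labels: Dict[str, str] = {}
    contig_count: Dict[str, int] = {}
    gene_ids = sorted(gene_tree.leaf_names())
    genomes_with_genes = set()
    for gene_id in gene_ids:
        genome = gene_tree.leaf_genome.get(gene_id, gene_id.split("|")[0])
        genomes_with_genes.add(genome)
        contig_count[genome] = contig_count.get(genome, 0) + 1
        contig = f"{genome}_ctg{contig_count[genome]}"
        category = LOCUS_CATEGORIES[int(rng.choice(3, p=list(locus_mix)))]
        labels[gene_id] = category
        if category == "cas_operon":
            name, pattern = _OPERON_PATTERNS[int(rng.integers(len(_OPERON_PATTERNS)))]
            annotations = ["other", "other"] + list(pattern)
            if rng.random() < 0.5:
                subtype = _EFFECTOR_SUBTYPES[int(rng.integers(len(_EFFECTOR_SUBTYPES)))]
                annotations += [f"effector_{subtype}", "crispr_array"]
            annotations += ["other", "other"]
            replicon = "chromosome"
            strands = ["+"] * len(annotations)
        elif category == "solo":
            annotations = ["other", "other", "other", "cas4*", "other", "other", "other"]
            replicon = "chromosome"
            strands = ["+" if rng.random() < 0.5 else "-" for _ in annotations]
        else:
            annotations = ["mge_marker", "other", "cas4*", "other", "mge_marker"]
            replicon = "viral" if rng.random() < 0.5 else "plasmid"
            strands = ["+" if rng.random() < 0.5 else "-" for _ in annotations]
        pos = 1
        aux = 0
        for annotation, strand in zip(annotations, strands):
            start, end = pos, pos + _GENE_LEN - 1
            pos = end + _GENE_GAP + 1
            if annotation.endswith("*"):
                feat_gene_id = gene_id
                feat_annotation = "cas4/cas1_fusion" if annotation.startswith("fusion") else "cas4"
                strand = "+" if category == "cas_operon" else strand
            else:
                aux += 1
                feat_gene_id = f"{contig}_g{aux}"
                feat_annotation = "cas4" if annotation == "cas4+" else annotation
            features.append(
                GeneFeature(
                    genome_id=genome,
                    contig_id=contig,
                    gene_id=feat_gene_id,
                    start=start,
                    end=end,
                    strand=strand,
                    annotation=feat_annotation,
                    replicon_class=replicon,
                )
            )
    # genomes with no surviving family copy still get a background contig
    for genome in sorted(ground_truth.species_tree.leaf_names()):
        if genome in genomes_with_genes:
            continue
        contig = f"{genome}_ctg1"
        pos = 1
        for k in range(3):
            features.append(
                GeneFeature(
                    genome_id=genome,
                    contig_id=contig,
                    gene_id=f"{contig}_g{k + 1}",
                    start=pos,
                    end=pos + _GENE_LEN - 1,
                    strand="+",
                    annotation="other",
                    replicon_class="chromosome",
                )
            )
            pos += _GENE_LEN + _GENE_GAP
    ground_truth.true_labels = labels
    return features, labels


def assign_lineage_rates(tree: PhyloTree, sigma: float, seed: int = 0) -> PhyloTree:
    """Draw a lognormal (mean-1) rate multiplier per branch.

    Rates model lineage effects shared by all markers of a genome: the
    sequence simulators multiply each branch's duration by its rate, so a
    fast lineage is fast for both the protein and the rRNA marker. Branch
    order is deterministic (preorder).
    """
    rng = substream(seed, "lineage_rates")
    for node in tree.preorder():
        if node is tree.root:
            continue
        node.rate = float(rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma))
    return tree


# -------------------------------------------------------------- orchestrator
@dataclass
class SimulationResult:
    config: SimulationConfig
    ground_truth: GroundTruth
    proteins: List[SequenceRecord]
    cds: List[SequenceRecord]
    rrna: List[SequenceRecord]
    features: List[GeneFeature]

    @property
    def genomes(self) -> List[str]:
        return self.ground_truth.species_tree.leaf_names()


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the full generator: tree, family, sequences, markers, tables."""
    species = simulate_species_tree(config.n_genomes, config.birth_rate, config.seed)
    if config.tree_height is not None and species.height() > 0:
        species.scale(config.tree_height / species.height())
    if config.rate_var > 0:
        assign_lineage_rates(species, config.rate_var, config.seed)
    truth = evolve_gene_family(
        species, config.hgt_rate, config.dup_rate, config.loss_rate, config.seed
    )
    truth.true_omega = config.omega
    cds, proteins = simulate_codon_sequences(
        truth.gene_trees[0], config.omega, config.kappa, config.seq_len_codons, config.seed
    )
    rrna = simulate_rrna(species, config.rrna_len, config.seed, config.rrna_rate)
    features, _ = emit_genome_tables(truth, config.locus_mix, config.seed)
    return SimulationResult(
        config=config,
        ground_truth=truth,
        proteins=proteins,
        cds=cds,
        rrna=rrna,
        features=features,
    )


def write_outputs(result: SimulationResult, outdir) -> Dict[str, str]:
    """Write FASTA/TSV/Newick/JSON artifacts; returns a name->path map."""
    from .sequence_io import write_fasta, write_feature_table, write_newick

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteins": outdir / "proteins.faa",
        "cds": outdir / "cds.fna",
        "rrna": outdir / "rrna.fna",
        "features": outdir / "features.tsv",
        "species_tree": outdir / "species_tree.nwk",
        "gene_tree": outdir / "gene_tree.nwk",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_fasta(result.proteins, paths["proteins"])
    write_fasta(result.cds, paths["cds"])
    write_fasta(result.rrna, paths["rrna"])
    write_feature_table(result.features, paths["features"])
    write_newick(result.ground_truth.species_tree, paths["species_tree"])
    write_newick(result.ground_truth.gene_trees[0], paths["gene_tree"])
    truth = result.ground_truth
    payload = {
        "true_labels": truth.true_labels,
        "true_omega": truth.true_omega,
        "transfer_events": [
            {"donor": e.donor, "recipient": e.recipient, "time": e.time}
            for e in truth.transfer_events
        ],
        "n_genomes": result.config.n_genomes,
        "seed": result.config.seed,
    }
    paths["ground_truth"].write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return {k: str(v) for k, v in paths.items()}
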