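"""Genomic-context classification of family genes.

Each gene is assigned to exactly one of three categories from its gene
neighborhood: CAS (adaptation/effector/CRISPR features nearby, or a
cas4/cas1 fusion), MGE (mobile replicon or mobile-element markers), or solo
(neither). Also detects the common adaptation-module arrangements and
produces genome-weighted presence summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .errors import InvalidArgumentError
from .sequence_io import EFFECTOR_PREFIX, GeneFeature

FUSION_LABEL = "cas4/cas1_fusion"
CAS_NEIGHBOR_LABELS = frozenset({"cas1", "cas2", "cas6", "crispr_array", FUSION_LABEL})
MGE_REPLICONS = frozenset({"viral", "plasmid"})

ARRANGEMENTS = (
    "cas4-cas1-cas2-cas6",
    "cas4-cas1-cas2",
    "cas4/cas1-cas2",
    "two-cas4",
    "none",
)

CATEGORIES = ("CAS", "solo", "MGE")


def _is_cas_evidence(annotation: str) -> bool:
    return annotation in CAS_NEIGHBOR_LABELS or annotation.startswith(EFFECTOR_PREFIX)


@dataclass(frozen=True)
class LocusClassification:
    gene_id: str
    category: str
    arrangement: str
    standalone_adaptation_module: bool
    evidence: Tuple[str, ...]
    genome_id: str = ""


def fusion_detect(gene: GeneFeature) -> bool:
    """True iff the gene itself carries the cas4/cas1 fusion annotation."""
    return gene.annotation == FUSION_LABEL


def _arrangement(sorted_feats: Sequence[GeneFeature], idx: int) -> str:
    """Match the adaptation-module arrangement around position ``idx``.

    Looks at the maximal contiguous run of adaptation-relevant annotations
    containing the gene and compares it (forward or reversed) with the known
    patterns.
    """
    relevant = {"cas4", "cas1", "cas2", "cas6", FUSION_LABEL}
    lo = idx
    while lo > 0 and sorted_feats[lo - 1].annotation in relevant:
        lo -= 1
    hi = idx
    while hi + 1 < len(sorted_feats) and sorted_feats[hi + 1].annotation in relevant:
        hi += 1
    block = [f.annotation for f in sorted_feats[lo : hi + 1]]
    for labels in (block, list(reversed(block))):
        if labels[:4] == ["cas4", "cas1", "cas2", "cas6"]:
            return "cas4-cas1-cas2-cas6"
        if labels[:4] == ["cas4", "cas4", "cas1", "cas2"]:
            return "two-cas4"
        if labels[:3] == ["cas4", "cas1", "cas2"]:
            return "cas4-cas1-cas2"
        if labels[:2] == [FUSION_LABEL, "cas2"]:
            return "cas4/cas1-cas2"
    return "none"


def classify(
    gene: GeneFeature,
    neighborhood: Sequence[GeneFeature],
    window_genes: int = 10,
) -> LocusClassification:
    """Classify one family gene from its contig neighborhood.

    Precedence: fusion with cas1 forces CAS; otherwise CAS if any cas/effector
    /CRISPR feature lies within ``window_genes`` positions on the contig; else
    MGE if the replicon is mobile or an mge_marker is within the window; else
    solo.
    """
    contig_feats = sorted(
        (f for f in neighborhood if f.contig_id == gene.contig_id),
        key=lambda f: (f.start, f.gene_id),
    )
    idx = next((k for k, f in enumerate(contig_feats) if f.gene_id == gene.gene_id), None)
    if idx is None:
        raise InvalidArgumentError(f"gene {gene.gene_id!r} not in its neighborhood list")
    window = [
        f
        for k, f in enumerate(contig_feats)
        if k != idx and abs(k - idx) <= window_genes
    ]
    cas_evidence = [f.annotation for f in window if _is_cas_evidence(f.annotation)]
    mge_evidence = [f.annotation for f in window if f.annotation == "mge_marker"]

    fused = fusion_detect(gene)
    if fused or cas_evidence:
        category = "CAS"
        evidence = tuple(["fusion"] if fused else []) + tuple(cas_evidence)
    elif gene.replicon_class in MGE_REPLICONS or mge_evidence:
        category = "MGE"
        evidence = (
            tuple([f"replicon:{gene.replicon_class}"] if gene.replicon_class in MGE_REPLICONS else [])
            + tuple(mge_evidence)
        )
    else:
        category = "solo"
        evidence = ()

    arrangement = _arrangement(contig_feats, idx) if category == "CAS" else "none"
    has_cas1 = fused or any(f.annotation in ("cas1", FUSION_LABEL) for f in window)
    has_cas2 = any(f.annotation == "cas2" for f in window)
    has_effector = any(f.annotation.startswith(EFFECTOR_PREFIX) for f in window)
    standalone = category == "CAS" and has_cas1 and has_cas2 and not has_effector
    return LocusClassification(
        gene_id=gene.gene_id,
        category=category,
        arrangement=arrangement,
        standalone_adaptation_module=standalone,
        evidence=evidence,
        genome_id=gene.genome_id,
    )


def classify_all(
    features: Sequence[GeneFeature],
    family_annotations: Iterable[str] = ("cas4", FUSION_LABEL),
    family_gene_ids: Optional[Set[str]] = None,
    window_genes: int = 10,
) -> List[LocusClassification]:
    """Classify every family gene in a feature table."""
    fam = set(family_annotations)
    by_contig: Dict[Tuple[str, str], List[GeneFeature]] = {}
    for f in features:
        by_contig.setdefault((f.genome_id, f.contig_id), []).append(f)
    out = []
    for f in features:
        if family_gene_ids is not None:
            if f.gene_id not in family_gene_ids:
                continue
        elif f.annotation not in fam:
            continue
        out.append(classify(f, by_contig[(f.genome_id, f.contig_id)], window_genes))
    return out


# --------------------------------------------------------- weighted summaries
@dataclass
class GenomeWeightTable:
    """Per-genome weights, inversely proportional to genomes per species."""

    weights: Dict[str, float]
    species: Dict[str, str]

    @classmethod
    def from_species_map(cls, species: Mapping[str, str]) -> "GenomeWeightTable":
        counts: Dict[str, int] = {}
        for sp in species.values():
            counts[sp] = counts.get(sp, 0) + 1
        weights = {g: 1.0 / counts[sp] for g, sp in species.items()}
        return cls(weights=weights, species=dict(species))


PRESENCE_CATEGORIES = ("cas_only", "solo_only", "both", "neither")


def presence_summary(
    classifications: Sequence[LocusClassification],
    weights: GenomeWeightTable,
    domains: Mapping[str, str],
    all_genomes: Optional[Sequence[str]] = None,
) -> Dict[str, Dict[str, float]]:
    """Weighted fractions of genomes with CAS only / solo only / both /
    neither, per domain (e.g. archaea vs bacteria).

    ``all_genomes`` lists every screened genome (so genomes without any
    family gene count as "neither"); defaults to the weight table's genomes.
    """
    genomes = list(all_genomes) if all_genomes is not None else sorted(weights.weights)
    has_cas: Dict[str, bool] = {g: False for g in genomes}
    has_solo: Dict[str, bool] = {g: False for g in genomes}
    for cl in classifications:
        if cl.genome_id not in has_cas:
            continue
        if cl.category == "CAS":
            has_cas[cl.genome_id] = True
        elif cl.category == "solo":
            has_solo[cl.genome_id] = True
    totals: Dict[str, float] = {}
    acc: Dict[str, Dict[str, float]] = {}
    for g in genomes:
        if g not in weights.weights:
            raise InvalidArgumentError(f"genome {g!r} has no weight")
        if g not in domains:
            raise InvalidArgumentError(f"genome {g!r} has no domain label")
        dom = domains[g]
        w = weights.weights[g]
        if has_cas[g] and has_solo[g]:
            cat = "both"
        elif has_cas[g]:
            cat = "cas_only"
        elif has_solo[g]:
            cat = "solo_only"
        else:
            cat = "neither"
        acc.setdefault(dom, {c: 0.0 for c in PRESENCE_CATEGORIES})[cat] += w
        totals[dom] = totals.get(dom, 0.0) + w
    return {
        dom: {c: v / totals[dom] for c, v in cats.items()} for dom, cats in acc.items()
    }


def one_per_species_counts(
    classifications: Sequence[LocusClassification],
    species: Mapping[str, str],
) -> Dict[str, int]:
    """Category counts with each species contributing at most one genome.

    The representative genome per (category, species) is the
    lexicographically smallest genome id carrying that category.
    """
    reps: Dict[Tuple[str, str], str] = {}
    for cl in sorted(classifications, key=lambda c: c.genome_id):
        sp = species.get(cl.genome_id)
        if sp is None:
            raise InvalidArgumentError(f"genome {cl.genome_id!r} has no species")
        key = (cl.category, sp)
        if key not in reps:
            reps[key] = cl.genome_id
    counts: Dict[str, int] = {}
    for (category, _sp), _genome in reps.items():
        counts[category] = counts.get(category, 0) + 1
    return counts
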