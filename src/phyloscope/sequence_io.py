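"""Readers and writers for FASTA, Newick, and gene feature tables.

Validation is strict: malformed records raise :class:`FormatError` rather
than being silently repaired. The one sanctioned repair is mapping unknown
feature annotations to ``"other"`` with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .errors import FormatError
from .tree import PhyloTree

logger = logging.getLogger(__name__)

SEQUENCE_KINDS = ("protein", "cds", "rrna")

#: Controlled annotation vocabulary for gene features. Effector-module genes
#: use subtype-qualified labels such as ``effector_I-B`` and are matched by
#: prefix.
CONTROLLED_ANNOTATIONS = frozenset(
    {"cas1", "cas2", "cas4", "cas4/cas1_fusion", "cas6", "crispr_array", "mge_marker", "other"}
)
EFFECTOR_PREFIX = "effector_"
REPLICON_CLASSES = frozenset({"chromosome", "plasmid", "viral", "unknown"})

FEATURE_COLUMNS = [
    "genome_id",
    "contig_id",
    "gene_id",
    "start",
    "end",
    "strand",
    "annotation",
    "replicon_class",
]


def is_valid_annotation(label: str) -> bool:
    return label in CONTROLLED_ANNOTATIONS or label.startswith(EFFECTOR_PREFIX)


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence with its genome of origin."""

    id: str
    genome_id: str
    residues: str
    kind: str = "protein"

    def __post_init__(self) -> None:
        if not self.residues:
            raise FormatError(f"record {self.id!r}: empty sequence")
        if self.kind not in SEQUENCE_KINDS:
            raise FormatError(f"record {self.id!r}: unknown kind {self.kind!r}")
        if self.kind == "cds" and len(self.residues) % 3 != 0:
            raise FormatError(
                f"record {self.id!r}: CDS length {len(self.residues)} not divisible by 3"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass(frozen=True)
class GeneFeature:
    """A located, annotated gene; coordinates are 1-based inclusive."""

    genome_id: str
    contig_id: str
    gene_id: str
    start: int
    end: int
    strand: str
    annotation: str
    replicon_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"feature {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise FormatError(f"feature {self.gene_id!r}: coordinates are 1-based")
        if self.strand not in ("+", "-"):
            raise FormatError(f"feature {self.gene_id!r}: bad strand {self.strand!r}")
        if self.replicon_class not in REPLICON_CLASSES:
            raise FormatError(
                f"feature {self.gene_id!r}: bad replicon_class {self.replicon_class!r}"
            )


# --------------------------------------------------------------------- FASTA
def read_fasta(path: Union[str, Path], kind: str = "protein") -> List[SequenceRecord]:
    """Read FASTA; headers look like ``>id genome=<genome_id>``."""
    records: List[SequenceRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        genome = ""
        for token in rec.description.split()[1:]:
            if token.startswith("genome="):
                genome = token[len("genome="):]
        records.append(SequenceRecord(rec.id, genome, str(rec.seq), kind))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: Union[str, Path]) -> None:
    bio = []
    for rec in records:
        desc = f"genome={rec.genome_id}" if rec.genome_id else ""
        bio.append(BioSeqRecord(Seq(rec.residues), id=rec.id, description=desc))
    with open(path, "w") as handle:
        SeqIO.write(bio, handle, "fasta")


# -------------------------------------------------------------------- Newick
def read_newick(path: Union[str, Path]) -> PhyloTree:
    text = Path(path).read_text()
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree, path: Union[str, Path]) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ------------------------------------------------------------ feature tables
def read_feature_table(path: Union[str, Path]) -> List[GeneFeature]:
    """Read the tab-separated feature table; unknown annotations map to "other"."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse feature table: {exc}") from exc
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    features: List[GeneFeature] = []
    for row in df.itertuples(index=False):
        annotation = row.annotation
        if not is_valid_annotation(annotation):
            logger.warning(
                "feature %s: unknown annotation %r mapped to 'other'",
                row.gene_id,
                annotation,
            )
            annotation = "other"
        try:
            start, end = int(row.start), int(row.end)
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer coordinates for {row.gene_id!r}") from exc
        features.append(
            GeneFeature(
                genome_id=row.genome_id,
                contig_id=row.contig_id,
                gene_id=row.gene_id,
                start=start,
                end=end,
                strand=row.strand,
                annotation=annotation,
                replicon_class=row.replicon_class,
            )
        )
    return features


def write_feature_table(features: Sequence[GeneFeature], path: Union[str, Path]) -> None:
    df = pd.DataFrame([[getattr(f, c) for c in FEATURE_COLUMNS] for f in features],
                      columns=FEATURE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
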