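"""Pairwise dN/dS estimation (Nei-Gojobori 1986) and group summaries.

Synonymous site counts consider all single-nucleotide changes of each codon,
excluding changes that create stop codons from the denominators, so per-codon
synonymous + nonsynonymous sites total exactly 3. Multiple mutational
pathways between codons differing at 2-3 positions are averaged uniformly
over orderings, skipping pathways that pass through stop codons. Raw
proportions are corrected with the Jukes-Cantor formula.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from itertools import permutations
from math import log
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from ._codon import CODON_TO_AA, NUCLEOTIDES, SENSE_CODONS, STOP_CODONS, translate
from .cluster_align import GAP, Alignment
from .errors import InvalidArgumentError
from .sequence_io import SequenceRecord


@dataclass
class CodonAlignment:
    """Gapped in-frame CDS rows mirroring a protein alignment column-for-column."""

    rows: List[SequenceRecord]

    def __post_init__(self) -> None:
        lengths = {len(r.residues) for r in self.rows}
        if len(lengths) != 1:
            raise InvalidArgumentError("codon alignment rows have unequal lengths")
        if self.length % 3 != 0:
            raise InvalidArgumentError("codon alignment length not divisible by 3")

    @property
    def length(self) -> int:
        return len(self.rows[0].residues)


@dataclass(frozen=True)
class DnDsResult:
    id_a: str
    id_b: str
    dn: float
    ds: float
    ratio: Optional[float]
    ps: float
    pn: float
    s_sites: float
    n_sites: float
    n_codons: int
    valid: bool


def backtranslate(protein_aln: Alignment, cds: Iterable[SequenceRecord]) -> CodonAlignment:
    """Expand a protein alignment into a codon alignment using matching CDS.

    Each CDS must translate exactly to its ungapped protein row (a single
    trailing stop codon is tolerated and trimmed).
    """
    by_id = {rec.id: rec for rec in cds}
    rows: List[SequenceRecord] = []
    for rec in protein_aln.rows:
        if rec.id not in by_id:
            raise InvalidArgumentError(f"no CDS for alignment row {rec.id!r}")
        seq = by_id[rec.id].residues.upper()
        protein = rec.residues.replace(GAP, "")
        if len(seq) == 3 * (len(protein) + 1) and seq[-3:] in STOP_CODONS:
            seq = seq[:-3]
        if len(seq) != 3 * len(protein):
            raise InvalidArgumentError(
                f"row {rec.id!r}: CDS length {len(seq)} does not match protein length"
                f" {len(protein)}"
            )
        translated = translate(seq)
        for pos, (aa_cds, aa_prot) in enumerate(zip(translated, protein), start=1):
            if aa_cds != aa_prot:
                raise InvalidArgumentError(
                    f"row {rec.id!r}: translation mismatch at residue {pos}"
                    f" ({aa_cds} != {aa_prot})"
                )
        out = []
        k = 0
        for char in rec.residues:
            if char == GAP:
                out.append("---")
            else:
                out.append(seq[3 * k : 3 * k + 3])
                k += 1
        rows.append(replace(by_id[rec.id], residues="".join(out), genome_id=rec.genome_id))
    return CodonAlignment(rows=rows)


# ----------------------------------------------------------------- NG86 core
@lru_cache(maxsize=None)
def synonymous_sites(codon: str) -> float:
    """Synonymous site count of a sense codon (0..3).

    At each position the fraction of synonymous changes is taken over the
    non-stop alternatives, so synonymous + nonsynonymous sites sum to 3.
    """
    aa = CODON_TO_AA[codon]
    total = 0.0
    for pos in range(3):
        syn = 0
        non_stop = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            non_stop += 1
            if CODON_TO_AA[alt] == aa:
                syn += 1
        if non_stop:
            total += syn / non_stop
    return total


@lru_cache(maxsize=None)
def count_differences(codon_a: str, codon_b: str) -> Tuple[float, float]:
    """Average (synonymous, nonsynonymous) difference counts between codons.

    Averaged uniformly over mutational orderings; pathways through stop
    codons are excluded (unless every pathway hits a stop, in which case all
    pathways count).
    """
    positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not positions:
        return 0.0, 0.0

    def walk(order: Tuple[int, ...], allow_stops: bool):
        current = codon_a
        sd = nd = 0.0
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                if not allow_stops:
                    return None
                # stop-crossing step scored as nonsynonymous
                nd += 1.0
            elif CODON_TO_AA[nxt] == CODON_TO_AA.get(current, None):
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        return sd, nd

    results = [walk(order, False) for order in permutations(positions)]
    valid = [r for r in results if r is not None]
    if not valid:
        valid = [walk(order, True) for order in permutations(positions)]
    sd = sum(r[0] for r in valid) / len(valid)
    nd = sum(r[1] for r in valid) / len(valid)
    return sd, nd


def _jukes_cantor(p: float) -> Optional[float]:
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def ng86_pair(a: SequenceRecord, b: SequenceRecord) -> DnDsResult:
    """Nei-Gojobori dN/dS for two equal-length in-frame (gapped) CDS rows.

    Codon columns with a gap in either row are skipped. The result carries
    ``valid=False`` (and no ratio) when either proportion is saturated
    (>= 0.75) or dS is zero.
    """
    sa, sb = a.residues.upper(), b.residues.upper()
    if len(sa) != len(sb):
        raise InvalidArgumentError("rows have different lengths")
    if len(sa) % 3 != 0:
        raise InvalidArgumentError("row length not divisible by 3")
    s_total_a = s_total_b = 0.0
    sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(sa), 3):
        ca, cb = sa[i : i + 3], sb[i : i + 3]
        if GAP in ca or GAP in cb:
            continue
        if ca not in CODON_TO_AA or cb not in CODON_TO_AA:
            continue  # stop or ambiguous codon: not comparable
        n_codons += 1
        s_total_a += synonymous_sites(ca)
        s_total_b += synonymous_sites(cb)
        step_sd, step_nd = count_differences(ca, cb)
        sd += step_sd
        nd += step_nd
    if n_codons == 0:
        raise InvalidArgumentError("no comparable codons")
    s_sites = (s_total_a + s_total_b) / 2.0
    n_sites = 3.0 * n_codons - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ds = _jukes_cantor(ps)
    dn = _jukes_cantor(pn)
    valid = ds is not None and dn is not None and ds > 0
    ratio = dn / ds if valid else None
    return DnDsResult(
        id_a=a.id,
        id_b=b.id,
        dn=dn if dn is not None else float("nan"),
        ds=ds if ds is not None else float("nan"),
        ratio=ratio,
        ps=ps,
        pn=pn,
        s_sites=s_sites,
        n_sites=n_sites,
        n_codons=n_codons,
        valid=valid,
    )


def aligned_identity(row_a: str, row_b: str) -> float:
    """Fraction identical over columns where both rows are ungapped."""
    both = [(x, y) for x, y in zip(row_a, row_b) if x != GAP and y != GAP]
    if not both:
        return 0.0
    return sum(1 for x, y in both if x == y) / len(both)


def select_pairs(
    protein_aln: Alignment,
    min_identity: float = 0.5,
    max_identity: float = 0.95,
) -> List[Tuple[int, int]]:
    """Row-index pairs inside the divergence window used for group medians."""
    rows = protein_aln.row_strings()
    out = []
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            ident = aligned_identity(rows[i], rows[j])
            if min_identity <= ident <= max_identity:
                out.append((i, j))
    return out


def group_medians(
    results: Sequence[DnDsResult], labels: Mapping[str, str]
) -> Dict[str, Dict[str, float]]:
    """Median dN/dS per label over valid within-group pairs.

    Pairs whose two genes carry different labels are skipped. Groups with no
    valid ratio are absent from the output (never reported as zero).
    """
    grouped: Dict[str, List[float]] = {}
    invalid: Dict[str, int] = {}
    for res in results:
        la, lb = labels.get(res.id_a), labels.get(res.id_b)
        if la is None or lb is None or la != lb:
            continue
        if res.valid:
            grouped.setdefault(la, []).append(res.ratio)
        else:
            invalid[la] = invalid.get(la, 0) + 1
    out: Dict[str, Dict[str, float]] = {}
    for label, ratios in grouped.items():
        series = pd.Series(ratios)
        out[label] = {
            "median": float(series.median()),
            "n_valid": len(ratios),
            "n_invalid": invalid.get(label, 0),
        }
    return out


def results_table(results: Sequence[DnDsResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
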