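"""Standard genetic code tables shared by the simulator and dN/dS code."""

from __future__ import annotations

from itertools import product
from typing import Dict, List

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

NUCLEOTIDES = "ACGT"
STOP_CODONS = frozenset(_STANDARD.stop_codons)
#: the 61 sense codons in lexicographic order
SENSE_CODONS: List[str] = [
    "".join(c) for c in product(NUCLEOTIDES, repeat=3) if "".join(c) not in STOP_CODONS
]
CODON_INDEX: Dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
CODON_TO_AA: Dict[str, str] = {c: _STANDARD.forward_table[c] for c in SENSE_CODONS}

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def is_transition(a: str, b: str) -> bool:
    return (a, b) in TRANSITIONS


def translate(cds: str) -> str:
    """Translate an in-frame, gap-free CDS; '*' for stop codons."""
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3].upper()
        if codon in STOP_CODONS:
            out.append("*")
        else:
            aa = CODON_TO_AA.get(codon)
            out.append(aa if aa is not None else "X")
    return "".join(out)
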