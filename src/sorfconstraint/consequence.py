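"""Frame-aware SNV consequence classification inside an sORF reading frame.

Each single-base change in a codon is classified against the standard
nuclear genetic code with the priority

    start_loss > stop_loss > stop_gain > (synonymous | missense)

Start-loss is any change in the first codon that alters the encoded amino
acid (for the canonical ATG start every single-base change qualifies).
A change in the stop codon that yields another stop codon is synonymous;
one that yields a coding codon is stop-loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterator

from .sequence_model import COMPLEMENT, CodingSequence, codon_iter


class ConsequenceType(str, Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    START_LOSS = "start_loss"


LOF_CLASSES = (ConsequenceType.START_LOSS, ConsequenceType.STOP_LOSS, ConsequenceType.STOP_GAIN)

# Standard nuclear genetic code, written out explicitly: this table is the
# single authority the classifier consults.
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_BASES = "ACGT"


def classify_change(
    codon: str,
    pos_in_codon: int,
    alt: str,
    is_start_codon: bool = False,
    is_stop_codon: bool = False,
) -> ConsequenceType:
    """Classify the single-base change ``codon[pos_in_codon] -> alt``."""
    codon = codon.upper()
    alt = alt.upper()
    if codon not in GENETIC_CODE or alt not in _BASES:
        raise ValueError(f"invalid codon/alt: {codon!r}, {alt!r}")
    if alt == codon[pos_in_codon]:
        raise ValueError(f"alt {alt!r} equals reference base in {codon!r}[{pos_in_codon}]")

    new_codon = codon[:pos_in_codon] + alt + codon[pos_in_codon + 1 :]
    aa_old, aa_new = GENETIC_CODE[codon], GENETIC_CODE[new_codon]

    if is_start_codon:
        return ConsequenceType.SYNONYMOUS if aa_new == aa_old else ConsequenceType.START_LOSS
    if is_stop_codon:
        return ConsequenceType.SYNONYMOUS if aa_new == "*" else ConsequenceType.STOP_LOSS
    if aa_new == "*":
        return ConsequenceType.STOP_GAIN
    return ConsequenceType.SYNONYMOUS if aa_new == aa_old else ConsequenceType.MISSENSE


@dataclass(frozen=True)
class CodingChange:
    """One possible single-base change in a coding sequence.

    ``coding_alt`` is the substituted base on the coding strand;
    ``genomic_alt`` its genomic-strand representation (complemented for
    minus-strand sORFs).  ``context`` is the coding-strand genomic
    trinucleotide around the base.
    """

    codon_index: int
    pos_in_codon: int
    genomic_pos: int
    ref: str           # coding strand
    coding_alt: str
    genomic_ref: str
    genomic_alt: str
    context: str       # coding strand orientation
    consequence: ConsequenceType


def iter_changes(cds: CodingSequence) -> Iterator[CodingChange]:
    """Enumerate the 9 possible single-base changes of every usable codon.

    Codons containing a reference N are skipped entirely, so each yielded
    codon contributes exactly 9 changes.
    """
    minus = cds.strand == "-"
    for codon in codon_iter(cds):
        if codon.excluded:
            continue
        for j in range(3):
            ref = codon.codon[j]
            for alt in _BASES:
                if alt == ref:
                    continue
                yield CodingChange(
                    codon_index=codon.index,
                    pos_in_codon=j,
                    genomic_pos=codon.genomic_pos[j],
                    ref=ref,
                    coding_alt=alt,
                    genomic_ref=ref.translate(COMPLEMENT) if minus else ref,
                    genomic_alt=alt.translate(COMPLEMENT) if minus else alt,
                    context=codon.contexts[j],
                    consequence=classify_change(
                        codon.codon, j, alt, codon.is_start, codon.is_stop
                    ),
                )


def classify_all(cds: CodingSequence) -> dict[tuple[int, str], ConsequenceType]:
    """Map every (genomic position, genomic alt) to its consequence.

    Three entries per non-excluded coding base; alts are genomic-strand so
    the map can be joined directly against a variant table.
    """
    return {(c.genomic_pos, c.genomic_alt): c.consequence for c in iter_changes(cds)}


def drop_splice_only(
    annotations: dict[tuple[int, str], list[str]],
    splice_terms: tuple[str, ...] = ("splice",),
) -> dict[tuple[int, str], list[str]]:
    """Import-time filter for externally annotated variants.

    The native engine has no splice class; when consequence annotations come
    from an external annotator, variants whose *only* predicted consequences
    are splice classes are excluded, and splice terms are stripped from the
    rest.
    """
    out: dict[tuple[int, str], list[str]] = {}
    for key, terms in annotations.items():
        kept = [t for t in terms if not any(s in t.lower() for s in splice_terms)]
        if kept:
            out[key] = kept
    return out
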