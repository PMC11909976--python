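"""Strand-oriented spliced coding sequences with per-base genomic context.

The mutation model needs, for every coding base, the trinucleotide formed
by the base and its two immediate *genomic* neighbours: mutation mechanisms
act on genomic DNA, so across a splice junction the context uses the
intronic neighbour, not the next coding base.  Codons, in contrast, are
read from the spliced sequence.  Both are oriented to the coding strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

from .io_formats import SORFRecord

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class RangeError(ValueError):
    """A block (plus its one-base flank) falls outside the reference."""


@dataclass(frozen=True)
class CodingSequence:
    """Spliced, strand-oriented coding bases of one sORF.

    ``bases[i]`` is the i-th base in translation order; ``genomic_pos[i]``
    its 0-based genomic position; ``context[i]`` its genomic trinucleotide
    oriented to the coding strand (middle base equals ``bases[i]`` unless
    the base is flagged); ``flagged[i]`` marks bases whose own or flanking
    reference call is N.
    """

    sorf_id: str
    chrom: str
    strand: str
    bases: str
    genomic_pos: tuple[int, ...]
    context: tuple[str, ...]
    flagged: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.bases) % 3 != 0:
            raise ValueError(f"{self.sorf_id}: coding length {len(self.bases)} not divisible by 3")
        for base, ctx, bad in zip(self.bases, self.context, self.flagged):
            if not bad and ctx[1] != base:
                raise ValueError(f"{self.sorf_id}: context middle base {ctx!r} != coding base {base!r}")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def n_codons(self) -> int:
        return len(self.bases) // 3

    @property
    def starts_with_atg(self) -> bool:
        return self.bases[:3] == "ATG"


@dataclass(frozen=True)
class Codon:
    """One codon yielded by :func:`codon_iter`."""

    index: int
    codon: str
    contexts: tuple[str, str, str]
    genomic_pos: tuple[int, int, int]
    is_start: bool
    is_stop: bool
    excluded: bool  # true when any base carries a reference N


def _fetch(genome: Mapping, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start:end) as an upper-case string.

    Works with pyfaidx.Fasta, plain dict-of-strings, or any mapping whose
    values support slicing.
    """
    seq = genome[chrom][start:end]
    return str(seq).upper()


def extract_coding_sequence(genome: Mapping, sorf: SORFRecord) -> CodingSequence:
    """Build the :class:`CodingSequence` of an sORF from the reference.

    Plus strand: bases are the concatenated block sequences in block order.
    Minus strand: blocks are traversed last-to-first, each base complemented,
    and each context reverse-complemented, so everything reads in
    translation order on the coding strand.
    """
    chrom_len = len(genome[sorf.chrom])
    for start, end in sorf.blocks:
        if start - 1 < 0 or end + 1 > chrom_len:
            raise RangeError(
                f"{sorf.id}: block ({start}, {end}) plus flanks outside reference {sorf.chrom}"
            )

    bases: list[str] = []
    positions: list[int] = []
    contexts: list[str] = []
    flagged: list[bool] = []

    blocks = sorf.blocks if sorf.strand == "+" else tuple(reversed(sorf.blocks))
    for start, end in blocks:
        block_with_flanks = _fetch(genome, sorf.chrom, start - 1, end + 1)
        offsets = range(start, end) if sorf.strand == "+" else range(end - 1, start - 1, -1)
        for pos in offsets:
            i = pos - (start - 1)
            triplet = block_with_flanks[i - 1 : i + 2]
            base = block_with_flanks[i]
            if sorf.strand == "-":
                triplet = revcomp(triplet)
                base = base.translate(COMPLEMENT)
            bad = any(c not in "ACGT" for c in triplet)
            bases.append(base)
            positions.append(pos)
            contexts.append(triplet)
            flagged.append(bad)

    return CodingSequence(
        sorf_id=sorf.id,
        chrom=sorf.chrom,
        strand=sorf.strand,
        bases="".join(bases),
        genomic_pos=tuple(positions),
        context=tuple(contexts),
        flagged=tuple(flagged),
    )


def codon_iter(cds: CodingSequence) -> Iterator[Codon]:
    """Yield the codons of a coding sequence in translation order.

    The first codon is flagged as the start and the last as the stop; a
    codon containing any N-flagged base is yielded with ``excluded=True``
    so downstream enumeration can skip it.
    """
    n = cds.n_codons
    for k in range(n):
        sl = slice(3 * k, 3 * k + 3)
        yield Codon(
            index=k,
            codon=cds.bases[sl],
            contexts=tuple(cds.context[sl]),
            genomic_pos=tuple(cds.genomic_pos[sl]),
            is_start=(k == 0),
            is_stop=(k == n - 1),
            excluded=any(cds.flagged[sl]),
        )
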