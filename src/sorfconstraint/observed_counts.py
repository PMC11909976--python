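"""Observed-variant filtering and per-class unique counting.

A variant counts as observed in an element when it is rare (AF < 0.1%),
passed all callset filters, sits on adequately covered sequence
(depth >= 1), and its (position, alt) pair is one of the element's
enumerated coding changes.  Counts are of unique (chrom, pos, ref, alt)
tuples; elements are counted independently, so a variant inside two
overlapping elements contributes to each.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .consequence import ConsequenceType, LOF_CLASSES
from .io_formats import VariantSite


def filter_observed(
    variants: Iterable[VariantSite],
    af_max: float = 0.001,
    depth_min: float = 1.0,
) -> list[VariantSite]:
    """Keep rare, PASS, adequately covered variants; collapse duplicates.

    Inclusion is AF strictly below ``af_max`` and depth at or above
    ``depth_min`` — both boundaries taken from the workflow's filter
    definition, which excludes at AF >= 0.1% and includes at depth >= 1.
    """
    seen: set[tuple[str, int, str, str]] = set()
    kept: list[VariantSite] = []
    for v in variants:
        if v.af >= af_max or not v.passed_filters or v.depth < depth_min:
            continue
        if v.key in seen:
            continue
        seen.add(v.key)
        kept.append(v)
    return kept


@dataclass
class ObservedCounts:
    """Unique observed variants per consequence class for one element."""

    element_id: str
    counts: dict[ConsequenceType, int]
    ignored_alleles: int = 0  # coding-position variants whose allele is not enumerable

    @property
    def snv_total(self) -> int:
        return sum(self.counts.values())

    @property
    def lof_total(self) -> int:
        return loeuf_class_counts(self)

    def get(self, cls: ConsequenceType) -> int:
        return self.counts.get(cls, 0)


def count_observed(
    variants: Iterable[VariantSite],
    consequence_map: Mapping[tuple[int, str], ConsequenceType],
    element_id: str,
    chrom: str | None = None,
) -> ObservedCounts:
    """Count unique filtered variants per consequence class for one element.

    ``consequence_map`` is keyed by (0-based genomic position, genomic alt)
    as produced by ``classify_all``.  Variants at coding positions whose
    allele is absent from the map (e.g. a ref mismatch) are skipped and
    tallied in ``ignored_alleles``; variants outside the element are simply
    ignored.
    """
    counts = {c: 0 for c in ConsequenceType}
    coding_positions = {pos for pos, _ in consequence_map}
    ignored = 0
    seen: set[tuple[str, int, str, str]] = set()
    for v in variants:
        if chrom is not None and v.chrom != chrom:
            continue
        if v.key in seen:
            continue
        seen.add(v.key)
        pos0 = v.pos - 1
        cons = consequence_map.get((pos0, v.alt))
        if cons is None:
            if pos0 in coding_positions:
                ignored += 1
            continue
        counts[cons] += 1
    return ObservedCounts(element_id=element_id, counts=counts, ignored_alleles=ignored)


def loeuf_class_counts(counts: ObservedCounts) -> int:
    """Loss-of-function SNV count: start-loss + stop-loss + stop-gain."""
    return sum(counts.counts.get(c, 0) for c in LOF_CLASSES)
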