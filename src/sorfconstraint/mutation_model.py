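"""Context- and methylation-aware mutational model for sORF coding bases.

For every usable codon the model enumerates the 9 possible single-base
changes, attaches to each its genomic context triplet, the local CpG
methylation bin and the per-generation mutation rate, removes sites the
population data cannot inform (low-quality, common, or under-covered), and
sums the surviving rates per consequence class into expected variant
counts via a proportionality constant calibrated on synonymous variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .consequence import ConsequenceType, LOF_CLASSES, iter_changes
from .io_formats import VariantSite
from .sequence_model import CodingSequence, revcomp

log = logging.getLogger(__name__)

N_METHYLATION_BINS = 16


class ExclusionReason(str, Enum):
    LOW_QUALITY_SITE = "low_quality_site"
    HIGH_AF = "high_af"
    LOW_COVERAGE = "low_coverage"


def methylation_bin(fraction: float) -> int:
    """Map a mean methylation fraction in [0, 1] to one of 16 equal bins.

    Bins are left-closed right-open except the last, which is closed, so
    a fraction of exactly 1.0 lands in bin 15.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"methylation fraction {fraction} outside [0, 1]")
    return min(int(fraction * N_METHYLATION_BINS), N_METHYLATION_BINS - 1)


class MutationRateTable:
    """(context triplet, alt base, methylation bin) -> per-generation rate.

    Lookups are strand-canonicalised: if the genomic-strand context is not
    in the table, the reverse-complement context with the complemented alt
    is tried, matching the strand-collapsed form in which published rate
    tables are distributed.
    """

    def __init__(self, entries: Mapping[tuple[str, str, int], float]):
        for (ctx, alt, mbin), rate in entries.items():
            if rate < 0:
                raise ValueError(f"negative rate for ({ctx}, {alt}, {mbin})")
        self._entries = dict(entries)

    def __len__(self) -> int:
        return len(self._entries)

    def lookup(self, context: str, alt: str, mbin: int) -> float:
        key = (context, alt, mbin)
        if key in self._entries:
            return self._entries[key]
        rc_key = (revcomp(context), revcomp(alt), mbin)
        if rc_key in self._entries:
            return self._entries[rc_key]
        raise KeyError(
            f"no mutation rate for context {context!r} alt {alt!r} bin {mbin} "
            "(after strand canonicalization)"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MutationRateTable":
        """Load from tab-separated columns: context, ref, alt, methylation_level, mu."""
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"context", "ref", "alt", "methylation_level", "mu"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: rate table needs columns {sorted(required)}")
        entries = {}
        for row in df.itertuples(index=False):
            if row.context[1] != row.ref:
                raise ValueError(f"{path}: context {row.context} middle base != ref {row.ref}")
            entries[(row.context, row.alt, int(row.methylation_level))] = float(row.mu)
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"context": ctx, "ref": ctx[1], "alt": alt, "methylation_level": mbin, "mu": rate}
            for (ctx, alt, mbin), rate in sorted(self._entries.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


class MethylationMap:
    """Per-position mean methylation fraction and its 16-level bin."""

    def __init__(self, fractions: Mapping[tuple[str, int], float]):
        self._fractions = dict(fractions)
        self._bins = {k: methylation_bin(v) for k, v in self._fractions.items()}

    def __len__(self) -> int:
        return len(self._fractions)

    def fraction_at(self, chrom: str, pos: int) -> float:
        return self._fractions.get((chrom, pos), 0.0)

    def bin_at(self, chrom: str, pos: int) -> int:
        """Methylation bin at a genomic position; unmapped positions are bin 0."""
        return self._bins.get((chrom, pos), 0)


def build_methylation_map(tracks: Sequence[pd.DataFrame]) -> MethylationMap:
    """Average per-position methylation fractions across epigenome tracks.

    Each track is a frame with columns (chrom, pos, fraction); the mean at a
    position is taken over the tracks that cover it.
    """
    if not tracks:
        raise ValueError("at least one methylation track is required")
    merged = pd.concat(tracks, ignore_index=True)
    if ((merged["fraction"] < 0) | (merged["fraction"] > 1)).any():
        raise ValueError("methylation fractions must lie in [0, 1]")
    means = merged.groupby(["chrom", "pos"])["fraction"].mean()
    return MethylationMap({(chrom, int(pos)): float(f) for (chrom, pos), f in means.items()})


def is_cpg_context(context: str) -> bool:
    """True when the genomic trinucleotide contains a CpG dinucleotide.

    CpG is strand-symmetric (its reverse complement is itself), so a single
    substring test suffices.
    """
    return "CG" in context


@dataclass
class PossibleVariant:
    """One enumerable SNV in an sORF with its model annotations."""

    sorf_id: str
    chrom: str
    genomic_pos: int  # 0-based
    ref: str          # genomic strand
    alt: str          # genomic strand
    consequence: ConsequenceType
    context: str      # genomic strand
    methylation_bin: int
    rate: float
    excluded: bool = False
    reason: ExclusionReason | None = None


def enumerate_possible(
    cds: CodingSequence,
    methylation: MethylationMap,
    rates: MutationRateTable,
    cpg_only_methylation: bool = True,
) -> list[PossibleVariant]:
    """Enumerate the 9 possible SNVs of every usable codon with model rates.

    Contexts and alts are reported on the genomic strand.  By default the
    methylation bin is consulted only at CpG-containing contexts; elsewhere
    bin 0 is forced, since the rate model is methylation-sensitive only at
    potentially methylated (CpG) sites.
    """
    out: list[PossibleVariant] = []
    minus = cds.strand == "-"
    for change in iter_changes(cds):
        genomic_context = revcomp(change.context) if minus else change.context
        if cpg_only_methylation and not is_cpg_context(genomic_context):
            mbin = 0
        else:
            mbin = methylation.bin_at(cds.chrom, change.genomic_pos)
        try:
            rate = rates.lookup(genomic_context, change.genomic_alt, mbin)
        except KeyError as err:
            raise KeyError(f"{cds.sorf_id}: {err}") from err
        out.append(
            PossibleVariant(
                sorf_id=cds.sorf_id,
                chrom=cds.chrom,
                genomic_pos=change.genomic_pos,
                ref=change.genomic_ref,
                alt=change.genomic_alt,
                consequence=change.consequence,
                context=genomic_context,
                methylation_bin=mbin,
                rate=rate,
            )
        )
    return out


class SiteTable:
    """Per-position site information derived from the variant-site table.

    Addresses depth and the low-quality flag by genomic position and allele
    frequency by (position, alt).  Positions without an entry fall back to
    ``default_depth`` and are not low-quality — the toy inputs carry depth
    only where a variant was called, whereas a production depth summary
    would cover every position.
    """

    def __init__(
        self,
        variants: Iterable[VariantSite],
        default_depth: float = 30.0,
        extra_depths: Mapping[tuple[str, int], float] | None = None,
    ):
        self._af: dict[tuple[str, int, str], float] = {}
        self._depth: dict[tuple[str, int], float] = dict(extra_depths or {})
        self._lowq: set[tuple[str, int]] = set()
        self.default_depth = float(default_depth)
        for v in variants:
            pos0 = v.pos - 1  # internal coordinates are 0-based
            key = (v.chrom, pos0)
            self._af[(v.chrom, pos0, v.alt)] = max(
                v.af, self._af.get((v.chrom, pos0, v.alt), 0.0)
            )
            self._depth[key] = v.depth
            if v.low_quality:
                self._lowq.add(key)

    def af(self, chrom: str, pos: int, alt: str) -> float:
        return self._af.get((chrom, pos, alt), 0.0)

    def depth(self, chrom: str, pos: int) -> float:
        return self._depth.get((chrom, pos), self.default_depth)

    def low_quality(self, chrom: str, pos: int) -> bool:
        return (chrom, pos) in self._lowq


def filter_possible(
    possible: Iterable[PossibleVariant],
    sites: SiteTable,
    af_max: float = 0.001,
    depth_min: float = 1.0,
) -> list[PossibleVariant]:
    """Mark possible variants the population data cannot inform as excluded.

    A possible variant is excluded when its position carries a low-quality
    call, when the matching observed allele is common (AF >= ``af_max``),
    or when site depth is below ``depth_min``.  Exclusion reasons are
    recorded; retained variants come back with ``excluded=False``.
    """
    out: list[PossibleVariant] = []
    for pv in possible:
        reason: ExclusionReason | None = None
        if sites.low_quality(pv.chrom, pv.genomic_pos):
            reason = ExclusionReason.LOW_QUALITY_SITE
        elif sites.af(pv.chrom, pv.genomic_pos, pv.alt) >= af_max:
            reason = ExclusionReason.HIGH_AF
        elif sites.depth(pv.chrom, pv.genomic_pos) < depth_min:
            reason = ExclusionReason.LOW_COVERAGE
        out.append(
            PossibleVariant(
                **{**pv.__dict__, "excluded": reason is not None, "reason": reason}
            )
        )
    return out


ALL_CLASSES = tuple(ConsequenceType)


@dataclass
class ExpectedCounts:
    """Per-class possible-variant counts, rate sums and expected counts."""

    sorf_id: str
    possible: dict[ConsequenceType, int]
    rate_sum: dict[ConsequenceType, float]
    expected: dict[ConsequenceType, float]
    calibration_k: float

    @property
    def snv_possible(self) -> int:
        return sum(self.possible.values())

    @property
    def snv_rate_sum(self) -> float:
        return sum(self.rate_sum.values())

    @property
    def snv_expected(self) -> float:
        return sum(self.expected.values())

    @property
    def lof_expected(self) -> float:
        return sum(self.expected[c] for c in LOF_CLASSES)

    @property
    def lof_possible(self) -> int:
        return sum(self.possible[c] for c in LOF_CLASSES)


def expected_counts(
    filtered_possible: Iterable[PossibleVariant],
    calibration_k: float = 1.0,
    sorf_id: str | None = None,
) -> ExpectedCounts:
    """Sum retained rates per consequence class and scale by the calibration.

    Only non-excluded possible variants contribute; a class with none
    reports an expected count of 0.
    """
    if calibration_k <= 0:
        raise ValueError(f"calibration_k must be positive, got {calibration_k}")
    possible = {c: 0 for c in ALL_CLASSES}
    rate_sum = {c: 0.0 for c in ALL_CLASSES}
    the_id = sorf_id
    for pv in filtered_possible:
        if the_id is None:
            the_id = pv.sorf_id
        if pv.excluded:
            continue
        possible[pv.consequence] += 1
        rate_sum[pv.consequence] += pv.rate
    expected = {c: calibration_k * s for c, s in rate_sum.items()}
    return ExpectedCounts(
        sorf_id=the_id or "", possible=possible, rate_sum=rate_sum,
        expected=expected, calibration_k=calibration_k,
    )


def fit_calibration(
    reference: Sequence[tuple[float, float]],
    allow_single: bool = False,
) -> float:
    """Fit the observed→expected proportionality on synonymous variation.

    ``reference`` holds (observed synonymous count, synonymous rate sum)
    pairs, one per reference element.  The constant is the slope of a
    zero-intercept least-squares fit of counts on rate sums:
    k = Σ(o·s) / Σ(s²).
    """
    if len(reference) < (1 if allow_single else 2):
        raise ValueError("calibration needs at least two reference elements")
    obs = np.array([o for o, _ in reference], dtype=float)
    sums = np.array([s for _, s in reference], dtype=float)
    denom = float(np.sum(sums**2))
    if denom == 0.0:
        raise ValueError("all synonymous rate sums are zero; cannot calibrate")
    return float(np.sum(obs * sums) / denom)
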