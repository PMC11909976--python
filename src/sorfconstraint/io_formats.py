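"""Readers and writers for the genomic file formats the workflow touches.

Internal coordinates are 0-based half-open everywhere.  Conversion to and
from 1-based conventions happens only at the format boundary: BED12 comes
in 0-based, GTF goes out 1-based inclusive, VCF positions come in 1-based
and are kept 1-based on the ``VariantSite.pos`` field (the sequence model
converts when it needs array offsets).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

log = logging.getLogger(__name__)

SORF_CLASSES = ("uORF", "dORF", "intORF", "uoORF", "doORF", "lncRNA-ORF")

#: token patterns used to recover the sORF class from a BED name field.
#: Order matters: "uoORF" must be tried before "uORF".
_CLASS_TOKENS = [
    (re.compile(r"uoorf", re.I), "uoORF"),
    (re.compile(r"doorf", re.I), "doORF"),
    (re.compile(r"uorf", re.I), "uORF"),
    (re.compile(r"dorf", re.I), "dORF"),
    (re.compile(r"intorf", re.I), "intORF"),
    (re.compile(r"lncrna[-_]?orf|lncrna", re.I), "lncRNA-ORF"),
]


class FormatError(ValueError):
    """A file does not follow the expected format."""


class RecordError(ValueError):
    """A single record is internally inconsistent."""


@dataclass(frozen=True)
class SORFRecord:
    """One short open reading frame with its genomic block structure.

    ``blocks`` are 0-based half-open genomic intervals, ascending by start
    regardless of strand; translation order on the minus strand runs from
    the last block backwards.
    """

    id: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    sorf_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise RecordError(f"{self.id}: strand must be '+' or '-', got {self.strand!r}")
        prev_end = -1
        for start, end in self.blocks:
            if not (0 <= start < end):
                raise RecordError(f"{self.id}: invalid block ({start}, {end})")
            if start < prev_end:
                raise RecordError(f"{self.id}: blocks overlap or are unsorted")
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]

    @property
    def coding_length(self) -> int:
        return sum(end - start for start, end in self.blocks)


@dataclass(frozen=True)
class VariantSite:
    """One biallelic SNV observed in a population callset."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    af: float
    passed_filters: bool
    depth: float
    low_quality: bool = False

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise RecordError(f"{self.chrom}:{self.pos} not an SNV ({self.ref}>{self.alt})")
        if self.ref == self.alt:
            raise RecordError(f"{self.chrom}:{self.pos} ref equals alt ({self.ref})")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def class_from_name(name: str) -> str:
    """Recover an sORF class label from a BED name field.

    The synthetic generator encodes ``<id>|<class>``; catalogue-style names
    carry a recognisable token instead.  Unrecognised names map to
    ``"unknown"``.
    """
    if "|" in name:
        candidate = name.rsplit("|", 1)[1]
        if candidate in SORF_CLASSES:
            return candidate
    for pattern, label in _CLASS_TOKENS:
        if pattern.search(name):
            return label
    return "unknown"


def read_bed12(
    path: str | Path,
    class_parser: Callable[[str], str] = class_from_name,
) -> list[SORFRecord]:
    """Read sORF definitions from a BED12 file.

    Blocks are reconstructed from blockStarts/blockSizes relative to
    chromStart.  Records whose total block length is not divisible by 3 or
    is shorter than two codons cannot hold a reading frame and are skipped
    with a warning.
    """
    records: list[SORFRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 BED columns, got {len(fields)}")
            chrom, chrom_start, _chrom_end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5]
            block_count = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != block_count or len(starts) != block_count:
                raise RecordError(f"{path}:{lineno}: blockCount {block_count} does not match block lists")
            blocks = tuple(
                (chrom_start + off, chrom_start + off + size) for off, size in zip(starts, sizes)
            )
            rec = SORFRecord(
                id=name, chrom=chrom, strand=strand, blocks=blocks, sorf_class=class_parser(name)
            )
            if rec.coding_length % 3 != 0 or rec.coding_length < 6:
                log.warning(
                    "%s:%d: skipping %s: coding length %d is not a valid reading frame",
                    path, lineno, name, rec.coding_length,
                )
                continue
            records.append(rec)
    return records


def write_sorf_gtf(sorfs: Iterable[SORFRecord], source: str = "sorfconstraint") -> str:
    """Render sORFs as GTF text: one gene feature per sORF, one exon per block.

    GTF coordinates are 1-based inclusive, so a 0-based half-open block
    (s, e) becomes (s+1, e).
    """
    lines: list[str] = []
    for sorf in sorfs:
        if not sorf.blocks:
            raise RecordError(f"{sorf.id}: sORF has no blocks")
        attrs = f'gene_id "{sorf.id}"; sorf_class "{sorf.sorf_class}";'
        start, end = sorf.span
        lines.append(
            "\t".join(
                [sorf.chrom, source, "gene", str(start + 1), str(end), ".", sorf.strand, ".", attrs]
            )
        )
        for bstart, bend in sorf.blocks:
            lines.append(
                "\t".join(
                    [sorf.chrom, source, "exon", str(bstart + 1), str(bend), ".", sorf.strand, ".", attrs]
                )
            )
    return "\n".join(lines) + "\n"


def parse_sorf_gtf(text: str) -> list[SORFRecord]:
    """Re-parse GTF text produced by :func:`write_sorf_gtf` (round-trip check)."""
    genes: dict[str, dict] = {}
    order: list[str] = []
    for line in text.strip().splitlines():
        chrom, _src, feature, start, end, _score, strand, _frame, attrs = line.split("\t")
        gene_id = re.search(r'gene_id "([^"]+)"', attrs).group(1)
        klass = re.search(r'sorf_class "([^"]+)"', attrs).group(1)
        if gene_id not in genes:
            genes[gene_id] = {"chrom": chrom, "strand": strand, "class": klass, "blocks": []}
            order.append(gene_id)
        if feature == "exon":
            genes[gene_id]["blocks"].append((int(start) - 1, int(end)))
    return [
        SORFRecord(
            id=g,
            chrom=genes[g]["chrom"],
            strand=genes[g]["strand"],
            blocks=tuple(sorted(genes[g]["blocks"])),
            sorf_class=genes[g]["class"],
        )
        for g in order
    ]


_BASES = frozenset("ACGT")


@dataclass
class VariantReadStats:
    """Counters reported by :func:`read_variant_sites`."""

    total_records: int = 0
    emitted: int = 0
    dropped_non_snv: int = 0


_SITES_COLUMNS = {
    "chrom": "chrom",
    "pos": "pos",
    "ref": "ref",
    "alt": "alt",
    "af": "af",
    "filter": "filter",
    "depth": "depth",
    "low_quality": "low_quality",
}


def read_variant_sites(
    path: str | Path,
    *,
    af_field: str = "AF",
    depth_field: str = "DP",
    low_quality_field: str = "lowqual",
    columns: dict[str, str] | None = None,
    stats: VariantReadStats | None = None,
) -> list[VariantSite]:
    """Read variant sites from a VCF or a VCF-like tab-separated table.

    Multi-allelic records are decomposed into one :class:`VariantSite` per
    alternate allele; non-SNV alleles are dropped and counted in ``stats``.
    ``passed_filters`` is true iff FILTER is PASS.

    For VCF input the allele frequency, per-site depth and low-quality flag
    are taken from the INFO fields named by ``af_field``, ``depth_field``
    and ``low_quality_field``.  For tabular input ``columns`` maps the
    logical names (chrom, pos, ref, alt, af, filter, depth, low_quality) to
    the file's column headers.
    """
    path = Path(path)
    stats = stats if stats is not None else VariantReadStats()
    head = path.read_text().lstrip()[:16] if path.stat().st_size else ""
    if head.startswith("##fileformat"):
        return _read_vcf(path, af_field, depth_field, low_quality_field, stats)
    return _read_sites_table(path, columns or _SITES_COLUMNS, stats)


def _read_vcf(path, af_field, depth_field, low_quality_field, stats):
    import pysam

    out: list[VariantSite] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            stats.total_records += 1
            info = rec.info
            afs = info.get(af_field)
            if afs is None:
                raise FormatError(f"{path}: INFO field {af_field!r} missing at {rec.chrom}:{rec.pos}")
            if not isinstance(afs, (tuple, list)):
                afs = (afs,)
            depth = float(info.get(depth_field, 0.0))
            lowq = bool(info.get(low_quality_field, False))
            filters = list(rec.filter.keys())
            passed = filters in ([], ["PASS"])
            for alt, af in zip(rec.alts or (), afs):
                if len(rec.ref) != 1 or len(alt) != 1 or rec.ref == alt or alt not in _BASES:
                    stats.dropped_non_snv += 1
                    continue
                out.append(
                    VariantSite(
                        chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                        af=float(af), passed_filters=passed, depth=depth, low_quality=lowq,
                    )
                )
                stats.emitted += 1
    return out


def _read_sites_table(path, columns, stats):
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["chrom", "pos", "ref", "alt", "af", "filter", "depth"]
    missing = [k for k in required if columns.get(k, k) not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    lowq_col = columns.get("low_quality", "low_quality")
    out: list[VariantSite] = []
    for row in df.itertuples(index=False):
        row = row._asdict()
        stats.total_records += 1
        ref = str(row[columns["ref"]])
        for alt in str(row[columns["alt"]]).split(","):
            if len(ref) != 1 or len(alt) != 1 or ref == alt or alt not in _BASES:
                stats.dropped_non_snv += 1
                continue
            out.append(
                VariantSite(
                    chrom=str(row[columns["chrom"]]),
                    pos=int(row[columns["pos"]]),
                    ref=ref,
                    alt=alt,
                    af=float(row[columns["af"]]),
                    passed_filters=str(row[columns["filter"]]) == "PASS",
                    depth=float(row[columns["depth"]]),
                    low_quality=bool(row[lowq_col]) if lowq_col in row else False,
                )
            )
            stats.emitted += 1
    return out


def variant_sites_from_frame(df) -> list[VariantSite]:
    """Convert a VCF-like frame (chrom, pos, ref, alt, af, filter, depth,
    low_quality) into :class:`VariantSite` records."""
    return [
        VariantSite(
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref=str(r.ref),
            alt=str(r.alt),
            af=float(r.af),
            passed_filters=str(r.filter) == "PASS",
            depth=float(r.depth),
            low_quality=bool(r.low_quality),
        )
        for r in df.itertuples(index=False)
    ]


def open_fasta(path: str | Path):
    """Open an indexed FASTA reference for random access."""
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)
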