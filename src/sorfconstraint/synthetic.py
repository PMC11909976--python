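"""Synthetic inputs with the statistical structure the workflow assumes.

The generator emulates, at desk scale, the shape of the real inputs: a
random reference genome, planted sORFs of the six classes with proper
start/stop structure and 1–3 blocks, a variant-site table sampled by
inverting the mutational model (each possible variant is observed with
probability 1 − exp(−scale·μ·s), where s is a per-consequence-class
selection factor), 37 CpG-localised methylation tracks, and sliding-window
score tracks.  Every draw flows from a single seed.

Selection factors of 1 everywhere make the callset neutral, so the
pipeline should recover observed/expected ratios near 1; factors below 1
deplete a class, which the constraint metrics should detect.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .consequence import ConsequenceType
from .io_formats import SORFRecord
from .mutation_model import MethylationMap, MutationRateTable, enumerate_possible
from .sequence_model import extract_coding_sequence, revcomp

STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_NON_STOP = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in STOP_CODONS
]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    ``cohort_scale`` plays the role of sample size: the probability of
    observing a possible variant with rate μ is 1 − exp(−scale·μ·s).  The
    default puts the mean per-site observation probability around 5%, deep
    in the linear (Poisson) regime.  ``selection`` maps consequence classes
    to factors in (0, 1]; missing classes default to 1 (neutral).
    """

    seed: int = 42
    genome_length: int = 400_000
    gc_fraction: float = 0.42
    chrom: str = "chrS"
    n_per_class: dict[str, int] = field(
        default_factory=lambda: {
            "uORF": 65, "dORF": 65, "lncRNA-ORF": 70,
            "intORF": 35, "uoORF": 35, "doORF": 30,
        }
    )
    min_codons: int = 30
    max_codons: int = 90
    max_blocks: int = 3
    intron_min: int = 30
    intron_max: int = 150
    gap_min: int = 200
    gap_max: int = 800
    selection: dict[str, float] = field(default_factory=dict)
    cohort_scale: float = 1.8e7
    high_af_fraction: float = 0.02
    low_quality_fraction: float = 0.01
    low_depth_fraction: float = 0.005
    n_methylation_tracks: int = 37
    score_window: int = 1000
    score_slide: int = 100

    def __post_init__(self) -> None:
        for cls, factor in self.selection.items():
            if not 0 < factor <= 1:
                raise ValueError(f"selection factor for {cls} must be in (0, 1], got {factor}")

    def selection_factor(self, consequence: ConsequenceType) -> float:
        return self.selection.get(consequence.value, 1.0)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def toy_rate_table(
    transversion: float = 2e-9,
    transition: float = 6e-9,
    cpg_transition: float = 2e-8,
    methylation_slope: float = 0.05,
) -> MutationRateTable:
    """Built-in toy mutation-rate table with the qualitative real structure.

    Transitions run 3x transversions; CpG transitions (C→T in a CpG, or
    its strand mirror G→A) run 10x non-CpG rates at bin 0 and grow
    linearly with the methylation bin: μ = cpg_transition · (1 + slope·bin).
    The slope is kept shallow so that, at the default cohort scale, even
    the hottest sites stay in the near-linear regime of the observation
    probability 1 − exp(−scale·μ) that the proportional calibration
    assumes.  All 64 contexts x 3 alts x 16 bins are populated so lookups
    are total.
    """
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    entries: dict[tuple[str, str, int], float] = {}
    for a in _BASES:
        for b in _BASES:
            for c in _BASES:
                ctx = a + b + c
                for alt in _BASES:
                    if alt == b:
                        continue
                    is_cpg_ts = (b == "C" and alt == "T" and c == "G") or (
                        b == "G" and alt == "A" and a == "C"
                    )
                    for mbin in range(16):
                        if is_cpg_ts:
                            rate = cpg_transition * (1.0 + methylation_slope * mbin)
                        elif (b, alt) in transitions:
                            rate = transition
                        else:
                            rate = transversion
                        entries[(ctx, alt, mbin)] = rate
    return MutationRateTable(entries)


def generate_reference(config: SimulationConfig, rng: np.random.Generator) -> str:
    """Random reference sequence at the configured GC fraction."""
    if config.genome_length <= 0:
        raise ValueError("genome length must be positive")
    gc = config.gc_fraction
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(_BASES), size=config.genome_length, p=p))


def _random_orf(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + (n-2) random non-stop codons + one stop codon."""
    middle = rng.choice(_NON_STOP, size=n_codons - 2)
    stop = rng.choice(list(STOP_CODONS))
    return "ATG" + "".join(middle) + stop


def plant_sorfs(
    config: SimulationConfig, genome: str, rng: np.random.Generator
) -> tuple[list[SORFRecord], list[tuple[int, int]], str]:
    """Plant sORFs of the six classes into the genome.

    sORFs are laid out left to right with random gaps, so they never
    overlap each other.  Classes that by definition overlap a canonical
    gene (intORF, uoORF, doORF) get a host-gene interval planted around
    them; the host intervals are returned for bookkeeping.  Returns the
    records, the host intervals and the genome with the coding sequence
    written in.
    """
    seq = list(genome)
    classes: list[str] = []
    for cls, n in config.n_per_class.items():
        classes.extend([cls] * n)
    rng.shuffle(classes)

    records: list[SORFRecord] = []
    hosts: list[tuple[int, int]] = []
    cursor = 10  # leave room for flanks and host-gene padding
    for i, cls in enumerate(classes):
        n_codons = int(rng.integers(config.min_codons, config.max_codons + 1))
        length = 3 * n_codons
        n_blocks = int(rng.integers(1, config.max_blocks + 1))
        # split the coding length into n_blocks chunks of >= 3 bases
        if n_blocks > 1:
            cuts = np.sort(rng.choice(np.arange(3, length - 2, 3), size=n_blocks - 1, replace=False))
            sizes = np.diff([0, *cuts, length]).tolist()
        else:
            sizes = [length]
        introns = [int(rng.integers(config.intron_min, config.intron_max + 1)) for _ in range(n_blocks - 1)]

        start = cursor + int(rng.integers(config.gap_min, config.gap_max + 1))
        blocks: list[tuple[int, int]] = []
        pos = start
        for j, size in enumerate(sizes):
            blocks.append((pos, pos + size))
            pos += size
            if j < len(introns):
                pos += introns[j]
        end = blocks[-1][1]
        if end + 400 > len(seq):
            break  # genome full; report what fits
        strand = "+" if rng.random() < 0.5 else "-"
        orf = _random_orf(n_codons, rng)
        coding = orf if strand == "+" else revcomp(orf)
        # write the coding bases into the blocks in ascending genomic order
        offset = 0
        for bstart, bend in blocks:
            seq[bstart:bend] = coding[offset : offset + (bend - bstart)]
            offset += bend - bstart
        rec = SORFRecord(
            id=f"SORF{i:04d}",
            chrom=config.chrom,
            strand=strand,
            blocks=tuple(blocks),
            sorf_class=cls,
        )
        records.append(rec)
        if cls in ("intORF", "uoORF", "doORF"):
            hosts.append((max(0, start - 300), min(len(seq), end + 300)))
        cursor = end
    return records, hosts, "".join(seq)


def sorfs_to_bed12(records: list[SORFRecord]) -> str:
    """Render sORF records as BED12 with the class encoded in the name."""
    lines = []
    for rec in records:
        start, end = rec.span
        sizes = ",".join(str(e - s) for s, e in rec.blocks)
        starts = ",".join(str(s - start) for s, e in rec.blocks)
        lines.append(
            "\t".join(
                [
                    rec.chrom, str(start), str(end), f"{rec.id}|{rec.sorf_class}",
                    "0", rec.strand, str(start), str(end), "0",
                    str(len(rec.blocks)), sizes, starts,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def generate_methylation_tracks(
    config: SimulationConfig, genome: str, rng: np.random.Generator
) -> list[pd.DataFrame]:
    """Per-epigenome methylation tracks localised to CpG dinucleotides.

    Each CpG gets a latent mean methylation state (mostly high, a minority
    lowly methylated, as in somatic tissue) shared by its C and G
    positions; each track observes it with noise.
    """
    cpg_c = np.array([i for i in range(len(genome) - 1) if genome[i : i + 2] == "CG"])
    positions = np.concatenate([cpg_c, cpg_c + 1]) if len(cpg_c) else np.array([], dtype=int)
    latent_c = np.where(rng.random(len(cpg_c)) < 0.8, 0.85, 0.08)
    latent = np.concatenate([latent_c, latent_c])
    tracks = []
    for _ in range(config.n_methylation_tracks):
        values = np.clip(latent + rng.normal(0, 0.08, size=len(latent)), 0.0, 1.0)
        tracks.append(
            pd.DataFrame({"chrom": config.chrom, "pos": positions, "fraction": values})
        )
    return tracks


def generate_score_track(
    config: SimulationConfig,
    rng: np.random.Generator,
    constant: float | None = None,
) -> pd.DataFrame:
    """Sliding-window score track (chrom, start, end, score).

    Window boundaries advance by ``score_slide``; scores are standard-
    normal draws unless a constant is requested (useful for matching
    tests).
    """
    starts = np.arange(0, config.genome_length - config.score_window + 1, config.score_slide)
    if constant is not None:
        scores = np.full(len(starts), float(constant))
    else:
        scores = rng.normal(0.0, 1.5, size=len(starts))
    return pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": starts,
            "end": starts + config.score_window,
            "score": scores,
        }
    )


def simulate_variants(
    config: SimulationConfig,
    genome,
    sorfs: list[SORFRecord],
    rates: MutationRateTable,
    methylation: MethylationMap,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sample a variant-site table by inverting the mutational model.

    Each enumerable SNV is observed with probability
    1 − exp(−scale·μ·s_class).  Observed variants get an allele frequency
    (a configured fraction of which exceeds the 0.1% rarity threshold), a
    FILTER status, a per-site depth and a low-quality flag at the
    configured planting rates.  Low-quality sites also fail FILTER, as in
    real callsets.
    """
    rows = []
    for sorf in sorfs:
        cds = extract_coding_sequence(genome, sorf)
        for pv in enumerate_possible(cds, methylation, rates):
            p = 1.0 - math.exp(
                -config.cohort_scale * pv.rate * config.selection_factor(pv.consequence)
            )
            if rng.random() >= p:
                continue
            if rng.random() < config.high_af_fraction:
                af = float(rng.uniform(0.001, 0.01))
            else:
                af = float(10 ** rng.uniform(-6, math.log10(5e-4)))
            low_quality = rng.random() < config.low_quality_fraction
            if rng.random() < config.low_depth_fraction:
                depth = float(rng.uniform(0.0, 0.9))
            else:
                depth = float(max(1.0, rng.normal(30.0, 5.0)))
            rows.append(
                {
                    "chrom": pv.chrom,
                    "pos": pv.genomic_pos + 1,  # VCF-style 1-based
                    "ref": pv.ref,
                    "alt": pv.alt,
                    "af": af,
                    "filter": "lowqual" if low_quality else "PASS",
                    "depth": depth,
                    "low_quality": low_quality,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "af", "filter", "depth", "low_quality"],
    )
    if len(df):
        df = df.drop_duplicates(["chrom", "pos", "ref", "alt"]).sort_values(
            ["chrom", "pos", "ref", "alt"], kind="stable"
        ).reset_index(drop=True)
    return df


@dataclass
class SyntheticDataset:
    """Everything one simulation produced, in memory."""

    config: SimulationConfig
    genome: dict[str, str]
    sorfs: list[SORFRecord]
    host_genes: list[tuple[int, int]]
    rates: MutationRateTable
    methylation_tracks: list[pd.DataFrame]
    methylation: MethylationMap
    variants: pd.DataFrame
    score_track: pd.DataFrame


def simulate(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Run the full generator chain from one seed."""
    from .mutation_model import build_methylation_map

    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    reference = generate_reference(config, rng)
    sorfs, hosts, reference = plant_sorfs(config, reference, rng)
    genome = {config.chrom: reference}
    rates = toy_rate_table()
    tracks = generate_methylation_tracks(config, reference, rng)
    methylation = build_methylation_map(tracks)
    variants = simulate_variants(config, genome, sorfs, rates, methylation, rng)
    score = generate_score_track(config, rng)
    return SyntheticDataset(
        config=config,
        genome=genome,
        sorfs=sorfs,
        host_genes=hosts,
        rates=rates,
        methylation_tracks=tracks,
        methylation=methylation,
        variants=variants,
        score_track=score,
    )


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, str]:
    """Write a dataset in the exact formats the pipeline reads.

    Emits the reference FASTA, BED12 sORFs, the VCF-like sites table, the
    rate table, the per-epigenome methylation tracks plus their
    pre-averaged form, the score track, and a manifest recording the seed
    and every parameter.  Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": str(outdir / "genome.fa"),
        "bed": str(outdir / "sorfs.bed"),
        "sites": str(outdir / "sites.tsv"),
        "rates": str(outdir / "rates.tsv"),
        "methylation_mean": str(outdir / "methylation_mean.tsv"),
        "score_track": str(outdir / "score_track.tsv"),
        "manifest": str(outdir / "manifest.json"),
    }
    write_fasta(dataset.genome, paths["fasta"])
    Path(paths["bed"]).write_text(sorfs_to_bed12(dataset.sorfs))
    dataset.variants.to_csv(paths["sites"], sep="\t", index=False, float_format="%.8g")
    dataset.rates.to_tsv(paths["rates"])
    merged = pd.concat(dataset.methylation_tracks, ignore_index=True)
    mean = merged.groupby(["chrom", "pos"], as_index=False)["fraction"].mean()
    mean.to_csv(paths["methylation_mean"], sep="\t", index=False, float_format="%.6g")
    track_dir = outdir / "methylation_tracks"
    track_dir.mkdir(exist_ok=True)
    for i, track in enumerate(dataset.methylation_tracks):
        track.to_csv(track_dir / f"epigenome_{i:02d}.tsv", sep="\t", index=False, float_format="%.6g")
    paths["methylation_tracks"] = str(track_dir)
    dataset.score_track.to_csv(paths["score_track"], sep="\t", index=False, float_format="%.6g")
    manifest = {"config": dataset.config.to_dict(), "n_sorfs": len(dataset.sorfs),
                "n_variants": int(len(dataset.variants))}
    Path(paths["manifest"]).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths
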