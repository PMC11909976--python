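import hashlib

import numpy as np
import pytest

from sorfconstraint.consequence import GENETIC_CODE
from sorfconstraint.io_formats import read_bed12
from sorfconstraint.sequence_model import extract_coding_sequence
from sorfconstraint.synthetic import (
    SimulationConfig,
    generate_methylation_tracks,
    generate_reference,
    generate_score_track,
    plant_sorfs,
    simulate,
    sorfs_to_bed12,
    toy_rate_table,
    write_dataset,
)

SMALL = dict(
    genome_length=60_000,
    n_per_class={"uORF": 6, "dORF": 5, "lncRNA-ORF": 5, "intORF": 3, "uoORF": 3, "doORF": 3},
)


class TestReference:
    def test_seed_reproducibility(self, tmp_path):
        a = simulate(SimulationConfig(seed=9, **SMALL))
        b = simulate(SimulationConfig(seed=9, **SMALL))
        pa = write_dataset(a, tmp_path / "a")
        pb = write_dataset(b, tmp_path / "b")
        ha = hashlib.sha256(open(pa["fasta"], "rb").read()).hexdigest()
        hb = hashlib.sha256(open(pb["fasta"], "rb").read()).hexdigest()
        assert ha == hb
        assert a.variants.equals(b.variants)

    def test_gc_fraction_close_to_target(self):
        config = SimulationConfig(seed=1, genome_length=100_000, gc_fraction=0.5)
        seq = generate_reference(config, np.random.default_rng(config.seed))
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.02

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            generate_reference(
                SimulationConfig(genome_length=0), np.random.default_rng(0)
            )


class TestPlanting:
    def test_requested_class_counts(self):
        config = SimulationConfig(seed=2, **SMALL)
        rng = np.random.default_rng(config.seed)
        genome = generate_reference(config, rng)
        sorfs, hosts, _ = plant_sorfs(config, genome, rng)
        by_class = {}
        for s in sorfs:
            by_class[s.sorf_class] = by_class.get(s.sorf_class, 0) + 1
        assert by_class == SMALL["n_per_class"]
        # every overlap-class sORF got a host gene interval
        assert len(hosts) == 3 + 3 + 3

    def test_planted_orfs_translate_cleanly(self, neutral_dataset):
        ds = neutral_dataset
        for sorf in ds.sorfs[:40]:
            cds = extract_coding_sequence(ds.genome, sorf)
            assert len(cds) % 3 == 0
            assert cds.bases[:3] == "ATG"
            codons = [cds.bases[i : i + 3] for i in range(0, len(cds), 3)]
            assert GENETIC_CODE[codons[-1]] == "*"
            assert all(GENETIC_CODE[c] != "*" for c in codons[:-1])

    def test_sorfs_do_not_overlap_each_other(self, neutral_dataset):
        spans = sorted(s.span for s in neutral_dataset.sorfs)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_bed12_round_trip(self, tmp_path):
        ds = simulate(SimulationConfig(seed=3, **SMALL))
        path = tmp_path / "s.bed"
        path.write_text(sorfs_to_bed12(ds.sorfs))
        back = read_bed12(path)
        assert len(back) == len(ds.sorfs)
        for orig, rec in zip(ds.sorfs, back):
            assert rec.blocks == orig.blocks
            assert rec.strand == orig.strand
            assert rec.sorf_class == orig.sorf_class


class TestVariantSimulation:
    def test_zero_scale_produces_no_variants(self):
        ds = simulate(SimulationConfig(seed=4, cohort_scale=0.0, **SMALL))
        assert len(ds.variants) == 0

    def test_selection_factor_bounds_validated(self):
        with pytest.raises(ValueError):
            SimulationConfig(selection={"missense": 1.5})

    def test_variant_positions_fall_in_sorf_blocks(self, neutral_dataset):
        ds = neutral_dataset
        block_positions = set()
        for s in ds.sorfs:
            for start, end in s.blocks:
                block_positions.update(range(start, end))
        assert set(ds.variants["pos"] - 1) <= block_positions

    def test_depletion_lowers_variant_count(self):
        neutral = simulate(SimulationConfig(seed=5, **SMALL))
        depleted = simulate(
            SimulationConfig(seed=5, selection={"missense": 0.3}, **SMALL)
        )
        assert len(depleted.variants) < len(neutral.variants)


class TestTracks:
    def test_methylation_track_count_and_range(self):
        config = SimulationConfig(seed=6, **SMALL)
        rng = np.random.default_rng(config.seed)
        genome = generate_reference(config, rng)
        tracks = generate_methylation_tracks(config, genome, rng)
        assert len(tracks) == config.n_methylation_tracks == 37
        for t in tracks[:3]:
            assert ((t["fraction"] >= 0) & (t["fraction"] <= 1)).all()

    def test_constant_score_track(self):
        config = SimulationConfig(seed=6, **SMALL)
        t = generate_score_track(config, np.random.default_rng(0), constant=2.5)
        assert (t["score"] == 2.5).all()

    def test_rate_table_structure(self):
        table = toy_rate_table()
        # CpG transition exceeds plain transition exceeds transversion
        cpg = table.lookup("ACG", "T", 0)   # C->T inside CpG
        ts = table.lookup("ACA", "T", 0)    # C->T outside CpG: plain transition
        tv = table.lookup("ACA", "G", 0)    # C->G: transversion
        assert cpg > ts > tv
        # methylation raises CpG transition rates only
        assert table.lookup("ACG", "T", 15) > cpg
        assert table.lookup("ACA", "T", 15) == ts


class TestWriteDataset:
    def test_written_formats_readable(self, tmp_path):
        ds = simulate(SimulationConfig(seed=8, **SMALL))
        paths = write_dataset(ds, tmp_path / "out")
        from sorfconstraint.io_formats import open_fasta, read_variant_sites
        from sorfconstraint.mutation_model import MutationRateTable

        genome = open_fasta(paths["fasta"])
        assert len(genome[ds.config.chrom]) == ds.config.genome_length
        sorfs = read_bed12(paths["bed"])
        assert len(sorfs) == len(ds.sorfs)
        sites = read_variant_sites(paths["sites"])
        assert len(sites) == len(ds.variants)
        rates = MutationRateTable.from_tsv(paths["rates"])
        assert len(rates) == 64 * 3 * 16
        import json

        manifest = json.loads((tmp_path / "out" / "manifest.json").read_text())
        assert manifest["config"]["seed"] == 8
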