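import numpy as np
import pandas as pd
import pytest

from sorfconstraint.consequence import ConsequenceType
from sorfconstraint.io_formats import SORFRecord, VariantSite
from sorfconstraint.mutation_model import (
    ExclusionReason,
    MethylationMap,
    MutationRateTable,
    SiteTable,
    build_methylation_map,
    enumerate_possible,
    expected_counts,
    filter_possible,
    fit_calibration,
    is_cpg_context,
    methylation_bin,
)
from sorfconstraint.sequence_model import extract_coding_sequence
from sorfconstraint.synthetic import toy_rate_table


def make_cds(seq, pad="A", strand="+"):
    genome = {"c": pad + seq + "G" + "AAAA"}
    sorf = SORFRecord(id="s", chrom="c", strand=strand, blocks=((1, 1 + len(seq)),))
    return extract_coding_sequence(genome, sorf)


NO_METH = MethylationMap({})


class TestMethylationBinning:
    @pytest.mark.parametrize(
        ("fraction", "expected"),
        [(0.0, 0), (1.0, 15), (0.5, 8), (0.4999, 7), (0.0625, 1), (0.9375, 15)],
    )
    def test_bin_edges(self, fraction, expected):
        assert methylation_bin(fraction) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            methylation_bin(1.5)

    def test_mean_across_tracks_with_partial_coverage(self):
        t1 = pd.DataFrame({"chrom": "c", "pos": [5, 6], "fraction": [0.2, 1.0]})
        t2 = pd.DataFrame({"chrom": "c", "pos": [5], "fraction": [0.8]})
        m = build_methylation_map([t1, t2])
        assert m.fraction_at("c", 5) == pytest.approx(0.5)
        assert m.bin_at("c", 5) == 8
        assert m.bin_at("c", 6) == 15  # only one track has a value
        assert m.bin_at("c", 99) == 0  # unmapped position

    def test_requires_tracks_and_valid_fractions(self):
        with pytest.raises(ValueError):
            build_methylation_map([])
        bad = pd.DataFrame({"chrom": "c", "pos": [1], "fraction": [1.2]})
        with pytest.raises(ValueError):
            build_methylation_map([bad])


class TestRateTable:
    def test_strand_canonicalized_lookup(self):
        # table holds only the pyrimidine-centred context
        table = MutationRateTable({("ACG", "T", 0): 1e-8})
        assert table.lookup("ACG", "T", 0) == 1e-8
        # reverse complement: CGT with alt A
        assert table.lookup("CGT", "A", 0) == 1e-8
        with pytest.raises(KeyError):
            table.lookup("AAA", "G", 0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            MutationRateTable({("ACG", "T", 0): -1.0})

    def test_tsv_round_trip(self, tmp_path):
        table = toy_rate_table()
        path = tmp_path / "rates.tsv"
        table.to_tsv(path)
        back = MutationRateTable.from_tsv(path)
        assert len(back) == len(table)
        assert back.lookup("ACG", "T", 7) == table.lookup("ACG", "T", 7)


class TestEnumeratePossible:
    def test_nine_variants_per_codon_three_per_base(self):
        pvs = enumerate_possible(make_cds("ATGTAA"), NO_METH, toy_rate_table())
        assert len(pvs) == 18  # 2 codons x 9
        for pos in {pv.genomic_pos for pv in pvs}:
            assert sum(1 for pv in pvs if pv.genomic_pos == pos) == 3

    def test_three_codons_27_variants(self):
        assert len(enumerate_possible(make_cds("ATGCTGTAA"), NO_METH, toy_rate_table())) == 27

    def test_n_codon_contributes_zero(self):
        assert len(enumerate_possible(make_cds("ATGCNGTAA"), NO_METH, toy_rate_table())) == 18

    def test_cpg_methylation_bin_applied_only_at_cpg(self):
        # sequence with a CpG inside: ATG CGG TAA ; C of CpG at coding idx 3
        cds = make_cds("ATGCGGTAA")
        meth = MethylationMap({("c", p): 0.99 for p in range(20)})
        pvs = enumerate_possible(cds, meth, toy_rate_table(), cpg_only_methylation=True)
        for pv in pvs:
            if is_cpg_context(pv.context):
                assert pv.methylation_bin == 15
            else:
                assert pv.methylation_bin == 0

    def test_per_codon_conservation_and_rate_decomposition(self, neutral_dataset):
        ds = neutral_dataset
        table = toy_rate_table()
        for sorf in ds.sorfs[:10]:
            cds = extract_coding_sequence(ds.genome, sorf)
            pvs = enumerate_possible(cds, ds.methylation, table)
            assert len(pvs) == 9 * cds.n_codons
            exp = expected_counts(pvs, calibration_k=1.0)
            assert exp.snv_rate_sum == pytest.approx(
                sum(exp.rate_sum[c] for c in ConsequenceType)
            )
            assert exp.snv_possible == 9 * cds.n_codons

    def test_methylation_monotonicity(self):
        # raising the methylation map uniformly cannot decrease expectation
        cds = make_cds("ATGCGGCGGTAA")
        table = toy_rate_table()  # CpG rates increase with bin
        totals = []
        for level in (0.0, 0.5, 1.0):
            meth = MethylationMap({("c", p): level for p in range(20)})
            pvs = enumerate_possible(cds, meth, table)
            totals.append(expected_counts(pvs, 1.0).snv_expected)
        assert totals == sorted(totals)


class TestFilterPossible:
    def make_possible(self):
        return enumerate_possible(make_cds("ATGCTGTAA"), NO_METH, toy_rate_table())

    def site_table(self, **kwargs):
        return SiteTable(kwargs.pop("variants", []), **kwargs)

    def test_high_af_excluded(self):
        pvs = self.make_possible()
        target = pvs[0]
        v = VariantSite("c", target.genomic_pos + 1, target.ref, target.alt,
                        af=0.002, passed_filters=True, depth=30.0)
        out = filter_possible(pvs, SiteTable([v]))
        flagged = [pv for pv in out if pv.genomic_pos == target.genomic_pos and pv.alt == target.alt]
        assert flagged[0].excluded and flagged[0].reason is ExclusionReason.HIGH_AF
        # same position, different alt: only AF of the matching allele counts
        others = [pv for pv in out if pv.genomic_pos == target.genomic_pos and pv.alt != target.alt]
        assert all(not pv.excluded for pv in others)

    def test_low_coverage_excluded(self):
        pvs = self.make_possible()
        target = pvs[0]
        v = VariantSite("c", target.genomic_pos + 1, target.ref, target.alt,
                        af=1e-5, passed_filters=True, depth=0.5)
        out = filter_possible(pvs, SiteTable([v]))
        flagged = [pv for pv in out if pv.genomic_pos == target.genomic_pos]
        assert all(pv.excluded and pv.reason is ExclusionReason.LOW_COVERAGE for pv in flagged)

    def test_low_quality_site_excluded(self):
        pvs = self.make_possible()
        target = pvs[0]
        v = VariantSite("c", target.genomic_pos + 1, target.ref, target.alt,
                        af=1e-5, passed_filters=False, depth=30.0, low_quality=True)
        out = filter_possible(pvs, SiteTable([v]))
        flagged = [pv for pv in out if pv.genomic_pos == target.genomic_pos]
        assert all(pv.reason is ExclusionReason.LOW_QUALITY_SITE for pv in flagged)

    def test_untouched_site_retained(self):
        out = filter_possible(self.make_possible(), SiteTable([]))
        assert all(not pv.excluded for pv in out)


class TestExpectedCounts:
    def test_identity_linearity_additivity(self):
        pvs = enumerate_possible(make_cds("ATGCTGTAA"), NO_METH, toy_rate_table())
        e1 = expected_counts(pvs, calibration_k=1.0)
        assert e1.snv_expected == pytest.approx(e1.snv_rate_sum)
        e2 = expected_counts(pvs, calibration_k=2.0)
        assert e2.snv_expected == pytest.approx(2 * e1.snv_expected)
        assert e1.snv_expected == pytest.approx(
            sum(e1.expected[c] for c in ConsequenceType)
        )

    def test_excluded_variants_do_not_contribute(self):
        pvs = enumerate_possible(make_cds("ATGCTGTAA"), NO_METH, toy_rate_table())
        v = VariantSite("c", pvs[0].genomic_pos + 1, pvs[0].ref, pvs[0].alt,
                        af=1e-5, passed_filters=True, depth=0.1)
        filtered = filter_possible(pvs, SiteTable([v]))
        full = expected_counts(pvs, 1.0)
        reduced = expected_counts(filtered, 1.0)
        assert reduced.snv_possible < full.snv_possible
        assert reduced.snv_rate_sum < full.snv_rate_sum

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            expected_counts([], calibration_k=0.0)


class TestCalibration:
    def test_exact_proportionality(self):
        assert fit_calibration([(10, 5), (20, 10)]) == pytest.approx(2.0)

    def test_single_pair_with_relaxed_config(self):
        assert fit_calibration([(8, 4)], allow_single=True) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            fit_calibration([(8, 4)])

    def test_all_zero_rate_sums(self):
        with pytest.raises(ValueError):
            fit_calibration([(1, 0.0), (2, 0.0)])

    def test_poisson_noise_recovery(self):
        rng = np.random.default_rng(3)
        k_true = 1.7e6
        sums = rng.uniform(1e-6, 1e-5, size=400)
        obs = rng.poisson(k_true * sums)
        k_hat = fit_calibration(list(zip(obs, sums)))
        assert k_hat == pytest.approx(k_true, rel=0.05)
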