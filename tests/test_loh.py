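"""Segmentation, purity/ploidy inference, LOH calling and %LOH aggregation."""

import numpy as np
import pandas as pd
import pytest

from panelval.loh import (
    AllelicCopyNumberModel,
    AscnSegment,
    RawSegment,
    SnpProfile,
    call_ascn,
    expected_baf,
    expected_logr,
    fit_purity_ploidy,
    gene_loh_intersect,
    sample_percent_loh,
    segment_profile,
)
from panelval.simulate import SegmentSpec, simulate_snp_profile


class TestClosedForms:
    def test_pure_diploid_identity(self):
        assert expected_baf(1.0, 1, 1) == pytest.approx(0.5)
        assert expected_logr(1.0, 2.0, 1, 1) == pytest.approx(0.0)

    def test_half_purity_copy_neutral_loh(self):
        # rho=0.5, (nA,nB)=(2,0), psi=2: BAF 0.25/0.75 by phase, logR 0
        assert expected_baf(0.5, 2, 0) == pytest.approx(0.25)
        assert expected_logr(0.5, 2.0, 2, 0) == pytest.approx(0.0)

    def test_deletion_lowers_logr(self):
        assert expected_logr(0.8, 2.0, 1, 0) < 0


def three_state_profile(rho=0.6, noise=0.0, seed=0, snps_per_mb=2.0):
    segs = [
        SegmentSpec("chr1", 30_000_000, 1, 1),
        SegmentSpec("chr1", 30_000_000, 2, 0),
        SegmentSpec("chr1", 40_000_000, 2, 1),
    ]
    return simulate_snp_profile(
        rho, segs, snps_per_mb=snps_per_mb, baf_sd=noise, logr_sd=noise, seed=seed
    )


class TestSegmentation:
    def test_noise_free_single_change_recovered_exactly(self):
        segs = [SegmentSpec("chr1", 50_000_000, 1, 1), SegmentSpec("chr1", 50_000_000, 2, 0)]
        profile = simulate_snp_profile(0.6, segs, snps_per_mb=1.0, baf_sd=0.0,
                                       logr_sd=0.0, seed=3)
        out = segment_profile(profile)
        assert len(out) == 2
        # boundary within one SNP spacing (~1 Mb) of the true change point
        assert abs(out[0].end - 50_000_000) < 2_000_000

    def test_homogeneous_chromosome_is_one_segment(self):
        profile = simulate_snp_profile(
            0.7, [SegmentSpec("chr1", 80_000_000, 1, 1)], snps_per_mb=1.0,
            baf_sd=0.01, logr_sd=0.02, seed=1,
        )
        assert len(segment_profile(profile)) == 1

    def test_three_segments_recovered_under_noise(self):
        """With sd 0.02 noise the three-state chromosome is recovered in at
        least 95% of seeded runs."""
        ok = 0
        n_runs = 200
        for seed in range(n_runs):
            profile = three_state_profile(noise=0.02, seed=seed)
            if len(segment_profile(profile)) == 3:
                ok += 1
        assert ok / n_runs >= 0.95

    def test_segments_tile_chromosome(self):
        profile = three_state_profile(noise=0.02, seed=5)
        out = segment_profile(profile)
        assert out[0].start == 0
        assert out[-1].end == profile.chrom_lengths["chr1"]
        for a, b in zip(out, out[1:]):
            assert a.end == b.start

    def test_unsorted_profile_rejected(self):
        df = pd.DataFrame({"chrom": "chr1", "pos": [10, 5, 20], "baf": 0.5, "logr": 0.0})
        with pytest.raises(ValueError, match="increasing"):
            SnpProfile(data=df)

    def test_too_few_snps_rejected(self):
        df = pd.DataFrame({"chrom": "chr1", "pos": range(1, 6), "baf": 0.5, "logr": 0.0})
        with pytest.raises(ValueError, match="SNPs"):
            segment_profile(SnpProfile(data=df))


class TestPurityPloidy:
    def test_recovery_at_intermediate_purity(self):
        profile = three_state_profile(rho=0.6, noise=0.02, seed=11)
        fit = fit_purity_ploidy(segment_profile(profile))
        assert fit.purity == pytest.approx(0.6, abs=0.05)
        # truth ploidy: (30*2 + 30*2 + 40*3)/100 = 2.4
        assert fit.ploidy == pytest.approx(2.4, abs=0.1)

    def test_pure_diploid_fits_identity_and_flags_degenerate(self):
        profile = simulate_snp_profile(
            1.0,
            [SegmentSpec(f"chr{i}", 50_000_000, 1, 1) for i in (1, 2, 3)],
            snps_per_mb=1.0, baf_sd=0.0, logr_sd=0.0, seed=2,
        )
        fit = fit_purity_ploidy(segment_profile(profile))
        assert (fit.purity, fit.ploidy) == (1.0, 2.0)
        assert fit.non_identifiable

    def test_equal_ploidy_ties_break_toward_higher_purity(self):
        """A balanced profile fits every purity equally well at psi=2; the
        reported solution is the highest-purity grid point."""
        segs = [RawSegment("chr1", 0, 10**7, 50, 0.5, 0.0) for _ in range(3)]
        segs = [RawSegment("chr1", i * 10**7, (i + 1) * 10**7, 50, 0.5, 0.0)
                for i in range(3)]
        fit = fit_purity_ploidy(segs)
        assert fit.purity == 1.0 and fit.ploidy == 2.0

    def test_requires_three_segments(self):
        with pytest.raises(ValueError):
            fit_purity_ploidy([RawSegment("chr1", 0, 100, 10, 0.5, 0.0)])


class TestAscn:
    def test_copy_neutral_loh_recovered(self):
        profile = three_state_profile(rho=0.6, noise=0.01, seed=7)
        raw = segment_profile(profile)
        ascn = call_ascn(raw, fit_purity_ploidy(raw))
        states = {(s.nA, s.nB) for s in ascn}
        assert (2, 0) in states and (1, 1) in states and (2, 1) in states
        assert all(s.is_loh == (s.nB == 0 and s.nA >= 1) for s in ascn)

    def test_balanced_and_deleted_states_are_not_loh(self):
        seg = AscnSegment("chr1", 0, 100, nA=1, nB=1, mean_baf=0.5, mean_logr=0.0)
        assert not seg.is_loh
        hom_del = AscnSegment("chr1", 0, 100, nA=0, nB=0, mean_baf=0.5, mean_logr=-2.0)
        assert not hom_del.is_loh


def seg(chrom, start, end, nA, nB):
    return AscnSegment(chrom, start, end, nA=nA, nB=nB, mean_baf=0.7, mean_logr=0.0)


class TestPercentLoh:
    def test_simple_arithmetic(self):
        ascn = [seg("chr1", 0, 30_000_000, 2, 0), seg("chr1", 30_000_000, 60_000_000, 1, 1),
                seg("chr2", 0, 40_000_000, 1, 1)]
        res = sample_percent_loh(ascn)
        assert res.sample_percent_loh == pytest.approx(30.0)
        assert res.excluded_whole_chromosome_bp == 0

    def test_whole_chromosome_event_excluded_from_both_sides(self):
        ascn = [
            seg("chr1", 0, 95_000_000, 2, 0),   # 95% of chr1 -> excluded
            seg("chr1", 95_000_000, 100_000_000, 1, 1),
            seg("chr2", 0, 100_000_000, 1, 1),
        ]
        res = sample_percent_loh(ascn)
        assert res.excluded_whole_chromosome_bp == 95_000_000
        assert res.sample_percent_loh == pytest.approx(0.0)
        off = sample_percent_loh(ascn, exclude_whole_chromosome=False)
        assert off.sample_percent_loh == pytest.approx(100 * 95 / 200)

    def test_no_loh_segments(self):
        res = sample_percent_loh([seg("chr1", 0, 10**8, 1, 1)])
        assert res.sample_percent_loh == 0.0 and not res.high_gloh

    def test_sex_chromosomes_excluded(self):
        ascn = [seg("chr1", 0, 10**8, 1, 1), seg("chrX", 0, 10**8, 1, 0)]
        res = sample_percent_loh(ascn)
        assert res.sample_percent_loh == 0.0

    def test_zero_eligible_length_raises(self):
        with pytest.raises(ValueError):
            sample_percent_loh([seg("chrX", 0, 10**8, 1, 0)])

    def test_converting_segment_to_loh_never_decreases(self):
        """On a fixed eligible genome, turning a heterozygous segment into
        LOH can only raise the sample %LOH."""
        base = [seg("chr1", 0, 50_000_000, 2, 0), seg("chr1", 50_000_000, 10**8, 1, 1),
                seg("chr2", 0, 40_000_000, 1, 1), seg("chr2", 40_000_000, 10**8, 1, 1)]
        before = sample_percent_loh(base).sample_percent_loh
        more = [s if not (s.chrom == "chr2" and s.start == 0) else
                seg("chr2", 0, 40_000_000, 1, 0) for s in base]
        after = sample_percent_loh(more).sample_percent_loh
        assert after >= before

    def test_high_gloh_cutoff(self):
        ascn = [seg("chr1", 0, 20_000_000, 2, 0), seg("chr1", 20_000_000, 10**8, 1, 1)]
        assert sample_percent_loh(ascn, high_gloh_cutoff=16.0).high_gloh
        assert not sample_percent_loh(ascn, high_gloh_cutoff=25.0).high_gloh


class TestGeneIntersect:
    genes = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [10_000, 49_999_999, 10_000],
            "end": [20_000, 50_050_000, 20_000],
            "name": ["BRCA1", "EDGE", "OTHER"],
        }
    )
    ascn = [seg("chr1", 0, 50_000_000, 2, 0), seg("chr1", 50_000_000, 10**8, 1, 1)]

    def test_gene_inside_loh_flagged(self):
        assert gene_loh_intersect(self.ascn, self.genes)["BRCA1"]

    def test_gene_on_other_chromosome_not_flagged(self):
        assert not gene_loh_intersect(self.ascn, self.genes)["OTHER"]

    def test_one_bp_overlap_flags_by_default(self):
        flags = gene_loh_intersect(self.ascn, self.genes)
        assert flags["EDGE"]
        strict = gene_loh_intersect(self.ascn, self.genes, min_overlap_fraction=0.5)
        assert not strict["EDGE"]

    def test_malformed_interval_rejected(self):
        bad = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [100], "name": ["X"]})
        with pytest.raises(ValueError, match="malformed"):
            gene_loh_intersect(self.ascn, bad)


class TestModelResults:
    def test_end_to_end_summary_and_frames(self):
        segs = [
            SegmentSpec("chr1", 50_000_000, 2, 0), SegmentSpec("chr1", 50_000_000, 1, 1),
            SegmentSpec("chr2", 100_000_000, 1, 1), SegmentSpec("chr3", 100_000_000, 1, 1),
        ]
        profile = simulate_snp_profile(0.6, segs, snps_per_mb=1.0, baf_sd=0.02,
                                       logr_sd=0.05, seed=9)
        res = AllelicCopyNumberModel(profile).fit()
        assert res.purity == pytest.approx(0.6, abs=0.05)
        assert res.percent_loh == pytest.approx(100 * 50 / 300, abs=3.0)
        frame = res.segments_frame()
        assert {"nA", "nB", "is_loh"} <= set(frame.columns)
        text = res.summary()
        assert "purity" in text and "%LOH" in text

    def test_percent_loh_invariant_to_snp_density(self):
        segs = [
            SegmentSpec("chr1", 50_000_000, 2, 0), SegmentSpec("chr1", 50_000_000, 1, 1),
            SegmentSpec("chr2", 100_000_000, 1, 1), SegmentSpec("chr3", 100_000_000, 1, 1),
        ]
        results = []
        for density in (1.0, 3.0):
            profile = simulate_snp_profile(0.7, segs, snps_per_mb=density,
                                           baf_sd=0.0, logr_sd=0.0, seed=4)
            results.append(AllelicCopyNumberModel(profile).fit().percent_loh)
        assert results[0] == pytest.approx(results[1], abs=1.0)
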