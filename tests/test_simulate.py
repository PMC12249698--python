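"""Synthetic-data layer: detection model, cohort draws, dilution, profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from panelval.biomarkers import msi_classify
from panelval.calls import Compartment, TruthVariant, VariantKind, match_calls
from panelval.fixtures import lod_tier_truth, s800_truth_variants
from panelval.simulate import (
    CohortSpec,
    PairedSampleSpec,
    ReferenceStandardSpec,
    SegmentSpec,
    simulate_cohort,
    simulate_msi_sites,
    simulate_paired_tissue_plasma,
    simulate_reference_standard,
    simulate_snp_profile,
)
from panelval.loh import expected_baf, expected_logr, _fold


class TestReferenceStandard:
    def test_two_percent_standard_fully_detected(self):
        """27 SNV/indel + 3 CNV + 6 fusions at 2% VAF and 1000x: per-variant
        detection probability exceeds 0.9999, so all replicates see all 36
        VAF-bearing variants."""
        spec = ReferenceStandardSpec(
            name="std2pct", variants=s800_truth_variants(0.02),
            depth_target=1000, n_replicates=3, seed=42,
        )
        replicates, truth = simulate_reference_standard(spec)
        assert len(truth.variants) == 36
        analytic = sps.binom.sf(2, 1000, 0.02)
        assert analytic > 0.9999
        for calls in replicates:
            counts, _ = match_calls(calls, truth)
            assert counts.fn == 0 and counts.fp == 0

    def test_zero_design_vaf_never_called(self):
        variants = [TruthVariant(kind=VariantKind.SNV, chrom="chr1", pos=10,
                                 ref="A", alt="T", design_vaf=0.0)]
        spec = ReferenceStandardSpec(name="wt", variants=variants, depth_target=5000,
                                     n_replicates=5, seed=0)
        replicates, _ = simulate_reference_standard(spec)
        assert all(calls == [] for calls in replicates)

    def test_determinism_identical_outputs(self):
        spec = ReferenceStandardSpec(
            name="std", variants=lod_tier_truth(0.013), depth_target=560,
            n_replicates=2, seed=7,
        )
        a, _ = simulate_reference_standard(spec)
        b, _ = simulate_reference_standard(spec)
        assert [[c.identity_key() for c in rep] for rep in a] == [
            [c.identity_key() for c in rep] for rep in b
        ]
        assert [[c.vaf for c in rep] for rep in a] == [[c.vaf for c in rep] for rep in b]

    def test_detection_rate_matches_binomial_tail(self):
        """Empirical per-variant detection over many replicates sits within
        3 standard errors of 1 - BinomCDF(min_alt-1; depth, VAF)."""
        n_rep = 400
        spec = ReferenceStandardSpec(
            name="lod", variants=lod_tier_truth(0.006, 25), depth_target=794,
            n_replicates=n_rep, seed=11,
        )
        replicates, truth = simulate_reference_standard(spec)
        n_trials = n_rep * len(truth.variants)
        detected = sum(len(r) for r in replicates)
        p = sps.binom.sf(2, 794, 0.006)
        se = np.sqrt(p * (1 - p) / n_trials)
        assert abs(detected / n_trials - p) < 3 * se

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ValueError):
            ReferenceStandardSpec(name="bad", variants=lod_tier_truth(0.02),
                                  depth_target=0)


class TestCohort:
    def spec(self, **kw):
        base = dict(
            n_patients=400,
            tumor_type_mix={"pancreatic": 0.4, "lung": 0.3, "ovarian": 0.3},
            gene_alteration_freqs={"TP53": 0.4, "KRAS": 0.25},
            seed=5,
        )
        base.update(kw)
        return CohortSpec(**base)

    def test_msi_prevalence_within_binomial_interval(self):
        n = 1000
        prev = 0.0119
        cohort = simulate_cohort(self.spec(n_patients=n, msi_high_prob=prev))
        count = sum(p["msi_high"] for p in cohort)
        lo, hi = sps.binom.ppf([0.005, 0.995], n, prev)
        assert lo <= count <= hi

    def test_zero_frequencies_give_no_alterations(self):
        cohort = simulate_cohort(self.spec(gene_alteration_freqs={"TP53": 0.0}))
        assert all(p["calls"] == [] for p in cohort)

    def test_fixed_seed_reproduces_cohort(self):
        a = simulate_cohort(self.spec())
        b = simulate_cohort(self.spec())
        assert [(p["tumor_type"], p["tmb"], p["msi_score"]) for p in a] == [
            (p["tumor_type"], p["tmb"], p["msi_score"]) for p in b
        ]

    def test_gloh_only_for_designated_types(self):
        cohort = simulate_cohort(self.spec())
        for p in cohort:
            assert (p["gloh"] is not None) == (p["tumor_type"] == "ovarian")

    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            self.spec(tumor_type_mix={"lung": 0.5})
        with pytest.raises(ValueError, match="mix"):
            self.spec(tumor_type_mix={})


class TestPairedDilution:
    def variants(self):
        return [
            TruthVariant(kind=VariantKind.SNV, chrom="chr12", pos=25_398_284,
                         ref="C", alt="A", gene="KRAS", design_vaf=0.3225),
            TruthVariant(kind=VariantKind.SNV, chrom="chr3", pos=178_952_085,
                         ref="C", alt="T", gene="PIK3CA", design_vaf=0.1269),
        ]

    def test_no_shedding_empty_plasma(self):
        spec = PairedSampleSpec(tissue_variants=self.variants(), ctdna_fraction=0.3,
                                plasma_depth=2000, shedding=False, seed=1)
        tissue, plasma = simulate_paired_tissue_plasma(spec)
        assert len(tissue) == 2 and plasma == []

    def test_strong_dilution_still_detected_at_depth(self):
        """A 32.25% tissue variant diluted to ~0.68% is detected at 2000x
        with probability > 0.999."""
        frac = 0.0068 / 0.3225
        p = sps.binom.sf(2, 2000, 0.3225 * frac)
        assert p > 0.999
        spec = PairedSampleSpec(tissue_variants=self.variants(), ctdna_fraction=frac,
                                plasma_depth=2000, seed=3)
        _, plasma = simulate_paired_tissue_plasma(spec)
        assert any(c.gene == "KRAS" for c in plasma)

    def test_full_ctdna_fraction_matches_tissue_vafs(self):
        spec = PairedSampleSpec(tissue_variants=self.variants(), ctdna_fraction=1.0,
                                plasma_depth=20_000, tissue_depth=20_000, seed=9)
        tissue, plasma = simulate_paired_tissue_plasma(spec)
        t = {c.gene: c.vaf for c in tissue}
        p = {c.gene: c.vaf for c in plasma}
        for gene in t:
            assert p[gene] == pytest.approx(t[gene], abs=0.02)

    def test_detection_monotone_in_ctdna_fraction(self):
        """Plasma recovery of tissue variants never improves as the ctDNA
        fraction falls."""
        variants = [
            TruthVariant(kind=VariantKind.SNV, chrom="chr1", pos=1000 + i,
                         ref="A", alt="G", design_vaf=0.05)
            for i in range(40)
        ]
        rates = []
        for frac in (0.5, 0.1, 0.02, 0.004):
            detected = 0
            for seed in range(30):
                spec = PairedSampleSpec(tissue_variants=variants, ctdna_fraction=frac,
                                        plasma_depth=1000, seed=seed)
                _, plasma = simulate_paired_tissue_plasma(spec)
                detected += len(plasma)
            rates.append(detected)
        assert rates == sorted(rates, reverse=True)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            PairedSampleSpec(tissue_variants=self.variants(), ctdna_fraction=1.2,
                             plasma_depth=1000)


class TestSnpProfileSimulation:
    def test_segment_means_converge_to_closed_forms(self):
        rho, psi = 0.5, 2.0
        segs = [SegmentSpec("chr1", 40_000_000, 2, 0), SegmentSpec("chr1", 60_000_000, 1, 1)]
        profile = simulate_snp_profile(rho, segs, ploidy=psi, snps_per_mb=5.0,
                                       baf_sd=0.0, logr_sd=0.0, seed=2)
        df = profile.data
        first = df[df["pos"] <= 40_000_000]
        folded = _fold(first["baf"].to_numpy())
        assert folded.mean() == pytest.approx(0.75, abs=1e-9)  # mirrored 0.25
        assert first["logr"].mean() == pytest.approx(0.0, abs=1e-9)
        second = df[df["pos"] > 40_000_000]
        assert second["baf"].mean() == pytest.approx(0.5, abs=0.01)

    def test_phase_randomized_raw_baf_spreads_both_sides(self):
        segs = [SegmentSpec("chr1", 50_000_000, 2, 0)]
        profile = simulate_snp_profile(0.5, segs, snps_per_mb=4.0, baf_sd=0.0,
                                       logr_sd=0.0, seed=8)
        baf = profile.data["baf"].to_numpy()
        assert (baf < 0.4).any() and (baf > 0.6).any()

    def test_invalid_purity_and_empty_segments(self):
        with pytest.raises(ValueError):
            simulate_snp_profile(0.0, [SegmentSpec("chr1", 10**6, 1, 1)])
        with pytest.raises(ValueError):
            simulate_snp_profile(0.5, [])


class TestMsiSites:
    def test_exact_unstable_count_and_score(self):
        sites = simulate_msi_sites(200, 0.25, seed=1)
        assert sites["unstable"].sum() == 50
        score = sites["unstable"].mean()
        assert msi_classify(score).status == "MSI-H"

    def test_all_stable_classifies_mss(self):
        sites = simulate_msi_sites(150, 0.0, seed=2)
        assert sites["unstable"].sum() == 0
        assert msi_classify(sites["unstable"].mean()).status == "MSS"

    def test_ffpe_boundary_fraction_is_msi_high(self):
        sites = simulate_msi_sites(200, 0.195, seed=3)
        assert msi_classify(sites["unstable"].mean(), Compartment.FFPE).status == "MSI-H"

    def test_zero_sites_rejected(self):
        with pytest.raises(ValueError):
            simulate_msi_sites(0, 0.5)
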