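"""End-to-end validation run: recompute every headline quantity from scratch.

Two kinds of quantities are produced:

* exact arithmetic on the built-in validation fixtures — per-tier
  reference-standard sensitivities, MSI sensitivity/specificity, the HER2
  combined concordance, paired tissue/plasma case concordance, and the
  clinical-cohort fractions (success rate, oncogenic fraction,
  actionability tiers, immunotherapy-marker prevalence, HRR and ovarian
  gLOH subgroups);

* seeded simulation — Monte-Carlo limit-of-detection rates under the
  binomial read-sampling model, end-to-end purity/ploidy/%LOH recovery of
  the allele-specific copy-number pipeline, and the cross-assay
  concordance harness (two noisy measurements of one truth) for TMB and
  %LOH.

Every value is computed at call time; :func:`run_validation` returns the
summary plus a list of failed internal assertions (empty on a clean run).
"""

from __future__ import annotations

import numpy as np

from .biomarkers import actionability_rollup, hrr_summary, percent, Tier
from .calls import ConfusionCounts, pair_concordance
from .fixtures import (
    cohort_actionability_records,
    cohort_counts,
    cohort_hrr_calls,
    her2_fish_counts,
    msi_validation_counts,
    ovarian_gloh_flags,
    paired_validation_cases,
    reference_control_rows,
)
from .loh import AllelicCopyNumberModel
from .simulate import SegmentSpec, simulate_snp_profile
from .stats import analytic_detection_rate, lod_profile, pearson_concordance

__all__ = ["run_validation", "loh_recovery_study", "concordance_harness"]

#: Wild-type positions declared by the reference standards; with zero false
#: positives the NPA is 100% for any universe size.
NEGATIVE_UNIVERSE = 100


def _fixture_summary() -> tuple[dict, list[str]]:
    out: dict = {}
    failures: list[str] = []

    rows = reference_control_rows()
    s800_1 = [r for r in rows if r["name"] == "S800-1"]
    tp = sum(r["tp"] for r in s800_1)
    fn = sum(r["fn"] for r in s800_1)
    fp = sum(r["fp"] for r in s800_1)
    out["ppa_2pct_vaf"] = {"value": percent(tp, tp + fn), "n": tp + fn}
    out["npa_2pct_vaf"] = {
        "value": percent(NEGATIVE_UNIVERSE - fp, NEGATIVE_UNIVERSE),
        "n": NEGATIVE_UNIVERSE,
    }
    s800_2 = [r for r in rows if r["name"] == "S800-2"]
    tp2 = sum(r["tp"] for r in s800_2)
    fn2 = sum(r["fn"] for r in s800_2)
    out["ppa_05pct_vaf"] = {"value": percent(tp2, tp2 + fn2), "n": tp2 + fn2}

    for key, name in (
        ("sensitivity_1_3pct_993x", "Tru-Q7-993x"),
        ("sensitivity_1_3pct_560x", "Tru-Q7-560x"),
        ("sensitivity_0_6pct_794x", "Tru-Q7+Q0-794x"),
    ):
        row = next(r for r in rows if r["name"] == name)
        n = row["tp"] + row["fn"]
        out[key] = {"value": percent(row["tp"], n), "n": n}

    msi = msi_validation_counts()
    out["msi_sensitivity"] = {"value": percent(msi.tp, msi.tp + msi.fn), "n": msi.tp + msi.fn}
    out["msi_specificity"] = {
        "value": percent(msi.tn, msi.tn + msi.fp, decimals=0),
        "n": msi.tn + msi.fp,
    }

    her2 = her2_fish_counts()
    total = her2.tp + her2.fp + her2.fn + her2.tn
    out["her2_concordance"] = {"value": percent(her2.tp + her2.tn, total), "n": total}

    cases = paired_validation_cases()
    concordant = sum(1 for tissue, plasma in cases if pair_concordance(tissue, plasma)[1])
    out["tissue_plasma_concordance"] = {"value": percent(concordant, len(cases)), "n": len(cases)}
    if concordant != 7:
        failures.append(f"paired concordance: expected 7 concordant cases, got {concordant}")

    c = cohort_counts()
    out["ngs_success_rate"] = {"value": percent(c["n_success"], c["n_attempted"]), "n": c["n_attempted"]}
    out["oncogenic_fraction"] = {
        "value": percent(c["n_oncogenic"], c["n_alterations"], decimals=1),
        "n": c["n_alterations"],
    }

    summary = actionability_rollup(cohort_actionability_records())
    out["on_label_pct"] = {"value": summary.tier_pct[Tier.ON_LABEL], "n": summary.n_patients}
    out["off_label_pct"] = {"value": summary.tier_pct[Tier.OFF_LABEL], "n": summary.n_patients}
    out["resistance_pct"] = {"value": summary.tier_pct[Tier.RESISTANCE], "n": summary.n_patients}
    out["combined_on_label_pct"] = {
        "value": summary.combined_on_label_pct,
        "n": summary.n_patients,
    }
    tier_sum = sum(summary.tier_pct.values())
    if abs(tier_sum - 100.0) > 0.05:
        failures.append(f"tier fractions sum to {tier_sum}, not 100")
    if summary.combined_on_label_pct < summary.tier_pct[Tier.ON_LABEL]:
        failures.append("combined on-label fraction below targeted-only fraction")

    out["msi_high_pct"] = {"value": percent(c["msi_high"], c["n_success"]), "n": c["n_success"]}
    out["tmb_high_pct"] = {"value": percent(c["tmb_high"], c["n_success"]), "n": c["n_success"]}

    hrr = hrr_summary(cohort_hrr_calls())["fractions"]
    out["hrr_brca_pct"] = {"value": hrr["brca_pct"], "n": hrr["n_patients"]}
    out["hrr_high_risk_pct"] = {"value": hrr["high_risk_pct"], "n": hrr["n_patients"]}

    ov = ovarian_gloh_flags()
    n_ov = len(ov)
    n_high = sum(f["high_gloh"] for f in ov)
    n_parp = sum(f["high_gloh"] or f["hrr_high_risk"] for f in ov)
    out["ovarian_high_gloh_pct"] = {"value": percent(n_high, n_ov), "n": n_ov}
    out["ovarian_parp_eligible_pct"] = {"value": percent(n_parp, n_ov), "n": n_ov}
    return out, failures


#: LOD tiers: (design VAF, mean depth, truth-set size)
LOD_TIERS = [
    (0.02, 1000, 27),
    (0.013, 993, 40),
    (0.013, 560, 40),
    (0.006, 794, 40),
    (0.005, 2000, 27),
]


def _lod_summary(seed: int, n_sims: int) -> tuple[dict, list[str]]:
    out: dict = {}
    failures: list[str] = []
    table = lod_profile(LOD_TIERS, n_sims=n_sims, seed=seed)
    keymap = {
        (0.02, 1000): "lod_mc_rate_2pct_1000x",
        (0.013, 993): "lod_mc_rate_1_3pct_993x",
        (0.013, 560): "lod_mc_rate_1_3pct_560x",
        (0.006, 794): "lod_mc_rate_0_6pct_794x",
        (0.005, 2000): "lod_mc_rate_0_5pct_2000x",
    }
    for row in table.itertuples(index=False):
        key = keymap[(row.vaf, row.depth)]
        out[key] = {"value": round(100.0 * row.detection_rate, 2), "n": row.n_sims}
        se = float(np.sqrt(max(row.analytic_rate * (1 - row.analytic_rate), 1e-12) / row.n_sims))
        if abs(row.detection_rate - row.analytic_rate) > max(4 * se, 0.005):
            failures.append(
                f"LOD tier {key}: MC rate {row.detection_rate:.4f} deviates from "
                f"analytic {row.analytic_rate:.4f}"
            )
    rates = [r.detection_rate for r in table.itertuples(index=False)]
    if not (rates[0] >= rates[1] >= rates[3]):  # monotone in VAF at comparable depth
        failures.append("LOD detection not monotone in VAF")
    return out, failures


def _recovery_genome() -> tuple[list[SegmentSpec], float, float]:
    """Ten 100-Mb chromosomes; 20% of the genome in copy-neutral-style
    (2,0) LOH split over four chromosomes, one 30-Mb single-copy gain.
    Returns (segments, truth %LOH, truth ploidy)."""
    segs: list[SegmentSpec] = []
    for i in range(1, 5):
        segs.append(SegmentSpec(f"chr{i}", 50_000_000, 2, 0))
        segs.append(SegmentSpec(f"chr{i}", 50_000_000, 1, 1))
    segs.append(SegmentSpec("chr5", 30_000_000, 2, 1))
    segs.append(SegmentSpec("chr5", 70_000_000, 1, 1))
    for i in range(6, 11):
        segs.append(SegmentSpec(f"chr{i}", 100_000_000, 1, 1))
    total = sum(s.length_bp for s in segs)
    loh = sum(s.length_bp for s in segs if s.n_minor == 0)
    ploidy = sum((s.n_major + s.n_minor) * s.length_bp for s in segs) / total
    return segs, 100.0 * loh / total, ploidy


def loh_recovery_study(
    seed: int,
    n_runs: int = 100,
    purities: tuple = (0.4, 0.6, 0.8),
    snps_per_mb: float = 1.0,
    baf_sd: float = 0.02,
    logr_sd: float = 0.05,
    tol_purity: float = 0.05,
    tol_ploidy: float = 0.1,
    tol_loh_points: float = 3.0,
) -> dict:
    """Seeded end-to-end parameter-recovery study for the %LOH pipeline.

    ``n_runs`` simulated genomes (purity cycling through ``purities``) are
    segmented and fitted from scratch; a run succeeds when purity, ploidy
    and sample %LOH are all within their tolerances of the truth.
    """
    segs, truth_loh, truth_ploidy = _recovery_genome()
    seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)
    n_ok = 0
    loh_err = []
    for k in range(n_runs):
        rho = purities[k % len(purities)]
        profile = simulate_snp_profile(
            rho, segs, snps_per_mb=snps_per_mb, baf_sd=baf_sd, logr_sd=logr_sd,
            seed=int(seeds[k]),
        )
        res = AllelicCopyNumberModel(profile).fit()
        loh_err.append(abs(res.percent_loh - truth_loh))
        if (
            abs(res.purity - rho) <= tol_purity
            and abs(res.ploidy - truth_ploidy) <= tol_ploidy
            and loh_err[-1] <= tol_loh_points
        ):
            n_ok += 1
    return {
        "n_runs": n_runs,
        "success_rate": n_ok / n_runs,
        "mean_abs_loh_error": float(np.mean(loh_err)),
        "truth_percent_loh": truth_loh,
        "truth_ploidy": truth_ploidy,
    }


def concordance_harness(
    seed: int,
    truth_draw,
    n_pairs: int,
    noise_ratio: float,
    n_reps: int = 200,
) -> float:
    """Mean Pearson r between two noisy measurements of one truth.

    Each repetition draws ``n_pairs`` truth values via ``truth_draw(rng)``
    and adds independent Gaussian noise with sd = ``noise_ratio`` x the
    truth sd to each of two measurements; the expected correlation is
    1 / (1 + noise_ratio^2).
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    rs = []
    for s in seeds:
        rng = np.random.default_rng(int(s))
        truth = np.asarray(truth_draw(rng), dtype=float)
        sd = truth.std()
        x = truth + rng.normal(0, noise_ratio * sd, n_pairs)
        y = truth + rng.normal(0, noise_ratio * sd, n_pairs)
        r, _, _ = pearson_concordance(x, y)
        rs.append(r)
    return float(np.mean(rs))


#: Cross-assay noise, as a fraction of the biological sd, calibrated to the
#: concordance the two orthogonal platforms report: r = 1/(1 + ratio^2).
TMB_NOISE_RATIO = float(np.sqrt(1 / 0.82 - 1))
LOH_NOISE_RATIO = float(np.sqrt(1 / 0.6782 - 1))


def run_validation(
    seed: int = 0,
    n_sims: int = 10_000,
    loh_runs: int = 100,
    concordance_reps: int = 200,
) -> tuple[dict, list[str]]:
    """Recompute the full validation summary.

    Returns ``(summary, failures)``: ``summary`` maps each quantity to
    ``{"value": number, "n": problem size}``; ``failures`` lists violated
    internal assertions (deterministic fixture identities and Monte-Carlo
    sanity bands) and is empty on a clean run.
    """
    children = np.random.SeedSequence(seed).spawn(4)
    sub = [int(c.generate_state(1)[0] % (2**31)) for c in children]

    summary, failures = _fixture_summary()

    lod, lod_fail = _lod_summary(sub[0], n_sims)
    summary.update(lod)
    failures += lod_fail

    rec = loh_recovery_study(sub[1], n_runs=loh_runs)
    summary["loh_recovery_success_pct"] = {
        "value": round(100.0 * rec["success_rate"], 2),
        "n": rec["n_runs"],
    }
    summary["loh_mean_abs_error_points"] = {
        "value": round(rec["mean_abs_loh_error"], 3),
        "n": rec["n_runs"],
    }
    if rec["success_rate"] < 0.9:
        failures.append(
            f"LOH recovery success rate {rec['success_rate']:.2f} below 0.90"
        )

    tmb_r = concordance_harness(
        sub[2],
        lambda rng: rng.lognormal(1.2, 0.9, 61),
        n_pairs=61,
        noise_ratio=TMB_NOISE_RATIO,
        n_reps=concordance_reps,
    )
    loh_r = concordance_harness(
        sub[3],
        lambda rng: np.clip(rng.normal(15.0, 8.0, 35), 0, None),
        n_pairs=35,
        noise_ratio=LOH_NOISE_RATIO,
        n_reps=concordance_reps,
    )
    summary["tmb_concordance_r"] = {"value": round(tmb_r, 4), "n": 61}
    summary["loh_concordance_r"] = {"value": round(loh_r, 4), "n": 35}
    return summary, failures
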