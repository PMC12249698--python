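"""Validation statistics: agreement rates, exact CIs, LOD profiles, QC.

PPA/NPA (positive/negative percent agreement) are sensitivity and
specificity computed against an orthogonal method treated as truth.
Confidence intervals are exact Clopper-Pearson (beta quantiles).  The
limit-of-detection profile reports, per (VAF, depth) tier, both the
Monte-Carlo detection rate of the binomial read-sampling model and its
analytic expectation 1 - BinomCDF(min_alt - 1; depth, VAF).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .calls import ConfusionCounts

__all__ = [
    "AgreementReport",
    "QcPolicy",
    "QcResult",
    "rates_from_confusion",
    "exact_binomial_ci",
    "lod_profile",
    "analytic_detection_rate",
    "pearson_concordance",
    "qc_gate",
    "format_p",
]


def exact_binomial_ci(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact binomial confidence interval (fractions).

    ``x = n`` gives (alpha/2)^(1/n) .. 1; ``x = 0`` gives 0 .. 1-(alpha/2)^(1/n).
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if not (0 <= x <= n):
        raise ValueError("need 0 <= x <= n")
    alpha = 1.0 - level
    low = 0.0 if x == 0 else float(sps.beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(sps.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


@dataclass
class AgreementReport:
    """Agreement rates (percent) with exact 95% CIs and cell sizes.

    A rate whose margin is empty is None (undefined), never 0.  PPA is an
    alias for sensitivity and NPA for specificity, reflecting comparison
    against an orthogonal method rather than absolute truth.
    """

    sensitivity: float | None
    specificity: float | None
    overall: float | None
    ci_sensitivity: tuple | None
    ci_specificity: tuple | None
    n_positive: int
    n_negative: int | None
    counts: ConfusionCounts = field(repr=False, default=None)

    ppa = property(lambda self: self.sensitivity)
    npa = property(lambda self: self.specificity)

    def summary(self) -> str:
        def fmt(rate, ci, n):
            if rate is None:
                return "undefined"
            s = f"{rate:6.2f}%  (n={n}"
            if ci is not None:
                s += f", 95% CI {ci[0]:.4f}-{ci[1]:.4f}"
            return s + ")"

        lines = [
            "Agreement report",
            f"  PPA / sensitivity: {fmt(self.sensitivity, self.ci_sensitivity, self.n_positive)}",
            f"  NPA / specificity: {fmt(self.specificity, self.ci_specificity, self.n_negative)}",
        ]
        if self.overall is not None:
            lines.append(f"  overall agreement: {self.overall:6.2f}%")
        return "\n".join(lines)


def rates_from_confusion(c: ConfusionCounts, ci_level: float = 0.95) -> AgreementReport:
    """Sensitivity/PPA, specificity/NPA and overall agreement from counts.

    sensitivity = 100 tp/(tp+fn); specificity = 100 tn/(tn+fp); overall =
    100 (tp+tn)/(tp+fp+fn+tn).  Rates whose denominators are empty (or
    whose tn is undefined) are None.
    """
    n_pos = c.tp + c.fn
    sens = ci_s = None
    if n_pos > 0:
        sens = 100.0 * c.tp / n_pos
        ci_s = exact_binomial_ci(c.tp, n_pos, ci_level)
    spec = ci_p = overall = None
    n_neg = None
    if c.tn_defined:
        n_neg = c.tn + c.fp
        if n_neg > 0:
            spec = 100.0 * c.tn / n_neg
            ci_p = exact_binomial_ci(c.tn, n_neg, ci_level)
        total = n_pos + n_neg
        if total > 0:
            overall = 100.0 * (c.tp + c.tn) / total
    return AgreementReport(
        sensitivity=sens,
        specificity=spec,
        overall=overall,
        ci_sensitivity=ci_s,
        ci_specificity=ci_p,
        n_positive=n_pos,
        n_negative=n_neg,
        counts=c,
    )


def analytic_detection_rate(vaf: float, depth: int, min_alt_reads: int = 3) -> float:
    """P(alt reads >= min_alt) = 1 - BinomCDF(min_alt - 1; depth, VAF)."""
    if vaf <= 0.0:
        return 0.0
    return float(sps.binom.sf(min_alt_reads - 1, depth, vaf))


def lod_profile(
    tiers: Sequence[tuple],
    min_alt_reads: int = 3,
    n_sims: int = 10_000,
    seed: int = 0,
    poisson_depth: bool = True,
) -> pd.DataFrame:
    """Limit-of-detection table over (design VAF, depth, truth size) tiers.

    Per tier, ``n_sims`` Monte-Carlo draws of the binomial detection model
    yield an empirical detection rate, reported alongside the analytic
    tail probability at the target depth.  Rows are ordered by VAF
    descending.  ``poisson_depth`` jitters depth around the target as the
    reference-standard simulator does.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    children = np.random.SeedSequence(seed).spawn(len(tiers))
    rows = []
    for (vaf, depth, n_truth), child in zip(tiers, children):
        rng = np.random.default_rng(child)
        if vaf <= 0.0:
            rate = 0.0
        else:
            d = rng.poisson(depth, size=n_sims) if poisson_depth else np.full(n_sims, depth)
            alt = rng.binomial(d, vaf)
            rate = float(np.mean(alt >= min_alt_reads))
        rows.append(
            {
                "vaf": vaf,
                "depth": depth,
                "n_truth": n_truth,
                "detection_rate": rate,
                "analytic_rate": analytic_detection_rate(vaf, depth, min_alt_reads),
                "expected_detected": n_truth * rate,
                "n_sims": n_sims,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("vaf", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def pearson_concordance(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Pearson r between paired measurements, with n and two-sided p.

    p comes from the t distribution with n-2 degrees of freedom.  Requires
    n >= 3 and non-degenerate variance in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite measurement")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one vector")
    res = sps.pearsonr(x, y)
    return float(res.statistic), int(x.size), float(res.pvalue)


def format_p(p: float, floor: float = 1e-5) -> str:
    """Report very small p-values as a bound, report style."""
    return f"<{floor:g}" if p < floor else f"{p:.5f}"


@dataclass
class QcPolicy:
    """Sample/run quality gates.

    Sequencing depth has two modes: 500x suffices for the 2%-VAF tissue
    application, 1000x is required for the 0.5%-VAF (ctDNA-compatible)
    application.  All comparisons are inclusive (>=).
    """

    min_dna_ng: float = 50.0
    min_library_ng: float = 600.0
    min_mean_depth_2pct: float = 500.0
    min_mean_depth_05pct: float = 1000.0
    min_fraction_50x: float = 0.99
    min_fraction_q30: float = 0.80

    def __post_init__(self) -> None:
        for name in (
            "min_dna_ng",
            "min_library_ng",
            "min_mean_depth_2pct",
            "min_mean_depth_05pct",
            "min_fraction_50x",
            "min_fraction_q30",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class QcResult:
    passed: bool
    reasons: list


def qc_gate(
    metrics: Mapping[str, float], policy: QcPolicy | None = None, mode: str = "2%"
) -> QcResult:
    """Gate one sample's QC metrics against the policy.

    ``metrics`` keys: dna_ng, library_ng, mean_depth, fraction_50x,
    fraction_q30.  ``mode`` ('2%' or '0.5%') selects the depth threshold.
    Every violated criterion is listed; a missing metric fails with a
    'missing' reason.
    """
    policy = policy or QcPolicy()
    if mode not in ("2%", "0.5%"):
        raise ValueError("mode must be '2%' or '0.5%'")
    depth_min = policy.min_mean_depth_2pct if mode == "2%" else policy.min_mean_depth_05pct
    checks = [
        ("dna_ng", policy.min_dna_ng, "DNA amount"),
        ("library_ng", policy.min_library_ng, "library amount"),
        ("mean_depth", depth_min, f"mean depth ({mode} VAF mode)"),
        ("fraction_50x", policy.min_fraction_50x, "fraction covered >=50x"),
        ("fraction_q30", policy.min_fraction_q30, "fraction base quality >=Q30"),
    ]
    reasons = []
    for key, threshold, label in checks:
        value = metrics.get(key)
        if value is None:
            reasons.append(f"missing: {key}")
        elif value < threshold:
            reasons.append(f"{label}: {value} < {threshold}")
    return QcResult(passed=not reasons, reasons=reasons)
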