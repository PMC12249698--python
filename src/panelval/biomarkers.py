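"""Immunotherapy and DNA-repair biomarkers: TMB, MSI, HRR, actionability.

Tumor mutational burden (TMB) is counted over all somatic SNVs/indels in
the panel's coding footprint (synonymous included, splice-region +/-2 bp
included), above a 5% VAF floor, with catalog-listed driver mutations
excluded, and normalized per megabase.  MSI status is the fraction of
unstable microsatellite sites against a compartment cutoff.  The module
also rolls a cohort up into the fractions a clinical validation reports:
HRR (homologous recombination repair) loss-of-function prevalence and the
on-label / off-label / resistance actionability tiers, with and without
the site-agnostic immunotherapy markers (MSI-high, TMB > 10 muts/Mb).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

from .calls import Compartment, VariantCall, VariantKind

__all__ = [
    "TmbPolicy",
    "MsiResult",
    "Tier",
    "ActionabilityRecord",
    "CohortSummary",
    "tmb_score",
    "tmb_eligible",
    "msi_classify",
    "hrr_summary",
    "actionability_rollup",
    "percent",
    "TMB_HIGH_THRESHOLD",
    "HRR_GENES",
    "HIGH_RISK_HRR_GENES",
]

#: TMB-high calls use a strict inequality: > 10 mutations per megabase.
TMB_HIGH_THRESHOLD = 10.0

#: 26 homologous recombination-repair genes interrogated by the panel.
HRR_GENES = (
    "ATM", "ATR", "BAP1", "BARD1", "BLM", "BRCA1", "BRCA2", "BRIP1",
    "CDK12", "CHEK1", "CHEK2", "FANCA", "FANCC", "FANCD2", "FANCE",
    "FANCF", "FANCM", "MRE11", "NBN", "PALB2", "RAD50", "RAD51",
    "RAD51B", "RAD51C", "RAD51D", "WRN",
)

#: High-risk subset tied to PARP-inhibitor eligibility.
HIGH_RISK_HRR_GENES = ("BRCA1", "BRCA2", "PALB2", "RAD51C")


def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """Percentage rounded half-up to ``decimals``, matching report style."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(numerator) / Decimal(denominator) * 100).quantize(q, rounding=ROUND_HALF_UP)
    )


@dataclass
class TmbPolicy:
    """Eligibility rules for the TMB count.

    ``coding_megabases`` is the panel's coding footprint (must exceed 1 Mb
    for the score to be meaningful); ``min_vaf`` is a strict lower VAF
    bound; ``driver_catalog`` maps excluded genes to their exclusion rule
    (tumor-suppressor inactivating, driver-sensitive, or driver
    high-frequency mutations never count toward TMB).
    """

    coding_megabases: float
    min_vaf: float = 0.05
    include_synonymous: bool = True
    splice_window: int = 2
    driver_catalog: frozenset = field(default_factory=frozenset)  # {(gene, rule)}

    def __post_init__(self) -> None:
        if self.coding_megabases <= 1:
            raise ValueError("coding_megabases must exceed 1 Mb")
        if not (0 < self.min_vaf < 1):
            raise ValueError("min_vaf must be in (0, 1)")
        self.driver_catalog = frozenset(self.driver_catalog)
        self._excluded_genes = frozenset(g for g, _rule in self.driver_catalog)


def tmb_eligible(call: VariantCall, policy: TmbPolicy) -> bool:
    """Whether one call counts toward TMB under ``policy``.

    Annotations consumed: ``consequence`` ('synonymous' is gated by the
    policy flag), ``coding`` (bool), ``distance_to_splice`` (bp; a
    non-coding call within the splice window still counts).
    """
    if call.kind not in (VariantKind.SNV, VariantKind.INDEL):
        return False
    if call.vaf is None or call.vaf <= policy.min_vaf:
        return False
    ann = call.annotations
    coding = bool(ann.get("coding", True))
    dist = ann.get("distance_to_splice")
    in_splice = dist is not None and abs(int(dist)) <= policy.splice_window
    if not (coding or in_splice):
        return False
    if not policy.include_synonymous and ann.get("consequence") == "synonymous":
        return False
    if call.gene in policy._excluded_genes and ann.get("driver", False):
        return False
    return True


def tmb_score(calls: Iterable[VariantCall], policy: TmbPolicy) -> float:
    """Mutations per megabase: eligible-call count / coding footprint."""
    count = sum(1 for c in calls if tmb_eligible(c, policy))
    return count / policy.coding_megabases


@dataclass(frozen=True)
class MsiResult:
    score: float  # fraction of unstable microsatellite sites
    status: str  # "MSI-H" | "MSS"
    compartment: Compartment


def msi_classify(
    score: float,
    compartment: Compartment | str = Compartment.FFPE,
    cutoff_ffpe: float = 0.195,
    cutoff_plasma: float = 0.18,
) -> MsiResult:
    """Classify an unstable-site fraction: MSI-H at >= 19.5% (FFPE) / 18% (plasma)."""
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"MSI score must be in [0, 1], got {score}")
    compartment = Compartment(compartment)
    cutoff = cutoff_ffpe if compartment is Compartment.FFPE else cutoff_plasma
    status = "MSI-H" if score >= cutoff else "MSS"
    return MsiResult(score=score, status=status, compartment=compartment)


def hrr_summary(
    cohort_calls: Mapping[str, Sequence[VariantCall]],
    hrr_genes: Sequence[str] = HRR_GENES,
    high_risk_subset: Sequence[str] = HIGH_RISK_HRR_GENES,
) -> dict:
    """Per-patient HRR loss-of-function flags and cohort fractions.

    A patient counts when any call in an HRR gene carries a loss-of-function
    annotation (``lof`` truthy).  Fractions (exact arithmetic, rounded
    half-up to 2 decimals): any HRR gene, BRCA1/2, the high-risk subset,
    and more than one distinct HRR gene altered.
    """
    hrr = frozenset(hrr_genes)
    if not hrr:
        raise ValueError("empty HRR gene list")
    high_risk = frozenset(high_risk_subset)
    brca = frozenset(("BRCA1", "BRCA2")) & hrr

    per_patient: dict[str, dict] = {}
    n_any = n_brca = n_high = n_multi = 0
    for patient, calls in cohort_calls.items():
        genes = sorted(
            {c.gene for c in calls if c.gene in hrr and c.annotations.get("lof", False)}
        )
        flags = {
            "hrr_genes_lof": genes,
            "any_hrr": bool(genes),
            "brca": any(g in brca for g in genes),
            "high_risk": any(g in high_risk for g in genes),
            "multi_hrr": len(genes) > 1,
        }
        per_patient[patient] = flags
        n_any += flags["any_hrr"]
        n_brca += flags["brca"]
        n_high += flags["high_risk"]
        n_multi += flags["multi_hrr"]

    n = len(per_patient)
    fractions = {
        "any_hrr_lof_pct": percent(n_any, n) if n else 0.0,
        "brca_pct": percent(n_brca, n) if n else 0.0,
        "high_risk_pct": percent(n_high, n) if n else 0.0,
        "multi_hrr_pct": percent(n_multi, n) if n else 0.0,
        "n_patients": n,
        "n_any": n_any,
        "n_brca": n_brca,
        "n_high_risk": n_high,
        "n_multi": n_multi,
    }
    return {"per_patient": per_patient, "fractions": fractions}


class Tier(enum.IntEnum):
    """Actionability tiers, ordered from most to least actionable."""

    ON_LABEL = 3
    OFF_LABEL = 2
    RESISTANCE = 1
    NONE = 0

    @classmethod
    def parse(cls, label: "Tier | str") -> "Tier":
        if isinstance(label, cls):
            return label
        try:
            return cls[str(label).upper()]
        except KeyError:
            raise ValueError(f"unknown actionability tier: {label!r}") from None


@dataclass
class ActionabilityRecord:
    """One patient's actionability: best variant tier + immunotherapy flags."""

    patient: str
    tiers: Sequence[Tier | str] = ()
    msi_high: bool = False
    tmb_high: bool = False

    @property
    def most_actionable(self) -> Tier:
        tiers = [Tier.parse(t) for t in self.tiers]
        return max(tiers, default=Tier.NONE)

    def combined_tier(self) -> Tier:
        """Best tier when MSI-high / TMB-high count as on-label immunotherapy."""
        if self.msi_high or self.tmb_high:
            return Tier.ON_LABEL
        return self.most_actionable


@dataclass
class CohortSummary:
    """Cohort actionability roll-up: per-tier fractions, targeted and combined."""

    n_patients: int
    tier_counts: dict
    tier_pct: dict
    combined_on_label_count: int
    combined_on_label_pct: float

    def as_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            **{f"{t.name.lower()}_pct": v for t, v in self.tier_pct.items()},
            "combined_on_label_pct": self.combined_on_label_pct,
        }


def actionability_rollup(records: Sequence[ActionabilityRecord]) -> CohortSummary:
    """Fractions of patients per most-actionable tier, plus the combined
    roll-up in which MSI-high or TMB-high counts as on-label.

    The combined on-label fraction can only grow relative to the targeted
    only fraction, since the immunotherapy flags promote but never demote.
    """
    if not records:
        raise ValueError("empty cohort")
    n = len(records)
    tier_counts = {t: 0 for t in Tier}
    combined = 0
    for rec in records:
        tier_counts[rec.most_actionable] += 1
        if rec.combined_tier() is Tier.ON_LABEL:
            combined += 1
    tier_pct = {t: percent(c, n) for t, c in tier_counts.items()}
    return CohortSummary(
        n_patients=n,
        tier_counts=tier_counts,
        tier_pct=tier_pct,
        combined_on_label_count=combined,
        combined_on_label_pct=percent(combined, n),
    )
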