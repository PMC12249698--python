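"""Allele-specific copy number and sample-level %LOH from SNP profiles.

The assay measures genomic instability as the percentage of the (autosomal)
genome in loss of heterozygosity (LOH): heterozygous population SNPs give a
B-allele frequency (BAF) and a copy-number log-ratio (logR) at each locus;
the genome is segmented into regions of constant allelic state; tumor
purity (cellularity) rho and average ploidy psi are inferred by a grid
search that inverts the standard allele-specific copy-number model

    BAF  = (1 - rho + rho * nB) / (2 (1 - rho) + rho (nA + nB))
    logR = log2( (2 (1 - rho) + rho (nA + nB)) / (2 (1 - rho) + rho * psi) )

to per-segment allele counts (nA, nB), scoring each (rho, psi) by the
length-weighted distance of the implied (nA, nB) to non-negative integers.
A segment is in LOH when its minor allele count is zero while at least one
copy remains (homozygous deletion is not LOH).  Whole-chromosome LOH events
are excluded from the sample-level aggregate by default, following the
standard genome-wide LOH (gLOH) definition used for PARP-inhibitor
biomarkers.

The pipeline is exposed as a model/results pair::

    res = AllelicCopyNumberModel(profile).fit()
    res.purity, res.ploidy, res.percent_loh
    print(res.summary())

with the individual stages (:func:`segment_profile`,
:func:`fit_purity_ploidy`, :func:`call_ascn`, :func:`sample_percent_loh`,
:func:`gene_loh_intersect`) available as functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SnpProfile",
    "RawSegment",
    "AscnSegment",
    "PurityPloidyFit",
    "LohResult",
    "AllelicCopyNumberModel",
    "AllelicCopyNumberResults",
    "segment_profile",
    "fit_purity_ploidy",
    "call_ascn",
    "sample_percent_loh",
    "gene_loh_intersect",
    "expected_baf",
    "expected_logr",
]

SEX_CHROMOSOMES = frozenset({"X", "Y", "chrX", "chrY"})


def expected_baf(rho: float, nA, nB) -> np.ndarray:
    """Noise-free B-allele frequency of the minor (B) allele."""
    nA = np.asarray(nA, dtype=float)
    nB = np.asarray(nB, dtype=float)
    return (1.0 - rho + rho * nB) / (2.0 * (1.0 - rho) + rho * (nA + nB))


def expected_logr(rho: float, psi: float, nA, nB) -> np.ndarray:
    """Noise-free copy-number log2 ratio against average ploidy ``psi``."""
    nA = np.asarray(nA, dtype=float)
    nB = np.asarray(nB, dtype=float)
    total = 2.0 * (1.0 - rho) + rho * (nA + nB)
    return np.log2(total / (2.0 * (1.0 - rho) + rho * psi))


@dataclass
class SnpProfile:
    """Per-SNP BAF and logR observations, ordered along the genome.

    ``data`` columns: chrom, pos (bp), baf (fraction), logr (log2 ratio).
    ``chrom_lengths`` gives the genome span each chromosome's segments
    should tile; defaults to the last SNP position per chromosome.
    """

    data: pd.DataFrame
    chrom_lengths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "baf", "logr"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"SnpProfile missing columns: {sorted(missing)}")
        if len(self.data) == 0:
            raise ValueError("empty SNP profile")
        if self.data["baf"].min() < 0 or self.data["baf"].max() > 1:
            raise ValueError("BAF outside [0, 1]")
        for chrom, grp in self.data.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError(f"positions not strictly increasing on {chrom}")
        for chrom in self.data["chrom"].unique():
            self.chrom_lengths.setdefault(
                chrom, int(self.data.loc[self.data["chrom"] == chrom, "pos"].max())
            )

    @property
    def chromosomes(self) -> list:
        return list(self.data["chrom"].unique())


@dataclass
class RawSegment:
    """A piecewise-constant region of the (folded BAF, logR) signal."""

    chrom: str
    start: int  # bp, half-open
    end: int
    n_snps: int
    mean_baf: float  # folded to [0.5, 1]
    mean_logr: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AscnSegment:
    """Allele-specific copy-number call for one segment."""

    chrom: str
    start: int
    end: int
    nA: int
    nB: int
    mean_baf: float
    mean_logr: float
    n_snps: int = 0
    spans_whole_chromosome: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")
        if self.nB > self.nA or self.nB < 0:
            raise ValueError("require nA >= nB >= 0")

    @property
    def is_loh(self) -> bool:
        return self.nB == 0 and self.nA >= 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PurityPloidyFit:
    purity: float
    ploidy: float
    goodness: float  # length-weighted squared distance to integer allele counts
    non_identifiable: bool = False
    grid: pd.DataFrame | None = None  # searched (purity, ploidy, goodness)


@dataclass
class LohResult:
    sample_percent_loh: float
    high_gloh: bool
    excluded_whole_chromosome_bp: int
    eligible_bp: int
    loh_bp: int
    gene_loh: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.sample_percent_loh <= 100.0):
            raise ValueError("sample %LOH must be in [0, 100]")


# ---------------------------------------------------------------------------
# segmentation


def _dp_changepoints(x: np.ndarray, penalty: float) -> list[int]:
    """Exact penalized least-squares change-point positions on rows of x.

    Minimizes  sum_seg SSE(seg) + penalty * (#segments - 1)  by dynamic
    programming (O(n^2) with cumulative sums).  Returns interior breakpoint
    indices (a breakpoint at i splits [0, i) from [i, n)).
    """
    n, p = x.shape
    cs = np.vstack([np.zeros(p), np.cumsum(x, axis=0)])
    cs2 = np.vstack([np.zeros(p), np.cumsum(x * x, axis=0)])

    best = np.full(n + 1, np.inf)
    best[0] = -penalty  # first segment pays no penalty
    prev = np.zeros(n + 1, dtype=int)
    for j in range(1, n + 1):
        m = (j - np.arange(j)).astype(float)
        s = cs[j] - cs[:j]
        s2 = cs2[j] - cs2[:j]
        cost = np.sum(s2 - s * s / m[:, None], axis=1)
        total = best[:j] + cost + penalty
        # argmin takes the earliest split on exact ties -> fewer segments
        i = int(np.argmin(total))
        best[j] = total[i]
        prev[j] = i
    cps: list[int] = []
    j = n
    while j > 0:
        i = prev[j]
        if i > 0:
            cps.append(i)
        j = i
    return sorted(cps)


def _fold(baf: np.ndarray) -> np.ndarray:
    """Mirror BAF to the major-allele side [0.5, 1] (allele phase unknown)."""
    return np.maximum(baf, 1.0 - baf)


def segment_profile(
    profile: SnpProfile,
    penalty: float | None = None,
    min_snps_per_chrom: int = 10,
) -> list[RawSegment]:
    """Joint change-point segmentation of (folded BAF, logR) per chromosome.

    Both channels are variance-normalized (noise scale estimated from the
    median absolute successive difference) and segmented with an exact
    penalized least-squares dynamic program.  ``penalty=None`` uses a
    BIC-style default ``10 * log(n_snps)`` on the normalized scale.
    Segments tile each chromosome: boundaries fall midway between flanking
    SNPs, the first starts at 0 and the last ends at the chromosome length.
    """
    segments: list[RawSegment] = []
    df = profile.data
    for chrom, grp in df.groupby("chrom", sort=False):
        if len(grp) < min_snps_per_chrom:
            raise ValueError(
                f"chromosome {chrom} has {len(grp)} SNPs; need >= {min_snps_per_chrom}"
            )
        pos = grp["pos"].to_numpy()
        folded = _fold(grp["baf"].to_numpy(dtype=float))
        logr = grp["logr"].to_numpy(dtype=float)
        x = np.column_stack([folded, logr])
        # per-channel noise from successive differences (robust to jumps)
        scale = np.array(
            [
                max(np.median(np.abs(np.diff(col))) / (0.6745 * math.sqrt(2)), 1e-6)
                for col in x.T
            ]
        )
        xn = x / scale
        pen = penalty if penalty is not None else 10.0 * math.log(len(grp))
        cps = _dp_changepoints(xn, max(pen, 1e-10))
        bounds = [0] + cps + [len(grp)]
        chrom_len = profile.chrom_lengths[chrom]
        for k in range(len(bounds) - 1):
            i, j = bounds[k], bounds[k + 1]
            start = 0 if i == 0 else int((pos[i - 1] + pos[i]) // 2)
            end = chrom_len if j == len(grp) else int((pos[j - 1] + pos[j]) // 2)
            segments.append(
                RawSegment(
                    chrom=chrom,
                    start=start,
                    end=end,
                    n_snps=j - i,
                    mean_baf=float(folded[i:j].mean()),
                    mean_logr=float(logr[i:j].mean()),
                )
            )
    return segments


# ---------------------------------------------------------------------------
# purity / ploidy grid search


def _implied_allele_counts(
    rho: np.ndarray, psi: np.ndarray, baf: np.ndarray, logr: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the ASCN model: continuous (nA, nB) per (grid point, segment).

    ``rho``/``psi`` broadcast against trailing segment axis; ``baf`` is the
    folded (major-allele) fraction, so nA is the major count.
    """
    tumor_scale = 2.0 * (1.0 - rho)
    total = (np.exp2(logr) * (tumor_scale + rho * psi) - tumor_scale) / rho
    n_major = (baf * (tumor_scale + rho * total) - (1.0 - rho)) / rho
    return n_major, total - n_major


def fit_purity_ploidy(
    segments: list[RawSegment],
    rho_grid: np.ndarray | None = None,
    psi_grid: np.ndarray | None = None,
    ploidy_penalty: float = 1e-3,
    keep_grid: bool = False,
) -> PurityPloidyFit:
    """Grid search for tumor purity and ploidy.

    Every (rho, psi) on the grid (defaults: rho 0.10..1.00 step 0.01,
    psi 1.5..5.0 step 0.05) is scored by the length-weighted squared
    distance of the implied per-segment (nA, nB) to the nearest
    non-negative integers, plus ``ploidy_penalty * psi``; the minimizer is
    returned, ties broken toward higher purity, then lower ploidy.

    The penalty term is a weak regularization resolving the exact
    whole-genome copy-offset degeneracy of the model: adding one copy to
    every allele of every segment, at purity rho/(1-rho) and ploidy
    psi + 2 (1-rho)/rho-adjusted, reproduces BAF and logR exactly, so the
    distance alone cannot distinguish a near-diploid genome from its
    shifted-up twin.  Preferring the lower-ploidy member matches how
    allele-specific copy-number callers break this ridge.  Genuinely
    polyploid genomes beyond the ridge spacing remain ambiguous (see
    limitations).

    An all-balanced profile (no allelic imbalance, flat logR) cannot
    constrain purity and is flagged ``non_identifiable`` (the tie-break
    then yields the pure-diploid solution).
    """
    if len(segments) < 3:
        raise ValueError("need >= 3 segments to fit purity/ploidy")
    if rho_grid is None:
        rho_grid = np.round(np.arange(0.10, 1.0 + 1e-9, 0.01), 10)
    if psi_grid is None:
        psi_grid = np.round(np.arange(1.5, 5.0 + 1e-9, 0.05), 10)

    baf = np.array([s.mean_baf for s in segments])
    logr = np.array([s.mean_logr for s in segments])
    w = np.array([s.length for s in segments], dtype=float)
    w = w / w.sum()

    rho = rho_grid[:, None, None]
    psi = psi_grid[None, :, None]
    nA, nB = _implied_allele_counts(rho, psi, baf[None, None, :], logr[None, None, :])
    dA = nA - np.clip(np.round(nA), 0, None)
    dB = nB - np.clip(np.round(nB), 0, None)
    goodness = np.einsum("ijk,k->ij", dA * dA + dB * dB, w)
    goodness = goodness + ploidy_penalty * psi_grid[None, :]

    gmin = goodness.min()
    ties = np.argwhere(np.isclose(goodness, gmin, rtol=0.0, atol=1e-9))
    # highest purity, then lowest ploidy
    order = np.lexsort((psi_grid[ties[:, 1]], -rho_grid[ties[:, 0]]))
    i, j = ties[order[0]]

    non_identifiable = bool(
        (baf.max() - baf.min() < 0.01) and (logr.max() - logr.min() < 0.01)
    )
    grid_df = None
    if keep_grid:
        rr, pp = np.meshgrid(rho_grid, psi_grid, indexing="ij")
        grid_df = pd.DataFrame(
            {"purity": rr.ravel(), "ploidy": pp.ravel(), "goodness": goodness.ravel()}
        )
    return PurityPloidyFit(
        purity=float(rho_grid[i]),
        ploidy=float(psi_grid[j]),
        goodness=float(gmin),
        non_identifiable=non_identifiable,
        grid=grid_df,
    )


def call_ascn(segments: list[RawSegment], fit: PurityPloidyFit) -> list[AscnSegment]:
    """Round the model inversion at the fitted (rho, psi) to integer allele
    counts per segment.  LOH is nB = 0 with nA >= 1; a homozygous deletion
    (0, 0) is not LOH."""
    out: list[AscnSegment] = []
    for seg in segments:
        nA, nB = _implied_allele_counts(
            np.float64(fit.purity),
            np.float64(fit.ploidy),
            np.float64(seg.mean_baf),
            np.float64(seg.mean_logr),
        )
        a = int(max(round(float(nA)), 0))
        b = int(max(round(float(nB)), 0))
        if b > a:
            a, b = b, a
        out.append(
            AscnSegment(
                chrom=seg.chrom,
                start=seg.start,
                end=seg.end,
                nA=a,
                nB=b,
                mean_baf=seg.mean_baf,
                mean_logr=seg.mean_logr,
                n_snps=seg.n_snps,
            )
        )
    _flag_whole_chromosome(out)
    return out


def _flag_whole_chromosome(segments: list[AscnSegment], fraction: float = 0.9) -> None:
    chrom_len: dict = {}
    for s in segments:
        chrom_len[s.chrom] = chrom_len.get(s.chrom, 0) + s.length
    for s in segments:
        s.spans_whole_chromosome = s.length >= fraction * chrom_len[s.chrom]


def sample_percent_loh(
    ascn: list[AscnSegment],
    exclude_whole_chromosome: bool = True,
    whole_chrom_fraction: float = 0.9,
    high_gloh_cutoff: float = 16.0,
    exclude_sex_chromosomes: bool = True,
    genes: pd.DataFrame | None = None,
) -> LohResult:
    """Aggregate segment LOH into the sample-level %LOH.

    %LOH = 100 x (bp in LOH segments) / (bp in eligible segments).  LOH
    segments spanning >= ``whole_chrom_fraction`` of their chromosome are
    excluded from numerator *and* denominator when
    ``exclude_whole_chromosome`` (whole-chromosome loss reflects aneuploidy
    rather than the focal instability gLOH measures).  Sex chromosomes are
    excluded (single germline allele in males breaks the model).
    ``high_gloh`` flags %LOH >= ``high_gloh_cutoff`` (percent).
    """
    _flag_whole_chromosome(ascn, whole_chrom_fraction)
    eligible = 0
    loh = 0
    excluded_bp = 0
    for s in ascn:
        if exclude_sex_chromosomes and s.chrom in SEX_CHROMOSOMES:
            continue
        if exclude_whole_chromosome and s.is_loh and s.spans_whole_chromosome:
            excluded_bp += s.length
            continue
        eligible += s.length
        if s.is_loh:
            loh += s.length
    if eligible == 0:
        raise ValueError("no eligible genome length for %LOH")
    pct = 100.0 * loh / eligible
    gene_flags = gene_loh_intersect(ascn, genes) if genes is not None else {}
    return LohResult(
        sample_percent_loh=pct,
        high_gloh=pct >= high_gloh_cutoff,
        excluded_whole_chromosome_bp=excluded_bp,
        eligible_bp=eligible,
        loh_bp=loh,
        gene_loh=gene_flags,
    )


def gene_loh_intersect(
    ascn: list[AscnSegment],
    genes: pd.DataFrame,
    min_overlap_fraction: float = 0.0,
) -> dict:
    """Flag genes overlapped by LOH segments.

    ``genes``: BED-convention DataFrame (chrom, start, end, name; 0-based
    half-open).  A gene is flagged when an LOH segment overlaps more than
    ``min_overlap_fraction`` of its length (default: any overlap >= 1 bp).
    """
    for col in ("chrom", "start", "end", "name"):
        if col not in genes.columns:
            raise ValueError(f"gene table missing column {col}")
    if (genes["end"] <= genes["start"]).any():
        bad = genes[genes["end"] <= genes["start"]].iloc[0]
        raise ValueError(f"malformed gene interval: {bad['name']}")
    loh_segs = [s for s in ascn if s.is_loh]
    flags: dict = {}
    for row in genes.itertuples(index=False):
        glen = row.end - row.start
        hit = False
        for s in loh_segs:
            if s.chrom != row.chrom:
                continue
            overlap = min(s.end, row.end) - max(s.start, row.start)
            if overlap > max(min_overlap_fraction * glen, 0):
                hit = True
                break
        flags[row.name] = hit
    return flags


# ---------------------------------------------------------------------------
# model / results


class AllelicCopyNumberModel:
    """Allele-specific copy-number model for one sample's SNP profile.

    Parameters
    ----------
    profile : SnpProfile
        Ordered per-SNP BAF/logR observations.
    penalty : float, optional
        Segmentation change-point penalty (None = BIC-style default).
    rho_grid, psi_grid : array, optional
        Purity / ploidy search grids.
    exclude_whole_chromosome, whole_chrom_fraction, high_gloh_cutoff,
    genes : %LOH aggregation settings (see :func:`sample_percent_loh`).
    """

    def __init__(
        self,
        profile: SnpProfile,
        penalty: float | None = None,
        rho_grid: np.ndarray | None = None,
        psi_grid: np.ndarray | None = None,
        exclude_whole_chromosome: bool = True,
        whole_chrom_fraction: float = 0.9,
        high_gloh_cutoff: float = 16.0,
        genes: pd.DataFrame | None = None,
    ) -> None:
        self.profile = profile
        self.penalty = penalty
        self.rho_grid = rho_grid
        self.psi_grid = psi_grid
        self.exclude_whole_chromosome = exclude_whole_chromosome
        self.whole_chrom_fraction = whole_chrom_fraction
        self.high_gloh_cutoff = high_gloh_cutoff
        self.genes = genes

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, chrom_lengths: dict | None = None, **kw):
        return cls(SnpProfile(data=data, chrom_lengths=dict(chrom_lengths or {})), **kw)

    def fit(self) -> "AllelicCopyNumberResults":
        raw = segment_profile(self.profile, penalty=self.penalty)
        ppfit = fit_purity_ploidy(raw, rho_grid=self.rho_grid, psi_grid=self.psi_grid)
        ascn = call_ascn(raw, ppfit)
        loh = sample_percent_loh(
            ascn,
            exclude_whole_chromosome=self.exclude_whole_chromosome,
            whole_chrom_fraction=self.whole_chrom_fraction,
            high_gloh_cutoff=self.high_gloh_cutoff,
            genes=self.genes,
        )
        return AllelicCopyNumberResults(self, raw, ppfit, ascn, loh)


class AllelicCopyNumberResults:
    """Fitted purity/ploidy, per-segment allele counts, and %LOH."""

    def __init__(self, model, raw_segments, fit, ascn, loh) -> None:
        self.model = model
        self.raw_segments: list[RawSegment] = raw_segments
        self.fit_: PurityPloidyFit = fit
        self.segments: list[AscnSegment] = ascn
        self.loh: LohResult = loh

    @property
    def purity(self) -> float:
        return self.fit_.purity

    @property
    def ploidy(self) -> float:
        return self.fit_.ploidy

    @property
    def percent_loh(self) -> float:
        return self.loh.sample_percent_loh

    @property
    def high_gloh(self) -> bool:
        return self.loh.high_gloh

    def segments_frame(self) -> pd.DataFrame:
        """Segments as a DataFrame (SEG-style plus nA/nB/is_loh)."""
        return pd.DataFrame(
            {
                "chrom": [s.chrom for s in self.segments],
                "start": [s.start for s in self.segments],
                "end": [s.end for s in self.segments],
                "num_mark": [s.n_snps for s in self.segments],
                "seg_mean": [s.mean_logr for s in self.segments],
                "mean_baf": [s.mean_baf for s in self.segments],
                "nA": [s.nA for s in self.segments],
                "nB": [s.nB for s in self.segments],
                "is_loh": [s.is_loh for s in self.segments],
                "whole_chrom": [s.spans_whole_chromosome for s in self.segments],
            }
        )

    def summary(self) -> str:
        lines = [
            "Allele-specific copy number fit",
            "=" * 47,
            f"SNPs: {len(self.model.profile.data):>8d}   segments: {len(self.segments)}",
            f"purity (rho):  {self.purity:6.2f}",
            f"ploidy (psi):  {self.ploidy:6.2f}",
            f"fit distance:  {self.fit_.goodness:8.4f}"
            + ("   [non-identifiable: balanced profile]" if self.fit_.non_identifiable else ""),
            f"sample %LOH:   {self.percent_loh:6.2f}"
            + ("  (high gLOH)" if self.high_gloh else ""),
            f"whole-chromosome LOH excluded: {self.loh.excluded_whole_chromosome_bp} bp",
            "-" * 47,
            f"{'chrom':<8}{'start':>10}{'end':>10}{'nA':>4}{'nB':>4}  LOH",
        ]
        for s in self.segments:
            lines.append(
                f"{s.chrom:<8}{s.start:>10}{s.end:>10}{s.nA:>4}{s.nB:>4}  "
                + ("yes" if s.is_loh else "no")
            )
        return "\n".join(lines)
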