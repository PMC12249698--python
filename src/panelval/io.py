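"""Readers and writers for the standard formats the pipeline touches.

Small variants travel as VCF 4.2 with ``VAF`` (fraction), ``DP`` and ``AD``
(alternate-read count) INFO keys; CNV and fusion calls as TSV; SNP
profiles as TSV (chrom, pos, BAF, logR); segments as SEG; gene intervals
as BED (0-based half-open, converted to the 1-based internal convention at
the boundary).  Run configuration is a schema-versioned YAML document.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam
import yaml

from .calls import Compartment, VariantCall, VariantKind
from .loh import AscnSegment, SnpProfile

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_cnv_tsv",
    "write_cnv_tsv",
    "read_fusion_tsv",
    "write_fusion_tsv",
    "read_bed",
    "write_seg",
    "read_snp_profile",
    "write_snp_profile",
    "write_pair_table",
    "RunConfig",
    "load_config",
]

CONFIG_SCHEMA_VERSION = 1


def write_vcf(calls: list[VariantCall], path: str | Path) -> None:
    """Write SNV/indel calls as VCF 4.2 with VAF/DP/AD INFO fields."""
    small = [c for c in calls if c.kind in (VariantKind.SNV, VariantKind.INDEL)]
    chroms = sorted({c.chrom for c in small})
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency (fraction)">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
        '##INFO=<ID=AD,Number=1,Type=Integer,Description="Alternate-allele read count">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=CMP,Number=1,Type=String,Description="Compartment (FFPE|PLASMA)">',
    ]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for c in sorted(small, key=lambda v: (v.chrom, v.pos)):
        info = [f"VAF={c.vaf:.6g}"]
        if c.depth is not None:
            info.append(f"DP={c.depth}")
            info.append(f"AD={round(c.vaf * c.depth)}")
        if c.gene:
            info.append(f"GENE={c.gene}")
        info.append(f"CMP={c.compartment.value}")
        lines.append(
            f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t" + ";".join(info)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path, compartment: Compartment | None = None) -> list[VariantCall]:
    """Read SNV/indel calls from a VCF 4.2 with a VAF INFO field.

    Raises ``ValueError`` naming the offending record when VAF is missing
    or unparseable.  ``compartment`` overrides the CMP INFO key (default
    FFPE when neither is given).
    """
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf.fetch() if vcf.index else vcf, start=1):
            try:
                vaf = rec.info.get("VAF")
                if vaf is None:
                    raise KeyError("VAF")
                vaf = float(vaf[0] if isinstance(vaf, tuple) else vaf)
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}: record {i} ({rec.chrom}:{rec.pos}): bad or missing VAF ({exc})"
                ) from exc
            dp = rec.info.get("DP")
            gene = rec.info.get("GENE")
            cmp_ = compartment or Compartment(rec.info.get("CMP", "FFPE"))
            ref, alt = rec.ref, rec.alts[0]
            calls.append(
                VariantCall(
                    kind=VariantKind.SNV if len(ref) == 1 and len(alt) == 1 else VariantKind.INDEL,
                    compartment=cmp_,
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=ref,
                    alt=alt,
                    gene=gene,
                    vaf=vaf,
                    depth=int(dp) if dp is not None else None,
                )
            )
    return calls


def write_cnv_tsv(calls: list[VariantCall], path: str | Path) -> None:
    rows = [
        {"gene": c.gene, "copies": c.copies, "compartment": c.compartment.value}
        for c in calls
        if c.kind is VariantKind.CNV
    ]
    pd.DataFrame(rows, columns=["gene", "copies", "compartment"]).to_csv(
        path, sep="\t", index=False
    )


def read_cnv_tsv(path: str | Path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t")
    return [
        VariantCall(
            kind=VariantKind.CNV,
            compartment=Compartment(row.compartment),
            gene=row.gene,
            copies=float(row.copies),
        )
        for row in df.itertuples(index=False)
    ]


def write_fusion_tsv(calls: list[VariantCall], path: str | Path) -> None:
    rows = [
        {
            "gene5": c.gene,
            "gene3": c.gene2,
            "vaf": c.vaf,
            "supporting_reads": c.annotations.get("supporting_reads"),
            "compartment": c.compartment.value,
        }
        for c in calls
        if c.kind is VariantKind.FUSION
    ]
    pd.DataFrame(
        rows, columns=["gene5", "gene3", "vaf", "supporting_reads", "compartment"]
    ).to_csv(path, sep="\t", index=False)


def read_fusion_tsv(path: str | Path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t")
    return [
        VariantCall(
            kind=VariantKind.FUSION,
            compartment=Compartment(row.compartment),
            gene=row.gene5,
            gene2=row.gene3,
            vaf=float(row.vaf),
        )
        for row in df.itertuples(index=False)
    ]


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED gene intervals (0-based half-open), columns chrom/start/end/name."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
    )
    if (df["end"] <= df["start"]).any():
        bad = df[df["end"] <= df["start"]].iloc[0]
        raise ValueError(f"malformed BED interval: {bad['name']}")
    return df


def write_seg(
    segments: list[AscnSegment], path: str | Path, sample: str = "sample"
) -> None:
    """SEG format (sample, chrom, start, end, num_mark, seg_mean) plus an
    extended companion written alongside with nA/nB/is_loh columns."""
    df = pd.DataFrame(
        {
            "sample": sample,
            "chrom": [s.chrom for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "num_mark": [s.n_snps for s in segments],
            "seg_mean": [s.mean_logr for s in segments],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    ext = df.assign(
        nA=[s.nA for s in segments],
        nB=[s.nB for s in segments],
        is_loh=[s.is_loh for s in segments],
    )
    ext.to_csv(str(path) + ".ascn.tsv", sep="\t", index=False)


def write_snp_profile(profile: SnpProfile, path: str | Path) -> None:
    profile.data.to_csv(path, sep="\t", index=False)


def read_snp_profile(path: str | Path, chrom_lengths: dict | None = None) -> SnpProfile:
    return SnpProfile(
        data=pd.read_csv(path, sep="\t"), chrom_lengths=dict(chrom_lengths or {})
    )


def write_pair_table(table: list[dict], path: str | Path) -> None:
    """Paired tissue/plasma concordance report; absent plasma findings are
    printed as 'Not Detected'."""
    rows = []
    for r in table:
        rows.append(
            {
                "variant": "|".join(str(k) for k in r["key"]),
                "tissue_vaf": r["tissue_vaf"],
                "tissue_copies": r["tissue_copies"],
                "plasma_vaf": r["plasma_vaf"] if r["detected_in_plasma"] else "Not Detected",
                "plasma_copies": r["plasma_copies"] if r["detected_in_plasma"] else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class RunConfig:
    """Run configuration: one seed drives every stage's randomness."""

    seed: int = 0
    mode: str = "ffpe"  # ffpe | plasma
    out_dir: str = "panelval_out"
    schema_version: int = CONFIG_SCHEMA_VERSION
    positivity: dict = field(default_factory=dict)
    tmb: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    loh: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("ffpe", "plasma"):
            raise ValueError("mode must be 'ffpe' or 'plasma'")
        if self.schema_version != CONFIG_SCHEMA_VERSION:
            raise ValueError(
                f"unsupported config schema version {self.schema_version}"
            )


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
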