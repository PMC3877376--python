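"""Cohort and genotype file formats.

Cohort tables travel as TSV (one row per individual, one dosage column per
panel SNP).  Genotypes can also be read from biallelic VCF; dosages are
always oriented to the panel's risk allele (if the risk allele is REF, the
dosage is 2 minus the ALT count), and a record whose alleles match neither
panel allele is a hard error naming the SNP.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .panel import SnpPanel

_CATEGORICALS = ("sex", "skin_color", "eye_color", "hair_color", "tanning")


def write_cohort_tsv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_cohort_tsv(path: str | Path, panel: SnpPanel | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in _CATEGORICALS:
        if col in df.columns:
            df[col] = df[col].astype(object).where(df[col].notna(), pd.NA)
    if "family_history" in df.columns:
        df["family_history"] = df["family_history"].astype("Int64")
    if panel is not None:
        missing = [s for s in panel.snp_ids if s not in df.columns]
        if missing:
            raise ValueError(f"cohort file lacks panel SNPs: {missing}")
        for s in panel.snp_ids:
            df[s] = df[s].astype("Int64")
    return df


def read_genotypes(path: str | Path, panel: SnpPanel, fmt: str | None = None) -> pd.DataFrame:
    """Dosage matrix oriented to the panel's risk alleles.

    ``fmt`` is inferred from the suffix when omitted: ``.vcf`` -> VCF,
    otherwise TSV with one dosage column per SNP.
    """
    path = Path(path)
    fmt = fmt or ("vcf" if path.suffix == ".vcf" or path.name.endswith(".vcf.gz") else "tsv")
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        missing = [s for s in panel.snp_ids if s not in df.columns]
        if missing:
            raise ValueError(f"dosage file lacks panel SNPs: {missing}")
        return df[panel.snp_ids].astype("Int64")
    if fmt == "vcf":
        return _read_vcf(path, panel)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: Path, panel: SnpPanel) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    n = len(vcf.samples)
    data: dict[str, np.ndarray] = {}
    for variant in vcf:
        snp_id = variant.ID
        if snp_id not in panel:
            continue
        rec = panel[snp_id]
        if len(variant.ALT) != 1:
            raise ValueError(f"{snp_id}: only biallelic records are supported")
        ref, alt = variant.REF, variant.ALT[0]
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        alt_count = np.array(
            [gt[0] + gt[1] if gt[0] >= 0 and gt[1] >= 0 else -1 for gt in variant.genotypes],
            dtype=float,
        )
        alt_count[alt_count < 0] = np.nan
        if rec.risk_allele == alt:
            dosage = alt_count
        elif rec.risk_allele == ref:
            dosage = 2.0 - alt_count
        else:
            raise ValueError(
                f"{snp_id}: risk allele {rec.risk_allele} matches neither REF={ref} nor ALT={alt}"
            )
        data[snp_id] = dosage
    absent = [s for s in panel.snp_ids if s not in data]
    if absent:
        raise ValueError(f"VCF lacks panel SNPs: {absent}")
    out = pd.DataFrame({s: data[s] for s in panel.snp_ids}, index=list(vcf.samples)[:n])
    return out.astype("Int64")


def write_vcf(dosages: pd.DataFrame, panel: SnpPanel, path: str | Path) -> None:
    """Emit dosages as a biallelic VCF (risk allele as ALT, RA INFO tag).

    Coordinates are synthetic 1-based positions on a single contig; the
    analysis is position-agnostic, so only the IDs carry meaning.
    """
    samples = [str(s) for s in dosages.index]
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=RA,Number=1,Type=String,Description="Risk allele for PRS scoring">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    for pos, rec in enumerate(panel, start=1):
        col = dosages[rec.snp_id]
        gts = [
            "./." if pd.isna(v) else gt_map[int(v)]
            for v in col
        ]
        lines.append(
            f"1\t{pos}\t{rec.snp_id}\t{rec.other_allele}\t{rec.risk_allele}\t.\tPASS\t"
            f"RA={rec.risk_allele}\tGT\t" + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_meta_input(path: str | Path) -> pd.DataFrame:
    """Read a TSV of ``label OR low high`` rows for direct meta-analysis."""
    df = pd.read_csv(path, sep="\t")
    required = {"label", "or", "low", "high"}
    cols = {c.lower(): c for c in df.columns}
    if not required.issubset(cols):
        raise ValueError(f"meta input needs columns {sorted(required)}, got {list(df.columns)}")
    out = df.rename(columns={cols[k]: k for k in required})
    return out[["label", "or", "low", "high"]]
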