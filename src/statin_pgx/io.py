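"""Reading and writing the four analysis tables and genotype files.

All tables are RFC-4180 CSV with ISO-8601 dates. Genotypes travel either
as a long CSV (patient_id, rsid, allele1, allele2) or as a minimal VCF
4.2 with only CHROM/POS/ID/REF/ALT and per-sample GT.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .genetics import GeneticModel, VariantInfo

PRESCRIPTION_COLUMNS = ["patient_id", "dispense_date", "statin_type",
                        "strength_mg", "quantity", "directions"]
LAB_COLUMNS = ["patient_id", "date", "total_cholesterol", "hdl_cholesterol"]
DEMOGRAPHIC_COLUMNS = ["patient_id", "sex", "birth_year", "t2d", "prior_mace"]
GENOTYPE_COLUMNS = ["patient_id", "rsid", "allele1", "allele2"]


class SchemaError(ValueError):
    """An input table is missing required columns or has malformed rows."""


def _check_columns(df: pd.DataFrame, required: Sequence[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table is missing columns {missing}")


def load_equivalence_table(path: str | Path | None = None) -> dict[str, float]:
    """Simvastatin-equivalence potency ratios; packaged defaults unless a
    YAML path overrides them."""
    if path is None:
        text = resources.files("statin_pgx.data").joinpath("statin_equivalence.yaml").read_text()
    else:
        text = Path(path).read_text()
    table = yaml.safe_load(text)
    return {str(k): float(v) for k, v in table.items()}


def load_variant_metadata(path: str | Path | None = None) -> list[VariantInfo]:
    """The candidate-variant metadata (packaged seven-SNP panel by default)."""
    if path is None:
        text = resources.files("statin_pgx.data").joinpath("variants.yaml").read_text()
    else:
        text = Path(path).read_text()
    entries = yaml.safe_load(text)
    return [VariantInfo(
        rsid=e["rsid"], gene=e["gene"],
        major_allele=str(e["major_allele"]), minor_allele=str(e["minor_allele"]),
        genetic_model=GeneticModel(e["genetic_model"]),
        protective_allele=str(e["protective_allele"]),
        maf=float(e["maf"]) if "maf" in e else None,
        chrom=str(e.get("chrom")) if e.get("chrom") is not None else None,
        pos=int(e["pos"]) if e.get("pos") is not None else None,
    ) for e in entries]


def read_prescriptions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["dispense_date"])
    _check_columns(df, PRESCRIPTION_COLUMNS, "prescriptions")
    bad = df.index[(df["strength_mg"] <= 0) | (df["quantity"] < 1) | (df["directions"] <= 0)]
    if len(bad):
        raise SchemaError(f"prescriptions rows {list(bad[:5])} violate strength/quantity/directions bounds")
    return df


def read_labs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    _check_columns(df, LAB_COLUMNS, "labs")
    bad = df.index[(df["hdl_cholesterol"] < 0) | (df["total_cholesterol"] < df["hdl_cholesterol"])]
    if len(bad):
        raise SchemaError(f"labs rows {list(bad[:5])} violate total >= HDL >= 0")
    return df


def read_demographics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, DEMOGRAPHIC_COLUMNS, "demographics")
    return df


def read_genotypes_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"allele1": "string", "allele2": "string"})
    _check_columns(df, GENOTYPE_COLUMNS, "genotypes")
    for col in ("allele1", "allele2"):
        df[col] = df[col].replace({".": pd.NA})
    return df


def write_vcf(genotypes: pd.DataFrame, variants: Iterable[VariantInfo],
              path: str | Path) -> None:
    """Write a minimal VCF 4.2 (CHROM/POS/ID/REF/ALT + GT) for the panel.

    REF is the major allele, ALT the minor; missing calls become `./.`.
    Samples are every patient present in the genotype table, in sorted order.
    """
    variants = list(variants)
    samples = sorted(genotypes["patient_id"].unique())
    sample_ix = {s: i for i, s in enumerate(samples)}
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(map(str, samples))]
    for v in variants:
        calls = genotypes[genotypes["rsid"] == v.rsid]
        gts = ["./."] * len(samples)
        for pid, a1, a2 in calls[["patient_id", "allele1", "allele2"]].itertuples(index=False):
            if pd.isna(a1) or pd.isna(a2):
                continue
            code = sorted(0 if a == v.major_allele else 1 for a in (a1, a2))
            gts[sample_ix[pid]] = f"{code[0]}/{code[1]}"
        chrom = v.chrom or "."
        pos = v.pos if v.pos is not None else 0
        lines.append(f"{chrom}\t{pos}\t{v.rsid}\t{v.major_allele}\t{v.minor_allele}"
                     f"\t.\tPASS\t.\tGT\t" + "\t".join(gts))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genotypes_vcf(path: str | Path, variants: Iterable[VariantInfo]) -> pd.DataFrame:
    """Read genotype calls for the panel from a (plain-text) VCF via cyvcf2,
    returning the long CSV schema."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading VCF genotypes requires the optional cyvcf2 dependency") from exc
    by_rsid = {v.rsid: v for v in variants}
    vcf = VCF(str(path))
    samples = vcf.samples
    rows = []
    for record in vcf:
        v = by_rsid.get(record.ID)
        if v is None:
            continue
        alleles = [record.REF] + list(record.ALT)
        for sample, gt in zip(samples, record.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                rows.append({"patient_id": sample, "rsid": record.ID,
                             "allele1": pd.NA, "allele2": pd.NA})
            else:
                rows.append({"patient_id": sample, "rsid": record.ID,
                             "allele1": alleles[a], "allele2": alleles[b]})
    return pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)


def write_cohort_csvs(cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the four analysis input tables of a synthetic cohort to
    `out_dir` as CSV; returns the file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("demographics", cohort.demographics),
                     ("prescriptions", cohort.prescriptions),
                     ("labs", cohort.labs),
                     ("genotypes", cohort.genotypes)):
        p = out / f"{name}.csv"
        frame = df.copy()
        for col in frame.columns:
            if pd.api.types.is_datetime64_any_dtype(frame[col]):
                frame[col] = frame[col].dt.strftime("%Y-%m-%d")
        frame.to_csv(p, index=False)
        paths[name] = p
    return paths
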