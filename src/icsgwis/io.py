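"""Readers and writers for the formats shared by all pipeline stages.

Genotypes travel as VCF (biallelic sites; dosage precedence DS over GT;
missing is "./." or an absent DS) or as a samples x variants dosage TSV
with a companion variant-metadata TSV.  Phenotypes/covariates are a TSV
with columns sample_id, outcome, age, sex, bmi, study.  All coordinates
are 1-based as in VCF.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidDataError
from .simulate import GenotypeMatrix, SyntheticCohort

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation quality score">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Additive minor-allele dosage">
"""


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Biallelic VCF with GT from rounded dosage and DS carried verbatim.

    The counted (minor) allele is written as ALT, so DS is the ALT
    dosage; missing entries become "./.:." .
    """
    v = genotypes.variants
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in dict.fromkeys(str(c) for c in v["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(genotypes.samples) + "\n")
        for j in range(genotypes.n_variants):
            row = v.iloc[j]
            info = f"INFO={row['info_score']:.4g}" if "info_score" in v.columns else "."
            fields = [str(row["chrom"]), str(int(row["pos"])), str(row["id"]),
                      str(row["major"]), str(row["minor"]), ".", "PASS", info, "GT:DS"]
            for i in range(genotypes.n_samples):
                if genotypes.missing[i, j]:
                    fields.append("./.:.")
                else:
                    d = genotypes.dosages[i, j]
                    gt = ("0/0", "0/1", "1/1")[int(np.clip(np.rint(d), 0, 2))]
                    fields.append(f"{gt}:{d:g}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path, info_keys: tuple[str, ...] = ("INFO", "R2")) -> GenotypeMatrix:
    """Parse a biallelic VCF into a GenotypeMatrix (DS preferred over GT).

    Multiallelic records are skipped with a warning count; the INFO
    score is looked up under the first key present in ``info_keys``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dos_cols, miss_cols, meta = [], [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        ds = None
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            miss = ~np.isfinite(col)
        else:
            gts = np.asarray(rec.genotypes)[:, :2].astype(int)
            miss = np.any(gts < 0, axis=1)
            col = np.where(miss, 0.0, gts.clip(min=0).sum(axis=1)).astype(float)
        score = np.nan
        for key in info_keys:
            val = rec.INFO.get(key)
            if val is not None:
                score = float(val)
                break
        dos_cols.append(col)
        miss_cols.append(miss)
        meta.append((rec.ID or f"{rec.CHROM}:{rec.POS}", str(rec.CHROM), rec.POS,
                     rec.REF, rec.ALT[0], score))
    if n_multi:
        warnings.warn(f"skipped {n_multi} multiallelic records", stacklevel=2)
    if not meta:
        raise InvalidDataError(f"no biallelic records in {path}")
    variants = pd.DataFrame(meta, columns=["id", "chrom", "pos", "major", "minor",
                                           "info_score"])
    return GenotypeMatrix(
        dosages=np.column_stack(dos_cols),
        missing=np.column_stack(miss_cols),
        variants=variants,
        samples=samples,
    )


def write_dosage_tsv(genotypes: GenotypeMatrix, dosage_path, variants_path) -> None:
    """Samples x variants dosage table (NA = missing) plus variant metadata."""
    df = pd.DataFrame(genotypes.dosages_with_nan(),
                      columns=genotypes.variants["id"].to_numpy())
    df.insert(0, "sample_id", genotypes.samples)
    df.to_csv(dosage_path, sep="\t", index=False, na_rep="NA", float_format="%g")
    genotypes.variants.to_csv(variants_path, sep="\t", index=False)


def read_dosage_tsv(dosage_path, variants_path) -> GenotypeMatrix:
    df = pd.read_csv(dosage_path, sep="\t")
    variants = pd.read_csv(variants_path, sep="\t",
                           dtype={"chrom": str, "id": str})
    samples = df["sample_id"].astype(str).tolist()
    dn = df.drop(columns="sample_id").to_numpy(dtype=float)
    if dn.shape[1] != len(variants):
        raise InvalidDataError(
            f"dosage columns ({dn.shape[1]}) != variant rows ({len(variants)})")
    miss = np.isnan(dn)
    return GenotypeMatrix(dosages=np.where(miss, 0.0, dn), missing=miss,
                          variants=variants, samples=samples)


def write_phenotypes(cohort: SyntheticCohort, path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": cohort.genotypes.samples,
            "outcome": cohort.outcome,
            "age": cohort.age,
            "sex": cohort.covariates["sex"].to_numpy(),
            "bmi": cohort.covariates["bmi"].to_numpy(),
            "study": cohort.covariates["study"].to_numpy(),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "study": str})
    required = {"sample_id", "outcome", "age"}
    if not required <= set(df.columns):
        raise InvalidDataError(f"phenotype table missing columns {required - set(df.columns)}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
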