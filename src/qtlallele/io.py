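"""Readers and writers for the pipeline's plain-text interchange formats.

Genotypes move as VCF (homozygous GT calls) or a SNP x accession matrix
TSV; trials as tidy CSV; markers, models, and matrices as TSV with ``#``
header comments carrying version, config hash, and seed.  All final
tables are written atomically (write to a temp file, then rename).
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import LocusResult, StepwiseModel
from .errors import DataError
from .snpldb import (
    ALT_HOM,
    GenotypeMatrix,
    HET,
    Marker,
    MarkerSet,
    MISSING,
    REF_HOM,
)

_TSV_CODE = {REF_HOM: "0", HET: "1", ALT_HOM: "2", MISSING: "."}
_TSV_DECODE = {v: k for k, v in _TSV_CODE.items()}


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write-then-rename so an aborted run leaves no partial table."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_table(df: pd.DataFrame, path: str | Path,
                meta: dict | None = None, index: bool = False) -> None:
    lines = [f"# {k}: {v}" for k, v in (meta or {}).items()]
    lines.append(df.to_csv(sep="\t", index=index))
    atomic_write_text(path, "\n".join(lines))


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_table_meta(path: str | Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition(":")
            meta[key.strip()] = val.strip()
    return meta


# ---------------------------------------------------------------- genotypes

def write_genotypes_tsv(gm: GenotypeMatrix, path: str | Path,
                        meta: dict | None = None) -> None:
    body = pd.DataFrame(
        {acc: [ _TSV_CODE[int(c)] for c in gm.calls[:, j] ]
         for j, acc in enumerate(gm.accessions)}
    )
    out = pd.concat([gm.snps.reset_index(drop=True), body], axis=1)
    write_table(out, path, meta)


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    df = read_table(path)
    fixed = ["chrom", "pos", "ref", "alt"]
    missing = set(fixed) - set(df.columns)
    if missing:
        raise DataError(f"matrix TSV missing columns: {sorted(missing)}")
    accessions = [c for c in df.columns if c not in fixed]
    calls = np.empty((len(df), len(accessions)), dtype=np.int8)
    for j, acc in enumerate(accessions):
        col = df[acc].astype(str)
        for i, v in enumerate(col):
            if v not in _TSV_DECODE:
                raise DataError(
                    f"bad genotype code {v!r} at row {i + 1}, column {acc!r}"
                )
            calls[i, j] = _TSV_DECODE[v]
    return GenotypeMatrix(accessions, df[fixed].copy(), calls)


_VCF_GT = {REF_HOM: "0/0", HET: "0/1", ALT_HOM: "1/1", MISSING: "./."}


def write_genotypes_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=qtlallele-{__version__}",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.accessions),
    ]
    for i in range(gm.n_snps):
        rec = gm.snps.iloc[i]
        gts = "\t".join(_VCF_GT[int(c)] for c in gm.calls[i])
        lines.append(
            f"{rec['chrom']}\t{rec['pos']}\t{rec['chrom']}_{rec['pos']}\t"
            f"{rec['ref']}\t{rec['alt']}\t.\t.\t.\tGT\t{gts}"
        )
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Parse an uncompressed VCF of biallelic homozygous-dominant calls.

    Multi-allelic sites are rejected by name.  Uses cyvcf2 when available,
    otherwise a plain-text parse of GT fields.
    """
    try:
        from cyvcf2 import VCF
    except ImportError:
        return _read_vcf_text(path)
    vcf = VCF(str(path))
    accessions = list(vcf.samples)
    rows, calls = [], []
    code = {0: REF_HOM, 1: HET, 2: MISSING, 3: ALT_HOM}
    for var in vcf:
        if len(var.ALT) != 1:
            raise DataError(
                f"multi-allelic site {var.CHROM}:{var.POS} not supported"
            )
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        calls.append([code[int(t)] for t in var.gt_types])
    vcf.close()
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(accessions, snps, np.array(calls, dtype=np.int8))


def _read_vcf_text(path: str | Path) -> GenotypeMatrix:
    accessions: list[str] = []
    rows, calls = [], []
    gt_code = {"0/0": REF_HOM, "1/1": ALT_HOM, "0/1": HET, "1/0": HET,
               "./.": MISSING, "0|0": REF_HOM, "1|1": ALT_HOM,
               "0|1": HET, "1|0": HET, ".|.": MISSING}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                accessions = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise DataError(f"malformed VCF record at line {ln}")
            chrom, pos, _, ref, alt = parts[:5]
            if "," in alt:
                raise DataError(f"multi-allelic site {chrom}:{pos} not supported")
            row_calls = []
            for p in parts[9:]:
                gt = p.split(":")[0]
                if gt not in gt_code:
                    raise DataError(f"bad GT {gt!r} at line {ln}")
                row_calls.append(gt_code[gt])
            rows.append((chrom, int(pos), ref, alt))
            calls.append(row_calls)
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(accessions, snps, np.array(calls, dtype=np.int8))


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    if format is None:
        format = "vcf" if str(path).endswith(".vcf") else "matrix_tsv"
    if format == "vcf":
        return read_genotypes_vcf(path)
    if format == "matrix_tsv":
        return read_genotypes_tsv(path)
    raise DataError(f"unknown genotype format {format!r}")


# ------------------------------------------------------------------ markers

def write_markers(ms: MarkerSet, directory: str | Path,
                  meta: dict | None = None) -> None:
    directory = Path(directory)
    rows = []
    for m in ms:
        freqs = m.allele_freqs()
        rows.append(
            {
                "marker": m.id,
                "chrom": m.chrom,
                "start": m.start,
                "end": m.end,
                "n_snps": m.n_snps,
                "snp_indices": ",".join(map(str, m.snp_indices)),
                "alleles": ",".join(m.alleles),
                "freqs": ",".join(f"{f:.6g}" for f in freqs),
            }
        )
    write_table(pd.DataFrame(rows), directory / "markers.tsv", meta)
    codes = pd.DataFrame(
        ms.code_matrix().T, index=ms.accessions, columns=[m.id for m in ms]
    )
    codes.index.name = "accession"
    write_table(codes, directory / "marker_codes.tsv", meta, index=True)


def read_markers(directory: str | Path) -> MarkerSet:
    directory = Path(directory)
    defs = read_table(directory / "markers.tsv")
    codes = read_table(directory / "marker_codes.tsv", index_col=0)
    accessions = list(codes.index)
    markers = []
    for _, r in defs.iterrows():
        markers.append(
            Marker(
                id=r["marker"],
                chrom=str(r["chrom"]),
                start=int(r["start"]),
                end=int(r["end"]),
                snp_indices=tuple(
                    int(x) for x in str(r["snp_indices"]).split(",")
                ),
                alleles=[str(a) for a in str(r["alleles"]).split(",")],
                codes=codes[r["marker"]].to_numpy(dtype=np.int16),
            )
        )
    return MarkerSet(accessions, markers)


# -------------------------------------------------------------------- model

def write_model(model: StepwiseModel, path: str | Path,
                meta: dict | None = None) -> None:
    rows = []
    for mid in model.loci:
        lr = model.locus_results[mid]
        for code, eff in sorted(lr.allele_effects.items()):
            rows.append(
                {
                    "locus": mid,
                    "allele": code,
                    "label": lr.allele_labels.get(code, str(code)),
                    "effect": eff,
                    "partial_r2": lr.partial_r2,
                    "neg_log10_p": lr.neg_log10_p,
                    "reference": int(code == lr.reference_code),
                }
            )
    full_meta = {
        "intercept": repr(model.intercept),
        "total_r2": repr(model.total_r2),
        "h2_cap": repr(model.h2_cap),
        "n": model.n,
        **(meta or {}),
    }
    write_table(pd.DataFrame(
        rows, columns=["locus", "allele", "label", "effect", "partial_r2",
                       "neg_log10_p", "reference"]
    ), path, full_meta)


def read_model(path: str | Path, accessions: list[str] | None = None
               ) -> StepwiseModel:
    meta = read_table_meta(path)
    df = read_table(path)
    loci = list(dict.fromkeys(df["locus"]))
    locus_results = {}
    for mid in loci:
        sub = df[df["locus"] == mid]
        ref_rows = sub[sub["reference"] == 1]
        locus_results[mid] = LocusResult(
            marker=mid,
            partial_r2=float(sub["partial_r2"].iloc[0]),
            neg_log10_p=float(sub["neg_log10_p"].iloc[0]),
            allele_effects={
                int(a): float(e) for a, e in zip(sub["allele"], sub["effect"])
            },
            allele_labels={
                int(a): str(l) for a, l in zip(sub["allele"], sub["label"])
            },
            n_alleles=len(sub),
            reference_code=int(ref_rows["allele"].iloc[0]) if len(ref_rows) else 0,
        )
    return StepwiseModel(
        loci=loci,
        locus_results=locus_results,
        intercept=float(meta["intercept"]),
        covariate_coefs=np.empty(0),
        total_r2=float(meta["total_r2"]),
        h2_cap=float(meta["h2_cap"]),
        n=int(meta["n"]),
        accessions=accessions or [],
    )


# -------------------------------------------------------------------- trial

def write_trial_csv(data: pd.DataFrame, path: str | Path) -> None:
    atomic_write_text(path, data.to_csv(index=False))


def read_trial_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_checks(tolerant: list[str], sensitive: list[str],
                 path: str | Path) -> None:
    rows = [{"accession": a, "role": "tolerant_check"} for a in tolerant]
    rows += [{"accession": a, "role": "sensitive_check"} for a in sensitive]
    write_table(pd.DataFrame(rows), path)


def read_checks(path: str | Path) -> tuple[list[str], list[str]]:
    df = read_table(path)
    tol = list(df.loc[df["role"] == "tolerant_check", "accession"])
    sen = list(df.loc[df["role"] == "sensitive_check", "accession"])
    if not tol or not sen:
        raise DataError("check roster needs both tolerant and sensitive checks")
    return tol, sen
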