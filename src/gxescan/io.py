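"""File formats: genotype/phenotype TSV, minimal VCF, results and reports.

Genotype TSV dialect: rows are loci, columns are samples, first column
``locus_id``, header row carries sample IDs, entries are 0/1/2 (``NA`` for
a missing hard call).  Phenotype TSV: one row per sample with columns
``sample_id``, ``y`` (or ``time`` and ``status`` for survival), ``e`` and
optionally ``subpop``.  VCF input is restricted to biallelic sites with a
GT field (hard calls); multi-allelic records are skipped with a logged
count.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, ParseError
from .gcdiag import RESULT_COLUMNS, GCReport, ScanResult
from .sim import Cohort

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


# ----------------------------------------------------------------------
# Genotypes
# ----------------------------------------------------------------------
def write_genotype_tsv(path, genotypes: np.ndarray, locus_ids, sample_ids) -> None:
    """Loci-by-samples TSV with a locus_id first column."""
    G = np.asarray(genotypes, dtype=float)
    n, m = G.shape
    with open(path, "w") as fh:
        fh.write("locus_id\t" + "\t".join(map(str, sample_ids)) + "\n")
        for j in range(m):
            row = G[:, j]
            cells = ["NA" if np.isnan(v) else str(int(v)) for v in row]
            fh.write(str(locus_ids[j]) + "\t" + "\t".join(cells) + "\n")


def read_genotype_tsv(path):
    """Returns (genotypes n x m float with NaN for missing, locus_ids, sample_ids)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "locus_id":
            raise ParseError(f"{path}:1: expected header starting with 'locus_id'")
        sample_ids = header[1:]
        if len(sample_ids) == 0:
            raise ParseError(f"{path}:1: no sample columns")
        rows, locus_ids = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}")
            locus_ids.append(parts[0])
            try:
                vals = [np.nan if v in ("NA", ".", "") else float(v)
                        for v in parts[1:]]
            except ValueError as err:
                raise ParseError(f"{path}:{lineno}: {err}") from None
            rows.append(vals)
    G = np.asarray(rows, dtype=float).T if rows else np.empty((len(sample_ids), 0))
    present = G[~np.isnan(G)]
    if present.size and not np.isin(present, (0.0, 1.0, 2.0)).all():
        raise ParseError(f"{path}: genotype entries must be 0/1/2 or NA")
    return G, locus_ids, sample_ids


def read_vcf_minimal(path):
    """Genotype matrix from a minimal biallelic VCF with GT hard calls.

    Counts ALT alleles per sample (0/1/2); ``./.`` becomes NaN; phased and
    unphased separators are equivalent.  Multi-allelic records are skipped
    (count logged).  Returns (genotypes n x m, locus_ids, sample_ids).
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as err:
        raise ParseError(f"{path}: cannot open VCF: {err}") from None
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise ParseError(f"{path}: VCF has no sample columns")
    cols, locus_ids = [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        gt = rec.genotype.array()[:, :2].astype(float)
        gt[gt < 0] = np.nan              # ./. missing hard calls
        dosage = gt.sum(axis=1)
        cols.append(dosage)
        locus_ids.append(rec.ID if rec.ID not in (None, ".")
                         else f"{rec.CHROM}:{rec.POS}")
    if n_multi:
        logger.info("read_vcf_minimal: skipped %d multi-allelic records", n_multi)
    G = np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))
    return G, locus_ids, sample_ids


# ----------------------------------------------------------------------
# Phenotypes
# ----------------------------------------------------------------------
def write_phenotype_tsv(path, cohort: Cohort) -> None:
    cols = {"sample_id": cohort.sample_ids}
    if cohort.family == "survival":
        cols["time"] = cohort.time
        cols["status"] = cohort.status.astype(int)
    else:
        y = cohort.phenotype
        cols["y"] = y.astype(int) if cohort.family == "logistic" else y
    cols["e"] = cohort.exposure
    if cohort.subpop is not None:
        cols["subpop"] = cohort.subpop.astype(int)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False,
                              float_format=_FLOAT_FMT)


def read_phenotype_tsv(path, family: str) -> pd.DataFrame:
    """Phenotype/exposure table keyed by sample_id; schema checked per family."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    except Exception as err:
        raise ParseError(f"{path}: {err}") from None
    needed = ["sample_id", "e"] + (["time", "status"] if family == "survival"
                                   else ["y"])
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing} for "
                         f"family {family!r}")
    if df.sample_id.duplicated().any():
        dups = df.sample_id[df.sample_id.duplicated()].tolist()[:5]
        raise DataError(f"{path}: duplicate sample ids {dups}")
    return df


def assemble_cohort(genotypes: np.ndarray, locus_ids, sample_ids,
                    pheno: pd.DataFrame, family: str) -> Cohort:
    """Align a phenotype table to genotype sample columns by id.

    Samples present in only one of the two inputs are dropped (count
    logged).  Sample allele frequencies stand in for the MAF column.
    """
    pheno = pheno.set_index("sample_id")
    common = [s for s in sample_ids if s in pheno.index]
    dropped = (len(sample_ids) - len(common)) + (len(pheno) - len(common))
    if dropped:
        logger.info("assemble_cohort: dropped %d unmatched samples", dropped)
    if not common:
        raise DataError("no overlapping sample ids between genotypes and phenotypes")
    idx = [sample_ids.index(s) for s in common]
    G = np.asarray(genotypes, dtype=float)[idx, :]
    sub = pheno.loc[common]
    af = np.nanmean(G, axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    kwargs: dict = {"family": family}
    if family == "survival":
        kwargs["time"] = sub.time.to_numpy(dtype=float)
        kwargs["status"] = sub.status.to_numpy(dtype=int)
    else:
        kwargs["phenotype"] = sub.y.to_numpy(dtype=float)
    if "subpop" in sub.columns:
        kwargs["subpop"] = sub.subpop.to_numpy(dtype=int)
    return Cohort(exposure=sub.e.to_numpy(dtype=float), genotypes=G, maf=maf,
                  locus_ids=list(locus_ids), sample_ids=list(common),
                  **kwargs).validate()


# ----------------------------------------------------------------------
# Results and reports
# ----------------------------------------------------------------------
def write_results_tsv(path, scan: ScanResult) -> None:
    scan.table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_results_tsv(path, family: str = "linear", n_subjects: int = 0,
                     scenario: str = "", seed: int | None = None) -> ScanResult:
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "status_code": str})
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return ScanResult(table=df, family=family, n_subjects=n_subjects,
                      scenario=scenario, seed=seed)


def write_gc_report(outdir, report: GCReport, prefix: str = "gc") -> dict:
    """Writes <prefix>_report.yaml plus QQ-pair TSVs; returns artifact paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    rpt = outdir / f"{prefix}_report.yaml"
    rpt.write_text(yaml.safe_dump(report.to_dict(), sort_keys=False))
    paths["report"] = str(rpt)
    for flavor in ("model", "robust"):
        qq = getattr(report, f"qq_pairs_{flavor}")
        p = outdir / f"{prefix}_qq_{flavor}.tsv"
        pd.DataFrame(qq, columns=["expected_neglog10p", "observed_neglog10p"]) \
            .to_csv(p, sep="\t", index=False, float_format=_FLOAT_FMT)
        paths[f"qq_{flavor}"] = str(p)
    return paths


def read_gc_report(path) -> GCReport:
    """Reload a GC report (lambdas and metadata; QQ pairs from sibling TSVs)."""
    path = Path(path)
    d = yaml.safe_load(path.read_text())
    prefix = path.name.replace("_report.yaml", "")
    qq = {}
    for flavor in ("model", "robust"):
        p = path.parent / f"{prefix}_qq_{flavor}.tsv"
        qq[flavor] = (pd.read_csv(p, sep="\t").to_numpy()
                      if p.exists() else np.empty((0, 2)))
    return GCReport(
        lambda_model=float(d["lambda_model"]),
        lambda_robust=float(d["lambda_robust"]),
        n_loci_used=int(d["n_loci_used"]),
        qq_pairs_model=qq["model"], qq_pairs_robust=qq["robust"],
        chisq_median_constant=float(d["chisq_median_constant"]),
        family=d.get("family", "linear"), n_subjects=int(d.get("n_subjects", 0)),
        scenario=d.get("scenario", ""), seed=d.get("seed"))


def write_pc_scores_tsv(path, scores: np.ndarray, sample_ids) -> None:
    k = scores.shape[1]
    df = pd.DataFrame(scores, columns=[f"pc{j + 1}" for j in range(k)])
    df.insert(0, "sample_id", list(sample_ids))
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
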