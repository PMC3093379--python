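"""Genomic control and QQ-plot diagnostics.

The genomic-control inflation factor is

    lambda = median(chi2_1, ..., chi2_m) / 0.4549

where 0.4549 is the median of the chi-squared distribution with one degree
of freedom and the chi2_j are the per-locus Wald statistics for the GxE
interaction coefficient.  Under calibrated tests lambda is approximately 1;
lambda > 1 signals genome-wide inflation, classically attributed to
population substructure but — for interaction scans — equally producible by
mean-model mis-specification or heteroskedasticity when model-based
standard errors are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, GxescanError

#: the chi^2_1 median as conventionally printed (used as the lambda denominator)
CHI2_1_MEDIAN = 0.4549
#: ... and at full precision, for reference and for the self-check in reports
CHI2_1_MEDIAN_EXACT = float(stats.chi2.ppf(0.5, 1))

#: fixed column order of the per-locus results table
RESULT_COLUMNS = ["locus_id", "maf", "n_used", "beta_gxe", "se_model",
                  "se_robust", "chi2_model", "chi2_robust", "p_model",
                  "p_robust", "status_code"]

STATUS_OK = "ok"
STATUS_LOW_MAC = "low_mac"
STATUS_NOT_CONVERGED = "not_converged"


@dataclass
class ScanResult:
    """Per-locus interaction scan results plus scenario metadata.

    ``table`` has the fixed columns of :data:`RESULT_COLUMNS`; rows whose
    ``status_code`` is not ``"ok"`` carry NaN statistics and are excluded
    from genomic-control computations.
    """

    table: pd.DataFrame
    family: str = "linear"
    n_subjects: int = 0
    scenario: str = ""
    seed: int | None = None

    def __post_init__(self):
        missing = [c for c in RESULT_COLUMNS if c not in self.table.columns]
        if missing:
            raise DataError(f"scan table missing columns: {missing}")
        self.table = self.table[RESULT_COLUMNS].reset_index(drop=True)

    @property
    def n_loci(self) -> int:
        return len(self.table)

    def converged(self) -> pd.DataFrame:
        return self.table[self.table.status_code == STATUS_OK]

    def validate(self) -> "ScanResult":
        ok = self.converged()
        for flavor in ("model", "robust"):
            p = ok[f"p_{flavor}"].to_numpy()
            if ((p <= 0) | (p > 1)).any():
                raise DataError(f"p_{flavor} outside (0, 1]")
            chi = (ok.beta_gxe / ok[f"se_{flavor}"]) ** 2
            if not np.allclose(chi, ok[f"chi2_{flavor}"], atol=1e-8, rtol=1e-8):
                raise DataError(f"chi2_{flavor} inconsistent with beta/se")
        return self


@dataclass
class GCReport:
    """Genomic-control lambdas and QQ coordinates for both SE flavors."""

    lambda_model: float
    lambda_robust: float
    n_loci_used: int
    qq_pairs_model: np.ndarray          # (k, 2): expected, observed -log10 p
    qq_pairs_robust: np.ndarray
    chisq_median_constant: float = CHI2_1_MEDIAN
    family: str = "linear"
    n_subjects: int = 0
    scenario: str = ""
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "lambda_model": float(self.lambda_model),
            "lambda_robust": float(self.lambda_robust),
            "n_loci_used": int(self.n_loci_used),
            "chisq_median_constant": float(self.chisq_median_constant),
            "family": self.family,
            "n_subjects": int(self.n_subjects),
            "scenario": self.scenario,
            "seed": self.seed,
        }


def genomic_lambda(chi2: np.ndarray) -> float:
    """Median chi-squared statistic divided by the chi^2_1 median 0.4549."""
    chi2 = np.asarray(chi2, dtype=float)
    chi2 = chi2[np.isfinite(chi2)]
    if chi2.size == 0:
        raise GxescanError("genomic_lambda needs at least one finite statistic")
    if (chi2 < 0).any():
        raise DataError("chi-squared statistics must be non-negative")
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def gc_correct(chi2: np.ndarray, lam: float) -> np.ndarray:
    """Divide statistics by the inflation factor (classic GC correction)."""
    if not lam > 0:
        raise GxescanError(f"lambda must be positive, got {lam}")
    return np.asarray(chi2, dtype=float) / lam


def qq_data(p: np.ndarray) -> np.ndarray:
    """(expected, observed) -log10 p pairs, sorted by expected ascending.

    Expected quantiles use the Hazen positions (i - 0.5)/m for rank i of
    the sorted p-values.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise DataError("qq_data needs at least one p-value")
    if ((p <= 0) | (p > 1)).any():
        raise DataError("p-values must lie in (0, 1]")
    m = p.size
    ranks = np.arange(1, m + 1)
    expected = -np.log10((ranks - 0.5) / m)          # decreasing in rank
    observed = -np.log10(np.sort(p))                 # decreasing in rank
    return np.column_stack([expected[::-1], observed[::-1]])


def build_gc_report(scan: ScanResult) -> GCReport:
    """Lambda and QQ coordinates for both SE flavors over converged loci."""
    ok = scan.converged()
    if len(ok) == 0:
        raise DataError("scan has no converged loci")
    return GCReport(
        lambda_model=genomic_lambda(ok.chi2_model.to_numpy()),
        lambda_robust=genomic_lambda(ok.chi2_robust.to_numpy()),
        n_loci_used=len(ok),
        qq_pairs_model=qq_data(ok.p_model.to_numpy()),
        qq_pairs_robust=qq_data(ok.p_robust.to_numpy()),
        family=scan.family,
        n_subjects=scan.n_subjects,
        scenario=scan.scenario,
        seed=scan.seed,
    )
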