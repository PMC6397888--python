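"""Normalization, negative-binomial differential expression, and qPCR stats.

Counts are normalized with median-of-ratios size factors, converted to
FPKM for filtering/correlation, and tested per pre-registered pairwise
contrast with a negative-binomial Wald test: per-feature dispersion by
method of moments within each group (combined conservatively by taking
the larger estimate), delta-method standard errors on log2 fold change,
two-sided normal p-values, Benjamini-Hochberg adjustment.  A feature is
differentially expressed when |log2FC| > 1 and adjusted p < 0.05.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import ExpressionMatrix, SampleSheet

LOG2FC_THRESHOLD = 1.0
ADJ_P_THRESHOLD = 0.05
#: The six pairwise comparisons of the 2-genotype x 3-stage design:
#: within-genotype time course plus between-genotype at each stage.
CONTRASTS = (
    ("FPW1", "FPW2"),
    ("FPW1", "FPW3"),
    ("FPR1", "FPR2"),
    ("FPR1", "FPR3"),
    ("FPW1", "FPR1"),
    ("FPW2", "FPR2"),
    ("FPW3", "FPR3"),
)

DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 0.5
#: prior weight of the across-feature median dispersion (2 pseudo-df
#: against the ~4 residual df a 3-vs-3 contrast leaves per feature)
MODERATION_WEIGHT = 1.0 / 3.0


@dataclass
class QpcrRecord:
    gene: str
    condition: str
    delta_ct: float
    delta_delta_ct: float
    fold_change: float


def counts_to_fpkm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """FPKM_gs = counts_gs * 1e9 / (length_g * total_s)."""
    if matrix.unit != "counts":
        raise ValueError("counts_to_fpkm expects a count matrix")
    if matrix.lengths is None:
        raise ValueError("counts_to_fpkm needs per-feature lengths")
    counts = matrix.values.astype(float)
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"samples with zero total counts: {bad}")
    fpkm = counts * 1e9
    fpkm = fpkm.div(matrix.lengths, axis=0).div(totals, axis=1)
    return ExpressionMatrix(fpkm, unit="FPKM", lengths=matrix.lengths)


def size_factors(matrix: ExpressionMatrix) -> pd.Series:
    """DESeq-style median-of-ratios normalization factors."""
    if matrix.unit != "counts":
        raise ValueError("size factors are computed on counts")
    counts = matrix.values.astype(float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature with positive counts in every sample; "
            "cannot compute median-of-ratios size factors"
        )
    ref = counts[positive]
    geomean = np.exp(np.log(ref.values).mean(axis=1))
    ratios = ref.values / geomean[:, None]
    return pd.Series(np.median(ratios, axis=0), index=matrix.sample_ids)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def _group_columns(sheet: SampleSheet, condition: str) -> list[str]:
    cols = sheet.samples_in(condition)
    if len(cols) < 2:
        raise ValueError(
            f"condition {condition!r} has {len(cols)} samples; need >= 2"
        )
    return cols


def nb_wald_test(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    contrast: tuple[str, str],
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Negative-binomial Wald test for one pairwise contrast (A vs B).

    log2FC is log2((mean_B + 0.5) / (mean_A + 0.5)) on normalized counts,
    so positive values mean higher expression in the second condition.
    """
    if matrix.unit != "counts":
        raise ValueError("nb_wald_test runs on raw counts")
    matrix = matrix.reconcile(sheet)
    cond_a, cond_b = contrast
    cols_a = _group_columns(sheet, cond_a)
    cols_b = _group_columns(sheet, cond_b)
    if factors is None:
        factors = size_factors(matrix)
    norm = matrix.values.astype(float) / factors

    a = norm[cols_a].values
    b = norm[cols_b].values
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)

    # per-group method-of-moments dispersion; the larger of the two is
    # used so that a quiet group never masks overdispersion in the other.
    # With 2-3 residual df per feature the raw estimate is noisy enough
    # to distort the Wald null, so it is lightly moderated toward the
    # across-feature median (prior weight 1/3, i.e. two pseudo-df
    # against the ~4 residual df per feature).
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_a = (a.var(axis=1, ddof=1) - mean_a) / np.maximum(mean_a, 1e-12) ** 2
        disp_b = (b.var(axis=1, ddof=1) - mean_b) / np.maximum(mean_b, 1e-12) ** 2
    per_feature = np.maximum(np.maximum(disp_a, disp_b), 0.0)
    median_disp = float(np.median(per_feature)) if per_feature.size else 0.0
    dispersion = np.maximum(
        (1.0 - MODERATION_WEIGHT) * per_feature + MODERATION_WEIGHT * median_disp,
        DISPERSION_FLOOR,
    )

    log2fc = np.log2((mean_b + PSEUDOCOUNT) / (mean_a + PSEUDOCOUNT))
    var_mean_a = (mean_a + dispersion * mean_a**2) / a.shape[1]
    var_mean_b = (mean_b + dispersion * mean_b**2) / b.shape[1]
    se = (
        np.sqrt(
            var_mean_a / (mean_a + PSEUDOCOUNT) ** 2
            + var_mean_b / (mean_b + PSEUDOCOUNT) ** 2
        )
        / np.log(2.0)
    )
    z = log2fc / np.maximum(se, 1e-12)
    p = 2.0 * stats.norm.sf(np.abs(z))
    adj = bh_adjust(p)
    result = pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "contrast": f"{cond_a}_vs_{cond_b}",
            "base_mean": norm[cols_a + cols_b].mean(axis=1).values,
            "log2_fold_change": log2fc,
            "standard_error": se,
            "p_value": p,
            "adjusted_p": adj,
        }
    )
    result["is_DE"] = (np.abs(result["log2_fold_change"]) > LOG2FC_THRESHOLD) & (
        result["adjusted_p"] < ADJ_P_THRESHOLD
    )
    return result


def run_contrasts(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    contrasts=CONTRASTS,
) -> dict[str, pd.DataFrame]:
    factors = size_factors(matrix.reconcile(sheet))
    return {
        f"{a}_vs_{b}": nb_wald_test(matrix, sheet, (a, b), factors)
        for a, b in contrasts
    }


def replicate_correlation(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    threshold: float = 0.9,
) -> pd.DataFrame:
    """Pearson r of log2(FPKM+1) for every within-condition replicate pair."""
    if matrix.unit != "FPKM":
        raise ValueError("replicate correlation runs on FPKM")
    matrix = matrix.reconcile(sheet)
    log_expr = np.log2(matrix.values + 1.0)
    log_expr = log_expr.loc[log_expr.var(axis=1) > 0]  # drop constant rows
    rows = []
    for condition in sorted(set(sheet.conditions)):
        samples = sheet.samples_in(condition)
        for s1, s2 in itertools.combinations(samples, 2):
            r = float(np.corrcoef(log_expr[s1], log_expr[s2])[0, 1])
            rows.append((condition, s1, s2, r, r <= threshold))
    return pd.DataFrame(
        rows, columns=["condition", "sample_a", "sample_b", "r", "flagged"]
    )


def ddct(ct_table: pd.DataFrame, calibrator: str) -> list[QpcrRecord]:
    """Relative quantification 2^-ddCt against a calibrator condition.

    dCt = Ct_target - Ct_reference (the actin internal reference);
    ddCt subtracts the calibrator condition's dCt per gene.
    """
    required = {"gene", "condition", "ct_target", "ct_reference"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    records: list[QpcrRecord] = []
    for gene, group in ct_table.groupby("gene", sort=True):
        group = group.copy()
        group["delta_ct"] = group["ct_target"] - group["ct_reference"]
        cal = group.loc[group["condition"] == calibrator, "delta_ct"]
        if cal.empty:
            raise ValueError(
                f"gene {gene!r} has no calibrator condition {calibrator!r}"
            )
        cal_dct = float(cal.mean())
        for _, row in group.iterrows():
            ddct_val = float(row["delta_ct"]) - cal_dct
            records.append(
                QpcrRecord(
                    gene=str(gene),
                    condition=str(row["condition"]),
                    delta_ct=float(row["delta_ct"]),
                    delta_delta_ct=ddct_val,
                    fold_change=float(2.0 ** (-ddct_val)),
                )
            )
    return records
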