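"""RNA-seq preprocessing and differential-expression calling.

The stage mirrors the hormone-response study design it supports: each donor's
RPKM matrix is processed separately (low-expression filter, baseline zero
replacement, per-contrast testing) and the per-donor DEG lists are then
unioned. The rules are deliberately literal:

* a gene is kept only if its maximum RPKM over all samples ("MAX") reaches
  1% of the mean RPKM of the whole dataset;
* zeros in the baseline (vehicle) group are replaced by 0.05% of the gene's
  MAX so fold changes against baseline are finite;
* a gene is a DEG for a contrast when |fold| >= 2 and BH-adjusted p < 0.05.

Significance comes from a one-way ANOVA model on log2(RPKM + eps) across all
treatment groups: each contrast is tested with the model's pooled
within-group variance (df = N - k, the classic ANOVA-contrast t), and the
p-values are BH-adjusted across retained genes per contrast. The overall
ANOVA F p-value is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix

LOG_EPSILON = 1e-3  # added before log2; keeps zero-adjacent values finite
FILTER_FRACTION = 0.01  # MAX threshold as a fraction of dataset mean RPKM
ZERO_REPLACEMENT_FRACTION = 5e-4  # 0.05% of per-gene MAX


@dataclass(frozen=True)
class FilterResult:
    matrix: ExpressionMatrix
    summary: pd.DataFrame  # gene_id, max_rpkm, per-group means, passed_filter
    threshold: float


def filter_low_expression(matrix: ExpressionMatrix) -> FilterResult:
    """Drop genes whose MAX RPKM is below 1% of the dataset-wide mean RPKM.

    The threshold is computed on the full matrix before any gene is removed;
    the boundary is strict (MAX exactly at the threshold is retained).
    """
    values = matrix.values
    if values.empty:
        raise ValueError("expression matrix is empty")
    threshold = FILTER_FRACTION * float(values.to_numpy().mean())
    max_rpkm = matrix.max_per_gene()
    passed = max_rpkm >= threshold
    if not passed.any():
        raise ValueError(
            f"all {len(passed)} genes fall below the expression threshold "
            f"{threshold:.6g}; degenerate dataset"
        )
    group_means = {
        f"mean_{g}": values[matrix.samples_in_group(g)].mean(axis=1)
        for g in matrix.groups
    }
    summary = pd.DataFrame(
        {"gene_id": values.index, "max_rpkm": max_rpkm.to_numpy(),
         **{k: v.to_numpy() for k, v in group_means.items()},
         "passed_filter": passed.to_numpy()}
    ).reset_index(drop=True)
    filtered = ExpressionMatrix(values.loc[passed], matrix.design)
    return FilterResult(filtered, summary, threshold)


def replace_vehicle_zeros(
    matrix: ExpressionMatrix, baseline_group: str
) -> ExpressionMatrix:
    """Replace baseline-group zeros with 0.05% of the gene's MAX RPKM.

    Zeros in non-baseline groups are left untouched. A gene with MAX = 0
    should have been removed by the expression filter and is an error here.
    """
    if baseline_group not in matrix.groups:
        raise ValueError(f"baseline group {baseline_group!r} not in design")
    max_rpkm = matrix.max_per_gene()
    if (max_rpkm == 0).any():
        bad = max_rpkm.index[max_rpkm == 0].tolist()
        raise ValueError(
            f"genes with MAX = 0 reached zero replacement (filter first): {bad[:5]}"
        )
    values = matrix.values.copy()
    baseline_cols = matrix.samples_in_group(baseline_group)
    sub = values[baseline_cols]
    replacement = ZERO_REPLACEMENT_FRACTION * max_rpkm
    values[baseline_cols] = sub.mask(sub == 0, replacement, axis=0)
    return ExpressionMatrix(values, matrix.design)


def call_deg(
    matrix: ExpressionMatrix,
    contrast: tuple[str, str],
    fold_cutoff: float = 2.0,
    fdr_cutoff: float = 0.05,
    exclude_samples: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-gene fold change and FDR for ``contrast = (A, B)`` (fold = A/B).

    Fold is the ratio of arithmetic group means of the (zero-replaced) RPKM.
    The p-value is the ANOVA-contrast t-test on log2(RPKM + eps): difference
    of the two group means over the pooled within-group standard error
    estimated from ALL groups (df = N - k), BH-adjusted across genes.
    ``is_deg`` requires |log2 fold| >= log2(fold_cutoff) AND fdr_p < fdr_cutoff.
    """
    group_a, group_b = contrast
    if exclude_samples:
        matrix = matrix.drop_samples(exclude_samples)
    for g in (group_a, group_b):
        if g not in matrix.groups:
            raise ValueError(f"contrast group {g!r} not in design")
        if len(matrix.samples_in_group(g)) < 2:
            raise ValueError(
                f"group {g!r} has fewer than 2 samples after exclusions"
            )
    values = matrix.values
    a = values[matrix.samples_in_group(group_a)].to_numpy()
    b = values[matrix.samples_in_group(group_b)].to_numpy()
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = mean_a / mean_b
        log2_fold = np.log2(fold)
    log_a = np.log2(a + LOG_EPSILON)
    log_b = np.log2(b + LOG_EPSILON)
    anova_groups = [
        np.log2(values[matrix.samples_in_group(g)].to_numpy() + LOG_EPSILON)
        for g in matrix.groups
    ]
    # pooled within-group variance over all groups (the ANOVA error term)
    ss_within = sum(
        ((arr - arr.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        for arr in anova_groups
    )
    n_total = sum(arr.shape[1] for arr in anova_groups)
    df_error = n_total - len(anova_groups)
    mse = ss_within / df_error
    diff = log_a.mean(axis=1) - log_b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(mse * (1.0 / log_a.shape[1] + 1.0 / log_b.shape[1]))
        t_stat = diff / se
    p_value = 2.0 * stats.t.sf(np.abs(t_stat), df_error)
    # zero pooled variance: identical constants -> 1, separated constants -> 0
    p_value = np.where(se == 0, np.where(diff == 0, 1.0, 0.0), p_value)
    anova_p = np.asarray(stats.f_oneway(*anova_groups, axis=1).pvalue, dtype=float)
    anova_p = np.where(np.isnan(anova_p), 1.0, anova_p)
    _, fdr_p, _, _ = multipletests(p_value, method="fdr_bh")
    is_deg = (np.abs(log2_fold) >= np.log2(fold_cutoff)) & (fdr_p < fdr_cutoff)
    direction = np.where(log2_fold > 0, "up", "down")
    table = pd.DataFrame(
        {
            "gene_id": values.index,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fold,
            "log2_fold": log2_fold,
            "p_value": p_value,
            "anova_p": anova_p,
            "fdr_p": fdr_p,
            "is_deg": is_deg,
            "direction": direction,
        }
    ).reset_index(drop=True)
    table.attrs["contrast"] = f"{group_a}:{group_b}"
    return table.sort_values("gene_id", kind="mergesort").reset_index(drop=True)


def deg_gene_set(table: pd.DataFrame) -> set[str]:
    return set(table.loc[table["is_deg"], "gene_id"])


def union_deg(per_donor: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Union of genes called DEG in any donor, carrying per-donor fold changes.

    Missing per-donor values (gene absent from that donor's retained set) are
    NaN with ``present_<donor>`` False.
    """
    if not isinstance(per_donor, Mapping):
        per_donor = {f"donor{i + 1}": t for i, t in enumerate(per_donor)}
    if not per_donor:
        raise ValueError("at least one DEG table required")
    union_genes = sorted(set().union(*(deg_gene_set(t) for t in per_donor.values())))
    out = pd.DataFrame({"gene_id": union_genes})
    for donor, table in per_donor.items():
        idx = table.set_index("gene_id")
        out[f"fold_{donor}"] = [
            idx.at[g, "fold_change"] if g in idx.index else np.nan
            for g in union_genes
        ]
        out[f"is_deg_{donor}"] = [
            bool(idx.at[g, "is_deg"]) if g in idx.index else False
            for g in union_genes
        ]
        out[f"present_{donor}"] = [g in idx.index for g in union_genes]
    return out
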