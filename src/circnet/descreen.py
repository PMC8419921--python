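"""Differential-expression screening between groups A (pre-IFN) and B (post-IFN).

Each feature is summarized by its group means on the normalized scale,
``log2FC = log2((mean_B + eps) / (mean_A + eps))``, and a p value from the
selected test. The screening thresholds are strict, as printed in the
study design they emulate: a feature is called *up* when log2FC > 2 and
p < 0.01, *down* when log2FC < -2 and p < 0.01, otherwise *ns*. BH
q values are reported for transparency but do not gate status.

Tests
-----
``welch``
    Welch's t on log2(value + eps) per feature (default). With the
    paired option, a paired t test on per-patient log ratios.
``mars``
    A DEGseq-flavoured MA z-test on group-pooled counts (normal
    approximation to the binomial split of a feature's reads between
    the two pooled libraries).
``exact``
    Exact binomial test on the pooled counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import ExpressionMatrix

STATUSES = ("up", "down", "ns")


def de_screen(matrix: ExpressionMatrix, test: str = "welch",
              lfc_cut: float = 2.0, p_cut: float = 0.01,
              epsilon: float = 1.0, paired: bool = False) -> pd.DataFrame:
    """Screen every feature; returns one record per feature.

    Columns: feature_id, rna_class, mean_A, mean_B, log2FC, p_value,
    q_value, status.
    """
    a_cols = matrix.samples_in_group("A")
    b_cols = matrix.samples_in_group("B")
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need at least 2 samples per group")
    A = matrix.values[a_cols].to_numpy(dtype=float)
    B = matrix.values[b_cols].to_numpy(dtype=float)
    zero_lib = [c for c in matrix.values.columns
                if matrix.values[c].sum() == 0]
    if zero_lib:
        raise ValueError(f"all-zero library for sample(s): {zero_lib}")

    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    log2fc = np.log2(mean_b + epsilon) - np.log2(mean_a + epsilon)

    if test == "welch":
        la, lb = np.log2(A + epsilon), np.log2(B + epsilon)
        import warnings as _warnings
        with _warnings.catch_warnings():
            # zero-variance features are handled explicitly below
            _warnings.simplefilter("ignore", RuntimeWarning)
            if paired:
                if la.shape[1] != lb.shape[1]:
                    raise ValueError("paired test needs equal group sizes")
                res = stats.ttest_rel(lb, la, axis=1)
            else:
                res = stats.ttest_ind(lb, la, axis=1, equal_var=False)
        pvals = np.asarray(res.pvalue, dtype=float)
        # degenerate zero-variance features: p=0 when means differ, 1 when equal
        var_zero = (la.var(axis=1) == 0) & (lb.var(axis=1) == 0)
        diff = lb.mean(axis=1) - la.mean(axis=1)
        pvals = np.where(var_zero, np.where(diff == 0, 1.0, 0.0), pvals)
        pvals = np.nan_to_num(pvals, nan=1.0)
    elif test in ("mars", "exact"):
        ka = A.sum(axis=1)
        kb = B.sum(axis=1)
        na, nb = ka.sum(), kb.sum()
        if na == 0 or nb == 0:
            raise ValueError("pooled counts must be positive for count tests")
        p0 = nb / (na + nb)
        tot = ka + kb
        if test == "mars":
            with np.errstate(divide="ignore", invalid="ignore"):
                z = (kb - tot * p0) / np.sqrt(tot * p0 * (1 - p0))
            pvals = np.where(tot > 0, 2 * stats.norm.sf(np.abs(z)), 1.0)
        else:
            pvals = np.array([
                stats.binomtest(int(round(k)), int(round(t)), p0).pvalue
                if t > 0 else 1.0
                for k, t in zip(kb, tot)])
    else:
        raise ValueError(f"unknown test {test!r}")

    qvals = multipletests(pvals, method="fdr_bh")[1]
    status = np.where((log2fc > lfc_cut) & (pvals < p_cut), "up",
                      np.where((log2fc < -lfc_cut) & (pvals < p_cut),
                               "down", "ns"))
    return pd.DataFrame({
        "feature_id": matrix.values.index,
        "rna_class": matrix.rna_class,
        "mean_A": mean_a, "mean_B": mean_b,
        "log2FC": log2fc, "p_value": pvals, "q_value": qvals,
        "status": status,
    }).reset_index(drop=True)


def summarize_de(records) -> pd.DataFrame:
    """Per-class up/down/ns counts. Accepts one frame or a class-keyed dict."""
    if isinstance(records, dict):
        records = pd.concat(records.values(), ignore_index=True)
    table = (records.groupby(["rna_class", "status"]).size()
             .unstack(fill_value=0))
    for st in STATUSES:
        if st not in table.columns:
            table[st] = 0
    return table[list(STATUSES)]


def write_de_tsv(records: pd.DataFrame, path, epsilon: float,
                 header_comments=None) -> None:
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        fh.write(f"# epsilon={epsilon}\n")
        records.to_csv(fh, sep="\t", index=False, float_format="%.8g")
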