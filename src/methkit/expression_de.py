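"""Paired differential expression on a log2-scale expression matrix.

Genes are tested with a paired t-test on the per-pair tumor-minus-normal
log2 differences, BH-corrected across genes, and called differentially
expressed when q < 0.05 and linear fold change > 2 (or < 1/2); fold
change is the antilog of the mean paired log2 difference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import bh_adjust
from .utils import log


def paired_t_test(tumor, normal) -> tuple[float, float]:
    """Two-sided paired t-test on log2 values; returns (t, p).

    All-zero differences give (0, 1). Nonzero mean with zero variance is
    degenerate: returns (signed inf, nan) and logs the event.
    """
    d = np.asarray(tumor, dtype=float) - np.asarray(normal, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 complete pairs")
    if np.all(d == d[0]):
        if d[0] == 0:
            return 0.0, 1.0
        log.warning("degenerate paired t-test: constant nonzero differences")
        return float(np.sign(d[0]) * np.inf), float("nan")
    res = stats.ttest_rel(np.asarray(tumor, float), np.asarray(normal, float))
    return float(res.statistic), float(res.pvalue)


def call_degs(
    expression: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    q_threshold: float = 0.05,
    fc_threshold: float = 2.0,
) -> pd.DataFrame:
    """Gene-level differential expression table.

    ``expression`` is genes x samples on log2 scale; the sample sheet
    supplies group and pair labels. Columns of the result:
    mean_expr_tumor, mean_expr_normal, log2_fc, fold_change, p_value,
    q_value, direction ("up" / "down" / "none").
    """
    sheet = sample_sheet.loc[sample_sheet.index.intersection(expression.columns)]
    pairs = {}
    for pair, sub in sheet.groupby("pair_id"):
        t = sub.index[(sub["group"] == "tumor").to_numpy()]
        n = sub.index[(sub["group"] == "normal").to_numpy()]
        if len(t) == 1 and len(n) == 1:
            pairs[pair] = (t[0], n[0])
    if len(pairs) < 2:
        raise ValueError("paired design requires at least 2 complete tumor/normal pairs")
    t_cols = [v[0] for v in pairs.values()]
    n_cols = [v[1] for v in pairs.values()]

    t_mat = expression[t_cols].to_numpy()
    n_mat = expression[n_cols].to_numpy()
    diffs = t_mat - n_mat
    n_pairs = diffs.shape[1]

    mean_d = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = mean_d / (sd / np.sqrt(n_pairs))
    p = 2.0 * stats.t.sf(np.abs(t_stat), df=n_pairs - 1)

    zero_var = sd == 0
    degenerate = zero_var & (mean_d != 0)
    null_const = zero_var & (mean_d == 0)
    t_stat[null_const] = 0.0
    p[null_const] = 1.0
    p[degenerate] = np.nan
    if degenerate.any():
        log.warning("%d genes with constant nonzero paired differences", int(degenerate.sum()))

    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    q[ok] = bh_adjust(p[ok])

    log2_fc = mean_d
    fold_change = np.power(2.0, log2_fc)
    called = ok & (q < q_threshold)
    direction = np.where(called & (fold_change > fc_threshold), "up", "none")
    direction = np.where(called & (fold_change < 1.0 / fc_threshold), "down", direction)

    return pd.DataFrame(
        {
            "mean_expr_tumor": t_mat.mean(axis=1),
            "mean_expr_normal": n_mat.mean(axis=1),
            "log2_fc": log2_fc,
            "fold_change": fold_change,
            "t_statistic": t_stat,
            "p_value": p,
            "q_value": q,
            "direction": direction,
        },
        index=expression.index,
    )


def deg_summary(degs: pd.DataFrame) -> dict:
    n_up = int((degs["direction"] == "up").sum())
    n_down = int((degs["direction"] == "down").sum())
    return {"n_tested": int(len(degs)), "n_deg": n_up + n_down, "n_up": n_up, "n_down": n_down}
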