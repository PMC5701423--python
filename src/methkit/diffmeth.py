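"""Probe-level differential methylation calling and gene aggregation.

Each probe is tested tumor vs normal with the two-sided Wilcoxon
rank-sum (Mann-Whitney) test, p-values are corrected genome-wide with
the Benjamini-Hochberg step-up FDR, and a probe is called differentially
methylated (a DMP) when q < 0.05 and the group-mean beta difference
|delta beta| >= 0.2. Delta beta is mean beta(tumor) - mean beta(normal);
called probes are labeled hyper- or hypomethylated by its sign. Genes
aggregate DMPs by the any-probe rule, taking direction from the probe
with the largest |delta beta| and flagging genes with both directions as
mixed.

The unpaired rank-sum test is used (not the paired signed-rank test):
the exact null distribution is used for small tie-free inputs, the
normal approximation with tie correction and continuity correction
otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import BetaMatrix
from .utils import log, round_percentages

EXACT_MAX_N = 12  # exact Wilcoxon null when combined n is at most this and tie-free


def wilcoxon_rank_sum(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (U statistic, p).

    Uses the exact null distribution when the combined sample size is
    small and there are no ties, the tie-corrected normal approximation
    with continuity correction otherwise. Identical pooled values give
    p = 1 (no evidence against exchangeability).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dmps(
    beta: BetaMatrix,
    q_threshold: float = 0.05,
    delta_threshold: float = 0.2,
) -> pd.DataFrame:
    """Per-probe differential methylation table.

    Columns: mean_beta_tumor, mean_beta_normal, delta_beta, p_value,
    q_value, direction ("hyper" / "hypo" / "none"). BH correction spans
    every probe in the (QC-filtered) matrix.
    """
    tumor = beta.beta[beta.tumor_samples].to_numpy()
    normal = beta.beta[beta.normal_samples].to_numpy()
    if tumor.shape[1] < 2 or normal.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")

    mean_t = tumor.mean(axis=1)
    mean_n = normal.mean(axis=1)
    delta = mean_t - mean_n

    combined_n = tumor.shape[1] + normal.shape[1]
    if combined_n <= EXACT_MAX_N:
        # small designs: per-probe scalar test so the exact null applies
        p = np.array(
            [wilcoxon_rank_sum(t, u)[1] for t, u in zip(tumor, normal)]
        )
    else:
        res = stats.mannwhitneyu(
            tumor, normal, alternative="two-sided", method="asymptotic",
            use_continuity=True, axis=1,
        )
        p = np.asarray(res.pvalue, dtype=float)
        constant = (tumor == tumor[:, :1]).all(axis=1) & (
            normal == tumor[:, :1]
        ).all(axis=1)
        p[constant | ~np.isfinite(p)] = 1.0

    q = bh_adjust(p)
    called = (q < q_threshold) & (np.abs(delta) >= delta_threshold)
    direction = np.where(called & (delta > 0), "hyper", "none")
    direction = np.where(called & (delta < 0), "hypo", direction)

    return pd.DataFrame(
        {
            "mean_beta_tumor": mean_t,
            "mean_beta_normal": mean_n,
            "delta_beta": delta,
            "p_value": p,
            "q_value": q,
            "direction": direction,
        },
        index=beta.beta.index,
    )


def dmp_summary(dmps: pd.DataFrame) -> dict:
    """Counts and largest-remainder percentages of hyper/hypo calls."""
    n_hyper = int((dmps["direction"] == "hyper").sum())
    n_hypo = int((dmps["direction"] == "hypo").sum())
    pct = round_percentages([n_hyper, n_hypo])
    return {
        "n_tested": int(len(dmps)),
        "n_dmp": n_hyper + n_hypo,
        "n_hyper": n_hyper,
        "n_hypo": n_hypo,
        "pct_hyper": int(pct[0]) if n_hyper + n_hypo else 0,
        "pct_hypo": int(pct[1]) if n_hyper + n_hypo else 0,
    }


def aggregate_to_genes(dmps: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Gene-level table: a gene is differentially methylated when at least
    one of its probes is. Direction follows the max-|delta beta| probe;
    genes with probes called in both directions carry mixed=True."""
    genes = manifest.loc[dmps.index, "gene"]
    unannotated = int((genes == "").sum() + genes.isna().sum())
    if unannotated:
        log.info("%d probes without gene annotation excluded from gene table", unannotated)
    tbl = dmps.join(genes.rename("gene"))
    tbl = tbl[(tbl["gene"] != "") & tbl["gene"].notna()]
    dm = tbl[tbl["direction"] != "none"]

    rows = []
    n_total = tbl.groupby("gene").size()
    for gene, sub in dm.groupby("gene"):
        rep = sub["delta_beta"].abs().idxmax()
        dirs = set(sub["direction"])
        rows.append(
            {
                "gene_id": gene,
                "n_probes_total": int(n_total[gene]),
                "n_probes_dm": int(len(sub)),
                "direction": sub.loc[rep, "direction"],
                "mixed": len(dirs) > 1,
                "representative_probe": rep,
                "delta_beta": float(sub.loc[rep, "delta_beta"]),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "n_probes_total",
            "n_probes_dm",
            "direction",
            "mixed",
            "representative_probe",
            "delta_beta",
        ],
    )
    return out.set_index("gene_id").sort_index() if len(out) else out.set_index("gene_id")
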