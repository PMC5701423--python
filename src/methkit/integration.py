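"""Starburst integration of differential methylation and expression.

Genes that are both differentially methylated and differentially
expressed are placed in one of four starburst quadrants
(hyper_down, hypo_up, hyper_up, hypo_down). The inverse quadrants
(hyper_down, hypo_up) are the methylation-consistent candidates; a
fourfold expression cutoff (|log2 FC| >= 2) refines them to the genes
with the greatest changes. Per-gene Spearman correlation between the
representative probe's beta and expression quantifies the coupling, and
a chi-square / Fisher test asks whether quadrant membership associates
with promoter or CpG-island localization of the representative probe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .context import PROMOTER_CONTEXTS
from .utils import log, round_percentages

QUADRANTS = ["hyper_down", "hypo_up", "hyper_up", "hypo_down"]
INVERSE_QUADRANTS = {"hyper_down", "hypo_up"}


def starburst_classify(
    dmgs: pd.DataFrame, degs: pd.DataFrame, manifest: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Intersect DM genes with DE genes and assign starburst quadrants.

    Genes with mixed methylation direction are excluded (logged). When a
    manifest is given, each record carries in_promoter / on_cgi flags of
    the representative probe.
    """
    de = degs[degs["direction"].isin(["up", "down"])]
    common = dmgs.index.intersection(de.index)
    if len(common) == 0:
        log.warning("no genes are both differentially methylated and expressed")
    dm = dmgs.loc[common]
    mixed = dm["mixed"].astype(bool)
    if mixed.any():
        log.info("%d genes with mixed methylation direction excluded", int(mixed.sum()))
    dm = dm[~mixed]

    records = pd.DataFrame(index=dm.index)
    records["meth_direction"] = dm["direction"]
    records["expr_direction"] = de.loc[dm.index, "direction"]
    records["quadrant"] = records["meth_direction"] + "_" + records["expr_direction"]
    records["delta_beta"] = dm["delta_beta"]
    records["log2_fc"] = de.loc[dm.index, "log2_fc"]
    records["representative_probe"] = dm["representative_probe"]
    if manifest is not None:
        rep = manifest.loc[dm["representative_probe"]]
        records["in_promoter"] = rep["gene_context"].isin(PROMOTER_CONTEXTS).to_numpy()
        records["on_cgi"] = (rep["cgi_context"] == "Island").to_numpy()
    return records


def quadrant_summary(records: pd.DataFrame) -> dict:
    """Quadrant counts, rounded percentages and the inverse-set size."""
    counts = [int((records["quadrant"] == q).sum()) for q in QUADRANTS]
    pct = round_percentages(counts)
    return {
        "n_integrated": int(len(records)),
        "quadrant_counts": dict(zip(QUADRANTS, counts)),
        "quadrant_pct": dict(zip(QUADRANTS, (int(x) for x in pct))),
        "n_inverse": counts[0] + counts[1],
    }


def apply_fourfold_cutoff(records: pd.DataFrame, fold: float = 4.0) -> pd.DataFrame:
    """Inverse-quadrant genes whose |log2 FC| meets log2(fold)."""
    if fold <= 1:
        raise ValueError("fold cutoff must exceed 1")
    cut = np.log2(fold)
    keep = records["quadrant"].isin(INVERSE_QUADRANTS) & (
        records["log2_fc"].abs() >= cut
    )
    return records[keep].copy()


def spearman_meth_expr(beta_values, expr_values) -> float:
    """Spearman rank correlation between per-sample beta and expression."""
    x = np.asarray(beta_values, dtype=float)
    y = np.asarray(expr_values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        log.warning("constant vector; Spearman correlation undefined")
        return float("nan")
    r, _ = stats.spearmanr(x, y)
    return float(r)


def correlation_table(
    records: pd.DataFrame, beta: pd.DataFrame, expression: pd.DataFrame
) -> pd.Series:
    """Spearman r per integrated gene over the samples shared by the beta
    and expression matrices (methylation from the representative probe)."""
    samples = [s for s in expression.columns if s in beta.columns]
    out = {}
    for gene, row in records.iterrows():
        probe = row["representative_probe"]
        if gene in expression.index and probe in beta.index:
            out[gene] = spearman_meth_expr(
                beta.loc[probe, samples].to_numpy(),
                expression.loc[gene, samples].to_numpy(),
            )
    return pd.Series(out, name="spearman_r")


def context_association_test(records: pd.DataFrame, grouping: str = "cgi") -> dict:
    """Quadrant x membership independence test.

    ``grouping`` is "cgi" (on_cgi) or "promoter" (in_promoter). Tables
    larger than 2x2 use the chi-square test without continuity
    correction; a 2x2 table with any expected count below 5 falls back to
    Fisher's exact test.
    """
    column = {"cgi": "on_cgi", "promoter": "in_promoter"}[grouping]
    present = [q for q in QUADRANTS if (records["quadrant"] == q).any()]
    table = np.array(
        [
            [
                int(((records["quadrant"] == q) & records[column]).sum()),
                int(((records["quadrant"] == q) & ~records[column]).sum()),
            ]
            for q in present
        ]
    )
    if table.size == 0 or (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("degenerate contingency table (zero margin)")
    if table.shape == (2, 2):
        expected = stats.contingency.expected_freq(table)
        if (expected < 5).any():
            _, p = stats.fisher_exact(table)
            return {"grouping": grouping, "table": table, "method": "fisher", "p_value": float(p)}
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {
        "grouping": grouping,
        "table": table,
        "method": "chi2",
        "chi_square": float(chi2),
        "p_value": float(p),
    }
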