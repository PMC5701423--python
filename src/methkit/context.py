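"""Genomic-context classification and region-level methylation summaries.

Probes are placed in CpG-island-based regions — Island, north/south
shore (within 2 kb of an island edge), north/south shelf (the next
2 kb), open sea beyond — and in gene-based regions (TSS1500, TSS200,
5'UTR, first exon, body, 3'UTR, intergenic). "North" is the lower
genomic-coordinate side of an island. Region summaries tabulate counts
and rounded percentages, and region-level group comparisons run the
Wilcoxon rank-sum test on per-sample region-mean beta.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffmeth import bh_adjust, wilcoxon_rank_sum
from .preprocess import BetaMatrix
from .utils import log, round_percentages

CGI_LABELS = ["Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"]
GENE_LABELS = ["TSS1500", "TSS200", "5UTR", "FirstExon", "Body", "3UTR", "Intergenic"]
PROMOTER_CONTEXTS = {"TSS1500", "TSS200", "5UTR", "FirstExon"}


def classify_cgi_context(
    position: int,
    chromosome: str,
    cgi_intervals: pd.DataFrame,
    shore_width: int = 2000,
    shelf_width: int = 2000,
) -> tuple[str, int]:
    """Classify one position relative to the nearest CpG island.

    ``cgi_intervals`` is BED-like (chromosome, start, end; 0-based
    half-open, sorted). Returns (label, distance to the nearest island
    edge; 0 inside an island). The south distance of the first base past
    an island is 0 under the half-open convention, and that base is
    already S_Shore.
    """
    chrom_iv = cgi_intervals[cgi_intervals["chromosome"] == chromosome]
    if chrom_iv.empty:
        log.warning("chromosome %s absent from CGI interval set", chromosome)
        return "OpenSea", int(position)
    starts = chrom_iv["start"].to_numpy()
    ends = chrom_iv["end"].to_numpy()

    i = np.searchsorted(starts, position, side="right") - 1
    if i >= 0 and starts[i] <= position < ends[i]:
        return "Island", 0
    # distance to the island on the lower side (south flank of it) and on
    # the higher side (north flank of the next island)
    d_south = position - ends[i] if i >= 0 else None
    d_north = starts[i + 1] - position if i + 1 < len(starts) else None

    if d_north is not None and (d_south is None or d_north <= d_south):
        dist, side = d_north, "N"
    else:
        dist, side = d_south, "S"
    if (side == "N" and 0 < dist <= shore_width) or (side == "S" and dist < shore_width):
        return f"{side}_Shore", int(dist)
    if (side == "N" and dist <= shore_width + shelf_width) or (
        side == "S" and dist < shore_width + shelf_width
    ):
        return f"{side}_Shelf", int(dist)
    return "OpenSea", int(dist)


def classify_cgi_contexts(
    manifest: pd.DataFrame,
    cgi_intervals: pd.DataFrame,
    shore_width: int = 2000,
    shelf_width: int = 2000,
) -> pd.Series:
    """Vectorized-by-row CGI classification of a whole manifest."""
    labels = [
        classify_cgi_context(p, c, cgi_intervals, shore_width, shelf_width)[0]
        for p, c in zip(manifest["position"], manifest["chromosome"])
    ]
    return pd.Series(labels, index=manifest.index, name="cgi_context")


def classify_gene_context(position: int, gene_model: dict) -> str:
    """Classify a position against one gene model.

    ``gene_model`` keys: tss, strand ('+'/'-'), gene_start, gene_end,
    first_exon (start, end) and optionally utr5 / utr3 as (start, end),
    all 0-based half-open. Precedence: TSS200 > TSS1500 > 5UTR >
    FirstExon > 3UTR > Body; positions outside the gene and its upstream
    windows are Intergenic. Upstream is strand-aware.
    """
    try:
        tss = int(gene_model["tss"])
        strand = gene_model["strand"]
        gs, ge = int(gene_model["gene_start"]), int(gene_model["gene_end"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed gene model: {exc}") from exc
    if strand not in "+-" or gs >= ge:
        raise ValueError("malformed gene model")

    upstream = tss - position if strand == "+" else position - tss
    if 1 <= upstream <= 200:
        return "TSS200"
    if 201 <= upstream <= 1500:
        return "TSS1500"

    def inside(bounds) -> bool:
        return bounds is not None and bounds[0] <= position < bounds[1]

    in_gene = gs <= position < ge
    if inside(gene_model.get("utr5")):
        return "5UTR"
    if inside(gene_model.get("first_exon")):
        return "FirstExon"
    if inside(gene_model.get("utr3")):
        return "3UTR"
    if in_gene:
        return "Body"
    return "Intergenic"


def region_distribution(
    probes: pd.DataFrame, partition: str = "cgi", direction: pd.Series | None = None
) -> pd.DataFrame:
    """Counts and rounded percentages of probes per region category.

    ``partition`` is "cgi", "gene" or "chromosome" and selects the
    manifest column (cgi_context / gene_context / chromosome). With a
    ``direction`` series (hyper/hypo/none per probe), separate tables for
    all, hyper and hypo probes are stacked with a ``subset`` column.
    """
    column = {"cgi": "cgi_context", "gene": "gene_context", "chromosome": "chromosome"}[
        partition
    ]
    categories = {"cgi": CGI_LABELS, "gene": GENE_LABELS}.get(partition)

    def one(sub: pd.DataFrame, name: str) -> pd.DataFrame:
        counts = sub[column].value_counts()
        cats = categories if categories is not None else sorted(counts.index)
        counts = counts.reindex(cats, fill_value=0)
        pct = round_percentages(counts.to_numpy())
        return pd.DataFrame(
            {"subset": name, "region": cats, "count": counts.to_numpy(), "pct": pct}
        )

    if probes.empty:
        return pd.DataFrame(columns=["subset", "region", "count", "pct"])
    tables = [one(probes, "all")]
    if direction is not None:
        d = direction.reindex(probes.index)
        for name in ("hyper", "hypo"):
            sel = probes[(d == name).to_numpy()]
            if len(sel):
                tables.append(one(sel, name))
    return pd.concat(tables, ignore_index=True)


def compare_region_methylation(
    beta: BetaMatrix, contexts: pd.Series, partition_labels=None
) -> pd.DataFrame:
    """Tumor-vs-normal comparison of per-sample region-mean beta.

    For every region, each sample is reduced to its mean beta over the
    region's probes; the two groups of sample means are compared with the
    Wilcoxon rank-sum test and BH-corrected across regions.
    """
    contexts = contexts.reindex(beta.beta.index)
    labels = partition_labels or sorted(contexts.dropna().unique())
    tumor_cols = beta.tumor_samples
    normal_cols = beta.normal_samples
    rows = []
    for region in labels:
        probes = contexts.index[(contexts == region).to_numpy()]
        if len(probes) == 0:
            log.warning("region %s has no probes; omitted", region)
            continue
        sub = beta.beta.loc[probes]
        t_means = sub[tumor_cols].mean(axis=0).to_numpy()
        n_means = sub[normal_cols].mean(axis=0).to_numpy()
        stat, p = wilcoxon_rank_sum(t_means, n_means)
        rows.append(
            {
                "region": region,
                "n_probes": len(probes),
                "mean_beta_tumor": float(t_means.mean()),
                "mean_beta_normal": float(n_means.mean()),
                "statistic": stat,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out


def beta_density_histogram(
    beta: BetaMatrix, contexts: pd.Series, n_bins: int = 50
) -> pd.DataFrame:
    """Per-region histogram of per-probe mean beta over [0, 1], split by
    group — the data behind region density plots."""
    contexts = contexts.reindex(beta.beta.index)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    rows = []
    for group, cols in (
        ("tumor", beta.tumor_samples),
        ("normal", beta.normal_samples),
    ):
        means = beta.beta[cols].mean(axis=1)
        for region in sorted(contexts.dropna().unique()):
            vals = means[(contexts == region).to_numpy()]
            hist, _ = np.histogram(vals, bins=edges)
            for lo, hi, c in zip(edges[:-1], edges[1:], hist):
                rows.append(
                    {
                        "group": group,
                        "region": region,
                        "bin_low": lo,
                        "bin_high": hi,
                        "count": int(c),
                    }
                )
    return pd.DataFrame(rows)


def histogram_mode(values, n_bins: int = 50) -> float:
    """Midpoint of the fullest histogram bin over [0, 1]."""
    hist, edges = np.histogram(np.asarray(values), bins=n_bins, range=(0.0, 1.0))
    i = int(np.argmax(hist))
    return float((edges[i] + edges[i + 1]) / 2.0)
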