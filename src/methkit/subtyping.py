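"""Unsupervised methylation subtyping and stratified correlation analysis.

Tumors are clustered hierarchically on the M-values of the called
differential probes (all of them, or the CpG-island subset), the
dendrogram is cut at k = 2, and clusters are relabeled so Cluster 2 is
the subgroup with the higher mean M-value (the hypermethylated
subgroup). The default distance is 1 - Pearson correlation across
features with average linkage. Clinical stratification reduces each
stratum to its per-probe mean beta profile and reports the Pearson
correlation between the two profiles, separately within tumors and
normals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

from .preprocess import BetaMatrix, beta_to_mvalue
from .utils import log


@dataclass
class ClusterResult:
    sample_labels: pd.Series  # sample_id -> cluster id (1-based)
    n_clusters: int
    linkage_method: str
    distance_metric: str
    cluster_mean_mvalue: dict  # cluster id -> mean M-value
    feature_set: str
    linkage_matrix: np.ndarray
    leaf_order: list


def hierarchical_cluster(
    matrix: pd.DataFrame,
    distance_metric: str = "correlation",
    linkage_method: str = "average",
):
    """Agglomerative clustering of samples (columns) of a feature matrix.

    Returns (linkage matrix, leaf order as column names). Distances of a
    constant matrix are all zero; the dendrogram is still built (one
    merged cluster) with a warning.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values")
    x = matrix.to_numpy().T  # observations = samples
    d = pdist(x, metric=distance_metric)
    d = np.nan_to_num(d, nan=0.0)  # constant samples give nan correlation distance
    if np.all(d == 0):
        log.warning("all pairwise distances are zero; degenerate dendrogram")
    z = linkage(d, method=linkage_method)
    order = [matrix.columns[i] for i in leaves_list(z)]
    return z, order


def subtype_tumors(
    beta: BetaMatrix,
    dmps: pd.DataFrame,
    manifest: pd.DataFrame | None = None,
    k: int = 2,
    feature_set: str = "all_dmp",
    distance_metric: str = "correlation",
    linkage_method: str = "average",
    epsilon: float = 1e-6,
) -> ClusterResult:
    """Cluster tumor samples on M-values of the DMP feature set.

    ``feature_set`` is "all_dmp" or "cgi_dmp" (island DMPs only; needs a
    manifest). Clusters are relabeled in increasing mean M-value order,
    so Cluster k is the most methylated.
    """
    called = dmps[dmps["direction"] != "none"]
    if feature_set == "cgi_dmp":
        if manifest is None:
            raise ValueError("cgi_dmp feature set requires a manifest")
        island = manifest.loc[called.index, "cgi_context"] == "Island"
        called = called[island.to_numpy()]
    elif feature_set != "all_dmp":
        raise ValueError("feature_set must be 'all_dmp' or 'cgi_dmp'")
    if len(called) < 2:
        raise ValueError("need at least 2 differential probes to cluster")

    tumors = beta.tumor_samples
    if len(tumors) < k:
        raise ValueError("fewer tumors than clusters requested")
    mvals = beta_to_mvalue(beta.beta.loc[called.index, tumors], epsilon=epsilon).m_value

    # center each probe across tumors before computing distances: the
    # shared probe-mean profile otherwise dominates sample-sample
    # correlation and hides subgroup structure (row-centering, as in
    # standard methylation heatmaps)
    centered = mvals.sub(mvals.mean(axis=1), axis=0)
    z, order = hierarchical_cluster(centered, distance_metric, linkage_method)
    raw = fcluster(z, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=tumors)

    # relabel so the cluster with the highest mean M-value gets the
    # highest id ("Cluster 2 is hypermethylated" stays assertable)
    means = {c: float(mvals[labels.index[labels == c]].mean().mean()) for c in np.unique(raw)}
    rank = {c: i + 1 for i, c in enumerate(sorted(means, key=means.get))}
    labels = labels.map(rank)
    means = {rank[c]: m for c, m in means.items()}

    return ClusterResult(
        sample_labels=labels,
        n_clusters=int(labels.nunique()),
        linkage_method=linkage_method,
        distance_metric=distance_metric,
        cluster_mean_mvalue=means,
        feature_set=feature_set,
        linkage_matrix=z,
        leaf_order=order,
    )


def stratified_correlation(
    beta: BetaMatrix, sample_sheet: pd.DataFrame, factor: str
) -> pd.DataFrame:
    """Correlation of mean methylation profiles between two clinical strata.

    For each group (tumor / normal) the samples are split by the factor's
    two levels; the per-probe mean beta profile of each stratum is
    computed and the Pearson correlation between the two profiles
    reported.
    """
    sheet = sample_sheet.reindex(beta.beta.columns)
    levels = sorted(sheet[factor].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"factor {factor!r} must have exactly two strata, got {levels}")
    rows = []
    for group in ("tumor", "normal"):
        g = sheet[sheet["group"] == group]
        profiles = []
        ok = True
        for lev in levels:
            cols = g.index[(g[factor] == lev).to_numpy()]
            if len(cols) == 0:
                log.warning("stratum %s=%s empty within %s; skipped", factor, lev, group)
                ok = False
                break
            profiles.append(beta.beta[cols].mean(axis=1).to_numpy())
        if not ok:
            continue
        r = float(np.corrcoef(profiles[0], profiles[1])[0, 1])
        rows.append(
            {
                "factor": factor,
                "stratum_a": levels[0],
                "stratum_b": levels[1],
                "group": group,
                "correlation": r,
            }
        )
    return pd.DataFrame(rows)
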