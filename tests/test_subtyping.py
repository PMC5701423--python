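"""Hierarchical clustering, tumor subtyping, stratified correlation."""

import numpy as np
import pandas as pd
import pytest

from methkit import (
    BetaMatrix,
    call_dmps,
    hierarchical_cluster,
    stratified_correlation,
    subtype_tumors,
)
from methkit.preprocess import beta_matrix_from_sheet


def test_identical_samples_merge_at_zero():
    m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [9.0, 1.0, 4.0]})
    z, _ = hierarchical_cluster(m, distance_metric="euclidean")
    assert z[0, 2] == pytest.approx(0.0)
    assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}


def test_first_merge_is_closest_pair():
    m = pd.DataFrame({"a": [0.0], "b": [1.0], "c": [10.0]})
    z, _ = hierarchical_cluster(m, distance_metric="euclidean", linkage_method="average")
    assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}


def test_dendrogram_heights_nondecreasing():
    rng = np.random.default_rng(1)
    m = pd.DataFrame(rng.normal(size=(30, 12)))
    z, _ = hierarchical_cluster(m, distance_metric="euclidean")
    assert (np.diff(z[:, 2]) >= -1e-12).all()


def test_missing_values_rejected():
    m = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]})
    with pytest.raises(ValueError):
        hierarchical_cluster(m)


def test_planted_blobs_recovered():
    from scipy.cluster.hierarchy import fcluster

    for seed in range(1, 6):
        rng = np.random.default_rng(seed)
        blob1 = rng.normal(0.0, 0.3, size=(40, 6))
        blob2 = rng.normal(3.0, 0.3, size=(40, 6))
        m = pd.DataFrame(np.concatenate([blob1, blob2], axis=1))
        z, _ = hierarchical_cluster(m, distance_metric="euclidean")
        labels = fcluster(z, t=2, criterion="maxclust")
        assert len(set(labels[:6])) == 1
        assert len(set(labels[6:])) == 1
        assert labels[0] != labels[6]


def _study_beta(study, beta):
    return beta


def test_subtype_recovery_and_relabeling(small_study, small_beta):
    """The k=2 cut recovers the planted tumor subgroups with the
    hypermethylated subgroup labeled Cluster 2."""
    from methkit import qc_filter

    study = small_study
    filtered, _ = qc_filter(small_beta, study["intensities"], study["manifest"])
    dmps = call_dmps(filtered)
    res = subtype_tumors(filtered, dmps, manifest=study["manifest"], k=2)
    truth = study["truth"].subtype_labels
    pred = res.sample_labels.copy()
    pred.index = [f"P{int(s[1:]):02d}" for s in pred.index]
    assert (pred.sort_index() == truth.sort_index()).all()
    assert res.cluster_mean_mvalue[2] > res.cluster_mean_mvalue[1]


def test_subtype_deterministic(small_study, small_beta):
    from methkit import qc_filter

    filtered, _ = qc_filter(
        small_beta, small_study["intensities"], small_study["manifest"]
    )
    dmps = call_dmps(filtered)
    a = subtype_tumors(filtered, dmps, manifest=small_study["manifest"], k=2)
    b = subtype_tumors(filtered, dmps, manifest=small_study["manifest"], k=2)
    assert (a.sample_labels == b.sample_labels).all()


def test_subtype_k1_single_cluster(small_study, small_beta):
    from methkit import qc_filter

    filtered, _ = qc_filter(
        small_beta, small_study["intensities"], small_study["manifest"]
    )
    dmps = call_dmps(filtered)
    res = subtype_tumors(filtered, dmps, manifest=small_study["manifest"], k=1)
    assert res.sample_labels.nunique() == 1


def test_subtype_cgi_feature_count(small_study, small_beta):
    from methkit import qc_filter

    man = small_study["manifest"]
    filtered, _ = qc_filter(small_beta, small_study["intensities"], man)
    dmps = call_dmps(filtered)
    res = subtype_tumors(filtered, dmps, manifest=man, k=2, feature_set="cgi_dmp")
    called = dmps[dmps["direction"] != "none"]
    n_island = int((man.loc[called.index, "cgi_context"] == "Island").sum())
    assert res.feature_set == "cgi_dmp"
    # the linkage was computed over exactly the island DMPs
    assert res.linkage_matrix.shape[0] == len(res.sample_labels) - 1
    assert n_island >= 2


def test_subtype_too_few_dmps_rejected(small_study, small_beta):
    dmps = pd.DataFrame(
        {"direction": ["none"] * 5, "delta_beta": [0.0] * 5},
        index=small_beta.beta.index[:5],
    )
    with pytest.raises(ValueError):
        subtype_tumors(small_beta, dmps, k=2)


def _strat_beta(n_probes, n_pairs, seed, shift_first=0.0, factor_split=None):
    rng = np.random.default_rng(seed)
    mu = rng.uniform(0.1, 0.9, size=n_probes)
    cols, groups, pairs = [], [], []
    vals = np.empty((n_probes, 2 * n_pairs))
    for p in range(n_pairs):
        vals[:, 2 * p] = np.clip(mu + rng.normal(0, 0.05, n_probes), 0, 1)
        vals[:, 2 * p + 1] = np.clip(mu + rng.normal(0, 0.05, n_probes), 0, 1)
        cols += [f"T{p}", f"N{p}"]
        groups += ["tumor", "normal"]
        pairs += [f"P{p}", f"P{p}"]
    sheet = pd.DataFrame({"group": groups, "pair_id": pairs}, index=cols)
    sheet["factor"] = [
        "a" if (int(c[1:]) < n_pairs // 2) else "b" for c in cols
    ] if factor_split is None else factor_split
    beta = pd.DataFrame(vals, columns=cols, index=[f"cg{i}" for i in range(n_probes)])
    if shift_first:
        stratum_b = [c for c in cols if sheet.loc[c, "factor"] == "b"]
        beta.loc[beta.index[: n_probes // 4], stratum_b] += shift_first
    return beta_matrix_from_sheet(beta, sheet), sheet


def test_stratified_identical_profiles_r_exactly_one():
    # strata whose samples carry identical per-probe values give r = 1
    rng = np.random.default_rng(0)
    mu = rng.uniform(0.1, 0.9, size=200)
    cols = [f"T{p}" for p in range(8)] + [f"N{p}" for p in range(8)]
    beta = pd.DataFrame(
        np.tile(mu[:, None], (1, 16)), columns=cols,
        index=[f"cg{i}" for i in range(200)],
    )
    sheet = pd.DataFrame(
        {
            "group": ["tumor"] * 8 + ["normal"] * 8,
            "pair_id": [f"P{p}" for p in range(8)] * 2,
            "factor": ["a", "b"] * 8,
        },
        index=cols,
    )
    out = stratified_correlation(beta_matrix_from_sheet(beta, sheet), sheet, "factor")
    assert np.allclose(out["correlation"], 1.0)


def test_stratified_same_generator_high_correlation():
    beta, sheet = _strat_beta(5000, 20, seed=3)
    out = stratified_correlation(beta, sheet, "factor")
    assert (out["correlation"] > 0.99).all()


def test_stratified_shift_lowers_correlation_monotonically():
    rs = []
    for shift in (0.0, 0.15, 0.3, 0.45):
        beta, sheet = _strat_beta(2000, 16, seed=7, shift_first=shift)
        out = stratified_correlation(beta, sheet, "factor")
        rs.append(float(out["correlation"].mean()))
    assert all(a > b for a, b in zip(rs, rs[1:]))


def test_stratified_requires_two_levels():
    beta, sheet = _strat_beta(100, 6, seed=1)
    sheet["factor"] = "only"
    with pytest.raises(ValueError):
        stratified_correlation(beta, sheet, "factor")
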