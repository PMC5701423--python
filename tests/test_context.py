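"""CGI/gene context classification and region-level summaries."""

import numpy as np
import pandas as pd
import pytest

from methkit import (
    BetaMatrix,
    classify_cgi_context,
    classify_gene_context,
    compare_region_methylation,
    region_distribution,
)
from methkit.context import CGI_LABELS


@pytest.fixture()
def one_island():
    return pd.DataFrame({"chromosome": ["chr1"], "start": [1000], "end": [2000]})


@pytest.mark.parametrize(
    "pos,label,dist",
    [
        (1500, "Island", 0),
        (1000, "Island", 0),
        (1999, "Island", 0),
        (2500, "S_Shore", 500),
        (999, "N_Shore", 1),
        (4500, "S_Shelf", 2500),
        (7000, "OpenSea", 5000),
        (-3500, "OpenSea", 4500),
    ],
)
def test_cgi_classification_examples(one_island, pos, label, dist):
    got_label, got_dist = classify_cgi_context(pos, "chr1", one_island)
    assert got_label == label
    assert got_dist == dist


def test_cgi_missing_chromosome_is_open_sea(one_island):
    label, _ = classify_cgi_context(100, "chr9", one_island)
    assert label == "OpenSea"


def test_cgi_labels_partition_and_reflect(one_island):
    # every position gets exactly one label; reflecting coordinates about
    # the island center swaps north and south labels
    start, end = 1000, 2000
    for pos in range(start - 4500, end + 4500, 37):
        label, _ = classify_cgi_context(pos, "chr1", one_island)
        assert label in CGI_LABELS
        mirrored = (start + end - 1) - pos
        m_label, _ = classify_cgi_context(mirrored, "chr1", one_island)
        swap = {"N_Shore": "S_Shore", "S_Shore": "N_Shore",
                "N_Shelf": "S_Shelf", "S_Shelf": "N_Shelf"}
        assert m_label == swap.get(label, label)


def test_cgi_nearest_island_wins():
    islands = pd.DataFrame(
        {"chromosome": ["chr1", "chr1"], "start": [0, 10_000], "end": [500, 10_500]}
    )
    # 9 kb past the first island but only 1 kb before the second
    label, dist = classify_cgi_context(9_000, "chr1", islands)
    assert label == "N_Shore"
    assert dist == 1_000


PLUS_MODEL = {
    "tss": 10_000,
    "strand": "+",
    "gene_start": 10_000,
    "gene_end": 20_000,
    "first_exon": (10_200, 10_800),
    "utr5": (10_000, 10_200),
    "utr3": (19_500, 20_000),
}


@pytest.mark.parametrize(
    "pos,label",
    [
        (9_900, "TSS200"),
        (9_000, "TSS1500"),
        (10_100, "5UTR"),
        (10_500, "FirstExon"),
        (19_700, "3UTR"),
        (15_000, "Body"),
        (8_000, "Intergenic"),
        (25_000, "Intergenic"),
    ],
)
def test_gene_context_examples(pos, label):
    assert classify_gene_context(pos, PLUS_MODEL) == label


def test_gene_context_5utr_precedes_first_exon():
    model = dict(PLUS_MODEL, utr5=(10_000, 10_500), first_exon=(10_000, 10_800))
    assert classify_gene_context(10_300, model) == "5UTR"


def test_gene_context_minus_strand_upstream():
    model = {
        "tss": 20_000,
        "strand": "-",
        "gene_start": 10_000,
        "gene_end": 20_000,
        "first_exon": (19_200, 19_900),
    }
    assert classify_gene_context(20_100, model) == "TSS200"
    assert classify_gene_context(21_000, model) == "TSS1500"
    assert classify_gene_context(15_000, model) == "Body"


def test_gene_context_malformed_model_rejected():
    with pytest.raises(ValueError):
        classify_gene_context(100, {"tss": 5})
    with pytest.raises(ValueError):
        classify_gene_context(100, dict(PLUS_MODEL, strand="x"))


def _probe_frame(cgi_labels):
    return pd.DataFrame(
        {
            "cgi_context": cgi_labels,
            "gene_context": "Body",
            "chromosome": "chr1",
        },
        index=[f"cg{i}" for i in range(len(cgi_labels))],
    )


def test_region_distribution_degenerate_partition():
    tbl = region_distribution(_probe_frame(["Island"] * 7), "cgi")
    row = tbl[tbl["region"] == "Island"].iloc[0]
    assert row["count"] == 7 and row["pct"] == 100
    assert tbl["pct"].sum() == 100


def test_region_distribution_island_share():
    # 60 of 100 hyper probes on islands -> Island 60%
    labels = ["Island"] * 60 + ["OpenSea"] * 40
    probes = _probe_frame(labels)
    direction = pd.Series(["hyper"] * 100, index=probes.index)
    tbl = region_distribution(probes, "cgi", direction=direction)
    hyper = tbl[tbl["subset"] == "hyper"]
    assert hyper.loc[hyper["region"] == "Island", "pct"].iloc[0] == 60
    assert hyper["pct"].sum() == 100


def test_region_distribution_rounding():
    labels = ["Island"] * 29 + ["OpenSea"] * 71
    tbl = region_distribution(_probe_frame(labels), "cgi")
    assert tbl.loc[tbl["region"] == "Island", "pct"].iloc[0] == 29
    assert tbl.loc[tbl["region"] == "OpenSea", "pct"].iloc[0] == 71


def test_region_distribution_empty():
    tbl = region_distribution(_probe_frame([]).iloc[0:0], "cgi")
    assert tbl.empty


def _region_beta(values, n_t, n_n):
    cols = [f"T{i}" for i in range(n_t)] + [f"N{i}" for i in range(n_n)]
    frame = pd.DataFrame(values, columns=cols)
    frame.index = [f"cg{i:03d}" for i in range(len(frame))]
    groups = pd.Series(["tumor"] * n_t + ["normal"] * n_n, index=cols)
    pairs = pd.Series(list(range(n_t)) + list(range(n_n)), index=cols).astype(str)
    return BetaMatrix(frame, groups, pairs)


def test_compare_regions_identical_groups():
    vals = np.tile(np.linspace(0.2, 0.8, 10)[:, None], (1, 8))
    beta = _region_beta(vals, 4, 4)
    contexts = pd.Series(["Island"] * 5 + ["OpenSea"] * 5, index=beta.beta.index)
    out = compare_region_methylation(beta, contexts)
    assert (out["p_value"] == 1.0).all()


def test_compare_regions_detects_planted_shift():
    rng = np.random.default_rng(5)
    n = 24
    base = rng.uniform(0.4, 0.6, size=(200, 2 * n))
    shelf_rows = slice(0, 80)
    base[shelf_rows, :n] += 0.2  # tumors hypermethylated on shelf probes
    beta = _region_beta(base, n, n)
    contexts = pd.Series(
        ["S_Shelf"] * 80 + ["Island"] * 120, index=beta.beta.index
    )
    out = compare_region_methylation(beta, contexts).set_index("region")
    assert out.loc["S_Shelf", "q_value"] < 0.05


def test_compare_regions_exact_small_groups():
    # with 2 samples per group the p-value comes from the exact null
    from tests_support_oracles import exact_ranksum_oracle

    rng = np.random.default_rng(2)
    vals = rng.uniform(0.2, 0.8, size=(6, 4))
    beta = _region_beta(vals, 2, 2)
    contexts = pd.Series(["Island"] * 6, index=beta.beta.index)
    out = compare_region_methylation(beta, contexts)
    t_means = beta.beta[["T0", "T1"]].mean(axis=0).to_numpy()
    n_means = beta.beta[["N0", "N1"]].mean(axis=0).to_numpy()
    assert out["p_value"].iloc[0] == pytest.approx(
        exact_ranksum_oracle(t_means, n_means)
    )
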