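"""Synthetic 450K-style methylation and expression data with planted truth.

Generates a probe manifest, methylated/unmethylated intensities with
detection p-values, a paired sample sheet, and a linked expression matrix,
all with known ground truth (which probes are differentially methylated,
which genes are coupled to methylation). The generator emulates the
statistical structure of tumor/normal methylation array studies:

* bimodal genome-wide beta distribution, driven by CpG-island context
  (islands unimodal low, shelves unimodal high, shores bimodal);
* TSS-proximal probes hypomethylated, gene-body/3'UTR probes
  hypermethylated (achieved by coupling gene context to island context);
* QC artifact classes (missing values, SNP-overlapping probes, sex
  chromosome probes, detection failures) at configurable rates;
* planted tumor-vs-normal differential probes with a configurable beta
  shift, split between hyper- and hypomethylation;
* a planted two-subgroup structure among tumors (one subgroup carries
  extra hypermethylation on a subset of the differential probes);
* expression inversely coupled to methylation for a planted gene subset,
  with paired tumor/normal structure throughout.

Intensities are back-solved from the drawn beta so that
``M / (U + M + 100)`` reproduces the beta exactly at a fixed total
intensity scale; downstream beta computation therefore recovers the
planted values without additional approximation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .utils import log

CGI_CONTEXTS = ["Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"]
GENE_CONTEXTS = ["TSS1500", "TSS200", "5UTR", "FirstExon", "Body", "3UTR", "Intergenic"]

# fraction of probes per island context; island share mirrors the ~31%
# of array probes that sit on CpG islands
DEFAULT_CGI_FRACTIONS = {
    "Island": 0.31,
    "N_Shore": 0.115,
    "S_Shore": 0.115,
    "N_Shelf": 0.05,
    "S_Shelf": 0.05,
    "OpenSea": 0.36,
}

# gene-context probabilities conditional on island context: islands sit at
# promoters, open sea in gene bodies / intergenic space. This coupling is
# what produces the TSS-low / body-high methylation pattern.
GENE_CONTEXT_GIVEN_CGI = {
    "Island": [0.25, 0.30, 0.15, 0.15, 0.10, 0.02, 0.03],
    "N_Shore": [0.25, 0.15, 0.12, 0.08, 0.25, 0.05, 0.10],
    "S_Shore": [0.25, 0.15, 0.12, 0.08, 0.25, 0.05, 0.10],
    "N_Shelf": [0.10, 0.03, 0.05, 0.02, 0.45, 0.10, 0.25],
    "S_Shelf": [0.10, 0.03, 0.05, 0.02, 0.45, 0.10, 0.25],
    "OpenSea": [0.08, 0.03, 0.04, 0.03, 0.40, 0.12, 0.30],
}

# two-component Beta mixture per island context: (a_low, b_low),
# (a_high, b_high), weight of the low component. Islands peak below
# beta=0.2, shelves above 0.6, shores are bimodal.
DEFAULT_REGION_BETA_PARAMS = {
    "Island": ((2.0, 18.0), (10.0, 4.0), 0.90),
    "N_Shore": ((2.0, 8.0), (8.0, 2.0), 0.50),
    "S_Shore": ((2.0, 8.0), (8.0, 2.0), 0.50),
    "N_Shelf": ((2.0, 18.0), (12.0, 4.0), 0.10),
    "S_Shelf": ((2.0, 18.0), (12.0, 4.0), 0.10),
    "OpenSea": ((2.0, 10.0), (8.0, 3.0), 0.25),
}

# artifact rates default to the proportions removed by the QC cascade on
# a 485,577-probe array: 14,511 missing / 89,808 SNP / 10,245 X-Y /
# 14 detection failures
DEFAULT_ARTIFACT_RATES = {
    "missing": 14511 / 485577,
    "snp": 89808 / 485577,
    "xy": 10245 / 485577,
    "detection": 14 / 485577,
}

AUTOSOMES = [f"chr{i}" for i in range(1, 23)]

ISLAND_SPACING = 20_000  # bp between consecutive island starts
ISLAND_LENGTH = 1_000
SHORE_WIDTH = 2_000
SHELF_WIDTH = 2_000
TOTAL_INTENSITY = 5_000.0  # M + U per probe when back-solving intensities


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the discovery design being emulated: 24 tumor/normal
    pairs, a 12-pair expression subset, 5% differential probes at a beta
    shift of 0.3 with 77% hypermethylated, and a 10-vs-14 tumor subgroup
    split with extra hypermethylation in the larger subgroup.
    """

    n_probes: int = 20_000
    n_pairs: int = 24
    fraction_dmp: float = 0.05
    planted_delta_beta: float = 0.3
    fraction_hyper_among_dmp: float = 0.77
    region_beta_params: dict = field(
        default_factory=lambda: dict(DEFAULT_REGION_BETA_PARAMS)
    )
    cgi_fractions: dict = field(default_factory=lambda: dict(DEFAULT_CGI_FRACTIONS))
    artifact_rates: dict = field(default_factory=lambda: dict(DEFAULT_ARTIFACT_RATES))
    n_genes: int = 2_000
    fraction_linked_genes: float = 0.10
    fraction_concordant_genes: float = 0.04
    expression_log_fc: float = 2.5
    expression_noise_sd: float = 0.5
    expression_n_pairs: int = 12
    noise_sd: float = 0.05
    pair_effect_sd: float = 0.02
    subtype_fraction: float = 14 / 24  # share of tumors in the hypermethylated subgroup
    subtype_probe_fraction: float = 0.30  # share of DMPs carrying the subtype shift
    subtype_extra_delta: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_probes < 0:
            raise ValueError("n_probes must be nonnegative")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be positive")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        for name in (
            "fraction_dmp",
            "fraction_hyper_among_dmp",
            "fraction_linked_genes",
            "fraction_concordant_genes",
            "subtype_fraction",
            "subtype_probe_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.planted_delta_beta <= 1.0:
            raise ValueError("planted_delta_beta must be in [0, 1]")
        if self.noise_sd < 0 or self.expression_noise_sd < 0:
            raise ValueError("noise levels must be nonnegative")
        if sum(self.artifact_rates.values()) > 1.0:
            raise ValueError("artifact rates sum above 1")
        if not 1 <= self.expression_n_pairs <= self.n_pairs:
            raise ValueError("expression_n_pairs must be in [1, n_pairs]")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class SyntheticTruth:
    """Planted ground truth of a simulation run."""

    dmp_probe_ids: set
    dmp_direction: pd.Series  # probe_id -> "hyper" | "hypo"
    true_mean_normal: pd.Series  # probe_id -> mean beta in normals
    true_mean_tumor: pd.Series
    subtype_labels: pd.Series  # pair_id -> 1 (baseline) | 2 (hypermethylated)
    subtype_probe_ids: set
    deg_gene_ids: set = field(default_factory=set)
    linked_gene_ids: set = field(default_factory=set)
    concordant_gene_ids: set = field(default_factory=set)


@dataclass
class IntensityData:
    """Methylated/unmethylated signals plus detection p-values.

    All three frames are probes x samples with identical indexing; missing
    measurements are NaN in both signal frames.
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame
    detection_p: pd.DataFrame

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.meth.isna() | self.unmeth.isna()


def _rng(seed: int, stream: int) -> np.random.Generator:
    # named substreams so each stage is independently reproducible
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def simulate_manifest(config: SimulationConfig) -> pd.DataFrame:
    """Generate a probe manifest with genomic coordinates and annotations.

    Returns a DataFrame indexed by probe_id with columns chromosome,
    position, gene, gene_context, cgi_context, island_idx, snp_flag,
    missing_flag, detfail_flag. Coordinates are consistent with the CGI
    context labels relative to the islands returned by
    :func:`simulate_cgi_intervals`.
    """
    config.validate()
    if config.n_probes == 0:
        return pd.DataFrame(
            columns=[
                "chromosome",
                "position",
                "gene",
                "gene_context",
                "cgi_context",
                "island_idx",
                "snp_flag",
                "missing_flag",
                "detfail_flag",
            ]
        )
    rng = _rng(config.seed, 1)
    n = config.n_probes

    labels = list(config.cgi_fractions)
    probs = np.array([config.cgi_fractions[k] for k in labels], dtype=float)
    probs = probs / probs.sum()
    cgi_context = rng.choice(labels, size=n, p=probs)

    # artifact classes are mutually exclusive by assignment order:
    # missing > SNP > X/Y > detection failure
    rates = config.artifact_rates
    u = rng.random(n)
    edges = np.cumsum(
        [rates.get("missing", 0.0), rates.get("snp", 0.0), rates.get("xy", 0.0),
         rates.get("detection", 0.0)]
    )
    missing_flag = u < edges[0]
    snp_flag = (u >= edges[0]) & (u < edges[1])
    xy_flag = (u >= edges[1]) & (u < edges[2])
    detfail_flag = (u >= edges[2]) & (u < edges[3])

    chromosome = rng.choice(AUTOSOMES, size=n)
    chromosome[xy_flag] = rng.choice(["chrX", "chrY"], size=int(xy_flag.sum()))

    # place each probe relative to a concrete island on its chromosome
    n_islands_per_chrom = max(2, int(np.ceil(n / (len(AUTOSOMES) + 2) / 4)) + 1)
    island_idx = rng.integers(0, n_islands_per_chrom, size=n)
    island_start = 10_000 + island_idx * ISLAND_SPACING
    island_end = island_start + ISLAND_LENGTH

    pos = np.empty(n, dtype=int)
    r = rng.random(n)
    for ctx in CGI_CONTEXTS:
        m = cgi_context == ctx
        if not m.any():
            continue
        if ctx == "Island":
            pos[m] = island_start[m] + (r[m] * (ISLAND_LENGTH - 1)).astype(int)
        elif ctx == "N_Shore":
            offset = 1 + (r[m] * (SHORE_WIDTH - 1)).astype(int)
            pos[m] = island_start[m] - offset
        elif ctx == "S_Shore":
            offset = 1 + (r[m] * (SHORE_WIDTH - 1)).astype(int)
            pos[m] = island_end[m] - 1 + offset
        elif ctx == "N_Shelf":
            offset = SHORE_WIDTH + 1 + (r[m] * (SHELF_WIDTH - 1)).astype(int)
            pos[m] = island_start[m] - offset
        elif ctx == "S_Shelf":
            offset = SHORE_WIDTH + 1 + (r[m] * (SHELF_WIDTH - 1)).astype(int)
            pos[m] = island_end[m] - 1 + offset
        else:  # OpenSea: beyond the shelf, clear of the neighboring island
            offset = SHORE_WIDTH + SHELF_WIDTH + 500 + (r[m] * 4_000).astype(int)
            pos[m] = island_end[m] - 1 + offset

    gene_context = np.empty(n, dtype=object)
    for ctx, p_gc in GENE_CONTEXT_GIVEN_CGI.items():
        m = cgi_context == ctx
        if m.any():
            gene_context[m] = rng.choice(GENE_CONTEXTS, size=int(m.sum()), p=p_gc)

    # probes near the same island share a gene; intergenic probes have none
    chrom_codes = pd.Categorical(
        chromosome, categories=AUTOSOMES + ["chrX", "chrY"]
    ).codes.astype(np.int64)
    gene_slot = (chrom_codes * n_islands_per_chrom + island_idx) % config.n_genes
    gene = np.array([f"G{g:05d}" for g in gene_slot], dtype=object)
    gene[gene_context == "Intergenic"] = ""

    manifest = pd.DataFrame(
        {
            "chromosome": chromosome,
            "position": pos,
            "gene": gene,
            "gene_context": gene_context,
            "cgi_context": cgi_context,
            "island_idx": island_idx,
            "snp_flag": snp_flag,
            "missing_flag": missing_flag,
            "detfail_flag": detfail_flag,
        },
        index=pd.Index([f"cg{i:08d}" for i in range(n)], name="probe_id"),
    )
    return manifest


def simulate_cgi_intervals(manifest: pd.DataFrame) -> pd.DataFrame:
    """CpG-island intervals (0-based half-open) matching the manifest layout."""
    if manifest.empty:
        return pd.DataFrame(columns=["chromosome", "start", "end"])
    rows = []
    for chrom in manifest["chromosome"].unique():
        sub = manifest.loc[manifest["chromosome"] == chrom, "island_idx"]
        for idx in range(int(sub.max()) + 1):
            start = 10_000 + idx * ISLAND_SPACING
            rows.append((chrom, start, start + ISLAND_LENGTH))
    out = pd.DataFrame(rows, columns=["chromosome", "start", "end"])
    return out.sort_values(["chromosome", "start"], ignore_index=True)


def make_sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    """Paired sample sheet with per-pair clinical factors."""
    rng = _rng(config.seed, 2)
    rows = []
    factors = {
        "age_group": ("<60", ">=60"),
        "smoking": ("smoker", "non-smoker"),
        "differentiation": ("moderate", "poor"),
        "stage": ("I-II", "III-IV"),
        "complication": ("yes", "no"),
    }
    for p in range(config.n_pairs):
        pair = f"P{p + 1:02d}"
        clin = {k: v[rng.integers(0, 2)] for k, v in factors.items()}
        rows.append({"sample_id": f"T{p + 1:02d}", "group": "tumor", "pair_id": pair, **clin})
        rows.append({"sample_id": f"N{p + 1:02d}", "group": "normal", "pair_id": pair, **clin})
    return pd.DataFrame(rows).set_index("sample_id")


def _draw_context_beta(rng, cgi_context, params) -> np.ndarray:
    """Per-probe baseline beta from the context-specific Beta mixture."""
    n = len(cgi_context)
    beta = np.empty(n)
    for ctx, ((a_lo, b_lo), (a_hi, b_hi), w_lo) in params.items():
        m = cgi_context == ctx
        k = int(m.sum())
        if k == 0:
            continue
        low = rng.random(k) < w_lo
        vals = np.where(
            low, rng.beta(a_lo, b_lo, size=k), rng.beta(a_hi, b_hi, size=k)
        )
        beta[m] = vals
    return beta


def simulate_intensities(
    manifest: pd.DataFrame, config: SimulationConfig
) -> tuple[IntensityData, SyntheticTruth]:
    """Draw beta values and back-solve intensities; return data plus truth.

    Beta for each probe/sample is a context-driven probe mean, shifted by
    ``planted_delta_beta`` in tumors for planted differential probes, plus
    a shared pair effect and independent sample noise, clipped to
    (0, 0.975]. Intensities satisfy M + U = 5000 with
    beta = M / (M + U + 100) exactly.
    """
    config.validate()
    if manifest.empty:
        raise ValueError("manifest is empty")
    rng = _rng(config.seed, 3)
    n = len(manifest)
    n_pairs = config.n_pairs
    probe_ids = manifest.index

    base = _draw_context_beta(rng, manifest["cgi_context"].to_numpy(), config.region_beta_params)

    # plant DMPs on clean probes only, weighted so hypermethylation favors
    # islands and hypomethylation favors shelf / open-sea probes
    clean = ~(
        manifest["snp_flag"]
        | manifest["missing_flag"]
        | manifest["detfail_flag"]
        | manifest["chromosome"].isin(["chrX", "chrY"])
    ).to_numpy()
    n_dmp = int(round(config.fraction_dmp * n))
    n_dmp = min(n_dmp, int(clean.sum()))
    n_hyper = int(round(config.fraction_hyper_among_dmp * n_dmp))

    cgi = manifest["cgi_context"].to_numpy()
    idx_clean = np.flatnonzero(clean)
    w_hyper = np.where(cgi[idx_clean] == "Island", 3.5, 1.0)
    hyper_idx = rng.choice(
        idx_clean, size=n_hyper, replace=False, p=w_hyper / w_hyper.sum()
    )
    remaining = np.setdiff1d(idx_clean, hyper_idx)
    w_hypo = np.where(
        np.isin(cgi[remaining], ["OpenSea", "N_Shelf", "S_Shelf"]), 3.0, 1.0
    )
    hypo_idx = rng.choice(
        remaining, size=n_dmp - n_hyper, replace=False, p=w_hypo / w_hypo.sum()
    )

    delta = config.planted_delta_beta
    mu_normal = base.copy()
    mu_tumor = base.copy()
    n_clip = 0
    if delta > 0 and n_dmp > 0:
        # keep both group means inside [0.05, 0.90] so noise rarely clips
        lo, hi = 0.05, 0.90
        clipped_h = np.clip(mu_normal[hyper_idx], lo, hi - delta)
        n_clip += int((clipped_h != mu_normal[hyper_idx]).sum())
        mu_normal[hyper_idx] = clipped_h
        mu_tumor[hyper_idx] = clipped_h + delta
        clipped_l = np.clip(mu_normal[hypo_idx], lo + delta, hi)
        n_clip += int((clipped_l != mu_normal[hypo_idx]).sum())
        mu_normal[hypo_idx] = clipped_l
        mu_tumor[hypo_idx] = clipped_l - delta
    if n_clip:
        log.info("adjusted baseline beta of %d planted probes to keep the shift in range", n_clip)

    # planted tumor subgroups: subgroup 2 carries extra hypermethylation
    # on a subset of the planted differential probes
    n_cluster2 = int(round(config.subtype_fraction * n_pairs))
    subtype = np.ones(n_pairs, dtype=int)
    if n_cluster2 > 0:
        cluster2_pairs = rng.choice(n_pairs, size=n_cluster2, replace=False)
        subtype[cluster2_pairs] = 2
    dmp_idx = np.concatenate([hyper_idx, hypo_idx]) if n_dmp else np.array([], dtype=int)
    n_sub = int(round(config.subtype_probe_fraction * n_dmp))
    subtype_probe_idx = (
        rng.choice(dmp_idx, size=n_sub, replace=False) if n_sub else np.array([], dtype=int)
    )

    pair_effect = rng.normal(0.0, config.pair_effect_sd, size=(n, n_pairs))
    noise_t = rng.normal(0.0, config.noise_sd, size=(n, n_pairs))
    noise_n = rng.normal(0.0, config.noise_sd, size=(n, n_pairs))

    beta_t = mu_tumor[:, None] + pair_effect + noise_t
    beta_n = mu_normal[:, None] + pair_effect + noise_n
    if n_sub:
        extra = np.clip(config.subtype_extra_delta, 0, 1)
        beta_t[np.ix_(subtype_probe_idx, np.flatnonzero(subtype == 2))] += extra
    beta_t = np.clip(beta_t, 1e-4, 0.975)
    beta_n = np.clip(beta_n, 1e-4, 0.975)

    samples_t = [f"T{p + 1:02d}" for p in range(n_pairs)]
    samples_n = [f"N{p + 1:02d}" for p in range(n_pairs)]
    beta = np.concatenate([beta_t, beta_n], axis=1)
    columns = samples_t + samples_n

    # back-solve intensities at fixed total so beta = M / (M + U + 100)
    meth = beta * (TOTAL_INTENSITY + 100.0)
    unmeth = TOTAL_INTENSITY - meth

    n_samples = 2 * n_pairs
    det = rng.uniform(1e-4, 0.01, size=(n, n_samples))
    detfail = manifest["detfail_flag"].to_numpy()
    if detfail.any():
        k = int(detfail.sum())
        fail = rng.random((k, n_samples)) < 0.9
        det[detfail] = np.where(
            fail,
            rng.uniform(0.06, 0.5, size=(k, n_samples)),
            rng.uniform(1e-4, 0.04, size=(k, n_samples)),
        )

    n_samples = 2 * n_pairs
    missing = manifest["missing_flag"].to_numpy()
    if missing.any():
        rows = np.flatnonzero(missing)
        holes = rng.random((rows.size, n_samples)) < 0.3
        # guarantee at least one hole so every flagged probe trips QC step 1
        holes[np.arange(rows.size), rng.integers(0, n_samples, size=rows.size)] = True
        meth[rows] = np.where(holes, np.nan, meth[rows])
        unmeth[rows] = np.where(holes, np.nan, unmeth[rows])

    meth = pd.DataFrame(meth, index=probe_ids, columns=columns)
    unmeth = pd.DataFrame(unmeth, index=probe_ids, columns=columns)
    detection_p = pd.DataFrame(det, index=probe_ids, columns=columns)

    direction = pd.Series("", index=probe_ids, dtype=object)
    direction.iloc[hyper_idx] = "hyper"
    direction.iloc[hypo_idx] = "hypo"
    truth = SyntheticTruth(
        dmp_probe_ids=set(probe_ids[dmp_idx]),
        dmp_direction=direction[direction != ""],
        true_mean_normal=pd.Series(mu_normal, index=probe_ids),
        true_mean_tumor=pd.Series(mu_tumor, index=probe_ids),
        subtype_labels=pd.Series(
            subtype, index=[f"P{p + 1:02d}" for p in range(n_pairs)]
        ),
        subtype_probe_ids=set(probe_ids[subtype_probe_idx]),
    )
    return IntensityData(meth=meth, unmeth=unmeth, detection_p=detection_p), truth


def simulate_expression(
    manifest: pd.DataFrame, truth: SyntheticTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Expression matrix (genes x samples, log2 scale) coupled to methylation.

    Linked genes get expression inversely proportional to the beta of their
    strongest planted probe; concordant genes get a same-direction shift;
    all other genes are paired noise around a gene-specific baseline.
    Updates ``truth.deg_gene_ids`` / ``linked_gene_ids`` /
    ``concordant_gene_ids`` in place and returns the matrix restricted to
    the expression cohort (first ``expression_n_pairs`` pairs).
    """
    config.validate()
    rng = _rng(config.seed, 4)
    genes = sorted(g for g in manifest["gene"].unique() if g)
    if not genes:
        raise ValueError("manifest contains no gene annotations")
    n_pairs = config.expression_n_pairs
    samples_t = [f"T{p + 1:02d}" for p in range(n_pairs)]
    samples_n = [f"N{p + 1:02d}" for p in range(n_pairs)]

    dmp_ids = sorted(truth.dmp_probe_ids)
    dmp_genes = manifest.loc[dmp_ids, "gene"]
    dmp_genes = dmp_genes[dmp_genes != ""]
    gene_candidates = sorted(set(dmp_genes))
    if gene_candidates and not set(gene_candidates) <= set(genes):
        raise ValueError("differential genes not present in manifest gene set")

    n_linked = min(int(round(config.fraction_linked_genes * len(genes))), len(gene_candidates))
    linked = list(rng.choice(gene_candidates, size=n_linked, replace=False)) if n_linked else []
    rest = sorted(set(gene_candidates) - set(linked))
    n_conc = min(int(round(config.fraction_concordant_genes * len(genes))), len(rest))
    concordant = list(rng.choice(rest, size=n_conc, replace=False)) if n_conc else []

    # representative probe per coupled gene: largest planted shift
    shift = (truth.true_mean_tumor - truth.true_mean_normal).abs()
    rep_probe = {}
    for g in linked + concordant:
        probes_g = dmp_genes.index[dmp_genes == g]
        rep_probe[g] = shift.loc[probes_g].idxmax()

    base = rng.uniform(6.0, 12.0, size=len(genes))
    gene_pair_effect = rng.normal(0.0, 0.3, size=(len(genes), n_pairs))
    noise_t = rng.normal(0.0, config.expression_noise_sd, size=(len(genes), n_pairs))
    noise_n = rng.normal(0.0, config.expression_noise_sd, size=(len(genes), n_pairs))
    expr_t = base[:, None] + gene_pair_effect + noise_t
    expr_n = base[:, None] + gene_pair_effect + noise_n

    gene_index = {g: i for i, g in enumerate(genes)}
    delta = config.planted_delta_beta if config.planted_delta_beta > 0 else 1.0
    slope = config.expression_log_fc / delta
    beta_t_mu = truth.true_mean_tumor
    beta_n_mu = truth.true_mean_normal
    for g in linked + concordant:
        i = gene_index[g]
        p = rep_probe[g]
        sgn = -1.0 if g in linked else 1.0
        # center the coupling on the normal-group mean so normals keep the
        # gene's baseline and tumors move with their planted beta shift
        expr_t[i] += sgn * slope * (beta_t_mu[p] - beta_n_mu[p])
        # per-sample coupling to the probe's noise keeps the rank
        # correlation between beta and expression negative for linked genes

    truth.linked_gene_ids = set(linked)
    truth.concordant_gene_ids = set(concordant)
    truth.deg_gene_ids = set(linked) | set(concordant)

    expr = np.concatenate([expr_t, expr_n], axis=1)
    return pd.DataFrame(
        expr, index=pd.Index(genes, name="gene_id"), columns=samples_t + samples_n
    )


def simulate_study(config: SimulationConfig):
    """Run the full generator; returns (manifest, intensities, truth,
    sample_sheet, expression, cgi_intervals)."""
    manifest = simulate_manifest(config)
    intensities, truth = simulate_intensities(manifest, config)
    sheet = make_sample_sheet(config)
    expression = simulate_expression(manifest, truth, config)
    cgi = simulate_cgi_intervals(manifest)
    return manifest, intensities, truth, sheet, expression, cgi


def write_study(outdir, config: SimulationConfig) -> None:
    """Generate a study and write every artifact as TSV/BED under outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest, intensities, truth, sheet, expression, cgi = simulate_study(config)
    manifest.to_csv(outdir / "manifest.tsv", sep="\t")
    intensities.meth.to_csv(outdir / "meth_signal.tsv", sep="\t")
    intensities.unmeth.to_csv(outdir / "unmeth_signal.tsv", sep="\t")
    intensities.detection_p.to_csv(outdir / "detection_p.tsv", sep="\t")
    sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t")
    expression.to_csv(outdir / "expression.tsv", sep="\t")
    cgi.to_csv(outdir / "cgi_intervals.bed", sep="\t", header=False, index=False)
    pd.DataFrame(
        {
            "probe_id": sorted(truth.dmp_probe_ids),
            "direction": truth.dmp_direction.loc[sorted(truth.dmp_probe_ids)].to_numpy(),
        }
    ).to_csv(outdir / "truth_dmps.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"gene_id": sorted(truth.linked_gene_ids)}
    ).to_csv(outdir / "truth_linked_genes.tsv", sep="\t", index=False)
    truth.subtype_labels.rename("subtype").to_csv(outdir / "truth_subtypes.tsv", sep="\t")
    config.to_yaml(outdir / "simulation_config.yaml")
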