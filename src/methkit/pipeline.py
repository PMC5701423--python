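"""End-to-end orchestration: simulate/load, preprocess, call, integrate,
evaluate, subtype; summary bookkeeping with partition-identity checks.

Every count reported as percentages is rounded by largest remainder so a
partition's shares always sum to 100, and the report asserts the
partition identities (hyper + hypo = total DMPs; the four starburst
quadrants sum to the integrated gene count; the two inverse quadrants
sum to the inverse set; the fourfold subset is contained in it). All
randomness descends from one root seed through named substreams, so each
stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import context as ctx
from . import diffmeth, expression_de, integration, preprocess, roc, subtyping
from .synthetic import SimulationConfig, simulate_study
from .utils import log, round_percentages

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Thresholds and run settings for a full pipeline run."""

    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    q_meth: float = 0.05
    delta_beta: float = 0.2
    q_expr: float = 0.05
    fc: float = 2.0
    fourfold: float = 4.0
    detection_alpha: float = 0.05
    detection_fraction: float = 0.75
    shore_width: int = 2000
    shelf_width: int = 2000
    n_boot: int = 1000
    n_markers: int = 6
    k: int = 2
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        for name, lo, hi in (
            ("q_meth", 0, 1),
            ("q_expr", 0, 1),
            ("delta_beta", 0, 1),
            ("detection_alpha", 0, 1),
            ("detection_fraction", 0, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name} out of range: {v}")
        if self.fc <= 1 or self.fourfold <= 1:
            raise ValueError("fold-change thresholds must exceed 1")
        if self.k < 1 or self.n_boot < 1:
            raise ValueError("k and n_boot must be positive")
        self.simulate.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulate", {}))
        cfg = cls(simulate=sim, **raw)
        cfg.validate()
        return cfg


def summarize_counts(
    dmp_counts: tuple[int, int],
    quadrant_counts: dict,
    fourfold_counts: tuple[int, int],
) -> dict:
    """Bookkeeping over stage counts with hard identity checks.

    ``dmp_counts`` = (hyper, hypo); ``quadrant_counts`` maps the four
    starburst quadrants to gene counts; ``fourfold_counts`` =
    (hyper_down, hypo_up) after the fourfold cutoff. Raises on any
    violated partition identity.
    """
    n_hyper, n_hypo = (int(x) for x in dmp_counts)
    total_dmp = n_hyper + n_hypo
    dmp_pct = round_percentages([n_hyper, n_hypo])

    quad = {q: int(quadrant_counts.get(q, 0)) for q in integration.QUADRANTS}
    total_integrated = sum(quad.values())
    quad_pct = round_percentages(list(quad.values()))
    n_inverse = quad["hyper_down"] + quad["hypo_up"]

    ff_hd, ff_hu = (int(x) for x in fourfold_counts)
    if ff_hd > quad["hyper_down"] or ff_hu > quad["hypo_up"]:
        raise ValueError("fourfold subset exceeds its quadrant count")
    if total_integrated and sum(quad_pct) != 100:
        raise ValueError("quadrant percentages do not sum to 100")
    if total_dmp and int(dmp_pct.sum()) != 100:
        raise ValueError("DMP percentages do not sum to 100")

    return {
        "dmp": {
            "total": total_dmp,
            "hyper": n_hyper,
            "hypo": n_hypo,
            "pct_hyper": int(dmp_pct[0]) if total_dmp else 0,
            "pct_hypo": int(dmp_pct[1]) if total_dmp else 0,
        },
        "integration": {
            "total": total_integrated,
            "counts": quad,
            "pct": dict(zip(integration.QUADRANTS, (int(x) for x in quad_pct))),
            "inverse_set": n_inverse,
        },
        "fourfold": {
            "hyper_down": ff_hd,
            "hypo_up": ff_hu,
            "total": ff_hd + ff_hu,
        },
    }


def _select_markers(dmps: pd.DataFrame, manifest: pd.DataFrame, n: int) -> pd.Index:
    """Top DMPs by |delta beta| on distinct genes — the validation-marker
    analog of picking one strong probe per candidate gene."""
    called = dmps[dmps["direction"] != "none"].copy()
    called["gene"] = manifest.loc[called.index, "gene"]
    called = called[called["gene"] != ""]
    called = called.reindex(
        called["delta_beta"].abs().sort_values(ascending=False).index
    )
    picked = called.drop_duplicates("gene").head(n)
    return picked.index


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage on a simulated study and return the run report.

    When ``config.outdir`` is set, all stage outputs are written there as
    TSV plus a YAML report.
    """
    config.validate()
    sim = dataclasses.replace(config.simulate, seed=config.seed)
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    manifest, intensities, truth, sheet, expression, cgi = simulate_study(sim)

    beta = preprocess.compute_beta(intensities, sheet)
    beta_f, filter_report = preprocess.qc_filter(
        beta,
        intensities,
        manifest,
        detection_alpha=config.detection_alpha,
        detection_sample_fraction=config.detection_fraction,
    )

    dmps = diffmeth.call_dmps(beta_f, config.q_meth, config.delta_beta)
    dmg = diffmeth.aggregate_to_genes(dmps, manifest)
    dsum = diffmeth.dmp_summary(dmps)

    contexts = manifest.loc[dmps.index, ["cgi_context", "gene_context", "chromosome"]]
    called_mask = dmps["direction"] != "none"
    dist_tables = {
        part: ctx.region_distribution(
            contexts[called_mask.to_numpy()], part, direction=dmps["direction"]
        )
        for part in ("cgi", "gene", "chromosome")
    }
    region_tests = ctx.compare_region_methylation(beta_f, contexts["cgi_context"])

    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "qc": {
            "initial": filter_report.initial_count,
            "removed": filter_report.removed_counts,
            "retained": filter_report.final_retained,
        },
        "dmp_summary": dsum,
        "n_dm_genes": int(len(dmg)),
    }

    degs = None
    records = pd.DataFrame()
    fourfold = pd.DataFrame()
    if dsum["n_dmp"] == 0:
        log.warning("no DMPs called; downstream integration skipped")
        report["integration_skipped"] = True
        esum = None
    else:
        degs = expression_de.call_degs(expression, sheet, config.q_expr, config.fc)
        esum = expression_de.deg_summary(degs)
        records = integration.starburst_classify(dmg, degs, manifest)
        fourfold = integration.apply_fourfold_cutoff(records, config.fourfold)
        qsum = integration.quadrant_summary(records)
        ff_counts = (
            int((fourfold["quadrant"] == "hyper_down").sum()),
            int((fourfold["quadrant"] == "hypo_up").sum()),
        )
        report["deg_summary"] = esum
        report["counts"] = summarize_counts(
            (dsum["n_hyper"], dsum["n_hypo"]), qsum["quadrant_counts"], ff_counts
        )
        if len(records):
            spearman = integration.correlation_table(records, beta_f.beta, expression)
            report["median_spearman_r"] = (
                float(spearman.median()) if len(spearman) else None
            )

    # biomarker evaluation on the strongest per-gene probes
    markers = _select_markers(dmps, manifest, config.n_markers)
    labels = (beta_f.sample_groups == "tumor").astype(int).to_numpy()
    marker_results = []
    rng = np.random.SeedSequence([config.seed, 7])
    marker_seeds = rng.generate_state(max(len(markers), 1)) % (2**31)
    for i, probe in enumerate(markers):
        orientation = (
            "tumor_high" if dmps.loc[probe, "direction"] == "hyper" else "tumor_low"
        )
        res = roc.evaluate_marker(
            probe,
            beta_f.beta.loc[probe].to_numpy(),
            labels,
            orientation=orientation,
            n_boot=config.n_boot,
            seed=int(marker_seeds[i]),
        )
        marker_results.append(res)
    report["markers"] = [dataclasses.asdict(r) for r in marker_results]

    cluster = None
    if dsum["n_dmp"] >= 2 and len(beta_f.tumor_samples) >= config.k:
        cluster = subtyping.subtype_tumors(
            beta_f, dmps, manifest=manifest, k=config.k, feature_set="all_dmp"
        )
        report["subtyping"] = {
            "cluster_sizes": cluster.sample_labels.value_counts().sort_index().to_dict(),
            "cluster_mean_mvalue": cluster.cluster_mean_mvalue,
        }

    strat = pd.concat(
        [
            subtyping.stratified_correlation(beta_f, sheet, f)
            for f in ("age_group", "smoking", "differentiation", "stage", "complication")
        ],
        ignore_index=True,
    )
    report["stratified_correlation"] = {
        f"{r.factor}:{r.group}": float(r.correlation) for r in strat.itertuples()
    }

    if outdir:
        manifest.to_csv(outdir / "manifest.tsv", sep="\t")
        beta_f.beta.to_csv(outdir / "beta_filtered.tsv", sep="\t")
        filter_report.to_frame().to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
        dmps.to_csv(outdir / "dmp_table.tsv", sep="\t")
        dmg.to_csv(outdir / "dmg_table.tsv", sep="\t")
        for part, tbl in dist_tables.items():
            tbl.to_csv(outdir / f"distribution_{part}.tsv", sep="\t", index=False)
        region_tests.to_csv(outdir / "region_tests.tsv", sep="\t", index=False)
        if degs is not None:
            degs.to_csv(outdir / "deg_table.tsv", sep="\t")
        if len(records):
            records.to_csv(outdir / "integration_table.tsv", sep="\t")
            fourfold.to_csv(outdir / "fourfold_table.tsv", sep="\t")
        pd.DataFrame([dataclasses.asdict(r) for r in marker_results]).to_csv(
            outdir / "marker_roc.tsv", sep="\t", index=False
        )
        if cluster is not None:
            cluster.sample_labels.rename("cluster").to_csv(
                outdir / "cluster_assignments.tsv", sep="\t"
            )
        strat.to_csv(outdir / "stratified_correlation.tsv", sep="\t", index=False)
        with open(outdir / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=str)

    return report
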