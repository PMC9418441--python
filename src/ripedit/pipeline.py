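"""End-to-end orchestration: simulate -> enrich -> call sites -> index ->
differential -> binding overlap, with one config and reproducible seeds.

Every stage persists its tables under the output directory, and the run
finishes with a machine-readable ``summary.json`` (stage counts, region
distribution, the direction x binding 2x2 bins, and the editing indices).
Each stage draws its randomness from a child of the run seed, so reruns of
the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffedit, editcall, ripenrich, synthdata
from .formats import SiteSet, read_pileup

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a full run, serializable to/from YAML.

    Thresholds default to the standard analysis values: confidence >= 0.99,
    coverage >= 20 reads in all replicates, delta >= 5 percentage points in
    the same direction across all replicate pairs, log2 ratio of ratios
    >= 0.5 with BH-adjusted p < 0.05, and FDR <= 0.05 for the secondary
    enrichment method.
    """

    seed: int = 0
    # simulation sizes
    n_genes: int = 30
    length_range: tuple = (1200, 2400)
    snp_density: float = 5e-4
    n_sites: int = 40
    n_diff_sites: int = 12
    base_fraction_dist: tuple = ("uniform", 0.10, 0.60)
    delta_dist: tuple = ("uniform", 0.10, 0.30)
    mean_coverage: float = 100.0
    error_rate: float = 1e-3
    n_replicates: int = 3
    n_enrich_genes: int = 400
    n_bound_genes: int = 40
    bound_ror: float = 4.0
    rip_dispersion: float = 0.05
    # thresholds
    confidence_min: float = 0.99
    coverage_min: int = 20
    delta_min: float = 5.0
    lfc_min: float = 0.5
    padj_max: float = 0.05
    fdr_max: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.confidence_min <= 1:
            raise ValueError("confidence_min must be in (0, 1]")
        if self.coverage_min < 1 or self.delta_min < 0:
            raise ValueError("invalid coverage/delta thresholds")
        if not 0 < self.padj_max <= 1 or not 0 < self.fdr_max <= 1:
            raise ValueError("padj/fdr thresholds must be in (0, 1]")
        self.length_range = tuple(self.length_range)
        self.base_fraction_dist = tuple(self.base_fraction_dist)
        self.delta_dist = tuple(self.delta_dist)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: list(v) if isinstance(v, tuple) else v
                 for k, v in dataclasses.asdict(self).items()},
                fh, sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline; returns the summary dict.

    Stage order: reference + truths, RIP counts + enrichment test + bound
    call, pileups for both conditions, candidate-site discovery on the
    control condition, editing indices over repeat regions, cross-condition
    quantification, differential calling, region annotation, and the
    direction x binding overlap.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    summary: dict = {"seed": config.seed}

    # --- stage 1: reference and truths -----------------------------------
    bundle = synthdata.simulate_reference(
        n_genes=config.n_genes, length_range=config.length_range,
        snp_density=config.snp_density, seed=seeds[0],
    )
    bundle.write(outdir)
    truth = synthdata.simulate_editing_truth(
        bundle, n_sites=config.n_sites,
        base_fraction_dist=config.base_fraction_dist,
        n_diff=config.n_diff_sites, delta_dist=config.delta_dist,
        seed=seeds[1],
    )
    truth.write(outdir / "truth_editing.tsv")
    features = bundle.feature_intervals()
    snp_mask = SiteSet.from_pairs((c, p) for c, p, _, _ in bundle.snp_sites)

    gene_ids = [f"g{i:05d}" for i in range(config.n_enrich_genes)]
    etruth = synthdata.simulate_enrichment_truth(
        gene_ids, n_bound=config.n_bound_genes, bound_ror=config.bound_ror,
        dispersion=config.rip_dispersion, seed=seeds[2],
    )
    etruth.write(outdir / "truth_enrichment.tsv")
    summary["n_truth_sites"] = len(truth.sites)
    summary["n_truth_differential"] = len(truth.differential_sites)
    summary["n_planted_bound"] = config.n_bound_genes

    # --- stage 2: RIP enrichment ------------------------------------------
    cm = synthdata.simulate_rip_counts(
        etruth, n_replicates=config.n_replicates, seed=seeds[3]
    )
    cm.counts.to_csv(outdir / "rip_counts.tsv", sep="\t")
    cm.sheet.to_csv(outdir / "rip_samples.tsv", sep="\t", index=False)
    logger.info("enrichment test on %d genes", cm.counts.shape[0])
    res_lrt = ripenrich.ror_test(cm, method="lrt")
    res_qlf = ripenrich.ror_test(cm, method="qlf")
    pd.concat([res_lrt, res_qlf]).to_csv(outdir / "enrichment.tsv", sep="\t")
    bound_call = ripenrich.call_bound(
        res_lrt, res_qlf, lfc_min=config.lfc_min,
        padj_max=config.padj_max, fdr_max=config.fdr_max,
    )
    bound_call.to_frame().to_csv(outdir / "bound_genes.tsv", sep="\t")
    planted = set(gene_ids[: config.n_bound_genes])
    summary["n_bound_primary"] = len(bound_call.primary)
    summary["n_bound_secondary"] = len(bound_call.secondary)
    summary["n_bound_intersection"] = len(bound_call.intersection)
    summary["n_bound_recovered"] = len(bound_call.intersection & planted)
    summary["n_bound_false"] = len(bound_call.intersection - planted)

    # --- stage 3: pileups --------------------------------------------------
    pileups = {}
    for cond, sub_seed in zip(("A", "B"), (seeds[4], seeds[5])):
        pileups[cond] = synthdata.simulate_pileups(
            bundle, truth, mean_coverage=config.mean_coverage,
            error_rate=config.error_rate,
            n_replicates=config.n_replicates, condition=cond, seed=sub_seed,
        )
        for tab in pileups[cond]:
            tab.write(outdir / f"pileup_{tab.sample}.tsv")

    # --- stage 4: candidate sites on the control condition -----------------
    sites = editcall.call_candidate_sites(
        pileups["A"], snp_mask=snp_mask, features=features,
        confidence_min=config.confidence_min,
        coverage_min=config.coverage_min, error_rate=config.error_rate,
    )
    editcall.sites_to_bed(sites).to_csv(
        outdir / "candidate_sites.bed", sep="\t", header=False, index=False
    )
    truth_keys = truth.keys()
    summary["n_candidate_sites"] = len(sites)
    summary["n_candidate_in_truth"] = sum(1 for s in sites if s.key in truth_keys)

    # --- stage 5: editing index over repeat regions ------------------------
    repeats = bundle.repeat_intervals()
    index_rows = []
    if len(repeats):
        for cond in ("A", "B"):
            results = editcall.editing_index(
                pileups[cond], repeats, mismatch="AtoG",
                region_label="repeat-regions",
            )
            index_rows.extend(results)
        idx_df = editcall.index_frame(index_rows)
        idx_df.to_csv(outdir / "editing_index.tsv", sep="\t", index=False)
        summary["editing_index_pct"] = {
            cond: float(np.mean([
                r.value for r in index_rows
                if r.sample.startswith(cond) and r.value is not None
            ]))
            for cond in ("A", "B")
        }

    # --- stage 6: differential editing and binding overlap ------------------
    matrix = diffedit.quantify_sites(
        sites, pileups["A"], pileups["B"], coverage_min=config.coverage_min
    )
    diff = diffedit.differential_sites(matrix, delta_min=config.delta_min)
    diffedit.annotate_sites(diff, features)
    diffedit.diff_frame(diff).to_csv(
        outdir / "differential_sites.tsv", sep="\t", index=False
    )
    # planted bound genes and editing-host genes come from separate spaces in
    # the simulation; binding status is looked up in the called bound set
    overlap = diffedit.overlap_with_bound(diff, bound_call.intersection)
    summary["n_quantified_sites"] = len(matrix.fractions)
    summary["n_differential_sites"] = len(diff)
    diff_truth = {(s["contig"], s["pos"]) for s in truth.differential_sites}
    summary["n_differential_in_truth"] = sum(
        1 for s in diff if s.key in diff_truth
    )
    summary["region_distribution"] = diffedit.region_distribution(diff)
    summary["overlap_bins"] = overlap.to_dict()
    summary["pairwise_tally"] = diffedit.pairwise_tally(
        matrix, delta_min=config.delta_min
    ).to_dict(orient="list")

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    config.to_yaml(outdir / "run_config.yaml")
    return summary
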