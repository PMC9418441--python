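"""Simulate the synthetic study: reference, planted truths, counts, pileups.

Writes everything under results/data/: FASTA reference, feature/repeat BED,
SNP-mask VCF, truth tables, the IP/input count matrix with its sample sheet,
and per-replicate pileup TSVs for both conditions.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CONFIG, DATA

import numpy as np

from ripedit import synthdata
from ripedit.formats import write_counts, write_sample_sheet


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    cfg = CONFIG
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]

    bundle = synthdata.simulate_reference(
        n_genes=cfg.n_genes, length_range=cfg.length_range,
        snp_density=cfg.snp_density, seed=seeds[0])
    bundle.write(DATA)
    truth = synthdata.simulate_editing_truth(
        bundle, n_sites=cfg.n_sites, base_fraction_dist=cfg.base_fraction_dist,
        n_diff=cfg.n_diff_sites, delta_dist=cfg.delta_dist, seed=seeds[1])
    truth.write(DATA / "truth_editing.tsv")

    gene_ids = [f"g{i:05d}" for i in range(cfg.n_enrich_genes)]
    etruth = synthdata.simulate_enrichment_truth(
        gene_ids, n_bound=cfg.n_bound_genes, bound_ror=cfg.bound_ror,
        dispersion=cfg.rip_dispersion, seed=seeds[2])
    etruth.write(DATA / "truth_enrichment.tsv")
    cm = synthdata.simulate_rip_counts(etruth, n_replicates=cfg.n_replicates,
                                       seed=seeds[3])
    write_counts(DATA / "rip_counts.tsv", cm.counts)
    write_sample_sheet(DATA / "rip_samples.tsv", cm.sheet)

    for cond, seed in zip(("A", "B"), (seeds[4], seeds[5])):
        for tab in synthdata.simulate_pileups(
                bundle, truth, mean_coverage=cfg.mean_coverage,
                error_rate=cfg.error_rate, n_replicates=cfg.n_replicates,
                condition=cond, seed=seed):
            tab.write(DATA / f"pileup_{tab.sample}.tsv")

    total_bp = sum(len(s) for s in bundle.sequences.values())
    print(f"reference: {len(bundle.sequences)} contigs, {total_bp} bp, "
          f"{len(bundle.snp_sites)} het SNPs")
    print(f"planted editing sites: {len(truth.sites)} "
          f"({len(truth.differential_sites)} differential between conditions)")
    print(f"RIP counts: {cm.counts.shape[0]} genes x {cm.counts.shape[1]} samples, "
          f"{cfg.n_bound_genes} genes planted at ratio-of-ratios {cfg.bound_ror}")
    cfg.to_yaml(DATA / "config.yaml")


if __name__ == "__main__":
    main()
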