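"""De novo editing-site discovery on the control-condition replicates.

Applies the three discovery criteria (confidence >= 0.99, informative
coverage >= 20 in every replicate, present in all replicates) and the SNP
mask, then reports sensitivity against the planted truth.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CONFIG, DATA, RESULTS, require

import pandas as pd

from ripedit.editcall import call_candidate_sites, sites_to_bed
from ripedit.formats import read_intervals, read_pileup, read_snp_mask


def main() -> None:
    require(DATA / "pileup_A_rep1.tsv", "01_simulate_dataset.py")
    pileups = [read_pileup(DATA / f"pileup_A_rep{r}.tsv")
               for r in range(1, CONFIG.n_replicates + 1)]
    mask = read_snp_mask(DATA / "reference_snps.vcf")
    features = read_intervals(DATA / "reference_features.bed")

    sites = call_candidate_sites(
        pileups, snp_mask=mask, features=features,
        confidence_min=CONFIG.confidence_min, coverage_min=CONFIG.coverage_min,
        error_rate=CONFIG.error_rate)

    out = RESULTS / "editing"
    out.mkdir(parents=True, exist_ok=True)
    sites_to_bed(sites).to_csv(out / "candidate_sites.bed", sep="\t",
                               header=False, index=False)

    truth = pd.read_csv(DATA / "truth_editing.tsv", sep="\t")
    truth_keys = set(zip(truth["contig"], truth["pos"]))
    called = {s.key for s in sites}
    print(f"{len(sites)} candidate editing sites "
          f"(mask removed {len(mask)} SNP positions from consideration)")
    print(f"sensitivity vs planted truth: "
          f"{len(called & truth_keys)}/{len(truth_keys)}; "
          f"{len(called - truth_keys)} called outside the truth set")
    warn = sum(s.allelic_balance_warning for s in sites)
    if warn:
        print(f"{warn} sites carry an allelic-balance warning (possible "
              "unmasked heterozygous SNPs)")


if __name__ == "__main__":
    main()
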