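"""Call bound transcripts from the simulated IP/input counts.

Fits the ratio-of-ratios NB GLM per gene with both the likelihood-ratio and
quasi-likelihood F tests, intersects the two calls at the standard
thresholds, and reports recovery of the planted bound genes.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CONFIG, DATA, RESULTS, require

import pandas as pd

from ripedit.formats import read_counts, read_sample_sheet
from ripedit.ripenrich import CountMatrix, call_bound, ror_test


def main() -> None:
    cm = CountMatrix(
        counts=read_counts(require(DATA / "rip_counts.tsv", "01_simulate_dataset.py")),
        sheet=read_sample_sheet(DATA / "rip_samples.tsv"),
    )
    res_lrt = ror_test(cm, method="lrt")
    res_qlf = ror_test(cm, method="qlf")
    call = call_bound(res_lrt, res_qlf, lfc_min=CONFIG.lfc_min,
                      padj_max=CONFIG.padj_max, fdr_max=CONFIG.fdr_max)

    out = RESULTS / "enrichment"
    out.mkdir(parents=True, exist_ok=True)
    pd.concat([res_lrt, res_qlf]).to_csv(out / "enrichment_tests.tsv", sep="\t")
    call.to_frame().to_csv(out / "bound_genes.tsv", sep="\t")

    truth = pd.read_csv(DATA / "truth_enrichment.tsv", sep="\t")
    planted = set(truth.loc[truth["fold_A"] > truth["fold_B"], "gene"])
    rec = len(call.intersection & planted)
    print(f"primary method (log2 RoR >= {CONFIG.lfc_min}, padj < "
          f"{CONFIG.padj_max}): {len(call.primary)} genes")
    print(f"secondary method (FDR <= {CONFIG.fdr_max}): {len(call.secondary)} genes")
    print(f"intersection: {len(call.intersection)} bound transcripts; "
          f"{rec}/{len(planted)} planted recovered, "
          f"{len(call.intersection - planted)} false")


if __name__ == "__main__":
    main()
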