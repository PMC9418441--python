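"""Differential editing between conditions at the candidate sites.

Quantifies editing per replicate pair, applies the >=5-point
same-direction-in-all-pairs rule, annotates each call by genomic region,
and reports the per-pair tallies alongside the strict consistent set.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CONFIG, DATA, RESULTS, require

import pandas as pd

from ripedit.diffedit import (
    annotate_sites,
    diff_frame,
    differential_sites,
    pairwise_tally,
    quantify_sites,
    region_distribution,
)
from ripedit.editcall import EditingSite
from ripedit.formats import read_intervals, read_pileup


def main() -> None:
    out = RESULTS / "editing"
    bed = pd.read_csv(
        require(out / "candidate_sites.bed", "03_call_editing_sites.py"),
        sep="\t", header=None,
        names=["contig", "start", "end", "name", "score", "strand"])
    sites = [EditingSite(contig=r.contig, pos=int(r.end), strand=r.strand,
                         ref="A" if r.strand == "+" else "T")
             for r in bed.itertuples(index=False)]
    piles = {
        cond: [read_pileup(DATA / f"pileup_{cond}_rep{r}.tsv")
               for r in range(1, CONFIG.n_replicates + 1)]
        for cond in ("A", "B")
    }
    matrix = quantify_sites(sites, piles["A"], piles["B"],
                            coverage_min=CONFIG.coverage_min)
    calls = differential_sites(matrix, delta_min=CONFIG.delta_min)
    annotate_sites(calls, read_intervals(DATA / "reference_features.bed"))

    diff_frame(calls).to_csv(out / "differential_sites.tsv", sep="\t",
                             index=False)
    tally = pairwise_tally(matrix, delta_min=CONFIG.delta_min)
    tally.to_csv(out / "pairwise_tally.tsv", sep="\t", index=False)

    n_dec = sum(s.direction == "decreased" for s in calls)
    print(f"{len(matrix.fractions)} sites quantified at >= "
          f"{CONFIG.coverage_min} reads in every replicate of both conditions")
    print(f"{len(calls)} consistently differential sites "
          f"({n_dec} decreased, {len(calls) - n_dec} increased in condition B)")
    print("per-replicate-pair tallies (relaxed rule):")
    print(tally.to_string(index=False))
    print("region distribution:", region_distribution(calls))


if __name__ == "__main__":
    main()
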