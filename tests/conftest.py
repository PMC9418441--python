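"""Shared fixtures: small synthetic datasets with known ground truth."""

import numpy as np
import pandas as pd
import pytest

from ripedit import synthdata
from ripedit.formats import BASE_COLUMNS, PileupTable


@pytest.fixture(scope="session")
def small_bundle():
    return synthdata.simulate_reference(
        n_genes=8, length_range=(1000, 1600), snp_density=1e-3, seed=101
    )


@pytest.fixture(scope="session")
def small_truth(small_bundle):
    return synthdata.simulate_editing_truth(
        small_bundle, n_sites=25, n_diff=8, seed=102
    )


@pytest.fixture(scope="session")
def small_pileups(small_bundle, small_truth):
    return {
        cond: synthdata.simulate_pileups(
            small_bundle, small_truth, mean_coverage=60, error_rate=1e-3,
            n_replicates=3, condition=cond, seed=103 + i,
        )
        for i, cond in enumerate(("A", "B"))
    }


def make_pileup(rows, sample="s1"):
    """Build a PileupTable from (contig, pos, ref, {base: (fwd, rev)}) rows."""
    out = []
    for contig, pos, ref, counts in rows:
        rec = {"contig": contig, "pos": pos, "ref": ref,
               **{c: 0 for c in BASE_COLUMNS}}
        for base, (fwd, rev) in counts.items():
            rec[f"{base}_fwd"] = fwd
            rec[f"{base}_rev"] = rev
        out.append(rec)
    df = pd.DataFrame(out, columns=["contig", "pos", "ref", *BASE_COLUMNS])
    return PileupTable(df=df, sample=sample)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
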