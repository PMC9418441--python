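"""Differential editing between two conditions under replicate consistency.

Editing at candidate sites is quantified per replicate in both conditions;
only sites with sufficient coverage in every replicate of both conditions
are analysed.  A site is called differentially edited when every paired
replicate comparison shows at least ``delta_min`` percentage points of
change in the same direction — a deterministic rule, not a per-site test.
Called sites are annotated by genomic region and binned by whether their
host transcript is in the called bound set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .editcall import EditingSite, SiteCounts, editing_fraction
from .formats import IntervalSet, PileupTable, SiteSet

#: genomic-region annotation precedence (first match wins)
REGION_PRECEDENCE = ["CDS", "3'UTR", "5'UTR", "noncoding-exon", "intron"]


@dataclass
class EditingMatrix:
    """Per-site, per-sample editing fractions with coverages.

    ``fractions`` and ``coverages`` are sites x samples frames whose columns
    are ``(condition, replicate)`` pairs; rows are (contig, pos) keys of
    sites that met the coverage requirement in every sample.
    """

    fractions: pd.DataFrame
    coverages: pd.DataFrame
    sites: dict  # key -> EditingSite
    conditions: tuple = ("A", "B")
    coverage_min: int = 20

    @property
    def n_replicates(self) -> int:
        return sum(1 for c, _ in self.fractions.columns if c == self.conditions[0])


@dataclass
class DiffSite:
    """A differential-editing call at one site."""

    contig: str
    pos: int
    strand: str
    deltas: list  # percentage points, one per replicate pair
    direction: str  # "decreased" | "increased"
    n_pairs_consistent: int
    region: str | None = None
    gene: str | None = None

    @property
    def key(self) -> tuple:
        return (self.contig, self.pos)


@dataclass
class OverlapSummary:
    """2x2 binning of differential sites by direction and binding status."""

    bins: dict = field(default_factory=dict)
    n_intergenic_excluded: int = 0
    external_overlap: int | None = None

    def total(self) -> int:
        return sum(self.bins.values())

    def to_dict(self) -> dict:
        out = {f"{d}_{b}": self.bins.get((d, b), 0)
               for d in ("decreased", "increased") for b in ("bound", "unbound")}
        out["intergenic_excluded"] = self.n_intergenic_excluded
        if self.external_overlap is not None:
            out["external_overlap"] = self.external_overlap
        return out


def _site_counts_at(pileup: PileupTable, wanted: dict) -> dict:
    """SiteCounts at the wanted keys, using each site's known strand."""
    df = pileup.df
    idx = pd.MultiIndex.from_frame(df[["contig", "pos"]])
    present = {k: i for i, k in enumerate(idx) if k in wanted}
    out = {}
    for key, i in present.items():
        row = df.iloc[i]
        site = wanted[key]
        ref, alt = ("A", "G") if site.strand == "+" else ("T", "C")
        if row["ref"] != ref:
            continue
        rf, rr = int(row[f"{ref}_fwd"]), int(row[f"{ref}_rev"])
        af, ar = int(row[f"{alt}_fwd"]), int(row[f"{alt}_rev"])
        total = int(sum(row[c] for c in
                        ("A_fwd", "A_rev", "C_fwd", "C_rev",
                         "G_fwd", "G_rev", "T_fwd", "T_rev")))
        out[key] = SiteCounts(
            contig=key[0], pos=key[1], strand=site.strand, ref=ref,
            ref_fwd=rf, ref_rev=rr, alt_fwd=af, alt_rev=ar,
            other=total - (rf + rr + af + ar),
        )
    return out


def quantify_sites(
    sites: Sequence[EditingSite],
    pileups_a: Sequence[PileupTable],
    pileups_b: Sequence[PileupTable],
    coverage_min: int = 20,
    conditions: tuple = ("A", "B"),
) -> EditingMatrix:
    """Quantify editing at candidate sites in both conditions.

    Retains only sites with informative (ref+alt) coverage of at least
    ``coverage_min`` reads in all replicates of both conditions; replicates
    are paired by index between conditions.
    """
    if len(pileups_a) != len(pileups_b):
        raise ValueError(
            "conditions have unequal replicate numbers; pairing requires equality"
        )
    wanted = {s.key: s for s in sites}
    per_sample = []
    columns = []
    for cond, pileups in zip(conditions, (pileups_a, pileups_b)):
        for r, p in enumerate(pileups, start=1):
            per_sample.append(_site_counts_at(p, wanted))
            columns.append((cond, r))

    keys = sorted(k for k in wanted
                  if all(k in d and d[k].informative >= coverage_min
                         for d in per_sample))
    frac = pd.DataFrame(
        [[editing_fraction(d[k]) for d in per_sample] for k in keys],
        index=pd.Index(keys), columns=pd.MultiIndex.from_tuples(columns),
        dtype=float,
    )
    cov = pd.DataFrame(
        [[d[k].informative for d in per_sample] for k in keys],
        index=pd.Index(keys), columns=pd.MultiIndex.from_tuples(columns),
        dtype=int,
    )
    return EditingMatrix(
        fractions=frac, coverages=cov, sites={k: wanted[k] for k in keys},
        conditions=conditions, coverage_min=coverage_min,
    )


def differential_sites(
    matrix: EditingMatrix,
    delta_min: float = 5.0,
    rule: str = "all-pairs",
) -> list[DiffSite]:
    """Call differential sites under the replicate-consistency rule.

    For each site, delta_r = 100 x (fraction in condition B replicate r −
    fraction in condition A replicate r).  Under the default ``all-pairs``
    rule a site is called iff every |delta_r| >= ``delta_min`` and all
    deltas share a sign.  The ``mean`` rule instead compares condition
    means (unpaired); it is provided for sensitivity analysis and is not
    the default.  ``n_pairs_consistent`` reports, for every site, how many
    replicate pairs individually satisfy the threshold with the majority
    sign (the relaxed k-of-n tally).
    """
    if rule not in ("all-pairs", "mean"):
        raise ValueError(f"unknown rule {rule!r}")
    cond_a, cond_b = matrix.conditions
    fa = matrix.fractions[cond_a].to_numpy()
    fb = matrix.fractions[cond_b].to_numpy()
    deltas = 100.0 * (fb - fa)  # percentage points, paired by column order
    # inclusive threshold, robust to float representation at the boundary
    eps = 1e-9

    out: list[DiffSite] = []
    for i, key in enumerate(matrix.fractions.index):
        d = deltas[i]
        n_up = int(np.sum(d >= delta_min - eps))
        n_down = int(np.sum(d <= -(delta_min - eps)))
        n_consistent = max(n_up, n_down)
        if rule == "all-pairs":
            called = (n_up == len(d)) or (n_down == len(d))
            direction = "increased" if n_up == len(d) else "decreased"
        else:
            mean_delta = float(np.mean(d))
            called = abs(mean_delta) >= delta_min
            direction = "increased" if mean_delta > 0 else "decreased"
        if not called:
            continue
        site = matrix.sites[key]
        out.append(
            DiffSite(
                contig=key[0], pos=key[1], strand=site.strand,
                deltas=[float(x) for x in d], direction=direction,
                n_pairs_consistent=n_consistent,
                region=site.region, gene=site.gene,
            )
        )
    return out


def pairwise_tally(matrix: EditingMatrix, delta_min: float = 5.0) -> pd.DataFrame:
    """Per-replicate-pair counts of sites over threshold, by direction.

    Mirrors a per-replicate Venn-style analysis: each pair's tally is kept
    separate, and a site changing in opposite directions in different pairs
    contributes to each pair on its own terms.
    """
    cond_a, cond_b = matrix.conditions
    deltas = 100.0 * (matrix.fractions[cond_b].to_numpy()
                      - matrix.fractions[cond_a].to_numpy())
    eps = 1e-9
    rows = []
    for r in range(deltas.shape[1]):
        d = deltas[:, r]
        rows.append((r + 1, int(np.sum(d <= -(delta_min - eps))),
                     int(np.sum(d >= delta_min - eps))))
    return pd.DataFrame(rows, columns=["replicate_pair", "decreased", "increased"])


def annotate_region(
    contig: str, pos: int, features: IntervalSet
) -> tuple[str, str | None]:
    """Region label and host gene for a 1-based position.

    Feature labels follow the ``gene|class`` convention; overlap precedence
    is CDS > 3'UTR > 5'UTR > noncoding-exon > intron, and positions outside
    all transcript features are intergenic (no host gene).
    """
    hits = features.overlapping(contig, pos - 1)
    best_rank = len(REGION_PRECEDENCE)
    best: tuple[str, str | None] | None = None
    for _strand, label in hits:
        gene, _, cls = label.rpartition("|")
        if cls in REGION_PRECEDENCE:
            rank = REGION_PRECEDENCE.index(cls)
            if rank < best_rank:
                best_rank = rank
                best = (cls, gene or None)
    if best is None:
        return "intergenic", None
    return best


def annotate_sites(sites: Iterable, features: IntervalSet) -> None:
    """Attach region/gene annotation to DiffSite or EditingSite objects."""
    for s in sites:
        region, gene = annotate_region(s.contig, s.pos, features)
        s.region = region
        s.gene = gene


def region_distribution(diff_sites: Sequence[DiffSite]) -> dict:
    dist: dict = {}
    for s in diff_sites:
        dist[s.region or "unannotated"] = dist.get(s.region or "unannotated", 0) + 1
    return dist


def overlap_with_bound(
    diff_sites: Sequence[DiffSite],
    bound: set,
    external_sites: SiteSet | None = None,
) -> OverlapSummary:
    """Bin differential sites by direction x binding status of host gene.

    Intergenic sites are excluded before binning.  When ``external_sites``
    is given (an externally curated editing-site list), the summary also
    reports how many differential sites appear in it.
    """
    bins: dict = {}
    n_intergenic = 0
    for s in diff_sites:
        if s.region is None:
            raise ValueError(f"site {s.key} is unannotated; run annotate_sites first")
        if s.region == "intergenic":
            n_intergenic += 1
            continue
        status = "bound" if s.gene in bound else "unbound"
        bins[(s.direction, status)] = bins.get((s.direction, status), 0) + 1
    ext = None
    if external_sites is not None:
        ext = sum(1 for s in diff_sites if s.key in external_sites)
    return OverlapSummary(
        bins=bins, n_intergenic_excluded=n_intergenic, external_overlap=ext
    )


def diff_frame(diff_sites: Sequence[DiffSite]) -> pd.DataFrame:
    rows = [
        (s.contig, s.pos, s.strand, s.direction,
         ";".join(f"{d:.2f}" for d in s.deltas),
         s.n_pairs_consistent, s.region, s.gene)
        for s in diff_sites
    ]
    return pd.DataFrame(
        rows,
        columns=["contig", "pos", "strand", "direction", "deltas_pct",
                 "n_pairs_consistent", "region", "gene"],
    )
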