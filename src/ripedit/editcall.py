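"""De novo A-to-I editing-site discovery and coverage-weighted editing indices.

Inosine is read as guanosine by sequencers, so editing appears as A→G
mismatches on the annotation (sense) strand, or T→C on the reference strand
for genes transcribed from the minus strand.  Discovery applies three
criteria per site — confidence at least ``confidence_min``, informative
coverage at least ``coverage_min`` reads, and identification in every
biological replicate — followed by removal of known SNP positions.

The confidence score is the posterior probability, under a binomial
likelihood with a Jeffreys Beta(1/2, 1/2) prior, that the true editing
fraction exceeds the sequencing error rate.  This is a transparent,
monotone surrogate for dedicated editing-caller scores (it is not a
reimplementation of any particular caller's generative model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .formats import BASE_COLUMNS, COMPLEMENT, IntervalSet, PileupTable, SiteSet


@dataclass
class SiteCounts:
    """DP4-style read support at one position for one sample.

    ``ref``/``alt`` counts are oriented so that the event is A→G on the
    recorded strand: on ``+`` the reference base is A and alt is G; on ``-``
    the reference base is T and alt is C (the antisense image of A→G).
    ``other`` counts reads supporting neither ref nor alt.
    """

    contig: str
    pos: int  # 1-based
    strand: str
    ref: str
    ref_fwd: int
    ref_rev: int
    alt_fwd: int
    alt_rev: int
    other: int = 0

    @property
    def ref_count(self) -> int:
        return self.ref_fwd + self.ref_rev

    @property
    def alt_count(self) -> int:
        return self.alt_fwd + self.alt_rev

    @property
    def informative(self) -> int:
        """Reads supporting ref or alt — the DP4 total."""
        return self.ref_count + self.alt_count

    @property
    def coverage(self) -> int:
        return self.informative + self.other

    @property
    def key(self) -> tuple:
        return (self.contig, self.pos)


@dataclass
class EditingSite:
    """A called editing site with per-replicate quantification."""

    contig: str
    pos: int
    strand: str
    ref: str
    fractions: list = field(default_factory=list)
    coverages: list = field(default_factory=list)
    confidence: float = 0.0
    allelic_balance_warning: bool = False
    region: str | None = None
    gene: str | None = None

    @property
    def key(self) -> tuple:
        return (self.contig, self.pos)

    @property
    def mean_fraction(self) -> float:
        vals = [f for f in self.fractions if f is not None]
        return float(np.mean(vals)) if vals else float("nan")


def _counts_for_strand(row, strand: str) -> SiteCounts | None:
    """Tally one pileup row under the given A→G strand convention."""
    ref = row.ref
    if strand == "+":
        if ref != "A":
            return None
        alt = "G"
    else:
        if ref != "T":
            return None
        alt = "C"
    rf, rr = getattr(row, f"{ref}_fwd"), getattr(row, f"{ref}_rev")
    af, ar = getattr(row, f"{alt}_fwd"), getattr(row, f"{alt}_rev")
    total = sum(getattr(row, c) for c in BASE_COLUMNS)
    return SiteCounts(
        contig=row.contig, pos=row.pos, strand=strand, ref=ref,
        ref_fwd=rf, ref_rev=rr, alt_fwd=af, alt_rev=ar,
        other=total - (rf + rr + af + ar),
    )


def site_counts(pileup: PileupTable, features: IntervalSet | None = None) -> list[SiteCounts]:
    """Extract A→G-informative positions from a pileup, strand-aware.

    Positions inside annotated features use the feature strand; positions
    outside any feature (or under conflicting strands) are evaluated under
    both conventions and reported on the one with the higher alt fraction.
    Positions whose reference base fits neither convention are dropped.
    """
    out: list[SiteCounts] = []
    for row in pileup.df.itertuples(index=False):
        strands = set()
        if features is not None:
            strands = {s for s, _ in features.overlapping(row.contig, row.pos - 1)}
            strands.discard(".")
        if strands == {"+"}:
            sc = _counts_for_strand(row, "+")
            if sc:
                out.append(sc)
        elif strands == {"-"}:
            sc = _counts_for_strand(row, "-")
            if sc:
                out.append(sc)
        else:
            plus = _counts_for_strand(row, "+")
            minus = _counts_for_strand(row, "-")
            cands = [sc for sc in (plus, minus) if sc is not None]
            if cands:
                out.append(max(cands, key=lambda sc: (editing_fraction(sc) or 0.0)))
    return out


def editing_fraction(site: SiteCounts) -> float | None:
    """Editing fraction alt/(ref+alt); None when no informative reads."""
    n = site.informative
    if n == 0:
        return None
    return site.alt_count / n


def site_confidence(site: SiteCounts, error_rate: float = 1e-3) -> float:
    """Posterior P(true fraction > error_rate) with a Jeffreys prior.

    Binomial(alt | ref+alt, p) likelihood, Beta(1/2, 1/2) prior: posterior
    is Beta(alt + 1/2, ref + 1/2) and the confidence is its upper tail above
    ``error_rate``.  Monotone in alt at fixed coverage and in coverage at
    fixed fraction above the error rate.
    """
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    if site.coverage <= 0:
        raise ValueError("site has zero coverage")
    return float(beta_dist.sf(error_rate, site.alt_count + 0.5, site.ref_count + 0.5))


def call_candidate_sites(
    samples: Sequence[PileupTable],
    snp_mask: SiteSet | None = None,
    features: IntervalSet | None = None,
    confidence_min: float = 0.99,
    coverage_min: int = 20,
    error_rate: float = 1e-3,
    min_alt: int = 2,
    max_other_fraction: float = 0.01,
) -> list[EditingSite]:
    """Call candidate editing sites across biological replicates.

    A site is called when, in every replicate, informative (ref+alt)
    coverage is at least ``coverage_min``, the confidence is at least
    ``confidence_min``, at least ``min_alt`` alt reads support it, and
    non-ref/non-alt reads make up at most ``max_other_fraction`` of
    coverage; the position must not be in ``snp_mask``.  Sites with near
    0.5 alt fraction at high coverage in every replicate carry an
    allelic-balance warning (possible unmasked heterozygous SNP).
    """
    if not samples:
        return []
    per_rep: list[dict] = []
    for pileup in samples:
        per_rep.append({sc.key: sc for sc in site_counts(pileup, features)})

    common = set(per_rep[0])
    for d in per_rep[1:]:
        common &= set(d)

    sites: list[EditingSite] = []
    for key in sorted(common):
        if snp_mask is not None and key in snp_mask:
            continue
        scs = [d[key] for d in per_rep]
        ok = True
        confidences = []
        for sc in scs:
            if sc.informative < coverage_min or sc.alt_count < min_alt:
                ok = False
                break
            # artifact guard: needs >1 supporting read, so one stray
            # sequencing error cannot veto a site on its own
            if sc.other > 1 and sc.other / sc.coverage > max_other_fraction:
                ok = False
                break
            conf = site_confidence(sc, error_rate)
            confidences.append(conf)
            if conf < confidence_min:
                ok = False
                break
        if not ok:
            continue
        fractions = [editing_fraction(sc) for sc in scs]
        warn = all(
            f is not None and 0.4 <= f <= 0.6 and sc.informative >= 50
            for f, sc in zip(fractions, scs)
        )
        first = scs[0]
        sites.append(
            EditingSite(
                contig=first.contig, pos=first.pos, strand=first.strand,
                ref=first.ref, fractions=fractions,
                coverages=[sc.informative for sc in scs],
                confidence=min(confidences),
                allelic_balance_warning=warn,
            )
        )
    return sites


def sites_to_bed(sites: Iterable[EditingSite]) -> pd.DataFrame:
    """BED-style frame (0-based) with score = mean fraction x 1000."""
    rows = [
        (s.contig, s.pos - 1, s.pos, f"{s.contig}:{s.pos}",
         int(round(1000 * s.mean_fraction)), s.strand)
        for s in sites
    ]
    return pd.DataFrame(
        rows, columns=["contig", "start", "end", "name", "score", "strand"]
    )


# ---------------------------------------------------------------------------
# Editing index


@dataclass
class IndexResult:
    """Coverage-weighted mismatch index over a region set.

    ``value`` = 100 x (mismatch reads at reference-base positions) /
    (total reads at those positions); None when the denominator is zero.
    """

    sample: str
    mismatch: str  # e.g. "AtoG"
    region_label: str
    numerator: int
    denominator: int

    @property
    def value(self) -> float | None:
        if self.denominator == 0:
            return None
        return 100.0 * self.numerator / self.denominator


_ALL_MISMATCHES = [
    f"{x}to{y}" for x in "ACGT" for y in "ACGT" if x != y
]


def editing_index(
    pileups: Sequence[PileupTable],
    regions: IntervalSet,
    mismatch: str = "all",
    region_label: str = "regions",
) -> list[IndexResult]:
    """Coverage-weighted average mismatch rate within a region set.

    For mismatch X→Y the numerator sums Y-base reads over all positions in
    ``regions`` whose reference base is X, and the denominator sums total
    reads at those positions — i.e. a per-site mismatch rate weighted by the
    site's coverage.  Within minus-strand regions base identities are
    complemented, so A→G pools antisense T→C.  Positions covered by several
    intervals count once per interval hit only if the intervals overlap;
    region sets are expected to be disjoint (as Alu annotations are).
    """
    if len(regions) == 0:
        raise ValueError("regions must be nonempty")
    mismatches = _ALL_MISMATCHES if mismatch == "all" else [mismatch]
    for mm in mismatches:
        if mm not in _ALL_MISMATCHES:
            raise ValueError(f"unknown mismatch type {mm!r}")

    results = []
    for pileup in pileups:
        num = {mm: 0 for mm in mismatches}
        den = {mm: 0 for mm in mismatches}
        df = pileup.df
        counted: set = set()
        for contig, start, end, strand, _label in regions:
            sub = df[(df["contig"] == contig) & (df["pos"] > start) & (df["pos"] <= end)]
            for row in sub.itertuples(index=False):
                rkey = (contig, row.pos)
                if rkey in counted:
                    continue
                counted.add(rkey)
                # orient to the region's sense strand
                ref = row.ref if strand != "-" else COMPLEMENT[row.ref]
                base_tot = {}
                for b in "ACGT":
                    sense_b = b if strand != "-" else COMPLEMENT[b]
                    base_tot[sense_b] = getattr(row, f"{b}_fwd") + getattr(row, f"{b}_rev")
                total = sum(base_tot.values())
                for mm in mismatches:
                    x, y = mm.split("to")
                    if ref == x:
                        num[mm] += base_tot[y]
                        den[mm] += total
        for mm in mismatches:
            results.append(
                IndexResult(
                    sample=pileup.sample, mismatch=mm,
                    region_label=region_label,
                    numerator=num[mm], denominator=den[mm],
                )
            )
    return results


def index_frame(results: Iterable[IndexResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.sample, r.mismatch, r.region_label, r.numerator, r.denominator,
             r.value)
            for r in results
        ],
        columns=["sample", "mismatch", "region_label", "numerator",
                 "denominator", "index_pct"],
    )
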