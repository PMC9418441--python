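"""Synthetic data with known ground truth for the RIP-seq / editing pipeline.

Emulates the statistical structure of a paired IP/input RIP-seq experiment
with two cell conditions and of RNA-seq read pileups carrying A-to-I editing
signal: negative-binomial gene counts with planted IP-enrichment interaction
folds, per-position base counts with planted editing fractions, uniform
sequencing error, heterozygous SNPs, and a configurable number of biological
replicates (three by default, matching a typical design).

Every generator takes an integer seed and is deterministic for a fixed seed.
Coverage is Poisson around the mean per position; sequencing error is a
symmetric substitution at ``error_rate/3`` per non-reference base; SNPs are
heterozygous (allele fraction 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import (
    BASE_COLUMNS,
    COMPLEMENT,
    IntervalSet,
    PileupTable,
    write_fasta,
    write_snp_vcf,
)

BASES = np.array(["A", "C", "G", "T"])
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: conditions of the two-cell-line comparison; A is the control line,
#: B the effector-expressing line
CONDITIONS = ("A", "B")


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Reference


@dataclass
class ReferenceBundle:
    """Synthetic genome: contig sequences, gene features, and SNP sites.

    ``features``: (contig, start, end, strand, gene_id, feature_class) with
    0-based half-open coordinates; classes are 5'UTR / CDS / 3'UTR / intron /
    repeat-region.  ``snp_sites``: (contig, 1-based pos, ref, alt),
    heterozygous by construction; never inside repeat regions.
    """

    sequences: dict[str, str]
    features: list = field(default_factory=list)
    snp_sites: list = field(default_factory=list)

    def feature_intervals(self) -> IntervalSet:
        """Features as an IntervalSet with ``gene|class`` labels."""
        return IntervalSet(
            [
                (contig, start, end, strand, f"{gene}|{cls}")
                for contig, start, end, strand, gene, cls in self.features
            ]
        )

    def repeat_intervals(self) -> IntervalSet:
        """Repeat-region (Alu stand-in) intervals only."""
        ivs = [
            (contig, start, end, strand, f"{gene}|{cls}")
            for contig, start, end, strand, gene, cls in self.features
            if cls == "repeat-region"
        ]
        return IntervalSet(ivs)

    def gene_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, _, _, _, gene, _ in self.features:
            seen.setdefault(gene, None)
        return list(seen)

    def snp_keys(self) -> set:
        return {(c, p) for c, p, _, _ in self.snp_sites}

    def write(self, outdir: str | Path, prefix: str = "reference") -> None:
        outdir = Path(outdir)
        write_fasta(outdir / f"{prefix}.fa", self.sequences)
        self.feature_intervals().write_bed(outdir / f"{prefix}_features.bed")
        self.repeat_intervals().write_bed(outdir / f"{prefix}_repeats.bed")
        write_snp_vcf(
            outdir / f"{prefix}_snps.vcf", self.snp_sites,
            contig_lengths={c: len(s) for c, s in self.sequences.items()},
        )


def simulate_reference(
    n_genes: int,
    length_range: tuple[int, int] = (1200, 2400),
    snp_density: float = 5e-4,
    intron_prob: float = 0.5,
    repeat_prob: float = 0.6,
    seed: int = 0,
) -> ReferenceBundle:
    """Simulate a gene-per-contig reference with annotated features and SNPs.

    Each gene occupies its own contig and carries a 5'UTR, a CDS (optionally
    split by one intron), and a 3'UTR; with probability ``repeat_prob`` an
    inverted-repeat stand-in (class ``repeat-region``) is embedded in the
    3'UTR.  Heterozygous SNPs are scattered at ``snp_density`` per base,
    excluding repeat regions.
    """
    if n_genes < 1:
        raise SimulationError("n_genes must be >= 1")
    lo, hi = length_range
    if lo <= 0 or hi < lo:
        raise SimulationError("length_range must be positive and ordered")
    if not 0 <= snp_density < 1:
        raise SimulationError("snp_density must be in [0, 1)")
    rng = np.random.default_rng(seed)

    sequences: dict[str, str] = {}
    features: list = []
    snp_sites: list = []
    for g in range(n_genes):
        gene = f"gene{g:04d}"
        contig = f"chr_{gene}"
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(BASES, size=length, p=[0.3, 0.2, 0.2, 0.3])
        strand = "+" if rng.random() < 0.5 else "-"

        # partition: 5'UTR ~10%, CDS ~65%, 3'UTR ~25% of the contig
        utr5_end = max(1, int(length * 0.10))
        cds_end = max(utr5_end + 1, int(length * 0.75))
        features.append((contig, 0, utr5_end, strand, gene, "5'UTR"))
        if rng.random() < intron_prob and cds_end - utr5_end > 200:
            mid = (utr5_end + cds_end) // 2
            ilen = int(rng.integers(50, 150))
            features.append((contig, utr5_end, mid, strand, gene, "CDS"))
            features.append((contig, mid, mid + ilen, strand, gene, "intron"))
            features.append((contig, mid + ilen, cds_end, strand, gene, "CDS"))
        else:
            features.append((contig, utr5_end, cds_end, strand, gene, "CDS"))
        features.append((contig, cds_end, length, strand, gene, "3'UTR"))

        repeat_mask = np.zeros(length, dtype=bool)
        if rng.random() < repeat_prob and length - cds_end > 120:
            rstart = cds_end + int(rng.integers(0, (length - cds_end) // 3 + 1))
            rend = min(length, rstart + int(rng.integers(80, 300)))
            features.append((contig, rstart, rend, strand, gene, "repeat-region"))
            repeat_mask[rstart:rend] = True
            # bias repeat body toward A/T on the sense strand, Alu-like target
            body = rng.choice(BASES, size=rend - rstart, p=[0.4, 0.1, 0.1, 0.4])
            seq[rstart:rend] = body

        if snp_density > 0:
            is_snp = rng.random(length) < snp_density
            is_snp &= ~repeat_mask
            for pos0 in np.flatnonzero(is_snp):
                ref = seq[pos0]
                alt = rng.choice([b for b in BASES if b != ref])
                snp_sites.append((contig, int(pos0) + 1, str(ref), str(alt)))

        sequences[contig] = "".join(seq)

    return ReferenceBundle(sequences=sequences, features=features, snp_sites=snp_sites)


# ---------------------------------------------------------------------------
# Editing truth


@dataclass
class EditingTruth:
    """Planted editing sites with per-condition true fractions.

    ``sites``: list of dicts with contig, pos (1-based), strand, ref,
    fractions: {condition: fraction}, delta (fraction_B - fraction_A).
    ``differential_sites`` is the subset with nonzero planted delta.
    """

    sites: list = field(default_factory=list)
    conditions: tuple = CONDITIONS

    @property
    def differential_sites(self) -> list:
        return [s for s in self.sites if s["delta"] != 0.0]

    def keys(self) -> set:
        return {(s["contig"], s["pos"]) for s in self.sites}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "contig": s["contig"],
                "pos": s["pos"],
                "strand": s["strand"],
                "ref": s["ref"],
                **{f"fraction_{c}": s["fractions"][c] for c in self.conditions},
                "delta": s["delta"],
            }
            for s in self.sites
        ]
        return pd.DataFrame(
            rows,
            columns=["contig", "pos", "strand", "ref",
                     *[f"fraction_{c}" for c in self.conditions], "delta"],
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _draw(dist: tuple, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw from a distribution spec ('uniform', lo, hi) or ('beta', a, b)."""
    kind = dist[0]
    if kind == "uniform":
        return rng.uniform(dist[1], dist[2], size=size)
    if kind == "beta":
        return rng.beta(dist[1], dist[2], size=size)
    if kind == "constant":
        return np.full(size, float(dist[1]))
    raise SimulationError(f"unknown distribution spec {dist!r}")


def simulate_editing_truth(
    bundle: ReferenceBundle,
    n_sites: int,
    base_fraction_dist: tuple = ("uniform", 0.10, 0.60),
    n_diff: int = 0,
    delta_dist: tuple = ("uniform", 0.10, 0.30),
    frac_decreased: float = 0.7,
    seed: int = 0,
) -> EditingTruth:
    """Plant editing sites on sense-strand adenosines of the reference.

    ``n_diff`` of the ``n_sites`` sites get a between-condition difference
    whose magnitude is drawn from ``delta_dist`` (fraction units; 0.05 is the
    5-percentage-point scale of interest) and whose sign is decreased-in-B
    with probability ``frac_decreased``.  Truth sites never coincide with SNP
    positions.
    """
    if n_diff > n_sites:
        raise SimulationError("n_diff cannot exceed n_sites")
    rng = np.random.default_rng(seed)
    snp_keys = bundle.snp_keys()

    # candidate positions: sense-strand adenosines inside gene features
    candidates: list = []
    gene_strand = {}
    for contig, start, end, strand, gene, cls in bundle.features:
        gene_strand.setdefault(contig, strand)
    for contig, seq in bundle.sequences.items():
        strand = gene_strand.get(contig, "+")
        target = "A" if strand == "+" else "T"
        arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
        for pos0 in np.flatnonzero(arr == target):
            key = (contig, int(pos0) + 1)
            if key not in snp_keys:
                candidates.append((contig, int(pos0) + 1, strand, target))
    if n_sites > len(candidates):
        raise SimulationError(
            f"not enough adenosine positions: need {n_sites}, have {len(candidates)}"
        )

    chosen = rng.choice(len(candidates), size=n_sites, replace=False)
    base = _draw(base_fraction_dist, n_sites, rng)
    deltas = np.zeros(n_sites)
    if n_diff:
        mag = _draw(delta_dist, n_diff, rng)
        sign = np.where(rng.random(n_diff) < frac_decreased, -1.0, 1.0)
        deltas[:n_diff] = sign * mag
    sites = []
    for i, ci in enumerate(chosen):
        contig, pos, strand, ref = candidates[ci]
        fa = float(np.clip(base[i], 0.0, 1.0))
        fb = float(np.clip(base[i] + deltas[i], 0.0, 1.0))
        sites.append(
            {
                "contig": contig,
                "pos": pos,
                "strand": strand,
                "ref": ref,
                "fractions": {"A": fa, "B": fb},
                "delta": fb - fa,
            }
        )
    sites.sort(key=lambda s: (s["contig"], s["pos"]))
    return EditingTruth(sites=sites)


# ---------------------------------------------------------------------------
# Pileups


def simulate_pileups(
    bundle: ReferenceBundle,
    truth: EditingTruth,
    mean_coverage: float = 50.0,
    error_rate: float = 1e-3,
    n_replicates: int = 3,
    condition: str = "A",
    seed: int = 0,
) -> list[PileupTable]:
    """Simulate per-replicate pileup tables for one condition.

    Per position, depth is Poisson(``mean_coverage``); each read reports the
    edited base with the site's true fraction (or the SNP alt with fraction
    0.5 at het sites), otherwise the reference; sequencing error then
    substitutes a uniformly chosen different base at ``error_rate``.
    Forward/reverse assignment is an even coin flip.  Zero-depth positions
    are omitted, as in mpileup output.
    """
    if mean_coverage <= 0:
        raise SimulationError("mean_coverage must be > 0")
    if not 0 <= error_rate < 0.25:
        raise SimulationError("error_rate must be in [0, 0.25)")
    if condition not in truth.conditions:
        raise SimulationError(f"condition {condition!r} not present in truth")

    truth_at = {(s["contig"], s["pos"]): s for s in truth.sites}
    snp_at = {(c, p): (r, a) for c, p, r, a in bundle.snp_sites}

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_replicates)
    tables = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(child_seeds[rep])
        frames = []
        for contig in sorted(bundle.sequences):
            seq = bundle.sequences[contig]
            L = len(seq)
            ref_idx = np.array([BASE_INDEX[b] for b in seq])
            cov = rng.poisson(mean_coverage, size=L)

            # per-position emission probabilities over A,C,G,T
            probs = np.full((L, 4), error_rate / 3.0)
            probs[np.arange(L), ref_idx] = 1.0 - error_rate
            for (c, pos), s in truth_at.items():
                if c != contig:
                    continue
                f = s["fractions"][condition]
                alt = "G" if s["ref"] == "A" else "C"
                base_p = np.full(4, error_rate / 3.0)
                base_p[BASE_INDEX[s["ref"]]] = (1 - f) * (1 - error_rate) \
                    + f * error_rate / 3.0
                base_p[BASE_INDEX[alt]] = f * (1 - error_rate) \
                    + (1 - f) * error_rate / 3.0
                probs[pos - 1] = base_p
            for (c, pos), (ref, alt) in snp_at.items():
                if c != contig:
                    continue
                base_p = np.full(4, error_rate / 3.0)
                base_p[BASE_INDEX[ref]] = 0.5 * (1 - error_rate) \
                    + 0.5 * error_rate / 3.0
                base_p[BASE_INDEX[alt]] = 0.5 * (1 - error_rate) \
                    + 0.5 * error_rate / 3.0
                probs[pos - 1] = base_p
            probs /= probs.sum(axis=1, keepdims=True)

            base_counts = rng.multinomial(cov, probs)
            fwd = rng.binomial(base_counts, 0.5)
            rev = base_counts - fwd
            keep = cov > 0
            pos1 = np.flatnonzero(keep) + 1
            data = {"contig": contig, "pos": pos1,
                    "ref": np.array(list(seq))[keep]}
            for bi, b in enumerate(BASES):
                data[f"{b}_fwd"] = fwd[keep, bi]
                data[f"{b}_rev"] = rev[keep, bi]
            frames.append(pd.DataFrame(data))
        df = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["contig", "pos", "ref", *BASE_COLUMNS])
        )
        tables.append(
            PileupTable(df=df, sample=f"{condition}_rep{rep + 1}", dedup=True)
        )
    return tables


# ---------------------------------------------------------------------------
# RIP-seq counts


@dataclass
class EnrichmentTruth:
    """Planted gene-level parameters for the IP-enrichment simulation.

    ``genes``: gene_id -> (baseline mean in input, IP fold in condition A,
    IP fold in condition B, NB dispersion).  The planted ratio of ratios for
    a gene is foldA / foldB; genes with foldA == foldB are nulls.
    """

    genes: dict

    def __post_init__(self) -> None:
        for g, (base, fa, fb, disp) in self.genes.items():
            if base > 0 and (fa <= 0 or fb <= 0):
                raise SimulationError(f"gene {g}: folds must be positive")
            if disp < 0:
                raise SimulationError(f"gene {g}: dispersion must be >= 0")

    def planted_log2_ror(self) -> pd.Series:
        vals = {
            g: np.log2(fa / fb) if base > 0 else np.nan
            for g, (base, fa, fb, disp) in self.genes.items()
        }
        return pd.Series(vals, name="log2_ror_true")

    def bound_genes(self, min_log2_ror: float = 0.5) -> set:
        lr = self.planted_log2_ror()
        return set(lr.index[lr >= min_log2_ror])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (g, base, fa, fb, disp)
                for g, (base, fa, fb, disp) in self.genes.items()
            ],
            columns=["gene", "baseline", "fold_A", "fold_B", "dispersion"],
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def simulate_enrichment_truth(
    gene_ids: Sequence[str],
    n_bound: int,
    bound_ror: float = 4.0,
    baseline_dist: tuple = ("lognormal", 5.0, 1.0),
    dispersion: float = 0.05,
    seed: int = 0,
) -> EnrichmentTruth:
    """Plant an IP-enrichment interaction in the first ``n_bound`` genes.

    Bound genes get IP fold ``bound_ror`` in condition A against fold 1 in
    condition B (ratio of ratios = ``bound_ror``); nulls have fold 1 in both.
    Baselines are log-normal (meanlog, sdlog) — heavy-tailed expression as in
    real RNA-seq.
    """
    if n_bound > len(gene_ids):
        raise SimulationError("n_bound exceeds number of genes")
    rng = np.random.default_rng(seed)
    kind = baseline_dist[0]
    if kind == "lognormal":
        base = rng.lognormal(baseline_dist[1], baseline_dist[2], len(gene_ids))
    elif kind == "constant":
        base = np.full(len(gene_ids), float(baseline_dist[1]))
    else:
        raise SimulationError(f"unknown baseline distribution {baseline_dist!r}")
    genes = {}
    for i, g in enumerate(gene_ids):
        fold_a = bound_ror if i < n_bound else 1.0
        genes[g] = (float(base[i]), float(fold_a), 1.0, float(dispersion))
    return EnrichmentTruth(genes=genes)


def simulate_rip_counts(
    truth: EnrichmentTruth,
    library_factors: Sequence[float] | None = None,
    n_replicates: int = 3,
    seed: int = 0,
):
    """Simulate an IP/input x condition x replicate NB count matrix.

    Expected count of gene g in sample j is
    ``baseline_g * library_factor_j * fold_g(condition_j)`` when the sample
    is an IP, and ``baseline_g * library_factor_j`` for inputs; counts are
    negative binomial with the gene's dispersion (Poisson when 0).  Returns a
    :class:`ripedit.ripenrich.CountMatrix` with the sample sheet attached.
    """
    from .ripenrich import CountMatrix

    samples = []
    for assay in ("IP", "input"):
        for cond in CONDITIONS:
            for rep in range(1, n_replicates + 1):
                samples.append((f"{assay}_{cond}_rep{rep}", assay, cond, rep))
    n_samples = len(samples)
    if library_factors is None:
        library_factors = np.ones(n_samples)
    library_factors = np.asarray(library_factors, dtype=float)
    if library_factors.shape != (n_samples,):
        raise SimulationError(
            f"library_factors must have length {n_samples}"
        )
    if (library_factors <= 0).any():
        raise SimulationError("library factors must be positive")

    rng = np.random.default_rng(seed)
    gene_ids = list(truth.genes)
    counts = np.zeros((len(gene_ids), n_samples), dtype=int)
    for gi, g in enumerate(gene_ids):
        base, fa, fb, disp = truth.genes[g]
        if base == 0:
            continue
        mu = np.empty(n_samples)
        for j, (_, assay, cond, _) in enumerate(samples):
            fold = (fa if cond == "A" else fb) if assay == "IP" else 1.0
            mu[j] = base * library_factors[j] * fold
        if disp == 0:
            counts[gi] = rng.poisson(mu)
        else:
            r = 1.0 / disp
            counts[gi] = rng.negative_binomial(r, r / (r + mu))

    counts_df = pd.DataFrame(
        counts, index=pd.Index(gene_ids, name="gene"),
        columns=[s[0] for s in samples],
    )
    sheet = pd.DataFrame(samples, columns=["sample", "assay", "condition", "replicate"])
    return CountMatrix(counts=counts_df, sheet=sheet)


# ---------------------------------------------------------------------------
# Sanger peaks


def simulate_sanger_peaks(
    fractions: Sequence[float],
    total_height: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate chromatogram A/G peak heights for given editing fractions.

    G height is ``fraction * total_height`` and A height the remainder, each
    plus Gaussian noise truncated at zero.
    """
    if total_height <= 0:
        raise SimulationError("total_height must be > 0")
    if noise_sd < 0:
        raise SimulationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    fractions = np.asarray(fractions, dtype=float)
    g = fractions * total_height
    a = (1.0 - fractions) * total_height
    if noise_sd > 0:
        g = np.maximum(0.0, g + rng.normal(0, noise_sd, size=g.shape))
        a = np.maximum(0.0, a + rng.normal(0, noise_sd, size=a.shape))
    return pd.DataFrame(
        {
            "site": [f"site{i + 1}" for i in range(len(fractions))],
            "A_height": a,
            "G_height": g,
        }
    )
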