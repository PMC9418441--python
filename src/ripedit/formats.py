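"""Readers and writers for the formats the pipeline touches.

The central dialect is a per-position pileup TSV that plays the role of
``samtools mpileup`` output with a DP4-style strand split: for every covered
position it records forward/reverse counts for each of the four bases against
a stated reference base.  Using a versioned TSV instead of raw mpileup text
keeps parsing unambiguous and round-trippable; a convenience converter from
standard mpileup text is provided.

Coordinate conventions
----------------------
Internal interval coordinates are 0-based half-open (BED-style).  Pileup rows
and VCF records are 1-based, matching those formats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PILEUP_MAGIC = "#ripedit-pileup"
PILEUP_VERSION = "v1"

#: column order of the pileup dialect after contig/pos/ref
BASE_COLUMNS = [
    "A_fwd", "A_rev", "C_fwd", "C_rev", "G_fwd", "G_rev", "T_fwd", "T_rev",
]

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass
class PileupTable:
    """Per-position base counts for one sample, DP4-style strand split.

    ``df`` columns: contig (str), pos (1-based int), ref (A/C/G/T), then
    ``BASE_COLUMNS``.  Positions are strictly increasing within each contig.
    ``dedup`` asserts that PCR duplicates were removed upstream.
    """

    df: pd.DataFrame
    sample: str = "sample"
    dedup: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        required = ["contig", "pos", "ref", *BASE_COLUMNS]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise FormatError(f"pileup table missing columns: {missing}")
        counts = self.df[BASE_COLUMNS].to_numpy()
        if counts.size and (counts < 0).any():
            raise FormatError("negative base count in pileup table")
        for contig, sub in self.df.groupby("contig", sort=False):
            pos = sub["pos"].to_numpy()
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise FormatError(
                    f"positions not strictly increasing on contig {contig!r}"
                )

    def __len__(self) -> int:
        return len(self.df)

    def coverage(self) -> np.ndarray:
        """Total read count per row (all bases, both strands)."""
        return self.df[BASE_COLUMNS].to_numpy().sum(axis=1)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(
                f"{PILEUP_MAGIC} {PILEUP_VERSION}\t"
                f"sample={self.sample}\tdedup={str(self.dedup).lower()}\n"
            )
            fh.write("\t".join(["contig", "pos", "ref", *BASE_COLUMNS]) + "\n")
            self.df.to_csv(fh, sep="\t", header=False, index=False)

    def equals(self, other: "PileupTable") -> bool:
        return (
            self.sample == other.sample
            and self.dedup == other.dedup
            and self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))
        )


def read_pileup(path: str | Path) -> PileupTable:
    """Read a pileup-dialect TSV, validating rows.

    Rows whose reference base is ``N`` are skipped with a logged warning
    (ambiguous reference positions carry no A-to-I information).  Duplicate
    (contig, pos) rows and malformed rows raise :class:`FormatError` with the
    offending line number.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith(PILEUP_MAGIC):
            raise FormatError(f"{path}: not a ripedit pileup file (bad magic)")
        meta = dict(
            part.split("=", 1) for part in header.split("\t")[1:] if "=" in part
        )
        colline = fh.readline().rstrip("\n").split("\t")
        expected = ["contig", "pos", "ref", *BASE_COLUMNS]
        if colline != expected:
            raise FormatError(f"{path}: unexpected column header {colline}")
        rows = []
        n_skipped = 0
        for lineno, line in enumerate(fh, start=3):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(expected):
                raise FormatError(f"{path}:{lineno}: expected {len(expected)} fields")
            ref = parts[2].upper()
            if ref == "N":
                n_skipped += 1
                continue
            if ref not in "ACGT":
                raise FormatError(f"{path}:{lineno}: bad reference base {ref!r}")
            try:
                pos = int(parts[1])
                counts = [int(x) for x in parts[3:]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field") from exc
            if any(c < 0 for c in counts):
                raise FormatError(f"{path}:{lineno}: negative count")
            rows.append((parts[0], pos, ref, *counts))
    if n_skipped:
        logger.warning("%s: skipped %d rows with reference base N", path, n_skipped)
    df = pd.DataFrame(rows, columns=expected)
    if len(df) and df.duplicated(["contig", "pos"]).any():
        dup = df[df.duplicated(["contig", "pos"])].iloc[0]
        raise FormatError(
            f"{path}: duplicate row for {dup['contig']}:{dup['pos']}"
        )
    if not len(df):
        df = df.astype({"pos": int, **{c: int for c in BASE_COLUMNS}}, errors="ignore")
    return PileupTable(
        df=df,
        sample=meta.get("sample", path.stem),
        dedup=meta.get("dedup", "true") == "true",
    )


def read_mpileup_text(path: str | Path, sample: str = "sample") -> PileupTable:
    """Convert classic ``samtools mpileup`` text output to a PileupTable.

    Supports the 6-column single-sample layout (chrom, pos, ref, depth,
    read bases, quals).  ``.`` / ``,`` are reference matches on the forward /
    reverse strand; explicit base letters are mismatches (upper = forward,
    lower = reverse).  Indels and read start/end markers are stripped.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                continue
            contig, pos, ref = parts[0], int(parts[1]), parts[2].upper()
            if ref not in "ACGT":
                continue
            bases = parts[4]
            counts = {c: 0 for c in BASE_COLUMNS}
            i = 0
            while i < len(bases):
                ch = bases[i]
                if ch == "^":  # read start, next char is mapping quality
                    i += 2
                    continue
                if ch == "$":
                    i += 1
                    continue
                if ch in "+-":  # indel: skip length digits then the sequence
                    j = i + 1
                    while j < len(bases) and bases[j].isdigit():
                        j += 1
                    n = int(bases[i + 1 : j])
                    i = j + n
                    continue
                if ch == ".":
                    counts[f"{ref}_fwd"] += 1
                elif ch == ",":
                    counts[f"{ref}_rev"] += 1
                elif ch.upper() in "ACGT":
                    strand = "fwd" if ch.isupper() else "rev"
                    counts[f"{ch.upper()}_{strand}"] += 1
                i += 1
            rows.append((contig, pos, ref, *[counts[c] for c in BASE_COLUMNS]))
    df = pd.DataFrame(rows, columns=["contig", "pos", "ref", *BASE_COLUMNS])
    return PileupTable(df=df, sample=sample)


# ---------------------------------------------------------------------------
# SNP masks


@dataclass
class SiteSet:
    """A set of (contig, 1-based position) keys, e.g. a SNP mask."""

    sites: set = field(default_factory=set)

    def __contains__(self, key) -> bool:
        return tuple(key) in self.sites

    def __len__(self) -> int:
        return len(self.sites)

    def __or__(self, other: "SiteSet") -> "SiteSet":
        return SiteSet(self.sites | other.sites)

    @classmethod
    def from_pairs(cls, pairs: Iterable) -> "SiteSet":
        return cls({(str(c), int(p)) for c, p in pairs})


def read_snp_mask(path: str | Path, extra_sites: SiteSet | None = None) -> SiteSet:
    """Read site-level SNP mask from a VCF, optionally unioned with extra sites.

    Masking is position-level: multi-allelic records contribute one key.  The
    ``extra_sites`` argument carries cell-line-specific variants supplied
    outside dbSNP-style VCFs.
    """
    import pysam

    path = Path(path)
    sites: set = set()
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: cannot parse VCF: {exc}") from exc
    with vcf:
        for rec in vcf:
            sites.add((rec.chrom, rec.pos))
    out = SiteSet(sites)
    if extra_sites is not None:
        out = out | extra_sites
    return out


def read_extra_sites(path: str | Path) -> SiteSet:
    """Read a two-column (contig, 1-based pos) TSV of extra mask sites."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["contig", "pos"], usecols=[0, 1])
    return SiteSet.from_pairs(zip(df["contig"].astype(str), df["pos"].astype(int)))


def write_snp_vcf(path: str | Path,
                  records: Sequence[tuple[str, int, str, str]],
                  contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write minimal VCF v4.2 records (CHROM, 1-based POS, REF, ALT)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ripedit-synthdata\n")
        for contig, length in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in records:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# Intervals


@dataclass
class IntervalSet:
    """Half-open 0-based genomic intervals with strand and label.

    ``intervals``: list of (contig, start, end, strand, label).  Overlaps are
    retained as-is; no merging happens at read time.
    """

    intervals: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for iv in self.intervals:
            contig, start, end, strand, label = iv
            if start >= end:
                raise FormatError(f"empty/inverted interval {iv}")
            if strand not in ("+", "-", "."):
                raise FormatError(f"bad strand in interval {iv}")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def trees(self) -> Mapping[str, "object"]:
        """Per-contig interval trees for overlap queries (lazy, cached)."""
        from intervaltree import IntervalTree

        if not hasattr(self, "_trees"):
            trees: dict = {}
            for contig, start, end, strand, label in self.intervals:
                trees.setdefault(contig, IntervalTree()).addi(
                    start, end, (strand, label)
                )
            self._trees = trees
        return self._trees

    def overlapping(self, contig: str, pos0: int) -> list:
        """(strand, label) pairs of intervals covering 0-based position."""
        tree = self.trees().get(contig)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(pos0)]

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for contig, start, end, strand, label in self.intervals:
                fh.write(f"{contig}\t{start}\t{end}\t{label}\t0\t{strand}\n")


def read_intervals(path: str | Path) -> IntervalSet:
    """Read a 3- or 6-column BED file (0-based half-open).

    Strand is taken from column 6 when present, else ``.``; the name column
    (4) becomes the label.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            contig = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            label = parts[3] if len(parts) >= 4 else ""
            strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else "."
            intervals.append((contig, start, end, strand, label))
    return IntervalSet(intervals)


# ---------------------------------------------------------------------------
# FASTA and count matrices


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif name is not None:
                chunks.append(line.strip())
    if name is not None:
        sequences[name] = "".join(chunks)
    return sequences


def write_counts(path: str | Path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_sample_sheet(path: str | Path, sheet: pd.DataFrame) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    required = {"sample", "assay", "condition", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet
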