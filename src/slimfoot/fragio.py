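"""Readers, writers and elementary operations on sequenced chromatin fragments.

A *fragment* is the genomic interval covered by one sequenced DNA molecule
(the paired-end template).  Because MNase digests DNA that is not shielded
by bound protein, the length of a fragment and the exact positions of its
two ends carry the protection signal that all downstream analyses consume.

Conventions
-----------
* All internal coordinates are 0-based, half-open (BED convention).
  BAM records (1-based internally in the text form) are converted on ingest
  by pysam.
* ChIP fragments carry strand ``"."`` — the template strand is
  uninformative for protection.  NET-seq reads keep their strand because
  it encodes the direction of transcription.
* Duplicate fragments are retained; no deduplication is applied.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

FRAGMENT_COLUMNS = ["chrom", "start", "end", "name", "strand"]

#: Default ingest cap on template length; mirrors the aligner's maximal
#: fragment size of 2,000 bp so downstream code never sees pathological
#: templates.
DEFAULT_MAX_FRAGMENT_LENGTH = 2000


class BedParseError(ValueError):
    """A BED line could not be parsed; carries the 1-based line number."""


@dataclass
class FragmentSet:
    """A collection of fragments plus the chromosome-size table.

    ``frags`` is a DataFrame with columns chrom/start/end/name/strand.
    The ``name`` field carries simulator ground truth (``site_id:class``)
    when present.
    """

    frags: pd.DataFrame
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.frags.columns) != FRAGMENT_COLUMNS:
            self.frags = self.frags.reindex(columns=FRAGMENT_COLUMNS)
        if len(self.frags):
            bad = self.frags["end"] <= self.frags["start"]
            if bad.any():
                raise ValueError(f"{int(bad.sum())} fragments with end <= start")

    def __len__(self) -> int:
        return len(self.frags)

    @property
    def lengths(self) -> np.ndarray:
        return (self.frags["end"] - self.frags["start"]).to_numpy()

    def subset(self, mask) -> "FragmentSet":
        return FragmentSet(self.frags[mask].reset_index(drop=True), self.chrom_sizes)

    def true_classes(self) -> pd.Series:
        """Ground-truth class parsed from ``site_id:class`` names."""
        return self.frags["name"].str.rsplit(":", n=1).str[-1]

    def site_ids(self) -> pd.Series:
        return self.frags["name"].str.rsplit(":", n=1).str[0]


@dataclass
class StrandedReadSet:
    """Strand-resolved single-base read marks (NET-seq 3' ends).

    ``reads`` columns: chrom, pos (0-based position of the 3' end, the last
    base incorporated by the polymerase), strand (+/-), name.
    """

    reads: pd.DataFrame
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.reads) and not self.reads["strand"].isin(["+", "-"]).all():
            raise ValueError("stranded reads must have strand + or -")

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class GenomeAnnotation:
    """TSS, ORF and telomere tables.

    tss columns: chrom, pos (0-based), strand, gene_id.
    orfs / telomeres columns: chrom, start, end (half-open).
    """

    tss: pd.DataFrame
    orfs: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end"]))
    telomeres: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end"]))


@dataclass(frozen=True)
class MotifOccurrence:
    chrom: str
    start: int
    end: int
    strand: str
    pattern_id: str


# ---------------------------------------------------------------------------
# Fragment ingest
# ---------------------------------------------------------------------------

def read_fragments(
    path,
    fmt: str = "BED",
    chrom_sizes: dict[str, int] | None = None,
    max_length: int = DEFAULT_MAX_FRAGMENT_LENGTH,
) -> FragmentSet:
    """Read paired-end fragments from BED6 or a coordinate-sorted BAM.

    Each BAM template (proper pair) becomes one fragment spanning the
    leftmost mate start to the rightmost mate end.  Fragments longer than
    ``max_length`` are dropped with a logged count; unpaired or orphan BAM
    records are skipped with a warning count.
    """
    fmt = fmt.upper()
    if fmt == "BED":
        frags = _read_bed(path)
    elif fmt in ("BAM", "SAM"):
        frags = _read_bam(path)
    else:
        raise ValueError(f"unknown fragment format: {fmt}")
    n_long = int(((frags["end"] - frags["start"]) > max_length).sum())
    if n_long:
        logger.info("dropped %d fragments longer than %d bp", n_long, max_length)
        frags = frags[(frags["end"] - frags["start"]) <= max_length].reset_index(drop=True)
    return FragmentSet(frags, chrom_sizes or {})


def _read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"line {i}: expected >=3 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(f"line {i}: non-integer coordinates") from exc
            name = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((parts[0], start, end, name, strand))
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


def _read_bam(path) -> pd.DataFrame:
    rows = []
    n_skipped = 0
    with pysam.AlignmentFile(str(path)) as bam:
        for rec in bam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if not rec.is_proper_pair or rec.template_length <= 0:
                # count each template once, from the leftmost (tlen>0) mate
                if not rec.is_proper_pair and not rec.is_read2:
                    n_skipped += 1
                continue
            rows.append(
                (rec.reference_name, rec.reference_start,
                 rec.reference_start + rec.template_length,
                 rec.query_name, ".")
            )
    if n_skipped:
        logger.warning("skipped %d unpaired/orphan records", n_skipped)
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


def write_bed(fs: FragmentSet, path) -> None:
    """Write fragments as BED6 (score column 0)."""
    df = fs.frags
    out = pd.DataFrame({
        "chrom": df["chrom"], "start": df["start"], "end": df["end"],
        "name": df["name"], "score": 0, "strand": df["strand"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_stranded_reads(path, chrom_sizes: dict[str, int] | None = None) -> StrandedReadSet:
    """Read 1-bp stranded BED intervals marking NET-seq 3' ends."""
    df = _read_bed(path)
    reads = pd.DataFrame({
        "chrom": df["chrom"], "pos": df["start"],
        "strand": df["strand"], "name": df["name"],
    })
    return StrandedReadSet(reads, chrom_sizes or {})


def write_stranded_reads(rs: StrandedReadSet, path) -> None:
    df = rs.reads
    out = pd.DataFrame({
        "chrom": df["chrom"], "start": df["pos"], "end": df["pos"] + 1,
        "name": df["name"], "score": 0, "strand": df["strand"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Elementary fragment operations
# ---------------------------------------------------------------------------

def select_by_length(fs: FragmentSet, min_len: int, max_len: int | None = None) -> FragmentSet:
    """Keep fragments with ``min_len <= length`` and ``length < max_len``.

    The right bound is exclusive so the short-read class "less than 80 bp"
    is expressible exactly as ``select_by_length(fs, 1, 80)``.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if max_len is not None and min_len >= max_len:
        raise ValueError("min_len must be < max_len")
    lengths = fs.lengths
    mask = lengths >= min_len
    if max_len is not None:
        mask &= lengths < max_len
    return fs.subset(mask)


def coverage_track(fs: FragmentSet) -> dict[str, np.ndarray]:
    """Per-base indicator coverage summed over fragments, per chromosome.

    Total mass equals the sum of fragment lengths.  Chromosomes absent from
    the size table are sized to the rightmost fragment end.
    """
    out: dict[str, np.ndarray] = {}
    for chrom, grp in fs.frags.groupby("chrom", sort=True):
        size = fs.chrom_sizes.get(chrom, int(grp["end"].max()))
        cov = np.zeros(size, dtype=np.int64)
        # difference-array accumulation, O(n + size)
        np.add.at(cov, grp["start"].to_numpy().clip(0, size - 1), 1)
        ends = grp["end"].to_numpy()
        in_bounds = ends < size
        np.add.at(cov, ends[in_bounds], -1)
        out[chrom] = np.cumsum(cov)
    return out


def write_bedgraph(track: dict[str, np.ndarray], path, track_line: bool = False) -> None:
    """Write a coverage track as bedGraph, merging equal-value runs."""
    with open(path, "w") as fh:
        if track_line:
            fh.write('track type=bedGraph name="coverage"\n')
        for chrom in sorted(track):
            cov = np.asarray(track[chrom])
            if cov.size == 0:
                continue
            change = np.flatnonzero(np.diff(cov)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [cov.size]])
            for s, e in zip(starts, ends):
                v = cov[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


def read_bedgraph(path, chrom_sizes: dict[str, int] | None = None) -> dict[str, np.ndarray]:
    """Read a bedGraph into per-chromosome dense arrays."""
    sizes = dict(chrom_sizes or {})
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            chrom, s, e, v = line.split("\t")
            rows.append((chrom, int(s), int(e), float(v)))
            sizes[chrom] = max(sizes.get(chrom, 0), int(e))
    out = {c: np.zeros(n) for c, n in sizes.items()}
    for chrom, s, e, v in rows:
        out[chrom][s:e] = v
    return out


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

def read_annotation(tss_path, orf_path=None, telomere_path=None) -> GenomeAnnotation:
    """Read annotation tables.

    The TSS table is a TSV with header columns chrom, pos, strand, gene_id;
    ORF and telomere tables are headerless BED3.
    """
    tss = pd.read_csv(tss_path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "pos", "strand", "gene_id"} - set(tss.columns)
    if missing:
        raise ValueError(f"TSS table missing columns: {sorted(missing)}")
    empty = pd.DataFrame(columns=["chrom", "start", "end"])

    def _bed3(p):
        if p is None:
            return empty.copy()
        df = pd.read_csv(p, sep="\t", header=None, usecols=[0, 1, 2],
                         names=["chrom", "start", "end"], dtype={0: str})
        return df

    return GenomeAnnotation(tss=tss, orfs=_bed3(orf_path), telomeres=_bed3(telomere_path))


# ---------------------------------------------------------------------------
# Consensus motif scanning
# ---------------------------------------------------------------------------

_IUPAC_CODES = "ACGTRYSWKMBDHVN"
_IUPAC_REGEX = {
    code: (vals if len(vals) == 1 else "[" + vals + "]")
    for code, vals in ambiguous_dna_values.items()
    if code in _IUPAC_CODES
}


def _iupac_to_regex(pattern: str) -> str:
    parts = []
    for ch in pattern.upper():
        if ch not in _IUPAC_REGEX:
            raise ValueError(f"invalid IUPAC symbol: {ch!r}")
        parts.append(_IUPAC_REGEX[ch])
    return "".join(parts)


def scan_consensus(fasta_path, iupac_pattern: str, pattern_id: str | None = None) -> list[MotifOccurrence]:
    """Find all exact IUPAC-consensus matches on both strands of a FASTA.

    Reverse-complement matches are reported on the minus strand with the
    coordinates of the matching window on the reference.  Overlapping
    occurrences are all reported.
    """
    if not iupac_pattern:
        raise ValueError("empty pattern")
    pattern_id = pattern_id or iupac_pattern
    fwd = re.compile("(?=(" + _iupac_to_regex(iupac_pattern) + "))")
    rev = re.compile("(?=(" + _iupac_to_regex(reverse_complement(iupac_pattern)) + "))")
    plen = len(iupac_pattern)
    hits = []
    fa = Fasta(str(fasta_path))
    for name in fa.keys():
        seq = str(fa[name][:]).upper()
        for m in fwd.finditer(seq):
            hits.append(MotifOccurrence(name, m.start(), m.start() + plen, "+", pattern_id))
        for m in rev.finditer(seq):
            hits.append(MotifOccurrence(name, m.start(), m.start() + plen, "-", pattern_id))
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits
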