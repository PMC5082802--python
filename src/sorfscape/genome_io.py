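"""Sequence and annotation I/O with a single internal coordinate convention.

Everything downstream of this module works with 0-based, half-open intervals
on the forward strand. GFF3 (1-based inclusive) and GenBank coordinates are
converted here, at the I/O boundary, and nowhere else.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class GenomeRecord:
    """A genome (or contig): uppercase DNA over {A,C,G,T,N}."""

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"genome {self.id!r}: invalid characters {sorted(bad)}; "
                "normalize before constructing GenomeRecord"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class FeatureRecord:
    """An annotated feature in internal 0-based half-open coordinates."""

    seq_id: str
    start: int
    end: int
    strand: str
    feature_type: str = "gene"
    locus_tag: str = ""
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.locus_tag!r}: invalid interval "
                f"[{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class IgrSet:
    """Intergenic regions: sorted, disjoint half-open intervals."""

    seq_id: str
    intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        prev_end = -1
        for s, e in self.intervals:
            if s >= e:
                raise ValueError(f"empty/inverted IGR interval ({s}, {e})")
            if s < prev_end:
                raise ValueError("IGR intervals overlap or are unsorted")
            prev_end = e
        self._starts = [s for s, _ in self.intervals]

    @property
    def total_length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def contains(self, start: int, end: int) -> bool:
        """True iff [start, end) lies fully inside one IGR interval."""
        i = bisect_right(self._starts, start) - 1
        if i < 0:
            return False
        s, e = self.intervals[i]
        return s <= start and end <= e

    def contains_position(self, pos: int) -> bool:
        return self.contains(pos, pos + 1)


def normalize_sequence(seq: str, record_id: str = "?") -> str:
    """Uppercase and map characters outside {A,C,G,T,N} to N."""
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        logger.warning(
            "record %s: %d character type(s) outside {A,C,G,T,N} mapped to N: %s",
            record_id, len(bad), "".join(sorted(bad)),
        )
        seq = "".join(c if c in VALID_BASES else "N" for c in seq)
    return seq


def read_fasta(path: str | Path, circular: bool = False) -> list[GenomeRecord]:
    """Read FASTA into GenomeRecords (uppercased, non-ACGTN mapped to N)."""
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA record id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            GenomeRecord(rec.id, normalize_sequence(str(rec.seq), rec.id), circular)
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def reverse_complement(seq: str) -> str:
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"cannot reverse-complement characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate DNA with the standard genetic code; stops rendered '*'.

    Trailing bases that do not fill a codon are dropped with a warning.
    """
    if len(seq) % 3:
        logger.warning("translate: dropping %d trailing base(s)", len(seq) % 3)
        seq = seq[: len(seq) - len(seq) % 3]
    # Bio.Seq renders codons containing N as 'X' which is what aligners expect
    return str(Seq(seq).translate())


def _parse_gff3(path: Path, known_ids: set[str] | None) -> list[FeatureRecord]:
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seq_id, _, ftype, start1, end1, _, strand, _, attr_col = cols
            if known_ids is not None and seq_id not in known_ids:
                raise ValueError(f"{path}:{lineno}: unknown seq_id {seq_id!r}")
            start, end = int(start1) - 1, int(end1)
            if end <= start:
                raise ValueError(
                    f"{path}:{lineno}: end < start after conversion "
                    f"({start1}..{end1})"
                )
            attrs = {}
            for item in attr_col.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k] = v
            features.append(
                FeatureRecord(
                    seq_id, start, end, strand, ftype,
                    attrs.get("locus_tag", attrs.get("ID", "")), attrs,
                )
            )
    return features


def _parse_genbank(path: Path) -> list[FeatureRecord]:
    features = []
    for rec in SeqIO.parse(str(path), "genbank"):
        for feat in rec.features:
            if feat.type == "source":
                continue
            strand = "-" if feat.location.strand == -1 else "+"
            quals = {k: v[0] if v else "" for k, v in feat.qualifiers.items()}
            features.append(
                FeatureRecord(
                    rec.id,
                    int(feat.location.start),
                    int(feat.location.end),
                    strand,
                    feat.type,
                    quals.get("locus_tag", ""),
                    quals,
                )
            )
    return features


def read_features(
    path: str | Path,
    dialect: str = "gff3",
    known_ids: Iterable[str] | None = None,
) -> list[FeatureRecord]:
    """Read annotation (GFF3 or GenBank) into internal coordinates."""
    path = Path(path)
    if dialect == "gff3":
        return _parse_gff3(path, set(known_ids) if known_ids is not None else None)
    if dialect == "genbank":
        return _parse_genbank(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_gff3(features: list[FeatureRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = dict(f.attributes)
            if f.locus_tag and "locus_tag" not in attrs:
                attrs["locus_tag"] = f.locus_tag
            attr_col = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            fh.write(
                f"{f.seq_id}\tsorfscape\t{f.feature_type}\t{f.start + 1}\t"
                f"{f.end}\t.\t{f.strand}\t.\t{attr_col}\n"
            )


def write_bed(intervals: Iterable[tuple], seq_id: str, path: str | Path) -> None:
    """Write (start, end[, name, score, strand]) tuples as BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            start, end = iv[0], iv[1]
            rest = list(iv[2:])
            fh.write("\t".join(str(x) for x in [seq_id, start, end] + rest) + "\n")


def compute_igrs(
    features: list[FeatureRecord],
    genome: GenomeRecord,
    feature_types: tuple[str, ...] = ("gene", "CDS"),
) -> IgrSet:
    """Maximal intervals covered by no gene feature on either strand.

    For a circular genome the origin-spanning gap appears as two linear
    intervals (one ending at the origin, one starting at it).
    """
    spans = sorted(
        (f.start, f.end)
        for f in features
        if f.seq_id == genome.id and f.feature_type in feature_types
    )
    igrs: list[tuple[int, int]] = []
    cursor = 0
    for s, e in spans:
        if s > genome.length or e > genome.length:
            raise ValueError(f"feature [{s},{e}) outside genome of {genome.length} bp")
        if s > cursor:
            igrs.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < genome.length:
        igrs.append((cursor, genome.length))
    return IgrSet(genome.id, igrs)
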