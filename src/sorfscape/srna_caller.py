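"""Orphan sRNA candidate calling from TSS tables and strand-specific coverage.

TSSs mapped by differential RNA-seq are classified relative to the
annotation; intergenic ("orphan") TSSs with a high read peak seed sRNA
candidates whose 3' ends are estimated from a sustained coverage drop.
5' ends are classified as primary vs processed from the ratio of peak
heights in TEX-treated vs untreated libraries (TEX degrades
5'-monophosphorylated, i.e. processed, transcripts).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .genome_io import FeatureRecord, IgrSet, compute_igrs, GenomeRecord

logger = logging.getLogger(__name__)


@dataclass
class TssRecord:
    seq_id: str
    position: int  # internal 0-based coordinate of the 5' nucleotide
    strand: str
    peak_tex_plus: float = 0.0
    peak_tex_minus: float = 0.0
    promoter_type: str = "none"  # RpoD | RpoN | none
    name: str = ""

    @classmethod
    def from_table_coordinates(cls, seq_id: str, position_1based: int, strand: str,
                               **kw) -> "TssRecord":
        """Construct from a 1-based published-table coordinate."""
        return cls(seq_id, position_1based - 1, strand, **kw)


def read_tss_table(path: str | Path, seq_id: str) -> list[TssRecord]:
    """Read a TSS table (TSV: name, strand, position [1-based], promoter_type,
    peak_tex_plus, peak_tex_minus)."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "strand", "position"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"TSS table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            TssRecord.from_table_coordinates(
                seq_id, int(row.position),
                "+" if str(row.strand).lower() in ("+", "plus") else "-",
                peak_tex_plus=float(getattr(row, "peak_tex_plus", 0.0)),
                peak_tex_minus=float(getattr(row, "peak_tex_minus", 0.0)),
                promoter_type=str(getattr(row, "promoter_type", "none")),
                name=str(row.name),
            )
        )
    return out


@dataclass
class CoverageTrack:
    """Per-position read counts for one library, both strands."""

    fwd: np.ndarray
    rev: np.ndarray

    def __post_init__(self) -> None:
        self.fwd = np.asarray(self.fwd, dtype=float)
        self.rev = np.asarray(self.rev, dtype=float)
        if self.fwd.shape != self.rev.shape:
            raise ValueError("strand tracks differ in length")
        if (self.fwd < 0).any() or (self.rev < 0).any():
            raise ValueError("negative coverage")

    def on_strand(self, strand: str) -> np.ndarray:
        return self.fwd if strand == "+" else self.rev


def read_bedgraph(path: str | Path, genome_length: int) -> np.ndarray:
    """Expand a bedGraph (0-based half-open) into a per-position vector."""
    cov = np.zeros(genome_length)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            _, start, end, value = line.split()[:4]
            cov[int(start): int(end)] = float(value)
    return cov


def write_bedgraph(cov: np.ndarray, seq_id: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        run_start = 0
        for i in range(1, len(cov) + 1):
            if i == len(cov) or cov[i] != cov[run_start]:
                if cov[run_start] != 0:
                    fh.write(f"{seq_id}\t{run_start}\t{i}\t{cov[run_start]:g}\n")
                run_start = i


@dataclass
class SrnaCandidate:
    start: int
    end: int
    strand: str
    tss: TssRecord
    five_prime_class: str  # primary | processed | ambiguous
    peak_height: float
    end_capped: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def classify_tss(
    tss: TssRecord,
    features: list[FeatureRecord],
    genome_length: int,
    igrs: Optional[IgrSet] = None,
    orphan_margin: int = 200,
) -> str:
    """orphan | gene_associated | internal | antisense.

    A TSS is orphan when intergenic with no same-strand gene start within
    orphan_margin downstream (such a TSS would be a 5'-UTR start instead).
    """
    if not (0 <= tss.position < genome_length):
        raise ValueError(f"TSS position {tss.position} outside genome")
    pos = tss.position
    feats = [f for f in features if f.seq_id == tss.seq_id]
    for f in feats:
        if f.start <= pos < f.end:
            return "internal" if f.strand == tss.strand else "antisense"
    for f in feats:
        if f.strand != tss.strand:
            continue
        gene_start = f.start if f.strand == "+" else f.end - 1
        dist = gene_start - pos if tss.strand == "+" else pos - gene_start
        if 0 <= dist <= orphan_margin:
            return "gene_associated"
    return "orphan"


def estimate_3prime_end(
    coverage: np.ndarray,
    tss: TssRecord,
    drop_fraction: float = 0.1,
    sustain: int = 10,
    max_len: int = 500,
) -> tuple[int, bool]:
    """Last covered position before coverage stays below drop_fraction x peak
    for >= sustain nt, scanning in the direction of transcription.

    Returns (end position inclusive, capped flag); capped means no sustained
    drop was seen within max_len.
    """
    peak = coverage[tss.position]
    if peak <= 0:
        raise ValueError("no coverage at TSS")
    threshold = drop_fraction * peak
    step = 1 if tss.strand == "+" else -1
    low_run = 0
    pos = tss.position
    for k in range(1, max_len + sustain + 1):
        pos = tss.position + step * k
        if pos < 0 or pos >= len(coverage):
            break
        if coverage[pos] < threshold:
            low_run += 1
            if low_run >= sustain:
                return pos - step * sustain, False
        else:
            low_run = 0
    return tss.position + step * min(max_len - 1, abs(pos - tss.position)), True


def classify_5prime(tss: TssRecord, ratio_threshold: float = 2.0) -> str:
    """primary | processed | ambiguous from TEX+/TEX- peak heights."""
    plus, minus = tss.peak_tex_plus, tss.peak_tex_minus
    if plus == 0 and minus == 0:
        logger.warning("TSS %s: both TEX peaks zero", tss.name or tss.position)
        return "ambiguous"
    ratio_plus = plus / minus if minus > 0 else math.inf
    ratio_minus = minus / plus if plus > 0 else math.inf
    if ratio_plus >= ratio_threshold:
        return "primary"
    if ratio_minus >= ratio_threshold:
        return "processed"
    return "ambiguous"


def call_srna_candidates(
    tss_list: list[TssRecord],
    coverage: CoverageTrack,
    features: list[FeatureRecord],
    genome: GenomeRecord,
    min_peak: float = 100.0,
    min_len: int = 50,
    max_len: int = 500,
    orphan_margin: int = 200,
    drop_fraction: float = 0.1,
    sustain: int = 10,
) -> list[SrnaCandidate]:
    """Orphan TSSs with high peaks, extended to a sustained coverage drop.

    Candidates are clipped to their intergenic region and filtered to
    [min_len, max_len].
    """
    igrs = compute_igrs(features, genome)
    candidates = []
    for tss in tss_list:
        if classify_tss(tss, features, genome.length, igrs, orphan_margin) != "orphan":
            continue
        if tss.peak_tex_plus < min_peak:
            continue
        cov = coverage.on_strand(tss.strand)
        # the peak must be real in the supplied coverage, not only in the table
        if cov[tss.position] < min_peak:
            continue
        end_pos, capped = estimate_3prime_end(
            cov, tss, drop_fraction, sustain, max_len
        )
        if capped:  # transcript runs past max_len: not a small RNA
            continue
        if tss.strand == "+":
            start, end = tss.position, end_pos + 1
        else:
            start, end = end_pos, tss.position + 1
        # clip to the containing IGR: candidates are intergenic by definition
        for s, e in igrs.intervals:
            if s <= tss.position < e:
                start, end = max(start, s), min(end, e)
                break
        if not (min_len <= end - start <= max_len):
            continue
        candidates.append(
            SrnaCandidate(
                start=start,
                end=end,
                strand=tss.strand,
                tss=tss,
                five_prime_class=classify_5prime(tss),
                peak_height=float(cov[tss.position]),
                end_capped=capped,
            )
        )
    return candidates
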