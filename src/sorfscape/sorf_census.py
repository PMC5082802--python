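"""Annotated-ORF census: sORF selection, length histograms, Shine-Dalgarno.

A "sORF" is an annotated ORF of at most 80 amino acids (stop codon excluded).
The boundary is inclusive and configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .genome_io import FeatureRecord, GenomeRecord, reverse_complement

logger = logging.getLogger(__name__)

SD_CONSENSUS = "AGGAGG"


@dataclass
class OrfRecord:
    locus_tag: str
    seq_id: str
    start: int  # internal coordinates, stop codon included in the span
    end: int
    strand: str
    aa_length: int  # codons excluding the stop codon
    start_codon: str
    proteomic_evidence: bool = False

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3:
            raise ValueError(f"{self.locus_tag}: span not divisible by 3")
        if self.aa_length != (self.end - self.start) // 3 - 1 or self.aa_length < 1:
            raise ValueError(f"{self.locus_tag}: inconsistent aa_length")


@dataclass
class LengthHistogram:
    bin_edges: np.ndarray  # right-open bins [e0, e1), [e1, e2), ...
    counts: np.ndarray

    @property
    def n_orfs(self) -> int:
        return int(self.counts.sum())

    @property
    def modal_bin(self) -> tuple[int, int]:
        i = int(np.argmax(self.counts))
        return int(self.bin_edges[i]), int(self.bin_edges[i + 1])


@dataclass
class SdMatch:
    """Best match of a 6-mer window to the AGGAGG consensus upstream of a start."""

    offset: int  # position of the window's first base relative to the start codon
    matched_seq: str
    score: int

    def __post_init__(self) -> None:
        if not (-20 <= self.offset <= -4):
            raise ValueError(f"SD offset {self.offset} outside [-20, -4]")
        if not (0 <= self.score <= 6):
            raise ValueError(f"SD score {self.score} outside [0, 6]")


def orf_sequence(orf: OrfRecord, genome: GenomeRecord) -> str:
    """Coding-strand nucleotide sequence of the ORF (stop codon included)."""
    seq = genome.sequence[orf.start: orf.end]
    return reverse_complement(seq) if orf.strand == "-" else seq


def extract_orfs(
    features: list[FeatureRecord],
    genome: GenomeRecord,
    feature_types: tuple[str, ...] = ("CDS", "gene"),
    proteomic_tags: Optional[set[str]] = None,
) -> list[OrfRecord]:
    """Build OrfRecords from annotated CDS/gene features.

    Features whose span is not divisible by 3 are skipped with a warning.
    aa_length excludes the stop codon; minus-strand start codons are read
    from the reverse complement.
    """
    proteomic_tags = proteomic_tags or set()
    orfs = []
    for f in features:
        if f.feature_type not in feature_types or f.seq_id != genome.id:
            continue
        if (f.end - f.start) % 3:
            logger.warning(
                "%s: span %d not divisible by 3, skipped", f.locus_tag, f.end - f.start
            )
            continue
        if (f.end - f.start) < 6:
            logger.warning("%s: span too short for codon + stop, skipped", f.locus_tag)
            continue
        seq = genome.sequence[f.start: f.end]
        if f.strand == "-":
            seq = reverse_complement(seq)
        orfs.append(
            OrfRecord(
                locus_tag=f.locus_tag,
                seq_id=f.seq_id,
                start=f.start,
                end=f.end,
                strand=f.strand,
                aa_length=(f.end - f.start) // 3 - 1,
                start_codon=seq[:3],
                proteomic_evidence=f.locus_tag in proteomic_tags
                or f.attributes.get("proteomic_evidence") in ("1", "true", True),
            )
        )
    return orfs


def select_sorfs(orfs: list[OrfRecord], max_aa: int = 80) -> list[OrfRecord]:
    """Keep ORFs of at most max_aa amino acids (inclusive boundary)."""
    return [o for o in orfs if o.aa_length <= max_aa]


def length_histogram(orfs: list[OrfRecord], bin_width: int = 10) -> LengthHistogram:
    """Histogram of aa lengths in right-open bins [0,w), [w,2w), ..."""
    lengths = [o.aa_length for o in orfs]
    top = (max(lengths) // bin_width + 1) * bin_width if lengths else bin_width
    edges = np.arange(0, top + bin_width, bin_width)
    counts, _ = np.histogram(lengths, bins=edges)
    return LengthHistogram(edges, counts)


def find_sd(
    genome: GenomeRecord,
    orf: OrfRecord,
    window: tuple[int, int] = (-20, -4),
    consensus: str = SD_CONSENSUS,
    min_score: int = 4,
) -> Optional[SdMatch]:
    """Best identity match to the SD consensus upstream of the start codon.

    The search window is given in bases relative to the first base of the
    start codon; candidate 6-mers must lie fully inside it. Ties are broken
    towards the start codon (largest offset). Returns None when the best
    score is below min_score or the upstream sequence is too short.
    """
    w_lo, w_hi = window
    k = len(consensus)
    if orf.strand == "+":
        anchor = orf.start
        upstream_avail = anchor
    else:
        anchor = orf.end  # first base of the start codon is end-1 on '-'
        upstream_avail = genome.length - anchor
    if upstream_avail < -w_lo:
        logger.warning("%s: <%d bases upstream, SD search skipped", orf.locus_tag, -w_lo)
        return None

    best: Optional[SdMatch] = None
    # offsets of the 6-mer's first base; window fully inside [w_lo, w_hi]
    for off in range(w_lo, w_hi - k + 2):
        if orf.strand == "+":
            s = anchor + off
            window_seq = genome.sequence[s: s + k]
        else:
            # offset -d means d bases upstream along the minus strand
            s = anchor - off - k
            window_seq = reverse_complement(genome.sequence[s: s + k])
        score = sum(a == b for a, b in zip(window_seq, consensus))
        if best is None or score >= best.score:
            best = SdMatch(off, window_seq, score)
    if best is None or best.score < min_score:
        return None
    return best


def plot_length_histogram(hist: LengthHistogram, path: str, title: str = "") -> None:
    """Render a length histogram to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(hist.bin_edges[:-1], hist.counts, width=np.diff(hist.bin_edges),
           align="edge", edgecolor="black")
    ax.set_xlabel("ORF length (codons)")
    ax.set_ylabel("number of ORFs")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
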