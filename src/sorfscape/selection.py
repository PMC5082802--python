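"""Pairwise dN/dS by Nei-Gojobori (1986) counting with Jukes-Cantor correction.

Synonymous and nonsynonymous sites are counted per codon as fractions of
single-nucleotide neighbours (paths and neighbours through stop codons are
excluded); substitutions between differing codons are averaged over all
orderings of single-step mutational paths. Proportions pS = Sd/S and
pN = Nd/N are corrected for multiple hits with the Jukes-Cantor formula
d = -(3/4) ln(1 - (4/3) p), and omega = dN/dS. A ratio well below one
indicates stabilizing (purifying) selection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations
from typing import Optional

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

logger = logging.getLogger(__name__)

BASES = "ACGT"

_TABLE = unambiguous_dna_by_id[1]  # standard genetic code
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(set(CODON_TO_AA) - STOP_CODONS))


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


@dataclass
class SiteCounts:
    S_sites: float
    N_sites: float


@dataclass
class CodonAlignment:
    """A gapless pair of coding sequences, codon-aligned.

    Columns containing N or a gap character must be removed before
    construction; the number of removed columns is carried along.
    """

    seq_a: str
    seq_b: str
    removed_columns: int = 0

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences differ in length")
        if len(self.seq_a) % 3:
            raise ValueError("aligned length not divisible by 3")
        for seq, name in ((self.seq_a, "a"), (self.seq_b, "b")):
            for i in range(0, len(seq), 3):
                if is_stop(seq[i : i + 3]):
                    raise ValueError(f"internal stop codon in seq_{name} at codon {i // 3}")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    @classmethod
    def from_sequences(cls, seq_a: str, seq_b: str) -> "CodonAlignment":
        """Drop codon columns containing N or '-' pairwise, then construct."""
        if len(seq_a) != len(seq_b) or len(seq_a) % 3:
            raise ValueError("sequences must be equal length, divisible by 3")
        keep_a, keep_b, removed = [], [], 0
        for i in range(0, len(seq_a), 3):
            ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
            if set(ca + cb) - set(BASES):
                removed += 1
                continue
            keep_a.append(ca)
            keep_b.append(cb)
        return cls("".join(keep_a), "".join(keep_b), removed)


@dataclass
class DnDsResult:
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: Optional[float]
    dN: Optional[float]
    omega: Optional[float]
    status: str  # ok | ds_zero | saturated_s | saturated_n
    n_codons: int = 0


def ng86_site_counts(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts for one sense codon.

    Per position, the synonymous fraction is (synonymous single-nt
    neighbours) / (non-stop single-nt neighbours); stop neighbours are
    excluded from the denominator. A position whose neighbours are all stops
    contributes nothing.
    """
    if is_stop(codon):
        raise ValueError(f"stop codon {codon}")
    aa = CODON_TO_AA[codon]
    s = n = 0.0
    for pos in range(3):
        syn = nonstop = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            neighbour = codon[:pos] + b + codon[pos + 1 :]
            if is_stop(neighbour):
                continue
            nonstop += 1
            if CODON_TO_AA[neighbour] == aa:
                syn += 1
        if nonstop:
            s += syn / nonstop
            n += 1 - syn / nonstop
    return s, n


def ng86_subst_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) substitution counts.

    All orderings of the differing positions are enumerated; paths passing
    through a stop codon are discarded. If every path hits a stop, the count
    falls back to averaging over all paths (with a warning).
    """
    for c in (codon_a, codon_b):
        if is_stop(c):
            raise ValueError(f"stop codon {c}")
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> Optional[tuple[int, int]]:
        sd = nd = 0
        cur = codon_a
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if is_stop(nxt) and not allow_stops:
                return None
            if is_stop(nxt) or is_stop(cur):
                nd += 1  # a step into/out of a stop cannot be synonymous
            elif CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    paths = [w for order in permutations(diff) if (w := walk(order, False)) is not None]
    if not paths:
        logger.warning(
            "no stop-free path between %s and %s; averaging over all paths",
            codon_a, codon_b,
        )
        paths = [walk(order, True) for order in permutations(diff)]
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> Optional[float]:
    """JC69 distance; None outside its domain (p >= 3/4)."""
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1 - (4.0 / 3.0) * p)


def pairwise_dnds(aln: CodonAlignment) -> DnDsResult:
    """NG86 dN/dS for one aligned sequence pair."""
    if aln.n_codons == 0:
        raise ValueError("empty alignment")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(aln.seq_a), 3):
        ca, cb = aln.seq_a[i : i + 3], aln.seq_b[i : i + 3]
        sa, na = ng86_site_counts(ca)
        sb, nb = ng86_site_counts(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = ng86_subst_counts(ca, cb)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS, dN = jukes_cantor(pS), jukes_cantor(pN)
    if dS is None:
        status, omega = "saturated_s", None
    elif dN is None:
        status, omega = "saturated_n", None
    elif dS == 0.0:
        status, omega = "ds_zero", None
    else:
        status, omega = "ok", dN / dS
    return DnDsResult(S, N, Sd, Nd, pS, pN, dS, dN, omega, status, aln.n_codons)


@dataclass
class OmegaHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    excluded: dict[str, int]  # non-ok results by status


def dnds_histogram(results: list[DnDsResult], bin_width: float = 0.05) -> OmegaHistogram:
    """Histogram of omega over status-ok pairs; others tallied by status."""
    ok = [r.omega for r in results if r.status == "ok"]
    excluded: dict[str, int] = {}
    for r in results:
        if r.status != "ok":
            excluded[r.status] = excluded.get(r.status, 0) + 1
    if not ok:
        return OmegaHistogram(np.array([0.0, bin_width]), np.array([0]), excluded)
    top = (math.floor(max(ok) / bin_width) + 1) * bin_width
    edges = np.arange(0.0, top + bin_width / 2, bin_width)
    counts, _ = np.histogram(ok, bins=edges)
    return OmegaHistogram(edges, counts, excluded)


def plot_omega_histogram(hist: OmegaHistogram, path: str, title: str = "") -> None:
    """Render a dN/dS histogram to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(hist.bin_edges[:-1], hist.counts, width=np.diff(hist.bin_edges),
           align="edge", edgecolor="black")
    ax.axvline(1.0, color="red", linestyle="--", linewidth=1, label="dN/dS = 1")
    ax.set_xlabel("dN/dS")
    ax.set_ylabel("number of pairs")
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
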