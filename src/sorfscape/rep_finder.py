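"""Palindromic repeat (REP element) discovery, scanning and hairpin folding.

REP elements are short palindromic repeats occurring at many intergenic
sites; at the RNA level they fold into stem-loops. This module finds DNA
palindromes, scans a genome for mismatch-tolerant matches to an IUPAC
consensus, restricts hits to intergenic regions, derives consensuses from
copies, and validates hairpin potential by Nussinov base-pair maximization
(Watson-Crick and G.U pairs, minimum hairpin loop length enforced).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genome_io import GenomeRecord, IgrSet, reverse_complement

logger = logging.getLogger(__name__)

# the central stem-loop consensus of the first B. japonicum REP family
BR_REP1_CONSENSUS = "CCGGAATCTCGAGATTCCGG"
# printed with an internal hyphen treated as typographic; 40 nt
BR_REP2_CONSENSUS = "CGAGATTCCGGGTTCGGCTCTTCGAGCCGCCCCGGAATGA"
# the central imperfect palindrome (bold part of the printed consensus)
BR_REP2_CORE = "ATTCCGGGTTCGGCTCTTCGAGCCGCCCCGGAAT"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_CODE_FOR = {frozenset(v): k for k, v in IUPAC.items()}
_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_BASE_INDEX = {b: i for i, b in enumerate("ACGTN")}


def iupac_reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class RepeatConsensus:
    name: str
    sequence: str  # IUPAC codes permitted
    max_mismatches: int = 2
    core: Optional[tuple[int, int]] = None  # sub-interval of a shorter core motif

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 10:
            raise ValueError("consensus shorter than 10 nt")
        if self.max_mismatches >= len(self.sequence) / 4:
            raise ValueError("max_mismatches must be < length/4")
        bad = set(self.sequence) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC characters in consensus: {sorted(bad)}")


@dataclass
class PalindromeHit:
    seq_id: str
    start: int
    end: int
    arm_len: int
    loop_len: int
    arm_mismatches: int

    def __post_init__(self) -> None:
        if self.end - self.start != 2 * self.arm_len + self.loop_len:
            raise ValueError("palindrome geometry inconsistent")


@dataclass
class RepeatHit:
    seq_id: str
    start: int
    end: int
    strand: str  # +, -, or both (palindromic self-match)
    n_mismatches: int
    in_igr: Optional[bool] = None


@dataclass
class HairpinFold:
    n_pairs: int
    structure: str  # dot-bracket
    min_loop: int


def palindrome_mismatches(seq: str) -> int:
    """Arm positions i < L//2 where seq[i] does not complement seq[L-1-i].

    The centre base of an odd-length sequence is ignored. A perfect DNA
    palindrome (equal to its own reverse complement) scores 0.
    """
    rc = reverse_complement(seq.upper().replace("U", "T"))
    half = len(seq) // 2
    return sum(1 for i in range(half) if seq[i].upper() != rc[i])


def find_palindromes(
    genome: GenomeRecord,
    arm_range: tuple[int, int] = (6, 12),
    loop_range: tuple[int, int] = (3, 8),
    max_arm_mismatches: int = 1,
) -> list[PalindromeHit]:
    """All palindromic stem-loop sites within the arm/loop ranges.

    Overlapping hits sharing a centre are merged, keeping the longest useful
    arm: most net-paired positions (arm length minus mismatches), then fewest
    mismatches — extending an arm across a mismatching position adds no
    pairing, so such extensions never displace a cleaner hit. Windows
    containing N are skipped.
    """
    seq = genome.sequence
    comp = str.maketrans("ACGTN", "TGCAN")
    cseq = seq.translate(comp)
    L = len(seq)
    best_by_center: dict[tuple[int, int], PalindromeHit] = {}
    for loop in range(loop_range[0], loop_range[1] + 1):
        for arm in range(arm_range[0], arm_range[1] + 1):
            width = 2 * arm + loop
            for start in range(0, L - width + 1):
                window = seq[start : start + width]
                if "N" in window:
                    continue
                mism = 0
                for i in range(arm):
                    if window[i] != cseq[start + width - 1 - i]:
                        mism += 1
                        if mism > max_arm_mismatches:
                            break
                if mism > max_arm_mismatches:
                    continue
                center = (start + arm, start + arm + loop)  # the loop interval
                prev = best_by_center.get(center)
                key = (arm - mism, -mism, arm)
                if prev is None or key > (
                    prev.arm_len - prev.arm_mismatches,
                    -prev.arm_mismatches,
                    prev.arm_len,
                ):
                    best_by_center[center] = PalindromeHit(
                        genome.id, start, start + width, arm, loop, mism
                    )
    return sorted(best_by_center.values(), key=lambda h: (h.start, h.end))


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


_ENC_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _i in _BASE_INDEX.items():
    _ENC_LUT[ord(_b)] = _i


def _mismatch_profile(genome_idx: np.ndarray, consensus: str) -> np.ndarray:
    """Mismatch count of every window of len(consensus) against the consensus.

    Genome N never matches any consensus code (scans do not cross N).
    """
    k = len(consensus)
    n_windows = len(genome_idx) - k + 1
    if n_windows <= 0:
        return np.zeros(0, dtype=np.int32)
    allowed = np.zeros((k, 5), dtype=bool)
    for pos, code in enumerate(consensus):
        for b in IUPAC[code]:
            allowed[pos, _BASE_INDEX[b]] = True
    windows = np.lib.stride_tricks.sliding_window_view(genome_idx, k)
    match = allowed[np.arange(k)[None, :], windows]
    return (k - match.sum(axis=1)).astype(np.int32)


def scan_consensus(genome: GenomeRecord, consensus: RepeatConsensus) -> list[RepeatHit]:
    """All windows within Hamming distance max_mismatches of the consensus.

    Both strands are scanned (IUPAC-aware); forward and reverse matches of a
    palindromic consensus at the same locus merge into one hit with strand
    'both'. Hits are sorted by coordinate.
    """
    idx = _ENC_LUT[_encode(genome.sequence)].astype(np.int64)
    k = len(consensus.sequence)
    fwd = _mismatch_profile(idx, consensus.sequence)
    rev = _mismatch_profile(idx, iupac_reverse_complement(consensus.sequence))
    hits: dict[int, RepeatHit] = {}
    for start in np.flatnonzero(fwd <= consensus.max_mismatches):
        start = int(start)
        hits[start] = RepeatHit(genome.id, start, start + k, "+", int(fwd[start]))
    for start in np.flatnonzero(rev <= consensus.max_mismatches):
        start = int(start)
        if start in hits:
            prev = hits[start]
            hits[start] = RepeatHit(
                genome.id, start, start + k, "both",
                min(prev.n_mismatches, int(rev[start])),
            )
        else:
            hits[start] = RepeatHit(genome.id, start, start + k, "-", int(rev[start]))
    return [hits[s] for s in sorted(hits)]


def restrict_to_igr(hits: list[RepeatHit], igrs: IgrSet) -> tuple[list[RepeatHit], int]:
    """Mark hits fully contained in an intergenic interval; return IGR count."""
    count = 0
    for h in hits:
        if h.seq_id != igrs.seq_id:
            raise ValueError(f"hit on {h.seq_id!r} but IGRs on {igrs.seq_id!r}")
        h.in_igr = igrs.contains(h.start, h.end)
        count += h.in_igr
    return hits, count


_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"),
          ("G", "U"), ("U", "G"), ("A", "U"), ("U", "A")}


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


def nussinov_fold(seq: str, min_loop: int = 3) -> HairpinFold:
    """Maximum nested base pairing (Watson-Crick + G.U) with a loop floor.

    Deterministic traceback: at each subproblem, pairing position i with the
    largest admissible j is preferred over leaving i unpaired when both are
    optimal.
    """
    seq = seq.upper()
    L = len(seq)
    if not (5 <= L <= 200):
        raise ValueError(f"sequence length {L} outside [5, 200]")
    M = np.zeros((L, L), dtype=np.int32)
    for span in range(min_loop + 1, L):
        for i in range(0, L - span):
            j = i + span
            best = M[i + 1, j]  # i unpaired
            for kk in range(i + min_loop + 1, j + 1):
                if _can_pair(seq[i], seq[kk]):
                    inner = M[i + 1, kk - 1] if kk - 1 > i + 1 else 0
                    right = M[kk + 1, j] if kk + 1 <= j else 0
                    best = max(best, 1 + inner + right)
            M[i, j] = best

    structure = ["."] * L

    def traceback(i: int, j: int) -> None:
        if i >= j:
            return
        target = M[i, j]
        if target == 0:
            return
        for kk in range(j, i + min_loop, -1):  # largest valid j first
            if not _can_pair(seq[i], seq[kk]):
                continue
            inner = M[i + 1, kk - 1] if kk - 1 > i + 1 else 0
            right = M[kk + 1, j] if kk + 1 <= j else 0
            if 1 + inner + right == target:
                structure[i], structure[kk] = "(", ")"
                traceback(i + 1, kk - 1)
                traceback(kk + 1, j)
                return
        traceback(i + 1, j)

    traceback(0, L - 1)
    return HairpinFold(int(M[0, L - 1]), "".join(structure), min_loop)


def derive_consensus(instances: Sequence[str]) -> str:
    """Per-column majority base over aligned equal-length copies.

    Ties produce the IUPAC code covering the tied bases.
    """
    if len(instances) < 2:
        raise ValueError("need at least 2 instances")
    L = len(instances[0])
    if any(len(s) != L for s in instances):
        raise ValueError("instances differ in length")
    out = []
    for col in range(L):
        counts: dict[str, int] = {}
        for s in instances:
            b = s[col].upper()
            counts[b] = counts.get(b, 0) + 1
        top = max(counts.values())
        tied = frozenset(b for b, c in counts.items() if c == top)
        out.append(_CODE_FOR[tied] if len(tied) > 1 else next(iter(tied)))
    return "".join(out)


@dataclass
class RepeatCandidate:
    consensus: RepeatConsensus
    n_igr_occurrences: int
    palindrome_mismatches: int
    fold_pairs: int
    members: list[str] = field(default_factory=list)


def discover_repeats(
    genome: GenomeRecord,
    igrs: IgrSet,
    k: int = 20,
    min_igr_count: int = 10,
    max_merge_mismatches: int = 2,
) -> list[RepeatCandidate]:
    """Find over-represented intergenic k-mers and cluster them into families.

    k-mers occurring in >= min_igr_count distinct IGRs (both strands counted,
    a palindromic k-mer once) seed a greedy Hamming clustering; each cluster
    yields a consensus over all of its genomic occurrences.
    """
    igr_sets: dict[str, set[int]] = {}
    occurrences: dict[str, list[str]] = {}
    for igr_i, (s, e) in enumerate(igrs.intervals):
        seq = genome.sequence[s:e]
        if len(seq) < k:
            continue
        seen_here: set[str] = set()
        for off in range(len(seq) - k + 1):
            kmer = seq[off : off + k]
            if "N" in kmer:
                continue
            canon = min(kmer, reverse_complement(kmer))
            if canon not in seen_here:
                seen_here.add(canon)
                igr_sets.setdefault(canon, set()).add(igr_i)
            occurrences.setdefault(canon, []).append(
                kmer if canon == kmer else reverse_complement(kmer)
            )
    frequent = {
        km: len(igr_set)
        for km, igr_set in igr_sets.items()
        if len(igr_set) >= min_igr_count
    }
    # greedy clustering: most widespread k-mer absorbs neighbours within distance
    ordered = sorted(frequent, key=lambda km: (-frequent[km], km))
    assigned: set[str] = set()
    candidates = []
    for seed in ordered:
        if seed in assigned:
            continue
        members = [
            km for km in ordered
            if km not in assigned
            and sum(a != b for a, b in zip(seed, km)) <= max_merge_mismatches
        ]
        assigned.update(members)
        igr_count = len(set().union(*(igr_sets[m] for m in members)))
        instance_pool = [occ for m in members for occ in occurrences[m]]
        cons_seq = (
            derive_consensus(instance_pool) if len(instance_pool) >= 2 else seed
        )
        try:
            cons = RepeatConsensus(f"rep_k{k}_{len(candidates) + 1}", cons_seq)
        except ValueError:  # degenerate consensus (too many ambiguity codes)
            continue
        candidates.append(
            RepeatCandidate(
                consensus=cons,
                n_igr_occurrences=igr_count,
                palindrome_mismatches=palindrome_mismatches(
                    cons_seq.replace("N", "A")
                ) if set(cons_seq) <= set("ACGT") else -1,
                fold_pairs=nussinov_fold(cons_seq).n_pairs
                if set(cons_seq) <= set("ACGT") and 10 <= len(cons_seq) <= 200
                else -1,
                members=members,
            )
        )
    return candidates
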