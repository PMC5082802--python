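"""Homolog search and taxonomic conservation classification.

A self-contained local-alignment search (exact Smith-Waterman with
Karlin-Altschul E-values) stands in for heuristic database search at desk
scale, in nucleotide mode (both strands) and translated mode (6x6 frames,
BLOSUM62, ungapped segments by default). Hits — from the search or from
ingested hit tables — are collapsed to distinct species and classified into
conservation categories:

    NO_HOMOLOGS      found only in the query organism
    B_JAPONICUM      found only in strains of the query species
    BRADYRHIZOBIUM   confined to the genus
    ALPHA_RARE       1-4 other alphaproteobacterial species, none outside
    ALPHA_CONSERVED  >=5 other alphaproteobacterial species, none outside
    OTHER            at least one species outside Alphaproteobacteria

OTHER profiles are further split on a 2x2 grid at 20 species in / outside
Alphaproteobacteria: SPORADIC, MORE_IN_ALPHA, MORE_OUTSIDE, CONSERVED.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from scipy.optimize import brentq

from .genome_io import reverse_complement, translate

logger = logging.getLogger(__name__)

UNIFORM_DNA = {b: 0.25 for b in "ACGT"}
QUERY_ORGANISM = "Bradyrhizobium japonicum USDA 110"


@dataclass
class ScoringScheme:
    """Match/mismatch or matrix scoring with affine gaps and Karlin statistics.

    Gap penalties are positive magnitudes. ``lam`` and ``K`` parameterize
    the E-value relation E = K * m * n * exp(-lam * S).
    """

    match: int = 1
    mismatch: int = -1
    gap_open: int = 2
    gap_extend: int = 2
    lam: Optional[float] = None
    K: float = 0.1
    background: dict = field(default_factory=lambda: dict(UNIFORM_DNA))
    matrix: Optional[str] = None  # e.g. "BLOSUM62" for protein mode

    def score_pair(self, a: str, b: str) -> float:
        if self.matrix is not None:
            return float(_load_matrix(self.matrix)[a, b])
        return self.match if a == b else self.mismatch


_MATRIX_CACHE: dict = {}


def _load_matrix(name: str):
    if name not in _MATRIX_CACHE:
        _MATRIX_CACHE[name] = substitution_matrices.load(name)
    return _MATRIX_CACHE[name]


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    score: float
    evalue: float
    query_interval: tuple[int, int] = (0, 0)
    subject_interval: tuple[int, int] = (0, 0)
    identity: float = 0.0
    organism: str = ""


def smith_waterman(
    a: str, b: str, scheme: ScoringScheme, query_id: str = "a", subject_id: str = "b"
) -> AlignmentHit:
    """Optimal local alignment by dynamic programming (Gotoh affine gaps).

    Traceback is deterministic with tie order diagonal > up > left; when
    gap_extend == gap_open the recursion reduces to linear gap costs.
    """
    if not a or not b:
        raise ValueError("smith_waterman: empty sequence")
    n, m = len(a), len(b)
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (left moves)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (up moves)
    go, ge = scheme.gap_open, scheme.gap_extend
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - go, E[i, j - 1] - ge)
            F[i, j] = max(H[i - 1, j] - go, F[i - 1, j] - ge)
            diag = H[i - 1, j - 1] + scheme.score_pair(ai, b[j - 1])
            H[i, j] = max(0.0, diag, F[i, j], E[i, j])
    score = float(H.max())
    i, j = np.unravel_index(int(H.argmax()), H.shape)

    # traceback: diagonal > up > left
    qi_end, si_end = int(i), int(j)
    matches = aln_len = 0
    state = "H"
    while H[i, j] > 0 or state != "H":
        if state == "H":
            diag = H[i - 1, j - 1] + scheme.score_pair(a[i - 1], b[j - 1])
            if H[i, j] == diag:
                matches += a[i - 1] == b[j - 1]
                aln_len += 1
                i, j = i - 1, j - 1
            elif H[i, j] == F[i, j]:
                state = "F"
            elif H[i, j] == E[i, j]:
                state = "E"
            else:  # H == 0: local start
                break
        elif state == "F":
            aln_len += 1
            if F[i, j] == H[i - 1, j] - go:
                state = "H"
            i -= 1
        else:  # E
            aln_len += 1
            if E[i, j] == H[i, j - 1] - go:
                state = "H"
            j -= 1
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        score=score,
        evalue=math.nan,
        query_interval=(int(i), qi_end),
        subject_interval=(int(j), si_end),
        identity=matches / aln_len if aln_len else 0.0,
    )


def ungapped_local_score(a: str, b: str, scheme: ScoringScheme) -> float:
    """Best ungapped local segment score (diagonal-only Smith-Waterman)."""
    if not a or not b:
        raise ValueError("empty sequence")
    n, m = len(a), len(b)
    best = 0.0
    prev = np.zeros(m + 1)
    for i in range(1, n + 1):
        cur = np.zeros(m + 1)
        ai = a[i - 1]
        for j in range(1, m + 1):
            cur[j] = max(0.0, prev[j - 1] + scheme.score_pair(ai, b[j - 1]))
        best = max(best, float(cur.max()))
        prev = cur
    return best


def karlin_lambda(
    scheme: ScoringScheme, background: Optional[dict] = None
) -> float:
    """Positive root of sum_ij p_i p_j exp(lambda * s_ij) = 1.

    Requires a Karlin regime: negative expected score and a positive maximal
    score. Solved by scalar root bracketing to relative tolerance 1e-9.
    """
    bg = background or scheme.background
    letters = sorted(bg)
    p = np.array([bg[x] for x in letters])
    p = p / p.sum()
    S = np.array(
        [[scheme.score_pair(x, y) for y in letters] for x in letters], dtype=float
    )
    w = np.outer(p, p)
    expected = float((w * S).sum())
    if expected >= 0 or S.max() <= 0:
        raise ValueError("no Karlin regime: expected score must be < 0 with max > 0")

    def f(lam: float) -> float:
        return float((w * np.exp(lam * S)).sum()) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    lo = 1e-12
    return float(brentq(f, lo, hi, xtol=1e-15, rtol=1e-10))


def evalue(score: float, m: int, n: int, scheme: ScoringScheme) -> float:
    """Karlin-Altschul expected chance hits: E = K * m * n * exp(-lambda S)."""
    if scheme.lam is None:
        raise ValueError("scheme.lam not set; call karlin_lambda first")
    return scheme.K * m * n * math.exp(-scheme.lam * score)


def _six_frames(seq: str) -> list[str]:
    frames = []
    for s in (seq, reverse_complement(seq)):
        for off in (0, 1, 2):
            sub = s[off:]
            if len(sub) >= 3:
                frames.append(translate(sub))
    return frames


DEFAULT_PROTEIN_SCHEME = ScoringScheme(
    gap_open=11, gap_extend=1, K=0.1,
    background={aa: 0.05 for aa in "ACDEFGHIKLMNPQRSTVWY"},
    matrix="BLOSUM62",
)


def search_homologs(
    query: str,
    db: Sequence[tuple[str, str]],
    mode: str = "nucleotide",
    e_threshold: float = 1e-5,
    scheme: Optional[ScoringScheme] = None,
    query_id: str = "query",
    self_organism: str = QUERY_ORGANISM,
    gapped_translated: bool = False,
) -> list[AlignmentHit]:
    """Search a (organism, sequence) database for local-alignment hits.

    Nucleotide mode aligns the DNA query (both strands) against each subject;
    translated mode scores ungapped local segments between all 6 query frames
    and all 6 subject frames under BLOSUM62 (gapped optional). Hits with
    E <= e_threshold are kept; subjects from the query organism itself are
    excluded.
    """
    if not db:
        raise ValueError("empty database")
    if mode == "nucleotide":
        scheme = scheme or ScoringScheme(match=1, mismatch=-2, gap_open=4, gap_extend=2)
    elif mode == "translated":
        scheme = scheme or DEFAULT_PROTEIN_SCHEME
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if scheme.lam is None:
        scheme = replace(scheme, lam=karlin_lambda(scheme))

    hits = []
    for organism, subject in db:
        if organism == self_organism:
            continue
        if mode == "nucleotide":
            best = None
            for q in (query, reverse_complement(query)):
                h = smith_waterman(q, subject, scheme, query_id, organism)
                if best is None or h.score > best.score:
                    best = h
            best.evalue = evalue(best.score, len(query), len(subject), scheme)
            best.organism = organism
            if best.evalue <= e_threshold:
                hits.append(best)
        else:
            qframes = _six_frames(query)
            sframes = _six_frames(subject)
            best_score = 0.0
            for qf in qframes:
                for sf in sframes:
                    if not qf or not sf:
                        continue
                    if gapped_translated:
                        s = smith_waterman(qf, sf, scheme).score
                    else:
                        s = ungapped_local_score(qf, sf, scheme)
                    best_score = max(best_score, s)
            ev = evalue(best_score, len(query) // 3, len(subject) // 3, scheme)
            if ev <= e_threshold:
                hits.append(
                    AlignmentHit(query_id, organism, best_score, ev, organism=organism)
                )
    return hits


# ---------------------------------------------------------------------------
# taxonomy and classification
# ---------------------------------------------------------------------------

@dataclass
class TaxonInfo:
    species: str
    genus: str
    is_bjaponicum_strain: bool = False
    is_bradyrhizobium: bool = False
    is_alphaproteobacteria: bool = False

    def __post_init__(self) -> None:
        if self.is_bjaponicum_strain and not self.is_bradyrhizobium:
            raise ValueError(f"{self.species}: B. japonicum strain must be Bradyrhizobium")
        if self.is_bradyrhizobium and not self.is_alphaproteobacteria:
            raise ValueError(f"{self.species}: Bradyrhizobium must be alphaproteobacterial")


class TaxonomyMap(dict):
    """organism name -> TaxonInfo"""

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyMap":
        df = pd.read_csv(path, sep="\t")
        required = {
            "organism", "species", "genus",
            "is_bjaponicum_strain", "is_bradyrhizobium", "is_alphaproteobacteria",
        }
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"taxonomy table missing columns: {sorted(missing)}")
        tm = cls()
        for row in df.itertuples(index=False):
            tm[row.organism] = TaxonInfo(
                species=row.species,
                genus=row.genus,
                is_bjaponicum_strain=bool(row.is_bjaponicum_strain),
                is_bradyrhizobium=bool(row.is_bradyrhizobium),
                is_alphaproteobacteria=bool(row.is_alphaproteobacteria),
            )
        return tm


@dataclass
class DistributionProfile:
    """Distinct-species counts with at least one qualifying hit."""

    query_id: str = ""
    n_bjap_strains: int = 0
    n_bradyrhizobium_species: int = 0  # excluding B. japonicum
    n_other_alpha_species: int = 0
    n_outside_species: int = 0

    @property
    def n_alpha_total_species(self) -> int:
        # B. japonicum strains collapse to one species
        return (
            self.n_bradyrhizobium_species
            + self.n_other_alpha_species
            + (1 if self.n_bjap_strains else 0)
        )


class ConservationCategory(Enum):
    NO_HOMOLOGS = "No homologs"
    B_JAPONICUM = "B. japonicum"
    BRADYRHIZOBIUM = "Bradyrhizobium"
    ALPHA_RARE = "Alphaproteobacteria_Rare"
    ALPHA_CONSERVED = "Alphaproteobacteria_Conserved"
    OTHER = "Other"


class OtherBreakdown(Enum):
    SPORADIC = "Sporadic"
    MORE_IN_ALPHA = "More in Alphaproteobacteria"
    MORE_OUTSIDE = "More outside Alphaproteobacteria"
    CONSERVED = "Conserved"


def parse_hit_table(path: str | Path) -> pd.DataFrame:
    """Read a homolog hit table (TSV: query_id, organism, evalue, ...).

    Rows with unparsable e-values are dropped with a warning; missing
    mandatory columns are a hard error.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"query_id", "organism", "evalue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    ev = pd.to_numeric(df["evalue"], errors="coerce")
    bad = ev.isna()
    if bad.any():
        logger.warning("dropping %d row(s) with unparsable e-values", int(bad.sum()))
    df = df.loc[~bad].copy()
    df["evalue"] = ev[~bad]
    return df


def profile_distribution(
    hits: Sequence[AlignmentHit] | pd.DataFrame,
    taxonomy: TaxonomyMap,
    query_id: str = "",
) -> DistributionProfile:
    """Collapse hits to distinct species and count per taxonomic class."""
    if isinstance(hits, pd.DataFrame):
        organisms = list(hits["organism"].unique())
        if not query_id and len(hits):
            query_id = str(hits["query_id"].iloc[0])
    else:
        organisms = list({h.organism or h.subject_id for h in hits})
    unknown = [o for o in organisms if o not in taxonomy]
    if unknown:
        raise KeyError(f"organisms missing from taxonomy: {sorted(unknown)}")

    bjap_strains: set[str] = set()
    brady: set[str] = set()
    other_alpha: set[str] = set()
    outside: set[str] = set()
    for org in organisms:
        t = taxonomy[org]
        if t.is_bjaponicum_strain:
            bjap_strains.add(org)  # strains counted individually here
        elif t.is_bradyrhizobium:
            brady.add(t.species)
        elif t.is_alphaproteobacteria:
            other_alpha.add(t.species)
        else:
            outside.add(t.species)
    return DistributionProfile(
        query_id=query_id,
        n_bjap_strains=len(bjap_strains),
        n_bradyrhizobium_species=len(brady),
        n_other_alpha_species=len(other_alpha),
        n_outside_species=len(outside),
    )


def classify_category(profile: DistributionProfile) -> ConservationCategory:
    """Map a species-count profile to its conservation category."""
    p = profile
    if (
        p.n_bjap_strains == 0 and p.n_bradyrhizobium_species == 0
        and p.n_other_alpha_species == 0 and p.n_outside_species == 0
    ):
        return ConservationCategory.NO_HOMOLOGS
    if p.n_outside_species >= 1:
        return ConservationCategory.OTHER
    if p.n_other_alpha_species >= 5:
        return ConservationCategory.ALPHA_CONSERVED
    if p.n_other_alpha_species >= 1:
        return ConservationCategory.ALPHA_RARE
    if p.n_bradyrhizobium_species >= 1:
        return ConservationCategory.BRADYRHIZOBIUM
    return ConservationCategory.B_JAPONICUM


def classify_other(
    profile: DistributionProfile,
    threshold: int = 20,
    include_bradyrhizobium: bool = True,
) -> OtherBreakdown:
    """2x2 split of OTHER profiles at `threshold` species in/outside the class.

    Alphaproteobacterial counts include Bradyrhizobium species by default.
    """
    if classify_category(profile) is not ConservationCategory.OTHER:
        raise ValueError("classify_other is defined only for OTHER profiles")
    n_alpha = (
        profile.n_alpha_total_species
        if include_bradyrhizobium
        else profile.n_other_alpha_species
    )
    many_alpha = n_alpha >= threshold
    many_outside = profile.n_outside_species >= threshold
    if many_alpha and many_outside:
        return OtherBreakdown.CONSERVED
    if many_alpha:
        return OtherBreakdown.MORE_IN_ALPHA
    if many_outside:
        return OtherBreakdown.MORE_OUTSIDE
    return OtherBreakdown.SPORADIC


def compare_methods(
    nt_outside: set[str], tx_outside: set[str]
) -> dict[str, set[str]]:
    """Set comparison of query IDs flagged by two search modes."""
    return {
        "overlap": nt_outside & tx_outside,
        "nt_only": nt_outside - tx_outside,
        "tx_only": tx_outside - nt_outside,
    }
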