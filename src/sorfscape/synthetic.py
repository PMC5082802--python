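"""Synthetic genomes, gene annotations, sORF families, repeat copies and
coverage tracks with exact planted ground truth.

Defaults emulate the study system: a high-GC (0.64) bacterial chromosome,
planted small ORFs, sORF families evolved over a toy taxonomy under a
controlled dN/dS, palindromic repeat copies with controlled mismatches,
and TEX+/TEX- dRNA-seq-like coverage with Poisson background. Every
generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genome_io import FeatureRecord, GenomeRecord, compute_igrs, reverse_complement
from .homology import (
    DistributionProfile,
    TaxonInfo,
    TaxonomyMap,
    classify_category,
    ConservationCategory,
)
from .selection import BASES, CODON_TO_AA, SENSE_CODONS, is_stop
from .srna_caller import CoverageTrack

DEFAULT_GC = 0.64


@dataclass
class PlantedRepeat:
    start: int
    end: int
    n_mismatches: int
    sequence: str


@dataclass
class PlantedSrna:
    start: int  # half-open interval, internal coordinates
    end: int
    strand: str
    peak: float
    primary: bool = True


@dataclass
class PlantedTruth:
    genes: list[FeatureRecord] = field(default_factory=list)
    sorf_aa_lengths: dict[str, int] = field(default_factory=dict)
    repeats: list[PlantedRepeat] = field(default_factory=list)
    srnas: list[PlantedSrna] = field(default_factory=list)
    family_categories: dict[str, ConservationCategory] = field(default_factory=dict)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def random_codon_sequence(rng: np.random.Generator, n_codons: int, gc: float = DEFAULT_GC) -> str:
    """A random stop-free coding sequence (no terminal stop appended)."""
    codons = []
    while len(codons) < n_codons:
        c = _random_bases(rng, 3, gc)
        if not is_stop(c):
            codons.append(c)
    return "".join(codons)


def simulate_genome(
    genome_length: int,
    gc: float = DEFAULT_GC,
    gene_aa_lengths: Sequence[int] = (),
    seed: int = 0,
    seq_id: str = "synth1",
) -> tuple[GenomeRecord, list[FeatureRecord], PlantedTruth]:
    """An i.i.d. random genome with non-overlapping planted CDS features.

    Each requested gene of L amino acids occupies 3(L+1) bases (stop codon
    included), starts with ATG and ends with TAA, alternating strands.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    seq = list(_random_bases(rng, genome_length, gc))
    spans = [3 * (aa + 1) for aa in gene_aa_lengths]
    needed = sum(spans) + 20 * (len(spans) + 1)
    if needed > genome_length:
        raise ValueError(f"genes need {needed} bp, genome is {genome_length} bp")

    # lay genes left to right with random intergenic gaps
    gaps = rng.integers(20, max(21, 2 * (genome_length - sum(spans)) // (len(spans) + 1)),
                        size=len(spans) + 1) if spans else []
    while spans and sum(spans) + sum(gaps) > genome_length:
        gaps = np.maximum(20, gaps - 10)
        if (gaps == 20).all():
            break
    truth = PlantedTruth()
    features = []
    cursor = 0
    for gi, span in enumerate(spans):
        cursor += int(gaps[gi])
        start, end = cursor, cursor + span
        strand = "+" if gi % 2 == 0 else "-"
        aa = span // 3 - 1
        body = random_codon_sequence(rng, aa - 1, gc)
        cds = "ATG" + body + "TAA"
        seq[start:end] = list(cds if strand == "+" else reverse_complement(cds))
        tag = f"sg{gi + 1:04d}"
        feat = FeatureRecord(seq_id, start, end, strand, "CDS", tag,
                             {"locus_tag": tag})
        features.append(feat)
        truth.genes.append(feat)
        truth.sorf_aa_lengths[tag] = aa
        cursor = end
    genome = GenomeRecord(seq_id, "".join(seq))
    return genome, features, truth


def evolve_codon_sequence(
    seq: str, n_events: int, omega: float, seed: int | np.random.Generator = 0
) -> str:
    """Accept-reject codon evolution at a controlled dN/dS.

    Repeats until n_events substitutions are accepted: a uniformly random
    single-nucleotide change is proposed; changes creating a stop codon are
    rejected, synonymous changes are always accepted, nonsynonymous changes
    are accepted with probability omega.
    """
    if not 0 <= omega <= 1:
        raise ValueError("omega must be in [0, 1]")
    if len(seq) % 3:
        raise ValueError("length not divisible by 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = list(seq)
    accepted = 0
    while accepted < n_events:
        pos = int(rng.integers(len(s)))
        new = BASES[int(rng.integers(4))]
        if new == s[pos]:
            continue
        ci = pos - pos % 3
        old_codon = "".join(s[ci : ci + 3])
        new_codon = old_codon[: pos % 3] + new + old_codon[pos % 3 + 1 :]
        if is_stop(new_codon):
            continue
        syn = CODON_TO_AA[old_codon] == CODON_TO_AA[new_codon]
        if syn or rng.random() < omega:
            s[pos] = new
            accepted += 1
    return "".join(s)


@dataclass
class TaxonPlanEntry:
    organism: str
    taxon: TaxonInfo
    divergence_events: int


def default_taxonomy(plan: Sequence[TaxonPlanEntry]) -> TaxonomyMap:
    tm = TaxonomyMap()
    for entry in plan:
        tm[entry.organism] = entry.taxon
    return tm


def make_family(
    ancestor: str,
    taxon_plan: Sequence[TaxonPlanEntry],
    omega: float,
    seed: int = 0,
) -> tuple[dict[str, str], ConservationCategory]:
    """Evolve one sORF family over a taxon plan; return sequences + the
    conservation category the plan's taxonomic spread is designed to yield."""
    rng = np.random.default_rng(seed)
    seqs = {
        e.organism: evolve_codon_sequence(ancestor, e.divergence_events, omega, rng)
        for e in taxon_plan
    }
    # the designed category follows from the plan by the classification rules
    profile = DistributionProfile(
        n_bjap_strains=sum(e.taxon.is_bjaponicum_strain for e in taxon_plan),
        n_bradyrhizobium_species=len(
            {e.taxon.species for e in taxon_plan
             if e.taxon.is_bradyrhizobium and not e.taxon.is_bjaponicum_strain}
        ),
        n_other_alpha_species=len(
            {e.taxon.species for e in taxon_plan
             if e.taxon.is_alphaproteobacteria and not e.taxon.is_bradyrhizobium}
        ),
        n_outside_species=len(
            {e.taxon.species for e in taxon_plan
             if not e.taxon.is_alphaproteobacteria}
        ),
    )
    return seqs, classify_category(profile)


def plant_repeats(
    genome: GenomeRecord,
    features: list[FeatureRecord],
    consensus: str,
    n_copies: int,
    mismatch_rate: float = 0.0,
    igr_only: bool = True,
    seed: int = 0,
    max_mismatches: Optional[int] = None,
) -> tuple[GenomeRecord, list[PlantedRepeat]]:
    """Plant non-overlapping copies of a consensus, each with a
    Binomial(length, mismatch_rate) number of random substitutions,
    optionally capped at max_mismatches per copy."""
    rng = np.random.default_rng(seed)
    k = len(consensus)
    if igr_only:
        igrs = compute_igrs(features, genome)
        slots = [(s, e) for s, e in igrs.intervals if e - s >= k]
        if not slots:
            raise ValueError("no intergenic space to plant into")
    else:
        slots = [(0, genome.length)]
    seq = list(genome.sequence)
    planted: list[PlantedRepeat] = []
    occupied: list[tuple[int, int]] = []
    attempts = 0
    while len(planted) < n_copies:
        attempts += 1
        if attempts > 1000 * n_copies:
            raise ValueError("could not place all repeat copies without overlap")
        s, e = slots[int(rng.integers(len(slots)))]
        if e - s < k:
            continue
        start = int(rng.integers(s, e - k + 1))
        if any(start < oe and start + k > os for os, oe in occupied):
            continue
        copy = list(consensus)
        n_mut = int(rng.binomial(k, mismatch_rate))
        if max_mismatches is not None:
            n_mut = min(n_mut, max_mismatches)
        for pos in rng.choice(k, size=n_mut, replace=False):
            alternatives = [b for b in BASES if b != copy[pos]]
            copy[pos] = alternatives[int(rng.integers(3))]
        seq[start : start + k] = copy
        occupied.append((start, start + k))
        planted.append(PlantedRepeat(start, start + k, n_mut, "".join(copy)))
    planted.sort(key=lambda r: r.start)
    return GenomeRecord(genome.id, "".join(seq), genome.circular), planted


def simulate_coverage(
    genome_length: int,
    srnas: Sequence[PlantedSrna],
    background: float = 5.0,
    tex_enrichment: float = 4.0,
    seed: int = 0,
) -> dict[str, CoverageTrack]:
    """TEX+/TEX- strand-specific coverage with Poisson background.

    Each planted sRNA adds a plateau of its peak height over its extent on
    its strand in both libraries; primary 5' ends are enriched in TEX+
    (plateau multiplied by tex_enrichment in TEX+), processed ends are
    depleted instead (divided by tex_enrichment in TEX+).
    """
    rng = np.random.default_rng(seed)
    tracks = {}
    for lib in ("tex_plus", "tex_minus"):
        fwd = rng.poisson(background, genome_length).astype(float)
        rev = rng.poisson(background, genome_length).astype(float)
        tracks[lib] = CoverageTrack(fwd, rev)
    for srna in srnas:
        for lib in ("tex_plus", "tex_minus"):
            height = srna.peak
            if lib == "tex_plus":
                height = height * tex_enrichment if srna.primary else height / tex_enrichment
            arr = tracks[lib].on_strand(srna.strand)
            arr[srna.start : srna.end] += height
    return tracks
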