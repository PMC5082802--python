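import numpy as np
import pytest

from sorfscape.genome_io import FeatureRecord, GenomeRecord
from sorfscape.homology import TaxonInfo
from sorfscape.synthetic import TaxonPlanEntry


@pytest.fixture
def rng():
    return np.random.default_rng(20160)


@pytest.fixture
def tiny_genome():
    # 60 bp: gene [10, 40) on '+' (ATG + 8 codons + TAA), flanked by IGRs
    coding = "ATG" + "GCT" * 8 + "TAA"
    seq = "A" * 10 + coding + "C" * 20
    genome = GenomeRecord("chr", seq)
    features = [FeatureRecord("chr", 10, 40, "+", "CDS", "g1")]
    return genome, features


def make_taxon(species, genus="", bjap=False, brady=False, alpha=False):
    return TaxonInfo(
        species=species,
        genus=genus or species.split()[0],
        is_bjaponicum_strain=bjap,
        is_bradyrhizobium=brady or bjap,
        is_alphaproteobacteria=alpha or brady or bjap,
    )


def make_plan(n_bjap=0, n_brady=0, n_other_alpha=0, n_outside=0, events=5):
    """A taxon plan with the requested species composition."""
    plan = []
    for i in range(n_bjap):
        plan.append(TaxonPlanEntry(
            f"B. japonicum strain{i}", make_taxon("Bradyrhizobium japonicum", bjap=True), events))
    for i in range(n_brady):
        plan.append(TaxonPlanEntry(
            f"Bradyrhizobium sp{i}", make_taxon(f"Bradyrhizobium sp{i}", brady=True), events))
    for i in range(n_other_alpha):
        plan.append(TaxonPlanEntry(
            f"Rhodopseudomonas sp{i}", make_taxon(f"Rhodopseudomonas sp{i}", alpha=True), events))
    for i in range(n_outside):
        plan.append(TaxonPlanEntry(
            f"Pseudomonas sp{i}", make_taxon(f"Pseudomonas sp{i}"), events))
    return plan
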