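import pytest

from airrbench import synthetic_data as sd
from airrbench.models import GermlineAllele, ReferenceSet, SimulationConfig


@pytest.fixture(scope="session")
def reference():
    """Small germline reference with one synonym pair."""
    return sd.generate_reference_set(n_v=10, n_d=4, n_j=3, n_synonyms=1, seed=7)


@pytest.fixture(scope="session")
def plain_reference():
    """Synonym-free reference for error-rate recovery tests."""
    return sd.generate_reference_set(n_v=12, n_d=4, n_j=3, n_synonyms=0, seed=11)


@pytest.fixture(scope="session")
def small_repertoire(reference):
    config = SimulationConfig(n_base=60, n_mutated=120, seed=3)
    return sd.generate_repertoire(reference, config)


def make_reference(label, gene_names, start=0):
    """Reference set with one allele per gene and globally unique sequences."""
    alleles = []
    for i, gene in enumerate(sorted(set(gene_names))):
        # unique sequence per (label-independent) gene so nt-level identity
        # never collides across synthetic fixtures
        n = start + i
        seq = "".join("ACGT"[(n >> (2 * k)) & 3] for k in range(6)) + "ACG"
        gt = "V" if "V" in gene[:4] else ("D" if "D" in gene[:4] else "J")
        alleles.append(GermlineAllele.from_name(f"{gene}*01", gt, seq))
    return ReferenceSet(label=label, alleles=alleles)


def sets_from_regions(region_counts, prefix="IGHV1-"):
    """Build per-label gene-name lists realizing exact exclusive regions.

    ``region_counts`` maps tuples of labels to counts; returns a dict of
    label -> list of gene names.
    """
    labels = sorted({lab for region in region_counts for lab in region})
    names = {lab: [] for lab in labels}
    counter = 0
    for region, count in sorted(region_counts.items()):
        for _ in range(count):
            counter += 1
            gene = f"{prefix}{counter}"
            for lab in region:
                names[lab].append(gene)
    return names
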