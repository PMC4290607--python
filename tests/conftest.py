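import pytest

from bacpg import PlantedGene, build_pseudo_database, generate_genome
from bacpg.annotation_import import protein_index


@pytest.fixture(scope="session")
def planted_fixture():
    """A synthetic genome with planted genes on both strands.

    g1/g2 annotations cover their whole frame segment (recovered by
    same-site dedup); g3/g4 carry stop-free coding residues upstream of the
    annotated start (their segments survive as tagged elongations while
    their ORFs are same-site-dropped).
    """
    return generate_genome(
        seed=11,
        length=9000,
        planted_genes=[
            PlantedGene(40, "+"),
            PlantedGene(35, "-"),
            PlantedGene(30, "+", elongation_aa=6),
            PlantedGene(28, "-", elongation_aa=5),
        ],
    )


@pytest.fixture(scope="session")
def planted_db(planted_fixture):
    """Known + pseudo protein index for the planted-genome fixture."""
    pseudo = build_pseudo_database([planted_fixture.genome], planted_fixture.proteins)
    return protein_index(planted_fixture.proteins + pseudo)
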