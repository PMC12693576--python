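from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from gscortho import io_core, synteny, synthetic_data as sd
from gscortho._codons import CODONS_BY_AA
from gscortho.io_core import AnnotatedGenome, GeneModel, PhylogenyConfig

settings.register_profile(
    "repro",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


def encode_protein(protein: str) -> str:
    """Deterministic reverse translation (first codon of each amino acid)."""
    return "".join(CODONS_BY_AA[aa][0] for aa in protein) + "TAA"


def toy_genome(species_id: str, proteins: dict[str, str],
               spacer: int = 30) -> AnnotatedGenome:
    """Single-contig genome with one gene per supplied protein."""
    parts = ["A" * spacer]
    pos = spacer
    genes = []
    for gid in proteins:
        cds = encode_protein(proteins[gid])
        genes.append(
            GeneModel(
                gene_id=gid,
                contig_id="c1",
                start=pos,
                end=pos + len(cds),
                strand="+",
                cds_sequence=cds,
                protein_sequence=proteins[gid],
            )
        )
        parts.append(cds)
        parts.append("A" * spacer)
        pos += len(cds) + spacer
    return AnnotatedGenome(species_id=species_id, contigs={"c1": "".join(parts)},
                           genes=genes)


@pytest.fixture(scope="session")
def reference() -> AnnotatedGenome:
    return sd.random_reference(n_genes=12, n_contigs=2, seed=11)


@pytest.fixture(scope="session")
def phylo() -> PhylogenyConfig:
    return PhylogenyConfig(
        "reference",
        {"reference": 0.0, "spA": 5.0, "spB": 25.0, "spC": 50.0, "spD": 70.0},
    )


@pytest.fixture(scope="session")
def planted_events() -> list[sd.PlantedEvent]:
    return [
        sd.PlantedEvent("g003", "spB", "loss"),
        sd.PlantedEvent("g008", "spB", "split"),
        sd.PlantedEvent("g005", "spC", "contig_end"),
        sd.PlantedEvent("g010", "spC", "diverged_extreme"),
        sd.PlantedEvent("g002", "spD", "loss"),
    ]


@pytest.fixture(scope="session")
def forged(reference, phylo, planted_events):
    genomes, ledger = sd.forge_clade(
        reference, phylo, events=planted_events, seed=101
    )
    return genomes, ledger


@pytest.fixture(scope="session")
def pipeline_result(reference, forged) -> synteny.PipelineResult:
    genomes, _ = forged
    genes = [g.gene_id for g in reference.genes]
    return synteny.run_pipeline(genes, reference, genomes)
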