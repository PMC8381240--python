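"""Shared fixtures: the packaged locus catalog and a planted synthetic genome."""

import pytest

from retroloci import load_table1_catalog
from retroloci import synthetic_data as sd


@pytest.fixture(scope="session")
def table1_loci():
    return load_table1_catalog()


def make_all_class_sim(seed: int = 7, **overrides) -> sd.SimulationSpec:
    """One planted locus per (integrity class x strand), each on its own chromosome."""
    specs = []
    chrom_lengths = {}
    classes = [("ERV", c) for c in sd.ERV_INTEGRITY_CLASSES] + [
        ("LINE1", c) for c in sd.LINE1_INTEGRITY_CLASSES
    ]
    i = 0
    for strand in "+-":
        for element_class, integrity in classes:
            chrom = f"chr{i + 1}"
            chrom_lengths[chrom] = 12000
            specs.append(
                sd.PlantedLocusSpec(
                    name=f"{element_class}_{integrity}_{strand}",
                    element_class=element_class,
                    integrity_class=integrity,
                    chrom=chrom,
                    offset=500,
                    strand=strand,
                )
            )
            i += 1
    kwargs = dict(
        seed=seed,
        chrom_lengths=chrom_lengths,
        loci=tuple(specs),
        expression={s.name: 1.0 for s in specs},
        n_reads=1500,
        multimap_fraction=0.1,
        multimap3_fraction=0.05,
        paralog_pairs=(("ERV_intact_+", "ERV_intact_-"),),
        background_fraction=0.1,
    )
    kwargs.update(overrides)
    return sd.SimulationSpec(**kwargs)


@pytest.fixture(scope="session")
def planted_sim():
    return make_all_class_sim()


@pytest.fixture(scope="session")
def planted_genome(planted_sim):
    return sd.build_genome(planted_sim)


@pytest.fixture(scope="session")
def planted_reads(planted_sim, planted_genome):
    return sd.simulate_alignments(planted_sim, planted_genome.genome, planted_genome.loci)
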