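import pytest

from gapsites.synthetic_data import UniverseConfig, generate_universe

# toy chromosome with one canonical junction: exon CCCAG | intron
# GTAAGT..TTTCAG | exon GCCC; lend = 5, rstart = 28 (1-based)
TOY_SEQ = "CCCAG" + "GTAAGT" + "T" * 10 + "TTTCAG" + "GCCC"
TOY_LEND = 5
TOY_RSTART = 28


@pytest.fixture
def toy_genome():
    return {"toy": TOY_SEQ}


@pytest.fixture(scope="session")
def universe():
    """Seeded synthetic universe shared across tests (read-only)."""
    return generate_universe(UniverseConfig(n_genes=12, seed=11))


@pytest.fixture(scope="session")
def universe_paths(universe, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("universe")
    return universe.write(str(outdir))
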