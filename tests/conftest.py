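import numpy as np
import pytest

from strnano.panel import build_reference_db, fixture_genotype_alleles, fixture_panel
from strnano.simulate import Genotype, MixtureSpec


@pytest.fixture(scope="session")
def panel():
    return fixture_panel()


@pytest.fixture(scope="session")
def db(panel):
    return build_reference_db(panel)


@pytest.fixture(scope="session")
def db_by_locus(db):
    out = {}
    for rec in db:
        out.setdefault(rec.locus, []).append(rec)
    return out


@pytest.fixture(scope="session")
def genotypes():
    profiles = fixture_genotype_alleles()
    return {name: Genotype(name, alleles) for name, alleles in profiles.items()}


@pytest.fixture(scope="session")
def single_a(genotypes):
    return MixtureSpec.single(genotypes["A"])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
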