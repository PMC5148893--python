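import pytest
from hypothesis import settings, HealthCheck

from barcodesig.records import Alignment, BarcodeRecord
from barcodesig.synthdata import SyntheticSpec, as_alignment, generate

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_alignment(seqs, species=None, genus=None, locus="matK"):
    """Build a labelled alignment from bare sequence strings."""
    records = []
    for i, seq in enumerate(seqs):
        sp = species[i] if species else "Genus species"
        g = genus[i] if genus else sp.split()[0]
        records.append(
            BarcodeRecord(id=f"S{i}", genus=g, species=sp, locus=locus, seq=seq)
        )
    return Alignment(records=tuple(records))


@pytest.fixture
def toy_alignment():
    """The 4x3 alignment {ACG, ACG, ATG, TTG} used as a worked example."""
    return make_alignment(
        ["ACG", "ACG", "ATG", "TTG"],
        species=["Pa x", "Pa x", "Pb y", "Pb y"],
        genus=["Pa", "Pa", "Pb", "Pb"],
    )


@pytest.fixture(scope="session")
def clean_synthetic():
    """Noise-free planted dataset: 3 genera x 2 species x 3 sequences."""
    spec = SyntheticSpec(
        n_genera=3, species_per_genus=2, seqs_per_species=3,
        seq_len=700, planted_sites_per_species=2,
        noise_rate=0.0, indel_rate=0.0, seed=42,
    )
    records, truth = generate(spec)
    return spec, records, truth


@pytest.fixture(scope="session")
def clean_alignment(clean_synthetic):
    _, records, _ = clean_synthetic
    return as_alignment(records)
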