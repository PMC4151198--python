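import pytest

from pepselect import DigestionParams, FixtureSpec, build_index
from pepselect.fixtures import generate_records

# Build params used by most index-level tests: full digest of a small
# synthetic proteome pair, clean tryptic fragments.
BUILD_PARAMS = DigestionParams(enzyme="trypsin", max_missed_cleavages=0,
                               min_peptide_length=3)

SMALL_SPEC = FixtureSpec(seed=11, n_proteins_fg=6, n_proteins_bg=6,
                         mean_protein_length=120, n_planted_unique=12,
                         shared_fragment_fraction=0.3, feature_density=0.8)


@pytest.fixture(scope="session")
def proteome_pair():
    """(fg_records, bg_records, truth) for a small synthetic pair."""
    return generate_records(SMALL_SPEC)


@pytest.fixture(scope="session")
def fg_index(proteome_pair):
    fg, _, _ = proteome_pair
    return build_index(fg, BUILD_PARAMS, "fg-test")


@pytest.fixture(scope="session")
def bg_index(proteome_pair):
    _, bg, _ = proteome_pair
    return build_index(bg, BUILD_PARAMS, "bg-test")
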