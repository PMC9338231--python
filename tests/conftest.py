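import pytest

from flymplex import SPECIES, load_panel
from flymplex.fixtures import FixtureSpec, synth_duplex_template, synth_template


@pytest.fixture(scope="session")
def panel():
    return load_panel("builtin:table1")


@pytest.fixture(scope="session")
def species_templates(panel):
    """One seeded synthetic template per panel species (seeds 1..5)."""
    return {
        sp: synth_template(panel.entry(sp), FixtureSpec(seed=i + 1), panel)
        for i, sp in enumerate(SPECIES)
    }


@pytest.fixture(scope="session")
def duplex_template(panel):
    """Cosyra template carrying the cross-amplifying quilicii cassette."""
    return synth_duplex_template(
        panel.entry("cosyra"), panel.entry("quilicii"), FixtureSpec(seed=7), panel
    )
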