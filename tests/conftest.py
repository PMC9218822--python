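"""Shared fixtures: small synthetic proteins and search configurations."""

from __future__ import annotations

import pytest

from propamp.config import RunConfig
from propamp.profiles import SearchConfig
from propamp.simulate import (EvolutionSpec, amplify_and_diverge,
                              make_ancestral_blade)


@pytest.fixture(scope="session")
def search_config() -> SearchConfig:
    return SearchConfig(rng_seed=11)


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig(rng_seed=11)


@pytest.fixture(scope="session")
def seven_blade():
    """A 7-blade propeller protein at ~90% blade identity, with truth."""
    spec = EvolutionSpec(blade_length_aa=42, n_blades=7,
                         per_site_sub_rate=0.05, rng_seed=31)
    blade = make_ancestral_blade(spec)
    protein, orf, truth = amplify_and_diverge(blade, spec,
                                              protein_id="seven")
    return {"spec": spec, "blade": blade, "protein": protein, "orf": orf,
            "truth": truth}
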