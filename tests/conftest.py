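import pytest

from cyclogic.dosage import DosageSpec
from cyclogic.engine import SimulationConfig, growth_rate, simulate, \
    wild_type_period
from cyclogic.logic_model import make_toy_model
from cyclogic.phases import _profile_from_summary
from cyclogic.yeast import load_extended_model


@pytest.fixture(scope="session")
def yeast():
    """The packaged extended cell-cycle model (parsed from the JSON)."""
    return load_extended_model()


@pytest.fixture(scope="session")
def yeast_wt_period(yeast):
    return wild_type_period(yeast)


@pytest.fixture(scope="session")
def ring6():
    return make_toy_model("ring-oscillator", 6)


@pytest.fixture(scope="session")
def toggle2():
    return make_toy_model("toggle", 2)


@pytest.fixture(scope="session")
def mc_config():
    """Monte-Carlo configuration used by the dosage-series checks.

    One replicate block of 256, two thousand steps: enough cycles per
    replicate for stable occupancies while keeping the suite quick.
    """
    return SimulationConfig(n_steps=2000, n_replicates=256, seed=20_260_131)


@pytest.fixture(scope="session")
def yeast_runner(yeast, yeast_wt_period, mc_config):
    """Memoised (gene, dose) -> (summary, growth, profile-raw) runner."""
    cache = {}
    wt_summary = simulate(yeast, DosageSpec(), mc_config)
    wt_profile = _profile_from_summary(wt_summary, None)

    def run(gene, dose):
        key = (gene, dose)
        if key not in cache:
            dosage = DosageSpec({gene: dose})
            summary = simulate(yeast, dosage, mc_config)
            growth = growth_rate(yeast, dosage, mc_config,
                                 wt_period=yeast_wt_period, summary=summary)
            profile = _profile_from_summary(summary, wt_profile.raw_fraction)
            cache[key] = (growth, profile)
        return cache[key]

    run.wt_profile = wt_profile
    return run
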