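import pytest

import frugalnpzd as f
from frugalnpzd.simulate import Grid

# Shared long runs: built once per session and reused by the diagnostic,
# experiment and acceptance tests.  Four years (one discarded as
# spin-up) is enough for stable climatological statistics at desk scale.
TWIN_YEARS = 4


@pytest.fixture(scope="session")
def column_twins():
    """Twin 1-D runs (redfield vs lof) for both open-sea scenarios."""
    out = {}
    for site in ("siteA", "siteB"):
        for stoich in ("redfield", "lof"):
            cfg = f.RunConfig(scenario=site, stoichiometry=stoich,
                              years=TWIN_YEARS, seed=0)
            out[(site, stoich)] = f.run(cfg)
    return out


@pytest.fixture(scope="session")
def box_runs_8y():
    """Closed 0-D box runs, 8 simulated years, for conservation audits."""
    out = {}
    for stoich, fixation in (("redfield", False), ("lof", False), ("lof", True)):
        cfg = f.RunConfig(scenario="siteA", stoichiometry=stoich, years=8,
                          dt=0.1, grid=Grid.box(20.0),
                          nitrogen_fixation=fixation, save_interval=5.0)
        out[(stoich, fixation)] = f.run(cfg)
    return out
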