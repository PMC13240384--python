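import numpy as np
import pytest

from pgtm.simulate import (
    CUL3_VARIANT,
    SimScenario,
    make_cohort_fixture,
    observe_direct_test,
    observe_genotypes,
    simulate_family,
)
from pgtm.types import SEA_DELETION, RunConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def config():
    return RunConfig(seed=1)


@pytest.fixture(scope="session")
def cohort_bundles():
    """Packaged three-family regression fixture (deterministic)."""
    return make_cohort_fixture()


def make_dominant_family(seed: int, n_markers: int = 30, n_embryos: int = 4,
                         ado: float = 0.05, err: float = 0.01,
                         force_proband_carrier: bool = True):
    """A paternal-dominant family with the first embryo forced to carry the
    variant (so it can serve as proband), plus its noisy observations."""
    rng = np.random.default_rng(seed)
    forced = {0: (0, None)} if force_proband_carrier else {}
    scn = SimScenario(variant=CUL3_VARIANT, n_markers=n_markers,
                      n_embryos=n_embryos, ado_rate=ado, genotype_error=err,
                      forced_transmission=forced)
    truth = simulate_family(scn, rng)
    genotypes = observe_genotypes(truth, ado, err, rng)
    direct = {e.embryo_id: observe_direct_test(truth, e, rng)
              for e in truth.embryos}
    return truth, genotypes, direct


def make_recessive_family(seed: int, n_markers: int = 40, n_inside: int = 4,
                          n_embryos: int = 4, ado: float = 0.0, err: float = 0.0,
                          proband_origin: str = "father"):
    """A both-carrier deletion family whose first embryo is a carrier of the
    requested parental origin."""
    rng = np.random.default_rng(seed)
    forced = {0: (0, 1) if proband_origin == "father" else (1, 0)}
    scn = SimScenario(variant=SEA_DELETION, n_markers=n_markers,
                      n_inside_markers=n_inside, n_embryos=n_embryos,
                      ado_rate=ado, genotype_error=err,
                      forced_transmission=forced)
    truth = simulate_family(scn, rng)
    genotypes = observe_genotypes(truth, ado, err, rng)
    direct = {e.embryo_id: observe_direct_test(truth, e, rng)
              for e in truth.embryos}
    return truth, genotypes, direct
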