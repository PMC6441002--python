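import numpy as np
import pandas as pd
import pytest

from foodwebsem import FoodWeb, niche_model_web, parse_model_spec
from foodwebsem.synthgen import unit_variance_theta


def make_web(web_id, links, extra_taxa=()):
    taxa = []
    for c, r in links:
        for t in (c, r):
            if t not in taxa:
                taxa.append(t)
    taxa.extend(t for t in extra_taxa if t not in taxa)
    return FoodWeb(web_id=web_id, taxa=tuple(taxa), links=frozenset(links))


@pytest.fixture
def chain_web():
    """A <- B <- C: B eats A, C eats B."""
    return make_web("chain", [("B", "A"), ("C", "B")])


@pytest.fixture
def omnivore_web():
    """A basal; B eats A; C eats A and B (an omnivore at level 2.5)."""
    return make_web("omni", [("B", "A"), ("C", "A"), ("C", "B")])


@pytest.fixture(scope="session")
def random_niche_webs():
    """100 small niche-model webs (S <= 50) shared across property tests."""
    rng = np.random.default_rng(20240901)
    webs = []
    for k in range(100):
        S = int(rng.integers(10, 51))
        C = float(rng.uniform(0.06, 0.25))
        webs.append(niche_model_web(S, C, seed=int(rng.integers(0, 2**31 - 1))))
    return webs


@pytest.fixture(scope="session")
def mediation_model():
    """A 4-variable recursive model with all paths in {+-0.3, +-0.5} on the
    standardized scale (residual variances chosen for unit variances)."""
    spec = parse_model_spec("m ~ x\nw ~ x + m\ny ~ x + m + w")
    paths = {
        ("m", "x"): 0.5,
        ("w", "x"): -0.3,
        ("w", "m"): 0.5,
        ("y", "x"): 0.3,
        ("y", "m"): -0.5,
        ("y", "w"): 0.3,
    }
    theta = unit_variance_theta(spec, paths)
    return spec, paths, theta


def frame(X, spec):
    return pd.DataFrame(X, columns=list(spec.variables))
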