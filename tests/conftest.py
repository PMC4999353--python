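"""Shared fixtures: the default phantom and plans are expensive, so they
are built once per session and reused across modules."""

import numpy as np
import pytest

from afplan import delivery as dlv
from afplan import planner as pln
from afplan.dose_engine import make_nodes
from afplan.phantom import PhantomSpec, generate_phantom

DEFAULT_SEED = 42


@pytest.fixture(scope="session")
def default_phantom():
    """Default two-target phantom, favorable esophagus position, probe on
    the chest (the probe does not alter any other structure)."""
    spec = PhantomSpec(seed=DEFAULT_SEED, esophagus_class="central-away", with_probe=True)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def structures(default_phantom):
    return default_phantom[1]


@pytest.fixture(scope="session")
def nodes(structures):
    centroid = structures.ptv_combined.centers_mm().mean(axis=0)
    return make_nodes(100, centroid)


@pytest.fixture(scope="session")
def prescription():
    return pln.Prescription()


@pytest.fixture(scope="session")
def constraints():
    return pln.ConstraintSet()


@pytest.fixture(scope="session")
def candidates(nodes, structures):
    return pln.generate_candidates(nodes, structures, seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_plan(candidates, structures, prescription, constraints):
    return pln.optimize_mu(
        candidates, structures, prescription, constraints, seed=DEFAULT_SEED
    )


@pytest.fixture(scope="session")
def default_timeline(default_plan):
    return dlv.build_timeline(default_plan, dlv.TimelineParams())


@pytest.fixture(scope="session")
def divided_delivery(nodes, structures, prescription, constraints):
    """Jointly optimized divided-node-set plan, sequenced R then L."""
    cands = pln.generate_candidates(
        nodes, structures, sectors=pln.DIVIDED_SECTORS, seed=DEFAULT_SEED
    )
    plan = pln.optimize_mu(
        cands, structures, prescription, constraints, seed=DEFAULT_SEED, mode="divided"
    )
    plan_R, plan_L = dlv.split_by_target(plan)
    combined, timeline = dlv.sequence_divided(plan_R, plan_L, dlv.TimelineParams())
    combined.coverage = plan.coverage
    return combined, timeline


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
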