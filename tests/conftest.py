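import numpy as np
import pytest

import nicholson as nc


def constant_model(alpha=1.0, beta=(0.5,), gamma=(1.0,), tau=(1.0,), t0=0.0):
    """Constant-coefficient blowflies model, tau_max = max delay."""
    betas = [nc.TimeFunction.constant(b) for b in beta]
    gammas = [nc.TimeFunction.constant(g) for g in gamma]
    taus = [nc.TimeFunction.constant(d) for d in tau]
    return nc.NicholsonModel(
        alpha=nc.TimeFunction.constant(alpha), betas=betas, gammas=gammas,
        taus=taus, tau_max=float(max(tau)), t0=t0, label="constant",
    )


def flat_history(model, value=1.0):
    return nc.InitialHistory(model.t0, lambda s: value, model.tau_max)


@pytest.fixture(scope="session")
def decay_model():
    """beta = 0: pure linear decay x' = -x with closed-form solution."""
    return constant_model(alpha=1.0, beta=(0.0,))


@pytest.fixture(scope="session")
def eq9():
    return nc.make_paper_fixture("eq9")


@pytest.fixture(scope="session")
def eq21():
    return nc.make_paper_fixture("eq21")


@pytest.fixture(scope="session")
def eq21_report(eq21):
    model, _ = eq21
    return nc.check_assumptions(model)


@pytest.fixture(scope="session")
def eq21_trajectory(eq21):
    model, history = eq21
    return nc.simulate(model, history, nc.SolverConfig(step=0.01, horizon=50.0))


@pytest.fixture(scope="session")
def eq9_trajectory(eq9):
    model, history = eq9
    return nc.simulate(model, history, nc.SolverConfig(step=0.01, horizon=40.0))


def synthetic_draw(seed, p=None, c=None):
    """Seeded admissible draw from the test family with ratio < 1."""
    rng = np.random.default_rng(seed)
    if p is None:
        p = float(rng.uniform(0.5, 1.0))
    if c is None:
        n = int(rng.integers(1, 3))
        total = float(rng.uniform(0.1, 0.9))
        weights = rng.dirichlet(np.ones(n))
        c = list(total * weights)
    return nc.generate_synthetic_model(p=p, c=c, seed=int(seed))
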