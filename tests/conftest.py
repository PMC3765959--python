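import numpy as np
import pytest

import cpgdyad as cd


@pytest.fixture(scope="session")
def default_panel():
    return cd.build_default_panel(seed=0)


@pytest.fixture(scope="session")
def standard_schedules():
    from cpgdyad.kinetics import default_schedules

    return default_schedules("demethylating_standard")


@pytest.fixture(scope="session")
def twoi_timecourse(default_panel):
    """Exact-mode 2i time course on the default grid (shared, read-only)."""
    return cd.simulate_timecourse(
        default_panel.locus_params(), [0, 24, 72, 168, 264, 576], mode="exact"
    )


def strand_recursion(m, h, rho_m, rho_h, kappa, delta):
    """Independent closed-form oracle for one division."""
    u = 1.0 - m - h
    qh = h + kappa * m
    m2 = ((1 - kappa) * m * (1 + rho_m) + rho_h * qh + delta * u) / 2.0
    return m2, qh / 2.0


@pytest.fixture(scope="session")
def oracle_strand_recursion():
    return strand_recursion


def random_distribution(rng) -> cd.DyadDistribution:
    p = rng.dirichlet(np.ones(9))
    return cd.DyadDistribution(p)
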