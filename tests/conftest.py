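"""Shared fixtures.

The expensive simulations (replica pulls, free-diffusion capture) are
session-scoped so the steered-pull curves are computed once and shared
between the module tests and the acceptance checks.
"""
from __future__ import annotations

import warnings

import numpy as np
import pytest

from pistack.dynamics import IntegratorConfig, run_free_md
from pistack.model import SimSystem
from pistack.smd import SMDConfig, run_smd
from pistack.structures import build_pah
from pistack.workflow import optimal_dimer, smd_binding_energy

PULL_K = 4.0  # kcal/(mol*A^2)
PULL_V = 0.01  # A/ps


@pytest.fixture(scope="session")
def anthracene():
    return build_pah("anthracene")


@pytest.fixture(scope="session")
def benzene():
    return build_pah("benzene")


@pytest.fixture(scope="session")
def anthracene_opt():
    """Force-field-optimal stacked anthracene dimer + its direct binding energy."""
    return optimal_dimer("anthracene")


def _cold_pull(opt, velocity):
    com0 = opt.system.com_separation()
    duration = (11.5 - com0 + 2.0) / velocity
    return run_smd(
        opt.system,
        SMDConfig(k_spring=PULL_K, pull_velocity=velocity),
        IntegratorConfig(thermostat="none"),
        duration,
        replicas=[None],
    )[0]


@pytest.fixture(scope="session")
def cold_curves(anthracene_opt):
    """Deterministic (start-at-rest) pulls of the anthracene dimer at three speeds."""
    return {v: _cold_pull(anthracene_opt, v) for v in (0.005, 0.01, 0.05)}


@pytest.fixture(scope="session")
def anthracene_replicas():
    """Four thermally seeded pulls of the anthracene dimer (seeds 1-4)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return smd_binding_energy("anthracene", seeds=(1, 2, 3, 4))


@pytest.fixture(scope="session")
def phenanthrene_replicas():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return smd_binding_energy("phenanthrene", seeds=(1, 2, 3, 4))


@pytest.fixture(scope="session")
def dimerization_run(anthracene):
    """Free-diffusion capture run: two monomers 15 A apart in a droplet."""
    a = anthracene.translated([-7.5, 0.0, 0.0])
    b = anthracene.translated([7.5, 0.0, 0.0])
    b.name = "anthracene_2"
    cfg = IntegratorConfig(thermostat="langevin", temperature=300.0, friction=1.0, seed=42)
    return run_free_md(
        SimSystem([a, b]),
        cfg,
        5000.0,
        record_every=1.0,
        confine_radius=25.0,
        stop_when=lambda s: s.com_separation() < 6.0,
    )
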