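"""Shared fixtures.

Heavy objects (phantom pairs, optimized plans) are session-scoped.  Most
tests run on a reduced 48-voxel phantom; the clinical acceptance-surface and
registration-QA tests use the default 96-voxel phantom.
"""

from __future__ import annotations

import numpy as np
import pytest

from posture4d.dose import DepthDoseTable, compute_dose
from posture4d.phantom import PhantomConfig, generate_phantom_pair
from posture4d.planning import (
    OptimizationSettings,
    Prescription,
    Scenario,
    make_plan,
    scenario_set,
)


def small_config(**overrides) -> PhantomConfig:
    base = dict(
        shape=(48, 48, 48),
        spacing_supine=(4.0, 4.0, 4.0),
        spacing_upright=(4.0, 4.0, 4.8),
        target_volume_cc=12.0,
        seed=20240915,
    )
    base.update(overrides)
    return PhantomConfig(**base)


@pytest.fixture(scope="session")
def table() -> DepthDoseTable:
    return DepthDoseTable.default()


@pytest.fixture(scope="session")
def rx() -> Prescription:
    return Prescription()


@pytest.fixture(scope="session")
def small_pair():
    return generate_phantom_pair(small_config())


@pytest.fixture(scope="session")
def small_phantom(small_pair):
    return small_pair.supine


@pytest.fixture(scope="session")
def small_plan(small_phantom, table, rx):
    """Quick nominal-only plan on the small phantom (property tests)."""
    ph = small_phantom
    return make_plan(
        ph.posture, ph.reference, ph.grid, table, ph.masks["itv"],
        {"lung": ph.lungs, "heart": ph.masks["heart"]}, (225.0, 315.0), rx,
        scenarios=[Scenario("nominal")], settings=OptimizationSettings(),
        max_iter=300, strict=False,
    )


@pytest.fixture(scope="session")
def small_robust_plan(small_phantom, table, rx):
    ph = small_phantom
    return make_plan(
        ph.posture, ph.reference, ph.grid, table, ph.masks["itv"],
        {"lung": ph.lungs, "heart": ph.masks["heart"]}, (225.0, 315.0), rx,
        scenarios=scenario_set(3.0, 0.035), settings=OptimizationSettings(),
        max_iter=300, strict=False,
    )


@pytest.fixture(scope="session")
def default_pair():
    return generate_phantom_pair(PhantomConfig())


@pytest.fixture(scope="session")
def default_plan(default_pair, table, rx):
    """Fully converged robust plan on the default supine phantom."""
    ph = default_pair.supine
    return make_plan(
        ph.posture, ph.reference, ph.grid, table, ph.masks["itv"],
        {"lung": ph.lungs, "heart": ph.masks["heart"]}, (225.0, 315.0), rx,
        scenarios=scenario_set(3.0, 0.035), settings=OptimizationSettings(),
    )


def static_dose(plan, phantom, table):
    return compute_dose(
        phantom.reference, phantom.grid, plan.spotsets, table,
        overrides=[(phantom.masks["itv"], 70.0)], roi_mask=phantom.masks["body"],
    )
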