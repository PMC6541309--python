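"""Shared fixtures.

Expensive objects (ground-truth models, their normalization currents,
the virtual population) are session-scoped: many tests reuse the same
holding/rheobase searches instead of re-running them.
"""
from __future__ import annotations

import numpy as np
import pytest

from tcneuron.cell import (
    Morphology,
    Section,
    SimConfig,
    build_cell,
    default_parameter_vector,
)
from tcneuron.stimuli import V_BURST, V_TONIC, find_holding, find_rheobase, make_battery
from tcneuron.synthetic_data import FAST_OBJECTIVES, make_ground_truth, make_population

POP_SEED = 3


def sphere_morphology(diam_um: float = 30.0, name: str = "sphere") -> Morphology:
    soma = Section("soma", np.zeros((1, 3)), np.array([diam_um]), parent=-1)
    return Morphology([soma], name=name)


def leak_only_cell(gleak: float = 1e-4, diam_um: float = 30.0):
    """Single compartment carrying only the leak current."""
    from tcneuron.cell.model import RegionDistribution, ParameterVector

    dist = RegionDistribution({
        "soma": [("leak", "gleak.s")],
        "dend": [("leak", "gleak.s")],
        "axon": [("leak", "gleak.s")],
    })
    pv = ParameterVector(["gleak.s", "gamma_Ca", "tau_Ca"],
                         np.array([gleak, 0.005, 80.0]),
                         np.array([1e-7, 0.001, 20.0]),
                         np.array([1.0, 0.05, 300.0]))
    return build_cell(sphere_morphology(diam_um), dist=dist, params=pv,
                      expected_count=None, add_axon_stub=False)


@pytest.fixture(scope="session")
def gt_cnad():
    return make_ground_truth("cNAD_ltb")


@pytest.fixture(scope="session")
def gt_cad():
    return make_ground_truth("cAD_ltb")


@pytest.fixture(scope="session")
def cnad_cell(gt_cnad):
    return gt_cnad.build(reduced=True)


@pytest.fixture(scope="session")
def cad_cell(gt_cad):
    return gt_cad.build(reduced=True)


@pytest.fixture(scope="session")
def cnad_norm(cnad_cell):
    """(i_hold_tonic, i_hold_burst, i_thr) of the reduced cNAD model."""
    ih_t = find_holding(cnad_cell, V_TONIC)
    ih_b = find_holding(cnad_cell, V_BURST)
    thr = find_rheobase(cnad_cell, ih_t)
    return ih_t, ih_b, thr


@pytest.fixture(scope="session")
def cad_norm(cad_cell):
    ih_t = find_holding(cad_cell, V_TONIC)
    ih_b = find_holding(cad_cell, V_BURST)
    thr = find_rheobase(cad_cell, ih_t)
    return ih_t, ih_b, thr


@pytest.fixture(scope="session")
def cnad_battery(cnad_norm):
    ih_t, ih_b, thr = cnad_norm
    return make_battery(thr, ih_t, ih_b)


@pytest.fixture(scope="session")
def cnad_population(gt_cnad):
    return make_population(gt_cnad, n=10, jitter=0.15, seed=POP_SEED,
                           objectives=FAST_OBJECTIVES)


@pytest.fixture(scope="session")
def cad_population(gt_cad):
    return make_population(gt_cad, n=10, jitter=0.15, seed=POP_SEED,
                           objectives=FAST_OBJECTIVES)
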