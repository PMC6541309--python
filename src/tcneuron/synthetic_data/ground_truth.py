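"""Bundled ground-truth e-models.

One frozen, versioned parameter set per e-type (cNAD_ltb / cAD_ltb),
each paired with a compact synthetic reference morphology generated
deterministically from a stored seed.  The sets were tuned by hand
against the qualitative phenomenology of relay cells — tonic firing
from depolarized holding, a low-threshold burst from hyperpolarized
holding, silence at rest and on holding — and those properties are
re-verified by simulation in the test suite.

The reference morphology is deliberately compact (about 24 terminal
tips instead of the 58-92 of the default population generator) so that
verification, optimization and sensitivity runs on the full cable
model stay fast; its radial extent and first branch point are inside
the measured TC ranges.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, Optional

import yaml

from ..cell.model import (
    CellModel,
    ParameterVector,
    SimConfig,
    build_cell,
    default_parameter_vector,
    single_compartment_reduction,
)
from ..cell.morphology import Morphology
from .morphologies import MorphologyParams, make_morphology

__all__ = ["GroundTruthModel", "make_ground_truth", "ETYPES", "COMPACT_MORPHOLOGY_PARAMS"]

ETYPES = ("cNAD_ltb", "cAD_ltb")

COMPACT_MORPHOLOGY_PARAMS = MorphologyParams(
    target_tips_range=(20.0, 24.0), extent_range=(122.0, 140.0)
)


@dataclass
class GroundTruthModel:
    """A fully specified reference model with both firing modes."""

    etype: str
    params: ParameterVector
    morphology: Morphology
    config: SimConfig

    def build(self, reduced: bool = False) -> CellModel:
        """Instantiate the cell; ``reduced=True`` gives the
        single-compartment surrogate used for fast runs."""
        cell = build_cell(self.morphology, params=self.params, cfg=self.config)
        return single_compartment_reduction(cell) if reduced else cell


def make_ground_truth(etype: str = "cNAD_ltb",
                      cfg: Optional[SimConfig] = None) -> GroundTruthModel:
    """Load the frozen ground-truth model for one e-type."""
    if etype not in ETYPES:
        raise ValueError(f"etype must be one of {ETYPES}, got {etype!r}")
    ref = resources.files("tcneuron.synthetic_data") / "data" / f"ground_truth_{etype}.yaml"
    doc = yaml.safe_load(ref.read_text())
    values: Dict[str, float] = {k: float(v) for k, v in doc["parameters"].items()}
    params = default_parameter_vector(values)
    morph = make_morphology(int(doc["morphology_seed"]),
                            params=COMPACT_MORPHOLOGY_PARAMS,
                            name=f"gt_{etype}")
    return GroundTruthModel(etype=doc["etype"], params=params, morphology=morph,
                            config=cfg or SimConfig())
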