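"""Loading of channel definition files.

Channel kinetics are shipped as YAML files (one per mechanism) under
``tcneuron/channels/data``.  Users can load modified copies from any
path; the engine is fully data-driven.
"""
from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, Optional, Union

import yaml

from .spec import ChannelSpec, GateSpec

__all__ = ["load_channel", "load_channel_file", "default_channels", "CHANNEL_IDS"]

CHANNEL_IDS = ("NaT", "Kd", "NaP", "KA", "CaT", "CaL", "SK", "h", "leak")


def _spec_from_dict(doc: Dict) -> ChannelSpec:
    gates = [
        GateSpec(
            name=g["name"],
            exponent=int(g["exponent"]),
            form=g["form"],
            params=g.get("params", {}),
            tau_floor=float(g.get("tau_floor", 1e-3)),
        )
        for g in doc.get("gates", [])
    ]
    return ChannelSpec(
        id=doc["id"],
        ion=doc["ion"],
        conduction=doc["conduction"],
        gates=gates,
        q10=float(doc.get("q10", 1.0)),
        t_ref=float(doc.get("t_ref", 34.0)),
        terms=doc.get("terms"),
    )


def load_channel_file(path: Union[str, Path]) -> ChannelSpec:
    """Load one channel definition from a YAML file on disk."""
    with open(path) as fh:
        return _spec_from_dict(yaml.safe_load(fh))


def load_channel(channel_id: str) -> ChannelSpec:
    """Load one of the bundled default channel definitions."""
    ref = resources.files("tcneuron.channels") / "data" / f"{channel_id}.yaml"
    return _spec_from_dict(yaml.safe_load(ref.read_text()))


def default_channels(ids: Optional[Iterable[str]] = None) -> Dict[str, ChannelSpec]:
    """Load the bundled channel set as a dict keyed by channel id."""
    return {cid: load_channel(cid) for cid in (ids or CHANNEL_IDS)}
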