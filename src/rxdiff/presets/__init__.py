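"""Registry of ready-to-run example systems.

Each preset is a complete, validated :class:`~rxdiff.model.SimulationConfig`
shipped as a JSON document (identical schema to user configs) plus a
provenance note recording the literature formulation the parameters follow.
The registry spans the classic teaching systems (heat, inhomogeneous wave,
Fisher-KPP, Allee invasion), pattern formation (Gray-Scott,
Gierer-Meinhardt, Brusselator, Swift-Hohenberg, Keller-Segel chemotaxis),
spatiotemporal dynamics (KdV solitons, Kuramoto-Sivashinsky chaos,
Cahn-Hilliard coarsening, Klausmeier vegetation stripes, cyclic
Lotka-Volterra spirals, FitzHugh-Nagumo waves) and Perona-Malik image
denoising.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from ..model import SimulationConfig

__all__ = ["PresetEntry", "get_preset", "get_entry", "list_presets", "PRESET_IDS"]

PRESET_IDS = (
    "heat",
    "wave_inhomogeneous",
    "kdv",
    "keller_segel",
    "gray_scott",
    "gierer_meinhardt",
    "fisher_kpp",
    "allee_invasion",
    "swift_hohenberg",
    "cahn_hilliard",
    "kuramoto_sivashinsky",
    "klausmeier",
    "cyclic_lv",
    "perona_malik",
    "brusselator",
    "fitzhugh_nagumo",
)


@dataclass(frozen=True)
class PresetEntry:
    id: str
    title: str
    provenance: str
    config: SimulationConfig


def _load(preset_id: str) -> dict:
    ref = resources.files(__package__).joinpath(f"data/{preset_id}.json")
    return json.loads(ref.read_text())


def get_entry(preset_id: str) -> PresetEntry:
    """Full registry entry (config plus provenance note)."""
    if preset_id not in PRESET_IDS:
        raise KeyError(
            f"unknown preset {preset_id!r}; available: {', '.join(PRESET_IDS)}"
        )
    doc = _load(preset_id)
    return PresetEntry(
        id=preset_id,
        title=doc["title"],
        provenance=doc["provenance"],
        config=SimulationConfig.from_dict(doc["config"]),
    )


def get_preset(preset_id: str) -> SimulationConfig:
    """A fresh config for the given preset id."""
    return get_entry(preset_id).config


def list_presets() -> list[tuple[str, str, str]]:
    """(id, title, provenance) rows in stable registry order."""
    out = []
    for pid in PRESET_IDS:
        doc = _load(pid)
        out.append((pid, doc["title"], doc["provenance"]))
    return out
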