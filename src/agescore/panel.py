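"""Marker panel: which readout feeds each marker, its hallmark category,
its expected direction with age, and the statistical test family.

The default panel is the ten-marker set used for the progerin-induced
microglia study: three primary hallmarks (DNA-damage foci up, H3K9Me3
down, telomere content down) and seven antagonistic hallmarks (p21 up,
p16 up, SA-βGal up, IL-6 up, IL-8 up, Lamin B1 down, nucleus area up).
Panels are data-driven YAML so alternative marker sets need no code
changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["MarkerDefinition", "Panel", "load_panel", "default_panel"]

READOUTS = (
    "foci_count",
    "ctcf",
    "mean_intensity",
    "mean_intensity_cell",
    "nucleus_area",
    "nc_ratio",
    "puncta_count",
    "qpcr_fold",
    "elisa",
    "telomere_tlr",
)
IMAGE_READOUTS = frozenset(
    {"foci_count", "ctcf", "mean_intensity", "mean_intensity_cell",
     "nucleus_area", "nc_ratio", "puncta_count"}
)


@dataclass(frozen=True)
class MarkerDefinition:
    """One panel entry."""

    name: str
    readout: str
    category: str  # "primary" | "antagonistic"
    expected_direction: str  # "up" | "down" (with age)
    test: str = "anova2_sidak"
    channel: str | None = None  # scene channel name for image readouts
    display: str | None = None

    def __post_init__(self) -> None:
        if self.readout not in READOUTS:
            raise ValueError(f"unknown readout {self.readout!r}")
        if self.category not in ("primary", "antagonistic"):
            raise ValueError(f"category must be primary/antagonistic, got {self.category!r}")
        if self.expected_direction not in ("up", "down"):
            raise ValueError("expected_direction must be 'up' or 'down'")

    @property
    def is_image_marker(self) -> bool:
        return self.readout in IMAGE_READOUTS


@dataclass
class Panel:
    markers: list[MarkerDefinition]
    alpha: float = 0.05
    name: str = "panel"

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate marker names in panel")

    def __iter__(self):
        return iter(self.markers)

    def __len__(self) -> int:
        return len(self.markers)

    def marker(self, name: str) -> MarkerDefinition:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(f"panel has no marker {name!r}")

    def by_category(self, category: str) -> list[MarkerDefinition]:
        return [m for m in self.markers if m.category == category]


def load_panel(path: str | Path) -> Panel:
    """Load a panel from YAML (keys: ``name``, ``alpha``, ``markers``)."""
    raw = yaml.safe_load(Path(path).read_text())
    markers = [MarkerDefinition(**entry) for entry in raw["markers"]]
    return Panel(markers=markers, alpha=float(raw.get("alpha", 0.05)),
                 name=raw.get("name", Path(path).stem))


def default_panel() -> Panel:
    """The packaged ten-marker aging panel."""
    ref = resources.files("agescore.data") / "default_panel.yaml"
    with resources.as_file(ref) as path:
        return load_panel(path)
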