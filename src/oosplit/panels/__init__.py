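"""Marker gene panels for blastocyst lineages and housekeeping reference.

Panels are shipped as editable one-symbol-per-line text files next to
this module: lineage markers for the epiblast (NANOG et al.), primitive
endoderm (SOX17 et al.) and trophectoderm (CDX2 et al.), plus a
housekeeping reference set that includes *Actb*, the transcript used to
rank twin and cotwin by cell number.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

BUILTIN_PANELS = (
    "epiblast",
    "primitive_endoderm",
    "trophectoderm",
    "housekeeping",
)


@dataclass(frozen=True)
class GenePanel:
    """A named, duplicate-free list of gene symbols."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"panel {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            dupes = [g for g in self.genes if self.genes.count(g) > 1]
            raise ValueError(f"panel {self.name!r} has duplicate symbols: {dupes}")

    def __iter__(self):
        return iter(self.genes)

    def __len__(self):
        return len(self.genes)


def _parse(text: str) -> tuple[str, ...]:
    return tuple(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    )


def load_panel(name: str) -> GenePanel:
    """Load a built-in panel by name ('epiblast', 'housekeeping', ...)."""
    if name not in BUILTIN_PANELS:
        raise KeyError(
            f"unknown built-in panel {name!r}; available: {BUILTIN_PANELS}"
        )
    text = resources.files(__package__).joinpath(f"{name}.txt").read_text()
    return GenePanel(name, _parse(text))


def read_panel_file(path, name: str | None = None) -> GenePanel:
    """Read a user panel from a one-symbol-per-line text file."""
    path = Path(path)
    return GenePanel(name or path.stem, _parse(path.read_text()))


def all_panels() -> dict[str, GenePanel]:
    return {name: load_panel(name) for name in BUILTIN_PANELS}
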