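"""PyMOL script generation: paint conservation onto a 3D model's surface.

Two scripts are produced per run. The discrete script maps the four-symbol
conservation classes to four shades (dark = invariant, medium = conservative
substitutions, light = semi-conservative, neutral = not conserved); the
continuous script interpolates each residue's colour linearly in RGB between
the neutral endpoint (0% of aligned sequences match the query) and the dark
endpoint (100% match). In every shade family darker means more conserved and
the unconserved surface stays near-white, so hotspots stand out.

Scripts are self-contained: custom colours are defined with ``set_color`` in
the header and applied with per-residue ``color ..., resi N`` commands, so
they replay in a vanilla viewer session. ``apply_offset`` shifts residue
numbers for fragment models whose numbering does not start at query
position 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .msa_conservation import ConservationAnnotation

RGB = tuple[float, float, float]

#: dark / medium / light / neutral per shade family; channel-wise the dark
#: endpoint never exceeds the neutral one, so linear interpolation darkens
#: monotonically with conservation.
PALETTES: dict[str, dict[str, RGB]] = {
    "blue": {
        "dark": (0.05, 0.15, 0.55),
        "medium": (0.30, 0.45, 0.75),
        "light": (0.62, 0.72, 0.90),
        "neutral": (0.95, 0.95, 0.95),
    },
    "red": {
        "dark": (0.60, 0.08, 0.08),
        "medium": (0.80, 0.35, 0.30),
        "light": (0.92, 0.65, 0.60),
        "neutral": (0.95, 0.95, 0.95),
    },
    "green": {
        "dark": (0.05, 0.40, 0.12),
        "medium": (0.30, 0.62, 0.35),
        "light": (0.65, 0.85, 0.65),
        "neutral": (0.95, 0.95, 0.95),
    },
    "gray": {
        "dark": (0.15, 0.15, 0.15),
        "medium": (0.42, 0.42, 0.42),
        "light": (0.70, 0.70, 0.70),
        "neutral": (0.95, 0.95, 0.95),
    },
}

_SYMBOL_TO_LEVEL = {"*": "dark", ":": "medium", ".": "light", " ": "neutral"}


@dataclass(frozen=True)
class ColorScheme:
    """A shade family plus a mode (discrete symbol levels or continuous ramp)."""

    shade_family: str = "blue"
    mode: str = "discrete"

    def __post_init__(self) -> None:
        if self.shade_family not in PALETTES:
            raise ValueError(f"unknown shade family {self.shade_family!r}")
        if self.mode not in ("discrete", "continuous"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def palette(self) -> dict[str, RGB]:
        return PALETTES[self.shade_family]


@dataclass(frozen=True)
class ProjectionScript:
    """Named colour definitions plus ordered residue-colour commands."""

    header: tuple[str, ...]
    color_defs: tuple[tuple[str, RGB], ...]
    commands: tuple[tuple[int, str], ...]  # (query_position 1-based, color name)

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.commands]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("command positions must be strictly increasing")

    def render(self) -> str:
        lines = [f"# {line}" for line in self.header]
        for name, (r, g, b) in self.color_defs:
            lines.append(f"set_color {name}, [{r:.4f}, {g:.4f}, {b:.4f}]")
        for pos, name in self.commands:
            lines.append(f"color {name}, resi {pos}")
        return "\n".join(lines) + "\n"


def discrete_script(
    annotation: ConservationAnnotation,
    scheme: ColorScheme,
    header: Sequence[str] = (),
) -> ProjectionScript:
    """One colour command per query residue from its conservation symbol."""
    if scheme.mode != "discrete":
        raise ValueError("discrete_script requires a discrete scheme")
    palette = scheme.palette
    defs = tuple(
        (f"cons_{level}", palette[level])
        for level in ("dark", "medium", "light", "neutral")
    )
    commands = tuple(
        (i + 1, f"cons_{_SYMBOL_TO_LEVEL[sym]}")
        for i, sym in enumerate(annotation.query_symbols)
    )
    return ProjectionScript(header=tuple(header), color_defs=defs, commands=commands)


def _interpolate(neutral: RGB, dark: RGB, fraction: float) -> RGB:
    return tuple(n + (d - n) * fraction for n, d in zip(neutral, dark))  # type: ignore[return-value]


def continuous_script(
    annotation: ConservationAnnotation,
    scheme: ColorScheme,
    header: Sequence[str] = (),
) -> ProjectionScript:
    """Percent-match ramp: 0% -> neutral endpoint, 100% -> dark endpoint."""
    if scheme.mode != "continuous":
        raise ValueError("continuous_script requires a continuous scheme")
    palette = scheme.palette
    defs = []
    commands = []
    for i, pct in enumerate(annotation.match_pct):
        name = f"pm_{i + 1}"
        defs.append((name, _interpolate(palette["neutral"], palette["dark"], pct / 100.0)))
        commands.append((i + 1, name))
    return ProjectionScript(
        header=tuple(header), color_defs=tuple(defs), commands=tuple(commands)
    )


def apply_offset(script: ProjectionScript, offset: int) -> ProjectionScript:
    """Shift every residue number by ``offset`` (fragment-model renumbering).

    E.g. a model of query residues 222-707 needs offset +221 so query
    position 1 colours model residue 222.
    """
    return replace(
        script,
        commands=tuple((pos + offset, name) for pos, name in script.commands),
    )
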