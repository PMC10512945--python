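"""Helical-wheel projection with shape and hydrophobicity coding.

Residues of an α-helix are projected onto the plane perpendicular to the
helix axis at the helical twist (100°/residue for an ideal α-helix), so
that residues on the same face of the helix cluster on one side of the
wheel.  Each residue is coded by chemistry: charged residues get distinct
marker shapes (Asp/Glu triangles, Lys/Arg/His pentagons — His counted as
potentially positively charged), hydrophobic residues squares, the rest
circles; the fill color runs green (most hydrophobic) through yellow (zero)
to red (most hydrophilic) on the Kyte–Doolittle scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .proteins import STANDARD_AA


class ConfigurationError(ValueError):
    pass


#: Kyte & Doolittle (1982) hydropathy scale
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

HYDROPHOBICITY_SCALES = {"kyte-doolittle": KYTE_DOOLITTLE}

#: marker-shape classes; together they partition the 20-residue alphabet
NEGATIVE = set("DE")  # triangles
POSITIVE = set("KRH")  # pentagons ("potentially" positively charged)
HYDROPHOBIC = set("AVLIMFWC")  # squares

DEFAULT_TWIST = 100.0  # degrees per residue, ideal alpha helix


def classify_residue(
    residue: str, scale: str = "kyte-doolittle"
) -> tuple[str, float]:
    """Shape class and hydrophobicity score for one residue."""
    try:
        values = HYDROPHOBICITY_SCALES[scale]
    except KeyError:
        raise ConfigurationError(
            f"unknown hydrophobicity scale {scale!r}; known: {sorted(HYDROPHOBICITY_SCALES)}"
        ) from None
    if residue not in STANDARD_AA:
        raise ConfigurationError(f"non-standard residue {residue!r}")
    score = values[residue]
    if residue in NEGATIVE:
        shape = "triangle"
    elif residue in POSITIVE:
        shape = "pentagon"
    elif residue in HYDROPHOBIC or score > 0:
        shape = "square"
    else:
        shape = "circle"
    return shape, score


def hydrophobicity_color(score: float, scale: str = "kyte-doolittle") -> tuple[float, float, float]:
    """RGB in [0,1]: green at the scale maximum, yellow at 0, red at minimum."""
    values = HYDROPHOBICITY_SCALES[scale]
    hi, lo = max(values.values()), min(values.values())
    if score >= 0:
        t = score / hi if hi else 0.0  # yellow -> green
        return (1.0 - t, 1.0, 0.0)
    t = score / lo if lo else 0.0  # yellow -> red
    return (1.0, 1.0 - t, 0.0)


@dataclass(frozen=True)
class WheelEntry:
    position: int  # 1-based within the projected segment
    residue: str
    angle: float  # degrees in [0, 360)
    layer: int  # radial layer, 0-based; co-angular residues stack outward
    shape: str
    score: float
    color: tuple[float, float, float]


@dataclass
class WheelProjection:
    entries: list[WheelEntry]
    start_angle: float
    twist: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "position": e.position,
                    "residue": e.residue,
                    "angle_deg": e.angle,
                    "layer": e.layer,
                    "shape": e.shape,
                    "hydrophobicity": e.score,
                    "color_rgb": ",".join(f"{c:.3f}" for c in e.color),
                }
                for e in self.entries
            ]
        )


def project_wheel(
    sequence: str,
    start_angle: float = 90.0,
    twist: float = DEFAULT_TWIST,
    scale: str = "kyte-doolittle",
) -> WheelProjection:
    """Angles, layers, shapes and colors for a helical wheel.

    angle(i) = (start_angle + (i-1)·twist) mod 360; residues landing on an
    angle already occupied (e.g. i and i+18 at 100°/residue) are assigned
    successive radial layers.
    """
    if not sequence:
        raise ValueError("empty sequence")
    entries: list[WheelEntry] = []
    occupancy: dict[float, int] = {}
    for i, aa in enumerate(sequence, start=1):
        angle = (start_angle + (i - 1) * twist) % 360.0
        key = round(angle, 6)
        layer = occupancy.get(key, 0)
        occupancy[key] = layer + 1
        shape, score = classify_residue(aa, scale)
        entries.append(
            WheelEntry(
                position=i,
                residue=aa,
                angle=angle,
                layer=layer,
                shape=shape,
                score=score,
                color=hydrophobicity_color(score, scale),
            )
        )
    return WheelProjection(entries=entries, start_angle=start_angle, twist=twist)


_MARKERS = {"circle": "o", "square": "s", "triangle": "v", "pentagon": "p"}


def render_wheel(
    projection: WheelProjection,
    path: str | Path,
    base_radius: float = 1.0,
    layer_step: float = 0.22,
) -> None:
    """Optional thin rendering layer: draw the wheel to a vector/image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    fig, ax = plt.subplots(figsize=(5, 5))
    for e in projection.entries:
        r = base_radius + layer_step * e.layer
        x = r * np.cos(np.deg2rad(e.angle))
        y = r * np.sin(np.deg2rad(e.angle))
        ax.scatter(x, y, marker=_MARKERS[e.shape], s=420, c=[e.color],
                   edgecolors="black", zorder=3)
        ax.annotate(f"{e.residue}{e.position}", (x, y), ha="center", va="center",
                    fontsize=7, zorder=4)
    ax.set_aspect("equal")
    ax.set_axis_off()
    lim = base_radius + layer_step * (max(e.layer for e in projection.entries) + 1)
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
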