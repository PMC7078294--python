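"""Per-position PB frequency map and PB logo renderings.

The frequency map is a positions x 16 heat map whose colour scale runs
from deep blue (a PB never seen at that position) through green, yellow
and orange to red (the only PB seen).  The logo stacks the PB letters at
each position with glyph heights proportional to their frequencies.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import LinearSegmentedColormap
from matplotlib.font_manager import FontProperties
from matplotlib.patches import PathPatch
from matplotlib.textpath import TextPath
from matplotlib.transforms import Affine2D

from pbentropy.ensemble_profile import PBCountMatrix
from pbentropy.pb_assignment import PB_LETTERS

__all__ = ["FREQUENCY_CMAP", "render_frequency_map", "logo_stack_heights", "render_logo"]

#: deep blue -> green -> yellow -> orange -> red
FREQUENCY_CMAP = LinearSegmentedColormap.from_list(
    "pb_frequency", ["#00008b", "#1f9e54", "#ffe200", "#ff8c00", "#d40000"]
)

# one stable colour per letter for logo glyphs
_LOGO_COLOURS = plt.get_cmap("tab20").colors[:16]


def render_frequency_map(
    matrix: PBCountMatrix, path: str | Path, dpi: int = 150
) -> Path:
    """Write the positions x 16 PB frequency heat map as PNG."""
    if matrix.n_positions == 0:
        raise ValueError("empty count matrix")
    freq = matrix.frequency_matrix().T  # 16 x positions, rows a..p
    fig, ax = plt.subplots(figsize=(max(4.0, 0.12 * matrix.n_positions + 1.5), 4.0))
    im = ax.imshow(
        freq, aspect="auto", origin="lower", cmap=FREQUENCY_CMAP, vmin=0.0, vmax=1.0,
        interpolation="nearest",
        extent=(0.5, matrix.n_positions + 0.5, -0.5, 15.5),
    )
    ax.set_yticks(range(16), labels=list(PB_LETTERS))
    ax.set_xlabel("residue position")
    ax.set_ylabel("Protein Block")
    fig.colorbar(im, ax=ax, label="frequency")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return path


def logo_stack_heights(matrix: PBCountMatrix) -> list[list[tuple[str, float]]]:
    """Data layer of the logo: per position, (letter, height) stacked
    bottom-up in increasing frequency; zero-frequency letters omitted."""
    freq = matrix.frequency_matrix()
    stacks = []
    for row in freq:
        pairs = [(PB_LETTERS[j], float(row[j])) for j in range(16) if row[j] > 0.0]
        pairs.sort(key=lambda p: (p[1], p[0]))
        stacks.append(pairs)
    return stacks


def render_logo(matrix: PBCountMatrix, path: str | Path, dpi: int = 150) -> Path:
    """Write the PB logo as PNG (glyph height proportional to frequency)."""
    if matrix.n_positions == 0:
        raise ValueError("empty count matrix")
    stacks = logo_stack_heights(matrix)
    fig, ax = plt.subplots(figsize=(max(4.0, 0.25 * matrix.n_positions + 1.0), 3.0))
    font = FontProperties(family="monospace", weight="bold")
    for x, stack in enumerate(stacks, start=1):
        bottom = 0.0
        for letter, height in stack:
            if height <= 0.0:
                continue
            tp = TextPath((0, 0), letter, size=1.0, prop=font)
            bbox = tp.get_extents()
            if bbox.width == 0 or bbox.height == 0:
                continue
            transform = (
                Affine2D()
                .translate(-bbox.x0, -bbox.y0)
                .scale(0.9 / bbox.width, height / bbox.height)
                .translate(x - 0.45, bottom)
            )
            colour = _LOGO_COLOURS[PB_LETTERS.index(letter)]
            ax.add_patch(PathPatch(transform.transform_path(tp), fc=colour, ec="none"))
            bottom += height
    ax.set_xlim(0.4, len(stacks) + 0.6)
    ax.set_ylim(0.0, 1.02)
    ax.set_xlabel("residue position")
    ax.set_ylabel("PB frequency")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return path
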