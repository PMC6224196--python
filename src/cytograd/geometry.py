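"""Tube geometry of the recipient epithelium.

The D-P axis is modeled as a constant-curvature arc parameterized by arc
length ``s`` (um), with the distal tip at ``s = 0`` and the ligand source on
the straight backward extension of the tip tangent.  Cells sit at arc length
``s_i = (i - 1/2) * cell_diameter`` (1-based from the distal tip, matching
the "1st-3rd cells" convention), so physical distances to the source are the
Euclidean (chord) distances, which fall below arc-length distances as soon
as the tube bends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SceneConfig

__all__ = ["SceneGeometry", "build_geometry", "cell_distances"]


@dataclass
class SceneGeometry:
    """Midline, per-cell centers and source position for one scene."""

    config: SceneConfig
    midline: np.ndarray        # (M, 2) polyline in um, distal -> proximal
    midline_s: np.ndarray      # (M,) arc-length parameter of the polyline
    cell_centers: np.ndarray   # (n_cells, 2) um
    cell_arclengths: np.ndarray
    source: np.ndarray         # (2,) um
    distances: np.ndarray      # (n_cells,) straight-line distance to the source

    def point(self, s):
        """Midline point(s) at arc length ``s`` um."""
        return _arc_point(np.asarray(s, dtype=float), self.config.curvature)

    def frame(self, s):
        """Return (point, unit tangent, unit normal) at arc length ``s``."""
        s = np.asarray(s, dtype=float)
        k = self.config.curvature
        p = _arc_point(s, k)
        t = np.stack([np.cos(k * s), np.sin(k * s)], axis=-1)
        n = np.stack([-np.sin(k * s), np.cos(k * s)], axis=-1)
        return p, t, n

    @property
    def tube_radius(self) -> float:
        return self.config.cell_diameter / 2.0


def _arc_point(s, curvature: float):
    """Constant-curvature arc through the origin with initial tangent +x."""
    s = np.asarray(s, dtype=float)
    if curvature == 0.0:
        return np.stack([s, np.zeros_like(s)], axis=-1)
    r = 1.0 / curvature
    return np.stack([r * np.sin(curvature * s), r * (1.0 - np.cos(curvature * s))], axis=-1)


def build_geometry(config: SceneConfig) -> SceneGeometry:
    """Lay out the midline, cell centers and source for a scene.

    Raises
    ------
    ValueError
        If the curvature is so large that the tube wraps past a half turn
        (``curvature * (axis_length + source_offset) >= pi``), beyond which
        the midline approaches self-intersection and distances to the source
        are no longer monotone in the cell index.
    """
    L = config.axis_length
    total_angle = config.curvature * (L + config.source_offset)
    if total_angle >= np.pi:
        raise ValueError(
            f"curvature {config.curvature}/um over a {L:.0f} um axis bends the tube "
            f"by {np.degrees(total_angle):.0f} deg (>= 180 deg); the midline would "
            "self-intersect or lose monotone source distances"
        )

    ds = min(0.5, config.cell_diameter / 8.0)
    s_samples = np.linspace(0.0, L, max(int(round(L / ds)), 2) + 1)
    midline = _arc_point(s_samples, config.curvature)

    s_cells = (np.arange(1, config.n_cells + 1) - 0.5) * config.cell_diameter
    centers = _arc_point(s_cells, config.curvature)

    # Source on the straight backward extension of the distal-tip tangent.
    source = np.array([-config.source_offset, 0.0])

    distances = np.linalg.norm(centers - source, axis=1)
    if not np.all(np.diff(distances) > 0):
        raise ValueError("cell-to-source distances are not strictly increasing; "
                         "reduce the curvature")
    return SceneGeometry(
        config=config,
        midline=midline,
        midline_s=s_samples,
        cell_centers=centers,
        cell_arclengths=s_cells,
        source=source,
        distances=distances,
    )


def cell_distances(n_cells: int, cell_diameter: float, source_offset: float = 0.0) -> np.ndarray:
    """Straight-axis distances from cell centers to the source.

    With no source offset this is the ``d_i = (i - 1/2) * cell_diameter``
    convention used by the feedback simulator.
    """
    return (np.arange(1, n_cells + 1) - 0.5) * cell_diameter + source_offset
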