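"""Cytoneme trace quantification: length classes, orientation, contacts.

Traces are polylines rooted at recipient-cell centers.  Length is polyline
arc length; orientation is the angle (degrees, in (-180, 180], 0 = toward
the source) between the trace's net displacement and the direction from its
origin to the source.  Lengths are grouped into the standard short (<15 um),
mid (15-30 um, closed on both ends) and long (>30 um) classes, and axis
positions into tip (cells 1-3), mid (4-7) and stalk (>7) zones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .stats import welch_t

__all__ = [
    "CytonemeTrace",
    "RoseTable",
    "measure_trace",
    "traces_from_polylines",
    "classify_bins",
    "length_bin",
    "rose_histogram",
    "assign_region",
    "count_contacts",
    "compare_contacting",
]

LENGTH_BIN_EDGES = (15.0, 30.0)  # short < 15 <= mid <= 30 < long
REGIONS = ("tip", "mid", "stalk")


@dataclass
class CytonemeTrace:
    trace_id: int
    cell_index: int          # 1-based from the distal tip
    vertices: np.ndarray     # (V, 2) um
    length: float            # um
    angle_deg: float         # in (-180, 180], 0 = toward the source
    length_bin: str          # short / mid / long
    contact_count: int = 0


def length_bin(length: float) -> str:
    """Length class; boundary rule: exactly 15 or 30 um falls in ``mid``."""
    if length < 0:
        raise ValueError("negative length")
    if length < LENGTH_BIN_EDGES[0]:
        return "short"
    if length <= LENGTH_BIN_EDGES[1]:
        return "mid"
    return "long"


def measure_trace(polyline, source_position) -> tuple[float, float]:
    """Arc length (um) and net-displacement angle (deg) of one trace.

    The angle is measured between ``last - first`` vertex and
    ``source - first`` vertex, wrapped to (-180, 180].  A degenerate trace
    whose vertices coincide has zero length and an angle of NaN.
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("polyline needs >= 2 (x, y) vertices")
    src = np.asarray(source_position, dtype=float)
    length = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    disp = pts[-1] - pts[0]
    to_src = src - pts[0]
    if length == 0 or np.linalg.norm(disp) == 0 or np.linalg.norm(to_src) == 0:
        return length, float("nan")
    ang = np.arctan2(disp[1], disp[0]) - np.arctan2(to_src[1], to_src[0])
    ang = (ang + np.pi) % (2 * np.pi) - np.pi
    if ang == -np.pi:
        ang = np.pi
    return length, float(np.degrees(ang))


def traces_from_polylines(polylines, source_position) -> list[CytonemeTrace]:
    """Measure a set of (trace_id, cell_index, vertices) tuples."""
    out = []
    for tid, cell, verts in polylines:
        length, angle = measure_trace(verts, source_position)
        out.append(CytonemeTrace(trace_id=tid, cell_index=cell,
                                 vertices=np.asarray(verts, float), length=length,
                                 angle_deg=angle, length_bin=length_bin(length)))
    return out


def classify_bins(lengths) -> dict[str, int]:
    """Counts per length class {short, mid, long}."""
    counts = {"short": 0, "mid": 0, "long": 0}
    for L in np.asarray(lengths, dtype=float).ravel():
        counts[length_bin(float(L))] += 1
    return counts


@dataclass
class RoseTable:
    """Angular histogram of trace orientations, optionally per length class."""

    bin_edges: np.ndarray                 # degrees, partition of (-180, 180]
    counts: np.ndarray                    # total counts per angular bin
    by_length_bin: pd.DataFrame | None = None  # rows = angular bins, cols = classes

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"bin_left_deg": self.bin_edges[:-1],
                           "bin_right_deg": self.bin_edges[1:],
                           "count": self.counts})
        if self.by_length_bin is not None:
            for c in self.by_length_bin.columns:
                df[c] = self.by_length_bin[c].to_numpy()
        return df


def rose_histogram(traces, bin_deg: float = 20.0, stratify: bool = True) -> RoseTable:
    """Angular histogram over (-180, 180] with ``bin_deg``-degree bins.

    Bins are right-closed so the total count always equals the number of
    traces with a defined angle.
    """
    if 360.0 % bin_deg != 0:
        raise ValueError("bin_deg must divide 360")
    edges = np.arange(-180.0, 180.0 + bin_deg / 2, bin_deg)

    def _hist(angles):
        a = np.asarray(angles, dtype=float)
        a = a[np.isfinite(a)]
        # right-closed bins on (-180, 180]
        idx = np.ceil((a + 180.0) / bin_deg).astype(int) - 1
        idx = np.clip(idx, 0, len(edges) - 2)
        return np.bincount(idx, minlength=len(edges) - 1)

    def bin_of(t) -> str:
        return getattr(t, "length_bin", None) or length_bin(t.length)

    counts = _hist([t.angle_deg for t in traces])
    by_bin = None
    if stratify:
        cols = {}
        for cls in ("short", "mid", "long"):
            cols[cls] = _hist([t.angle_deg for t in traces if bin_of(t) == cls])
        by_bin = pd.DataFrame(cols)
    return RoseTable(bin_edges=edges, counts=counts, by_length_bin=by_bin)


def assign_region(cell_index: int, axis_cells: int = 12) -> str:
    """Zone of a 1-based cell index: tip (1-3), mid (4-7), stalk (>7)."""
    if not 1 <= cell_index <= axis_cells:
        raise ValueError(f"cell index {cell_index} outside [1, {axis_cells}]")
    if cell_index <= 3:
        return "tip"
    if cell_index <= 7:
        return "mid"
    return "stalk"


def count_contacts(traces, grasp_puncta, max_dist: float = 1.0) -> np.ndarray:
    """Per-trace GRASP contact counts.

    Each punctum is assigned to the nearest trace whose polyline passes
    within ``max_dist`` um of it (distance to the densified polyline);
    puncta farther than ``max_dist`` from every trace are unassigned.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be > 0")
    pts = np.asarray(grasp_puncta, dtype=float)
    if isinstance(grasp_puncta, pd.DataFrame):
        pts = grasp_puncta[["x_um", "y_um"]].to_numpy(dtype=float)
    counts = np.zeros(len(traces), dtype=int)
    if pts.size == 0:
        return counts
    pts = np.atleast_2d(pts)

    samples = []
    owner = []
    for k, tr in enumerate(traces):
        verts = tr.vertices if hasattr(tr, "vertices") else np.asarray(tr, float)
        for a, b in zip(verts[:-1], verts[1:]):
            seg = np.linalg.norm(b - a)
            n = max(int(np.ceil(seg / (max_dist / 2))), 1) + 1
            ts = np.linspace(0.0, 1.0, n)
            samples.append(a + ts[:, None] * (b - a))
            owner.append(np.full(n, k))
    dense = np.vstack(samples)
    owner = np.concatenate(owner)
    d, idx = cKDTree(dense).query(pts)
    for punctum_owner in owner[idx[d <= max_dist]]:
        counts[punctum_owner] += 1
    return counts


def compare_contacting(traces, contact_counts=None) -> dict:
    """Compare per-trace punctum loads of source-contacting vs non-contacting
    cytonemes with Welch's two-tailed t-test.

    ``traces`` must expose ``contacts_source`` (e.g. scene ground truth);
    loads default to each trace's ``contact_count`` unless given explicitly.
    """
    if contact_counts is None:
        contact_counts = [t.contact_count for t in traces]
    loads = np.asarray(contact_counts, dtype=float)
    mask = np.asarray([bool(t.contacts_source) for t in traces])
    a, b = loads[mask], loads[~mask]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 contacting and >= 2 non-contacting traces")
    t, p = welch_t(a, b)
    return {"t": t, "p": p, "n_contacting": int(mask.sum()),
            "n_noncontacting": int((~mask).sum()),
            "mean_contacting": float(a.mean()), "mean_noncontacting": float(b.mean())}
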