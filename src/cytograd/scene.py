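"""Synthetic multi-channel microscopy scenes with known ground truth.

Emulates the imaging content of the ASP / wing-disc experiments the
quantification pipeline was built for: a tubular epithelium along a D-P
axis, an exponential receptor-bound ligand gradient rendered as a diffuse
cytoplasmic pool plus discrete fluorescent puncta, marked clones with
altered uptake, surface-only (EIF-like) and endosomal punctum channels,
cytoneme polylines with length/orientation structure and GRASP-like contact
puncta, all passed through a PSF-blur + Poisson + Gaussian noise model.

Every stochastic choice is drawn from one ``numpy`` Generator seeded from
``SceneConfig.seed``, so an identical config yields a bit-identical scene,
and the :class:`GroundTruth` record carries the exact values each
quantification operation should recover.

Design notes
------------
* The scene is 2-D, a max-projection analogue of the confocal stacks; true
  3-D rendering and the two-layer epithelial topology are out of scope.
* Punctum peak brightness is proportional to the local expected ligand
  intensity, so band-maximum profiles remain proportional to the underlying
  exponential gradient rather than saturating at a fixed spot amplitude.
* Noise order is fixed: PSF blur of the expected image, then Poisson shot
  noise on expected counts, then additive Gaussian read noise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .config import SceneConfig
from .geometry import SceneGeometry, build_geometry

__all__ = [
    "CHANNELS",
    "ImageStack",
    "TraceTruth",
    "GroundTruth",
    "place_cytonemes",
    "render_scene",
    "write_scene",
    "read_stack",
    "traces_to_frame",
    "traces_from_frame",
]

CHANNELS = ("ligand", "receptor", "clone", "eif", "endosome", "grasp")

MAX_PUNCTA = 1_000_000


@dataclass
class ImageStack:
    """Multi-channel 2-D image with physical calibration.

    ``origin`` is the physical (x, y) position in um of the center of pixel
    ``[0, 0]``; arrays are indexed row-major as ``[row=y, col=x]``.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    origin: tuple[float, float]

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def to_pixels(self, xy_um: np.ndarray) -> np.ndarray:
        """Physical um coordinates -> fractional (row, col) pixel coordinates."""
        xy = np.atleast_2d(np.asarray(xy_um, dtype=float))
        col = (xy[:, 0] - self.origin[0]) / self.pixel_size
        row = (xy[:, 1] - self.origin[1]) / self.pixel_size
        return np.stack([row, col], axis=1)

    def to_um(self, rowcol: np.ndarray) -> np.ndarray:
        rc = np.atleast_2d(np.asarray(rowcol, dtype=float))
        x = self.origin[0] + rc[:, 1] * self.pixel_size
        y = self.origin[1] + rc[:, 0] * self.pixel_size
        return np.stack([x, y], axis=1)


@dataclass
class TraceTruth:
    """Ground truth for one cytoneme trace."""

    trace_id: int
    cell_index: int             # 1-based from the distal tip
    vertices: np.ndarray        # (V, 2) um
    length: float               # um, polyline arc length
    angle_deg: float            # net direction relative to the source direction
    contacts_source: bool
    contact_count: int
    contact_points: np.ndarray  # (contact_count, 2) um, GRASP punctum positions


@dataclass
class GroundTruth:
    """True values every quantification operation should recover."""

    distances: np.ndarray             # (n_cells,) cell-center distance to source, um
    expected_intensity: np.ndarray    # (n_cells,) noise-free ligand intensity, AU
    expected_puncta: np.ndarray       # (n_cells,) expected punctum count per cell
    true_lambda: float                # configured decay length, um
    true_slope: float                 # Cmax / (2 lambda ln 2) when background = 0, else NaN
    clone_expected_ratios: list[float]  # expected outside/inside density ratio per clone
    puncta: pd.DataFrame              # x_um, y_um, cell_index, receptor_bound, internalized, ...
    traces: list[TraceTruth]
    clone_masks: list[np.ndarray] = field(default_factory=list)
    tube_mask: np.ndarray | None = None
    midline: np.ndarray | None = None


def _true_slope(Cmax: float, lam: float, background: float) -> float:
    if background == 0.0:
        return Cmax / (2.0 * lam * np.log(2.0))
    return float("nan")


def place_cytonemes(geometry: SceneGeometry, config: SceneConfig,
                    rng: np.random.Generator) -> list[TraceTruth]:
    """Sample cytoneme polylines rooted at cell centers.

    Lengths come from the configured short/mid/long mixture; the emission
    direction is the cell's direction toward the source plus a von Mises
    deviate of concentration ``kappa`` (``kappa = 0`` is isotropic).  A trace
    contacts the source when its reach is at least the cell's straight-line
    distance to the source; contacting traces carry GRASP puncta near their
    tips at Poisson(``contact_puncta_mean``), non-contacting ones at
    Poisson(``noncontact_puncta_mean``).
    """
    cc = config.cytonemes
    n_cells = config.n_cells
    if cc.per_cell_counts is not None:
        counts = list(cc.per_cell_counts) + [0] * (n_cells - len(cc.per_cell_counts))
        counts = np.asarray(counts[:n_cells], dtype=int)
    else:
        counts = rng.poisson(cc.mean_per_cell, size=n_cells)

    weights = np.asarray(cc.length_mixture, dtype=float)
    weights = weights / weights.sum()
    traces: list[TraceTruth] = []
    tid = 0
    for i in range(n_cells):
        origin = geometry.cell_centers[i]
        to_source = geometry.source - origin
        base_angle = np.arctan2(to_source[1], to_source[0])
        dist = geometry.distances[i]
        for _ in range(int(counts[i])):
            cls = rng.choice(3, p=weights)
            lo, hi = cc.length_ranges[cls]
            length = float(rng.uniform(lo, hi))
            if cc.kappa == 0.0:
                dev = rng.uniform(-np.pi, np.pi)
            else:
                dev = rng.vonmises(0.0, cc.kappa)
            theta = base_angle + dev
            direction = np.array([np.cos(theta), np.sin(theta)])
            # straight 3-vertex polyline; arc length equals the drawn length
            vertices = origin + np.outer([0.0, 0.5, 1.0], direction * length)
            contacts = length >= dist
            mean = cc.contact_puncta_mean if contacts else cc.noncontact_puncta_mean
            k = int(rng.poisson(mean))
            tip = vertices[-1]
            pts = tip + rng.normal(0.0, 0.2, size=(k, 2)) if k else np.empty((0, 2))
            angle = float(np.degrees(_wrap(dev)))
            traces.append(TraceTruth(
                trace_id=tid, cell_index=i + 1, vertices=vertices,
                length=length, angle_deg=angle, contacts_source=bool(contacts),
                contact_count=k, contact_points=pts,
            ))
            tid += 1
    return traces


def _wrap(angle_rad: float) -> float:
    """Wrap to (-pi, pi]."""
    a = (angle_rad + np.pi) % (2.0 * np.pi) - np.pi
    return np.pi if a == -np.pi else a


def render_scene(config: SceneConfig) -> tuple[ImageStack, GroundTruth]:
    """Render a scene and return the image stack plus its ground truth."""
    geom = build_geometry(config)
    rng = np.random.default_rng(config.seed)
    grad = config.gradient
    pc = config.puncta

    # --- canvas -----------------------------------------------------------
    pts = np.vstack([geom.midline, geom.source[None, :]])
    pad = geom.tube_radius + config.margin_um
    x0, y0 = pts.min(axis=0) - pad
    x1, y1 = pts.max(axis=0) + pad
    px = config.pixel_size
    n_cols = int(np.ceil((x1 - x0) / px))
    n_rows = int(np.ceil((y1 - y0) / px))
    if n_cols <= 0 or n_rows <= 0:
        raise ValueError("zero-size image; check pixel_size and geometry")
    origin = (float(x0), float(y0))

    cols = x0 + np.arange(n_cols) * px
    rows = y0 + np.arange(n_rows) * px
    X, Y = np.meshgrid(cols, rows)
    pix = np.stack([X.ravel(), Y.ravel()], axis=1)

    # --- tube fields ------------------------------------------------------
    tree = cKDTree(geom.midline)
    d_mid, idx = tree.query(pix)
    s_pix = geom.midline_s[idx]
    inside = (d_mid <= geom.tube_radius).reshape(n_rows, n_cols)
    m_pts, m_tan, _ = geom.frame(s_pix)
    rel = pix - m_pts
    side = np.sign(m_tan[:, 0] * rel[:, 1] - m_tan[:, 1] * rel[:, 0])
    side = np.where(side == 0, 1.0, side).reshape(n_rows, n_cols)
    cell_of_pix = np.clip((s_pix / config.cell_diameter).astype(int) + 1,
                          1, config.n_cells).reshape(n_rows, n_cols)
    source_dist_pix = np.linalg.norm(m_pts - geom.source, axis=1).reshape(n_rows, n_cols)

    uptake = np.ones((n_rows, n_cols))
    clone_masks = []
    for clone in config.clones:
        lo, hi = clone.cell_range
        mask = inside & (cell_of_pix >= lo) & (cell_of_pix <= hi) & (side == clone.side)
        uptake[mask] = clone.uptake_factor
        clone_masks.append(mask)

    d_cells = geom.distances
    if config.per_cell_intensity is not None:
        E_cells = np.asarray(config.per_cell_intensity, dtype=float)

        def E_of_s(s):
            # interpolate the per-cell expectations along the arc length
            return np.interp(s, geom.cell_arclengths, E_cells)

        E_field_raw = E_of_s(np.clip(s_pix, 0, None)).reshape(n_rows, n_cols)
    else:
        E_cells = grad.expected_intensity(d_cells)

        def E_of_s(s):
            p_pts = geom.point(np.asarray(s, dtype=float))
            return grad.expected_intensity(np.linalg.norm(p_pts - geom.source, axis=-1))

        E_field_raw = grad.expected_intensity(source_dist_pix)
    E_field = E_field_raw * uptake * inside

    # --- puncta -----------------------------------------------------------
    expected_puncta = pc.density_scale * E_cells
    uptake_cell_side = {}
    for i in range(config.n_cells):
        for s in (-1, 1):
            uptake_cell_side[(i + 1, s)] = 1.0
    for clone in config.clones:
        for ci in range(clone.cell_range[0], clone.cell_range[1] + 1):
            uptake_cell_side[(ci, clone.side)] = clone.uptake_factor

    exp_total = sum(0.5 * expected_puncta[i] * uptake_cell_side[(i + 1, s)]
                    for i in range(config.n_cells) for s in (-1, 1))
    if exp_total > MAX_PUNCTA:
        raise ValueError(f"density_scale implies ~{exp_total:.2e} puncta (> {MAX_PUNCTA})")

    records = []
    for i in range(config.n_cells):
        s_lo = i * config.cell_diameter
        for sgn in (-1, 1):
            lam_side = 0.5 * expected_puncta[i] * uptake_cell_side[(i + 1, sgn)]
            n_p = int(rng.poisson(lam_side))
            if n_p == 0:
                continue
            # axial positions follow the local expected intensity within the
            # cell (rejection sampling), so punctum density varies smoothly
            s_hi = s_lo + config.cell_diameter
            bound = float(np.max(E_of_s(np.linspace(s_lo, s_hi, 9)))) or 1.0
            s_samp = np.empty(n_p)
            filled = 0
            while filled < n_p:
                cand = rng.uniform(s_lo, s_hi, 2 * (n_p - filled))
                acc = cand[rng.random(len(cand)) * bound <= E_of_s(cand)]
                take = min(len(acc), n_p - filled)
                s_samp[filled:filled + take] = acc[:take]
                filled += take
            t_samp = rng.uniform(0.0, geom.tube_radius, n_p) * sgn
            p_pts, _, p_nrm = geom.frame(s_samp)
            pos = p_pts + t_samp[:, None] * p_nrm
            # constant punctum brightness: the gradient is carried by punctum
            # *density*, so band-averaged profiles stay proportional to it
            bound = rng.random(n_p) < pc.receptor_binding_prob
            internal = rng.random(n_p) < pc.endosome_prob
            for j in range(n_p):
                records.append((pos[j, 0], pos[j, 1], i + 1, pc.amplitude,
                                bool(bound[j]), bool(internal[j])))
    puncta = pd.DataFrame(
        records,
        columns=["x_um", "y_um", "cell_index", "amplitude",
                 "receptor_bound", "internalized"],
    )
    puncta["endosome"] = puncta["internalized"] if len(puncta) else pd.Series(dtype=bool)
    puncta["surface"] = ~puncta["internalized"] if len(puncta) else pd.Series(dtype=bool)

    traces = place_cytonemes(geom, config, rng)

    # --- channel images ---------------------------------------------------
    stack = {name: np.zeros((n_rows, n_cols)) for name in CHANNELS}
    stack["ligand"] += config.diffuse_fraction * E_field
    stack["clone"] += 50.0 * inside
    for mask in clone_masks:
        stack["clone"][mask] += 100.0

    def splat(img, x, y, amp, sigma_um):
        _add_spot(img, (x - origin[0]) / px, (y - origin[1]) / px, amp, sigma_um / px)

    for p in puncta.itertuples(index=False):
        splat(stack["ligand"], p.x_um, p.y_um, p.amplitude, pc.sigma_um)
        if p.receptor_bound:
            splat(stack["receptor"], p.x_um, p.y_um, p.amplitude, pc.sigma_um)
        if p.surface:
            splat(stack["eif"], p.x_um, p.y_um, p.amplitude, pc.sigma_um)
        if p.endosome:
            splat(stack["endosome"], p.x_um, p.y_um, p.amplitude, pc.sigma_um)
    for tr in traces:
        for q in tr.contact_points:
            splat(stack["grasp"], q[0], q[1], pc.amplitude, pc.sigma_um)

    # --- imaging model: PSF blur, then Poisson, then Gaussian read noise --
    nz = config.noise
    for name in CHANNELS:
        img = stack[name]
        if nz.psf_sigma_um > 0:
            img = gaussian_filter(img, nz.psf_sigma_um / px)
        if nz.poisson:
            img = rng.poisson(np.clip(img, 0.0, None)).astype(float)
        if nz.gaussian_sd > 0:
            img = img + rng.normal(0.0, nz.gaussian_sd, img.shape)
        stack[name] = img

    truth = GroundTruth(
        distances=d_cells,
        expected_intensity=E_cells,
        expected_puncta=expected_puncta,
        true_lambda=grad.lam if config.per_cell_intensity is None else float("nan"),
        true_slope=(_true_slope(grad.Cmax, grad.lam, grad.background)
                    if config.per_cell_intensity is None else float("nan")),
        clone_expected_ratios=[
            np.inf if c.uptake_factor == 0 else 1.0 / c.uptake_factor
            for c in config.clones
        ],
        puncta=puncta,
        traces=traces,
        clone_masks=clone_masks,
        tube_mask=inside,
        midline=geom.midline,
    )
    return ImageStack(channels=stack, pixel_size=px, origin=origin), truth


def _add_spot(img: np.ndarray, col: float, row: float, amp: float, sigma_px: float) -> None:
    """Add a Gaussian spot in place on a +-4 sigma window."""
    half = max(int(np.ceil(4.0 * sigma_px)), 2)
    r0, r1 = int(np.floor(row)) - half, int(np.floor(row)) + half + 1
    c0, c1 = int(np.floor(col)) - half, int(np.floor(col)) + half + 1
    r0c, c0c = max(r0, 0), max(c0, 0)
    r1c, c1c = min(r1, img.shape[0]), min(c1, img.shape[1])
    if r0c >= r1c or c0c >= c1c:
        return
    rr = np.arange(r0c, r1c)[:, None]
    cc = np.arange(c0c, c1c)[None, :]
    img[r0c:r1c, c0c:c1c] += amp * np.exp(
        -((rr - row) ** 2 + (cc - col) ** 2) / (2.0 * sigma_px ** 2))


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def traces_to_frame(traces: list[TraceTruth]) -> pd.DataFrame:
    """Long-format vertex table: trace_id, cell_index, vertex, x_um, y_um."""
    rows = []
    for tr in traces:
        for v, (x, y) in enumerate(tr.vertices):
            rows.append((tr.trace_id, tr.cell_index, v, x, y))
    return pd.DataFrame(rows, columns=["trace_id", "cell_index", "vertex", "x_um", "y_um"])


def traces_from_frame(frame: pd.DataFrame) -> list[tuple[int, int, np.ndarray]]:
    """Inverse of :func:`traces_to_frame`: (trace_id, cell_index, vertices) tuples."""
    out = []
    for tid, g in frame.groupby("trace_id", sort=True):
        g = g.sort_values("vertex")
        out.append((int(tid), int(g["cell_index"].iloc[0]),
                    g[["x_um", "y_um"]].to_numpy(dtype=float)))
    return out


def write_scene(stack: ImageStack, truth: GroundTruth, outdir,
                config: SceneConfig | None = None) -> dict[str, Path]:
    """Write TIFF stack, ground-truth JSON and trace/punctum CSV tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    tif = outdir / "scene.tif"
    data = np.stack([stack.channels[c] for c in CHANNELS]).astype(np.float32)
    meta = {"axes": "CYX", "channels": list(CHANNELS),
            "pixel_size_um": stack.pixel_size, "origin_um": list(stack.origin)}
    tifffile.imwrite(tif, data, metadata=meta)
    paths["stack"] = tif

    gt = {
        "distances_um": truth.distances.tolist(),
        "expected_intensity": truth.expected_intensity.tolist(),
        "expected_puncta": truth.expected_puncta.tolist(),
        "true_lambda_um": truth.true_lambda,
        "true_slope": None if np.isnan(truth.true_slope) else truth.true_slope,
        "clone_expected_ratios": [
            None if np.isinf(r) else r for r in truth.clone_expected_ratios],
        "n_traces": len(truth.traces),
        "n_puncta": int(len(truth.puncta)),
    }
    gt_path = outdir / "ground_truth.json"
    gt_path.write_text(json.dumps(gt, indent=2))
    paths["ground_truth"] = gt_path

    tr_path = outdir / "traces.csv"
    traces_to_frame(truth.traces).to_csv(tr_path, index=False)
    paths["traces"] = tr_path

    pq_path = outdir / "puncta.csv"
    truth.puncta.to_csv(pq_path, index=False)
    paths["puncta"] = pq_path

    grasp = np.vstack([tr.contact_points for tr in truth.traces]) \
        if any(tr.contact_count for tr in truth.traces) else np.empty((0, 2))
    gr_path = outdir / "grasp_puncta.csv"
    pd.DataFrame(grasp, columns=["x_um", "y_um"]).to_csv(gr_path, index=False)
    paths["grasp"] = gr_path

    if config is not None:
        from .config import save_scene_config
        cfg_path = outdir / "scene_config.yaml"
        save_scene_config(config, cfg_path)
        paths["config"] = cfg_path
    return paths


def read_stack(path) -> ImageStack:
    """Read a multi-channel TIFF written by :func:`write_scene`."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    names = list(meta.get("channels", [f"ch{i}" for i in range(data.shape[0])]))
    if data.ndim == 2:
        data = data[None]
        names = names or ["ch0"]
    channels = {name: data[i].astype(float) for i, name in enumerate(names)}
    return ImageStack(
        channels=channels,
        pixel_size=float(meta.get("pixel_size_um", 1.0)),
        origin=tuple(meta.get("origin_um", (0.0, 0.0))),
    )
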