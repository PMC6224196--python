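"""Gradient quantification: straightening, band profiles, exponential fits.

Implements the image-side measurements used throughout the analysis: fitting
a midline along a curved tubular epithelium, extracting a band-limited
intensity profile perpendicular to it (digital straightening), fitting an
exponential trend ``v(x) = background + A * exp(-(x - x_max)/lambda)``, the
Cmax-to-C-half-max slope statistic, the slope-vs-axis-length correlation,
area-normalized inside/outside clone intensity ratios, blob-based punctum
detection and nearest-neighbour colocalization fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats
from scipy.spatial import cKDTree

__all__ = [
    "Midline",
    "IntensityProfile",
    "GradientFit",
    "CloneMeasurement",
    "fit_midline",
    "axis_midline",
    "extract_profile",
    "profile_from_values",
    "fit_exponential",
    "correlate_slope_length",
    "clone_ratio",
    "detect_puncta",
    "colocalization_fraction",
]

LN2 = float(np.log(2.0))


# --------------------------------------------------------------------------
# midline
# --------------------------------------------------------------------------

@dataclass
class Midline:
    """Arc-length parameterized polyline, oriented distal -> proximal."""

    vertices: np.ndarray   # (M, 2) in um
    s: np.ndarray          # (M,) cumulative arc length, s[0] = 0

    @property
    def length(self) -> float:
        return float(self.s[-1])

    def point(self, s):
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length)
        x = np.interp(s, self.s, self.vertices[:, 0])
        y = np.interp(s, self.s, self.vertices[:, 1])
        return np.stack([x, y], axis=-1)

    def frame(self, s):
        """(point, unit tangent, unit normal) at arc length ``s``."""
        s = np.asarray(s, dtype=float)
        eps = max(self.length * 1e-4, 1e-6)
        p = self.point(s)
        ahead = self.point(np.minimum(s + eps, self.length))
        behind = self.point(np.maximum(s - eps, 0.0))
        t = ahead - behind
        t = t / np.maximum(np.linalg.norm(t, axis=-1, keepdims=True), 1e-12)
        n = np.stack([-t[..., 1], t[..., 0]], axis=-1)
        return p, t, n


def _polyline_midline(points: np.ndarray) -> Midline:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return Midline(vertices=points, s=s)


def _is_simple(points: np.ndarray) -> bool:
    from shapely.geometry import LineString

    return LineString(points).is_simple


def fit_midline(points_or_mask, smoothing: float | None = None,
                max_deviation: float = 2.0, n_samples: int = 400) -> Midline:
    """Fit a smoothing-spline midline through anchor points or a mask.

    Parameters
    ----------
    points_or_mask
        Either an ``(N, 2)`` array of anchor points (um or px, distal
        first) with ``N >= 4``, or a 2-D boolean mask of the structure, in
        which case the midline follows the ordered skeleton of the mask (in
        pixel units, ``(col, row)`` order to match ``(x, y)``).
    smoothing
        Spline smoothing factor passed to ``scipy.interpolate.splprep``;
        defaults to a small multiple of the anchor count.
    max_deviation
        Maximum allowed RMS deviation of the spline from the anchors.
    """
    from scipy.interpolate import splev, splprep

    pts = points_or_mask
    if isinstance(pts, np.ndarray) and pts.ndim == 2 and pts.dtype != bool \
            and pts.shape[1] == 2:
        anchors = np.asarray(pts, dtype=float)
    else:
        anchors = _skeleton_path(np.asarray(points_or_mask, dtype=bool))
    if len(anchors) < 4:
        raise ValueError("need at least 4 anchor points (or a connected mask)")

    if smoothing is None:
        smoothing = 0.5 * len(anchors)
    # splprep rejects duplicate consecutive points
    keep = np.concatenate([[True], np.linalg.norm(np.diff(anchors, axis=0), axis=1) > 1e-9])
    anchors = anchors[keep]
    tck, u = splprep(anchors.T, s=smoothing, k=min(3, len(anchors) - 1))
    uu = np.linspace(0.0, 1.0, n_samples)
    xy = np.stack(splev(uu, tck), axis=1)

    if not _is_simple(xy):
        raise ValueError("fitted midline self-intersects")
    fit_at_anchors = np.stack(splev(u, tck), axis=1)
    rms = float(np.sqrt(np.mean(np.sum((fit_at_anchors - anchors) ** 2, axis=1))))
    if rms > max_deviation:
        raise ValueError(f"midline deviates from anchors by {rms:.2f} (RMS) "
                         f"> allowed {max_deviation}")
    return _polyline_midline(xy)


def _skeleton_path(mask: np.ndarray) -> np.ndarray:
    """Ordered (x, y) pixel path along the skeleton of a mask."""
    from skimage.morphology import skeletonize

    skel = skeletonize(mask)
    rows, cols = np.nonzero(skel)
    if len(rows) < 4:
        raise ValueError("mask skeleton too short to define a midline")
    pts = np.stack([cols, rows], axis=1).astype(float)
    # order by greedy nearest-neighbour walk from one end (lowest x)
    tree = cKDTree(pts)
    start = int(np.argmin(pts[:, 0]))
    order = [start]
    used = np.zeros(len(pts), dtype=bool)
    used[start] = True
    current = start
    for _ in range(len(pts) - 1):
        dist, nbrs = tree.query(pts[current], k=min(8, len(pts)))
        nxt = next((int(j) for j in np.atleast_1d(nbrs) if not used[int(j)]), None)
        if nxt is None:
            remaining = np.nonzero(~used)[0]
            d = np.linalg.norm(pts[remaining] - pts[current], axis=1)
            if d.min() > 3.0:
                break
            nxt = int(remaining[np.argmin(d)])
        order.append(nxt)
        used[nxt] = True
        current = nxt
    return pts[order]


def axis_midline(length: float, origin=(0.0, 0.0), n: int = 200) -> Midline:
    """Straight midline of a given length along +x (the D-P axis)."""
    xs = np.linspace(0.0, length, n)
    pts = np.stack([origin[0] + xs, np.full(n, origin[1])], axis=1)
    return _polyline_midline(pts)


# --------------------------------------------------------------------------
# profiles
# --------------------------------------------------------------------------

@dataclass
class IntensityProfile:
    positions: np.ndarray   # um from the distal tip, strictly increasing
    values: np.ndarray      # AU, band-projected
    band_width_px: int = 1
    projection: str = "max"
    channel: str = ""
    n_clipped: int = 0      # band samples that fell outside the image

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.positions) != len(self.values) or len(self.positions) < 3:
            raise ValueError("profile needs >= 3 matched positions/values")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


def profile_from_values(positions, values, **kw) -> IntensityProfile:
    """Build a profile directly from arrays (e.g. simulated steady states)."""
    return IntensityProfile(positions=np.asarray(positions, float),
                            values=np.asarray(values, float), **kw)


def extract_profile(image, midline: Midline, band_width_px: int = 40,
                    projection: str = "mean", pixel_size: float = 1.0,
                    origin=(0.0, 0.0), spacing: float | None = None,
                    channel: str = "") -> IntensityProfile:
    """Band-limited intensity profile along a midline (digital straightening).

    At each arc-length sample the image is resampled along the perpendicular
    over ``band_width_px`` pixels and reduced with ``projection``: ``mean``
    (default; a wide profile line averages across its width) or ``max``.
    ``image`` may be a 2-D array with ``pixel_size``/``origin`` calibration,
    or a :class:`~cytograd.scene.ImageStack` together with ``channel``.
    """
    from .scene import ImageStack

    if isinstance(image, ImageStack):
        if not channel:
            raise ValueError("channel name required with an ImageStack")
        arr = image.channels[channel]
        pixel_size = image.pixel_size
        origin = image.origin
    else:
        arr = np.asarray(image, dtype=float)
    if projection not in ("max", "mean"):
        raise ValueError("projection must be 'max' or 'mean'")

    if spacing is None:
        spacing = pixel_size
    s_samples = np.arange(0.0, midline.length + spacing / 2, spacing)
    p, _, nrm = midline.frame(s_samples)
    offsets = (np.arange(band_width_px) - (band_width_px - 1) / 2.0) * pixel_size
    # (S, B, 2) sample positions in um
    pos = p[:, None, :] + offsets[None, :, None] * nrm[:, None, :]
    col = (pos[..., 0] - origin[0]) / pixel_size
    row = (pos[..., 1] - origin[1]) / pixel_size
    valid = (row >= 0) & (row <= arr.shape[0] - 1) & (col >= 0) & (col <= arr.shape[1] - 1)
    samples = ndimage.map_coordinates(arr, [row.ravel(), col.ravel()],
                                      order=1, mode="constant", cval=np.nan)
    samples = samples.reshape(row.shape)
    samples[~valid] = np.nan
    n_clipped = int((~valid).sum())
    if n_clipped:
        warnings.warn(f"{n_clipped} band samples fell outside the image and were clipped")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vals = np.nanmax(samples, axis=1) if projection == "max" \
            else np.nanmean(samples, axis=1)
    ok = np.isfinite(vals)
    return IntensityProfile(positions=s_samples[ok], values=vals[ok],
                            band_width_px=band_width_px, projection=projection,
                            channel=channel, n_clipped=n_clipped)


# --------------------------------------------------------------------------
# exponential trend fit and the slope statistic
# --------------------------------------------------------------------------

@dataclass
class GradientFit:
    """Exponential trend fit and the Cmax -> C-half-max slope statistic.

    ``slope = (Cmax - C_half) / (x_half - x_max)`` where
    ``C_half = background + (Cmax - background) / 2``; for a background-free
    fit this reduces to the closed form ``Cmax / (2 * lambda * ln 2)``.
    """

    Cmax: float          # fitted value at x_max (background + amplitude), AU
    amplitude: float     # fitted decaying amplitude A, AU
    background: float    # fitted offset, AU
    lam: float           # decay length, um
    x_max: float         # position of the profile maximum, um
    x_half: float        # position where the fit reaches C_half, um
    slope: float         # AU / um
    r2: float
    ok: bool = True      # False for flagged (non-decaying / failed) fits
    message: str = ""

    @property
    def C_half(self) -> float:
        return self.background + (self.Cmax - self.background) / 2.0


def _flagged(x_max: float, message: str) -> GradientFit:
    nan = float("nan")
    return GradientFit(Cmax=nan, amplitude=nan, background=nan, lam=nan,
                       x_max=x_max, x_half=nan, slope=nan, r2=nan,
                       ok=False, message=message)


def fit_exponential(profile: IntensityProfile, fit_background: bool = True) -> GradientFit:
    """Least-squares exponential trend fit of an intensity profile.

    The model is ``v(x) = background + A * exp(-(x - x_max)/lambda)`` with
    ``x_max`` pinned at the position of the profile maximum; points distal
    to ``x_max`` are excluded from the fit.  Initialized from a log-linear
    regression.  Non-decaying profiles are returned flagged (``ok=False``)
    with the slope undefined.
    """
    x = profile.positions
    v = profile.values
    if len(x) < 5:
        raise ValueError("need at least 5 profile points")
    if np.ptp(v) == 0:
        return _flagged(float(x[np.argmax(v)]), "constant profile")
    # anchor at the maximum of a lightly smoothed profile (the "maximum
    # average" value), so single-pixel spikes do not shift the anchor
    spacing = float(np.median(np.diff(x)))
    win = max(int(round(2.0 / spacing)), 1) if spacing > 0 else 1
    if win > 1 and len(v) > win:
        smooth = ndimage.uniform_filter1d(v, size=win, mode="nearest")
    else:
        smooth = v
    i_max = int(np.argmax(smooth))
    x_max = float(x[i_max])
    xs = x[i_max:] - x_max
    vs = v[i_max:]
    if len(xs) < 5:
        return _flagged(x_max, "profile maximum too close to the proximal end")

    bg0 = max(float(np.min(vs)), 0.0)
    amp0 = max(float(vs[0] - bg0), 1e-9)
    pos = vs - bg0 > amp0 * 1e-3
    if pos.sum() >= 2:
        coef = np.polyfit(xs[pos], np.log(vs[pos] - bg0 + amp0 * 1e-6), 1)
        lam0 = -1.0 / coef[0] if coef[0] < 0 else np.ptp(xs)
    else:
        lam0 = np.ptp(xs) / 2
    lam0 = float(np.clip(lam0, np.ptp(xs) * 1e-3, np.ptp(xs) * 100))

    span = float(np.ptp(xs))
    try:
        if fit_background:
            def model(xx, A, lam, bg):
                return bg + A * np.exp(-xx / lam)
            p0 = [amp0, lam0, bg0]
            bounds = ([0.0, span * 1e-4, 0.0], [np.inf, span * 1e3, np.inf])
        else:
            def model(xx, A, lam):
                return A * np.exp(-xx / lam)
            p0 = [amp0 + bg0, lam0]
            bounds = ([0.0, span * 1e-4], [np.inf, span * 1e3])
        popt, _ = optimize.curve_fit(model, xs, vs, p0=p0, bounds=bounds,
                                     maxfev=20000, xtol=1e-13, ftol=1e-13,
                                     gtol=1e-13)
    except (RuntimeError, ValueError) as exc:
        return _flagged(x_max, f"fit failed: {exc}")

    if fit_background:
        A, lam, bg = (float(q) for q in popt)
    else:
        A, lam = (float(q) for q in popt)
        bg = 0.0
    if lam >= span * 1e2 or A <= 0:
        return _flagged(x_max, "non-decaying profile (lambda unbounded or amplitude <= 0)")

    fitted = model(xs, *popt)
    ss_res = float(np.sum((vs - fitted) ** 2))
    ss_tot = float(np.sum((vs - vs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    x_half = x_max + lam * LN2
    slope = A / (2.0 * lam * LN2)
    return GradientFit(Cmax=bg + A, amplitude=A, background=bg, lam=lam,
                       x_max=x_max, x_half=x_half, slope=slope, r2=r2)


def correlate_slope_length(pairs) -> tuple[float, float, int]:
    """Pearson correlation of (axis length, gradient slope) pairs.

    Returns ``(r, p_two_sided, n)``; raises on fewer than 3 pairs or zero
    variance in either coordinate.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
        raise ValueError("need >= 3 (length, slope) pairs")
    if np.ptp(arr[:, 0]) == 0 or np.ptp(arr[:, 1]) == 0:
        raise ValueError("zero variance in lengths or slopes")
    r, p = stats.pearsonr(arr[:, 0], arr[:, 1])
    return float(r), float(p), len(arr)


# --------------------------------------------------------------------------
# clone ratios
# --------------------------------------------------------------------------

@dataclass
class CloneMeasurement:
    inside_density: float    # AU / um^2
    outside_density: float   # AU / um^2
    ratio_out_in: float      # inf flag when inside density is zero
    inside_area_um2: float = 0.0
    outside_area_um2: float = 0.0


def mirror_mask(mask: np.ndarray, midline: Midline, pixel_size: float = 1.0,
                origin=(0.0, 0.0)) -> np.ndarray:
    """Reflect a mask about the midline (the 'equivalent position' control).

    Each masked pixel is mapped to ``2 m - p`` where ``m`` is its nearest
    midline point, which preserves the arc-length position and lateral
    distance on the opposite side of the tube.
    """
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        raise ValueError("empty mask")
    x = origin[0] + cols * pixel_size
    y = origin[1] + rows * pixel_size
    pts = np.stack([x, y], axis=1)
    dense_s = np.linspace(0.0, midline.length, 2000)
    dense = midline.point(dense_s)
    tree = cKDTree(dense)
    _, idx = tree.query(pts)
    reflected = 2.0 * dense[idx] - pts
    rc = np.stack([(reflected[:, 1] - origin[1]) / pixel_size,
                   (reflected[:, 0] - origin[0]) / pixel_size], axis=1)
    rc = np.round(rc).astype(int)
    out = np.zeros_like(mask, dtype=bool)
    ok = (rc[:, 0] >= 0) & (rc[:, 0] < mask.shape[0]) \
        & (rc[:, 1] >= 0) & (rc[:, 1] < mask.shape[1])
    out[rc[ok, 0], rc[ok, 1]] = True
    return out


def clone_ratio(image, clone_mask: np.ndarray, control_mask: np.ndarray | None = None,
                midline: Midline | None = None, pixel_size: float = 1.0,
                origin=(0.0, 0.0), area_tolerance: float = 0.10,
                channel: str = "ligand") -> CloneMeasurement:
    """Area-normalized intensity densities inside / outside a marked clone.

    Total intensity in each ROI is divided by the ROI area (um^2), matching
    area-normalized clone quantification; the statistic reported is
    ``outside_density / inside_density``.  If no control ROI is given it is
    auto-constructed as the mirror image of the clone about the midline.
    Control and clone areas must agree within ``area_tolerance``.
    """
    from .scene import ImageStack

    if isinstance(image, ImageStack):
        arr = image.channels[channel]
        pixel_size = image.pixel_size
        origin = image.origin
    else:
        arr = np.asarray(image, dtype=float)
    clone_mask = np.asarray(clone_mask, dtype=bool)
    if clone_mask.sum() == 0:
        raise ValueError("empty clone mask")
    if control_mask is None:
        if midline is None:
            raise ValueError("need either a control mask or a midline to mirror about")
        control_mask = mirror_mask(clone_mask, midline, pixel_size, origin)
        control_mask &= ~clone_mask  # midline row reflects onto itself
    control_mask = np.asarray(control_mask, dtype=bool)
    if control_mask.sum() == 0:
        raise ValueError("empty control mask")
    if np.any(clone_mask & control_mask):
        raise ValueError("clone and control masks overlap")

    a_in = clone_mask.sum() * pixel_size ** 2
    a_out = control_mask.sum() * pixel_size ** 2
    if abs(a_out - a_in) > area_tolerance * a_in:
        raise ValueError(f"control ROI area {a_out:.1f} um^2 differs from clone "
                         f"area {a_in:.1f} um^2 by more than {area_tolerance:.0%}")
    inside = float(arr[clone_mask].sum()) / a_in
    outside = float(arr[control_mask].sum()) / a_out
    ratio = np.inf if inside == 0 else outside / inside
    return CloneMeasurement(inside_density=inside, outside_density=outside,
                            ratio_out_in=float(ratio),
                            inside_area_um2=float(a_in), outside_area_um2=float(a_out))


# --------------------------------------------------------------------------
# puncta
# --------------------------------------------------------------------------

def detect_puncta(image, pixel_size: float = 1.0, origin=(0.0, 0.0),
                  sigma_um: float = 0.3, threshold: float = 5.0,
                  channel: str = "") -> pd.DataFrame:
    """Scale-space (Laplacian-of-Gaussian) blob detection of puncta.

    Returns a table with ``x_um``, ``y_um`` and ``peak`` intensity columns.
    """
    from skimage.feature import blob_log

    from .scene import ImageStack

    if isinstance(image, ImageStack):
        arr = image.channels[channel]
        pixel_size = image.pixel_size
        origin = image.origin
    else:
        arr = np.asarray(image, dtype=float)
    sigma_px = sigma_um / pixel_size
    blobs = blob_log(arr, min_sigma=0.6 * sigma_px, max_sigma=1.8 * sigma_px,
                     num_sigma=5, threshold=threshold)
    rows = blobs[:, 0].astype(int) if len(blobs) else np.array([], dtype=int)
    cols = blobs[:, 1].astype(int) if len(blobs) else np.array([], dtype=int)
    return pd.DataFrame({
        "x_um": origin[0] + cols * pixel_size,
        "y_um": origin[1] + rows * pixel_size,
        "peak": arr[rows, cols] if len(blobs) else np.array([]),
    })


def colocalization_fraction(puncta_a, puncta_b, max_dist: float = 0.5) -> float:
    """Fraction of puncta in A with a punctum of B within ``max_dist`` um.

    Nearest-centroid criterion; returns NaN (flagged undefined) for empty A.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be > 0")
    a = _punctum_coords(puncta_a)
    b = _punctum_coords(puncta_b)
    if len(a) == 0:
        warnings.warn("empty reference punctum set; colocalization undefined")
        return float("nan")
    if len(b) == 0:
        return 0.0
    d, _ = cKDTree(b).query(a)
    return float(np.mean(d <= max_dist))


def _punctum_coords(p) -> np.ndarray:
    if isinstance(p, pd.DataFrame):
        return p[["x_um", "y_um"]].to_numpy(dtype=float)
    arr = np.asarray(p, dtype=float)
    return arr.reshape(0, 2) if arr.size == 0 else np.atleast_2d(arr)
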