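"""Dendrite ROI refinement, path fitting, segmentation and clustering.

A manually drawn dendrite mask ``X`` is refined to ``N(G(X))^3`` (Gaussian
blur, peak-normalize, elementwise cube) which suppresses low-intensity
pixels.  The refined mask is reduced to an intensity-weighted third-order
polynomial backbone, cut into ~4.8 um segments, and per-segment fluorescence
traces are extracted as weighted pixel averages.  Segments are finally
grouped into putative cells by average-linkage clustering of the pairwise
Pearson correlation of their spike-band (baseline-removed) traces: segments
of one Purkinje dendrite share every complex spike and therefore correlate
strongly, while photobleaching and slow drift - which are correlated across
the whole field of view - are removed before the correlation is computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform

from .data import Movie

__all__ = [
    "refine_mask",
    "DendritePath",
    "fit_dendrite_path",
    "arc_segment_edges",
    "SegmentSet",
    "segment_path",
    "extract_traces",
    "CellCluster",
    "cluster_segments",
]


def refine_mask(raw: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Refine a raw (binary or weighted) mask: ``N(G(X))^3``.

    Parameters
    ----------
    raw : 2-D array
        Manually drawn mask; any non-negative weighting.
    sigma : float
        Gaussian blur in pixels.  ``sigma=0`` only normalizes and cubes.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not np.any(raw > 0):
        raise ValueError("mask is empty")
    g = gaussian_filter(raw, sigma) if sigma > 0 else raw
    n = g / g.max()
    return n**3


@dataclass
class DendritePath:
    """Third-order polynomial backbone of a dendrite.

    The cubic ``v(u)`` lives in the principal-axis frame of the weighted
    mask (``origin_um`` + rows of ``axes``), which keeps the fit well-posed
    for dendrites at any orientation.  ``coeffs_xy`` re-expresses the path
    as image-coordinate ``y(x)`` coefficients when the path is monotone in x.
    """

    origin_um: np.ndarray  # (2,) image coords (x, y), um
    axes: np.ndarray  # (2, 2) rows = unit vectors (u axis, v axis)
    coeffs: np.ndarray  # (4,) v(u) = c0 + c1 u + c2 u^2 + c3 u^3
    u_range: tuple[float, float]
    arc_length_um: float
    pixel_size_um: float

    def sample(self, n: int = 2000) -> tuple[np.ndarray, np.ndarray]:
        """Densely sample the path.

        Returns ``(points_um, arc_um)``: (n, 2) image coordinates and the
        arc-length position of each point.
        """
        u = np.linspace(self.u_range[0], self.u_range[1], n)
        v = np.polynomial.polynomial.polyval(u, self.coeffs)
        pts = self.origin_um + u[:, None] * self.axes[0] + v[:, None] * self.axes[1]
        d = np.hypot(np.diff(pts[:, 0]), np.diff(pts[:, 1]))
        arc = np.concatenate([[0.0], np.cumsum(d)])
        return pts, arc

    @property
    def coeffs_xy(self) -> np.ndarray | None:
        """Image-frame cubic ``y(x)`` coefficients, or None if not x-monotone."""
        pts, _ = self.sample()
        x, y = pts[:, 0], pts[:, 1]
        if np.all(np.diff(x) > 0) or np.all(np.diff(x) < 0):
            return np.polynomial.polynomial.polyfit(x, y, 3)
        return None


def fit_dendrite_path(mask: np.ndarray, pixel_size_um: float) -> DendritePath:
    """Fit an intensity-weighted third-order polynomial to a refined mask.

    The weighted principal axis of the mask defines the abscissa of the fit,
    so vertical or oblique dendrites are handled identically to horizontal
    ones.  Arc length is computed by dense quadrature along the fitted cubic.
    """
    w = np.asarray(mask, dtype=float)
    rows, cols = np.nonzero(w > 0)
    if rows.size == 0:
        raise ValueError("mask is empty")
    weights = w[rows, cols]
    pts = np.stack([cols * pixel_size_um, rows * pixel_size_um], axis=1)
    mu = np.average(pts, axis=0, weights=weights)
    centered = pts - mu
    cov = (centered * weights[:, None]).T @ centered / weights.sum()
    evals, evecs = np.linalg.eigh(cov)
    # eigh returns ascending order: axis 0 = major, axis 1 = minor
    e1, e2 = evecs[:, 1], evecs[:, 0]
    if evals[0] > 0 and evals[1] / max(evals[0], 1e-30) < 2.25:
        raise ValueError("mask support is isotropic; no principal direction")
    u = centered @ e1
    v = centered @ e2
    span_px = (u.max() - u.min()) / pixel_size_um
    if span_px < 10:
        raise ValueError(
            f"mask spans only {span_px:.1f} px along its principal axis (need >= 10)"
        )
    coeffs = np.polynomial.polynomial.polyfit(u, v, 3, w=np.sqrt(weights))
    # trim the path to the central 99% of the weight mass along u, so faint
    # blur tails beyond the dendrite ends do not stretch the backbone
    order = np.argsort(u)
    cum = np.cumsum(weights[order])
    cum = cum / cum[-1]
    u_lo = float(u[order][np.searchsorted(cum, 0.005)])
    u_hi = float(u[order][np.searchsorted(cum, 0.995, side="right") - 1])
    path = DendritePath(
        origin_um=mu,
        axes=np.stack([e1, e2]),
        coeffs=coeffs,
        u_range=(u_lo, u_hi),
        arc_length_um=0.0,
        pixel_size_um=pixel_size_um,
    )
    _, arc = path.sample()
    path.arc_length_um = float(arc[-1])
    return path


def arc_segment_edges(length_um: float, segment_length_um: float = 4.8) -> np.ndarray:
    """Arc-length segment boundaries with the trailing-remainder policy.

    ``floor(L / s)`` full segments; a remainder shorter than half the target
    length is merged into the last segment, otherwise it stands alone.
    """
    if segment_length_um <= 0:
        raise ValueError("segment length must be positive")
    if length_um < segment_length_um / 2:
        raise ValueError(
            f"arc length {length_um:.2f} um shorter than half a segment "
            f"({segment_length_um / 2:.2f} um)"
        )
    n_full = int(np.floor(length_um / segment_length_um + 1e-9))
    edges = [i * segment_length_um for i in range(n_full + 1)]
    if n_full == 0:
        return np.array([0.0, length_um])
    remainder = length_um - edges[-1]
    if remainder > 1e-9:
        if remainder < 0.5 * segment_length_um:
            edges[-1] = length_um
        else:
            edges.append(length_um)
    return np.asarray(edges)


@dataclass
class SegmentSet:
    """Ordered dendritic segments with per-pixel weights."""

    path: DendritePath
    edges_um: np.ndarray  # (n_segments + 1,)
    labels: np.ndarray  # (H, W) segment index or -1
    weights: np.ndarray  # (H, W) mask weights
    pixel_size_um: float

    @property
    def n_segments(self) -> int:
        return len(self.edges_um) - 1

    @property
    def lengths_um(self) -> np.ndarray:
        return np.diff(self.edges_um)

    def segment_weight_map(self, i: int) -> np.ndarray:
        out = np.where(self.labels == i, self.weights, 0.0)
        return out


def segment_path(
    path: DendritePath,
    mask: np.ndarray,
    segment_length_um: float = 4.8,
) -> SegmentSet:
    """Cut the dendrite into ~``segment_length_um`` segments.

    Every mask pixel is assigned to the segment of its nearest point on the
    fitted path (measured in image coordinates).
    """
    edges = arc_segment_edges(path.arc_length_um, segment_length_um)
    w = np.asarray(mask, dtype=float)
    rows, cols = np.nonzero(w > 0)
    pts = np.stack([cols * path.pixel_size_um, rows * path.pixel_size_um], axis=1)
    dense, arc = path.sample(4000)
    tree = cKDTree(dense)
    _, idx = tree.query(pts)
    pix_arc = arc[idx]
    labels_flat = np.clip(np.searchsorted(edges, pix_arc, side="right") - 1, 0, len(edges) - 2)
    labels = np.full(w.shape, -1, dtype=int)
    labels[rows, cols] = labels_flat
    return SegmentSet(
        path=path,
        edges_um=edges,
        labels=labels,
        weights=w,
        pixel_size_um=path.pixel_size_um,
    )


def extract_traces(
    movie: Movie,
    segments: SegmentSet,
    gated_frames: np.ndarray | None = None,
) -> np.ndarray:
    """Weighted-average fluorescence trace of every segment.

    ``trace_t = sum_i w_i F_i(t) / sum_i w_i`` over the segment's pixels.
    Gated frames propagate as NaN (missing samples).
    """
    if movie.data.shape[1:] != segments.labels.shape:
        raise ValueError("movie and segmentation geometry differ")
    flat = movie.data.reshape(movie.n_frames, -1)
    wmat = np.empty((flat.shape[1], segments.n_segments), dtype=flat.dtype)
    for i in range(segments.n_segments):
        wmap = segments.segment_weight_map(i).ravel()
        total = wmap.sum()
        if total <= 0:
            raise ValueError(f"segment {i} has zero total weight")
        wmat[:, i] = wmap / total
    traces = (flat @ wmat).T.astype(float)
    if gated_frames is not None:
        traces[:, np.asarray(gated_frames, dtype=bool)] = np.nan
    return traces


@dataclass
class CellCluster:
    """A putative cell: a group of mutually correlated dendrite segments."""

    segment_ids: np.ndarray
    trace: np.ndarray  # mean of member traces
    corr: np.ndarray  # pairwise Pearson r of member spike-band traces


def _spike_band(traces: np.ndarray, frame_rate: float, cutoff_hz: float) -> np.ndarray:
    """One-frame-smoothed, baseline-removed traces: keeps the shared complex
    spikes, discards the (globally correlated) photobleach and slow drift."""
    from .traces import compute_baseline  # local import: avoid a cycle at load

    from scipy.ndimage import gaussian_filter1d

    out = np.empty_like(traces)
    for i, tr in enumerate(traces):
        filled = tr.copy()
        bad = ~np.isfinite(filled)
        if bad.any():
            good = ~bad
            filled[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(good), filled[good])
        smooth = gaussian_filter1d(filled, 1.0)
        out[i] = smooth - compute_baseline(smooth, frame_rate, cutoff_hz=cutoff_hz)
    return out


def cluster_segments(
    traces: np.ndarray,
    frame_rate: float,
    threshold_r: float = 0.5,
    baseline_cutoff_hz: float = 4.0,
) -> tuple[list[CellCluster], list[int]]:
    """Group segments into cells by average-linkage correlation clustering.

    Pearson r is computed between the spike-band (baseline-removed) traces of
    every pair of segments; the dendrogram on distance ``1 - r`` is cut at
    ``1 - threshold_r``.  Constant (zero-variance) segments are excluded with
    a warning.

    Returns ``(clusters, excluded_segment_ids)``.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 1:
        raise ValueError("need a (n_segments, T) trace array with >= 1 segment")
    if traces.shape[1] < 200:
        raise ValueError("traces must be at least 200 frames long")
    band = _spike_band(traces, frame_rate, baseline_cutoff_hz)
    sd = band.std(axis=1)
    with np.errstate(invalid="ignore"):
        const = (np.nanmax(traces, axis=1) - np.nanmin(traces, axis=1)) == 0
    sd[const] = 0.0
    excluded = [int(i) for i in np.flatnonzero(sd == 0)]
    if excluded:
        warnings.warn(f"excluding {len(excluded)} constant segment(s): {excluded}")
    keep = np.flatnonzero(sd > 0)
    if keep.size == 0:
        return [], excluded
    band = band[keep]
    if keep.size == 1:
        r = np.ones((1, 1))
        assign = np.array([1])
    else:
        r = np.corrcoef(band)
        d = np.clip(1.0 - r, 0.0, None)
        np.fill_diagonal(d, 0.0)
        z = linkage(squareform((d + d.T) / 2, checks=False), method="average")
        assign = fcluster(z, t=1.0 - threshold_r, criterion="distance")
    clusters = []
    for label in np.unique(assign):
        members = keep[assign == label]
        clusters.append(
            CellCluster(
                segment_ids=members,
                trace=traces[members].mean(axis=0),
                corr=r[np.ix_(np.searchsorted(keep, members), np.searchsorted(keep, members))],
            )
        )
    clusters.sort(key=lambda c: int(c.segment_ids.min()))
    return clusters, excluded
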