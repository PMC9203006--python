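"""Wall-surface hemodynamic metrics: WSS, TAWSS, OSI, mixed-viscosity
conversion, ridge/groove classification, regional averages, endocardial
area strain, and the exact Wilcoxon signed-rank test.

Conventions: wall shear stress tau = mu * gamma (Pa) where gamma (1/s) is
the signed tangential wall shear rate produced by the solver. Time series
are sampled uniformly over one cycle with periodic closure, so the
time-averaged magnitude (TAWSS) is the periodic trapezoidal mean and the
oscillatory shear index is OSI = (1 - |integral tau dt| / integral |tau| dt)/2,
which is 0 for unidirectional shear, 1/2 for zero-mean oscillation, and is
invariant under positive rescaling of tau -- hence viscosity-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "WSSSeries", "RegionMask", "StrainField", "MetricsError",
    "wss", "mixed_viscosity_wss", "tawss", "osi",
    "classify_ridge_groove", "region_average",
    "area_strain", "extrude_boundary", "wilcoxon_exact", "metrics_table",
]

PLASMA_CP = 1.5e-3   # Pa s
BLOOD_CP = 7.35e-3   # Pa s

_REGIONS = ("ridge", "groove", "excluded", "cell")


class MetricsError(ValueError):
    """Invalid metric input."""


@dataclass
class WSSSeries:
    """Per-node wall shear stress over one cycle.

    ``values`` has shape (n_frames, n_nodes) for the signed tangential
    component or (n_frames, n_nodes, 2) for the in-plane vector; both
    integrate identically into TAWSS/OSI because the tangential component
    carries the sign information in 2D.
    """

    values: np.ndarray
    cycle_duration: float
    labels: np.ndarray | None = None
    weights: np.ndarray | None = None
    viscosity: float | np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def magnitude(self) -> np.ndarray:
        if self.values.ndim == 3:
            return np.linalg.norm(self.values, axis=-1)
        return np.abs(self.values)


@dataclass
class RegionMask:
    """Frame-invariant per-node region labels."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        bad = set(map(str, self.labels)) - set(_REGIONS)
        if bad:
            raise MetricsError(f"unknown region labels: {sorted(bad)}")

    def nodes(self, region: str) -> np.ndarray:
        return np.flatnonzero(self.labels == region)


def _values(series) -> np.ndarray:
    return series.values if isinstance(series, WSSSeries) else np.asarray(series, float)


# --------------------------------------------------------------------------
# WSS from shear rate
# --------------------------------------------------------------------------

def wss(gamma, mu: float, cycle_duration: float = 0.25, **kw) -> WSSSeries:
    """Wall shear stress series tau = mu * gamma (Pa) from a shear-rate
    series (1/s). ``gamma`` is an array (n_frames, n_nodes[, 2])."""
    if mu <= 0:
        raise MetricsError("viscosity must be > 0")
    g = _values(gamma)
    return WSSSeries(values=mu * g, cycle_duration=cycle_duration,
                     viscosity=mu, **kw)


def mixed_viscosity_wss(gamma, mask: RegionMask,
                        mu_plasma: float = PLASMA_CP,
                        mu_blood: float = BLOOD_CP,
                        cycle_duration: float = 0.25, **kw) -> WSSSeries:
    """Mixed-viscosity WSS: intra-trabecular (groove) surfaces use plasma
    viscosity -- blood cells are excluded from the narrow spaces by their
    size -- while all other wall surfaces use whole-blood viscosity.
    Trapped-cell surfaces sit inside grooves and also use plasma. By Stokes
    linearity this equals the node-wise combination of two full solves.
    """
    g = _values(gamma)
    labels = np.asarray(mask.labels, dtype=object)
    if labels.shape[0] != g.shape[1]:
        raise MetricsError("mask does not cover every wall node")
    mu = np.where(np.isin(labels.astype(str), ("groove", "cell")),
                  mu_plasma, mu_blood).astype(float)
    shape = (1, -1) + (1,) * (g.ndim - 2)
    return WSSSeries(values=g * mu.reshape(shape), cycle_duration=cycle_duration,
                     labels=labels, viscosity=mu, **kw)


# --------------------------------------------------------------------------
# temporal statistics
# --------------------------------------------------------------------------

def tawss(series) -> np.ndarray:
    """Time-averaged WSS magnitude, (1/T) integral |tau| dt per node, by the
    periodic trapezoidal rule on the uniform frame grid (which reduces to
    the frame mean of |tau|)."""
    v = _values(series)
    if v.shape[0] < 2:
        raise MetricsError("tawss needs at least two frames")
    mag = np.linalg.norm(v, axis=-1) if v.ndim == 3 else np.abs(v)
    return mag.mean(axis=0)


def osi(series) -> np.ndarray:
    """Oscillatory shear index in [0, 1/2] per node.

    OSI = (1 - ||integral tau dt|| / integral ||tau|| dt) / 2; nodes with
    identically zero shear are assigned 0 by convention.
    """
    v = _values(series)
    if v.ndim == 2:
        num = np.abs(v.sum(axis=0))
        den = np.abs(v).sum(axis=0)
    else:
        num = np.linalg.norm(v.sum(axis=0), axis=-1)
        den = np.linalg.norm(v, axis=-1).sum(axis=0)
    out = np.zeros(v.shape[1])
    nz = den > 0
    out[nz] = 0.5 * (1.0 - num[nz] / den[nz])
    return np.clip(out, 0.0, 0.5)


# --------------------------------------------------------------------------
# regions
# --------------------------------------------------------------------------

def classify_ridge_groove(boundary: np.ndarray, threshold: float = 2.0,
                          iterations: int = 5, trim: float = 0.55,
                          manual_mask: RegionMask | None = None) -> RegionMask:
    """Label boundary nodes ridge/groove by signed recession beyond the
    smooth ridge-crest envelope.

    Automated surrogate for manual delineation of the indented regions:
    the crest envelope is estimated as a general conic (ellipse) fitted by
    trimmed least squares -- each pass drops the most recessed nodes so the
    intra-trabecular excursions cannot drag the envelope outward. Nodes
    receding more than ``threshold`` um beyond the envelope are grooves.
    A supplied manual mask is honoured verbatim.
    """
    if manual_mask is not None:
        return manual_mask
    if threshold <= 0:
        raise MetricsError("threshold must be > 0")
    pts = np.asarray(boundary, dtype=float)
    if pts.shape[0] < 8:
        raise MetricsError("need at least 8 boundary nodes")
    keep = np.ones(pts.shape[0], dtype=bool)
    resid = np.zeros(pts.shape[0])
    for _ in range(iterations):
        x, y = pts[keep, 0], pts[keep, 1]
        design = np.stack([x * x, x * y, y * y, x, y], axis=1)
        w, *_ = np.linalg.lstsq(design, np.ones(len(x)), rcond=None)
        a, b, c, d, e = w
        quad = np.array([[a, b / 2], [b / 2, c]])
        eig = np.linalg.eigvalsh(quad)
        if np.any(eig <= 0):      # degenerate fit: fall back to a circle
            ctr = pts[keep].mean(axis=0)
            v = pts - ctr
            renv = np.full(pts.shape[0],
                           np.linalg.norm(pts[keep] - ctr, axis=1).mean())
        else:
            ctr = np.linalg.solve(-2 * quad, [d, e])
            f_ctr = ctr @ quad @ ctr + np.array([d, e]) @ ctr - 1.0
            norm_quad = quad / (-f_ctr)
            v = pts - ctr
            u = v / np.linalg.norm(v, axis=1, keepdims=True)
            renv = 1.0 / np.sqrt(np.einsum("ni,ij,nj->n", u, norm_quad, u))
        resid = np.linalg.norm(v, axis=1) - renv
        keep = resid <= max(float(np.quantile(resid, trim)), 0.0)
        if keep.sum() < 8:
            break
    labels = np.where(resid > threshold, "groove", "ridge")
    return RegionMask(labels.astype(object))


def region_average(field: np.ndarray, mask: RegionMask, region: str,
                   weights: np.ndarray | None = None
                   ) -> tuple[float, float]:
    """Area-weighted (mean, sd) of a per-node scalar over one region;
    weights default to uniform, normally the incident boundary segment
    half-lengths."""
    field = np.asarray(field, dtype=float)
    idx = mask.nodes(region)
    if idx.size == 0:
        raise MetricsError(f"region '{region}' is empty")
    w = np.ones(field.shape[0]) if weights is None else np.asarray(weights, float)
    w = w[idx]
    f = field[idx]
    mean = float(np.sum(w * f) / np.sum(w))
    sd = float(np.sqrt(np.sum(w * (f - mean) ** 2) / np.sum(w)))
    return mean, sd


def metrics_table(series: WSSSeries, mask: RegionMask,
                  weights: np.ndarray | None = None) -> pd.DataFrame:
    """Per-region table of TAWSS and OSI (area-weighted means +- sd)."""
    ta = tawss(series)
    os_ = osi(series)
    rows = []
    for region in ("ridge", "groove", "cell"):
        idx = mask.nodes(region)
        if idx.size == 0:
            continue
        tm, ts = region_average(ta, mask, region, weights)
        om, osd = region_average(os_, mask, region, weights)
        rows.append({"region": region, "n_nodes": int(idx.size),
                     "tawss_pa": tm, "tawss_sd": ts,
                     "osi": om, "osi_sd": osd})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# endocardial area strain
# --------------------------------------------------------------------------

@dataclass
class StrainField:
    """Per-element relative area change end-diastole -> end-systole."""

    strain: np.ndarray
    ed_areas: np.ndarray
    meta: dict = field(default_factory=dict)

    def mean_abs(self) -> float:
        """Area-weighted mean of |strain| (the averaging convention is
        recorded in ``meta``)."""
        return float(np.sum(self.ed_areas * np.abs(self.strain))
                     / np.sum(self.ed_areas))

    def histogram(self, bins: int = 20, range_=None):
        return np.histogram(self.strain, bins=bins, range=range_,
                            weights=self.ed_areas)


def _face_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    p = vertices[faces]
    return 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=-1)


def area_strain(surface_ed, surface_es) -> StrainField:
    """Per-element area strain (A_ES - A_ED)/A_ED between two triangulated
    surfaces with identical topology (element correspondence by index)."""
    v_ed, f_ed = surface_ed
    v_es, f_es = surface_es
    f_ed, f_es = np.asarray(f_ed), np.asarray(f_es)
    if f_ed.shape != f_es.shape or not np.array_equal(f_ed, f_es):
        raise MetricsError("surfaces must share element topology")
    a_ed = _face_areas(np.asarray(v_ed, float), f_ed)
    a_es = _face_areas(np.asarray(v_es, float), f_es)
    if np.any(a_ed <= 0):
        raise MetricsError("degenerate element in end-diastolic surface")
    strain = (a_es - a_ed) / a_ed
    return StrainField(strain=strain, ed_areas=a_ed,
                       meta={"summary": "area-weighted mean of |strain|",
                             "weights": "end-diastolic element areas"})


def extrude_boundary(mb, frame: int, height: float | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Triangulated prismatic surface from the main boundary loop of one
    frame, extruded out of plane by ``height`` (defaults to the mean
    longitudinal groove dimension, the out-of-plane extent an optical
    section does not resolve). Face ordering is frame-independent, giving
    the element correspondence needed for strain."""
    if height is None:
        longs = mb.metadata.get("groove_longs")
        height = float(np.mean(longs)) if longs is not None and len(longs) \
            else 12.5
    ring = mb.loop_coords(frame, 0)
    n = ring.shape[0]
    bottom = np.column_stack([ring, np.zeros(n)])
    top = np.column_stack([ring, np.full(n, height)])
    vertices = np.vstack([bottom, top])
    i = np.arange(n)
    j = (i + 1) % n
    faces = np.vstack([np.column_stack([i, j, n + i]),
                       np.column_stack([j, n + j, n + i])])
    return vertices, faces


# --------------------------------------------------------------------------
# exact Wilcoxon signed-rank test
# --------------------------------------------------------------------------

def wilcoxon_exact(differences, alternative: str = "greater") -> float:
    """Exact signed-rank p-value by full enumeration of the 2^n sign
    assignments of the ranks of |d| (ties get average ranks; zeros are
    dropped with a warning). ``alternative``: 'greater' tests for positive
    shift (the one-sided test whose floor at n = 4 is 1/16 = 0.0625),
    'less' for negative shift, 'two-sided' doubles the smaller tail.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise MetricsError("no differences supplied")
    nz = d != 0
    if not nz.any():
        raise MetricsError("all paired differences are zero")
    if not nz.all():
        warnings.warn(f"dropping {np.sum(~nz)} zero difference(s)",
                      stacklevel=2)
        d = d[nz]
    n = d.size
    if n > 24:
        raise MetricsError("exact enumeration limited to n <= 24")
    ranks = rankdata(np.abs(d))
    r2 = np.rint(2.0 * ranks).astype(int)        # integer lattice (ties -> .5)
    w_plus2 = int(np.sum(r2[d > 0]))
    total2 = int(r2.sum())

    # subset-sum distribution of W+ over all 2^n assignments
    counts = np.zeros(total2 + 1, dtype=np.int64)
    counts[0] = 1
    for r in r2:
        counts[r:] = counts[r:] + counts[:-r]
    denom = float(2 ** n)
    p_greater = float(counts[w_plus2:].sum()) / denom
    p_less = float(counts[: w_plus2 + 1].sum()) / denom
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    if alternative == "two-sided":
        return min(1.0, 2.0 * min(p_greater, p_less))
    raise MetricsError(f"unknown alternative '{alternative}'")
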