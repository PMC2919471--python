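"""Embryo midsagittal geometry: contour vs projected distance.

The early *Drosophila* embryo is asymmetric about its anterior-posterior
(A-P) axis: the ventral perimeter is longer than the dorsal one.  Position
along the axis can therefore be measured two ways that disagree with each
other away from the poles:

* **projected distance** ``x`` -- the scalar projection of a point onto the
  A-P axis, measured from the anterior pole;
* **contour distance** ``c`` -- the arc length accumulated along the dorsal
  or ventral perimeter from the anterior pole.

This module holds the planar midsagittal representation of an embryo
(:class:`MidsagittalContour`), both distance measures, the dorsoventral
shape-difference profile ``delta_c_embryo(x/L) = c_D(x) - c_V(x)``, cohort
average shapes, and the semi-ellipsoid 3-D model used by the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ShapeParams",
    "MidsagittalContour",
    "AverageFrame",
    "cumulative_contour_distance",
    "project_to_axis",
    "build_semi_ellipsoid_shape",
    "delta_c_embryo_profile",
    "average_embryo_frame",
    "read_contour_tsv",
    "write_contour_tsv",
    "write_frame_tsv",
]


@dataclass(frozen=True)
class ShapeParams:
    """Semi-axes of the two-semi-ellipsoid embryo model, all in micrometres.

    The embryo is modelled as two half-ellipsoids joined on the coronal
    plane: a dorsal half with D-V semi-axis ``dorsal_height`` and a ventral
    half with ``ventral_height``, sharing the A-P semi-axis ``length/2``
    and the lateral semi-axis ``lateral_diameter/2``.
    """

    length: float = 560.0
    lateral_diameter: float = 220.0
    dorsal_height: float = 92.0
    ventral_height: float = 128.0

    def __post_init__(self) -> None:
        for name in ("length", "lateral_diameter", "dorsal_height", "ventral_height"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"ShapeParams.{name} must be positive, got {getattr(self, name)!r}")


def cumulative_contour_distance(points: np.ndarray | Sequence) -> np.ndarray:
    """Cumulative arc length along an ordered planar polyline, in um.

    ``out[j]`` is the sum of Euclidean segment lengths from the first point
    up to point ``j``; ``out[0] == 0``.  This is the contour distance ``c``
    of a chain of scanning-window centres.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("empty path")
    pts = pts.reshape(-1, 2)
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinates in path")
    seg = np.hypot(np.diff(pts[:, 0]), np.diff(pts[:, 1]))
    return np.concatenate([[0.0], np.cumsum(seg)])


def project_to_axis(
    point: np.ndarray | Sequence,
    anterior_pole: np.ndarray | Sequence,
    posterior_pole: np.ndarray | Sequence,
) -> np.ndarray | float:
    """Scalar projection of ``point`` onto the anterior->posterior unit axis.

    Returns 0 at the anterior pole and the pole-to-pole distance ``L`` at
    the posterior pole.  ``point`` may be one point or an ``(n, 2)`` array.
    """
    a = np.asarray(anterior_pole, dtype=float)
    p = np.asarray(posterior_pole, dtype=float)
    axis = p - a
    norm = np.hypot(*axis)
    if norm == 0:
        raise ValueError("anterior and posterior poles coincide")
    pts = np.asarray(point, dtype=float)
    single = pts.ndim == 1
    pts = pts.reshape(-1, 2)
    x = (pts - a) @ (axis / norm)
    return float(x[0]) if single else x


@dataclass
class MidsagittalContour:
    """Ordered dorsal and ventral perimeter arcs of one embryo.

    Both arcs run from the anterior pole to the posterior pole.  After
    :meth:`align`, the anterior pole sits at the origin, the A-P axis is +x,
    dorsal points have y >= 0 and ventral points y <= 0.
    """

    dorsal_arc: np.ndarray
    ventral_arc: np.ndarray
    anterior_pole: np.ndarray = field(default=None)  # type: ignore[assignment]
    posterior_pole: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dorsal_arc = np.asarray(self.dorsal_arc, dtype=float).reshape(-1, 2)
        self.ventral_arc = np.asarray(self.ventral_arc, dtype=float).reshape(-1, 2)
        if self.anterior_pole is None:
            self.anterior_pole = self.dorsal_arc[0].copy()
        if self.posterior_pole is None:
            self.posterior_pole = self.dorsal_arc[-1].copy()
        self.anterior_pole = np.asarray(self.anterior_pole, dtype=float)
        self.posterior_pole = np.asarray(self.posterior_pole, dtype=float)

    # -- basic measures -------------------------------------------------
    @property
    def L(self) -> float:
        """Projected A-P axis length (pole-to-pole distance), um."""
        return float(np.hypot(*(self.posterior_pole - self.anterior_pole)))

    @property
    def C_D(self) -> float:
        """Total dorsal contour length, um."""
        return float(cumulative_contour_distance(self.dorsal_arc)[-1])

    @property
    def C_V(self) -> float:
        """Total ventral contour length, um."""
        return float(cumulative_contour_distance(self.ventral_arc)[-1])

    def align(self) -> "MidsagittalContour":
        """Return a pole-aligned copy: anterior at origin, A-P axis = +x.

        Poles are re-identified as the two contour points at maximal mutual
        distance; the anterior pole is the one nearest the stored anterior.
        Dorsal y is made non-negative.
        """
        allpts = np.vstack([self.dorsal_arc, self.ventral_arc])
        # candidate pole pair: ends of the arcs are poles by construction,
        # but re-derive from max mutual distance among hull-ish extremes
        from scipy.spatial.distance import cdist

        ends = np.vstack([self.dorsal_arc[0], self.dorsal_arc[-1],
                          self.ventral_arc[0], self.ventral_arc[-1]])
        cand = np.vstack([ends, allpts[np.argmax(allpts[:, 0])],
                          allpts[np.argmin(allpts[:, 0])]])
        dmat = cdist(cand, cand)
        i, j = np.unravel_index(np.argmax(dmat), dmat.shape)
        p1, p2 = cand[i], cand[j]
        if np.hypot(*(p1 - self.anterior_pole)) <= np.hypot(*(p2 - self.anterior_pole)):
            ant, post = p1, p2
        else:
            ant, post = p2, p1
        axis = post - ant
        theta = np.arctan2(axis[1], axis[0])
        rot = np.array([[np.cos(-theta), -np.sin(-theta)],
                        [np.sin(-theta), np.cos(-theta)]])
        d = (self.dorsal_arc - ant) @ rot.T
        v = (self.ventral_arc - ant) @ rot.T
        if np.trapezoid(d[:, 1], d[:, 0]) < 0:  # dorsal should sit above the axis
            d[:, 1] *= -1.0
            v[:, 1] *= -1.0
        return MidsagittalContour(d, v, np.zeros(2), (post - ant) @ rot.T)

    # -- coordinate mapping ---------------------------------------------
    def _arc_tables(self, side: str) -> tuple[np.ndarray, np.ndarray]:
        """Monotone (x, c) interpolation table for one arc."""
        arc = self.dorsal_arc if side == "D" else self.ventral_arc
        x = project_to_axis(arc, self.anterior_pole, self.posterior_pole)
        c = cumulative_contour_distance(arc)
        # restrict to the pole-to-pole parameterization: enforce monotone x
        x = np.maximum.accumulate(x)
        return x, c

    def contour_at_x(self, x: np.ndarray | float, side: str) -> np.ndarray | float:
        """Interpolate contour distance c at projected distance x on one arc."""
        xs, cs = self._arc_tables(side)
        return np.interp(x, xs, cs)

    def x_at_contour(self, c: np.ndarray | float, side: str) -> np.ndarray | float:
        """Interpolate projected distance x at contour distance c on one arc."""
        xs, cs = self._arc_tables(side)
        return np.interp(c, cs, xs)

    def y_at_x(self, x: np.ndarray | float, side: str) -> np.ndarray | float:
        """Interpolate the perimeter D-V coordinate y at projected x."""
        arc = self.dorsal_arc if side == "D" else self.ventral_arc
        xs = np.maximum.accumulate(
            project_to_axis(arc, self.anterior_pole, self.posterior_pole))
        return np.interp(x, xs, arc[:, 1])


@dataclass
class AverageFrame:
    """Cohort-mean normalized midsagittal shape on a shared x/L grid."""

    x_over_L: np.ndarray
    yD_over_L: np.ndarray
    yV_over_L: np.ndarray
    n: int


def build_semi_ellipsoid_shape(
    params: ShapeParams, n_points: int = 400
) -> tuple[MidsagittalContour, Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]]:
    """Two-semi-ellipsoid embryo: midsagittal contour plus 3-D interior test.

    The midsagittal dorsal arc is the half-ellipse with semi-axes
    ``(length/2, dorsal_height)``; ventral likewise.  The interior predicate
    evaluates ``((x-a)/a)^2 + (y/b_side)^2 + (z/(lateral_diameter/2))^2 <= 1``
    with ``b_side`` selected by the sign of y.

    Returns ``(contour, interior)`` where ``interior(x, y, z)`` accepts
    scalar or broadcastable arrays of coordinates in um.
    """
    if n_points < 16:
        raise ValueError("n_points must be >= 16")
    a = params.length / 2.0
    cz = params.lateral_diameter / 2.0
    t = np.linspace(0.0, np.pi, n_points)
    x = a - a * np.cos(t)
    dorsal = np.column_stack([x, params.dorsal_height * np.sin(t)])
    ventral = np.column_stack([x, -params.ventral_height * np.sin(t)])

    bD, bV = params.dorsal_height, params.ventral_height

    def interior(px, py, pz):
        px = np.asarray(px, dtype=float)
        py = np.asarray(py, dtype=float)
        pz = np.asarray(pz, dtype=float)
        b = np.where(py >= 0, bD, bV)
        return ((px - a) / a) ** 2 + (py / b) ** 2 + (pz / cz) ** 2 <= 1.0

    contour = MidsagittalContour(dorsal, ventral, np.array([0.0, 0.0]),
                                 np.array([params.length, 0.0]))
    return contour, interior


def inset_arc(
    contour: MidsagittalContour, side: str, inset: float, step: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Scanning-window centre chain on an arc offset inward by ``inset``.

    Centres are placed at constant steps of projected distance x along the
    arc shifted ``inset`` um along its inward normal (toward the A-P
    axis), emulating the sliding-window trajectory in the cortical nuclear
    layer.  Returns ``(x, y, c, centres)``: projected distance, centre
    D-V coordinate, cumulative contour distance over the centres (arc
    length from the anterior start of the chain), and the raw (n, 2)
    centre coordinates in the contour frame.
    """
    arc = contour.dorsal_arc if side == "D" else contour.ventral_arc
    d = np.gradient(arc, axis=0)
    tang = d / np.maximum(np.hypot(d[:, 0], d[:, 1]), 1e-12)[:, None]
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    # inward = toward the A-P axis (midline through the poles)
    midline = 0.5 * (contour.anterior_pole[1] + contour.posterior_pole[1])
    sgn = -np.sign(np.sum(normal[:, 1] * (arc[:, 1] - midline)) or 1.0)
    centres = arc + sgn * inset * normal
    xproj = np.maximum.accumulate(
        project_to_axis(centres, contour.anterior_pole, contour.posterior_pole))
    xg = np.arange(xproj[0], xproj[-1], step)
    cx = np.interp(xg, xproj, centres[:, 0])
    cy = np.interp(xg, xproj, centres[:, 1])
    pts = np.column_stack([cx, cy])
    c = cumulative_contour_distance(pts)
    return xg, cy, c, pts


def delta_c_embryo_profile(
    contour: MidsagittalContour, xl_grid: np.ndarray | Sequence
) -> np.ndarray:
    """Shape-difference profile (c_D(x) - c_V(x)) / C_D at each x/L.

    The contour-distance lead of one side over the other at matched
    projected positions; identically zero for a dorsoventrally symmetric
    shape.  With the convention delta_c = c_D - c_V the values are <= 0
    wherever the ventral arc is longer.
    """
    xl = np.asarray(xl_grid, dtype=float)
    if np.any(xl < 0) or np.any(xl > 1):
        raise ValueError("x/L grid must lie in [0, 1]")
    x = xl * contour.L
    cD = contour.contour_at_x(x, "D")
    cV = contour.contour_at_x(x, "V")
    return (cD - cV) / contour.C_D


def average_embryo_frame(
    cohort: Sequence[MidsagittalContour], n_grid: int = 101
) -> AverageFrame:
    """Pointwise mean of normalized D-V perimeter positions across a cohort.

    Each embryo's arcs are sampled at a shared fractional grid x/L and the
    normalized heights y/L are averaged side by side.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    xl = np.linspace(0.0, 1.0, n_grid)
    yD = np.zeros((len(cohort), n_grid))
    yV = np.zeros((len(cohort), n_grid))
    for k, emb in enumerate(cohort):
        L = emb.L
        yD[k] = np.asarray(emb.y_at_x(xl * L, "D")) / L
        yV[k] = np.asarray(emb.y_at_x(xl * L, "V")) / L
    return AverageFrame(xl, yD.mean(axis=0), yV.mean(axis=0), len(cohort))


# ---------------------------------------------------------------------------
# TSV round trip

def write_contour_tsv(contour: MidsagittalContour, path: str | Path) -> None:
    rows = []
    for side, arc in (("D", contour.dorsal_arc), ("V", contour.ventral_arc)):
        for i, (x, y) in enumerate(arc):
            rows.append((side, i, x, y))
    df = pd.DataFrame(rows, columns=["side", "index", "x_um", "y_um"])
    df.to_csv(path, sep="\t", index=False)


def read_contour_tsv(path: str | Path) -> MidsagittalContour:
    df = pd.read_csv(path, sep="\t", comment="#")
    d = df[df["side"] == "D"].sort_values("index")[["x_um", "y_um"]].to_numpy()
    v = df[df["side"] == "V"].sort_values("index")[["x_um", "y_um"]].to_numpy()
    return MidsagittalContour(d, v)


def write_frame_tsv(frame: AverageFrame, path: str | Path) -> None:
    df = pd.DataFrame({
        "x_over_L": frame.x_over_L,
        "yD_over_L": frame.yD_over_L,
        "yV_over_L": frame.yV_over_L,
        "n": frame.n,
    })
    df.to_csv(path, sep="\t", index=False)
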