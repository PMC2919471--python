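"""Synthetic embryo cohorts with the statistical structure the analysis
assumes, so every downstream stage is testable with known ground truth.

Each synthetic embryo gets

* an asymmetric two-semi-ellipse midsagittal shape sampled around the
  cohort mean (truncated so no D-V height degenerates),
* a Bicoid profile exponential in **contour** distance on each side,
  ``B(c) = B0 * exp(-c / lambda_c) * (1 + eps_window) + background``, with
  multiplicative per-window Gaussian noise and an embryo-level amplitude
  factor ``B0 * (1 + eta)``,
* a Hunchback readout generated from the background-free Bicoid signal via
  the Hill input-output relation ``H = (B/K_d)^n / (1 + (B/K_d)^n)`` plus
  additive Gaussian expression noise, scaled to raw-like intensity units.

Default calibration: the contour length constants (104.8 / 115.5 um), the
Hill parameters (K_d = 5 intensity units, n = 5), the backgrounds
(2.19 / 2.13) and the half-maximal boundary contour positions
(c_HbD = 284.6, c_HbV = 279.1 um) are the wild-type cohort values the
pipeline is expected to recover; the amplitudes B0 follow from
``B0 = K_d * exp(c_Hb / lambda_c)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import (
    MidsagittalContour,
    ShapeParams,
    build_semi_ellipsoid_shape,
    cumulative_contour_distance,
    project_to_axis,
)
from .profiles import CorticalTrace, DEFAULT_INSET, DEFAULT_WINDOW_AREA

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticEmbryo",
    "hill",
    "generate_cohort",
    "rasterize_embryo",
    "save_cohort",
]

# wild-type calibration: half-max Hb boundary contour positions, um
C_HB_D = 284.6
C_HB_V = 279.1
LAMBDA_C_D = 104.8
LAMBDA_C_V = 115.5
HILL_KD = 5.0
HILL_N = 5.0


def hill(B: np.ndarray | float, Kd: float = HILL_KD, n: float = HILL_N):
    """Hill input-output relation H = (B/Kd)^n / (1 + (B/Kd)^n), H(Kd) = 1/2."""
    B = np.asarray(B, dtype=float)
    out = np.zeros_like(B)
    pos = B > 0
    u = (B[pos] / Kd) ** n
    out[pos] = u / (1.0 + u)
    return out if out.ndim else float(out)


@dataclass
class SyntheticCohortSpec:
    """Cohort parameterization; defaults are the wild-type study conditions."""

    n_embryos: int = 28
    shape_mean: ShapeParams = field(default_factory=ShapeParams)
    shape_sd: tuple[float, float, float, float] = (15.0, 8.0, 5.0, 5.0)
    lambda_c_D: float = LAMBDA_C_D
    lambda_c_V: float = LAMBDA_C_V
    B0_D: float = HILL_KD * math.exp(C_HB_D / LAMBDA_C_D)  # ~75.57
    B0_V: float = HILL_KD * math.exp(C_HB_V / LAMBDA_C_V)  # ~56.03
    amplitude_cv: float = 0.25
    window_cv_D: float = 0.10
    window_cv_V: float = 0.15
    background_mean_D: float = 2.19
    background_mean_V: float = 2.13
    hill_Kd: float = HILL_KD
    hill_n: float = HILL_N
    hb_noise_sd: float = 0.10
    hb_amplitude: float = 180.0
    hb_amplitude_cv: float = 0.30
    hb_baseline: float = 10.0
    pixel_scale: float = 0.5  # um/px
    inset: float = DEFAULT_INSET
    min_height: float = 20.0  # reject shapes with a degenerate half
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_embryos < 1:
            raise ValueError("n_embryos must be >= 1")
        if self.lambda_c_D <= 0 or self.lambda_c_V <= 0:
            raise ValueError("length constants must be positive")
        if self.B0_D <= 0 or self.B0_V <= 0:
            raise ValueError("amplitudes must be positive")
        for nm in ("amplitude_cv", "window_cv_D", "window_cv_V", "hb_noise_sd"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")


@dataclass
class SyntheticEmbryo:
    """One generated embryo: shape, per-side ground truth, per-side traces."""

    contour: MidsagittalContour
    shape: ShapeParams
    ground_truth: dict  # per side: B0, lambda_c, Kd, n, background, c_Hb, x_Hb
    traces: dict[str, CorticalTrace]
    embryo_id: int = 0


def _sample_shape(spec: SyntheticCohortSpec, rng: np.random.Generator) -> ShapeParams:
    mean = spec.shape_mean
    sd = spec.shape_sd
    for _ in range(1000):
        vals = rng.normal(
            [mean.length, mean.lateral_diameter, mean.dorsal_height, mean.ventral_height],
            sd)
        if vals[0] > 4 * spec.min_height and vals[1] > 2 * spec.min_height \
                and vals[2] > spec.min_height and vals[3] > spec.min_height:
            return ShapeParams(*vals)
    raise RuntimeError("shape sampling failed (degenerate parameters)")


def _window_centres(contour: MidsagittalContour, side: str, inset: float,
                    step: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    from .geometry import inset_arc

    x, y, c, _ = inset_arc(contour, side, inset, step)
    return x, y, c


def generate_cohort(spec: SyntheticCohortSpec,
                    rng: np.random.Generator | None = None) -> list[SyntheticEmbryo]:
    """Generate a reproducible cohort of synthetic embryos.

    With all noise terms at zero the traces equal the stated model exactly,
    so the full analysis pipeline recovers every ground-truth parameter to
    fit tolerance.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    cohort = []
    for k in range(spec.n_embryos):
        shape = _sample_shape(spec, rng)
        contour, _ = build_semi_ellipsoid_shape(shape)
        # embryo-level amplitude factor, truncated so intensities stay positive
        eta = 0.0
        if spec.amplitude_cv > 0:
            eta = rng.normal(0.0, spec.amplitude_cv)
            while 1.0 + eta < 0.1:
                eta = rng.normal(0.0, spec.amplitude_cv)
        truth: dict = {}
        traces: dict[str, CorticalTrace] = {}
        for side in ("D", "V"):
            lam = spec.lambda_c_D if side == "D" else spec.lambda_c_V
            B0 = (spec.B0_D if side == "D" else spec.B0_V) * (1.0 + eta)
            wcv = spec.window_cv_D if side == "D" else spec.window_cv_V
            bg = spec.background_mean_D if side == "D" else spec.background_mean_V
            x, y, c = _window_centres(contour, side, spec.inset, spec.pixel_scale)
            B_free = B0 * np.exp(-c / lam)
            eps = rng.normal(0.0, wcv, size=c.shape) if wcv > 0 else 0.0
            bcd_raw = B_free * (1.0 + eps) + bg
            H_true = hill(B_free, spec.hill_Kd, spec.hill_n)
            hn = rng.normal(0.0, spec.hb_noise_sd, size=c.shape) \
                if spec.hb_noise_sd > 0 else 0.0
            H_noisy = np.clip(H_true + hn, 0.0, None)
            amp = spec.hb_amplitude * (1.0 + (rng.normal(0.0, spec.hb_amplitude_cv)
                                              if spec.hb_amplitude_cv > 0 else 0.0))
            amp = max(amp, 10.0)
            hb_raw = spec.hb_baseline + amp * H_noisy
            c_hb = lam * math.log(B0 / spec.hill_Kd)  # where B_free == Kd
            traces[side] = CorticalTrace(side, x, y, c, {"bcd": bcd_raw, "hb": hb_raw},
                                         contour.L, DEFAULT_WINDOW_AREA, spec.inset, k)
            truth[side] = {
                "B0": B0, "lambda_c": lam, "Kd": spec.hill_Kd, "n": spec.hill_n,
                "background": bg, "c_Hb": c_hb,
                "x_Hb": float(np.interp(c_hb, c, x)),
            }
        cohort.append(SyntheticEmbryo(contour, shape, truth, traces, k))
    return cohort


def rasterize_embryo(
    embryo: SyntheticEmbryo,
    pixel_scale: float | None = None,
    band_depth: float = 10.0,
    quantize_8bit: bool = False,
    max_canvas_px: int = 4096,
) -> tuple[np.ndarray, MidsagittalContour]:
    """Paint a midsagittal two-channel image (bcd, hb) of one embryo.

    The cortical band (depth ``band_depth`` um inside the perimeter) takes
    the trace intensity of the nearest perimeter arc position; the interior
    is painted at the side's background; outside the embryo is 0.  Returns
    the image stack of shape (2, ny, nx) and the contour shifted into image
    coordinates (um, with row 0 at the most ventral extent).
    """
    from scipy.ndimage import distance_transform_edt
    from scipy.spatial import cKDTree
    from skimage.draw import polygon2mask

    if pixel_scale is None:
        pixel_scale = 0.5
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be > 0")
    contour = embryo.contour
    margin = 4.0  # um of empty canvas around the embryo
    ymin = contour.ventral_arc[:, 1].min() - margin
    ymax = contour.dorsal_arc[:, 1].max() + margin
    xmax = contour.L + margin
    nx = int(np.ceil((xmax + margin) / pixel_scale))
    ny = int(np.ceil((ymax - ymin) / pixel_scale))
    if nx > max_canvas_px or ny > max_canvas_px:
        raise ValueError("embryo larger than allowed canvas")

    shifted = MidsagittalContour(
        contour.dorsal_arc - [-margin, ymin], contour.ventral_arc - [-margin, ymin],
        contour.anterior_pole - [-margin, ymin], contour.posterior_pole - [-margin, ymin])

    poly = np.vstack([shifted.dorsal_arc, shifted.ventral_arc[::-1]])
    # polygon2mask takes (row, col) = (y, x) vertices in pixel units
    mask = polygon2mask((ny, nx), np.column_stack([poly[:, 1], poly[:, 0]]) / pixel_scale)
    dist = distance_transform_edt(mask) * pixel_scale
    band = mask & (dist <= band_depth)

    img = np.zeros((2, ny, nx))
    for ci, chan in enumerate(("bcd", "hb")):
        bgD = embryo.ground_truth["D"]["background"] if chan == "bcd" else 0.0
        bgV = embryo.ground_truth["V"]["background"] if chan == "bcd" else 0.0
        rows, cols = np.nonzero(mask)
        py = rows * pixel_scale
        img[ci, rows, cols] = np.where(py >= shifted.anterior_pole[1], bgD, bgV)
        # nearest arc position per band pixel, per side
        rows, cols = np.nonzero(band)
        px = cols * pixel_scale
        py = rows * pixel_scale
        up = py >= shifted.anterior_pole[1]
        for side, sel in (("D", up), ("V", ~up)):
            if not np.any(sel):
                continue
            # nearest scanning-window centre (the trace's own arc
            # parameterization), shifted into image coordinates
            tr = embryo.traces[side]
            centres = np.column_stack([tr.x + margin, tr.y - ymin])
            tree = cKDTree(centres)
            _, idx = tree.query(np.column_stack([px[sel], py[sel]]))
            img[ci, rows[sel], cols[sel]] = tr.channels[chan][idx]
    if quantize_8bit:
        top = img.max() or 1.0
        img = np.round(img / top * 255.0) / 255.0 * top
    return img, shifted


def save_cohort(cohort: Sequence[SyntheticEmbryo], outdir: str | Path,
                spec: SyntheticCohortSpec | None = None) -> None:
    """Serialize a cohort: per-embryo trace TSVs plus ground-truth JSON."""
    from .profiles import write_trace_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truths = {}
    for emb in cohort:
        write_trace_tsv(emb.traces.values(), outdir / f"embryo_{emb.embryo_id:03d}.tsv")
        truths[str(emb.embryo_id)] = {
            "shape": asdict(emb.shape),
            "ground_truth": emb.ground_truth,
        }
    (outdir / "ground_truth.json").write_text(json.dumps(truths, indent=1))
    if spec is not None:
        d = asdict(spec)
        d["shape_mean"] = asdict(spec.shape_mean)
        (outdir / "cohort_spec.json").write_text(json.dumps(d, indent=1))
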