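"""Quantitative gradient analyses.

Everything the study measures on a cohort lives here: exponential
length-constant fits ``B = B0 exp(-s/lambda)`` on either distance axis,
half-maximal expression boundaries in both coordinate systems, the Hill
input-output fit between the morphogen and its target, intensity-noise
(delta B / B) and positional-error (sigma_c = delta B / |dB/dc|) profiles,
bootstrap standard deviations, per-position two-sample t-tests,
iso-concentration contours on an average embryo frame, and the paired
dorsal-ventral slant of target boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import optimize, stats as sps

from .geometry import AverageFrame
from .profiles import BinnedProfile, CorticalTrace
from .synthetic import hill

__all__ = [
    "GradientFit",
    "HillFit",
    "BoundaryEstimate",
    "NoiseProfile",
    "IsoContourSet",
    "fit_exponential",
    "find_half_max_boundary",
    "measure_kd",
    "fit_hill",
    "intensity_noise_profile",
    "positional_error",
    "bootstrap_sd",
    "compare_sides_ttest",
    "iso_concentration_contours",
    "target_slant",
]

log = logging.getLogger(__name__)

#: Default exponential fit window in fractional position (x/L or c/C):
#: excludes the anterior region where profiles deviate from an exponential
#: and the posterior floor.
DEFAULT_FIT_WINDOW = (0.10, 0.60)


@dataclass
class GradientFit:
    B0: float
    lam: float  # length constant, um
    axis: str  # "projected" or "contour"
    fit_range: tuple[float, float]
    residual: float  # RMS residual of log-intensity
    n_points: int
    n_excluded: int = 0  # non-positive intensities dropped before the log fit


@dataclass
class HillFit:
    Kd: float
    n: float
    Kd_mode: str  # "measured_at_boundary" or "fitted"
    side: str = "D"
    residual: float = float("nan")

    def __post_init__(self) -> None:
        if self.Kd <= 0 or self.n <= 0:
            raise ValueError("Hill parameters must be positive")


@dataclass
class BoundaryEstimate:
    x_b: float  # um
    c_b: float  # um
    side: str
    half_max_level: float = 0.5
    embryo_id: int | str | None = None


@dataclass
class NoiseProfile:
    abscissa: np.ndarray  # position (um) or B/Kd
    noise: np.ndarray  # delta B / B or delta H / H_max
    mean: np.ndarray
    sd: np.ndarray
    n_embryos: np.ndarray
    side: str = "D"
    kind: str = "bcd"


@dataclass
class IsoContourSet:
    thresholds: np.ndarray
    xD: np.ndarray
    xV: np.ndarray
    cD: np.ndarray
    cV: np.ndarray
    yD: np.ndarray  # frame y at xD (um, for plotting)
    yV: np.ndarray

    @property
    def dx(self) -> np.ndarray:
        """Delta x_Bcd = x_D - x_V at each threshold, um."""
        return self.xD - self.xV

    @property
    def dc(self) -> np.ndarray:
        """Delta c_Bcd = c_D - c_V at each threshold, um."""
        return self.cD - self.cV


# ---------------------------------------------------------------------------
# exponential fit

def fit_exponential(
    positions: np.ndarray,
    intensities: np.ndarray,
    fit_range: tuple[float, float] | None = None,
    axis: str = "contour",
    nonlinear_refine: bool = False,
) -> GradientFit:
    """Least-squares fit of ``B = B0 exp(-s/lambda)`` in log space.

    Non-positive intensities cannot enter the log fit; they are excluded
    and counted.  ``fit_range`` is in the same units as ``positions``
    (give ``None`` to use all points).
    """
    pos = np.asarray(positions, dtype=float)
    val = np.asarray(intensities, dtype=float)
    sel = np.isfinite(pos) & np.isfinite(val)
    if fit_range is not None:
        sel &= (pos >= fit_range[0]) & (pos <= fit_range[1])
    n_nonpos = int(np.sum(sel & (val <= 0)))
    sel &= val > 0
    if sel.sum() < 5:
        raise ValueError(f"fewer than 5 usable points in fit range ({sel.sum()})")
    p, c = pos[sel], np.log(val[sel])
    slope, intercept = np.polyfit(p, c, 1)
    if not np.isfinite(slope) or slope >= 0:
        raise ValueError("non-finite or non-decaying exponential fit")
    lam, B0 = -1.0 / slope, float(np.exp(intercept))
    resid = float(np.sqrt(np.mean((c - (intercept + slope * p)) ** 2)))
    if nonlinear_refine:
        popt, _ = optimize.curve_fit(lambda s, b0, l: b0 * np.exp(-s / l),
                                     p, val[sel], p0=[B0, lam], maxfev=10000)
        B0, lam = float(popt[0]), float(popt[1])
    rng = (float(p.min()), float(p.max())) if fit_range is None else fit_range
    return GradientFit(B0, float(lam), axis, rng, resid, int(sel.sum()), n_nonpos)


# ---------------------------------------------------------------------------
# boundaries

def find_half_max_boundary(
    x: np.ndarray,
    c: np.ndarray,
    values: np.ndarray,
    level: float = 0.5,
    side: str = "D",
    embryo_id: int | str | None = None,
    search_range_xl: tuple[float, float] | None = None,
    L: float | None = None,
) -> BoundaryEstimate:
    """Most anterior downward crossing of ``level`` in a normalized profile.

    The boundary is linearly interpolated between the bracketing windows
    and reported simultaneously in projected (x) and contour (c) distance
    from the same window pair.
    """
    x = np.asarray(x, float)
    c = np.asarray(c, float)
    v = np.asarray(values, float)
    if not (0.0 < level < 1.0):
        raise ValueError("half-max level must be inside (0, 1)")
    sel = np.ones(len(x), dtype=bool)
    if search_range_xl is not None:
        if L is None:
            raise ValueError("search range in x/L requires L")
        sel = (x / L >= search_range_xl[0]) & (x / L <= search_range_xl[1])
    idx = np.nonzero(sel)[0]
    down = [i for i in idx[:-1] if v[i] >= level > v[i + 1] and sel[i + 1]]
    if not down:
        raise ValueError("profile does not cross the half-max level")
    if len(down) > 1:
        log.warning("multiple half-max crossings; using the most anterior (%d found)",
                    len(down))
    i = down[0]
    f = (v[i] - level) / (v[i] - v[i + 1])
    return BoundaryEstimate(float(x[i] + f * (x[i + 1] - x[i])),
                            float(c[i] + f * (c[i + 1] - c[i])),
                            side, level, embryo_id)


def measure_kd(c: np.ndarray, B: np.ndarray, c_hb: float) -> float:
    """Background-subtracted morphogen intensity interpolated at c_Hb."""
    c = np.asarray(c, float)
    B = np.asarray(B, float)
    if not (c.min() <= c_hb <= c.max()):
        raise ValueError("c_Hb outside trace support")
    return float(np.interp(c_hb, c, B))


# ---------------------------------------------------------------------------
# Hill input-output fit

def fit_hill(
    B: np.ndarray,
    H: np.ndarray,
    Kd_mode: str = "fitted",
    fixed_Kd: float | None = None,
    side: str = "D",
) -> HillFit:
    """Nonlinear least squares of the Hill relation on (B, H) pairs.

    ``B`` must be background-subtracted; pairs with B <= 0 are excluded.
    The Hill exponent is always free; ``Kd`` is free (``Kd_mode="fitted"``)
    or held at ``fixed_Kd`` (``Kd_mode="measured_at_boundary"``).  The fit
    is multi-started over n in {1, 3, 5, 8} to avoid local minima.
    """
    B = np.asarray(B, float)
    H = np.asarray(H, float)
    sel = np.isfinite(B) & np.isfinite(H) & (B > 0)
    B, H = B[sel], H[sel]
    if len(B) < 8:
        raise ValueError("need >= 8 usable (B, H) pairs")
    if Kd_mode == "measured_at_boundary":
        if fixed_Kd is None or fixed_Kd <= 0:
            raise ValueError("measured_at_boundary mode requires a positive fixed_Kd")
        best = None
        for n0 in (1.0, 3.0, 5.0, 8.0):
            try:
                popt, _ = optimize.curve_fit(
                    lambda b, n: hill(b, fixed_Kd, n), B, H, p0=[n0],
                    bounds=([0.1], [50.0]), maxfev=10000)
            except RuntimeError:
                continue
            r = float(np.sum((hill(B, fixed_Kd, popt[0]) - H) ** 2))
            if best is None or r < best[1]:
                best = (popt, r)
        if best is None:
            raise RuntimeError("Hill fit failed to converge from all starts")
        return HillFit(float(fixed_Kd), float(best[0][0]), Kd_mode, side, best[1])
    if Kd_mode != "fitted":
        raise ValueError(f"unknown Kd_mode {Kd_mode!r}")
    kd0 = float(np.interp(0.5, np.sort(H), np.sort(B))) or float(np.median(B))
    best = None
    for n0 in (1.0, 3.0, 5.0, 8.0):
        try:
            popt, _ = optimize.curve_fit(
                lambda b, kd, n: hill(b, kd, n), B, H,
                p0=[max(kd0, 1e-6), n0],
                bounds=([1e-9, 0.1], [np.inf, 50.0]), maxfev=10000)
        except RuntimeError:
            continue
        r = float(np.sum((hill(B, *popt) - H) ** 2))
        if best is None or r < best[1]:
            best = (popt, r)
    if best is None:
        raise RuntimeError("Hill fit failed to converge from all starts")
    return HillFit(float(best[0][0]), float(best[0][1]), Kd_mode, side, best[1])


# ---------------------------------------------------------------------------
# noise and positional error

def intensity_noise_profile(
    per_embryo_bins,  # DataFrame: rows = embryos, cols = bin centres
    side: str = "D",
    kind: str = "bcd",
    min_embryos: int = 3,
    normalizer: float | None = None,
) -> NoiseProfile:
    """Cross-embryo noise per bin: SD of embryo-mean intensity / mean.

    ``normalizer`` replaces the per-bin mean in the denominator (used for
    delta H / H_max where H_max is the plateau level, 1 after
    normalization).  Bins with fewer than ``min_embryos`` contributing
    embryos are omitted.
    """
    counts = per_embryo_bins.notna().sum(axis=0).to_numpy()
    centers = np.asarray(per_embryo_bins.columns, dtype=float)
    mean = per_embryo_bins.mean(axis=0).to_numpy()
    sd = per_embryo_bins.std(axis=0, ddof=1).to_numpy()
    keep = counts >= min_embryos
    denom = normalizer if normalizer is not None else mean[keep]
    return NoiseProfile(centers[keep], sd[keep] / denom, mean[keep], sd[keep],
                        counts[keep], side, kind)


def positional_error(
    noise: NoiseProfile,
    span: int = 5,
) -> np.ndarray:
    """Convert intensity noise to positional error sigma_c = delta B / |dB/dc|.

    The local gradient slope is estimated by linear regression of the mean
    profile over ``span`` neighbouring bins (centred; clipped at the
    ends).  For an exponential profile this reduces to lambda * (dB/B).
    Bins with a vanishing slope get NaN.
    """
    pos, mean, sd = noise.abscissa, noise.mean, noise.sd
    half = span // 2
    out = np.full(len(pos), np.nan)
    for i in range(len(pos)):
        lo, hi = max(0, i - half), min(len(pos), i + half + 1)
        if hi - lo < 2:
            continue
        slope = np.polyfit(pos[lo:hi], mean[lo:hi], 1)[0]
        if abs(slope) < 1e-12 * max(1.0, abs(mean[i])):
            continue
        out[i] = sd[i] / abs(slope)
    return out


def bootstrap_sd(
    statistic: Callable[[Sequence], float],
    cohort: Sequence,
    n_reps: int = 500,
    rng: np.random.Generator | int | None = None,
    max_failure_frac: float = 0.10,
) -> float:
    """SD of a cohort statistic under resampling embryos with replacement."""
    if len(cohort) < 3:
        raise ValueError("cohort size must be >= 3 for bootstrapping")
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    vals, failures = [], 0
    n = len(cohort)
    for _ in range(n_reps):
        idx = rng.integers(0, n, size=n)
        try:
            vals.append(statistic([cohort[i] for i in idx]))
        except Exception:
            failures += 1
    if failures > max_failure_frac * n_reps:
        raise RuntimeError(f"statistic failed on {failures}/{n_reps} replicates")
    if failures:
        log.warning("bootstrap: %d/%d replicates dropped", failures, n_reps)
    return float(np.std(vals, ddof=1))


def compare_sides_ttest(
    dorsal: Sequence[np.ndarray],
    ventral: Sequence[np.ndarray],
    welch: bool = False,
) -> list[tuple[float, float]]:
    """Two-tailed two-sample Student's t per position bin.

    ``dorsal`` and ``ventral`` are sequences of per-bin value arrays
    (embryo-level values).  Classical pooled-variance Student's t by
    default; Welch by flag.  Returns (t, p) per bin; degenerate bins with
    zero variance on both sides and equal means give p = 1.
    """
    out = []
    for d, v in zip(dorsal, ventral):
        d = np.asarray(d, float)
        v = np.asarray(v, float)
        if len(d) < 2 or len(v) < 2:
            raise ValueError("need >= 2 embryos per side per bin")
        if d.std(ddof=1) == 0 and v.std(ddof=1) == 0:
            out.append((0.0, 1.0) if d.mean() == v.mean() else (np.inf, 0.0))
            continue
        t, p = sps.ttest_ind(d, v, equal_var=not welch)
        out.append((float(t), float(p)))
    return out


# ---------------------------------------------------------------------------
# iso-concentration contours and target slant

def _invert_monotone(pos: np.ndarray, val: np.ndarray, t: float) -> float:
    """Position where a post-peak decreasing profile crosses value t."""
    i = int(np.argmax(val))
    v, p = val[i:], pos[i:]
    if not (v.min() <= t <= v.max()):
        raise ValueError("threshold outside profile range")
    return float(np.interp(-t, -v, p))


def iso_concentration_contours(
    profile_xD: BinnedProfile,
    profile_xV: BinnedProfile,
    profile_cD: BinnedProfile,
    profile_cV: BinnedProfile,
    frame: AverageFrame | None = None,
    L: float | None = None,
    thresholds: np.ndarray | None = None,
    interval: float = 1.0,
) -> IsoContourSet:
    """Dorsal/ventral positions of equal mean concentration, by interpolation.

    For each threshold t_k the four binned mean profiles (dorsal/ventral,
    projected/contour axis) are inverted in their monotone post-peak
    region, giving Delta x_Bcd = x_D - x_V and Delta c_Bcd = c_D - c_V.
    ``thresholds`` defaults to multiples of ``interval`` spanning the
    common range (the study used intervals 0.5 / 1 / 1.5 intensity units
    for 1x / wild-type / 3x dosage cohorts).  Frame y coordinates are
    attached when an average frame and L are supplied.
    """
    if thresholds is None:
        lo = max(p.mean[np.argmax(p.mean):].min() for p in
                 (profile_xD, profile_xV, profile_cD, profile_cV))
        hi = min(p.mean.max() for p in (profile_xD, profile_xV, profile_cD, profile_cV))
        thresholds = np.arange(np.ceil(lo / interval), np.floor(hi / interval) + 1) \
            * interval
    thresholds = np.asarray(thresholds, dtype=float)
    rows = []
    for t in thresholds:
        try:
            xD = _invert_monotone(profile_xD.centers, profile_xD.mean, t)
            xV = _invert_monotone(profile_xV.centers, profile_xV.mean, t)
            cD = _invert_monotone(profile_cD.centers, profile_cD.mean, t)
            cV = _invert_monotone(profile_cV.centers, profile_cV.mean, t)
        except ValueError:
            log.info("threshold %.3g outside profile range; skipped", t)
            continue
        rows.append((t, xD, xV, cD, cV))
    if not rows:
        z = np.array([])
        return IsoContourSet(z, z, z, z, z, z, z)
    t, xD, xV, cD, cV = map(np.array, zip(*rows))
    yD = np.full_like(xD, np.nan)
    yV = np.full_like(xV, np.nan)
    if frame is not None and L is not None:
        yD = np.interp(xD / L, frame.x_over_L, frame.yD_over_L) * L
        yV = np.interp(xV / L, frame.x_over_L, frame.yV_over_L) * L
    return IsoContourSet(t, xD, xV, cD, cV, yD, yV)


def target_slant(
    boundaries: Sequence[tuple[BoundaryEstimate, BoundaryEstimate]],
) -> dict:
    """Paired dorsal-ventral slant of a target boundary across a cohort.

    Input: per-embryo (dorsal, ventral) boundary pairs.  Returns cohort
    means and SDs of the paired differences Delta x_Target = x_D - x_V and
    Delta c_Target = c_D - c_V, paired two-tailed t-test p-values, and the
    per-side positional spread sigma_c_Hb (SD of c_b across embryos).
    """
    dx = np.array([d.x_b - v.x_b for d, v in boundaries])
    dc = np.array([d.c_b - v.c_b for d, v in boundaries])
    if len(dx) < 2:
        raise ValueError("need >= 2 paired embryos")
    cD = np.array([d.c_b for d, _ in boundaries])
    cV = np.array([v.c_b for _, v in boundaries])

    def paired_p(diff: np.ndarray) -> float:
        if diff.std(ddof=1) == 0:
            return 1.0 if diff.mean() == 0 else 0.0
        return float(sps.ttest_1samp(diff, 0.0).pvalue)

    return {
        "dx_mean": float(dx.mean()), "dx_sd": float(dx.std(ddof=1)),
        "dc_mean": float(dc.mean()), "dc_sd": float(dc.std(ddof=1)),
        "dx_p": paired_p(dx), "dc_p": paired_p(dc),
        "sigma_c_Hb_D": float(cD.std(ddof=1)),
        "sigma_c_Hb_V": float(cV.std(ddof=1)),
        "n": len(dx),
    }
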