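"""End-to-end cohort analysis: the dorsal-vs-ventral comparison suite.

Given per-embryo cortical traces (synthetic, extracted from images, or
simulated), this module runs the full measurement battery in both distance
systems: background subtraction, expression normalization, per-embryo
half-max boundaries, pooled exponential fits, the Hill input-output fit,
intensity-noise and positional-error profiles, iso-concentration contours
and the paired target-boundary slant.
"""

from __future__ import annotations

import numpy as np

from . import profiles as prf
from . import stats as st
from .profiles import BinnedProfile, CorticalTrace

__all__ = ["analyze_cohort", "block_average_trace", "recovery_study"]

#: Search window (x/L) for the anterior target-boundary crossing.
BOUNDARY_SEARCH_XL = (0.20, 0.75)
#: Window pairs pooled for the Hill input-output fit, x/L.
HILL_RANGE_XL = (0.15, 0.70)


def block_average_trace(trace: CorticalTrace, channel: str,
                        block: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average consecutive windows in blocks: (x, c, value) per block.

    Smooths a per-window trace to bin resolution before boundary
    detection, keeping x and c paired window-by-window.
    """
    v = trace.channels[channel]
    n = (len(v) // block) * block
    if n == 0:
        return trace.x, trace.c, v

    def blk(a):
        return a[:n].reshape(-1, block).mean(axis=1)

    return blk(trace.x), blk(trace.c), blk(v)


def analyze_cohort(
    cohort_traces: list[dict[str, CorticalTrace]],
    background: dict[str, float] | None = None,
    bin_interval: float = 5.5,
    fit_window: tuple[float, float] = st.DEFAULT_FIT_WINDOW,
    group: str = "wt",
    iso_interval: float = 1.0,
) -> dict:
    """Run the full D-vs-V analysis suite on a cohort of paired traces.

    Parameters
    ----------
    cohort_traces
        One dict per embryo mapping side ("D"/"V") to its
        :class:`~bcdgeom.profiles.CorticalTrace` with channels ``bcd``
        (raw, background included) and optionally ``hb``.
    background
        Side-specific mean background intensities to subtract from the
        morphogen channel (measured from null embryos in the experimental
        design).  Defaults to the wild-type calibration 2.19 / 2.13.
    bin_interval
        Bin width in um on both axes (11 px at 0.5 um/px).
    """
    if background is None:
        background = {"D": 2.19, "V": 2.13}
    have_hb = all("hb" in tr.channels for e in cohort_traces for tr in e.values())

    # background-subtracted morphogen traces, per embryo per side
    bcd: dict[str, list[CorticalTrace]] = {"D": [], "V": []}
    for emb in cohort_traces:
        for side in ("D", "V"):
            bcd[side].append(prf.subtract_background(emb[side], background[side]))

    results: dict = {"group": group, "n_embryos": len(cohort_traces)}

    # pooled binned profiles and exponential fits, both axes
    binned: dict[tuple[str, str], BinnedProfile] = {}
    fits = {}
    for side in ("D", "V"):
        Lbar = float(np.mean([t.L for t in bcd[side]]))
        Cbar = float(np.mean([t.c[-1] for t in bcd[side]]))
        for axis, span in (("projected", Lbar), ("contour", Cbar)):
            prof = prf.bin_profiles(bcd[side], axis, bin_interval, "bcd",
                                    side=side, group=group)
            binned[(side, axis)] = prof
            fits[(side, axis)] = st.fit_exponential(
                prof.centers, prof.mean,
                (fit_window[0] * span, fit_window[1] * span), axis)
    results["lambda"] = {f"{side}_{ax[0]}": fits[(side, ax)].lam
                         for side in ("D", "V") for ax in ("projected", "contour")}
    results["B0"] = {f"{side}_{ax[0]}": fits[(side, ax)].B0
                     for side in ("D", "V") for ax in ("projected", "contour")}
    results["fits"] = fits
    results["binned"] = binned

    if have_hb:
        # expression normalization and per-embryo boundaries
        hbn = {s: prf.normalize_expression([e[s] for e in cohort_traces])
               for s in ("D", "V")}
        pairs = []
        n_excluded = 0
        for k in range(len(cohort_traces)):
            bd = {}
            try:
                for side in ("D", "V"):
                    tr = hbn[side][k]
                    step = np.median(np.diff(tr.x)) if len(tr.x) > 1 else 1.0
                    block = max(1, int(round(bin_interval / step)))
                    bx, bc, bv = block_average_trace(tr, "hb", block)
                    bd[side] = st.find_half_max_boundary(
                        bx, bc, bv, side=side, embryo_id=k,
                        search_range_xl=BOUNDARY_SEARCH_XL, L=tr.L)
            except ValueError:
                # boundary outside the search window on one side: the
                # embryo cannot contribute a paired measurement
                st.log.warning("embryo %s excluded: no paired boundary", k)
                n_excluded += 1
                continue
            pairs.append((bd["D"], bd["V"]))
        if not pairs:
            raise ValueError("no embryo yielded a paired boundary")
        results["boundaries"] = pairs
        results["n_boundary_excluded"] = n_excluded
        results["slant"] = st.target_slant(pairs)

        # dissociation constant at the measured boundary, per embryo
        kd = {"D": [], "V": []}
        for bD, bV in pairs:
            for side, b in (("D", bD), ("V", bV)):
                tr = bcd[side][int(b.embryo_id)]
                c_hb = min(max(b.c_b, tr.c.min()), tr.c.max())
                kd[side].append(st.measure_kd(tr.c, tr.channels["bcd"], c_hb))
        results["Kd"] = {s: {"mean": float(np.mean(kd[s])),
                             "sd": float(np.std(kd[s], ddof=1)) if len(kd[s]) > 1 else 0.0,
                             "values": kd[s]} for s in ("D", "V")}

        # pooled Hill input-output fit per side (Kd fixed at the measured value)
        results["hill"] = {}
        for side in ("D", "V"):
            Bs, Hs = [], []
            for k in range(len(cohort_traces)):
                tr = bcd[side][k]
                xl = tr.x / tr.L
                sel = (xl >= HILL_RANGE_XL[0]) & (xl <= HILL_RANGE_XL[1])
                Bs.append(tr.channels["bcd"][sel])
                Hs.append(hbn[side][k].channels["hb"][sel])
            B = np.concatenate(Bs)
            H = np.concatenate(Hs)
            results["hill"][side] = {
                "measured": st.fit_hill(B, H, "measured_at_boundary",
                                        results["Kd"][side]["mean"], side),
                "fitted": st.fit_hill(B, H, "fitted", side=side),
            }

    # intensity noise and positional error (contour axis)
    results["noise"] = {}
    results["sigma_c"] = {}
    for side in ("D", "V"):
        tab = prf.per_embryo_binned(bcd[side], "contour", bin_interval, "bcd",
                                    side=side)
        noise = st.intensity_noise_profile(tab, side=side)
        sigma = st.positional_error(noise)
        results["noise"][side] = noise
        results["sigma_c"][side] = sigma
        if have_hb:
            c_hb = float(np.mean([b.c_b for b in
                                  (p[0] if side == "D" else p[1]
                                   for p in results["boundaries"])]))
            ok = np.isfinite(sigma)
            results["sigma_c"][f"{side}_at_cHb"] = float(
                np.interp(c_hb, noise.abscissa[ok], sigma[ok]))
            results["noise"][f"{side}_at_cHb"] = float(
                np.interp(c_hb, noise.abscissa, noise.noise))

    # iso-concentration contours (thresholds on the raw background-free scale)
    iso = st.iso_concentration_contours(
        binned[("D", "projected")], binned[("V", "projected")],
        binned[("D", "contour")], binned[("V", "contour")],
        interval=iso_interval)
    results["iso"] = iso
    if have_hb and len(iso.thresholds):
        # Delta x_Bcd and Delta c_Bcd at the Hb-boundary concentration
        xhb = float(np.mean([p[0].x_b for p in results["boundaries"]]))
        pD = binned[("D", "projected")]
        i = int(np.argmax(pD.mean))
        t_hb = float(np.interp(xhb, pD.centers[i:], pD.mean[i:]))
        one = st.iso_concentration_contours(
            binned[("D", "projected")], binned[("V", "projected")],
            binned[("D", "contour")], binned[("V", "contour")],
            thresholds=np.array([t_hb]))
        if len(one.thresholds):
            results["iso_at_Hb"] = {"threshold": t_hb,
                                    "dx": float(one.dx[0]), "dc": float(one.dc[0])}
    return results


def recovery_study(
    n_cohorts: int = 200,
    base_seed: int = 0,
    n_embryos: int = 28,
    **spec_overrides,
):
    """Repeated-cohort parameter recovery at the calibrated study conditions.

    Generates ``n_cohorts`` independent synthetic cohorts (seeds
    ``base_seed + i``), runs the full analysis on each, and tabulates the
    recovered length constants, dissociation constant, Hill exponent,
    boundary separations and positional errors next to the generator
    truths.  Returns a pandas DataFrame with one row per cohort.
    """
    import pandas as pd

    from .synthetic import SyntheticCohortSpec, generate_cohort

    rows = []
    for i in range(n_cohorts):
        spec = SyntheticCohortSpec(n_embryos=n_embryos,
                                   seed=int(base_seed + i), **spec_overrides)
        cohort = generate_cohort(spec)
        res = analyze_cohort([e.traces for e in cohort],
                             background={"D": spec.background_mean_D,
                                         "V": spec.background_mean_V})
        truth_dx = float(np.mean([e.ground_truth["D"]["x_Hb"]
                                  - e.ground_truth["V"]["x_Hb"] for e in cohort]))
        truth_dc = float(np.mean([e.ground_truth["D"]["c_Hb"]
                                  - e.ground_truth["V"]["c_Hb"] for e in cohort]))
        rows.append({
            "seed": spec.seed,
            "lambda_cD": res["lambda"]["D_c"], "lambda_cV": res["lambda"]["V_c"],
            "kd_D": res["Kd"]["D"]["mean"], "kd_V": res["Kd"]["V"]["mean"],
            "n_D": res["hill"]["D"]["measured"].n,
            "n_V": res["hill"]["V"]["measured"].n,
            "dx_hb": res["slant"]["dx_mean"], "dc_hb": res["slant"]["dc_mean"],
            "sigma_cD": res["sigma_c"]["D_at_cHb"],
            "sigma_cV": res["sigma_c"]["V_at_cHb"],
            "truth_lambda_cD": spec.lambda_c_D, "truth_lambda_cV": spec.lambda_c_V,
            "truth_kd": spec.hill_Kd, "truth_n": spec.hill_n,
            "truth_dx_hb": truth_dx, "truth_dc_hb": truth_dc,
        })
    return pd.DataFrame(rows)
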