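# bcdgeom

Quantifying how embryo geometry shapes a morphogen gradient: the Bicoid
(Bcd) gradient of the early *Drosophila* embryo, measured in two distance
systems, plus a 3-D nuclear-cycle reaction–diffusion simulator of gradient
formation on asymmetric embryo shapes.

## The problem

Bcd forms an exponential anterior–posterior concentration gradient,
`B(s) = B₀ e^(−s/λ)`, that positions target-gene boundaries such as
Hunchback (Hb) through a steep Hill response,

    H(B) = (B/K_d)^n / (1 + (B/K_d)^n),          H(K_d) = 1/2,

with dissociation constant `K_d` and Hill coefficient `n ≈ 5`.  But "the
position `s`" is ambiguous on a curved embryo: the **projected distance**
`x` (straight-line position along the A-P axis) and the **contour
distance** `c` (arc length along the dorsal or ventral perimeter) disagree,
because the ventral perimeter is ~30 μm longer than the dorsal one.
Comparing dorsal and ventral profiles in both coordinate systems reveals
which distance the gradient actually "measures": boundaries and profiles
that diverge in `x` converge in `c`, so positional information follows the
perimeter.  The package is aimed at quantitative developmental biologists
and modellers who want that full measurement chain — and the accompanying
physical model — as reusable, tested code.

Components:

* **geometry** — midsagittal contours, `x`/`c` coordinate maps, the
  dorsoventral shape-difference profile Δc(x/L)/C_D, average embryo
  frames, and two-semi-ellipsoid 3-D shapes;
* **synthetic** — cohort generator with known ground truth (exponential-
  in-`c` Bcd with window-level multiplicative noise and additive
  background, Hill-readout Hb with expression noise, shape variability,
  optional rasterized midsagittal images);
* **profiles** — the sliding circular scanning window (~25 μm², centred
  ~6 μm inside the perimeter) that extracts cortical traces from images,
  background subtraction, Hb normalization, dual-axis binning;
* **stats** — exponential and Hill fits, half-max boundary detection in
  both coordinate systems, intensity noise δB/B, positional error
  σ_c = δB/|dB/dc|, bootstrap SDs, per-bin Student's t-tests,
  iso-concentration contours, paired boundary-slant statistics;
* **simulate** — explicit 3-D reaction–diffusion of Bcd on a voxelized
  irregular domain: anterior mRNA-sphere source, free-molecule diffusion
  retarded by fast-equilibrium non-specific DNA binding whose capacity
  doubles every nuclear cycle and relocates to a 10-μm cortical layer at
  cycle 10, uniform degradation, zero-flux surface;
* **cli / pipeline** — `bcdgeom synth | extract | analyze | simulate |
  compare` orchestration with seeded, provenance-stamped TSV/JSON outputs.

## Worked example

```python
from bcdgeom import SyntheticCohortSpec, generate_cohort, analyze_cohort

cohort = generate_cohort(SyntheticCohortSpec(n_embryos=28, seed=1))
res = analyze_cohort([e.traces for e in cohort])

lam = res["lambda"]
print(f"lambda_D = {lam['D_c']:.1f} um, lambda_V = {lam['V_c']:.1f} um (contour)")
print(f"K_d = {res['Kd']['D']['mean']:.2f} (D), {res['Kd']['V']['mean']:.2f} (V)")
print(f"Hill n = {res['hill']['D']['measured'].n:.1f} (D), "
      f"{res['hill']['V']['measured'].n:.1f} (V)")
s = res["slant"]
print(f"Delta x_Hb = {s['dx_mean']:.1f} um, Delta c_Hb = {s['dc_mean']:.1f} um")
```

prints

```
lambda_D = 104.8 um, lambda_V = 115.4 um (contour)
K_d = 5.20 (D), 4.92 (V)
Hill n = 5.1 (D), 5.0 (V)
Delta x_Hb = 26.8 um, Delta c_Hb = 5.2 um
```

The cohort was generated with contour length constants 104.8/115.5 μm,
`K_d = 5`, `n = 5`; the pipeline recovers them, and the Hb boundary
separation between the two sides collapses from ~27 μm in projected
distance to ~5 μm in contour distance — the geometric convergence the
measurement is designed to expose.

The simulator runs from the shell:

```sh
bcdgeom simulate --grid 5 --dt 0.5 --out sim_out/
```

writing cortical nuclear-concentration profiles (`sim_profiles.tsv`, same
format as experimental traces, so `analyze` applies unchanged), a
midsagittal heat-map table and a mass-budget audit log.

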