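# Methods

This note records the models, parameter choices and numerical decisions
behind `bcdgeom`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinate systems and geometry

An embryo's midsagittal outline is stored as two ordered arcs (dorsal,
ventral) from the anterior to the posterior pole.  Axis alignment places
the anterior pole at the origin with the A-P axis along +x; poles are the
two outline points at maximal mutual distance.  Two positions are computed
for every measurement site:

* projected distance `x`: scalar projection onto the anterior→posterior
  unit vector;
* contour distance `c`: cumulative Euclidean length over the chain of
  scanning-window centres (piecewise-linear arc length).

Matching `c` to an `x` position uses linear interpolation of cumulative
arc length against projected distance, with the projection made monotone
by restricting each arc to its pole-to-pole parameterization.  The
shape-difference profile is reported as `(c_D(x) − c_V(x))/C_D`; with the
ventral side taller it is negative over most of the embryo, and we keep
the signed value rather than a display convention.

The 3-D embryo is two semi-ellipsoids joined on the coronal plane:
A-P semi-axis 280 μm, lateral semi-axis 110 μm, dorsal/ventral D-V
semi-axes 92/128 μm by default.  An arbitrary measured outline can be
turned into a 3-D shape by giving each A-P station a half-elliptical
cross-section whose lateral semi-axis scales with the local D-V
half-height; this construction is a modelling choice, not a measured
quantity.

## Synthetic cohorts: what they emulate

Each synthetic embryo draws its shape from a truncated normal around the
cohort mean (SDs 15/8/5/5 μm for length, lateral diameter and the two
heights; halves shorter than 20 μm are resampled).  Bicoid along each
perimeter is exponential in contour distance,

    B(c) = B0 · e^(−c/λ_c) · (1 + ε_window) + background,

with λ_c = 104.8 μm (dorsal) and 115.5 μm (ventral), backgrounds
2.19/2.13 intensity units, multiplicative per-window noise
ε ~ N(0, cv_window) with cv 0.10 dorsal / 0.15 ventral, and an
embryo-level amplitude factor (1 + η), η ~ N(0, 0.25) truncated positive.
The amplitude CV matches the observed spread of per-embryo dissociation
constants (≈24%); the window CVs are set so the ventral intensity noise
and positional error exceed the dorsal ones, the contrast the comparative
statistics are designed to detect.  Hunchback is generated from the
background-free Bicoid via the Hill relation (K_d = 5 intensity units,
n = 5) plus additive expression noise (SD 0.1, clipped at 0), then scaled
to raw-like units with embryo-specific amplitude so that normalization is
a real analysis step.  The amplitudes B0 are fixed by requiring the
half-maximal boundary to sit at c_Hb = 284.6 μm (dorsal) and 279.1 μm
(ventral): B0 = K_d · e^(c_Hb/λ_c).

What this generator does **not** emulate: nucleus-level texture (the
raster paints a smooth cortical band), staging variability within nuclear
cycle 14, spatially structured background, optical sectioning artifacts,
and any dorsoventral difference in nuclear density.  Passing recovery
tests therefore demonstrate that the measurement chain is unbiased and
correctly propagates the modelled noise — not that it is robust to every
imaging artifact of real embryos.

## Measurement pipeline

The scanning window is circular with area 25 μm² (radius 2.82 μm), its
centre kept 6 μm inside the perimeter, advanced one pixel of A-P
projection per step; window means are recorded per channel together with
x and c of the centre.  Backgrounds are subtracted as side-specific
constants (negative values retained).  Expression traces are normalized
per embryo so the plateau mean (x/L 0.15–0.30) maps to 1 and the
non-expression mean (x/L 0.65–0.80) to 0; these windows were chosen so
that, at the calibrated boundary position (x/L ≈ 0.42–0.45) and gradient
shallowness, both windows genuinely sample saturated and silent tissue —
windows closer to the boundary measurably bias the recovered boundary and
Hill steepness.  Boundaries are the most anterior downward half-max
crossing of the block-averaged (≈5.5 μm) normalized trace, searched in
x/L 0.20–0.75, interpolated linearly, and reported simultaneously in x
and c from the same window pair; embryos without a crossing on both sides
are excluded with a warning.

Exponential fits are linear least squares in log space over the window
x/L (or c/C) 0.10–0.60, excluding the anterior deviation from
exponentiality and the posterior floor; non-positive intensities are
excluded and counted, and a nonlinear refinement is available by flag.
The Hill fit is nonlinear least squares with the exponent always free and
K_d either free or fixed at the intensity measured at the boundary,
multi-started over n ∈ {1, 3, 5, 8}.  Intensity noise δB/B is the
cross-embryo SD of per-embryo bin means divided by the cross-embryo mean
(bins with fewer than three embryos omitted; measurement and background
noise are not deconvolved).  Positional error is σ_c = δB/|dB/dc| with
the slope from a local linear regression over five bins — for an
exponential profile this is λ·(δB/B), which the tests verify to 2%.
Student's t-tests use the classical pooled-variance form (Welch by flag);
no multiple-testing correction is applied, matching how the per-position
p-values are conventionally reported.  Iso-concentration contours invert
the four binned mean profiles (side × axis) in their monotone post-peak
region at a ladder of thresholds, giving Δx_Bcd and Δc_Bcd per threshold.

## The 3-D nuclear-cycle reaction–diffusion model

State: total Bcd concentration T (molecules/μm³) on a cubic voxel grid
restricted to the embryo interior.  Non-specific nuclear DNA binding is in
fast local equilibrium with capacity ratio r, so the free, mobile fraction
is `B_free = T/(1+r)`; only free molecules diffuse (explicit 6-neighbour
stencil on B_free, flux form, zero-flux at the surface), synthesis adds
J/(source volume) inside the anterior mRNA sphere (radius 45 μm at
(75, 0, 0)), and degradation removes ω·T everywhere — degradation is
applied to total Bcd since it is described as spatially uniform.  Defaults:
D = 2 μm²/s, ω = 5×10⁻⁵ s⁻¹, J = 1000 molecules/s, r = 0.15 at cycle 10.

Binding capacity doubles each nuclear cycle with the nuclear number.
Before cycle 10 the nuclei occupy the whole interior; at cycle 10 onset
the capacity relocates to the 10-μm cortical layer (interior voxels
within 10 μm of the surface by Euclidean distance transform).  The
pre-relocation r is back-scaled by the cortical/interior volume ratio so
total binding capacity is conserved across the relocation — the published
description fixes only the cycle-10 ratio and the doubling, so this
conservation rule is our choice.  The default schedule is 8 min per cycle
for cycles 1–9, then 9, 10, 12 and 21 min for cycles 10–13, with readout
14 min into cycle 14 (≈138 min total); it is fully configurable.

Numerics.  Stability requires dt < h²/(6D); the constructor rejects
violations and states the admissible bound.  The flux-form stencil
conserves mass exactly: with ω = 0 the total equals J·t to 1e-8 relative
over 10⁴ steps (tested).  Grids are aligned so a voxel face lies on the
y = 0 and z = 0 planes; a dorsoventrally symmetric shape then voxelizes
symmetrically and its two profiles agree to half a percent.  Profile
readout mimics the experimental pipeline: windows along the midsagittal
contour inset by half the cortical depth, one per grid column, each
averaging the cortical voxels of the two central z-slabs within a
circular footprint of 1.25 voxel edges — a mask-aware average, because
interpolating across the embryo surface mixes in exterior zeros; this
readout is the variant whose length constants are stable under grid
refinement (within 3.5% between h = 5 and 4 μm, under 1% between 5 and
3 μm).

At the published operating point (grid 5³ μm³, Δt = 0.5 s) the model
reproduces the three observed dorsoventral orderings — higher dorsal peak
concentration, larger ventral length constant in both x and c, and
projected iso-concentration offsets exceeding contour offsets — and these
persist when the mRNA sphere moves along either axis or the binding ratio
changes by ±50%.

Known limitations.  (i) The aggregate synthesis rate J = 1000 molecules/s
bounds the total protein at J·t ≈ 8.3×10⁶ molecules over the modelled
138 min; distributed over the ≈1.4×10⁷ μm³ embryo with a ≈95-μm gradient
and cortical enrichment (1+r₁₄) = 3.4, peak cortical concentrations come
out near 6 molecules/μm³.  Literature estimates of peak nuclear Bcd are
several-fold higher; reconciling them would require per-nucleus-volume
bookkeeping (nuclei occupy only part of the cortical layer) or a larger
J, neither of which is constrained by the parameters we implement, so we
report the volumetric cortical concentration as-is.  (ii) The
dorsal–ventral offsets at a target-boundary threshold are shape
properties: on the semi-ellipsoid the purely geometric x-vs-c mapping
difference at the Hb level is ≈20.5 μm, and the simulation converges to
exactly that value of Δx_Bcd − Δc_Bcd, confirming that this quantity
reflects geometry alone; a real average embryo frame (flatter dorsally)
gives about half of it.  (iii) No intra-cycle nucleocytoplasmic
shuttling, mitotic release, nuclear-density asymmetry or cortical flow.

## Scaled problem sizes

The repeated-cohort recovery study uses 200 cohorts of 28 embryos in the
test suite and 50 in the acceptance script; the grid-robustness check
refines 5 → 4 μm on the full embryo and the timestep check 0.5 → 0.125 s
on a reduced embryo; the parameter sweep runs on a 7-μm grid where the
qualitative orderings are already stable.  These sizes keep the full
suite to a few minutes while leaving every estimate's Monte-Carlo error
well below the tolerances asserted.
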