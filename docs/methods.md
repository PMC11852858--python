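# Methods

This note records the models, conventions and numerical choices behind
`evchip`, and what the synthetic-data generators do and do not emulate.

## Chip layout

`build_layout(panel, n_rows, n_cols, scheme="alternating_columns")`
places capture ligands on the even-indexed columns and the single
negative-control ligand on every odd column. When there are more
capture ligands than capture columns, `k = n_capture / (n_cols/2)`
ligands share each capture column in consecutive row blocks of
`n_rows / k` spots. This is the unique column-alternating arrangement
that simultaneously gives, on a 10 x 10 grid with a ten-ligand panel,
100 spots in total, 50 negative-control spots, and 5 spots per capture
family — the counts a multiplexed EV chip of this design reports. All
of a ligand's spots are analysis ROIs. Preconditions: even `n_cols`,
`n_capture` divisible by `n_cols/2`, `n_rows` divisible by `k`. Spot
diameter (200 µm) and pitch (600 µm) are carried as metadata only; no
optics are modelled. Grafting pH per ligand is metadata as well.

## SPRi chain

**Sensorgram model (synthetic).** Each ROI follows a 1:1 Langmuir-style
observed-rate curve: during the injection
`R(t) = Rmax_spot (1 - exp(-k_obs (t - t_start)))`, afterwards
exponential decay at `k_off`. `Rmax_spot = Rmax (1 + cv·g)` with `g ~
N(0,1)` truncated at -1/cv models spot-to-spot grafting variability
(default cv 0.08). Negative-control spots get a weak nonspecific
amplitude (default 0.05 %). Optional linear drift and i.i.d. Gaussian
read noise (default sd 0.005 %) are added last. Defaults: injection
from 2 to 22 min (a 20-minute injection), sampling every 0.1 min,
record to 30 min. The generator's ground truth is the noise- and
drift-free end-point response evaluated on the same sample grid and
windows the extraction uses, which is what makes the exactness
invariant (recovery to ≤ 1e-9 relative error) well defined even with
`k_off > 0`.

**Response extraction.** `raw_response = mean(plateau window) -
mean(baseline window)`, windows inclusive. Defaults relative to the
injection markers: baseline `[t_start - 2 min, t_start]`, plateau
`[t_end + 5 min, t_end + 7 min]` — the post-injection delay samples the
stabilized level rather than the dissociation transient. Both windows
are configurable; a window containing no samples, overlapping the
injection, is an error naming the window.

**Control subtraction.** `adjusted = raw - mean(raw over control
ROIs)`; control ROIs are themselves adjusted, so their adjusted mean is
exactly zero. Negative adjusted responses are kept (weak binders stay
informative) and logged, never clipped.

**Plasmon shift.** The reflectivity-vs-angle minimum is located by a
parabola through the discrete minimum and its two neighbours; a minimum
on the range edge is a QC error (truncated curve). The shift (after
minus before) quantifies grafting; an acceptance band for
RSA-passivation QC is left to the caller since no reference values
exist.

## Phenotype profile

The reference ligand minimizes the worse of its two per-condition
coefficients of variation (sample sd / mean over experiments), with
ties broken by lower mean CV then name; ligands with non-positive mean
response in either condition are ineligible. Normalization is per
experiment (each experiment divided by its own reference response),
which removes per-preparation scale exactly — profiles are invariant
under any positive per-experiment rescaling. Error bars are the sd over
experiments of the normalized values (sd rather than sem; a config
switch would be trivial but sd is what the profile plots here show).
Profile comparison reports treated-minus-control differences with sds
propagated in quadrature, ordered by |difference|. A configurable
exclusion list drops unresponsive ligands after aggregation (logged).

## AFM metrology

**Leveling.** `iterative_plane` (default): classify background as
pixels below `median + 3·MAD`, least-squares-fit a plane to it (normal
equations on centered coordinates), subtract, repeat once, then
recenter so the background median is ~0. The median/MAD are estimated
on a 2x-strided subsample above 65k pixels — indistinguishable
statistically, several times faster. The 8.5 nm "dynamic" threshold is
interpreted as relative to this locally leveled background; the
numeric value stays fixed.

**Segmentation.** Mask `height ≥ 8.5 nm`; connected components
(8-connectivity default); drop components with projected area
`< 200 nm²`; drop border-touching components by default (truncated
footprints bias diameters). No watershed splitting: the generator
guarantees non-overlap, and real touching blobs would count as one.
Tables are sorted by centroid row-major, so identical inputs give
identical tables.

**Metrics.** Max diameter = largest pairwise distance between the
component's pixel centers (via convex hull for larger components) plus
one pixel for pixel extent; single-pixel components report one pixel
size. This convention is unbiased for large particles and defined for
degenerate ones: a 10-pixel row at 4 nm/px reads 36 + 4 = 40 nm.
Height = max leveled height in the component (config switch for mean).
Area = pixel count x pixel size². On a rendered cap of footprint D and
apex h, the expected measured diameter is the analytic above-threshold
chord `2·sqrt(h'(2R - h'))` with `h' = h - 8.5` and `R = D²/8h + h/2`;
the suite holds measurements to within 2 px of it.

**Pooling.** Per-image tables for one ligand/condition are
concatenated; fewer than 100 pooled particles triggers a coverage
warning (the acquisition target for a reliable per-ligand size
profile).

## Particle generator

Diameters follow a two-component log-normal mixture: a small-EV bulk
(median 120 nm, log-sd 0.35) and a large-EV tail (median 350 nm,
log-sd 0.40, weight 0.10 in the control condition). No public
quantitative EV size distribution accompanies studies of this design,
so these are stated assumptions chosen to put the bulk below the lEV
cut and a realistic minority above it. Heights are `h = 0.12·D + eps`
(`eps ~ N(0, 1.5 nm)`, floored at 0.5 nm): captured vesicles flatten,
so apex heights are roughly an order of magnitude below diameters.
Density defaults to 6.25 /µm² (25 particles per 2 x 2 µm scan).
Diameters above 900 nm are redrawn (field-of-view truncation, < 2 %
tail mass for every population used): a near-micron vesicle does not
fit a usable 2 µm scan field, and two can never coexist on one.

Rendering: each particle is a spherical cap evaluated at pixel centers;
the substrate is a tilted plane (≤ 0.02 nm/px) plus Gaussian roughness
(sd 1 nm) applied only where no particle covers the surface — the
vesicle membrane is smooth relative to the bare substrate, and this
keeps the apex-height metric unbiased. Placement is uniform rejection
sampling without footprint overlap, largest first; a draw whose
footprints cannot pack (heavy-tail accident) causes a bounded
whole-field redraw, mirroring how an operator selects usable scan
fields, with a placement error after 20 redraws. Rendered cap volume
matches the closed form `pi h²(3R - h)/3` within 2 % (pixel
quantization). Tip convolution is not simulated (no tip geometry to
base it on); footprint diameters are as-imaged by construction.

**Treatment effects** are expressed per ligand by a `Scenario`:
response amplification (treated `Rmax` x factor), and a size shift
acting on the large-EV component — its median diameter scaled and/or
its mixture weight raised (the built-in `cd36-shift` scenario uses
x1.25 and 0.10 → 0.25 on Anti-CD36, with response x1.5). The shift
deliberately targets the large-EV component: scaling the whole mixture
mostly pushes small-EV crossovers just past the 200 nm cut, which
dilutes rather than shifts the large-EV comparison. The null scenario
draws both conditions from identical distributions. The manifest
records every programmed effect.

## Mann-Whitney U

U is computed from midranks; `U_x + U_y = n_x n_y` always. Two-sided
p-values throughout. `auto` mode: exact enumeration of all
`C(n+m, n)` group assignments when both groups have ≤ 8 observations
and the pooled sample is tie-free; otherwise the normal approximation
with tie correction `var = nm/12 [(N+1) - Σ(t³-t)/(N(N-1))]` and a
0.5 continuity correction. Exact mode can be forced on tied data
(midrank enumeration, capped at 2x10⁵ assignments). The two-sided
exact p uses the symmetry of the null U distribution about `nm/2`:
`p = P(U ≤ u_low) + P(U ≥ nm - u_low)`, `u_low = min(u, nm - u)`,
clamped to 1. No multiple-testing correction across ligands by default
(a Holm option exists, logged when used). Classification: `+` per
parameter iff `p < 0.05`; combined `++`/`+`/`=` for both/one/neither.

## Scaled-down study sizes

The Monte-Carlo validation helpers (`evchip.validation`) choose problem
sizes that keep the operating characteristics meaningful: null
calibration and power use 150 large EVs per group (1000 and 200
replicates), the group size at which the x1.25 shift test is well
powered; the end-to-end recovery study uses a two-capture-ligand chip,
12 particles per scan (so the enlarged treated vesicles still place
without overlap) and 80 scans per ligand/condition, pooling on the
order of 150 control large EVs, across 20 independently seeded full
studies.

## What the generators do not emulate

SPR optics (angle-to-reflectivity physics), mass-transport-limited
kinetics, analyte depletion, AFM tip convolution and feedback
artifacts, vesicle deformation mechanics, spatial correlation of
substrate roughness, and touching/overlapping particles. Passing tests
therefore demonstrate the correctness and calibration of the analysis
chain under the stated statistical model of the data — not the
instrument physics. On real data the absolute detection thresholds
(8.5 nm, 200 nm²) and the diameter-to-height relation would need
instrument-specific validation.

## Known limitations

* The exact response windows of a given instrument run are an analyst
  choice; the defaults here are declared, configurable assumptions.
* Feret diameters are quantized by pixel size; particles below ~3
  pixels across carry large relative diameter uncertainty.
* The exact Mann-Whitney mode is combinatorial; group sizes beyond ~10
  fall back to the (tie-corrected) normal approximation.
* Border-touching particles are dropped, which slightly undersamples
  the largest vesicles on dense fields.
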