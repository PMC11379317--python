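# Methods

## Problem and approach

Large copepods dominate mesozooplankton abundance in eastern-boundary
upwelling systems, but nets undersample them (avoidance, extrusion) and
single-frequency echosounders cannot separate them from fish and krill.
`zoosonde` implements a bi-frequency (38/120 kHz) pipeline that:

1. echo-integrates raw volume backscatter into analysis cells,
2. classifies each cell from the dB sum and dB difference of the two
   channels (fish gate, then fluid-like windows),
3. inverts copepod-classified cells through a high-pass fluid-sphere
   scattering model to an equivalent spherical radius (ESR) and a
   numerical density,
4. integrates density over depth into along-track elementary sampling
   units (ESUs), converts to biomass with a mean individual dry mass
   from scanned net samples,
5. removes diel transitions, contrasts day and night, and maps areal
   biomass by ordinary kriging with a total and an approximate CV.

Because no suitable survey data are distributable, the package carries a
forward-model generator (`synthdata`) that simulates exactly the
physics the pipeline inverts, so every stage is tested against known
truth.

## Echo integration (`echogram`)

Backscatter is held as the linear volume backscattering coefficient
`sv` (m⁻¹); `MVBS = 10·log₁₀(sv)` is derived. Cells are 3 pings × 1 m
by default, anchored at the first ping and at the 10 m top of the
10–200 m analysis layer; trailing partial cells are dropped rather than
padded (a partial mean is a biased mean). The integration threshold
(default −80 dB) is applied per raw sample before averaging, mirroring
echo-integration practice; a cell is missing only if no sample
qualifies. Averaging is always linear-domain; thresholds always dB.
Depth bins are half-open `[top, bottom)`, positive down.

The two channels are joined on an identical lattice; a cell missing in
either channel is EXCLUDED in both. `∑MVBS = MVBS₁₂₀ + MVBS₃₈` is the
literal dB sum — a discriminant score, not a physical power sum — and
`ΔMVBS = MVBS₁₂₀ − MVBS₃₈`.

## Classification (`classify`)

Fixed-order cascade per cell:

| step | rule | label |
|---|---|---|
| 1 | ∑MVBS > −119 dB (default, or GMM-fitted) | FISH |
| 2 | ΔMVBS < 2 dB | OTHER |
| 3 | 2 ≤ ΔMVBS < 7 dB | KRILL |
| 4 | 7 ≤ ΔMVBS ≤ 25 dB | COPEPOD |
| 5 | ΔMVBS > 25 dB | OTHER |
| 6 | rescue pass (below) | KRILL/COPEPOD |
| 7 | non-FISH cell with MVBS₁₂₀ > −65 dB | OTHER |

The fish gate can be refitted per survey as the equal-density boundary
of a two-component Gaussian mixture on the ∑MVBS histogram (EM, k = 2,
10 restarts, seeded; fallback to the configured default when the
components are closer than 1 dB). The krill/copepod windows are
half-open at 2 and 7 dB with the 7 dB tie going to copepod, the
headline class; the printed ranges overlap at the boundary so a
tie-break had to be chosen.

The rescue pass re-admits fluid-like echoes swallowed by the fish gate:
a FISH cell whose ΔMVBS lies in a fluid window and whose 3×3
neighbourhood holds a strict majority of that fluid label is relabelled
(provenance `rescued`). It is a single deterministic ping-major pass
reading pre-pass labels only; the smoothing operator is not specified
more precisely in the source method, and majority voting with a
dB-window guard is the simplest faithful reading. The −65 dB upper
threshold is applied to the 120 kHz channel (where fluid scatterers are
strongest) after the rescue, so rescued-but-loud cells are still
demoted.

## Scattering model (`scattering`)

High-pass fluid sphere of radius `a`, density contrast `g = 1.02` and
sound-speed contrast `h = 1.058` (literature values for calanoid
copepods), seawater sound speed `c = 1508 m s⁻¹` (Mackenzie 1981
nine-term formula at 14.9 °C, 35.7 PSU; the formula is exposed as
`sound_speed` and the reference depth is configurable):

    σ_bs = a²(ka)⁴α²  /  (1 + 4(ka)⁴α²/R²)
    R    = (gh − 1)/(gh + 1)
    α    = (1 − gh²)/(3gh²) + (1 − g)/(1 + 2g)

with `k = 2πf/c`. The model is Rayleigh (`σ_bs ∝ a⁶f⁴`) for `ka ≪ 1`
and plateaus at `a²R²/4` for `ka ≫ 1`; the plateau follows from the
full expression (a printed geometric-limit form omitting `R²` is
treated as a typographic slip). `TS = 10·log₁₀ σ_bs`.

`ΔTS(a) = TS₁₂₀ − TS₃₈` starts at the Rayleigh ceiling
`40·log₁₀(120/38) = 19.98 dB` and decreases monotonically while
`ka₁₂₀ ≲ 2`, which makes it invertible to size. The working window is
ΔTS ∈ [7.0, 19.7] dB; its ESR image is computed from the model
(≈ 0.64–2.78 mm at the default parameters) rather than hard-coded,
because the printed anchor pairs (19.7 dB ↔ 0.5 mm, 7.0 dB ↔ 3.1 mm /
ka 0.81) are not exactly consistent with the model as written — the
model value at 0.5 mm is 19.87 dB. Inversion is bisection to 1e-4 mm;
out-of-window differences clamp to the nearest band edge and are
flagged. `ka` uses the geometric-mean frequency
`f_m = √(f₃₈·f₁₂₀) = 67.5 kHz` (0.5 mm ↦ ka = 0.14).

## Density inversion and ESUs (`invert`)

Per copepod cell: `ESR = ΔTS⁻¹(ΔMVBS)`, TS at both frequencies from
the model, and

    N_f = 10^((Sv_f − TS_f)/10)   [ind m⁻³]

with the 120 kHz channel by default (stronger fluid-like signal; the
38 kHz route is supported and agrees within 1 % at zero noise). TS is
per-cell, size-specific — the defensible reading of the inversion
identity, rather than a survey-mean TS. Depth integration is the
rectangle rule on 1 m cells over 10–200 m; the track is partitioned
into 0.001 nmi ESUs by cumulative great-circle distance; ESU areal
abundance is the mean of its member columns' integrals, biomass is
`B_m = N · DM_m` (default `DM_m = 217 µg`, normally recomputed from the
ZooScan table), and copepod NASC is `4π·1852²·Σ(sv·Δz)`.

## Net samples and allometry (`zooscan`)

Scanned object areas convert at 0.0106 mm/pixel; ESR is the
area-equivalent circle radius `√(S/π)` (the source method never defines
its area→ESR convention; this is the standard one). Dry mass follows
`DM = a·S^b` with mandatory configuration coefficients; the defaults
(a = 45.25 µg, b = 1.59) are literature values for subtropical
mesozooplankton, and any absolute biomass inherits them. Station
summaries filter to ESR > 0.5 mm, weight by Motoda split factors, and
divide by flowmeter volumes (mouth-area × wire-distance fallback).
Method comparison uses Spearman rank correlation with the two-sided
t-approximation.

## Geostatistics (`geostats`)

Matheron empirical variogram on great-circle distances; weighted least
squares (weights `n_pairs/h²`) for spherical or exponential models; a
fitted range inside the first distance bin is flagged as structureless.
Kriging is *ordinary* kriging (the figure-level description of the
source method; its text also says "simple interpolation kriging") with
a 16-nearest-neighbour neighbourhood, solved per node with the
unbiasedness constraint; singular systems get one jittered retry. Grid
nodes are a 0.05° lattice clipped to the data's convex hull (bounding
box when the track is degenerate); cell areas scale with cos(latitude).

The total is `B_t = Σ B_i·A_i` (mg → tons, negative predictions clipped
and counted). The CV treats per-cell kriging variances as independent,
`CV = √(Σ σ²ᵢA²ᵢ)/B_t`; this understates the spatial covariance of the
errors and is an approximation, documented as such and not used as an
accuracy claim. Moran's I uses row-standardised inverse great-circle
distance weights (or an explicit matrix, e.g. rook adjacency).

## Solar geometry (`solar`)

NOAA low-accuracy solar position (Julian-century polynomial, equation
of time, no refraction), accurate to a few tenths of a degree over
1990–2040. Diel labels: day at altitude ≥ +18°, night at ≤ −18°,
transition in the open band between (boundaries closed on the day/night
side; the band's endpoints are astronomically conventional — the end of
astronomical twilight). Transition ESUs are excluded from day/night
aggregation.

## Synthetic surveys (`synthdata`)

The generator forward-models cell MVBS as `10·log₁₀(N·σ_bs(ESR, f))`
per channel, adds independent Gaussian dB noise per cell and channel
(default σ = 1 dB), and replicates each cell over its 3 × 1 m raw
samples so echo-integration reproduces the cell exactly. Defaults
describe the study conditions: a log-Gaussian along-track density field
(σ_ln = 0.8, 20-cell correlation) with median 100 ind m⁻³ in a Gaussian
vertical layer at 15–55 m by night, 70–110 m and 1/7 the density by
day (diel factor 7, driven by the actual solar altitude along the
simulated track off Senegal in March 2014); copepod ESR lognormal with
median 0.9 mm and σ_ln = 0.13, calibrated so the analytic mean dry mass
under the default allometry is ≈ 217 µg; krill patches drawn at sizes
whose model ΔTS falls in 2–7 dB; fish schools as cell rectangles with
Sv₃₈ = −48 dB and ΔMVBS ∈ [−5, 0]; background at −130 dB. Net counts
are Poisson around `density × filtered volume × q` with catch
efficiency q = 0.1 (reproducing the order-of-magnitude acoustic-vs-net
gap typical of these comparisons); ZooScan pixel areas invert the
area→ESR chain with 5 % lognormal measurement noise. All draws descend
from one seed.

The synthetic scenarios integrate with a −120 dB threshold rather than
the −80 dB survey default: at realistic densities the model-consistent
38 kHz copepod signal sits near −100 dB, and the gate's job is to
remove sub-noise samples, so the scenario places it between the signal
and the silent background. What the generator does *not* emulate:
within-cell size mixtures (one ESR per column, so ΔMVBS inverts
exactly at zero noise), vessel motion, bubble sweep-down, range-dependent
noise, school morphology beyond rectangles, and taxonomic confusion in
the net tables. Passing tests therefore demonstrate correctness of the
inversion chain and estimator logic under the stated noise model, not
field performance on real echograms.

## Numerical choices

- Size inversion: bisection on the monotone band, 1e-4 mm tolerance;
  repeated ΔMVBS values are cached (rounded to 1e-6 dB).
- GMM gate: 10 EM restarts, seeded; analytic equal-density boundary
  between the component means.
- Kriging: 16 neighbours; one diagonal-jitter retry (1e-9 × sill) on a
  singular system; negative-weight nodes are counted, not failed.
- Variogram fit: `scipy.optimize.least_squares` with bounds; weights
  √n/h.
- Degenerate inputs raise: constant GMM input, coincident variogram
  points, constant Moran/Spearman vectors, descending depth columns,
  duplicate (ping, depth) keys.

## Problem sizes

Tests and the acceptance checks run on 40–200-column surveys
(120–600 pings × 190 one-metre cells), 20-seed replicate loops for the
stochastic recoveries, and 100 Poisson replicates for the net-sampling
check — sizes at which every statistic of interest is already stable.

## Known limitations

- **Band-edge conditioning.** Near the 19.7 dB edge (sizes ≲ 0.7 mm,
  including the 0.9 mm reference size whose ΔTS is 19.0 dB) a 1 dB cell
  noise in each channel moves ΔMVBS across the band edge; the size
  clamps small, the implied TS drops, and densities inflate severely
  (bias ≈ ×3 at the reference conditions; `analysis/03` quantifies it).
  Mid-band sizes (ΔTS ≈ 10–15 dB) recover ESU abundance with ≈ 11 %
  median error at the same noise. This is a property of the per-cell
  ΔdB→size→TS chain itself, worth knowing before applying it to noisy
  data.
- The inversion assumes one dominant scatterer size per cell; real
  layers are size mixtures, which biases the aggregate ΔMVBS.
- The CV of the total biomass ignores between-cell error covariance.
- No DWBA/bent-cylinder models, no orientation averaging, isotropic
  variograms only, two frequencies only.
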