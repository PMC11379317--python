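# zoosonde

Bi-frequency (38/120 kHz) acoustic estimation of large-copepod density
and biomass: dB-difference classification, fluid-sphere inversion,
echo-integration to elementary sampling units, diel stratification and
kriged biomass mapping — with a forward-model survey generator so the
whole chain is testable against known truth.

## Who this is for

Fisheries-acoustics and zooplankton-ecology workflows that have
co-registered 38 and 120 kHz volume backscatter (`Sv`, dB re 1 m⁻¹) and
want copepod abundance (ind m⁻²) and biomass (mg m⁻²) along track, plus
survey totals. Nets undersample large copepods; the dB difference
between 120 and 38 kHz separates fluid-like scatterers from fish and,
through a scattering model, carries size information.

## The model

Cells (3 pings × 1 m, integrated at −80 dB) are classified by
`∑MVBS = MVBS₁₂₀ + MVBS₃₈` and `ΔMVBS = MVBS₁₂₀ − MVBS₃₈`: a fish gate
at ∑MVBS > −119 dB (fittable as the equal-density point of a
two-Gaussian mixture), then ΔMVBS windows — < 2 dB other, 2–7 dB krill,
7–25 dB copepod — a 3×3 majority rescue of fluid echoes inside fish
schools, and a −65 dB upper threshold.

Copepod cells are inverted through the high-pass fluid-sphere model

    σ_bs = a²(ka)⁴α² / (1 + 4(ka)⁴α²/R²),   R = (gh−1)/(gh+1),
    α = (1−gh²)/(3gh²) + (1−g)/(1+2g)

with g = 1.02, h = 1.058, c = 1508 m s⁻¹. The dB difference
`ΔTS(a) = TS₁₂₀ − TS₃₈` falls monotonically from the Rayleigh ceiling
40·log₁₀(120/38) = 19.98 dB, so ΔMVBS in the 7.0–19.7 dB window maps to
an equivalent spherical radius, and density follows from
`N_f = 10^((Sv_f − TS_f)/10)`. Depth-integrated densities per 0.001 nmi
ESU times the mean individual dry mass (DM = a·S^b allometry on ZooScan
areas; reference 217 µg) give areal biomass, which is kriged
(ordinary kriging, 0.05° grid) and totalled. Diel transitions (solar
altitude between −18° and +18°) are excluded from day/night contrasts.

See `docs/methods.md` for assumptions, parameter defaults and known
limitations — in particular the noise sensitivity of the size inversion
near the 19.7 dB band edge.

## Worked example

The numbered scripts under `analysis/` run a synthetic survey off
Senegal (200 columns × 190 m, March 2014 track, 1 dB cell noise,
copepod layer with a ×7 night:day migration, krill patches, fish
schools) end to end, writing tables to `results/`:

    cd analysis
    python 01_simulate_survey.py
    python 02_classify_echogram.py
    python 03_invert_density.py
    python 04_krige_biomass.py
    python 05_method_comparison.py

Output from this build:

    copepod recall at 1 dB noise: 99.4%
    fish cells leaking into fluid classes: 0.0%

    ESU abundance recovery at 1 dB cell noise:
      reference_0.9mm: median rel. error 2.11, bias x3.20, clamped cells 28.3%
      midband_2.0mm:   median rel. error 0.11, bias x1.13, clamped cells 0.0%

    kriged 16 nodes at 0.05 deg; B_t = 1617.1 t, CV = 40.0%
    Moran's I of ESU biomass: 0.449
    day:   mean 775 +/- 874 mg m-2 (n=84)
    night: mean 6668 +/- 7301 mg m-2 (n=74)

    32 station/stratum pairs: Spearman rho = 0.96 (p = 9e-19)
    acoustic/net abundance ratio 11.2 (net catch efficiency q = 0.1)
    ZooScan mean individual dry mass: 220 ug (n=5000)

Reading: classification is near-perfect at 1 dB noise; the density
inversion is accurate for mid-band sizes (11 % median ESU error) but
biased high for sizes near the ΔTS band edge, where noise clamps the
inverted size small — quantified, not hidden; the night:day biomass
contrast and the acoustic-vs-net ratio recover the generator's ×7
migration factor and 0.1 catch efficiency; the mean scanned dry mass
reproduces the 217 µg reference individual.

There is also a CLI for running the pipeline on survey CSVs:

    zoosonde simulate --seed 1 --n-cells 100 --out simdir/
    zoosonde run --survey simdir/survey.csv --out rundir/

## Layout

    src/zoosonde/     echogram, scattering, classify, invert, zooscan,
                      geostats, solar, synthdata, config, pipeline, cli
    analysis/         numbered drivers for the synthetic-survey study
    tests/            pytest suite (unit, property, acceptance)
    scripts/          acceptance.py
    docs/methods.md   model documentation and design rationale
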