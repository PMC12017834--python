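# paleorange

Quantitative palaeoecology tools for asking how far an extinct herbivore
ranged: a reusable implementation of the inference chain used to study the
foraging range of *Protemnodon*, a genus of large extinct macropodids from
the Mt Etna Caves (central eastern Queensland) Middle Pleistocene rainforest
deposits.

The package covers four linked analyses plus a synthetic-data module:

1. **Phylogenetic allometry** (`paleorange.allometry`) — fits the power law
   `log10 Y = b·log10 X + a` (Y home range in km², X body mass in kg) across
   extant macropodids by generalised least squares under Brownian-motion
   phylogenetic covariance (PGLS), and predicts home ranges for extinct body
   masses. For the published macropodid coefficients (b = 1.4, a = −1.82) a
   50 kg animal predicts 3.6 km² and a 170 kg animal 19.8 km².
2. **Luminescence dating** (`paleorange.luminescence`) — central and minimum
   age models (CAM, MAM-3/4) for single-grain TT-OSL equivalent-dose (De)
   distributions, likelihood-based model selection, the precision-weighted
   skewness test, dose-rate budgets with moisture attenuation, and ages
   `t = De/Ḋ` with random/systematic error split.
3. **U-Th dating** (`paleorange.useries`) — closed-system ages by inverting
   the ²³⁰Th ingrowth equation, and open-system ages for tooth-enamel
   transects using a planar diffusion–adsorption–decay (DAD) model with an
   exact cosine-series solution and a profile-likelihood inversion for
   (age, initial ²³⁴U/²³⁸U).
4. **Sr isotope reduction and provenance** (`paleorange.sr`,
   `paleorange.foraging`) — reduction of raw LA-MC-ICP-MS beam cycles to
   corrected ⁸⁷Sr/⁸⁶Sr (baseline, Kr and Rb interference stripping,
   exponential-law mass bias, standard-sample-standard bracketing against
   modern seawater 0.709182), per-transect summaries and group tests
   (Welch, Kruskal–Wallis/Dunn, one-way ANOVA), bioavailable-Sr baselines
   per geological unit, and local vs extra-local classification of fossil
   specimens.

`paleorange.synthetic` generates seeded inputs for every stage with the
statistical structure each analysis assumes, so the whole pipeline is
testable without any external downloads; it also packages the study's
published summary values (specimen and vegetation-baseline means, the
dose-rate/De table, the per-transect age table) as the `mt_etna` fixture.

## Worked example

Everything is reachable from the `paleorange` CLI (each command is a thin
wrapper over the library). Generate a synthetic 17-species trait set, fit
the allometry and predict:

```text
$ paleorange synth traits --seed 7 --out .
$ paleorange allometry fit --tree tree.nwk --traits traits.csv --out fit.json
n=17  logY = 2.437 logX + -3.692  R^2=0.493  F(1,15)=14.610  p=0.0017
$ paleorange allometry predict --fit fit.json 50 131 170
50 kg -> 2.8 km^2  [0.1, 53.2] (+/-2SE)
131 kg -> 29.3 km^2  [0.5, 1673.8] (+/-2SE)
170 kg -> 55.3 km^2  [0.7, 4305.9] (+/-2SE)
```

(The seed-7 draw happens to fall steeper than the published slope; the
intervals are ±2SE of the regression line, exponentiated and therefore
asymmetric.) Fit a burial dose to synthetic single grains in the 40-grain,
30%-overdispersion regime of the older sediment sample, and turn it into an
age with that sample's published dose-rate budget:

```text
$ paleorange synth grains --scenario mte17_1 --seed 7 --out .
$ paleorange lum fit --grains grains.csv --model auto --out burial.json
model  log_likelihood  n_parameters
  CAM      -15.038469             2
 MAM3      -14.959685             3
 MAM4      -14.912652             4
CAM: burial dose 249.8 +/- 13.9 Gy, OD 11%
$ paleorange lum age --burial burial.json --budget budget.csv
dose rate 0.96 +/- 0.04 Gy/ka; age 260.2 +/- 18.6 ka (random 17.9, systematic 5.2)
```

The likelihood-ratio model selection keeps the central age model (the extra
minimum-age-model parameters do not pay for themselves), and the age error
combines the De and dose-rate uncertainties with a 2% beta-source
calibration term. U-Th ages, closed and open system:

```text
$ paleorange useries closed --a234 1.110 --a230 0.764 --a234-2sd 0.002 --a230-2sd 0.007
age 123.5 ka +/- 2.1 (2SD); initial (234U/238U) 1.1558
$ paleorange synth useries --seed 7 --out .
$ paleorange useries idad --profile transects.csv
SYN_1: 250 +3/-3 ka (2SD), initial (234U/238U) 1.494
SYN_2: 249 +3/-3 ka (2SD), initial (234U/238U) 1.501
```

The closed-system solve reproduces the ~124 ka reference coral; the two
synthetic enamel transects (truth: 250 ka) invert to ages within error of
each other. Finally, reduce a synthetic Sr session and classify the four
specimens with published summaries against the 11-unit vegetation baseline:

```text
$ paleorange synth beams --seed 7 --out . && paleorange sr reduce --cycles cycles.csv --out spots.csv
$ paleorange synth baseline --seed 7 --out .
$ paleorange forage classify --baseline baseline.csv --specimens specimens.csv
WIGL8547: local-formation  (nearest unit: Mount Alma Formation, |delta| = 0.000297)
WIGL8548: local-formation  (nearest unit: Mount Alma Formation, |delta| = 0.000033)
WIGL8549: local-formation  (nearest unit: Mount Alma Formation, |delta| = 0.000318)
WIGL8550: extra-local  (nearest unit: Permian-Triassic Gabbro, |delta| = 0.000016)
```

Three specimens sit inside the Mount Alma Formation interval (local
foragers); WIGL8550 is isotopically lighter than anything local and ranks
the Permian–Triassic Gabbro and Alton Downs Basalt as nearest candidate
source substrates.

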