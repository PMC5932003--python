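# peatflux

Quantitative analysis of peat-core carbon and dust records: radiocarbon
chronologies, Monte-Carlo accumulation rates, rare-earth-element (REE)
provenance proxies, organic-matter-quality PCA, and Bayesian changepoint
detection — with a synthetic-core simulator that makes every stage testable
against known truth.

## Who this is for

Paleoecologists and biogeochemists working with dated peat (or lake)
sequences who need the standard chain

```
14C dates ──calibrate──► age-depth model ──rates──► PAR / CAR / element MAR
core data ──────────────────────────────► REE proxies, OM-quality PCA
any series ─────────────────────────────► changepoint posterior
```

as reproducible, seeded, scriptable components rather than a collection of
one-off spreadsheets and R sessions.

## The models in brief

**Calibration.** A measured radiocarbon age r ± σ maps to a probability
mass over calendar age θ through the calibration curve (μ(θ), τ(θ)):

L(θ) ∝ (σ² + τ²(θ))^(−1/2) · exp[ −(r − μ(θ))² / 2(σ² + τ²(θ)) ].

Reported ranges are 95% highest-posterior-density envelopes.

**Age-depth model.** Per Monte-Carlo iteration one calendar age is drawn
from each date's calibrated distribution and a cubic smoothing spline of
age on depth is fitted (roughness penalty parameterised by a 0–1 smoothing
knob, default 0.3, the classical spline-smoother convention); iterations
that reverse stratigraphic order are rejected. Outliers are screened as
stratigraphic reversals, flagging the bulk-peat member of a reversing pair.

**Accumulation rates.** PAR = ρ·s·10⁴ g m⁻² yr⁻¹ (ρ bulk density g/cm³,
s sedimentation rate cm/yr), CAR = PAR·C%/100, element MAR = PAR·conc·10⁻⁶.
Uncertainty by measurement-level Monte Carlo (default n = 100,000):
uniform ±0.1 cm on radius and thickness, ±0.002 g on mass, ±5% on the
rate; Normal on concentrations. Errors are reported as 25–75% quartiles.

**Dust proxies.** UCC-normalised La/Lu and Gd/Lu fractionation,
[Eu/Eu*] = Eu_N/√(Sm_N·Gd_N), and dust flux = Al MAR / 0.0804.

**Changepoint model.** Piecewise-constant mean with conjugate
Normal(m₀, v₀) segment-mean prior (marginalised analytically) and a single
noise SD; reversible-jump MCMC over the number and positions of jumps and
σ. An exhaustive enumeration oracle validates the sampler on small series.

## Worked example

Simulate the default bog record — 8,900 years, background PAR ≈ 45
g m⁻² yr⁻¹, C ≈ 49%, and a high-accumulation event between 5420 and
4550 cal BP with a seven-fold rate increase — then recover the event from
the observations alone:

```
$ peatflux curve --out curve.14c --cal-max 15000
wrote synthetic stand-in curve to curve.14c
$ peatflux simulate --curve curve.14c --seed 11 --out-dir sim
wrote 847 slices, 19 dates to sim/
```

```python
from peatflux import SyntheticCoreSpec, simulate_core, synthetic_calibration_curve
from peatflux.synthetic import recover_accumulation_event

curve = synthetic_calibration_curve(cal_max=15000)
core = simulate_core(SyntheticCoreSpec(), curve, seed=11)
print(recover_accumulation_event(core.profile, core.dates, curve, seed=11))
```

prints

```
{'boundary_depths': (273.5, 638.5), 'onset_age': 5423.1,
 'termination_age': 4538.0, 'amplification': 6.8}
```

i.e. from 19 noisy radiocarbon dates and the dilution signal in the Al
profile the pipeline locates the event onset within ~3 yr of the true
5420 cal BP, its end within ~12 yr of 4550, and the rate amplification
within 3% of the true factor 7. The full stage chain (calibrate →
agemodel → accumulate → proxies → pca → changepoint) runs from one YAML
config:

```
$ peatflux pipeline --config run.yaml
```

writing `calibrated.csv`, `agemodel.csv`, `rates.csv`, `proxies.csv`,
`loadings.csv`/`scores.csv`/`variance.json`, changepoint summaries and a
`manifest.json`; identical (inputs, config, seed) reproduce every output
bit-for-bit.

The published Draftinge Mosse date table is packaged
(`peatflux.io.draftinge_dates()`); the outlier screen on it flags exactly
the two bulk-peat dates at 308 and 338 cm, each older than the date below
it.

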