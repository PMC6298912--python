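# ceusquant

Quantification of bolus wash-in kinetics in contrast-enhanced ultrasound
(CEUS), built for small-animal perfusion studies such as longitudinal
imaging of the mouse ovary. After an intravenous microbubble bolus, the
linearised contrast signal inside a region of interest (ROI) rises from a
baseline to a peak; `ceusquant` extracts that time–intensity curve (TIC)
from a cine loop, fits a parametric bolus model to it, derives the nine
standard perfusion parameters, and compares two study arms timepoint by
timepoint. A synthetic-study generator reproduces the statistical
structure of a two-arm, three-timepoint design (treated vs. control mice,
n = 10 per arm, 55 s acquisitions at 36 frames/s), so the whole pipeline
is testable without any imaging data.

## Model

The wash-in TIC is modelled as a lognormal bolus above a baseline:

```
f(t) = O                                                   t ≤ t0
f(t) = O + A · exp(−(ln(t−t0) − μ)² / (2σ²)) / ((t−t0)·σ·√(2π))   t > t0
```

with baseline `O` (a.u.), bolus area `A` (a.u.·s), log-time location `μ`
(ln s), spread `σ`, and arrival time `t0` (s). Fitting is bounded
nonlinear least squares with an analytic Jacobian and seeded multi-starts.
The fitted curve yields:

| parameter | definition | closed form (lognormal) |
|---|---|---|
| PE | peak enhancement: fitted maximum − baseline | `A·e^(σ²/2−μ)/(σ√2π)` |
| WiR | maximum wash-in slope | numeric (grid + refinement) |
| TTP | time from acquisition origin to peak | `t0 + e^(μ−σ²) − origin` |
| RT | rise time: max-slope tangent baseline crossing → peak | via tangent |
| AUC | baseline-subtracted area to infinite time | `A` |
| MTT | mean transit time from arrival | `e^(μ+σ²/2)` |
| PI | AUC / MTT | — |
| WiAUC | area from starting enhancement to peak | lognormal CDF |
| WiPI | WiAUC / RT | — |

Arm comparisons use Welch's two-tailed unequal-variance t-test
(Welch–Satterthwaite degrees of freedom), per parameter and timepoint at
α = 0.05, computable from raw samples or directly from published
mean ± SD summaries.

## Worked example

```python
from ceusquant import (BolusModelParams, FitConfig, simulate_tic,
                       fit_bolus_model, extract_parameters)

params = BolusModelParams(O=5.0, A=100.0, mu=1.0, sigma=0.5, t0=2.0)
tic = simulate_tic(params, duration=55.0, frame_rate=36.0,
                   noise_sd=0.67, seed=3)         # ~2% of peak
fit = fit_bolus_model(tic, FitConfig(seed=0))
pp = extract_parameters(fit)
print(f"converged={fit.converged}  rss={fit.rss:.1f}")
for name, value in pp.as_dict().items():
    print(f"{name:>6}: {value:8.3f}")
```

prints

```
converged=True  rss=875.5
    pe:   33.327
   wir:   33.725
   ttp:    4.115
    rt:    1.436
   auc:  100.285
   mtt:    3.080
    pi:   32.565
  wipi:   21.326
 wiauc:   30.624
```

The generating curve has true PE = 33.26 a.u. (peak ≈ 38.26 a.u. over a
baseline of 5), TTP = 2 + e^0.75 ≈ 4.117 s, AUC = 100 a.u.·s and
MTT = e^1.125 ≈ 3.080 s; the fit recovers each to a few tenths of a
percent at 2%-of-peak noise. The same steps are available from a shell:

```
ceusquant simulate --out study/ --seed 1
ceusquant pipeline --input study/ --out results/
```

which fits every generated TIC and writes per-animal parameters plus the
per-parameter, per-timepoint Welch comparison table.

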