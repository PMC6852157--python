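# benthic-encounters

Tools for studying how body size and encounter strategy shape feeding
interactions in the marine benthos: maximum-likelihood fitting of
generalised functional responses to depletion feeding trials, allometric
scaling of the quantities that drive encounters, a mixed-effects
meta-analysis of fitted feeding parameters, and an agent-based model of
resource **biomass encounter rates** for passive (filter-feeding) and
active (searching) consumers.

It is written for quantitative ecologists who have trial-level feeding
data (initial densities, numbers eaten, durations, masses) or who want
to explore, in simulation, why consumers that passively strain tiny,
abundant resources out of moving water meet far less resource *biomass*
than active searchers of the same body mass — even while encountering
far more resource *individuals*.

## The models

**Functional response.** Per-capita consumption rate at resource
density *N* follows the generalised Holling form

    f(N) = b N^(q+1) / (1 + b h N^(q+1))

with capture (search) coefficient *b*, handling time *h*, and shape
exponent *q* (0 = hyperbolic type II, 1 = sigmoidal type III).  Feeding
trials that do not replace eaten resources violate the constant-density
assumption, so the expected number eaten over a trial of duration *T*
started at *N0* resources solves the Rogers random-predator (depletion)
equation

    Ne = N0 (1 - exp(c (h Ne - T))),   c = b N0^q,

computed in closed form via the Lambert-W function (with a bracketed
root-finder as an independent check).  Counts are fitted by binomial
maximum likelihood; variants I (*h* = *q* = 0), II (*q* = 0), III
(*q* = 1) and the free general model are compared by small-sample AICc,
with ties resolved by the shape of proportional consumption versus
density (flat / decreasing / rise-then-fall).  Fits are summarised by
the capture rate at the half-saturation density (commensurable across
*q*) and the maximum feeding rate 1/*h*, in biomass units (g/day).

**Meta-analysis.** Log capture and maximum feeding rates are modelled
as random-intercept (taxonomic group) linear mixed effects of log
consumer mass, log resource mass and log temperature, with encounter
strategy as a non-interacting categorical predictor.  All 36
marginality-closed fixed-effect structures (including the null) are
ranked by AICc from ML fits; scaling exponents are compared between
strategies by nonparametric bootstrap.

**Encounter simulation.** A consumer with a mass-scaled encounter
region — a discoid of radius r0·m^0.36 in the seabed plane for active
searchers, a seabed hemisphere for filter feeders — sits in a toroidal
arena of resources at constant unitary density.  Movers follow
correlated random walks at the velocity-length allometry
V = 2.67·l^1.05 (m/s, l in m); planktonic resources additionally ride a
laminar current of 0.1 ± 0.01 m/s.  Encountered resources are relocated
uniformly, keeping the system in the encounter-limited regime.  Outputs
are unitary (individuals/s) and biomass (g/s) encounter rates;
kinetic-theory closed forms (2rVn sweeps, hemisphere flux nUπr²/2)
validate the simulator.

## Worked example

```python
from benthic_encounters import HollingParams, fit_all_variants, select_response
from benthic_encounters.synthetic_data import generate_trials, geometric_levels

true = HollingParams(b=0.5, h=0.1, q=0.0)
trials = generate_trials(true, geometric_levels(6), replicates=25, T=1.0, seed=42)
fits = fit_all_variants(trials, compute_se=False)
for name, fit in fits.items():
    print(name, round(fit.params.b, 4), round(fit.params.h, 4), round(fit.AICc, 2))
print("selected:", select_response(fits, trials).variant)
```

prints

```
I 0.1819 0.0 601.0
II 0.4667 0.1052 501.94
III 0.1005 0.1656 539.44
general 0.4667 0.1052 504.02
selected: II
```

The type-II fit wins by ~37 AICc over type III and recovers the
generating b = 0.5 and h = 0.1 to within about 7%; the general model
collapses onto it (q̂ = 0) and is penalised only for its extra
parameter.  The `examples/` directory holds similar short scripts for
the allometries, the encounter simulator, the meta-analysis and the
full pipeline; the `benthic-encounters` console command exposes
`generate`, `fit`, `meta`, `simulate` and `run` subcommands over the
same code.

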