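# apcmap

Age-period-cohort decomposition and stabilized disease maps for
multi-area cancer-registry incidence data.

Descriptive registry epidemiology keeps answering three questions: how
fast is incidence changing (AAPC), whether the change is driven by
calendar period or birth cohort (APC decomposition), and where the risk
and its trend concentrate geographically (small-area maps). Each question
has a standard statistical obstacle: joinpoint selection, the exact
non-identifiability of the APC model (cohort = period − age), and the
instability of small-area estimates. `apcmap` implements the full chain
for registry analysts:

- **rates** — age-specific rates, direct standardization to the WHO 2000
  world standard (`ASR = Σ_a w_a r_a`), expected counts and standardized
  incidence ratios (`SIR_i = O_i / E_i`), histology shares;
- **trends** — continuous piecewise Poisson log-linear fits with BIC
  joinpoint selection and `AAPC = 100·(exp(Σ_j w_j β_j) − 1)`;
- **apc_crv** — the APC model `log r_ap = μ + α_a + π_p + γ_c`
  identified by the *constant relative variation* rule: age effects are
  treated as deterministic, and the drift allocation δ between period and
  cohort is chosen so that the coefficient of variation of `exp(π)`
  equals that of `exp(γ)`;
- **spatial** — empirical-Bayes shrinkage of SIR/AAPC toward the null
  with weight `τ²/(τ² + σ_i²)`, semivariogram fitting, ordinary kriging
  with heteroscedastic measurement error, and red/white/blue contour maps;
- **synthetic** — a multi-area registry generator with known age curves,
  period/cohort structure, spatial risk field and per-area trends, since
  real registry microdata are access-restricted.

## Worked example

Generate a registry and run the chain (the numbered drivers under
`analysis/` do exactly this and write tables to `results/`):

```sh
cd analysis
python 01_simulate.py && python 02_rates.py && python 03_trends.py
python 04_apc.py && python 05_maps.py
```

On the shipped default scenario (306 areas, 1997–2017, seed 1) this
prints, among other lines:

```
male   adenocarcinoma            ASR 1997:   29.9 -> 2017:   61.5 per 100,000
male   adenocarcinoma            pooled SIR 1.000000000000  (areas: 306, SIR range 0.59-1.73)
male   adenocarcinoma            AAPC  3.78 (95% CI 3.64, 3.92), joinpoints at none
male_adenocarcinoma          delta* = +0.1404 (net drift +0.1784/band), RV = 0.1567
male_adenocarcinoma          MSE vs true field: raw 0.00843 -> kriged 0.00666 (21% lower)
```

Reading these: the ASR doubles over the period, consistent with the
configured +4%/yr drift (the estimated AAPC of 3.78 recovers it); the
pooled SIR is exactly 1 because the reference rates come from the pooled
data itself (an algebraic conservation); the CRV rule allocates drift
δ* = 0.140 of the total 0.178 per 5-year band to the period side, at which
point period and cohort effects share relative variation 0.157; and the
stabilized kriged SIR surface is 21% closer (mean squared error) to the
generator's true risk field than the raw SIR map — the sparser squamous
strata gain 39–52%. One stratum (male squamous) is reported as
*CRV balancing not attainable*: its noisy cohort curvature has larger
relative variation than any drift allocation can give the period side,
and the solver fails loudly with a diagnostic profile rather than pick an
allocation silently.

The same pipeline runs from a shell on real registry extracts
(CSV incidence + person-years, GeoJSON geometries) via the CLI:

```sh
apcmap all --config myrun.yaml --seed 1 --outdir out/
apcmap trends --config myrun.yaml --stratum sex=female,histology=adenocarcinoma
```

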