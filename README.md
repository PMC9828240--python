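# mdtfit

Preference studies in benefit–harm assessment increasingly elicit how much
patients are willing to trade off between treatment attributes (say,
one-year progression-free survival against the risk of severe toxicity).
Under an additive value model

v(x) = Σᵢ wᵢ·vᵢ(xᵢ),  w on the unit simplex,

each respondent's trade-offs are captured by the attribute weight vector
**w**. Multi-dimensional thresholding (MDT) elicits **w** with
cognitively light questions — a swing ranking of the attributes followed
by a handful of binary bisection choices per consecutively ranked pair —
but the price is that the answers never pin **w** down to a point: they
only confine it to a convex polytope Ω of the simplex (*region-censored*
data).

`mdtfit` is a toolkit for working with such data end to end:

- **Elicitation simulation** — runs the full MDT questioning procedure for
  respondents with known weights, producing response records and the
  feasible weight spaces they induce, and enumerates the questioning tree.
- **Polytope machinery** — membership tests, hit-and-run uniform sampling,
  Monte Carlo centroids and volume fractions for regions of the simplex.
- **Population model fitting** — a Dirichlet model in mean–precision form
  (α = φ·μ) fitted either exactly to observed weight vectors, naively to
  region centroids, or — the core of the package — directly to the regions
  by **simulated maximum likelihood (SML)**: each respondent's likelihood
  contribution P_j = ∫_{Ω_j} f(w) dw is approximated by the average density
  over m uniform draws from Ω_j, frozen across optimizer iterations, so
  that region-volume constants cancel from the argmax and never need to be
  computed.
- **Simulation study** — a configurable experiment grid comparing the SML
  and centroid estimators against an exact-information reference fit, by
  the Euclidean error of the estimated population mean and the relative
  error of the precision parameter.

Intended users: health-preference and benefit–risk researchers analysing
thresholding-style elicitation data, and methodologists studying
estimators for region-censored compositional data.

## Worked example

A study with three attributes — PFS (50→90%, benefit), moderate chronic
toxicity MT (85→45%, harm), severe toxicity ST (80→20%, harm) — and two
bisection steps per trade-off, described in `study.yaml`:

```yaml
attributes:
  - {name: PFS, worst: 50, best: 90}
  - {name: MT, worst: 85, best: 45}
  - {name: ST, worst: 80, best: 20}
steps_per_tradeoff: 2
sml: {m: 500, seed: 1}
```

Simulate 300 respondents from a Dirichlet population with mean
(0.5, 0.2, 0.3) and precision 7, then fit both estimators:

```bash
$ mdtfit simulate --config study.yaml --mu 0.5,0.2,0.3 --phi 7 -N 300 \
    --seed 11 --out responses.jsonl
$ mdtfit fit --config study.yaml --responses responses.jsonl --method sml \
    --out params_sml.json
{"method": "sml", "mu": [0.4983691038102292, 0.2070608193484177,
 0.29457007684135317], "phi": 6.963004469285414, "sll": 352.2079842301057,
 "iterations": 5, "m": 500, "N": 300, "seed": 1, "converged": true}
$ mdtfit fit --config study.yaml --responses responses.jsonl --method centroid \
    --out params_centroid.json
{"method": "centroid", "mu": [0.4988461950997463, 0.20929235935246882,
 0.2918614455477848], "phi": 6.832080038860663, "m": 500, "N": 300, "seed": 1}
```

The SML fit recovers the generating mean to within ~0.005 per component
and the precision to within 0.5% from purely region-censored answers (four
binary thresholding questions per respondent). With only one bisection
step per trade-off the centroid baseline's precision estimate inflates
markedly while SML's stays close — the pattern quantified by the
simulation study:

```bash
$ mdtfit experiment --n-attributes 4 --models 20 -N 100 -N 300 \
    --steps 1 --steps 2 --steps 3 --m 500 --seed 0 --out results.csv
```

The same machinery is available as a library; see `mdtfit.run_mdt`,
`mdtfit.fit_sml`, `mdtfit.run_experiment`, and `docs/methods.md` for the
model details.

```bash
$ mdtfit enumerate-paths --n-attributes 3 --steps 2
paths: 96 (thresholding questions per respondent: 4)
```

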