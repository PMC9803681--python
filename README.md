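# durleak

Tools for studying how the **temporal context** — the durations of
simultaneous, task-irrelevant stimuli — biases duration judgments, built
around a duration-channel *leaking* model with a single free parameter.

The package targets two-interval forced-choice (2AFC) experiments in which
observers compare two targets of identical physical duration (1 s), each
accompanied by homogeneous distractors of a different duration, and judge
which target lasted longer. Any systematic response bias must then come
from the distractors. `durleak` provides:

- the forward model (perceived durations, response probabilities),
- maximum-likelihood estimation of the leaking factor *k* per participant,
- logistic psychometric fitting with lapse-rate AIC selection and bootstrap
  confidence intervals for the control/ensemble conditions,
- a seeded synthetic-observer generator emulating the full design,
- a per-participant pipeline and cohort summary, as a library, a CLI
  (`durleak simulate|fit|pipeline|report`), and numbered analysis drivers.

## Model

A target of duration *t* presented with distractors of duration *d* is
perceived as the weighted average

$$\hat t = \frac{t + d\,w}{1 + w},$$

where the target always has unit weight and the distractor weight decays
with dissimilarity:

$$w = k^{\,|d-t|}, \qquad 0 \le k \le 1 \quad \text{(leaking variant)}$$

*k* = 1 weighs every distractor fully (pure averaging); *k* → 0 confines the
influence to distractors nearly identical to the target. This always pulls
the percept toward the distractor (central tendency). A lateral-inhibition
variant replaces the weight with a Ricker (Mexican-hat) profile,

$$w = \Bigl(1 - \bigl(\tfrac{d-t}{k}\bigr)^2\Bigr)\,
      2^{-\frac{(d-t)^2}{k^2}}, \qquad k > 0,$$

which attracts for |d−t| < k and repels beyond (w ranges from −0.265 to 1);
it accounts for participants whose judgments shift *away* from the
distractors.

A 2AFC response compares the two perceived targets under standard Gaussian
decision noise, P("second longer") = Φ(t̂₂ − t̂₁), and *k* is estimated by
maximizing the binomial log-likelihood of the per-combination response
counts (12 ordered distractor pairs × 30 repetitions in the full design),
scored by a Pearson χ² goodness of fit with df = 11.

## Worked example

Simulate a 22-observer cohort (19 central-tendency leaking observers with
k ~ U(0.05, 0.95), 3 repulsion observers with Ricker k = 0.3 s), run the
full pipeline, and score recovery against the generator's ground truth:

```bash
python analysis/01_simulate_cohort.py --seed 5 --out results/cohort
python analysis/02_run_pipeline.py --input results/cohort/trials.csv --out results
python analysis/03_summarize.py --report results/report.json --truth results/cohort/truth.csv
```

which prints (seed 5, n_boot 500):

```
22 participants: central=16 repulsion=1 null=5
percent correct: control 95.5%, ensemble 90.4%
psychometric SD: control 0.315 s vs ensemble 1.155 s (paired t = -33.84, p = 8.3e-20)
k over central participants: mean=0.604 sd=0.228 range 0.239-0.971
leaking-k recovery over 16 participants: Pearson r = 0.966, median |k_hat - k_true| = 0.032
variance-ratio vs k: r(14) = -0.454, p = 0.078
```

Reading: 16 of the 19 leaking observers are classified *central* (their
distractors-condition slope CI excludes 0 from above) and their fitted k
track the generating values closely (r = 0.97, median error 0.03); low-k
observers produce slopes too shallow to resolve and fall in the *null*
class; Ricker repulsion at k = 0.3 s is a weak, nonmonotone signal under
unit decision noise, so only some repulsion observers are detected.
Discrimination is better with single-stimulus intervals (control) than with
multi-element intervals (ensemble), visible in both percent correct and the
psychometric SDs. The variance-ratio/k correlation carries no built-in
effect in this generator — its value here is sampling noise around zero.

The same pipeline runs on real trial tables: a CSV with columns
`participant,condition,t1,d1,t2,d2,response` (seconds; `response` = 1 for
"second longer"; `d1`/`d2` empty in the control condition), e.g. exported
from a deposited dataset, via
`durleak pipeline --input trials.csv --output report/`.

`analysis/04_perceptual_increment.py` tabulates the model's predicted
perceptual increment t̂ − t versus distractor duration for both variants.

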