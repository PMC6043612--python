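# treedelay

**Dating unobserved cell-fate decisions from delayed, correlated
lineage-marker onsets in single-cell genealogies.**

When a stem cell commits to a lineage, nothing observable happens at
that moment: the lineage marker that reports the decision (a surface
antigen such as CD16/32, or a fluorescent reporter such as
GATA1-mCherry) appears only after a long, stochastic expression delay —
often several cell generations later.  In a single non-dividing cell
the decision time is therefore unidentifiable.  In a *genealogy* it is
not: cells that divide during the delay hand their partial marker
expression to both daughters, so sisters and cousins show correlated
onset times, and the strength and range of those correlations encode
when the decision fell.

`treedelay` is a toolkit for this inference problem, aimed at
quantitative biologists working with tracked time-lapse genealogies:

* a **generative model** — a memory-less decision process with clipped
  linear hazard λ(t) = max(0, a0 + a1·t), followed by a birth–death
  marker-expression delay (production α, degradation γ·x, detection
  threshold x*) whose state is inherited at division;
* an exact **hidden-tree likelihood**: the probability of an observed
  genealogy is the sum over all "hidden trees" — assignments of the
  decision event to an antichain of cells consistent with the observed
  onsets — computed by sum–product message passing over the expression
  state within decision-rooted subtrees and a dynamic program over
  scenarios (the doubly-exponential explicit enumeration is kept as a
  cross-check for small trees);
* **maximum-likelihood fitting** of (a0, a1, α, γ, x*) with
  Latin-hypercube multistart and a profile over the integer threshold,
  plus **MAP / k-best prediction** of which cells made the decision and
  when;
* validation machinery: a **forward simulator**, a **branching-process
  model of colony assays** (per-generation decision probabilities from
  the fitted hazard; pure/mixed colony frequencies by recursion), a
  tristable **toggle-switch simulator** (Gillespie dynamics on dividing
  lineages, quasi-potential wells, basin-entry marker calls), and
  **marker-slope statistics** (per-cell OLS slopes grouped by
  generation offset from the predicted decision, Wilcoxon rank-sum
  comparisons).

See `docs/methods.md` for the model, algorithms, and numerical choices.

## Worked example

Simulate 40 genealogies (12 ± 5 h cycles, 120 h movie) under known
parameters, refit them, and predict the decision cells:

```bash
cat > sim.yaml <<EOF
seed: 11
decision: {a0: 0.15, a1: -0.002}
delay: {alpha: 0.5, gamma: 0.01, x_star: 25}
cellcycle: {mean: 12, sd: 5}
movie_end: 120.0
n_trees: 40
EOF
cat > fit.yaml <<EOF
x_star_grid: [15, 25, 40]
n_restarts: 8
n_polish: 1
outer_maxfev: 40
EOF

treedelay simulate --config sim.yaml --out trees.tsv --truth truth.tsv
treedelay fit --trees trees.tsv --config fit.yaml --out fit.json --seed 1
treedelay predict --trees trees.tsv --fit fit.json --out pred.tsv
```

The fit prints

```json
{
  "theta_hat": {"a0": 0.1136865997314451, "a1": -0.0011876068115234386},
  "eta_hat": {"alpha": 1.0264004490314926, "gamma": 0.017930694253126794, "x_star": 40},
  "total_log_likelihood": -18256.74816788331,
  "converged": true,
  "n_trees": 40
}
```

Read this on the scale that is actually identified: the implied
decision CDF Φ(t) deviates from the generating Φ by at most 0.097
(sup-norm over the 120 h movie) and the implied mean decision-to-onset
delay is 63.9 h against a true 67.5 h — even though the individual
delay parameters differ from the truth (α and x* trade off strongly;
at 200 trees both errors shrink to a few percent).  The predictions

```
tree_id  cell_id  is_predicted_decision  decision_generation  scenario_rank  scenario_loglik
sim0000  1        1                      0                    1              -280.622
sim0001  1        1                      0                    1              -163.938
```

say that in these genealogies the most likely scenario places the
lineage decision in the founding cell (generation 0) — generations
before the first marker onsets, which here occur around generations
4–7.

The library API mirrors the CLI (`treedelay.simulate_trees`,
`treedelay.fit`, `treedelay.map_hidden_tree`,
`treedelay.colony_frequencies`, ...); the CLI subcommands `colony`,
`toggle-sim` and `slopes` drive the colony-assay model, the
toggle-switch simulator and the slope statistics.

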