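# shadematch

Computer color matching for dental ceramic restorations: predict the
mixing recipe of five dentin porcelain powders from a target CIELAB
colour with a small neural network whose initial weights are optimized
by a genetic algorithm.

## The problem

Matching the colour of a ceramic restoration to a natural tooth is a
central difficulty of esthetic prosthodontics.  Instead of visual shade
selection, computer color matching inverts the relationship between a
powder recipe and the fired specimen's measured colour: given a target
`(L*, a*, b*)`, find the mass fractions `(A1, A4, B4, C4, D4)` of five
VITA VMK95 dentin porcelain powders that reproduce it.  In the study
design the package emulates, every recipe is a non-negative multiple of
0.08 summing to 0.40 g/g.

## The method

The core model is a three-layer feed-forward network, 3 inputs → *h*
hidden → 5 outputs, trained by backpropagation on squared error with
three refinements:

* **momentum** — ΔW_t = −η∇E + α·ΔW_{t−1};
* **adaptive learning efficiency** — after each full-batch pass the
  step is kept and η ← θη if the total error fell, or rolled back and
  η ← βη (β < 1) if it rose;
* **gradient factor** — when |ΔE| ≈ 0 while residuals d_k − o_k remain
  large (a flat area caused by saturated neurons), the activations' net
  inputs are divided by λ > 1 until the trajectory recovers.

Because gradient training from random weights is unstable — different
initializations land in different local minima — a real-coded genetic
algorithm first searches the initial-weight space.  Chromosomes are the
flat parameter vector (input–hidden weights, hidden–output weights,
hidden thresholds, output thresholds); fitness is `1/(E + ε)` where `E`
is the network error after a few Levenberg–Marquardt iterations;
selection is fitness-proportional (roulette, `p_i = f_i / Σf_j`) with
single-point crossover, uniform-resampling mutation, and elitism.  The
best individual ever seen initializes gradient training (the GA+BP
model).

Error metrics follow the field's reporting convention: per sample
`E_p = Σ_k (d_k − o_k)²`, and the dataset-level figure
`E_MSE = (1/P) Σ_p E_p²` (the mean of *squared* per-sample errors; the
conventional mean of `E_p` is also reported everywhere).

The hidden width *h* comes from `h = √(n+m) + a`, `a ∈ [1,10]` — widths
4–13 for this network — refined by seeded trial and error.

Because the laboratory specimen database is not public, the package
ships a synthetic generator: recipes drawn uniformly from the 126-member
composition grid, colours from a smooth linear-plus-quadratic surrogate
mixing model with Gaussian measurement noise (see `docs/methods.md`).

## Worked example

```bash
shadematch generate --n 119 --seed 1 --out specimens.csv
shadematch split --data specimens.csv --seed 1 --train-out train.csv --test-out test.csv
shadematch train --data train.csv --method gabp --seed 1 --hidden 12 --out model.json
shadematch evaluate --model model.json --data test.csv --out eval.json
```

The last command prints:

```
E_MSE (mean of squared E_p) = 0.00059616; mean E_p = 0.020505
```

meaning the model's per-sample squared-error sums on the 30 held-out
specimens average 0.0205 — typical per-powder errors of a few
hundredths of a mass fraction — and the field-convention squared
aggregate is 6.0e-4.  (The `train` step also prints its final training
total error, 1.3245 here.)
Predict recipes for new colours with:

```bash
shadematch predict --model model.json --data test.csv --out recipes.csv
```

The same workflow is available as a library — `generate_dataset`,
`split_dataset`, `fit_model`, `evaluate_model`, `compare_bp_gabp` — see
the module docstrings.

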