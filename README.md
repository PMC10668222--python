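# tooltouch

Computational models of tactile localization on hand-held tools.

When you hold a rod and strike an object with it, you can tell *where along
the rod* the contact happened, even though the rod has no touch receptors.
`tooltouch` implements a complete computational account of this ability for
researchers in computational neuroscience and psychophysics:

* a **Bayesian trilateration observer** — touch at location `L` (in % of
  tool space, 0 = hand, 100 = tip) is localized by fusing two noisy distance
  estimates anchored at the rod's landmarks, with SDs growing linearly with
  distance,

  ```
  σ1 = ε̂1 + d1·σ̂        σ2 = ε̂2 + d2·σ̂
  σINT(L) = sqrt( σ1²σ2² / (σ1² + σ2²) )
  ```

  which predicts the behavioral signature of *perceptual anchoring*: an
  inverted-U of variable error across the rod, most precise at hand and tip;

* a **vibratory feature space** — the first five bending modes of a
  clamped-free (cantilever) rod; each contact location excites a unique
  combination of modal amplitudes (a *vibratory motif*), so motif space is
  isomorphic to physical rod space and can stand in for it;

* a **three-layer probabilistic population-coding network** (Poisson
  spiking units) that turns a motif into a tool-centered location estimate:
  a mode layer tuned to modal amplitudes, a feature layer encoding the
  isomorphism via winner-take-all of matched-filter synaptic drive, and two
  distance-decoding subpopulations with gain falling (`κ0/(1+βd)²`) and
  tuning width growing (`(γ·ln(d+1)+1)·σ0`) with distance from their anchor;
  log-likelihood decoding of each subpopulation and of their sum implements
  the two distance estimates and their optimal fusion;

* a **synthetic behavioral cohort generator** for the study design (38
  participants, 2 report tasks, 6 touch locations on a 60-cm rod, 10 trials
  per location per task) with trilateration-law or boundary-truncation-law
  judgment noise; and

* an **analysis pipeline**: response normalization into % tool space,
  per-participant accuracy regressions, variable-error summaries, bounded
  multistart least-squares fits of the trilateration and boundary-truncation
  models, and BIC model comparison (ΔBIC cutoffs 2 and 6).

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic data
and write their tables under `results/`:

```
$ python analysis/02_predicted_curves.py
symmetric        peak SD 2.47% at 50.0% of tool space
distal_uncertain peak SD 3.18% at 70.0% of tool space
2_segments       peak SD 1.59% at 25.0% of tool space
```

With equal landmark intercepts the variable-error curve peaks at midline
(50%); raising the distal intercept ε̂2 (an uncertain tip position) skews
the peak toward the tip (70%), the asymmetry seen behaviorally. A
two-segment rod shows an independent inverted-U per segment, peaking at
25% and 75%.

```
$ python analysis/03_network_simulation.py --seed 1 --runs 500
max |bias| of integrated estimate: 0.72% of space
integrated SD at 10/50/90%: 0.69 / 0.82 / 0.74 (inverted U)
```

The network decodes touch essentially without constant error; each
single-landmark decoder's noise grows with distance from its anchor (the
X-shaped pattern visible in the printed SD table), and the integrated
estimate shows the inverted-U.

```
$ python analysis/04_generate_behavior.py --seed 1
$ python analysis/05_fit_models.py
accuracy: slope 0.996 95% CI [0.993, 1.000], intercept 0.09% CI [-0.12, 0.29]
trilateration fit R2: median 0.74 (range 0.18-0.94)
```

The synthetic cohort localizes accurately (slope ≈ 1, intercept ≈ 0) and
the trilateration model fits the variable errors well at the study's trial
counts.

A command-line interface exposes the same steps
(`tooltouch modes export`, `predict-curve`, `simulate-network`,
`generate-behavior`, `fit`, `compare`); see `tooltouch --help`.

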