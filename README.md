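# crowdedda

**Stacked model-based classification from multiple sets of noisy labels.**

When the same training samples are labeled independently by several
annotators — say, seven clinicians grading colonoscopy lesions as
hyperplastic, serrated adenoma or adenoma — the label sets disagree, and no
single one is the ground truth. `crowdedda` trains one parsimonious
Gaussian classifier per annotator and combines the *fitted parameters*
(not the predictions) into a single ensemble classifier, with the
combination weights reflecting each annotator's estimated reliability. As
a by-product, the weights themselves rank the annotators' expertise.

## The model

Each annotator *m* gets a Gaussian discriminant classifier: class priors
τ<sub>mg</sub>, means μ<sub>mg</sub> and covariances Σ<sub>mg</sub>
estimated by maximum likelihood from the features paired with that
annotator's labels. Covariances are eigendecomposed as

    Σ_mg = λ_mg · D_mg · A_mg · D_mgᵀ

(volume λ, shape A diagonal with unit determinant, orientation D
orthogonal). Constraining each factor to be **E**qual or **V**ariable
across classes — with diagonal (**I**) or spherical special cases — gives
the classical family of 14 models (EII … VVV), where EEE is pooled-
covariance LDA and VVV is QDA; the BIC picks among them ("EDDA").

The ensemble is a convex parameter average over annotators,

    τ̂_g = Σ_m w_m τ̂_mg,   μ̂_g = Σ_m w_m μ̂_mg,   Σ̂_g = Σ_m w_m Σ̂_mg,

followed by the MAP rule on the stacked parameters. Six strategies produce
the weights **w** on the simplex:

| tag | strategy | needs |
|---|---|---|
| `PGT` | agreement counts against a known-truth subset | partial ground truth |
| `EN`  | declared tiers share fixed mass (e.g. experts 80%) | expertise labels |
| `E`   | equal weights 1/M | nothing |
| `MV`  | agreement with per-unit majority labels (deadlocks skipped, agreement threshold configurable) | nothing |
| `ItAlg1` | iterate: score against current ensemble labels (hard counts) → re-stack → relabel | nothing |
| `ItAlg2` | same loop with posterior-probability scores gated by agreement | nothing |

A Dirichlet-multinomial simulator generates the validation conditions:
Gaussian feature scenarios plus annotators whose labels are multinomial
draws from Dirichlet-distributed class probabilities concentrated on the
true class (concentration = expertise).

## Worked example

```python
import numpy as np
import crowdedda as cd

Y = np.array([[1, 1, 1, 3, 1],
              [3, 2, 3, 1, 3],
              [1, 1, 2, 3, 3]])   # 3 units, 5 annotators

w = cd.weights_mv(Y)
print(w.s, np.round(w.w, 3))
```

prints

```
[2 1 2 0 2] [0.286 0.143 0.286 0.    0.286]
```

unit 1's majority label is 1 (4 of 5 agree), unit 2's is 3, and unit 3 is
a 2–2 deadlock that awards no points; annotators 1, 3 and 5 matched the
majority twice each and share the weight, annotator 4 never did and is
weighted out. Longer narrative walkthroughs live in `examples/`
(`fit_base_learners.py`, `weighting_strategies.py`, `simulation_study.py`,
`evaluate_predictions.py`); a thin CLI (`crowdedda simulate|fit|predict|
evaluate|replicate-table4`) wraps the same functions for shell use.

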