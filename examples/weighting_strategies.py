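"""Score annotators and turn the scores into ensemble weights.

Walks the two small worked examples: majority-vote scoring of a 3-unit,
5-annotator label matrix (one row deadlocks and is skipped), and the
single-observation comparison of hard vs posterior-probability scores in
the iterative algorithms. Weights sum to one; annotator 4, who never
matches the majority, is weighted out entirely.
"""

import numpy as np

import crowdedda as cd
from crowdedda.weights import soft_scores

Y = np.array([
    [1, 1, 1, 3, 1],
    [3, 2, 3, 1, 3],
    [1, 1, 2, 3, 3],
])

mv = cd.majority_labels(Y)
print("majority labels per unit (-1 = deadlock):", mv.labels)
w = cd.weights_mv(Y)
print("agreement scores:", w.s.astype(int))
print("weights:        ", np.round(w.w, 3))
print("-> annotators 1, 3, 5 matched the majority twice each (weight 2/7), "
      "annotator 4 never did (weight 0).\n")

# hard vs soft scoring for one observation whose estimated label is class 1
posteriors = np.array([
    [[0.8, 0.1, 0.1]],
    [[0.5, 0.3, 0.2]],
    [[0.4, 0.5, 0.1]],
])
labels = np.array([[1, 1, 2]])
estimated = np.array([1])
print("hard scores (agreement counts):  ",
      cd.score_against_reference(labels, estimated))
print("soft scores (posterior at label):",
      soft_scores(labels, estimated, posteriors))
print("-> both annotators 1 and 2 agree with the estimated label, but the "
      "soft score rewards annotator 1's higher confidence (0.8 vs 0.5); "
      "annotator 3 disagrees and earns 0 either way.")

# expertise tiers: four experts share 80% of the mass, three novices 20%
en = cd.weights_en(["expert"] * 4 + ["novice"] * 3)
print("\nexpert/novice weights:", np.round(en.w, 3),
      "(each expert 0.2, each novice 0.2/3)")
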