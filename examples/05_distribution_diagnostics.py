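"""Project the document classes onto two principal components.

The diagnostic behind the dual-classifier design: the labeled negatives
sit closer to the unreviewed background than the positives do, yet part
of the background overlaps neither labeled class — so one classifier per
negative population is needed.
"""

import numpy as np

from altriage import generate_corpus, paper_like_spec, select_features, build_tdm
from altriage.al_engine import FeatureSpace
from altriage.evaluation import distribution_diagnostics

corpus, truth = generate_corpus(paper_like_spec(n_random=2000, seed=1))
fs = FeatureSpace(corpus, select_features(build_tdm(corpus)))

rng = np.random.default_rng(0)
ids = corpus.ids()
sel = rng.choice(len(ids), size=900, replace=False)
groups = [truth.true_class[ids[i]] for i in sel]

diag = distribution_diagnostics(fs.X[sel, :], groups)
print("per-group centroids (PC1, PC2):")
print(diag.centroids.round(2))
print("\npairwise centroid distances:")
print(diag.centroid_distances.round(2))

d = diag.centroid_distances
closer = d.loc["LABELED_NEG_LIKE", "BACKGROUND"] < d.loc["POSITIVE", "BACKGROUND"]
print(f"\nlabeled negatives closer to background than positives are: {closer}")
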