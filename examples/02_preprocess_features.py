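"""Stem, count, and select features by count standard deviation.

Terms whose per-document count SD falls at or below 0.03 are dropped:
they are either near-constant boilerplate or too rare to discriminate.
"""

import numpy as np

from altriage import build_tdm, generate_corpus, paper_like_spec, select_features, term_sd

corpus, _ = generate_corpus(paper_like_spec(n_random=2000, seed=1))
tdm = build_tdm(corpus)
sds = term_sd(tdm)
features = select_features(tdm, sd_threshold=0.03)

print(f"documents:               {tdm.n_docs}")
print(f"distinct stemmed terms:  {tdm.n_terms}")
print(f"total token count:       {tdm.total_count()}")
print(f"terms with SD <= 0.03:   {int((sds <= 0.03).sum())} (discarded)")
print(f"selected features:       {len(features)}")
print(f"SD quantiles (10/50/90%): {np.round(np.quantile(sds, [0.1, 0.5, 0.9]), 4)}")

# The generator plants filler words appearing once in every document;
# their SD is exactly zero, so the filter removes them by construction.
zero_sd = [t for t in tdm.terms if features.sd_values[t] == 0.0]
print(f"zero-SD terms (e.g. {zero_sd[:3]}): {len(zero_sd)}")
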