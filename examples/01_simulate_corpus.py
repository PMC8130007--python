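"""Generate a synthetic screening corpus and inspect its structure.

Builds a scaled-down corpus with the three document populations the
active-learning workflows assume: manually labeled positives, manually
labeled (drug-related) negatives, and an unreviewed random pool in which
a small number of true positives hide.
"""

from altriage import Label, PoolKind, paper_like_spec, generate_corpus

spec = paper_like_spec(n_random=2000, seed=1)
corpus, truth = generate_corpus(spec)

print(f"documents:          {len(corpus)}")
print(f"labeled positives:  {len(corpus.label_ids(Label.POSITIVE))}")
print(f"labeled negatives:  {len(corpus.label_ids(Label.NEGATIVE))}")
print(f"random pool:        {len(corpus.pool_ids(PoolKind.RANDOM))}")
print(f"hidden positives:   {len(truth.hidden_positive_ids(corpus))}")

doc = corpus.documents[0]
print(f"\nexample record {doc.doc_id} ({doc.label.value}):")
print(" ", doc.title)
print(" ", doc.abstract[:120], "...")

# The hidden positives are the documents random-negative sampling silently
# mislabels; high-confidence mining exists to pull them out for review.
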