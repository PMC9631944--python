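"""Choosing a topic count with the two-step evaluation harness.

Step 1 fits the (pluggable) topic backend at each candidate cluster
count; step 2 flags topic pairs whose top-10 word sets overlap by at
least half — likely duplicates.  The harness reports; choosing k stays a
human decision.
"""

import numpy as np

from vaxpress import evaluate_cluster_counts

rng = np.random.default_rng(0)
vocabs = [
    ["trial", "dose", "phase", "efficacy", "volunteer", "result"],
    ["blood", "clot", "illness", "pause", "regulator", "risk"],
    ["putin", "russia", "soviet", "kremlin", "export", "deal"],
]
docs = [" ".join(rng.choice(v, size=5)) for v in vocabs for _ in range(40)]

for report in evaluate_cluster_counts(docs, candidates=[2, 3, 5], seed=0):
    print(f"k={report.k}: sizes={list(report.topic_set.sizes)}, "
          f"review-flagged pairs={report.n_review_pairs}")
    for flag in report.flags:
        if flag.verdict == "review":
            print(f"   pair {flag.pair} overlap {flag.score:.1f}")
# With three planted vocabularies, k=3 shows no flagged pairs while k=5
# splits clusters into near-duplicates — the signature that the candidate
# exceeds the true topic count.
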