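"""The pairwise similarity score underlying duplicate removal and cluster
membership.

score = match_length x identity / (len_a + len_b)

ranges over [0, 0.5]: 0.5 only for identical sequences, >= 0.45 flags
within-taxon duplicates, > 0.2 grants cluster membership during insertion.
"""

import numpy as np

from proteodendro.alignment import pair_similarity, smith_waterman

rng = np.random.default_rng(0)
AA = list("ACDEFGHIKLMNPQRSTVWY")
seq = "".join(rng.choice(AA, size=150))


def mutated(fraction):
    chars = list(seq)
    for pos in rng.choice(len(chars), size=int(fraction * len(chars)), replace=False):
        chars[pos] = rng.choice([a for a in AA if a != chars[pos]])
    return "".join(chars)


for label, other in [
    ("identical copy", seq),
    ("2% diverged (duplicate)", mutated(0.02)),
    ("30% diverged (homolog)", mutated(0.30)),
    ("unrelated random", "".join(rng.choice(AA, size=150))),
]:
    aln = smith_waterman(seq, other)
    score = pair_similarity(seq, other)
    print(
        f"{label:<26} aligned {aln.match_length:>3} cols, "
        f"identity {aln.identity:.2f}, score {score:.3f}"
    )
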