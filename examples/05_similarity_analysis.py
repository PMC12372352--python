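"""Pairwise medium similarity from feature distributions.

Computes the four distribution-comparison metrics (KDE area overlap,
symmetrized KL divergence, cosine similarity, Euclidean distance) for
every fingerprint feature and medium pair of the heterogeneous study,
aggregates them, and ranks the features that make PNCM resemble
PACM-HEC more than PACM-PAA.
"""

import warnings

from diffprint import (aggregate_similarity, fingerprint_table,
                       overlap_difference_ranking, similarity_matrix)
from diffprint.simulate import build_synthetic_study, default_study_design

warnings.filterwarnings("ignore")

design = default_study_design("heterogeneous", n_per_cell=60)
trajs, labels = build_synthetic_study(design, seed=7)
table = fingerprint_table(trajs, labels)

matrix = similarity_matrix(table[~table.flagged])
print("mean similarity per medium pair (across all 20 features):")
print(aggregate_similarity(matrix).round(3).to_string(index=False))

ranking = overlap_difference_ranking(matrix, top_k=5)
print("\nfeatures with the largest overlap(PNCM, PACM-HEC) - "
      "overlap(PNCM, PACM-PAA) difference:")
print(ranking.round(3).to_string(index=False))
print("\nA large positive delta marks a feature whose distribution in the "
      "native-mucus stand-in matches the HEC model much better than the "
      "PAA model - the basis for picking a biosimilar artificial medium.")
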