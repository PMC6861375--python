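"""Network-specificity (NS) scores on cohorts with planted group structure.

A cohort of rasters is grouped by the realization that generated it.  NS
contrasts the similarity of a feature (rates or phases) within a group with
its similarity across groups: ~0.5 for perfectly group-specific features,
0 when the grouping is irrelevant.  Scrambling neuron identities gives the
chance-level control.
"""

import numpy as np

import ratephase as rp
from ratephase.metrics import (feature_similarity, firing_rates,
                               network_similarity_score)
from ratephase.synth import grouped_cohort


def score(rasters, labels, scramble=False):
    x = np.array([firing_rates(r).rates for r in rasters])
    sim = feature_similarity(x, labels, mode="pearson", scramble=scramble,
                             seed=0)
    return np.mean([s.ns for s in network_similarity_score(sim)])


for effect in (0.0, 0.5, 1.5):
    rasters, labels = grouped_cohort(4, 5, structure="rate", effect=effect,
                                     seed=11, n_neurons=80, duration=8000.0)
    print(f"rate effect {effect:.1f}: NS_freq = {score(rasters, labels):+.3f}, "
          f"scrambled = {score(rasters, labels, scramble=True):+.3f}")

print()
print("With no planted effect NS sits at 0; as the group-specific rate")
print("signature grows, NS rises toward its 0.5 ceiling while the scrambled")
print("control stays at chance.")
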