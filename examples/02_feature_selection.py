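"""Chi-squared / Cramér's V filter selection on planted-signal data.

Generates 2000 samples with 100 features of which 10 carry signal, ranks
every feature by Cramér's V against the binned target, and checks how
many informative features land in the top 10.
"""

import numpy as np

from toxqsar.featselect import rank_and_select
from toxqsar.synthdata import gen_feature_table

table, activity, truth = gen_feature_table(
    n=2000, p=100, k_informative=10, coef_magnitude=1.0, noise_sd=1.0, seed=7
)
ranking = rank_and_select(table, activity, k=10, target_bins=5, feature_bins=10)

informative = {f"f{j:04d}" for j in np.flatnonzero(truth)}
selected = set(ranking.selected_features())
print(ranking.table.head(12).to_string(index=False))
print(f"\ninformative features recovered in top 10: {len(selected & informative)}/10")
# V is a [0, 1] association strength: the planted features separate
# cleanly from the noise floor (V around the 2-sigma sampling level).
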