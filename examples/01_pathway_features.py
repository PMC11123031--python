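"""Build pathway feature vectors from member metabolites.

Three metabolites with counts over two bond-inclusion levels are summed into
one pathway category's vector, then converted to within-bond-level
proportions; each printed proportion is that atom color's share of its bond
level's total for the category.
"""

import numpy as np

from pathpair import (
    FeatureDescriptor,
    FeatureMatrix,
    PathwayMembership,
    deduplicate_columns,
    normalize_within_bond_level,
    sum_pathway_counts,
)

metabolites = FeatureMatrix(
    entry_ids=["glucose", "fructose", "citrate"],
    descriptors=[
        FeatureDescriptor("C0", 0),
        FeatureDescriptor("O0", 0),
        FeatureDescriptor("C0(C0)(O0)", 1),
        FeatureDescriptor("C0(2_C0)", 1),
    ],
    values=np.array(
        [
            [6, 6, 4, 1],
            [6, 6, 4, 1],
            [6, 7, 2, 2],
        ],
        dtype=float,
    ),
)
membership = PathwayMembership({"Carbohydrate metabolism": {"glucose", "fructose", "citrate"}})

summed = sum_pathway_counts(metabolites, membership)
print("summed counts:", dict(zip(summed.feature_names, summed.values[0])))

normalized = normalize_within_bond_level(summed)
print("proportions:  ", {n: round(v, 4) for n, v in zip(normalized.feature_names, normalized.values[0])})
# Within each bond level the proportions sum to 1: e.g. C0 is 18 of the
# 37 level-0 atoms, so its pathway feature value is 18/37 ~ 0.486.

deduped, removed, keep_map = deduplicate_columns(normalized)
print("removed duplicate columns:", removed, "->", keep_map)
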