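"""End-to-end convenience wrappers over the stage modules.

The canonical flow from raw counts to a labelled pair dataset:

raw metabolite counts -> sum into pathway counts -> within-bond-level
proportion normalization (both kinds) -> de-duplicate pathway columns ->
[optional: min-max scale, autoencode, re-scale] -> cross join with labels.

Pathway feature vectors are computed from all metabolites, including those a
later split holds out for testing: the pathway representation is treated as
fixed knowledge about the category, not as something re-estimated per split.
Set ``pathway_features_from`` to restrict the summed metabolites if a
leakage-free variant is wanted.
"""

from __future__ import annotations

from .encoding import EncoderSpec, TrainedEncoder, encode, train_autoencoder
from .features import (
    build_pathway_features,
    normalize_within_bond_level,
)
from .matrix import FeatureMatrix, PathwayMembership
from .pairs import PairDataset, cross_join


def prepare_features(
    metabolites_raw: FeatureMatrix,
    membership: PathwayMembership,
    encoded: bool = False,
    encoder_spec: EncoderSpec | None = None,
    pathway_features_from: PathwayMembership | None = None,
) -> tuple[FeatureMatrix, FeatureMatrix, TrainedEncoder | None]:
    """Raw counts + membership -> (metabolite features, pathway features).

    Non-encoded route: normalized metabolites and the de-duplicated
    normalized pathway matrix.  Encoded route: both matrices pushed through
    an autoencoder trained on their stacked rows (the full, non-de-duplicated
    pathway matrix, whose width matches the metabolites').
    """
    source_membership = pathway_features_from or membership
    metabolites = normalize_within_bond_level(metabolites_raw)
    pathways_full, pathways_dedup = build_pathway_features(
        metabolites_raw, source_membership
    )
    if not encoded:
        return metabolites, pathways_dedup, None
    if encoder_spec is None:
        encoder_spec = EncoderSpec(input_width=metabolites.n_features)
    enc = train_autoencoder(metabolites, pathways_full, encoder_spec)
    return encode(enc, metabolites), encode(enc, pathways_full), enc


def build_pair_dataset(
    metabolites_raw: FeatureMatrix,
    membership: PathwayMembership,
    encoded: bool = False,
    encoder_spec: EncoderSpec | None = None,
) -> PairDataset:
    """Full pipeline from raw counts to the labelled cross-join dataset."""
    met, path, _ = prepare_features(
        metabolites_raw, membership, encoded=encoded, encoder_spec=encoder_spec
    )
    return cross_join(met, path, membership)
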