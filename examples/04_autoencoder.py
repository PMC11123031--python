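"""Compress atom-color features to one-tenth width with an autoencoder.

The encoder trains on the stacked metabolite + full pathway rows (the two
matrices share a column set) and emits [0, 1]-scaled embeddings named
``enc_*``.  The printed reconstruction losses should fall over training;
the encoded matrices keep their row counts but shrink to width
floor(0.1 x input width).
"""

from pathpair import (
    EncoderSpec,
    SimConfig,
    build_pathway_features,
    encode,
    normalize_within_bond_level,
    simulate,
    train_autoencoder,
)

raw, membership, _ = simulate(SimConfig(n_metabolites=200, n_pathways=4, seed=5))
metabolites = normalize_within_bond_level(raw)
pathways_full, pathways_dedup = build_pathway_features(raw, membership)
print(
    f"widths: metabolites {metabolites.n_features}, pathway full "
    f"{pathways_full.n_features}, pathway de-duplicated {pathways_dedup.n_features}"
)

spec = EncoderSpec(input_width=metabolites.n_features, epochs=150, seed=0)
enc = train_autoencoder(metabolites, pathways_full, spec)
print(
    f"reconstruction loss: first epoch {enc.loss_curve[0]:.5f} -> "
    f"final epoch {enc.loss_curve[-1]:.5f}"
)

enc_met = encode(enc, metabolites)
enc_path = encode(enc, pathways_full)
print(
    f"encoded: metabolites {enc_met.n_entries} x {enc_met.n_features}, "
    f"pathways {enc_path.n_entries} x {enc_path.n_features} "
    f"(one-tenth of {metabolites.n_features})"
)
print(
    "encoded value range: "
    f"[{enc_met.values.min():.3f}, {enc_met.values.max():.3f}]"
)
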