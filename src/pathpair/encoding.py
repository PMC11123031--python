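"""Autoencoder compression of atom-color features to one-tenth width.

The metabolite and full (non-de-duplicated) pathway matrices share a column
set, so a single autoencoder is trained on their stacked rows.  Inputs are
min-max scaled per column before training, and the encoder's outputs are
min-max scaled again (ranges fitted on the training rows, later inputs
clipped) so every encoded feature lies in [0, 1].

The network is a symmetric fully-connected autoencoder: input -> (optional
hidden widths) -> code -> mirrored widths -> input, ReLU on every hidden
layer including the code layer, mean-squared-error reconstruction loss,
mini-batch Adam with early stopping on a held-out fraction of rows.  It is
fitted with scikit-learn's ``MLPRegressor`` (targets = inputs); encoding is a
manual forward pass through the encoder half of the fitted weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.neural_network import MLPRegressor

from .errors import ConfigError, ShapeError
from .features import min_max_scale
from .matrix import FeatureDescriptor, FeatureMatrix, ScalingRanges


def encoded_width(input_width: int, ratio: float = 0.1) -> int:
    """Code-layer width: floor(ratio * input_width); must be >= 1."""
    k = math.floor(ratio * input_width)
    if k < 1:
        raise ConfigError(
            f"encoded width floor({ratio} * {input_width}) = {k} < 1"
        )
    return k


@dataclass
class EncoderSpec:
    """Autoencoder architecture and training settings.

    ``hidden_layout`` lists the widths of hidden layers between the input and
    the code layer; the decoder mirrors them.  The default (empty) layout is
    the single-bottleneck network input -> code -> input.
    """

    input_width: int
    ratio: float = 0.1
    hidden_layout: list[int] = field(default_factory=list)
    epochs: int = 400
    learning_rate: float = 1e-3
    batch_size: int = 32
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.ratio < 1:
            raise ConfigError(f"ratio must be in (0, 1), got {self.ratio}")
        self.encoded = encoded_width(self.input_width, self.ratio)

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return tuple(self.hidden_layout) + (self.encoded,) + tuple(
            reversed(self.hidden_layout)
        )


@dataclass
class TrainedEncoder:
    """Fitted autoencoder plus the scaling ranges bracketing it."""

    model: MLPRegressor
    pre_ranges: ScalingRanges
    post_ranges: ScalingRanges
    spec: EncoderSpec
    feature_names: list[str]

    @property
    def loss_curve(self) -> list[float]:
        return list(self.model.loss_curve_)

    def encode_rows(self, x: np.ndarray) -> np.ndarray:
        """Forward pass through the encoder half (pre-scaled input rows)."""
        h = x
        n_encoder_layers = len(self.spec.hidden_layout) + 1
        for i in range(n_encoder_layers):
            h = h @ self.model.coefs_[i] + self.model.intercepts_[i]
            np.maximum(h, 0.0, out=h)  # ReLU, matching the fitted activation
        return h


def _check_same_columns(a: FeatureMatrix, b: FeatureMatrix) -> None:
    if a.feature_names != b.feature_names:
        raise ShapeError(
            "metabolite and pathway matrices must share an identical, "
            "identically ordered column set"
        )


def train_autoencoder(
    metabolites: FeatureMatrix,
    pathways_full: FeatureMatrix,
    spec: EncoderSpec,
) -> TrainedEncoder:
    """Fit the autoencoder on the stacked metabolite + pathway rows."""
    _check_same_columns(metabolites, pathways_full)
    if spec.input_width != metabolites.n_features:
        raise ShapeError(
            f"spec.input_width {spec.input_width} != matrix width "
            f"{metabolites.n_features}"
        )
    stacked = FeatureMatrix(
        entry_ids=[f"m::{e}" for e in metabolites.entry_ids]
        + [f"p::{e}" for e in pathways_full.entry_ids],
        descriptors=list(metabolites.descriptors),
        values=np.vstack([metabolites.values, pathways_full.values]),
    )
    scaled, pre_ranges = min_max_scale(stacked)
    x = scaled.values
    n = x.shape[0]
    use_early_stopping = n >= 20  # hold-out split needs enough rows
    model = MLPRegressor(
        hidden_layer_sizes=spec.layer_sizes,
        activation="relu",
        solver="adam",
        learning_rate_init=spec.learning_rate,
        batch_size=min(spec.batch_size, n),
        max_iter=spec.epochs,
        early_stopping=use_early_stopping,
        validation_fraction=spec.validation_fraction,
        n_iter_no_change=25,
        tol=1e-7,
        random_state=spec.seed,
    )
    model.fit(x, x)
    enc = TrainedEncoder(
        model=model,
        pre_ranges=pre_ranges,
        post_ranges=pre_ranges,  # placeholder until fitted below
        spec=spec,
        feature_names=list(stacked.feature_names),
    )
    codes = enc.encode_rows(x)
    enc.post_ranges = ScalingRanges(
        [f"enc_{i}" for i in range(spec.encoded)],
        codes.min(axis=0),
        codes.max(axis=0),
    )
    return enc


def encode(enc: TrainedEncoder, m: FeatureMatrix) -> FeatureMatrix:
    """Map a matrix into the encoded feature space (columns ``enc_0..``).

    The input is min-max scaled with the encoder's training ranges (clipped),
    passed through the encoder half, then min-max scaled with the
    post-training ranges and clipped, so outputs always lie in [0, 1].
    Encoded features carry no bond level; they are never re-normalized.
    """
    if m.feature_names != enc.feature_names:
        raise ShapeError("matrix columns do not match the encoder's training columns")
    scaled, _ = min_max_scale(m, enc.pre_ranges)
    codes = enc.encode_rows(scaled.values)
    span = enc.post_ranges.maxs - enc.post_ranges.mins
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(span > 0, (codes - enc.post_ranges.mins) / span, 0.0)
    out = np.clip(out, 0.0, 1.0)
    kind = m.descriptors[0].entity_kind if m.descriptors else "metabolite"
    descriptors = [
        FeatureDescriptor(name=f"enc_{i}", bond_level=None, entity_kind=kind)
        for i in range(enc.spec.encoded)
    ]
    return FeatureMatrix(list(m.entry_ids), descriptors, out)
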