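"""Synthetic atom-color count data with planted pathway signal.

Counts are Poisson: substructure counts are small non-negative integers and
low background rates give the sparsity seen in real atom-color matrices.
Each pathway category owns a disjoint set of signature features; a
metabolite that belongs to the category draws those features at
``signal_multiplier`` times the background rate, so membership is learnable
from the features and the planted truth is unambiguous for recovery tests.
Memberships are independent Bernoulli draws per (metabolite, pathway), so a
metabolite can belong to several categories, as in KEGG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import FeatureDescriptor, FeatureMatrix, PathwayMembership
from .errors import ConfigError


@dataclass
class SimConfig:
    """Generator settings.

    Defaults emulate a small study: 500 metabolites over 12 pathway
    categories, 60 features across three bond-inclusion levels, Poisson(4)
    background counts (a typical metabolite carries a handful of matches per
    common atom color, e.g. ~10-20 carbons at bond level 0), 4 signature
    features per pathway at 5x enrichment, and a ~10% positive pair
    proportion (independent membership draws at 0.1), mirroring the class
    imbalance of real pathway-annotation data.
    """

    n_metabolites: int = 500
    n_pathways: int = 12
    features_per_level: dict[int, int] = field(
        default_factory=lambda: {0: 12, 1: 24, 2: 24}
    )
    signatures_per_pathway: int = 4
    background_rate: float = 4.0
    signal_multiplier: float = 5.0
    membership_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        n_features = sum(self.features_per_level.values())
        if n_features < self.n_pathways * self.signatures_per_pathway:
            raise ConfigError(
                f"{n_features} features cannot host "
                f"{self.n_pathways} x {self.signatures_per_pathway} disjoint signatures"
            )
        if self.background_rate <= 0:
            raise ConfigError("background_rate must be > 0")
        if self.signal_multiplier < 1:
            raise ConfigError("signal_multiplier must be >= 1")
        if not 0 < self.membership_fraction < 1:
            raise ConfigError("membership_fraction must be in (0, 1)")
        if self.n_metabolites < 1 or self.n_pathways < 1:
            raise ConfigError("need at least one metabolite and one pathway")


def simulate(
    config: SimConfig,
) -> tuple[FeatureMatrix, PathwayMembership, dict[str, list[str]]]:
    """Draw a metabolite count matrix, memberships, and the signature truth map.

    Fully deterministic for a given ``config.seed``.  Every pathway is
    guaranteed at least one member (a deterministic fallback assignment when
    the Bernoulli draws leave a category empty).
    """
    rng = np.random.default_rng(config.seed)
    descriptors: list[FeatureDescriptor] = []
    for level in sorted(config.features_per_level):
        for j in range(config.features_per_level[level]):
            descriptors.append(
                FeatureDescriptor(name=f"ac{level}_{j:03d}", bond_level=level)
            )
    n_features = len(descriptors)
    feature_names = [d.name for d in descriptors]
    metabolite_ids = [f"m{i:05d}" for i in range(config.n_metabolites)]
    pathway_names = [f"P{p:02d}" for p in range(config.n_pathways)]

    # disjoint signature features per pathway
    chosen = rng.choice(
        n_features,
        size=config.n_pathways * config.signatures_per_pathway,
        replace=False,
    )
    truth = {
        pathway_names[p]: sorted(
            feature_names[j]
            for j in chosen[
                p * config.signatures_per_pathway : (p + 1)
                * config.signatures_per_pathway
            ]
        )
        for p in range(config.n_pathways)
    }

    member = rng.random((config.n_metabolites, config.n_pathways)) < (
        config.membership_fraction
    )
    for p in range(config.n_pathways):  # every pathway needs >= 1 member
        if not member[:, p].any():
            member[int(rng.integers(config.n_metabolites)), p] = True

    rates = np.full((config.n_metabolites, n_features), config.background_rate)
    name_index = {n: j for j, n in enumerate(feature_names)}
    for p, pname in enumerate(pathway_names):
        cols = [name_index[n] for n in truth[pname]]
        rows = np.flatnonzero(member[:, p])
        rates[np.ix_(rows, cols)] *= config.signal_multiplier
    counts = rng.poisson(rates).astype(np.float64)

    metabolites = FeatureMatrix(metabolite_ids, descriptors, counts)
    membership = PathwayMembership(
        {
            pname: {metabolite_ids[i] for i in np.flatnonzero(member[:, p])}
            for p, pname in enumerate(pathway_names)
        }
    )
    return metabolites, membership, truth


def permute_labels(
    membership: PathwayMembership,
    seed: int,
    universe: list[str] | None = None,
) -> PathwayMembership:
    """Randomly reassign members, preserving each pathway's member count.

    Destroys any feature-label association while keeping the label marginals,
    for permutation-null checks.  ``universe`` is the pool of metabolite ids
    to draw from; by default the union of all current members.
    """
    rng = np.random.default_rng(seed)
    if universe is None:
        universe = sorted(set().union(*membership.pathways.values()))
    pool = np.asarray(universe, dtype=object)
    permuted = {
        name: set(rng.choice(pool, size=len(members), replace=False))
        for name, members in membership.pathways.items()
    }
    return PathwayMembership(permuted)
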