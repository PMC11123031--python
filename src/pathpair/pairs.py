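"""Metabolite-pathway pair dataset: cross join, splits, oversampling.

Every metabolite feature vector is joined with every pathway feature vector;
the concatenated row (metabolite features first) is one classifier input and
its binary label says whether the metabolite is annotated to that pathway
category.  Rows are kept as (metabolite index, pathway index) pairs and the
concatenated vectors are materialized on demand, so memory stays linear in
the two source matrices instead of their product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    BalanceError,
    MissingMemberError,
    NamingError,
    StratificationError,
    ValidationError,
)
from .matrix import FeatureMatrix, PathwayMembership

MET_PREFIX = "metabolite::"
PATH_PREFIX = "pathway::"


def atom_color_of(feature_name: str) -> str | None:
    """Strip the entity-kind prefix off a pair-dataset feature name."""
    for prefix in (MET_PREFIX, PATH_PREFIX):
        if feature_name.startswith(prefix):
            return feature_name[len(prefix):]
    return None


@dataclass
class PairDataset:
    """Lazily materialized cross-join rows over two feature matrices."""

    metabolites: FeatureMatrix
    pathways: FeatureMatrix
    met_idx: np.ndarray
    path_idx: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.met_idx = np.asarray(self.met_idx, dtype=np.int64)
        self.path_idx = np.asarray(self.path_idx, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if not (self.met_idx.shape == self.path_idx.shape == self.labels.shape):
            raise ValidationError("met_idx, path_idx and labels must align")

    @property
    def n_rows(self) -> int:
        return self.met_idx.size

    @property
    def width(self) -> int:
        return self.metabolites.n_features + self.pathways.n_features

    @property
    def feature_names(self) -> list[str]:
        return [MET_PREFIX + n for n in self.metabolites.feature_names] + [
            PATH_PREFIX + n for n in self.pathways.feature_names
        ]

    @property
    def metabolite_ids(self) -> np.ndarray:
        return np.asarray(self.metabolites.entry_ids, dtype=object)[self.met_idx]

    @property
    def pathway_ids(self) -> np.ndarray:
        return np.asarray(self.pathways.entry_ids, dtype=object)[self.path_idx]

    def features(self) -> np.ndarray:
        """Materialize the concatenated feature block for all rows."""
        return np.hstack(
            [self.metabolites.values[self.met_idx], self.pathways.values[self.path_idx]]
        )

    def subset(self, rows: np.ndarray) -> "PairDataset":
        rows = np.asarray(rows)
        return PairDataset(
            self.metabolites,
            self.pathways,
            self.met_idx[rows],
            self.path_idx[rows],
            self.labels[rows],
        )

    def n_positive(self) -> int:
        return int(self.labels.sum())

    def positive_proportion(self) -> float:
        return self.n_positive() / self.n_rows


def cross_join(
    metabolites: FeatureMatrix,
    pathways: FeatureMatrix,
    membership: PathwayMembership,
) -> PairDataset:
    """Cartesian product of metabolite and pathway rows, metabolite-major.

    Labels come from the membership map: row (m, p) is positive iff ``m`` is
    a member of pathway category ``p``.
    """
    met_ids = metabolites.entry_ids
    path_ids = pathways.entry_ids
    collision = set(met_ids) & set(path_ids)
    if collision:
        raise NamingError(
            f"ids used for both a metabolite and a pathway: {sorted(collision)[:5]}"
        )
    unknown_paths = set(membership.pathway_names) - set(path_ids)
    if unknown_paths:
        raise MissingMemberError(
            f"membership pathways missing from pathway matrix: "
            f"{sorted(unknown_paths)[:5]}"
        )
    membership.validate_against(metabolites)
    nm, npth = metabolites.n_entries, pathways.n_entries
    met_idx = np.repeat(np.arange(nm), npth)
    path_idx = np.tile(np.arange(npth), nm)
    member_mask = np.zeros((nm, npth), dtype=np.int8)
    met_pos = {mid: i for i, mid in enumerate(met_ids)}
    for p, pname in enumerate(path_ids):
        members = membership.pathways.get(pname, set())
        for mid in members:
            member_mask[met_pos[mid], p] = 1
    labels = member_mask[met_idx, path_idx]
    return PairDataset(metabolites, pathways, met_idx, path_idx, labels)


@dataclass
class SplitPlan:
    """Stratified Monte-Carlo train/test split settings.

    Stratification is on (pathway, label) so every pathway category's
    positives are represented in every test set -- required for per-pathway
    metric reporting.
    """

    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValidationError(
                f"test_fraction must be in (0, 1), got {self.test_fraction}"
            )


def stratified_split(
    ds: PairDataset, plan: SplitPlan
) -> tuple[PairDataset, PairDataset]:
    """One independent stratified split; deterministic for a given seed.

    Per-stratum test counts are ``round(test_fraction * stratum size)``,
    then adjusted by +/-1 (largest fractional remainders first) so the global
    test size equals ``round(test_fraction * n)``; every stratum of size >= 2
    keeps at least one row on each side.
    """
    rng = np.random.default_rng(plan.seed)
    strata: dict[tuple[int, int], np.ndarray] = {}
    keys = np.stack([ds.path_idx, ds.labels.astype(np.int64)], axis=1)
    order = np.lexsort((ds.labels, ds.path_idx))
    for row in order:
        strata.setdefault((int(keys[row, 0]), int(keys[row, 1])), []).append(row)  # type: ignore[union-attr]
    strata = {k: np.asarray(v) for k, v in strata.items()}
    for (p, lab), rows in strata.items():
        if rows.size < 2:
            raise StratificationError(
                f"stratum (pathway={ds.pathways.entry_ids[p]!r}, label={lab}) has "
                f"{rows.size} row(s); every (pathway, label) stratum needs >= 2 rows "
                "- merge tiny pathways or drop single-member categories"
            )
    target_total = round(plan.test_fraction * ds.n_rows)
    skeys = sorted(strata)
    sizes = {k: strata[k].size for k in skeys}
    counts = {k: round(plan.test_fraction * sizes[k]) for k in skeys}
    for k in skeys:  # keep both sides non-empty per stratum
        counts[k] = min(max(counts[k], 1), sizes[k] - 1)
    residual = {k: plan.test_fraction * sizes[k] - counts[k] for k in skeys}
    diff = target_total - sum(counts.values())
    adjustable = skeys
    while diff != 0:
        if diff > 0:
            cands = [k for k in adjustable if counts[k] < sizes[k] - 1]
            if not cands:
                break
            k = max(cands, key=lambda k: (residual[k], k))
            counts[k] += 1
            residual[k] -= 1
            diff -= 1
        else:
            cands = [k for k in adjustable if counts[k] > 1]
            if not cands:
                break
            k = min(cands, key=lambda k: (residual[k], k))
            counts[k] -= 1
            residual[k] += 1
            diff += 1
    test_rows: list[np.ndarray] = []
    train_rows: list[np.ndarray] = []
    for k in skeys:
        perm = rng.permutation(strata[k])
        test_rows.append(perm[: counts[k]])
        train_rows.append(perm[counts[k]:])
    test = np.sort(np.concatenate(test_rows))
    train = np.sort(np.concatenate(train_rows))
    return ds.subset(train), ds.subset(test)


def oversample_positives(train: PairDataset) -> PairDataset:
    """Duplicate every positive row k = floor(n_neg / n_pos) times.

    Equal whole-number duplication brings the positive proportion to 50% or
    just under, the closest achievable while keeping every positive equally
    weighted.  With k = 1 (positives already >= negatives) the set is
    returned unchanged.  Never apply this to a test set: duplicated test rows
    give overly optimistic metrics.
    """
    pos = np.flatnonzero(train.labels == 1)
    neg = np.flatnonzero(train.labels == 0)
    if pos.size == 0 or neg.size == 0:
        raise BalanceError(
            f"need both classes to balance (got {pos.size} positives, "
            f"{neg.size} negatives)"
        )
    k = max(1, neg.size // pos.size)
    if k == 1:
        return train
    extra = np.tile(pos, k - 1)
    rows = np.concatenate([np.arange(train.n_rows), extra])
    return train.subset(rows)
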