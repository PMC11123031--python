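"""Core in-memory containers.

A :class:`FeatureMatrix` holds entries (metabolites or pathway categories) by
atom-color substructure-count features.  Each feature carries a
:class:`FeatureDescriptor` giving its bond-inclusion level -- the neighborhood
depth at which the atom color is defined -- and the kind of entity the row
represents.  Bond levels drive the proportion normalization: features are only
ever compared against other features of the same bond-inclusion level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MissingMemberError, PartitionError, ValidationError

METABOLITE = "metabolite"
PATHWAY = "pathway"
_KINDS = (METABOLITE, PATHWAY)


@dataclass(frozen=True)
class FeatureDescriptor:
    """Metadata for one atom-color feature column.

    Parameters
    ----------
    name
        Atom-color identifier, unique within a matrix.
    bond_level
        Non-negative bond-inclusion level (0 = element only, 1 = one bond
        out, ...).  ``None`` for derived features without a bond level, such
        as autoencoder embeddings.
    entity_kind
        ``"metabolite"`` or ``"pathway"``.
    """

    name: str
    bond_level: int | None
    entity_kind: str = METABOLITE

    def __post_init__(self) -> None:
        if self.entity_kind not in _KINDS:
            raise ValidationError(
                f"entity_kind must be one of {_KINDS}, got {self.entity_kind!r}"
            )
        if self.bond_level is not None and self.bond_level < 0:
            raise ValidationError(f"bond_level must be >= 0, got {self.bond_level}")

    def with_kind(self, entity_kind: str) -> "FeatureDescriptor":
        return FeatureDescriptor(self.name, self.bond_level, entity_kind)


@dataclass
class FeatureMatrix:
    """Dense entries-by-features matrix with per-column descriptors.

    Invariants (checked on construction): unique entry ids, unique feature
    names, finite non-negative values, column count equal to descriptor count.
    """

    entry_ids: list[str]
    descriptors: list[FeatureDescriptor]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        n_rows, n_cols = self.values.shape
        if n_rows != len(self.entry_ids):
            raise ValidationError(
                f"{len(self.entry_ids)} entry ids for {n_rows} rows"
            )
        if n_cols != len(self.descriptors):
            raise ValidationError(
                f"{len(self.descriptors)} descriptors for {n_cols} columns"
            )
        if len(set(self.entry_ids)) != len(self.entry_ids):
            raise ValidationError("duplicate entry ids")
        names = [d.name for d in self.descriptors]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate feature names")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values must be finite")
        if np.any(self.values < 0):
            raise ValidationError("values must be non-negative")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_entries(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def row(self, entry_id: str) -> np.ndarray:
        return self.values[self.entry_ids.index(entry_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.entry_ids, columns=self.feature_names
        )

    def select_columns(self, indices: list[int]) -> "FeatureMatrix":
        return FeatureMatrix(
            entry_ids=list(self.entry_ids),
            descriptors=[self.descriptors[i] for i in indices],
            values=self.values[:, indices].copy(),
        )

    def bond_level_partition(self) -> "BondLevelPartition":
        return BondLevelPartition.from_descriptors(self.descriptors)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        return (
            self.entry_ids == other.entry_ids
            and self.descriptors == other.descriptors
            and np.array_equal(self.values, other.values)
        )


@dataclass
class BondLevelPartition:
    """Grouping of column indices by bond-inclusion level.

    The groups must partition all columns of the companion matrix exactly
    once; normalization is applied independently within each group.
    """

    groups: dict[int, list[int]] = field(default_factory=dict)

    @classmethod
    def from_descriptors(
        cls, descriptors: list[FeatureDescriptor]
    ) -> "BondLevelPartition":
        groups: dict[int, list[int]] = {}
        for i, d in enumerate(descriptors):
            if d.bond_level is None:
                raise PartitionError(
                    f"feature {d.name!r} has no bond level; cannot partition"
                )
            groups.setdefault(d.bond_level, []).append(i)
        return cls(groups=groups)

    def validate_covers(self, n_columns: int) -> None:
        seen = sorted(i for idx in self.groups.values() for i in idx)
        if seen != list(range(n_columns)):
            raise PartitionError(
                f"partition covers {len(seen)} of {n_columns} columns"
            )


@dataclass
class ScalingRanges:
    """Fitted per-feature (min, max) pairs for min-max scaling."""

    names: list[str]
    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=np.float64)
        self.maxs = np.asarray(self.maxs, dtype=np.float64)
        if not (len(self.names) == self.mins.size == self.maxs.size):
            raise ValidationError("ranges must have one (min, max) per name")
        if np.any(self.mins > self.maxs):
            raise ValidationError("min > max in scaling ranges")

    def for_columns(self, names: list[str]) -> "ScalingRanges":
        """Reorder/subset to the given column names (error if any missing)."""
        from .errors import RangeError

        pos = {n: i for i, n in enumerate(self.names)}
        try:
            idx = [pos[n] for n in names]
        except KeyError as exc:
            raise RangeError(f"scaling ranges missing column {exc.args[0]!r}") from exc
        return ScalingRanges(list(names), self.mins[idx], self.maxs[idx])


@dataclass
class PathwayMembership:
    """Map from pathway-category name to its set of member metabolite ids."""

    pathways: dict[str, set[str]]

    def __post_init__(self) -> None:
        for name, members in self.pathways.items():
            if not members:
                raise ValidationError(
                    f"pathway {name!r} has no members; pathway features undefined"
                )
            self.pathways[name] = set(members)

    @property
    def pathway_names(self) -> list[str]:
        return list(self.pathways)

    @property
    def n_pathways(self) -> int:
        return len(self.pathways)

    def total_annotations(self) -> int:
        """Number of (metabolite, pathway) annotation pairs = positive labels."""
        return sum(len(m) for m in self.pathways.values())

    def validate_against(self, metabolites: FeatureMatrix) -> None:
        known = set(metabolites.entry_ids)
        for name, members in self.pathways.items():
            missing = members - known
            if missing:
                raise MissingMemberError(
                    f"pathway {name!r} references unknown metabolites: "
                    f"{sorted(missing)[:5]}"
                )
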