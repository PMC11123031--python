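"""Feature engineering: pathway vectors, proportion normalization, scaling.

A pathway category is represented by summing the raw atom-color counts of its
member metabolites.  Because categories differ wildly in size, the summed
counts are converted to within-bond-level proportions: each count is divided
by the total count of all atom colors of the same bond-inclusion level in the
same entry.  A group totalling 10,000 with a focal count of 1,000 therefore
normalizes to 0.1.  Metabolite vectors are normalized with the same operation
so the two entity kinds stay comparable.
"""

from __future__ import annotations

import numpy as np

from .errors import MissingMemberError, RangeError
from .matrix import (
    PATHWAY,
    BondLevelPartition,
    FeatureMatrix,
    PathwayMembership,
    ScalingRanges,
)


def sum_pathway_counts(
    metabolites: FeatureMatrix, membership: PathwayMembership
) -> FeatureMatrix:
    """Build one raw pathway feature vector per category by summing members.

    Each pathway row is the element-wise sum of the raw count vectors of its
    member metabolites; the column set is identical to the metabolite matrix
    (with ``entity_kind`` flipped to pathway).  Rows follow the membership's
    stable pathway order.
    """
    index = {mid: i for i, mid in enumerate(metabolites.entry_ids)}
    rows = np.zeros((membership.n_pathways, metabolites.n_features))
    for p, name in enumerate(membership.pathway_names):
        members = membership.pathways[name]
        missing = [m for m in members if m not in index]
        if missing:
            raise MissingMemberError(
                f"pathway {name!r}: member ids not in metabolite matrix: "
                f"{sorted(missing)[:5]}"
            )
        idx = [index[m] for m in sorted(members)]
        rows[p] = metabolites.values[idx].sum(axis=0)
    return FeatureMatrix(
        entry_ids=list(membership.pathway_names),
        descriptors=[d.with_kind(PATHWAY) for d in metabolites.descriptors],
        values=rows,
    )


def normalize_within_bond_level(
    m: FeatureMatrix, partition: BondLevelPartition | None = None
) -> FeatureMatrix:
    """Convert counts to within-bond-level proportions, entry by entry.

    For each entry and each bond-level group with a positive total, every cell
    becomes ``cell / group total`` (the denominator includes the cell itself).
    A group whose total is zero for an entry maps to all zeros -- an entry
    with no substructures at that level carries no proportional signal, and
    zeros keep the vectors finite.
    """
    if partition is None:
        partition = m.bond_level_partition()
    partition.validate_covers(m.n_features)
    out = np.zeros_like(m.values)
    for cols in partition.groups.values():
        block = m.values[:, cols]
        totals = block.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            normalized = np.where(totals > 0, block / totals, 0.0)
        out[:, cols] = normalized
    return FeatureMatrix(list(m.entry_ids), list(m.descriptors), out)


def deduplicate_columns(
    m: FeatureMatrix,
) -> tuple[FeatureMatrix, list[str], dict[str, str]]:
    """Drop columns whose value vectors exactly equal an earlier column.

    Two columns are duplicates iff their full value vectors are bitwise
    equal; the earliest column of each duplicate class is kept, and output
    order preserves the input order of kept columns.  Exact (tolerance-zero)
    comparison is appropriate because, at the stage this is applied, values
    are rational proportions of integer counts and reproduce exactly.

    Returns
    -------
    (deduplicated matrix, removed column names, map removed name -> kept name)
    """
    first_seen: dict[bytes, int] = {}
    kept: list[int] = []
    removed: list[str] = []
    keep_map: dict[str, str] = {}
    names = m.feature_names
    for j in range(m.n_features):
        key = np.ascontiguousarray(m.values[:, j]).tobytes()
        if key in first_seen:
            removed.append(names[j])
            keep_map[names[j]] = names[first_seen[key]]
        else:
            first_seen[key] = j
            kept.append(j)
    return m.select_columns(kept), removed, keep_map


def min_max_scale(
    m: FeatureMatrix, ranges: ScalingRanges | None = None
) -> tuple[FeatureMatrix, ScalingRanges]:
    """Column-wise min-max scaling to [0, 1].

    With ``ranges`` absent, per-column (min, max) are fitted from ``m`` and
    applied; a constant column maps to all zeros.  With ``ranges`` supplied
    (e.g. ranges fitted on training rows), values are transformed with them
    and clipped into [0, 1].
    """
    names = m.feature_names
    if ranges is None:
        mins = m.values.min(axis=0)
        maxs = m.values.max(axis=0)
        fitted = ScalingRanges(list(names), mins, maxs)
        clip = False
    else:
        fitted = ranges.for_columns(names)
        mins, maxs = fitted.mins, fitted.maxs
        clip = True
    span = maxs - mins
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(span > 0, (m.values - mins) / span, 0.0)
    if clip:
        scaled = np.clip(scaled, 0.0, 1.0)
    return FeatureMatrix(list(m.entry_ids), list(m.descriptors), scaled), fitted


def build_pathway_features(
    metabolites_raw: FeatureMatrix,
    membership: PathwayMembership,
    deduplicate: bool = True,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Raw metabolite counts + membership -> (full, de-duplicated) pathway matrices.

    Runs the sum -> normalize -> de-duplicate chain.  The full (pre-dedup)
    matrix feeds the autoencoder, whose input width must match the metabolite
    width; the de-duplicated matrix is what classifiers train on directly.
    """
    summed = sum_pathway_counts(metabolites_raw, membership)
    full = normalize_within_bond_level(summed)
    if not deduplicate:
        return full, full
    dedup, _, _ = deduplicate_columns(full)
    return full, dedup


def _check_ranges_cover(ranges: ScalingRanges, names: list[str]) -> None:
    missing = set(names) - set(ranges.names)
    if missing:
        raise RangeError(f"ranges missing columns: {sorted(missing)[:5]}")
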