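"""Reading, writing and persisting artifacts.

Feature matrices travel as CSV (first column = entry id, header = feature
names, with a ``<stem>.meta.json`` sidecar mapping each feature name to its
bond level and entity kind) or as a self-describing HDF5 file.  Pathway
memberships are plain JSON objects mapping pathway name to a list of member
metabolite ids.  Model-evaluation output is persisted in a single embedded
SQLite database so downstream summaries are plain SQL.
"""

from __future__ import annotations

import json
import sqlite3
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import ConstraintError, MetadataError, ValidationError
from .matrix import FeatureDescriptor, FeatureMatrix, PathwayMembership

_FORMATS = ("csv", "hdf5")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise ValidationError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
        return fmt
    return "hdf5" if path.suffix in (".h5", ".hdf5") else "csv"


def read_feature_matrix(path: str | Path, fmt: str | None = None) -> FeatureMatrix:
    """Read a feature matrix from CSV (+ JSON sidecar) or HDF5."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "hdf5":
        return _read_hdf5(path)
    return _read_csv(path)


def write_feature_matrix(
    m: FeatureMatrix, path: str | Path, fmt: str | None = None
) -> None:
    """Write a feature matrix; CSV round-trips within 1e-12, HDF5 exactly."""
    if m.n_entries == 0:
        raise ValidationError("refusing to write a matrix with zero entries")
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "hdf5":
        _write_hdf5(m, path)
    else:
        _write_csv(m, path)


def _read_csv(path: Path) -> FeatureMatrix:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    try:
        frame = pd.read_csv(path, index_col=0)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    if frame.shape[1] == 0 or frame.shape[0] == 0:
        raise ValidationError(f"{path} holds an empty matrix")
    descriptors = []
    for name in frame.columns:
        if name not in meta:
            raise MetadataError(f"column {name!r} absent from sidecar {sidecar}")
        entry = meta[name]
        descriptors.append(
            FeatureDescriptor(
                name=name,
                bond_level=entry.get("bond_level"),
                entity_kind=entry.get("entity_kind", "metabolite"),
            )
        )
    values = frame.to_numpy(dtype=np.float64, na_value=np.nan)
    if np.isnan(values).any():
        raise ValidationError(f"{path} contains missing or non-numeric values")
    return FeatureMatrix(
        entry_ids=[str(i) for i in frame.index],
        descriptors=descriptors,
        values=values,
    )


def _write_csv(m: FeatureMatrix, path: Path) -> None:
    # %.17g preserves doubles to full precision -> round-trip well within 1e-12
    m.to_frame().to_csv(path, float_format="%.17g", index_label="entry_id")
    meta = {
        d.name: {"bond_level": d.bond_level, "entity_kind": d.entity_kind}
        for d in m.descriptors
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_hdf5(path: Path) -> FeatureMatrix:
    with h5py.File(path, "r") as f:
        values = f["values"][()]
        entry_ids = [s.decode() for s in f["entry_ids"][()]]
        names = [s.decode() for s in f["feature_names"][()]]
        levels = f["bond_levels"][()]
        kinds = [s.decode() for s in f["entity_kinds"][()]]
    descriptors = [
        FeatureDescriptor(
            name=n,
            bond_level=None if lv < 0 else int(lv),
            entity_kind=k,
        )
        for n, lv, k in zip(names, levels, kinds)
    ]
    return FeatureMatrix(entry_ids=entry_ids, descriptors=descriptors, values=values)


def _write_hdf5(m: FeatureMatrix, path: Path) -> None:
    str_dt = h5py.string_dtype()
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=m.values)
        f.create_dataset("entry_ids", data=np.array(m.entry_ids, dtype=object), dtype=str_dt)
        f.create_dataset(
            "feature_names", data=np.array(m.feature_names, dtype=object), dtype=str_dt
        )
        f.create_dataset(
            "bond_levels",
            data=np.array(
                [-1 if d.bond_level is None else d.bond_level for d in m.descriptors],
                dtype=np.int64,
            ),
        )
        f.create_dataset(
            "entity_kinds",
            data=np.array([d.entity_kind for d in m.descriptors], dtype=object),
            dtype=str_dt,
        )


def read_pathway_membership(path: str | Path) -> PathwayMembership:
    """Read a pathway -> member list JSON object.

    Member lists are deduplicated into sets and pathways are ordered
    lexicographically for a stable downstream row order.
    """
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValidationError("membership JSON must be an object of name -> list")
    pathways: dict[str, set[str]] = {}
    for name in sorted(raw):
        members = raw[name]
        if not isinstance(members, list):
            raise ValidationError(f"pathway {name!r}: members must be a list")
        if not members:
            raise ValidationError(f"pathway {name!r} has an empty member list")
        pathways[name] = set(str(x) for x in members)
    return PathwayMembership(pathways=pathways)


def write_pathway_membership(membership: PathwayMembership, path: str | Path) -> None:
    payload = {
        name: sorted(members) for name, members in membership.pathways.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# Results store


_SCHEMA = """
CREATE TABLE IF NOT EXISTS cv_results (
    model_kind  TEXT NOT NULL,
    feature_set TEXT NOT NULL,
    iteration   INTEGER NOT NULL,
    pathway     TEXT NOT NULL,
    metric_name TEXT NOT NULL,
    value       REAL NOT NULL,
    UNIQUE (model_kind, feature_set, iteration, pathway, metric_name)
);
CREATE TABLE IF NOT EXISTS importance (
    feature_name   TEXT NOT NULL,
    entity_kind    TEXT NOT NULL,
    iteration      INTEGER NOT NULL,
    raw_score      REAL NOT NULL,
    relative_score REAL NOT NULL CHECK (relative_score BETWEEN 0 AND 1),
    UNIQUE (feature_name, entity_kind, iteration)
);
CREATE TABLE IF NOT EXISTS trials (
    study      TEXT NOT NULL DEFAULT '',
    trial_id   INTEGER NOT NULL,
    params     TEXT NOT NULL,
    median_mcc REAL,
    pruned     INTEGER NOT NULL DEFAULT 0,
    UNIQUE (study, trial_id)
);
"""

OVERALL = "overall"  # pathway column value for whole-test-set metrics


class ResultsStore:
    """Embedded SQLite store for CV metrics, importances and tuning trials.

    Use ``":memory:"`` for a transient store.  Uniqueness is enforced at the
    database level; violating it raises :class:`ConstraintError`.
    """

    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    # -- generic row insertion (dispatch on table name) --------------------

    def record(self, table: str, row: dict) -> None:
        if table not in ("cv_results", "importance", "trials"):
            raise ValidationError(f"unknown table {table!r}")
        cols = ", ".join(row)
        marks = ", ".join("?" for _ in row)
        try:
            self._conn.execute(
                f"INSERT INTO {table} ({cols}) VALUES ({marks})", list(row.values())
            )
            self._conn.commit()
        except sqlite3.IntegrityError as exc:
            raise ConstraintError(f"{table}: {exc}") from exc

    def record_cv_metric(
        self,
        model_kind: str,
        feature_set: str,
        iteration: int,
        pathway: str,
        metric_name: str,
        value: float,
    ) -> None:
        self.record(
            "cv_results",
            dict(
                model_kind=model_kind,
                feature_set=feature_set,
                iteration=iteration,
                pathway=pathway,
                metric_name=metric_name,
                value=float(value),
            ),
        )

    def record_importance(
        self,
        feature_name: str,
        entity_kind: str,
        iteration: int,
        raw_score: float,
        relative_score: float,
    ) -> None:
        self.record(
            "importance",
            dict(
                feature_name=feature_name,
                entity_kind=entity_kind,
                iteration=iteration,
                raw_score=float(raw_score),
                relative_score=float(relative_score),
            ),
        )

    def record_trial(
        self,
        trial_id: int,
        params: dict,
        median_mcc: float | None,
        pruned: bool,
        study: str = "",
    ) -> None:
        self.record(
            "trials",
            dict(
                study=study,
                trial_id=trial_id,
                params=json.dumps(params, sort_keys=True),
                median_mcc=median_mcc,
                pruned=int(pruned),
            ),
        )

    # -- queries -----------------------------------------------------------

    def query(self, sql: str, params: tuple = ()) -> pd.DataFrame:
        return pd.read_sql_query(sql, self._conn, params=params)

    def summarize_cv(
        self, metric_name: str = "mcc", per_pathway: bool = True
    ) -> pd.DataFrame:
        """Mean/std/count of a metric per model, feature set (and pathway)."""
        group = "model_kind, feature_set" + (", pathway" if per_pathway else "")
        where = "metric_name = ?"
        if not per_pathway:
            where += f" AND pathway = '{OVERALL}'"
        return self.query(
            f"SELECT {group}, AVG(value) AS mean, "
            "SQRT(AVG(value * value) - AVG(value) * AVG(value)) AS std, "
            f"COUNT(*) AS n FROM cv_results WHERE {where} GROUP BY {group}",
            (metric_name,),
        )

    def export_csv(self, table: str, path: str | Path) -> None:
        if table not in ("cv_results", "importance", "trials"):
            raise ValidationError(f"unknown table {table!r}")
        self.query(f"SELECT * FROM {table}").to_csv(path, index=False)

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "ResultsStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def record_result(store: ResultsStore, table: str, record: dict) -> None:
    """Persist one row into the store; duplicates raise :class:`ConstraintError`."""
    store.record(table, record)
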