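"""Core data types and readers/writers for nanoparticle datasets and predictions.

A :class:`Dataset` holds one row per nanoparticle: an identifier, optional
core/coating structures (SMILES), a sparse map of measured quantitative
descriptors, and one or more toxicity endpoints.  Endpoints are stored and
modelled on log2 scale throughout; raw-scale input is converted exactly once
at import.  Missing descriptor values are first-class (absent map entries) and
are never imputed at the IO layer — how a missing measurement is handled is a
similarity / applicability-domain question, decided downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DescriptorClass",
    "Substance",
    "Dataset",
    "DatasetSchema",
    "PredictionRecord",
    "DatasetError",
    "read_dataset",
    "write_dataset",
    "dataset_from_frame",
    "log2_transform",
    "write_predictions",
    "read_predictions",
]


class DatasetError(ValueError):
    """Raised for malformed dataset files or invariant violations."""


class DescriptorClass:
    """The four descriptor classes a model can be built on."""

    MP2D = "MP2D"
    PCHEM = "P-CHEM"
    PROTEOMICS = "Proteomics"
    PCHEM_PROTEOMICS = "P-CHEM+Proteomics"

    ALL = (MP2D, PCHEM, PROTEOMICS, PCHEM_PROTEOMICS)
    QUANTITATIVE = (PCHEM, PROTEOMICS, PCHEM_PROTEOMICS)


@dataclass
class Substance:
    """One nanoparticle: identity, composition and measurements.

    Parameters
    ----------
    id : unique identifier within a dataset.
    core_smiles : SMILES of the core compound, or None when the core has no
        defined structure.
    coating_smiles : SMILES of zero or more coating compounds.
    properties : measured quantitative descriptors; absent keys mean the
        property was not measured.
    endpoints : toxicity endpoint values on log2 scale.
    """

    id: str
    core_smiles: str | None = None
    coating_smiles: list[str] = field(default_factory=list)
    properties: dict[str, float] = field(default_factory=dict)
    endpoints: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise DatasetError("substance id must be nonempty")
        for name, value in {**self.properties, **self.endpoints}.items():
            if not math.isfinite(value):
                raise DatasetError(
                    f"non-finite value {value!r} for {name!r} on substance {self.id!r}"
                )

    @property
    def has_structure(self) -> bool:
        return self.core_smiles is not None or len(self.coating_smiles) > 0


@dataclass
class Dataset:
    """An ordered collection of substances with a shared feature vocabulary."""

    substances: list[Substance]
    feature_names: list[str]
    endpoint_names: list[str]
    descriptor_class: str = DescriptorClass.PCHEM
    # maps feature name -> "P-CHEM" or "Proteomics"; used to carve class views
    feature_classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.substances]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise DatasetError(f"duplicate substance ids: {', '.join(dupes)}")
        known = set(self.feature_names)
        for s in self.substances:
            extra = set(s.properties) - known
            if extra:
                raise DatasetError(
                    f"substance {s.id!r} has properties outside feature_names: {sorted(extra)}"
                )

    def __len__(self) -> int:
        return len(self.substances)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.substances]

    def substance(self, substance_id: str) -> Substance:
        for s in self.substances:
            if s.id == substance_id:
                return s
        raise KeyError(substance_id)

    def feature_frame(self, features: Sequence[str] | None = None) -> pd.DataFrame:
        """Feature matrix as a DataFrame (NaN for missing), rows indexed by id."""
        features = list(features) if features is not None else self.feature_names
        data = np.full((len(self.substances), len(features)), np.nan)
        for i, s in enumerate(self.substances):
            for j, f in enumerate(features):
                if f in s.properties:
                    data[i, j] = s.properties[f]
        return pd.DataFrame(data, index=self.ids, columns=features)

    def endpoint_series(self, endpoint: str) -> pd.Series:
        if endpoint not in self.endpoint_names:
            raise DatasetError(f"unknown endpoint {endpoint!r}")
        return pd.Series(
            [s.endpoints.get(endpoint, np.nan) for s in self.substances],
            index=self.ids,
            name=endpoint,
        )

    def features_for_class(self, descriptor_class: str) -> list[str]:
        """Feature names belonging to a quantitative descriptor class."""
        if descriptor_class == DescriptorClass.MP2D:
            return []
        if descriptor_class == DescriptorClass.PCHEM_PROTEOMICS:
            wanted = {DescriptorClass.PCHEM, DescriptorClass.PROTEOMICS}
        elif descriptor_class in (DescriptorClass.PCHEM, DescriptorClass.PROTEOMICS):
            wanted = {descriptor_class}
        else:
            raise DatasetError(f"unknown descriptor class {descriptor_class!r}")
        return [
            f
            for f in self.feature_names
            if self.feature_classes.get(f, DescriptorClass.PCHEM) in wanted
        ]

    def subset(self, substance_ids: Iterable[str]) -> "Dataset":
        """New dataset restricted to the given substances (order preserved)."""
        keep = set(substance_ids)
        return Dataset(
            substances=[s for s in self.substances if s.id in keep],
            feature_names=list(self.feature_names),
            endpoint_names=list(self.endpoint_names),
            descriptor_class=self.descriptor_class,
            feature_classes=dict(self.feature_classes),
        )


@dataclass
class DatasetSchema:
    """Column-role mapping for the dataset CSV format.

    Any column not named as id/core/coating/endpoint is treated as a
    quantitative feature.  Features whose name is listed in
    ``proteomics_columns`` (or matches ``proteomics_prefix``) are classed as
    Proteomics descriptors, the remainder as P-CHEM.
    """

    id_column: str = "id"
    core_column: str | None = "core_smiles"
    coating_column: str | None = "coating_smiles"
    endpoint_columns: list[str] = field(default_factory=lambda: ["net_cell_association"])
    proteomics_columns: list[str] | None = None
    proteomics_prefix: str | None = "prot_"
    endpoint_scale: str = "log2"  # "log2" (stored as-is) or "raw" (log2 at import)

    def feature_class(self, column: str) -> str:
        if self.proteomics_columns is not None and column in self.proteomics_columns:
            return DescriptorClass.PROTEOMICS
        if self.proteomics_prefix and column.startswith(self.proteomics_prefix):
            return DescriptorClass.PROTEOMICS
        return DescriptorClass.PCHEM


@dataclass
class PredictionRecord:
    """Outcome of one read-across prediction for one query substance.

    ``value`` is None when the query lies outside the applicability domain
    (no neighbors, or no usable representation); in that case ``warnings``
    explains why.  Intervals are present only when the local model provides an
    internal RMSE estimate (PLS/RF); the weighted-average benchmark does not.
    """

    query_id: str
    endpoint: str
    value: float | None = None
    interval_low: float | None = None
    interval_high: float | None = None
    neighbors: list[tuple[str, float]] = field(default_factory=list)
    algorithm_used: str = "WA"
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.value is not None and self.interval_low is not None:
            if not (self.interval_low <= self.value <= self.interval_high):
                raise DatasetError(
                    f"interval [{self.interval_low}, {self.interval_high}] does not "
                    f"bracket the prediction {self.value} for {self.query_id!r}"
                )
        if self.value is None and (self.neighbors or not self.warnings):
            raise DatasetError(
                "a record without a prediction must carry warnings and no neighbors"
            )

    @property
    def has_interval(self) -> bool:
        return self.interval_low is not None

    def to_dict(self) -> dict:
        return {
            "query_id": self.query_id,
            "endpoint": self.endpoint,
            "value": self.value,
            "interval_low": self.interval_low,
            "interval_high": self.interval_high,
            "neighbors": [[i, s] for i, s in self.neighbors],
            "algorithm_used": self.algorithm_used,
            "warnings": list(self.warnings),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PredictionRecord":
        return cls(
            query_id=d["query_id"],
            endpoint=d["endpoint"],
            value=d["value"],
            interval_low=d["interval_low"],
            interval_high=d["interval_high"],
            neighbors=[(i, float(s)) for i, s in d["neighbors"]],
            algorithm_used=d["algorithm_used"],
            warnings=list(d["warnings"]),
        )


def log2_transform(values: Sequence[float], ids: Sequence[str] | None = None) -> np.ndarray:
    """Elementwise base-2 logarithm of positive endpoint values.

    Applied once at import when raw-scale endpoint data is supplied.  A value
    <= 0 is a domain violation and the error names the offending substance.
    """
    arr = np.asarray(values, dtype=float)
    bad = np.nonzero(~(arr > 0) & ~np.isnan(arr))[0]
    if bad.size:
        i = int(bad[0])
        who = ids[i] if ids is not None else f"index {i}"
        raise DatasetError(f"log2 transform requires positive values; got {arr[i]} for {who}")
    return np.log2(arr)


def _parse_cell(raw: object, row_id: str, column: str) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    if isinstance(raw, str):
        raw = raw.strip()
        if raw == "":
            return None
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise DatasetError(
            f"unparseable numeric cell {raw!r} in column {column!r}, row {row_id!r}"
        ) from None


def read_dataset(path: str | Path, schema: DatasetSchema | None = None) -> Dataset:
    """Read a dataset CSV (UTF-8, comma-separated, header row, '.' decimals).

    Empty cells become missing values.  Multiple coatings are held in one cell
    as a ';'-separated SMILES list.  When ``schema.endpoint_scale == "raw"``
    endpoint columns are log2-transformed at import.
    """
    schema = schema or DatasetSchema()
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    if schema.id_column not in df.columns:
        raise DatasetError(f"id column {schema.id_column!r} not found in {path}")
    for ep in schema.endpoint_columns:
        if ep not in df.columns:
            raise DatasetError(f"endpoint column {ep!r} not found in {path}")

    structural = {schema.id_column}
    if schema.core_column:
        structural.add(schema.core_column)
    if schema.coating_column:
        structural.add(schema.coating_column)
    feature_names = [
        c for c in df.columns if c not in structural and c not in schema.endpoint_columns
    ]

    substances: list[Substance] = []
    for _, row in df.iterrows():
        sid = str(row[schema.id_column]).strip()
        core = None
        if schema.core_column and schema.core_column in df.columns:
            raw = str(row[schema.core_column]).strip()
            core = raw or None
        coatings: list[str] = []
        if schema.coating_column and schema.coating_column in df.columns:
            raw = str(row[schema.coating_column]).strip()
            if raw:
                coatings = [c.strip() for c in raw.split(";") if c.strip()]
        props = {}
        for f in feature_names:
            v = _parse_cell(row[f], sid, f)
            if v is not None:
                props[f] = v
        endpoints = {}
        for ep in schema.endpoint_columns:
            v = _parse_cell(row[ep], sid, ep)
            if v is not None:
                if schema.endpoint_scale == "raw":
                    v = float(log2_transform([v], [sid])[0])
                endpoints[ep] = v
        substances.append(
            Substance(
                id=sid,
                core_smiles=core,
                coating_smiles=coatings,
                properties=props,
                endpoints=endpoints,
            )
        )

    feature_classes = {f: schema.feature_class(f) for f in feature_names}
    classes_present = set(feature_classes.values())
    if classes_present == {DescriptorClass.PROTEOMICS}:
        dclass = DescriptorClass.PROTEOMICS
    elif DescriptorClass.PROTEOMICS in classes_present:
        dclass = DescriptorClass.PCHEM_PROTEOMICS
    else:
        dclass = DescriptorClass.PCHEM
    return Dataset(
        substances=substances,
        feature_names=feature_names,
        endpoint_names=list(schema.endpoint_columns),
        descriptor_class=dclass,
        feature_classes=feature_classes,
    )


def write_dataset(dataset: Dataset, path: str | Path, schema: DatasetSchema | None = None) -> None:
    """Write a dataset to CSV in the schema's column layout (read_dataset inverse)."""
    schema = schema or DatasetSchema(endpoint_columns=list(dataset.endpoint_names))
    rows = []
    for s in dataset.substances:
        row: dict[str, object] = {schema.id_column: s.id}
        if schema.core_column:
            row[schema.core_column] = s.core_smiles or ""
        if schema.coating_column:
            row[schema.coating_column] = ";".join(s.coating_smiles)
        for f in dataset.feature_names:
            row[f] = s.properties.get(f, "")
        for ep in dataset.endpoint_names:
            row[ep] = s.endpoints.get(ep, "")
        rows.append(row)
    cols = [schema.id_column]
    if schema.core_column:
        cols.append(schema.core_column)
    if schema.coating_column:
        cols.append(schema.coating_column)
    cols += list(dataset.feature_names) + list(dataset.endpoint_names)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, encoding="utf-8")


def dataset_from_frame(
    features: pd.DataFrame,
    endpoints: pd.DataFrame | pd.Series,
    feature_classes: Mapping[str, str] | None = None,
    cores: Mapping[str, str | None] | None = None,
    coatings: Mapping[str, list[str]] | None = None,
) -> Dataset:
    """Assemble a Dataset from an in-memory feature matrix and endpoint table.

    NaN cells become missing values.  Row index supplies substance ids.
    """
    if isinstance(endpoints, pd.Series):
        endpoints = endpoints.to_frame()
    fnames = [str(c) for c in features.columns]
    enames = [str(c) for c in endpoints.columns]
    fvals = features.to_numpy(dtype=float)
    evals = endpoints.to_numpy(dtype=float)
    substances = []
    for i, sid in enumerate(features.index):
        frow, erow = fvals[i], evals[i]
        props = {f: frow[j] for j, f in enumerate(fnames) if frow[j] == frow[j]}
        eps = {e: erow[j] for j, e in enumerate(enames) if erow[j] == erow[j]}
        substances.append(
            Substance(
                id=str(sid),
                core_smiles=(cores or {}).get(sid),
                coating_smiles=list((coatings or {}).get(sid, [])),
                properties=props,
                endpoints=eps,
            )
        )
    fclasses = dict(feature_classes or {})
    classes_present = {fclasses.get(f, DescriptorClass.PCHEM) for f in features.columns}
    if classes_present == {DescriptorClass.PROTEOMICS}:
        dclass = DescriptorClass.PROTEOMICS
    elif DescriptorClass.PROTEOMICS in classes_present:
        dclass = DescriptorClass.PCHEM_PROTEOMICS
    else:
        dclass = DescriptorClass.PCHEM
    return Dataset(
        substances=substances,
        feature_names=[str(c) for c in features.columns],
        endpoint_names=[str(c) for c in endpoints.columns],
        descriptor_class=dclass,
        feature_classes=fclasses,
    )


def write_predictions(records: Sequence[PredictionRecord], path: str | Path) -> None:
    """Serialize prediction records as JSON lines (one record per query)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_dict()) + "\n")


def read_predictions(path: str | Path) -> list[PredictionRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(PredictionRecord.from_dict(json.loads(line)))
    return records
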