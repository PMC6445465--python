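"""Patient-by-feature cohort container and its CSV dialect.

Missing measurements are carried as an explicit boolean mask in memory and
encoded by the sentinel value 9999 on disk (the convention of the source
database).  A sidecar JSON file can carry the schema, the simulation seed and
the latent group labels of synthetic cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import FeatureSchema, default_schema

#: On-disk missing-value sentinel.
MISSING_SENTINEL = 9999.0


@dataclass
class CohortMatrix:
    """Raw-scale patient x variable matrix with an explicit missing mask."""

    values: np.ndarray          # (n_patients, n_variables) float, raw scale
    missing_mask: np.ndarray    # same shape, bool
    schema: FeatureSchema
    true_labels: np.ndarray | None = None   # synthetic cohorts only
    patient_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != self.missing_mask.shape:
            raise ValueError("values and missing_mask must have identical shape")
        if self.values.shape[1] != self.schema.total_variables:
            raise ValueError(
                f"matrix has {self.values.shape[1]} columns but schema defines "
                f"{self.schema.total_variables} variables"
            )
        if np.any(self.values[~self.missing_mask] == MISSING_SENTINEL):
            raise ValueError("sentinel 9999 present in observed entries")
        if not self.patient_ids:
            self.patient_ids = [f"P{i + 1:03d}" for i in range(self.values.shape[0])]
        if self.true_labels is not None:
            self.true_labels = np.asarray(self.true_labels, dtype=int)
            if self.true_labels.shape[0] != self.values.shape[0]:
                raise ValueError("true_labels length must equal n_patients")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def drop_block(self, block: str) -> "CohortMatrix":
        """Cohort restricted to all variables outside ``block``."""
        cols = self.schema.columns_of(block)
        keep = [j for j in range(self.n_variables) if j not in cols]
        return CohortMatrix(
            self.values[:, keep],
            self.missing_mask[:, keep],
            self.schema.drop_block(block),
            true_labels=self.true_labels,
            patient_ids=list(self.patient_ids),
        )

    def drop_variable(self, variable: str) -> "CohortMatrix":
        j = self.schema.variable_names.index(variable)
        keep = [c for c in range(self.n_variables) if c != j]
        return CohortMatrix(
            self.values[:, keep],
            self.missing_mask[:, keep],
            self.schema.drop_variable(variable),
            true_labels=self.true_labels,
            patient_ids=list(self.patient_ids),
        )


def write_cohort(cohort: CohortMatrix, path: str | Path, *,
                 seed: int | None = None) -> None:
    """Write the cohort as CSV with 9999 encoding missing, plus a sidecar JSON.

    The sidecar (``<path>.meta.json``) records the block schema, patient ids,
    the latent group labels (synthetic cohorts) and the generating seed.
    """
    path = Path(path)
    out = cohort.values.copy()
    out[cohort.missing_mask] = MISSING_SENTINEL
    frame = pd.DataFrame(out, columns=cohort.schema.variable_names)
    frame.insert(0, "patient_id", cohort.patient_ids)
    frame.to_csv(path, index=False, float_format="%.6g")
    meta = {
        "blocks": [[name, list(names)] for name, names in cohort.schema.blocks],
        "patient_ids": list(cohort.patient_ids),
        "true_labels": None
        if cohort.true_labels is None
        else [int(x) for x in cohort.true_labels],
        "seed": seed,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_cohort(path: str | Path, schema: FeatureSchema | None = None) -> CohortMatrix:
    """Read a cohort CSV, converting every 9999 cell to a masked entry.

    Raises a parse error naming the offending row/column on non-numeric cells
    and a schema error when the header does not match ``schema`` (defaults to
    the canonical 53-variable schema, or to the sidecar schema if present).
    """
    path = Path(path)
    sidecar = Path(str(path) + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else None
    if schema is None:
        if meta is not None:
            schema = FeatureSchema(
                tuple((name, tuple(names)) for name, names in meta["blocks"])
            )
        else:
            schema = default_schema()

    frame = pd.read_csv(path, dtype=str)
    patient_ids = None
    if frame.columns[0] == "patient_id":
        patient_ids = frame["patient_id"].tolist()
        frame = frame.drop(columns=["patient_id"])
    if list(frame.columns) != schema.variable_names:
        raise ValueError(
            "header does not match schema: expected "
            f"{schema.variable_names[:3]}..., got {list(frame.columns)[:3]}..."
        )

    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        for i, cell in enumerate(frame[col]):
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric cell {cell!r} at row {i + 1}, column {col!r}"
                ) from None
    mask = values == MISSING_SENTINEL
    values = values.copy()
    values[mask] = np.nan
    true_labels = None
    if meta is not None and meta.get("true_labels") is not None:
        true_labels = np.asarray(meta["true_labels"], dtype=int)
    return CohortMatrix(values, mask, schema, true_labels=true_labels,
                        patient_ids=patient_ids or [])
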