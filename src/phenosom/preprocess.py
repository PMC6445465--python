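"""Cohort ingestion, median imputation and z-score standardization.

The pipeline order is fixed: convert the 9999 sentinel to an explicit missing
mask at ingestion, replace each missing entry by its column median (robust to
the outliers deliberately kept in the data), then standardize every column to
zero mean and unit sample standard deviation.  Clustering always runs on the
standardized matrix so that variables with large raw ranges do not dominate
the Euclidean geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortMatrix, read_cohort  # noqa: F401  (re-export)
from .schema import FeatureSchema


@dataclass
class ZMatrix:
    """Standardized feature matrix plus the raw-scale statistics behind it."""

    values: np.ndarray            # (n_patients, n_variables), z-score units
    column_medians: np.ndarray    # raw scale, used for imputation
    column_means: np.ndarray      # raw scale
    column_sds: np.ndarray        # raw scale, sample (n-1) sd
    schema: FeatureSchema

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, columns=self.schema.variable_names).to_csv(
            path, sep="\t", index=False
        )


def impute_median(cohort: CohortMatrix) -> CohortMatrix:
    """Replace every missing entry by the median of its column's observations.

    Observed entries are untouched; the even-count median is the midpoint of
    the two central order statistics.  A fully missing column is an error
    (there is nothing to impute from).
    """
    if not cohort.missing_mask.any():
        return cohort
    values = cohort.values.copy()
    for j in range(cohort.n_variables):
        col_mask = cohort.missing_mask[:, j]
        if not col_mask.any():
            continue
        if col_mask.all():
            name = cohort.schema.variable_names[j]
            raise ValueError(f"column {name!r} is entirely missing; cannot impute")
        med = float(np.median(cohort.values[~col_mask, j]))
        values[col_mask, j] = med
    return CohortMatrix(
        values,
        np.zeros_like(cohort.missing_mask),
        cohort.schema,
        true_labels=cohort.true_labels,
        patient_ids=list(cohort.patient_ids),
    )


def zscore(cohort: CohortMatrix) -> ZMatrix:
    """Standardize each column to mean 0 / sample sd 1 (n-1 denominator).

    Requires a fully imputed cohort.  A constant column cannot be scaled and
    maps to all zeros with a warning; it is retained so that column indices
    stay aligned with the schema.
    """
    if cohort.missing_mask.any():
        raise ValueError("cohort has missing entries; run impute_median first")
    x = cohort.values
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    medians = np.median(x, axis=0)
    z = np.zeros_like(x)
    nonconst = sds > 0
    z[:, nonconst] = (x[:, nonconst] - means[nonconst]) / sds[nonconst]
    for j in np.where(~nonconst)[0]:
        warnings.warn(
            f"column {cohort.schema.variable_names[j]!r} is constant; "
            "standardized to zeros",
            stacklevel=2,
        )
    return ZMatrix(z, medians, means, sds, cohort.schema)


def preprocess(cohort: CohortMatrix) -> ZMatrix:
    """Impute-then-standardize convenience wrapper."""
    return zscore(impute_median(cohort))
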