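"""Group-level statistics: PCA with varimax rotation, Mann-Whitney U with
eta-squared effect sizes, Bonferroni correction, and symptom contrasts.

Between-group tests are nonparametric (the diagnostic variables carry
outliers that were deliberately kept); descriptive statistics are reported
on the raw measurement scale for clinical readability while tests run on
standardized values (rank-based, so the monotone rescaling is inert).  The
effect size is eta squared, Z^2 / N, from the tie-corrected normal
approximation of the U statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.multivariate.factor_rotation import rotate_factors

from .cohort import CohortMatrix
from .preprocess import ZMatrix
from .schema import SymptomTable

#: Eta-squared interpretation bands (lower bounds).
ETA_SQUARED_BANDS = {"small": 0.1, "medium": 0.3, "large": 0.5}

#: Band rule for symptom frequency differences (absolute percentage points).
SYMPTOM_BAND_POINTS = 10.0

#: Pooled sample size at or below which the exact Mann-Whitney path is used.
EXACT_MW_LIMIT = 12


# ---------------------------------------------------------------- PCA

@dataclass
class PcaResult:
    loadings: np.ndarray                 # (variables x retained), rotated
    unrotated_loadings: np.ndarray       # (variables x all), orthonormal
    explained_variance_fraction: np.ndarray   # all components
    scores: np.ndarray                   # (patients x retained), rotated basis
    n_retained: int
    rotation: str


def pca(
    data: ZMatrix | np.ndarray,
    rotation: str = "varimax",
    retain_fraction: float = 0.8,
) -> PcaResult:
    """Principal components of the standardized matrix, varimax-rotated.

    Components are retained up to the smallest count whose cumulative
    explained-variance fraction reaches ``retain_fraction`` (default 0.8);
    the orthogonal rotation is applied to the retained loadings only and
    preserves each variable's communality over them.
    """
    x = np.asarray(getattr(data, "values", data), dtype=float)
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 observations")
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / (x.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    total = eigval.sum()
    if total <= 0:
        raise ValueError("degenerate (rank-0) matrix; PCA undefined")
    frac = eigval / total
    n_retained = int(np.searchsorted(np.cumsum(frac), retain_fraction) + 1)
    n_retained = min(n_retained, len(frac))
    retained = eigvec[:, :n_retained]
    if rotation == "varimax" and n_retained > 1:
        rotated, _ = rotate_factors(retained, "varimax")
    elif rotation in (None, "none") or n_retained == 1:
        rotated = retained
    else:
        raise ValueError(f"unsupported rotation {rotation!r}")
    return PcaResult(
        loadings=rotated,
        unrotated_loadings=eigvec,
        explained_variance_fraction=frac,
        scores=xc @ rotated,
        n_retained=n_retained,
        rotation=rotation or "none",
    )


# ------------------------------------------------- rank tests & effect sizes

def mann_whitney(a, b) -> tuple[float, float, float]:
    """Mann-Whitney U for two independent samples: returns (U, Z, p).

    U is the rank-sum statistic of sample ``a`` (midranks for ties); Z uses
    the tie-corrected normal approximation without continuity correction;
    the two-sided p comes from exact enumeration of all group assignments
    when n_a + n_b <= 12 and from the normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_a = ranks[:na].sum() - na * (na + 1) / 2.0

    n = na + nb
    mu = na * nb / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    z = 0.0 if var == 0 else (u_a - mu) / math.sqrt(var)

    if n <= EXACT_MW_LIMIT:
        p = _exact_mw_p(ranks, na, u_a)
    else:
        p = min(1.0, 2.0 * sps.norm.sf(abs(z))) if var > 0 else 1.0
    return float(u_a), float(z), float(p)


def _exact_mw_p(ranks: np.ndarray, na: int, u_obs: float) -> float:
    """Two-sided exact p by enumerating every split of the pooled midranks.

    The null distribution of U is symmetric about n_a n_b / 2 (rank reversal
    maps U to its complement), so the two-sided p is the probability of a
    deviation from the mean at least as large as observed.
    """
    n = len(ranks)
    nb = n - na
    mu = na * nb / 2.0
    dev = abs(u_obs - mu) - 1e-9
    hits = total = 0
    offset = na * (na + 1) / 2.0
    for idx in combinations(range(n), na):
        u = ranks[list(idx)].sum() - offset
        total += 1
        if abs(u - mu) >= dev:
            hits += 1
    return hits / total


def eta_squared(z: float, n: int) -> float:
    """Effect size eta^2 = Z^2 / N for a rank test on N subjects."""
    if n <= 0:
        raise ValueError("N must be positive")
    return float(z) ** 2 / n


def eta_squared_band(value: float) -> str:
    if value > ETA_SQUARED_BANDS["large"]:
        return "large"
    if value > ETA_SQUARED_BANDS["medium"]:
        return "medium"
    if value > ETA_SQUARED_BANDS["small"]:
        return "small"
    return "negligible"


def bonferroni_alpha(base_alpha: float = 0.05, m: int = 1) -> float:
    """Family-wise corrected threshold base_alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return base_alpha / m


# ------------------------------------------------------- group comparison

@dataclass
class GroupComparison:
    """Per-variable two-group contrast with medians/IQRs, U, Z, p, eta^2."""

    table: pd.DataFrame
    alpha_corrected: float

    @property
    def significant_variables(self) -> list[str]:
        return self.table.loc[self.table["significant"], "variable"].tolist()


def _iqr(x: np.ndarray) -> float:
    q75, q25 = np.percentile(x, [75, 25])
    return float(q75 - q25)


def compare_groups(
    cohort: CohortMatrix,
    zdata: ZMatrix,
    labels,
    alpha_corrected: float,
) -> GroupComparison:
    """Mann-Whitney contrast of the two clusters on every variable.

    Descriptives (median [IQR]) are computed on the raw, imputed scale;
    the test runs on the standardized values.  Rows are sorted with
    significant variables first (ascending p within each stratum).
    """
    labels = np.asarray(labels)
    ids = np.unique(labels)
    if len(ids) != 2:
        raise ValueError(f"expected exactly two groups, got {len(ids)}")
    g1, g2 = labels == ids[0], labels == ids[1]
    if not (g1.any() and g2.any()):
        raise ValueError("both groups must be non-empty")
    n = len(labels)
    rows = []
    for j, name in enumerate(zdata.schema.variable_names):
        raw = cohort.values[:, j]
        za, zb = zdata.values[g1, j], zdata.values[g2, j]
        u, z, p = mann_whitney(za, zb)
        es = eta_squared(z, n)
        rows.append({
            "variable": name,
            "block": zdata.schema.block_of(name),
            "median_1": float(np.median(raw[g1])),
            "iqr_1": _iqr(raw[g1]),
            "median_2": float(np.median(raw[g2])),
            "iqr_2": _iqr(raw[g2]),
            "U": u,
            "Z": z,
            "p": p,
            "eta_squared": es,
            "effect_band": eta_squared_band(es),
            "significant": p < alpha_corrected,
        })
    table = pd.DataFrame(rows).sort_values(
        ["significant", "p"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return GroupComparison(table, alpha_corrected)


def symptom_contrast(symptoms: SymptomTable, labels) -> pd.DataFrame:
    """Per-symptom frequency contrast between the two clusters.

    Frequencies use non-missing responses only; the 2x2 association test is
    chi-squared, switching to Fisher's exact test when any expected cell
    count falls below 5.  Symptoms are banded by the 10-percentage-point
    rule into more-in-group-1 / more-in-group-2 / similar.
    """
    labels = np.asarray(labels)
    ids = np.unique(labels)
    if len(ids) != 2:
        raise ValueError("symptom contrast requires exactly two groups")
    pres = symptoms.presence
    rows = []
    for k, name in enumerate(symptoms.symptoms):
        col = pres[:, k]
        ok = ~np.isnan(col)
        if not ok.any():
            import warnings

            warnings.warn(f"symptom {name!r} has zero responses; excluded",
                          stacklevel=2)
            continue
        table = np.zeros((2, 2))
        for gi, gid in enumerate(ids):
            sel = ok & (labels == gid)
            table[gi, 0] = np.sum(col[sel] == 1.0)
            table[gi, 1] = np.sum(col[sel] == 0.0)
        f1 = table[0, 0] / max(table[0].sum(), 1)
        f2 = table[1, 0] / max(table[1].sum(), 1)
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / max(total, 1)
        if (expected < 5).any() or (table.sum(axis=0) == 0).any():
            _, p = sps.fisher_exact(table.astype(int))
            test = "fisher"
        else:
            _, p, _, _ = sps.chi2_contingency(table, correction=False)
            test = "chi2"
        diff = 100.0 * (f1 - f2)
        if diff >= SYMPTOM_BAND_POINTS:
            band = "more in group 1"
        elif diff <= -SYMPTOM_BAND_POINTS:
            band = "more in group 2"
        else:
            band = "similar"
        rows.append({
            "symptom": name,
            "freq_1": float(f1),
            "freq_2": float(f2),
            "test": test,
            "p": float(p),
            "band": band,
        })
    return pd.DataFrame(rows)
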