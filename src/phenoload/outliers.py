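"""Per-gene variant-load regression and residual-outlier calling.

For each gene, the load in a phenotype group is the number of distinct
qualifying variants with at least one carrier in that group.  An ordinary
least-squares line (with intercept) predicts the case-group load from the
control-group load across genes.  Outliers are genes whose residual falls
far outside the residual interquartile range: with Q1 and Q3 the first and
third residual quartiles and D = Q3 - Q1,

* residual > Q3 + 6D  ->  outlier in the case (impaired) group,
* residual < Q1 - 6D  ->  outlier in the control (normal) group.

Both directions are kept because rare variants may protect from, as well
as predispose to, the phenotype.  Comparisons are strict, so with D = 0
no gene is an outlier.  Quartiles use linear interpolation at fractional
order-statistic position p*(n-1) (the common "type 7" convention).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, UsageError
from .filtering import CARRIER_PREFIX

logger = logging.getLogger(__name__)

#: Multiplier of the residual interquartile distance defining the outlier fences.
IQR_MULTIPLIER = 6.0


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of case load on control load, with residual fence statistics."""

    slope: float
    intercept: float
    residuals: pd.Series  # indexed by gene
    q1: float
    q3: float
    d: float
    lower_threshold: float
    upper_threshold: float

    def summary(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "n_genes": int(len(self.residuals)),
            "q1": self.q1,
            "q3": self.q3,
            "d": self.d,
            "lower_threshold": self.lower_threshold,
            "upper_threshold": self.upper_threshold,
        }


@dataclass(frozen=True)
class OutlierCalls:
    """Directional outlier gene lists plus the fit that produced them."""

    outliers_case: tuple[str, ...]
    outliers_control: tuple[str, ...]
    fit: RegressionFit

    def summary(self) -> dict:
        return {
            **self.fit.summary(),
            "n_outliers_case": len(self.outliers_case),
            "n_outliers_control": len(self.outliers_control),
        }


def compute_gene_loads(
    variants: pd.DataFrame,
    control_group: str = "normal",
    case_group: str = "impaired",
) -> pd.DataFrame:
    """Count distinct qualifying variants present per gene and group.

    A variant is "present" in a group when its carrier count there is at
    least one; a variant present in both groups counts once in each column.
    Genes with zero load in both groups are absent from the result.
    Returns a DataFrame with columns ``gene``, ``load_control``,
    ``load_case``, sorted by gene.
    """
    ctrl_col = CARRIER_PREFIX + control_group
    case_col = CARRIER_PREFIX + case_group
    known = sorted(
        c[len(CARRIER_PREFIX):] for c in variants.columns if c.startswith(CARRIER_PREFIX)
    )
    for col, label in ((ctrl_col, control_group), (case_col, case_group)):
        if col not in variants.columns:
            raise UsageError(
                f"unknown group label {label!r}; carrier columns present for: {known}"
            )
    df = variants.drop_duplicates(subset=["gene", "variant_id"])
    present = pd.DataFrame(
        {
            "gene": df["gene"],
            "load_control": (df[ctrl_col].fillna(0) >= 1).astype(int),
            "load_case": (df[case_col].fillna(0) >= 1).astype(int),
        }
    )
    loads = present.groupby("gene", sort=True).sum().reset_index()
    loads = loads[(loads["load_control"] > 0) | (loads["load_case"] > 0)]
    return loads.reset_index(drop=True)


def quartiles(values: Sequence[float] | np.ndarray) -> tuple[float, float]:
    """First and third quartiles by linear interpolation at p*(n-1)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise DegenerateInputError(
            f"quartiles need at least 2 values, got {arr.size}"
        )
    q1, q3 = np.quantile(arr, [0.25, 0.75], method="linear")
    return float(q1), float(q3)


def fit_load_regression(table: pd.DataFrame) -> RegressionFit:
    """OLS of case load on control load across genes, with fence statistics.

    Requires at least three genes and a non-constant control load.
    Residuals sum to zero (up to numerical tolerance) because the model
    includes an intercept.
    """
    n = len(table)
    if n < 3:
        raise DegenerateInputError(
            f"load regression needs at least 3 genes, got {n}"
        )
    x = table["load_control"].to_numpy(dtype=float)
    y = table["load_case"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateInputError("control load is constant; regression undefined")
    res = stats.linregress(x, y)
    residuals = pd.Series(
        y - (res.slope * x + res.intercept), index=table["gene"].to_numpy()
    )
    q1, q3 = quartiles(residuals.to_numpy())
    d = q3 - q1
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        residuals=residuals,
        q1=q1,
        q3=q3,
        d=d,
        lower_threshold=q1 - IQR_MULTIPLIER * d,
        upper_threshold=q3 + IQR_MULTIPLIER * d,
    )


def call_outliers(fit: RegressionFit) -> OutlierCalls:
    """Apply the strict fence rule to a fitted regression's residuals."""
    res = fit.residuals
    case = tuple(sorted(res.index[res > fit.upper_threshold]))
    control = tuple(sorted(res.index[res < fit.lower_threshold]))
    return OutlierCalls(outliers_case=case, outliers_control=control, fit=fit)


def find_outliers(
    variants: pd.DataFrame,
    control_group: str = "normal",
    case_group: str = "impaired",
) -> OutlierCalls:
    """Convenience chain: loads -> regression -> outlier calls."""
    table = compute_gene_loads(variants, control_group, case_group)
    return call_outliers(fit_load_regression(table))


def outlier_table(calls: OutlierCalls, loads: pd.DataFrame) -> pd.DataFrame:
    """Per-gene table of loads, residuals and outlier flags."""
    out = loads.copy()
    out["residual"] = calls.fit.residuals.loc[out["gene"]].to_numpy()
    out["is_outlier_case"] = out["gene"].isin(calls.outliers_case)
    out["is_outlier_control"] = out["gene"].isin(calls.outliers_control)
    return out


def write_outlier_outputs(
    calls: OutlierCalls, loads: pd.DataFrame, out_prefix: str | Path
) -> None:
    """Write the gene table as TSV and the fit summary as JSON."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    outlier_table(calls, loads).to_csv(
        prefix.with_suffix(".genes.tsv"), sep="\t", index=False
    )
    with open(prefix.with_suffix(".fit.json"), "w") as fh:
        json.dump(calls.summary(), fh, indent=2)
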