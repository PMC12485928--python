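"""Donor-level association tests on neighborhood percentages.

Replicates are individual donors: neighborhood percentages are computed
per image/region, averaged per donor, and only then tested — an unpaired
t-test for condition contrasts (Welch's form by default), a paired t-test
for within-donor tissue contrasts (e.g. small bowel vs colon), and
ordinary least squares for continuous covariates such as BMI. All tests
are two-sided. No multiple-testing correction is applied by default; an
optional Benjamini–Hochberg helper is provided for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateDesignError,
    InsufficientDataError,
    PairingError,
    SchemaError,
)


def build_donor_summaries(
    region_percentages: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    donor_key: str = "donor_id",
) -> pd.DataFrame:
    """Average per-region neighborhood fractions into per-donor percentages.

    ``region_percentages`` is the output of
    :func:`anchordist.neighborhoods.neighborhood_percentages` grouped by
    (donor, region): a fraction table whose index includes ``donor_key``.
    Fractions are averaged over each donor's regions and scaled to percent
    (rows sum to 100 when complete); donor ``metadata`` (condition flags,
    BMI, ...) is joined on the donor id.
    """
    if donor_key not in (region_percentages.index.names or []):
        raise SchemaError(f"region percentages index must include {donor_key!r}")
    donor_means = region_percentages.groupby(level=donor_key).mean() * 100.0
    if metadata is not None:
        meta = metadata.set_index(donor_key) if donor_key in metadata.columns else metadata
        donor_means = donor_means.join(meta, how="left")
    return donor_means


@dataclass
class UnpairedTestResult:
    neighborhood: str
    t: float
    p: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    group_a: object
    group_b: object
    equal_var: bool


@dataclass
class PairedTestResult:
    neighborhood: str
    t: float
    p: float
    mean_diff: float
    n: int
    class_a: object
    class_b: object
    degenerate: bool = False


@dataclass
class RegressionResult:
    neighborhood: str
    slope: float
    intercept: float
    r: float
    p: float
    stderr: float
    n: int


def unpaired_condition_test(
    summaries: pd.DataFrame,
    condition_key: str,
    neighborhood: str,
    equal_var: bool = False,
) -> UnpairedTestResult:
    """Two-sided unpaired t-test of donor-level percentages between the two
    condition groups (Welch's unequal-variance form by default;
    ``equal_var=True`` gives the pooled-variance form)."""
    for col in (condition_key, neighborhood):
        if col not in summaries.columns:
            raise SchemaError(f"donor summaries are missing the {col!r} column")
    values = summaries[[condition_key, neighborhood]].dropna()
    groups = sorted(values[condition_key].unique(), key=str)
    if len(groups) != 2:
        raise SchemaError(
            f"condition {condition_key!r} must have exactly 2 groups, found {groups}"
        )
    a = values.loc[values[condition_key] == groups[0], neighborhood].to_numpy(float)
    b = values.loc[values[condition_key] == groups[1], neighborhood].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each condition group needs at least 2 donors")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # no within-group variation: identical means are a perfect null
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = float(np.sign(a.mean() - b.mean()) * np.inf)
            p = 0.0
    else:
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return UnpairedTestResult(
        neighborhood=neighborhood,
        t=float(t),
        p=float(p),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=len(a),
        n_b=len(b),
        group_a=groups[0],
        group_b=groups[1],
        equal_var=equal_var,
    )


def paired_region_test(
    region_values: pd.DataFrame,
    region_class_key: str,
    neighborhood: str,
    donor_key: str = "donor_id",
    value_key: str | None = None,
) -> PairedTestResult:
    """Two-sided paired t-test between two region classes within donors.

    ``region_values`` holds one row per donor × region with a percentage
    column (``value_key``, default: the ``neighborhood`` name). Values are
    first averaged over each donor's regions within a class, giving one
    pair per donor; permuting region order within a donor therefore cannot
    change the result. Equivalent to a one-sample t-test on the per-donor
    differences. A donor missing one side raises :class:`PairingError`;
    zero-variance nonzero differences are reported as degenerate (p → 0).
    """
    value_key = value_key or neighborhood
    for col in (region_class_key, donor_key, value_key):
        if col not in region_values.columns:
            raise SchemaError(f"region values are missing the {col!r} column")
    classes = sorted(region_values[region_class_key].unique(), key=str)
    if len(classes) != 2:
        raise SchemaError(
            f"region class {region_class_key!r} must have exactly 2 classes, found {classes}"
        )
    means = (
        region_values.groupby([donor_key, region_class_key])[value_key].mean().unstack()
    )
    incomplete = means.index[means.isna().any(axis=1)].tolist()
    if incomplete:
        raise PairingError(f"donor(s) missing one region class: {incomplete}")
    diffs = (means[classes[0]] - means[classes[1]]).to_numpy(float)
    if len(diffs) < 2:
        raise InsufficientDataError("paired test needs at least 2 donors")
    if np.all(diffs == 0):
        t, p, degenerate = 0.0, 1.0, False
    elif diffs.std(ddof=1) == 0:
        t = float(np.sign(diffs.mean()) * np.inf)
        p, degenerate = 0.0, True
    else:
        t, p = sps.ttest_1samp(diffs, 0.0)
        degenerate = False
    return PairedTestResult(
        neighborhood=neighborhood,
        t=float(t),
        p=float(p),
        mean_diff=float(diffs.mean()),
        n=len(diffs),
        class_a=classes[0],
        class_b=classes[1],
        degenerate=degenerate,
    )


def covariate_regression(
    summaries: pd.DataFrame,
    covariate_key: str,
    neighborhood: str,
) -> RegressionResult:
    """OLS of donor-mean neighborhood percentage on a continuous covariate
    (e.g. BMI); returns slope, intercept, Pearson r, and the two-sided p
    for the slope."""
    for col in (covariate_key, neighborhood):
        if col not in summaries.columns:
            raise SchemaError(f"donor summaries are missing the {col!r} column")
    values = summaries[[covariate_key, neighborhood]].dropna()
    if len(values) < 3:
        raise InsufficientDataError("regression needs at least 3 donors with the covariate")
    x = values[covariate_key].to_numpy(float)
    y = values[neighborhood].to_numpy(float)
    if np.all(x == x[0]):
        raise DegenerateDesignError(f"covariate {covariate_key!r} is constant")
    fit = sps.linregress(x, y)
    return RegressionResult(
        neighborhood=neighborhood,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p=float(fit.pvalue),
        stderr=float(fit.stderr),
        n=len(values),
    )


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional transparency column;
    not applied to any test by default)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]
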