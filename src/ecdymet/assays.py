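"""Bench-assay arithmetic: ddCt qPCR quantification, densitometry
normalisation, percent-of-control scaling and two-group significance tests.

The two-group test selection mirrors common wet-lab practice for these
designs: Student's pooled-variance t-test for triplicate experiments,
the Mann-Whitney U-test for five-replicate extracellular-flux runs.
Significance labels follow the conventional cutoffs
(* p < 0.05, ** p < 0.01, *** p < 0.001, else ns).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seahorse import mann_whitney

logger = logging.getLogger(__name__)

LABEL_NS = "ns"


def significance_label(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return LABEL_NS


@dataclass(frozen=True)
class TwoGroupResult:
    test_name: str  # "student_t" | "mann_whitney"
    statistic: float
    pvalue: float
    n1: int
    n2: int

    @property
    def significance_label(self) -> str:
        return significance_label(self.pvalue)


def ddct_expression(
    table: pd.DataFrame,
    reference_gene: str,
    control_group: str = "control",
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    ``table`` has columns sample, group, gene, ct; technical-replicate Ct
    values are averaged per (sample, gene) first. Per sample,
    dCt = Ct(target) - Ct(reference); per gene, ddCt subtracts the
    arithmetic mean control-group dCt, and relative expression is 2^-ddCt,
    so the control group's geometric-mean expression is 1 by construction.
    """
    required = {"sample", "group", "gene", "ct"}
    if not required.issubset(table.columns):
        raise ValueError(f"qPCR table needs columns {sorted(required)}")
    ct_out = table[(table["ct"] < 5) | (table["ct"] > 40)]
    if len(ct_out):
        logger.warning("%d Ct value(s) outside the typical 5-40 cycle range", len(ct_out))
    mean_ct = (
        table.groupby(["sample", "group", "gene"], sort=False)["ct"].mean().reset_index()
    )
    ref = mean_ct[mean_ct["gene"] == reference_gene].set_index("sample")["ct"]
    targets = mean_ct[mean_ct["gene"] != reference_gene].copy()
    missing_ref = sorted(set(targets["sample"]) - set(ref.index))
    if missing_ref:
        raise ValueError(f"reference gene {reference_gene!r} missing for sample(s): {missing_ref}")
    if not (table["group"] == control_group).any():
        raise ValueError(f"control group {control_group!r} is empty")
    targets["delta_ct"] = targets["ct"].to_numpy() - ref.loc[targets["sample"]].to_numpy()
    control_mean_dct = (
        targets[targets["group"] == control_group].groupby("gene")["delta_ct"].mean()
    )
    targets["ddct"] = targets["delta_ct"] - control_mean_dct.loc[targets["gene"]].to_numpy()
    targets["rel_expr"] = 2.0 ** (-targets["ddct"])
    return targets[["sample", "group", "gene", "delta_ct", "ddct", "rel_expr"]].reset_index(
        drop=True
    )


def densitometry_normalize(
    table: pd.DataFrame,
    control_group: str = "control",
    rescale: bool = True,
) -> pd.DataFrame:
    """Loading-control normalisation of band intensities.

    ``table`` has columns sample, group, band, loading. The protein/loading
    ratio is computed per sample and (by default) divided by the
    control-group mean ratio so the control averages 1.
    """
    required = {"sample", "group", "band", "loading"}
    if not required.issubset(table.columns):
        raise ValueError(f"densitometry table needs columns {sorted(required)}")
    loading = table["loading"].to_numpy(dtype=float)
    if np.any(loading <= 0):
        raise ValueError("loading-control values must be strictly positive")
    out = table.copy()
    out["ratio"] = out["band"].to_numpy(dtype=float) / loading
    if rescale:
        ctrl = out[out["group"] == control_group]
        if ctrl.empty:
            raise ValueError(f"control group {control_group!r} is empty")
        out["ratio"] = out["ratio"] / ctrl["ratio"].mean()
    return out


def group_mean_sem(table: pd.DataFrame, value_col: str = "ratio") -> pd.DataFrame:
    """Per-group mean and SEM of a value column."""
    g = table.groupby("group", sort=True)[value_col]
    return pd.DataFrame(
        {"mean": g.mean(), "sem": g.std(ddof=1) / np.sqrt(g.count()), "n": g.count()}
    ).reset_index()


def percent_of_control(table: pd.DataFrame, control_group: str = "control") -> pd.DataFrame:
    """Express assay values as a percentage of the control-group mean."""
    required = {"sample", "group", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"assay table needs columns {sorted(required)}")
    ctrl = table[table["group"] == control_group]
    if ctrl.empty:
        raise ValueError(f"control group {control_group!r} is empty")
    ctrl_mean = ctrl["value"].mean()
    if ctrl_mean <= 0:
        raise ValueError("control mean must be positive")
    out = table.copy()
    out["percent_of_control"] = out["value"].to_numpy(dtype=float) / ctrl_mean * 100.0
    return out


def two_group_test(a, b, kind: str = "auto") -> TwoGroupResult:
    """Two-sided two-group test with N-based automatic selection.

    ``auto`` picks Student's pooled-variance t when min(n1, n2) <= 3, the
    Mann-Whitney U-test when min >= 5, and falls back to Student's t for
    n = 4 (logged). Zero pooled variance is resolved by convention: p = 1
    when the means are equal, p = 0 otherwise (both logged).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if min(n1, n2) < 2:
        raise ValueError("need >= 2 observations per group")
    if kind == "auto":
        n_min = min(n1, n2)
        if n_min <= 3:
            kind = "student_t"
        elif n_min >= 5:
            kind = "mann_whitney"
        else:
            logger.info("min group size 4: defaulting to Student's t-test")
            kind = "student_t"
    if kind == "student_t":
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            if a.mean() == b.mean():
                logger.warning("zero pooled variance with equal means: p = 1 by convention")
                return TwoGroupResult("student_t", 0.0, 1.0, n1, n2)
            logger.warning("zero pooled variance with unequal means: p = 0 by convention")
            stat = math.inf if a.mean() > b.mean() else -math.inf
            return TwoGroupResult("student_t", stat, 0.0, n1, n2)
        res = stats.ttest_ind(a, b, equal_var=True)
        return TwoGroupResult("student_t", float(res.statistic), float(res.pvalue), n1, n2)
    if kind == "mann_whitney":
        u, p = mann_whitney(a, b)
        return TwoGroupResult("mann_whitney", u, p, n1, n2)
    raise ValueError(f"unknown test kind {kind!r}")
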