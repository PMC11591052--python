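"""Transcript-length bias diagnosis and correction for log2 fold changes.

Bulk RNA-seq fold-change estimates can acquire a spurious dependence on
transcript length (classically via 3'-coverage-bias differences between
comparison groups). This module diagnoses the trend by regressing per-gene
log2 fold change (LogFC) on log2 transcript length (LogTL), removes it by
subtracting the fitted line, and then reconciles the initial and corrected
fold changes conservatively: the value of smaller magnitude wins, and a
sign disagreement zeroes the gene. Significance (p/FDR) is never
recomputed - the correction touches effect size only, while p-values derive
from the counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CALL_UP = "up"
CALL_DOWN = "down"
CALL_NS = "not_significant"


class DegenerateRegressionError(ValueError):
    """All transcript lengths identical; the slope is unidentifiable."""


@dataclass(frozen=True)
class CorrectionModel:
    """OLS fit of LogFC on LogTL with rank/linear correlation diagnostics.

    slope is in log2-fold-change units per log2 bp; ``n_genes`` counts the
    genes actually used in the fit and ``n_missing_length`` those excluded
    for missing/invalid length or non-finite LogFC.
    """

    slope: float
    intercept: float
    spearman_rho: float
    pearson_r: float
    n_genes: int
    n_missing_length: int = 0

    def predict(self, logtl: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(logtl, dtype=float)


def _safe_corr(func, x: np.ndarray, y: np.ndarray) -> float:
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("constant input to correlation; returning rho = 0")
        return 0.0
    return float(func(x, y)[0])


def _merge(de: pd.DataFrame, meta: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    meta = meta.set_index("gene_id") if "gene_id" in meta.columns else meta
    lengths = meta["transcript_length_bp"].reindex(de.index)
    df = pd.DataFrame(
        {"logfc": de["logfc"], "length": lengths.to_numpy(dtype=float)},
        index=de.index,
    )
    ok = np.isfinite(df["logfc"]) & np.isfinite(df["length"]) & (df["length"] > 0)
    return df[ok], int((~ok).sum())


def fit_correction(de: pd.DataFrame, meta: pd.DataFrame) -> CorrectionModel:
    """Fit the LogFC ~ LogTL trend line.

    Ordinary least squares with intercept on all genes with finite LogFC and
    positive transcript length; Spearman's rho uses average ranks for ties.
    """
    df, n_missing = _merge(de, meta)
    if len(df) < 3:
        raise ValueError(f"need >= 3 usable genes, got {len(df)}")
    logtl = np.log2(df["length"].to_numpy())
    lfc = df["logfc"].to_numpy(dtype=float)
    if np.all(logtl == logtl[0]):
        raise DegenerateRegressionError("all transcript lengths identical")
    # centred fit for conditioning; slope unchanged, intercept recovered exactly
    xc = logtl - logtl.mean()
    slope = float(xc @ (lfc - lfc.mean()) / (xc @ xc))
    intercept = float(lfc.mean() - slope * logtl.mean())
    return CorrectionModel(
        slope=slope,
        intercept=intercept,
        spearman_rho=_safe_corr(stats.spearmanr, logtl, lfc),
        pearson_r=_safe_corr(stats.pearsonr, logtl, lfc),
        n_genes=len(df),
        n_missing_length=n_missing,
    )


def reconcile_logfc(initial: float, corrected: float) -> float:
    """Conservative reconciliation of initial and length-corrected LogFC.

    Returns the input of smaller magnitude when both share a strict sign;
    returns 0 when the signs differ, when exactly one value is 0, or when
    both are 0.
    """
    if not (math.isfinite(initial) and math.isfinite(corrected)):
        raise ValueError("reconcile_logfc requires finite inputs")
    if initial == 0.0 or corrected == 0.0 or (initial > 0) != (corrected > 0):
        return 0.0
    return initial if abs(initial) <= abs(corrected) else corrected


def _reconcile_vec(initial: np.ndarray, corrected: np.ndarray) -> np.ndarray:
    agree = (np.sign(initial) == np.sign(corrected)) & (initial != 0)
    minabs = np.where(np.abs(initial) <= np.abs(corrected), initial, corrected)
    return np.where(agree, minabs, 0.0)


def correct_table(
    de: pd.DataFrame,
    meta: pd.DataFrame,
    fdr_threshold: float = 0.05,
    logfc_threshold: float = 0.1,
) -> tuple[pd.DataFrame, CorrectionModel]:
    """Apply the length-bias correction and call DE genes.

    corrected = initial - (intercept + slope * LogTL); the final LogFC is the
    min-abs/sign-flip reconciliation of initial and corrected. A gene is
    called ``up`` when fdr <= fdr_threshold and final >= logfc_threshold,
    ``down`` symmetrically, else ``not_significant``. FDR values pass through
    unchanged.
    """
    if not 0.0 < fdr_threshold <= 1.0:
        raise ValueError("fdr_threshold must be in (0, 1]")
    if logfc_threshold <= 0:
        raise ValueError("logfc_threshold must be positive")
    df, _ = _merge(de, meta)
    if len(df) < 3:
        raise ValueError("de table and gene metadata share fewer than 3 genes")
    model = fit_correction(de, meta)
    logtl = np.log2(df["length"].to_numpy())
    initial = df["logfc"].to_numpy(dtype=float)
    corrected = initial - model.predict(logtl)
    final = _reconcile_vec(initial, corrected)
    fdr = de["fdr"].reindex(df.index).to_numpy(dtype=float)
    call = np.full(len(df), CALL_NS, dtype=object)
    sig = fdr <= fdr_threshold
    call[sig & (final >= logfc_threshold)] = CALL_UP
    call[sig & (final <= -logfc_threshold)] = CALL_DOWN
    out = pd.DataFrame(
        {
            "initial_logfc": initial,
            "corrected_logfc": corrected,
            "final_logfc": final,
            "fdr": fdr,
            "call": call,
        },
        index=df.index,
    )
    out.index.name = "gene_id"
    return out, model


def model_summary(model: CorrectionModel) -> str:
    """Human-readable one-block summary of a fitted correction model."""
    return (
        "LogFC ~ LogTL correction model\n"
        f"  slope      {model.slope:+.6f} log2FC per log2 bp\n"
        f"  intercept  {model.intercept:+.6f} log2FC\n"
        f"  spearman   {model.spearman_rho:+.4f}\n"
        f"  pearson    {model.pearson_r:+.4f}\n"
        f"  n_genes    {model.n_genes}"
        + (
            f"\n  excluded   {model.n_missing_length} (missing length / non-finite)"
            if model.n_missing_length
            else ""
        )
    )
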