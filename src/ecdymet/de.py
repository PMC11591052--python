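"""Minimal two-group negative-binomial differential-expression engine.

Implements the classic exact-test pipeline for bulk RNA-seq counts:
median-of-ratios size factors, method-of-moments dispersion with shrinkage
toward a common value, a conditional NB exact test, prior-stabilised log2
fold changes, and Benjamini-Hochberg FDR.

The exact test conditions on the per-gene total of library-size-equalised
pseudo-counts. When every replicate shares the same mean and dispersion,
the group sum of ``n`` NB(mu, phi) draws is NB(n*mu, phi/n), and the
conditional distribution of one group's sum given the total is negative
hypergeometric - free of the unknown mean, so no nuisance parameter needs
to be profiled out. In the Poisson limit (phi = 0) it reduces to the exact
binomial split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import binom, trim_mean
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CONTROL = "control"
TREATED = "treated"


class NormalizationError(ValueError):
    """No gene is expressed in every sample; size factors are undefined."""


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with a two-group design.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, genes as rows (index = gene ids),
        samples as columns.
    groups
        Series mapping sample id -> ``"control"`` or ``"treated"``.
    """

    counts: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        missing = [s for s in self.counts.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group assignment: {missing}")
        self.groups = self.groups.loc[self.counts.columns]
        bad = set(self.groups.unique()) - {CONTROL, TREATED}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for g in (CONTROL, TREATED):
            if (self.groups == g).sum() == 0:
                raise ValueError(f"group {g!r} has no samples")
        vals = self.counts.to_numpy()
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be non-negative integers")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_in(self, group: str) -> pd.Index:
        return self.groups.index[self.groups == group]


@dataclass
class DispersionEstimate:
    """Per-gene NB dispersions with the common value they are shrunk toward."""

    per_gene: pd.Series
    common: float
    raw: pd.Series = field(repr=False)


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample, the factor is the median over genes (with a positive
    geometric mean across samples, i.e. expressed everywhere) of the ratio
    of that sample's count to the gene's geometric mean.
    """
    counts = cm.counts.to_numpy(dtype=float)
    expressed = np.all(counts > 0, axis=1)
    if not expressed.any():
        raise NormalizationError("no gene has positive counts in every sample")
    logc = np.log(counts[expressed])
    log_geomean = logc.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logc - log_geomean, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.sample_ids, name="size_factor")


def estimate_dispersion(
    cm: CountMatrix,
    factors: pd.Series,
    shrink_weight: float = 0.7,
    trim: float = 0.1,
) -> DispersionEstimate:
    """Method-of-moments NB dispersion per gene, shrunk toward a common value.

    The raw per-gene estimate is ``max(0, (s^2 - mu) / mu^2)`` on normalised
    counts, where the sample variance is computed from residuals about each
    group's own mean (so a true expression difference does not inflate the
    estimate) with ``n - 2`` denominator, and ``mu`` is the grand mean.
    The common dispersion is a trimmed mean of raw estimates over genes with
    positive mean; the returned per-gene value is
    ``shrink_weight * common + (1 - shrink_weight) * raw``.
    """
    if not 0.0 <= shrink_weight <= 1.0:
        raise ValueError("shrink_weight must be in [0, 1]")
    for g in (CONTROL, TREATED):
        if len(cm.samples_in(g)) < 2:
            raise ValueError(f"need >= 2 replicates in group {g!r}")
    norm = cm.counts.to_numpy(dtype=float) / factors.loc[cm.sample_ids].to_numpy()
    n_samples = norm.shape[1]
    resid = np.empty_like(norm)
    for g in (CONTROL, TREATED):
        cols = cm.groups.to_numpy() == g
        resid[:, cols] = norm[:, cols] - norm[:, cols].mean(axis=1, keepdims=True)
    s2 = (resid**2).sum(axis=1) / (n_samples - 2)
    mu = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, np.maximum(0.0, (s2 - mu) / mu**2), 0.0)
    usable = raw[mu > 0]
    common = float(trim_mean(usable, trim)) if usable.size else 0.0
    per_gene = shrink_weight * common + (1.0 - shrink_weight) * raw
    idx = cm.gene_ids
    return DispersionEstimate(
        per_gene=pd.Series(per_gene, index=idx, name="dispersion"),
        common=common,
        raw=pd.Series(raw, index=idx, name="dispersion_raw"),
    )


def _conditional_two_sided_p(a: int, s: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact p for observing group-A sum ``a`` of total ``s``.

    Conditional on the total, the group-A sum follows a negative
    hypergeometric law with sizes ``n_a/phi`` and ``n_b/phi`` (binomial when
    phi = 0). The two-sided p doubles the smaller tail (observed point
    included once per tail) and is capped at 1.
    """
    if s == 0:
        return 1.0
    if phi <= 1e-12:
        p_lo = float(binom.cdf(a, s, n_a / (n_a + n_b)))
        p_hi = float(binom.sf(a - 1, s, n_a / (n_a + n_b)))
    else:
        r_a = n_a / phi
        r_b = n_b / phi
        k = np.arange(s + 1)
        logw = (
            gammaln(k + r_a)
            - gammaln(k + 1)
            + gammaln(s - k + r_b)
            - gammaln(s - k + 1)
        )
        logp = logw - logsumexp(logw)
        p = np.exp(logp)
        p_lo = float(p[: a + 1].sum())
        p_hi = float(p[a:].sum())
    return min(1.0, 2.0 * min(p_lo, p_hi))


def nb_exact_test(
    cm: CountMatrix,
    factors: pd.Series,
    dispersion: float | pd.Series | np.ndarray,
) -> pd.Series:
    """Conditional NB exact test p-value per gene.

    Counts are first equalised to a common effective library size by dividing
    by the size factors (whose geometric mean is 1) and rounding to the
    nearest integer; the test then compares the treated-group sum of these
    pseudo-counts against its conditional null distribution given the total.
    """
    disp = np.asarray(
        dispersion.loc[cm.gene_ids] if isinstance(dispersion, pd.Series) else dispersion,
        dtype=float,
    )
    disp = np.broadcast_to(disp, (len(cm.gene_ids),)).copy()
    if np.any(disp < 0):
        raise ValueError("dispersion must be non-negative")
    pseudo = np.rint(
        cm.counts.to_numpy(dtype=float) / factors.loc[cm.sample_ids].to_numpy()
    ).astype(np.int64)
    treated_cols = (cm.groups == TREATED).to_numpy()
    n_t = int(treated_cols.sum())
    n_c = int((~treated_cols).sum())
    sum_t = pseudo[:, treated_cols].sum(axis=1)
    total = pseudo.sum(axis=1)
    pvals = np.ones(len(cm.gene_ids))
    for i in range(len(pvals)):
        pvals[i] = _conditional_two_sided_p(
            int(sum_t[i]), int(total[i]), n_t, n_c, float(disp[i])
        )
    return pd.Series(pvals, index=cm.gene_ids, name="pvalue")


def estimate_logfc(
    cm: CountMatrix, factors: pd.Series, prior_count: float = 0.5
) -> pd.Series:
    """Per-gene log2 fold change, treated over control, with a prior count.

    ``log2((mean normalised treated + prior) / (mean normalised control +
    prior))``. When both group means and the prior are all zero the fold
    change is undefined; 0 is returned and a warning logged.
    """
    if prior_count < 0:
        raise ValueError("prior_count must be >= 0")
    norm = cm.counts.to_numpy(dtype=float) / factors.loc[cm.sample_ids].to_numpy()
    treated_cols = (cm.groups == TREATED).to_numpy()
    mean_t = norm[:, treated_cols].mean(axis=1)
    mean_c = norm[:, ~treated_cols].mean(axis=1)
    undefined = (mean_t + prior_count == 0) & (mean_c + prior_count == 0)
    if undefined.any():
        logger.warning(
            "log fold change undefined (all-zero means, zero prior) for %d genes; "
            "reporting 0",
            int(undefined.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(mean_t + prior_count) - np.log2(mean_c + prior_count)
    lfc[undefined] = 0.0
    return pd.Series(lfc, index=cm.gene_ids, name="logfc")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def run_de(cm: CountMatrix, prior_count: float = 0.5) -> pd.DataFrame:
    """Full two-group DE analysis.

    Returns a DataFrame indexed by gene id with columns ``logfc``,
    ``pvalue``, ``fdr`` and ``mean_norm_count``.
    """
    factors = size_factors(cm)
    disp = estimate_dispersion(cm, factors)
    pvals = nb_exact_test(cm, factors, disp.per_gene)
    lfc = estimate_logfc(cm, factors, prior_count)
    norm = cm.counts.to_numpy(dtype=float) / factors.to_numpy()
    table = pd.DataFrame(
        {
            "logfc": lfc,
            "pvalue": pvals,
            "fdr": bh_adjust(pvals.to_numpy()),
            "mean_norm_count": norm.mean(axis=1),
        },
        index=cm.gene_ids,
    )
    table.index.name = "gene_id"
    return table


def read_counts(counts_path, samples_path) -> CountMatrix:
    """Read a CountMatrix from a counts TSV and a sample-sheet TSV.

    The counts TSV has gene ids in the first column and sample ids in the
    header; the sample sheet has columns ``sample_id`` and ``group``.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = pd.read_csv(samples_path, sep="\t")
    groups = pd.Series(
        sheet["group"].to_numpy(), index=sheet["sample_id"].to_numpy(), name="group"
    )
    return CountMatrix(counts=counts, groups=groups)


def write_de_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")
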