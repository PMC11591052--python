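"""Extracellular-flux (Seahorse-style) ATP-rate decomposition.

A real-time ATP rate assay measures oxygen consumption rate (OCR,
pmol O2/min) and extracellular acidification rate (ECAR, mpH/min) across
three phases: basal, after oligomycin (ATP-synthase inhibitor, isolating
ATP-linked respiration) and after Rotenone/Antimycin A (Complex I/III
inhibitors, leaving non-mitochondrial OCR). From these:

* mitoATP = (OCR_basal - OCR_oligo) * 2 * P/O, with P/O the pmol of ATP per
  pmol of atomic oxygen (vendor default 2.75) and 2 oxygen atoms per O2;
* the basal proton efflux rate PER = ECAR * buffer_factor * volume * Kvol;
* the mitochondrial share of acidification is (OCR_basal - OCR_rotaa) * CCF
  (CO2 contribution factor, vendor default 0.61);
* glycoATP = PER - mitoPER, and totalATP = mitoATP + glycoATP.

Negative intermediate rates (possible under noise) are clamped to 0 with a
logged warning.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PHASES = ("basal", "post_oligomycin", "post_rotaa")
TRACE_COLUMNS = ["well", "group", "phase", "time_min", "ocr_pmol_per_min", "ecar_mpH_per_min"]


class TraceFormatError(ValueError):
    """Trace table violates the well/phase/time contract."""


@dataclass(frozen=True)
class ATPRateConstants:
    """Conversion constants of the ATP-rate arithmetic.

    Defaults keep ``buffer_factor * chamber_volume_ul * kvol = 1`` so that
    PER equals ECAR numerically; real plates substitute the instrument's
    calibrated values (e.g. buffer factor in mmol H+/L/pH and the microplate
    chamber volume in uL).
    """

    po_ratio: float = 2.75
    o_per_o2: float = 2.0
    ccf: float = 0.61
    buffer_factor: float = 1.0
    chamber_volume_ul: float = 1.0
    kvol: float = 1.0

    def __post_init__(self) -> None:
        for name in ("po_ratio", "o_per_o2", "ccf", "buffer_factor", "chamber_volume_ul", "kvol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def validate_traces(traces: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonically sort a trace table.

    Checks the column set, that every well has at least one measurement in
    each of the three phases in basal -> post-oligomycin -> post-Rot/AA
    order, that time is strictly increasing within each well, and that
    OCR/ECAR are finite. Returns the table sorted by (well, time).
    """
    missing_cols = [c for c in TRACE_COLUMNS if c not in traces.columns]
    if missing_cols:
        raise TraceFormatError(f"missing columns: {missing_cols}")
    bad_phase = set(traces["phase"].unique()) - set(PHASES)
    if bad_phase:
        raise TraceFormatError(f"unknown phases: {sorted(bad_phase)}")
    if not np.isfinite(traces[["time_min", "ocr_pmol_per_min", "ecar_mpH_per_min"]].to_numpy()).all():
        raise TraceFormatError("non-finite time/OCR/ECAR values")
    traces = traces.sort_values(["well", "time_min"], kind="mergesort").reset_index(drop=True)
    phase_rank = {p: i for i, p in enumerate(PHASES)}
    for well, sub in traces.groupby("well", sort=False):
        t = sub["time_min"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise TraceFormatError(f"time not strictly increasing within well {well}")
        present = set(sub["phase"])
        lacking = [p for p in PHASES if p not in present]
        if lacking:
            raise TraceFormatError(f"well {well} is missing phase(s): {lacking}")
        ranks = sub["phase"].map(phase_rank).to_numpy()
        if np.any(np.diff(ranks) < 0):
            raise TraceFormatError(f"phases out of order within well {well}")
    return traces


def read_traces(path) -> pd.DataFrame:
    """Read and validate a trace CSV (columns as in ``TRACE_COLUMNS``)."""
    return validate_traces(pd.read_csv(path, float_precision="round_trip"))


def write_traces(traces: pd.DataFrame, path) -> None:
    # %.17g uniquely identifies a double, so write(read(f)) is idempotent
    traces.to_csv(path, index=False, columns=TRACE_COLUMNS, float_format="%.17g")


def phase_rates(traces: pd.DataFrame, statistic: str = "vendor") -> pd.DataFrame:
    """Per-well phase summary rates.

    With the default ``vendor`` statistic: basal OCR/ECAR are the last basal
    reading (cells fully equilibrated), while post-injection OCRs take the
    phase minimum (deepest inhibition). ``statistic="mean"`` averages each
    phase instead.
    """
    if statistic not in ("vendor", "mean"):
        raise ValueError("statistic must be 'vendor' or 'mean'")
    traces = validate_traces(traces)
    rows = []
    for well, sub in traces.groupby("well", sort=True):
        basal = sub[sub["phase"] == "basal"]
        oligo = sub[sub["phase"] == "post_oligomycin"]
        rotaa = sub[sub["phase"] == "post_rotaa"]
        if statistic == "vendor":
            ocr_basal = basal["ocr_pmol_per_min"].iloc[-1]
            ecar_basal = basal["ecar_mpH_per_min"].iloc[-1]
            ocr_oligo = oligo["ocr_pmol_per_min"].min()
            ocr_rotaa = rotaa["ocr_pmol_per_min"].min()
        else:
            ocr_basal = basal["ocr_pmol_per_min"].mean()
            ecar_basal = basal["ecar_mpH_per_min"].mean()
            ocr_oligo = oligo["ocr_pmol_per_min"].mean()
            ocr_rotaa = rotaa["ocr_pmol_per_min"].mean()
        rows.append(
            {
                "well": well,
                "group": sub["group"].iloc[0],
                "ocr_basal": float(ocr_basal),
                "ocr_oligo": float(ocr_oligo),
                "ocr_rotaa": float(ocr_rotaa),
                "ecar_basal": float(ecar_basal),
            }
        )
    return pd.DataFrame(rows)


def atp_rates(rates: pd.DataFrame, constants: ATPRateConstants | None = None) -> pd.DataFrame:
    """Decompose per-well phase rates into mito/glyco/total ATP production."""
    constants = constants or ATPRateConstants()
    out = rates.copy()
    atp_linked_ocr = out["ocr_basal"] - out["ocr_oligo"]
    mito_ocr = out["ocr_basal"] - out["ocr_rotaa"]
    n_clamped = int((atp_linked_ocr < 0).sum() + (mito_ocr < 0).sum())
    if n_clamped:
        logger.warning("clamped %d negative intermediate OCR difference(s) to 0", n_clamped)
    atp_linked_ocr = atp_linked_ocr.clip(lower=0.0)
    mito_ocr = mito_ocr.clip(lower=0.0)
    out["mito_atp"] = atp_linked_ocr * constants.o_per_o2 * constants.po_ratio
    per_basal = (
        out["ecar_basal"] * constants.buffer_factor * constants.chamber_volume_ul * constants.kvol
    )
    mito_per = mito_ocr * constants.ccf
    glyco = per_basal - mito_per
    n_glyco_clamped = int((glyco < 0).sum())
    if n_glyco_clamped:
        logger.warning("clamped %d negative glycolytic ATP rate(s) to 0", n_glyco_clamped)
    out["glyco_atp"] = glyco.clip(lower=0.0)
    out["total_atp"] = out["mito_atp"] + out["glyco_atp"]
    return out


def _u_statistic(pooled_ranks: np.ndarray, idx_a, n_a: int) -> float:
    # U for group A from midranks: U = R_A - n_a(n_a+1)/2
    return float(pooled_ranks[list(idx_a)].sum() - n_a * (n_a + 1) / 2)


def mann_whitney_exact(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U test by full enumeration.

    Computes U for sample ``a`` from midranks of the pooled data and
    enumerates all C(n1+n2, n1) assignments of the pooled values to group A.
    The two-sided p doubles the smaller tail mass (observed U included) and
    is capped at 1. Midranks make the enumeration valid under ties.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a < 2 or n_b < 2:
        raise ValueError("need >= 2 observations per group")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = _u_statistic(ranks, range(n_a), n_a)
    us = np.array(
        [_u_statistic(ranks, idx, n_a) for idx in itertools.combinations(range(n_a + n_b), n_a)]
    )
    eps = 1e-9
    p_lo = float(np.mean(us <= u_obs + eps))
    p_hi = float(np.mean(us >= u_obs - eps))
    return u_obs, min(1.0, 2.0 * min(p_lo, p_hi))


def mann_whitney(a, b, exact_max: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact enumeration for small samples.

    Enumeration when ``min(n1, n2) <= exact_max``; otherwise the normal
    approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if min(len(a), len(b)) <= exact_max:
        return mann_whitney_exact(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def summarize_groups(
    results: pd.DataFrame,
    control_group: str,
    metrics: tuple[str, ...] = ("mito_atp", "glyco_atp", "total_atp"),
) -> pd.DataFrame:
    """Per-group mean +/- SEM, fold over control and Mann-Whitney p vs control.

    The control group's own p-value is reported as NaN. SEM uses the
    unbiased (n-1) standard deviation.
    """
    if control_group not in set(results["group"]):
        raise ValueError(f"unknown control group {control_group!r}")
    ctrl = results[results["group"] == control_group]
    if len(ctrl) < 2:
        raise ValueError("control group needs >= 2 wells")
    rows = []
    for group, sub in results.groupby("group", sort=True):
        for metric in metrics:
            vals = sub[metric].to_numpy(dtype=float)
            ctrl_vals = ctrl[metric].to_numpy(dtype=float)
            mean = float(vals.mean())
            sem = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else float("nan")
            fold = mean / ctrl_vals.mean() if ctrl_vals.mean() != 0 else float("nan")
            if group == control_group:
                pval = float("nan")
            else:
                _, pval = mann_whitney(vals, ctrl_vals)
            rows.append(
                {
                    "group": group,
                    "metric": metric,
                    "n_wells": len(vals),
                    "mean": mean,
                    "sem": sem,
                    "fold_vs_control": fold,
                    "mw_pvalue": pval,
                }
            )
    return pd.DataFrame(rows)
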