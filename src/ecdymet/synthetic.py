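"""Seeded synthetic data with the structure the analysis stages assume.

Three generators:

* ``simulate_counts`` - bulk RNA-seq gene counts for a two-group design
  (negative binomial, six biological replicates per group by default) with
  a minority of true DE genes, more up- than down-regulated, and an
  optional transcript-length-coupled artifact added to every gene's log2
  fold change. The artifact can be given directly as a slope (log2FC per
  log2 bp) or calibrated by root-finding so that the realised Spearman
  correlation between log2 transcript length and the count-estimated log2
  fold change hits a target (default -0.42).
* ``simulate_seahorse`` - three-phase OCR/ECAR well traces
  (basal -> post-oligomycin -> post-Rotenone/Antimycin A) with five
  replicate wells per group by default and multiplicative log-normal noise.
* ``simulate_assays`` - triplicate-style assay values with multiplicative
  noise around group means.

All generators are bit-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from . import de as de_mod
from .seahorse import PHASES, TRACE_COLUMNS

_LN2 = float(np.log(2.0))

# post-injection ECAR response relative to basal: glycolysis compensates after
# oligomycin and partially persists after Rot/AA
ECAR_PHASE_MULTIPLIERS = (1.0, 1.35, 1.25)
MEASUREMENT_INTERVAL_MIN = 6.5


class ConfigurationError(ValueError):
    """Simulation configuration violates its invariants."""


class CalibrationError(ValueError):
    """Spearman-target calibration impossible for this configuration."""


@dataclass(frozen=True)
class SimCountsConfig:
    """Configuration of the bulk RNA-seq count simulator.

    Exactly one of ``artifact_slope`` (log2FC per log2 bp) and
    ``target_spearman`` must be set. Defaults emulate a 6 vs 6 design with
    ~6% up- and ~4.5% down-regulated genes (up-dominant), NB dispersion
    0.05, baseline means log10-uniform over 10-1000 counts, and transcript
    lengths log2-uniform over 512 bp - 16 kb.
    """

    n_genes: int
    n_replicates_per_group: int = 6
    frac_up: float = 0.06
    frac_down: float = 0.045
    effect_logfc_scale: float = 1.0
    baseline_mean_log_range: tuple[float, float] = (1.0, 3.0)
    dispersion: float = 0.05
    length_log2_range: tuple[float, float] = (9.0, 14.0)
    artifact_slope: float | None = None
    target_spearman: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_replicates_per_group < 1:
            raise ConfigurationError("n_genes and n_replicates_per_group must be positive")
        if not (0 <= self.frac_up <= 1 and 0 <= self.frac_down <= 1):
            raise ConfigurationError("frac_up/frac_down must lie in [0, 1]")
        if self.frac_up + self.frac_down > 1:
            raise ConfigurationError("frac_up + frac_down must be <= 1")
        if self.effect_logfc_scale <= 0:
            raise ConfigurationError("effect_logfc_scale must be positive")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be non-negative")
        for name in ("baseline_mean_log_range", "length_log2_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name} must be ordered low <= high")
        n_set = (self.artifact_slope is not None) + (self.target_spearman is not None)
        if n_set != 1:
            raise ConfigurationError(
                "exactly one of artifact_slope and target_spearman must be set"
            )
        if self.target_spearman is not None:
            if not -1.0 <= self.target_spearman <= 1.0:
                raise ConfigurationError("target_spearman must lie in [-1, 1]")
            if self.n_genes < 10:
                raise CalibrationError("target_spearman calibration needs >= 10 genes")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one count simulation.

    ``table`` holds per-gene true_logfc, is_de and the injected length
    artifact component; ``realized_spearman`` is the Spearman correlation of
    log2 transcript length with the log2 fold change estimated back from the
    generated counts, and ``artifact_slope`` the slope actually injected
    (equal to the configured one, or the calibrated one under a target).
    """

    table: pd.DataFrame
    realized_spearman: float
    artifact_slope: float


def _logfc_noise_sd(baseline: np.ndarray, phi: float, n_rep: int) -> np.ndarray:
    # delta-method sd of the count-estimated log2 fold change:
    # var(log mean) ~ (1/mu + phi)/n per group, two independent groups
    var_log = 2.0 * (1.0 / baseline + phi) / n_rep
    return np.sqrt(var_log) / _LN2


def _calibrate_slope(
    target: float,
    logtl: np.ndarray,
    true_logfc: np.ndarray,
    baseline: np.ndarray,
    phi: float,
    n_rep: int,
    rng: np.random.Generator,
) -> float:
    """Root-find the artifact slope whose pilot realised Spearman hits target.

    The pilot replaces the full count simulation with the delta-method
    normal approximation of log fold-change noise; the same pilot noise
    draws are reused across candidate slopes so the objective is smooth and
    monotone in the slope.
    """
    n_pilot = 3
    noise = rng.normal(size=(n_pilot, logtl.size)) * _logfc_noise_sd(baseline, phi, n_rep)
    centred = logtl - logtl.mean()

    def realised(slope: float) -> float:
        rhos = [
            stats.spearmanr(logtl, true_logfc + slope * centred + noise[i]).statistic
            for i in range(n_pilot)
        ]
        return float(np.mean(rhos))

    if target == 0.0:
        return 0.0
    lo, hi = -4.0, 4.0
    if not realised(lo) <= target <= realised(hi):
        raise CalibrationError(f"target Spearman {target} unreachable for this configuration")
    return float(brentq(lambda s: realised(s) - target, lo, hi, xtol=1e-4))


def simulate_counts(
    config: SimCountsConfig,
) -> tuple[de_mod.CountMatrix, pd.DataFrame, SimTruth]:
    """Simulate a two-group NB count matrix with a length-coupled artifact.

    Returns the count matrix, a gene metadata table (gene_id,
    transcript_length_bp) and the simulation ground truth. True DE effect
    magnitudes are ``effect_logfc_scale`` times a LogNormal(0, 0.25) draw;
    the artifact adds ``slope * (LogTL - mean LogTL)`` to every gene's
    observed log2 fold change, applied to the treated group's mean.
    """
    root = np.random.SeedSequence(config.seed)
    ss_main, ss_pilot = root.spawn(2)
    rng = np.random.default_rng(ss_main)

    n = config.n_genes
    lo_l, hi_l = config.length_log2_range
    logtl = rng.uniform(lo_l, hi_l, size=n)
    lengths = np.maximum(1, np.rint(2.0**logtl)).astype(np.int64)
    lo_b, hi_b = config.baseline_mean_log_range
    baseline = 10.0 ** rng.uniform(lo_b, hi_b, size=n)

    n_up = int(round(config.frac_up * n))
    n_down = int(round(config.frac_down * n))
    order = rng.permutation(n)
    magnitudes = config.effect_logfc_scale * rng.lognormal(0.0, 0.25, size=n)
    true_logfc = np.zeros(n)
    true_logfc[order[:n_up]] = magnitudes[order[:n_up]]
    true_logfc[order[n_up : n_up + n_down]] = -magnitudes[order[n_up : n_up + n_down]]

    if config.target_spearman is not None:
        slope = _calibrate_slope(
            config.target_spearman,
            np.log2(lengths.astype(float)),
            true_logfc,
            baseline,
            config.dispersion,
            config.n_replicates_per_group,
            np.random.default_rng(ss_pilot),
        )
    else:
        slope = float(config.artifact_slope)
    logtl_exact = np.log2(lengths.astype(float))
    artifact = slope * (logtl_exact - logtl_exact.mean())
    observed_logfc = true_logfc + artifact

    n_rep = config.n_replicates_per_group
    mean_control = baseline
    mean_treated = baseline * 2.0**observed_logfc
    counts = np.empty((n, 2 * n_rep), dtype=np.int64)
    for j, mu in enumerate([mean_control] * n_rep + [mean_treated] * n_rep):
        if config.dispersion > 0:
            r = 1.0 / config.dispersion
            counts[:, j] = rng.negative_binomial(r, r / (r + mu))
        else:
            counts[:, j] = rng.poisson(mu)

    gene_ids = pd.Index([f"g{i:06d}" for i in range(n)], name="gene_id")
    sample_ids = [f"ctrl_{j + 1}" for j in range(n_rep)] + [f"trt_{j + 1}" for j in range(n_rep)]
    groups = pd.Series(
        [de_mod.CONTROL] * n_rep + [de_mod.TREATED] * n_rep, index=sample_ids, name="group"
    )
    cm = de_mod.CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids), groups=groups
    )
    meta = pd.DataFrame({"gene_id": gene_ids, "transcript_length_bp": lengths}).set_index(
        "gene_id"
    )

    factors = de_mod.size_factors(cm)
    est_logfc = de_mod.estimate_logfc(cm, factors).to_numpy()
    realized = float(stats.spearmanr(logtl_exact, est_logfc).statistic) if n >= 3 else float("nan")

    truth = pd.DataFrame(
        {
            "true_logfc": true_logfc,
            "is_de": true_logfc != 0.0,
            "artifact_component": artifact,
        },
        index=gene_ids,
    )
    return cm, meta, SimTruth(table=truth, realized_spearman=realized, artifact_slope=slope)


@dataclass(frozen=True)
class SimSeahorseConfig:
    """Configuration of the three-phase OCR/ECAR trace simulator.

    ``groups`` lists (name, ocr_multiplier, ecar_multiplier) tuples; the
    multipliers scale the basal means per group. OCR drops to
    ``oligo_ocr_fraction`` of basal after oligomycin and further to
    ``rotaa_ocr_fraction`` after Rotenone/Antimycin A.
    """

    groups: tuple[tuple[str, float, float], ...] = (
        ("control", 1.0, 1.0),
        ("treated", 1.5, 1.4),
    )
    wells_per_group: int = 5
    measurements_per_phase: int = 3
    basal_ocr_mean: float = 100.0
    basal_ecar_mean: float = 80.0
    oligo_ocr_fraction: float = 0.4
    rotaa_ocr_fraction: float = 0.1
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ConfigurationError("at least one group is required")
        if self.wells_per_group < 1 or self.measurements_per_phase < 1:
            raise ConfigurationError("wells_per_group and measurements_per_phase must be >= 1")
        if self.basal_ocr_mean <= 0 or self.basal_ecar_mean <= 0:
            raise ConfigurationError("basal means must be positive")
        if not 0.0 <= self.rotaa_ocr_fraction < self.oligo_ocr_fraction < 1.0:
            raise ConfigurationError(
                "need 0 <= rotaa_ocr_fraction < oligo_ocr_fraction < 1"
            )
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be non-negative")


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(-0.5 * sigma**2, sigma, size=size)  # unit mean


def simulate_seahorse(config: SimSeahorseConfig) -> pd.DataFrame:
    """Simulate a three-phase extracellular-flux trace table.

    ``noise_cv`` is the between-well coefficient of variation: each well
    carries one multiplicative log-normal factor applied to its whole trace
    (seeding-density-style variability), plus a five-fold smaller
    per-measurement instrument jitter. Time advances by one measurement
    interval per reading, identically across wells.
    """
    rng = np.random.default_rng(config.seed)
    m = config.measurements_per_phase
    ocr_fracs = (1.0, config.oligo_ocr_fraction, config.rotaa_ocr_fraction)
    rows = []
    for name, ocr_mult, ecar_mult in config.groups:
        for w in range(config.wells_per_group):
            well = f"{name}_w{w + 1}"
            well_factor = float(_lognormal_noise(rng, config.noise_cv, 1)[0])
            t = 0.0
            for phase, ocr_frac, ecar_frac in zip(PHASES, ocr_fracs, ECAR_PHASE_MULTIPLIERS):
                ocr_mean = config.basal_ocr_mean * ocr_mult * ocr_frac * well_factor
                ecar_mean = config.basal_ecar_mean * ecar_mult * ecar_frac * well_factor
                ocr = ocr_mean * _lognormal_noise(rng, config.noise_cv / 5.0, m)
                ecar = ecar_mean * _lognormal_noise(rng, config.noise_cv / 5.0, m)
                for k in range(m):
                    t += MEASUREMENT_INTERVAL_MIN
                    rows.append(
                        {
                            "well": well,
                            "group": name,
                            "phase": phase,
                            "time_min": t,
                            "ocr_pmol_per_min": float(ocr[k]),
                            "ecar_mpH_per_min": float(ecar[k]),
                        }
                    )
    return pd.DataFrame(rows, columns=TRACE_COLUMNS)


def simulate_assays(
    n_per_group: int,
    control_mean: float,
    effect_multiplier: float,
    noise_cv: float,
    seed: int = 0,
    control_group: str = "control",
    treated_group: str = "treated",
) -> pd.DataFrame:
    """Simulate a two-group assay value table with multiplicative noise.

    Values are log-normal with unit-mean noise around ``control_mean`` for
    the control group and ``control_mean * effect_multiplier`` for the
    treated group.
    """
    if n_per_group < 2:
        raise ConfigurationError("n_per_group must be >= 2")
    if control_mean <= 0 or effect_multiplier <= 0:
        raise ConfigurationError("control_mean and effect_multiplier must be positive")
    if noise_cv < 0:
        raise ConfigurationError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for group, mean in ((control_group, control_mean), (treated_group, control_mean * effect_multiplier)):
        vals = mean * _lognormal_noise(rng, noise_cv, n_per_group)
        for i in range(n_per_group):
            rows.append({"sample": f"{group}_{i + 1}", "group": group, "value": float(vals[i])})
    return pd.DataFrame(rows, columns=["sample", "group", "value"])
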