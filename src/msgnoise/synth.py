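"""Synthetic gene tables and noise datasets with the analysis' statistical structure.

Real proteome-scale inputs (RNA-Seq message numbers, flow-cytometry noise,
essentiality calls) are not redistributable, so every pipeline stage is
exercised on generated tables that share their statistical skeleton:

* per-class lognormal message numbers — essential genes peaked near ~15
  messages per cycle, truncated at a floor of ~1 with a small configurable
  "leak" of essential genes left below it; nonessential genes broader and
  lower, with a configurable fraction of silent (zero-message) genes;
* a power-law translation law ``mu_p = B * mu_m^A`` with lognormal scatter;
* gamma-model noise ``CV_p^2 = ln2/mu_m + c`` (floor ``c``) with
  multiplicative measurement error;
* a left-censoring flag for proteins under the detection threshold
  (fitting modules own the exclusion policy — rows are never deleted here).

Every draw records its ground truth, so recovery tests can compare planted
and estimated parameters exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import LN2, OrganismConstants

__all__ = ["GeneratorConfig", "generate_gene_table", "generate_noise_dataset"]

_RESAMPLE_CAP = 1000  # truncation resampling rounds before declaring infeasible


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic gene-table generator.

    Message numbers are lognormal per class, parameterized by the log10
    median and log10 standard deviation.  Defaults emulate a yeast-like
    proteome: essential genes peaked at ~15 messages per cycle and floored
    near 1 (with a 2% leak below), nonessential genes centred lower with a
    10% silent fraction, the yeast translation law (8.0, 2.1) with 0.3
    decades of scatter, a noise floor of 0.01, 10% relative measurement
    error on the noise, and a 10-molecule detection threshold.
    """

    n_genes: int = 3000
    fraction_essential: float = 0.2
    essential_log10_median: float = math.log10(15.0)
    essential_log10_sd: float = 0.6
    nonessential_log10_median: float = math.log10(5.0)
    nonessential_log10_sd: float = 0.9
    mu_m_floor: float = 1.0
    leak_fraction: float = 0.02
    nonessential_zero_fraction: float = 0.1
    translation_amplitude: float = 8.0
    translation_exponent: float = 2.1
    translation_scatter_log10: float = 0.3
    noise_floor: float = 0.01
    cv2_relative_sd: float = 0.1
    detection_threshold: float = 10.0
    match_total: bool = False
    seed: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("fraction_essential", "leak_fraction", "nonessential_zero_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value!r}")
        for name in (
            "essential_log10_sd",
            "nonessential_log10_sd",
            "translation_scatter_log10",
            "cv2_relative_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_floor < 0 or self.detection_threshold < 0 or self.mu_m_floor < 0:
            raise ValueError("noise_floor, detection_threshold, mu_m_floor must be >= 0")


def _truncated_lognormal(
    rng: np.random.Generator,
    n: int,
    log10_median: float,
    log10_sd: float,
    low: float | None = None,
    high: float | None = None,
) -> np.ndarray:
    """Lognormal draws (base-10 parametrization) truncated to [low, high)."""
    out = 10.0 ** (log10_median + log10_sd * rng.standard_normal(n))
    if low is None and high is None:
        return out
    for _ in range(_RESAMPLE_CAP):
        bad = np.zeros(n, dtype=bool)
        if low is not None:
            bad |= out < low
        if high is not None:
            bad |= out >= high
        n_bad = int(bad.sum())
        if n_bad == 0:
            return out
        out[bad] = 10.0 ** (log10_median + log10_sd * rng.standard_normal(n_bad))
    raise ValueError(
        "truncation region has negligible mass under the configured lognormal "
        f"(gave up after {_RESAMPLE_CAP} resampling rounds)"
    )


def generate_gene_table(
    cfg: GeneratorConfig, org: OrganismConstants
) -> tuple[pd.DataFrame, dict]:
    """Generate a per-gene table plus its ground truth.

    Essential genes draw message numbers truncated at ``mu_m_floor`` except
    for a planted ``leak_fraction`` kept strictly below it; a configured
    fraction of nonessential genes is silent (zero messages).  Cellular
    message number and transcription rate follow from the organism constants
    (``mu_m/c = mu_m * tau_m / T``, ``beta_m = mu_m / T``); protein means
    from the translation law with scatter; noise from ``ln2/mu_m`` plus the
    floor with multiplicative lognormal measurement error.  Rows with
    protein mean under the detection threshold carry ``below_detection=1``.

    With ``match_total`` the drawn message numbers are rescaled so their sum
    equals the organism's total messages per cycle (downstream quantities
    are computed after rescaling, so the planted laws still hold).

    Returns ``(records, ground_truth)`` where ``ground_truth`` echoes the
    config and records planted per-class counts and latent values.
    """
    rng = np.random.default_rng(cfg.seed)
    n_ess = int(round(cfg.n_genes * cfg.fraction_essential))
    n_non = cfg.n_genes - n_ess

    # essential class: truncated above the floor, except a planted leak below
    n_leak = int(round(n_ess * cfg.leak_fraction))
    mu_m_ess = np.empty(n_ess)
    if n_ess - n_leak > 0:
        mu_m_ess[: n_ess - n_leak] = _truncated_lognormal(
            rng, n_ess - n_leak, cfg.essential_log10_median, cfg.essential_log10_sd,
            low=cfg.mu_m_floor,
        )
    if n_leak > 0:
        if cfg.mu_m_floor <= 0:
            raise ValueError("leak_fraction > 0 requires mu_m_floor > 0")
        mu_m_ess[n_ess - n_leak:] = _truncated_lognormal(
            rng, n_leak, cfg.essential_log10_median, cfg.essential_log10_sd,
            high=cfg.mu_m_floor,
        )

    # nonessential class: free lognormal with a silent (zero) fraction
    n_zero = int(round(n_non * cfg.nonessential_zero_fraction))
    mu_m_non = np.empty(n_non)
    if n_non - n_zero > 0:
        mu_m_non[: n_non - n_zero] = _truncated_lognormal(
            rng, n_non - n_zero, cfg.nonessential_log10_median, cfg.nonessential_log10_sd
        )
    mu_m_non[n_non - n_zero:] = 0.0

    mu_m = np.concatenate([mu_m_ess, mu_m_non])
    essential = np.concatenate(
        [np.ones(n_ess, dtype=bool), np.zeros(n_non, dtype=bool)]
    )

    if cfg.match_total:
        total = mu_m.sum()
        if total <= 0:
            raise ValueError("cannot match totals: all message numbers are zero")
        mu_m = mu_m * (org.total_messages_per_cycle / total)

    mrna_per_cell = mu_m * org.mrna_lifetime_h / org.doubling_time_h
    beta_m = mu_m / org.doubling_time_h

    positive = mu_m > 0
    scatter = cfg.translation_scatter_log10 * rng.standard_normal(cfg.n_genes)
    mu_p = np.zeros(cfg.n_genes)
    mu_p[positive] = (
        cfg.translation_amplitude
        * mu_m[positive] ** cfg.translation_exponent
        * 10.0 ** scatter[positive]
    )

    cv2_true = np.full(cfg.n_genes, np.nan)
    cv2_true[positive] = LN2 / mu_m[positive] + cfg.noise_floor
    noise_factor = np.exp(cfg.cv2_relative_sd * rng.standard_normal(cfg.n_genes))
    cv2 = cv2_true * noise_factor

    records = pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(cfg.n_genes)],
            "essential": essential.astype(int),
            "mrna_per_cell": mrna_per_cell,
            "protein_mean": np.where(positive, mu_p, np.nan),
            "protein_cv2": cv2,
            "message_number": mu_m,
            "transcription_rate_per_h": beta_m,
            "below_detection": (mu_p < cfg.detection_threshold).astype(int),
        }
    )

    ground_truth = {
        "config": asdict(cfg),
        "n_essential": n_ess,
        "n_nonessential": n_non,
        "n_essential_below_floor": n_leak,
        "n_nonessential_zero": n_zero,
        "mu_m_latent": mu_m.tolist(),
        "cv2_noiseless": cv2_true.tolist(),
        "organism": org.name,
    }
    return records, ground_truth


def generate_noise_dataset(
    a: float,
    b: float,
    c: float,
    n: int,
    scatter_log10: float = 0.15,
    mu_p_range: tuple[float, float] = (1.0, 1e5),
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw (abundance, noise) pairs from a planted noise law.

    Abundances are log-uniform over ``mu_p_range`` (even leverage per
    decade); noise is ``b * mu_p^-a + c`` with lognormal scatter of
    ``scatter_log10`` decades.  Used for calibration and power studies of
    the noise-model fit and the canonical-scaling test.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if seed is None:
        raise ValueError("seed is mandatory for reproducibility")
    if b < 0 or c < 0:
        raise ValueError("b and c must be >= 0")
    lo, hi = mu_p_range
    if not (0 < lo < hi):
        raise ValueError("mu_p_range must satisfy 0 < low < high")
    rng = np.random.default_rng(seed)
    mu_p = 10.0 ** rng.uniform(math.log10(lo), math.log10(hi), size=n)
    cv2 = (b * mu_p ** (-a) + c) * 10.0 ** (
        scatter_log10 * rng.standard_normal(n)
    )
    return pd.DataFrame({"protein_mean": mu_p, "protein_cv2": cv2})
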