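"""Closed-form relations of the gamma statistical model of gene expression.

The telegraph (birth--death) model of the central dogma has four first-order
rates: transcription ``beta_m``, message degradation ``gamma_m``, translation
``beta_p`` and protein depletion ``gamma_p`` (all per hour here).  Under rapid
growth, dilution dominates protein depletion, so ``gamma_p = ln2 / T`` with
``T`` the doubling time.  At steady state the protein copy number per cell at
birth is gamma distributed, ``Np ~ Gamma(k, theta)``, with

* shape  ``k = beta_m / gamma_p``, more usefully expressed through the
  *message number* ``mu_m = beta_m * T = k * ln2`` -- the mean number of
  messages transcribed per cell cycle;
* scale  ``theta = eps * ln2`` where ``eps = beta_p / gamma_m`` is the
  *translation efficiency*, the mean number of proteins made per message.

Hence the two experimentally meaningful consequences implemented here::

    mu_p   = k * theta = mu_m * eps        (mean protein number)
    CV_p^2 = 1 / k     = ln2 / mu_m        (protein noise)

Noise is set by the message number alone, not by the protein abundance.
Because RNA-Seq and FISH measure the *cellular* message number ``mu_m/c``
(copies present per cell), conversion uses the message recycling ratio
``T / tau_m`` (``tau_m = 1/gamma_m`` is the message lifetime):
``mu_m = (T / tau_m) * mu_m/c``.

The floor arithmetic turns a minimum message number (one message per cell
cycle for essential genes) into floors on the other central-dogma statistics
and a ceiling ``ln2 / mu_m_min`` on tolerable protein noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "LN2",
    "KineticParams",
    "OrganismConstants",
    "GammaParams",
    "FloorEstimates",
    "recycling_ratio",
    "message_number_from_cellular",
    "cellular_from_message_number",
    "translation_efficiency",
    "gamma_from_kinetics",
    "protein_stats",
    "noise_from_abundance",
    "floors",
    "round_sig",
]

LN2 = math.log(2.0)

#: Below this translation efficiency the gamma approximation for protein
#: noise degrades (it assumes many proteins per message burst).
EPSILON_VALIDITY_THRESHOLD = 5.0


def round_sig(x: float, sig: int = 1) -> float:
    """Round ``x`` to ``sig`` significant figures, half away from zero.

    Used to reproduce printed table values; computations always retain
    full precision and round only at presentation time.
    """
    if sig < 1:
        raise ValueError("sig must be >= 1")
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    quantum = Decimal(1).scaleb(-(sig - 1))
    mantissa = Decimal(repr(x)).scaleb(-exponent)
    return float(mantissa.quantize(quantum, rounding=ROUND_HALF_UP).scaleb(exponent))


@dataclass(frozen=True)
class KineticParams:
    """The four telegraph-model rates, in events per hour.

    ``transcription_rate`` (beta_m), ``message_degradation_rate`` (gamma_m),
    ``translation_rate`` (beta_p) and ``protein_depletion_rate`` (gamma_p).
    """

    transcription_rate: float
    message_degradation_rate: float
    translation_rate: float
    protein_depletion_rate: float

    def __post_init__(self) -> None:
        for name in (
            "transcription_rate",
            "message_degradation_rate",
            "translation_rate",
            "protein_depletion_rate",
        ):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")

    @property
    def message_lifetime(self) -> float:
        """Mean message lifetime tau_m = 1/gamma_m, hours."""
        if self.message_degradation_rate <= 0:
            raise ValueError("message lifetime undefined for gamma_m <= 0")
        return 1.0 / self.message_degradation_rate


@dataclass(frozen=True)
class OrganismConstants:
    """Organism-level central-dogma constants (one table row per organism).

    Times are in hours; totals are molecule counts summed over all genes.
    """

    name: str
    growth_condition: str
    doubling_time_h: float
    mrna_lifetime_h: float
    total_mrna_per_cell: float
    total_messages_per_cycle: float
    total_protein: float

    def __post_init__(self) -> None:
        if self.doubling_time_h <= 0:
            raise ValueError("doubling_time_h must be > 0")
        if self.mrna_lifetime_h <= 0:
            raise ValueError("mrna_lifetime_h must be > 0")
        for name in ("total_mrna_per_cell", "total_messages_per_cycle", "total_protein"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def recycling_ratio(self) -> float:
        """T / tau_m: how many times the message pool turns over per cycle."""
        return self.doubling_time_h / self.mrna_lifetime_h

    @property
    def mean_translation_efficiency(self) -> float:
        """Proteome-wide mean proteins per message: Np_tot / Nm_tot."""
        if self.total_messages_per_cycle <= 0:
            raise ValueError("total_messages_per_cycle must be > 0 for efficiency")
        return self.total_protein / self.total_messages_per_cycle

    @property
    def mean_translation_rate_per_h(self) -> float:
        """Mean translation rate beta_p = eps * gamma_m, per hour."""
        return self.mean_translation_efficiency / self.mrna_lifetime_h


@dataclass(frozen=True)
class GammaParams:
    """Gamma-distribution parameters of protein copy number at cell birth.

    ``shape`` is k (dimensionless), ``scale`` is theta (proteins).  The
    biologically meaningful reparametrization is exposed read-only:
    message number ``mu_m = k * ln2`` and translation efficiency
    ``eps = theta / ln2``.
    """

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not (self.shape > 0):
            raise ValueError(f"shape must be > 0, got {self.shape!r}")
        if not (self.scale >= 0):
            raise ValueError(f"scale must be >= 0, got {self.scale!r}")

    @property
    def message_number(self) -> float:
        return self.shape * LN2

    @property
    def translation_efficiency(self) -> float:
        return self.scale / LN2


@dataclass(frozen=True)
class FloorEstimates:
    """Floors on central-dogma statistics implied by a message-number minimum.

    All values at full precision; use :meth:`rounded` for the one-significant-
    figure presentation convention of printed threshold tables.
    """

    max_noise: float
    min_message_number: float
    min_cellular_message_number: float
    min_transcription_rate_per_h: float
    min_protein: float

    def rounded(self, sig: int = 1) -> dict[str, float]:
        return {
            "max_noise": round_sig(self.max_noise, sig),
            "min_message_number": round_sig(self.min_message_number, sig),
            "min_cellular_message_number": round_sig(self.min_cellular_message_number, sig),
            "min_transcription_rate_per_h": round_sig(self.min_transcription_rate_per_h, sig),
            "min_protein": round_sig(self.min_protein, sig),
        }


def recycling_ratio(doubling_time_h: float, mrna_lifetime_h: float) -> float:
    """Message recycling ratio T / tau_m.

    The average number of times the cellular message pool is replaced during
    one cell cycle; also the conversion factor between cellular message
    number and message number per cycle.
    """
    if doubling_time_h <= 0 or mrna_lifetime_h <= 0:
        raise ValueError("doubling time and message lifetime must be > 0")
    return doubling_time_h / mrna_lifetime_h


def message_number_from_cellular(
    cellular_message_number: float, doubling_time_h: float, mrna_lifetime_h: float
) -> float:
    """Convert copies-per-cell (RNA-Seq/FISH observable) to messages per cycle.

    ``mu_m = (T / tau_m) * mu_m/c``.
    """
    if cellular_message_number < 0:
        raise ValueError("cellular message number must be >= 0")
    return recycling_ratio(doubling_time_h, mrna_lifetime_h) * cellular_message_number


def cellular_from_message_number(
    message_number: float, doubling_time_h: float, mrna_lifetime_h: float
) -> float:
    """Inverse of :func:`message_number_from_cellular`."""
    if message_number < 0:
        raise ValueError("message number must be >= 0")
    return message_number / recycling_ratio(doubling_time_h, mrna_lifetime_h)


def translation_efficiency(translation_rate: float, message_degradation_rate: float) -> float:
    """Mean proteins produced per message over its lifetime: eps = beta_p / gamma_m."""
    if message_degradation_rate <= 0:
        raise ValueError("message degradation rate must be > 0")
    if translation_rate < 0:
        raise ValueError("translation rate must be >= 0")
    return translation_rate / message_degradation_rate


def gamma_from_kinetics(
    kinetics: KineticParams, doubling_time_h: float | None = None
) -> GammaParams:
    """Map telegraph rates to the gamma statistical parameters.

    ``k = beta_m / gamma_p`` and ``theta = (beta_p / gamma_m) * ln2``.

    When ``doubling_time_h`` is given, the dilution-dominated depletion rate
    ``gamma_p = ln2 / T`` is used (the usual rapid-growth case), so the
    derived message number is exactly ``beta_m * T``.  Otherwise the explicit
    ``protein_depletion_rate`` from ``kinetics`` is used, and the derived
    message number ``k * ln2`` no longer equals ``beta_m * T`` -- active
    degradation shrinks the shape parameter and inflates the noise.
    """
    if doubling_time_h is not None:
        if doubling_time_h <= 0:
            raise ValueError("doubling time must be > 0")
        gamma_p = LN2 / doubling_time_h
    else:
        gamma_p = kinetics.protein_depletion_rate
        if gamma_p <= 0:
            raise ValueError("protein depletion rate must be > 0 (or pass doubling_time_h)")
    if kinetics.message_degradation_rate <= 0:
        raise ValueError("message degradation rate must be > 0")
    shape = kinetics.transcription_rate / gamma_p
    if shape <= 0:
        raise ValueError("transcription rate must be > 0 to define gamma shape")
    eps = translation_efficiency(
        kinetics.translation_rate, kinetics.message_degradation_rate
    )
    return GammaParams(shape=shape, scale=eps * LN2)


def protein_stats(params: GammaParams) -> tuple[float, float]:
    """Mean and noise of protein number under the gamma model.

    Returns ``(mu_p, CV_p^2)`` with ``mu_p = k*theta = mu_m*eps`` and
    ``CV_p^2 = 1/k = ln2/mu_m``.

    The noise expression assumes each message yields many proteins
    (``eps >> 0``); a warning is emitted below a translation efficiency of
    ``EPSILON_VALIDITY_THRESHOLD``, where low-efficiency (Poisson-like)
    corrections become relevant.
    """
    eps = params.translation_efficiency
    if eps < EPSILON_VALIDITY_THRESHOLD:
        warnings.warn(
            f"gamma noise model assumes eps >> 0; got eps = {eps:.3g} "
            f"(< {EPSILON_VALIDITY_THRESHOLD:g}), noise may be underestimated",
            UserWarning,
            stacklevel=2,
        )
    mean = params.shape * params.scale
    noise = 1.0 / params.shape
    return mean, noise


def noise_from_abundance(protein_mean: float, eps: float) -> float:
    """Protein noise in terms of abundance: CV_p^2 = eps * ln2 / mu_p.

    Equivalent to ``ln2 / mu_m``; makes explicit that noise scales as the
    canonical 1/mu_p only if the translation efficiency is constant.
    """
    if protein_mean <= 0:
        raise ValueError("protein mean must be > 0")
    if eps < 0:
        raise ValueError("translation efficiency must be >= 0")
    return eps * LN2 / protein_mean


def floors(
    org: OrganismConstants,
    eps_mean: float | None = None,
    min_message_number: float = 1.0,
) -> FloorEstimates:
    """Central-dogma floors implied by a minimum message number per cycle.

    With ``mu_m_min`` (default one message per cell cycle, the conservative
    reading of the essential-gene floor):

    * noise ceiling       ``CV_p^2_max = ln2 / mu_m_min``
    * cellular messages   ``mu_m/c_min = mu_m_min * tau_m / T``
    * transcription rate  ``beta_m_min = mu_m_min / T``   (per hour)
    * protein abundance   ``mu_p_min   = mu_m_min * eps`` (mean efficiency)

    ``eps_mean`` defaults to the organism's proteome-wide mean efficiency
    derived from its totals.  ``min_message_number = 0`` yields all-zero
    floors and an unbounded (infinite) noise ceiling, with a warning.
    """
    if min_message_number < 0:
        raise ValueError("min_message_number must be >= 0")
    if eps_mean is None:
        eps_mean = org.mean_translation_efficiency
    if eps_mean < 0:
        raise ValueError("eps_mean must be >= 0")
    if min_message_number == 0:
        warnings.warn(
            "min_message_number = 0: noise ceiling is unbounded", UserWarning, stacklevel=2
        )
        max_noise = math.inf
    else:
        max_noise = LN2 / min_message_number
    return FloorEstimates(
        max_noise=max_noise,
        min_message_number=min_message_number,
        min_cellular_message_number=min_message_number
        * org.mrna_lifetime_h
        / org.doubling_time_h,
        min_transcription_rate_per_h=min_message_number / org.doubling_time_h,
        min_protein=min_message_number * eps_mean,
    )
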