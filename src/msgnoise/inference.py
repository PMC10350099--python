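"""Model fitting: empirical noise law, translation power law, gamma fits.

Three estimation problems arise in the noise analysis:

1. **Empirical noise model.**  Across the proteome, noise versus abundance
   is described by ``CV_p^2 = b * mu_p^-a + c`` with a noise floor ``c``.
   Canonical scaling fixes ``a = 1``; the alternative frees ``a``.  The fit
   is least squares on ``log10 CV_p^2`` (noise spans decades, and the
   residual scatter is roughly multiplicative), and the two nested
   hypotheses are compared with a likelihood-ratio chi-square test on one
   degree of freedom.

2. **Empirical translation model.**  Mean protein number versus message
   number follows a power law ``mu_p = amplitude * mu_m^exponent`` (in
   yeast, exponent ~2 rather than the constant-efficiency exponent 1).
   Fit by OLS in log10-log10 space.  Composing this with the gamma noise
   law ``CV_p^2 = ln2/mu_m`` yields a *parameter-free* prediction of noise
   versus abundance (:func:`derive_noise_prediction`) and of translation
   efficiency versus message number (:func:`derive_efficiency_model`).

3. **Gamma fits** to simulated protein-count samples, method of moments
   with optional maximum-likelihood refinement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .core import LN2, GammaParams

__all__ = [
    "NoiseFit",
    "PowerLawFit",
    "fit_noise_model",
    "test_canonical_scaling",
    "fit_translation_model",
    "derive_noise_prediction",
    "derive_efficiency_model",
    "fit_gamma",
]

#: Default protein-abundance detection threshold (molecules).  Fluorescence
#: assays cannot resolve noise below roughly ten molecules per cell
#: (autofluorescence background), so genes under this abundance are censored.
DEFAULT_ABUNDANCE_THRESHOLD = 10.0

_A_BOUNDS = (0.0, 3.0)
# deterministic multi-start grid over the exponent; b, c re-seeded from data
_A_STARTS = (0.3, 0.5, 1.0, 1.5, 2.0)


@dataclass(frozen=True)
class PowerLawFit:
    """A fitted power law ``y = amplitude * x**exponent``.

    ``cov`` is the 2x2 covariance of ``(log10 amplitude, exponent)`` from
    the log-log OLS (None for analytically derived laws).
    """

    amplitude: float
    exponent: float
    cov: np.ndarray | None = None
    n: int | None = None
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if not (self.amplitude > 0):
            raise ValueError(f"amplitude must be > 0, got {self.amplitude!r}")

    @property
    def amplitude_log10_se(self) -> float | None:
        return None if self.cov is None else float(np.sqrt(self.cov[0, 0]))

    @property
    def exponent_se(self) -> float | None:
        return None if self.cov is None else float(np.sqrt(self.cov[1, 1]))

    def __call__(self, x):
        return self.amplitude * np.asarray(x, dtype=float) ** self.exponent


@dataclass(frozen=True)
class NoiseFit:
    """Fit of the empirical noise model ``CV_p^2 = b * mu_p^-a + c``.

    ``loglik`` is the Gaussian log-likelihood of the log10 residuals with
    the variance profiled out; ``fixed_a`` marks the canonical-scaling null
    (a pinned at 1).  ``c_at_bound`` flags a floor driven to its lower
    bound, where its standard error is unreliable.
    """

    exponent: float
    amplitude: float
    floor: float
    exponent_se: float
    amplitude_se: float
    floor_se: float
    loglik: float
    n: int
    fixed_a: bool
    sigma_log10: float
    c_at_bound: bool
    abundance_threshold: float
    n_excluded: int

    def predict(self, mu_p):
        mu_p = np.asarray(mu_p, dtype=float)
        return self.amplitude * mu_p ** (-self.exponent) + self.floor


def _noise_residuals(params: np.ndarray, log_mu: np.ndarray, log_cv2: np.ndarray,
                     fixed_a: float | None) -> np.ndarray:
    if fixed_a is None:
        a, b, c = params
    else:
        a = fixed_a
        b, c = params
    model = b * 10.0 ** (-a * log_mu) + c
    return np.log10(np.maximum(model, 1e-300)) - log_cv2


def fit_noise_model(
    records: pd.DataFrame,
    hypothesis: Literal["null", "alternative"] = "alternative",
    abundance_threshold: float = DEFAULT_ABUNDANCE_THRESHOLD,
) -> NoiseFit:
    """Fit ``CV_p^2 = b * mu_p^-a + c`` to per-gene (abundance, noise) data.

    ``records`` needs columns ``protein_mean`` and ``protein_cv2``.  Genes
    at or below ``abundance_threshold`` (detection limit) or with
    non-finite/non-positive values are excluded; at least 10 genes must
    remain.  The ``null`` hypothesis pins the scaling exponent at ``a = 1``
    (canonical inverse-abundance noise); the ``alternative`` frees it within
    [0, 3].  Least squares on log10 noise with bounds ``b, c >= 0``,
    multi-started from a deterministic exponent grid to dodge local minima.

    Raises on degenerate data (a single distinct abundance cannot fix both
    a slope and a floor).
    """
    if hypothesis not in ("null", "alternative"):
        raise ValueError(f"unknown hypothesis {hypothesis!r}")
    mu_p = np.asarray(records["protein_mean"], dtype=float)
    cv2 = np.asarray(records["protein_cv2"], dtype=float)
    ok = (
        np.isfinite(mu_p) & np.isfinite(cv2) & (mu_p > abundance_threshold) & (cv2 > 0)
    )
    n_excluded = int(len(mu_p) - ok.sum())
    mu_p, cv2 = mu_p[ok], cv2[ok]
    if len(mu_p) < 10:
        raise ValueError(
            f"need >= 10 usable records above threshold {abundance_threshold:g}; "
            f"got {len(mu_p)}"
        )
    if np.unique(mu_p).size < 2:
        raise ValueError("degenerate data: a single distinct abundance value")

    log_mu = np.log10(mu_p)
    log_cv2 = np.log10(cv2)
    n = len(mu_p)
    fixed_a = 1.0 if hypothesis == "null" else None

    # data-driven (deterministic) starts for amplitude and floor
    c0 = max(0.5 * float(np.min(cv2)), 0.0)
    best = None
    a_starts = (1.0,) if fixed_a is not None else _A_STARTS
    for a0 in a_starts:
        b0 = float(np.median(cv2 * mu_p**a0))
        if fixed_a is None:
            x0 = np.array([a0, b0, c0])
            lb = np.array([_A_BOUNDS[0], 0.0, 0.0])
            ub = np.array([_A_BOUNDS[1], np.inf, np.inf])
        else:
            x0 = np.array([b0, c0])
            lb = np.array([0.0, 0.0])
            ub = np.array([np.inf, np.inf])
        res = optimize.least_squares(
            _noise_residuals, x0, bounds=(lb, ub),
            args=(log_mu, log_cv2, fixed_a),
            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000,
        )
        if best is None or res.cost < best.cost:
            best = res

    if fixed_a is None:
        a_hat, b_hat, c_hat = best.x
    else:
        a_hat = 1.0
        b_hat, c_hat = best.x

    rss = float(2.0 * best.cost)
    sigma2 = rss / n
    # profiled-Gaussian log-likelihood of the log10 residuals
    loglik = -0.5 * n * (math.log(2.0 * math.pi * max(sigma2, 1e-300)) + 1.0)

    # parameter covariance from the Jacobian at the optimum
    J = best.jac
    try:
        cov = sigma2 * np.linalg.inv(J.T @ J)
        ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        ses = np.full(best.x.size, np.nan)
    if fixed_a is None:
        a_se, b_se, c_se = ses
    else:
        a_se = 0.0
        b_se, c_se = ses

    c_at_bound = bool(c_hat <= 1e-12)
    return NoiseFit(
        exponent=float(a_hat),
        amplitude=float(b_hat),
        floor=float(c_hat),
        exponent_se=float(a_se),
        amplitude_se=float(b_se),
        floor_se=float(c_se),
        loglik=float(loglik),
        n=n,
        fixed_a=fixed_a is not None,
        sigma_log10=float(math.sqrt(sigma2)),
        c_at_bound=c_at_bound,
        abundance_threshold=abundance_threshold,
        n_excluded=n_excluded,
    )


def test_canonical_scaling(null: NoiseFit, alternative: NoiseFit) -> float:
    """Likelihood-ratio test of canonical noise scaling (a = 1).

    The null (a fixed at 1) is nested in the alternative (a free); the
    statistic ``2 * (loglik_alt - loglik_null)`` is referred to chi-square
    with one degree of freedom.  Both fits must be on the same records.
    Returns the p-value; small values reject inverse-abundance scaling.
    """
    if not null.fixed_a or alternative.fixed_a:
        raise ValueError("pass (null with fixed a, alternative with free a)")
    if null.n != alternative.n or null.abundance_threshold != alternative.abundance_threshold:
        raise ValueError("null and alternative fits use different record sets")
    lr = 2.0 * (alternative.loglik - null.loglik)
    # numerical jitter can make the nested fit marginally "better"
    lr = max(lr, 0.0)
    return float(stats.chi2.sf(lr, df=1))


def fit_translation_model(records: pd.DataFrame) -> PowerLawFit:
    """Fit the empirical translation law ``mu_p = amplitude * mu_m^exponent``.

    OLS of log10 protein mean on log10 message number.  Rows with
    non-positive or missing values are excluded (count reported on the
    result); at least 3 usable rows are required.  Measurement error in the
    message number is ignored: the law's purpose is to map abundance onto
    message number, not to be a mechanistic regression.
    """
    mu_m = np.asarray(records["message_number"], dtype=float)
    mu_p = np.asarray(records["protein_mean"], dtype=float)
    ok = np.isfinite(mu_m) & np.isfinite(mu_p) & (mu_m > 0) & (mu_p > 0)
    n_excluded = int(len(mu_m) - ok.sum())
    mu_m, mu_p = mu_m[ok], mu_p[ok]
    if len(mu_m) < 3:
        raise ValueError(f"need >= 3 records with positive mu_m and mu_p, got {len(mu_m)}")
    X = sm.add_constant(np.log10(mu_m))
    fit = sm.OLS(np.log10(mu_p), X).fit()
    intercept, slope = fit.params
    return PowerLawFit(
        amplitude=float(10.0**intercept),
        exponent=float(slope),
        cov=np.asarray(fit.cov_params()),
        n=len(mu_m),
        n_excluded=n_excluded,
    )


def derive_noise_prediction(translation: PowerLawFit) -> PowerLawFit:
    """Parameter-free noise law over protein abundance from the translation law.

    Inverting ``mu_p = B * mu_m^A`` and substituting into
    ``CV_p^2 = ln2 / mu_m`` gives

        CV_p^2 = ln2 * B^(1/A) * mu_p^(-1/A).

    For the constant-efficiency case A = 1 this reduces to the canonical
    model ``CV_p^2 = B * ln2 / mu_p``.
    """
    if translation.exponent == 0:
        raise ValueError("translation exponent must be nonzero to invert the law")
    A = translation.exponent
    B = translation.amplitude
    return PowerLawFit(amplitude=LN2 * B ** (1.0 / A), exponent=-1.0 / A)


def derive_efficiency_model(translation: PowerLawFit) -> PowerLawFit:
    """Translation efficiency versus message number implied by the law.

    ``eps = mu_p / mu_m = B * mu_m^(A-1)``: efficiency grows with
    transcription whenever A > 1 (the yeast regime), and is constant for
    A = 1 (the bacterial regime).
    """
    return PowerLawFit(
        amplitude=translation.amplitude, exponent=translation.exponent - 1.0
    )


def fit_gamma(
    samples, method: Literal["moments", "mle"] = "moments"
) -> GammaParams:
    """Fit a gamma distribution to protein-count samples.

    Method of moments by default (``k = mean^2/var``, ``theta = var/mean``
    with unbiased variance), which is robust for the discrete, occasionally
    zero-inflated counts the simulator produces; ``method="mle"`` refines by
    maximum likelihood (location pinned at zero), which requires strictly
    positive samples.  At least 50 positive samples are required; zero
    sample variance is an error.
    """
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    if (x > 0).sum() < 50:
        raise ValueError("need >= 50 positive samples to fit a gamma distribution")
    mean = float(x.mean())
    var = float(x.var(ddof=1))
    if var <= 0:
        raise ValueError("zero sample variance: gamma fit undefined")
    if method == "moments":
        return GammaParams(shape=mean**2 / var, scale=var / mean)
    if method == "mle":
        pos = x[x > 0]
        if len(pos) < len(x):
            warnings.warn(
                f"dropping {len(x) - len(pos)} zero samples for the gamma MLE",
                UserWarning,
                stacklevel=2,
            )
        shape, _, scale = stats.gamma.fit(pos, floc=0.0)
        return GammaParams(shape=float(shape), scale=float(scale))
    raise ValueError(f"unknown method {method!r}")
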