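"""Barcode validation by read count.

Barcodes below a hard floor (default 30,000 reads) are discarded outright;
the survivors are modelled as a mixture of two log-normal components
(invalid D1, valid D2) fitted by expectation-maximisation, and a read-count
cutoff between the components separates valid from invalid barcodes.

The responsibilities use the unweighted two-density form
``gamma_i = f2(x_i) / (f1(x_i) + f2(x_i))`` by default (no mixing
proportions); a standard mixing-weighted EM is available via
``weighted=True``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats

DEFAULT_MIN_READS = 30_000


@dataclass
class MixtureFit:
    mu_d1: float
    sigma_d1: float
    mu_d2: float
    sigma_d2: float
    gamma: np.ndarray  # P(barcode belongs to the valid component D2)
    n_iter: int
    converged: bool
    bimodal: bool
    counts: np.ndarray
    min_reads: Optional[float] = None
    cutoff: Optional[float] = None
    delta_trace: Optional[list] = None  # max|delta gamma| per iteration

    def component_modes(self) -> tuple[float, float]:
        """Modes of the two log-normal densities."""
        return (
            math.exp(self.mu_d1 - self.sigma_d1 ** 2),
            math.exp(self.mu_d2 - self.sigma_d2 ** 2),
        )


def prefilter_counts(counts, min_reads: int = DEFAULT_MIN_READS) -> np.ndarray:
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("empty barcode count input")
    if np.any(counts < 0):
        raise ValueError("read counts must be non-negative")
    kept = counts[counts >= min_reads]
    if kept.size == 0:
        raise ValueError("no barcodes survive prefilter")
    return kept


def _log_density(log_x: np.ndarray, x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return -np.log(x * sigma * math.sqrt(2 * math.pi)) - (log_x - mu) ** 2 / (2 * sigma ** 2)


def fit_lognormal_mixture(
    counts,
    max_iter: int = 500,
    tol: float = 1e-6,
    weighted: bool = False,
    min_reads: Optional[float] = None,
) -> MixtureFit:
    """EM fit of two log-normal components to positive read counts.

    Components are initialised by splitting at the median of the log counts
    and are kept ordered so that D1 is the lower one.  Convergence is
    declared when ``max |delta gamma| < tol``.
    """
    x = np.asarray(counts, dtype=np.float64)
    if np.any(x <= 0):
        raise ValueError("counts must be positive after prefiltering")
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct counts to fit a mixture")

    log_x = np.log(x)
    med = np.median(log_x)
    lo, hi = log_x[log_x <= med], log_x[log_x > med]
    if hi.size == 0:  # all logs equal to the median
        lo, hi = log_x[log_x < med], log_x[log_x >= med]
    mu1, mu2 = float(np.mean(lo)), float(np.mean(hi))
    sigma1 = max(float(np.std(lo)), 1e-3)
    sigma2 = max(float(np.std(hi)), 1e-3)
    pi2 = hi.size / x.size

    gamma = np.full(x.size, 0.5)
    converged = False
    n_iter = 0
    trace: list[float] = []
    for n_iter in range(1, max_iter + 1):
        lp1 = _log_density(log_x, x, mu1, sigma1)
        lp2 = _log_density(log_x, x, mu2, sigma2)
        if weighted:
            lp1 = lp1 + math.log(max(1 - pi2, 1e-12))
            lp2 = lp2 + math.log(max(pi2, 1e-12))
        m = np.maximum(lp1, lp2)
        new_gamma = np.exp(lp2 - m) / (np.exp(lp1 - m) + np.exp(lp2 - m))

        delta = float(np.max(np.abs(new_gamma - gamma)))
        trace.append(delta)
        gamma = new_gamma

        w2, w1 = gamma, 1.0 - gamma
        s1, s2 = float(w1.sum()), float(w2.sum())
        if s1 <= 1e-12 or s2 <= 1e-12:
            break  # one component vanished; treated as non-bimodal below
        mu1 = float((w1 * log_x).sum() / s1)
        mu2 = float((w2 * log_x).sum() / s2)
        sigma1 = max(math.sqrt(float((w1 * (log_x - mu1) ** 2).sum() / s1)), 1e-6)
        sigma2 = max(math.sqrt(float((w2 * (log_x - mu2) ** 2).sum() / s2)), 1e-6)
        pi2 = s2 / x.size

        if delta < tol:
            converged = True
            break

    if mu1 > mu2:  # keep D1 the lower read-count distribution
        mu1, mu2 = mu2, mu1
        sigma1, sigma2 = sigma2, sigma1
        gamma = 1.0 - gamma

    # Ashman's D: separation of the components relative to their spreads.
    # EM splits even a unimodal cloud into two overlapping halves, so a
    # small-location-difference test alone cannot detect that case.
    ashman_d = math.sqrt(2.0) * abs(mu2 - mu1) / math.sqrt(sigma1 ** 2 + sigma2 ** 2)
    bimodal = ashman_d >= 2.0
    if not converged:
        warnings.warn("EM did not converge within max_iter", RuntimeWarning)
    if not bimodal:
        warnings.warn(
            "read counts look unimodal; all prefiltered barcodes will be accepted",
            RuntimeWarning,
        )
    return MixtureFit(mu1, sigma1, mu2, sigma2, gamma, n_iter, converged, bimodal,
                      x, min_reads=min_reads, delta_trace=trace)


def find_cutoff(
    fit: MixtureFit,
    mode: str = "posterior",
    alpha: float = 0.05,
    floor: Optional[float] = None,
) -> float:
    """Read-count threshold separating D1 from D2.

    ``posterior`` finds the density crossing between the component modes
    (where the D2 membership probability reaches 0.5); ``type1`` places the
    cutoff at the upper ``alpha`` tail of D1.  The result never drops below
    the prefilter floor.
    """
    if floor is None:
        floor = fit.min_reads if fit.min_reads is not None else 0.0
    if not fit.bimodal:
        return float(floor)
    if mode == "type1":
        cut = math.exp(fit.mu_d1 + fit.sigma_d1 * stats.norm.ppf(1 - alpha))
        return float(max(cut, floor))
    if mode != "posterior":
        raise ValueError(f"unknown cutoff mode {mode!r}")

    m1, m2 = fit.component_modes()
    lo, hi = min(m1, m2), max(m1, m2)

    def diff(v: float) -> float:
        lx = np.array([math.log(v)])
        xv = np.array([float(v)])
        return float(
            (_log_density(lx, xv, fit.mu_d2, fit.sigma_d2)
             - _log_density(lx, xv, fit.mu_d1, fit.sigma_d1))[0]
        )

    if diff(lo) * diff(hi) > 0:
        raise ValueError("components overlap too much: no density crossing between modes")
    root = optimize.brentq(diff, lo, hi, xtol=1e-6)
    return float(max(math.ceil(root), floor))


def classify_barcodes(
    barcodes,
    counts,
    min_reads: int = DEFAULT_MIN_READS,
    mode: str = "posterior",
    alpha: float = 0.05,
    weighted: bool = False,
):
    """Full barcode-validation pass: prefilter, EM fit, cutoff, valid flags.

    Returns ``(table, fit)`` where the table has one row per *input*
    barcode with columns ``barcode, read_count, gamma, valid`` (gamma is
    NaN for prefiltered barcodes).
    """
    import pandas as pd

    barcodes = np.asarray(barcodes, dtype=object)
    counts = np.asarray(counts, dtype=np.int64)
    keep = counts >= min_reads
    if not keep.any():
        raise ValueError("no barcodes survive prefilter")
    fit = fit_lognormal_mixture(counts[keep], min_reads=min_reads, weighted=weighted)
    fit.cutoff = find_cutoff(fit, mode=mode, alpha=alpha)

    gamma = np.full(counts.size, np.nan)
    gamma[keep] = fit.gamma
    valid = counts >= fit.cutoff
    table = pd.DataFrame(
        {"barcode": barcodes, "read_count": counts, "gamma": gamma, "valid": valid}
    )
    return table, fit
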