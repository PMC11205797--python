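"""Sloan neutral community model: occurrence frequency vs mean abundance.

For a metacommunity relative abundance p and per-sample size N, the model's
beta stationary approximation predicts the probability that a taxon's local
relative abundance exceeds a detection limit d:

    f_hat(p) = 1 - BetaCDF(d; N*m*p, N*m*(1-p))

with a single free parameter, the migration rate m in (0, 1]. m is estimated
by bounded nonlinear least squares of observed occurrence frequencies on
f_hat; the goodness of fit R^2 (centred; can be negative) measures how close
the community sits to neutral expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import betaln
from scipy.stats import beta as beta_dist
from statsmodels.stats.proportion import proportion_confint

from .dataset import AbundanceTable, ValidationError


class DegenerateFitError(ValidationError):
    """The occurrence frequencies carry no information to fit m."""


@dataclass
class NCMFit:
    """Fitted migration rate, goodness of fit and per-taxon detail."""

    m: float
    r2: float
    N: int
    n_samples: int
    n_taxa: int
    table: pd.DataFrame  # taxon_id index: p, freq_obs, freq_pred, ci_lo, ci_hi, position

    @property
    def Nm(self) -> float:
        return self.N * self.m


def predict_frequency(p, N: int, m: float, d: float):
    """Predicted occurrence frequency 1 - BetaCDF(d; N m p, N m (1-p)).

    Vectorized over ``p``; all of p, d must lie in (0, 1), N >= 1, m in (0, 1].
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr <= 0) or np.any(p_arr >= 1):
        raise ValidationError("p must lie in (0, 1)")
    if N < 1:
        raise ValidationError("N must be >= 1")
    if not (0 < m <= 1):
        raise ValidationError("m must be in (0, 1]")
    if not (0 < d < 1):
        raise ValidationError("detection limit d must be in (0, 1)")
    out = 1.0 - beta_dist.cdf(d, N * m * p_arr, N * m * (1.0 - p_arr))
    return float(out) if np.isscalar(p) else out


def predict_occurrence_sampled(p, N: int, m: float):
    """Occurrence probability with the finite-read sampling layer included.

    Local relative abundance x ~ Beta(N m p, N m (1-p)) and the observed count
    is Binomial(N, x), so P(count >= 1) = 1 - BetaBinomial(0; N, a, b) —
    computed in log space from beta functions. This is the exact occurrence
    probability for a rarefied sample of N reads, whereas the classic
    threshold form ``predict_frequency(p, N, m, d=1/N)`` idealizes detection
    as a hard cut at one read's relative abundance.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr <= 0) or np.any(p_arr >= 1):
        raise ValidationError("p must lie in (0, 1)")
    if N < 1:
        raise ValidationError("N must be >= 1")
    if not (0 < m <= 1):
        raise ValidationError("m must be in (0, 1]")
    a = N * m * p_arr
    b = N * m * (1.0 - p_arr)
    out = 1.0 - np.exp(betaln(a, b + N) - betaln(a, b))
    return float(out) if np.isscalar(p) else out


def fit_ncm(table: AbundanceTable, detection_limit: float | None = None,
            ci_alpha: float = 0.05,
            occurrence_model: str = "sampling") -> NCMFit:
    """Fit the neutral model to a rarefied count table.

    Requires equal column sums (rarefy first); p_i is each taxon's mean
    relative abundance across samples, f_i its occurrence frequency
    (count >= 1). ``occurrence_model="sampling"`` (default) predicts
    occurrence through the beta-binomial zero term, matching how counts are
    actually observed at finite depth; ``"threshold"`` is the classic hard
    detection limit, defaulting to one read (d = 1/N). The 95% band around
    the prediction uses Wilson score intervals at n = n_samples.
    """
    if occurrence_model not in ("sampling", "threshold"):
        raise ValidationError("occurrence_model must be 'sampling' or 'threshold'")
    sums = table.sample_sums().to_numpy()
    if len(np.unique(sums)) != 1:
        raise ValidationError(
            "unequal sample sums — rarefy the table before fitting the NCM")
    N = int(sums[0])
    rel = table.relative_abundance()
    p = rel.mean(axis=1)
    freq = (table.counts > 0).mean(axis=1)
    keep = p > 0
    p, freq = p[keep], freq[keep]
    if len(p) < 10:
        raise ValidationError("fit_ncm needs >= 10 taxa with positive abundance")
    if freq.nunique() == 1:
        raise DegenerateFitError(
            "all taxa share one occurrence frequency; m is unidentifiable")
    d = detection_limit if detection_limit is not None else 1.0 / N

    p_arr, f_arr = p.to_numpy(), freq.to_numpy()

    if occurrence_model == "sampling":
        def predict(m):
            return predict_occurrence_sampled(p_arr, N, m)
    else:
        def predict(m):
            return predict_frequency(p_arr, N, m, d)

    def sse(m: float) -> float:
        return float(np.sum((f_arr - predict(m)) ** 2))

    opt = minimize_scalar(sse, bounds=(1e-6, 1.0), method="bounded",
                          options={"xatol": 1e-8})
    m_hat = float(opt.x)
    f_pred = predict(m_hat)
    ss_res = float(np.sum((f_arr - f_pred) ** 2))
    ss_tot = float(np.sum((f_arr - f_arr.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot

    n = table.n_samples
    ci_lo, ci_hi = proportion_confint(f_pred * n, n, alpha=ci_alpha,
                                      method="wilson")
    position = np.where(f_arr > ci_hi, "above",
                        np.where(f_arr < ci_lo, "below", "within"))
    detail = pd.DataFrame({
        "p": p_arr, "freq_obs": f_arr, "freq_pred": f_pred,
        "ci_lo": ci_lo, "ci_hi": ci_hi, "position": position,
    }, index=pd.Index(p.index, name="taxon_id"))
    return NCMFit(m=m_hat, r2=r2, N=N, n_samples=n, n_taxa=len(p_arr),
                  table=detail)
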