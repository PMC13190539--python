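"""Two-component normal mixture on log-methylation and its intersection cut-off.

Quantitative MGMT promoter methylation in glioblastoma is bimodal: a low
mode from unmethylated tumors (assay background) and a high mode from
methylated tumors.  Fitting a two-component normal mixture to the
*logarithmized* percent methylation and cutting where the two weighted
component densities intersect yields an unsupervised, distribution-based
classification threshold.

The model object follows the statsmodels convention::

    res = MethylationMixture(values).fit(seed=0)
    res.summary()
    cut = res.intersection_cutoff()   # CutoffEstimate, percent scale
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .errors import DegenerateMixtureError, NoIntersectionError

_SD_FLOOR = 1e-6


@dataclass
class CutoffEstimate:
    """A classification threshold on the percent-methylation scale.

    ``value_pct`` is the raw (unrounded) percentage; ``value_int`` its
    round-half-up integer, the form in which thresholds are reported
    clinically.  ``method`` is ``"unsupervised"`` (mixture intersection) or
    ``"supervised"`` (survival-informed search); ``diagnostics`` carries the
    method-specific payload.
    """

    value_pct: float
    method: str
    diagnostics: object = None

    @property
    def value_int(self) -> int:
        return int(np.floor(self.value_pct + 0.5))


class MethylationMixture:
    """Two-component normal mixture model for log percent methylation.

    Parameters
    ----------
    values : array-like
        Percent methylation values in [0, 100]; at least 10 required.
    floor_pct : float
        Values below this are raised to it before the natural-log transform
        (fully unmethylated assay reads can be exactly 0).
    """

    def __init__(self, values, floor_pct: float = 0.5):
        values = np.asarray(values, dtype=float)
        if values.ndim != 1 or len(values) < 10:
            raise ValueError("need a 1-d array of at least 10 values")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        if values.min() < 0 or values.max() > 100:
            raise ValueError("values must lie in [0, 100]")
        if floor_pct <= 0:
            raise ValueError("floor_pct must be positive")
        self.values = values
        self.floor_pct = floor_pct
        self.log_values = np.log(np.maximum(values, floor_pct))

    # -- EM ---------------------------------------------------------------
    def _em(self, w, mu, sd, tol, max_iter):
        x = self.log_values
        n = len(x)
        trace = []
        converged = False
        for _ in range(max_iter):
            log_comp = (np.log(w)[None, :]
                        + norm.logpdf(x[:, None], mu[None, :], sd[None, :]))
            log_norm = logsumexp(log_comp, axis=1)
            ll = float(log_norm.sum())
            if trace and (ll - trace[-1]) < tol * max(1.0, abs(trace[-1])):
                trace.append(ll)
                converged = True
                break
            trace.append(ll)
            resp = np.exp(log_comp - log_norm[:, None])
            nk = resp.sum(axis=0)
            if np.any(nk < 1.0):
                raise DegenerateMixtureError(
                    "a component weight collapsed below 1/n; the data may "
                    "not support two components")
            w = nk / n
            mu = (resp * x[:, None]).sum(axis=0) / nk
            var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
            sd = np.sqrt(var)
            if np.any(sd < _SD_FLOOR):
                raise DegenerateMixtureError(
                    "a component standard deviation collapsed below 1e-6; "
                    "more data or fewer components needed")
        return w, mu, sd, trace, converged

    def fit(self, tol: float = 1e-10, max_iter: int = 1000,
            n_starts: int = 10, seed: int = 0) -> "MixtureResults":
        """Fit by EM from multiple starts; return the best-likelihood fit.

        The first start splits the data at the median (quantile split); the
        remaining ``n_starts - 1`` perturb it randomly with sub-seeds derived
        from ``seed``.  Components in the result are sorted by mean.
        Equal-log-likelihood ties break toward the lower first-component
        mean.
        """
        x = self.log_values
        if np.ptp(x) < 1e-12:
            raise DegenerateMixtureError(
                "all values identical after flooring; zero variance")
        rng = np.random.default_rng(seed)
        med = np.median(x)
        lo, hi = x[x <= med], x[x > med]
        base = dict(
            w=np.array([len(lo), len(hi)], dtype=float) / len(x),
            mu=np.array([lo.mean(), hi.mean() if len(hi) else lo.mean() + 1]),
            sd=np.array([max(lo.std(), 0.05),
                         max(hi.std() if len(hi) else x.std(), 0.05)]),
        )
        best = None
        for start in range(n_starts):
            w, mu, sd = base["w"].copy(), base["mu"].copy(), base["sd"].copy()
            if start > 0:
                mu = mu + rng.normal(0.0, 0.5 * x.std(), size=2)
                sd = sd * np.exp(rng.normal(0.0, 0.3, size=2))
                w = np.clip(w + rng.normal(0.0, 0.1, size=2), 0.05, 0.95)
                w = w / w.sum()
            try:
                w, mu, sd, trace, conv = self._em(w, mu, sd, tol, max_iter)
            except DegenerateMixtureError:
                if start == 0 and n_starts == 1:
                    raise
                continue
            order = np.argsort(mu)
            cand = MixtureResults(
                model=self, weights=tuple(w[order]), means=tuple(mu[order]),
                sds=tuple(sd[order]), loglik=trace[-1],
                loglik_trace=list(trace), n_iter=len(trace),
                converged=conv, n_obs=len(x))
            if (best is None or cand.loglik > best.loglik + 1e-9
                    or (abs(cand.loglik - best.loglik) <= 1e-9
                        and cand.means[0] < best.means[0])):
                best = cand
        if best is None:
            raise DegenerateMixtureError(
                "every EM start collapsed; the data may not support two "
                "components")
        if min(best.weights) < 1.0 / len(x):
            raise DegenerateMixtureError("fitted component weight below 1/n")
        return best


@dataclass
class MixtureResults:
    """Fitted two-component normal mixture on the log scale.

    Components are sorted by mean, so index 0 is the low (unmethylated) and
    index 1 the high (methylated) component.
    """

    model: MethylationMixture
    weights: tuple
    means: tuple
    sds: tuple
    loglik: float
    loglik_trace: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True
    n_obs: int = 0

    def posterior(self, values=None) -> np.ndarray:
        """Posterior component membership probabilities, shape (n, 2)."""
        if values is None:
            x = self.model.log_values
        else:
            x = np.log(np.maximum(np.asarray(values, dtype=float),
                                  self.model.floor_pct))
        w = np.asarray(self.weights)
        mu = np.asarray(self.means)
        sd = np.asarray(self.sds)
        log_comp = (np.log(w)[None, :]
                    + norm.logpdf(x[:, None], mu[None, :], sd[None, :]))
        return np.exp(log_comp - logsumexp(log_comp, axis=1)[:, None])

    def intersection_cutoff(self) -> CutoffEstimate:
        """Cut-off where the weighted component densities intersect.

        Solves pi_1 N(x; mu_1, s_1^2) = pi_2 N(x; mu_2, s_2^2) on the log
        scale.  With unequal variances this is a quadratic in x and the root
        inside the open interval (mu_1, mu_2) is taken; with equal variances
        the solution is linear.  The result is back-transformed to percent.
        """
        x = _density_intersection(self.weights, self.means, self.sds)
        return CutoffEstimate(value_pct=float(np.exp(x)),
                              method="unsupervised", diagnostics=self)

    def summary(self) -> str:
        lines = [
            "Two-component normal mixture on log percent methylation",
            f"  n = {self.n_obs}, log-likelihood = {self.loglik:.3f}, "
            f"EM iterations = {self.n_iter}, converged = {self.converged}",
            "  component      weight     mu(log)   sd(log)   median(%)",
        ]
        for k, name in enumerate(("unmethylated", "methylated")):
            lines.append(
                f"  {name:<13} {self.weights[k]:>7.3f}  {self.means[k]:>9.3f}"
                f"  {self.sds[k]:>8.3f}  {np.exp(self.means[k]):>9.2f}")
        try:
            cut = self.intersection_cutoff()
            lines.append(f"  intersection cut-off: {cut.value_pct:.3f}% "
                         f"(reported as {cut.value_int}%)")
        except NoIntersectionError:
            lines.append("  intersection cut-off: none in (mu_1, mu_2)")
        return "\n".join(lines)


def _density_intersection(weights, means, sds) -> float:
    """Root of pi_1 phi_1(x) = pi_2 phi_2(x) inside (mu_1, mu_2), log scale."""
    (w1, w2), (m1, m2), (s1, s2) = weights, means, sds
    if not (m1 < m2):
        raise ValueError("component means must be distinct and sorted")
    # log w1 - log s1 - (x-m1)^2/(2 s1^2) = log w2 - log s2 - (x-m2)^2/(2 s2^2)
    c0 = np.log(w1 / s1) - np.log(w2 / s2)
    if abs(s1 - s2) < 1e-12:
        # linear: (x-m1)^2 - (x-m2)^2 = 2 s^2 c0
        x = (m2 ** 2 - m1 ** 2 + 2.0 * s1 ** 2 * c0) / (2.0 * (m2 - m1))
        roots = [x]
    else:
        a = 1.0 / (2.0 * s2 ** 2) - 1.0 / (2.0 * s1 ** 2)
        b = m1 / s1 ** 2 - m2 / s2 ** 2
        c = (m2 ** 2 / (2.0 * s2 ** 2) - m1 ** 2 / (2.0 * s1 ** 2)) + c0
        disc = b * b - 4.0 * a * c
        if disc < 0:
            raise NoIntersectionError(
                "no real intersection of the weighted densities",
                density_ratio=disc)
        sq = np.sqrt(disc)
        roots = sorted([(-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)])
    inside = [r for r in roots if m1 < r < m2]
    if not inside:
        # one component dominates everywhere between the means
        mid = 0.5 * (m1 + m2)
        ratio = (np.log(w1 / s1) - (mid - m1) ** 2 / (2 * s1 ** 2)
                 - np.log(w2 / s2) + (mid - m2) ** 2 / (2 * s2 ** 2))
        raise NoIntersectionError(
            "no intersection inside (mu_1, mu_2); one component dominates "
            "the whole interval", density_ratio=float(ratio))
    return float(inside[0])
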