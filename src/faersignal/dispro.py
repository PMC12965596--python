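"""Disproportionality statistics on 2x2 contingency tables.

Four detectors are implemented:

* ROR  — reporting odds ratio with a log-normal 95% CI,
* PRR  — proportional reporting ratio with a Yates-corrected chi-square,
* BCPNN information component in the shrinkage observed/expected form
  ``IC = log2((a+0.5)/(E+0.5))`` with the closed-form credibility bound
  ``IC025 = IC - 3.3 (a+0.5)^{-1/2} - 2.4 (a+0.5)^{-1}``,
* MGPS — empirical-Bayes geometric mean (EBGM) and its 5th posterior
  percentile (EBGM05) under a two-component gamma mixture prior fitted by
  marginal maximum likelihood across all drug-event pairs.

A pair is a signal only when every detector clears its threshold
(conjunctive gate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import DataError, FitError


@dataclass(frozen=True)
class ContingencyTable:
    """Counts for one drug-event pair against the database background.

    ``a``: target drug & target term, ``b``: target drug & other terms,
    ``c``: other drugs & target term, ``d``: other drugs & other terms.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count of cell ``a`` under row/column independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n


def build_tables(cohort_pt_pairs: Iterable[Tuple[int, str]],
                 all_pt_pairs: Iterable[Tuple[int, str]],
                 ) -> Dict[str, ContingencyTable]:
    """One 2x2 table per term, counting distinct reports.

    ``cohort_pt_pairs`` are (report id, term) pairs for the cohort;
    ``all_pt_pairs`` for the full database (cohort included).  Repeated
    mentions of a term within a report count once.
    """
    cohort = pd.DataFrame(cohort_pt_pairs, columns=["pid", "term"])
    everything = pd.DataFrame(all_pt_pairs, columns=["pid", "term"])
    if len(everything) == 0:
        raise DataError("empty report database")
    cohort = cohort.drop_duplicates()
    everything = everything.drop_duplicates()

    cohort_pids = set(cohort["pid"].unique())
    n_cohort = len(cohort_pids)
    n_total = everything["pid"].nunique()
    n_background = n_total - n_cohort

    a_counts = cohort.groupby("term", sort=True)["pid"].nunique()
    background = everything[~everything["pid"].isin(cohort_pids)]
    c_counts = background.groupby("term", sort=True)["pid"].nunique()

    tables: Dict[str, ContingencyTable] = {}
    for term in sorted(set(a_counts.index) | set(c_counts.index)):
        a = int(a_counts.get(term, 0))
        c = int(c_counts.get(term, 0))
        tables[term] = ContingencyTable(a, n_cohort - a, c, n_background - c)
    return tables


# --------------------------------------------------------------------------
# frequentist statistics

@dataclass(frozen=True)
class RorResult:
    ror: float
    lo: float
    hi: float
    reason: Optional[str] = None

    @property
    def defined(self) -> bool:
        return self.reason is None


def ror_stat(t: ContingencyTable) -> RorResult:
    """Reporting odds ratio ``ad/(bc)`` with 95% log-normal CI.

    Any zero cell makes the statistic undefined (no continuity
    correction is applied by default).
    """
    if min(t.a, t.b, t.c, t.d) == 0:
        return RorResult(math.nan, math.nan, math.nan,
                         reason="zero cell in 2x2 table")
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    half = 1.96 * se
    return RorResult(ror, ror * math.exp(-half), ror * math.exp(half))


@dataclass(frozen=True)
class PrrResult:
    prr: float
    chi2: float
    reason: Optional[str] = None

    @property
    def defined(self) -> bool:
        return self.reason is None


def prr_stat(t: ContingencyTable, yates: bool = True) -> PrrResult:
    """PRR = (a/(a+b)) / (c/(c+d)) with a (Yates-corrected) chi-square."""
    if t.a + t.b == 0 or t.c + t.d == 0 or t.a + t.c == 0:
        return PrrResult(math.nan, math.nan, reason="empty margin")
    if t.c == 0:
        return PrrResult(math.nan, math.nan,
                         reason="no background reports with term")
    if t.a == 0:
        prr = 0.0
    else:
        prr = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    table = np.array([[t.a, t.b], [t.c, t.d]])
    if table[:, 1].sum() == 0:
        chi2 = 0.0
    else:
        chi2 = float(stats.chi2_contingency(table, correction=yates)[0])
    return PrrResult(prr, chi2)


# --------------------------------------------------------------------------
# BCPNN information component

def bcpnn_ic(t: ContingencyTable) -> Tuple[float, float]:
    """Shrinkage IC and its closed-form lower 95% credibility bound."""
    e = t.expected
    shrunk = t.a + 0.5
    ic = math.log2(shrunk / (e + 0.5))
    ic025 = ic - 3.3 * shrunk ** -0.5 - 2.4 / shrunk
    return ic, ic025


def bcpnn_ic025_mc(t: ContingencyTable, n_draws: int = 100_000,
                   rng=None) -> float:
    """Monte-Carlo 2.5% posterior quantile of the IC (test oracle).

    Samples the beta-binomial posterior of the event probability in the
    cohort row under a Jeffreys-style +0.5 prior and maps draws through
    the observed/expected transform.  Used only as an independent check
    of the closed-form bound.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    e = t.expected
    p = rng.beta(t.a + 0.5, t.n - t.a + 0.5, size=n_draws)
    ic_draws = np.log2(p * t.n / (e + 0.5))
    return float(np.quantile(ic_draws, 0.025))


# --------------------------------------------------------------------------
# MGPS: gamma-mixture empirical Bayes

@dataclass(frozen=True)
class GpsPrior:
    """Hyperparameters of the two-gamma mixture prior on the rate ratio."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p_mix: float

    def __post_init__(self):
        for name in ("alpha1", "beta1", "alpha2", "beta2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.p_mix < 1.0):
            raise ValueError("p_mix must lie strictly inside (0, 1)")

    @property
    def mean(self) -> float:
        return (self.p_mix * self.alpha1 / self.beta1
                + (1 - self.p_mix) * self.alpha2 / self.beta2)


#: DuMouchel's classic starting point (alpha1, beta1, alpha2, beta2, p_mix)
GPS_INIT = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


def _nb_logpmf(a, alpha, beta, e):
    """log P(a) for a gamma-Poisson mixture: lambda~Gamma(alpha, beta),
    a~Poisson(lambda*e); a negative binomial with size alpha and
    success probability beta/(beta+e)."""
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    logp = np.log(beta / (beta + e))
    log1mp = np.log(e / (beta + e))
    return (special.gammaln(alpha + a) - special.gammaln(alpha)
            - special.gammaln(a + 1) + alpha * logp + a * log1mp)


def gps_loglik(params: Sequence[float], a: np.ndarray, e: np.ndarray,
               weights: Optional[np.ndarray] = None) -> float:
    """Marginal log-likelihood of observed counts under the mixture prior."""
    alpha1, beta1, alpha2, beta2, p_mix = params
    l1 = _nb_logpmf(a, alpha1, beta1, e)
    l2 = _nb_logpmf(a, alpha2, beta2, e)
    m = np.logaddexp(np.log(p_mix) + l1, np.log1p(-p_mix) + l2)
    if weights is None:
        return float(m.sum())
    return float((m * weights).sum())


def gps_fit(tables: Iterable[ContingencyTable],
            init: Sequence[float] = GPS_INIT,
            tol: float = 1e-6,
            max_iter: int = 500,
            single_component: bool = False) -> GpsPrior:
    """Fit the mixture prior by deterministic quasi-Newton ML.

    Parameters are optimized on the log scale (logit for the weight) so
    positivity holds by construction.  ``single_component=True`` pins the
    mixture weight to (effectively) one gamma component, fitted into the
    (alpha2, beta2) slot — used for parameter-recovery checks.
    """
    tables = list(tables)
    a = np.array([t.a for t in tables], dtype=float)
    e = np.array([t.expected for t in tables], dtype=float)
    keep = e > 0
    a, e = a[keep], e[keep]
    if len(a) == 0:
        raise DataError("no tables with positive expected counts")

    # collapse identical (a, E) pairs to weighted unique rows for speed
    pairs = np.column_stack([a, e])
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    weights = np.bincount(inverse).astype(float)
    ua, ue = uniq[:, 0], uniq[:, 1]

    trace: List[float] = []

    if single_component:
        def objective(x):
            alpha, beta = np.exp(x)
            ll = float((_nb_logpmf(ua, alpha, beta, ue) * weights).sum())
            trace.append(ll)
            return -ll

        x0 = np.log([init[2], init[3]])
    else:
        def objective(x):
            alpha1, beta1, alpha2, beta2 = np.exp(x[:4])
            p_mix = special.expit(x[4])
            ll = gps_loglik((alpha1, beta1, alpha2, beta2, p_mix),
                            ua, ue, weights)
            trace.append(ll)
            return -ll

        x0 = np.concatenate([np.log(init[:4]),
                             [special.logit(init[4])]])

    res = optimize.minimize(
        objective, x0, method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8})
    if not res.success and res.status != 2:  # 2: precision-loss stop is fine
        raise FitError(f"MGPS prior fit did not converge: {res.message}",
                       last_iterate=res.x, trace=trace)
    if single_component:
        alpha, beta = np.exp(res.x)
        return GpsPrior(alpha1=alpha, beta1=beta, alpha2=alpha, beta2=beta,
                        p_mix=0.5)
    alpha1, beta1, alpha2, beta2 = np.exp(res.x[:4])
    p_mix = float(np.clip(special.expit(res.x[4]), 1e-12, 1 - 1e-12))
    return GpsPrior(alpha1, beta1, alpha2, beta2, p_mix)


def posterior_mixture(t: ContingencyTable, prior: GpsPrior
                      ) -> Tuple[float, Tuple[float, float], Tuple[float, float]]:
    """Posterior over the rate ratio: weight and two gamma components.

    Returns ``(q, (shape1, rate1), (shape2, rate2))`` where ``q`` is the
    posterior probability of the first component.
    """
    e = t.expected
    l1 = _nb_logpmf(t.a, prior.alpha1, prior.beta1, e)
    l2 = _nb_logpmf(t.a, prior.alpha2, prior.beta2, e)
    log_q = (np.log(prior.p_mix) + l1
             - np.logaddexp(np.log(prior.p_mix) + l1,
                            np.log1p(-prior.p_mix) + l2))
    q = float(np.exp(log_q))
    return (q, (prior.alpha1 + t.a, prior.beta1 + e),
            (prior.alpha2 + t.a, prior.beta2 + e))


def posterior_cdf(x: float, t: ContingencyTable, prior: GpsPrior) -> float:
    q, (s1, r1), (s2, r2) = posterior_mixture(t, prior)
    return (q * stats.gamma.cdf(x, s1, scale=1 / r1)
            + (1 - q) * stats.gamma.cdf(x, s2, scale=1 / r2))


def ebgm_stat(t: ContingencyTable, prior: GpsPrior,
              cdf_tol: float = 1e-6) -> Tuple[float, float]:
    """EBGM (posterior geometric mean) and EBGM05 (5th percentile).

    EBGM uses the digamma closed form for E[ln lambda]; EBGM05 is found
    by root-finding on the posterior-mixture CDF to ``cdf_tol``.
    """
    if t.expected <= 0:
        raise DataError("expected count must be positive")
    q, (s1, r1), (s2, r2) = posterior_mixture(t, prior)
    mean_log = (q * (special.digamma(s1) - math.log(r1))
                + (1 - q) * (special.digamma(s2) - math.log(r2)))
    ebgm = float(np.exp(mean_log))

    # bracket the 5th percentile of the mixture by component quantiles
    q1 = stats.gamma.ppf(0.05, s1, scale=1 / r1)
    q2 = stats.gamma.ppf(0.05, s2, scale=1 / r2)
    lo, hi = 0.5 * min(q1, q2), 2.0 * max(q1, q2)

    def f(x):
        return posterior_cdf(x, t, prior) - 0.05

    ebgm05 = float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16))
    assert abs(posterior_cdf(ebgm05, t, prior) - 0.05) < cdf_tol
    return ebgm, ebgm05


# --------------------------------------------------------------------------
# conjunctive signal gate

@dataclass(frozen=True)
class SignalThresholds:
    """Field-standard conjunctive criteria, all configurable."""

    min_a: int = 3
    ror_lo_gt: float = 1.0
    prr_ge: float = 2.0
    chi2_ge: float = 4.0
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0


@dataclass
class SignalMetrics:
    a: int
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    flags: Dict[str, bool] = field(default_factory=dict)
    positive: bool = False
    reasons: List[str] = field(default_factory=list)


def evaluate_signal(metrics: SignalMetrics, t: ContingencyTable,
                    thresholds: SignalThresholds) -> bool:
    """Conjunction of the four per-algorithm criteria plus the count gate."""
    reasons: List[str] = []
    flags: Dict[str, bool] = {}

    count_ok = t.a >= thresholds.min_a
    if not count_ok:
        reasons.append(f"a={t.a} below min_a={thresholds.min_a}")
    flags["count"] = count_ok

    if math.isnan(metrics.ror_lo):
        flags["ror"] = False
        reasons.append("ROR undefined (zero cell)")
    else:
        flags["ror"] = metrics.ror_lo > thresholds.ror_lo_gt

    if math.isnan(metrics.prr) or math.isnan(metrics.chi2):
        flags["prr"] = False
        reasons.append("PRR undefined")
    else:
        flags["prr"] = (metrics.prr >= thresholds.prr_ge
                        and metrics.chi2 >= thresholds.chi2_ge)

    flags["bcpnn"] = metrics.ic025 > thresholds.ic025_gt
    flags["mgps"] = metrics.ebgm05 > thresholds.ebgm05_gt

    metrics.flags = flags
    metrics.reasons = reasons
    metrics.positive = all(flags.values())
    return metrics.positive


def compute_metrics(t: ContingencyTable, prior: GpsPrior,
                    thresholds: Optional[SignalThresholds] = None,
                    yates: bool = True) -> SignalMetrics:
    """All four statistics plus the conjunctive verdict for one table."""
    ror = ror_stat(t)
    prr = prr_stat(t, yates=yates)
    ic, ic025 = bcpnn_ic(t)
    ebgm, ebgm05 = ebgm_stat(t, prior)
    metrics = SignalMetrics(
        a=t.a, ror=ror.ror, ror_lo=ror.lo, ror_hi=ror.hi,
        prr=prr.prr, chi2=prr.chi2, ic=ic, ic025=ic025,
        ebgm=ebgm, ebgm05=ebgm05)
    evaluate_signal(metrics, t, thresholds or SignalThresholds())
    return metrics
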