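"""Mismatch distributions and sudden-expansion dating.

The sudden-expansion model: a population at mutation-scaled size theta0
instantaneously grows to theta1 at time tau before present, tau measured in
units of mutational time (tau = 2*mu*t with mu the per-locus per-generation
rate and t in generations).  The expected distribution of pairwise nucleotide
differences has a closed form; writing Fhat_j(theta) = theta^j/(theta+1)^(j+1)
for the equilibrium geometric law and a = (theta1+1)/theta1,

    F_j(tau, theta0, theta1)
        = Fhat_j(theta1) * P[Gamma(j+1, a) <= tau]
        + exp(-a*tau) * sum_{m=0..j} tau^(j-m)/(j-m)! * Fhat_m(theta0)

which follows from conditioning on whether the pair coalesces before or after
the expansion.  Parameters are estimated by least squares on the observed
frequencies; goodness of fit and the tau confidence interval come from a
parametric bootstrap (coalescent simulation under the fitted model).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .haplotypes import HaplotypeAlignment, InputError, n_differences


@dataclass
class RateModel:
    """Substitution-rate and generation-time constants for dating.

    mu_site_year: substitutions/site/year; L: locus length in sites;
    T: generation time in years.
    """

    mu_site_year: float
    L: int
    T: float

    def __post_init__(self):
        if self.mu_site_year <= 0 or self.L <= 0 or self.T <= 0:
            raise InputError("rate-model fields must all be positive")

    @property
    def mu_locus_year(self) -> float:
        return self.mu_site_year * self.L

    @property
    def mu_locus_gen(self) -> float:
        return self.mu_locus_year * self.T


@dataclass
class MismatchResult:
    histogram: np.ndarray
    tau: float
    theta0: float
    theta1: float
    r: float
    ssd: float
    p_ssd: float | None = None
    p_r: float | None = None
    tau_ci: tuple[float, float] | None = None
    boundary_fit: bool = False
    bootstrap_taus: np.ndarray | None = field(default=None, repr=False)


def mismatch_histogram(aln: HaplotypeAlignment) -> np.ndarray:
    """Normalized frequencies of pairwise nucleotide differences."""
    if aln.n < 2:
        raise InputError("need at least 2 sequences")
    from .haplotypes import pairwise_difference_matrix

    D = pairwise_difference_matrix(aln)
    iu = np.triu_indices(aln.n, k=1)
    return counts_to_histogram(np.rint(D[iu]).astype(int))


def counts_to_histogram(diffs) -> np.ndarray:
    diffs = np.asarray(diffs, dtype=int)
    hist = np.bincount(diffs)
    return hist / hist.sum()


def raggedness(histogram) -> float:
    """Harpending's raggedness r = sum (x_i - x_{i-1})^2 including a terminal
    (0 - x_d)^2 term."""
    x = np.asarray(histogram, dtype=float)
    if x.size == 0:
        raise InputError("empty histogram")
    padded = np.concatenate([x, [0.0]])
    return float(np.sum(np.diff(padded) ** 2))


def expected_mismatch(
    tau: float, theta0: float, theta1: float, n_classes: int
) -> np.ndarray:
    """Closed-form sudden-expansion class probabilities F_0..F_{n_classes-1}."""
    j = np.arange(n_classes)
    fhat0 = _geom(theta0, j)
    with np.errstate(under="ignore", divide="ignore"):
        if tau > 0:
            pois = np.exp(j * math.log(tau) - tau - special.gammaln(j + 1.0))
        else:
            pois = np.zeros(n_classes)
            pois[0] = 1.0
        # convolution sum_{m<=j} tau^{j-m}/(j-m)! e^{-tau} * Fhat_m(theta0)
        conv = np.array([np.sum(pois[: jj + 1][::-1] * fhat0[: jj + 1]) for jj in j])
        if theta1 > 0:
            fhat1 = _geom(theta1, j)
            a = (theta1 + 1.0) / theta1
            gamma_cdf = special.gammainc(j + 1, a * tau)
            # e^{-a tau} conv-with-exp(tau) factor == e^{-(a-1)tau} * pois-conv
            out = fhat1 * gamma_cdf + np.exp(-(a - 1.0) * tau) * conv
        elif tau > 0:
            # vanishing recent size: the pair coalesces immediately
            out = np.zeros(n_classes)
            out[0] = 1.0
        else:
            out = fhat0.copy()
    return out


def _geom(theta: float, j: np.ndarray) -> np.ndarray:
    if theta <= 0:
        out = np.zeros_like(j, dtype=float)
        out[0] = 1.0
        return out
    with np.errstate(under="ignore"):
        return np.exp(
            j * math.log(theta) - (j + 1.0) * math.log(theta + 1.0)
        )


def expected_mismatch_full(
    tau: float, theta0: float, theta1: float, tail: float = 1e-9
) -> np.ndarray:
    """Extend classes until cumulative probability exceeds 1 - tail."""
    n_classes = 16
    while True:
        f = expected_mismatch(tau, theta0, theta1, n_classes)
        if f.sum() >= 1.0 - tail or n_classes > 100000:
            return f
        n_classes *= 2


def _ssd(params, obs) -> float:
    tau, th0, th1 = params
    exp = expected_mismatch(tau, th0, th1, len(obs))
    return float(np.sum((obs - exp) ** 2))


_BOUNDS = [(0.0, 60.0), (0.0, 100.0), (1e-6, 5000.0)]


def _minimize(obs, starts):
    best = None
    for s in starts:
        res = optimize.minimize(
            _ssd, np.asarray(s, dtype=float), args=(obs,),
            method="L-BFGS-B", bounds=_BOUNDS,
        )
        key = (res.fun, res.x[0])
        if best is None or key < (best.fun, best.x[0]):
            best = res
    return best


def _grid_starts(obs):
    j = np.arange(len(obs))
    k = float(np.sum(obs * j))
    taus = [0.5 * t for t in range(1, 21)]
    th0s = [0.0, max(k / 2.0, 0.1)]
    th1s = [max(k, 0.5), max(10 * k, 5.0), 1000.0]
    return [(t, a, b) for t in taus for a in th0s for b in th1s]


def fit_sudden_expansion(
    histogram, n: int, bootstrap_reps: int = 1000, seed: int | None = None,
    refit_bootstrap: bool = True,
) -> MismatchResult:
    """Least-squares fit of (tau, theta0, theta1) with parametric-bootstrap
    goodness of fit and percentile tau confidence interval.

    Bootstrap replicates are coalescent simulations under the fitted model
    with the same sample size; each is refit (warm start at the point
    estimate) to produce the tau distribution, and its SSD/raggedness feed the
    p-values p_ssd and p_r (fraction of replicates with statistic >= observed,
    add-one corrected).
    """
    obs = np.asarray(histogram, dtype=float)
    if n < 8:
        raise InputError("mismatch fitting requires at least 8 sequences")
    best = _minimize(obs, _grid_starts(obs))
    if not best.success and best.fun > 1e-2:
        warnings.warn(f"optimizer did not fully converge: {best.message}")
    tau, th0, th1 = (float(v) for v in best.x)
    ssd_obs = float(best.fun)
    r_obs = raggedness(obs)
    boundary = bool(
        np.isclose(tau, _BOUNDS[0][1]) or np.isclose(th1, _BOUNDS[2][1])
        or np.allclose(obs[1:], 0.0)
    )

    p_ssd = p_r = None
    tau_ci = None
    taus = None
    if bootstrap_reps and bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        taus = np.empty(bootstrap_reps)
        ssd_count = 0
        r_count = 0
        for b in range(bootstrap_reps):
            diffs = simulate_pairwise_differences(n, tau, th0, th1, rng)
            hist_b = counts_to_histogram(diffs)
            if refit_bootstrap:
                # refits need representative starts, not just a warm start:
                # the estimator hops between local minima (e.g. theta0
                # absorbed into tau), and the tau CI must reflect that noise
                jb = np.arange(len(hist_b))
                kb = float(np.sum(hist_b * jb))
                starts_b = [
                    (tau, th0, th1),
                    (kb, 0.0, max(10.0 * kb, 5.0)),
                    (kb / 2.0, max(kb / 2.0, 0.1), 1000.0),
                ]
                fit_b = _minimize(hist_b, starts_b)
                tau_b, th0_b, th1_b = fit_b.x
                ssd_b = float(fit_b.fun)
            else:
                tau_b = tau
                ssd_b = _ssd((tau, th0, th1), hist_b)
            taus[b] = tau_b
            if ssd_b >= ssd_obs:
                ssd_count += 1
            if raggedness(hist_b) >= r_obs:
                r_count += 1
        p_ssd = (1 + ssd_count) / (bootstrap_reps + 1)
        p_r = (1 + r_count) / (bootstrap_reps + 1)
        tau_ci = (
            float(np.percentile(taus, 2.5)),
            float(np.percentile(taus, 97.5)),
        )
    return MismatchResult(
        histogram=obs, tau=tau, theta0=th0, theta1=th1, r=r_obs, ssd=ssd_obs,
        p_ssd=p_ssd, p_r=p_r, tau_ci=tau_ci, boundary_fit=boundary,
        bootstrap_taus=taus,
    )


def simulate_pairwise_differences(
    n: int, tau: float, theta0: float, theta1: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Coalescent simulation of the sudden-expansion model in mutational time.

    Time unit x = 2*mu_locus*t; pairwise coalescence rate 1/theta(x); each
    lineage mutates at rate 1/2 per unit x (so a pair accumulates Poisson(x)
    differences).  Returns the n(n-1)/2 pairwise difference counts.
    """
    masks = [1 << i for i in range(n)]
    opens = [0.0] * n
    branches: list[tuple[int, float]] = []
    t = 0.0
    k = n
    theta_floor = 1e-8
    while k > 1:
        theta = theta1 if t < tau else theta0
        rate = (k * (k - 1) / 2.0) / max(theta, theta_floor)
        if theta <= theta_floor:
            # effectively instantaneous coalescence in a vanishing epoch
            w = 0.0
        else:
            w = rng.exponential(1.0 / rate)
        if t < tau and t + w > tau:
            dt = tau - t
            opens = [o + dt for o in opens]
            t = tau
            continue
        opens = [o + w for o in opens]
        t += w
        i, j = sorted(rng.choice(k, size=2, replace=False))
        branches.append((masks[i], opens[i]))
        branches.append((masks[j], opens[j]))
        merged = masks[i] | masks[j]
        masks = [m for idx, m in enumerate(masks) if idx not in (i, j)] + [merged]
        opens = [o for idx, o in enumerate(opens) if idx not in (i, j)] + [0.0]
        k -= 1

    diff = np.zeros((n, n), dtype=np.int64)
    idx = np.arange(n)
    for mask, length in branches:
        nm = rng.poisson(length / 2.0)
        if nm == 0:
            continue
        carriers = np.array(
            [bool(mask >> i & 1) for i in range(n)]
        )
        diff[np.ix_(carriers, ~carriers)] += nm
    iu = np.triu_indices(n, k=1)
    sym = diff + diff.T
    return sym[iu]


def expansion_time(
    tau: float, rates: RateModel, mode: str = "study",
    ci: tuple[float, float] | None = None,
):
    """Convert the expansion parameter tau to years before present.

    ``study`` mode replicates the source study's arithmetic,
    t_years = tau * T / (2 * mu_locus_year), which treats tau = 2*mu*t with mu
    per locus per year and then multiplies by generation time; ``dimensional``
    drops the generation-time factor (t_years = tau / (2 * mu_locus_year)).
    Returns years, or (years, (lo, hi)) when a tau CI is given.
    """
    if tau < 0:
        raise InputError("tau must be nonnegative")
    if mode == "study":
        conv = rates.T / (2.0 * rates.mu_locus_year)
    elif mode == "dimensional":
        conv = 1.0 / (2.0 * rates.mu_locus_year)
    else:
        raise InputError(f"unknown mode {mode!r}")
    t_years = tau * conv
    if ci is None:
        return t_years
    lo, hi = sorted(ci)
    return t_years, (lo * conv, hi * conv)
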