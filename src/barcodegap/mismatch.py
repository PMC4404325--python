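"""Mismatch distributions, sudden-expansion fitting, and expansion dating.

The mismatch distribution is the histogram of pairwise difference counts
in a population sample.  Under a sudden demographic expansion — a
population jumping from scaled size theta0 to theta1 at tau mutational
time units ago — it is smooth and unimodal with mode near tau; under
stationarity it is geometric-ish and ragged.  The expectation used here
is derived exactly from the coalescence-time density of a pair of
lineages under the two-epoch demography:

    f(x) = (1/theta1) exp(-x/theta1)                       for x < tau
    f(x) = exp(-tau/theta1) (1/theta0) exp(-(x-tau)/theta0) for x >= tau

mixed with Poisson(x) differences, which integrates to incomplete-gamma
closed forms.  This equals the classical sudden-expansion expectation
(it reduces to the stationary geometric F_i = theta^i/(1+theta)^(i+1)
when theta0 = theta1 and to the Poisson e^(-tau) tau^i / i! pulse in the
limit theta0 -> 0, theta1 -> inf).

A spatial-expansion variant adds a scaled migration parameter M under an
infinite-island "escape" model: a sampled pair coalesces within its deme
at rate 1/theta or separates at pair rate M/theta until tau, after which
all lineages coalesce panmictically.  The literature only exercises this
model through its goodness-of-fit p-value, so it is flagged experimental.

Fitting minimizes the sum of squared deviations (SSD) between observed
and expected relative frequencies; significance comes from a parametric
bootstrap (simulate under the fitted model, refit, compare SSD and
Harpending's raggedness).  Dated expansions convert tau to years via a
per-year per-sequence mutation rate built from a pairwise divergence
rate and a generations-per-year figure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammainc, gammaincc
from scipy.stats import qmc

from .coalescent import (
    SuddenExpansion,
    drop_mutations,
    mismatch_counts_from_mutations,
    simulate_genealogy,
    simulate_structured_genealogy,
)
from .popgen import _encode_matrix

THETA1_CAP = 1e6  # operational infinity for the post-expansion size


@dataclass
class MismatchFit:
    observed: np.ndarray          # counts per difference class 0..d
    model: str                    # stationary | demographic | spatial
    params: dict                  # tau, theta0, theta1 (or tau, theta, M)
    ssd: float
    raggedness: float
    p_ssd: float | None = None
    p_rg: float | None = None
    bootstrap_reps: int = 0
    expected: np.ndarray | None = field(default=None, repr=False)

    @property
    def tau(self) -> float:
        return self.params.get("tau", math.nan)


@dataclass
class ExpansionDate:
    tau: float
    L: int = 640
    generations_per_year: float = 13.5
    divergence_rate_per_my: float = 0.065  # pairwise, per million years
    u_per_generation: float = 0.0          # per sequence, derived
    t_generations: float = 0.0
    t_years: float = 0.0


def mismatch_distribution(seqs: list[str]) -> np.ndarray:
    """Counts of pairwise difference values over all C(n,2) pairs."""
    mat = _encode_matrix(seqs)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least two sequences")
    diffs = []
    for i in range(n):
        both = (mat[i] >= 0) & (mat[i + 1 :] >= 0)
        diffs.extend(((mat[i] != mat[i + 1 :]) & both).sum(axis=1).tolist())
    return np.bincount(np.asarray(diffs, dtype=np.int64))


def _poisson_mix_lower(rate: float, scale_log: float, j: np.ndarray, tau: float):
    """int_0^tau rate * e^{-x*a} x^j/j! dx with a = 1 + rate (see module doc)."""
    a = 1.0 + rate
    return rate * np.exp(
        scale_log - (j + 1.0) * math.log(a)
    ) * gammainc(j + 1.0, a * tau)


def _log_gammaincc(a: np.ndarray, z: float) -> np.ndarray:
    """log of the regularized upper incomplete gamma Q(a, z).

    Direct evaluation where Q is representable; for extreme z (strong
    expansions push z ~ tau/theta0 far beyond the underflow range) it
    falls back on the asymptotic series
    Q(a, z) ~ z^{a-1} e^{-z} / Gamma(a) * sum_k (a-1)...(a-k) / z^k.
    """
    q = gammaincc(a, z)
    with np.errstate(divide="ignore"):
        out = np.log(q)
    bad = ~np.isfinite(out)
    if bad.any():
        ab = a[bad]
        series = np.ones_like(ab)
        term = np.ones_like(ab)
        for k in range(1, 12):
            term = term * (ab - k) / z
            series = series + term
        out[bad] = (
            (ab - 1.0) * math.log(z)
            - z
            - np.array([math.lgamma(v) for v in ab])
            + np.log(np.maximum(series, 1e-300))
        )
    return out


def _poisson_mix_upper(rate: float, scale_log: float, j: np.ndarray, tau: float):
    """rate * e^{scale_log} * int_tau^inf e^{-x*b} x^j/j! dx, b = 1 + rate.

    Evaluated in log space so that the huge e^{tau/theta0} factors
    typical of strong expansions cannot overflow.
    """
    b = 1.0 + rate
    if tau <= 0:
        return rate * np.exp(scale_log - (j + 1.0) * math.log(b))
    logq = _log_gammaincc(j + 1.0, b * tau)
    return rate * np.exp(scale_log - (j + 1.0) * math.log(b) + logq)


def expected_mismatch(
    model: str, params: dict, d_max: int
) -> np.ndarray:
    """Expected relative frequencies F_0..F_{d_max}, tail folded into last.

    Models: ``stationary`` (theta), ``demographic`` (tau, theta0,
    theta1; theta1 may be inf), ``spatial`` (tau, theta, M).
    """
    j = np.arange(d_max + 1, dtype=float)
    if model == "stationary":
        theta = params["theta"]
        if theta < 0:
            raise ValueError("theta must be non-negative")
        if theta == 0:
            f = np.zeros(d_max + 1)
            f[0] = 1.0
            return f
        f = np.exp(
            j * math.log(theta) - (j + 1.0) * math.log(1.0 + theta)
        )
    elif model == "demographic":
        tau, theta0, theta1 = params["tau"], params["theta0"], params["theta1"]
        if tau < 0 or theta0 < 0 or (theta1 < 0):
            raise ValueError("negative expansion parameters")
        theta0 = max(theta0, 1e-9)
        theta1 = min(theta1, THETA1_CAP) if math.isfinite(theta1) else THETA1_CAP
        f = _poisson_mix_lower(1.0 / theta1, 0.0, j, tau)
        f = f + _poisson_mix_upper(
            1.0 / theta0, tau / theta0 - tau / theta1, j, tau
        )
    elif model == "spatial":
        tau, theta, M = params["tau"], params["theta"], params["M"]
        if tau < 0 or theta < 0 or M < 0:
            raise ValueError("negative spatial-expansion parameters")
        theta = max(theta, 1e-9)
        a_rate = (1.0 + M) / theta
        # coalescence before tau: pair still together, rate 1/theta
        a = 1.0 + a_rate
        f = (1.0 / theta) * np.exp(
            -(j + 1.0) * math.log(a)
        ) * gammainc(j + 1.0, a * tau)
        # mass reaching tau uncoalesced (together or escaped)
        log_surv = -a_rate * tau
        c = math.exp(log_surv) + (M / (1.0 + M)) * (1.0 - math.exp(log_surv))
        f = f + c * _poisson_mix_upper(1.0 / theta, tau / theta, j, tau)
    else:
        raise ValueError(f"unknown mismatch model: {model}")
    f = np.clip(f, 0.0, None)
    total = f.sum()
    f[-1] += max(0.0, 1.0 - total)  # fold tail mass into the last class
    return f


def raggedness(frequencies) -> float:
    """Harpending's raggedness rg = sum_i (x_i - x_{i-1})^2, i = 1..d."""
    x = np.asarray(frequencies, dtype=float)
    if x.size < 2:
        return 0.0
    return float(np.sum(np.diff(x) ** 2))


def _ssd(observed_rel: np.ndarray, model: str, params: dict) -> float:
    exp_f = expected_mismatch(model, params, observed_rel.size - 1)
    return float(np.sum((observed_rel - exp_f) ** 2))


_BOUNDS = {
    # parameterization: demographic (tau, theta0, 1/theta1), spatial
    # (tau, theta, M), stationary (theta,)
    "demographic": [(0.0, None), (1e-9, 50.0), (1e-9, 2.0)],
    "spatial": [(0.0, None), (1e-9, 50.0), (1e-9, 50.0)],
    "stationary": [(1e-9, 200.0)],
}


def _unpack(model: str, x: np.ndarray) -> dict:
    if model == "demographic":
        return {"tau": x[0], "theta0": x[1], "theta1": 1.0 / x[2]}
    if model == "spatial":
        return {"tau": x[0], "theta": x[1], "M": x[2]}
    return {"theta": x[0]}


def fit_expansion(
    observed,
    model: str = "demographic",
    bootstrap_reps: int = 16000,
    seed: int = 0,
    n_starts: int = 8,
    sample_size: int | None = None,
) -> MismatchFit:
    """Least-squares fit of a mismatch model, with parametric bootstrap.

    ``observed`` is the vector of difference-class counts.  The SSD
    between observed and expected relative frequencies is minimized with
    L-BFGS-B from ``n_starts`` Latin-hypercube starting points (theta1
    enters as 1/theta1 in [0, 2] so an effectively infinite
    post-expansion size is reachable).  Set ``bootstrap_reps=0`` to skip
    the bootstrap; otherwise ``sample_size`` (the n behind the observed
    distribution) is required to resimulate samples under the fitted
    model, refit each, and report p_SSD and p_rg as the fraction of
    bootstrap SSD (raggedness) values at least as large as the observed.
    """
    observed = np.asarray(observed, dtype=float)
    if (observed > 0).sum() < 2 and model != "stationary":
        raise ValueError("need at least two occupied difference classes")
    rel = observed / observed.sum()
    d_max = rel.size - 1
    rng = np.random.default_rng(seed)
    bounds = [
        (lo, 2.0 * d_max if hi is None else hi) for lo, hi in _BOUNDS[model]
    ]
    ndim = len(bounds)
    sampler = qmc.LatinHypercube(d=ndim, seed=rng)
    starts = qmc.scale(
        sampler.random(n_starts),
        [b[0] for b in bounds],
        [b[1] for b in bounds],
    )
    mean_k = float(np.dot(np.arange(rel.size), rel))
    if model == "demographic":
        starts[0] = [mean_k, 0.1, 1e-3]  # moment-flavored start
    elif model == "spatial":
        starts[0] = [mean_k, 1.0, 1.0]
    else:
        starts[0] = [max(mean_k, 1e-6)]

    def objective(x: np.ndarray) -> float:
        params = _unpack(model, x)
        penalty = 0.0
        if model == "demographic" and params["theta0"] > params["theta1"]:
            penalty = 10.0 * (params["theta0"] - params["theta1"]) ** 2
        return _ssd(rel, model, params) + penalty

    best = None
    for x0 in starts:
        res = minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    params = _unpack(model, best.x)
    if model == "demographic" and params["theta1"] >= THETA1_CAP:
        params["theta1"] = math.inf
    ssd = _ssd(rel, model, params)
    rg = raggedness(rel)
    fit = MismatchFit(
        observed=observed.astype(np.int64),
        model=model,
        params=params,
        ssd=ssd,
        raggedness=rg,
        expected=expected_mismatch(model, params, d_max),
    )
    if bootstrap_reps > 0:
        if sample_size is None:
            raise ValueError("bootstrap requires sample_size")
        fit.p_ssd, fit.p_rg = _parametric_bootstrap(
            fit, sample_size, bootstrap_reps, rng
        )
        fit.bootstrap_reps = bootstrap_reps
    return fit


def _simulate_under(model: str, params: dict, n: int, rng) -> np.ndarray:
    if model == "spatial":
        g = simulate_structured_genealogy(
            n, params["theta"], params["M"], params["tau"], rng
        )
    else:
        if model == "stationary":
            demog = SuddenExpansion(params["theta"], params["theta"], 1.0)
        else:
            theta1 = min(params["theta1"], THETA1_CAP)
            demog = SuddenExpansion(
                max(params["theta0"], 1e-9), theta1, params["tau"]
            )
        g = simulate_genealogy(n, demog, rng)
    masks = drop_mutations(g, rng)
    return mismatch_counts_from_mutations(n, masks)


def _parametric_bootstrap(
    fit: MismatchFit, n: int, reps: int, rng
) -> tuple[float, float]:
    ssd_hits = 0
    rg_hits = 0
    for _ in range(reps):
        counts = _simulate_under(fit.model, fit.params, n, rng)
        if (counts > 0).sum() < 2:
            # degenerate sample (all pairs identical): refit is meaningless;
            # its SSD is 0 under the stationary-zero model
            sim_ssd, sim_rg = 0.0, raggedness(counts / counts.sum())
        else:
            seed = int(rng.integers(2**31 - 1))
            refit = fit_expansion(
                counts, model=fit.model, bootstrap_reps=0,
                seed=seed, n_starts=3,
            )
            sim_ssd, sim_rg = refit.ssd, refit.raggedness
        if sim_ssd >= fit.ssd - 1e-15:
            ssd_hits += 1
        if sim_rg >= fit.raggedness - 1e-15:
            rg_hits += 1
    return ssd_hits / reps, rg_hits / reps


def date_expansion(
    tau: float,
    L: int = 640,
    generations_per_year: float = 13.5,
    divergence_rate_per_my: float = 0.065,
) -> ExpansionDate:
    """Convert a fitted tau to an expansion time in generations and years.

    tau = 2*u*t with u the per-sequence per-generation mutation rate.
    u is built from a pairwise divergence rate (fraction per million
    years; halved for the per-lineage rate), the sequence length, and
    the number of generations per year.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    if L <= 0 or generations_per_year <= 0 or divergence_rate_per_my <= 0:
        raise ValueError("length and rates must be positive")
    u_per_year = (divergence_rate_per_my / 2.0) / 1e6 * L
    u_per_generation = u_per_year / generations_per_year
    t_generations = tau / (2.0 * u_per_generation) if tau > 0 else 0.0
    t_years = t_generations / generations_per_year
    return ExpansionDate(
        tau=tau,
        L=L,
        generations_per_year=generations_per_year,
        divergence_rate_per_my=divergence_rate_per_my,
        u_per_generation=u_per_generation,
        t_generations=t_generations,
        t_years=t_years,
    )
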