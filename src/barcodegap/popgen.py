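"""Per-population diversity and neutrality statistics.

Implements the classical summary statistics for a population sample of
aligned sequences — segregating sites S, singletons eta_s, mean pairwise
differences k, nucleotide diversity pi, haplotype diversity HD, Watterson's
theta — and the neutrality / expansion test statistics built on them:
Tajima's D, Fu & Li's D* and F* (outgroup-free forms), Fu's Fs via the
Ewens sampling formula, and Ramos-Onsins & Rozas' R2.  Significance is
assessed against simulated null distributions from the neutral coalescent
(conditioned on S or on theta), the same way DnaSP does it.  Also here:
the exact test of population differentiation on haplotype contingency
tables, and AMOVA with Phi statistics and permutation p-values.

Missing data policy (the source analyses are silent on it): pairwise
deletion for k and pi; S and singletons are counted over columns with at
least two resolved states; sites with gaps/ambiguity are ignored at those
columns only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import logsumexp

from .coalescent import (
    ConstantSize,
    SampleStats,
    simulate_sample_stats,
)
from .distances import _encode, tn93_distance


# ---------------------------------------------------------------------------
# basic diversity
# ---------------------------------------------------------------------------


@dataclass
class DiversityStats:
    n: int
    L: int
    S: int
    eta_s: int
    k: float
    pi: float
    hd: float
    theta_w: float
    K: int
    U: np.ndarray = field(repr=False, default=None)


def _encode_matrix(seqs: list[str]) -> np.ndarray:
    """n x L int matrix; ACGT -> 0..3, anything unresolved -> -1."""
    return np.stack([_encode(s) for s in seqs])


def segregating_sites(seqs: list[str]) -> tuple[int, int, np.ndarray]:
    """(S, eta_s, U) over columns with >= 2 resolved states.

    A singleton is a non-majority state carried by exactly one sequence
    (the majority state at a tied column is the alphabetically smallest
    of the tied states, so the count is deterministic); U[i] is the
    number of singletons carried by sequence i.
    """
    mat = _encode_matrix(seqs)
    n, L = mat.shape
    S = 0
    eta_s = 0
    U = np.zeros(n)
    counts = np.zeros((4, L), dtype=np.int64)
    for b in range(4):
        counts[b] = (mat == b).sum(axis=0)
    n_states = (counts > 0).sum(axis=0)
    for col in np.nonzero(n_states >= 2)[0]:
        S += 1
        col_counts = counts[:, col]
        major = int(np.argmax(col_counts))  # ties -> smallest index (A<C<G<T)
        for state in range(4):
            if state != major and col_counts[state] == 1:
                eta_s += 1
                U[int(np.nonzero(mat[:, col] == state)[0][0])] += 1
    return S, eta_s, U


def mean_pairwise_differences(seqs: list[str]) -> float:
    """Mean pairwise difference count with pairwise deletion."""
    mat = _encode_matrix(seqs)
    n = mat.shape[0]
    total = 0.0
    for i in range(n):
        both = (mat[i] >= 0) & (mat[i + 1 :] >= 0)
        total += ((mat[i] != mat[i + 1 :]) & both).sum()
    return total / (n * (n - 1) / 2.0)


def haplotype_diversity(seqs: list[str]) -> tuple[float, int]:
    """(HD, number of distinct haplotypes); HD = n(1 - sum p_i^2)/(n-1)."""
    n = len(seqs)
    counts: dict[str, int] = {}
    for s in seqs:
        counts[s] = counts.get(s, 0) + 1
    sum_p2 = sum((c / n) ** 2 for c in counts.values())
    hd = n * (1.0 - sum_p2) / (n - 1)
    return hd, len(counts)


def harmonic(n: int, power: int = 1) -> float:
    return sum(1.0 / i**power for i in range(1, n + 1))


def basic_diversity(seqs: list[str]) -> DiversityStats:
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least two sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences of unequal length")
    S, eta_s, U = segregating_sites(seqs)
    k = mean_pairwise_differences(seqs)
    hd, K = haplotype_diversity(seqs)
    a1 = harmonic(n - 1)
    return DiversityStats(
        n=n, L=L, S=S, eta_s=eta_s, k=k, pi=k / L, hd=hd,
        theta_w=S / a1, K=K, U=U,
    )


# ---------------------------------------------------------------------------
# neutrality statistics
# ---------------------------------------------------------------------------


def tajima_constants(n: int) -> dict:
    a1 = harmonic(n - 1)
    a2 = harmonic(n - 1, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(n: int, S: int, k: float) -> float:
    """Tajima (1989) D from sample size, segregating sites and k."""
    if S < 1:
        return math.nan
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    if var <= 0:
        return math.nan
    return (k - S / c["a1"]) / math.sqrt(var)


def fu_li_constants(n: int) -> dict:
    """Variance coefficients for the outgroup-free D* and F*.

    Corrected forms (Simonsen, Churchill & Aquadro 1995), as used by
    DnaSP; the originally printed coefficients contain typos.
    """
    an = harmonic(n - 1)
    bn = harmonic(n - 1, 2)
    an1 = an + 1.0 / n  # a_{n+1}
    if n > 2:
        cn = 2.0 * (n * an - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
    else:
        cn = 1.0
    if n > 2:
        dn = (
            cn
            + (n - 2.0) / (n - 1) ** 2
            + (2.0 / (n - 1)) * (1.5 - (2.0 * an1 - 3.0) / (n - 2) - 1.0 / n)
        )
    else:
        dn = 2.0
    v_d = (
        (n / (n - 1.0)) ** 2 * bn
        + an**2 * dn
        - 2.0 * (n * an * (an + 1.0)) / (n - 1.0) ** 2
    ) / (an**2 + bn)
    u_d = (n / (n - 1.0)) * (an - n / (n - 1.0)) - v_d
    v_f = (
        dn
        + 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
        - (2.0 / (n - 1.0)) * (4.0 * bn - 6.0 + 8.0 / n)
    ) / (an**2 + bn)
    u_f = (
        n / (n - 1.0)
        + (n + 1.0) / (3.0 * (n - 1.0))
        - 4.0 / (n * (n - 1.0))
        + (2.0 * (n + 1.0) / (n - 1.0) ** 2) * (an1 - 2.0 * n / (n + 1.0))
    ) / an - v_f
    return dict(an=an, bn=bn, cn=cn, dn=dn, u_d=u_d, v_d=v_d, u_f=u_f, v_f=v_f)


def fu_li_tests(n: int, S: int, eta_s: int, k: float) -> tuple[float, float]:
    """Outgroup-free Fu & Li (1993) (D*, F*) from eta = S total mutations."""
    if S < 1:
        return math.nan, math.nan
    c = fu_li_constants(n)
    eta = float(S)
    var_d = c["u_d"] * eta + c["v_d"] * eta**2
    var_f = c["u_f"] * eta + c["v_f"] * eta**2
    d_star = (
        (n / (n - 1.0)) * eta - c["an"] * eta_s
    ) / math.sqrt(var_d) if var_d > 0 else math.nan
    f_star = (
        k - ((n - 1.0) / n) * eta_s
    ) / math.sqrt(var_f) if var_f > 0 else math.nan
    return d_star, f_star


@lru_cache(maxsize=64)
def _log_stirling_row(n: int) -> tuple:
    """log |S(n, k)| for k = 0..n (unsigned Stirling numbers, 1st kind)."""
    row = np.full(2, -np.inf)
    row[1] = 0.0  # |S(1,1)| = 1
    for m in range(1, n):
        new = np.full(m + 2, -np.inf)
        # |S(m+1, k)| = m * |S(m, k)| + |S(m, k-1)|
        new[1 : m + 1] = np.logaddexp(
            math.log(m) + row[1 : m + 1], np.append(-np.inf, row[1:m])
        )
        new[m + 1] = 0.0
        row = new
    return tuple(row)


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k | theta, n) for k = 1..n under the Ewens distribution."""
    log_stirling = np.asarray(_log_stirling_row(n))[1:]
    log_rising = sum(math.log(theta + i) for i in range(n))
    ks = np.arange(1, n + 1)
    return log_stirling + ks * math.log(theta) - log_rising


def fus_fs(n: int, k: float, K_obs: int) -> float:
    """Fu's Fs = ln(S' / (1 - S')), S' = P(K >= K_obs | theta = k).

    Undefined (NaN) when k = 0 or when K_obs = 1 (S' = 1 exactly).
    """
    if k <= 0 or K_obs < 1 or K_obs > n:
        return math.nan
    if K_obs == 1:
        return math.nan  # S' = 1: +inf guarded, reported missing
    log_pmf = ewens_log_pmf(n, k)
    log_sp = logsumexp(log_pmf[K_obs - 1 :])
    log_1msp = logsumexp(log_pmf[: K_obs - 1])
    return float(log_sp - log_1msp)


def r2_from_parts(n: int, S: int, k: float, U: np.ndarray) -> float:
    if S < 1:
        return math.nan
    return float(math.sqrt(np.mean((U - k / 2.0) ** 2)) / S)


def r2_statistic(seqs: list[str]) -> float:
    """Ramos-Onsins & Rozas (2002) R2 from a population alignment."""
    d = basic_diversity(seqs)
    return r2_from_parts(d.n, d.S, d.k, d.U)


STAT_NAMES = ("D", "Dstar", "Fstar", "Fs", "R2")
#: tail convention per statistic: left-tail for Fs and R2, two-tailed else
LEFT_TAILED = {"Fs", "R2"}


def statistics_from_sample(stats: SampleStats) -> dict:
    d = tajimas_d(stats.n, stats.S, stats.k)
    d_star, f_star = fu_li_tests(stats.n, stats.S, stats.eta_s, stats.k)
    fs = fus_fs(stats.n, stats.k, stats.K)
    r2 = r2_from_parts(stats.n, stats.S, stats.k, stats.U)
    return {"D": d, "Dstar": d_star, "Fstar": f_star, "Fs": fs, "R2": r2}


def statistics_from_seqs(seqs: list[str]) -> dict:
    div = basic_diversity(seqs)
    d = tajimas_d(div.n, div.S, div.k)
    d_star, f_star = fu_li_tests(div.n, div.S, div.eta_s, div.k)
    fs = fus_fs(div.n, div.k, div.K)
    r2 = r2_from_parts(div.n, div.S, div.k, div.U)
    return {"D": d, "Dstar": d_star, "Fstar": f_star, "Fs": fs, "R2": r2}


class NeutralNull:
    """Simulated null distributions of the five test statistics.

    Built from ``reps`` standard neutral coalescent samples, conditioned
    either on a fixed number of segregating sites (``fixed_S``) or on a
    scaled mutation rate (``theta``, Poisson mutations).  p-values follow
    each statistic's convention: left-tailed for Fs and R2 (expansion
    pushes them down), two-tailed (doubled smaller tail, capped at 1)
    for D, D* and F*.
    """

    def __init__(
        self,
        n: int,
        reps: int = 16000,
        seed: int = 0,
        fixed_S: int | None = None,
        theta: float | None = None,
    ) -> None:
        if reps < 100:
            raise ValueError("need at least 100 replicates")
        if (fixed_S is None) == (theta is None):
            raise ValueError("condition on exactly one of fixed_S or theta")
        self.n = n
        self.reps = reps
        self.fixed_S = fixed_S
        self.theta = theta
        rng = np.random.default_rng(seed)
        demog = ConstantSize(theta if theta is not None else 1.0)
        null: dict[str, list[float]] = {s: [] for s in STAT_NAMES}
        for _ in range(reps):
            stats = simulate_sample_stats(n, demog, rng, fixed_S=fixed_S)
            for name, value in statistics_from_sample(stats).items():
                null[name].append(value)
        self.null = {s: np.asarray(v) for s, v in null.items()}

    def p_value(self, stat: str, observed: float) -> float:
        """Empirical mid-p against the simulated null.

        Ties get half weight (Lancaster's mid-p): under fixed-S
        conditioning statistics like D* are functions of small integers
        and fall on few atoms, where inclusive-tie counting would make
        the two-tailed test badly conservative.
        """
        if math.isnan(observed):
            return math.nan
        values = self.null[stat]
        values = values[~np.isnan(values)]
        if values.size == 0:
            return math.nan
        lt = float(np.mean(values < observed))
        eq = float(np.mean(values == observed))
        lo = lt + eq / 2.0
        if stat in LEFT_TAILED:
            return lo
        hi = 1.0 - lt - eq / 2.0
        return min(1.0, 2.0 * min(lo, hi))

    def p_values(self, observed: dict) -> dict:
        return {s: self.p_value(s, observed[s]) for s in STAT_NAMES}


def neutral_null(
    n: int,
    conditioning: tuple[str, float],
    reps: int = 16000,
    seed: int = 0,
) -> NeutralNull:
    """Convenience constructor: conditioning = ("S", value) or ("theta", value)."""
    mode, value = conditioning
    if mode == "S":
        return NeutralNull(n, reps=reps, seed=seed, fixed_S=int(value))
    if mode == "theta":
        return NeutralNull(n, reps=reps, seed=seed, theta=float(value))
    raise ValueError(f"unknown conditioning mode: {mode}")


# ---------------------------------------------------------------------------
# exact test of differentiation
# ---------------------------------------------------------------------------


@dataclass
class DifferentiationResult:
    populations: tuple
    p_value: float
    method: str  # "exact" or "monte-carlo"
    replicates: int


class _EnumerationCap(Exception):
    pass


def _log_table_prob(table: np.ndarray, log_margin_const: float) -> float:
    return log_margin_const - sum(
        math.lgamma(v + 1.0) for v in table.ravel()
    )


def exact_differentiation(
    counts,
    reps: int = 100000,
    seed: int = 0,
    enumeration_cap: int = 1_000_000,
) -> DifferentiationResult:
    """Exact test of differentiation on a haplotype x population table.

    p is the total probability, under fixed margins, of tables as likely
    or less likely than the observed one.  Computed by complete
    enumeration when the table universe is small (at most
    ``enumeration_cap`` tables), otherwise by Monte-Carlo sampling of
    margin-preserving tables via random reassignment of individuals to
    populations.
    """
    table = np.asarray(counts, dtype=np.int64)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need a table with >= 2 haplotypes and >= 2 populations")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if (cols == 0).any():
        raise ValueError("population with zero samples")
    table = table[rows > 0]
    rows = rows[rows > 0]
    n_total = int(table.sum())
    log_margin_const = (
        sum(math.lgamma(r + 1.0) for r in rows)
        + sum(math.lgamma(c + 1.0) for c in cols)
        - math.lgamma(n_total + 1.0)
    )
    log_p_obs = _log_table_prob(table, log_margin_const)
    tol = 1e-9

    # --- complete enumeration with a visited-table cap ----------------
    r, c = table.shape
    visited = 0
    acc_logs: list[float] = []

    def recurse(row: int, col_rem: np.ndarray, current_log_fact: float) -> None:
        nonlocal visited
        if row == r - 1:
            visited += 1
            if visited > enumeration_cap:
                raise _EnumerationCap
            lp = (
                log_margin_const
                - current_log_fact
                - sum(math.lgamma(v + 1.0) for v in col_rem)
            )
            if lp <= log_p_obs + tol:
                acc_logs.append(lp)
            return
        # enumerate row `row` cell by cell
        def fill(col: int, rem: int, col_rem2: np.ndarray, logf: float) -> None:
            if col == c - 1:
                if col_rem2[col] >= rem:
                    nxt = col_rem2.copy()
                    nxt[col] -= rem
                    recurse(row + 1, nxt, logf + math.lgamma(rem + 1.0))
                return
            hi = min(rem, col_rem2[col])
            for v in range(hi + 1):
                nxt = col_rem2.copy()
                nxt[col] -= v
                fill(col + 1, rem - v, nxt, logf + math.lgamma(v + 1.0))

        fill(0, int(rows[row]), col_rem, current_log_fact)

    try:
        recurse(0, cols.copy(), 0.0)
        p = float(np.exp(logsumexp(acc_logs))) if acc_logs else 0.0
        return DifferentiationResult(
            tuple(range(c)), min(p, 1.0), "exact", visited
        )
    except _EnumerationCap:
        pass

    # --- Monte-Carlo fallback ------------------------------------------
    rng = np.random.default_rng(seed)
    hap_of_individual = np.repeat(np.arange(r), rows)
    pop_sizes = cols
    hits = 0
    for _ in range(reps):
        perm = rng.permutation(hap_of_individual)
        sim = np.zeros((r, c), dtype=np.int64)
        start = 0
        for j, size in enumerate(pop_sizes):
            np.add.at(sim[:, j], perm[start : start + size], 1)
            start += size
        if _log_table_prob(sim, log_margin_const) <= log_p_obs + tol:
            hits += 1
    p = (hits + 1.0) / (reps + 1.0)
    return DifferentiationResult(tuple(range(c)), p, "monte-carlo", reps)


def haplotype_count_table(membership: dict, pop_of_sample: dict, pops=None):
    """Build a haplotype x population count matrix from table membership."""
    if pops is None:
        pops = sorted({pop_of_sample[s] for s in membership})
    haps = sorted({h for h in membership.values()})
    table = np.zeros((len(haps), len(pops)), dtype=np.int64)
    hidx = {h: i for i, h in enumerate(haps)}
    pidx = {p: j for j, p in enumerate(pops)}
    for s, h in membership.items():
        p = pop_of_sample.get(s)
        if p in pidx:
            table[hidx[h], pidx[p]] += 1
    return table, haps, list(pops)


def pool_populations(
    pops: dict,
    species_of_pop: dict | None = None,
    alpha: float = 0.05,
    min_n: int = 7,
    reps: int = 20000,
    seed: int = 0,
):
    """Pool populations that an exact test cannot distinguish.

    Populations with n >= ``min_n`` sharing a putative species are merged
    whenever their pairwise exact-test p-value is >= alpha.  Returns
    (pooled mapping pop -> pooled label, list of log lines).
    """
    names = sorted(pops)
    parent = {p: p for p in names}

    def find(p):
        while parent[p] != p:
            parent[p] = parent[parent[p]]
            p = parent[p]
        return p

    log: list[str] = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if len(pops[a]) < min_n or len(pops[b]) < min_n:
                continue
            if species_of_pop and species_of_pop.get(a) != species_of_pop.get(b):
                continue
            seqs = list(pops[a]) + list(pops[b])
            uniq = {s: idx for idx, s in enumerate(dict.fromkeys(seqs))}
            table = np.zeros((len(uniq), 2), dtype=np.int64)
            for s in pops[a]:
                table[uniq[s], 0] += 1
            for s in pops[b]:
                table[uniq[s], 1] += 1
            res = exact_differentiation(table, reps=reps, seed=seed)
            if res.p_value >= alpha:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
                log.append(
                    f"pooled {a}+{b} (exact test p={res.p_value:.3f})"
                )
            else:
                log.append(
                    f"kept {a} vs {b} separate (exact test p={res.p_value:.3f})"
                )
    return {p: find(p) for p in names}, log


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


@dataclass
class AmovaResult:
    components: dict          # sigma2_a (among groups), sigma2_b, sigma2_c
    phi: dict                 # Phi_ST, Phi_SC, Phi_CT as applicable
    p_values: dict
    permutations: int
    excluded: list = field(default_factory=list)


def _pairwise_sq_tn93(seqs: list[str]) -> np.ndarray:
    n = len(seqs)
    d2 = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = tn93_distance(seqs[i], seqs[j])
            if math.isnan(d):  # saturated pair: fall back on max finite later
                d = np.nan
            d2[i, j] = d2[j, i] = d * d
    if np.isnan(d2).any():
        mx = np.nanmax(d2)
        d2 = np.where(np.isnan(d2), mx, d2)
    return d2


def _ssd_within(d2: np.ndarray, index_groups: list[np.ndarray]) -> float:
    total = 0.0
    for idx in index_groups:
        if idx.size >= 2:
            sub = d2[np.ix_(idx, idx)]
            total += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    return total


def _amova_decompose(d2, pop_idx: list[np.ndarray], group_of_pop: list[int]):
    n_total = d2.shape[0]
    all_idx = np.arange(n_total)
    n_groups = len(set(group_of_pop))
    n_pops = len(pop_idx)
    ssd_total = d2[np.triu_indices(n_total, k=1)].sum() / n_total
    ssd_wp = _ssd_within(d2, pop_idx)
    group_members: dict[int, list[np.ndarray]] = {}
    for pidx, g in zip(pop_idx, group_of_pop):
        group_members.setdefault(g, []).append(pidx)
    group_idx = [np.concatenate(v) for v in group_members.values()]
    ssd_wg = _ssd_within(d2, group_idx)
    ssd_ap = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg

    sizes = np.array([idx.size for idx in pop_idx], dtype=float)
    gsizes = {g: sum(p.size for p in v) for g, v in group_members.items()}
    sigma_c = ssd_wp / (n_total - n_pops) if n_total > n_pops else 0.0
    if n_groups < n_pops:
        s2g = {
            g: sum(p.size**2 for p in v) for g, v in group_members.items()
        }
        n1 = (n_total - sum(s2g[g] / gsizes[g] for g in s2g)) / (
            n_pops - n_groups
        )
        msd_ap = ssd_ap / (n_pops - n_groups)
        sigma_b = (msd_ap - sigma_c) / n1
    else:
        sigma_b = 0.0
    if n_groups > 1:
        s2g = {
            g: sum(p.size**2 for p in v) for g, v in group_members.items()
        }
        s2 = float((sizes**2).sum())
        n2 = (sum(s2g[g] / gsizes[g] for g in s2g) - s2 / n_total) / (
            n_groups - 1
        )
        n3 = (n_total - sum(gsizes[g] ** 2 for g in gsizes) / n_total) / (
            n_groups - 1
        )
        msd_ag = ssd_ag / (n_groups - 1)
        sigma_a = (msd_ag - sigma_c - n2 * sigma_b) / n3
    else:
        sigma_a = 0.0
    return sigma_a, sigma_b, sigma_c


def amova(
    populations: dict,
    groups: dict | None = None,
    permutations: int = 16000,
    seed: int = 0,
    distance_fn=None,
) -> AmovaResult:
    """Excoffier-style AMOVA on squared model-corrected distances.

    ``populations`` maps population code -> list of sequences;
    ``groups`` optionally maps population code -> group label (one group
    assumed if omitted).  Distances default to Tamura–Nei.  Populations
    of n = 1 are excluded with a warning.  p-values come from permuting
    individuals among populations (Phi_ST / Phi_SC) and populations
    among groups (Phi_CT).
    """
    excluded = [p for p, s in populations.items() if len(s) < 2]
    pops = {p: s for p, s in populations.items() if len(s) >= 2}
    if len(pops) < 2:
        raise ValueError("need >= 2 populations with n >= 2")
    names = sorted(pops)
    seqs: list[str] = []
    pop_idx: list[np.ndarray] = []
    for p in names:
        start = len(seqs)
        seqs.extend(pops[p])
        pop_idx.append(np.arange(start, len(seqs)))
    if groups is None:
        group_of_pop = [0] * len(names)
    else:
        glabels = sorted({groups[p] for p in names})
        group_of_pop = [glabels.index(groups[p]) for p in names]
    n_groups = len(set(group_of_pop))

    d2 = _pairwise_sq_tn93(seqs) if distance_fn is None else distance_fn(seqs)
    sigma_a, sigma_b, sigma_c = _amova_decompose(d2, pop_idx, group_of_pop)
    total = sigma_a + sigma_b + sigma_c
    phi: dict[str, float] = {}
    if total > 0:
        phi["Phi_ST"] = (sigma_a + sigma_b) / total
        if n_groups > 1:
            phi["Phi_CT"] = sigma_a / total
            phi["Phi_SC"] = (
                sigma_b / (sigma_b + sigma_c)
                if (sigma_b + sigma_c) > 0
                else math.nan
            )
    else:
        phi["Phi_ST"] = math.nan

    rng = np.random.default_rng(seed)
    p_values: dict[str, float] = {}
    if total <= 0:
        p_values["Phi_ST"] = 1.0
    else:
        sizes = [idx.size for idx in pop_idx]
        hits_st = 0
        for _ in range(permutations):
            perm = rng.permutation(d2.shape[0])
            pidx = []
            start = 0
            for size in sizes:
                pidx.append(perm[start : start + size])
                start += size
            sa, sb, sc = _amova_decompose(d2, pidx, group_of_pop)
            tot = sa + sb + sc
            phi_sim = (sa + sb) / tot if tot > 0 else 0.0
            if phi_sim >= phi["Phi_ST"] - 1e-12:
                hits_st += 1
        p_values["Phi_ST"] = (hits_st + 1.0) / (permutations + 1.0)
        if n_groups > 1:
            hits_ct = 0
            for _ in range(permutations):
                gperm = list(rng.permutation(group_of_pop))
                sa, sb, sc = _amova_decompose(d2, pop_idx, gperm)
                tot = sa + sb + sc
                phi_sim = sa / tot if tot > 0 else 0.0
                if phi_sim >= phi["Phi_CT"] - 1e-12:
                    hits_ct += 1
            p_values["Phi_CT"] = (hits_ct + 1.0) / (permutations + 1.0)
    return AmovaResult(
        components={
            "among_groups": sigma_a,
            "among_populations_within_groups": sigma_b,
            "within_populations": sigma_c,
        },
        phi=phi,
        p_values=p_values,
        permutations=permutations,
        excluded=excluded,
    )
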