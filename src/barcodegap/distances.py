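"""Pairwise genetic distances under nested substitution models.

Implemented models, from least to most parameter-rich:

* ``p`` — raw mismatch proportion over resolved sites,
* ``jc69`` — Jukes–Cantor, d = -(3/4) ln(1 - 4p/3),
* ``k2p`` — Kimura two-parameter, separate transition/transversion rates,
* ``tn93`` — Tamura–Nei, two transition classes plus empirical base
  frequencies,
* ``gtr_i`` — pairwise maximum-likelihood branch length under a general
  time-reversible rate matrix with empirical base frequencies, optional
  exchangeability equality constraints, and a fixed proportion of
  invariant sites.  With the default constraint classes this is the
  TIM3 model (AC=CG and AT=GT tied, the two transitions free), the
  model used for the barcode-gap histogram analysis; ``tim3i`` is an
  alias for it.

Sites where either sequence carries a gap, an N, or a partial-ambiguity
code are excluded pair-by-pair.  When a corrected distance is
non-estimable (saturation drives a logarithm argument non-positive) the
pair is reported as missing (NaN) and flagged, never silently infinite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize_scalar

from .alignment_io import HaplotypeTable

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: unordered base pairs related by a transition
TRANSITIONS = {frozenset("AG"), frozenset("CT")}

#: exchangeability tying for TIM3 in the jModelTest six-letter convention
#: (AC, AG, AT, CG, CT, GT) -> "012032": AC=CG and AT=GT, transitions free.
TIM3_CLASSES = (0, 1, 2, 0, 3, 2)
GTR_CLASSES = (0, 1, 2, 3, 4, 5)
JC_CLASSES = (0, 0, 0, 0, 0, 0)

PAIR_ORDER = list(itertools.combinations(range(4), 2))  # AC AG AT CG CT GT


class DistanceError(ValueError):
    pass


_ENCODE = np.full(256, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i


@lru_cache(maxsize=8192)
def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def site_pattern_counts(a: str, b: str) -> np.ndarray:
    """4x4 matrix N[x, y] of resolved site patterns between two sequences."""
    if len(a) != len(b):
        raise DistanceError(
            f"sequence length mismatch: {len(a)} vs {len(b)}"
        )
    ea, eb = _encode(a), _encode(b)
    ok = (ea >= 0) & (eb >= 0)
    flat = np.bincount(
        (ea[ok].astype(np.intp) << 2) | eb[ok].astype(np.intp), minlength=16
    )
    return flat.reshape(4, 4).astype(float)


def count_substitution_types(a: str, b: str) -> tuple[int, int]:
    """(transitions, transversions) over resolved differing sites."""
    n = site_pattern_counts(a, b)
    ts = n[0, 2] + n[2, 0] + n[1, 3] + n[3, 1]
    tv = n.sum() - np.trace(n) - ts
    return int(round(ts)), int(round(tv))


def p_distance(a: str, b: str) -> float:
    n = site_pattern_counts(a, b)
    total = n.sum()
    if total == 0:
        raise DistanceError("no shared resolved sites")
    return float((total - np.trace(n)) / total)


def jc69_distance(a: str, b: str) -> float:
    p = p_distance(a, b)
    return jc69_from_p(p)


def jc69_from_p(p: float) -> float:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return math.nan
    return -0.75 * math.log(arg)


def k2p_distance(a: str, b: str) -> float:
    n = site_pattern_counts(a, b)
    total = n.sum()
    if total == 0:
        raise DistanceError("no shared resolved sites")
    ts = (n[0, 2] + n[2, 0] + n[1, 3] + n[3, 1]) / total
    tv = (total - np.trace(n)) / total - ts
    w1 = 1.0 - 2.0 * ts - tv
    w2 = 1.0 - 2.0 * tv
    if w1 <= 0 or w2 <= 0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def tn93_distance(a: str, b: str, freqs=None) -> float:
    """Tamura–Nei distance with empirical (pair-pooled) base frequencies."""
    n = site_pattern_counts(a, b)
    total = n.sum()
    if total == 0:
        raise DistanceError("no shared resolved sites")
    if freqs is None:
        freqs = (n.sum(axis=0) + n.sum(axis=1)) / (2.0 * total)
    pa, pc, pg, pt = freqs
    pr, py = pa + pg, pc + pt
    if min(pa, pc, pg, pt) <= 0:
        # TN93 undefined with a zero frequency; fall back is reported missing
        return math.nan
    p1 = (n[0, 2] + n[2, 0]) / total          # A<->G transitions
    p2 = (n[1, 3] + n[3, 1]) / total          # C<->T transitions
    q = (total - np.trace(n)) / total - p1 - p2
    a1 = 1.0 - pr * p1 / (2.0 * pa * pg) - q / (2.0 * pr)
    a2 = 1.0 - py * p2 / (2.0 * pc * pt) - q / (2.0 * py)
    b = 1.0 - q / (2.0 * pr * py)
    if a1 <= 0 or a2 <= 0 or b <= 0:
        return math.nan
    return float(
        -(2.0 * pa * pg / pr) * math.log(a1)
        - (2.0 * pc * pt / py) * math.log(a2)
        - 2.0
        * (pr * py - pa * pg * py / pr - pc * pt * pr / py)
        * math.log(b)
    )


# ---------------------------------------------------------------------------
# constrained GTR (+I) pairwise maximum likelihood
# ---------------------------------------------------------------------------


def build_rate_matrix(rates, freqs) -> np.ndarray:
    """Normalized reversible rate matrix from 6 exchangeabilities.

    ``rates`` follow the (AC, AG, AT, CG, CT, GT) order.  The matrix is
    scaled so the expected substitution rate at stationarity is 1, hence
    branch lengths are in substitutions per (variable) site.
    """
    pi = np.asarray(freqs, dtype=float)
    q = np.zeros((4, 4))
    for (i, j), r in zip(PAIR_ORDER, rates):
        q[i, j] = r * pi[j]
        q[j, i] = r * pi[i]
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(q)))
    if mu <= 0:
        raise DistanceError("degenerate rate matrix")
    return q / mu


def apply_rate_classes(class_rates, classes) -> np.ndarray:
    """Expand per-class rates into the 6 exchangeabilities."""
    return np.asarray([class_rates[c] for c in classes], dtype=float)


def estimate_exchangeabilities(
    sequences, classes=TIM3_CLASSES
) -> np.ndarray:
    """Method-of-moments exchangeabilities from pooled pairwise counts.

    For each unordered base pair (i, j) the observed change count over
    all sequence pairs, divided by pi_i * pi_j, gives a relative
    exchangeability; counts are pooled within each tying class.  The
    result is normalized so the last class (GT by convention) is 1.
    Crude, but deterministic — intended to supply plausible relative
    rates for the pairwise ML distance, which is dominated by the branch
    length, not the exchangeabilities.
    """
    freqs = empirical_frequencies(sequences)
    pair_counts = np.zeros(6)
    for a, b in itertools.combinations(sequences, 2):
        n = site_pattern_counts(a, b)
        for k, (i, j) in enumerate(PAIR_ORDER):
            pair_counts[k] += n[i, j] + n[j, i]
    nclass = max(classes) + 1
    class_num = np.zeros(nclass)
    class_den = np.zeros(nclass)
    for k, (i, j) in enumerate(PAIR_ORDER):
        class_num[classes[k]] += pair_counts[k]
        class_den[classes[k]] += freqs[i] * freqs[j]
    with np.errstate(invalid="ignore", divide="ignore"):
        class_rates = class_num / class_den
    # pseudocount floor so unobserved classes keep a small positive rate
    class_rates[~np.isfinite(class_rates) | (class_rates <= 0)] = 1e-3
    rates = apply_rate_classes(class_rates, classes)
    return rates / rates[-1]


def empirical_frequencies(sequences) -> np.ndarray:
    counts = np.zeros(4)
    for s in sequences:
        for c in s:
            i = BASE_INDEX.get(c)
            if i is not None:
                counts[i] += 1
    if counts.sum() == 0:
        raise DistanceError("no resolved bases")
    return counts / counts.sum()


def proportion_invariant(sequences) -> float:
    """Observed proportion of constant columns (resolved bases only)."""
    length = len(sequences[0])
    const = 0
    for col in range(length):
        states = {s[col] for s in sequences if s[col] in BASE_INDEX}
        if len(states) <= 1:
            const += 1
    return const / length


def gtr_i_distance(
    a: str,
    b: str,
    freqs,
    rates,
    pinv: float = 0.0,
    t_max: float = 10.0,
    xatol: float = 1e-8,
) -> float:
    """ML pairwise distance under constrained GTR with invariant sites.

    The branch length of the variable-site process is found by bounded
    scalar optimization of the pair likelihood

        L(t) = prod_sites [ pinv * pi_x * delta(x, y)
                            + (1 - pinv) * pi_x * P(t)[x, y] ]

    and the reported distance is the expected number of substitutions
    per site, (1 - pinv) * t_hat.
    """
    n = site_pattern_counts(a, b)
    if n.sum() == 0:
        raise DistanceError("no shared resolved sites")
    if not (0.0 <= pinv < 1.0):
        raise DistanceError(f"pinv must be in [0, 1): {pinv}")
    if n.sum() == np.trace(n):
        return 0.0
    pi = np.asarray(freqs, dtype=float)
    q = build_rate_matrix(rates, pi)
    pi_col = pi[:, None]
    eye = np.eye(4)

    def negloglik(t: float) -> float:
        site_lik = pinv * pi_col * eye + (1.0 - pinv) * pi_col * expm(q * t)
        with np.errstate(divide="ignore"):
            logl = np.where(n > 0, np.log(np.maximum(site_lik, 1e-300)), 0.0)
        return -float((n * logl).sum())

    res = minimize_scalar(
        negloglik, bounds=(1e-9, t_max), method="bounded",
        options={"xatol": xatol},
    )
    t_hat = float(res.x)
    if t_hat >= t_max * 0.999:
        return math.nan  # effectively saturated
    return (1.0 - pinv) * t_hat


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, NaN where non-estimable
    model: str
    pinv: float = 0.0
    non_estimable: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise DistanceError("matrix shape does not match ids")

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def to_tsv(self, path, lower_triangle: bool = False) -> None:
        with open(path, "w") as fh:
            if lower_triangle:
                fh.write(f"{len(self.ids)}\n")
                for i, h in enumerate(self.ids):
                    row = "\t".join(f"{self.values[i, j]:.6f}" for j in range(i))
                    fh.write(f"{h}\t{row}\n" if row else f"{h}\n")
            else:
                fh.write("id\t" + "\t".join(self.ids) + "\n")
                for i, h in enumerate(self.ids):
                    row = "\t".join(f"{v:.6f}" for v in self.values[i])
                    fh.write(f"{h}\t{row}\n")


MODEL_ALIASES = {
    "p": "p", "jc": "jc69", "jc69": "jc69", "k2p": "k2p",
    "tn93": "tn93", "gtr_i": "gtr_i", "tim3i": "gtr_i", "tim3+i": "gtr_i",
}


def pairwise_distance(a: str, b: str, model: str = "jc69", **params) -> float:
    model = MODEL_ALIASES[model.lower()]
    if model == "p":
        return p_distance(a, b)
    if model == "jc69":
        return jc69_distance(a, b)
    if model == "k2p":
        return k2p_distance(a, b)
    if model == "tn93":
        return tn93_distance(a, b, freqs=params.get("freqs"))
    return gtr_i_distance(
        a, b,
        freqs=params["freqs"], rates=params["rates"],
        pinv=params.get("pinv", 0.0),
    )


def distance_matrix(
    table: HaplotypeTable,
    model: str = "tim3i",
    classes=TIM3_CLASSES,
    rates=None,
    pinv=None,
) -> DistanceMatrix:
    """All-pairs distance matrix over the unique haplotypes.

    For the constrained-GTR model, base frequencies and (unless given)
    exchangeabilities are estimated once from the whole haplotype set,
    and the invariant-site proportion defaults to the observed fraction
    of constant columns.
    """
    ids = table.ids
    seqs = table.sequences
    if len(ids) < 2:
        raise DistanceError("need at least two haplotypes")
    canonical = MODEL_ALIASES[model.lower()]
    params: dict = {}
    used_pinv = 0.0
    if canonical == "gtr_i":
        params["freqs"] = empirical_frequencies(seqs)
        params["rates"] = (
            np.asarray(rates, dtype=float)
            if rates is not None
            else estimate_exchangeabilities(seqs, classes)
        )
        used_pinv = proportion_invariant(seqs) if pinv is None else pinv
        params["pinv"] = used_pinv
    values = np.zeros((len(ids), len(ids)))
    bad: list[tuple[str, str]] = []
    for i, j in itertools.combinations(range(len(ids)), 2):
        d = pairwise_distance(seqs[i], seqs[j], canonical, **params)
        if math.isnan(d):
            bad.append((ids[i], ids[j]))
        values[i, j] = values[j, i] = d
    return DistanceMatrix(ids, values, model.lower(), used_pinv, bad)
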