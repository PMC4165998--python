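"""Likelihood core: Poisson rate model, closed-form ML VAF, genotyping.

Every evidence channel (a depth bin, a junction's discordant-pair count, a
junction's soft-clip count) is modelled as an independent Poisson draw whose
rate is affine in the variant allele fraction p:

    rate(p) = alpha + beta * p

* deletion depth bin:    a_i * (1 - p)         (alpha=a_i, beta=-a_i)
* duplication depth bin: a_i * (1 + p)         (one extra copy)
* discordant pairs:      v_d * c * (t - 2r) * p  per junction
* soft-clipped reads:    v_s * c * 2r * p        per junction

with a_i = c(theta_i) * width_i the expected normal pairs in bin i at p=0,
c(theta) the GC-normalized pair rate per bp, t the insert median and r the
read length. Balanced SVs (INV/TRA) have no depth channel and two junctions.

Because all rates are affine in p, d/dp of the Poisson log-likelihood is a
rational function whose numerator is a low-degree polynomial; the maximizing
p is found in closed form (quadratic for a single SV) and only compared
against boundaries. Rates are floored at a small fraction of the channel
maximum before evaluating log-pmfs: this models mismapping noise and keeps
the p=0 likelihood finite when stray junction evidence exists, so confidence
scores stay finite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.special import gammaln, logsumexp

from .types import GCRateTable, LibraryParams, ObservedCounts, SVCall

#: relative noise floor: each channel rate is clipped below at
#: NOISE_FLOOR_EPS * max_{p in [0,1]} rate(p)
NOISE_FLOOR_EPS = 0.01
#: absolute rate floor (expected counts) applied after the relative floor
ABS_RATE_FLOOR = 1e-6
#: Phred cap for VarScore and the matching floor on the error probability
VARSCORE_CAP = 99.0
ERROR_PROB_FLOOR = 1e-10

GENOTYPES = ("AA", "AB", "BB")
GENOTYPE_P = (0.0, 0.5, 1.0)


@dataclass(frozen=True)
class ChannelRate:
    """Affine Poisson rate for one evidence channel: rate(p) = alpha + beta*p."""

    alpha: float
    beta: float

    def __post_init__(self):
        if min(self.alpha, self.alpha + self.beta) < -1e-12:
            raise ValueError("rate(p) must be non-negative on [0, 1]")

    def rate(self, p):
        return self.alpha + self.beta * np.asarray(p, dtype=float)

    @property
    def max_rate(self) -> float:
        return max(self.alpha, self.alpha + self.beta)

    @property
    def dropped(self) -> bool:
        """A placeholder channel carrying no information (kept for alignment
        with the observed-count vector)."""
        return self.alpha == 0.0 and self.beta == 0.0


@dataclass(frozen=True)
class GenotypePrior:
    """Genotype prior over (AA, AB, BB).

    ``uniform`` puts equal weight on the three genotypes — appropriate for a
    heterogeneous tumor sample where p is continuous anyway. ``hwe`` uses
    Hardy-Weinberg weights ((1-q)^2, 2q(1-q), q^2) with population allele
    frequency ``allele_freq_q``, appropriate for homogeneous germline samples.
    """

    mode: str = "uniform"
    allele_freq_q: float = 0.01

    def __post_init__(self):
        if self.mode not in ("uniform", "hwe"):
            raise ValueError("prior mode must be 'uniform' or 'hwe'")
        if self.mode == "hwe" and not 0.0 < self.allele_freq_q < 1.0:
            raise ValueError("allele_freq_q must lie in (0, 1)")

    def weights(self) -> np.ndarray:
        if self.mode == "uniform":
            return np.full(3, 1.0 / 3.0)
        q = self.allele_freq_q
        return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


@dataclass
class VAFEstimate:
    """Result of estimating one SV's allele fraction in one sample."""

    p_hat: float
    genotype: str
    loglik_at_p_hat: float
    genotype_logliks: tuple
    error_prob: float
    var_score: float


# ---------------------------------------------------------------------------
# Expected rates
# ---------------------------------------------------------------------------


def expected_rates(
    sv: SVCall,
    counts_shape: ObservedCounts,
    params: LibraryParams,
    gc: GCRateTable,
) -> list[ChannelRate]:
    """Build the per-channel affine rates for ``sv``, aligned with
    ``counts_shape.flat_counts()``.

    Depth bins use the GC-stratified pair rate; junction channels use the
    rate at the breakpoint GC when recorded, else the library mean. If the
    insert median does not exceed twice the read length the span coverage is
    non-positive and the discordant-pair channel is dropped (zero-rate
    placeholder) with a warning.
    """
    rates: list[ChannelRate] = []
    for b in counts_shape.bins:
        a_i = gc.rate(b.gc_theta) * b.width
        if sv.sv_type == "DEL":
            rates.append(ChannelRate(a_i, -a_i))
        elif sv.sv_type == "DUP":
            rates.append(ChannelRate(a_i, a_i))
        else:
            raise ValueError(f"balanced SV {sv.sv_type} should carry no depth bins")

    span = params.span_per_pair
    drp_dropped = span <= 0
    if drp_dropped and counts_shape.junctions:
        warnings.warn(
            "insert median <= 2x read length: non-positive span coverage, "
            "discordant-pair channel dropped",
            stacklevel=2,
        )
    for j, _ in enumerate(counts_shape.junctions):
        if counts_shape.junction_gc is not None:
            c_bp = gc.rate(counts_shape.junction_gc[j])
        else:
            c_bp = params.inserts_per_bp_c
        beta_d = 0.0 if drp_dropped else params.offset_vd * c_bp * span
        beta_s = params.offset_vs * c_bp * 2 * params.read_length_r
        rates.append(ChannelRate(0.0, beta_d))
        rates.append(ChannelRate(0.0, beta_s))
    return rates


def _floors(rates: Sequence[ChannelRate], noise_floor_eps: float) -> np.ndarray:
    mx = np.array([r.max_rate for r in rates])
    return np.maximum(noise_floor_eps * mx, ABS_RATE_FLOOR)


# ---------------------------------------------------------------------------
# Log-likelihood
# ---------------------------------------------------------------------------

CountsLike = Union[ObservedCounts, np.ndarray, Sequence[float]]


def _as_flat(counts: CountsLike) -> np.ndarray:
    if isinstance(counts, ObservedCounts):
        return counts.flat_counts()
    return np.asarray(counts, dtype=float)


def log_likelihood(
    counts: Union[CountsLike, Sequence[tuple]],
    rates: Union[Sequence[ChannelRate], None] = None,
    p: Union[float, np.ndarray] = 0.0,
    *,
    noise_floor_eps: float = NOISE_FLOOR_EPS,
):
    """Poisson log-likelihood of the observed counts at allele fraction ``p``.

    ``counts``/``rates`` describe one library; to combine independently
    constructed libraries pass ``counts`` as a list of ``(counts, rates)``
    pairs (and ``rates=None``) — their log-likelihoods add. ``p`` may be a
    scalar or an array (evaluated pointwise). Dropped channels contribute
    nothing; all remaining rates are floored before the log-pmf.
    """
    if rates is None:
        pairs = list(counts)  # multi-library form
        return sum(
            log_likelihood(c, r, p, noise_floor_eps=noise_floor_eps) for c, r in pairs
        )

    k = _as_flat(counts)
    if np.any(k < 0):
        raise ValueError("negative counts")
    if len(k) != len(rates):
        raise ValueError(f"{len(k)} counts vs {len(rates)} rate channels")

    keep = np.array([not r.dropped for r in rates], dtype=bool)
    k = k[keep]
    kept = [r for r in rates if not r.dropped]
    if not kept:
        return np.zeros_like(np.asarray(p, dtype=float)) if np.ndim(p) else 0.0

    alpha = np.array([r.alpha for r in kept])
    beta = np.array([r.beta for r in kept])
    floor = _floors(kept, noise_floor_eps)

    p_arr = np.asarray(p, dtype=float)
    lam = alpha + np.multiply.outer(p_arr, beta)  # (..., nchan)
    lam = np.maximum(lam, floor)
    ll = k * np.log(lam) - lam - gammaln(k + 1.0)
    out = ll.sum(axis=-1)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Closed-form maximum-likelihood VAF
# ---------------------------------------------------------------------------

# Channel families by rate shape u(p). Every rate the constructors above
# produce has the form scale * u(p) with u one of {1-p, 1+p, p}, so the
# score d/dp log L collapses to a few grouped terms and its numerator is a
# low-degree polynomial in p (a quadratic for any single unbalanced SV).
_FAMILIES = {1: (1.0, -1.0), 2: (1.0, 1.0), 0: (0.0, 1.0)}  # u0 + u1*p


def _stationary_roots(groups: dict) -> list[float]:
    """Roots of sum_f sigma_f * (K_f / u_f(p) - S_f) = 0 on [0, 1].

    ``groups`` maps a family code to (K, S): K the summed counts, S the
    summed scales. sigma_f = u_f' is the family's slope sign. Multiplying
    through by prod_f u_f turns the score's numerator into a polynomial of
    degree <= #families.
    """
    fams = [(_FAMILIES[f], K, S) for f, (K, S) in groups.items()]
    poly = np.polynomial.Polynomial([0.0])
    full = np.polynomial.Polynomial([1.0])
    for (u0, u1), _, _ in fams:
        full *= np.polynomial.Polynomial([u0, u1])
    for (u0, u1), K, S in fams:
        others = np.polynomial.Polynomial([1.0])
        for (v0, v1), _, _ in fams:
            if (v0, v1) != (u0, u1):
                others *= np.polynomial.Polynomial([v0, v1])
        poly += u1 * (K * others - S * full)
    coef = poly.coef
    if not np.any(np.abs(coef) > 0):
        return []
    roots = np.polynomial.Polynomial(coef).roots()
    out = []
    for z in np.atleast_1d(roots):
        if abs(z.imag) < 1e-9 and -1e-9 < z.real < 1 + 1e-9:
            out.append(min(1.0, max(0.0, float(z.real))))
    return out


def _gather_channels(counts, rates):
    """Flatten (multi-library) counts/rates into live-channel arrays."""
    if rates is None:
        pairs = [(_as_flat(c), list(r)) for c, r in counts]
    else:
        pairs = [(_as_flat(counts), list(rates))]
    alphas, betas, ks = [], [], []
    for k_vec, rate_list in pairs:
        if len(k_vec) != len(rate_list):
            raise ValueError("counts/rates length mismatch")
        if np.any(k_vec < 0):
            raise ValueError("negative counts")
        for k, r in zip(k_vec, rate_list):
            if not r.dropped:
                alphas.append(r.alpha)
                betas.append(r.beta)
                ks.append(k)
    return np.array(alphas), np.array(betas), np.array(ks, dtype=float)


def mle_vaf(
    counts: Union[CountsLike, Sequence[tuple]],
    rates: Union[Sequence[ChannelRate], None] = None,
    *,
    noise_floor_eps: float = NOISE_FLOOR_EPS,
) -> float:
    """Maximum-likelihood allele fraction on [0, 1], in closed form.

    Within each interval of p on which no channel is pinned at its noise
    floor, the stationary condition of the log-likelihood is polynomial
    (quadratic for a single unbalanced SV); candidate maximizers are those
    roots plus the interval endpoints and the boundaries {0, 1}. The
    candidate with the highest (floored) log-likelihood wins; ties break
    toward the smaller p.
    """
    alpha, beta, k = _gather_channels(counts, rates)
    return _mle_arrays(alpha, beta, k, noise_floor_eps)


def _mle_arrays(
    alpha: np.ndarray, beta: np.ndarray, k: np.ndarray, noise_floor_eps: float
) -> float:
    """Closed-form MLE on live-channel arrays (the engine behind mle_vaf)."""
    if alpha.size == 0 or np.all(beta == 0):
        raise ValueError("unidentifiable: no informative evidence channel")
    floor = np.maximum(noise_floor_eps * np.maximum(alpha, alpha + beta), ABS_RATE_FLOOR)

    # family codes: 0 junction-like (u=p), 1 deletion-like (u=1-p),
    # 2 duplication-like (u=1+p), -1 general affine (numeric fallback)
    fam = np.full(alpha.size, -1, dtype=int)
    fam[(alpha == 0) & (beta != 0)] = 0
    with np.errstate(invalid="ignore"):
        fam[(alpha > 0) & np.isclose(beta, -alpha, rtol=1e-9, atol=0.0)] = 1
        fam[(alpha > 0) & np.isclose(beta, alpha, rtol=1e-9, atol=0.0)] = 2
    scale = np.where(fam == 0, beta, alpha)
    informative = beta != 0

    # interval breakpoints where a channel's affine rate crosses its floor
    with np.errstate(divide="ignore", invalid="ignore"):
        pc = (floor[informative] - alpha[informative]) / beta[informative]
    cuts = np.unique(np.round(pc[(pc > 0) & (pc < 1)], 12))
    grid = np.concatenate(([0.0], cuts, [1.0]))

    def _ll(p: float) -> float:
        # gammaln(k+1) omitted: constant in p, irrelevant to the argmax
        lam = np.maximum(alpha + beta * p, floor)
        return float(np.sum(k * np.log(lam) - lam))

    candidates = set(grid.tolist())
    for lo, hi in zip(grid[:-1], grid[1:]):
        mid = 0.5 * (lo + hi)
        active = informative & (alpha + beta * mid > floor)
        if not np.any(active):
            continue
        if np.any(fam[active] == -1):
            from scipy.optimize import minimize_scalar

            res = minimize_scalar(lambda q: -_ll(q), bounds=(lo, hi), method="bounded")
            candidates.add(float(res.x))
            continue
        groups = {}
        for f in np.unique(fam[active]):
            sel = active & (fam == f)
            groups[int(f)] = (float(k[sel].sum()), float(scale[sel].sum()))
        for root in _stationary_roots(groups):
            if lo - 1e-9 <= root <= hi + 1e-9:
                candidates.add(min(hi, max(lo, root)))

    cand = sorted(candidates)
    lls = np.array([_ll(q) for q in cand])
    best_ll = lls.max()
    tol = 1e-10 * max(1.0, abs(best_ll))
    best = int(np.nonzero(lls >= best_ll - tol)[0][0])  # tie: smaller p
    return float(cand[best])


# ---------------------------------------------------------------------------
# Genotyping and confidence scoring
# ---------------------------------------------------------------------------


def genotype_and_score(
    counts: Union[CountsLike, Sequence[tuple]],
    rates: Union[Sequence[ChannelRate], None] = None,
    prior: Optional[GenotypePrior] = None,
    *,
    noise_floor_eps: float = NOISE_FLOOR_EPS,
) -> VAFEstimate:
    """Estimate p, the discrete genotype, and a Phred-scaled confidence.

    Genotypes AA/AB/BB correspond to p = 0, 0.5, 1. The posterior over
    genotypes follows Bayes' theorem with the supplied prior (uniform by
    default); the error probability is the posterior mass on AA ("no
    variant"), and VarScore = -10*log10(error_prob), capped at 99.
    All arithmetic is in log space, so extreme evidence never yields NaN.
    """
    prior = prior or GenotypePrior()
    g_ll = np.array(
        [
            log_likelihood(counts, rates, pg, noise_floor_eps=noise_floor_eps)
            for pg in GENOTYPE_P
        ]
    )
    log_post = np.log(prior.weights()) + g_ll
    log_post -= logsumexp(log_post)
    post = np.exp(log_post)

    error_prob = max(float(post[0]), ERROR_PROB_FLOOR)
    var_score = min(VARSCORE_CAP, -10.0 * math.log10(error_prob))
    genotype = GENOTYPES[int(np.argmax(post))]
    p_hat = mle_vaf(counts, rates, noise_floor_eps=noise_floor_eps)
    return VAFEstimate(
        p_hat=p_hat,
        genotype=genotype,
        loglik_at_p_hat=float(
            log_likelihood(counts, rates, p_hat, noise_floor_eps=noise_floor_eps)
        ),
        genotype_logliks=tuple(float(x) for x in g_ll),
        error_prob=error_prob,
        var_score=var_score,
    )
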