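"""Statistical inference on (genome sketch, sample sketch) pairs.

Genome k-mer multiplicities inside a read sketch are modelled as i.i.d.
zero-inflated Poisson draws: a k-mer is absent with probability 1 - tau^k
(divergence between reference and sample organism) and otherwise carries a
Poisson(lambda) coverage count. Everything here operates on the multiplicity
histogram, which is the sufficient statistic for that model.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import poisson

from .sketch import GenomeSketch, SampleSketch, ParameterMismatchError, _in_sorted

logger = logging.getLogger(__name__)


class TooFewKmersError(ValueError):
    """Genome sketch has too few k-mers for a trustworthy estimate."""


@dataclass(frozen=True)
class CoveragePolicy:
    """Filters and knobs for the coverage-adjustment path."""

    lambda_method_max_median: float = 3.0
    robust_mean_max_median: float = 15.0
    tail_prob: float = 1e-10
    min_kmers: int = 50
    bootstrap_iters: int = 100
    bootstrap_min_valid: int = 50
    ci_percentiles: tuple[float, float] = (5.0, 95.0)

    def __post_init__(self) -> None:
        if min(self.lambda_method_max_median, self.robust_mean_max_median,
               self.tail_prob, self.min_kmers, self.bootstrap_iters,
               self.bootstrap_min_valid) <= 0:
            raise ValueError("policy thresholds must be positive")
        lo, hi = self.ci_percentiles
        if not (0 < lo < 100 and 0 < hi < 100):
            raise ValueError("ci_percentiles must lie in (0, 100)")


@dataclass
class MultiplicityHistogram:
    """Counts N_a of genome k-mers seen ``a`` times in a sample.

    ``n_sketch_kmers`` is N = |A|; the zero class N_0 is implicit as
    N - n_contained.
    """

    n_sketch_kmers: int
    counts: dict  # a >= 1 -> N_a

    @property
    def n_contained(self) -> int:
        return sum(self.counts.values())

    @property
    def mode_a(self) -> Optional[int]:
        """Multiplicity a >= 1 maximizing N_a, smallest on ties."""
        if not self.counts:
            return None
        best = max(self.counts.values())
        return min(a for a, n in self.counts.items() if n == best)

    @property
    def median_nonzero(self) -> Optional[float]:
        """Median multiplicity over k-mers with multiplicity >= 1."""
        if not self.counts:
            return None
        items = sorted(self.counts.items())
        total = sum(n for _, n in items)
        # linear-interpolation-free weighted median: average the two middle
        # order statistics when total is even
        targets = ((total - 1) // 2, total // 2)
        vals = []
        cum = 0
        it = iter(items)
        a, n = next(it)
        for t in targets:
            while cum + n <= t:
                cum += n
                a, n = next(it)
            vals.append(a)
        return (vals[0] + vals[1]) / 2.0

    @classmethod
    def from_multiplicities(cls, n_sketch_kmers: int, mults) -> "MultiplicityHistogram":
        vals, cnts = np.unique(np.asarray(mults, dtype=np.int64), return_counts=True)
        counts = {int(a): int(n) for a, n in zip(vals, cnts) if a > 0}
        return cls(n_sketch_kmers=n_sketch_kmers, counts=counts)


@dataclass
class SampleErrorModel:
    """Expected k-mer error-survival probability E = E[(1-eps)^k]."""

    E: float
    source: str  # "user_epsilon", "auto", or "default"
    sample_counts: Optional[dict] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.E <= 1.0:
            raise ValueError(f"E must be in (0, 1], got {self.E}")


@dataclass
class AniEstimate:
    """Inference output for one genome against one sample."""

    genome_id: str
    naive_ani: float
    adjusted_ani: float
    lambda_hat: Optional[float]
    effective_coverage: Optional[float]
    true_coverage: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    n_sketch_kmers: int
    n_contained: int
    adjustment_applied: bool


# ---------------------------------------------------------------------------
# Histogram construction
# ---------------------------------------------------------------------------

def build_histogram(genome: GenomeSketch, sample: SampleSketch) -> MultiplicityHistogram:
    """Tally sample multiplicities of the genome's sketch k-mers."""
    genome.params.require_compatible(
        sample.params, context=f"genome {genome.genome_id} vs sample {sample.sample_id}"
    )
    hashes, mults = sample.count_arrays()
    if genome.kmers.size and hashes.size:
        idx = np.searchsorted(hashes, genome.kmers)
        inside = idx < hashes.size
        hit = np.zeros(genome.kmers.shape, dtype=bool)
        hit[inside] = hashes[idx[inside]] == genome.kmers[inside]
        found = mults[idx[hit]]
        counts = Counter(found.tolist())
    else:
        counts = Counter()
    return MultiplicityHistogram(n_sketch_kmers=genome.n_kmers, counts=dict(counts))


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def naive_ani(hist: MultiplicityHistogram, k: int) -> float:
    """Containment index to the power 1/k, with no coverage correction."""
    if hist.n_sketch_kmers <= 0:
        raise ValueError("naive ANI is undefined for an empty genome sketch")
    return (hist.n_contained / hist.n_sketch_kmers) ** (1.0 / k)


def estimate_lambda(hist: MultiplicityHistogram, policy: CoveragePolicy) -> Optional[float]:
    """Ratio-of-multiplicity coverage estimate (N_{a+1}/N_a)*(a+1).

    Returns None unless both N_a and N_{a+1} are at least 3, where a is the
    modal multiplicity.
    """
    a = hist.mode_a
    if a is None:
        return None
    n_a = hist.counts.get(a, 0)
    n_a1 = hist.counts.get(a + 1, 0)
    if n_a < 3 or n_a1 < 3:
        return None
    return (n_a1 / n_a) * (a + 1)


def adjusted_ani(hist: MultiplicityHistogram, lambda_hat: float, k: int) -> float:
    """Coverage-adjusted ANI, clamped to 1 from above."""
    if lambda_hat <= 0:
        raise ValueError(f"lambda_hat must be positive, got {lambda_hat}")
    containment = hist.n_contained / hist.n_sketch_kmers
    value = (containment / (1.0 - math.exp(-lambda_hat))) ** (1.0 / k)
    return min(1.0, value)


def bootstrap_ci(
    hist: MultiplicityHistogram,
    k: int,
    policy: CoveragePolicy,
    seed=0,
) -> Optional[tuple[float, float]]:
    """Percentile bootstrap CI for the coverage-adjusted ANI.

    Resamples the full length-N multiplicity vector (zeros included) with
    replacement, recomputes the adjusted ANI per resample with the modal
    multiplicity ``a`` held fixed, and discards resamples whose N_a or
    N_{a+1} is zero. Returns None unless more than
    ``policy.bootstrap_min_valid`` resamples survive. Deterministic given
    ``seed`` (an int or a numpy SeedSequence).
    """
    N = hist.n_sketch_kmers
    if N <= 0 or hist.n_contained == 0:
        return None
    a = hist.mode_a
    if hist.counts.get(a + 1, 0) == 0:
        return None
    values = [0] + sorted(hist.counts)
    base = np.array([N - hist.n_contained] + [hist.counts[v] for v in values[1:]],
                    dtype=np.float64)
    probs = base / N
    idx_a = values.index(a)
    idx_a1 = values.index(a + 1)

    rng = np.random.default_rng(seed)
    draws = rng.multinomial(N, probs, size=policy.bootstrap_iters)
    n_a = draws[:, idx_a].astype(np.float64)
    n_a1 = draws[:, idx_a1].astype(np.float64)
    valid = (n_a > 0) & (n_a1 > 0)
    if int(valid.sum()) <= policy.bootstrap_min_valid:
        return None
    lam = (n_a1[valid] / n_a[valid]) * (a + 1)
    contained = (N - draws[valid, 0]) / N
    ani = np.minimum(1.0, (contained / (1.0 - np.exp(-lam))) ** (1.0 / k))
    lo, hi = np.percentile(ani, policy.ci_percentiles)
    return float(lo), float(hi)


def robust_mean_alpha(m: float, tail_prob: float) -> int:
    """Smallest integer alpha with Pr(Pois(m) > alpha) < tail_prob."""
    alpha = max(0, int(math.ceil(m)))
    while poisson.sf(alpha, m) >= tail_prob:
        alpha += 1
    return alpha


def effective_coverage(
    hist: MultiplicityHistogram,
    lambda_hat: Optional[float],
    policy: CoveragePolicy,
) -> float:
    """Effective coverage of a genome in a sample.

    Uses lambda_hat when the median multiplicity m is <= 3 and the estimate
    exists, a Poisson-tail-trimmed robust mean when 4 <= m <= 15, and the
    median itself otherwise.
    """
    if hist.n_contained == 0:
        raise ValueError("effective coverage is undefined with no contained k-mers")
    m = hist.median_nonzero
    if m <= policy.lambda_method_max_median and lambda_hat is not None:
        return float(lambda_hat)
    if policy.lambda_method_max_median < m <= policy.robust_mean_max_median and m >= 4:
        alpha = robust_mean_alpha(m, policy.tail_prob)
        num = sum(a * n for a, n in hist.counts.items() if a < alpha)
        den = sum(n for a, n in hist.counts.items() if a < alpha)
        if den > 0:
            return num / den
    return float(m)


def estimate_error_term(
    sample: SampleSketch,
    user_epsilon: Optional[float],
    k: int,
) -> SampleErrorModel:
    """Estimate E = E[(1-eps)^k] for a sample.

    With a user-supplied error rate, E = (1-eps)^k. Otherwise E is inferred
    from the sample-wide multiplicity histogram as 1 - n_1 / sum_{a>1} a*n_a,
    falling back to E = 1 (with a warning) when that is degenerate.
    """
    if user_epsilon is not None:
        if not 0.0 <= user_epsilon < 1.0:
            raise ValueError("epsilon must be in [0, 1)")
        return SampleErrorModel(E=(1.0 - user_epsilon) ** k, source="user_epsilon")
    n_a = sample.multiplicity_histogram()
    n1 = n_a.get(1, 0)
    denom = sum(a * n for a, n in n_a.items() if a > 1)
    if denom == 0:
        logger.warning(
            "sample %s: cannot auto-estimate the error term (no multi-copy "
            "k-mers); using E = 1. Consider supplying an error rate of "
            "0.001-0.010.", sample.sample_id,
        )
        return SampleErrorModel(E=1.0, source="auto", sample_counts=dict(n_a))
    E = 1.0 - n1 / denom
    if E <= 0.0:
        logger.warning(
            "sample %s: auto error-term estimate is non-positive (%.4f); "
            "using E = 1. Consider supplying an error rate of 0.001-0.010.",
            sample.sample_id, E,
        )
        E = 1.0
    return SampleErrorModel(E=min(1.0, E), source="auto", sample_counts=dict(n_a))


def true_coverage(lam: float, L: float, k: int, E: float) -> float:
    """Invert the effective-coverage relation: delta = lam * (L/(L-k+1)) / E."""
    if L <= k:
        raise ValueError(f"mean read length {L} must exceed k={k}")
    if E <= 0:
        raise ValueError("E must be positive")
    return lam * (L / (L - k + 1.0)) / E


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def estimate_from_histogram(
    hist: MultiplicityHistogram,
    genome_id: str,
    k: int,
    policy: CoveragePolicy,
    error_model: Optional[SampleErrorModel] = None,
    mean_read_length: Optional[float] = None,
    seed=0,
) -> AniEstimate:
    """Full ANI/coverage estimate from a prebuilt multiplicity histogram."""
    if hist.n_sketch_kmers <= policy.min_kmers:
        raise TooFewKmersError(
            f"genome {genome_id}: {hist.n_sketch_kmers} sketch k-mers "
            f"(> {policy.min_kmers} required)"
        )
    nai = naive_ani(hist, k)
    if hist.n_contained == 0:
        return AniEstimate(
            genome_id=genome_id, naive_ani=0.0, adjusted_ani=0.0,
            lambda_hat=None, effective_coverage=None, true_coverage=None,
            ci_low=None, ci_high=None, n_sketch_kmers=hist.n_sketch_kmers,
            n_contained=0, adjustment_applied=False,
        )
    m = hist.median_nonzero
    lam_hat = None
    if m <= policy.lambda_method_max_median:
        lam_hat = estimate_lambda(hist, policy)
    if lam_hat is not None:
        adj = adjusted_ani(hist, lam_hat, k)
        ci = bootstrap_ci(hist, k, policy, seed=seed)
        eff = float(lam_hat)
        applied = True
    else:
        adj = nai
        ci = None
        eff = effective_coverage(hist, None, policy)
        applied = False
    tc = None
    if error_model is not None and mean_read_length and mean_read_length > k:
        tc = true_coverage(eff, mean_read_length, k, error_model.E)
    lo, hi = ci if ci is not None else (None, None)
    return AniEstimate(
        genome_id=genome_id, naive_ani=nai, adjusted_ani=adj,
        lambda_hat=lam_hat, effective_coverage=eff, true_coverage=tc,
        ci_low=lo, ci_high=hi, n_sketch_kmers=hist.n_sketch_kmers,
        n_contained=hist.n_contained, adjustment_applied=applied,
    )


def estimate_ani(
    genome: GenomeSketch,
    sample: SampleSketch,
    policy: Optional[CoveragePolicy] = None,
    error_model: Optional[SampleErrorModel] = None,
    seed=0,
) -> AniEstimate:
    """Estimate containment ANI and coverage of one genome in one sample."""
    policy = policy or CoveragePolicy()
    hist = build_histogram(genome, sample)
    if error_model is None:
        error_model = estimate_error_term(sample, None, genome.params.k)
    return estimate_from_histogram(
        hist, genome_id=genome.genome_id, k=genome.params.k, policy=policy,
        error_model=error_model, mean_read_length=sample.mean_read_length,
        seed=seed,
    )
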