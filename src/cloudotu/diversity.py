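"""Alpha-diversity, richness and evenness statistics from closed forms.

All statistics operate on a single sample-fraction's count vector:

* Shannon–Wiener H in natural-log units (nats);
* the abundance-based coverage estimator (ACE) of total richness, with
  the classic rare cutoff of 10 and a Chao1 fallback when every rare
  read is a singleton;
* the Gini coefficient and Lorenz curve of the abundance distribution
  over observed OTUs (0 = perfectly even, -> 1 = dominated by few);
* sample coverage as observed / estimated richness;
* exact (hypergeometric) rarefaction and seeded subsampling without
  replacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "DiversityReport",
    "RarefactionCurve",
    "shannon",
    "ace",
    "chao1",
    "gini",
    "lorenz",
    "coverage_ratio",
    "goods_coverage",
    "rarefaction_exact",
    "rarefy",
    "diversity_report",
]


def _as_counts(counts: Sequence[float] | np.ndarray) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    if x.sum() <= 0:
        raise ValueError("counts must contain at least one positive entry")
    return x


def shannon(counts: Sequence[float] | np.ndarray) -> float:
    """Shannon–Wiener index H = -sum p_i ln p_i (natural log)."""
    x = _as_counts(counts)
    p = x[x > 0] / x.sum()
    return float(-(p * np.log(p)).sum())


def chao1(counts: Sequence[int] | np.ndarray) -> float:
    """Chao1 richness: S_obs + F1^2 / (2 F2), bias-corrected when F2 = 0."""
    x = _as_counts(counts)
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def ace(counts: Sequence[int] | np.ndarray, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator of total species richness.

    Rare OTUs are those with 1..``rare_cutoff`` reads. When the rare
    coverage C_ace is zero (all rare reads are singletons) ACE is
    undefined and Chao1 is returned instead.
    """
    x = _as_counts(counts)
    if rare_cutoff < 1:
        raise ValueError("rare_cutoff must be >= 1")
    obs = x[x > 0]
    rare = obs[obs <= rare_cutoff]
    s_abund = int((obs > rare_cutoff).sum())
    s_rare = len(rare)
    if s_rare == 0:
        return float(s_abund)
    n_rare = rare.sum()
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        return chao1(counts)
    freqs = np.array([(rare == i).sum() for i in range(1, rare_cutoff + 1)])
    i = np.arange(1, rare_cutoff + 1)
    gamma2 = max(
        (s_rare / c_ace) * (i * (i - 1) * freqs).sum() / (n_rare * (n_rare - 1)) - 1.0,
        0.0,
    ) if n_rare > 1 else 0.0
    return float(s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2)


def gini(counts: Sequence[float] | np.ndarray) -> float:
    """Gini coefficient of abundance inequality over observed OTUs.

    Sample (uncorrected) formula on ascending-sorted abundances:
    G = 2 sum_i i x_(i) / (n sum x) - (n + 1)/n; 0 for a perfectly even
    community, bounded above by 1 - 1/n.
    """
    x = _as_counts(counts)
    x = np.sort(x[x > 0])
    n = len(x)
    i = np.arange(1, n + 1)
    return float(2.0 * (i * x).sum() / (n * x.sum()) - (n + 1) / n)


def lorenz(counts: Sequence[float] | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lorenz curve over observed OTUs.

    Returns (cumulative OTU fraction, cumulative read fraction), both
    starting at 0 and ending at 1, abundances sorted ascending so the
    curve is convex and lies under the diagonal.
    """
    x = _as_counts(counts)
    x = np.sort(x[x > 0])
    n = len(x)
    cum_otus = np.concatenate([[0.0], np.arange(1, n + 1) / n])
    cum_reads = np.concatenate([[0.0], np.cumsum(x) / x.sum()])
    return cum_otus, cum_reads


def coverage_ratio(observed: float, estimated: float) -> float:
    """Fraction of estimated total richness actually observed."""
    if estimated <= 0:
        raise ValueError("estimated richness must be positive")
    return observed / estimated


def goods_coverage(counts: Sequence[int] | np.ndarray) -> float:
    """Good's coverage 1 - F1/N (secondary coverage definition)."""
    x = _as_counts(counts)
    return float(1.0 - (x == 1).sum() / x.sum())


@dataclass(frozen=True)
class RarefactionCurve:
    depths: tuple[int, ...]
    expected_richness: tuple[float, ...]
    method: str  # "exact" or "subsample"
    n_reps: int | None = None
    seed: int | None = None


def rarefaction_exact(
    counts: Sequence[int] | np.ndarray, depths: Sequence[int]
) -> RarefactionCurve:
    """Expected richness in a without-replacement subsample of each depth.

    E[S_m] = sum_i [1 - C(N - N_i, m) / C(N, m)], evaluated with
    log-gamma arithmetic so large totals do not overflow.
    """
    x = _as_counts(counts)
    ni = x[x > 0]
    n = ni.sum()
    values: list[float] = []
    for m in depths:
        if m < 0 or m > n:
            raise ValueError(f"depth {m} exceeds total count {int(n)}")
        # log C(N - N_i, m) - log C(N, m), defined only when N - N_i >= m
        ok = (n - ni) >= m
        log_p = np.full(len(ni), -np.inf)
        if m == 0:
            log_p[:] = 0.0
        else:
            a = n - ni[ok]
            log_p[ok] = (
                gammaln(a + 1)
                - gammaln(m + 1)
                - gammaln(a - m + 1)
                - (gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1))
            )
        values.append(float((1.0 - np.exp(log_p)).sum()))
    return RarefactionCurve(
        depths=tuple(int(m) for m in depths),
        expected_richness=tuple(values),
        method="exact",
    )


def rarefy(
    counts: Sequence[int] | np.ndarray,
    depth: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Subsample a count vector to ``depth`` reads without replacement.

    A multivariate hypergeometric draw; the output sums to ``depth``
    exactly and is reproducible for a given seed.
    """
    x = np.asarray(counts)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    total = int(x.sum())
    if depth < 0 or depth > total:
        raise ValueError(f"depth {depth} exceeds total count {total}")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    return rng.multivariate_hypergeometric(x.astype(np.int64), depth)


@dataclass(frozen=True)
class DiversityReport:
    """Per-sample-fraction summary of richness, diversity and evenness."""

    label: str
    total_reads: int
    observed_richness: int
    shannon_h: float
    ace: float
    gini: float
    coverage: float


def diversity_report(counts: Sequence[int] | np.ndarray, label: str = "") -> DiversityReport:
    """Compute the full per-column summary used in the headline tables."""
    x = _as_counts(counts)
    observed = int((x > 0).sum())
    ace_val = ace(x)
    return DiversityReport(
        label=label,
        total_reads=int(x.sum()),
        observed_richness=observed,
        shannon_h=shannon(x),
        ace=ace_val,
        gini=gini(x),
        coverage=coverage_ratio(observed, ace_val),
    )
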