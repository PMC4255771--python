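"""Standard neutral coalescent machinery: genealogies, infinite-sites
mutation dropping, and empirical null distributions / p-values for Tajima's D
and the normalized Fay-Wu H.

Time is measured in units of 2N generations: with k lineages the waiting time
to the next coalescence is Exp(k(k-1)/2) and merging pairs are uniform. Nulls
are conditioned on the observed number of segregating sites S (the behaviour
of the simulation program the null replicates emulate); a theta-conditioned
mode is available via :func:`drop_mutations_theta`.

The object-level API (:class:`Genealogy`) is used by the synthetic-data
generator; large null samples use a vectorized sampler over branch-size
segments that draws the same distribution far faster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .popstats import harmonic, harmonic2, tajima_constants


@dataclass(frozen=True)
class Branch:
    """A branch of the genealogy: the leaves below it and its length."""

    leaves: frozenset[int]
    length: float


@dataclass(frozen=True)
class Genealogy:
    n: int
    coalescent_times: tuple[float, ...]  # T_k for k = n, n-1, ..., 2
    branches: tuple[Branch, ...]  # 2n-2 branches, root branch excluded

    @property
    def total_length(self) -> float:
        return sum(b.length for b in self.branches)

    @property
    def tmrca(self) -> float:
        return sum(self.coalescent_times)


def simulate_genealogy(n: int, rng: np.random.Generator) -> Genealogy:
    """Simulate a Kingman coalescent genealogy for n leaves."""
    if n < 2:
        raise ValueError("simulate_genealogy requires n >= 2")
    # active lineages: (leaf set, birth time)
    active: list[tuple[frozenset[int], float]] = [
        (frozenset([i]), 0.0) for i in range(n)
    ]
    t = 0.0
    times: list[float] = []
    branches: list[Branch] = []
    for k in range(n, 1, -1):
        wait = rng.exponential(2.0 / (k * (k - 1)))
        times.append(wait)
        t += wait
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        (leaves_i, birth_i), (leaves_j, birth_j) = active[i], active[j]
        branches.append(Branch(leaves_i, t - birth_i))
        branches.append(Branch(leaves_j, t - birth_j))
        merged = (leaves_i | leaves_j, t)
        # remove the two merged lineages, append the parent
        for idx in sorted((i, j), reverse=True):
            active.pop(idx)
        active.append(merged)
    return Genealogy(n=n, coalescent_times=tuple(times), branches=tuple(branches))


def drop_mutations_fixed_s(
    g: Genealogy, S: int, rng: np.random.Generator
) -> np.ndarray:
    """Place exactly S infinite-sites mutations on branches with probability
    proportional to branch length; returns an (n, S) 0/1 matrix of derived
    carriers."""
    if S < 0:
        raise ValueError("S must be >= 0")
    matrix = np.zeros((g.n, S), dtype=np.int8)
    if S == 0:
        return matrix
    lengths = np.array([b.length for b in g.branches])
    cum = np.cumsum(lengths)
    picks = np.searchsorted(cum, rng.random(S) * cum[-1], side="right")
    for col, b_idx in enumerate(picks):
        for leaf in g.branches[int(b_idx)].leaves:
            matrix[leaf, col] = 1
    return matrix


def drop_mutations_theta(
    g: Genealogy, theta: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson mutation dropping: S ~ Poisson(theta * total_length / 2), then
    fixed-S placement."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    S = int(rng.poisson(theta * g.total_length / 2.0))
    return drop_mutations_fixed_s(g, S, rng)


# ---------------------------------------------------------------------------
# vectorized null sampling
#
# A mutation's derived-allele count is the descendant count of the branch
# segment it lands on; conditioning on S we only need, per replicate, the
# (descendant count, length) of every lineage segment at every level k.


def _simulate_segments(
    n: int, reps: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate `reps` genealogies at once, returning per-replicate segment
    descendant counts and lengths, shape (reps, M) with M = n(n+1)/2 - 1."""
    counts = np.ones((reps, n), dtype=np.int32)
    seg_counts = []
    seg_lengths = []
    rows = np.arange(reps)
    for k in range(n, 1, -1):
        t_k = rng.exponential(2.0 / (k * (k - 1)), size=reps)
        seg_counts.append(counts[:, :k].copy())
        seg_lengths.append(np.repeat(t_k[:, None], k, axis=1))
        a = rng.integers(0, k, size=reps)
        b = rng.integers(0, k - 1, size=reps)
        b = b + (b >= a)
        counts[rows, a] += counts[rows, b]
        # move the last active lineage into slot b, shrinking the active set
        counts[rows, b] = counts[rows, k - 1]
    return np.concatenate(seg_counts, axis=1), np.concatenate(seg_lengths, axis=1)


def sample_null_sfs_counts(
    n: int, S: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw `reps` neutral replicates of S derived-allele counts each,
    conditioned on S segregating sites. Returns an (reps, S) integer array of
    derived counts in 1..n-1."""
    seg_counts, seg_lengths = _simulate_segments(n, reps, rng)
    cum = np.cumsum(seg_lengths, axis=1)
    totals = cum[:, -1:]
    # row-wise searchsorted via the flattened offset trick
    norm = cum / totals
    u = rng.random((reps, S))
    offsets = np.arange(reps)[:, None].astype(float)
    idx = np.searchsorted((norm + offsets).ravel(), (u + offsets).ravel())
    idx = np.clip(idx - np.repeat(np.arange(reps), S) * norm.shape[1], 0, norm.shape[1] - 1)
    return seg_counts[np.repeat(np.arange(reps), S), idx.astype(np.int64)].reshape(reps, S)


def _d_from_counts(dcounts: np.ndarray, n: int) -> np.ndarray:
    """Tajima's D per replicate from (reps, S) derived-count matrices."""
    S = dcounts.shape[1]
    c = tajima_constants(n)
    pairs = n * (n - 1) / 2.0
    pi_total = np.sum(dcounts * (n - dcounts), axis=1) / pairs
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return (pi_total - S / c["a1"]) / np.sqrt(var)


def _h_from_counts(dcounts: np.ndarray, n: int) -> np.ndarray:
    """Normalized Fay-Wu H per replicate from derived-count matrices."""
    S = dcounts.shape[1]
    theta_pi = np.sum(2.0 * dcounts * (n - dcounts), axis=1) / (n * (n - 1))
    theta_L = np.sum(dcounts, axis=1) / (n - 1.0)
    an = harmonic(n)
    bn = harmonic2(n)
    bn1 = bn + 1.0 / n**2
    theta_w = S / an
    theta_sq = S * (S - 1) / (an**2 + bn)
    var = (n - 2) / (6.0 * (n - 1)) * theta_w + (
        18.0 * n**2 * (3 * n + 2) * bn1 - (88.0 * n**3 + 9 * n**2 - 13 * n + 6)
    ) / (9.0 * n * (n - 1) ** 2) * theta_sq
    return (theta_pi - theta_L) / np.sqrt(var)


_STAT_FUNCS = {"D": _d_from_counts, "H": _h_from_counts}


def sample_null_statistics(
    statistic: str,
    n: int,
    S: int,
    replicates: int,
    rng: np.random.Generator,
    batch: int = 20000,
) -> np.ndarray:
    """Neutral null sample of Tajima's D or normalized Fay-Wu H, conditioned
    on S segregating sites in a sample of n haplotypes."""
    if statistic not in _STAT_FUNCS:
        raise ValueError("statistic must be 'D' or 'H'")
    if S < 1:
        raise ValueError("null sampling requires S >= 1")
    if n < 4:
        raise ValueError("null sampling requires n >= 4")
    func = _STAT_FUNCS[statistic]
    out = []
    remaining = replicates
    while remaining > 0:
        b = min(batch, remaining)
        out.append(func(sample_null_sfs_counts(n, S, b, rng), n))
        remaining -= b
    return np.concatenate(out)


@dataclass(frozen=True)
class NullResult:
    statistic: str
    observed: float
    p: float
    tail: str
    replicates: int
    null_mean: float
    null_sd: float
    null_q025: float
    null_q975: float


def null_pvalue(
    statistic: str,
    observed: float,
    n: int,
    S: int,
    replicates: int,
    rng: np.random.Generator,
    null_sample: Optional[np.ndarray] = None,
) -> NullResult:
    """Empirical p-value of an observed D or H against the standard-neutral
    null conditioned on S.

    D is two-tailed (2 * min(lower, upper), capped at 1); H is lower-tailed
    (excess of high-frequency derived alleles). p is floored at
    1/(replicates+1) through the add-one empirical estimator. A precomputed
    ``null_sample`` may be supplied to share one null across loci.
    """
    if replicates < 1000:
        raise ValueError("use >= 1000 replicates for a stable empirical p")
    null = (
        null_sample
        if null_sample is not None
        else sample_null_statistics(statistic, n, S, replicates, rng)
    )
    reps = len(null)
    # the statistics are discrete at small S: count ties inclusively with a
    # relative tolerance so scalar- and vector-computed values compare equal
    eps = 1e-9 * max(1.0, abs(float(observed)))
    p_low = (np.count_nonzero(null <= observed + eps) + 1) / (reps + 1)
    p_high = (np.count_nonzero(null >= observed - eps) + 1) / (reps + 1)
    if statistic == "D":
        p = min(1.0, 2.0 * min(p_low, p_high))
        tail = "two-tailed"
    else:
        p = min(1.0, p_low)
        tail = "lower"
    q025, q975 = np.quantile(null, [0.025, 0.975])
    return NullResult(
        statistic=statistic,
        observed=float(observed),
        p=float(p),
        tail=tail,
        replicates=reps,
        null_mean=float(np.mean(null)),
        null_sd=float(np.std(null)),
        null_q025=float(q025),
        null_q975=float(q975),
    )
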