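"""Core population-genetic statistics.

Implements per-site nucleotide diversity (pi), Watterson's theta, a
sample-size-corrected SNP density (S/L divided by ln(n-1)), Tajima's D,
the normalized Fay-Wu H of Zeng et al. (2006) as used by the DH program,
Jukes-Cantor divergence, Hudson's F_ST (1 - Hw/Hb) with a variance-components
alternative, and Benjamini-Hochberg FDR adjustment.

All estimators treat columns under complete deletion (any ingroup gap removes
the column) unless noted; pairwise operations (Jukes-Cantor, F_ST) use
pairwise deletion over the two sequences involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import SampleSizeError, SaturationError
from .variants import SFSpectrum


@dataclass
class DomainSummary:
    """Per-locus, per-domain summary statistics."""

    locus_id: str
    domain: str
    n: int
    L: int
    S: int
    pi: Optional[float] = None
    theta_w: Optional[float] = None
    snp_density: Optional[float] = None
    tajima_D: Optional[float] = None
    faywu_H: Optional[float] = None
    p_D: Optional[float] = None
    p_H: Optional[float] = None
    K_jc: Optional[float] = None


# ---------------------------------------------------------------------------
# helpers


def harmonic(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i."""
    return sum(1.0 / i for i in range(1, n))


def harmonic2(n: int) -> float:
    """b_n = sum_{i=1}^{n-1} 1/i^2."""
    return sum(1.0 / i**2 for i in range(1, n))


def _column_matrix(sequences: Sequence[str]) -> np.ndarray:
    return np.array([list(s) for s in sequences], dtype="U1")


# ---------------------------------------------------------------------------
# diversity


def nucleotide_diversity(sequences: Sequence[str]) -> tuple[Optional[float], float]:
    """Nucleotide diversity over the gap-free columns of an alignment slice.

    Returns ``(pi, pi_total)``: pi_total is the average number of pairwise
    differences per haplotype pair, pi the per-site value (pi_total / L with
    L the gap-free column count). pi is None when L = 0.

    Computed in the heterozygosity form
    ``sum_sites (n/(n-1)) (1 - sum_b p_b^2)``, which equals the all-pairs
    average exactly.
    """
    n = len(sequences)
    if n < 2:
        raise SampleSizeError("nucleotide diversity needs >= 2 haplotypes")
    mat = _column_matrix(sequences)
    mask = ~(mat == "-").any(axis=0)
    L = int(mask.sum())
    if L == 0:
        return None, 0.0
    sub = mat[:, mask]
    pi_total = 0.0
    for col in range(L):
        _, cnts = np.unique(sub[:, col], return_counts=True)
        if len(cnts) > 1:
            p2 = np.sum((cnts / n) ** 2)
            pi_total += (1.0 - p2) * n / (n - 1)
    return pi_total / L, pi_total


def watterson_theta(S: int, n: int, L: int) -> float:
    """Watterson's estimator per site: S / a_n / L with a_n = sum 1/i."""
    if n < 2 or L < 1:
        raise SampleSizeError("watterson_theta requires n >= 2, L >= 1")
    return S / harmonic(n) / L


def snp_density(S: int, n: int, L: int) -> Optional[float]:
    """SNP density per bp, (S/L) / ln(n-1); sample-size correction analogous
    to Watterson's. Undefined (None) for n <= 2 where ln(n-1) <= 0. The log
    base is natural (matching a_n ~ ln n); callers wanting another base can
    rescale."""
    if L < 1:
        raise SampleSizeError("snp_density requires L >= 1")
    if n <= 2:
        return None
    return (S / L) / math.log(n - 1)


# ---------------------------------------------------------------------------
# Tajima's D


def tajima_constants(n: int) -> dict[str, float]:
    """The constants of Tajima (1989) for sample size n."""
    a1 = harmonic(n)
    a2 = harmonic2(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(S: int, pi_total: float, n: int) -> Optional[float]:
    """Tajima's D from the segregating-site count and the mean pairwise
    difference total. None when undefined (S = 0 or n < 4)."""
    if S == 0 or n < 4:
        return None
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return (pi_total - S / c["a1"]) / math.sqrt(var)


# ---------------------------------------------------------------------------
# normalized Fay-Wu H


def faywu_h_normalized(
    sfs: SFSpectrum, n: Optional[int] = None
) -> Optional[tuple[float, float, float, float]]:
    """Normalized Fay-Wu H from an unfolded SFS.

    Returns (H_norm, theta_pi, theta_L, theta_H), or None for an empty
    spectrum. The normalization follows Zeng et al. (2006):

        Var(theta_pi - theta_L) = (n-2)/(6(n-1)) * theta
            + [18 n^2 (3n+2) b_{n+1} - (88 n^3 + 9 n^2 - 13 n + 6)]
              / (9 n (n-1)^2) * theta^2

    with theta estimated by Watterson's S/a_n and theta^2 unbiasedly by
    S(S-1)/(a_n^2 + b_n), where a_n = sum_{i<n} 1/i, b_n = sum_{i<n} 1/i^2.
    """
    if sfs.mode != "unfolded":
        raise ValueError("faywu_h_normalized requires an unfolded spectrum")
    n = n if n is not None else sfs.n
    if n < 3:
        raise SampleSizeError("faywu_h_normalized requires n >= 3")
    counts = np.asarray(sfs.counts, dtype=float)
    S = counts.sum()
    if S < 1:
        return None
    i = np.arange(1, n)
    theta_pi = float(np.sum(2.0 * i * (n - i) * counts) / (n * (n - 1)))
    theta_L = float(np.sum(i * counts) / (n - 1))
    theta_H = float(np.sum(2.0 * i**2 * counts) / (n * (n - 1)))
    an = harmonic(n)
    bn = harmonic2(n)
    bn1 = bn + 1.0 / n**2  # b_{n+1}
    theta_w = S / an
    theta_sq = S * (S - 1) / (an**2 + bn)
    var = (n - 2) / (6.0 * (n - 1)) * theta_w + (
        18.0 * n**2 * (3 * n + 2) * bn1 - (88.0 * n**3 + 9 * n**2 - 13 * n + 6)
    ) / (9.0 * n * (n - 1) ** 2) * theta_sq
    h_norm = (theta_pi - theta_L) / math.sqrt(var)
    return h_norm, theta_pi, theta_L, theta_H


# ---------------------------------------------------------------------------
# divergence


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor distance K = -(3/4) ln(1 - 4p/3) for a raw difference
    proportion p in [0, 0.75)."""
    if not 0.0 <= p < 0.75:
        raise SaturationError(f"Jukes-Cantor undefined for p = {p}")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def pairwise_p_distance(seq_a: str, seq_b: str) -> tuple[Optional[float], int]:
    """Raw proportion of differing sites between two aligned sequences under
    pairwise deletion. Returns (p, L); p is None when no gap-free column
    remains."""
    a = np.frombuffer(seq_a.encode(), dtype="S1")
    b = np.frombuffer(seq_b.encode(), dtype="S1")
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    mask = (a != b"-") & (b != b"-")
    L = int(mask.sum())
    if L == 0:
        return None, 0
    return float((a[mask] != b[mask]).mean()), L


def jc_divergence(seq_a: str, seq_b: str) -> Optional[float]:
    """Jukes-Cantor divergence between two aligned sequences (pairwise
    deletion); None when no comparable site exists."""
    p, _ = pairwise_p_distance(seq_a, seq_b)
    if p is None:
        return None
    return jukes_cantor(p)


# ---------------------------------------------------------------------------
# F_ST


def _pair_rates(seqs_a: Sequence[str], seqs_b: Sequence[str], within: bool) -> list[float]:
    rates = []
    if within:
        pairs = [(i, j) for i in range(len(seqs_a)) for j in range(i + 1, len(seqs_a))]
        for i, j in pairs:
            p, L = pairwise_p_distance(seqs_a[i], seqs_a[j])
            if p is not None:
                rates.append(p)
    else:
        for sa in seqs_a:
            for sb in seqs_b:
                p, L = pairwise_p_distance(sa, sb)
                if p is not None:
                    rates.append(p)
    return rates


def hudson_fst(
    populations: dict[str, Sequence[str]], estimator: str = "hudson"
) -> Optional[float]:
    """F_ST over >= 2 population haplotype sets.

    The primary estimator is Hudson's 1 - Hw/Hb where Hw is the mean
    within-population pairwise difference rate (populations weighted equally)
    and Hb the mean between-population rate (population pairs weighted
    equally). Returns None when Hb = 0 (monomorphic across populations).
    Negative estimates are reported, not clamped.

    ``estimator="variance_components"`` gives a haploid ANOVA estimator
    (among/within mean squares summed over sites).
    """
    pops = {k: list(v) for k, v in populations.items()}
    if len(pops) < 2:
        raise SampleSizeError("F_ST requires >= 2 populations")
    for name, seqs in pops.items():
        if len(seqs) < 2:
            raise SampleSizeError(f"population {name!r} has < 2 haplotypes")
    if estimator == "variance_components":
        return _fst_variance_components(pops)
    if estimator != "hudson":
        raise ValueError(f"unknown estimator {estimator!r}")
    hw_means = []
    for seqs in pops.values():
        rates = _pair_rates(seqs, seqs, within=True)
        hw_means.append(float(np.mean(rates)) if rates else 0.0)
    hw = float(np.mean(hw_means))
    names = list(pops)
    hb_means = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rates = _pair_rates(pops[names[i]], pops[names[j]], within=False)
            if rates:
                hb_means.append(float(np.mean(rates)))
    if not hb_means:
        return None
    hb = float(np.mean(hb_means))
    if hb == 0.0:
        return None
    return 1.0 - hw / hb


def _fst_variance_components(pops: dict[str, list[str]]) -> Optional[float]:
    """Haploid ANOVA F_ST: per-site among/within variance components summed
    over sites (Weir-Cockerham style with haploid samples)."""
    names = list(pops)
    r = len(names)
    ns = np.array([len(pops[k]) for k in names], dtype=float)
    n_tot = ns.sum()
    nc = (n_tot - np.sum(ns**2) / n_tot) / (r - 1)
    mats = {k: _column_matrix(pops[k]) for k in names}
    L = mats[names[0]].shape[1]
    num = 0.0
    den = 0.0
    for col in range(L):
        cols = {k: mats[k][:, col] for k in names}
        if any((c == "-").any() for c in cols.values()):
            continue
        alleles = sorted(set(b for c in cols.values() for b in c))
        if len(alleles) < 2:
            continue
        for allele in alleles:
            p_i = np.array([(cols[k] == allele).mean() for k in names])
            p_bar = float(np.sum(ns * p_i) / n_tot)
            msp = float(np.sum(ns * (p_i - p_bar) ** 2) / (r - 1))
            msg = float(np.sum(ns * p_i * (1 - p_i)) / (n_tot - r))
            num += msp - msg
            den += msp + (nc - 1) * msg
    if den == 0.0:
        return None
    return num / den


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(pvalues: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns (reject, p_adjusted) aligned with the input order: reject[i] is
    True iff the i-th hypothesis is rejected at FDR q; p_adjusted is the
    monotone BH-adjusted p-value.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresholds = q * np.arange(1, m + 1) / m
    passing = np.nonzero(ranked <= thresholds)[0]
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        reject[order[: passing[-1] + 1]] = True
    adj = ranked * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    p_adj = np.empty(m)
    p_adj[order] = np.minimum(adj, 1.0)
    return reject, p_adj
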