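"""Hardy-Weinberg and linkage-disequilibrium screening for biallelic loci.

The HWE test is the exact biallelic test: conditional on the sample size n
and the minor-allele count, every admissible heterozygote count (same
parity as the minor-allele count) is enumerated and the two-sided p-value
sums the probabilities of all outcomes no more likely than the observed
one (probability-ordering tail convention).

The LD test estimates the four two-locus haplotype frequencies from
unphased genotypes by EM (the double heterozygote is the only ambiguous
class), forms the likelihood-ratio G statistic against the
allele-frequency-product null, and assesses significance by permutation
of one locus's genotypes across individuals (chi-square df=1 p-value also
reported).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2

__all__ = [
    "HweResult",
    "LdResult",
    "hwe_exact",
    "hwe_scan",
    "ld_test",
    "ld_scan",
    "bonferroni_threshold",
]


@dataclass
class HweResult:
    locus_id: str
    n: int
    n_het: int
    p_value: float
    direction: str  # "excess" | "deficit" | "none"


@dataclass
class LdResult:
    locus_a: str
    locus_b: str
    hap_freqs: np.ndarray  # (f_II, f_ID, f_DI, f_DD) for alleles (ins, del)
    D: float
    r2: float
    G: float
    p_value: float  # permutation p if permutations > 0, else chi-square p
    p_chi2: float
    permutations: int
    flagged: bool = False  # monomorphic / degenerate input


def _het_probabilities(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact P(n_het | n diploids, n_minor minor alleles) for all admissible
    heterozygote counts.

    Uses the stable mid-out recurrence
    P(h+2)/P(h) = 4 (n_a - h)/2 * (n_b - h)/2 / ((h+2)(h+1)) applied from the
    most probable class, then normalizes.
    """
    n_major = 2 * n - n_minor
    h_min = n_minor % 2
    h_max = min(n_minor, n_major)
    hs = np.arange(h_min, h_max + 1, 2)
    # unnormalized log-probabilities via lgamma (independent of recurrence
    # concerns; n is small enough that this is exact to double precision)
    logp = np.empty(hs.size)
    for i, h in enumerate(hs):
        naa = (n_minor - h) // 2
        nbb = (n_major - h) // 2
        logp[i] = (
            h * math.log(2.0)
            + math.lgamma(n + 1)
            - math.lgamma(naa + 1) - math.lgamma(h + 1) - math.lgamma(nbb + 1)
        )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return hs, p


def hwe_exact(genotype_counts: Sequence[int], locus_id: str = "") -> HweResult:
    """Exact biallelic Hardy-Weinberg test from (n_DD, n_ID, n_II) counts."""
    c0, c1, c2 = (int(x) for x in genotype_counts)
    if min(c0, c1, c2) < 0:
        raise ValueError("negative genotype count")
    n = c0 + c1 + c2
    if n < 1:
        raise ValueError("empty genotype counts")
    n_ins = c1 + 2 * c2
    n_minor = min(n_ins, 2 * n - n_ins)
    if n_minor == 0:  # monomorphic: p = 1 by convention
        return HweResult(locus_id, n, c1, 1.0, "none")
    hs, probs = _het_probabilities(n, n_minor)
    p_obs = probs[np.searchsorted(hs, c1)]
    # two-sided by probability ordering; 1e-12 relative slack absorbs
    # floating-point ties
    p_value = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    p_value = min(1.0, p_value)
    exp_het = float((hs * probs).sum())
    direction = "excess" if c1 > exp_het else ("deficit" if c1 < exp_het else "none")
    return HweResult(locus_id, n, c1, p_value, direction)


def hwe_scan(g, population: str | None = None) -> list[HweResult]:
    """Exact HWE test per autosomal locus of a GenotypeMatrix."""
    sub = g.subset_population(population) if population else g
    out = []
    for j, loc in enumerate(sub.loci):
        d = sub.dosage[:, j]
        d = d[~np.isnan(d)]
        counts = [int((d == k).sum()) for k in (0, 1, 2)]
        out.append(hwe_exact(counts, loc.locus_id))
    return out


# ---------------------------------------------------------------------------
# two-locus LD


def _em_haplotypes(n33: np.ndarray, tol: float = 1e-8, max_iter: int = 1000
                   ) -> tuple[np.ndarray, float]:
    """EM haplotype frequencies from the 3x3 two-locus genotype count table.

    ``n33[i, j]`` counts individuals with dosage i at locus A and j at
    locus B.  Returns (f_II, f_ID, f_DI, f_DD) — first index is locus A
    allele (ins/del), second locus B — and the maximized log-likelihood.
    Haplotype labels: 0 = I_A I_B, 1 = I_A D_B, 2 = D_A I_B, 3 = D_A D_B.
    """
    n = n33.sum()
    # known haplotype contributions: every cell except the double het (1,1)
    # resolves into definite haplotypes
    pA = (n33[1, :].sum() + 2 * n33[2, :].sum()) / (2 * n)
    pB = (n33[:, 1].sum() + 2 * n33[:, 2].sum()) / (2 * n)
    f = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    f = np.maximum(f, 1e-12)
    f /= f.sum()
    ndh = n33[1, 1]

    def fixed_counts() -> np.ndarray:
        c = np.zeros(4)
        for i in range(3):
            for j in range(3):
                if i == 1 and j == 1:
                    continue
                cnt = n33[i, j]
                # haplotypes are determined when either locus is homozygous
                if i == 1:  # A het, B hom
                    c[0 if j == 2 else 1] += cnt  # I_A with B allele
                    c[2 if j == 2 else 3] += cnt  # D_A with B allele
                elif j == 1:  # B het, A hom
                    c[0 if i == 2 else 2] += cnt
                    c[1 if i == 2 else 3] += cnt
                else:  # both hom
                    hap = (0 if i == 2 else 2) if j == 2 else (1 if i == 2 else 3)
                    c[hap] += 2 * cnt
        return c

    base = fixed_counts()

    def loglik(f: np.ndarray) -> float:
        ll = 0.0
        for i in range(3):
            for j in range(3):
                cnt = n33[i, j]
                if cnt == 0:
                    continue
                ll += cnt * math.log(_genotype_prob(f, i, j))
        return ll

    prev = -np.inf
    for _ in range(max_iter):
        # E-step: split double heterozygotes between cis (0,3) and
        # trans (1,2) phases
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        w = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        c = base.copy()
        c[0] += ndh * w
        c[3] += ndh * w
        c[1] += ndh * (1 - w)
        c[2] += ndh * (1 - w)
        f = c / (2 * n)
        ll = loglik(np.maximum(f, 1e-300))
        if ll - prev < tol and ll >= prev - 1e-9:
            prev = ll
            break
        prev = ll
    return f, prev


def _genotype_prob(f: np.ndarray, i: int, j: int) -> float:
    """P(dosage pair (i, j)) given haplotype frequencies, HWE at hap level."""
    # haplotypes: 0=(I,I) 1=(I,D) 2=(D,I) 3=(D,D); genotype = unordered pair
    p = 0.0
    haps = [(0, (1, 1)), (1, (1, 0)), (2, (0, 1)), (3, (0, 0))]
    for h1, (a1, b1) in haps:
        for h2, (a2, b2) in haps:
            if a1 + a2 == i and b1 + b2 == j:
                p += f[h1] * f[h2]
    return max(p, 1e-300)


def _ld_stats(n33: np.ndarray) -> tuple[np.ndarray, float, float, float]:
    """(hap freqs, D, r2, G) for one 3x3 table."""
    n = n33.sum()
    f, ll1 = _em_haplotypes(n33)
    pA = f[0] + f[1]
    pB = f[0] + f[2]
    D = f[0] - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = (D * D / denom) if denom > 0 else 0.0
    f0 = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    ll0 = 0.0
    for i in range(3):
        for j in range(3):
            cnt = n33[i, j]
            if cnt:
                ll0 += cnt * math.log(_genotype_prob(f0, i, j))
    G = max(0.0, 2.0 * (ll1 - ll0))
    return f, D, min(r2, 1.0), G


def ld_test(
    gA: np.ndarray,
    gB: np.ndarray,
    permutations: int = 10_000,
    seed: int | None = None,
    locus_a: str = "A",
    locus_b: str = "B",
) -> LdResult:
    """Two-locus LD test on paired dosage vectors.

    Missing calls at either locus drop the pair.  Significance by
    permutation of one locus's genotypes across individuals (the G
    statistic is recomputed per shuffle); `p_chi2` is the analytic
    chi-square(1) p-value for the same G.
    """
    gA = np.asarray(gA, dtype=float)
    gB = np.asarray(gB, dtype=float)
    keep = ~(np.isnan(gA) | np.isnan(gB))
    a, b = gA[keep].astype(int), gB[keep].astype(int)
    if a.size < 2:
        raise ValueError("need at least 2 paired non-missing calls")

    def table(a, b):
        t = np.zeros((3, 3), dtype=int)
        np.add.at(t, (a, b), 1)
        return t

    if len(np.unique(a)) == 1 or len(np.unique(b)) == 1:
        warnings.warn("monomorphic locus in LD test")
        f = np.full(4, np.nan)
        return LdResult(locus_a, locus_b, f, 0.0, 0.0, 0.0, 1.0, 1.0, 0, flagged=True)

    f, D, r2, G = _ld_stats(table(a, b))
    p_chi2 = float(chi2.sf(G, df=1))
    if permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        bp = b.copy()
        for _ in range(permutations):
            rng.shuffle(bp)
            _, _, _, Gp = _ld_stats(table(a, bp))
            if Gp >= G - 1e-12:
                hits += 1
        p_perm = (hits + 1) / (permutations + 1)
    else:
        p_perm = p_chi2
    return LdResult(locus_a, locus_b, f, float(D), float(r2), float(G),
                    float(p_perm), p_chi2, permutations)


def ld_scan(g, population: str | None = None, permutations: int = 0,
            seed: int | None = None) -> list[LdResult]:
    """All-pairs LD tests for a GenotypeMatrix (chi-square by default;
    set permutations > 0 for the permutation p-value)."""
    sub = g.subset_population(population) if population else g
    out = []
    m = len(sub.loci)
    for i in range(m):
        for j in range(i + 1, m):
            out.append(ld_test(sub.dosage[:, i], sub.dosage[:, j],
                               permutations=permutations, seed=seed,
                               locus_a=sub.loci[i].locus_id,
                               locus_b=sub.loci[j].locus_id))
    return out


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("need at least one test")
    return alpha / m
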