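"""Full-sibling likelihood ratios and simulation-based power study.

For a pair of genotypes (g1, g2) at one biallelic locus with insertion
frequency p, the likelihood ratio comparing H1 (full siblings) against
H2 (unrelated) follows from the IBD-sharing coefficients of full
siblings, kappa = (1/4, 1/2, 1/4):

    LR = k0 + k1 * T1(g2 | g1, p) / P(g2 | p) + k2 * [g1 == g2] / P(g2 | p)

where P(. | p) are Hardy-Weinberg genotype probabilities and T1 is the
one-IBD-allele transition kernel.  Panel LRs multiply across loci
(accumulated in log10), justified by the panel's LD screen.

The power study simulates full-sibling pairs through explicit parents
(two HWE parents, each child receiving one uniformly chosen allele from
each parent) and unrelated pairs as independent HWE draws, then reports,
for each LR limit, the fraction of sibling pairs with LR >= limit
(accuracy) and of unrelated pairs with LR >= limit (false-positive
ratio).  The comparison is inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KAPPA_FULL_SIBLING",
    "DEFAULT_LIMITS",
    "KinshipSimResult",
    "sib_lr_locus",
    "panel_log_lr",
    "simulate_pair",
    "simulate_pairs",
    "power_study",
]

#: IBD-sharing probabilities (kappa0, kappa1, kappa2) for full siblings
KAPPA_FULL_SIBLING = (0.25, 0.5, 0.25)

#: LR decision limits of the power study
DEFAULT_LIMITS = (1.0, 10.0, 100.0, 1000.0, 10000.0)


@dataclass
class KinshipSimResult:
    log10_lr_fs: np.ndarray
    log10_lr_un: np.ndarray
    limits: list[float]
    accuracy: np.ndarray        # P(LR >= limit | full siblings)
    false_positive: np.ndarray  # P(LR >= limit | unrelated)
    n_pairs: int
    seed: int | None


def _hwe_probs(p: float) -> np.ndarray:
    """HWE genotype probabilities for dosages (0, 1, 2)."""
    q = 1.0 - p
    return np.array([q * q, 2 * p * q, p * p])


def _t1_kernel(p: float) -> np.ndarray:
    """T1[g1, g2] = P(g2 | g1, pair shares exactly 1 allele IBD).

    The non-IBD allele of the second individual is a fresh draw from the
    population; the IBD allele is one of g1's two alleles, equally likely.
    """
    q = 1.0 - p
    return np.array([
        [q, p, 0.0],                       # g1 = DD: IBD allele is D
        [q / 2, 0.5, p / 2],               # g1 = ID: IBD allele D or I
        [0.0, q, p],                       # g1 = II: IBD allele is I
    ])


def sib_lr_locus(g1: int, g2: int, p: float) -> float:
    """Single-locus full-sibling vs unrelated LR for a genotype pair."""
    if not 0.0 < p < 1.0:
        raise ValueError("locus uninformative: p must be strictly inside (0, 1)")
    if g1 not in (0, 1, 2) or g2 not in (0, 1, 2):
        raise ValueError("genotypes must be dosages 0, 1 or 2")
    k0, k1, k2 = KAPPA_FULL_SIBLING
    pg2 = _hwe_probs(p)[g2]
    t1 = _t1_kernel(p)[g1, g2]
    return k0 + k1 * t1 / pg2 + k2 * (1.0 if g1 == g2 else 0.0) / pg2


def _locus_lr_table(p: np.ndarray) -> np.ndarray:
    """Vectorized LR[locus, g1, g2] over a frequency vector."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    hwe = np.stack([q * q, 2 * p * q, p * p], axis=1)       # (L, 3)
    t1 = np.stack([
        np.stack([q, p, np.zeros_like(p)], axis=1),
        np.stack([q / 2, np.full_like(p, 0.5), p / 2], axis=1),
        np.stack([np.zeros_like(p), q, p], axis=1),
    ], axis=1)                                              # (L, g1, g2)
    k0, k1, k2 = KAPPA_FULL_SIBLING
    eye = np.eye(3)
    return k0 + (k1 * t1 + k2 * eye[None]) / hwe[:, None, :]


def panel_log_lr(g1: np.ndarray, g2: np.ndarray, p: np.ndarray) -> float:
    """log10 LR over a panel; loci with a missing call or degenerate
    frequency are skipped."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    p = np.asarray(p, dtype=float)
    keep = ~(np.isnan(g1) | np.isnan(g2)) & (p > 0) & (p < 1)
    if not keep.any():
        warnings.warn("no informative loci: LR = 1")
        return 0.0
    lr = _locus_lr_table(p[keep])
    idx = np.arange(keep.sum())
    vals = lr[idx, g1[keep].astype(int), g2[keep].astype(int)]
    return float(np.log10(vals).sum())


def simulate_pair(p: np.ndarray, relationship: str, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray]:
    """One genotype pair over all loci.

    Unrelated: two independent HWE draws.  Full siblings: two HWE parents
    per locus; each child receives one uniformly chosen allele from each
    parent, independently per child and per locus.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    if relationship == "unrelated":
        return (rng.binomial(2, p).astype(float),
                rng.binomial(2, p).astype(float))
    if relationship == "full_sibling":
        L = p.size
        father = rng.random((L, 2)) < p  # two allele draws per parent
        mother = rng.random((L, 2)) < p
        out = []
        for _child in range(2):
            fa = father[np.arange(L), rng.integers(0, 2, L)]
            mo = mother[np.arange(L), rng.integers(0, 2, L)]
            out.append((fa.astype(int) + mo.astype(int)).astype(float))
        return out[0], out[1]
    raise ValueError(f"unknown relationship {relationship!r}")


def simulate_pairs(p: np.ndarray, relationship: str, n_pairs: int,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized block of genotype pairs, shape (n_pairs, n_loci) each."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    if relationship == "unrelated":
        return (rng.binomial(2, p, size=(n_pairs, p.size)).astype(float),
                rng.binomial(2, p, size=(n_pairs, p.size)).astype(float))
    if relationship == "full_sibling":
        shape = (n_pairs, p.size)
        father = rng.random(shape + (2,)) < p[None, :, None]
        mother = rng.random(shape + (2,)) < p[None, :, None]
        kids = []
        for _child in range(2):
            fa = np.take_along_axis(father, rng.integers(0, 2, shape)[..., None], -1)[..., 0]
            mo = np.take_along_axis(mother, rng.integers(0, 2, shape)[..., None], -1)[..., 0]
            kids.append((fa.astype(int) + mo.astype(int)).astype(float))
        return kids[0], kids[1]
    raise ValueError(f"unknown relationship {relationship!r}")


def _block_log_lr(g1: np.ndarray, g2: np.ndarray, p: np.ndarray) -> np.ndarray:
    keep = (p > 0) & (p < 1)
    if not keep.any():
        warnings.warn("no informative loci: all LR = 1")
        return np.zeros(g1.shape[0])
    lr = _locus_lr_table(p[keep])
    a = g1[:, keep].astype(int)
    b = g2[:, keep].astype(int)
    vals = lr[np.arange(keep.sum())[None, :], a, b]
    return np.log10(vals).sum(axis=1)


def power_study(
    p: np.ndarray,
    n_pairs: int = 1000,
    limits: tuple[float, ...] = DEFAULT_LIMITS,
    seed: int | None = None,
) -> KinshipSimResult:
    """Simulate sibling and unrelated pairs and score LR >= limit rates."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    p = np.asarray(p, dtype=float)
    rng = np.random.default_rng(seed)
    fs1, fs2 = simulate_pairs(p, "full_sibling", n_pairs, rng)
    un1, un2 = simulate_pairs(p, "unrelated", n_pairs, rng)
    log_fs = _block_log_lr(fs1, fs2, p)
    log_un = _block_log_lr(un1, un2, p)
    lim = np.asarray(limits, dtype=float)
    log_lim = np.log10(lim)
    tol = 1e-9  # inclusive comparison robust to log-space rounding
    acc = np.array([(log_fs >= t - tol).mean() for t in log_lim])
    fpr = np.array([(log_un >= t - tol).mean() for t in log_lim])
    return KinshipSimResult(log_fs, log_un, [float(x) for x in lim],
                            acc, fpr, n_pairs, seed)
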