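"""Population differentiation and assignment-informativeness summaries.

* Pairwise FST: the Weir & Cockerham (1984) theta estimator from per-locus
  variance components a (among populations), b (among individuals within
  populations) and c (within individuals), combined multi-locus as
  sum(a) / sum(a + b + c).
* Nei's DA distance: 1 - (1/L) sum_l sum_alleles sqrt(x * y).
* Rosenberg's informativeness for assignment In (natural log, unweighted
  population mean), the expected information an allele draw carries about
  the population label.
* Hierarchical AMOVA on allele dosage (each diploid contributes two allele
  copies), with unequal-size coefficients; 2-level (populations / within)
  or 3-level (groups / populations within groups / within populations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import DistanceMatrix, FrequencyTable, GenotypeMatrix

__all__ = [
    "AmovaResult",
    "wc_fst_components",
    "wc_fst",
    "pairwise_fst_matrix",
    "da_distance",
    "da_matrix",
    "informativeness_in",
    "amova",
]


@dataclass
class AmovaResult:
    design: str  # "2-level" | "3-level"
    sigma2_among_groups: float
    sigma2_among_pops: float  # within groups for the 3-level design
    sigma2_within: float
    percentages: dict[str, float]
    phi: dict[str, float]  # phi_CT, phi_SC, phi_ST (subset for 2-level)


# ---------------------------------------------------------------------------
# Weir & Cockerham theta


def _pop_summaries(dosage: np.ndarray) -> tuple[int, float, float]:
    """(n called, insertion freq, observed het) for one locus, one pop."""
    d = dosage[~np.isnan(dosage)]
    n = d.size
    if n == 0:
        return 0, np.nan, np.nan
    p = d.sum() / (2.0 * n)
    h = float((d == 1).mean())
    return n, p, h


def wc_fst_components(
    dosage_by_pop: Sequence[np.ndarray],
) -> tuple[float, float, float]:
    """Per-locus W&C (1984) variance components (a, b, c).

    ``dosage_by_pop`` is one dosage vector per population for a single
    locus.  Populations with no calls at the locus are dropped.
    """
    stats = [_pop_summaries(np.asarray(d, dtype=float)) for d in dosage_by_pop]
    stats = [(n, p, h) for n, p, h in stats if n > 0]
    r = len(stats)
    if r < 2:
        return np.nan, np.nan, np.nan
    n_i = np.array([s[0] for s in stats], dtype=float)
    p_i = np.array([s[1] for s in stats])
    h_i = np.array([s[2] for s in stats])
    nbar = n_i.mean()
    if nbar <= 1:
        return np.nan, np.nan, np.nan
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n_i * p_i).sum() / (r * nbar)
    s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum() / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return float(a), float(b), float(c)


def wc_fst(gA: GenotypeMatrix, gB: GenotypeMatrix) -> float:
    """Multi-locus pairwise theta between two single-population matrices.

    Negative estimates are retained (they arise at near-zero
    differentiation); floor them only for geometry-consuming stages.
    """
    if gA.locus_ids != gB.locus_ids:
        raise ValueError("locus sets differ")
    num = den = 0.0
    informative = 0
    for j in range(len(gA.loci)):
        a, b, c = wc_fst_components([gA.dosage[:, j], gB.dosage[:, j]])
        if np.isnan(a):
            continue
        tot = a + b + c
        if tot == 0.0:  # locus monomorphic across both pops
            continue
        num += a
        den += tot
        informative += 1
    if informative == 0 or den == 0.0:
        raise ValueError("no shared informative loci")
    return num / den


def pairwise_fst_matrix(g: GenotypeMatrix, clamp: bool = False) -> DistanceMatrix:
    """All-pairs W&C theta between the populations of a GenotypeMatrix."""
    pops = list(dict.fromkeys(g.population))
    subs = {p: g.subset_population(p) for p in pops}
    k = len(pops)
    vals = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            t = wc_fst(subs[pops[i]], subs[pops[j]])
            vals[i, j] = vals[j, i] = t
    d = DistanceMatrix(pops, vals, "fst")
    return d.clamp_nonnegative() if clamp else d


# ---------------------------------------------------------------------------
# Nei DA distance


def da_distance(fA: np.ndarray, fB: np.ndarray) -> float:
    """Nei et al. (1983) DA distance between two insertion-frequency
    vectors over the same loci (both alleles enter the geometric mean)."""
    fA = np.asarray(fA, dtype=float)
    fB = np.asarray(fB, dtype=float)
    if fA.shape != fB.shape:
        raise ValueError("locus sets differ")
    keep = ~(np.isnan(fA) | np.isnan(fB))
    if not keep.any():
        raise ValueError("no shared loci with frequencies")
    x, y = fA[keep], fB[keep]
    shared = np.sqrt(x * y) + np.sqrt((1 - x) * (1 - y))
    return float(1.0 - shared.mean())


def da_matrix(t: FrequencyTable, clamp: bool = False) -> DistanceMatrix:
    k = len(t.populations)
    vals = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            vals[i, j] = vals[j, i] = da_distance(t.p_ins[:, i], t.p_ins[:, j])
    d = DistanceMatrix(list(t.populations), vals, "da")
    return d.clamp_nonnegative() if clamp else d


# ---------------------------------------------------------------------------
# Rosenberg informativeness for assignment


def _xlogx(x: np.ndarray) -> np.ndarray:
    """x * ln(x) with the 0 * ln(0) := 0 convention."""
    out = np.zeros_like(x, dtype=float)
    pos = x > 0
    out[pos] = x[pos] * np.log(x[pos])
    return out


def informativeness_in(p_by_pop: np.ndarray) -> np.ndarray:
    """Rosenberg's In per locus.

    ``p_by_pop`` has shape (n_loci, K populations) of insertion
    frequencies.  Returns In in nats per locus:
    In = sum_alleles( -pbar ln pbar + (1/K) sum_i p_i ln p_i ),
    with pbar the unweighted mean across populations.
    """
    p = np.atleast_2d(np.asarray(p_by_pop, dtype=float))
    K = p.shape[1]
    if K < 2:
        raise ValueError("need at least 2 populations")
    out = np.zeros(p.shape[0])
    for allele in (p, 1.0 - p):
        pbar = allele.mean(axis=1)
        out += -_xlogx(pbar) + _xlogx(allele).sum(axis=1) / K
    return np.maximum(out, 0.0)  # clip -0.0 / rounding at identical freqs


# ---------------------------------------------------------------------------
# AMOVA


def amova(
    g: GenotypeMatrix,
    grouping: Mapping[str, str] | None = None,
) -> AmovaResult:
    """Hierarchical analysis of molecular variance on allele dosage.

    Each diploid contributes 2 allele copies per locus (the within-
    individual level is collapsed into the within-population component).
    ``grouping`` maps population -> group for the 3-level design; omit it
    for the 2-level among/within-population partition.  Sums of squares
    are accumulated over loci, then variance components are estimated
    from expected mean squares with unequal-sample-size coefficients.
    """
    pops = list(dict.fromkeys(g.population))
    if grouping is None:
        grouping = {p: "ALL" for p in pops}
        design = "2-level"
    else:
        missing = [p for p in pops if p not in grouping]
        if missing:
            raise ValueError(f"populations without a group: {missing}")
        design = "3-level"
    groups = list(dict.fromkeys(grouping[p] for p in pops))
    if design == "3-level":
        sizes = {gr: sum(1 for p in pops if grouping[p] == gr) for gr in groups}
        if any(v == 1 for v in sizes.values()):
            warnings.warn("a group contains a single population; the 3-level "
                          "design is degenerate for that group")

    pop_of = np.array(g.population)
    SSw = SSp = SSg = 0.0
    # size coefficients accumulate per locus because missingness varies
    sum_np2_over_ng = sum_np2_over_N = sum_ng2_over_N = 0.0
    N_tot = 0.0
    P_tot = G_tot = 0
    n_loci_used = 0

    for j in range(len(g.loci)):
        d = g.dosage[:, j]
        called = ~np.isnan(d)
        if called.sum() < 2:
            continue
        # allele-copy means: each sample holds 2 copies with mean d/2
        pop_n = {}
        pop_mean = {}
        for p in pops:
            m = called & (pop_of == p)
            if m.sum() == 0:
                continue
            pop_n[p] = 2.0 * m.sum()  # allele copies
            pop_mean[p] = d[m].sum() / pop_n[p]
        if len(pop_n) < 2:
            continue
        grp_n, grp_sum = {}, {}
        for p, n_p in pop_n.items():
            gr = grouping[p]
            grp_n[gr] = grp_n.get(gr, 0.0) + n_p
            grp_sum[gr] = grp_sum.get(gr, 0.0) + pop_mean[p] * n_p
        grp_mean = {gr: grp_sum[gr] / grp_n[gr] for gr in grp_n}
        N = sum(pop_n.values())
        grand = sum(pop_mean[p] * pop_n[p] for p in pop_n) / N

        # within-population SS over allele copies: for a sample with
        # dosage d the two copies are d-1 ones... explicitly:
        # sum over copies (x - pop mean)^2 = sum_x x^2 - n * mean^2 where
        # sum of squared copies = sum of dosage (copies are 0/1)
        for p in pop_n:
            m = called & (pop_of == p)
            sum_sq = d[m].sum()  # 0/1 copies: x^2 == x
            SSw += sum_sq - pop_n[p] * pop_mean[p] ** 2
        SSp += sum(pop_n[p] * (pop_mean[p] - grp_mean[grouping[p]]) ** 2
                   for p in pop_n)
        SSg += sum(grp_n[gr] * (grp_mean[gr] - grand) ** 2 for gr in grp_n)

        sum_np2_over_ng += sum(pop_n[p] ** 2 / grp_n[grouping[p]] for p in pop_n)
        sum_np2_over_N += sum(v**2 for v in pop_n.values()) / N
        sum_ng2_over_N += sum(v**2 for v in grp_n.values()) / N
        N_tot += N
        P_tot += len(pop_n)
        G_tot += len(grp_n)
        n_loci_used += 1

    if n_loci_used == 0:
        raise ValueError("no usable loci for AMOVA")
    # degrees of freedom summed across loci
    df_w = N_tot - P_tot
    df_p = P_tot - G_tot
    df_g = G_tot - n_loci_used

    sigma_w = SSw / df_w if df_w > 0 else 0.0
    if df_p > 0:
        n_prime = (N_tot - sum_np2_over_ng) / df_p
        sigma_p = (SSp / df_p - sigma_w) / n_prime
    else:
        sigma_p = 0.0
    if df_g > 0:
        n_dprime = (sum_np2_over_ng - sum_np2_over_N) / df_g
        n_tprime = (N_tot - sum_ng2_over_N) / df_g
        sigma_g = (SSg / df_g - sigma_w - n_dprime * sigma_p) / n_tprime
    else:
        sigma_g = 0.0

    total = sigma_g + sigma_p + sigma_w
    pct = {
        "among_groups": 100.0 * sigma_g / total if design == "3-level" else 0.0,
        "among_populations": 100.0 * sigma_p / total,
        "within_populations": 100.0 * sigma_w / total,
    }
    if design == "2-level":
        pct.pop("among_groups")
    phi = {"phi_ST": (sigma_g + sigma_p) / total}
    if design == "3-level":
        phi["phi_CT"] = sigma_g / total
        phi["phi_SC"] = sigma_p / (sigma_p + sigma_w)
    return AmovaResult(design, float(sigma_g), float(sigma_p), float(sigma_w),
                       pct, {k: float(v) for k, v in phi.items()})
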