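"""Per-locus forensic parameters and panel-wide cumulative indices.

For a biallelic DIP locus with insertion frequency p (q = 1 - p) observed
in n diploid individuals:

* unbiased expected heterozygosity  He = 2pq * 2n / (2n - 1)
* polymorphism information content  PIC = 1 - (p^2 + q^2) - 2 p^2 q^2
* match probability                 MP = sum over genotypes of (observed
  genotype frequency)^2, PD = 1 - MP
* trio power of exclusion           PE = h^2 (1 - 2 h H^2), with h the
  observed heterozygosity and H = 1 - h
* typical paternity index           TPI = 1 / (2 H)

Panel-wide: CMP is the product of per-locus MP, CPD = 1 - CMP and
CPE = 1 - prod(1 - PE).  The long decimal expansions of CPD are computed
with arbitrary-precision decimal arithmetic so the report strings are
exact, not float-rounded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import Decimal, getcontext
from typing import Sequence

import numpy as np

from .io_formats import GenotypeMatrix

__all__ = [
    "LocusForensicStats",
    "PanelCumulative",
    "unbiased_he",
    "pic",
    "match_probability",
    "pe_trio",
    "tpi",
    "locus_stats",
    "panel_stats",
    "cumulative",
]


@dataclass
class LocusForensicStats:
    locus_id: str
    n: int
    p_ins: float
    Ho: float
    He: float
    PIC: float
    MP: float
    PD: float
    PE: float
    TPI: float


@dataclass
class PanelCumulative:
    CMP: float
    CPD: float
    CPE: float
    log10_CMP: float
    CMP_sci: str  # e.g. "2.7029E-24"
    CPD_str: str  # exact decimal expansion of 1 - prod(MP)
    CPE_str: str


def unbiased_he(p: float, n: int) -> float:
    """Unbiased expected heterozygosity 2pq * 2n/(2n-1) (Nei 1978)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("allele frequency outside [0, 1]")
    if n < 2:
        raise ValueError("need at least 2 diploid samples for unbiased He")
    return 2.0 * p * (1.0 - p) * (2 * n) / (2 * n - 1)


def pic(p: float) -> float:
    """Polymorphism information content of a biallelic locus."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("allele frequency outside [0, 1]")
    q = 1.0 - p
    return 1.0 - (p * p + q * q) - 2.0 * p * p * q * q


def match_probability(genotype_counts: Sequence[int]) -> tuple[float, float]:
    """(MP, PD) from observed genotype counts at one locus.

    MP is the probability two random individuals share a genotype,
    computed from observed genotype frequencies (not HWE expectations).
    """
    counts = np.asarray(genotype_counts, dtype=float)
    total = counts.sum()
    if counts.size == 0 or total < 1:
        raise ValueError("empty genotype counts")
    freqs = counts / total
    mp = float(np.sum(freqs**2))
    return mp, 1.0 - mp


def pe_trio(ho: float) -> float:
    """Trio power of exclusion h^2 (1 - 2 h H^2) from observed het Ho."""
    if not 0.0 <= ho <= 1.0:
        raise ValueError("heterozygosity outside [0, 1]")
    h, H = ho, 1.0 - ho
    return h * h * (1.0 - 2.0 * h * H * H)


def tpi(ho: float) -> float:
    """Typical paternity index 1/(2H); +inf (with warning) when Ho = 1."""
    if not 0.0 <= ho <= 1.0:
        raise ValueError("heterozygosity outside [0, 1]")
    H = 1.0 - ho
    if H == 0.0:
        warnings.warn("Ho = 1: TPI is infinite")
        return math.inf
    return 1.0 / (2.0 * H)


def locus_stats(locus_id: str, dosages: np.ndarray) -> LocusForensicStats:
    """All seven forensic parameters for one locus from dosage calls."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    n = d.size
    if n < 2:
        raise ValueError(f"locus {locus_id}: fewer than 2 called samples")
    counts = [int((d == g).sum()) for g in (0, 1, 2)]
    p = (counts[1] + 2 * counts[2]) / (2.0 * n)
    ho = counts[1] / n
    mp, pd_ = match_probability(counts)
    return LocusForensicStats(
        locus_id=locus_id, n=n, p_ins=p, Ho=ho,
        He=unbiased_he(p, n), PIC=pic(p),
        MP=mp, PD=pd_, PE=pe_trio(ho), TPI=tpi(ho),
    )


def panel_stats(g: GenotypeMatrix, population: str | None = None) -> list[LocusForensicStats]:
    """Per-locus forensic parameters for a panel (optionally one population)."""
    sub = g.subset_population(population) if population else g
    return [locus_stats(loc.locus_id, sub.dosage[:, j])
            for j, loc in enumerate(sub.loci)]


def _sci_string(d: Decimal, digits: int = 5) -> str:
    """Scientific-notation string like 2.7029E-24 with `digits` significant."""
    if d == 0:
        return "0"
    k = int(d.log10().to_integral_value(rounding="ROUND_FLOOR"))
    mant = (d.scaleb(-k)).quantize(Decimal(1).scaleb(-(digits - 1)))
    return f"{mant}E{k:+d}"


def cumulative(stats: Sequence[LocusForensicStats], precision: int = 80) -> PanelCumulative:
    """Panel cumulative indices CMP, CPD, CPE.

    Accumulates in log space for the float values and in arbitrary-precision
    decimal for the exact report strings (the decimal expansion of
    1 - prod(MP) needs every digit).
    """
    if len(stats) == 0:
        raise ValueError("need at least one locus")
    mps = np.array([s.MP for s in stats], dtype=float)
    pes = np.array([s.PE for s in stats], dtype=float)
    if (mps == 0).any():
        warnings.warn("MP = 0 at some locus; CMP = 0")
        log10_cmp = -math.inf
    else:
        log10_cmp = float(np.sum(np.log10(mps)))
    cmp_f = float(np.prod(mps))
    cpe_f = 1.0 - float(np.prod(1.0 - pes))

    getcontext().prec = precision
    cmp_d = Decimal(1)
    one_minus_pe = Decimal(1)
    for s in stats:
        cmp_d *= Decimal(repr(float(s.MP)))
        one_minus_pe *= 1 - Decimal(repr(float(s.PE)))
    cpd_d = 1 - cmp_d
    # show the exact expansion of CPD down to 5 significant digits of CMP
    if cmp_d > 0:
        k = int(cmp_d.log10().to_integral_value(rounding="ROUND_FLOOR"))
        cpd_str = str(cpd_d.quantize(Decimal(1).scaleb(k - 4)))
    else:
        cpd_str = "1"
    return PanelCumulative(
        CMP=cmp_f,
        CPD=1.0 - cmp_f,
        CPE=cpe_f,
        log10_CMP=log10_cmp,
        CMP_sci=_sci_string(+cmp_d) if cmp_d > 0 else "0",
        CPD_str=cpd_str,
        CPE_str=f"{cpe_f:.6f}",
    )
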