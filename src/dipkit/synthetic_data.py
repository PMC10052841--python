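"""Synthetic population-structured DIP datasets.

Generates genotypes under a hierarchical Balding-Nichols model: ancestral
insertion frequencies are drawn uniformly on a configurable interval
(default [0.3, 0.72], the realistic span for forensic DIP panels selected
for balanced allele frequencies); continental frequencies are Beta draws
around the ancestral value with dispersion set by a continental FST;
population frequencies are Beta draws around their continent with a
within-continent FST; genotypes are Hardy-Weinberg draws within each
population.  Loci are independent, so the generated data are LD-free by
construction.  The true frequency table is returned alongside the
genotypes for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import FrequencyTable, GenotypeMatrix, LocusDef

__all__ = ["PopulationSpec", "ContinentSpec", "SyntheticConfig",
           "bn_frequencies", "make_dataset", "default_config",
           "sibling_pair_dataset"]

_FREQ_FLOOR = 1e-4  # keep frequencies strictly inside (0, 1)


@dataclass
class PopulationSpec:
    name: str
    n_samples: int = 100
    fst_within_continent: float = 0.01

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not 0.0 < self.fst_within_continent < 1.0:
            raise ValueError("FST must be in (0, 1)")


@dataclass
class ContinentSpec:
    name: str
    fst_to_ancestral: float
    populations: list[PopulationSpec]

    def __post_init__(self) -> None:
        if not 0.0 < self.fst_to_ancestral < 1.0:
            raise ValueError("FST must be in (0, 1)")


@dataclass
class SyntheticConfig:
    n_loci: int = 57
    continents: list[ContinentSpec] = field(default_factory=list)
    p_lo: float = 0.3
    p_hi: float = 0.72
    seed: int | None = None


def default_config(seed: int | None = None,
                   n_samples: int = 100) -> SyntheticConfig:
    """Five continental groups with FST magnitudes typical of human
    continental structure (Africa most diverged from the out-of-Africa
    groups; East Asian populations ~0.01 apart)."""
    continents = [
        ContinentSpec("Africa", 0.15, [
            PopulationSpec("AFR1", n_samples, 0.02),
            PopulationSpec("AFR2", n_samples, 0.02),
        ]),
        ContinentSpec("Europe", 0.08, [
            PopulationSpec("EUR1", n_samples, 0.01),
            PopulationSpec("EUR2", n_samples, 0.01),
        ]),
        ContinentSpec("East_Asia", 0.10, [
            PopulationSpec("EAS1", n_samples, 0.01),
            PopulationSpec("EAS2", n_samples, 0.01),
            PopulationSpec("EAS3", n_samples, 0.01),
        ]),
        ContinentSpec("South_Asia", 0.06, [
            PopulationSpec("SAS1", n_samples, 0.01),
            PopulationSpec("SAS2", n_samples, 0.01),
        ]),
        ContinentSpec("America", 0.07, [
            PopulationSpec("AMR1", n_samples, 0.02),
            PopulationSpec("AMR2", n_samples, 0.02),
        ]),
    ]
    return SyntheticConfig(57, continents, seed=seed)


def bn_frequencies(p_anc: np.ndarray, F: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols draw: Beta(p(1-F)/F, (1-p)(1-F)/F) per locus."""
    p_anc = np.asarray(p_anc, dtype=float)
    if np.any((p_anc <= 0) | (p_anc >= 1)):
        raise ValueError("ancestral frequencies must be in (0, 1)")
    if not 0.0 < F < 1.0:
        raise ValueError("F must be in (0, 1)")
    scale = (1.0 - F) / F
    draws = rng.beta(p_anc * scale, (1.0 - p_anc) * scale)
    return np.clip(draws, _FREQ_FLOOR, 1.0 - _FREQ_FLOOR)


def make_dataset(cfg: SyntheticConfig) -> tuple[GenotypeMatrix, FrequencyTable]:
    """Genotypes plus the true population frequency table."""
    rng = np.random.default_rng(cfg.seed)
    loci = [LocusDef(f"rs{1000 + i}") for i in range(cfg.n_loci)]
    p_anc = rng.uniform(cfg.p_lo, cfg.p_hi, cfg.n_loci)

    pop_names: list[str] = []
    pop_continent: list[str] = []
    pop_freqs: list[np.ndarray] = []
    pop_sizes: list[int] = []
    for cont in cfg.continents:
        p_cont = bn_frequencies(p_anc, cont.fst_to_ancestral, rng)
        for pop in cont.populations:
            p_pop = bn_frequencies(p_cont, pop.fst_within_continent, rng)
            pop_names.append(pop.name)
            pop_continent.append(cont.name)
            pop_freqs.append(p_pop)
            pop_sizes.append(pop.n_samples)

    sample_ids, population, continent = [], [], []
    blocks = []
    for name, cont, p_pop, n in zip(pop_names, pop_continent, pop_freqs, pop_sizes):
        blocks.append(rng.binomial(2, p_pop, size=(n, cfg.n_loci)).astype(float))
        sample_ids += [f"{name}_{i:04d}" for i in range(n)]
        population += [name] * n
        continent += [cont] * n
    g = GenotypeMatrix(sample_ids, population, continent, loci,
                       np.vstack(blocks))
    truth = FrequencyTable(
        loci, pop_names,
        np.column_stack(pop_freqs),
        np.tile(np.asarray(pop_sizes), (cfg.n_loci, 1)),
    )
    return g, truth


def sibling_pair_dataset(p: np.ndarray, n_pairs: int, seed: int | None = None):
    """Convenience wrapper: (sibling pairs, unrelated pairs) genotype
    blocks from one frequency vector, for LR power experiments."""
    from .kinship_lr import simulate_pairs

    rng = np.random.default_rng(seed)
    fs = simulate_pairs(p, "full_sibling", n_pairs, rng)
    un = simulate_pairs(p, "unrelated", n_pairs, rng)
    return fs, un
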