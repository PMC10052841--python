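"""Tabular and tree I/O for DIP panel data.

Genotypes are coded as insertion-allele dosage (0, 1, 2), the count of
insertion ("I") alleles an individual carries at a biallelic
deletion/insertion locus.  Missing calls ("N/N") become NaN.  Only
autosomal DIP loci ever enter a statistic; Y-DIP and Amelogenin columns
are carried as sample metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LocusDef",
    "GenotypeMatrix",
    "FrequencyTable",
    "DistanceMatrix",
    "read_genotype_table",
    "write_genotype_table",
    "allele_frequencies",
    "read_frequency_table",
    "write_frequency_table",
    "write_phylip_distance",
    "read_phylip_distance",
    "write_newick",
    "read_newick",
    "write_results_json",
    "read_results_json",
]

_METADATA_COLS = ("sample_id", "population", "continent", "sex")

#: genotype-cell spellings accepted on input, mapped to insertion dosage
_GENOTYPE_TOKENS = {
    "I/I": 2, "I/D": 1, "D/I": 1, "D/D": 0,
    "2": 2, "1": 1, "0": 0,
}
_MISSING_TOKENS = {"N/N", "NN", "", ".", "NA", "nan"}


class GenotypeParseError(ValueError):
    """Raised when a genotype table cell or layout cannot be interpreted."""


@dataclass(frozen=True)
class LocusDef:
    """One marker of the panel."""

    locus_id: str
    marker_class: str = "autosomal_dip"  # autosomal_dip | y_dip | amelogenin

    def __post_init__(self) -> None:
        if self.marker_class not in {"autosomal_dip", "y_dip", "amelogenin"}:
            raise ValueError(f"unknown marker class {self.marker_class!r}")


@dataclass
class GenotypeMatrix:
    """Samples x loci insertion dosages with population/continent metadata.

    ``dosage`` is a float array so missing calls can be NaN; non-missing
    autosomal values are exactly 0.0, 1.0 or 2.0.
    """

    sample_ids: list[str]
    population: list[str]
    continent: list[str]
    loci: list[LocusDef]
    dosage: np.ndarray
    sex: list[str] | None = None
    metadata_loci: pd.DataFrame | None = None  # raw Y-DIP / Amelogenin calls

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if n != len(self.sample_ids):
            raise ValueError("dosage rows do not match sample_ids")
        if m != len(self.loci):
            raise ValueError("dosage columns do not match loci")
        if len(self.population) != n or len(self.continent) != n:
            raise ValueError("metadata length mismatch")
        if len(set(self.sample_ids)) != n:
            raise GenotypeParseError("duplicate sample_id")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosage values must be 0, 1, 2 or missing")
        pop2cont: dict[str, str] = {}
        for p, c in zip(self.population, self.continent):
            if pop2cont.setdefault(p, c) != c:
                raise ValueError(f"population {p!r} mapped to multiple continents")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def subset_population(self, population: str) -> "GenotypeMatrix":
        mask = np.array([p == population for p in self.population])
        if not mask.any():
            raise KeyError(f"population {population!r} not present")
        return GenotypeMatrix(
            sample_ids=[s for s, m in zip(self.sample_ids, mask) if m],
            population=[p for p, m in zip(self.population, mask) if m],
            continent=[c for c, m in zip(self.continent, mask) if m],
            loci=list(self.loci),
            dosage=self.dosage[mask],
            sex=[s for s, m in zip(self.sex, mask) if m] if self.sex else None,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "population": self.population,
                "continent": self.continent,
                "sex": self.sex if self.sex is not None else "",
            }
        )
        geno = pd.DataFrame(self.dosage, columns=self.locus_ids)
        out = pd.concat([df, geno], axis=1)
        if self.metadata_loci is not None:
            out = pd.concat([out, self.metadata_loci.reset_index(drop=True)], axis=1)
        return out


@dataclass
class FrequencyTable:
    """Loci x populations insertion-allele frequencies with sample sizes.

    Deletion frequency is always ``1 - p_ins``; it is never stored.
    """

    loci: list[LocusDef]
    populations: list[str]
    p_ins: np.ndarray  # shape (n_loci, n_pops)
    n: np.ndarray  # diploid sample size per locus x population

    def __post_init__(self) -> None:
        self.p_ins = np.asarray(self.p_ins, dtype=float)
        self.n = np.asarray(self.n)
        if self.p_ins.shape != (len(self.loci), len(self.populations)):
            raise ValueError("p_ins shape mismatch")
        if self.n.shape != self.p_ins.shape:
            raise ValueError("n shape mismatch")
        with np.errstate(invalid="ignore"):
            bad = (self.p_ins < 0) | (self.p_ins > 1)
        if np.any(bad & ~np.isnan(self.p_ins)):
            raise ValueError("p_ins outside [0, 1]")

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def column(self, population: str) -> np.ndarray:
        """Insertion-frequency vector over loci for one population."""
        j = self.populations.index(population)
        return self.p_ins[:, j]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, loc in enumerate(self.loci):
            for j, pop in enumerate(self.populations):
                rows.append(
                    {"locus": loc.locus_id, "population": pop,
                     "p_ins": self.p_ins[i, j], "n": int(self.n[i, j])}
                )
        return pd.DataFrame(rows)


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    metric_name: str = "other"  # fst | da | other
    clamped: bool = False  # True if negative estimates were floored at 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("distance matrix shape mismatch")
        if k == 0:
            raise ValueError("empty distance matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")

    def clamp_nonnegative(self) -> "DistanceMatrix":
        """Floor negative entries at 0 for geometry-consuming stages."""
        if (self.values >= 0).all():
            return self
        vals = np.maximum(self.values, 0.0)
        return DistanceMatrix(list(self.labels), vals, self.metric_name, clamped=True)


# ---------------------------------------------------------------------------
# genotype tables


def _parse_cell(token: str, row: str, col: str) -> float:
    token = token.strip()
    if token in _MISSING_TOKENS:
        return np.nan
    try:
        return float(_GENOTYPE_TOKENS[token])
    except KeyError:
        raise GenotypeParseError(
            f"unknown genotype token {token!r} at sample {row!r}, locus {col!r}"
        ) from None


def read_genotype_table(
    path: str | Path,
    sep: str = "\t",
    marker_classes: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Read a sample-by-locus genotype table.

    Expected columns: ``sample_id, population, continent, sex`` then one
    column per locus with cells ``I/I``, ``I/D``, ``D/D``, ``N/N`` or the
    dosage digits 0/1/2.  ``marker_classes`` maps locus id to marker class;
    unlisted loci default to ``autosomal_dip``.  Pass ``sep=','`` for the
    comma dialect.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _METADATA_COLS[:3] if c not in df.columns]
    if missing:
        raise GenotypeParseError(f"missing metadata columns: {missing}")
    locus_cols = [c for c in df.columns if c not in _METADATA_COLS]
    marker_classes = dict(marker_classes or {})
    loci, meta_cols = [], []
    for c in locus_cols:
        cls = marker_classes.get(c, "autosomal_dip")
        if cls == "autosomal_dip":
            loci.append(LocusDef(c, cls))
        else:
            meta_cols.append(c)
    dosage = np.empty((len(df), len(loci)))
    for j, loc in enumerate(loci):
        col = df[loc.locus_id]
        for i, token in enumerate(col):
            dosage[i, j] = _parse_cell(token, df["sample_id"].iat[i], loc.locus_id)
    return GenotypeMatrix(
        sample_ids=df["sample_id"].tolist(),
        population=df["population"].tolist(),
        continent=df["continent"].tolist(),
        loci=loci,
        dosage=dosage,
        sex=df["sex"].tolist() if "sex" in df.columns else None,
        metadata_loci=df[meta_cols] if meta_cols else None,
    )


def write_genotype_table(g: GenotypeMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a genotype table with I/D-style cells (round-trips with read)."""
    back = {2.0: "I/I", 1.0: "I/D", 0.0: "D/D"}
    df = pd.DataFrame(
        {
            "sample_id": g.sample_ids,
            "population": g.population,
            "continent": g.continent,
            "sex": g.sex if g.sex is not None else [""] * g.n_samples,
        }
    )
    for j, loc in enumerate(g.loci):
        col = g.dosage[:, j]
        df[loc.locus_id] = ["N/N" if np.isnan(v) else back[v] for v in col]
    if g.metadata_loci is not None:
        for c in g.metadata_loci.columns:
            df[c] = g.metadata_loci[c].values
    df.to_csv(path, sep=sep, index=False)


def allele_frequencies(
    g: GenotypeMatrix, by: str = "population"
) -> FrequencyTable:
    """Estimate insertion-allele frequencies per locus per group.

    ``by`` is ``"population"``, ``"continent"`` or ``"all"``.  The frequency
    is the observed allele proportion, sum(dosage) / (2 * non-missing count);
    ``n`` is the non-missing diploid count.  A locus with no calls in a group
    gets NaN frequency and n=0 (flagged via warning).
    """
    import warnings

    if by == "all":
        groups = {"ALL": np.ones(g.n_samples, bool)}
    elif by in ("population", "continent"):
        labels = g.population if by == "population" else g.continent
        groups = {}
        for lab in dict.fromkeys(labels):  # preserve first-seen order
            groups[lab] = np.array([x == lab for x in labels])
    else:
        raise ValueError(f"unknown grouping {by!r}")

    n_loci = len(g.loci)
    p = np.full((n_loci, len(groups)), np.nan)
    n = np.zeros((n_loci, len(groups)), dtype=int)
    for j, (lab, mask) in enumerate(groups.items()):
        sub = g.dosage[mask]
        called = ~np.isnan(sub)
        counts = called.sum(axis=0)
        n[:, j] = counts
        with np.errstate(invalid="ignore"):
            p[:, j] = np.nansum(sub, axis=0) / (2.0 * counts)
        if (counts == 0).any():
            bad = [g.loci[i].locus_id for i in np.where(counts == 0)[0]]
            warnings.warn(f"group {lab!r}: all-missing loci excluded: {bad}")
    return FrequencyTable(list(g.loci), list(groups), p, n)


def read_frequency_table(path: str | Path, sep: str = "\t") -> FrequencyTable:
    df = pd.read_csv(path, sep=sep)
    loci = list(dict.fromkeys(df["locus"]))
    pops = list(dict.fromkeys(df["population"]))
    p = np.full((len(loci), len(pops)), np.nan)
    n = np.zeros((len(loci), len(pops)), dtype=int)
    li = {l: i for i, l in enumerate(loci)}
    pj = {q: j for j, q in enumerate(pops)}
    for _, r in df.iterrows():
        p[li[r["locus"]], pj[r["population"]]] = r["p_ins"]
        n[li[r["locus"]], pj[r["population"]]] = r["n"]
    return FrequencyTable([LocusDef(l) for l in loci], pops, p, n)


def write_frequency_table(t: FrequencyTable, path: str | Path, sep: str = "\t") -> None:
    t.to_frame().to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# PHYLIP distance matrices


def write_phylip_distance(
    d: DistanceMatrix, path: str | Path, relaxed_names: bool = False
) -> None:
    """Write a square PHYLIP distance file.

    Strict mode pads/truncates labels to 10 characters and errors on a
    collision after truncation; ``relaxed_names`` writes full labels.
    """
    labels = list(d.labels)
    if not relaxed_names:
        short = [l[:10] for l in labels]
        if len(set(short)) != len(short):
            raise ValueError("label collision after PHYLIP 10-char padding "
                             "(use relaxed_names=True)")
        labels = [s.ljust(10) for s in short]
    else:
        labels = [l + "  " for l in labels]
    with open(path, "w") as fh:
        fh.write(f"{len(labels)}\n")
        for lab, row in zip(labels, d.values):
            fh.write(lab + "  ".join(f"{v:.10f}" for v in row) + "\n")


def read_phylip_distance(path: str | Path, metric_name: str = "other") -> DistanceMatrix:
    with open(path) as fh:
        k = int(fh.readline().split()[0])
        labels, rows = [], []
        for _ in range(k):
            parts = fh.readline().split()
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(labels, np.array(rows), metric_name)


# ---------------------------------------------------------------------------
# Newick trees (dendropy-backed)


def write_newick(tree, path: str | Path) -> None:
    """Write a dendropy Tree as Newick with full-precision branch lengths."""
    tree.write(path=str(path), schema="newick",
               suppress_rooting=True, real_value_format_specifier=".17g")


def read_newick(path: str | Path):
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick")


# ---------------------------------------------------------------------------
# JSON result envelopes


def write_results_json(obj: Mapping, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
        fh.write("\n")


def read_results_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
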