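"""One-command reproduction of the full panel evaluation.

Runs every analysis stage on a genotype table — per-locus forensic
parameters and cumulative indices, HWE and LD screens, the sibling-LR
power study, distance matrices and AMOVA, ordination and NJ trees, and
the biogeographic-origin classifiers — writing TSV/JSON/PHYLIP/Newick
outputs plus a manifest of input hashes, seeds and per-stage status.
Stage failures are recorded; independent later stages still run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io_formats import (GenotypeMatrix, allele_frequencies,
                         write_frequency_table, write_newick,
                         write_phylip_distance, write_results_json)

log = logging.getLogger("dipkit")

__all__ = ["RunConfig", "RunManifest", "run_all"]


@dataclass
class RunConfig:
    seed: int = 0
    target_population: str | None = None  # default: first population
    kinship_pairs: int = 1000
    lr_limits: tuple[float, ...] = (1.0, 10.0, 100.0, 1000.0, 10000.0)
    ld_permutations: int = 0  # 0 -> chi-square p-values only
    classifier_models: tuple[str, ...] = ("rf", "xgb", "svm", "dt")
    classifier_test_size: float = 0.25
    hwe_alpha: float = 0.05
    ld_alpha: float = 0.05


@dataclass
class RunManifest:
    input_path: str
    input_sha256: str
    seed: int
    parameters: dict
    version: str
    stages: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(g: GenotypeMatrix, out_dir: str | Path, cfg: RunConfig | None = None,
            input_path: str | Path | None = None) -> RunManifest:
    """Execute every stage; outputs land under ``out_dir``."""
    from . import (bgo_classifier, equilibrium, forensic_stats, kinship_lr,
                   ordination_phylo, popgen_distances)

    cfg = cfg or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if g.n_samples == 0 or len(g.loci) == 0:
        raise ValueError("empty genotype input")
    manifest = RunManifest(
        input_path=str(input_path or "<in-memory>"),
        input_sha256=_sha256(input_path) if input_path else "",
        seed=cfg.seed,
        parameters={k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in vars(cfg).items()},
        version=__version__,
    )
    pops = list(dict.fromkeys(g.population))
    target = cfg.target_population or pops[0]
    freqs = allele_frequencies(g, by="population")

    def stage(name):
        def deco(fn):
            try:
                fn()
                manifest.stages[name] = "ok"
                log.info("stage %s: ok", name)
            except Exception as exc:  # record and continue
                manifest.stages[name] = f"failed: {exc}"
                log.error("stage %s failed:\n%s", name, traceback.format_exc())
        return deco

    @stage("frequencies")
    def _freqs():
        path = out / "allele_frequencies.tsv"
        write_frequency_table(freqs, path)
        manifest.outputs["frequencies"] = str(path)

    @stage("forensic")
    def _forensic():
        stats = forensic_stats.panel_stats(g, target)
        df = pd.DataFrame([vars(s) for s in stats])
        path = out / "forensic_per_locus.tsv"
        df.round(6).to_csv(path, sep="\t", index=False)
        cum = forensic_stats.cumulative(stats)
        write_results_json(vars(cum) | {"population": target},
                           out / "forensic_cumulative.json")
        manifest.outputs["forensic"] = str(path)

    @stage("hwe")
    def _hwe():
        res = equilibrium.hwe_scan(g, target)
        thr = equilibrium.bonferroni_threshold(cfg.hwe_alpha, len(res))
        df = pd.DataFrame([vars(r) for r in res])
        df["bonferroni_threshold"] = thr
        df["significant"] = df["p_value"] < thr
        path = out / "hwe.tsv"
        df.to_csv(path, sep="\t", index=False)
        manifest.outputs["hwe"] = str(path)

    @stage("ld")
    def _ld():
        res = equilibrium.ld_scan(g, target, permutations=cfg.ld_permutations,
                                  seed=cfg.seed)
        thr = equilibrium.bonferroni_threshold(cfg.ld_alpha, len(res)) if res else np.nan
        rows = [{"locus_a": r.locus_a, "locus_b": r.locus_b, "D": r.D,
                 "r2": r.r2, "G": r.G, "p_value": r.p_value,
                 "p_chi2": r.p_chi2, "significant": r.p_value < thr}
                for r in res]
        path = out / "ld.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        manifest.outputs["ld"] = str(path)

    @stage("kinship")
    def _kin():
        p = freqs.column(target)
        ok = ~np.isnan(p)
        res = kinship_lr.power_study(p[ok], n_pairs=cfg.kinship_pairs,
                                     limits=cfg.lr_limits, seed=cfg.seed)
        table = pd.DataFrame({
            "lr_limit": res.limits,
            "accuracy_pct": 100 * res.accuracy,
            "false_positive_pct": 100 * res.false_positive,
        })
        path = out / "kinship_power.tsv"
        table.to_csv(path, sep="\t", index=False)
        np.savetxt(out / "kinship_log10lr_fs.txt", res.log10_lr_fs)
        np.savetxt(out / "kinship_log10lr_un.txt", res.log10_lr_un)
        manifest.outputs["kinship"] = str(path)

    multi_pop = len(pops) >= 2

    @stage("distances")
    def _dist():
        if not multi_pop:
            raise ValueError("needs >= 2 populations")
        fst = popgen_distances.pairwise_fst_matrix(g)
        da = popgen_distances.da_matrix(freqs)
        write_phylip_distance(fst.clamp_nonnegative(), out / "fst.phylip",
                              relaxed_names=True)
        write_phylip_distance(da.clamp_nonnegative(), out / "da.phylip",
                              relaxed_names=True)
        i_n = popgen_distances.informativeness_in(freqs.p_ins)
        pd.DataFrame({"locus": freqs.locus_ids, "In": i_n}).to_csv(
            out / "informativeness.tsv", sep="\t", index=False)
        manifest.outputs["distances"] = str(out / "fst.phylip")

    @stage("amova")
    def _amova():
        if not multi_pop:
            raise ValueError("needs >= 2 populations")
        grouping = {p: c for p, c in zip(g.population, g.continent)}
        n_groups = len(set(grouping.values()))
        res = popgen_distances.amova(g, grouping if n_groups >= 2 else None)
        write_results_json(vars(res), out / "amova.json")
        manifest.outputs["amova"] = str(out / "amova.json")

    @stage("ordination")
    def _ordination():
        pr = ordination_phylo.genotype_pca(g, n_components=2)
        pd.DataFrame({"sample_id": g.sample_ids, "population": g.population,
                      "PC1": pr.coordinates[:, 0], "PC2": pr.coordinates[:, 1]}
                     ).to_csv(out / "pca_individual.tsv", sep="\t", index=False)
        write_results_json({"explained_pct": pr.explained_pct},
                           out / "pca_individual_variance.json")
        if multi_pop:
            da = popgen_distances.da_matrix(freqs).clamp_nonnegative()
            coords = ordination_phylo.classical_mds(da, dims=2)
            pd.DataFrame({"population": da.labels, "dim1": coords[:, 0],
                          "dim2": coords[:, 1]}).to_csv(
                out / "mds_da.tsv", sep="\t", index=False)
        manifest.outputs["ordination"] = str(out / "pca_individual.tsv")

    @stage("nj_tree")
    def _tree():
        if len(pops) < 3:
            raise ValueError("needs >= 3 populations")
        da = popgen_distances.da_matrix(freqs).clamp_nonnegative()
        tree = ordination_phylo.nj_tree(da)
        write_newick(tree, out / "nj_da.nwk")
        manifest.outputs["nj_tree"] = str(out / "nj_da.nwk")

    @stage("classifier")
    def _classify():
        if len(set(g.continent)) < 2:
            raise ValueError("needs >= 2 continents")
        res = bgo_classifier.train_eval(g, models=cfg.classifier_models,
                                        test_size=cfg.classifier_test_size,
                                        seed=cfg.seed)
        summary = {}
        for name, (cm, ci) in res.items():
            pd.DataFrame(cm.counts, index=cm.labels, columns=cm.labels
                         ).to_csv(out / f"confusion_{name}.tsv", sep="\t")
            summary[name] = {"accuracy": ci.accuracy, "ci_lower": ci.lower,
                             "ci_upper": ci.upper, "n": cm.total}
        write_results_json(summary, out / "classifier_stats.json")
        manifest.outputs["classifier"] = str(out / "classifier_stats.json")

    with open(out / "manifest.json", "w") as fh:
        json.dump(vars(manifest), fh, indent=2)
        fh.write("\n")
    return manifest
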