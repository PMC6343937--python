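"""Synthetic paired mouse/human case studies with known ground truth.

The generator emulates the structure of the inflammatory-disease cohort
collection at desk scale: a mouse training cohort and a human test cohort
measured on a shared (identity-homology) gene space, with three planted
gene classes — genes differentially expressed in both species (shared),
in the mouse only, and in the human only.  Expression is Gaussian noise
with additive class-mean shifts (in units of the noise SD) on the
species' DEG genes, then z-scored by gene exactly as the real pipeline
does.  Pathway gene sets are planted alongside: "true" pathways draw a
configurable fraction of their members from the human truth DEGs (and
are verified to be hypergeometrically enriched at generation time),
decoys draw only from non-DEG genes.

The scenario library encodes the benchmark's characteristic regimes:
easy transfer (shared signal only), divergent (human-only signal dominant
with a small, weak mouse cohort — the CLP/endotoxemia regime in which the
mouse calls no DEGs at all), an imbalanced small mouse cohort (1:4), and
a heterogeneous two-strain mouse cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .datasets import (CONTROL, DISEASE, CaseStudy, ExpressionDataset,
                       GeneSetCollection, HomologyMap, write_expression,
                       write_gene_sets, zscore_by_gene)

_MAX_REDRAWS = 50


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth generator settings (effect sizes in noise-SD units)."""

    n_genes: int = 200
    n_shared_deg: int = 20
    n_mouse_only_deg: int = 0
    n_human_only_deg: int = 0
    effect_mouse: float = 2.5
    effect_human: float = 2.5
    n_mouse_per_class: tuple[int, int] = (20, 20)   # (control, disease)
    n_human_per_class: tuple[int, int] = (20, 20)
    noise_sd: float = 1.0
    n_pathways: int = 20
    pathway_size: int = 10
    deg_pathway_purity: float = 0.8
    frac_true_pathways: float = 0.5
    n_mouse_subcohorts: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        n_deg = self.n_shared_deg + self.n_mouse_only_deg + self.n_human_only_deg
        if n_deg > self.n_genes:
            raise ValueError("DEG class counts exceed n_genes")
        if min(self.n_mouse_per_class) < 1 or min(self.n_human_per_class) < 1:
            raise ValueError("all per-class sample counts must be >= 1")
        if not (0.0 <= self.deg_pathway_purity <= 1.0):
            raise ValueError("deg_pathway_purity must be in [0, 1]")
        if self.n_mouse_subcohorts not in (1, 2):
            raise ValueError("n_mouse_subcohorts must be 1 or 2")


@dataclass
class SimTruth:
    """The planted ground truth of one simulated case study."""

    shared_degs: set[str]
    mouse_only_degs: set[str]
    human_only_degs: set[str]
    true_human_pathways: set[str]
    case_study: CaseStudy

    @property
    def human_truth_degs(self) -> set[str]:
        return self.shared_degs | self.human_only_degs

    @property
    def mouse_truth_degs(self) -> set[str]:
        return self.shared_degs | self.mouse_only_degs


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _simulate_cohort(rng, genes, effect_genes, effect, n_per_class, noise_sd,
                     prefix, species, name, subcohort_effects=None):
    n_ctrl, n_dis = n_per_class
    sample_ids = ([f"{prefix}_ctrl_{i:02d}" for i in range(1, n_ctrl + 1)]
                  + [f"{prefix}_dis_{i:02d}" for i in range(1, n_dis + 1)])
    labels = pd.Series([CONTROL] * n_ctrl + [DISEASE] * n_dis, index=sample_ids)
    vals = rng.normal(0.0, noise_sd, size=(len(genes), len(sample_ids)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    dis_cols = np.arange(n_ctrl, n_ctrl + n_dis)
    if subcohort_effects is None:
        rows = [gene_pos[g] for g in effect_genes]
        vals[np.ix_(rows, dis_cols)] += effect * noise_sd
    else:
        # two sub-cohorts, each with its own effect-gene vector; samples are
        # split evenly per class, with sub-cohort tags in the sample IDs
        new_ids = list(sample_ids)
        for ci, (tag, sub_genes) in enumerate(subcohort_effects.items()):
            rows = [gene_pos[g] for g in sub_genes]
            cols = [c for c in dis_cols if c % 2 == ci]
            vals[np.ix_(rows, cols)] += effect * noise_sd
            for c in [j for j in range(len(sample_ids)) if j % 2 == ci]:
                new_ids[c] = f"{tag}{sample_ids[c][len(prefix):]}"
        sample_ids = new_ids
        labels.index = sample_ids
    df = pd.DataFrame(vals, index=list(genes), columns=sample_ids)
    ds = ExpressionDataset(values=df, labels=labels, species=species, name=name)
    return zscore_by_gene(ds)


def _plant_pathways(rng, cfg: SimConfig, genes, human_degs, non_degs):
    n_true = int(round(cfg.frac_true_pathways * cfg.n_pathways))
    if not human_degs:
        n_true = 0
    sets: dict[str, set[str]] = {}
    true_names: set[str] = set()
    universe = set(genes)
    n_pure = int(round(cfg.deg_pathway_purity * cfg.pathway_size))
    n_pure = min(n_pure, len(human_degs))
    human_degs = sorted(human_degs)
    non_degs = sorted(non_degs)
    if cfg.pathway_size - n_pure > len(non_degs) or (
            n_true == 0 and cfg.n_pathways > 0 and cfg.pathway_size > len(non_degs)):
        raise ValueError("pathway_size infeasible for the non-DEG gene pool")
    for i in range(cfg.n_pathways):
        name = f"PATH_{i + 1:03d}"
        if i < n_true:
            # redraw (escalating the DEG fraction if needed) until the set
            # is verifiably enriched under the truth DEGs at a Bonferroni-
            # level bound, which guarantees it survives BH at q < 0.05
            # across the whole collection
            members = None
            for pure in range(n_pure, min(cfg.pathway_size, len(human_degs)) + 1):
                for _ in range(_MAX_REDRAWS):
                    cand = set(rng.choice(human_degs, size=pure, replace=False))
                    cand |= set(rng.choice(non_degs, size=cfg.pathway_size - pure,
                                           replace=False))
                    p = hypergeom.sf(len(cand & set(human_degs)) - 1,
                                     len(universe), len(cand), len(human_degs))
                    if p < 0.05 / max(cfg.n_pathways, 1):
                        members = cand
                        break
                if members is not None:
                    break
            if members is None:
                raise ValueError(f"could not plant an enriched pathway {name}")
            true_names.add(name)
        else:
            members = set(rng.choice(non_degs, size=min(cfg.pathway_size,
                                                        len(non_degs)),
                                     replace=False))
        sets[name] = members
    return GeneSetCollection(sets=sets, universe=universe), true_names


def generate_case_study(cfg: SimConfig, seed: int | None = None
                        ) -> tuple[CaseStudy, SimTruth, GeneSetCollection]:
    """Generate one harmonized synthetic case study with planted truth.

    Fully reproducible from the seed (``cfg.seed`` unless overridden).
    The returned case study is already in the harmonized, z-scored form
    the translation loop consumes (identity homology map).
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed % (2 ** 31))
    genes = _gene_names(cfg.n_genes)
    perm = rng.permutation(cfg.n_genes)
    i = 0
    shared = {genes[j] for j in perm[i:i + cfg.n_shared_deg]}; i += cfg.n_shared_deg
    mouse_only = {genes[j] for j in perm[i:i + cfg.n_mouse_only_deg]}; i += cfg.n_mouse_only_deg
    human_only = {genes[j] for j in perm[i:i + cfg.n_human_only_deg]}; i += cfg.n_human_only_deg
    non_deg = {genes[j] for j in perm[i:]}

    mouse_effect_genes = sorted(shared | mouse_only)
    subcohort_effects = None
    if cfg.n_mouse_subcohorts == 2:
        mo = sorted(mouse_only)
        half = len(mo) // 2
        subcohort_effects = {"mA": sorted(shared | set(mo[:half])),
                            "mB": sorted(shared | set(mo[half:]))}
    mouse = _simulate_cohort(rng, genes, mouse_effect_genes, cfg.effect_mouse,
                             cfg.n_mouse_per_class, cfg.noise_sd, "m", "mouse",
                             "sim_mouse", subcohort_effects=subcohort_effects)
    human = _simulate_cohort(rng, genes, sorted(shared | human_only),
                             cfg.effect_human, cfg.n_human_per_class,
                             cfg.noise_sd, "h", "human", "sim_human")
    cs = CaseStudy(mouse=mouse, human=human, disease="simulated",
                   identifier=f"sim(seed={seed})")
    gsc, true_names = _plant_pathways(rng, cfg, genes, shared | human_only,
                                      non_deg)
    truth = SimTruth(shared_degs=shared, mouse_only_degs=mouse_only,
                     human_only_degs=human_only, true_human_pathways=true_names,
                     case_study=cs)
    return cs, truth, gsc


def scenario_library() -> dict[str, SimConfig]:
    """Named study regimes used throughout the benchmark and its tests."""
    return {
        "easy_transfer": SimConfig(
            n_genes=200, n_shared_deg=20, n_mouse_only_deg=0,
            n_human_only_deg=0, effect_mouse=2.5, effect_human=2.5,
            n_mouse_per_class=(20, 20), n_human_per_class=(20, 20)),
        "divergent": SimConfig(
            n_genes=200, n_shared_deg=10, n_mouse_only_deg=25,
            n_human_only_deg=25, effect_mouse=1.0, effect_human=2.5,
            n_mouse_per_class=(5, 5), n_human_per_class=(20, 20)),
        "imbalanced_mouse": SimConfig(
            n_genes=200, n_shared_deg=20, n_mouse_only_deg=0,
            n_human_only_deg=0, effect_mouse=2.5, effect_human=2.5,
            n_mouse_per_class=(4, 16), n_human_per_class=(20, 20)),
        "heterogeneous_mouse": SimConfig(
            n_genes=200, n_shared_deg=20, n_mouse_only_deg=20,
            n_human_only_deg=0, effect_mouse=2.5, effect_human=2.5,
            n_mouse_per_class=(20, 20), n_human_per_class=(20, 20),
            n_mouse_subcohorts=2),
    }


def identity_homology(genes) -> HomologyMap:
    return HomologyMap(pairs=[(g, g) for g in genes])


def write_case_study(cs: CaseStudy, truth: SimTruth, gsc: GeneSetCollection,
                     outdir: str | Path) -> dict[str, Path]:
    """Serialize a simulated case study in the pipeline's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mouse_matrix": outdir / "mouse_expression.tsv",
        "mouse_phenotypes": outdir / "mouse_phenotypes.tsv",
        "human_matrix": outdir / "human_expression.tsv",
        "human_phenotypes": outdir / "human_phenotypes.tsv",
        "homology": outdir / "homology.tsv",
        "gene_sets": outdir / "pathways.gmt",
        "truth": outdir / "truth.json",
    }
    write_expression(cs.mouse, paths["mouse_matrix"], paths["mouse_phenotypes"])
    write_expression(cs.human, paths["human_matrix"], paths["human_phenotypes"])
    pd.DataFrame(identity_homology(cs.genes).pairs).to_csv(
        paths["homology"], sep="\t", header=False, index=False)
    write_gene_sets(gsc, paths["gene_sets"])
    with open(paths["truth"], "w") as fh:
        json.dump({"shared_degs": sorted(truth.shared_degs),
                   "mouse_only_degs": sorted(truth.mouse_only_degs),
                   "human_only_degs": sorted(truth.human_only_degs),
                   "true_human_pathways": sorted(truth.true_human_pathways)},
                  fh, indent=1)
    return paths
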