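"""Expression datasets, homology harmonization, and file formats.

The unit of analysis is a gene-by-sample expression matrix with a binary
phenotype (control / disease) per sample.  A mouse training cohort and a
human test cohort are harmonized into one shared homolog feature space:
duplicate gene rows are collapsed to the row with maximal mean expression,
mouse symbols are renamed to their human homologs, both matrices are
restricted to the common gene list, and each dataset is z-scored by gene
on its own samples (so no information leaks between cohorts).

On-disk formats are plain tab-separated text: expression matrices with a
header row of sample IDs and gene symbols in the first column; two-column
phenotype and homology tables; gene sets in standard GMT.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from gseapy.parser import read_gmt as _read_gmt

logger = logging.getLogger(__name__)

CONTROL = "control"
DISEASE = "disease"
LABELS = (CONTROL, DISEASE)


@dataclass
class ExpressionDataset:
    """A gene-by-sample expression matrix with per-sample binary phenotypes.

    Parameters
    ----------
    values
        Genes x samples matrix (``pandas.DataFrame``); index = gene symbols,
        columns = sample IDs.  Arbitrary expression units before z-scoring,
        dimensionless after.
    labels
        Mapping sample ID -> ``"control"`` | ``"disease"``; every sample
        must be labeled.
    species
        ``"mouse"`` or ``"human"``.
    name
        Free-text cohort identifier (e.g. a GEO-style accession).
    """

    values: pd.DataFrame
    labels: pd.Series
    species: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.species not in ("mouse", "human"):
            raise ValueError(f"species must be 'mouse' or 'human', got {self.species!r}")
        if not isinstance(self.labels, pd.Series):
            self.labels = pd.Series(self.labels)
        missing = [s for s in self.values.columns if s not in self.labels.index]
        if missing:
            raise ValueError(f"samples without a phenotype label: {missing[:5]}")
        self.labels = self.labels.loc[list(self.values.columns)]
        bad = sorted(set(self.labels) - set(LABELS))
        if bad:
            raise ValueError(f"labels must be in {LABELS}, got {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> dict[str, int]:
        counts = self.labels.value_counts().to_dict()
        return {lab: int(counts.get(lab, 0)) for lab in LABELS}

    def has_both_classes(self) -> bool:
        counts = self.class_counts()
        return all(counts[lab] > 0 for lab in LABELS)

    def subset_genes(self, genes: list[str]) -> "ExpressionDataset":
        return replace(self, values=self.values.loc[list(genes)].copy(),
                       labels=self.labels.copy())

    def copy(self) -> "ExpressionDataset":
        return replace(self, values=self.values.copy(), labels=self.labels.copy())


@dataclass
class HomologyMap:
    """Ordered mouse-symbol -> human-symbol pairs (first occurrence wins)."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        for m, h in self.pairs:
            if not m or not h:
                raise ValueError("homology map contains an empty symbol")

    def as_dict(self) -> dict[str, str]:
        d: dict[str, str] = {}
        for m, h in self.pairs:
            d.setdefault(m, h)
        return d


@dataclass
class CaseStudy:
    """One (mouse training cohort, human test cohort) pairing.

    After :func:`map_homologs` both datasets carry the identical ordered
    human-symbol gene list.
    """

    mouse: ExpressionDataset
    human: ExpressionDataset
    disease: str = ""
    identifier: str = ""

    def __post_init__(self) -> None:
        if self.mouse.species != "mouse" or self.human.species != "human":
            raise ValueError("CaseStudy requires a mouse and a human dataset")

    @property
    def genes(self) -> list[str]:
        return self.mouse.gene_ids


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways) plus the gene universe they live in."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def restricted(self, measured: set[str]) -> "GeneSetCollection":
        """Intersect every set with the measured genes (empty sets dropped)."""
        sets = {n: g & measured for n, g in self.sets.items()}
        return GeneSetCollection(
            sets={n: g for n, g in sets.items() if g},
            universe=self.universe & measured if self.universe else set(measured),
        )


# ---------------------------------------------------------------------------
# Readers / writers

def read_expression(matrix_path: str | Path, phenotype_path: str | Path,
                    species: str, name: str = "") -> ExpressionDataset:
    """Read a gene-by-sample TSV and its phenotype table.

    The matrix has a header row of sample IDs with gene symbols in the
    first column; the phenotype table is two columns (sample_id, label)
    without a header.  Duplicate gene rows are kept as-is — collapsing is
    a separate, explicit step (:func:`collapse_duplicates`).
    """
    matrix_path, phenotype_path = Path(matrix_path), Path(phenotype_path)
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad_rows = df.index[coerced.isna() & df[col].notna()]
            raise ValueError(
                f"non-numeric cell in {matrix_path} at gene {bad_rows[0]!r}, "
                f"sample {col!r}")
    ph = pd.read_csv(phenotype_path, sep="\t", header=None,
                     names=["sample_id", "label"], dtype=str)
    labels = pd.Series(ph["label"].values, index=ph["sample_id"].values)
    missing = [s for s in df.columns if s not in labels.index]
    if missing:
        raise ValueError(
            f"sample {missing[0]!r} in {matrix_path} is missing from the "
            f"phenotype table {phenotype_path}")
    return ExpressionDataset(values=df.astype(float), labels=labels,
                             species=species, name=name or matrix_path.stem)


def write_expression(ds: ExpressionDataset, matrix_path: str | Path,
                     phenotype_path: str | Path) -> None:
    """Inverse of :func:`read_expression` (round-trips values, IDs, labels)."""
    out = ds.values.copy()
    out.index.name = "gene"
    out.to_csv(matrix_path, sep="\t")
    ds.labels.to_csv(phenotype_path, sep="\t", header=False)


def read_homology_map(path: str | Path) -> HomologyMap:
    """Read a two-column (mouse_symbol, human_symbol) TSV without header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["mouse", "human"],
                     dtype=str)
    return HomologyMap(pairs=list(zip(df["mouse"], df["human"])))


def read_gene_sets(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read gene sets from a standard GMT file."""
    sets = {name: set(genes) for name, genes in _read_gmt(str(path)).items()}
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    return GeneSetCollection(sets=sets, universe=universe)


def write_gene_sets(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in gsc.sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# Preprocessing

def collapse_duplicates(ds: ExpressionDataset) -> ExpressionDataset:
    """Collapse duplicated gene symbols to the row with maximal mean expression.

    For each duplicated symbol the retained row is the one whose mean across
    all samples is largest; ties keep the first occurrence.  Idempotent.
    """
    if not ds.values.index.has_duplicates:
        return ds.copy()
    means = ds.values.mean(axis=1).to_numpy()
    keep: dict[str, int] = {}
    for pos, gene in enumerate(ds.values.index):
        best = keep.get(gene)
        if best is None or means[pos] > means[best]:
            keep[gene] = pos
    rows = sorted(keep.values())
    return replace(ds, values=ds.values.iloc[rows].copy(), labels=ds.labels.copy())


def zscore_by_gene(ds: ExpressionDataset) -> ExpressionDataset:
    """Center and scale every gene to mean 0, sample SD 1 (ddof=1).

    Zero-variance genes cannot be scaled; they are set to all zeros and a
    warning is emitted (constant genes carry no class signal).
    """
    vals = ds.values.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0) | ~np.isfinite(sd)
    if flat.any():
        names = [g for g, f in zip(ds.values.index, flat.ravel()) if f]
        msg = f"{len(names)} zero-variance gene(s) set to zeros (e.g. {names[:3]})"
        warnings.warn(msg)
        logger.warning(msg)
    sd = np.where(flat, 1.0, sd)
    z = (vals - mean) / sd
    z[flat.ravel(), :] = 0.0
    out = pd.DataFrame(z, index=ds.values.index, columns=ds.values.columns)
    return replace(ds, values=out, labels=ds.labels.copy())


def map_homologs(mouse: ExpressionDataset, human: ExpressionDataset,
                 hm: HomologyMap, disease: str = "",
                 identifier: str = "") -> CaseStudy:
    """Harmonize a mouse/human pair into a shared homolog feature space.

    Both datasets must already be duplicate-collapsed.  The homology map is
    restricted to 1:1 pairs measured in both datasets (among many-to-one
    conflicts the first-listed pair wins, with a warning); the mouse rows
    are renamed to human symbols and both matrices take the same row order.
    """
    mouse_genes = set(mouse.gene_ids)
    human_genes = set(human.gene_ids)
    used_human: set[str] = set()
    pairs: list[tuple[str, str]] = []
    seen_mouse: set[str] = set()
    dropped = 0
    for m, h in hm.pairs:
        if m in seen_mouse:
            continue
        seen_mouse.add(m)
        if m not in mouse_genes or h not in human_genes:
            continue
        if h in used_human:
            dropped += 1
            continue
        used_human.add(h)
        pairs.append((m, h))
    if dropped:
        warnings.warn(f"{dropped} many-to-one homology pair(s) dropped "
                      "(first-listed pair retained)")
    if not pairs:
        raise ValueError("no shared homologous genes between the two datasets")
    m_order = [m for m, _ in pairs]
    h_order = [h for _, h in pairs]
    mvals = mouse.values.loc[m_order].copy()
    mvals.index = h_order
    new_mouse = replace(mouse, values=mvals, labels=mouse.labels.copy())
    new_human = replace(human, values=human.values.loc[h_order].copy(),
                        labels=human.labels.copy())
    return CaseStudy(mouse=new_mouse, human=new_human, disease=disease,
                     identifier=identifier or f"{mouse.name}->{human.name}")


def harmonize(mouse: ExpressionDataset, human: ExpressionDataset,
              hm: HomologyMap, disease: str = "", identifier: str = "") -> CaseStudy:
    """Full preprocessing chain: collapse -> homolog restriction -> z-score.

    Z-scoring is done per dataset independently (mouse on mouse samples,
    human on human samples) so that no test-set information leaks into the
    training cohort.
    """
    cs = map_homologs(collapse_duplicates(mouse), collapse_duplicates(human),
                      hm, disease=disease, identifier=identifier)
    return CaseStudy(mouse=zscore_by_gene(cs.mouse), human=zscore_by_gene(cs.human),
                     disease=cs.disease, identifier=cs.identifier)


def concat_samples(a: ExpressionDataset, b: ExpressionDataset,
                   labels_b: pd.Series | None = None) -> ExpressionDataset:
    """Column-concatenate two datasets sharing the same gene list.

    Used to build the augmented (mouse + pseudo-labeled human) training set;
    ``labels_b`` overrides ``b``'s labels with predicted phenotypes.
    """
    if list(a.gene_ids) != list(b.gene_ids):
        raise ValueError("datasets do not share an identical gene list")
    lb = b.labels if labels_b is None else pd.Series(labels_b)
    values = pd.concat([a.values, b.values], axis=1)
    labels = pd.concat([a.labels, lb.loc[list(b.sample_ids)]])
    return ExpressionDataset(values=values, labels=labels, species=a.species,
                             name=f"{a.name}+{b.name}")
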