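"""Orchestration: scan many genes across many species combinations, join
variant counts with branch features, and run the correlation battery.

For every combination, group A is the combination's species and group B
defaults to all remaining non-excluded species (an explicit background
can override). Per-gene scan reports are aggregated into a per-
combination counts table:

=========  =======================================================
column     meaning
=========  =======================================================
ConSAV     amino-acid variants of Types 1-2 (identical target state)
DivSAV     amino-acid variants of Types 3-4
SAV_total  ConSAV + DivSAV
ConSCV     codon-level variants of Types 1-2
DivSCV     codon-level variants of Types 3-4
ConSNV     nucleotide-level variants of Types 1-2
DivSNV     nucleotide-level variants of Types 3-4
=========  =======================================================

Scans are independent per combination (merge by combo_id, no shared
state); an optional checkpoint directory makes long runs resumable with
byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy
import pandas as pd

from .combin import PhyloFeatures, SpeciesCombination, TreeIndex, compute_phylo_features
from .core_scan import (
    CONVERGENT,
    DIVERGENT,
    ScanLevel,
    SpeciesPartition,
    scan_alignment,
)
from .seqio import IdentityError, Level, MultipleAlignment
from .stats import bonferroni_outlier_test, fit_linear_regression, spearman_rho

COUNT_COLUMNS = [
    "ConSAV", "DivSAV", "SAV_total", "ConSCV", "DivSCV", "ConSNV", "DivSNV",
]


@dataclass
class GeneAlignments:
    """One gene's amino-acid and/or in-frame codon alignment."""

    gene_id: str
    aa: Optional[MultipleAlignment] = None
    codon: Optional[MultipleAlignment] = None

    def species(self) -> set[str]:
        out: set[str] = set()
        if self.aa is not None:
            out |= set(self.aa.species_ids)
        if self.codon is not None:
            out |= set(self.codon.species_ids)
        return out


def _combo_counts(
    genes: Sequence[GeneAlignments],
    part: SpeciesPartition,
    levels: Sequence[ScanLevel],
    run_threshold: Optional[int],
) -> dict[str, int]:
    counts = {c: 0 for c in COUNT_COLUMNS}
    for gene in genes:
        if ScanLevel.AMINO_ACID in levels and gene.aa is not None:
            rep = scan_alignment(
                gene.aa, part, ScanLevel.AMINO_ACID, run_threshold, gene.gene_id
            )
            counts["ConSAV"] += rep.n_convergent
            counts["DivSAV"] += rep.n_divergent
        if ScanLevel.CODON in levels and gene.codon is not None:
            rep = scan_alignment(
                gene.codon, part, ScanLevel.CODON, run_threshold, gene.gene_id
            )
            counts["ConSCV"] += rep.n_convergent
            counts["DivSCV"] += rep.n_divergent
        if ScanLevel.NUCLEOTIDE in levels and gene.codon is not None:
            rep = scan_alignment(
                gene.codon, part, ScanLevel.NUCLEOTIDE, run_threshold, gene.gene_id
            )
            counts["ConSNV"] += rep.n_convergent
            counts["DivSNV"] += rep.n_divergent
    counts["SAV_total"] = counts["ConSAV"] + counts["DivSAV"]
    return counts


def run_combination_scan(
    genes: Sequence[GeneAlignments],
    combos: Iterable[SpeciesCombination],
    excluded: Iterable[str] = (),
    levels: Sequence[ScanLevel | str] = (
        ScanLevel.AMINO_ACID,
        ScanLevel.CODON,
        ScanLevel.NUCLEOTIDE,
    ),
    tree: Optional[dendropy.Tree] = None,
    run_threshold: Optional[int] = 2,
    checkpoint_dir: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Per-combination variant counts over a gene set.

    Group B for each combination is every species not in the combination
    and not excluded. Output rows are sorted by combo_id, independent of
    gene or combination input order.
    """
    levels = [ScanLevel(l) for l in levels]
    if not genes:
        raise ValueError("no genes supplied")
    universe: set[str] = set()
    for g in genes:
        universe |= g.species()
    if tree is not None:
        tree_leaves = {n.taxon.label for n in tree.leaf_node_iter()}
        if not tree_leaves <= universe:
            raise IdentityError(
                f"tree leaves missing from alignments: {sorted(tree_leaves - universe)}"
            )
    excluded = frozenset(excluded)

    ckpt = Path(checkpoint_dir) if checkpoint_dir is not None else None
    if ckpt is not None:
        ckpt.mkdir(parents=True, exist_ok=True)

    rows = []
    for combo in combos:
        combo_id = combo.combo_id
        if ckpt is not None:
            f = ckpt / f"{_safe_name(combo_id)}.json"
            if f.exists():
                rows.append(json.loads(f.read_text()))
                continue
        part = SpeciesPartition.against_rest(universe, combo.species, excluded)
        counts = _combo_counts(genes, part, levels, run_threshold)
        record = {"combo_id": combo_id, **counts}
        if ckpt is not None:
            (ckpt / f"{_safe_name(combo_id)}.json").write_text(
                json.dumps(record, sort_keys=True)
            )
        rows.append(record)

    df = pd.DataFrame(rows, columns=["combo_id"] + COUNT_COLUMNS)
    return df.sort_values("combo_id", kind="stable").reset_index(drop=True)


def _safe_name(combo_id: str) -> str:
    return combo_id.replace("|", "_")


def features_table(
    tree: dendropy.Tree | TreeIndex, combos: Iterable[SpeciesCombination]
) -> pd.DataFrame:
    """POB/PTB/DTB/DTN per combination, keyed by combo_id."""
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    rows = []
    for combo in combos:
        f = compute_phylo_features(index, combo)
        rows.append(
            {"combo_id": combo.combo_id, "POB": f.pob, "PTB": f.ptb,
             "DTB": f.dtb, "DTN": f.dtn}
        )
    df = pd.DataFrame(rows, columns=["combo_id", "POB", "PTB", "DTB", "DTN"])
    return df.sort_values("combo_id", kind="stable").reset_index(drop=True)


def correlate_features(
    counts: pd.DataFrame,
    features: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    focal_combo_id: Optional[str] = None,
    n_max: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman + OLS + Bonferroni-outlier analysis for (x, y) column pairs.

    Tables are joined on combo_id; every output row carries the outlier
    combo_ids and, when a focal combination is designated, whether it is
    among them.
    """
    merged = counts.merge(features, on="combo_id", how="inner", validate="1:1")
    if merged.empty or len(merged) != len(counts) or len(merged) != len(features):
        raise KeyError("counts and features tables do not join 1:1 on combo_id")
    rows = []
    for xcol, ycol in pairs:
        if xcol not in merged.columns or ycol not in merged.columns:
            raise KeyError(f"unknown column in pair ({xcol!r}, {ycol!r})")
        x = merged[xcol].to_numpy(dtype=float)
        y = merged[ycol].to_numpy(dtype=float)
        sp = spearman_rho(x, y)
        fit = fit_linear_regression(x, y)
        outliers = bonferroni_outlier_test(fit, n_max=n_max, alpha=alpha)
        outlier_ids = [merged["combo_id"].iloc[i] for i in outliers.indices]
        row = {
            "x": xcol,
            "y": ycol,
            "n": sp.n,
            "spearman_rho": sp.rho,
            "spearman_p": sp.p_value,
            "slope": fit.slope,
            "intercept": fit.intercept,
            "adjusted_r2": fit.adjusted_r2,
            "outlier_combo_ids": ",".join(outlier_ids),
            "focal_combo_id": focal_combo_id or "",
            "focal_is_outlier": (
                focal_combo_id in outlier_ids if focal_combo_id else False
            ),
        }
        rows.append(row)
    return pd.DataFrame(rows)
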