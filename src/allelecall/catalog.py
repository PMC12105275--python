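"""Feature catalog: the gene / isoform / exon hierarchy used by every stage.

A *feature* is a gene, an isoform (transcript), or an exon.  The catalog keeps
1-based inclusive coordinates, the merged exonic length of each feature (union
of exon intervals, so exons shared between isoforms are never double counted),
and the set of chromosomes each feature is annotated on.  Only autosomes are
retained; a feature annotated on more than one autosome is kept but flagged,
because its copy-number and allelic inference is unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd
from intervaltree import IntervalTree

AUTOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))


class FeatureLevel(str, Enum):
    GENE = "gene"
    ISOFORM = "isoform"
    EXON = "exon"


def merged_interval_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of 1-based inclusive intervals."""
    if not intervals:
        return 0
    total = 0
    cur_s, cur_e = None, None
    for s, e in sorted(intervals):
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    total += cur_e - cur_s + 1
    return total


@dataclass
class FeatureCatalog:
    """Hierarchy of genes, isoforms and exons with coordinates and lengths.

    Attributes
    ----------
    features : pandas.DataFrame
        Indexed by feature_id with columns ``level`` (FeatureLevel value),
        ``gene_id``, ``parent_id`` (gene of an isoform, gene of an exon; empty
        for genes), ``chromosomes`` (sorted tuple), ``start``, ``end``,
        ``exonic_length``, ``multi_chromosome_flag``.
    exon_isoforms : dict
        exon_id -> tuple of isoform ids containing it.
    isoform_exons : dict
        isoform_id -> tuple of exon ids.
    gene_isoforms : dict
        gene_id -> tuple of isoform ids.
    gene_exons : dict
        gene_id -> tuple of exon ids (union over isoforms).
    """

    features: pd.DataFrame
    exon_isoforms: dict[str, tuple[str, ...]]
    isoform_exons: dict[str, tuple[str, ...]]
    gene_isoforms: dict[str, tuple[str, ...]]
    gene_exons: dict[str, tuple[str, ...]]
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._trees:
            self._trees = self._build_trees()

    def _build_trees(self) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        exons = self.features[self.features["level"] == FeatureLevel.EXON.value]
        for exon_id, row in exons.iterrows():
            for chrom in row["chromosomes"]:
                # interval tree is half-open; features are 1-based inclusive
                trees.setdefault(chrom, IntervalTree()).addi(
                    row["start"], row["end"] + 1, exon_id
                )
        return trees

    def ids(self, level: FeatureLevel | str) -> list[str]:
        level = FeatureLevel(level).value
        return list(self.features.index[self.features["level"] == level])

    def members(self, feature_id: str, level: FeatureLevel | str) -> tuple[str, ...]:
        """Exon ids making up *feature_id* (itself, for an exon)."""
        row_level = self.features.at[feature_id, "level"]
        if row_level == FeatureLevel.EXON.value:
            return (feature_id,)
        if row_level == FeatureLevel.ISOFORM.value:
            return self.isoform_exons[feature_id]
        return self.gene_exons[feature_id]

    def exons_at(self, chrom: str, pos: int) -> set[str]:
        """Exon ids overlapping a 1-based position."""
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.at(pos)}

    def features_at(self, chrom: str, pos: int) -> dict[str, set[str]]:
        """Feature ids at each level whose exonic territory covers a site."""
        exons = self.exons_at(chrom, pos)
        isoforms: set[str] = set()
        for e in exons:
            isoforms.update(self.exon_isoforms[e])
        genes = {self.features.at[i, "gene_id"] for i in isoforms}
        return {
            FeatureLevel.EXON.value: exons,
            FeatureLevel.ISOFORM.value: isoforms,
            FeatureLevel.GENE.value: genes,
        }

    @property
    def n_genes(self) -> int:
        return int((self.features["level"] == FeatureLevel.GENE.value).sum())
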