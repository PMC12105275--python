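"""Allelic-pattern classification of each feature in each sample.

The decision cascade (first match wins) for one feature x sample:

1. gene-level linear copy number < 1.5            -> copy_number_loss
2. zero het SNVs in both WES and RNA-seq          -> no_snv_data
3. RNA expression (log10 counts/bp) < -0.5        -> not_expressed
4. het SNVs present in both WES and RNA-seq       -> biallelic
5. WES het SNVs present, none in RNA, and WES
   coverage >= -0.5                               -> monoallelic
6. anything else                                  -> unresolved

Presence of both alleles of a heterozygous SNV in the RNA reads is the
evidence for biallelic expression; a WES-confirmed het site expressed as a
single allele is the evidence for monoallelic expression.  Copy-number loss
is assessed on gene-level data (loss of at least one allelic copy), so a
gene called copy_number_loss forces the same call for all of its isoforms
and exons.  A QC flag marks the discrepant case where RNA-seq shows het
SNVs that WES lacks although both assays had sufficient coverage (possible
sequencing error or RNA editing); such cases classify as unresolved.

All inference is per sample: no information is shared across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .catalog import FeatureCatalog, FeatureLevel

CALL_COPY_NUMBER_LOSS = "copy_number_loss"
CALL_NO_SNV_DATA = "no_snv_data"
CALL_NOT_EXPRESSED = "not_expressed"
CALL_BIALLELIC = "biallelic"
CALL_MONOALLELIC = "monoallelic"
CALL_UNRESOLVED = "unresolved"

#: Category order used in summary tables.
CALL_CATEGORIES = (
    CALL_COPY_NUMBER_LOSS,
    CALL_NO_SNV_DATA,
    CALL_NOT_EXPRESSED,
    CALL_BIALLELIC,
    CALL_MONOALLELIC,
    CALL_UNRESOLVED,
)


@dataclass(frozen=True)
class ClassifierThresholds:
    """Decision thresholds, defaulting to the published operating point."""

    cn_loss_threshold: float = 1.5   # copies; < threshold means loss of an allele
    expr_cutoff: float = -0.5        # log10 length-normalized RNA counts
    wes_cov_cutoff: float = -0.5     # log10 length-normalized WES counts


def classify_feature(
    cn_linear: float,
    rna_het_snv_count: int,
    wes_het_snv_count: int,
    rna_expr: float,
    wes_cov: float,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> tuple[str, bool]:
    """Classify a single feature x sample; returns (call, qc_discrepancy_flag).

    NaN copy number never satisfies the loss rule; the MINUS_INF expression
    sentinel always fails the >= cutoffs.
    """
    t = thresholds
    qc = bool(
        rna_het_snv_count > 0
        and wes_het_snv_count == 0
        and rna_expr >= t.expr_cutoff
        and wes_cov >= t.wes_cov_cutoff
    )
    if cn_linear < t.cn_loss_threshold:  # NaN-safe: NaN comparisons are False
        return CALL_COPY_NUMBER_LOSS, qc
    if wes_het_snv_count == 0 and rna_het_snv_count == 0:
        return CALL_NO_SNV_DATA, qc
    if rna_expr < t.expr_cutoff:
        return CALL_NOT_EXPRESSED, qc
    if wes_het_snv_count > 0 and rna_het_snv_count > 0:
        return CALL_BIALLELIC, qc
    if wes_het_snv_count > 0 and rna_het_snv_count == 0 and wes_cov >= t.wes_cov_cutoff:
        return CALL_MONOALLELIC, qc
    return CALL_UNRESOLVED, qc


def classify_matrix(
    evidence: pd.DataFrame,
    catalog: FeatureCatalog,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    level: FeatureLevel | str = FeatureLevel.GENE,
) -> pd.DataFrame:
    """Vectorized classification of an evidence table at one feature level.

    ``evidence`` is long-format with columns feature_id, sample_id,
    rna_het_snv_count, wes_het_snv_count, rna_expr, wes_cov, cn_linear.
    Missing feature x sample pairs (relative to the catalog level x the
    samples present) are reported with a warning and called unresolved.
    Returns a long table with call, qc_discrepancy_flag and
    multi_chromosome_flag columns.
    """
    level = FeatureLevel(level)
    ids = catalog.ids(level)
    samples = sorted(evidence["sample_id"].unique())
    full = pd.MultiIndex.from_product([ids, samples], names=["feature_id", "sample_id"])
    ev = evidence.set_index(["feature_id", "sample_id"]).reindex(full)
    n_missing = int(ev["rna_het_snv_count"].isna().sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} feature x sample pair(s) lack evidence; called unresolved",
            stacklevel=2,
        )

    cn = ev["cn_linear"].to_numpy(dtype=float)
    rna_het = ev["rna_het_snv_count"].to_numpy(dtype=float)
    wes_het = ev["wes_het_snv_count"].to_numpy(dtype=float)
    rna_expr = ev["rna_expr"].to_numpy(dtype=float)
    wes_cov = ev["wes_cov"].to_numpy(dtype=float)
    t = thresholds

    have = ~np.isnan(rna_het)
    conds = [
        have & (cn < t.cn_loss_threshold),
        have & (wes_het == 0) & (rna_het == 0),
        have & (rna_expr < t.expr_cutoff),
        have & (wes_het > 0) & (rna_het > 0),
        have & (wes_het > 0) & (rna_het == 0) & (wes_cov >= t.wes_cov_cutoff),
    ]
    call = np.select(conds, CALL_CATEGORIES[:5], default=CALL_UNRESOLVED)
    qc = (
        have
        & (rna_het > 0)
        & (wes_het == 0)
        & (rna_expr >= t.expr_cutoff)
        & (wes_cov >= t.wes_cov_cutoff)
    )

    out = pd.DataFrame(
        {
            "feature_id": full.get_level_values(0),
            "level": level.value,
            "sample_id": full.get_level_values(1),
            "call": call,
            "qc_discrepancy_flag": qc,
        }
    )
    out["multi_chromosome_flag"] = (
        catalog.features["multi_chromosome_flag"].reindex(out["feature_id"]).to_numpy()
    )
    return out


def expression_cutoff_curve(
    evidence: pd.DataFrame,
    bin_width: float = 0.25,
    span: float = 0.5,
    assay: str = "rna",
) -> pd.DataFrame:
    """Diagnostic for choosing the expression cutoff.

    Bins features by log10 length-normalized expression and reports, per
    bin, the proportion of feature x sample observations with zero detected
    het SNVs, together with a locally weighted (LOWESS) smooth of that
    proportion.  The inflection of the smooth is where SNV detection starts
    to fail for lack of reads; the cutoff itself stays a configuration
    choice.  With a single populated bin the smoothed column is left empty.
    """
    expr_col = "rna_expr" if assay == "rna" else "wes_cov"
    het_col = "rna_het_snv_count" if assay == "rna" else "wes_het_snv_count"
    finite = evidence[np.isfinite(evidence[expr_col])]
    if finite.empty:
        raise ValueError("no finite expression values to bin")
    bin_idx = np.floor(finite[expr_col].to_numpy() / bin_width).astype(int)
    centers = (bin_idx + 0.5) * bin_width
    zero = (finite[het_col].to_numpy() == 0).astype(float)
    table = (
        pd.DataFrame({"bin_center": centers, "zero": zero})
        .groupby("bin_center", sort=True)
        .agg(n=("zero", "size"), prop_zero_het=("zero", "mean"))
        .reset_index()
    )
    if len(table) >= 2:
        sm = lowess(
            table["prop_zero_het"].to_numpy(),
            table["bin_center"].to_numpy(),
            frac=min(1.0, span),
            return_sorted=False,
        )
        table["smoothed"] = sm
    else:
        table["smoothed"] = np.nan
    return table
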