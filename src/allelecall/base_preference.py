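"""Base-preference analysis of monoallelically expressed SNVs (the flip test).

Monoallelic expression driven by imprinting silences an allele by parental
origin, so across cell lines the expressed base at a heterozygous site
should be reference or alternative with equal probability.  Mechanisms tied
to the sequence itself (RNA editing, allele-specific expression favoring a
base) instead express the same base again and again.  The flip test makes
that distinction: for each SNV, count the cell lines monoallelically
expressing the reference base versus the alternative base and apply an
exact two-sided binomial test against a 50/50 null.

Extraction chain per SNV x cell line:

a. capture single-base-expressing SNVs from RNA-seq and heterozygous SNVs
   from WES;
b. keep only SNVs inside features called monoallelic in that cell line;
c. when WES shows a het site but RNA-seq recorded no alternative-base
   expression there, infer that the reference base was the expressed one;
d. drop SNVs with no WES het support in any cell line — this removes sites
   that are merely homozygous (two copies of one base is not monoallelic
   expression).

SNVs informative in fewer than 6 cell lines are flagged untested: even a
fully one-sided 5-cell-line split gives p = 0.0625, which can never reach
p < 0.05.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import CALL_MONOALLELIC

SET_IMPRINTED = "imprinted"
SET_OTHER = "other_monoallelic"


def extract_monoallelic_snvs(
    base_table: pd.DataFrame,
    calls: pd.DataFrame,
    gene_set: list[str] | set[str] | None = None,
) -> pd.DataFrame:
    """Build per-SNV reference/alternative expression counts.

    ``base_table`` is the per-site record table from ingest (snv assay,
    genotype, gene); ``calls`` is a call matrix (typically gene level) used
    to restrict to monoallelic feature x sample pairs.  ``gene_set`` limits
    the genes considered (ids absent from the table are skipped with a
    warning); None keeps every gene.

    Returns one row per retained SNV site: snv_id (chrom:pos:ref:alt with
    the primary alternative base), gene_id, n_ref (cell lines inferred to
    express the reference base), n_alt (cell lines expressing the primary
    alternative base), n_other_alt (cell lines expressing a different
    alternative base at multi-allelic sites).
    """
    if gene_set is not None:
        gene_set = set(gene_set)
        present = set(base_table["gene_id"].unique())
        missing = gene_set - present
        if missing:
            warnings.warn(
                f"{len(missing)} gene-set id(s) have no SNV records; skipped",
                stacklevel=2,
            )
        base_table = base_table[base_table["gene_id"].isin(gene_set)]

    mono_pairs = set(
        map(
            tuple,
            calls.loc[
                calls["call"] == CALL_MONOALLELIC, ["feature_id", "sample_id"]
            ].itertuples(index=False, name=None),
        )
    )

    wes_het = base_table[
        (base_table["assay"] == "wes") & (base_table["genotype"] == "het")
    ]
    # single-base expression in RNA: a hom-alt style record (only the
    # alternative base seen); het RNA records mean both alleles were read
    rna_alt = base_table[
        (base_table["assay"] == "rna") & (base_table["genotype"] == "hom_alt")
    ]

    rows = []
    site_cols = ["chrom", "pos", "ref", "gene_id"]
    rna_by_site: dict[tuple, pd.DataFrame] = {
        k: v for k, v in rna_alt.groupby(site_cols)
    } if len(rna_alt) else {}
    for site_key, wes_site in wes_het.groupby(site_cols):
        chrom, pos, ref, gene_id = site_key
        # primary alternative base: the most frequent alt among WES het calls
        alt_counts = wes_site["alt"].value_counts()
        primary_alt = sorted(
            alt_counts.index[alt_counts == alt_counts.max()]
        )[0]
        rna_site = rna_by_site.get(site_key)
        n_ref = n_alt = n_other = 0
        for sample_id in sorted(wes_site["sample_id"].unique()):
            if (gene_id, sample_id) not in mono_pairs:
                continue
            expressed = None
            if rna_site is not None:
                hit = rna_site[rna_site["sample_id"] == sample_id]
                if len(hit):
                    expressed = hit["alt"].iloc[0]
            if expressed is None:
                n_ref += 1  # WES het, no alternative base seen in RNA
            elif expressed == primary_alt:
                n_alt += 1
            else:
                n_other += 1
        if n_ref + n_alt + n_other == 0:
            continue
        rows.append(
            dict(
                snv_id=f"{chrom}:{pos}:{ref}:{primary_alt}",
                gene_id=gene_id,
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=primary_alt,
                n_ref=n_ref,
                n_alt=n_alt,
                n_other_alt=n_other,
            )
        )
    cols = ["snv_id", "gene_id", "chrom", "pos", "ref", "alt",
            "n_ref", "n_alt", "n_other_alt"]
    return pd.DataFrame(rows, columns=cols)


def flip_test(n_ref: int, n_alt: int) -> float:
    """Exact two-sided binomial p-value for a 50/50 null on (n_ref, n_alt).

    With a symmetric null the doubled-smaller-tail and minimum-likelihood
    definitions coincide; the value is capped at 1.  Returns NaN when no
    informative cell line exists.
    """
    if n_ref < 0 or n_alt < 0:
        raise ValueError("counts must be nonnegative")
    n = n_ref + n_alt
    if n == 0:
        return float("nan")
    return float(stats.binomtest(n_ref, n, 0.5, alternative="two-sided").pvalue)


def run_flip_tests(records: pd.DataFrame, min_cells: int = 6) -> pd.DataFrame:
    """Apply the flip test to extracted SNV records.

    SNVs monoallelically expressed in fewer than ``min_cells`` cell lines
    (n_ref + n_alt) are kept in the output but flagged tested = False and
    get no p-value; significant = tested and p < 0.05.
    """
    out = records.copy()
    n = out["n_ref"] + out["n_alt"]
    out["n_informative"] = n
    out["tested"] = n >= min_cells
    out["p_binomial"] = [
        flip_test(r, a) if t else float("nan")
        for r, a, t in zip(out["n_ref"], out["n_alt"], out["tested"])
    ]
    out["significant"] = out["tested"] & (out["p_binomial"] < 0.05)
    return out


def gene_level_flip_summary(
    results: pd.DataFrame,
    gene_to_set: dict[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Summarize flip-test results per gene and contrast gene sets.

    ``gene_to_set`` maps each gene id to "imprinted" or "other_monoallelic".
    Genes with no tested SNV are excluded from set totals.  Returns
    (per-gene table, 2x2 contingency table of significant / non-significant
    SNVs by set, {"chi2_p": ..., "fisher_p": ...}).  Both a Pearson
    chi-square (no continuity correction) and Fisher's exact test are
    reported, as either is defensible on a 2x2 table.
    """
    tested = results[results["tested"]]
    per_gene = (
        tested.groupby("gene_id")
        .agg(
            n_tested=("significant", "size"),
            n_significant=("significant", "sum"),
        )
        .reset_index()
    )
    per_gene["n_non_significant"] = per_gene["n_tested"] - per_gene["n_significant"]
    per_gene["set"] = per_gene["gene_id"].map(gene_to_set)

    table = pd.DataFrame(
        0,
        index=pd.Index([SET_IMPRINTED, SET_OTHER], name="set"),
        columns=["significant", "non_significant"],
    )
    for _, row in per_gene.dropna(subset=["set"]).iterrows():
        table.loc[row["set"], "significant"] += int(row["n_significant"])
        table.loc[row["set"], "non_significant"] += int(row["n_non_significant"])

    pvals: dict[str, float] = {"chi2_p": float("nan"), "fisher_p": float("nan")}
    arr = table.to_numpy(dtype=float)
    if (arr.sum(axis=1) > 0).all() and (arr.sum(axis=0) > 0).all():
        pvals["chi2_p"] = float(stats.chi2_contingency(arr, correction=False)[1])
        pvals["fisher_p"] = float(stats.fisher_exact(arr)[1])
    return per_gene, table, pvals


def set_contrast_test(table) -> dict[str, float]:
    """Chi-square (no correction) and Fisher exact p-values for a 2x2 table."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    return {
        "chi2_p": float(stats.chi2_contingency(arr, correction=False)[1]),
        "fisher_p": float(stats.fisher_exact(arr)[1]),
    }
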