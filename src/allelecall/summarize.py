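"""Summary tables over call matrices and tissue-specificity statistics.

A feature's summary row counts, within a sample group, how many samples fell
in each of the six call categories.  The headline statistic is the percent of
monoallelic calls among informative calls (monoallelic + biallelic).  Also
here: comparisons of a curated gene set (the imprinted list) against the
remaining background, stratified subsampling of background genes, and the
chi-square test for histology-specific isoform patterns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import CALL_BIALLELIC, CALL_CATEGORIES, CALL_MONOALLELIC

PANCANCER = "pancancer"


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero to *ndigits* decimals (65.855 -> 65.86)."""
    scale = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


def percentage(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """100 * numerator / denominator rounded half away from zero.

    Returns NaN for a zero denominator (the undefined case is written as a
    missing marker in output tables).
    """
    if denominator == 0:
        return float("nan")
    return round_half_away(100.0 * numerator / denominator, ndigits)


def pct_monoallelic(n_mono: int, n_bi: int) -> float:
    """Percent monoallelic among informative (monoallelic + biallelic) calls."""
    return percentage(n_mono, n_mono + n_bi)


def _check_grouping(calls: pd.DataFrame, grouping: dict[str, str]) -> None:
    unknown = set(calls["sample_id"].unique()) - set(grouping)
    if unknown:
        raise ValueError(f"samples missing from grouping: {sorted(unknown)[:5]}")


def summarize_calls(
    calls: pd.DataFrame,
    grouping: dict[str, str],
    include_pancancer: bool = True,
) -> pd.DataFrame:
    """Per feature x group counts of each call category.

    ``calls`` is the long output of the classifier (feature_id, sample_id,
    call).  ``grouping`` maps every sample to exactly one group (tumor
    histology); a "pancancer" group covering all samples is appended unless
    disabled.  Adds total_informative and pct_monoallelic (2 decimals, NaN
    when no informative calls).
    """
    _check_grouping(calls, grouping)
    frames = [calls.assign(group=calls["sample_id"].map(grouping))]
    if include_pancancer:
        frames.append(calls.assign(group=PANCANCER))
    long = pd.concat(frames, ignore_index=True)
    counts = (
        long.pivot_table(
            index=["feature_id", "group"],
            columns="call",
            values="sample_id",
            aggfunc="count",
            fill_value=0,
        )
        .reindex(columns=list(CALL_CATEGORIES), fill_value=0)
        .reset_index()
    )
    counts.columns.name = None
    counts["total_informative"] = counts[CALL_MONOALLELIC] + counts[CALL_BIALLELIC]
    counts["pct_monoallelic"] = [
        pct_monoallelic(m, b)
        for m, b in zip(counts[CALL_MONOALLELIC], counts[CALL_BIALLELIC])
    ]
    return counts


def _set_proportions(calls: pd.DataFrame, label: str) -> dict:
    row: dict = {"set": label, "n_calls": len(calls)}
    counts = calls["call"].value_counts()
    for cat in CALL_CATEGORIES:
        row[f"n_{cat}"] = int(counts.get(cat, 0))
    informative = row[f"n_{CALL_MONOALLELIC}"] + row[f"n_{CALL_BIALLELIC}"]
    row["n_informative"] = informative
    row["prop_monoallelic"] = (
        row[f"n_{CALL_MONOALLELIC}"] / informative if informative else float("nan")
    )
    return row


def compare_gene_sets(
    calls: pd.DataFrame,
    set_a_ids: list[str] | set[str],
    set_b_ids: list[str] | set[str],
    grouping: dict[str, str],
    labels: tuple[str, str] = ("set_a", "set_b"),
) -> pd.DataFrame:
    """Aggregate call-category proportions for two disjoint gene sets.

    One row per (group, set), plus pancancer rows; the key column is
    prop_monoallelic among informative calls.  Empty groups yield rows with
    NaN proportions.
    """
    set_a, set_b = set(set_a_ids), set(set_b_ids)
    if set_a & set_b:
        raise ValueError(f"gene sets overlap: {sorted(set_a & set_b)[:5]}")
    _check_grouping(calls, grouping)
    groups = sorted(set(grouping.values())) + [PANCANCER]
    rows = []
    for group in groups:
        if group == PANCANCER:
            sub = calls
        else:
            members = {s for s, g in grouping.items() if g == group}
            sub = calls[calls["sample_id"].isin(members)]
        for ids, label in ((set_a, labels[0]), (set_b, labels[1])):
            row = _set_proportions(sub[sub["feature_id"].isin(ids)], label)
            row["group"] = group
            rows.append(row)
    cols = ["group", "set", "n_calls", "n_informative", "prop_monoallelic"] + [
        f"n_{c}" for c in CALL_CATEGORIES
    ]
    return pd.DataFrame(rows)[cols]


def subsample_comparison(
    calls: pd.DataFrame,
    reference_set_ids: list[str] | set[str],
    background_ids: list[str] | set[str],
    n_genes: int,
    n_reps: int,
    seed: int,
    grouping: dict[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distribution of category proportions over subsampled background genes.

    Draws ``n_genes`` background genes without replacement per replicate and
    computes, per group (stratified summarization) and pancancer, the
    proportion of monoallelic calls among informative calls for the draw.
    Returns (per-replicate table, summary with mean/SD per group plus the
    reference-set proportion).  Deterministic given ``seed``.
    """
    background = sorted(set(background_ids))
    if n_genes > len(background):
        raise ValueError(f"n_genes={n_genes} exceeds background size {len(background)}")
    _check_grouping(calls, grouping)
    rng = np.random.default_rng(seed)
    groups = sorted(set(grouping.values())) + [PANCANCER]
    group_of = {**grouping}

    informative = calls[calls["call"].isin([CALL_MONOALLELIC, CALL_BIALLELIC])].copy()
    informative["group"] = informative["sample_id"].map(group_of)
    background_arr = np.array(background)

    rep_rows = []
    for rep in range(n_reps):
        draw = set(rng.choice(background_arr, size=n_genes, replace=False))
        sub = informative[informative["feature_id"].isin(draw)]
        for group in groups:
            gsub = sub if group == PANCANCER else sub[sub["group"] == group]
            n_mono = int((gsub["call"] == CALL_MONOALLELIC).sum())
            n_inf = len(gsub)
            rep_rows.append(
                dict(
                    replicate=rep,
                    group=group,
                    n_monoallelic=n_mono,
                    n_informative=n_inf,
                    prop_monoallelic=n_mono / n_inf if n_inf else float("nan"),
                )
            )
    reps = pd.DataFrame(rep_rows)

    ref = informative[informative["feature_id"].isin(set(reference_set_ids))]
    sum_rows = []
    for group in groups:
        gsub = reps[reps["group"] == group]
        rsub = ref if group == PANCANCER else ref[ref["group"] == group]
        n_mono = int((rsub["call"] == CALL_MONOALLELIC).sum())
        n_inf = len(rsub)
        sum_rows.append(
            dict(
                group=group,
                mean_prop_monoallelic=float(gsub["prop_monoallelic"].mean()),
                sd_prop_monoallelic=float(gsub["prop_monoallelic"].std(ddof=1)),
                reference_prop_monoallelic=n_mono / n_inf if n_inf else float("nan"),
            )
        )
    return reps, pd.DataFrame(sum_rows)


def select_monoallelic_genes(
    calls: pd.DataFrame,
    exclude: set[str] | list[str] = (),
    min_mono_calls: int = 50,
    min_mono_fraction: float = 0.5,
) -> list[str]:
    """Genes with predominantly monoallelic expression across the cohort.

    A gene qualifies with more than ``min_mono_calls`` monoallelic calls and
    at least ``min_mono_fraction`` of all its calls monoallelic.  The default
    operating point (50 calls, 50%) matches a 108-cell-line cohort; scale
    ``min_mono_calls`` down for smaller cohorts.  ``exclude`` removes the
    curated (imprinted) genes so the result is the *additional* set.
    """
    exclude = set(exclude)
    per_gene = calls.groupby("feature_id")["call"].agg(
        n_mono=lambda s: (s == CALL_MONOALLELIC).sum(), n_total="size"
    )
    keep = per_gene[
        (per_gene["n_mono"] > min_mono_calls)
        & (per_gene["n_mono"] / per_gene["n_total"] >= min_mono_fraction)
    ]
    return sorted(set(keep.index) - exclude)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    pvalue: float
    table: np.ndarray


def histology_pattern_test(counts) -> ChiSquareResult:
    """Pearson chi-square test of independence on a groups x 2 count table.

    ``counts`` holds per-group (monoallelic isoforms, biallelic isoforms);
    groups whose two cells are both zero are dropped before testing.  No
    continuity correction is applied; df = G - 1 for G retained groups.
    Raises ValueError with fewer than two eligible groups.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2:
        raise ValueError("expected a G x 2 table of (monoallelic, biallelic) counts")
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be nonnegative integers")
    table = table[table.sum(axis=1) > 0]
    if len(table) < 2:
        raise ValueError("insufficient groups: need >= 2 with informative isoforms")
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return ChiSquareResult(statistic=float(stat), df=int(df), pvalue=float(p), table=table)


def isoform_pattern_counts(
    calls: pd.DataFrame, grouping: dict[str, str]
) -> pd.DataFrame:
    """Per-group counts of purely monoallelic vs purely biallelic isoforms.

    An isoform contributes to a group only when its informative calls within
    that group are all monoallelic or all biallelic; isoforms mixing both
    patterns inside the group, or with no informative call there, are
    excluded.  Feed the result (one gene at a time) to
    :func:`histology_pattern_test`.
    """
    _check_grouping(calls, grouping)
    informative = calls[calls["call"].isin([CALL_MONOALLELIC, CALL_BIALLELIC])].copy()
    informative["group"] = informative["sample_id"].map(grouping)
    rows = []
    for group, sub in informative.groupby("group", sort=True):
        per_iso = sub.groupby("feature_id")["call"].agg(set)
        n_mono = int(per_iso.apply(lambda s: s == {CALL_MONOALLELIC}).sum())
        n_bi = int(per_iso.apply(lambda s: s == {CALL_BIALLELIC}).sum())
        rows.append(dict(group=group, n_monoallelic=n_mono, n_biallelic=n_bi))
    return pd.DataFrame(rows)
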