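"""Isoform-group association of allelic patterns and expression with drug response.

Isoforms of one gene with identical per-sample call vectors form an isoform
group, tested once.  Three association families, each with its own
Benjamini-Hochberg FDR adjustment:

- allelic_vs_response: Student's (pooled-variance) t-test of log10(IC50)
  between cell lines with monoallelic vs biallelic calls (>= 3 per arm);
- expr_vs_response: Spearman correlation of the group's mean isoform
  expression with log10(IC50) (>= 10 cell lines with both);
- allelic_vs_expr: Student's t-test of group expression between monoallelic
  and biallelic cell lines (>= 3 per arm).

Drug datasets (PRISM / GDSC1 / GDSC2) are never pooled: an agent screened
in several datasets is tested separately per dataset.  Samples whose call
is non-informative or QC-flagged are excluded from both arms.  Eligibility
filters run before FDR, so skipped pairs never inflate a family.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import FeatureCatalog
from .classifier import CALL_BIALLELIC, CALL_MONOALLELIC

FAMILY_ALLELIC_VS_RESPONSE = "allelic_vs_response"
FAMILY_EXPR_VS_RESPONSE = "expr_vs_response"
FAMILY_ALLELIC_VS_EXPR = "allelic_vs_expr"

DIRECTION_MONO_SENSITIVE = "monoallelic_more_sensitive"
DIRECTION_BI_SENSITIVE = "biallelic_more_sensitive"
DIRECTION_NONE = "none"

RESULT_COLUMNS = [
    "group_id", "gene_id", "agent_id", "dataset", "family",
    "statistic", "direction", "n_mono", "n_bi", "n_total",
    "p0", "p_fdr", "degenerate",
]


def build_isoform_groups(calls: pd.DataFrame, catalog: FeatureCatalog) -> pd.DataFrame:
    """Group isoforms of a gene sharing an identical allelic pattern vector.

    The grouping key is the full categorical vector over samples — all six
    call categories plus the QC flag — compared exactly; isoforms of
    different genes never merge.  Group ids are deterministic
    (gene id + short hash of the pattern).  Arm membership for downstream
    tests: samples whose call in the shared vector is monoallelic or
    biallelic and not QC-flagged.
    """
    samples = sorted(calls["sample_id"].unique())
    wide_call = calls.pivot(index="feature_id", columns="sample_id", values="call")
    wide_qc = calls.pivot(
        index="feature_id", columns="sample_id", values="qc_discrepancy_flag"
    )
    gene_of = catalog.features["gene_id"]

    buckets: dict[tuple, dict] = {}
    for iso in wide_call.index:
        pattern = tuple(
            (wide_call.at[iso, s], bool(wide_qc.at[iso, s])) for s in samples
        )
        key = (gene_of.get(iso, iso), pattern)
        buckets.setdefault(key, {"members": []})["members"].append(iso)

    rows = []
    for (gene_id, pattern), info in sorted(buckets.items(), key=lambda kv: kv[0][0]):
        digest = hashlib.sha1(repr(pattern).encode()).hexdigest()[:8]
        mono = [s for s, (c, q) in zip(samples, pattern) if c == CALL_MONOALLELIC and not q]
        bi = [s for s, (c, q) in zip(samples, pattern) if c == CALL_BIALLELIC and not q]
        rows.append(
            dict(
                group_id=f"{gene_id}:{digest}",
                gene_id=gene_id,
                members=tuple(sorted(info["members"])),
                n_members=len(info["members"]),
                mono_samples=tuple(mono),
                bi_samples=tuple(bi),
                n_mono=len(mono),
                n_bi=len(bi),
            )
        )
    return pd.DataFrame(rows).sort_values("group_id").reset_index(drop=True)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _student_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, bool]:
    """Pooled-variance two-sample t-test; degenerate zero-variance cases
    with equal means are recorded as t = 0, p = 1."""
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        return 0.0, 1.0, True
    t, p = stats.ttest_ind(a, b, equal_var=True)
    if not np.isfinite(p):
        return float(t), 1.0, True
    return float(t), float(p), False


def _finish_family(rows: list[dict], family: str) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df["family"] = family
    if len(df):
        df["p_fdr"] = bh_fdr(df["p0"].to_numpy())
    return df


def test_allelic_vs_response(
    groups: pd.DataFrame,
    drug_table: pd.DataFrame,
    min_per_arm: int = 3,
) -> pd.DataFrame:
    """t-test of log10(IC50) between monoallelic and biallelic cell lines.

    Tested per (isoform group, agent, dataset) with >= ``min_per_arm`` cell
    lines carrying IC50 data in each arm; the direction labels which arm was
    more sensitive (lower mean log IC50).  FDR is adjusted within this
    family only.
    """
    rows = []
    eligible = groups[(groups["n_mono"] >= min_per_arm) & (groups["n_bi"] >= min_per_arm)]
    by_agent = {
        k: v.set_index("sample_id")["log_ic50"]
        for k, v in drug_table.groupby(["agent_id", "dataset"], sort=True)
    }
    for _, g in eligible.iterrows():
        mono_set, bi_set = set(g["mono_samples"]), set(g["bi_samples"])
        for (agent_id, dataset), values in by_agent.items():
            a = values.reindex(sorted(mono_set)).dropna().to_numpy()
            b = values.reindex(sorted(bi_set)).dropna().to_numpy()
            if len(a) < min_per_arm or len(b) < min_per_arm:
                continue
            t, p, degenerate = _student_t(a, b)
            if a.mean() < b.mean():
                direction = DIRECTION_MONO_SENSITIVE
            elif a.mean() > b.mean():
                direction = DIRECTION_BI_SENSITIVE
            else:
                direction = DIRECTION_NONE
            rows.append(
                dict(
                    group_id=g["group_id"], gene_id=g["gene_id"],
                    agent_id=agent_id, dataset=dataset, family="",
                    statistic=t, direction=direction,
                    n_mono=len(a), n_bi=len(b), n_total=len(a) + len(b),
                    p0=p, p_fdr=np.nan, degenerate=degenerate,
                )
            )
    return _finish_family(rows, FAMILY_ALLELIC_VS_RESPONSE)


def group_expression(groups: pd.DataFrame, expression: pd.DataFrame) -> pd.DataFrame:
    """Mean member-isoform expression per sample for each group.

    ``expression`` is an isoform x sample table of log10 length-normalized
    counts; the group value is the mean over member isoforms.
    """
    rows = {}
    for _, g in groups.iterrows():
        members = [m for m in g["members"] if m in expression.index]
        if members:
            rows[g["group_id"]] = expression.loc[members].mean(axis=0)
    return pd.DataFrame(rows).T.reindex(groups["group_id"])


def test_expression_vs_response(
    groups: pd.DataFrame,
    expression: pd.DataFrame,
    drug_table: pd.DataFrame,
    min_n: int = 10,
) -> pd.DataFrame:
    """Spearman correlation of group mean expression with log10(IC50).

    Requires >= ``min_n`` cell lines with both measurements; pairs with a
    constant expression vector (rho undefined) are skipped.  Tie-corrected
    ranks, two-sided p via the t approximation.
    """
    rows = []
    expr = group_expression(groups, expression)
    by_agent = {
        k: v.set_index("sample_id")["log_ic50"]
        for k, v in drug_table.groupby(["agent_id", "dataset"], sort=True)
    }
    gene_of = groups.set_index("group_id")["gene_id"]
    for group_id, evec in expr.iterrows():
        evec = evec.replace(-np.inf, np.nan).dropna()
        for (agent_id, dataset), values in by_agent.items():
            joined = pd.concat([evec, values], axis=1, join="inner").dropna()
            if len(joined) < min_n:
                continue
            x = joined.iloc[:, 0].to_numpy()
            if np.all(x == x[0]):
                continue  # rho undefined for a constant vector
            rho, p = stats.spearmanr(x, joined.iloc[:, 1].to_numpy())
            if not np.isfinite(p):
                continue
            rows.append(
                dict(
                    group_id=group_id, gene_id=gene_of[group_id],
                    agent_id=agent_id, dataset=dataset, family="",
                    statistic=float(rho),
                    direction=DIRECTION_MONO_SENSITIVE if rho > 0 else (
                        DIRECTION_BI_SENSITIVE if rho < 0 else DIRECTION_NONE
                    ),
                    n_mono=np.nan, n_bi=np.nan, n_total=len(joined),
                    p0=float(p), p_fdr=np.nan, degenerate=False,
                )
            )
    out = _finish_family(rows, FAMILY_EXPR_VS_RESPONSE)
    # direction for a correlation is the sign of rho; relabel for clarity
    out.loc[out["statistic"] > 0, "direction"] = "positive"
    out.loc[out["statistic"] < 0, "direction"] = "negative"
    return out


def test_allelic_vs_expression(
    groups: pd.DataFrame,
    expression: pd.DataFrame,
    min_per_arm: int = 3,
) -> pd.DataFrame:
    """t-test of group mean expression between monoallelic and biallelic lines.

    A lower monoallelic-arm mean is the allele-dosage direction (one active
    copy producing less transcript).
    """
    rows = []
    expr = group_expression(groups, expression)
    eligible = groups[(groups["n_mono"] >= min_per_arm) & (groups["n_bi"] >= min_per_arm)]
    for _, g in eligible.iterrows():
        evec = expr.loc[g["group_id"]]
        a = evec.reindex(list(g["mono_samples"])).replace(-np.inf, np.nan).dropna().to_numpy()
        b = evec.reindex(list(g["bi_samples"])).replace(-np.inf, np.nan).dropna().to_numpy()
        if len(a) < min_per_arm or len(b) < min_per_arm:
            continue
        t, p, degenerate = _student_t(a, b)
        direction = (
            "monoallelic_lower" if a.mean() < b.mean()
            else "monoallelic_higher" if a.mean() > b.mean() else DIRECTION_NONE
        )
        rows.append(
            dict(
                group_id=g["group_id"], gene_id=g["gene_id"],
                agent_id=".", dataset=".", family="",
                statistic=t, direction=direction,
                n_mono=len(a), n_bi=len(b), n_total=len(a) + len(b),
                p0=p, p_fdr=np.nan, degenerate=degenerate,
            )
        )
    return _finish_family(rows, FAMILY_ALLELIC_VS_EXPR)


def filter_significant(results: pd.DataFrame, level: float = 0.05) -> pd.DataFrame:
    """Rows with p_fdr strictly below ``level``, sorted by raw p0."""
    return results[results["p_fdr"] < level].sort_values("p0").reset_index(drop=True)
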