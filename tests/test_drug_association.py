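"""Isoform grouping, association tests, and FDR handling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from allelecall.classifier import (
    CALL_BIALLELIC,
    CALL_MONOALLELIC,
    CALL_NO_SNV_DATA,
)
from allelecall import drug_association as da
from allelecall.drug_association import (
    bh_fdr,
    build_isoform_groups,
    filter_significant,
    group_expression,
)
from allelecall.ingest import read_drug_response
from allelecall.synthetic import plant_drug_effect
from allelecall.workflow import InputSet, classify_cohort


def bh_oracle(p):
    """Hand-applied step-up: p_(i) * m / i with running minimum from the top."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def student_t_oracle(a, b):
    """Pooled-variance t statistic and two-sided p from first principles."""
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return t, 2 * stats.t.sf(abs(t), na + nb - 2)


def spearman_oracle(x, y):
    """Pearson correlation of tie-corrected ranks, p via the t approximation."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    r = np.corrcoef(rx, ry)[0, 1]
    n = len(x)
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return r, 2 * stats.t.sf(abs(t), n - 2)


def calls_frame(vectors, samples):
    """vectors: isoform -> list of calls aligned to samples."""
    rows = []
    for iso, vec in vectors.items():
        for s, call in zip(samples, vec):
            rows.append(
                dict(feature_id=iso, sample_id=s, call=call,
                     qc_discrepancy_flag=False)
            )
    return pd.DataFrame(rows)


class FakeCatalog:
    def __init__(self, gene_of):
        self.features = pd.DataFrame({"gene_id": pd.Series(gene_of)})


class TestGrouping:
    samples = ["S1", "S2", "S3"]

    def test_identical_vectors_merge(self):
        vec = [CALL_MONOALLELIC, CALL_BIALLELIC, CALL_BIALLELIC]
        calls = calls_frame({"i1": vec, "i2": vec}, self.samples)
        groups = build_isoform_groups(calls, FakeCatalog({"i1": "g1", "i2": "g1"}))
        assert len(groups) == 1
        assert groups.iloc[0]["members"] == ("i1", "i2")
        assert groups.iloc[0]["n_mono"] == 1 and groups.iloc[0]["n_bi"] == 2

    def test_same_vector_different_genes_stay_apart(self):
        vec = [CALL_MONOALLELIC] * 3
        calls = calls_frame({"i1": vec, "i2": vec}, self.samples)
        groups = build_isoform_groups(calls, FakeCatalog({"i1": "g1", "i2": "g2"}))
        assert len(groups) == 2

    def test_one_sample_difference_splits(self):
        v1 = [CALL_MONOALLELIC, CALL_BIALLELIC, CALL_BIALLELIC]
        v2 = [CALL_MONOALLELIC, CALL_MONOALLELIC, CALL_BIALLELIC]
        calls = calls_frame({"i1": v1, "i2": v2}, self.samples)
        groups = build_isoform_groups(calls, FakeCatalog({"i1": "g1", "i2": "g1"}))
        assert len(groups) == 2

    def test_qc_flag_differentiates_and_excludes_arm(self):
        vec = [CALL_MONOALLELIC, CALL_BIALLELIC, CALL_BIALLELIC]
        calls = calls_frame({"i1": vec}, self.samples)
        calls.loc[
            (calls.feature_id == "i1") & (calls.sample_id == "S1"),
            "qc_discrepancy_flag",
        ] = True
        groups = build_isoform_groups(calls, FakeCatalog({"i1": "g1"}))
        assert groups.iloc[0]["n_mono"] == 0  # flagged sample leaves the arm


def make_group(mono, bi, gene="g1"):
    return pd.DataFrame(
        [
            dict(
                group_id=f"{gene}:x", gene_id=gene, members=("i1",), n_members=1,
                mono_samples=tuple(mono), bi_samples=tuple(bi),
                n_mono=len(mono), n_bi=len(bi),
            )
        ]
    )


def drug_frame(agent, values, dataset="PRISM"):
    return pd.DataFrame(
        {
            "agent_id": agent,
            "dataset": dataset,
            "sample_id": list(values),
            "log_ic50": list(values.values()),
        }
    )


class TestAllelicVsResponse:
    def test_undersized_arm_skipped(self):
        groups = make_group(["S1", "S2"], [f"B{i}" for i in range(8)])
        drug = drug_frame("A", {s: 0.1 for s in ["S1", "S2"] + [f"B{i}" for i in range(8)]})
        out = da.test_allelic_vs_response(groups, drug, min_per_arm=3)
        assert out.empty

    def test_degenerate_equal_constant_arms(self):
        groups = make_group(["M1", "M2", "M3"], ["B1", "B2", "B3"])
        drug = drug_frame("A", {s: 1.0 for s in ["M1", "M2", "M3", "B1", "B2", "B3"]})
        out = da.test_allelic_vs_response(groups, drug)
        row = out.iloc[0]
        assert row["p0"] == 1.0 and row["statistic"] == 0.0 and row["degenerate"]

    def test_matches_pooled_t_oracle_on_random_arms(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            na, nb = rng.integers(3, 9, 2)
            a, b = rng.normal(0, 1, na), rng.normal(0.5, 1.5, nb)
            mono = [f"M{i}" for i in range(na)]
            bi = [f"B{i}" for i in range(nb)]
            drug = drug_frame("A", dict(zip(mono + bi, np.r_[a, b])))
            out = da.test_allelic_vs_response(make_group(mono, bi), drug)
            t, p = student_t_oracle(a, b)
            assert out.iloc[0]["statistic"] == pytest.approx(t, abs=1e-10)
            assert out.iloc[0]["p0"] == pytest.approx(p, abs=1e-10)

    def test_direction_labels_sensitive_arm(self):
        mono, bi = ["M1", "M2", "M3"], ["B1", "B2", "B3"]
        low_mono = drug_frame("A", dict(zip(mono + bi, [0, 0.1, 0.2, 1, 1.1, 1.2])))
        out = da.test_allelic_vs_response(make_group(mono, bi), low_mono)
        assert out.iloc[0]["direction"] == "monoallelic_more_sensitive"
        high_mono = drug_frame("A", dict(zip(mono + bi, [1, 1.1, 1.2, 0, 0.1, 0.2])))
        out = da.test_allelic_vs_response(make_group(mono, bi), high_mono)
        assert out.iloc[0]["direction"] == "biallelic_more_sensitive"


class TestExpressionVsResponse:
    def _setup(self, n, rho_sign=1):
        samples = [f"S{i}" for i in range(n)]
        expr = pd.DataFrame({s: [float(i)] for i, s in enumerate(samples)}, index=["i1"])
        drug = drug_frame("A", {s: rho_sign * float(i) for i, s in enumerate(samples)})
        groups = make_group([], [])
        groups.at[0, "members"] = ("i1",)
        return groups, expr, drug

    def test_perfect_monotone_correlations(self):
        groups, expr, drug = self._setup(10, 1)
        out = da.test_expression_vs_response(groups, expr, drug)
        assert out.iloc[0]["statistic"] == pytest.approx(1.0)
        groups, expr, drug = self._setup(10, -1)
        out = da.test_expression_vs_response(groups, expr, drug)
        assert out.iloc[0]["statistic"] == pytest.approx(-1.0)

    def test_below_min_n_skipped(self):
        groups, expr, drug = self._setup(9)
        assert da.test_expression_vs_response(groups, expr, drug).empty

    def test_constant_expression_skipped(self):
        groups, expr, drug = self._setup(12)
        expr.loc["i1"] = 1.0
        assert da.test_expression_vs_response(groups, expr, drug).empty

    def test_matches_rank_pearson_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            n = int(rng.integers(10, 25))
            x, y = rng.normal(size=n), rng.normal(size=n)
            samples = [f"S{i}" for i in range(n)]
            expr = pd.DataFrame([x], index=["i1"], columns=samples)
            drug = drug_frame("A", dict(zip(samples, y)))
            groups = make_group([], [])
            out = da.test_expression_vs_response(groups, expr, drug)
            r, p = spearman_oracle(x, y)
            assert out.iloc[0]["statistic"] == pytest.approx(r, abs=1e-10)
            assert out.iloc[0]["p0"] == pytest.approx(p, abs=1e-10)


class TestAllelicVsExpression:
    def test_minimal_eligible_arms_tested(self):
        groups = make_group(["M1", "M2", "M3"], ["B1", "B2", "B3"])
        expr = pd.DataFrame(
            [dict(M1=0.0, M2=0.1, M3=0.2, B1=0.5, B2=0.6, B3=0.7)], index=["i1"]
        )
        out = da.test_allelic_vs_expression(groups, expr)
        assert len(out) == 1
        assert out.iloc[0]["direction"] == "monoallelic_lower"

    def test_dosage_shift_detected_at_oracle_power(self):
        # monoallelic arm shifted by -log10(2): one active copy halves output
        rng = np.random.default_rng(17)
        shift, sd, n = np.log10(2.0), 0.08, 10
        detected = 0
        n_trials = 200
        for _ in range(n_trials):
            a = rng.normal(-shift, sd, n)
            b = rng.normal(0.0, sd, n)
            _, p = stats.ttest_ind(a, b, equal_var=True)
            detected += p < 0.05
        # noncentral-t power oracle
        delta = shift / (sd * np.sqrt(2 / n))
        df = 2 * n - 2
        crit = stats.t.ppf(0.975, df)
        power = 1 - stats.nct.cdf(crit, df, delta) + stats.nct.cdf(-crit, df, delta)
        se = np.sqrt(power * (1 - power) / n_trials)
        assert abs(detected / n_trials - power) <= 3 * max(se, 1e-3)


class TestBhFdr:
    def test_worked_examples(self):
        assert bh_fdr([0.02]) == pytest.approx([0.02])
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_matches_step_up_oracle_on_random_vectors(self):
        rng = np.random.default_rng(44)
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 60)))
            np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_fdr([np.nan])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(45)
        p = rng.uniform(size=40)
        assert (bh_fdr(p) >= p - 1e-15).all()


class TestFamilyHandling:
    def test_families_adjusted_independently(self, noisy_cohort):
        bundle, result = noisy_cohort
        groups = build_isoform_groups(result.calls["isoform"], result.catalog)
        drug = pd.concat(
            [read_drug_response(p, ds) for ds, p in bundle.paths["drug_response"].items()],
            ignore_index=True,
        )
        expr = result.expression["isoform"]
        r1 = da.test_allelic_vs_response(groups, drug)
        r3 = da.test_allelic_vs_expression(groups, expr)
        assert not r1.empty and not r3.empty
        # each family's adjustment is a function of its own p0 vector alone
        np.testing.assert_allclose(r1["p_fdr"], bh_oracle(r1["p0"]), atol=1e-12)
        np.testing.assert_allclose(r3["p_fdr"], bh_oracle(r3["p0"]), atol=1e-12)

    def test_ineligible_groups_do_not_inflate_family(self):
        eligible = make_group(["M1", "M2", "M3"], ["B1", "B2", "B3"], gene="g1")
        small = make_group(["M4"], ["B4"], gene="g2")
        both = pd.concat([eligible, small], ignore_index=True)
        rng = np.random.default_rng(2)
        values = dict(zip(["M1", "M2", "M3", "B1", "B2", "B3", "M4", "B4"],
                          rng.normal(size=8)))
        drug = drug_frame("A", values)
        out_both = da.test_allelic_vs_response(both, drug)
        out_one = da.test_allelic_vs_response(eligible, drug)
        assert len(out_both) == len(out_one) == 1
        assert out_both.iloc[0]["p_fdr"] == out_one.iloc[0]["p_fdr"]

    def test_filter_significant_strict_inequality(self):
        df = pd.DataFrame(
            {"p0": [0.001, 0.01, 0.2], "p_fdr": [0.01, 0.05, 0.4]}
        )
        out = filter_significant(df, 0.05)
        assert len(out) == 1  # the row at exactly 0.05 is excluded
        assert filter_significant(df.iloc[0:0], 0.05).empty


class TestPlantedEffect:
    def test_shift_detected_and_direction_flips(self, tmp_path):
        from allelecall.synthetic import CohortConfig, generate_cohort

        cfg = CohortConfig(
            seed=23, n_samples=30, n_genes=40, fraction_imprinted=0.4,
            n_agents=6, datasets=("PRISM",),
        )
        bundle = generate_cohort(cfg, tmp_path / "c")
        gene_truth = bundle.truth_calls.query("level == 'gene'")
        counts = (
            gene_truth.groupby("feature_id")["true_call"]
            .value_counts().unstack(fill_value=0)
        )
        ok = counts[(counts.get("monoallelic", 0) >= 5) & (counts.get("biallelic", 0) >= 5)]
        gene = ok.index[0]
        plant_drug_effect(bundle, gene, "PRISM_A001", "PRISM", shift=-3.0)
        result = classify_cohort(InputSet.from_bundle(tmp_path / "c"))
        groups = build_isoform_groups(result.calls["isoform"], result.catalog)
        drug = read_drug_response(bundle.paths["drug_response"]["PRISM"], "PRISM")
        out = da.test_allelic_vs_response(groups, drug)
        hit = out[(out.gene_id == gene) & (out.agent_id == "PRISM_A001")]
        assert not hit.empty
        assert (hit["p_fdr"] < 0.05).any()
        assert (hit["direction"] == "monoallelic_more_sensitive").all()

    def test_arm_too_small_rejected(self, tmp_path):
        from allelecall.synthetic import CohortConfig, generate_cohort

        cfg = CohortConfig(seed=29, n_samples=8, n_genes=10, datasets=("PRISM",))
        bundle = generate_cohort(cfg, tmp_path / "c")
        gene_truth = bundle.truth_calls.query("level == 'gene'")
        biallelic_only = (
            gene_truth.groupby("feature_id")["true_call"]
            .apply(lambda s: (s == "monoallelic").sum() == 0)
        )
        gene = biallelic_only[biallelic_only].index[0]
        with pytest.raises(ValueError, match="arms too small"):
            plant_drug_effect(bundle, gene, "PRISM_A001", "PRISM", shift=1.0)
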