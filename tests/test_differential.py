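import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from rbprofiler import (
    GroupDesign,
    SimulationConfig,
    ValidationError,
    aggregate_genes,
    classify_probes,
    cross_dataset_fc_concordance,
    detection_filter,
    generate_dataset,
    median_normalize,
    percent,
    probe_differential,
    run_comparison,
    signed_fold_change,
)
from statsmodels.stats.multitest import multipletests

from conftest import make_matrix


def three_group_design(n_per_group=1):
    samples, labels = [], []
    for g in ("NS", "S", "COPD"):
        for i in range(n_per_group):
            samples.append(f"{g}{i}")
            labels.append(g)
    return GroupDesign(groups=pd.Series(labels, index=samples))


class TestDetectionFilter:
    def test_detected_in_every_group_is_kept(self):
        design = three_group_design()
        m = make_matrix([[5, 5, 5]], detection_p=[[0.01, 0.01, 0.01]],
                        samples=["NS0", "S0", "COPD0"])
        assert detection_filter(m, design) == ["p0"]

    def test_detected_in_one_group_only_is_removed(self):
        design = three_group_design()
        m = make_matrix([[5, 5, 5]], detection_p=[[0.01, 0.5, 0.5]],
                        samples=["NS0", "S0", "COPD0"])
        assert detection_filter(m, design) == []

    def test_never_detected_is_removed(self):
        design = three_group_design()
        m = make_matrix([[5, 5, 5]], detection_p=[[0.5, 0.5, 0.5]],
                        samples=["NS0", "S0", "COPD0"])
        assert detection_filter(m, design) == []

    def test_order_preserved(self):
        design = three_group_design()
        det = [[0.01] * 3, [0.5] * 3, [0.01] * 3, [0.01] * 3]
        m = make_matrix(np.full((4, 3), 5.0), detection_p=det,
                        samples=["NS0", "S0", "COPD0"])
        assert detection_filter(m, design) == ["p0", "p2", "p3"]


class TestMedianNormalize:
    def test_column_divided_by_its_median(self):
        m = make_matrix([[1.0], [2.0], [3.0]])
        out = median_normalize(m)
        assert out.intensities["s0"].tolist() == [0.5, 1.0, 1.5]

    def test_idempotent(self):
        m = make_matrix([[1.0], [2.0], [3.0]])
        once = median_normalize(m)
        twice = median_normalize(once)
        assert twice.intensities.equals(once.intensities)

    def test_constant_column(self):
        m = make_matrix([[4.0], [4.0], [4.0], [4.0]])
        assert median_normalize(m).intensities["s0"].tolist() == [1, 1, 1, 1]

    def test_post_condition_unit_median(self, default_cohort):
        matrix, _, _ = default_cohort
        out = median_normalize(matrix)
        assert np.allclose(out.intensities.median(axis=0), 1.0)

    def test_zero_median_rejected(self):
        m = make_matrix([[0.0], [0.0], [5.0]])
        with pytest.raises(ValidationError, match="median"):
            median_normalize(m)


class TestSignedFoldChange:
    def test_ratio_convention(self):
        assert signed_fold_change(2.0, 1.0) == pytest.approx(2.0)
        assert signed_fold_change(1.0, 2.0) == pytest.approx(-2.0)
        assert abs(signed_fold_change(1.0, 1.0)) == 1.0

    @given(st.floats(0.01, 100), st.floats(0.01, 100))
    def test_antisymmetry(self, a, b):
        fwd = signed_fold_change(a, b)
        rev = signed_fold_change(b, a)
        if a == b:
            # equal means sit exactly on the |FC| = 1 boundary, which the
            # signed-ratio convention maps to +1 from either side
            assert fwd == rev == 1.0
        else:
            assert fwd == pytest.approx(-rev, rel=1e-9)

    @given(st.floats(0.01, 100), st.floats(0.01, 100))
    def test_magnitude_at_least_one(self, a, b):
        assert abs(signed_fold_change(a, b)) >= 1.0


def bh_oracle(pvals):
    """Brute-force Benjamini-Hochberg adjusted p-values from the definition."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, pvals[idx] * m / rank)
        adj[idx] = running
    return adj


class TestBenjaminiHochberg:
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, pvals):
        p = np.array(pvals)
        _, fdr, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(fdr, bh_oracle(p), atol=1e-12)

    def test_monotone_in_sorted_p(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=50)
        _, fdr, _, _ = multipletests(p, method="fdr_bh")
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-15).all()


class TestProbeDifferential:
    def test_fc_sign_follows_group_means(self):
        rng = np.random.default_rng(1)
        case = 2.0 * np.ones((1, 4)) + rng.normal(0, 1e-6, (1, 4))
        control = np.ones((1, 4)) + rng.normal(0, 1e-6, (1, 4))
        m = make_matrix(np.hstack([case, control]),
                        samples=[f"C{i}" for i in range(4)] + [f"N{i}" for i in range(4)])
        design = GroupDesign(groups=pd.Series(
            ["COPD"] * 4 + ["NS"] * 4, index=m.sample_ids))
        df = probe_differential(m, design, ("COPD", "NS"))
        assert df["fc_signed"].iloc[0] == pytest.approx(2.0, rel=1e-4)
        swapped = probe_differential(m, design, ("NS", "COPD"))
        assert swapped["fc_signed"].iloc[0] == pytest.approx(
            -df["fc_signed"].iloc[0], rel=1e-9
        )

    def test_single_sample_group_rejected(self):
        m = make_matrix([[1, 2, 3]], samples=["a", "b", "c"])
        design = GroupDesign(groups=pd.Series({"a": "X", "b": "Y", "c": "Y"}))
        with pytest.raises(ValidationError, match=">= 2 samples"):
            probe_differential(m, design, ("X", "Y"))

    def test_null_probes_type_one_error_rate(self):
        # 100 probes with no group difference: the fraction of raw p < 0.05
        # must sit inside the exact 99% binomial envelope of 0.05
        rng = np.random.default_rng(3)
        n = 100
        log2x = rng.normal(8, 0.5, (n, 24))
        m = make_matrix(2.0 ** log2x, samples=[f"s{j}" for j in range(24)])
        design = GroupDesign(groups=pd.Series(
            ["A"] * 12 + ["B"] * 12, index=m.sample_ids))
        df = probe_differential(m, design, ("A", "B"))
        hits = int((df["p_value"] < 0.05).sum())
        lo = int(sps.binom.ppf(0.005, n, 0.05))
        hi = int(sps.binom.ppf(0.995, n, 0.05))
        assert lo <= hits <= hi


class TestClassifyProbes:
    @pytest.mark.parametrize(
        "fdr,fc,tier,direction",
        [
            (0.04, -1.6, "SDEG", "down"),
            (0.04, 1.2, "DEG", "up"),
            (0.20, -3.0, "none", "none"),
            (0.05, 1.5, "SDEG", "up"),  # thresholds are inclusive
        ],
    )
    def test_tier_assignment(self, fdr, fc, tier, direction):
        df = pd.DataFrame({"fdr": [fdr], "fc_signed": [fc]})
        out = classify_probes(df)
        assert out["tier"].iloc[0] == tier
        assert out["direction"].iloc[0] == direction


def probe_frame(rows):
    """rows: list of (gene, tier, direction, fc)."""
    return pd.DataFrame(
        [
            {
                "probeset_id": f"p{i}",
                "gene_symbol": g,
                "tier": t,
                "direction": d,
                "fc_signed": fc,
            }
            for i, (g, t, d, fc) in enumerate(rows)
        ]
    )


class TestAggregateGenes:
    def test_two_of_three_concordant_kept(self):
        df = probe_frame([
            ("G1", "SDEG", "up", 2.0),
            ("G1", "DEG", "up", 1.2),
            ("G1", "DEG", "down", -1.3),
        ])
        out = aggregate_genes(df)
        row = out.iloc[0]
        assert row["consistency"] == pytest.approx(2 / 3)
        assert not row["excluded_for_discordance"]
        assert row["direction"] == "up"
        assert row["tier"] == "SDEG"

    def test_even_split_excluded(self):
        df = probe_frame([("G1", "DEG", "up", 1.2), ("G1", "DEG", "down", -1.2)])
        out = aggregate_genes(df)
        assert bool(out["excluded_for_discordance"].iloc[0])

    def test_single_probe_gene_kept(self):
        df = probe_frame([("G1", "SDEG", "down", -2.0)])
        out = aggregate_genes(df)
        assert out["consistency"].iloc[0] == 1.0
        assert not out["excluded_for_discordance"].iloc[0]

    def test_gene_fc_is_median_of_majority_probes(self):
        df = probe_frame([
            ("G1", "SDEG", "down", -4.0),
            ("G1", "SDEG", "down", -2.0),
            ("G1", "DEG", "down", -1.2),
            ("G1", "DEG", "up", 1.1),
        ])
        out = aggregate_genes(df)
        assert out["gene_fc"].iloc[0] == pytest.approx(-2.0)

    def test_unannotated_probes_dropped(self):
        df = probe_frame([("G1", "DEG", "up", 1.2), (None, "SDEG", "up", 3.0)])
        out = aggregate_genes(df)
        assert out["gene_symbol"].tolist() == ["G1"]

    def test_threshold_zero_excludes_nothing(self, default_comparison):
        res, _ = default_comparison
        out = aggregate_genes(res.probe_stats, consistency_min=0.0)
        assert not out["excluded_for_discordance"].any()

    def test_threshold_one_excludes_exactly_disagreements(self, default_comparison):
        res, _ = default_comparison
        out = aggregate_genes(res.probe_stats, consistency_min=1.0)
        disagree = (out["n_up"] > 0) & (out["n_down"] > 0)
        assert (out["excluded_for_discordance"] == disagree).all()


class TestRunComparison:
    def test_sdeg_subset_of_deg(self, default_comparison):
        res, _ = default_comparison
        ps = res.probe_stats
        sdeg_probes = set(ps.loc[ps["tier"] == "SDEG", "probeset_id"])
        deg_probes = set(ps.loc[ps["tier"] != "none", "probeset_id"])
        assert sdeg_probes <= deg_probes
        gc = res.gene_calls
        assert set(gc.loc[gc["tier"] == "SDEG", "gene_symbol"]) <= set(
            gc["gene_symbol"]
        )

    def test_counts_recomputable_from_tables(self, default_comparison):
        res, _ = default_comparison
        ps, gc, c = res.probe_stats, res.gene_calls, res.counts
        kept = gc[~gc["excluded_for_discordance"]]
        assert c["probes_sdeg"] == int((ps["tier"] == "SDEG").sum())
        assert c["genes_deg"] == len(kept)
        assert c["genes_sdeg"] == int((kept["tier"] == "SDEG").sum())
        assert c["genes_sdeg_down"] == int(
            ((kept["tier"] == "SDEG") & (kept["direction"] == "down")).sum()
        )
        assert c["genes_excluded_discordant"] == int(
            gc["excluded_for_discordance"].sum()
        )

    def test_deterministic_counts(self, default_cohort):
        matrix, design, truth = default_cohort
        runs = [
            run_comparison(matrix, design, ("COPD", "NS"), census=truth.census())
            for _ in range(2)
        ]
        assert runs[0].counts == runs[1].counts

    def test_empty_census_gives_no_calls(self, default_normalized):
        norm, design = default_normalized
        res = run_comparison(norm, design, ("COPD", "NS"), census=set(),
                             prefiltered_normalized=True)
        assert len(res.gene_calls) == 0
        assert res.counts["genes_sdeg"] == 0

    def test_census_restriction_does_not_change_fdr(self, default_normalized,
                                                    default_cohort):
        # the multiple-testing family is the detection-filtered probe set,
        # not the census subset searched afterwards
        _, _, truth = default_cohort
        norm, design = default_normalized
        full = run_comparison(norm, design, ("COPD", "NS"),
                              prefiltered_normalized=True)
        restricted = run_comparison(norm, design, ("COPD", "NS"),
                                    census=truth.census(),
                                    prefiltered_normalized=True)
        merged = restricted.probe_stats.merge(
            full.probe_stats, on="probeset_id", suffixes=("_r", "_f")
        )
        assert np.allclose(merged["fdr_r"], merged["fdr_f"])


class TestPercent:
    @pytest.mark.parametrize(
        "num,den,expected",
        [(194, 267, 73), (202, 257, 79), (13, 41, 32), (30, 267, 11),
         (217, 390, 56), (4, 13, 31), (1, 2, 50), (0, 7, 0)],
    )
    def test_half_up_rounding(self, num, den, expected):
        assert percent(num, den) == expected


class TestCrossDatasetConcordance:
    def _result(self, genes, fcs):
        from rbprofiler import ComparisonResult
        gc = pd.DataFrame({
            "gene_symbol": genes,
            "gene_fc": fcs,
            "tier": ["SDEG"] * len(genes),
            "direction": ["up" if f > 0 else "down" for f in fcs],
            "excluded_for_discordance": [False] * len(genes),
        })
        return ComparisonResult(("COPD", "S"), pd.DataFrame(), gc)

    def test_identical_results_agree_fully(self):
        a = self._result(["G1", "G2"], [2.0, -3.0])
        table, agree = cross_dataset_fc_concordance(a, a)
        assert agree == 1.0

    def test_flipped_signs_agree_never(self):
        a = self._result(["G1", "G2"], [2.0, -3.0])
        b = self._result(["G1", "G2"], [-2.0, 3.0])
        _, agree = cross_dataset_fc_concordance(a, b)
        assert agree == 0.0

    def test_missing_genes_reported_not_fatal(self):
        a = self._result(["G1"], [2.0])
        b = self._result(["G2"], [2.0])
        table, agree = cross_dataset_fc_concordance(a, b, ["G1", "G2", "G3"])
        assert len(table) == 3
        assert np.isnan(agree)

    def test_replicate_cohorts_agree_on_regulated_genes(self):
        # same planted biology, independent subjects/noise: the disease
        # signature direction replicates across cohorts
        def one(seed):
            m, d, t = generate_dataset(
                SimulationConfig(seed=seed, biology_seed=42))
            kept = detection_filter(m, d)
            norm = median_normalize(m.subset_probes(kept))
            return run_comparison(norm, d, ("COPD", "NS"), census=t.census(),
                                  prefiltered_normalized=True), t
        a, truth = one(1)
        b, _ = one(2)
        table, agree = cross_dataset_fc_concordance(
            a, b, sorted(truth.regulated_genes()))
        assert table.dropna().shape[0] >= 50
        assert agree >= 0.9
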