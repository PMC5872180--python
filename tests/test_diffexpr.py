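import math
import subprocess
import sys

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_dataset
from netbiomark.diffexpr import (
    VariancePrior,
    bh_adjust,
    call_de,
    estimate_variance_prior,
    fit_group_contrast,
    moderated_t,
    run_de,
)
from netbiomark.simulate import make_expression_truth, simulate_expression
from oracles import brute_force_bh


class TestFitGroupContrast:
    def test_constant_groups_have_zero_variance(self):
        dataset = make_dataset([[1, 1, 3, 3]], n_control=2, n_case=2)
        row = fit_group_contrast(dataset).iloc[0]
        assert row.log_fc == pytest.approx(2.0)
        assert row.s_sq == pytest.approx(0.0)
        assert row.df == 2

    def test_pooled_variance_hand_computation(self):
        # control (0,2), case (1,3): squared deviations 2 + 2 over df 2
        dataset = make_dataset([[0, 2, 1, 3]], n_control=2, n_case=2)
        row = fit_group_contrast(dataset).iloc[0]
        assert row.log_fc == pytest.approx(1.0)
        assert row.s_sq == pytest.approx(2.0)
        assert row.df == 2

    def test_identical_groups_give_zero_logfc(self):
        dataset = make_dataset([[5, 7, 5, 7]], n_control=2, n_case=2)
        assert fit_group_contrast(dataset).iloc[0].log_fc == pytest.approx(0.0)

    def test_single_sample_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            make_dataset([[1, 2, 3]], n_control=1, n_case=2)


class TestEstimateVariancePrior:
    def test_recovers_generating_hyperparameters(self):
        # scaled inverse-chi-square draws with known (d0, s0²) at microarray scale
        rng = np.random.default_rng(42)
        d0_true, s0_true, df = 4.0, 0.05, 2.0
        s_sq = s0_true * d0_true / rng.chisquare(d0_true, size=2000) \
            * rng.chisquare(df, size=2000) / df
        prior = estimate_variance_prior(s_sq, df)
        assert prior.d0 == pytest.approx(d0_true, rel=0.20)
        assert prior.s0_sq == pytest.approx(s0_true, rel=0.10)

    def test_equal_variances_collapse_to_infinite_d0(self):
        prior = estimate_variance_prior(np.full(100, 0.25), df=4.0)
        assert math.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.25)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        s_sq = rng.chisquare(3, size=500) / 3 * 0.1
        base = estimate_variance_prior(s_sq, df=3.0)
        doubled = estimate_variance_prior(2 * s_sq, df=3.0)
        assert doubled.d0 == pytest.approx(base.d0, rel=1e-6)
        assert doubled.s0_sq == pytest.approx(2 * base.s0_sq, rel=1e-6)

    def test_zero_variance_genes_excluded(self):
        rng = np.random.default_rng(8)
        s_sq = np.concatenate([rng.chisquare(4, size=200), np.zeros(50)])
        prior = estimate_variance_prior(s_sq, df=4.0)
        assert prior.d0 > 0 and prior.s0_sq > 0

    def test_too_few_genes_advises_fallback(self):
        with pytest.raises(ValueError, match="ordinary-t"):
            estimate_variance_prior(np.ones(5) * 0.1 + np.arange(5) * 0.01, df=2.0)


class TestModeratedT:
    def test_d0_zero_reproduces_ordinary_pooled_t_exhaustively(self):
        # every small two-group dataset: moderated t with no prior weight must
        # equal scipy's equal-variance two-sample t
        rng = np.random.default_rng(11)
        prior = VariancePrior(d0=0.0, s0_sq=1.0)
        for n1 in (2, 3, 5):
            for n2 in (2, 4):
                for _ in range(20):
                    a = rng.normal(0, 1, size=n1)
                    b = rng.normal(0.5, 1.3, size=n2)
                    log_fc = b.mean() - a.mean()
                    ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
                    df = n1 + n2 - 2
                    s_sq = ss / df
                    t_mod, df_total, p_raw = moderated_t(log_fc, s_sq, df, prior, n1, n2)
                    t_ref, p_ref = stats.ttest_ind(b, a, equal_var=True)
                    assert t_mod[0] == pytest.approx(t_ref, rel=1e-10)
                    assert df_total[0] == df
                    assert p_raw[0] == pytest.approx(p_ref, rel=1e-10)

    def test_zero_logfc_gives_zero_t_unit_p(self):
        t_mod, _, p_raw = moderated_t(0.0, 0.5, 4.0, VariancePrior(2.0, 0.1), 3, 3)
        assert t_mod[0] == 0.0
        assert p_raw[0] == pytest.approx(1.0)

    def test_prior_equal_to_observed_is_shrinkage_fixed_point(self):
        prior = VariancePrior(d0=4.0, s0_sq=1.0)
        t_mod, _, _ = moderated_t(2.0, 1.0, 6.0, prior, 4, 4)
        # posterior variance stays 1.0, so t = 2 / sqrt(1 * (1/4 + 1/4))
        assert t_mod[0] == pytest.approx(2.0 / math.sqrt(0.5))

    def test_infinite_d0_uses_normal_reference(self):
        prior = VariancePrior(d0=math.inf, s0_sq=0.25)
        t_mod, df_total, p_raw = moderated_t(1.0, 0.9, 4.0, prior, 2, 2)
        assert t_mod[0] == pytest.approx(1.0 / math.sqrt(0.25 * 1.0))
        assert math.isinf(df_total[0])
        assert p_raw[0] == pytest.approx(2 * stats.norm.sf(t_mod[0]))

    def test_zero_posterior_variance_flagged_not_crashed(self):
        prior = VariancePrior(d0=0.0, s0_sq=1.0)
        t_mod, _, p_raw = moderated_t(0.0, 0.0, 2.0, prior, 2, 2)
        assert np.isnan(t_mod[0])
        assert p_raw[0] == 1.0


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_hand_step_up_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    @settings(derandomize=True, max_examples=200)
    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40)
    )
    def test_agrees_with_quadratic_brute_force(self, p):
        assert bh_adjust(p) == pytest.approx(brute_force_bh(p), abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20)
    )
    def test_adjusted_at_least_raw(self, p):
        assert np.all(bh_adjust(p) >= np.asarray(p) - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCallDe:
    def test_direction_follows_sign_and_significance(self):
        import pandas as pd

        table = pd.DataFrame(
            {
                "log_fc": [1.0, -1.0, 0.5, 2.0],
                "p_raw": [0.001, 0.002, 0.9, 0.012],
            },
            index=["up", "down", "ns_p", "borderline"],
        )
        out = call_de(table, alpha=0.05)
        assert out.loc["up", "direction"] == "Up"
        assert out.loc["down", "direction"] == "Down"
        assert out.loc["ns_p", "direction"] == "NS"
        assert (out["p_adj"] >= out["p_raw"] - 1e-15).all()

    def test_adjusted_p_exactly_alpha_is_not_significant(self):
        import pandas as pd

        table = pd.DataFrame({"log_fc": [1.0], "p_raw": [0.05]})
        out = call_de(table, alpha=0.05)  # m = 1: p_adj == 0.05 == alpha
        assert out["direction"].iloc[0] == "NS"


class TestFdrCalibrationAndPower:
    def test_global_null_family_error_within_alpha(self):
        # 200 null studies; under the global null BH controls the probability
        # of any false discovery at alpha, so the rate of studies with >= 1
        # call must not exceed 0.05 by more than binomial Monte-Carlo error
        n_studies, n_genes = 200, 400
        n_with_discovery = 0
        for i in range(n_studies):
            truth = make_expression_truth(
                [f"g{j}" for j in range(n_genes)], n_datasets=1, seed=10_000 + i
            )
            table = run_de(simulate_expression(truth)[0], alpha=0.05)
            n_with_discovery += int((table["direction"] != "NS").any())
        limit = 0.05 + 2 * math.sqrt(0.05 * 0.95 / n_studies)
        assert n_with_discovery / n_studies <= limit

    def test_power_on_planted_effects_exceeds_ninety_percent(self):
        # |logFC| = 1.5 at per-gene sd ~ 0.3 and n = 10 + 10
        genes = [f"g{j}" for j in range(1000)]
        planted = {f"g{j}": 1.5 if j % 2 else -1.5 for j in range(0, 1000, 10)}
        truth = make_expression_truth(
            genes, de_genes=planted, d0=8.0, s0_sq=0.09,
            n_control=10, n_case=10, n_datasets=1, seed=77,
        )
        table = run_de(simulate_expression(truth)[0], alpha=0.05)
        called = set(table.index[table["direction"] != "NS"])
        recovered = sum(g in called for g in planted)
        assert recovered / len(planted) > 0.9


R_SCRIPT = """
suppressMessages(library(limma))
args <- commandArgs(trailingOnly = TRUE)
m <- as.matrix(read.delim(args[1], row.names = 1, check.names = FALSE))
groups <- read.delim(args[2], header = FALSE)$V2
design <- model.matrix(~ factor(groups, levels = c("control", "case")))
fit <- eBayes(lmFit(m, design))
out <- data.frame(
  gene = rownames(m),
  t = fit$t[, 2],
  p = fit$p.value[, 2],
  d0 = fit$df.prior,
  s0_sq = fit$s2.prior
)
write.table(out, args[3], sep = "\t", row.names = FALSE, quote = FALSE)
"""


class TestLimmaCrossCheck:
    def test_moderated_t_matches_limma_on_small_fixture(self, tmp_path):
        """Independent oracle: Bioconductor limma on the same 80-gene matrix."""
        rng = np.random.default_rng(123)
        n_genes, n1, n2 = 80, 4, 4
        values = rng.normal(8, 1, size=(n_genes, 1)) + rng.normal(
            0, 0.4, size=(n_genes, n1 + n2)
        )
        values[:10, n1:] += 1.0
        dataset = make_dataset(values, n_control=n1, n_case=n2, dataset_id="xcheck")
        table = run_de(dataset, alpha=0.05)

        matrix_path = tmp_path / "matrix.tsv"
        groups_path = tmp_path / "groups.tsv"
        out_path = tmp_path / "limma.tsv"
        dataset.matrix.to_csv(matrix_path, sep="\t")
        with open(groups_path, "w") as fh:
            for sample, group in dataset.groups.items():
                fh.write(f"{sample}\t{group}\n")
        script = tmp_path / "limma_check.R"
        script.write_text(R_SCRIPT)
        proc = subprocess.run(
            ["Rscript", str(script), str(matrix_path), str(groups_path), str(out_path)],
            capture_output=True,
            text=True,
        )
        assert proc.returncode == 0, f"Rscript failed: {proc.stderr}"

        import pandas as pd

        limma = pd.read_csv(out_path, sep="\t", index_col="gene")
        prior = table.attrs["prior"]
        assert prior.d0 == pytest.approx(limma["d0"].iloc[0], rel=1e-4)
        assert prior.s0_sq == pytest.approx(limma["s0_sq"].iloc[0], rel=1e-4)
        for gene in table.index:
            assert table.loc[gene, "t_mod"] == pytest.approx(
                limma.loc[gene, "t"], rel=1e-6, abs=1e-8
            )
            assert table.loc[gene, "p_raw"] == pytest.approx(
                limma.loc[gene, "p"], rel=1e-6, abs=1e-12
            )
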