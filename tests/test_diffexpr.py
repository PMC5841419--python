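"""Moderated t-test: limits, shrinkage, hyperparameter recovery, and a
cross-check against the Bioconductor reference implementation."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cerna_net import EBayesFit, fit_ebayes, moderated_t_test, run_de, select_sde
from cerna_net.diffexpr import _trigamma_inverse
from scipy.special import polygamma

from conftest import make_expression, make_labels


def _simulated_matrix(rng, n_genes=200, n0=6, n1=6, d0=None, s0_sq=1.0, effect=0.0):
    """Genes with inverse-chi-square-distributed true variances."""
    if d0 is None:
        sigma2 = np.full(n_genes, s0_sq)
    else:
        sigma2 = d0 * s0_sq / rng.chisquare(d0, size=n_genes)
    x = rng.standard_normal((n_genes, n0 + n1)) * np.sqrt(sigma2)[:, None]
    x[:, n0:] += effect
    return make_expression(x), make_labels(n0, n1)


class TestFit:
    def test_identical_variances_give_infinite_prior_df(self):
        rng = np.random.default_rng(0)
        # same true variance everywhere; excess dispersion of log s^2 is
        # within chi-square sampling noise, so d0 = inf
        expr, labels = _simulated_matrix(rng, n_genes=2000, d0=None, s0_sq=2.0)
        fit = fit_ebayes(expr, labels)
        assert np.isinf(fit.d0)
        assert fit.s0_sq == pytest.approx(2.0, rel=0.15)

    def test_hyperparameter_recovery(self):
        # variances drawn from the scaled inverse-chi-square prior itself
        d0s, s0s = [], []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            expr, labels = _simulated_matrix(
                rng, n_genes=2000, n0=4, n1=4, d0=4.0, s0_sq=1.0
            )
            fit = fit_ebayes(expr, labels)
            d0s.append(fit.d0)
            s0s.append(fit.s0_sq)
        assert all(2.5 <= d <= 6.5 for d in d0s)
        assert all(0.8 <= s <= 1.25 for s in s0s)

    def test_single_sample_group_rejected(self):
        expr = make_expression(np.arange(8.0).reshape(2, 4))
        labels = pd.Series([0, 0, 0, 1], index=expr.samples)
        with pytest.raises(ValueError, match="at least 2 samples"):
            fit_ebayes(expr, labels)

    def test_trigamma_inverse_roundtrip(self):
        for x in (0.1, 0.5, 2.0, 10.0, 250.0):
            y = float(polygamma(1, x))
            assert _trigamma_inverse(y) == pytest.approx(x, rel=1e-6)


class TestModeratedT:
    def test_d0_zero_equals_ordinary_t(self):
        rng = np.random.default_rng(1)
        expr, labels = _simulated_matrix(rng, n_genes=50, n0=5, n1=7)
        fit = EBayesFit(d0=0.0, s0_sq=1.0, dg=10)
        res = moderated_t_test(expr, labels, fit)
        x = expr.values.to_numpy()
        ref = stats.ttest_ind(x[:, 5:], x[:, :5], axis=1, equal_var=True)
        np.testing.assert_allclose(res["t_mod"], ref.statistic, atol=1e-10)
        np.testing.assert_allclose(res["p_value"], ref.pvalue, atol=1e-10)

    def test_three_vs_three_example(self):
        # group0=[1,2,3], group1=[2,3,4]: pooled s^2=1, mean_diff=+1,
        # t = 1/sqrt(2/3) = 1.2247, df=4, p = 0.2879 (ordinary-t oracle)
        expr = make_expression(np.array([[1.0, 2, 3, 2, 3, 4]]))
        labels = make_labels(3, 3)
        res = moderated_t_test(expr, labels, EBayesFit(d0=0.0, s0_sq=1.0, dg=4))
        oracle = stats.ttest_ind([2, 3, 4], [1, 2, 3], equal_var=True)
        assert res["t_mod"].iloc[0] == pytest.approx(1.224744871, abs=1e-8)
        assert res["t_mod"].iloc[0] == pytest.approx(oracle.statistic, abs=1e-10)
        assert res["p_value"].iloc[0] == pytest.approx(oracle.pvalue, abs=1e-10)
        assert res["direction"].iloc[0] == "up"

    def test_zero_mean_diff_gives_p_one(self):
        expr = make_expression(np.array([[1.0, 2, 3, 1, 2, 3]]))
        labels = make_labels(3, 3)
        res = moderated_t_test(expr, labels, EBayesFit(d0=0.0, s0_sq=1.0, dg=4))
        assert res["t_mod"].iloc[0] == 0.0
        assert res["p_value"].iloc[0] == 1.0

    def test_shrinkage_bounds_and_monotonicity(self):
        rng = np.random.default_rng(2)
        expr, labels = _simulated_matrix(rng, n_genes=500, d0=4.0)
        fit = fit_ebayes(expr, labels)
        assert np.isfinite(fit.d0)
        from cerna_net.diffexpr import residual_variances

        s_g_sq, n0, n1, dg = residual_variances(expr, labels)
        s_tilde_sq = (fit.d0 * fit.s0_sq + dg * s_g_sq) / (fit.d0 + dg)
        lo = np.minimum(s_g_sq, fit.s0_sq)
        hi = np.maximum(s_g_sq, fit.s0_sq)
        assert ((s_tilde_sq >= lo - 1e-12) & (s_tilde_sq <= hi + 1e-12)).all()
        # |t| non-increasing in s_g^2 at fixed mean_diff
        res = moderated_t_test(expr, labels, fit)
        order = np.argsort(s_g_sq)
        t_abs = np.abs(res["t_mod"].to_numpy()[order])
        md = np.abs(res["mean_diff"].to_numpy()[order])
        scaled = t_abs / md  # removes the mean-diff dependence
        assert (np.diff(scaled) <= 1e-12).all()

    def test_infinite_d0_uses_normal_tail(self):
        # every gene is the same row plus an offset: identical s_g^2,
        # no excess dispersion, hence d0 = inf and s0^2 = that variance
        rng = np.random.default_rng(3)
        row = rng.standard_normal(12)
        x = row[None, :] + np.arange(100.0)[:, None]
        expr = make_expression(x)
        labels = make_labels(6, 6)
        fit = fit_ebayes(expr, labels)
        assert np.isinf(fit.d0)
        from cerna_net.diffexpr import residual_variances

        s_g_sq, *_ = residual_variances(expr, labels)
        assert fit.s0_sq == pytest.approx(s_g_sq[0], rel=1e-9)
        res = moderated_t_test(expr, labels, fit)
        z = res["t_mod"].to_numpy()
        np.testing.assert_allclose(
            res["p_value"], 2 * stats.norm.sf(np.abs(z)), atol=1e-12
        )


class TestSelect:
    def test_threshold_counting(self):
        df = pd.DataFrame(
            {
                "gene_class": ["mRNA"] * 3,
                "p_value": [0.005, 0.02, 0.5],
                "direction": ["up", "down", "up"],
            },
            index=["g1", "g2", "g3"],
        )
        sde, counts = select_sde(df, 0.01)
        assert counts["n_sde"] == 1
        sde, counts = select_sde(df, 0.05)
        assert counts["n_sde"] == 2
        assert counts["n_up"] == 1 and counts["n_down"] == 1

    def test_bad_threshold(self):
        df = pd.DataFrame({"p_value": [0.5], "direction": ["up"]})
        for bad in (0.0, 1.0, -1, 2):
            with pytest.raises(ValueError):
                select_sde(df, bad)

    def test_null_false_positive_rate(self):
        rates = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            expr, labels = _simulated_matrix(rng, n_genes=400, n0=10, n1=10)
            table, _, _ = run_de(expr, labels, 0.05)
            rates.append((table["p_value"] < 0.05).mean())
        mean = np.mean(rates)
        se = np.sqrt(0.05 * 0.95 / (400 * 20))
        # moderated t is continuous: type-I error matches the nominal level
        assert abs(mean - 0.05) < max(2 * se, 0.01)


def test_matches_limma_reference():
    """Cross-check d0, s0^2, t and p against Bioconductor limma."""
    rscript = shutil.which("Rscript")
    assert rscript, "Rscript required for the limma cross-check"
    rng = np.random.default_rng(11)
    expr, labels = _simulated_matrix(
        rng, n_genes=300, n0=5, n1=5, d0=4.0, s0_sq=1.0, effect=0.5
    )
    fit = fit_ebayes(expr, labels)
    res = moderated_t_test(expr, labels, fit)

    import tempfile
    from pathlib import Path

    with tempfile.TemporaryDirectory() as td:
        td = Path(td)
        expr.values.to_csv(td / "x.csv")
        script = textwrap.dedent(
            """
            suppressMessages(library(limma))
            x <- as.matrix(read.csv("x.csv", row.names=1))
            design <- cbind(Intercept=1, Group=c(rep(0,5), rep(1,5)))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t=fit$t[,2], p=fit$p.value[,2])
            write.csv(out, "out.csv")
            cat(fit$df.prior, fit$s2.prior, sep="\\n")
            """
        )
        (td / "run.R").write_text(script)
        proc = subprocess.run(
            [rscript, "run.R"], cwd=td, capture_output=True, text=True, check=True
        )
        d0_ref, s0_ref = (float(v) for v in proc.stdout.split())
        ref = pd.read_csv(td / "out.csv", index_col=0)

    assert fit.d0 == pytest.approx(d0_ref, rel=1e-4)
    assert fit.s0_sq == pytest.approx(s0_ref, rel=1e-4)
    np.testing.assert_allclose(res["t_mod"], ref["t"], rtol=1e-6)
    np.testing.assert_allclose(res["p_value"], ref["p"], rtol=1e-6)
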