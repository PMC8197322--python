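import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

from mirpipe import GroupDesign, fit_ebayes, storey_qvalues
from mirpipe.diffexpr import differential_expression, trigamma_inverse
from mirpipe.normalization import NormalizedExpression


def _design(n1=3, n2=3):
    cond = {f"r{i}": "ref" for i in range(n1)}
    cond.update({f"t{i}": "test" for i in range(n2)})
    return GroupDesign(cond, ("ref", "test")), \
        [f"r{i}" for i in range(n1)], [f"t{i}" for i in range(n2)]


def _matrix(rng, n_assays=50, n1=3, n2=3, scale_df=6.0):
    """Hierarchical simulation: per-assay variance from a scaled inv-chi2."""
    s2 = 0.04 * scale_df / rng.chisquare(scale_df, size=n_assays)
    data = rng.normal(0, np.sqrt(s2)[:, None], size=(n_assays, n1 + n2))
    design, ref, test = _design(n1, n2)
    df = pd.DataFrame(data, index=[f"g{i}" for i in range(n_assays)],
                      columns=ref + test)
    return df, design


# ---------------------------------------------------------------------------
# independent oracle: the closed-form moment equations, solved by bracketing
# ---------------------------------------------------------------------------

def ebayes_oracle(delta: pd.DataFrame, ref_cols, test_cols):
    a = delta[ref_cols].to_numpy()
    b = delta[test_cols].to_numpy()
    n1, n2 = a.shape[1], b.shape[1]
    dg = n1 + n2 - 2
    effect = a.mean(1) - b.mean(1)
    sg2 = (((a - a.mean(1, keepdims=True)) ** 2).sum(1)
           + ((b - b.mean(1, keepdims=True)) ** 2).sum(1)) / dg
    z = np.log(sg2)
    e = z - special.digamma(dg / 2) + np.log(dg / 2)
    n = len(e)
    evar = ((e - e.mean()) ** 2).mean() * n / (n - 1) - special.polygamma(1, dg / 2)
    if evar > 0:
        half_d0 = brentq(lambda x: special.polygamma(1, x) - evar, 1e-8, 1e8,
                         xtol=1e-14, rtol=1e-15)
        d0 = 2 * half_d0
        s02 = np.exp(e.mean() + special.digamma(half_d0) - np.log(half_d0))
        post = (d0 * s02 + dg * sg2) / (d0 + dg)
        df_tot = d0 + dg
    else:
        d0 = np.inf
        s02 = np.exp(e.mean())
        post = np.full_like(sg2, s02)
        df_tot = np.inf
    t = effect / np.sqrt(post * (1 / n1 + 1 / n2))
    if np.isinf(df_tot):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_tot)
    return d0, s02, t, p


class TestModeratedT:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_moment_oracle(self, seed):
        rng = np.random.default_rng(seed)
        delta, design = _matrix(rng)
        fit = fit_ebayes(delta, design)
        d0_o, s02_o, t_o, p_o = ebayes_oracle(
            delta, design.samples("ref"), design.samples("test"))
        assert fit.params.d0 == pytest.approx(d0_o, rel=1e-6)
        assert fit.params.s0_sq == pytest.approx(s02_o, rel=1e-6)
        assert np.allclose(fit.table["t_mod"], t_o, rtol=1e-6)
        assert np.allclose(fit.table["p"], p_o, rtol=1e-6)

    def test_zero_prior_df_recovers_ordinary_t(self):
        rng = np.random.default_rng(3)
        delta, design = _matrix(rng, n_assays=30)
        fit = fit_ebayes(delta, design, prior_df=0.0)
        t_ref, p_ref = stats.ttest_ind(
            delta[design.samples("ref")], delta[design.samples("test")],
            axis=1)
        assert np.allclose(fit.table["t_mod"], t_ref, rtol=1e-10)
        assert np.allclose(fit.table["p"], p_ref, rtol=1e-10)

    def test_infinite_prior_df_pins_variance_to_prior(self):
        rng = np.random.default_rng(4)
        delta, design = _matrix(rng, n_assays=30)
        fit = fit_ebayes(delta, design, prior_df=np.inf)
        assert np.allclose(fit.table["s_tilde_sq"], fit.params.s0_sq)
        assert np.isinf(fit.table["df_total"]).all()

    def test_posterior_variance_is_fixed_point_at_prior(self):
        # if the prior variance equals the common residual variance, the
        # posterior equals it for any prior df
        sg = 0.25
        for d0 in (0.5, 4.0, 100.0):
            post = (d0 * sg + 4 * sg) / (d0 + 4)
            assert post == pytest.approx(sg)

    def test_identical_variances_drive_d0_to_infinity(self):
        # equal residual variances leave no excess spread in log s^2, so
        # the moment estimator assigns infinite prior df
        rng = np.random.default_rng(5)
        design, ref, test = _design()
        base = rng.normal(0, 1, 6)
        delta = pd.DataFrame(
            [np.concatenate([base[:3] * 0.3, base[3:] * 0.3]) + i
             for i in range(20)],
            index=[f"g{i}" for i in range(20)], columns=ref + test)
        fit = fit_ebayes(delta, design)
        assert np.isinf(fit.params.d0)
        assert np.allclose(fit.table["s_tilde_sq"], fit.params.s0_sq)

    def test_shrinkage_pulls_extreme_variances_inward(self):
        rng = np.random.default_rng(6)
        delta, design = _matrix(rng, n_assays=200, scale_df=3.0)
        fit = fit_ebayes(delta, design)
        raw = fit.table["sg_sq"]
        post = fit.table["s_tilde_sq"]
        assert post[raw.idxmax()] < raw.max()
        assert post[raw.idxmin()] > raw.min()

    def test_small_groups_rejected(self):
        delta = pd.DataFrame(np.ones((3, 3)), columns=["r0", "r1", "t0"])
        design = GroupDesign({"r0": "ref", "r1": "ref", "t0": "test", "t1": "test"},
                             ("ref", "test"))
        with pytest.raises(ValueError):
            fit_ebayes(delta, design)

    def test_trigamma_inverse_round_trip(self):
        for y in (1e-4, 0.01, 0.5, 2.0, 50.0):
            x = trigamma_inverse(y)
            assert special.polygamma(1, x) == pytest.approx(y, rel=1e-6)


class TestLimmaCrossCheck:
    def test_matches_limma_ebayes(self, tmp_path):
        """The moderated t, prior df and prior variance agree with the
        reference Bioconductor implementation on a simulated matrix."""
        rng = np.random.default_rng(7)
        delta, design = _matrix(rng, n_assays=60)
        mat_path = tmp_path / "mat.tsv"
        delta.to_csv(mat_path, sep="\t")
        script = tmp_path / "fit.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'm <- as.matrix(read.delim("{mat_path}", row.names=1))\n'
            'grp <- factor(c(rep("ref",3), rep("test",3)), levels=c("ref","test"))\n'
            'design <- model.matrix(~grp)\n'
            'fit <- eBayes(lmFit(m, design))\n'
            'out <- data.frame(t=fit$t[,2], p=fit$p.value[,2])\n'
            f'write.table(out, "{tmp_path / "out.tsv"}", sep="\\t", quote=FALSE)\n'
            'cat(fit$df.prior, fit$s2.prior, sep="\\n")\n'
        )
        proc = subprocess.run(["Rscript", str(script)], capture_output=True,
                              text=True, timeout=300)
        assert proc.returncode == 0, proc.stderr
        d0_r, s02_r = [float(v) for v in proc.stdout.strip().splitlines()[-2:]]
        r_out = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        fit = fit_ebayes(delta, design)
        assert fit.params.d0 == pytest.approx(d0_r, rel=1e-4)
        assert fit.params.s0_sq == pytest.approx(s02_r, rel=1e-4)
        # limma's coefficient is test-minus-reference: opposite sign
        assert np.allclose(fit.table["t_mod"], -r_out["t"], rtol=1e-4)
        assert np.allclose(fit.table["p"], r_out["p"], rtol=1e-4)


class TestStoreyQValues:
    def test_worked_example(self):
        q, pi0 = storey_qvalues([0.01, 0.2, 0.8, 0.9], lambda_=0.5)
        assert pi0 == 1.0
        assert np.allclose(q, [0.04, 0.4, 0.9, 0.9])

    def test_all_ones_capped(self):
        q, pi0 = storey_qvalues([1.0] * 5)
        assert pi0 == 1.0
        assert np.allclose(q, 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_bh_equivalence_at_pi0_one(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1, 200)
        q, _ = storey_qvalues(p, lambda_=0.0)  # pi0 = 1 by construction
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, bh, rtol=1e-12)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(1e-6, 1, 500)
        q, _ = storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_single_p_value(self):
        p = 0.3
        q, pi0 = storey_qvalues([p], lambda_=0.5)
        assert pi0 == min(1.0, (p > 0.5) / 0.5)
        assert q[0] == pytest.approx(min(p * pi0, 1.0))

    def test_ties_share_q(self):
        q, _ = storey_qvalues([0.01, 0.05, 0.05, 0.9])
        assert q[1] == q[2]

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.0, 0.5])
        with pytest.raises(ValueError):
            storey_qvalues([])


class TestDifferentialExpression:
    def _norm_from(self, delta):
        return NormalizedExpression(
            delta_ct=delta, rel_quantity=np.power(2.0, -delta), hkgs=[],
            reference_profile=pd.Series(0.0, index=delta.columns))

    def test_null_simulation_controls_fdr(self):
        """No true effects: the mean significant proportion at FDR 10%
        stays at or below the nominal level (plus Monte-Carlo error)."""
        rng = np.random.default_rng(11)
        props = []
        for _ in range(100):
            delta, design = _matrix(rng, n_assays=111)
            de = differential_expression(self._norm_from(delta), design)
            props.append(de["significant"].mean())
        props = np.array(props)
        mc_se = props.std(ddof=1) / np.sqrt(len(props))
        assert props.mean() <= 0.10 + 2 * mc_se

    def test_direction_partition(self):
        rng = np.random.default_rng(12)
        delta, design = _matrix(rng, n_assays=40)
        delta.iloc[0, 3:] -= 1.0  # strongly increased in test group
        de = differential_expression(self._norm_from(delta), design)
        assert de.loc["g0", "direction"] == "increased"
        assert de.loc["g0", "fc"] > 1
        assert set(de["direction"]) <= {"increased", "decreased", "flat"}

    def test_q_matches_storey_on_own_pvalues(self):
        rng = np.random.default_rng(13)
        delta, design = _matrix(rng, n_assays=40)
        de = differential_expression(self._norm_from(delta), design)
        q, pi0 = storey_qvalues(de["p"].to_numpy())
        assert np.allclose(de["q"], q)
        assert de.attrs["pi0"] == pi0
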