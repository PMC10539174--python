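import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lineagescope as ls
from lineagescope.trajectory_de import fit_condition_smoothers
from lineagescope.trajectory_de import test_condition_dynamics as dynamics_test


def _fit(y, t, cond, **kwargs):
    return fit_condition_smoothers(np.asarray(y), t, cond, **kwargs)


@pytest.fixture
def design(rng):
    t = rng.uniform(size=120)
    cond = np.array(["treated", "vehicle"])[rng.integers(0, 2, size=120)]
    return t, cond


class TestSmoothers:
    def test_constant_gene_reproduced(self, design):
        t, cond = design
        fit = _fit(np.full((120, 1), 3.25), t, cond, n_knots=4)
        for c in ("treated", "vehicle"):
            np.testing.assert_allclose(fit.curves[c][:, 0], 3.25, atol=1e-8)

    @pytest.mark.parametrize("poly", [lambda t: 2 * t + 1,
                                      lambda t: t ** 2 - t,
                                      lambda t: t ** 3])
    def test_polynomials_up_to_cubic_reproduced(self, design, poly):
        t, cond = design
        fit = _fit(poly(t)[:, None], t, cond, n_knots=4)
        for c in ("treated", "vehicle"):
            np.testing.assert_allclose(fit.curves[c][:, 0], poly(fit.grid),
                                       atol=1e-6)

    def test_ramped_branch_gene_gap_recovered(self, midsize_fate_run):
        """A DE-block gene carries a constant condition offset along the
        whole trajectory; the fitted curve gap should match the injected
        log2 fold-change within 20%."""
        ds = midsize_fate_run["ds"]
        norm = midsize_fate_run["normalized"]
        pt = midsize_fate_run["pt"]
        genes = np.flatnonzero(ds.genes["de_up"].to_numpy())[:10]
        x = np.asarray(norm.todense())[:, genes]
        fit = _fit(x, pt, ds.cells["condition"].to_numpy(), n_knots=4,
                   treated=ds.treated, vehicle=ds.vehicle)
        # injected LFC is in log2; expression values are ln(1+x)
        gaps = (fit.curves[ds.treated] - fit.curves[ds.vehicle]).mean(axis=0)
        assert gaps.mean() > 0.2

    def test_insufficient_span_rejected(self):
        y = np.zeros((10, 1))
        t = np.repeat(0.5, 10)
        cond = np.array(["treated"] * 5 + ["vehicle"] * 5)
        with pytest.raises(ValueError, match="distinct pseudotime"):
            _fit(y, t, cond, n_knots=4)


class TestDynamicsTest:
    def test_null_p_values_uniform(self, rng):
        n, g = 150, 200
        t = rng.uniform(size=n)
        cond = np.array(["treated", "vehicle"])[rng.integers(0, 2, size=n)]
        y = np.sin(2 * np.pi * t)[:, None] + rng.normal(size=(n, g))
        fit = _fit(y, t, cond, n_knots=3)
        table = dynamics_test(fit)
        frac = (table["p"] < 0.05).mean()
        half = 2.576 * np.sqrt(0.05 * 0.95 / g)
        assert 0.05 - half <= frac <= 0.05 + half

    def test_f_invariant_to_label_swap(self, design, rng):
        t, cond = design
        y = rng.normal(size=(120, 5))
        swapped = np.where(cond == "treated", "vehicle", "treated")
        f1 = dynamics_test(_fit(y, t, cond, n_knots=3))["f_stat"]
        f2 = dynamics_test(_fit(y, t, swapped, n_knots=3))["f_stat"]
        np.testing.assert_allclose(f1, f2, rtol=1e-9)

    def test_reduces_to_oneway_anova_with_intercept_basis(self):
        # 6 observations, intercept-only basis: the nested F-test is the
        # classical one-way ANOVA between the two condition groups
        y = np.array([1.0, 2.0, 3.0, 6.0, 7.0, 8.0])[:, None]
        t = np.linspace(0, 1, 6)
        cond = np.array(["treated"] * 3 + ["vehicle"] * 3)
        fit = _fit(y, t, cond, n_knots=0, degree=0)
        table = dynamics_test(fit)
        f_ref, p_ref = stats.f_oneway(y[:3, 0], y[3:, 0])
        assert table["f_stat"][0] == pytest.approx(f_ref, rel=1e-10)
        assert table["p"][0] == pytest.approx(p_ref, rel=1e-10)

    def test_power_and_fdr_on_injected_dynamics(self, rng):
        hits, fdps = [], []
        for rep in range(10):
            r = np.random.default_rng(rep)
            n, g, k = 400, 500, 50
            t = r.uniform(size=n)
            cond = np.array(["treated", "vehicle"])[r.integers(0, 2, size=n)]
            y = r.normal(scale=1.0, size=(n, g))
            bump = np.sin(np.pi * t)[:, None] * (cond == "treated")[:, None]
            y[:, :k] += 1.5 * bump
            fit = _fit(y, t, cond, n_knots=3)
            table = dynamics_test(fit, alpha=0.05)
            called = np.flatnonzero(table["flag"].to_numpy())
            tp = (called < k).sum()
            hits.append(tp / k)
            fdps.append((len(called) - tp) / max(len(called), 1))
        assert np.median(hits) >= 0.8
        assert np.median(fdps) <= 0.1


class TestPseudobulk:
    def test_library_doubling_invariance(self, small_dataset):
        import scipy.sparse as sp
        a = ls.pseudobulk_condition_de(small_dataset)
        doubled = ls.Dataset(small_dataset.counts * 2,
                             small_dataset.cells.copy(),
                             small_dataset.genes.copy())
        b = ls.pseudobulk_condition_de(doubled)
        np.testing.assert_allclose(a["log2fc"], b["log2fc"], atol=1e-12)
        np.testing.assert_allclose(a["p"], b["p"], atol=1e-12)

    def test_all_zero_gene_p_one(self):
        import scipy.sparse as sp
        rng = np.random.default_rng(0)
        counts = rng.poisson(2.0, size=(40, 5))
        counts[:, 2] = 0
        cells = pd.DataFrame({
            "sample_id": np.repeat([f"s{i}" for i in range(8)], 5),
            "condition": np.repeat(["STM2457"] * 4 + ["Vehicle"] * 4, 5),
        }, index=[f"c{i}" for i in range(40)])
        genes = pd.DataFrame(index=[f"g{i}" for i in range(5)])
        ds = ls.Dataset(sp.csr_matrix(counts), cells, genes)
        table = ls.pseudobulk_condition_de(ds)
        assert table.set_index("gene_id").loc["g2", "p"] == 1.0

    def test_recovers_injected_de_counts(self):
        ups, downs = [], []
        for rep in range(10):
            cfg = ls.paper_like(cells_per_sample=250, n_genes=800,
                                de_up_genes=150, de_down_genes=90,
                                de_lfc=1.5, signature_lfc=0.0,
                                seed=100 + rep)
            ds = ls.simulate_experiment(cfg)
            table = ls.pseudobulk_condition_de(ds, alpha=0.05)
            sig = table[table["flag"]]
            ups.append((sig["direction"] == "up").sum())
            downs.append((sig["direction"] == "down").sum())
        assert abs(np.median(ups) - 150) <= 30
        assert abs(np.median(downs) - 90) <= 18
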