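import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sncrna import diffexpr, synthetic
from sncrna.core_io import CountMatrix
from sncrna.diffexpr import (
    bh_fdr, de_summary, estimate_common_dispersion, exact_test, tmm_factors,
)
from sncrna.synthetic import SynthDesign


def _matrix(arr, n_tbi):
    df = pd.DataFrame(np.asarray(arr),
                      index=[f"g{i}" for i in range(len(arr))],
                      columns=[f"s{j}" for j in range(np.shape(arr)[1])])
    groups = {f"s{j}": ("TBI" if j < n_tbi else "sham")
              for j in range(np.shape(arr)[1])}
    return CountMatrix(df, groups)


def reference_tmm(counts, ref_idx, trim_m=0.3, trim_a=0.05):
    """Direct transcription of the published TMM definition (test oracle)."""
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    out = []
    for j in range(counts.shape[1]):
        y, r = counts[:, j], counts[:, ref_idx]
        keep = (y > 0) & (r > 0)
        m = np.log2((y[keep] / lib[j]) / (r[keep] / lib[ref_idx]))
        a = 0.5 * np.log2((y[keep] / lib[j]) * (r[keep] / lib[ref_idx]))
        w = (lib[j] - y[keep]) / (lib[j] * y[keep]) + \
            (lib[ref_idx] - r[keep]) / (lib[ref_idx] * r[keep])
        n = m.size
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        rm, ra = stats.rankdata(m), stats.rankdata(a)
        kept = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if np.max(np.abs(m)) < 1e-6 or not kept.any():
            out.append(0.0)
        else:
            out.append(np.sum(m[kept] / w[kept]) / np.sum(1 / w[kept]))
    f = 2.0 ** np.array(out)
    return f / np.exp(np.mean(np.log(f)))


class TestTmm:
    def test_identical_libraries_give_unit_factors(self):
        arr = np.tile([[10], [20], [30], [40]], (1, 4))
        f = tmm_factors(_matrix(arr, 2))
        assert np.allclose(f, 1.0)

    def test_composition_preserving_rescaling_gives_unit_factors(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(100, size=(50, 1))
        arr = np.hstack([base, base * 2, base * 5, base])
        f = tmm_factors(_matrix(arr, 2))
        assert np.allclose(f, 1.0, atol=1e-12)

    def test_matches_direct_definition_on_toy_matrix(self):
        rng = np.random.default_rng(2)
        arr = rng.negative_binomial(10, 0.1, size=(20, 4))
        arr[:, 1] *= 3
        m = _matrix(arr, 2)
        f = tmm_factors(m, ref_sample="s0")
        expected = reference_tmm(arr, ref_idx=0)
        assert np.allclose(f.to_numpy(), expected)

    def test_matches_edger_calcnormfactors(self, tmp_path):
        # independent cross-check against the Bioconductor implementation
        rng = np.random.default_rng(7)
        arr = rng.negative_binomial(5, 0.01, size=(200, 6))
        arr[:, 2] *= 3
        arr[:50, 4] *= 2
        m = _matrix(arr, 3)
        f = tmm_factors(m)
        tsv = tmp_path / "m.tsv"
        m.counts.to_csv(tsv, sep="\t")
        script = (
            'suppressMessages(library(edgeR));'
            f'x<-as.matrix(read.delim("{tsv}",row.names=1));'
            'cat(calcNormFactors(x,method="TMM"),sep="\\n")'
        )
        res = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        edger = np.array([float(v) for v in res.stdout.split()])
        assert np.allclose(f.to_numpy(), edger, atol=1e-4)

    def test_all_zero_sample_raises(self):
        arr = np.array([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="all-zero sample"):
            tmm_factors(_matrix(arr, 1))


class TestDispersion:
    def test_poisson_data_estimates_near_zero(self):
        d = SynthDesign(n_features=1000, nb_dispersion=0.0, baseline_mean=100,
                        rng_seed=3)
        m = synthetic.gen_count_matrix(d)
        phi = estimate_common_dispersion(m, tmm_factors(m))
        assert phi <= 0.02

    def test_planted_dispersion_recovered(self):
        d = SynthDesign(n_features=1000, nb_dispersion=0.1, baseline_mean=500,
                        rng_seed=4)
        m = synthetic.gen_count_matrix(d)
        phi = estimate_common_dispersion(m, tmm_factors(m))
        assert 0.07 <= phi <= 0.13

    def test_equal_counts_single_feature_gives_zero(self):
        arr = np.full((1, 6), 50)
        m = _matrix(arr, 3)
        phi = estimate_common_dispersion(m, tmm_factors(m))
        assert phi == 0.0


class TestExactTest:
    def test_identical_groups_give_p_one(self):
        arr = np.tile([[10, 20, 30]], (4, 2)).reshape(4, 6)
        m = _matrix(np.hstack([np.full((5, 3), 17), np.full((5, 3), 17)]), 3)
        table = exact_test(m, tmm_factors(m), 0.1)
        assert np.allclose(table["p_value"], 1.0)
        assert np.allclose(table["log2fc"], 0.0)

    def test_poisson_case_matches_binomial_enumeration(self):
        # one sample per group with equal library sizes: conditional on the
        # total z, the group-1 count is Binomial(z, 1/2)
        arr = np.array([[10, 0], [100, 100], [3, 7]])
        m = _matrix(arr, 1)
        factors = pd.Series([1.0, 1.0], index=["s0", "s1"])
        table = exact_test(m, factors, 0.0)

        def binom_p(za, z):
            pmf = np.array([stats.binom.pmf(k, z, 0.5) for k in range(z + 1)])
            lower, upper = pmf[: za + 1].sum(), pmf[za:].sum()
            return min(1.0, 2 * min(lower, upper))

        lib = arr.sum(axis=0)
        common = np.exp(np.mean(np.log(lib)))
        scaled = np.rint(arr * (common / lib)).astype(int)
        for i in range(3):
            za, zb = scaled[i]
            assert table["p_value"].iloc[i] == pytest.approx(
                binom_p(za, za + zb), rel=1e-9)

    def test_planted_log2fc_recovered_in_median(self):
        # keep planted features a minority so TMM's mostly-null assumption
        # holds; the 50 planted features stand in for replicate simulations
        planted = [(f"p{i}", 1.5) for i in range(50)]
        d = SynthDesign(n_features=450, planted_de=planted, baseline_mean=500,
                        nb_dispersion=0.1, rng_seed=5)
        m = synthetic.gen_count_matrix(d)
        table = exact_test(m, tmm_factors(m), 0.1)
        est = table.loc[[f"p{i}" for i in range(50)], "log2fc"]
        assert np.median(est) == pytest.approx(1.5, abs=0.2)

    def test_library_scaling_leaves_p_values_unchanged(self):
        rng = np.random.default_rng(6)
        arr = rng.poisson(200, size=(30, 6))
        m1 = _matrix(arr, 3)
        arr2 = arr.copy()
        arr2[:, 0] *= 4  # composition unchanged -> TMM absorbs the scale
        m2 = _matrix(arr2, 3)
        t1 = exact_test(m1, tmm_factors(m1), 0.05)
        t2 = exact_test(m2, tmm_factors(m2), 0.05)
        assert np.allclose(t1["p_value"], t2["p_value"], atol=0.02)


class TestBh:
    def test_single_p_value_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        # (0.01,0.02,0.03,0.04), m=4: adjusted = min over j>=i of p_j*m/j = 0.04
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1,
                    max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_dominance_and_permutation_invariance(self, ps):
        adj = bh_fdr(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        perm = np.random.default_rng(0).permutation(len(ps))
        adj_perm = bh_fdr(np.asarray(ps)[perm])
        assert np.allclose(adj_perm, adj[perm])


class TestSummary:
    def test_empty_table(self):
        assert de_summary(pd.DataFrame(columns=["log2fc", "fdr"])) == (0, 0, 0)

    def test_threshold_one_counts_everything(self):
        t = pd.DataFrame({"log2fc": [1.0, -2.0, 0.5], "fdr": [0.9, 0.5, 0.2]})
        assert de_summary(t, 1.0) == (3, 2, 1)
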