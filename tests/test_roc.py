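"""Empirical AUC and the DeLong paired comparison against independent oracles."""

import json
import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nvugib.roc import delong_paired_test, empirical_auc, roc_points


def pairwise_auc(cases, controls):
    """Oracle: exhaustive comparison over all case-control pairs."""
    c = np.asarray(cases)[:, None]
    k = np.asarray(controls)[None, :]
    return ((c > k).sum() + 0.5 * (c == k).sum()) / (c.shape[0] * k.shape[1])


def pairwise_placements(cases, controls):
    """Oracle placements: per-case fraction of controls beaten (ties half)."""
    v10 = np.array([
        np.mean([(c > k) + 0.5 * (c == k) for k in controls]) for c in cases
    ])
    v01 = np.array([
        np.mean([(k < c) + 0.5 * (k == c) for c in cases]) for k in controls
    ])
    return v10, v01


score_lists = st.lists(st.integers(0, 23), min_size=1, max_size=60)


class TestEmpiricalAuc:
    def test_perfect_separation(self):
        assert empirical_auc([1], [0]).auc == 1.0

    def test_identical_distributions(self):
        assert empirical_auc([0, 1], [0, 1]).auc == 0.5

    def test_study_aucs(self, scores):
        gbs, comb, hrel = scores
        auc_g = empirical_auc(gbs[hrel], gbs[~hrel]).auc
        auc_c = empirical_auc(comb[hrel], comb[~hrel]).auc
        assert auc_g == pytest.approx(1790 / 2800)
        assert round(auc_g, 3) == 0.639
        assert round(auc_c, 3) == 0.854

    def test_study_auc_cis_to_two_decimals(self, scores):
        gbs, comb, hrel = scores
        r_g = empirical_auc(gbs[hrel], gbs[~hrel])
        r_c = empirical_auc(comb[hrel], comb[~hrel])
        assert (round(r_g.ci_low, 2), round(r_g.ci_high, 2)) == (0.53, 0.75)
        assert (round(r_c.ci_low, 2), round(r_c.ci_high, 2)) == (0.79, 0.92)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(cases=score_lists, controls=score_lists)
    def test_matches_pairwise_oracle(self, cases, controls):
        res = empirical_auc(cases, controls)
        assert res.auc == pytest.approx(pairwise_auc(cases, controls))
        v10, v01 = pairwise_placements(cases, controls)
        assert res.case_placements == pytest.approx(v10)
        assert res.control_placements == pytest.approx(v01)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(cases=score_lists, controls=score_lists)
    def test_complement_symmetry(self, cases, controls):
        a = empirical_auc(cases, controls).auc
        b = empirical_auc(controls, cases).auc
        assert a + b == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            empirical_auc([], [1])

    def test_variance_matches_jackknife(self):
        """DeLong variance within 10% of the leave-one-out jackknife on
        moderate-size random inputs."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            cases = rng.integers(5, 24, size=60)
            controls = rng.integers(0, 20, size=80)
            res = empirical_auc(cases, controls)

            def jk(group, other, is_case):
                aucs = []
                for i in range(len(group)):
                    sub = np.delete(group, i)
                    a = pairwise_auc(sub, other) if is_case \
                        else pairwise_auc(other, sub)
                    aucs.append(a)
                aucs = np.array(aucs)
                m = len(group)
                return (m - 1) / m * ((aucs - aucs.mean()) ** 2).sum()

            var_jack = jk(cases, controls, True) + jk(controls, cases, False)
            assert res.variance == pytest.approx(var_jack, rel=0.10)


class TestDelongPairedTest:
    def test_identical_scores(self, scores):
        gbs, _, hrel = scores
        res = delong_paired_test(gbs, gbs, hrel)
        assert res.z == 0.0 and res.p_value == 1.0

    def test_study_comparison(self, scores):
        gbs, comb, hrel = scores
        res = delong_paired_test(gbs, comb, hrel)
        assert res.p_value < 0.001
        assert res.difference == pytest.approx(0.854 - 0.639, abs=5e-4)

    def test_matches_stratified_bootstrap(self):
        """On a small synthetic set the DeLong p agrees with a stratified
        bootstrap z-test (variance from 10^4 resamples) within Monte-Carlo
        error of that oracle."""
        rng = np.random.default_rng(11)
        hrel = np.array([True] * 7 + [False] * 13)
        a = np.where(hrel, rng.integers(6, 18, 20), rng.integers(2, 14, 20))
        b = np.clip(a + np.where(hrel, rng.integers(0, 7, 20),
                                 rng.integers(-3, 3, 20)), 0, 23)
        res = delong_paired_test(a, b, hrel)

        ev, ne = np.flatnonzero(hrel), np.flatnonzero(~hrel)
        diffs = []
        for _ in range(10_000):
            idx = np.concatenate([rng.choice(ev, len(ev)), rng.choice(ne, len(ne))])
            y = hrel[idx]
            d = (pairwise_auc(b[idx][y], b[idx][~y])
                 - pairwise_auc(a[idx][y], a[idx][~y]))
            diffs.append(d)
        from scipy.stats import norm
        z_boot = res.difference / np.std(diffs, ddof=1)
        p_boot = 2 * norm.sf(abs(z_boot))
        assert res.p_value == pytest.approx(p_boot, abs=0.1)

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            delong_paired_test([1, 2], [1, 2, 3], [True, False])

    def test_single_stratum_rejected(self):
        with pytest.raises(ValueError):
            delong_paired_test([1, 2], [1, 2], [True, True])


def test_roc_points_monotone(scores):
    gbs, _, hrel = scores
    pts = roc_points(gbs[hrel], gbs[~hrel])
    assert np.all(np.diff(pts[:, 0]) >= 0)
    assert pts[0].tolist() == [0.0, 0.0] and pts[-1].tolist() == [1.0, 1.0]


def test_agrees_with_r_proc_reference(scores, tmp_path):
    """Independent cross-check: pROC's DeLong implementation on the study
    cohort reproduces both AUCs and the paired-test p-value."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript unavailable; cross-check cannot run")
    gbs, comb, hrel = scores
    script = tmp_path / "check.R"
    script.write_text(
        "suppressMessages(library(pROC))\n"
        f"y <- c({','.join(str(int(v)) for v in hrel)})\n"
        f"g <- c({','.join(map(str, gbs))})\n"
        f"a <- c({','.join(map(str, comb))})\n"
        "rg <- roc(y, g, quiet=TRUE, direction='<')\n"
        "ra <- roc(y, a, quiet=TRUE, direction='<')\n"
        "tt <- roc.test(rg, ra, method='delong', paired=TRUE)\n"
        "cat(sprintf('{\"auc_g\": %.10f, \"auc_a\": %.10f, \"p\": %.10g}',\n"
        "    as.numeric(auc(rg)), as.numeric(auc(ra)), tt$p.value))\n"
    )
    out = subprocess.run(["Rscript", str(script)], capture_output=True,
                         text=True, check=True)
    ref = json.loads(out.stdout)
    res = delong_paired_test(gbs, comb, hrel)
    assert res.auc_a == pytest.approx(ref["auc_g"], abs=1e-9)
    assert res.auc_b == pytest.approx(ref["auc_a"], abs=1e-9)
    assert res.p_value == pytest.approx(ref["p"], rel=1e-6)
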