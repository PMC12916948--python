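"""Motion QC and behavioral statistics against hand-computed oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bindnet import dprime, exclude_high_motion, framewise_displacement, rm_anova_2x2, summarize_behavior
from bindnet.qc import PipelineAbort


class TestFramewiseDisplacement:
    def test_constant_trace_is_zero(self):
        fd, mean_fd = framewise_displacement(np.ones((10, 6)))
        np.testing.assert_array_equal(fd, 0.0)
        assert mean_fd == 0.0

    def test_single_translation_step(self):
        """0.1 mm step on one translation axis at frame k -> FD_k = 0.1."""
        trace = np.zeros((8, 6))
        trace[4:, 1] = 0.1
        fd, mean_fd = framewise_displacement(trace)
        assert fd[4] == pytest.approx(0.1)
        assert np.count_nonzero(fd) == 1
        assert mean_fd == pytest.approx(0.1 / 7)

    def test_single_rotation_step_uses_sphere_radius(self):
        """0.002 rad step -> 50 mm * 0.002 = 0.1 mm displacement."""
        trace = np.zeros((8, 6))
        trace[3:, 5] = 0.002
        fd, _ = framewise_displacement(trace, sphere_radius_mm=50)
        assert fd[3] == pytest.approx(0.1)

    @settings(max_examples=25, deadline=None)
    @given(st.floats(-5, 5, allow_nan=False), st.integers(0, 5))
    def test_invariant_to_constant_offsets(self, offset, column):
        rng = np.random.default_rng(0)
        trace = rng.normal(size=(12, 6)) * 0.05
        shifted = trace.copy()
        shifted[:, column] += offset
        fd_a, _ = framewise_displacement(trace)
        fd_b, _ = framewise_displacement(shifted)
        np.testing.assert_allclose(fd_a, fd_b, atol=1e-12)

    def test_rejects_nonfinite(self):
        trace = np.zeros((5, 6))
        trace[2, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            framewise_displacement(trace)


class TestExclusion:
    def test_low_motion_keeps_everyone(self):
        retained, log = exclude_high_motion({s: 0.1 for s in range(5)})
        assert retained == list(range(5))
        assert all("retained" in line for line in log)

    def test_high_motion_subject_excluded(self):
        retained, log = exclude_high_motion({0: 0.1, 1: 0.8, 2: 0.2})
        assert retained == [0, 2]
        assert any("subject 1" in line and "excluded" in line for line in log)

    def test_infinite_threshold_keeps_everyone(self):
        retained, _ = exclude_high_motion({0: 3.0, 1: 99.0}, threshold_mm=np.inf)
        assert retained == [0, 1]

    def test_empty_retained_set_aborts(self):
        with pytest.raises(PipelineAbort):
            exclude_high_motion({0: 1.0, 1: 2.0})


class TestDprime:
    def test_equal_rates_give_zero(self):
        assert dprime(10, 20, 10, 20) == pytest.approx(0.0)

    def test_clamp_oracle_value(self):
        # Phi^-1(0.75) - Phi^-1(0.25), frozen from the normal-quantile oracle
        assert dprime(15, 20, 5, 20, correction="clamp") == pytest.approx(
            1.3489795003921634
        )

    def test_loglinear_perfect_rates(self):
        # corrected rates 20.5/21 and 0.5/21 via the quantile oracle
        assert dprime(20, 20, 0, 20, correction="loglinear") == pytest.approx(
            3.9615047932945577
        )

    @settings(max_examples=40, deadline=None)
    @given(
        st.integers(0, 20), st.integers(0, 20), st.sampled_from(["loglinear", "clamp"])
    )
    def test_antisymmetric_under_hit_fa_swap(self, hits, fas, correction):
        a = dprime(hits, 20, fas, 20, correction)
        b = dprime(fas, 20, hits, 20, correction)
        assert a == pytest.approx(-b)

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            dprime(0, 0, 1, 10)


class TestSummarizeBehavior:
    @staticmethod
    def _trials(n=20, rt=1.0):
        rows = []
        for cond in ("either", "binding"):
            for size in (3, 6):
                for k in range(n):
                    change = k % 2 == 0
                    rows.append(
                        {
                            "subject": 0,
                            "condition": cond,
                            "set_size": size,
                            "is_change": change,
                            "response": "change" if change else "no_change",
                            "rt_seconds": rt,
                        }
                    )
        return pd.DataFrame(rows)

    def test_all_correct_constant_rt(self):
        out = summarize_behavior(self._trials(rt=1.0))
        assert (out["mean_rt_correct_seconds"] == 1.0).all()
        assert (out["hit_rate"] == 1.0).all()
        assert (out["fa_rate"] == 0.0).all()

    def test_composition_with_dprime_op(self):
        """Summary d' equals the dprime op applied to the same counts."""
        trials = self._trials()
        # flip 5 signal trials to misses and 5 noise to false alarms in one cell
        cell = (trials["condition"] == "either") & (trials["set_size"] == 3)
        sig_idx = trials[cell & trials["is_change"]].index[:5]
        noi_idx = trials[cell & ~trials["is_change"]].index[:5]
        trials.loc[sig_idx, "response"] = "no_change"
        trials.loc[noi_idx, "response"] = "change"
        out = summarize_behavior(trials)
        row = out[(out["condition"] == "either") & (out["set_size"] == 3)].iloc[0]
        assert row["dprime"] == pytest.approx(dprime(5, 10, 5, 10))

    def test_empty_cell_rejected(self):
        trials = self._trials()
        trials = trials[~((trials["condition"] == "binding") & trials["is_change"])]
        with pytest.raises(ValueError, match="lacks signal"):
            summarize_behavior(trials)


class TestRmAnova2x2:
    def test_flat_data_gives_zero_f(self):
        out = rm_anova_2x2(np.full((5, 2, 2), 3.0))
        assert (out["F"] == 0.0).all()

    def test_invariant_to_subject_offsets(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(8, 2, 2))
        shifted = y + rng.normal(size=(8, 1, 1)) * 10
        a = rm_anova_2x2(y)
        b = rm_anova_2x2(shifted)
        np.testing.assert_allclose(a["F"], b["F"], rtol=1e-9)

    def test_matches_sums_of_squares_oracle(self):
        """4-subject worked dataset against a hand-computed SS decomposition."""
        y = np.array(
            [
                [[2.0, 1.0], [3.0, 2.0]],
                [[2.5, 1.5], [3.5, 2.0]],
                [[1.8, 1.2], [2.6, 1.9]],
                [[2.2, 0.9], [3.1, 2.3]],
            ]
        )
        out = rm_anova_2x2(y).set_index("effect")

        # independent oracle: F for a df-1 within effect = squared paired t
        # on the corresponding within-subject contrast
        def f_from_contrast(c):
            n = len(c)
            t = c.mean() / (c.std(ddof=1) / np.sqrt(n))
            return t**2

        contrast_a = y[:, 1, :].mean(axis=1) - y[:, 0, :].mean(axis=1)
        contrast_b = y[:, :, 1].mean(axis=1) - y[:, :, 0].mean(axis=1)
        contrast_ab = (y[:, 1, 1] - y[:, 1, 0]) - (y[:, 0, 1] - y[:, 0, 0])
        assert out.loc["condition", "F"] == pytest.approx(f_from_contrast(contrast_a))
        assert out.loc["set_size", "F"] == pytest.approx(f_from_contrast(contrast_b))
        assert out.loc["condition x set_size", "F"] == pytest.approx(
            f_from_contrast(contrast_ab)
        )

    def test_matches_pingouin(self):
        """Cross-check F, p and partial eta squared against pingouin.rm_anova."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        y = rng.normal(size=(10, 2, 2)) + np.array([[0.5, 0.0], [0.9, 0.1]])
        out = rm_anova_2x2(y).set_index("effect")
        rows = []
        for s in range(10):
            for ai, a in enumerate(("e", "b")):
                for bi, b in enumerate((3, 6)):
                    rows.append({"subject": s, "A": a, "B": b, "y": y[s, ai, bi]})
        df = pd.DataFrame(rows)
        ref = pg.rm_anova(
            data=df, dv="y", within=["A", "B"], subject="subject", detailed=True
        ).set_index("Source")
        # pingouin reports generalized eta^2 (a different effect size), so the
        # cross-check covers F and p only
        for mine, theirs in (("condition", "A"), ("set_size", "B"), ("condition x set_size", "A * B")):
            assert out.loc[mine, "F"] == pytest.approx(ref.loc[theirs, "F"], rel=1e-6)
            assert out.loc[mine, "p"] == pytest.approx(ref.loc[theirs, "p_unc"], rel=1e-6)

    def test_incomplete_design_rejected(self):
        y = np.full((4, 2, 2), 1.0)
        y[2, 1, 0] = np.nan
        with pytest.raises(ValueError, match="missing cell"):
            rm_anova_2x2(y)
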