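"""Detection, Pearson correlation, BH adjustment, and the DE stand-in."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lncregnet.expression import (
    bh_adjust,
    de_call,
    de_features,
    detect_expressed,
    pcc,
    stage_specific,
)
from lncregnet.io_formats import ExpressionMatrix


def _matrix(values, samples=None, stages=None):
    df = pd.DataFrame(values).T if isinstance(values, dict) else values
    samples = samples or list(df.columns)
    stage_of = {s: s.rsplit("-", 1)[0] for s in samples}
    stages = stages or list(dict.fromkeys(stage_of.values()))
    return ExpressionMatrix(df, stage_of, stages)


class TestDetection:
    def test_zero_never_detected_and_threshold(self):
        m = _matrix(
            pd.DataFrame(
                {"A-1": [0.0, 0.3], "A-2": [0.0, 0.3], "A-3": [0.0, 0.3]},
                index=["f0", "f1"],
            )
        )
        assert detect_expressed(m, "A", 0.0) == {"f1"}
        assert detect_expressed(m, "A", 0.1) == {"f1"}
        assert detect_expressed(m, "A", 0.3) == set()  # strict >

    def test_unknown_stage(self):
        m = _matrix(pd.DataFrame({"A-1": [1.0]}, index=["f"]))
        with pytest.raises(KeyError):
            detect_expressed(m, "B")

    def test_detected_count_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            rng.gamma(1.0, 2.0, size=(50, 3)),
            index=[f"f{i}" for i in range(50)],
            columns=["A-1", "A-2", "A-3"],
        )
        m = _matrix(df)
        sizes = [len(detect_expressed(m, "A", t)) for t in (0.0, 0.1, 0.5, 1.0, 5.0)]
        assert sizes == sorted(sizes, reverse=True)


class TestPcc:
    @pytest.mark.parametrize(
        "x,y,r",
        [
            ([1, 2, 3, 4, 5], [2, 4, 6, 8, 10], 1.0),
            ([1, 2, 3, 4, 5], [5, 4, 3, 2, 1], -1.0),
            ([1, 2, 3, 4, 5], [1, 3, 2, 5, 4], 0.8),
        ],
    )
    def test_known_values(self, x, y, r):
        assert pcc(x, y).r == pytest.approx(r, abs=1e-12)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(5)
        for n in (5, 8, 15):
            x, y = rng.normal(size=n), rng.normal(size=n)
            res = pcc(x, y)
            # independent route: raw summation formula + t transform
            sx, sy, sxy = x.sum(), y.sum(), (x * y).sum()
            sxx, syy = (x * x).sum(), (y * y).sum()
            r = (n * sxy - sx * sy) / np.sqrt((n * sxx - sx**2) * (n * syy - sy**2))
            t = r * np.sqrt((n - 2) / (1 - r * r))
            p = 2 * stats.t.sf(abs(t), n - 2)
            assert res.r == pytest.approx(r, abs=1e-12)
            assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pcc([1, 1, 1, 1], [1, 2, 3, 4])

    def test_scale_shift_invariance(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=6), rng.normal(size=6)
        base = pcc(x, y).r
        assert pcc(3 * x + 7, y).r == pytest.approx(base, abs=1e-12)
        assert pcc(-2 * x + 1, y).r == pytest.approx(-base, abs=1e-12)

    def test_critical_value_at_n5(self):
        """With n=5 the two-sided 1% critical value of |r| is ~0.9587."""
        t_crit = stats.t.ppf(0.995, 3)
        r_crit = t_crit / np.sqrt(3 + t_crit**2)
        assert r_crit == pytest.approx(0.9587, abs=5e-4)
        x = np.arange(5.0)
        e = np.array([1.0, -1, 0, 1, -1]) - 0.0
        e -= e.mean()
        e -= (e @ (x - x.mean())) / ((x - x.mean()) @ (x - x.mean())) * (x - x.mean())
        for target, below in [(r_crit + 1e-3, True), (r_crit - 1e-3, False)]:
            xc = x - x.mean()
            y = target * xc / np.linalg.norm(xc) + np.sqrt(1 - target**2) * e / np.linalg.norm(e)
            res = pcc(x, y)
            assert res.r == pytest.approx(target, abs=1e-9)
            assert (res.p_value < 0.01) is below


class TestBH:
    def test_step_up_hand_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_definition_on_random_p(self):
        rng = np.random.default_rng(4)
        p = rng.random(25)
        q = bh_adjust(p)
        # step-up definition computed independently
        order = np.argsort(p)
        m = len(p)
        raw = p[order] * m / np.arange(1, m + 1)
        exp = np.minimum.accumulate(raw[::-1])[::-1]
        exp_full = np.empty(m)
        exp_full[order] = np.minimum(exp, 1.0)
        assert np.allclose(q, exp_full, atol=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.001, 1.0), min_size=2, max_size=12), st.integers(0, 11))
    def test_shrinking_a_p_never_loses_rejections(self, ps, idx):
        ps = list(ps)
        idx = idx % len(ps)
        before = int((bh_adjust(ps) < 0.05).sum())
        ps[idx] = ps[idx] / 10
        after = int((bh_adjust(ps) < 0.05).sum())
        assert after >= before


class TestDECall:
    def _planted_matrix(self, n_planted=200, n_null=200, fold=8.0, sd=0.05, seed=13):
        rng = np.random.default_rng(seed)
        rows, names = [], []
        for i in range(n_planted + n_null):
            base = 4.0
            treat = base * fold if i < n_planted else base
            vals = np.concatenate(
                [
                    base * 2 ** rng.normal(0, sd, 3),
                    treat * 2 ** rng.normal(0, sd, 3),
                ]
            )
            rows.append(vals)
            names.append(f"f{i}")
        df = pd.DataFrame(
            rows, index=names,
            columns=["control-1", "control-2", "control-3", "T1-1", "T1-2", "T1-3"],
        )
        return _matrix(df)

    def test_identical_values_never_de(self):
        df = pd.DataFrame(
            [[3.0] * 6], index=["f"],
            columns=["control-1", "control-2", "control-3", "T1-1", "T1-2", "T1-3"],
        )
        recs = de_call(_matrix(df), "control", "T1")
        assert recs[0].p_value == 1.0 and recs[0].q_value == 1.0

    def test_planted_eightfold_recovery(self):
        """>=95% of 200 planted 8-fold shifts called DE at q<0.05, 3v3."""
        m = self._planted_matrix()
        recs = de_call(m, "control", "T1")
        de = de_features(recs, 0.05)
        planted = {f"f{i}" for i in range(200)}
        assert len(de & planted) / 200 >= 0.95
        # direction of planted features is up
        up = {r.feature_id for r in recs if r.direction == "up"}
        assert planted <= up

    def test_replicate_requirement(self):
        df = pd.DataFrame(
            [[1.0, 2.0]], index=["f"], columns=["control-1", "T1-1"]
        )
        with pytest.raises(ValueError, match="replicates"):
            de_call(_matrix(df), "control", "T1")


class TestStageSpecific:
    def test_exclusive_sets(self):
        det = {
            "control": {"a", "b"},
            "T1": {"b", "c"},
            "T12": {"d"},
        }
        ss = stage_specific(det)
        assert ss == {"control": {"a"}, "T1": {"c"}, "T12": {"d"}}
        assert sum(len(v) for v in ss.values()) <= len({"a", "b", "c", "d"})
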