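"""Censoring substitution, class sums, Mann-Whitney, BH and correlations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from hmolink import (
    class_sums,
    correlation_matrix,
    mann_whitney,
    substitute_censored,
)
from hmolink.hmotable import COLUMNS, HMOTable
from hmolink.panel import DEFAULT_PANEL
from hmolink.stats import benjamini_hochberg, log_transform


def tiny_table(records):
    return HMOTable(pd.DataFrame(records, columns=COLUMNS))


class TestSubstituteCensored:
    def test_half_loq(self):
        t = tiny_table([("s1", 3, "2'FL", 12.0, "below_loq")])
        out = substitute_censored(t, "half_loq")
        assert out["value"].iloc[0] == 10.0  # LoQ 20 / 2

    def test_quantified_untouched(self):
        t = tiny_table([("s1", 3, "2'FL", 1500.0, "quantified")])
        for policy in ("zero", "half_loq", "loq_over_sqrt2"):
            assert substitute_censored(t, policy)["value"].iloc[0] == 1500.0

    def test_unknown_policy(self):
        t = tiny_table([("s1", 3, "2'FL", 1.0, "quantified")])
        with pytest.raises(ValueError, match="policy"):
            substitute_censored(t, "drop")

    def test_zero_policy_log_guarded_by_offset(self):
        t = tiny_table([("s1", 3, "2'FL", 0.0, "below_lod")])
        v = substitute_censored(t, "zero")["value"]
        logged = log_transform(v)
        assert np.isfinite(logged).all()
        assert logged[0] == pytest.approx(math.log(1.0))


class TestClassSums:
    def test_partition_6_13_5(self):
        p = DEFAULT_PANEL
        sizes = {c: len(p.members(c)) for c in ("core", "fucosylated", "sialylated")}
        assert sizes == {"core": 6, "fucosylated": 13, "sialylated": 5}
        assert len(p.analytes) == 24
        members = [a for c in sizes for a in p.members(c)]
        assert sorted(members) == sorted(p.analytes)

    def test_sialylated_arithmetic(self):
        recs = [("s1", 3, a, 0.0, "below_lod") for a in DEFAULT_PANEL.analytes
                if a not in ("3'SL", "6'SL", "LSTb", "LSTc", "DSLNT")]
        recs += [("s1", 3, "3'SL", 200.0, "quantified"),
                 ("s1", 3, "6'SL", 300.0, "quantified"),
                 ("s1", 3, "LSTb", 50.0, "quantified"),
                 ("s1", 3, "LSTc", 150.0, "quantified"),
                 ("s1", 3, "DSLNT", 300.0, "quantified")]
        out = class_sums(tiny_table(recs), policy="zero")
        assert out["sialylated"].iloc[0] == 1000.0
        assert out["core"].iloc[0] == 0.0

    def test_total_is_sum_of_classes(self, small_cohort):
        out = class_sums(small_cohort.hmo, policy="zero")
        assert np.allclose(
            out["total"], out["core"] + out["fucosylated"] + out["sialylated"]
        )

    def test_missing_analyte_raises(self):
        recs = [("s1", 3, a, 1.0, "quantified") for a in DEFAULT_PANEL.analytes[:-1]]
        with pytest.raises(ValueError, match=DEFAULT_PANEL.analytes[-1]):
            class_sums(tiny_table(recs))


def mann_whitney_enumeration(a, b):
    """Exact two-sided p by full enumeration of group assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    n_a = len(a)

    def u_stat(xs, ys):
        return sum(1.0 for x in xs for y in ys if x > y) + 0.5 * sum(
            1 for x in xs for y in ys if x == y
        )

    u_obs = u_stat(a, b)
    mean_u = n_a * len(b) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(xs, ys) - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return u_stat(a, b), count / total


class TestMannWhitney:
    def test_separated_groups_exact(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6], mode="exact")
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 arrangements as extreme

    def test_identical_groups_approx_p_near_one(self):
        u, p = mann_whitney([1, 2, 2, 3], [1, 2, 2, 3], mode="normal_approx")
        assert p >= 0.99

    def test_u_plus_uprime(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 10))
            b = rng.normal(size=rng.integers(2, 10))
            u_a, _ = mann_whitney(a, b, mode="normal_approx")
            u_b, _ = mann_whitney(b, a, mode="normal_approx")
            assert u_a + u_b == pytest.approx(len(a) * len(b))

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(200):
            n_a = int(rng.integers(1, 5))
            n_b = int(rng.integers(1, 5))
            vals = rng.choice(100, size=n_a + n_b, replace=False).astype(float)
            a, b = vals[:n_a], vals[n_a:]
            u, p = mann_whitney(a, b, mode="exact")
            u_ref, p_ref = mann_whitney_enumeration(a, b)
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref, abs=1e-9)


class TestBenjaminiHochberg:
    def direct_bh(self, p):
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p)
        q = np.empty(m)
        prev = 1.0
        for rank_from_end, i in enumerate(order[::-1]):
            rank = m - rank_from_end
            prev = min(prev, p[i] * m / rank)
            q[i] = prev
        return q

    def test_matches_direct_formula(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(benjamini_hochberg(p), self.direct_bh(p))

    def test_monotone_in_raw_p(self, rng):
        p = np.sort(rng.random(25))
        q = benjamini_hochberg(p)
        assert (np.diff(q) >= -1e-12).all()


class TestCorrelationMatrix:
    def test_duplicate_and_negated_columns(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": x, "c": -x, "d": rng.normal(size=50)})
        r, q, mask = correlation_matrix(df)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert r.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(r.to_numpy(), r.to_numpy().T)
        assert np.allclose(np.diag(r), 1.0)

    def test_constant_column_reported_missing(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=30), "b": np.ones(30)})
        r, q, mask = correlation_matrix(df)
        assert np.isnan(r.loc["a", "b"])
        assert not mask.loc["a", "b"]

    def test_fut2_analytes_positively_intercorrelated(self, small_cohort):
        """FUT2-dependent analytes correlate with each other and against the
        FUT3 side, mirroring the secretor/Lewis antagonism."""
        from hmolink.stats import log_concentration_matrix

        logm = log_concentration_matrix(small_cohort.hmo, month=3)
        r, _, _ = correlation_matrix(logm)
        fut2 = ["LDFT", "LNDFH-I", "DFLNHa", "2'FL", "LNFP-I"]
        for a, b in itertools.combinations(fut2, 2):
            assert r.loc[a, b] > 0.3
        for a in ("2'FL", "LNFP-I"):
            for b in ("3FL", "LNFP-II"):
                assert r.loc[a, b] < 0
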