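"""Generator properties: MAF convergence, LD structure, status gating and
the deterministic fixture's printed counts."""

import numpy as np
import pandas as pd
import pytest

from hmolink import (
    CohortSimParams,
    call_statuses,
    compute_maf,
    simulate_cohort,
    simulate_genotypes,
    simulate_score_cohort,
)
from hmolink.panel import DEFAULT_PANEL, FUT2_DEPENDENT
from hmolink.reference import CLASS_SLOPES
from hmolink.simulate import max_attainable_r2
from hmolink.stats import class_sums
from hmolink.variants import VariantSpec


def haplotype_r2(d1: np.ndarray, d2: np.ndarray) -> float:
    """Composite r^2 from dosage correlation (exact for pooled haplotypes
    drawn independently, which is how the generator samples)."""
    return float(np.corrcoef(d1, d2)[0, 1] ** 2)


class TestSimulateGenotypes:
    def test_maf_converges_within_3_se(self):
        params = CohortSimParams(n_samples=10_000, seed=3)
        g = simulate_genotypes(params)
        for rsid, target in [("rs601338", 0.3553), ("rs812936", 0.2007)]:
            se = np.sqrt(target * (1 - target) / (2 * params.n_samples))
            assert abs(compute_maf(g, rsid) - target) < 3 * se

    def test_same_seed_identical(self):
        a = simulate_genotypes(CohortSimParams(n_samples=500, seed=9))
        b = simulate_genotypes(CohortSimParams(n_samples=500, seed=9))
        assert a.equals(b)

    def test_within_block_r2_exceeds_target(self):
        g = simulate_genotypes(CohortSimParams(n_samples=5_000, seed=5))
        d = g.dosages
        # FUT2 stop-gain pair shares a block (equal MAFs)
        assert haplotype_r2(d["rs601338"], d["rs681343"]) > 0.8
        # FUT3 pair with close MAFs shares a block
        assert haplotype_r2(d["rs812936"], d["rs778986"]) > 0.8

    def test_maf_validation(self):
        bad = [VariantSpec("rs1", "FUT2", 1, "A", "G", 0.0, "missense")]
        with pytest.raises(ValueError, match="MAF"):
            CohortSimParams(n_samples=10, variant_specs=bad)

    def test_unreachable_ld_target_raises_with_diagnostic(self):
        specs = [
            VariantSpec("rsA", "FUT2", 1, "A", "G", 0.45, "missense"),
            VariantSpec("rsB", "FUT2", 2, "C", "T", 0.01, "missense"),
        ]
        params = CohortSimParams(
            n_samples=10, variant_specs=specs, blocks={"FUT2": [["rsA", "rsB"]]}
        )
        with pytest.raises(ValueError, match="max attainable"):
            simulate_genotypes(params)

    def test_max_attainable_r2_formula(self):
        # equal MAFs are fully linkable; highly unequal MAFs are not
        assert max_attainable_r2(0.3, 0.3) == pytest.approx(1.0)
        assert max_attainable_r2(0.01, 0.45) < 0.05


class TestSimulateHMO:
    def test_nonsecretors_below_loq_for_fut2_analytes(self, small_cohort):
        truth = small_cohort.truth.set_index("sample_id")
        se_neg = truth.index[truth["secretor"] == "Se-"]
        df = small_cohort.hmo.df
        sub = df[df["sample_id"].isin(se_neg) & df["analyte"].isin(FUT2_DEPENDENT)]
        assert len(sub) > 0
        assert (sub["flag"] == "below_lod").all()
        assert (sub["conc_mg_per_L"] == 0).all()

    def test_a_tetra_requires_secretor_and_blood_group_a(self, small_cohort):
        truth = small_cohort.truth.set_index("sample_id")
        df = small_cohort.hmo.df
        at = df[df["analyte"] == "A-tetra"].set_index("sample_id")
        for sid, row in at.iterrows():
            ok = truth.loc[sid, "secretor"] == "Se+" and truth.loc[sid, "blood_group"] == "A"
            if row["conc_mg_per_L"] > 0:
                assert ok

    def test_degenerate_generator_identical_within_group(self):
        params = CohortSimParams(
            n_samples=60, seed=1, residual_sd=0.0, dosage_effect=0.0,
            time_slopes={}, class_slopes={k: 0.0 for k in CLASS_SLOPES},
        )
        cohort = simulate_cohort(params)
        truth = cohort.truth.set_index("sample_id")
        df = cohort.hmo.df
        df["group"] = df["sample_id"].map(truth["milk_group"])
        df["bg"] = df["sample_id"].map(truth["blood_group"])
        for (_, _, _, analyte), sub in df.groupby(["group", "bg", "month", "analyte"]):
            assert sub["conc_mg_per_L"].nunique() == 1

    def test_3fl_higher_in_nonsecretor_groups(self):
        cohort = simulate_cohort(CohortSimParams(n_samples=2_000, seed=17))
        truth = cohort.truth.set_index("sample_id")
        df = cohort.hmo.df
        sub = df[(df["analyte"] == "3FL") & (df["month"] == 3)].copy()
        sub["group"] = sub["sample_id"].map(truth["milk_group"])
        med24 = sub.loc[sub["group"].isin([2, 4]), "conc_mg_per_L"].median()
        med13 = sub.loc[sub["group"].isin([1, 3]), "conc_mg_per_L"].median()
        assert med24 > med13

    def test_truth_equals_rule_classifier(self, small_cohort):
        calls = {c.sample_id: c.milk_group for c in call_statuses(small_cohort.genotypes)}
        truth = small_cohort.truth
        assert all(calls[s] == g for s, g in zip(truth["sample_id"], truth["milk_group"]))

    def test_zero_noise_class_sums_decay_at_class_slopes(self):
        params = CohortSimParams(
            n_samples=40, seed=2, residual_sd=0.0, dosage_effect=0.0,
            uniform_class_slopes=True,
            panel=DEFAULT_PANEL.without_censoring(),
        )
        cohort = simulate_cohort(params)
        sums = class_sums(cohort.hmo, params.panel, policy="zero")
        wide = sums.set_index(["sample_id", "month"])
        for cls, slope in CLASS_SLOPES.items():
            s3 = wide.xs(3, level="month")[cls]
            s12 = wide.xs(12, level="month")[cls]
            ratio = np.log(s12 / s3.loc[s12.index])
            assert np.allclose(ratio, slope * 9, atol=1e-9)

    def test_reproducible_full_cohort(self):
        a = simulate_cohort(CohortSimParams(n_samples=50, seed=7))
        b = simulate_cohort(CohortSimParams(n_samples=50, seed=7))
        assert a.genotypes.equals(b.genotypes)
        pd.testing.assert_frame_equal(a.hmo.df, b.hmo.df)
        pd.testing.assert_frame_equal(a.truth, b.truth)


class TestFixtureCohort:
    def test_total_samples(self, fixture_cohort):
        assert fixture_cohort.genotypes.n_samples == 152

    def test_18_rs601338_homozygotes(self, fixture_cohort):
        d = fixture_cohort.genotypes.dosages["rs601338"]
        assert int((d == 2).sum()) == 18

    def test_rs601338_allele_count_and_maf(self, fixture_cohort):
        d = fixture_cohort.genotypes.dosages["rs601338"]
        assert int(d.sum()) == 108  # 18*2 + 72*1
        assert round(compute_maf(fixture_cohort.genotypes, "rs601338"), 4) == 0.3553

    def test_lewis_homozygote_counts_disjoint(self, fixture_cohort):
        d = fixture_cohort.genotypes.dosages
        hom_812936 = set(d.index[d["rs812936"] == 2])
        hom_28362459 = set(d.index[d["rs28362459"] == 2])
        assert len(hom_812936) == 7
        assert len(hom_28362459) == 2
        assert not (hom_812936 & hom_28362459)

    def test_all_mafs_round_to_panel(self, fixture_cohort):
        g = fixture_cohort.genotypes
        for rsid, spec in g.variants.items():
            # integer-rounded allele counts: within half an allele of target
            assert abs(compute_maf(g, rsid) - spec.maf) <= 0.5 / 304 + 1e-9

    def test_hmo_consistent_with_genetic_status(self, fixture_cohort):
        truth = fixture_cohort.truth.set_index("sample_id")
        df = fixture_cohort.hmo.df
        se_neg = truth.index[truth["secretor"] == "Se-"]
        two_fl = df[(df["analyte"] == "2'FL") & df["sample_id"].isin(se_neg)]
        assert (two_fl["flag"] == "below_lod").all()


class TestScoreCohort:
    def test_secretor_conditioning(self):
        X, y = simulate_score_cohort(500, seed=1)
        assert (X["rs601338"] < 2).all()

    def test_response_follows_linear_model(self):
        X, y = simulate_score_cohort(4_000, seed=2, residual_sd=0.0)
        from hmolink.reference import SCORE_BETAS
        eta = np.log(2500.0) + X.to_numpy() @ np.array(
            [SCORE_BETAS[c] for c in X.columns]
        )
        assert np.allclose(y.to_numpy(), eta)
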