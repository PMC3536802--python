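import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from mirdx.ct_data import aggregate_replicates
from mirdx.diagnostics import roc_curve
from mirdx.quantification import combined_score
from mirdx.synth_cohort import (AssayEffect, SynthDesign, SynthDesignError,
                                default_blind_design, default_discovery_design,
                                default_training_design,
                                default_validation_design, generate_discovery,
                                generate_training, generate_validation,
                                planted_truth)


def combined_log2_scores(table):
    scores, _ = combined_score(table)
    groups = (table.records.drop_duplicates("sample_id")
              .set_index("sample_id")["group"])
    return pd.Series({s.sample_id: s.log2_score for s in scores}), groups


class TestDeterminism:
    @pytest.mark.parametrize("gen,design", [
        (generate_discovery, default_discovery_design()),
        (generate_training, default_training_design()),
    ])
    def test_same_seed_identical_tables(self, gen, design):
        a = gen(design, seed=5)
        b = gen(design, seed=5)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_different_seeds_differ(self):
        a = generate_discovery(default_discovery_design(), seed=1)
        b = generate_discovery(default_discovery_design(), seed=2)
        assert not a.records["ct"].equals(b.records["ct"])

    def test_validation_meta_deterministic(self):
        d = default_validation_design()
        t1, m1 = generate_validation(d, seed=9)
        t2, m2 = generate_validation(d, seed=9)
        pd.testing.assert_frame_equal(m1.records, m2.records)


class TestNoiselessLimit:
    def test_fold_changes_exact(self):
        """With all noise off, plasma fold changes equal 2^(-shift) exactly."""
        design = dataclasses.replace(
            default_discovery_design(),
            noise_sd=0.0, replicate_sd=0.0, reference_sd=0.0,
            patient_effect_sd=0.0)
        from mirdx.pipeline import run_discovery
        table = generate_discovery(design, seed=1)
        _, log = run_discovery(table)
        folds = log.set_index("assay")["plasma_fold"]
        assert folds["miR-451"] == pytest.approx(4.0, rel=1e-9)
        assert folds["miR-145"] == pytest.approx(0.25, rel=1e-9)
        assert folds["ctl-01"] == pytest.approx(1.0, rel=1e-9)


class TestDesignValidation:
    def test_negative_sd_rejected(self):
        with pytest.raises(SynthDesignError):
            SynthDesign(assays=(AssayEffect("m"),), group_sizes={"BC": 5},
                        noise_sd=-1.0)

    def test_recovery_out_of_range_rejected(self):
        with pytest.raises(SynthDesignError):
            SynthDesign(assays=(AssayEffect("m"),), group_sizes={"BC": 5},
                        postop_recovery=1.5)

    def test_training_generator_requires_paired(self):
        with pytest.raises(SynthDesignError, match="paired"):
            generate_training(default_discovery_design())


class TestReferenceStability:
    def test_reference_group_means_stable(self):
        """RNU6B means differ by < 0.1 Ct between groups at n >= 100."""
        design = dataclasses.replace(default_validation_design(),
                                     group_sizes={"BC": 120, "N": 100})
        table, _ = generate_validation(design, seed=4)
        agg, _ = aggregate_replicates(table)
        ref = agg.records[agg.records["assay"] == "RNU6B"]
        means = ref.groupby("group")["ct"].mean()
        assert means.max() - means.min() < 0.1


class TestPlantedTruth:
    def test_one_cycle_shift_doubles(self):
        design = SynthDesign(assays=(AssayEffect("m", plasma_shift=-1.0),),
                             group_sizes={"BC": 5, "N": 5})
        t = planted_truth(design)
        assert t.expected_plasma_fold["m"] == pytest.approx(2.0)

    def test_combined_auc_closed_form(self):
        t = planted_truth(default_validation_design())
        assert t.combined_log2_separation == pytest.approx(3.5)
        assert t.expected_combined_auc == pytest.approx(norm.cdf(1.75), abs=1e-9)
        assert t.expected_combined_auc == pytest.approx(0.9599, abs=0.001)

    def test_zero_shift_auc_half(self):
        design = SynthDesign(assays=(AssayEffect("miR-451"),
                                     AssayEffect("miR-145")),
                             group_sizes={"BC": 5, "N": 5})
        assert planted_truth(design).expected_combined_auc == pytest.approx(0.5)


class TestMonteCarloConvergence:
    def test_empirical_auc_error_shrinks_at_root_n(self):
        """RMSE of the empirical combined-score AUC scales ~ 1/sqrt(n)."""
        truth = planted_truth(default_validation_design()).expected_combined_auc

        def rmse(n, seeds):
            errs = []
            for seed in seeds:
                design = dataclasses.replace(
                    default_validation_design(),
                    group_sizes={"BC": n, "N": n})
                table, _ = generate_validation(design, seed=seed)
                scores, groups = combined_log2_scores(table)
                y = (groups.loc[scores.index] == "BC").astype(int).to_numpy()
                errs.append(roc_curve(scores.to_numpy(), y).auc - truth)
            return float(np.sqrt(np.mean(np.square(errs))))

        r_small = rmse(25, range(12))
        r_large = rmse(400, range(12))
        # 16x the samples: RMSE ratio should be near 4, generously bracketed
        assert r_small / r_large == pytest.approx(4.0, abs=2.5)


class TestValidationCohortStructure:
    def test_group_sizes_and_stages(self):
        table, meta = generate_validation(default_validation_design(), seed=2)
        groups = (table.records.drop_duplicates("sample_id")
                  .groupby("group").size())
        assert groups["BC"] == 170 and groups["N"] == 100
        assert groups[["CRC", "EC", "GC", "HCC", "LC"]].sum() == 95
        m = meta.records
        bc_stages = m.loc[m["stage"] != "none", "stage"]
        assert set(bc_stages) <= {"DCIS", "I", "II", "III", "IV"}
        # DCIS grades only on DCIS samples (enforced by SampleMeta too)
        assert (m.loc[m["dcis_grade"] != "none", "stage"] == "DCIS").all()

    def test_lung_cancer_score_planted_below_normal(self):
        table, _ = generate_validation(default_validation_design(), seed=6)
        scores, groups = combined_log2_scores(table)
        lc = scores[groups.loc[scores.index] == "LC"]
        n = scores[groups.loc[scores.index] == "N"]
        assert lc.median() < n.median()

    def test_blind_design_sizes(self):
        table, _ = generate_validation(default_blind_design(), seed=3,
                                       sample_prefix="B")
        groups = (table.records.drop_duplicates("sample_id")
                  .groupby("group").size())
        assert groups["BC"] == 70 and groups["N"] == 50


class TestTrainingStructure:
    def test_preop_postop_share_patients(self):
        table = generate_training(default_training_design(), seed=8)
        df = table.records
        pre = set(df.loc[df["timepoint"] == "preop", "sample_id"])
        post = set(df.loc[df["timepoint"] == "postop", "sample_id"])
        assert pre == post and len(pre) == 15

    def test_postop_recovery_reduces_tumor_derived_shift(self):
        """miR-451 Ct rises post-op by recovery*|shift| on average."""
        design = default_training_design()
        table = generate_training(design, seed=10)
        agg, _ = aggregate_replicates(table.subset(assay="miR-451", group="BC"))
        df = agg.records.pivot(index="sample_id", columns="timepoint",
                               values="ct")
        mean_rise = (df["postop"] - df["preop"]).mean()
        assert mean_rise == pytest.approx(0.8 * 2.0, abs=0.8)
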