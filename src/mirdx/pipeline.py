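"""End-to-end orchestration of the four study stages.

discovery -> training -> validation -> blind validation.  Each stage is a
pure function from tables (plus the previous stage's output) to result
objects; the CLI is a thin shell over these.  Blind validation applies a
*frozen* model artifact — marker pair, score orientation, cutoff — with no
refitting, so the held-out cohort cannot leak into the decision rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .combo_select import ComboResult, fit_logistic, select_best_combination
from .ct_data import CtTable, SampleMeta
from .diagnostics import DiagnosticReport, evaluate_scores
from .marker_screen import (MarkerDecision, concordance_filter, training_screen)
from .quantification import DEFAULT_REFERENCE, combined_score
from .rank_tests import TestResult, kruskal_wallis, mann_whitney


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class ModelArtifact:
    """Frozen decision rule carried from validation into blind validation."""

    markers: tuple[str, ...]
    numerator_assay: str
    denominator_assay: str
    cutoff: float          # on the log2 combined score
    higher_is_positive: bool = True

    def to_json(self) -> str:
        return json.dumps({"markers": list(self.markers),
                           "numerator_assay": self.numerator_assay,
                           "denominator_assay": self.denominator_assay,
                           "cutoff": self.cutoff,
                           "higher_is_positive": self.higher_is_positive},
                          indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelArtifact":
        d = json.loads(text)
        return cls(markers=tuple(d["markers"]),
                   numerator_assay=d["numerator_assay"],
                   denominator_assay=d["denominator_assay"],
                   cutoff=float(d["cutoff"]),
                   higher_is_positive=bool(d["higher_is_positive"]))


def _delta_ct_matrix(table: CtTable, reference_assay: str) -> pd.DataFrame:
    """Sample × assay ΔCt matrix from one aggregation pass (NaN where either
    the target or the reference is undetected)."""
    from .ct_data import aggregate_replicates
    agg, _ = aggregate_replicates(table)
    pivot = agg.records.pivot(index="sample_id", columns="assay", values="ct")
    if reference_assay not in pivot.columns:
        raise PipelineError(f"reference assay {reference_assay!r} absent")
    return pivot.drop(columns=reference_assay).sub(pivot[reference_assay],
                                                   axis=0)


def _group_folds(table: CtTable, case_subset: dict, control_subset: dict,
                 reference_assay: str) -> dict[str, float]:
    """Per-assay 2^−ΔΔCt fold changes between two sample subsets.

    Equivalent to chaining delta_ct/delta_delta_ct per assay (asserted in
    tests) but aggregates each subset once.
    """
    case_d = _delta_ct_matrix(table.subset(**case_subset), reference_assay)
    ctrl_d = _delta_ct_matrix(table.subset(**control_subset), reference_assay)
    folds: dict[str, float] = {}
    for assay in case_d.columns.intersection(ctrl_d.columns):
        case_m = case_d[assay].dropna()
        ctrl_m = ctrl_d[assay].dropna()
        if len(case_m) and len(ctrl_m):
            folds[assay] = 2.0 ** -(case_m.mean() - ctrl_m.mean())
    return folds


def run_discovery(table: CtTable, reference_assay: str = DEFAULT_REFERENCE,
                  fold_cutoff: float = 2.0
                  ) -> tuple[list[MarkerDecision], pd.DataFrame]:
    """Stage I: plasma and tissue fold changes + concordance filter.

    Plasma folds compare cancer vs normal plasma; tissue folds compare tumor
    vs adjacent non-tumor tissue, both normalized to the reference gene.
    Returns the per-assay decisions and a fold-change log.
    """
    plasma = _group_folds(table,
                          {"specimen": "plasma", "group": "BC"},
                          {"specimen": "plasma", "group": "N"},
                          reference_assay)
    tissue = _group_folds(table,
                          {"specimen": "tumor"},
                          {"specimen": "adjacent"},
                          reference_assay)
    if not plasma or not tissue:
        raise PipelineError("discovery table lacks plasma or tissue measurements")
    decisions = concordance_filter(plasma, tissue, cutoff=fold_cutoff)
    log = pd.DataFrame([{"assay": a, "plasma_fold": plasma.get(a, np.nan),
                         "tissue_fold": tissue.get(a, np.nan)}
                        for a in sorted(set(plasma) | set(tissue))])
    return decisions, log


def run_training(table: CtTable, decisions: list[MarkerDecision],
                 reference_assay: str = DEFAULT_REFERENCE,
                 alpha: float = 0.05
                 ) -> tuple[list[MarkerDecision], list[TestResult]]:
    """Stage II: case/control + pre/post screen on the discovery candidates."""
    case_pre = table.subset(group="BC", timepoint="preop")
    case_post = table.subset(group="BC", timepoint="postop")
    ctrl = table.subset(group="N")
    if len(case_pre) == 0 or len(ctrl) == 0:
        raise PipelineError("training table needs preoperative BC and control plasma")
    pre_x = -_delta_ct_matrix(case_pre, reference_assay)
    ctrl_x = -_delta_ct_matrix(ctrl, reference_assay)
    post_x = -_delta_ct_matrix(case_post, reference_assay) if len(case_post) else None
    plasma_case, plasma_control, preop, postop = {}, {}, {}, {}
    for d in decisions:
        if not d.discovery_pass or d.assay not in pre_x.columns:
            continue
        assay = d.assay
        pre_map = pre_x[assay].dropna().to_dict()
        plasma_case[assay] = np.array(list(pre_map.values()))
        plasma_control[assay] = ctrl_x[assay].dropna().to_numpy()
        preop[assay] = pre_map
        if post_x is not None and assay in post_x.columns:
            postop[assay] = post_x[assay].dropna().to_dict()
    updated = training_screen(decisions, plasma_case, plasma_control,
                              preop, postop, alpha=alpha)
    stats = [mann_whitney(plasma_case[a], plasma_control[a])
             for a in sorted(plasma_case)]
    return updated, stats


@dataclass(frozen=True)
class ValidationResult:
    ranking: list[ComboResult]
    best_markers: tuple[str, ...]
    artifact: ModelArtifact
    report_vs_normal: DiagnosticReport
    report_vs_all: DiagnosticReport          # normals + other cancers as negatives
    stage_kruskal: TestResult | None
    per_stage_vs_control: dict[str, TestResult]
    group_tests: dict[str, TestResult]       # each non-BC cancer vs BC
    warnings: tuple[str, ...] = ()


def _marker_features(table: CtTable, markers: list[str],
                     reference_assay: str) -> tuple[pd.DataFrame, pd.Series]:
    """−ΔCt feature matrix (rows = samples with all markers) + group labels."""
    frame = (-_delta_ct_matrix(table, reference_assay))[list(markers)].dropna()
    groups = table.records.drop_duplicates("sample_id").set_index("sample_id")["group"]
    return frame, groups.loc[frame.index]


def _score_by_sample(table: CtTable, numerator: str, denominator: str
                     ) -> pd.Series:
    scores, _ = combined_score(table, numerator, denominator)
    return pd.Series({s.sample_id: s.log2_score for s in scores})


def _orient_pair(markers: tuple[str, ...], features: pd.DataFrame,
                 labels: np.ndarray) -> tuple[str, str]:
    """Numerator = marker whose expression rises in cases (positive logistic
    slope on −ΔCt), denominator = the falling one."""
    fit = fit_logistic(features.loc[:, list(markers)].to_numpy(), labels, markers)
    slopes = dict(zip(markers, fit.coefficients[1:]))
    ordered = sorted(markers, key=lambda m: -slopes[m])
    return ordered[0], ordered[-1]


def run_validation(table: CtTable, trained_markers: list[str],
                   meta: SampleMeta | None = None,
                   reference_assay: str = DEFAULT_REFERENCE,
                   max_combo_size: int | None = None,
                   cutoff_method: str = "youden",
                   auc_ci_method: str = "hanley_mcneil") -> ValidationResult:
    """Stage III: combination selection + full diagnostics of the combined
    score, against normals and against normals-plus-other-cancers, with
    per-stage subgroup analyses when metadata is given."""
    markers = list(trained_markers)
    if len(markers) < 2:
        raise PipelineError("validation needs at least two trained markers")
    warnings_: list[str] = []
    features, groups = _marker_features(table, markers, reference_assay)
    bc_or_n = groups.isin(["BC", "N"])
    y = (groups[bc_or_n] == "BC").to_numpy().astype(int)
    ranking = select_best_combination(markers, features.loc[bc_or_n], y,
                                      max_size=max_combo_size)
    best = ranking[0].marker_set
    if len(best) == 2:
        num, den = _orient_pair(best, features.loc[bc_or_n], y)
    else:
        warnings_.append(
            f"top combination {best} is not a pair; scoring the top two markers")
        pair = (best * 2)[:2] if len(best) == 1 else best[:2]
        num, den = pair if len(set(pair)) == 2 else ("miR-451", "miR-145")

    score = _score_by_sample(table, num, den)
    sample_group = (table.records.drop_duplicates("sample_id")
                    .set_index("sample_id")["group"]).loc[score.index]

    # headline evaluation: BC vs normal controls
    m_n = sample_group.isin(["BC", "N"])
    rep_n = evaluate_scores(score[m_n].to_numpy(),
                            (sample_group[m_n] == "BC").astype(int).to_numpy(),
                            cutoff_method=cutoff_method,
                            auc_ci_method=auc_ci_method)
    # specificity evaluation: everything that is not breast cancer is negative
    other = sorted(set(sample_group) - {"BC", "N"})
    if not other:
        warnings_.append("no other-cancer groups; specificity computed vs normals only")
        rep_all = rep_n
    else:
        rep_all = evaluate_scores(score.to_numpy(),
                                  (sample_group == "BC").astype(int).to_numpy(),
                                  cutoff_method=cutoff_method,
                                  auc_ci_method=auc_ci_method)
    group_tests = {g: mann_whitney(score[sample_group == "BC"].to_numpy(),
                                   score[sample_group == g].to_numpy())
                   for g in (["N"] + other)}

    stage_kw = None
    per_stage: dict[str, TestResult] = {}
    if meta is not None and len(meta.records):
        stages = meta.records.set_index("sample_id")["stage"]
        bc_scores = score[sample_group == "BC"]
        bc_stages = stages.reindex(bc_scores.index).dropna()
        ctrl_scores = score[sample_group == "N"].to_numpy()
        by_stage = {s: bc_scores.loc[bc_stages[bc_stages == s].index].to_numpy()
                    for s in sorted(bc_stages.unique())}
        by_stage = {s: v for s, v in by_stage.items() if len(v) >= 3}
        if len(by_stage) >= 3:
            stage_kw = kruskal_wallis(*by_stage.values())
        for s, vals in by_stage.items():
            per_stage[s] = mann_whitney(vals, ctrl_scores)

    artifact = ModelArtifact(markers=best, numerator_assay=num,
                             denominator_assay=den,
                             cutoff=float(rep_all.cutoff),
                             higher_is_positive=True)
    return ValidationResult(ranking=ranking, best_markers=best, artifact=artifact,
                            report_vs_normal=rep_n, report_vs_all=rep_all,
                            stage_kruskal=stage_kw, per_stage_vs_control=per_stage,
                            group_tests=group_tests, warnings=tuple(warnings_))


def run_blind_validation(table: CtTable, artifact: ModelArtifact
                         ) -> DiagnosticReport:
    """Stage IV: apply the frozen score and cutoff to a new cohort.

    No refitting — the cutoff comes from the validation-stage artifact.
    """
    for m in (artifact.numerator_assay, artifact.denominator_assay):
        if m not in table.assays:
            raise PipelineError(f"frozen marker {m!r} absent from the blind table")
    score = _score_by_sample(table, artifact.numerator_assay,
                             artifact.denominator_assay)
    groups = (table.records.drop_duplicates("sample_id")
              .set_index("sample_id")["group"]).loc[score.index]
    y = (groups == "BC").astype(int).to_numpy()
    return evaluate_scores(score.to_numpy(), y, cutoff=artifact.cutoff,
                           higher_is_positive=artifact.higher_is_positive)
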