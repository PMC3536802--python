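"""Relative quantification of qPCR data: ΔCt, 2^−ΔΔCt fold change, and the
reference-free two-marker combined score 2^−(Ct_num − Ct_den).

ΔCt = Ct(target) − Ct(reference gene) puts each sample's expression on an
inverted log2 scale relative to a stable endogenous control (here RNU6B by
default).  ΔΔCt = mean ΔCt(case) − mean ΔCt(control) and 2^−ΔΔCt is the
case/control fold change.  The combined score divides one marker's abundance
by another's within the same sample, so no reference gene enters it and any
per-sample additive Ct shift (pipetting, input amount) cancels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ct_data import CtTable, aggregate_replicates

DEFAULT_REFERENCE = "RNU6B"


class QuantificationError(ValueError):
    pass


@dataclass(frozen=True)
class ExpressionResult:
    """Per-sample normalized expression for one assay."""

    sample_id: str
    assay: str
    delta_ct: float  # Ct(target) − Ct(reference), cycles
    reference_assay: str

    @property
    def log2_expression(self) -> float:
        """−ΔCt: log2 expression relative to the reference gene."""
        return -self.delta_ct


@dataclass(frozen=True)
class FoldChange:
    """Group-level case/control fold change for one assay."""

    assay: str
    delta_delta_ct: float
    fold: float  # 2^−ΔΔCt
    case_n: int
    control_n: int


@dataclass(frozen=True)
class CombinedScore:
    """Reference-free two-marker score for one sample.

    score = 2^−(Ct_num − Ct_den); higher when the numerator marker is more
    abundant and/or the denominator marker less abundant.
    """

    sample_id: str
    numerator_assay: str
    denominator_assay: str
    score: float
    log2_score: float


def _aggregated_ct(table: CtTable, assay: str) -> pd.Series:
    """Mean-aggregated Ct per sample for one assay (NaN where undetected)."""
    sub = table.subset(assay=assay)
    if len(sub) == 0:
        raise QuantificationError(f"assay {assay!r} absent from table")
    agg, _ = aggregate_replicates(sub)
    df = agg.records
    if df.duplicated("sample_id").any():
        # multiple timepoints present; caller must subset to one first
        sid = df.loc[df.duplicated("sample_id").idxmax(), "sample_id"]
        raise QuantificationError(
            f"sample {sid!r} has several timepoints for assay {assay!r}; "
            "subset the table to one timepoint before quantification"
        )
    return df.set_index("sample_id")["ct"]


def delta_ct(table: CtTable, target_assay: str,
             reference_assay: str = DEFAULT_REFERENCE
             ) -> tuple[list[ExpressionResult], int]:
    """Per-sample ΔCt = Ct(target) − Ct(reference).

    Samples missing an aggregated Ct for either assay are skipped; the second
    return value counts them.
    """
    tgt = _aggregated_ct(table, target_assay)
    ref = _aggregated_ct(table, reference_assay)
    samples = tgt.index.union(ref.index)
    results: list[ExpressionResult] = []
    skipped = 0
    for sid in samples:
        t = tgt.get(sid, np.nan)
        r = ref.get(sid, np.nan)
        if np.isnan(t) or np.isnan(r):
            skipped += 1
            continue
        results.append(ExpressionResult(sample_id=sid, assay=target_assay,
                                        delta_ct=float(t - r),
                                        reference_assay=reference_assay))
    return results, skipped


def delta_delta_ct(case_results: list[ExpressionResult],
                   control_results: list[ExpressionResult]) -> FoldChange:
    """ΔΔCt = mean ΔCt(case) − mean ΔCt(control); fold = 2^−ΔΔCt.

    The calibrator is the control-group mean ΔCt (cohort design), not a
    single calibrator sample.
    """
    if not case_results or not control_results:
        raise QuantificationError("both case and control collections must be non-empty")
    assays = {r.assay for r in case_results} | {r.assay for r in control_results}
    refs = {r.reference_assay for r in case_results} | {r.reference_assay for r in control_results}
    if len(assays) != 1 or len(refs) != 1:
        raise QuantificationError(
            f"assay/reference mismatch between groups: assays={assays}, references={refs}"
        )
    ddct = float(np.mean([r.delta_ct for r in case_results])
                 - np.mean([r.delta_ct for r in control_results]))
    return FoldChange(assay=assays.pop(), delta_delta_ct=ddct, fold=2.0 ** (-ddct),
                      case_n=len(case_results), control_n=len(control_results))


def per_sample_fold(case_results: list[ExpressionResult],
                    control_results: list[ExpressionResult]
                    ) -> tuple[dict[str, float], dict[str, float]]:
    """Per-sample fold changes against the control-group mean ΔCt.

    fold_i = 2^−(ΔCt_i − mean ΔCt(control)) for every case and control
    sample, all against the same calibrator mean (the construction behind
    per-sample expression box plots).
    """
    if not case_results or not control_results:
        raise QuantificationError("both case and control collections must be non-empty")
    assays = {r.assay for r in case_results} | {r.assay for r in control_results}
    if len(assays) != 1:
        raise QuantificationError(f"assay mismatch: {assays}")
    calibrator = float(np.mean([r.delta_ct for r in control_results]))
    case = {r.sample_id: 2.0 ** (-(r.delta_ct - calibrator)) for r in case_results}
    ctrl = {r.sample_id: 2.0 ** (-(r.delta_ct - calibrator)) for r in control_results}
    return case, ctrl


def combined_score(table: CtTable, numerator_assay: str = "miR-451",
                   denominator_assay: str = "miR-145"
                   ) -> tuple[list[CombinedScore], int]:
    """Reference-free two-marker score per sample.

    score = 2^−(Ct(numerator) − Ct(denominator)).  Samples missing either
    assay are skipped; the second return value counts them.
    """
    num = _aggregated_ct(table, numerator_assay)
    den = _aggregated_ct(table, denominator_assay)
    samples = num.index.union(den.index)
    out: list[CombinedScore] = []
    skipped = 0
    for sid in samples:
        a = num.get(sid, np.nan)
        b = den.get(sid, np.nan)
        if np.isnan(a) or np.isnan(b):
            skipped += 1
            continue
        dct = float(a - b)
        out.append(CombinedScore(sample_id=sid, numerator_assay=numerator_assay,
                                 denominator_assay=denominator_assay,
                                 score=2.0 ** (-dct), log2_score=-dct))
    return out, skipped


def expression_frame(results: list[ExpressionResult]) -> pd.DataFrame:
    """ΔCt results as a DataFrame (``sample_id, assay, delta_ct, fold``)."""
    return pd.DataFrame(
        [{"sample_id": r.sample_id, "assay": r.assay, "delta_ct": r.delta_ct,
          "fold": 2.0 ** (-r.delta_ct)} for r in results]
    )


def combined_score_frame(scores: list[CombinedScore]) -> pd.DataFrame:
    """Combined scores as a DataFrame (``sample_id, score, log2_score``)."""
    return pd.DataFrame(
        [{"sample_id": s.sample_id, "score": s.score, "log2_score": s.log2_score}
         for s in scores]
    )
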