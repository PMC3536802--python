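"""Two-stage marker screening.

Stage I (discovery): a miRNA is a candidate only when its case/control fold
change points the same way in *both* plasma and tumor tissue at a 2-fold
cutoff — concordance rules out plasma miRNAs that come from sources other
than the tumor.

Stage II (training): an up-regulated candidate must be significantly
elevated in pre-operative case plasma versus controls (Mann-Whitney) *and*
significantly reduced 14 days after tumor resection (paired Wilcoxon) — a
marker that does not fall when the tumor is removed is not tumor-derived.
Down-regulated candidates keep only the case/control criterion: loss of a
circulating tumor-suppressor signal need not rebound two weeks after
surgery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .rank_tests import mann_whitney, wilcoxon_signed_rank


class MarkerScreenError(ValueError):
    pass


@dataclass(frozen=True)
class MarkerDecision:
    """One miRNA's path through discovery and training."""

    assay: str
    direction: str | None  # "up", "down", or None (no concordant call)
    plasma_fold: float = math.nan
    tissue_fold: float = math.nan
    discovery_pass: bool = False
    casecontrol_p: float = math.nan
    prepost_p: float = math.nan
    training_pass: bool = False
    reasons: tuple[str, ...] = field(default=())


def concordance_filter(plasma_folds: dict[str, float],
                       tissue_folds: dict[str, float],
                       cutoff: float = 2.0) -> list[MarkerDecision]:
    """Discovery-stage plasma/tumor concordance filter.

    An assay passes "up" iff both folds exceed ``cutoff`` (strict), "down"
    iff both are below ``1/cutoff``; anything discordant or inside the band
    fails.  Assays present in only one specimen are reported unevaluable.
    """
    if not cutoff > 1:
        raise MarkerScreenError(f"cutoff must exceed 1, got {cutoff}")
    decisions = []
    for assay in sorted(set(plasma_folds) | set(tissue_folds)):
        if assay not in plasma_folds or assay not in tissue_folds:
            missing = "tissue" if assay not in tissue_folds else "plasma"
            decisions.append(MarkerDecision(
                assay=assay, direction=None, discovery_pass=False,
                plasma_fold=plasma_folds.get(assay, math.nan),
                tissue_fold=tissue_folds.get(assay, math.nan),
                reasons=(f"unevaluable: no {missing} fold change",)))
            continue
        pf, tf = plasma_folds[assay], tissue_folds[assay]
        if pf <= 0 or tf <= 0:
            raise MarkerScreenError(f"fold changes must be positive ({assay}: {pf}, {tf})")
        if pf > cutoff and tf > cutoff:
            decisions.append(MarkerDecision(
                assay=assay, direction="up", plasma_fold=pf, tissue_fold=tf,
                discovery_pass=True,
                reasons=(f"up-regulated >{cutoff}-fold in plasma and tumor",)))
        elif pf < 1 / cutoff and tf < 1 / cutoff:
            decisions.append(MarkerDecision(
                assay=assay, direction="down", plasma_fold=pf, tissue_fold=tf,
                discovery_pass=True,
                reasons=(f"down-regulated >{cutoff}-fold in plasma and tumor",)))
        else:
            decisions.append(MarkerDecision(
                assay=assay, direction=None, plasma_fold=pf, tissue_fold=tf,
                discovery_pass=False,
                reasons=("discordant or below cutoff",)))
    return decisions


def _paired_arrays(preop: dict[str, float], postop: dict[str, float],
                   assay: str) -> tuple[np.ndarray, np.ndarray]:
    orphans = sorted(set(preop) ^ set(postop))
    if orphans:
        raise MarkerScreenError(
            f"unpaired pre/post records for assay {assay!r}; orphan patients: {orphans}")
    patients = sorted(preop)
    return (np.array([preop[p] for p in patients], dtype=float),
            np.array([postop[p] for p in patients], dtype=float))


def training_screen(candidates: list[MarkerDecision],
                    plasma_case: dict[str, np.ndarray],
                    plasma_control: dict[str, np.ndarray],
                    preop: dict[str, dict[str, float]],
                    postop: dict[str, dict[str, float]],
                    alpha: float = 0.05) -> list[MarkerDecision]:
    """Training-stage screen on per-sample log2 expression (−ΔCt).

    ``plasma_case``/``plasma_control`` map assay -> per-sample expression
    arrays; ``preop``/``postop`` map assay -> {patient_id: expression} and
    must be paired by patient.  Direction calls use group medians.
    """
    out = []
    for cand in candidates:
        if not cand.discovery_pass:
            out.append(replace(cand, training_pass=False,
                               reasons=cand.reasons + ("not a discovery candidate",)))
            continue
        assay = cand.assay
        if assay not in plasma_case or assay not in plasma_control:
            out.append(replace(cand, training_pass=False,
                               reasons=cand.reasons + ("no training measurements",)))
            continue
        case = np.asarray(plasma_case[assay], dtype=float)
        ctrl = np.asarray(plasma_control[assay], dtype=float)
        cc = mann_whitney(case, ctrl)
        reasons = list(cand.reasons)
        case_higher = float(np.median(case)) > float(np.median(ctrl))
        prepost_p = math.nan

        if cand.direction == "up":
            cc_ok = cc.p_value < alpha and case_higher
            reasons.append(
                f"case vs control p={cc.p_value:.3g} "
                + ("elevated" if case_higher else "not elevated"))
            pp_ok = False
            if assay in preop and assay in postop:
                pre, post = _paired_arrays(preop[assay], postop[assay], assay)
                pp = wilcoxon_signed_rank(pre, post)
                prepost_p = pp.p_value
                post_lower = float(np.median(post)) < float(np.median(pre))
                pp_ok = pp.p_value < alpha and post_lower
                reasons.append("postoperative reduction" if pp_ok
                               else "no postoperative reduction")
            else:
                reasons.append("no pre/post measurements")
            passed = cc_ok and pp_ok
        else:  # down: case/control criterion only
            cc_ok = cc.p_value < alpha and not case_higher
            reasons.append(
                f"case vs control p={cc.p_value:.3g} "
                + ("reduced" if not case_higher else "not reduced"))
            if assay in preop and assay in postop:
                pre, post = _paired_arrays(preop[assay], postop[assay], assay)
                prepost_p = wilcoxon_signed_rank(pre, post).p_value
            reasons.append("pre/post criterion not required for down-regulated markers")
            passed = cc_ok
        out.append(replace(cand, casecontrol_p=cc.p_value, prepost_p=prepost_p,
                           training_pass=passed, reasons=tuple(reasons)))
    return out


def decisions_frame(decisions: list[MarkerDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"assay": d.assay, "direction": d.direction or "",
          "plasma_fold": d.plasma_fold, "tissue_fold": d.tissue_fold,
          "discovery_pass": d.discovery_pass, "casecontrol_p": d.casecontrol_p,
          "prepost_p": d.prepost_p, "training_pass": d.training_pass,
          "reasons": "; ".join(d.reasons)} for d in decisions]
    )


def decisions_from_frame(df: pd.DataFrame) -> list[MarkerDecision]:
    out = []
    for _, row in df.iterrows():
        out.append(MarkerDecision(
            assay=row["assay"], direction=row["direction"] or None,
            plasma_fold=float(row["plasma_fold"]), tissue_fold=float(row["tissue_fold"]),
            discovery_pass=bool(row["discovery_pass"]),
            casecontrol_p=float(row.get("casecontrol_p", math.nan)),
            prepost_p=float(row.get("prepost_p", math.nan)),
            training_pass=bool(row.get("training_pass", False)),
            reasons=tuple(str(row.get("reasons", "")).split("; ")) if row.get("reasons") else ()))
    return out
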