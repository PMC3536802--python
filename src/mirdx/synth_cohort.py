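"""Synthetic qPCR cohorts with the statistical structure of a three-stage
plasma-miRNA biomarker study.

The generators emit tidy Ct tables for (1) a small four-class discovery set
(cancer plasma, normal plasma, tumor, adjacent non-tumor tissue from the
same patients), (2) a paired pre-/post-operative training set with matched
controls, and (3) a large multi-disease validation set (breast cancer,
healthy controls, and five other cancer types) with TNM stage labels.

Noise model: Gaussian on the Ct (cycle) scale — equivalently log-normal
expression, the standard qPCR error model.  Each sample carries a random
per-sample offset shared by every assay including the reference gene
(global RNA input/pipetting variation); it cancels exactly under ΔCt
normalization and in the two-marker combined score.  Duplicate wells are
drawn so that the *aggregated* (duplicate-mean) Ct has standard deviation
``noise_sd`` exactly, which keeps the closed-form planted truths exact.
Each patient in the paired design carries an additional offset shared
between their pre- and post-operative samples.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ct_data import COLUMNS, CtTable, SampleMeta

UP_MIRNAS = ("miR-16", "miR-21", "miR-27a", "miR-150", "miR-191",
             "miR-200c", "miR-210", "miR-451")
DOWN_MIRNA = "miR-145"
TRAINING_VALIDATED = ("miR-16", "miR-21", "miR-451")
OTHER_CANCERS = ("CRC", "EC", "GC", "HCC", "LC")


class SynthDesignError(ValueError):
    pass


@dataclass(frozen=True)
class AssayEffect:
    """Per-assay planted effect, all shifts in Ct cycles.

    Negative shifts mean *lower* Ct, i.e. higher expression (up-regulation).
    """

    name: str
    base_ct: float = 30.0
    plasma_shift: float = 0.0          # added in breast-cancer plasma
    tissue_shift: float = 0.0          # added in tumor vs adjacent tissue
    tumor_derived: bool = False        # post-op Ct reverts toward base
    group_shifts: dict[str, float] = field(default_factory=dict)  # other cancers


@dataclass(frozen=True)
class SynthDesign:
    """Parametric description of a simulated cohort."""

    assays: tuple[AssayEffect, ...]
    group_sizes: dict[str, int]
    reference_assay: str = "RNU6B"
    reference_ct: float = 24.0
    reference_sd: float = 0.25
    noise_sd: float = 1.0              # SD of the aggregated per-sample Ct
    patient_effect_sd: float = 0.5
    paired: bool = False
    postop_recovery: float = 0.8       # fraction of the cancer shift removed post-op
    n_replicates: int = 2
    replicate_sd: float = 0.15         # technical well-to-well SD
    stage_proportions: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.reference_sd < 0 or self.patient_effect_sd < 0:
            raise SynthDesignError("standard deviations must be non-negative")
        if not 0 <= self.postop_recovery <= 1:
            raise SynthDesignError("postop_recovery must lie in [0, 1]")
        if any(n < 1 for n in self.group_sizes.values()):
            raise SynthDesignError("group sizes must be >= 1")
        if self.n_replicates < 1:
            raise SynthDesignError("n_replicates must be >= 1")
        if self.noise_sd ** 2 < self.replicate_sd ** 2 / self.n_replicates:
            raise SynthDesignError(
                "noise_sd too small for the replicate noise it must absorb")

    def assay_map(self) -> dict[str, AssayEffect]:
        return {a.name: a for a in self.assays}

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass(frozen=True)
class PlantedTruth:
    """Closed-form expectations implied by a design."""

    directions: dict[str, str]           # assay -> up/down/null (plasma)
    expected_plasma_fold: dict[str, float]
    expected_tissue_fold: dict[str, float]
    expected_combined_auc: float         # combined miR-451/miR-145 score, BC vs N
    combined_log2_separation: float
    combined_log2_sd: float


def planted_truth(design: SynthDesign,
                  numerator: str = "miR-451",
                  denominator: str = "miR-145") -> PlantedTruth:
    """Expected fold changes 2^(−shift) and the binormal AUC Φ(Δμ/σ_diff)
    of the combined score for case vs control."""
    amap = design.assay_map()
    directions, pfold, tfold = {}, {}, {}
    for a in design.assays:
        pfold[a.name] = 2.0 ** (-a.plasma_shift)
        tfold[a.name] = 2.0 ** (-a.tissue_shift)
        directions[a.name] = ("up" if a.plasma_shift < 0
                              else "down" if a.plasma_shift > 0 else "null")
    sep = sd = auc = math.nan
    if numerator in amap and denominator in amap:
        # log2 score = −(Ct_num − Ct_den); BC shift = shift_den − shift_num
        sep = amap[denominator].plasma_shift - amap[numerator].plasma_shift
        per_group_var = 2.0 * design.noise_sd ** 2
        sd = math.sqrt(per_group_var)
        auc = float(norm.cdf(sep / math.sqrt(2.0 * per_group_var)))
    return PlantedTruth(directions=directions, expected_plasma_fold=pfold,
                        expected_tissue_fold=tfold, expected_combined_auc=auc,
                        combined_log2_separation=sep, combined_log2_sd=sd)


def expected_auc(delta_mu: float, per_group_sd: float) -> float:
    """Binormal AUC Φ(Δμ / (σ√2)) for equal-variance two-class scores."""
    return float(norm.cdf(delta_mu / (per_group_sd * math.sqrt(2.0))))


# ---------------------------------------------------------------------------
# generation internals

def _sample_rows(rng: np.random.Generator, design: SynthDesign, *,
                 sample_id: str, group: str, specimen: str, timepoint: str,
                 assay_shifts: dict[str, float], sample_offset: float) -> list[dict]:
    """Duplicate-well rows for one sample across all assays + reference."""
    rows = []
    n_rep = design.n_replicates
    bio_sd = math.sqrt(design.noise_sd ** 2 - design.replicate_sd ** 2 / n_rep)
    ref_bio_sd = math.sqrt(max(design.reference_sd ** 2
                               - design.replicate_sd ** 2 / n_rep, 0.0))
    for assay in design.assays:
        mean = assay.base_ct + assay_shifts.get(assay.name, 0.0) + sample_offset
        true_ct = rng.normal(mean, bio_sd)
        for rep in range(1, n_rep + 1):
            rows.append({"sample_id": sample_id, "assay": assay.name,
                         "specimen": specimen, "group": group,
                         "timepoint": timepoint, "replicate": rep,
                         "ct": true_ct + rng.normal(0.0, design.replicate_sd)})
    ref_true = rng.normal(design.reference_ct + sample_offset, ref_bio_sd)
    for rep in range(1, n_rep + 1):
        rows.append({"sample_id": sample_id, "assay": design.reference_assay,
                     "specimen": specimen, "group": group,
                     "timepoint": timepoint, "replicate": rep,
                     "ct": ref_true + rng.normal(0.0, design.replicate_sd)})
    return rows


def _finish(rows: list[dict], provenance: str) -> CtTable:
    df = pd.DataFrame(rows, columns=COLUMNS)
    df["ct"] = df["ct"].round(4)  # instrument-like precision; keeps files stable
    return CtTable(records=df, provenance=provenance)


def generate_discovery(design: SynthDesign, seed: int | None = None) -> CtTable:
    """Four-class discovery set.

    Each breast-cancer patient contributes plasma, tumor, and adjacent
    non-tumor tissue (sharing that patient's offset); healthy controls
    contribute plasma.  Tumor tissue carries each assay's ``tissue_shift``
    relative to adjacent tissue; cancer plasma carries ``plasma_shift``.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n_bc = design.group_sizes.get("BC", 5)
    n_n = design.group_sizes.get("N", 5)
    rows: list[dict] = []
    for i in range(n_bc):
        off = rng.normal(0.0, design.patient_effect_sd)
        shifts_p = {a.name: a.plasma_shift for a in design.assays}
        shifts_t = {a.name: a.tissue_shift for a in design.assays}
        rows += _sample_rows(rng, design, sample_id=f"D-BC{i+1:02d}-P", group="BC",
                             specimen="plasma", timepoint="preop",
                             assay_shifts=shifts_p, sample_offset=off)
        rows += _sample_rows(rng, design, sample_id=f"D-BC{i+1:02d}-T", group="BC",
                             specimen="tumor", timepoint="none",
                             assay_shifts=shifts_t, sample_offset=off)
        rows += _sample_rows(rng, design, sample_id=f"D-BC{i+1:02d}-A", group="BC",
                             specimen="adjacent", timepoint="none",
                             assay_shifts={}, sample_offset=off)
    for i in range(n_n):
        off = rng.normal(0.0, design.patient_effect_sd)
        rows += _sample_rows(rng, design, sample_id=f"D-N{i+1:02d}-P", group="N",
                             specimen="plasma", timepoint="none",
                             assay_shifts={}, sample_offset=off)
    return _finish(rows, "synthetic discovery cohort")


def generate_training(design: SynthDesign, seed: int | None = None) -> CtTable:
    """Paired pre-/post-operative training set plus unpaired controls.

    A patient's pre- and post-operative samples share one patient offset.
    Post-operative Ct shift = (1 − postop_recovery) × plasma_shift for
    tumor-derived assays; non-tumor-derived assays keep their full shift.
    """
    if not design.paired:
        raise SynthDesignError("training design must have paired=True")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n_bc = design.group_sizes.get("BC", 15)
    n_n = design.group_sizes.get("N", 15)
    rows: list[dict] = []
    for i in range(n_bc):
        off = rng.normal(0.0, design.patient_effect_sd)
        pre = {a.name: a.plasma_shift for a in design.assays}
        post = {a.name: (a.plasma_shift * (1.0 - design.postop_recovery)
                         if a.tumor_derived else a.plasma_shift)
                for a in design.assays}
        sid = f"T-BC{i+1:02d}"
        rows += _sample_rows(rng, design, sample_id=sid, group="BC",
                             specimen="plasma", timepoint="preop",
                             assay_shifts=pre, sample_offset=off)
        rows += _sample_rows(rng, design, sample_id=sid, group="BC",
                             specimen="plasma", timepoint="postop",
                             assay_shifts=post, sample_offset=off)
    for i in range(n_n):
        off = rng.normal(0.0, design.patient_effect_sd)
        rows += _sample_rows(rng, design, sample_id=f"T-N{i+1:02d}", group="N",
                             specimen="plasma", timepoint="none",
                             assay_shifts={}, sample_offset=off)
    return _finish(rows, "synthetic paired training cohort")


def generate_validation(design: SynthDesign, seed: int | None = None,
                        sample_prefix: str = "V") -> tuple[CtTable, SampleMeta]:
    """Multi-disease validation set with stage labels.

    Breast-cancer plasma carries each assay's ``plasma_shift``; other cancer
    groups carry that assay's ``group_shifts`` entry (default none); healthy
    controls none.  Stage labels for BC follow ``stage_proportions``.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    rows: list[dict] = []
    meta_rows: list[dict] = []
    stage_props = design.stage_proportions or {"DCIS": 27, "I": 31, "II": 34,
                                               "III": 23, "IV": 5}
    stage_names = list(stage_props)
    stage_p = np.array([stage_props[s] for s in stage_names], dtype=float)
    stage_p /= stage_p.sum()
    for group, n in design.group_sizes.items():
        for i in range(n):
            sid = f"{sample_prefix}-{group}{i+1:03d}"
            off = rng.normal(0.0, design.patient_effect_sd)
            if group == "BC":
                shifts = {a.name: a.plasma_shift for a in design.assays}
                stage = str(rng.choice(stage_names, p=stage_p))
                sex = "F"
            else:
                shifts = {a.name: a.group_shifts.get(group, 0.0)
                          for a in design.assays}
                stage = "none"
                # controls 60:40 F:M; other cancers roughly balanced
                f_prob = 0.6 if group == "N" else 0.5
                sex = "F" if rng.random() < f_prob else "M"
            grade = (str(rng.choice(["low", "intermediate", "high"]))
                     if stage == "DCIS" else "none")
            rows += _sample_rows(rng, design, sample_id=sid, group=group,
                                 specimen="plasma", timepoint="none",
                                 assay_shifts=shifts, sample_offset=off)
            meta_rows.append({"sample_id": sid,
                              "age": int(np.clip(rng.normal(59, 10), 30, 85)),
                              "sex": sex, "stage": stage, "dcis_grade": grade})
    table = _finish(rows, "synthetic validation cohort")
    meta = SampleMeta(records=pd.DataFrame(
        meta_rows, columns=["sample_id", "age", "sex", "stage", "dcis_grade"]))
    return table, meta


# ---------------------------------------------------------------------------
# default designs: the study conditions each pipeline stage is tested under

def default_discovery_design(noise_sd: float = 0.3, n_null: int = 20,
                             n_per_class: int = 5, seed: int = 0) -> SynthDesign:
    """Discovery conditions: 8 up-markers at −2 Ct in cancer plasma *and*
    tumor, 1 down-marker at +2 Ct, 20 null assays, 5 patients per class,
    tight profiling noise (σ = 0.3 Ct)."""
    assays = [AssayEffect(name=m, plasma_shift=-2.0, tissue_shift=-2.0,
                          tumor_derived=True) for m in UP_MIRNAS]
    assays.append(AssayEffect(name=DOWN_MIRNA, plasma_shift=2.0, tissue_shift=2.0))
    assays += [AssayEffect(name=f"ctl-{i+1:02d}") for i in range(n_null)]
    return SynthDesign(assays=tuple(assays), noise_sd=noise_sd,
                       group_sizes={"BC": n_per_class, "N": n_per_class}, seed=seed)


def default_training_design(noise_sd: float = 1.0, seed: int = 0) -> SynthDesign:
    """Training conditions: 15 paired pre/post breast-cancer patients and 15
    controls; only miR-16/miR-21/miR-451 carry the −2 Ct tumor-derived
    plasma shift (post-op recovery 0.8); miR-145 is +2 Ct but not
    tumor-derived; the other five discovery candidates are null in plasma."""
    assays = []
    for m in UP_MIRNAS:
        if m in TRAINING_VALIDATED:
            assays.append(AssayEffect(name=m, plasma_shift=-2.0, tumor_derived=True))
        else:
            assays.append(AssayEffect(name=m))
    assays.append(AssayEffect(name=DOWN_MIRNA, plasma_shift=2.0))
    return SynthDesign(assays=tuple(assays), noise_sd=noise_sd, paired=True,
                       postop_recovery=0.8,
                       group_sizes={"BC": 15, "N": 15}, seed=seed)


def default_validation_design(noise_sd: float = 1.0, lc_mir451_shift: float = 1.0,
                              seed: int = 0) -> SynthDesign:
    """Validation conditions: 170 BC vs 100 healthy controls plus 95 other
    cancers (CRC/EC/GC 20 each, HCC 20, LC 15).  Only the informative pair
    is shifted in BC: miR-451 −2.5 Ct, miR-145 +1.0 Ct, so the combined
    score's planted log2 separation is 3.5 with per-group SD √2·noise_sd
    (binormal AUC Φ(1.75) ≈ 0.960 at the default noise).  Lung cancer
    optionally carries a positive miR-451 shift (combined score *below*
    normal), echoing the depressed miR-451 seen in lung tumors."""
    assays = (
        AssayEffect(name="miR-16"),
        AssayEffect(name="miR-21"),
        AssayEffect(name="miR-451", plasma_shift=-2.5,
                    group_shifts={"LC": lc_mir451_shift}),
        AssayEffect(name="miR-145", plasma_shift=1.0),
    )
    return SynthDesign(assays=assays, noise_sd=noise_sd,
                       group_sizes={"BC": 170, "N": 100, "CRC": 20, "EC": 20,
                                    "GC": 20, "HCC": 20, "LC": 15},
                       seed=seed)


def default_blind_design(noise_sd: float = 1.0, seed: int = 1) -> SynthDesign:
    """Blind-validation conditions: an independent 70 BC vs 50 controls
    drawn from the same effect structure as the validation design."""
    base = default_validation_design(noise_sd=noise_sd, seed=seed)
    return replace(base, group_sizes={"BC": 70, "N": 50})
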