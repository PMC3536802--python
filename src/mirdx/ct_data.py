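"""Data model and I/O for qPCR cycle-threshold (Ct) measurements.

A Ct value is the PCR cycle at which the fluorescence of one well crosses a
fixed threshold; lower Ct means more abundant template, and one cycle
corresponds to roughly a two-fold difference in abundance.  The tables here
are tidy: one row per (sample, assay, timepoint, replicate) well, carrying the
sample's group (disease) label, specimen type, and surgical timepoint.

Undetected wells ("Undetermined" on the instrument) are kept as explicit
missing values and never imputed to the run-length ceiling; downstream
quantification skips them and reports how many samples were usable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SPECIMENS = frozenset({"plasma", "serum", "tumor", "adjacent"})
GROUPS = frozenset({"BC", "N", "CRC", "EC", "GC", "HCC", "LC"})
TIMEPOINTS = frozenset({"none", "preop", "postop"})
STAGES = frozenset({"benign", "DCIS", "I", "II", "III", "IV", "none"})
DCIS_GRADES = frozenset({"low", "intermediate", "high", "none"})

#: Sentinels that an exported qPCR table may use for an undetected well.
MISSING_SENTINELS = frozenset({"", "Undetermined", "undetermined", "NA", "NaN", "nan"})

COLUMNS = ["sample_id", "assay", "specimen", "group", "timepoint", "replicate", "ct"]
KEY = ["sample_id", "assay", "timepoint", "replicate"]

DEFAULT_MAX_CYCLES = 40.0


class CtDataError(ValueError):
    """Raised for malformed Ct tables (bad header, enums, duplicate keys)."""


@dataclass(frozen=True)
class CtTable:
    """Tidy collection of Ct measurements.

    Parameters
    ----------
    records
        DataFrame with columns ``sample_id, assay, specimen, group,
        timepoint, replicate, ct``.  Missing Ct values are ``NaN``.
    max_cycles
        Upper bound of valid Ct values (run length of the instrument).
    provenance
        Free-text note on where the table came from.
    """

    records: pd.DataFrame
    max_cycles: float = DEFAULT_MAX_CYCLES
    provenance: str = ""

    def __post_init__(self) -> None:
        df = self.records
        missing_cols = [c for c in COLUMNS if c not in df.columns]
        if missing_cols:
            raise CtDataError(f"Ct table is missing columns: {missing_cols}")
        _validate_enums(df)
        dup = df.duplicated(subset=KEY)
        if dup.any():
            key = tuple(df.loc[dup.idxmax(), KEY])
            raise CtDataError(f"duplicate (sample_id, assay, timepoint, replicate) key: {key}")
        ct = df["ct"].to_numpy(dtype=float)
        bad = (~np.isnan(ct)) & ((ct <= 0) | (ct > self.max_cycles))
        if bad.any():
            i = int(np.argmax(bad))
            raise CtDataError(
                f"ct value {ct[i]} out of (0, {self.max_cycles}] at row {i}"
            )
        # per-sample labels must be consistent
        for col in ("group", "specimen"):
            n = df.groupby("sample_id", sort=False)[col].nunique()
            clash = n[n > 1]
            if len(clash):
                raise CtDataError(
                    f"sample {clash.index[0]!r} carries more than one {col} label"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def assays(self) -> list[str]:
        return sorted(self.records["assay"].unique())

    @property
    def samples(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())

    def subset(self, **conditions: object) -> "CtTable":
        """Rows matching all column=value (or column=list) conditions."""
        df = self.records
        mask = np.ones(len(df), dtype=bool)
        for col, val in conditions.items():
            if col not in df.columns:
                raise CtDataError(f"unknown column {col!r}")
            if isinstance(val, (list, tuple, set, frozenset)):
                mask &= df[col].isin(list(val)).to_numpy()
            else:
                mask &= (df[col] == val).to_numpy()
        return replace(self, records=df.loc[mask].reset_index(drop=True))


def _validate_enums(df: pd.DataFrame, row_offset: int = 0) -> None:
    for col, allowed in (("specimen", SPECIMENS), ("group", GROUPS), ("timepoint", TIMEPOINTS)):
        vals = df[col].astype(str)
        bad = ~vals.isin(allowed)
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise CtDataError(
                f"row {i + row_offset}: unknown {col} value {vals.iloc[i]!r} "
                f"(allowed: {sorted(allowed)})"
            )
    rep = pd.to_numeric(df["replicate"], errors="coerce")
    if rep.isna().any() or (rep < 1).any() or (rep != rep.round()).any():
        i = int(np.argmax((rep.isna() | (rep < 1) | (rep != rep.round())).to_numpy()))
        raise CtDataError(f"row {i + row_offset}: replicate must be a positive integer")


def read_ct_table(source, dialect: str = "comma", max_cycles: float = DEFAULT_MAX_CYCLES,
                  provenance: str = "") -> CtTable:
    """Read a Ct table from CSV/TSV.

    The header must name ``sample_id,assay,specimen,group,timepoint,
    replicate,ct``.  Ct cells that are empty or read "Undetermined" become
    missing values; any other non-numeric cell is a parse error naming the
    row.
    """
    sep = {"comma": ",", "tab": "\t"}.get(dialect)
    if sep is None:
        raise CtDataError(f"unknown dialect {dialect!r} (use 'comma' or 'tab')")
    df = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise CtDataError(f"malformed header, missing columns: {missing_cols}")
    ct_raw = df["ct"].str.strip()
    ct = pd.to_numeric(ct_raw, errors="coerce")
    bad = ct.isna() & ~ct_raw.isin(MISSING_SENTINELS)
    if bad.any():
        i = int(np.argmax(bad.to_numpy()))
        raise CtDataError(f"row {i}: non-numeric ct value {ct_raw.iloc[i]!r}")
    out = df[COLUMNS[:-1]].copy()
    out["replicate"] = pd.to_numeric(df["replicate"], errors="coerce")
    _validate_enums(out, row_offset=0)
    out["replicate"] = out["replicate"].astype(int)
    out["ct"] = ct.astype(float)
    return CtTable(records=out, max_cycles=max_cycles,
                   provenance=provenance or getattr(source, "name", str(source)))


def write_ct_table(table: CtTable, target, dialect: str = "comma",
                   missing: str = "") -> None:
    """Write a Ct table in the dialect :func:`read_ct_table` reads."""
    sep = {"comma": ",", "tab": "\t"}.get(dialect)
    if sep is None:
        raise CtDataError(f"unknown dialect {dialect!r}")
    df = table.records.copy()
    df["ct"] = df["ct"].map(lambda v: missing if pd.isna(v) else repr(float(v)))
    df.to_csv(target, sep=sep, index=False)


def ct_table_to_string(table: CtTable, dialect: str = "comma") -> str:
    buf = io.StringIO()
    write_ct_table(table, buf, dialect=dialect)
    return buf.getvalue()


@dataclass(frozen=True)
class ReplicateQC:
    """QC report from replicate aggregation."""

    discord_limit: float
    #: (sample_id, assay, timepoint) keys whose replicate range exceeded the limit
    flagged: tuple = ()
    n_groups: int = 0

    @property
    def n_flagged(self) -> int:
        return len(self.flagged)


def aggregate_replicates(table: CtTable, policy: str = "mean",
                         discord_limit: float = 1.0) -> tuple[CtTable, ReplicateQC]:
    """Collapse replicate wells to one Ct per (sample, assay, timepoint).

    The aggregated Ct is the arithmetic mean of the *present* replicate
    values; a group whose replicate range exceeds ``discord_limit`` cycles is
    flagged in the QC report but still aggregated (flag-but-keep).  A group
    whose replicates are all missing aggregates to a missing Ct.
    """
    if policy != "mean":
        raise CtDataError(f"unknown aggregation policy {policy!r}")
    df = table.records
    keys = ["sample_id", "assay", "timepoint"]
    gb = df.groupby(keys, sort=False)
    agg = gb.agg(specimen=("specimen", "first"), group=("group", "first"),
                 ct=("ct", "mean"), ct_min=("ct", "min"), ct_max=("ct", "max"),
                 n_present=("ct", "count")).reset_index()
    discord = (agg["n_present"] >= 2) & (agg["ct_max"] - agg["ct_min"] > discord_limit)
    flagged = [tuple(r) for r in agg.loc[discord, keys].itertuples(index=False)]
    out = agg.assign(replicate=1)[COLUMNS].copy()
    qc = ReplicateQC(discord_limit=discord_limit, flagged=tuple(flagged),
                     n_groups=len(out))
    return replace(table, records=out), qc


def detection_rate(table: CtTable, assay: str, specimen: str | None = None,
                   group: str | None = None) -> float:
    """Fraction of matching samples with a detected (non-missing) Ct.

    Replicates are aggregated first, so a sample counts as detected when at
    least one of its wells produced a Ct.
    """
    conditions: dict[str, object] = {"assay": assay}
    if specimen is not None:
        conditions["specimen"] = specimen
    if group is not None:
        conditions["group"] = group
    sub = table.subset(**conditions)
    if len(sub) == 0:
        raise CtDataError(
            f"no measurements match assay={assay!r}, specimen={specimen!r}, group={group!r}"
        )
    agg, _ = aggregate_replicates(sub)
    n = len(agg.records)
    detected = int(agg.records["ct"].notna().sum())
    return detected / n


# ---------------------------------------------------------------------------
# Sample metadata

META_COLUMNS = ["sample_id", "age", "sex", "stage", "dcis_grade"]


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample clinical metadata: age, sex, TNM stage, DCIS grade."""

    records: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=META_COLUMNS))

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in META_COLUMNS if c not in df.columns]
        if missing:
            raise CtDataError(f"sample metadata missing columns: {missing}")
        if not df["sex"].isin({"F", "M"}).all():
            raise CtDataError("sex must be F or M")
        if not df["stage"].isin(STAGES).all():
            raise CtDataError(f"stage must be one of {sorted(STAGES)}")
        if not df["dcis_grade"].isin(DCIS_GRADES).all():
            raise CtDataError(f"dcis_grade must be one of {sorted(DCIS_GRADES)}")
        bad = (df["dcis_grade"] != "none") & (df["stage"] != "DCIS")
        if bad.any():
            sid = df.loc[bad.idxmax(), "sample_id"]
            raise CtDataError(f"sample {sid!r} has a DCIS grade but stage != DCIS")


def read_sample_meta(source, dialect: str = "comma") -> SampleMeta:
    sep = {"comma": ",", "tab": "\t"}.get(dialect)
    if sep is None:
        raise CtDataError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(source, sep=sep, dtype={"sample_id": str, "sex": str,
                                             "stage": str, "dcis_grade": str})
    return SampleMeta(records=df)


def write_sample_meta(meta: SampleMeta, target, dialect: str = "comma") -> None:
    sep = {"comma": ",", "tab": "\t"}[dialect]
    meta.records.to_csv(target, sep=sep, index=False)
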