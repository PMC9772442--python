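"""NONMEM-dialect event dataset: reading, validation, quantitation-limit
rules and per-subject assembly.

The on-disk dialect is a CSV with header

    ID,TIME,EVID,AMT,DVID,DV,MDV,SS,II,ADDL,BLQ,
    MORBID,SEX,AGE,WT,FORM,SMOK,DRINK,VPA,QTP,CLZ,OLZ,RIS,AMI,ALT,AST,BUN,CR

where EVID 1 marks a dose row and 0 an observation row, DVID 1 is the parent
drug (VEN) and 2 the metabolite (ODV).  Times are absolute hours from the
subject's first record; a dose and an observation may share a time, in which
case the dose sorts first.  Floats are written with full repr fidelity so a
write/read round trip is bit-exact.

Quantitation rules differ between the two source designs and are keyed on
the MORBID covariate (healthy volunteers vs. patients): the intensive
healthy-subject assay zeroes below-limit values in the absorption phase and
excludes them in the elimination phase, whereas the patient TDM assay simply
excludes anything outside its quantitation range.  The absorption phase of
an observation is operationalised as "at or before the time of the maximum
observed concentration for that subject, analyte and dosing interval".
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError, ValidationError
from .model import DoseEvent, Regimen

DVID_VEN = 1
DVID_ODV = 2
ANALYTE_NAME = {DVID_VEN: "VEN", DVID_ODV: "ODV"}
ANALYTE_DVID = {"VEN": DVID_VEN, "ODV": DVID_ODV}

EVENT_COLUMNS = ["ID", "TIME", "EVID", "AMT", "DVID", "DV", "MDV", "SS", "II", "ADDL", "BLQ"]
COVARIATE_COLUMNS = {
    "morbid": "MORBID",
    "sex": "SEX",
    "age": "AGE",
    "weight": "WT",
    "formulation": "FORM",
    "smoking": "SMOK",
    "drinking": "DRINK",
    "valproic_acid": "VPA",
    "quetiapine": "QTP",
    "clozapine": "CLZ",
    "olanzapine": "OLZ",
    "risperidone": "RIS",
    "amisulpride": "AMI",
    "alt": "ALT",
    "ast": "AST",
    "bun": "BUN",
    "cr": "CR",
}
ALL_COLUMNS = EVENT_COLUMNS + list(COVARIATE_COLUMNS.values())

_BINARY_FIELDS = (
    "morbid",
    "sex",
    "formulation",
    "smoking",
    "drinking",
    "valproic_acid",
    "quetiapine",
    "clozapine",
    "olanzapine",
    "risperidone",
    "amisulpride",
)


@dataclass(frozen=True)
class CovariateSet:
    """Subject-level covariates.

    Binary codings: morbid 0 healthy / 1 patient; sex 0 male / 1 female;
    formulation 0 rapid-release / 1 sustained-release; the six concomitant
    medications and smoking/drinking are 0/1 indicators.  Laboratory values
    are ALT and AST in U/L, BUN in mmol/L and CR in umol/L.
    """

    morbid: float = 0.0
    sex: float = 0.0
    age: float = 30.0
    weight: float = 62.5
    formulation: float = 0.0
    smoking: float = 0.0
    drinking: float = 0.0
    valproic_acid: float = 0.0
    quetiapine: float = 0.0
    clozapine: float = 0.0
    olanzapine: float = 0.0
    risperidone: float = 0.0
    amisulpride: float = 0.0
    alt: float = 20.0
    ast: float = 20.0
    bun: float = 4.0
    cr: float = 70.0

    def __post_init__(self) -> None:
        if not (self.age > 0.0 and self.weight > 0.0):
            raise ValidationError("age and weight must be positive")
        for name in _BINARY_FIELDS:
            if getattr(self, name) not in (0, 1, 0.0, 1.0):
                raise ValidationError(f"covariate {name} must be 0 or 1")

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class PKRecord:
    """One dosing or observation row of the event stream."""

    subject_id: int
    time: float
    event_type: str  # "dose" | "observation"
    amount: float | None = None
    analyte: str | None = None  # "VEN" | "ODV"
    dv: float | None = None
    below_lloq: bool = False
    steady_state: bool = False
    interdose_interval: float = 0.0
    n_additional_doses: int = 0
    covariates: CovariateSet = field(default_factory=CovariateSet)

    def __post_init__(self) -> None:
        if self.event_type == "dose":
            if self.dv is not None or self.analyte is not None:
                raise ValidationError("dose rows must not carry DV or analyte")
            if self.amount is None or not self.amount > 0.0:
                raise ValidationError("dose rows need a positive amount")
        elif self.event_type == "observation":
            if self.amount is not None:
                raise ValidationError("observation rows must not carry an amount")
            if self.analyte not in ANALYTE_DVID:
                raise ValidationError("observation rows need an analyte (VEN or ODV)")
            if self.dv is None:
                raise ValidationError("observation rows need a DV")
        else:
            raise ValidationError(f"unknown event type {self.event_type!r}")
        if self.time < 0.0:
            raise ValidationError("record time must be >= 0")


@dataclass(frozen=True)
class QuantRule:
    """Quantitation limits and below-limit handling for one analyte/assay.

    ``blq_mode`` is ``"phase"`` (zero in absorption phase, exclude in
    elimination phase, as for the intensive healthy-volunteer assay) or
    ``"range"`` (exclude everything outside [lloq, uloq], as for the TDM
    assay).
    """

    lloq: float
    uloq: float
    blq_mode: str = "range"

    def __post_init__(self) -> None:
        if not (0.0 < self.lloq < self.uloq):
            raise ConfigurationError("need 0 < lloq < uloq")
        if self.blq_mode not in ("phase", "range"):
            raise ConfigurationError(f"unknown blq_mode {self.blq_mode!r}")


#: Default quantitation rules, keyed by (DVID, MORBID).
DEFAULT_RULES: dict[tuple[int, int], QuantRule] = {
    (DVID_VEN, 0): QuantRule(0.2, 200.0, "phase"),
    (DVID_VEN, 1): QuantRule(4.0, 400.0, "range"),
    (DVID_ODV, 1): QuantRule(20.0, 2000.0, "range"),
}


@dataclass
class ExclusionReport:
    """Bookkeeping of quantitation-rule processing."""

    n_input: int = 0
    n_retained: int = 0
    n_zeroed_absorption: int = 0
    n_excluded_elimination_blq: int = 0
    n_excluded_below_range: int = 0
    n_excluded_above_range: int = 0

    @property
    def n_excluded(self) -> int:
        return (
            self.n_excluded_elimination_blq
            + self.n_excluded_below_range
            + self.n_excluded_above_range
        )

    def to_tsv(self) -> str:
        rows = [("category", "count")] + [
            (f.name, str(getattr(self, f.name))) for f in dataclasses.fields(self)
        ]
        return "\n".join("\t".join(r) for r in rows) + "\n"


class Dataset:
    """An ordered event stream with per-assay quantitation rules.

    Thin wrapper around a typed :class:`pandas.DataFrame` in the dialect
    described in the module docstring.
    """

    def __init__(self, df: pd.DataFrame, rules: Mapping[tuple[int, int], QuantRule] | None = None):
        missing = [c for c in ALL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"dataset missing columns: {missing}")
        self.df = df.reset_index(drop=True)[ALL_COLUMNS].copy()
        self.rules = dict(DEFAULT_RULES if rules is None else rules)
        self.validate()

    # -- construction ------------------------------------------------------
    @classmethod
    def from_records(
        cls,
        records: list[PKRecord],
        rules: Mapping[tuple[int, int], QuantRule] | None = None,
    ) -> "Dataset":
        rows = []
        for rec in records:
            cov = rec.covariates.as_dict()
            row = {
                "ID": rec.subject_id,
                "TIME": rec.time,
                "EVID": 1 if rec.event_type == "dose" else 0,
                "AMT": rec.amount if rec.event_type == "dose" else np.nan,
                "DVID": ANALYTE_DVID[rec.analyte] if rec.analyte else 0,
                "DV": rec.dv if rec.event_type == "observation" else np.nan,
                "MDV": 1 if rec.event_type == "dose" else 0,
                "SS": int(rec.steady_state),
                "II": rec.interdose_interval,
                "ADDL": rec.n_additional_doses,
                "BLQ": int(rec.below_lloq),
            }
            row.update({col: cov[f] for f, col in COVARIATE_COLUMNS.items()})
            rows.append(row)
        df = pd.DataFrame(rows, columns=ALL_COLUMNS)
        return cls(df, rules)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        df = self.df
        problems: list[str] = []
        if (df["TIME"] < 0).any():
            bad = df.index[df["TIME"] < 0][0]
            problems.append(f"row {bad}: negative TIME")
        obs = df["EVID"] == 0
        dose = df["EVID"] == 1
        if not (obs | dose).all():
            bad = df.index[~(obs | dose)][0]
            problems.append(f"row {bad}: EVID must be 0 or 1")
        bad_obs_amt = obs & df["AMT"].notna() & (df["AMT"] != 0)
        if bad_obs_amt.any():
            problems.append(
                f"row {df.index[bad_obs_amt][0]}: observation row carries a dose amount"
            )
        bad_dose_dv = dose & df["DV"].notna()
        if bad_dose_dv.any():
            problems.append(f"row {df.index[bad_dose_dv][0]}: dose row carries a DV")
        bad_dvid = obs & ~df["DVID"].isin([DVID_VEN, DVID_ODV])
        if bad_dvid.any():
            problems.append(f"row {df.index[bad_dvid][0]}: observation with invalid DVID")
        bad_amt = dose & (df["AMT"].isna() | (df["AMT"] <= 0))
        if bad_amt.any():
            problems.append(f"row {df.index[bad_amt][0]}: dose row without positive AMT")
        for sid, sub in df.groupby("ID", sort=False):
            if (np.diff(sub["TIME"].to_numpy()) < 0).any():
                problems.append(f"subject {sid}: times not non-decreasing")
            if (sub["EVID"] == 0).any() and not (sub["EVID"] == 1).any():
                problems.append(f"subject {sid}: observations without any dose")
        if problems:
            raise ValidationError("; ".join(problems))

    # -- convenience -------------------------------------------------------
    @property
    def subject_ids(self) -> np.ndarray:
        return self.df["ID"].unique()

    @property
    def n_observations(self) -> int:
        return int((self.df["EVID"] == 0).sum())

    def copy(self) -> "Dataset":
        return Dataset(self.df.copy(), self.rules)


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write the CSV dialect; floats keep full repr fidelity."""
    df = dataset.df.copy()
    for col in ("ID", "EVID", "MDV", "SS", "ADDL", "BLQ", "DVID"):
        df[col] = df[col].astype(int)
    df.to_csv(path, index=False, na_rep="")


def read_dataset(
    path: str | Path,
    rules: Mapping[tuple[int, int], QuantRule] | None = None,
) -> Dataset:
    """Read the CSV dialect into a validated :class:`Dataset`.

    Unparseable rows and schema violations raise :class:`SchemaError` /
    :class:`ValidationError` carrying the offending line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SchemaError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in ALL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    for col in ALL_COLUMNS:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            newly_bad = coerced.isna() & df[col].notna()
            if newly_bad.any():
                lines = [i + 2 for i in df.index[newly_bad][:5]]  # 1-based + header
                raise SchemaError(f"{path}: non-numeric {col} at line(s) {lines}")
            df[col] = coerced
    return Dataset(df, rules)


# ---------------------------------------------------------------------------
# Quantitation-limit processing
# ---------------------------------------------------------------------------


def _interval_index(sub: pd.DataFrame) -> np.ndarray:
    """Index of the most recent dose row at or before each row (doses sort
    first at shared times because they precede observations in the file)."""
    is_dose = (sub["EVID"] == 1).to_numpy()
    return np.maximum(np.cumsum(is_dose) - 1, 0)


def apply_blq_rules(dataset: Dataset) -> tuple[Dataset, ExclusionReport]:
    """Apply per-assay quantitation rules.

    Phase-mode assays retain below-limit absorption-phase observations with
    DV set to 0 and drop below-limit elimination-phase observations;
    range-mode assays drop anything outside [lloq, uloq].  Idempotent: a
    second application changes nothing and excludes nothing.
    """
    df = dataset.df.copy()
    report = ExclusionReport(n_input=int((df["EVID"] == 0).sum()))
    drop = np.zeros(len(df), dtype=bool)
    zero = np.zeros(len(df), dtype=bool)

    for (sid,), sub in df.groupby(["ID"], sort=False):
        interval = _interval_index(sub)
        obs_mask = (sub["EVID"] == 0).to_numpy()
        for pos_local in np.nonzero(obs_mask)[0]:
            row = sub.iloc[pos_local]
            key = (int(row["DVID"]), int(row["MORBID"]))
            rule = dataset.rules.get(key)
            if rule is None:
                raise ConfigurationError(
                    f"no quantitation rule for DVID={key[0]}, MORBID={key[1]}"
                )
            dv = row["DV"]
            idx_global = sub.index[pos_local]
            if rule.blq_mode == "range":
                if dv < rule.lloq:
                    drop[idx_global] = True
                    report.n_excluded_below_range += 1
                elif dv > rule.uloq:
                    drop[idx_global] = True
                    report.n_excluded_above_range += 1
            else:  # phase
                if dv > rule.uloq:
                    drop[idx_global] = True
                    report.n_excluded_above_range += 1
                elif dv < rule.lloq:
                    if bool(row["BLQ"]) and dv == 0.0:
                        continue  # already zeroed on a previous pass
                    same = (
                        obs_mask
                        & (sub["DVID"].to_numpy() == row["DVID"])
                        & (interval == interval[pos_local])
                    )
                    tmax_time = sub["TIME"].to_numpy()[same][
                        np.argmax(sub["DV"].to_numpy()[same])
                    ]
                    if row["TIME"] <= tmax_time:
                        zero[idx_global] = True
                        report.n_zeroed_absorption += 1
                    else:
                        drop[idx_global] = True
                        report.n_excluded_elimination_blq += 1

    df.loc[zero, "DV"] = 0.0
    df.loc[zero, "BLQ"] = 1
    df = df.loc[~drop].reset_index(drop=True)
    report.n_retained = int((df["EVID"] == 0).sum())
    return Dataset(df, dataset.rules), report


# ---------------------------------------------------------------------------
# Per-subject assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectData:
    """One subject's regimen, observation vectors and covariates.

    Observation times are hours since the subject's first dose.
    """

    subject_id: int
    regimen: Regimen
    times: dict[str, np.ndarray]
    dv: dict[str, np.ndarray]
    blq: dict[str, np.ndarray]
    covariates: CovariateSet


def build_subject(dataset: Dataset, subject_id: int) -> SubjectData:
    """Assemble one subject into model-ready structures."""
    sub = dataset.df[dataset.df["ID"] == subject_id]
    if sub.empty:
        raise ValidationError(f"subject {subject_id} not in dataset")
    doses = sub[sub["EVID"] == 1]
    obs = sub[sub["EVID"] == 0]
    if doses.empty:
        raise ValidationError(f"subject {subject_id} has no dose records")
    t0 = float(doses["TIME"].iloc[0])
    if (obs["TIME"] < t0).any():
        raise ValidationError(f"subject {subject_id}: observation before any dose")
    events = [
        DoseEvent(
            time=float(r["TIME"]) - t0,
            amount=float(r["AMT"]),
            interdose_interval=float(r["II"]),
            n_additional_doses=int(r["ADDL"]),
            steady_state=bool(r["SS"]),
        )
        for _, r in doses.iterrows()
    ]
    times: dict[str, np.ndarray] = {}
    dv: dict[str, np.ndarray] = {}
    blq: dict[str, np.ndarray] = {}
    for dvid, name in ANALYTE_NAME.items():
        sel = obs[obs["DVID"] == dvid]
        times[name] = sel["TIME"].to_numpy(dtype=float) - t0
        dv[name] = sel["DV"].to_numpy(dtype=float)
        blq[name] = sel["BLQ"].to_numpy(dtype=bool)
    first = sub.iloc[0]
    cov = CovariateSet(**{f: float(first[col]) for f, col in COVARIATE_COLUMNS.items()})
    return SubjectData(
        subject_id=int(subject_id),
        regimen=Regimen.from_events(events),
        times=times,
        dv=dv,
        blq=blq,
        covariates=cov,
    )
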