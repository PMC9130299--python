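"""Multi-omic cohort containers, delimited-table I/O, and MGMT calling.

A cohort bundles four aligned tables keyed by ``patient_id``:

* clinical — age (years), gender, extent of resection, MGMT status
* features — real-valued radiomic columns tagged ``conventional`` or ``deep``
  (column names are prefixed ``conv_`` / ``deep_``; image processing is
  upstream and the matrix is consumed as given)
* mutations — binary gene-mutation indicators over a fixed gene panel
* survival — overall survival in months, fully observed (no censoring)

Missing cells are forbidden throughout; the loaders fail loudly on schema,
alignment, or missingness problems rather than imputing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GENE_PANEL",
    "SchemaError",
    "AlignmentError",
    "ValidationError",
    "PatientRecord",
    "Cohort",
    "MgmtAssay",
    "classify_mgmt_status",
    "read_cohort",
    "write_cohort",
    "summarize_cohort",
    "encode_covariates",
]

#: Genes shared by the two sequencing panels; the mutation matrix is defined
#: over (a subset of) this panel.
GENE_PANEL: tuple[str, ...] = (
    "ARID2", "ATRX", "BRAF", "CDKN2A", "CIC", "DNMT3A", "EGFR", "FGFR2",
    "FUBP1", "IDH1", "IDH2", "KDR", "KRAS", "MDM4", "MET", "NF1", "NOTCH2",
    "NTRK1", "PDGFRA", "PIK3CA", "PIK3R1", "PTEN", "PTPN11", "RB1", "SETD2",
    "SMARCB1", "TP53",
)

GENDER_LEVELS = ("female", "male")
EOR_LEVELS = ("gross_or_near_total", "partial_or_biopsy")
MGMT_LEVELS = ("methylated", "unmethylated", "indeterminate")

#: Risk-extreme thresholds in months (short survivors vs long survivors).
HIGH_RISK_MONTHS = 6.0
LOW_RISK_MONTHS = 18.0


class SchemaError(ValueError):
    """A required column is missing or has an unknown level."""


class AlignmentError(ValueError):
    """Patient ids disagree between tables."""


class ValidationError(ValueError):
    """A cohort invariant (no missing data, no censoring, ...) is violated."""


@dataclass
class PatientRecord:
    patient_id: str
    age: float
    gender: str
    eor: str
    mgmt: str
    mutations: dict[str, str]
    os_months: float
    event_observed: bool = True


@dataclass
class Cohort:
    """Aligned multi-omic tables for one patient cohort.

    All frames are indexed by ``patient_id`` in an identical order; the
    constructor enforces the bijection, uniqueness, completeness, and the
    no-censoring contract.
    """

    clinical: pd.DataFrame
    features: pd.DataFrame
    mutations: pd.DataFrame
    survival: pd.DataFrame
    role: str = "discovery"
    gene_panel: tuple[str, ...] = GENE_PANEL

    def __post_init__(self) -> None:
        ids = self.clinical.index
        if ids.has_duplicates:
            dupes = ids[ids.duplicated()].unique().tolist()
            raise AlignmentError(f"duplicate patient ids: {dupes}")
        for name, frame in (
            ("features", self.features),
            ("mutations", self.mutations),
            ("survival", self.survival),
        ):
            if not frame.index.equals(ids):
                missing = sorted(set(ids) ^ set(frame.index))
                raise AlignmentError(
                    f"{name} table is not aligned with clinical; "
                    f"mismatched ids: {missing[:10]}"
                )
        for name, frame in self.tables().items():
            if frame.isna().any().any():
                bad = frame.columns[frame.isna().any()].tolist()
                raise ValidationError(
                    f"missing values in {name} table (columns {bad}); "
                    "the data model forbids missingness"
                )
        unknown = set(self.mutations.columns) - set(self.gene_panel)
        if unknown:
            raise ValidationError(
                f"mutation genes outside the configured panel: {sorted(unknown)}"
            )
        os_m = self.survival["os_months"].to_numpy(dtype=float)
        if not np.all(np.isfinite(os_m)) or np.any(os_m < 0):
            raise ValidationError("os_months must be finite and non-negative")
        if not self.survival["event_observed"].astype(bool).all():
            raise ValidationError(
                "event_observed must be true for every patient (no censoring)"
            )
        for col, levels in (("gender", GENDER_LEVELS), ("eor", EOR_LEVELS),
                            ("mgmt", MGMT_LEVELS)):
            bad = set(self.clinical[col].unique()) - set(levels)
            if bad:
                raise SchemaError(f"unknown {col} level(s): {sorted(bad)}")
        vals = self.mutations.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("mutation table must be binary 0/1")

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "clinical": self.clinical,
            "features": self.features,
            "mutations": self.mutations,
            "survival": self.survival,
        }

    @property
    def patient_ids(self) -> pd.Index:
        return self.clinical.index

    @property
    def n_patients(self) -> int:
        return len(self.clinical)

    @property
    def os_months(self) -> pd.Series:
        return self.survival["os_months"].astype(float)

    @property
    def modality_tags(self) -> pd.Series:
        """Per-feature modality derived from the column-name prefix."""
        return pd.Series(
            ["conventional" if c.startswith("conv_") else "deep"
             for c in self.features.columns],
            index=self.features.columns,
        )

    @property
    def records(self) -> list[PatientRecord]:
        recs = []
        for pid in self.patient_ids:
            row = self.clinical.loc[pid]
            muts = {
                g: ("mutated" if self.mutations.loc[pid, g] else "wildtype")
                for g in self.mutations.columns
            }
            recs.append(PatientRecord(
                patient_id=str(pid), age=float(row["age"]),
                gender=str(row["gender"]), eor=str(row["eor"]),
                mgmt=str(row["mgmt"]), mutations=muts,
                os_months=float(self.survival.loc[pid, "os_months"]),
            ))
        return recs


@dataclass
class MgmtAssay:
    """Pyrosequencing percent methylation at 4 promoter CpG sites."""

    cpg_percent: Sequence[float]
    detection_limit: float = 4.5
    call_threshold: float = 10.0

    def __post_init__(self) -> None:
        if len(self.cpg_percent) != 4:
            raise ValueError("exactly 4 CpG percentages are required")
        arr = np.asarray(self.cpg_percent, dtype=float)
        if np.any(arr < 0) or np.any(arr > 100):
            raise ValueError("CpG percentages must lie in [0, 100]")
        if not (0 < self.detection_limit < self.call_threshold):
            raise ValueError("need 0 < detection_limit < call_threshold")


def classify_mgmt_status(assay: MgmtAssay) -> str:
    """Call MGMT promoter methylation from a 4-CpG pyrosequencing assay.

    ``methylated`` iff both the mean and the median across the 4 sites are at
    or above the call threshold (10%); ``not_detected`` iff both fall below
    the detection limit (4.5%); everything else is ``low_positive``.
    """
    vals = np.asarray(assay.cpg_percent, dtype=float)
    mean, median = vals.mean(), float(np.median(vals))
    if mean >= assay.call_threshold and median >= assay.call_threshold:
        return "methylated"
    if mean < assay.detection_limit and median < assay.detection_limit:
        return "not_detected"
    return "low_positive"


def _read_table(path: str | os.PathLike) -> pd.DataFrame:
    # comma default, tab accepted: sniff the delimiter
    df = pd.read_csv(path, sep=None, engine="python")
    if "patient_id" not in df.columns:
        raise SchemaError(f"{path}: required column 'patient_id' is missing")
    return df.set_index(df["patient_id"].astype(str)).drop(columns="patient_id")


def _require(df: pd.DataFrame, cols: Iterable[str], label: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{label} table is missing column(s): {missing}")


def read_cohort(
    clinical_path,
    features_path,
    mutations_path,
    survival_path,
    role: str = "discovery",
    gene_panel: Sequence[str] = GENE_PANEL,
) -> Cohort:
    """Read and validate the four cohort tables, aligning rows by patient_id."""
    clinical = _read_table(clinical_path)
    features = _read_table(features_path)
    mutations = _read_table(mutations_path)
    survival = _read_table(survival_path)

    _require(clinical, ("age", "gender", "eor", "mgmt"), "clinical")
    _require(survival, ("os_months",), "survival")
    if "event_observed" not in survival.columns:
        survival["event_observed"] = True

    base = set(clinical.index)
    for name, df in (("features", features), ("mutations", mutations),
                     ("survival", survival)):
        if set(df.index) != base:
            only = sorted(base ^ set(df.index))
            raise AlignmentError(
                f"patient ids in {name} differ from clinical: {only[:10]}"
            )
    order = clinical.index
    return Cohort(
        clinical=clinical,
        features=features.loc[order].astype(float),
        mutations=mutations.loc[order].astype(int),
        survival=survival.loc[order],
        role=role,
        gene_panel=tuple(gene_panel),
    )


def write_cohort(cohort: Cohort, outdir: str | os.PathLike) -> dict[str, str]:
    """Write the four cohort tables as CSV files; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for name, frame in cohort.tables().items():
        path = os.path.join(outdir, f"{name}.csv")
        frame.rename_axis("patient_id").to_csv(path)
        paths[name] = path
    return paths


def _table1_pct(count: int, total: int) -> float:
    """Percentage rounded the way cohort summary tables print them.

    Integer precision, except one decimal is kept when the exact value has
    exactly one decimal (42/112 → 37.5, 176/404 → 44).
    """
    pct = 100.0 * count / total
    one_dec = round(pct, 1)
    if abs(one_dec - pct) < 1e-9 and abs(one_dec - round(pct)) > 1e-9:
        return one_dec
    return float(round(pct))


def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """Cohort characteristics: counts/percentages per categorical block,
    median ± std survival, and the numbers of risk-extreme patients
    (OS < 6 months, OS ≥ 18 months)."""
    if cohort.n_patients == 0:
        raise ValidationError("cannot summarize an empty cohort")
    n = cohort.n_patients
    rows: list[dict] = [
        {"block": "demographics", "item": "n_patients", "count": n,
         "percent": np.nan, "value": np.nan}
    ]
    for block, col, levels in (
        ("gender", "gender", GENDER_LEVELS),
        ("eor", "eor", EOR_LEVELS),
        ("mgmt", "mgmt", MGMT_LEVELS),
    ):
        counts = cohort.clinical[col].value_counts()
        for level in levels:
            c = int(counts.get(level, 0))
            rows.append({"block": block, "item": level, "count": c,
                         "percent": _table1_pct(c, n), "value": np.nan})
    os_m = cohort.os_months.to_numpy()
    rows.append({"block": "survival", "item": "median_os_months",
                 "count": np.nan, "percent": np.nan,
                 "value": float(np.median(os_m))})
    rows.append({"block": "survival", "item": "std_os_months",
                 "count": np.nan, "percent": np.nan,
                 "value": float(np.std(os_m, ddof=1)) if n > 1 else 0.0})
    rows.append({"block": "risk_extremes", "item": "high_risk_os_lt_6",
                 "count": int(np.sum(os_m < HIGH_RISK_MONTHS)),
                 "percent": np.nan, "value": np.nan})
    rows.append({"block": "risk_extremes", "item": "low_risk_os_ge_18",
                 "count": int(np.sum(os_m >= LOW_RISK_MONTHS)),
                 "percent": np.nan, "value": np.nan})
    return pd.DataFrame(rows)


def encode_covariates(
    cohort: Cohort, low_positive_as_methylated: bool = False
) -> pd.DataFrame:
    """Numeric clinical design columns for regression.

    female=1/male=0; gross-or-near-total resection=1; MGMT methylated=1
    (``indeterminate`` maps to 0 — unmethylated-like — matching the
    two-level modelling of MGMT).
    """
    cl = cohort.clinical
    mgmt_pos = {"methylated"}
    if low_positive_as_methylated:
        mgmt_pos.add("low_positive")
    return pd.DataFrame(
        {
            "age": cl["age"].astype(float),
            "gender": (cl["gender"] == "female").astype(float),
            "eor": (cl["eor"] == "gross_or_near_total").astype(float),
            "mgmt": cl["mgmt"].isin(mgmt_pos).astype(float),
        },
        index=cohort.patient_ids,
    )
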