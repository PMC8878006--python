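"""Data model and I/O for LC-MS feature tables and crossover sample metadata.

A :class:`FeatureTable` holds a samples x features intensity matrix (NaN
marks a missing measurement; zero is a valid measured intensity) together
with per-feature m/z and retention-time metadata.  A :class:`StudyDesign`
holds the per-sample crossover factors: subject, phase (baseline, placebo
or oleuropein), week, day, injection order and a QC flag.

On disk a feature table is a CSV/TSV with features as rows: ``feature_id,
mz, rt, polarity[, matrix_origin]`` followed by one column per sample.
The loader also accepts the transposed (samples-as-rows) orientation and
detects it from the reserved ``mz``/``rt`` header names.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHASES = ("baseline", "placebo", "oleuropein")
QC_PHASE = "qc"

_RESERVED_META = ["mz", "rt", "polarity", "matrix_origin"]
_DESIGN_COLUMNS = ["subject", "phase", "week", "day", "injection_order", "is_qc"]


class DesignError(ValueError):
    """Raised when a table or design violates its structural invariants."""


def _check_unique(ids, what: str) -> None:
    counts = pd.Series(ids).value_counts()
    dups = counts[counts > 1].index.tolist()
    if dups:
        raise DesignError(f"duplicate {what}: {dups}")


@dataclass
class FeatureTable:
    """Samples x features intensity matrix with per-feature metadata.

    Parameters
    ----------
    intensities : DataFrame
        Rows indexed by sample id, columns by feature id.  ``NaN`` encodes
        a missing measurement; observed values must be >= 0.
    feature_meta : DataFrame
        Indexed by feature id with at least ``mz`` (Th, > 0) and ``rt``
        (minutes, >= 0); optional ``polarity`` and ``matrix_origin``.
    """

    intensities: pd.DataFrame
    feature_meta: pd.DataFrame
    raw: bool = True  # False after centering/transforming (negatives allowed)

    def __post_init__(self) -> None:
        _check_unique(self.intensities.index, "sample ids")
        _check_unique(self.intensities.columns, "feature ids")
        if not self.feature_meta.index.equals(self.intensities.columns):
            self.feature_meta = self.feature_meta.reindex(self.intensities.columns)
        if self.feature_meta["mz"].isna().any():
            missing = self.feature_meta.index[self.feature_meta["mz"].isna()].tolist()
            raise DesignError(f"features without metadata: {missing}")
        vals = self.intensities.to_numpy(dtype=float)
        neg = np.argwhere(vals < 0) if self.raw else np.empty((0, 2), int)
        if neg.size:
            i, j = neg[0]
            raise DesignError(
                f"negative intensity at sample {self.intensities.index[i]!r}, "
                f"feature {self.intensities.columns[j]!r}"
            )
        if (self.feature_meta["mz"] <= 0).any():
            raise DesignError("feature m/z must be > 0")
        if "rt" in self.feature_meta and (self.feature_meta["rt"] < 0).any():
            raise DesignError("feature rt must be >= 0")

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.intensities.index)

    @property
    def feature_ids(self) -> list:
        return list(self.intensities.columns)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.intensities.to_numpy(dtype=float)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.intensities.copy(), self.feature_meta.copy(), self.raw)

    def with_values(self, values: np.ndarray, raw: bool | None = None) -> "FeatureTable":
        """Return a copy carrying ``values`` in place of the intensity matrix."""
        if values.shape != self.intensities.shape:
            raise DesignError(
                f"shape mismatch: {values.shape} vs {self.intensities.shape}"
            )
        df = pd.DataFrame(
            values, index=self.intensities.index, columns=self.intensities.columns
        )
        return FeatureTable(df, self.feature_meta.copy(),
                            self.raw if raw is None else raw)

    def subset_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.intensities.loc[list(sample_ids)],
                            self.feature_meta.copy(), self.raw)


@dataclass
class StudyDesign:
    """Per-sample crossover factors, indexed by sample id.

    Non-QC samples carry subject (label in a finite roster), phase
    (baseline/placebo/oleuropein), week (1 or 2), day (1-2 for baseline
    days, 1-5 for administration days) and a unique positive injection
    order.  QC rows have ``is_qc`` true and phase ``"qc"``.
    """

    samples: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.samples.index, "sample ids")
        missing = [c for c in _DESIGN_COLUMNS if c not in self.samples.columns]
        if missing:
            raise DesignError(f"design missing columns: {missing}")
        df = self.samples
        bad = df.loc[~df["is_qc"] & ~df["phase"].isin(PHASES)]
        if len(bad):
            raise DesignError(
                f"unknown phase label(s) {sorted(bad['phase'].unique())} "
                f"in rows {bad.index.tolist()}"
            )
        orders = df["injection_order"]
        if (orders < 1).any():
            raise DesignError("injection orders must be positive")
        _check_unique(orders, "injection orders")

    @property
    def sample_ids(self) -> list:
        return list(self.samples.index)

    @property
    def non_qc(self) -> pd.DataFrame:
        return self.samples.loc[~self.samples["is_qc"]]

    @property
    def qc(self) -> pd.DataFrame:
        return self.samples.loc[self.samples["is_qc"]]

    @property
    def subjects(self) -> list:
        return sorted(self.non_qc["subject"].unique())

    def subset(self, sample_ids) -> "StudyDesign":
        return StudyDesign(self.samples.loc[list(sample_ids)].copy())

    def copy(self) -> "StudyDesign":
        return StudyDesign(self.samples.copy())


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_crossover`; balanced iff no issues."""

    n_subjects: int
    n_samples_expected: int
    n_samples_found: int
    issues: list = field(default_factory=list)

    @property
    def balance_ok(self) -> bool:
        return not self.issues


# ---------------------------------------------------------------------------
# feature-table I/O
# ---------------------------------------------------------------------------

def _sep(dialect: str) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    raise DesignError(f"unknown dialect {dialect!r}")


def load_feature_table(path, dialect: str = "csv") -> FeatureTable:
    """Load a feature table CSV/TSV, auto-detecting on-disk orientation.

    Empty cells become missing markers (NaN), never zero.
    """
    raw = pd.read_csv(path, sep=_sep(dialect), dtype={0: str})
    first = raw.columns[0]
    header = set(raw.columns)
    if {"mz", "rt"} <= header:
        # features-as-rows layout
        _check_unique(raw[first], "feature ids")
        raw = raw.set_index(first)
        meta_cols = [c for c in _RESERVED_META if c in raw.columns]
        meta = raw[meta_cols].copy()
        meta["mz"] = meta["mz"].astype(float)
        meta["rt"] = meta["rt"].astype(float)
        data = raw.drop(columns=meta_cols).astype(float)
        return FeatureTable(data.T, meta)
    if {"mz", "rt"} <= set(raw[first].astype(str)):
        # samples-as-rows layout: metadata stored as reserved rows
        raw = raw.set_index(first)
        meta_rows = [r for r in _RESERVED_META if r in raw.index]
        meta = raw.loc[meta_rows].T
        meta["mz"] = meta["mz"].astype(float)
        meta["rt"] = meta["rt"].astype(float)
        data = raw.drop(index=meta_rows).astype(float)
        _check_unique(data.index, "sample ids")
        return FeatureTable(data, meta)
    raise DesignError("cannot detect orientation: no reserved mz/rt headers found")


def write_feature_table(table: FeatureTable, path, dialect: str = "csv") -> None:
    """Write the features-as-rows CSV/TSV layout; NaN becomes an empty cell."""
    meta_cols = [c for c in _RESERVED_META if c in table.feature_meta.columns]
    out = pd.concat([table.feature_meta[meta_cols], table.intensities.T], axis=1)
    out.index.name = "feature_id"
    out.to_csv(path, sep=_sep(dialect))


def load_design(path) -> StudyDesign:
    df = pd.read_csv(path, dtype={"sample_id": str, "subject": str, "phase": str})
    missing = [c for c in ["sample_id"] + _DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise DesignError(f"design file missing columns: {missing}")
    df = df.set_index("sample_id")
    df["week"] = df["week"].astype(int)
    df["day"] = df["day"].astype(int)
    df["injection_order"] = df["injection_order"].astype(int)
    df["is_qc"] = df["is_qc"].astype(bool)
    return StudyDesign(df)


def write_design(design: StudyDesign, path) -> None:
    out = design.samples.copy()
    out.index.name = "sample_id"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# crossover validation
# ---------------------------------------------------------------------------

def validate_crossover(
    design: StudyDesign,
    n_weeks: int = 2,
    n_baseline_days: int = 2,
    n_admin_days: int = 5,
) -> ValidationReport:
    """Check a crossover layout for balance and completeness.

    Expected sample count is ``n_subjects * n_weeks * (baseline + admin
    days)``; each subject must appear in both weeks, receive each of
    placebo and oleuropein in exactly one week, and have a complete day
    series.  Problems are reported, never raised.
    """
    df = design.non_qc
    issues: list[str] = []
    subjects = sorted(df["subject"].unique())
    expected = len(subjects) * n_weeks * (n_baseline_days + n_admin_days)

    for subj in subjects:
        sub = df.loc[df["subject"] == subj]
        weeks = set(sub["week"])
        if weeks != set(range(1, n_weeks + 1)):
            issues.append(f"subject {subj}: present in weeks {sorted(weeks)}, "
                          f"expected 1..{n_weeks}")
            continue
        admin_phases = []
        for week in range(1, n_weeks + 1):
            wk = sub.loc[sub["week"] == week]
            admin = wk.loc[wk["phase"] != "baseline"]
            phases = set(admin["phase"])
            if len(phases) != 1:
                issues.append(
                    f"subject {subj} week {week}: administration phases {sorted(phases)}"
                )
                continue
            admin_phases.append(next(iter(phases)))
            base_days = sorted(wk.loc[wk["phase"] == "baseline", "day"])
            if base_days != list(range(1, n_baseline_days + 1)):
                issues.append(
                    f"subject {subj} week {week}: baseline days {base_days}"
                )
            admin_days = sorted(admin["day"])
            if admin_days != list(range(1, n_admin_days + 1)):
                issues.append(
                    f"subject {subj} week {week}: administration days {admin_days}"
                )
        if len(admin_phases) == n_weeks and len(set(admin_phases)) != min(n_weeks, 2):
            issues.append(
                f"subject {subj}: same treatment ({admin_phases[0]}) in every week"
            )

    dup = df.reset_index().duplicated(subset=["subject", "phase", "week", "day"])
    if dup.any():
        issues.append(f"{int(dup.sum())} duplicate (subject, phase, week, day) rows")

    return ValidationReport(
        n_subjects=len(subjects),
        n_samples_expected=expected,
        n_samples_found=len(df),
        issues=issues,
    )
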