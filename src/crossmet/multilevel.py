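"""Crossover variance decomposition and multilevel sPLS-DA.

In a crossover study the total variation is a sum of within-subject,
between-subject, week, day and analytical components.  Treatment effects
are typically dwarfed by between-subject variation, so a plain
discriminant model fails; removing the offending component first — the
multilevel step — exposes the effect.

:func:`remove_variation` splits a data matrix into the between-group
component of a chosen grouping (subject, week, day, ...) and a residual
that keeps the grand mean, with exact sum-of-squares additivity.
:class:`MultilevelSPLSDA` chains this with an sPLS-DA fit on one- or
two-factor class encodings (e.g. keep phase, or phase x day, subtract
subject).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design_io import FeatureTable, StudyDesign, DesignError
from .splsda import SPLSDA, SPLSDAResults, SplsdaError

FACTORS = ("phase", "week", "day", "subject")


@dataclass
class Grouping:
    """A named per-sample level assignment used for variance removal."""

    name: str
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.size == 0:
            raise DesignError("grouping must cover at least one sample")

    @classmethod
    def from_design(cls, design: StudyDesign, factor: str,
                    sample_ids=None, nested_in_subject: bool = False) -> "Grouping":
        """Grouping by a design factor; optionally nested within subject.

        With ``nested_in_subject`` the levels are (subject, factor) pairs,
        so e.g. week centering happens within each subject separately.
        """
        if factor not in FACTORS:
            raise DesignError(f"unknown factor {factor!r}; choose from {FACTORS}")
        df = design.samples if sample_ids is None else design.samples.loc[list(sample_ids)]
        labels = df[factor].astype(str)
        if nested_in_subject and factor != "subject":
            labels = df["subject"].astype(str) + "/" + labels
            return cls(f"subject:{factor}", labels.to_numpy())
        return cls(factor, labels.to_numpy())


@dataclass
class DecompositionResult:
    """Split of X into residual + removed between-group component.

    ``residual = X - group_mean + grand_mean`` row-wise, so the grand
    mean (hence the intensity scale) is retained in the residual;
    ``removed = group_mean - grand_mean``.  Sum-of-squares additivity
    ``ss_between + ss_residual = ss_total`` holds about the grand mean.
    """

    residual: np.ndarray
    removed: np.ndarray
    ss_between_groups: float
    ss_residual: float
    ss_total: float
    grouping: Grouping


def remove_variation(X, grouping: Grouping) -> DecompositionResult:
    """Subtract the between-group component of ``grouping`` from X."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DesignError("X must be 2-dimensional")
    if len(grouping.labels) != X.shape[0]:
        raise DesignError(
            f"grouping covers {len(grouping.labels)} rows, X has {X.shape[0]}"
        )
    grand = X.mean(axis=0)
    residual = np.empty_like(X)
    removed = np.empty_like(X)
    ss_between = 0.0
    for level in pd.unique(grouping.labels):
        idx = np.flatnonzero(grouping.labels == level)
        gmean = X[idx].mean(axis=0)
        residual[idx] = X[idx] - gmean + grand
        removed[idx] = gmean - grand
        ss_between += len(idx) * float(np.sum((gmean - grand) ** 2))
    ss_total = float(np.sum((X - grand) ** 2))
    ss_residual = float(np.sum((residual - grand) ** 2))
    return DecompositionResult(residual, removed, ss_between, ss_residual,
                               ss_total, grouping)


def encode_classes(
    design: StudyDesign,
    factors,
    include_baseline: bool = False,
) -> pd.Series:
    """Class labels from one or two design factors.

    Samples are restricted to administration days with phase placebo or
    oleuropein unless ``include_baseline`` is set or the only factor is
    ``subject``.  Two factors produce interaction labels.  Returns a
    Series indexed by the retained sample ids.
    """
    factors = list(factors)
    if not 1 <= len(factors) <= 2:
        raise DesignError("factors must contain 1 or 2 entries")
    for f in factors:
        if f not in FACTORS:
            raise DesignError(f"unknown factor {f!r}")
    df = design.non_qc
    subject_only = factors == ["subject"]
    if not (include_baseline or subject_only):
        df = df.loc[df["phase"].isin(["placebo", "oleuropein"])]
    if "phase" in factors and df["phase"].isin(["placebo", "oleuropein"]).sum() == 0:
        raise DesignError("phase labels requested but no placebo/oleuropein samples")
    if df.empty:
        raise DesignError("no samples left after restriction")
    parts = [df[f].astype(str) for f in factors]
    labels = parts[0] if len(parts) == 1 else parts[0] + ":" + parts[1]
    labels.name = "+".join(factors)
    return labels


class MultilevelSPLSDA:
    """Multilevel sPLS-DA: variance removal followed by sparse PLS-DA.

    Parameters
    ----------
    table : FeatureTable
        Preprocessed intensities (the matrix is used as given).
    design : StudyDesign
        Crossover factors per sample.
    discriminant : sequence of str
        One or two factors kept as the discriminant encoding (one-level /
        two-level analysis).
    subtract : str or Grouping
        Variance component removed before fitting (e.g. ``"subject"``).
        Must not overlap the discriminant factors.
    nested : bool
        Center the subtracted factor within subject instead of marginally.
    """

    def __init__(self, table: FeatureTable, design: StudyDesign,
                 discriminant=("phase",), subtract="subject",
                 n_components: int = 2, keepx=None, scale: bool = False,
                 nested: bool = False, include_baseline: bool = False):
        self.table = table
        self.design = design
        self.discriminant = list(discriminant)
        self.subtract = subtract
        sub_name = subtract if isinstance(subtract, str) else subtract.name
        if sub_name in self.discriminant:
            raise DesignError(
                f"subtracted factor {sub_name!r} overlaps the discriminant factors"
            )
        self.n_components = n_components
        self.keepx = keepx
        self.scale = scale
        self.nested = nested
        self.include_baseline = include_baseline

        self.class_series = encode_classes(design, self.discriminant,
                                           include_baseline=include_baseline)
        ids = self.class_series.index
        self.X = table.intensities.loc[ids].to_numpy(dtype=float)
        if np.isnan(self.X).any():
            raise DesignError("matrix contains missing values; impute first")
        if isinstance(subtract, Grouping):
            self.grouping = subtract
        else:
            self.grouping = Grouping.from_design(design, subtract, sample_ids=ids,
                                                 nested_in_subject=nested)

    def fit(self) -> "MultilevelSPLSDAResults":
        decomp = remove_variation(self.X, self.grouping)
        inner = SPLSDA(decomp.residual, self.class_series.to_numpy(),
                       n_components=self.n_components, keepx=self.keepx,
                       scale=self.scale).fit()
        return MultilevelSPLSDAResults(self, decomp, inner)


@dataclass
class MultilevelSPLSDAResults:
    """Fitted multilevel model; delegates to the inner sPLS-DA results."""

    model: MultilevelSPLSDA
    decomposition: DecompositionResult
    splsda: SPLSDAResults

    @property
    def sample_ids(self):
        return list(self.model.class_series.index)

    @property
    def feature_ids(self):
        return self.model.table.feature_ids

    @property
    def classes(self):
        return self.splsda.classes

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"X-variate {h + 1}" for h in range(self.splsda.n_components)]
        df = pd.DataFrame(self.splsda.x_scores, index=self.sample_ids, columns=cols)
        df["class"] = self.model.class_series.to_numpy()
        return df

    def summary(self) -> str:
        d = self.decomposition
        frac = d.ss_between_groups / d.ss_total if d.ss_total else 0.0
        head = [
            "Multilevel sparse PLS-DA",
            "=" * 46,
            f"discriminant factors: {' x '.join(self.model.discriminant)}",
            f"subtracted component: {d.grouping.name} "
            f"({frac:.1%} of total sum of squares)",
        ]
        return "\n".join(head) + "\n" + self.splsda.summary()

    def to_json(self) -> dict:
        d = self.decomposition
        return {
            "discriminant": self.model.discriminant,
            "subtracted": d.grouping.name,
            "class_map": {str(k): v for k, v in self.splsda.class_map.items()},
            "n_components": self.splsda.n_components,
            "keepx": list(map(int, self.splsda.keepx)),
            "ss_between_groups": d.ss_between_groups,
            "ss_residual": d.ss_residual,
            "ss_total": d.ss_total,
        }


def fit_mlsplsda(table: FeatureTable, design: StudyDesign, discriminant,
                 subtract, n_components: int = 2, keepx=None,
                 **kw) -> MultilevelSPLSDAResults:
    """Functional shorthand for ``MultilevelSPLSDA(...).fit()``."""
    return MultilevelSPLSDA(table, design, discriminant, subtract,
                            n_components=n_components, keepx=keepx, **kw).fit()
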