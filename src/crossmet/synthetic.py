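"""Synthetic crossover-study generator with a known variance decomposition.

Log intensities are built additively from the variance components of a
crossover design: a per-feature baseline, a between-subject random offset,
a week offset shared by all subjects, a day offset shared within each
(week, day) cell, a treatment contribution for affected features under
oleuropein, and analytical noise:

    log x(s, f) = baseline_f + subj(s, f) + week(s, f) + day(s, f)
                  + 1{phase = oleuropein, f affected}
                    * direction_f * effect_size * reset_profile[day(s)]
                  + noise(s, f)

Intensities are the exponential of this sum, so treatment effects are
multiplicative fold changes on the raw scale.  ``reset_profile`` scales
the treatment effect per administration day; a profile decaying to zero
reproduces the day-5 retraction of treated samples toward placebo (the
"metabolome reset" geometry).

Every realized component is returned in a :class:`GroundTruth` so that
downstream stages can be validated against exact arithmetic.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design_io import FeatureTable, StudyDesign, DesignError


@dataclass
class SyntheticSpec:
    """Parameters of the simulated crossover study.

    Defaults mirror the study layout (9 subjects, 2 crossover weeks of 2
    baseline + 5 administration days) and a regime where between-subject
    variation dominates the treatment effect, the situation that motivates
    multilevel analysis.  Standard deviations are on the natural-log
    intensity scale.
    """

    n_subjects: int = 9
    n_weeks: int = 2
    n_baseline_days: int = 2
    n_admin_days: int = 5
    n_features: int = 500
    n_affected: int = 50
    effect_size: float = 0.5
    sigma_between: float = 1.0
    sigma_week: float = 0.3
    sigma_day: float = 0.2
    sigma_error: float = 0.25
    reset_profile: tuple = (1.0, 0.9, 0.7, 0.4, 0.1)
    baseline_log_mean: float = 7.0
    baseline_log_sd: float = 1.0
    missing_rate: float = 0.0
    drift_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_between", "sigma_week", "sigma_day", "sigma_error",
                     "baseline_log_sd"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be >= 0")
        if not 0 <= self.n_affected <= self.n_features:
            raise DesignError("n_affected must be in [0, n_features]")
        if len(self.reset_profile) != self.n_admin_days:
            raise DesignError("reset_profile length must equal n_admin_days")
        if any(not 0 <= v <= 1 for v in self.reset_profile):
            raise DesignError("reset_profile values must lie in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise DesignError("missing_rate must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Realized per-cell components of the generated log intensities.

    ``log_total`` equals ``baseline + subject + week + day + treatment +
    noise`` exactly (cellwise), before any missingness is applied.
    """

    affected_feature_ids: list
    effect_directions: pd.Series
    baseline: pd.Series                 # per feature
    subject_component: pd.DataFrame     # samples x features
    week_component: pd.DataFrame
    day_component: pd.DataFrame
    treatment_component: pd.DataFrame
    noise: pd.DataFrame
    log_total: pd.DataFrame

    def component_sum(self) -> pd.DataFrame:
        total = (self.subject_component + self.week_component
                 + self.day_component + self.treatment_component + self.noise)
        return total.add(self.baseline, axis=1)


def _subject_labels(n: int) -> list:
    letters = string.ascii_uppercase
    if n <= len(letters):
        return list(letters[:n])
    return [f"S{i + 1:03d}" for i in range(n)]


def generate_crossover(spec: SyntheticSpec):
    """Simulate one crossover study.

    Returns ``(table, design, truth)``.  Treatment arms are assigned in a
    randomized balanced fashion: half the subjects (rounded up) receive
    oleuropein in week 1 and placebo in week 2, the rest the reverse.
    Missing cells (MCAR at ``spec.missing_rate``) are injected into the
    returned table only; the ground truth stays complete.
    """
    rng = np.random.default_rng(spec.seed)
    subjects = _subject_labels(spec.n_subjects)
    feature_ids = [f"F{i + 1:04d}" for i in range(spec.n_features)]
    p = spec.n_features

    baseline = rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, p)
    subj_off = {s: rng.normal(0.0, spec.sigma_between, p) for s in subjects}
    week_off = {w: rng.normal(0.0, spec.sigma_week, p)
                for w in range(1, spec.n_weeks + 1)}
    n_days = spec.n_baseline_days + spec.n_admin_days
    day_off = {(w, slot): rng.normal(0.0, spec.sigma_day, p)
               for w in range(1, spec.n_weeks + 1) for slot in range(n_days)}

    affected_idx = np.sort(rng.choice(p, spec.n_affected, replace=False))
    directions = np.zeros(p)
    directions[affected_idx] = rng.choice([-1.0, 1.0], spec.n_affected)
    affected_ids = [feature_ids[i] for i in affected_idx]

    # randomized balanced arm assignment: which subjects get oleuropein first
    order = rng.permutation(spec.n_subjects)
    o_first = {subjects[i] for i in order[: (spec.n_subjects + 1) // 2]}

    rows, design_rows = [], []
    comp = {k: [] for k in ("subject", "week", "day", "treatment", "noise")}
    injection = 0
    for week in range(1, spec.n_weeks + 1):
        for slot in range(n_days):
            is_baseline = slot < spec.n_baseline_days
            day = slot + 1 if is_baseline else slot - spec.n_baseline_days + 1
            for subj in subjects:
                injection += 1
                if is_baseline:
                    phase = "baseline"
                else:
                    o_week = 1 if subj in o_first else 2
                    phase = "oleuropein" if week == o_week else "placebo"
                tag = "B" if is_baseline else "A"
                sample_id = f"{subj}_W{week}_{tag}{day}"
                treat = np.zeros(p)
                if phase == "oleuropein":
                    treat = directions * spec.effect_size * spec.reset_profile[day - 1]
                noise = rng.normal(0.0, spec.sigma_error, p)
                comp["subject"].append(subj_off[subj])
                comp["week"].append(week_off[week])
                comp["day"].append(day_off[(week, slot)])
                comp["treatment"].append(treat)
                comp["noise"].append(noise)
                rows.append(sample_id)
                design_rows.append(
                    dict(sample_id=sample_id, subject=subj, phase=phase, week=week,
                         day=day, injection_order=injection, is_qc=False)
                )

    def frame(key):
        return pd.DataFrame(np.vstack(comp[key]), index=rows, columns=feature_ids)

    baseline_s = pd.Series(baseline, index=feature_ids)
    truth = GroundTruth(
        affected_feature_ids=affected_ids,
        effect_directions=pd.Series(directions, index=feature_ids),
        baseline=baseline_s,
        subject_component=frame("subject"),
        week_component=frame("week"),
        day_component=frame("day"),
        treatment_component=frame("treatment"),
        noise=frame("noise"),
        log_total=None,
    )
    truth.log_total = truth.component_sum()

    meta = pd.DataFrame(
        {
            "mz": np.sort(rng.uniform(80.0, 1000.0, p)),
            "rt": np.round(rng.uniform(0.5, 25.0, p), 3),
            "polarity": "positive",
            "matrix_origin": "urine",
        },
        index=feature_ids,
    )
    table = FeatureTable(np.exp(truth.log_total), meta)
    design = StudyDesign(pd.DataFrame(design_rows).set_index("sample_id"))

    if spec.missing_rate > 0:
        table = inject_missing(table, spec.missing_rate, "mcar",
                               seed=int(rng.integers(2**31)))
    return table, design, truth


def make_qc_series(
    table: FeatureTable,
    design: StudyDesign,
    qc_every: int = 10,
    n_lead: int = 5,
    n_tail: int = 5,
):
    """Insert pooled QC injections into the acquisition sequence.

    The QC sample is the feature-wise mean over all study samples (a
    pooled aliquot).  ``n_lead`` QCs open the run, one QC follows every
    ``qc_every`` study samples, and ``n_tail`` QCs close it.  Injection
    orders are renumbered sequentially over the combined run.
    """
    if qc_every < 1:
        raise DesignError("qc_every must be >= 1")
    if table.n_samples == 0:
        raise DesignError("empty feature table")
    pooled = np.nanmean(table.values, axis=0)

    study = design.samples.sort_values("injection_order")
    seq: list[tuple[str, bool]] = []
    qc_count = 0

    def add_qc():
        nonlocal qc_count
        qc_count += 1
        seq.append((f"QC{qc_count:03d}", True))

    for _ in range(n_lead):
        add_qc()
    for i, sid in enumerate(study.index, start=1):
        seq.append((sid, False))
        if i % qc_every == 0:
            add_qc()
    for _ in range(n_tail):
        add_qc()

    design_rows, data_rows, ids = [], [], []
    for order, (sid, is_qc) in enumerate(seq, start=1):
        ids.append(sid)
        if is_qc:
            data_rows.append(pooled)
            design_rows.append(dict(sample_id=sid, subject="QC", phase="qc",
                                    week=0, day=0, injection_order=order, is_qc=True))
        else:
            data_rows.append(table.intensities.loc[sid].to_numpy())
            row = study.loc[sid].to_dict()
            row.update(sample_id=sid, injection_order=order)
            design_rows.append(row)

    new_table = FeatureTable(
        pd.DataFrame(np.vstack(data_rows), index=ids, columns=table.feature_ids),
        table.feature_meta.copy(),
    )
    new_design = StudyDesign(pd.DataFrame(design_rows).set_index("sample_id"))
    return new_table, new_design


def apply_drift(table: FeatureTable, design: StudyDesign, drift_slope: float) -> FeatureTable:
    """Multiply each sample by ``1 + drift_slope * (injection_order - 1)``.

    Models a monotone instrument-response drift over the run; exactly
    invertible given the slope.
    """
    orders = design.samples.loc[table.sample_ids, "injection_order"].to_numpy()
    factors = 1.0 + drift_slope * (orders - 1)
    if (factors <= 0).any():
        raise DesignError("drift multiplier <= 0 for some injection")
    return table.with_values(table.values * factors[:, None])


def inject_missing(
    table: FeatureTable,
    rate: float,
    mechanism: str = "mcar",
    seed: int | None = None,
) -> FeatureTable:
    """Censor a fraction ``rate`` of cells.

    ``mcar`` deletes cells uniformly at random; ``low_intensity`` censors
    preferentially below the intensity distribution's lower quantiles
    (weights decay quadratically with intensity rank).  Each feature keeps
    at least one observed value so downstream imputation stays defined.
    """
    if not 0 <= rate < 1:
        raise DesignError("rate must lie in [0, 1)")
    if rate == 0:
        return table.copy()
    rng = np.random.default_rng(seed)
    vals = table.values.copy()
    observed = np.argwhere(~np.isnan(vals))
    n_target = int(round(rate * len(observed)))
    if mechanism == "mcar":
        pick = rng.choice(len(observed), n_target, replace=False)
    elif mechanism == "low_intensity":
        flat = vals[observed[:, 0], observed[:, 1]]
        ranks = np.argsort(np.argsort(flat))
        weights = (1.0 - ranks / len(flat)) ** 2 + 1e-9
        weights /= weights.sum()
        pick = rng.choice(len(observed), n_target, replace=False, p=weights)
    else:
        raise DesignError(f"unknown mechanism {mechanism!r}")
    cells = observed[pick]
    vals[cells[:, 0], cells[:, 1]] = np.nan

    # re-instate the largest value of any feature left fully missing
    for j in np.where(np.all(np.isnan(vals), axis=0))[0]:
        col = table.values[:, j]
        i = int(np.nanargmax(col))
        vals[i, j] = col[i]
    return table.with_values(vals)


def simulate_study(spec: SyntheticSpec):
    """Full simulated acquisition: crossover table, QC series, drift, missingness.

    QC pooling uses drift-free intensities (the physical pool is made
    before acquisition); drift then applies to every injection.
    """
    base_spec = dataclass_replace(spec, missing_rate=0.0)
    table, design, truth = generate_crossover(base_spec)
    table, design = make_qc_series(table, design)
    if spec.drift_slope:
        table = apply_drift(table, design, spec.drift_slope)
    if spec.missing_rate:
        table = inject_missing(table, spec.missing_rate, "mcar",
                               seed=spec.seed + 1)
    return table, design, truth


def dataclass_replace(spec: SyntheticSpec, **kw) -> SyntheticSpec:
    import dataclasses

    return dataclasses.replace(spec, **kw)
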