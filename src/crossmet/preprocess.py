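"""Feature-table preprocessing for LC-MS crossover studies.

Covers four standard stages, in the order the pipeline applies them:

1. :func:`qc_rlsc` — per-feature signal-drift correction anchored on
   pooled QC injections (locally weighted regression over injection
   order, QC-RLSC).
2. :func:`impute_ppca` — missing-value imputation under a probabilistic
   PCA model fitted by expectation-maximization.
3. :func:`normalize_reference` — probabilistic quotient normalization
   against a pseudo-reference sample (feature-wise mean of a reference
   group).
4. :func:`transform_scale` — log transform plus feature-wise centering
   and unit-variance or Pareto scaling.

The module also provides consensus matching between two peak-picker
outputs (:func:`consensus_features`), the m/z–retention-time Venn
arithmetic used to merge two peak lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .design_io import FeatureTable, StudyDesign, DesignError


class PreprocessError(ValueError):
    pass


# ---------------------------------------------------------------------------
# consensus of two peak lists
# ---------------------------------------------------------------------------

@dataclass
class PeakList:
    """Peak entries of (mz in Th, rt in minutes, optional intensity)."""

    mz: np.ndarray
    rt: np.ndarray
    intensity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.rt = np.asarray(self.rt, dtype=float)
        if self.mz.shape != self.rt.shape:
            raise PreprocessError("mz and rt must have equal length")
        if (self.mz <= 0).any():
            raise PreprocessError("mz must be > 0")
        if (self.rt < 0).any():
            raise PreprocessError("rt must be >= 0")

    def __len__(self) -> int:
        return len(self.mz)

    @classmethod
    def from_csv(cls, path) -> "PeakList":
        df = pd.read_csv(path)
        inten = df["intensity"].to_numpy() if "intensity" in df else None
        return cls(df["mz"].to_numpy(), df["rt"].to_numpy(), inten)


@dataclass
class ConsensusResult:
    """Venn counts and merged list from matching two peak lists."""

    n_common: int
    n_unique_a: int
    n_unique_b: int
    merged: PeakList
    pairs: list  # (index in a, index in b) for matched entries

    @property
    def total(self) -> int:
        return self.n_common + self.n_unique_a + self.n_unique_b


def consensus_features(
    a: PeakList, b: PeakList, ppm_tol: float, rt_tol: float
) -> ConsensusResult:
    """One-to-one closest-pair matching of two peak lists.

    Entries match when ``|dmz|/mz <= ppm_tol * 1e-6`` and ``|drt| <=
    rt_tol``.  Candidate pairs are assigned greedily by ascending
    normalized distance (ppm and rt deviations scaled by their
    tolerances), ties broken by smaller ppm difference then smaller
    index.  Matched entries are merged by averaging.
    """
    if ppm_tol <= 0 or rt_tol <= 0:
        raise PreprocessError("tolerances must be > 0")
    candidates = []
    for i in range(len(a)):
        for j in range(len(b)):
            mz_ref = a.mz[i]
            ppm = abs(b.mz[j] - a.mz[i]) / mz_ref * 1e6
            drt = abs(b.rt[j] - a.rt[i])
            if ppm <= ppm_tol and drt <= rt_tol:
                dist = np.hypot(ppm / ppm_tol, drt / rt_tol)
                candidates.append((dist, ppm, i, j))
    candidates.sort()
    used_a, used_b, pairs = set(), set(), []
    for _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    pairs.sort()
    mz, rt = [], []
    for i, j in pairs:
        mz.append((a.mz[i] + b.mz[j]) / 2)
        rt.append((a.rt[i] + b.rt[j]) / 2)
    only_a = [i for i in range(len(a)) if i not in used_a]
    only_b = [j for j in range(len(b)) if j not in used_b]
    mz += [a.mz[i] for i in only_a] + [b.mz[j] for j in only_b]
    rt += [a.rt[i] for i in only_a] + [b.rt[j] for j in only_b]
    merged = PeakList(np.array(mz), np.array(rt)) if mz else PeakList(
        np.empty(0), np.empty(0))
    return ConsensusResult(len(pairs), len(only_a), len(only_b), merged, pairs)


def consensus_percentages(n_common: int, n_unique_a: int, n_unique_b: int):
    """Percent share of each Venn category, rounded to nearest integer."""
    total = n_common + n_unique_a + n_unique_b
    if total == 0:
        raise PreprocessError("empty consensus result")
    return tuple(int(round(100 * n / total)) for n in (n_common, n_unique_a, n_unique_b))


def summarize_consensus(result: ConsensusResult):
    return consensus_percentages(result.n_common, result.n_unique_a, result.n_unique_b)


# ---------------------------------------------------------------------------
# PPCA imputation
# ---------------------------------------------------------------------------

def impute_ppca(
    table: FeatureTable,
    n_components: int = 3,
    max_iter: int = 1000,
    tol: float = 1e-9,
    seed: int | None = None,
) -> FeatureTable:
    """Impute missing cells under a probabilistic PCA model fitted by EM.

    Missing cells are initialized at feature means (classical PCA start),
    then the PPCA loadings, noise variance and missing-cell expectations
    are re-estimated until the relative change of the reconstruction of
    the missing cells drops below ``tol`` or ``max_iter`` is reached.
    Observed cells are never altered.
    """
    X = table.values.copy()
    mask = np.isnan(X)
    if not mask.any():
        return table.copy()
    all_missing = np.where(mask.all(axis=0))[0]
    if all_missing.size:
        names = [table.feature_ids[j] for j in all_missing]
        raise PreprocessError(f"features with no observed value: {names}")
    n, p = X.shape
    if not 0 < n_components < min(n, p):
        raise PreprocessError("n_components must be in (0, min(n_samples, n_features))")

    rng = np.random.default_rng(seed)
    col_means = np.nanmean(X, axis=0)
    X[mask] = np.take(col_means, np.where(mask)[1])

    q = n_components
    # classical PCA initialization on the mean-imputed matrix
    mu = X.mean(axis=0)
    Xc = X - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    W = Vt[:q].T * s[:q] / np.sqrt(n)
    sigma2 = max(np.mean(s[q:] ** 2) / n, 1e-12) if len(s) > q else 1e-12
    _ = rng  # seed reserved for stochastic restarts; EM itself is deterministic

    prev = X[mask].copy()
    for _ in range(max_iter):
        Xc = X - mu
        M = W.T @ W + sigma2 * np.eye(q)
        Minv = np.linalg.inv(M)
        T = Xc @ W @ Minv                     # E[t_n]
        sumTT = n * sigma2 * Minv + T.T @ T    # sum E[t_n t_n^T]
        W = Xc.T @ T @ np.linalg.inv(sumTT)
        recon = T @ W.T
        resid = Xc - recon
        sigma2 = max(
            (np.sum(resid**2) + n * sigma2 * np.trace(W @ Minv @ W.T)) / (n * p),
            1e-15,
        )
        X[mask] = (mu + recon)[mask]
        mu = X.mean(axis=0)
        cur = X[mask]
        denom = np.linalg.norm(prev) or 1.0
        if np.linalg.norm(cur - prev) / denom < tol:
            break
        prev = cur.copy()
    # imputed cells are model expectations and may fall below zero, so the
    # result no longer guarantees the raw-intensity invariant
    return table.with_values(X, raw=False)


# ---------------------------------------------------------------------------
# probabilistic quotient normalization
# ---------------------------------------------------------------------------

def normalize_reference(table: FeatureTable, reference_sample_ids) -> FeatureTable:
    """Probabilistic quotient normalization against a pseudo-reference.

    The pseudo-reference is the feature-wise mean of the reference
    samples; each sample is divided by the median of its intensity
    ratios to that reference.  Zero-reference features are excluded from
    the quotient (with a warning).
    """
    ref_ids = list(reference_sample_ids)
    missing = set(ref_ids) - set(table.sample_ids)
    if missing:
        raise PreprocessError(f"reference samples not in table: {sorted(missing)}")
    ref_matrix = table.intensities.loc[ref_ids].to_numpy(dtype=float)
    if np.isnan(ref_matrix).any():
        raise PreprocessError("reference samples contain missing values; impute first")
    reference = ref_matrix.mean(axis=0)
    usable = reference > 0
    if not usable.any():
        raise PreprocessError("all-zero pseudo-reference")
    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} zero-reference features excluded from quotients"
        )
    X = table.values
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = X[:, usable] / reference[usable]
    quotients = np.nanmedian(ratios, axis=1)
    if np.isnan(quotients).any() or (quotients <= 0).any():
        raise PreprocessError("undefined or non-positive quotient for some sample")
    return table.with_values(X / quotients[:, None])


# ---------------------------------------------------------------------------
# QC-RLSC drift correction
# ---------------------------------------------------------------------------

def qc_rlsc(
    table: FeatureTable, design: StudyDesign, span: float = 0.75
) -> FeatureTable:
    """QC-anchored locally weighted signal correction.

    Per feature, a tricube-weighted linear (loess) curve is fitted to QC
    intensities against injection order with fraction ``span``, evaluated
    at every injection by linear interpolation (constant extrapolation
    beyond the outermost QCs), and each intensity is divided by the
    fitted curve scaled to the median of the fitted QC values.  Features
    whose fitted curve touches zero or below are left uncorrected with a
    warning.
    """
    orders_all = design.samples.loc[table.sample_ids, "injection_order"].to_numpy()
    is_qc = design.samples.loc[table.sample_ids, "is_qc"].to_numpy(bool)
    if is_qc.sum() < 4:
        raise PreprocessError("need at least 4 QC injections for drift correction")
    X = table.values.copy()
    qc_orders = orders_all[is_qc]
    sort = np.argsort(qc_orders)
    qc_x = qc_orders[sort].astype(float)

    flagged = []
    for j in range(X.shape[1]):
        qc_y = X[is_qc, j][sort]
        ok = ~np.isnan(qc_y)
        if ok.sum() < 4:
            flagged.append(table.feature_ids[j])
            continue
        fitted_qc = lowess(qc_y[ok], qc_x[ok], frac=span, it=0,
                           return_sorted=False)
        curve = np.interp(orders_all, qc_x[ok], fitted_qc)
        scale = np.median(fitted_qc)
        if (curve <= 0).any() or scale <= 0:
            flagged.append(table.feature_ids[j])
            continue
        X[:, j] = X[:, j] / (curve / scale)
    if flagged:
        warnings.warn(f"{len(flagged)} features left uncorrected: "
                      f"{flagged[:5]}{'...' if len(flagged) > 5 else ''}")
    return table.with_values(X)


# ---------------------------------------------------------------------------
# transform and scale
# ---------------------------------------------------------------------------

def transform_scale(
    table: FeatureTable, transform: str = "none", scaling: str = "none"
) -> FeatureTable:
    """Elementwise transform, then feature-wise centering plus scaling.

    ``transform``: ``log10`` or ``none``; ``scaling``: ``unit_variance``,
    ``pareto`` (divide by sqrt of SD) or ``none`` (centering only).
    """
    X = table.values.copy()
    if transform == "log10":
        bad = np.argwhere(X <= 0)
        if bad.size:
            cells = [(table.sample_ids[i], table.feature_ids[j]) for i, j in bad[:5]]
            raise PreprocessError(f"log10 of non-positive intensity at {cells}")
        X = np.log10(X)
    elif transform != "none":
        raise PreprocessError(f"unknown transform {transform!r}")

    mu = np.nanmean(X, axis=0)
    X = X - mu
    if scaling in ("unit_variance", "pareto"):
        sd = np.nanstd(X, axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / (sd if scaling == "unit_variance" else np.sqrt(sd))
    elif scaling != "none":
        raise PreprocessError(f"unknown scaling {scaling!r}")
    return table.with_values(X, raw=False)
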