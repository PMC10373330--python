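"""Taxon filtering, zero replacement, and propensity-score matching.

Because group membership in disparity studies is not randomizable,
confounding must be controlled before mediation estimation: a logistic
propensity model P(R=1 | X) is fitted and comparison/reference samples
are pair-matched 1:1 without replacement on the logit of the score,
optionally within exact strata, subject to a caliper. Balance is judged
by standardized mean differences (SMD); below 0.1 is conventionally
balanced.

Zero replacement makes log(M) well defined for the log-contrast and
digamma machinery; the default replaces each zero with half the
sample's smallest nonzero abundance and renormalizes.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np
from scipy.special import logit
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

from .io import SampleMetadata, StudyData, TaxaTable

__all__ = [
    "FilterConfig",
    "MatchResult",
    "filter_taxa",
    "replace_zeros",
    "fit_propensity",
    "match_samples",
    "standardized_mean_difference",
    "overall_smd",
    "PropensityMatcher",
]


@dataclasses.dataclass
class FilterConfig:
    """Taxon filtering and zero-replacement settings.

    prevalence_min : minimum fraction of samples in which a taxon must
        be nonzero; mean_abund_min : minimum mean relative abundance;
        zero_method : 'half_min' (replace zeros by half the sample's
        smallest nonzero value, then renormalize) or
        'multiplicative_pseudo' (same pseudo-value but non-zero parts
        shrunk multiplicatively so the row stays on the simplex).
    """

    prevalence_min: float = 0.2
    mean_abund_min: float = 1e-4
    zero_method: str = "half_min"

    def __post_init__(self):
        if not 0 <= self.prevalence_min <= 1:
            raise ValueError("prevalence_min must be in [0, 1]")
        if not 0 <= self.mean_abund_min < 1:
            raise ValueError("mean_abund_min must be in [0, 1)")
        if self.zero_method not in ("half_min", "multiplicative_pseudo"):
            raise ValueError(f"unknown zero_method {self.zero_method!r}")


@dataclasses.dataclass
class MatchResult:
    matched_pairs: list  # (comparison id, reference id)
    propensity: np.ndarray
    smd_before: dict
    smd_after: dict
    overall_smd_before: float
    overall_smd_after: float


def filter_taxa(data: StudyData, cfg: FilterConfig) -> StudyData:
    """Drop taxa below the prevalence or mean-abundance threshold; renormalize."""
    m = data.m
    prevalence = (m > 0).mean(axis=0)
    mean_ab = m.mean(axis=0)
    keep = (prevalence >= cfg.prevalence_min) & (mean_ab >= cfg.mean_abund_min)
    if keep.sum() < 2:
        raise ValueError(
            f"only {int(keep.sum())} taxa survive filtering "
            f"(prevalence_min={cfg.prevalence_min}, mean_abund_min={cfg.mean_abund_min}); "
            "loosen the thresholds"
        )
    sub = m[:, keep]
    sums = sub.sum(axis=1)
    if np.any(sums <= 0):
        bad = [data.sample_ids[i] for i in np.flatnonzero(sums <= 0)]
        raise ValueError(f"samples with no surviving taxa: {bad}")
    sub = sub / sums[:, None]
    taxa = TaxaTable(
        data.sample_ids, [t for t, k in zip(data.taxon_ids, keep) if k], sub
    )
    return StudyData(taxa, data.meta)


def replace_zeros(data: StudyData, cfg: Optional[FilterConfig] = None) -> StudyData:
    """Replace zero abundances so every composition is strictly positive."""
    cfg = cfg or FilterConfig()
    m = data.m.copy()
    if np.all(m > 0):
        return data
    for i in range(m.shape[0]):
        row = m[i]
        zeros = row == 0
        if not zeros.any():
            continue
        nz_min = row[row > 0].min()
        if cfg.zero_method == "half_min":
            row[zeros] = 0.5 * nz_min
            row /= row.sum()
        else:  # multiplicative_pseudo: keep the non-zero part positive
            k = int(zeros.sum())
            delta = min(0.5 * nz_min, 0.5 / k)
            row[~zeros] *= 1.0 - k * delta
            row[zeros] = delta
            row /= row.sum()
        m[i] = row
    taxa = TaxaTable(data.sample_ids, data.taxon_ids, m)
    return StudyData(taxa, data.meta)


def standardized_mean_difference(values: np.ndarray, groups: np.ndarray) -> float:
    """Absolute SMD of one covariate between the two exposure groups.

    Continuous: |m1 - m0| / sqrt((s1^2 + s0^2) / 2); a 0/1 covariate
    uses the binomial variance p(1-p) instead of the sample variance.
    Zero pooled variance with unequal means yields +inf.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    v1 = values[groups == 1]
    v0 = values[groups == 0]
    if len(v1) == 0 or len(v0) == 0:
        raise ValueError("both groups must be non-empty")
    binary = np.isin(values, [0.0, 1.0]).all()
    if binary:
        p1, p0 = v1.mean(), v0.mean()
        pooled = (p1 * (1 - p1) + p0 * (1 - p0)) / 2
        diff = abs(p1 - p0)
    else:
        pooled = (v1.var(ddof=1) + v0.var(ddof=1)) / 2
        diff = abs(v1.mean() - v0.mean())
    if pooled <= 0:
        return 0.0 if diff == 0 else float("inf")
    return float(diff / np.sqrt(pooled))


def overall_smd(x: np.ndarray, groups: np.ndarray) -> float:
    """Mean of per-covariate absolute SMDs (reported-as-one-number summary)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == len(groups) and x.ndim == 2:
        cols = x.T
    else:
        cols = x
    return float(np.mean([standardized_mean_difference(c, groups) for c in cols]))


def fit_propensity(meta: SampleMetadata, covariate_names: Sequence[str]) -> np.ndarray:
    """P(R=1 | X) from a logistic regression of exposure on covariates."""
    x = np.asarray(meta.frame[list(covariate_names)], dtype=float)
    scores, _ = _propensity_scores(x, meta.r)
    return scores


def _propensity_scores(x: np.ndarray, r: np.ndarray):
    model = LogisticRegression(penalty=None, max_iter=1000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(x, r)
    p = model.predict_proba(x)[:, 1]
    separated = np.all((p > 0.5) == (r == 1)) and (p.max() > 0.99 or p.min() < 0.01)
    if separated or np.abs(model.coef_).max() > 30:
        warnings.warn(
            "propensity model near-separated; falling back to a penalized fit",
            stacklevel=2,
        )
        model = LogisticRegression(C=1.0, max_iter=1000)
        model.fit(x, r)
    p = model.predict_proba(x)[:, 1]
    return np.clip(p, 1e-12, 1 - 1e-12), model


def match_samples(
    meta: SampleMetadata,
    scores: np.ndarray,
    exact_vars: Sequence[str] = (),
    caliper: Optional[float] = None,
    seed: int = 0,
    covariate_names: Optional[Sequence[str]] = None,
) -> MatchResult:
    """Greedy 1:1 nearest-neighbor matching on the propensity logit.

    Comparison samples (R=0) are processed hardest-first (largest
    initial distance to the nearest reference) and paired without
    replacement to the nearest reference sample in the same exact
    stratum within the caliper (default 0.2 x SD of the logit scores).
    The seed only breaks exact distance ties.
    """
    if isinstance(scores, tuple):
        scores = scores[0]
    scores = np.asarray(scores, dtype=float)
    ls = logit(np.clip(scores, 1e-12, 1 - 1e-12))
    sd = ls.std(ddof=1) if len(ls) > 1 else 0.0
    cal = 0.2 * sd if caliper is None else float(caliper)
    r = meta.r
    ids = meta.sample_ids
    rng = np.random.default_rng(seed)
    jitter = rng.random(len(ids)) * 1e-12  # deterministic tie-break only

    if exact_vars:
        strata_vals = meta.frame[list(exact_vars)].astype(str).agg("|".join, axis=1)
        strata = np.asarray(strata_vals)
    else:
        strata = np.array(["all"] * len(ids))

    used_ref = np.zeros(len(ids), dtype=bool)
    pairs = []
    for stratum in np.unique(strata):
        in_s = strata == stratum
        comp = np.flatnonzero(in_s & (r == 0))
        ref = np.flatnonzero(in_s & (r == 1))
        if len(comp) == 0 or len(ref) == 0:
            continue
        dist = np.abs(ls[comp][:, None] - ls[ref][None, :])
        order = np.argsort(-(dist.min(axis=1) + jitter[comp]))
        for ci in order:
            avail = ~used_ref[ref]
            if not avail.any():
                break
            d = dist[ci] + jitter[ref]
            d = np.where(avail, d, np.inf)
            ri = int(np.argmin(d))
            if dist[ci, ri] <= cal:
                used_ref[ref[ri]] = True
                pairs.append((ids[comp[ci]], ids[ref[ri]]))
    if not pairs:
        warnings.warn("no admissible matches found", stacklevel=2)

    cov_names = list(covariate_names) if covariate_names else list(meta.covariates)
    matched_ids = [i for pair in pairs for i in pair]
    pos = {s: i for i, s in enumerate(ids)}
    midx = np.array([pos[s] for s in matched_ids], dtype=int)

    def smds(index):
        sub = meta.frame.iloc[index] if index is not None else meta.frame
        g = np.asarray(sub[meta.exposure], dtype=float)
        out = {}
        for c in cov_names:
            out[c] = standardized_mean_difference(np.asarray(sub[c], dtype=float), g)
        return out

    smd_before = smds(None)
    if len(midx):
        smd_after = smds(midx)
    else:
        smd_after = {c: float("nan") for c in cov_names}
    return MatchResult(
        matched_pairs=pairs,
        propensity=scores,
        smd_before=smd_before,
        smd_after=smd_after,
        overall_smd_before=float(np.mean(list(smd_before.values()))),
        overall_smd_after=float(np.mean(list(smd_after.values()))),
    )


class PropensityMatcher(BaseEstimator):
    """Propensity-score matcher with balance diagnostics.

    ``fit(X, y)`` takes the covariate matrix ``X`` and 0/1 group labels
    ``y`` (1 = reference); after fitting, ``pairs_`` holds index pairs
    ``(comparison, reference)`` and ``matched_indices_`` the flat index
    set of retained samples.
    """

    def __init__(self, exact: Sequence[int] = (), caliper: Optional[float] = None,
                 random_state: int = 0):
        self.exact = exact
        self.caliper = caliper
        self.random_state = random_state

    def fit(self, X, y):
        x = np.asarray(X, dtype=float)
        r = np.asarray(y, dtype=float)
        self.propensity_, self.model_ = _propensity_scores(x, r)
        import pandas as pd

        frame = pd.DataFrame({"exposure": r, "outcome": np.zeros(len(r))})
        names = [f"c{i}" for i in range(x.shape[1])]
        for i, nm in enumerate(names):
            frame[nm] = x[:, i]
        frame.index = [str(i) for i in range(len(r))]
        meta = SampleMetadata(frame, "exposure", "outcome", names)
        res = match_samples(
            meta,
            self.propensity_,
            exact_vars=[names[i] for i in self.exact],
            caliper=self.caliper,
            seed=self.random_state,
        )
        self.result_ = res
        self.pairs_ = [(int(a), int(b)) for a, b in res.matched_pairs]
        self.matched_indices_ = np.array(sorted(i for p in self.pairs_ for i in p), dtype=int)
        self.smd_before_ = res.overall_smd_before
        self.smd_after_ = res.overall_smd_after
        self.n_features_in_ = x.shape[1]
        return self

    def transform(self, X):
        """Rows of ``X`` restricted to the matched sample set."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "matched_indices_")
        return np.asarray(X)[self.matched_indices_]


def match_study(data: StudyData, covariate_names=None, exact_vars=(), caliper=None, seed=0):
    """Match a StudyData on its metadata covariates; returns (matched data, MatchResult)."""
    cov = list(covariate_names) if covariate_names else list(data.meta.covariates)
    scores, _ = _propensity_scores(np.asarray(data.meta.frame[cov], dtype=float), data.r)
    res = match_samples(
        data.meta, scores, exact_vars=exact_vars, caliper=caliper, seed=seed,
        covariate_names=cov,
    )
    keep_ids = {i for p in res.matched_pairs for i in p}
    idx = np.array([i for i, s in enumerate(data.sample_ids) if s in keep_ids], dtype=int)
    if len(idx) < 4:
        raise ValueError("matching retained fewer than 4 samples")
    return data.subset_samples(idx), res
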