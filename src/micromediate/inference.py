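"""Split-based estimation and permutation testing of disparity measures.

Penalized selection is biased, so point estimates come from repeated
sample splitting: one random half (stratified by exposure) selects taxa
with the sparse-group penalty, the other half refits both models
unpenalized on the selected taxa and evaluates MDM/RDM/ODM. Across
repetitions the mean is reported with SE = the standard deviation of
the per-repetition estimates (the halves overlap between repetitions,
so the SD itself is the honest spread) and a normal 95% CI.

Significance of the community-level statistic OMD = mean MDM and the
component-wise statistic CMD = sum_j (mean MDM_j)^2 is assessed by
permuting the exposure labels of the whole dataset and rerunning the
entire split procedure on each permuted dataset.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .dirichlet import DirichletRegression, fit_dirichlet
from .disparity import DisparityValues, compute_disparity, percent_manipulable
from .io import SampleMetadata, StudyData, TaxaTable
from .outcome import (
    PenaltyConfig,
    fit_ols_arrays,
    fit_penalized,
    lambda_grid_arrays,
    penalized_path_arrays,
    refit_unpenalized,
)

__all__ = [
    "SplitSummary",
    "TestResult",
    "DisparityReport",
    "single_split_estimate",
    "repeated_split_inference",
    "omd_cmd_statistics",
    "permutation_test",
    "MicrobiomeMediationDisparity",
]


@dataclasses.dataclass
class SplitSummary:
    """Aggregate of repeated split estimates."""

    mean_mdm: float
    mean_rdm: float
    mean_odm: float
    se_mdm: float
    se_rdm: float
    mean_mdm_j: np.ndarray
    se_mdm_j: np.ndarray
    ci_low_j: np.ndarray
    ci_high_j: np.ndarray
    selection_freq_j: np.ndarray
    n_reps: int

    @property
    def percent_manipulable(self) -> float:
        return percent_manipulable(self.mean_mdm, self.mean_odm)


@dataclasses.dataclass
class TestResult:
    omd_stat: float
    cmd_stat: float
    p_omd: float
    p_cmd: float
    n_perm: int


@dataclasses.dataclass
class DisparityReport:
    """Serializable end-to-end result (see io.write_results)."""

    summary: SplitSummary
    test: Optional[TestResult]
    taxon_ids: list
    seed: int
    config: dict

    def per_taxon_frame(self) -> pd.DataFrame:
        s = self.summary
        return pd.DataFrame(
            {
                "mdm": s.mean_mdm_j,
                "se": s.se_mdm_j,
                "ci_low": s.ci_low_j,
                "ci_high": s.ci_high_j,
                "selection_freq": s.selection_freq_j,
                "selected": s.selection_freq_j > 0.5,
            },
            index=pd.Index(self.taxon_ids, name="taxon_id"),
        )

    def summary_dict(self) -> dict:
        s = self.summary
        out = {
            "odm": s.mean_odm,
            "mdm": s.mean_mdm,
            "rdm": s.mean_rdm,
            "se_mdm": s.se_mdm,
            "se_rdm": s.se_rdm,
            "percent_manipulable": s.percent_manipulable,
            "n_reps": s.n_reps,
            "seed": self.seed,
            "config": self.config,
        }
        if self.test is not None:
            out.update(
                {
                    "omd_stat": self.test.omd_stat,
                    "cmd_stat": self.test.cmd_stat,
                    "p_omd": self.test.p_omd,
                    "p_cmd": self.test.p_cmd,
                    "n_perm": self.test.n_perm,
                }
            )
        return out


def _stratified_half_split(r: np.ndarray, rng: np.random.Generator):
    """Random equal-halves split keeping both exposure levels in each half."""
    a_idx, b_idx = [], []
    for level in (0.0, 1.0):
        idx = np.flatnonzero(r == level)
        idx = rng.permutation(idx)
        half = len(idx) // 2
        a_idx.append(idx[:half])
        b_idx.append(idx[half:])
    return np.sort(np.concatenate(a_idx)), np.sort(np.concatenate(b_idx))


def _restrict_taxa(data: StudyData, selected: np.ndarray) -> StudyData:
    """Subcomposition on the selected taxa, renormalized to the simplex."""
    m = data.m[:, selected]
    m = m / m.sum(axis=1, keepdims=True)
    taxa = TaxaTable(data.sample_ids, [data.taxon_ids[i] for i in selected], m)
    return StudyData(taxa, data.meta)


@dataclasses.dataclass
class _Arrays:
    """Plain-array view of a study used inside the hot split loop."""

    m: np.ndarray
    logm: np.ndarray
    r: np.ndarray
    x: np.ndarray
    y: np.ndarray

    @classmethod
    def from_study(cls, data: StudyData) -> "_Arrays":
        m = data.m
        return cls(m=m, logm=np.log(m), r=data.r, x=data.x, y=data.y)

    def take(self, idx: np.ndarray) -> "_Arrays":
        return _Arrays(self.m[idx], self.logm[idx], self.r[idx], self.x[idx], self.y[idx])


def _split_core(arr: _Arrays, seed, penalty, dirichlet_max_iter, warm):
    penalty = penalty or PenaltyConfig()
    j = arr.m.shape[1]
    rng = np.random.default_rng(seed)
    for _ in range(10):
        a_idx, b_idx = _stratified_half_split(arr.r, rng)
        if len(a_idx) >= 4 and len(b_idx) >= 4:
            break
    a = arr.take(a_idx)
    b = arr.take(b_idx)

    # group weights only need the coefficient scale, not 1e-6 gradients
    dir_est = DirichletRegression(max_iter=dirichlet_max_iter, gtol=1e-4)
    dir_est.fit(np.column_stack([a.r, a.x]), a.m, init=warm.get("dir_full"))
    dir_a = dir_est.params_()
    warm["dir_full"] = dir_a

    grid = penalty.grid
    if grid is None and penalty.lambda1 is not None:
        grid = [(penalty.lambda1, penalty.lambda2)]
    if grid is None:
        grid = lambda_grid_arrays(a.r, a.x, a.logm, a.y)
    _, selected = penalized_path_arrays(
        a.r, a.x, a.logm, a.y, grid, beta_r=dir_a.beta_r,
        criterion=penalty.criterion, max_iter=penalty.max_iter, tol=penalty.tol,
        warm_cache=warm,
    )

    mdm_j = np.zeros(j)
    if selected.size >= 2:
        m_sub = b.m[:, selected]
        m_sub = m_sub / m_sub.sum(axis=1, keepdims=True)
        dir_est_b = DirichletRegression(max_iter=dirichlet_max_iter)
        dir_est_b.fit(np.column_stack([b.r, b.x]), m_sub)
        dir_b = dir_est_b.params_()
        # log-contrast invariance: the subcomposition's logs differ from the
        # original ones by a per-sample constant that sum-to-zero annihilates
        out_b = fit_ols_arrays(b.r, b.x, b.logm[:, selected], b.y)
        xs = b.x[b.r == 1] if b.x.shape[1] else None
        vals = compute_disparity(out_b, dir_b, xs)
        mdm_j[selected] = vals.mdm_j
        result = DisparityValues(odm=vals.odm, mdm=vals.mdm, rdm=vals.rdm, mdm_j=mdm_j)
    else:
        out_b = fit_ols_arrays(b.r, b.x, b.logm[:, :2], b.y, restrict=[])
        result = DisparityValues(
            odm=out_b.alpha_r, mdm=0.0, rdm=out_b.alpha_r, mdm_j=mdm_j
        )
    return result, selected


def single_split_estimate(
    data: StudyData,
    seed: int,
    penalty: Optional[PenaltyConfig] = None,
    dirichlet_max_iter: int = 300,
    _warm=None,
):
    """One selection/estimation split; returns (DisparityValues, selected indices).

    Half A drives the sparse-group selection (with mediator-model
    exposure coefficients fitted on the same half as group weights);
    half B refits the Dirichlet and outcome models unpenalized on the
    selected subcomposition and evaluates the disparity formulas with
    half B's reference-group covariates. Unselected taxa contribute
    ``MDM_j = 0``.
    """
    warm = _warm if _warm is not None else {}
    return _split_core(
        _Arrays.from_study(data), seed, penalty, dirichlet_max_iter, warm
    )


def repeated_split_inference(
    data: StudyData,
    n_reps: int = 50,
    base_seed: int = 0,
    penalty: Optional[PenaltyConfig] = None,
    ci_method: str = "normal",
    dirichlet_max_iter: int = 300,
) -> SplitSummary:
    """Average of ``n_reps`` split estimates with SE and 95% CI.

    SE is the across-repetition standard deviation; the CI is
    mean +- 1.96 SE (``ci_method='percentile'`` uses the empirical
    2.5/97.5 percentiles of the repetition values instead).
    """
    if n_reps < 2:
        raise ValueError("need at least 2 repetitions")
    arr = data if isinstance(data, _Arrays) else _Arrays.from_study(data)
    n, j = arr.m.shape
    k = arr.x.shape[1]
    n_free = 2 + k + 2 * (j - 1)
    if n < 4 * n_free:
        import warnings

        warnings.warn(
            f"n = {n} is below the recommended 4x the {n_free} free outcome "
            "parameters; half-sample fits may be unstable",
            stacklevel=2,
        )
    return _repeated_core(arr, n_reps, base_seed, penalty, ci_method, dirichlet_max_iter)


def _repeated_core(arr, n_reps, base_seed, penalty, ci_method, dirichlet_max_iter):
    j = arr.m.shape[1]
    mdms, rdms, odms = [], [], []
    mdm_js = np.empty((n_reps, j))
    sel_count = np.zeros(j)
    warm = {}
    n_fail = 0
    rep = 0
    for i in range(n_reps):
        try:
            vals, selected = _split_core(
                arr, base_seed + 1 + i, penalty, dirichlet_max_iter, warm
            )
        except (ValueError, np.linalg.LinAlgError):
            n_fail += 1
            continue
        mdms.append(vals.mdm)
        rdms.append(vals.rdm)
        odms.append(vals.odm)
        mdm_js[rep] = vals.mdm_j
        sel_count[selected] += 1
        rep += 1
    if rep < max(2, int(np.ceil(0.8 * n_reps))):
        raise RuntimeError(f"too many failed split repetitions ({n_fail}/{n_reps})")
    mdm_js = mdm_js[:rep]
    mdms = np.array(mdms)
    rdms = np.array(rdms)
    odms = np.array(odms)
    se_mdm_j = mdm_js.std(axis=0, ddof=1)
    mean_mdm_j = mdm_js.mean(axis=0)
    if ci_method == "normal":
        lo = mean_mdm_j - 1.96 * se_mdm_j
        hi = mean_mdm_j + 1.96 * se_mdm_j
    elif ci_method == "percentile":
        lo = np.percentile(mdm_js, 2.5, axis=0)
        hi = np.percentile(mdm_js, 97.5, axis=0)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return SplitSummary(
        mean_mdm=float(mdms.mean()),
        mean_rdm=float(rdms.mean()),
        mean_odm=float(odms.mean()),
        se_mdm=float(mdms.std(ddof=1)),
        se_rdm=float(rdms.std(ddof=1)),
        mean_mdm_j=mean_mdm_j,
        se_mdm_j=se_mdm_j,
        ci_low_j=lo,
        ci_high_j=hi,
        selection_freq_j=sel_count / rep,
        n_reps=rep,
    )


def omd_cmd_statistics(summary: SplitSummary):
    """OMD = mean MDM; CMD = sum of squared per-taxon mean MDM_j."""
    return float(summary.mean_mdm), float(np.sum(summary.mean_mdm_j**2))


def _permute_exposure(data: StudyData, rng: np.random.Generator) -> StudyData:
    perm = rng.permutation(data.n_samples)
    frame = data.meta.frame.copy()
    frame[data.meta.exposure] = np.asarray(frame[data.meta.exposure])[perm]
    meta = SampleMetadata(frame, data.meta.exposure, data.meta.outcome, data.meta.covariates)
    return StudyData(data.taxa, meta)


def permutation_test(
    data: StudyData,
    n_perm: int = 1000,
    n_reps_inner: int = 5,
    seed: int = 0,
    penalty: Optional[PenaltyConfig] = None,
    dirichlet_max_iter: int = 300,
) -> TestResult:
    """Permutation p-values for OMD (two-sided) and CMD (one-sided).

    Exposure labels are permuted across subjects — breaking both the
    exposure-to-taxa and exposure-to-outcome paths, a valid null for
    MDM = 0 — and the full split procedure (``n_reps_inner``
    repetitions, matching the observed statistic) is rerun per
    permutation. Add-one p-values: the floor is ``1/(n_perm + 1)``.
    """
    if n_perm < 19:
        raise ValueError("need at least 19 permutations")
    arr = _Arrays.from_study(data)
    obs = _repeated_core(arr, n_reps_inner, seed, penalty, "normal", dirichlet_max_iter)
    omd_obs, cmd_obs = omd_cmd_statistics(obs)
    rng = np.random.default_rng(seed + 1)
    omd_perm = np.empty(n_perm)
    cmd_perm = np.empty(n_perm)
    done = 0
    attempts = 0
    while done < n_perm and attempts < 3 * n_perm:
        attempts += 1
        perm_arr = dataclasses.replace(arr, r=arr.r[rng.permutation(len(arr.r))])
        try:
            ps = _repeated_core(
                perm_arr, n_reps_inner, seed + 1000 + attempts, penalty,
                "normal", dirichlet_max_iter,
            )
        except RuntimeError:
            continue
        omd_perm[done], cmd_perm[done] = omd_cmd_statistics(ps)
        done += 1
    if done < n_perm:
        raise RuntimeError("too many permutation failures")
    p_omd = (1.0 + np.sum(np.abs(omd_perm) >= abs(omd_obs))) / (n_perm + 1.0)
    p_cmd = (1.0 + np.sum(cmd_perm >= cmd_obs)) / (n_perm + 1.0)
    return TestResult(
        omd_stat=omd_obs, cmd_stat=cmd_obs, p_omd=float(p_omd), p_cmd=float(p_cmd), n_perm=n_perm
    )


class MicrobiomeMediationDisparity(BaseEstimator):
    """End-to-end disparity decomposition estimator.

    ``fit(X, y)`` takes ``X`` with columns ``[R, X_1..X_K, M_1..M_J]``
    (exposure, then ``n_covariates`` covariates, then strictly positive
    compositions) and the continuous outcome ``y``; it runs repeated
    split estimation and, when ``n_permutations > 0``, the permutation
    tests.

    Attributes (after fit)
    ----------------------
    odm_, mdm_, rdm_ : float
        Mean disparity decomposition across splits.
    mdm_per_taxon_ : array (J,)
    summary_ : SplitSummary
    test_ : TestResult or None
    """

    def __init__(
        self,
        n_covariates: int = 0,
        n_splits: int = 50,
        n_permutations: int = 0,
        inner_reps: int = 5,
        lambda_grid=None,
        ci_method: str = "normal",
        random_state: int = 0,
    ):
        self.n_covariates = n_covariates
        self.n_splits = n_splits
        self.n_permutations = n_permutations
        self.inner_reps = inner_reps
        self.lambda_grid = lambda_grid
        self.ci_method = ci_method
        self.random_state = random_state

    def _to_study(self, X, y) -> StudyData:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        k = self.n_covariates
        r = X[:, 0]
        xc = X[:, 1 : 1 + k]
        m = X[:, 1 + k :]
        m = m / m.sum(axis=1, keepdims=True)
        ids = [f"s{i}" for i in range(len(y))]
        taxa = TaxaTable(ids, [f"t{j}" for j in range(m.shape[1])], m)
        frame = pd.DataFrame({"exposure": r, "outcome": y}, index=ids)
        cov_names = [f"x{i + 1}" for i in range(k)]
        for i, name in enumerate(cov_names):
            frame[name] = xc[:, i]
        return StudyData(taxa, SampleMetadata(frame, "exposure", "outcome", cov_names))

    def fit(self, X, y):
        data = self._to_study(X, y)
        return self.fit_study(data)

    def fit_study(self, data: StudyData):
        penalty = PenaltyConfig(grid=self.lambda_grid) if self.lambda_grid else None
        self.summary_ = repeated_split_inference(
            data,
            n_reps=self.n_splits,
            base_seed=self.random_state,
            penalty=penalty,
            ci_method=self.ci_method,
        )
        self.test_ = None
        if self.n_permutations:
            self.test_ = permutation_test(
                data,
                n_perm=self.n_permutations,
                n_reps_inner=self.inner_reps,
                seed=self.random_state,
                penalty=penalty,
            )
        self.odm_ = self.summary_.mean_odm
        self.mdm_ = self.summary_.mean_mdm
        self.rdm_ = self.summary_.mean_rdm
        self.mdm_per_taxon_ = self.summary_.mean_mdm_j
        self.n_features_in_ = 1 + self.n_covariates + data.n_taxa
        return self

    def report(self, data: StudyData = None, taxon_ids=None) -> DisparityReport:
        ids = taxon_ids or (data.taxon_ids if data is not None else
                            [f"t{j}" for j in range(len(self.mdm_per_taxon_))])
        return DisparityReport(
            summary=self.summary_,
            test=self.test_,
            taxon_ids=list(ids),
            seed=self.random_state,
            config={
                "n_splits": self.n_splits,
                "n_permutations": self.n_permutations,
                "inner_reps": self.inner_reps,
                "ci_method": self.ci_method,
            },
        )
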