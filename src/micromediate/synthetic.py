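"""Synthetic study generator.

Data are drawn from the same generative laws the estimators assume: a
Dirichlet mediator model with log-linked, covariate-dependent
concentrations, and a Gaussian linear log-contrast outcome model with
exposure x taxon interactions. Each generated study carries a truth
record with the analytic MDM/RDM/ODM implied by the generating
parameters, so recovery can be checked against a known target.

Named presets cover the qualitative regimes of interest: no mediation
(exposure affects taxa but taxa do not affect the outcome), mediation
only, direct effect only, both, and a confounded design where
covariates drive group membership (for propensity-matching tests).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.special import expit

from .dirichlet import DirichletParams
from .disparity import compute_disparity
from .io import SampleMetadata, StudyData, TaxaTable, write_taxa_table
from .outcome import OutcomeParams

import pandas as pd

__all__ = ["ScenarioConfig", "generate_study", "preset", "write_fixture", "PRESETS"]

PRESETS = ("null_no_mediation", "mediation_only", "direct_only", "mixed", "confounded")


@dataclasses.dataclass
class ScenarioConfig:
    """Generating parameters for one synthetic study."""

    n_per_group: int
    dirichlet: DirichletParams
    outcome: OutcomeParams
    confounding_strength: np.ndarray  # (K,) logistic coefficients of X on R
    noise_sd: float = 1.0
    binary_covariates: tuple = ()  # indices of X columns drawn Bernoulli(0.5)
    seed: int = 0

    def __post_init__(self):
        self.confounding_strength = np.atleast_1d(
            np.asarray(self.confounding_strength, dtype=float)
        )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if abs(self.outcome.alpha_m.sum()) > 1e-8 or abs(self.outcome.alpha_c.sum()) > 1e-8:
            raise ValueError("outcome truth violates the sum-to-zero constraints")

    @property
    def n_taxa(self) -> int:
        return self.dirichlet.n_taxa

    @property
    def n_covariates(self) -> int:
        return self.dirichlet.n_covariates


def generate_study(cfg: ScenarioConfig, seed: Optional[int] = None):
    """Draw one study; returns ``(StudyData, truth)``.

    ``truth`` holds the generating parameters and the analytic
    MDM/RDM/ODM evaluated at them, averaged over the realized reference
    group covariates (the same covariate set the estimators use).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = 2 * cfg.n_per_group
    k = cfg.n_covariates
    j = cfg.n_taxa

    x = rng.standard_normal((n, k))
    for idx in cfg.binary_covariates:
        x[:, idx] = rng.integers(0, 2, n).astype(float)

    if np.any(cfg.confounding_strength != 0):
        p_ref = expit(x @ cfg.confounding_strength)
        r = (rng.random(n) < p_ref).astype(float)
        # guard: both groups need at least 2 samples
        for level in (0.0, 1.0):
            short = int(2 - (r == level).sum())
            if short > 0:
                flip = np.flatnonzero(r != level)[:short]
                r[flip] = level
    else:
        r = np.zeros(n)
        r[rng.permutation(n)[: cfg.n_per_group]] = 1.0

    d = np.hstack([np.ones((n, 1)), r[:, None], x])
    b = np.vstack([cfg.dirichlet.beta0, cfg.dirichlet.beta_r, cfg.dirichlet.beta_x.T])
    gam = np.exp(d @ b)
    draws = rng.standard_gamma(gam)
    draws = np.clip(draws, 1e-12, None)
    m = draws / draws.sum(axis=1, keepdims=True)

    out = cfg.outcome
    logm = np.log(m)
    y = (
        out.alpha0
        + x @ out.alpha_x
        + out.alpha_r * r
        + logm @ out.alpha_m
        + (logm * r[:, None]) @ out.alpha_c
        + cfg.noise_sd * rng.standard_normal(n)
    )

    ids = [f"s{i:04d}" for i in range(n)]
    taxa = TaxaTable(ids, [f"taxon_{j_:02d}" for j_ in range(j)], m)
    frame = pd.DataFrame(
        {"exposure": r.astype(int), "outcome": y}, index=pd.Index(ids, name="sample_id")
    )
    for kk in range(k):
        frame[f"x{kk + 1}"] = x[:, kk]
    meta = SampleMetadata(frame, "exposure", "outcome", [f"x{kk + 1}" for kk in range(k)])
    data = StudyData(taxa, meta)

    xs = x[r == 1] if k else None
    truth_vals = compute_disparity(out, cfg.dirichlet, xs)
    truth = {
        "mdm": truth_vals.mdm,
        "rdm": truth_vals.rdm,
        "odm": truth_vals.odm,
        "mdm_j": truth_vals.mdm_j,
        "percent_manipulable": truth_vals.percent_manipulable,
        "active_taxa": np.flatnonzero(
            (np.abs(out.alpha_m) + np.abs(out.alpha_c) > 0)
            & (np.abs(cfg.dirichlet.beta_r) > 0)
        ),
        "config": cfg,
    }
    return data, truth


def _active_pattern(j: int, values) -> np.ndarray:
    a = np.zeros(j)
    a[: len(values)] = values
    return a


def preset(
    name: str,
    n_per_group: int = 150,
    n_taxa: int = 10,
    n_covariates: int = 1,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> ScenarioConfig:
    """Named scenario configurations (see module docstring)."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    j, k = n_taxa, n_covariates
    if j < 4:
        raise ValueError("presets need at least 4 taxa")
    binary = ()

    # uneven baseline concentrations typical of a small community
    beta0 = np.log(np.geomspace(2.0, 0.4, j))
    beta_x = np.zeros((j, k))
    if k:
        beta_x[:, 0] = _active_pattern(j, [0.2, 0.0, -0.2, 0.1])
    beta_r = _active_pattern(j, [0.8, -0.8, 0.6])

    alpha_m = _active_pattern(j, [1.0, -0.5, -0.5])
    alpha_c = _active_pattern(j, [0.4, -0.2, -0.2])
    alpha_x = np.full(k, 0.5)
    alpha_r = 1.0

    if name == "null_no_mediation":
        alpha_m = np.zeros(j)
        alpha_c = np.zeros(j)
    elif name == "direct_only":
        beta_r = np.zeros(j)
        alpha_c = np.zeros(j)
        alpha_r = 1.5
    elif name == "mediation_only":
        alpha_r = 0.0
    elif name == "confounded":
        k = max(k, 2)
        beta_x = np.zeros((j, k))
        beta_x[:, 0] = _active_pattern(j, [0.2, 0.0, -0.2, 0.1])
        alpha_x = np.full(k, 0.5)
        binary = (k - 1,)

    dir_params = DirichletParams(beta0=beta0, beta_r=beta_r, beta_x=beta_x)

    if name in ("mixed", "confounded"):
        # direct effect sized so the manipulable share sits near 25%
        # (RDM ~= 3 x MDM at the covariate origin)
        probe = OutcomeParams(0.0, np.zeros(k), 0.0, alpha_m, alpha_c, 1.0)
        vals = compute_disparity(probe, dir_params, np.zeros((1, k)))
        alpha_r = 3.0 * vals.mdm - vals.rdm

    outcome = OutcomeParams(
        alpha0=20.0,  # BMI-like baseline level
        alpha_x=alpha_x,
        alpha_r=alpha_r,
        alpha_m=alpha_m,
        alpha_c=alpha_c,
        sigma=noise_sd,
    )
    confounding = np.zeros(k)
    if name == "confounded":
        confounding = np.array([0.8] + [0.0] * (k - 2) + [1.0]) if k >= 2 else np.array([0.8])

    return ScenarioConfig(
        n_per_group=n_per_group,
        dirichlet=dir_params,
        outcome=outcome,
        confounding_strength=confounding,
        noise_sd=noise_sd,
        binary_covariates=binary,
        seed=seed,
    )


def write_fixture(data: StudyData, truth: dict, out_dir) -> dict:
    """Write taxa + metadata TSVs and a truth JSON; returns the file map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "taxa": out_dir / "taxa.tsv",
        "metadata": out_dir / "metadata.tsv",
        "truth": out_dir / "truth.json",
    }
    write_taxa_table(data.taxa, paths["taxa"])
    data.meta.frame.to_csv(paths["metadata"], sep="\t", index_label="sample_id")
    record = {
        "mdm": truth["mdm"],
        "rdm": truth["rdm"],
        "odm": truth["odm"],
        "mdm_j": list(map(float, truth["mdm_j"])),
        "percent_manipulable": truth["percent_manipulable"],
        "active_taxa": [int(i) for i in truth["active_taxa"]],
    }
    with open(paths["truth"], "w") as fh:
        json.dump(record, fh, indent=2)
    return paths
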