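"""Synthetic multi-site cohorts with planted connectome-outcome signal.

Restricted-access developmental-cohort data (multi-site, family-nested,
t-score-like symptom severity, Fisher-z connectomes) are emulated by a
compact generative model:

* A latent vulnerability ``v_i ~ N(0, 1)``, shared within families with
  intra-family correlation 0.5, drives both the planted connectivity
  edges and (partly) the follow-up severity score.
* Baseline and follow-up severity arise from a bivariate Gaussian latent
  pair whose correlation is calibrated — by Gauss-Hermite quadrature,
  inverting the attenuation induced by the skewing transform — so that
  the *observed* Pearson correlation matches the target.  Positive skew
  is induced by a sinh-arcsinh shift, a strictly monotone map that
  preserves the rank structure Spearman statistics rely on.  Each cohort
  is affinely standardized so its sample mean/SD equal the calibration
  targets exactly (correlations are unaffected by the affine).
* Edges are generated directly in Fisher-z space: per-edge baseline level
  + per-(site, edge) offset + (for planted edges) gamma * v_i + noise.
  A small time-series mode routes through :mod:`cpmkit.connectome` for
  end-to-end tests.
* A clinical/control mixture (for the single-site adolescent preset) is
  expressed as group-specific score means/SDs; the within-group latent
  correlation is solved from the printed group moments so the pooled
  base-follow-up correlation hits its target.
* Head motion is log-normal with a configurable latent correlation to the
  follow-up score (default 0) for stress-testing covariate correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .cohort import AlignedCohort, PhenotypeTable
from .connectome import (CohortEdgeMatrix, EdgeIndexMap, TimeSeriesMatrix,
                         n_edges)

INTRA_FAMILY_CORR = 0.5


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """One diagnostic group of the score mixture."""

    name: str
    fraction: float
    base_mean: float
    base_sd: float
    y1_mean: float
    y1_sd: float


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic-cohort generator.

    Scores are "t-score-like": ``score_mean``/``score_sd`` (and the y1
    counterparts) are the pooled targets the generated cohort matches
    exactly in-sample.  ``gamma`` is the loading of the latent
    vulnerability on each planted edge, in Fisher-z units per SD of v.
    """

    n_participants: int = 500
    n_sites: int = 6
    n_regions: int = 352
    family_rate: float = 0.2          # fraction of participants with a sibling
    planted_edges: int = 20
    gamma: float = 0.0
    edge_mu: float = 0.25             # planted-edge baseline z level
    edge_mu_sd: float = 0.20          # spread of background edge baselines
    edge_sigma: float = 0.20          # between-participant edge noise SD
    site_sd: float = 0.05             # per-(site, edge) additive offset SD
    base_y1_r: float = 0.68           # target pooled Pearson r(base, y1)
    v_loading_base: float = 0.15      # latent v loading on baseline score
    v_loading_y1: float = 0.4         # latent v loading on follow-up score
    skew: float = 0.5                 # sinh-arcsinh shift; 0 = Gaussian
    score_mean: float = 53.51
    score_sd: float = 6.02
    y1_mean: float = 53.48
    y1_sd: float = 6.06
    groups: tuple[GroupSpec, ...] = ()
    p_female: float = 0.529
    age_mean: float = 10.0
    age_sd: float = 0.6
    motion_mean: float = 0.12         # mean FD, mm
    motion_sd: float = 0.05
    motion_outcome_r: float = 0.0
    #: the planted edge set is drawn from this seed, not from ``seed``, so
    #: cohorts sharing a configuration share their planted edges (the
    #: discovery -> extension transfer scenario)
    planted_seed: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.family_rate <= 1.0:
            raise ValueError("family_rate must be in [0, 1]")
        if self.planted_edges > n_edges(self.n_regions):
            raise ValueError("more planted edges than edges exist")
        if abs(self.base_y1_r) >= 1 or abs(self.motion_outcome_r) > 1:
            raise ValueError("impossible correlation parameter (|r| must be < 1)")
        if self.score_sd <= 0 or self.y1_sd <= 0:
            raise ValueError("score SDs must be positive")
        if self.n_sites < 1 or self.n_participants < 2:
            raise ValueError("need >= 1 site and >= 2 participants")

    @property
    def n_edges(self) -> int:
        return n_edges(self.n_regions)

    def effective_groups(self) -> tuple[GroupSpec, ...]:
        if self.groups:
            if abs(sum(g.fraction for g in self.groups) - 1.0) > 1e-9:
                raise ValueError("group fractions must sum to 1")
            return self.groups
        return (GroupSpec("none", 1.0, self.score_mean, self.score_sd,
                          self.y1_mean, self.y1_sd),)

    # -- YAML round trip ----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["groups"] = [asdict(g) for g in self.groups]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["groups"] = tuple(GroupSpec(**g) for g in d.get("groups", []))
        return cls(**d)


def preset(name: str, seed: int = 0) -> SimulationConfig:
    """Calibrated cohort presets.

    ``abcd_like``: n=3,718 across 21 sites, positively skewed t-scores
    (baseline 53.51 +/- 6.02, follow-up 53.48 +/- 6.06, r = 0.68),
    52.9% girls, ages ~10.0 +/- 0.6, sibling nesting.

    ``banda_like``: n=150, one site, a clinical/control mixture whose
    group moments pool to 49.11 +/- 15.28 at baseline and 44.62 +/- 11.39
    at follow-up with r = 0.63, 61.3% girls, ages ~15.4 +/- 0.9.
    """
    if name == "abcd_like":
        cfg = SimulationConfig(
            n_participants=3718, n_sites=21, n_regions=352,
            family_rate=0.2, planted_edges=20, gamma=0.0,
            base_y1_r=0.68, skew=0.5,
            score_mean=53.51, score_sd=6.02, y1_mean=53.48, y1_sd=6.06,
            p_female=0.529, age_mean=10.0, age_sd=0.6, seed=seed)
        return replace(cfg, gamma=gamma_for_marginal_r(0.15, cfg))
    if name == "banda_like":
        groups = (
            GroupSpec("clinical", 0.64, 56.47, 14.26, 49.07, 11.50),
            GroupSpec("control", 0.36, 36.04, 4.43, 36.70, 5.25),
        )
        cfg = SimulationConfig(
            n_participants=150, n_sites=1, n_regions=352,
            family_rate=0.0, planted_edges=20, gamma=0.0,
            base_y1_r=0.63, skew=0.0,
            score_mean=49.11, score_sd=15.28, y1_mean=44.62, y1_sd=11.39,
            groups=groups,
            p_female=0.613, age_mean=15.4, age_sd=0.9, seed=seed)
        return replace(cfg, gamma=gamma_for_marginal_r(0.15, cfg))
    raise ValueError(f"unknown preset {name!r} (use 'abcd_like' or 'banda_like')")


def planted_benchmark(n_participants: int = 2000, n_regions: int = 46,
                      n_sites: int = 6, marginal_r: float = 0.15,
                      n_planted: int = 20, seed: int = 0) -> SimulationConfig:
    """Desk-scale benchmark with a recoverable planted edge set."""
    cfg = SimulationConfig(
        n_participants=n_participants, n_sites=n_sites, n_regions=n_regions,
        planted_edges=n_planted, seed=seed)
    return replace(cfg, gamma=gamma_for_marginal_r(marginal_r, cfg))


def null_benchmark(n_participants: int = 500, n_regions: int = 46,
                   n_sites: int = 6, seed: int = 0) -> SimulationConfig:
    """Desk-scale cohort with no edge-outcome signal (gamma = 0)."""
    return SimulationConfig(
        n_participants=n_participants, n_sites=n_sites, n_regions=n_regions,
        planted_edges=20, gamma=0.0, seed=seed)


def gamma_for_marginal_r(r: float, config: SimulationConfig) -> float:
    """Planted-edge loading giving a target marginal edge-outcome Pearson r.

    From the generative model, corr(z_k, y1-latent) =
    gamma * b_v / sqrt(gamma^2 + site_sd^2 + edge_sigma^2); inverting
    gives gamma = r * s / sqrt(b_v^2 - r^2) with s^2 the non-signal edge
    variance.  The skewing transform attenuates the realized Pearson r
    slightly (Spearman is unaffected); the formula targets the latent
    scale.
    """
    b_v = config.v_loading_y1
    if not 0 < abs(r) < abs(b_v):
        raise ValueError(f"target r must satisfy 0 < |r| < v_loading_y1={b_v}")
    s2 = config.site_sd ** 2 + config.edge_sigma ** 2
    return float(r * math.sqrt(s2) / math.sqrt(b_v ** 2 - r ** 2))


# ---------------------------------------------------------------------------
# score-distribution calibration (deterministic, quadrature-based)
# ---------------------------------------------------------------------------

def sinh_arcsinh(u: np.ndarray, skew: float) -> np.ndarray:
    """Monotone skewing transform; identity at skew = 0."""
    if skew == 0.0:
        return np.asarray(u, dtype=float)
    return np.sinh(np.arcsinh(np.asarray(u, dtype=float)) + skew)


@lru_cache(maxsize=64)
def _sas_moments(skew: float) -> tuple[float, float]:
    """Population mean and SD of sinh_arcsinh(U, skew), U ~ N(0,1)."""
    x, w = np.polynomial.hermite_e.hermegauss(128)
    w = w / w.sum()
    f = sinh_arcsinh(x, skew)
    m = float(w @ f)
    s = float(math.sqrt(w @ (f - m) ** 2))
    return m, s


@lru_cache(maxsize=256)
def _transformed_corr(latent_rho: float, skew: float) -> float:
    """Pearson corr of (g(U1), g(U2)) for standard bivariate normal U."""
    if skew == 0.0:
        return latent_rho
    x, w = np.polynomial.hermite_e.hermegauss(64)
    w = w / w.sum()
    m, s = _sas_moments(skew)
    g1 = (sinh_arcsinh(x, skew) - m) / s
    u2 = latent_rho * x[:, None] + math.sqrt(1 - latent_rho ** 2) * x[None, :]
    g2 = (sinh_arcsinh(u2, skew) - m) / s
    return float(w @ ((g1[:, None] * g2) @ w))


@lru_cache(maxsize=256)
def latent_corr_for_target(target_r: float, skew: float) -> float:
    """Latent Gaussian correlation whose transformed Pearson r hits target."""
    if skew == 0.0 or target_r == 0.0:
        return target_r
    return float(brentq(lambda r: _transformed_corr(r, skew) - target_r,
                        -0.999, 0.999, xtol=1e-10))


def _within_group_corr(groups: tuple[GroupSpec, ...], r_target: float,
                       ) -> float:
    """Common within-group score correlation so the pooled r hits target."""
    p = np.array([g.fraction for g in groups])
    mb = np.array([g.base_mean for g in groups])
    my = np.array([g.y1_mean for g in groups])
    sb = np.array([g.base_sd for g in groups])
    sy = np.array([g.y1_sd for g in groups])
    mb_tot, my_tot = p @ mb, p @ my
    var_b = p @ (sb ** 2 + (mb - mb_tot) ** 2)
    var_y = p @ (sy ** 2 + (my - my_tot) ** 2)
    cov_between = p @ ((mb - mb_tot) * (my - my_tot))
    cov_within = r_target * math.sqrt(var_b * var_y) - cov_between
    r_w = cov_within / (p @ (sb * sy))
    if not -1.0 < r_w < 1.0:
        raise ValueError(
            f"pooled correlation target {r_target} is infeasible for the "
            f"given group moments (implied within-group r = {r_w:.3f})")
    return float(r_w)


def _latent_weights(cfg: SimulationConfig, latent_rho: float,
                    ) -> tuple[float, float, float]:
    """Decompose u_y1 = b_v*v + beta*e_base + w*e_new given corr targets."""
    a, b_v = cfg.v_loading_base, cfg.v_loading_y1
    if not 0 <= a < 1:
        raise ValueError("v_loading_base must be in [0, 1)")
    beta = (latent_rho - a * b_v) / math.sqrt(1 - a ** 2)
    resid = 1.0 - b_v ** 2 - beta ** 2
    if resid < 0:
        raise ValueError(
            "infeasible latent structure: v_loading_y1 and base_y1_r imply "
            "total variance > 1; lower the loadings")
    return b_v, beta, math.sqrt(resid)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    """An aligned cohort plus the planted ground truth.

    ``latent_v`` exposes the per-participant vulnerability latent for
    diagnostics (e.g. checking the intra-family correlation).
    """

    cohort: AlignedCohort
    ground_truth: pd.DataFrame   # edge_index, region_i, region_j, gamma
    config: SimulationConfig
    latent_v: np.ndarray | None = None

    @property
    def planted_edge_indices(self) -> np.ndarray:
        return self.ground_truth["edge_index"].to_numpy(int)


def _assign_sites_and_families(cfg: SimulationConfig, rng: np.random.Generator,
                               ) -> tuple[np.ndarray, np.ndarray]:
    n = cfg.n_participants
    sites = rng.permutation(np.arange(n) % cfg.n_sites)
    site_ids = np.array([f"site{s:02d}" for s in sites])

    family_ids = np.array([f"fam{i:05d}" for i in range(n)], dtype=object)
    n_pairs = int(round(cfg.family_rate * n / 2))
    if n_pairs:
        # siblings never span sites: pair within site blocks, round-robin
        per_site = [list(rng.permutation(np.flatnonzero(sites == s)))
                    for s in range(cfg.n_sites)]
        made = 0
        while made < n_pairs:
            progressed = False
            for members in per_site:
                if len(members) >= 2 and made < n_pairs:
                    a, b = members.pop(), members.pop()
                    family_ids[b] = family_ids[a]
                    made += 1
                    progressed = True
            if not progressed:
                break
    return site_ids, family_ids


def _family_latent(family_ids: np.ndarray, rng: np.random.Generator,
                   ) -> np.ndarray:
    """v with intra-family correlation INTRA_FAMILY_CORR."""
    _, fam_idx = np.unique(family_ids, return_inverse=True)
    shared = rng.standard_normal(fam_idx.max() + 1)[fam_idx]
    own = rng.standard_normal(family_ids.size)
    w = math.sqrt(INTRA_FAMILY_CORR)
    return w * shared + math.sqrt(1 - INTRA_FAMILY_CORR) * own


def _standardize_to(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    s = x.std()
    if s == 0:
        raise ValueError("degenerate score distribution (zero variance)")
    return (x - x.mean()) / s * sd + mean


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw one synthetic cohort; identical seeds give identical cohorts."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, E = cfg.n_participants, cfg.n_edges
    edge_map = EdgeIndexMap(cfg.n_regions)

    site_ids, family_ids = _assign_sites_and_families(cfg, rng)
    v = _family_latent(family_ids, rng)

    # -- diagnostic groups (deterministic counts, random assignment)
    groups = cfg.effective_groups()
    counts = np.array([int(round(g.fraction * n)) for g in groups])
    counts[-1] = n - counts[:-1].sum()
    group_idx = rng.permutation(np.repeat(np.arange(len(groups)), counts))

    # -- bivariate score latents, calibrated to the pooled Pearson target
    r_within = _within_group_corr(groups, cfg.base_y1_r)
    latent_rho = latent_corr_for_target(r_within, cfg.skew)
    b_v, beta, w_new = _latent_weights(cfg, latent_rho)
    a = cfg.v_loading_base
    e_base = rng.standard_normal(n)
    e_new = rng.standard_normal(n)
    u_base = a * v + math.sqrt(1 - a ** 2) * e_base
    u_y1 = b_v * v + beta * e_base + w_new * e_new

    m_f, s_f = _sas_moments(cfg.skew)
    g_base = (sinh_arcsinh(u_base, cfg.skew) - m_f) / s_f
    g_y1 = (sinh_arcsinh(u_y1, cfg.skew) - m_f) / s_f
    gb_mean = np.array([g.base_mean for g in groups])[group_idx]
    gb_sd = np.array([g.base_sd for g in groups])[group_idx]
    gy_mean = np.array([g.y1_mean for g in groups])[group_idx]
    gy_sd = np.array([g.y1_sd for g in groups])[group_idx]
    score_base = _standardize_to(gb_mean + gb_sd * g_base,
                                 cfg.score_mean, cfg.score_sd)
    score_y1 = _standardize_to(gy_mean + gy_sd * g_y1,
                               cfg.y1_mean, cfg.y1_sd)

    # -- demographics and motion
    sex = np.where(rng.random(n) < cfg.p_female, "F", "M")
    age = np.maximum(cfg.age_mean + cfg.age_sd * rng.standard_normal(n), 1.0)
    r_m = cfg.motion_outcome_r
    m_lat = r_m * u_y1 + math.sqrt(1 - r_m ** 2) * rng.standard_normal(n)
    ln_sig2 = math.log(1 + (cfg.motion_sd / cfg.motion_mean) ** 2)
    mean_fd = np.exp(math.log(cfg.motion_mean) - ln_sig2 / 2
                     + math.sqrt(ln_sig2) * m_lat)

    # -- edges in Fisher-z space
    plant_rng = np.random.default_rng(cfg.planted_seed)
    planted = np.sort(plant_rng.choice(E, size=cfg.planted_edges,
                                       replace=False))
    mu = cfg.edge_mu + cfg.edge_mu_sd * rng.standard_normal(E)
    mu[planted] = cfg.edge_mu
    site_codes = pd.factorize(site_ids)[0]
    site_offsets = cfg.site_sd * rng.standard_normal((cfg.n_sites, E))
    X = mu[None, :] + site_offsets[site_codes]
    X += cfg.edge_sigma * rng.standard_normal((n, E))
    if cfg.planted_edges:
        X[:, planted] += cfg.gamma * v[:, None]

    pids = [f"sub{i:05d}" for i in range(n)]
    edges = CohortEdgeMatrix(X=X, participant_ids=pids, edge_map=edge_map)
    pheno = PhenotypeTable(df=pd.DataFrame({
        "participant_id": pids,
        "site_id": site_ids,
        "family_id": family_ids,
        "sex": sex,
        "age": age,
        "mean_fd": mean_fd,
        "score_base": score_base,
        "score_y1": score_y1,
        "group": [groups[g].name for g in group_idx],
    }))
    ground_truth = pd.DataFrame({
        "edge_index": planted,
        "region_i": edge_map.rows[planted],
        "region_j": edge_map.cols[planted],
        "gamma": np.full(planted.size, cfg.gamma),
    })
    return SimulatedCohort(cohort=AlignedCohort(edges=edges, phenotypes=pheno),
                           ground_truth=ground_truth, config=cfg, latent_v=v)


# ---------------------------------------------------------------------------
# small time-series mode for end-to-end tests
# ---------------------------------------------------------------------------

def simulate_time_series(sim: SimulatedCohort, n_timepoints: int = 200,
                         seed: int | None = None) -> list[TimeSeriesMatrix]:
    """Per-participant time series whose connectomes approximate sim's z.

    Each participant's target correlation matrix is tanh of their simulated
    z row (eigenvalue-clipped to the nearest positive-definite matrix);
    time series are i.i.d. multivariate-normal draws.  Intended for small
    region counts only.
    """
    cfg = sim.config
    if cfg.n_regions > 100:
        raise ValueError("time-series mode is for small region counts (<= 100)")
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    edge_map = sim.cohort.edges.edge_map
    out = []
    N = cfg.n_regions
    for row, pid in zip(sim.cohort.edges.X, sim.cohort.participant_ids):
        R = np.eye(N)
        R[edge_map.rows, edge_map.cols] = np.tanh(row)
        R[edge_map.cols, edge_map.rows] = np.tanh(row)
        vals, vecs = np.linalg.eigh(R)
        vals = np.maximum(vals, 1e-3)
        L = vecs * np.sqrt(vals)
        ts = L @ rng.standard_normal((N, n_timepoints))
        out.append(TimeSeriesMatrix(values=ts, participant_id=pid))
    return out
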