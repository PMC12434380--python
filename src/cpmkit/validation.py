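"""Leave-half-sites-out cross-validation and permutation-null testing.

The discovery analysis repeats five steps: (1) partition acquisition
sites at random into a training and a testing half — participants follow
their site, so no site (and, when families never span sites, no family)
straddles the two sets; (2) screen every edge in the training half for a
(partial) Spearman correlation with the follow-up score at p < alpha;
(3) fit the strength -> outcome line on the training half; (4) score the
testing half and record the partial Spearman correlation between observed
and predicted outcomes given the covariates; (5) average the per-iteration
correlations and compare that mean against a permutation null built by
re-running the same machinery with the connectome <-> phenotype linkage
shuffled (outcome and covariates travel together).

Permutations are paired with the observed run: each permutation reuses
the observed site splits and only re-randomizes the linkage, which keeps
the observed and permuted statistics exchangeable under the null
conditional on the splits.  p_perm is the strict proportion of permuted
mean correlations larger than the observed one.

Performance notes: screening inside the permutation loop uses ordinal
ranks (ties broken by stable sort order — almost surely absent for
continuous connectivity data, in which case ordinal and average ranks
coincide) via numba kernels over a per-column sort order that is computed
once per cohort.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import stats

from .cohort import AlignedCohort
from .cpm import (DEFAULT_ALPHA, NetworkMask, fit_strength_model,
                  rho_threshold, screen_edges)

log = logging.getLogger("cpmkit")

MIN_SPLIT_N = 30


# ---------------------------------------------------------------------------
# configuration / results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVConfig:
    """Cross-validation and permutation-test settings."""

    n_iterations: int = 100
    alpha: float = DEFAULT_ALPHA
    adjust: bool = True               # covariate-adjusted screening
    seed: int = 0
    n_permutations: int = 1000
    perm_iterations: int | None = None  # defaults to n_iterations (paired)
    participant_split: bool = False   # fallback for single-site cohorts
    plus_one: bool = False            # (1 + #>=) / (1 + P) p-value variant

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be >= 0")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")

    @property
    def effective_perm_iterations(self) -> int:
        return self.perm_iterations or self.n_iterations


@dataclass
class SiteSplit:
    """One train/test partition of sites and their participants."""

    train_sites: list[str]
    test_sites: list[str]
    train_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class CVResult:
    """Per-iteration test-set correlations and their mean."""

    rhos: np.ndarray                 # NaN marks zero-edge iterations
    splits: list[SiteSplit]
    masks: list[np.ndarray] = field(default_factory=list)
    seed: int = 0
    alpha: float = DEFAULT_ALPHA
    adjusted: bool = True

    @property
    def mean_rho(self) -> float:
        valid = self.rhos[~np.isnan(self.rhos)]
        return float(valid.mean()) if valid.size else float("nan")

    @property
    def n_zero_edge(self) -> int:
        return int(np.isnan(self.rhos).sum())


@dataclass
class PermutationResult:
    """Permutation null distribution of mean rho and its p-value."""

    null_rhos: np.ndarray
    p_perm: float
    observed_mean_rho: float
    n_failed: int = 0                # permutations with no scoreable iteration


# ---------------------------------------------------------------------------
# site splitting
# ---------------------------------------------------------------------------

def split_half_sites(site_ids: np.ndarray,
                     rng: np.random.Generator | int) -> SiteSplit:
    """Randomly assign ceil(S/2) sites to training, the rest to testing.

    Every participant follows their site; train and test participant sets
    are disjoint and no site straddles them.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    site_ids = np.asarray(site_ids)
    sites = np.unique(site_ids)
    if sites.size < 2:
        raise ValueError(
            "cannot split a single-site cohort by site; use the "
            "participant_split flag for a participant-level random split")
    order = rng.permutation(sites)
    n_train = math.ceil(sites.size / 2)
    train_sites = sorted(order[:n_train].tolist())
    test_sites = sorted(order[n_train:].tolist())
    in_train = np.isin(site_ids, train_sites)
    return SiteSplit(train_sites=train_sites, test_sites=test_sites,
                     train_idx=np.flatnonzero(in_train),
                     test_idx=np.flatnonzero(~in_train))


def _participant_split(n: int, rng: np.random.Generator) -> SiteSplit:
    perm = rng.permutation(n)
    half = math.ceil(n / 2)
    return SiteSplit(train_sites=[], test_sites=[],
                     train_idx=np.sort(perm[:half]),
                     test_idx=np.sort(perm[half:]))


def _check_family_site_consistency(cohort: AlignedCohort) -> None:
    fams = cohort.phenotypes.families
    sites = cohort.sites
    import pandas as pd
    spread = pd.DataFrame({"f": fams, "s": sites}).groupby("f")["s"].nunique()
    if (spread > 1).any():
        log.warning(
            "%d families span more than one site; site splitting cannot "
            "guarantee family disjointness for them",
            int((spread > 1).sum()))


# ---------------------------------------------------------------------------
# ordinal-rank Spearman kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _plain_rank_dots(order_T, W):          # pragma: no cover - numba
    """S[p, k] = sum over subset of (ordinal rank of edge k) * W[p, row].

    ``order_T`` is (E, n): row indices of each edge column sorted by value.
    ``W[p, i]`` carries the training y-rank of the phenotype linked to X
    row i under permutation p, and 0 marks rows outside the training set.
    """
    P, n = W.shape
    E = order_T.shape[0]
    S = np.empty((P, E))
    for p in range(P):
        w = W[p]
        for k in range(E):
            row = order_T[k]
            r = 0
            s = 0.0
            for t in range(n):
                wv = w[row[t]]
                if wv != 0.0:
                    r += 1
                    s += r * wv
            S[p, k] = s
    return S


@njit(cache=True)
def _adjusted_rank_dots(order_T, member, W):   # pragma: no cover - numba
    """S[p, q, k] = sum of (ordinal rank of edge k) * W[p, q, row].

    ``member[p, i]`` flags X rows in the training subset (rank counter
    advances only there); W rows may legitimately contain zeros.
    """
    P, Q, n = W.shape
    E = order_T.shape[0]
    S = np.zeros((P, Q, E))
    for p in range(P):
        memb = member[p]
        for k in range(E):
            row = order_T[k]
            r = 0
            acc = np.zeros(Q)
            for t in range(n):
                i = row[t]
                if memb[i]:
                    r += 1
                    for q in range(Q):
                        acc[q] += r * W[p, q, i]
            for q in range(Q):
                S[p, q, k] = acc[q]
    return S


def _ordinal_ranks(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties broken by stable sort order."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size)
    ranks[order] = np.arange(1, x.size + 1)
    return ranks


def _orthonormal_covariate_basis(cov: np.ndarray) -> np.ndarray:
    """Orthonormal basis of span{1, rank(cov)} (first column is constant)."""
    n = cov.shape[0]
    ranked = stats.rankdata(cov, axis=0)
    design = np.column_stack([np.ones(n), ranked])
    q, r = np.linalg.qr(design)
    if np.any(np.abs(np.diag(r)) < 1e-10 * n):
        raise ValueError("rank-deficient covariates inside a split")
    return q


# ---------------------------------------------------------------------------
# the CV machinery (observed and permuted runs share this path)
# ---------------------------------------------------------------------------

class _CVEngine:
    """Per-cohort precomputation for repeated screened CV runs."""

    def __init__(self, cohort: AlignedCohort):
        self.cohort = cohort
        self.X = cohort.edges.X
        self.y = cohort.outcome
        self.cov = cohort.covariates()
        self.n = cohort.n
        # per-edge sort order, computed once; this is the expensive part
        self.order_T = np.ascontiguousarray(
            np.argsort(self.X, axis=0, kind="stable").T).astype(np.int32)

    def run(self, splits: list[SiteSplit], row_maps: np.ndarray,
            alphas: list[float], adjust: bool,
            collect_masks: bool) -> tuple[np.ndarray, dict]:
        """Screened CV over |splits| iterations for every linkage row map.

        ``row_maps`` is (P, n): phenotype j is linked to X row
        row_maps[p, j].  Returns rhos of shape (len(alphas), P, n_iter)
        and, when requested, the per-iteration selected-edge masks of the
        first (observed) row map at each alpha.
        """
        X, y, cov, n = self.X, self.y, self.cov, self.n
        P = row_maps.shape[0]
        A = len(alphas)
        rhos = np.full((A, P, len(splits)), np.nan)
        masks: dict = {a: [] for a in range(A)}

        for it, split in enumerate(splits):
            tr, te = split.train_idx, split.test_idx
            m_tr, m_te = tr.size, te.size
            if min(m_tr, m_te) < MIN_SPLIT_N:
                raise ValueError(
                    f"iteration {it}: split sizes ({m_tr}, {m_te}) below "
                    f"the minimum of {MIN_SPLIT_N}")
            k = 4 if adjust else 0
            rstars = [rho_threshold(a, m_tr, k) for a in alphas]
            ytr_ranks = _ordinal_ranks(y[tr])

            # screening statistics for all linkages at once
            if not adjust:
                W = np.zeros((P, n))
                np.put_along_axis(W, row_maps[:, tr], ytr_ranks[None, :],
                                  axis=1)
                S = _plain_rank_dots(self.order_T, W)
                mu = m_tr * (m_tr + 1.0) ** 2 / 4.0
                sig = m_tr * (m_tr ** 2 - 1.0) / 12.0
                rho_scr = (S - mu) / sig
            else:
                q_all = _orthonormal_covariate_basis(cov[tr])
                q_cov = q_all[:, 1:]
                b = ytr_ranks - q_all @ (q_all.T @ ytr_ranks)
                b_unit = b / np.linalg.norm(b)
                Q = 1 + q_cov.shape[1]
                W3 = np.zeros((P, Q, n))
                member = np.zeros((P, n), dtype=np.bool_)
                np.put_along_axis(member, row_maps[:, tr],
                                  np.ones((1, m_tr), dtype=np.bool_), axis=1)
                np.put_along_axis(W3[:, 0, :], row_maps[:, tr],
                                  b_unit[None, :], axis=1)
                for c in range(q_cov.shape[1]):
                    np.put_along_axis(W3[:, 1 + c, :], row_maps[:, tr],
                                      q_cov[None, :, c], axis=1)
                S = _adjusted_rank_dots(self.order_T, member, W3)
                sum_r2 = m_tr * (m_tr + 1.0) * (2 * m_tr + 1.0) / 6.0
                mean_term = m_tr * (m_tr + 1.0) ** 2 / 4.0
                a_perp2 = sum_r2 - mean_term - (S[:, 1:, :] ** 2).sum(axis=1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    rho_scr = S[:, 0, :] / np.sqrt(np.maximum(a_perp2, 1e-12))

            # evaluation-side precomputation (shared by all linkages)
            q_te = _orthonormal_covariate_basis(cov[te])
            yte_ranks = _ordinal_ranks(y[te])
            b_te = yte_ranks - q_te @ (q_te.T @ yte_ranks)
            b_te_unit = b_te / np.linalg.norm(b_te)

            for p in range(P):
                tr_rows = row_maps[p, tr]
                te_rows = row_maps[p, te]
                for ai, rstar in enumerate(rstars):
                    sel = np.flatnonzero(np.abs(rho_scr[p]) > rstar)
                    if collect_masks and p == 0:
                        masks[ai].append(sel)
                    if sel.size == 0:
                        continue
                    s_tr = np.abs(X[np.ix_(tr_rows, sel)]).sum(axis=1)
                    if np.ptp(s_tr) == 0:
                        continue
                    model = fit_strength_model(s_tr, y[tr])
                    s_te = np.abs(X[np.ix_(te_rows, sel)]).sum(axis=1)
                    pred = model.predict(s_te)
                    pr = _ordinal_ranks(np.asarray(pred))
                    proj = q_te.T @ pr
                    den2 = pr @ pr - proj @ proj
                    if den2 <= 0:
                        continue
                    rhos[ai, p, it] = (pr @ b_te_unit) / math.sqrt(den2)
        return rhos, masks


def _make_splits(cohort: AlignedCohort, config: CVConfig,
                 n_iterations: int) -> list[SiteSplit]:
    ss = np.random.SeedSequence(config.seed).spawn(2)[0]
    rng = np.random.default_rng(ss)
    if config.participant_split:
        return [_participant_split(cohort.n, rng) for _ in range(n_iterations)]
    sites = cohort.sites
    return [split_half_sites(sites, rng) for _ in range(n_iterations)]


def run_cv(cohort: AlignedCohort, config: CVConfig) -> CVResult:
    """Observed leave-half-sites-out CV; same seed gives identical results."""
    _check_family_site_consistency(cohort)
    splits = _make_splits(cohort, config, config.n_iterations)
    engine = _CVEngine(cohort)
    identity = np.arange(cohort.n)[None, :]
    rhos, masks = engine.run(splits, identity, [config.alpha],
                             config.adjust, collect_masks=True)
    result = CVResult(rhos=rhos[0, 0], splits=splits, masks=masks[0],
                      seed=config.seed, alpha=config.alpha,
                      adjusted=config.adjust)
    if result.n_zero_edge:
        log.info("run_cv: %d of %d iterations selected zero edges and are "
                 "excluded from the mean", result.n_zero_edge,
                 config.n_iterations)
    return result


def alpha_sweep(cohort: AlignedCohort, config: CVConfig,
                alphas: list[float]) -> dict[float, CVResult]:
    """run_cv at several selection thresholds, reusing screening statistics."""
    splits = _make_splits(cohort, config, config.n_iterations)
    engine = _CVEngine(cohort)
    identity = np.arange(cohort.n)[None, :]
    rhos, masks = engine.run(splits, identity, list(alphas),
                             config.adjust, collect_masks=True)
    return {a: CVResult(rhos=rhos[ai, 0], splits=splits, masks=masks[ai],
                        seed=config.seed, alpha=a, adjusted=config.adjust)
            for ai, a in enumerate(alphas)}


def permutation_test(cohort: AlignedCohort, config: CVConfig,
                     observed: CVResult) -> PermutationResult:
    """Permutation-null significance of the observed mean correlation.

    Each permutation shuffles the connectome <-> phenotype linkage
    (outcome and covariates stay together) and reruns the CV with the
    observed run's site splits (the first ``perm_iterations`` of them).
    p_perm is the strict proportion of permuted mean rhos larger than the
    observed mean rho.
    """
    if config.n_permutations == 0:
        raise ValueError("n_permutations must be positive")
    obs = observed.mean_rho
    if math.isnan(obs):
        raise ValueError("observed CV produced no scoreable iterations")
    n_it = min(config.effective_perm_iterations, len(observed.splits))
    splits = observed.splits[:n_it]
    perm_ss = np.random.SeedSequence(config.seed).spawn(2)[1]
    rng = np.random.default_rng(perm_ss)
    P = config.n_permutations
    row_maps = np.stack([rng.permutation(cohort.n) for _ in range(P)])
    engine = _CVEngine(cohort)
    rhos, _ = engine.run(splits, row_maps, [config.alpha], config.adjust,
                         collect_masks=False)
    with np.errstate(invalid="ignore"):
        null = np.array([np.nanmean(r) if np.any(~np.isnan(r)) else np.nan
                         for r in rhos[0]])
    n_failed = int(np.isnan(null).sum())
    if config.plus_one:
        p = (1 + int(np.nansum(null >= obs))) / (1 + P)
    else:
        p = int(np.nansum(null > obs)) / P
    return PermutationResult(null_rhos=null, p_perm=float(p),
                             observed_mean_rho=obs, n_failed=n_failed)


def consensus_network(cohort: AlignedCohort, alpha: float = DEFAULT_ALPHA,
                      adjust: bool = True) -> NetworkMask:
    """Screen the full cohort (no split) into the consensus edge set."""
    screen = screen_edges(cohort, alpha=alpha, adjust=adjust)
    if screen.n_selected == 0:
        log.warning("consensus network is empty at alpha=%g", alpha)
    return NetworkMask.from_screen(screen, cohort.edges.edge_map,
                                   provenance={"kind": "consensus"})
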