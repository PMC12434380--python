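"""Core CPM statistics.

Connectome-based predictive modeling screens every functional connection
for a rank correlation with the follow-up severity score, summarizes the
surviving connections into a single per-participant "network strength"
(the sum of absolute Fisher-z values), and predicts the outcome from
strength with an ordinary least-squares line.

The screening correlation is Spearman's, optionally partial with respect
to the standard covariate set (baseline severity, sex, age, mean head
motion): ranks of x, y and each covariate are taken first, ranked x and
ranked y are residualized on the ranked covariates plus an intercept, and
the Pearson correlation of the residuals is the partial Spearman rho.
p-values use the t approximation  t = rho * sqrt((n-2-k)/(1-rho^2))  on
n-2-k degrees of freedom, two-sided — standard practice at the sample
sizes this pipeline targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AlignedCohort
from .connectome import EdgeIndexMap

DEFAULT_ALPHA = 1e-3


# ---------------------------------------------------------------------------
# rank primitives
# ---------------------------------------------------------------------------

def rank_transform(x: np.ndarray) -> np.ndarray:
    """Average ranks in [1, n]; ties receive the mean of their positions."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot rank an empty vector")
    if not np.isfinite(x).all():
        raise ValueError("cannot rank non-finite values")
    return stats.rankdata(x, axis=0 if x.ndim > 1 else None)


def _residualize(ranked: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Residuals of columns of ``ranked`` against an orthonormal basis q."""
    return ranked - q @ (q.T @ ranked)


def _design_basis(cov_ranks: np.ndarray, n: int) -> np.ndarray:
    """Orthonormal basis of span{intercept, ranked covariates}."""
    design = np.column_stack([np.ones(n), cov_ranks]) if cov_ranks.size \
        else np.ones((n, 1))
    q, r = np.linalg.qr(design)
    if np.any(np.abs(np.diag(r)) < 1e-10 * n):
        raise ValueError("rank-deficient covariate matrix")
    return q


def partial_spearman(x: np.ndarray, y: np.ndarray,
                     covariates: np.ndarray | None = None,
                     ) -> tuple[float, float]:
    """Partial Spearman correlation of x and y given covariate columns.

    With no covariates this is exactly the classic Spearman rho.

    Returns
    -------
    (rho, p) : tuple of float
        Correlation of covariate-residualized ranks and its two-sided
        t-approximation p-value on n-2-k degrees of freedom.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have the same length")
    cov = (np.empty((n, 0)) if covariates is None
           else np.asarray(covariates, dtype=float).reshape(n, -1))
    k = cov.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")

    xr, yr = rank_transform(x), rank_transform(y)
    if np.ptp(xr) == 0 or np.ptp(yr) == 0:
        raise ValueError("constant x or y after ranking")
    cr = rank_transform(cov) if k else cov
    q = _design_basis(cr, n)
    xres, yres = _residualize(xr, q), _residualize(yr, q)
    denom = np.linalg.norm(xres) * np.linalg.norm(yres)
    if denom == 0:
        raise ValueError("x or y lies entirely in the covariate span")
    rho = float(xres @ yres / denom)
    rho = min(1.0, max(-1.0, rho))
    df = n - 2 - k
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1.0 - rho * rho))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return rho, p


def rho_threshold(alpha: float, n: int, k: int = 0) -> float:
    """|rho| above which the two-sided t-approximation p falls below alpha."""
    df = n - 2 - k
    if df <= 0:
        raise ValueError("non-positive degrees of freedom")
    tcrit = stats.t.isf(alpha / 2.0, df)
    return float(tcrit / np.sqrt(df + tcrit * tcrit))


# ---------------------------------------------------------------------------
# edge screening
# ---------------------------------------------------------------------------

@dataclass
class EdgeScreenResult:
    """Per-edge statistics from the screening step."""

    rho: np.ndarray
    p: np.ndarray
    mask: np.ndarray          # True where p < alpha (strict)
    alpha: float
    adjusted: bool
    n: int

    @property
    def sign(self) -> np.ndarray:
        """+1/-1 for selected edges, 0 elsewhere."""
        return np.where(self.mask, np.sign(self.rho), 0).astype(int)

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


def screen_from_ranks(x_ranks: np.ndarray, y_ranks: np.ndarray,
                      cov_ranks: np.ndarray, alpha: float,
                      adjusted: bool) -> EdgeScreenResult:
    """Screening core on pre-ranked data (columns of x_ranks are edges)."""
    n, _ = x_ranks.shape
    k = cov_ranks.shape[1]
    q = _design_basis(cov_ranks, n)
    xres = _residualize(x_ranks, q)
    yres = _residualize(y_ranks.reshape(-1, 1), q).ravel()
    xnorm = np.sqrt(np.einsum("ij,ij->j", xres, xres))
    ynorm = np.linalg.norm(yres)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (xres.T @ yres) / (xnorm * ynorm)
    rho = np.clip(np.nan_to_num(rho, nan=0.0), -1.0, 1.0)
    df = n - 2 - k
    with np.errstate(divide="ignore"):
        t = rho * np.sqrt(df / np.maximum(1.0 - rho * rho, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    mask = p < alpha
    return EdgeScreenResult(rho=rho, p=p, mask=mask, alpha=alpha,
                            adjusted=adjusted, n=n)


def screen_edges(cohort: AlignedCohort, alpha: float = DEFAULT_ALPHA,
                 adjust: bool = True) -> EdgeScreenResult:
    """Rank-correlate every edge with score_y1 and keep p < alpha.

    With ``adjust=True`` (default) the correlation is partial with respect
    to (score_base, sex, age, mean_fd); with ``adjust=False`` it is the
    plain Spearman screen.
    """
    n = cohort.n
    if n < 20:
        raise ValueError(f"screening needs n >= 20 (got {n})")
    y = cohort.outcome
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant; nothing to screen against")
    x_ranks = rank_transform(cohort.edges.X)
    y_ranks = rank_transform(y)
    cov = cohort.covariates() if adjust else np.empty((n, 0))
    cov_ranks = rank_transform(cov) if cov.size else cov
    return screen_from_ranks(x_ranks, y_ranks, cov_ranks, alpha, adjust)


# ---------------------------------------------------------------------------
# network strength and the strength -> outcome line
# ---------------------------------------------------------------------------

def network_strength(edge_vector: np.ndarray, mask: np.ndarray) -> float:
    """Sum of |z| over the masked edges; an empty mask scores 0."""
    edge_vector = np.asarray(edge_vector, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != edge_vector.shape:
        raise ValueError("mask length does not match edge vector")
    vals = edge_vector[mask]
    if not np.isfinite(vals).all():
        raise ValueError("non-finite z value inside the mask")
    return float(np.abs(vals).sum())


def cohort_strengths(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-row network strength over a participants x edges matrix."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(X.shape[0])
    return np.abs(X[:, mask]).sum(axis=1)


@dataclass
class StrengthModel:
    """Ordinary least-squares line from network strength to outcome."""

    intercept: float
    slope: float

    def predict(self, strengths: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(strengths, dtype=float)


def fit_strength_model(strengths: np.ndarray,
                       outcomes: np.ndarray) -> StrengthModel:
    """OLS fit of outcome on strength (closed form)."""
    s = np.asarray(strengths, dtype=float).ravel()
    y = np.asarray(outcomes, dtype=float).ravel()
    if s.size != y.size or s.size < 3:
        raise ValueError("need matching strength/outcome vectors with n >= 3")
    if np.ptp(s) == 0:
        raise ValueError("constant strengths; line is unidentifiable")
    sc, yc = s - s.mean(), y - y.mean()
    slope = float(sc @ yc / (sc @ sc))
    intercept = float(y.mean() - slope * s.mean())
    if not (np.isfinite(slope) and np.isfinite(intercept)):
        raise ValueError("non-finite regression coefficients")
    return StrengthModel(intercept=intercept, slope=slope)


def predict(model: StrengthModel,
            strengths: np.ndarray | float) -> np.ndarray | float:
    """Elementwise intercept + slope * strength."""
    out = model.predict(strengths)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite prediction input")
    return out


# ---------------------------------------------------------------------------
# the selected-edge set ("Symptoms Network")
# ---------------------------------------------------------------------------

@dataclass
class NetworkMask:
    """A named set of selected edges with per-edge statistic and sign.

    ``table`` columns: region_i, region_j (0-based, i < j), rho, sign.
    ``provenance`` records alpha, whether covariates were used, and n.
    """

    table: pd.DataFrame
    n_regions: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.table
        if len(t):
            if (t["region_i"] >= t["region_j"]).any():
                raise ValueError("mask pairs must satisfy i < j")
            if t.duplicated(["region_i", "region_j"]).any():
                raise ValueError("duplicate region pairs in mask")

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_screen(cls, screen: EdgeScreenResult, edge_map: EdgeIndexMap,
                    provenance: dict | None = None) -> "NetworkMask":
        sel = np.flatnonzero(screen.mask)
        table = pd.DataFrame({
            "region_i": edge_map.rows[sel],
            "region_j": edge_map.cols[sel],
            "rho": screen.rho[sel],
            "sign": np.sign(screen.rho[sel]).astype(int),
        })
        prov = dict(alpha=screen.alpha, adjusted=screen.adjusted, n=screen.n)
        prov.update(provenance or {})
        return cls(table=table, n_regions=edge_map.n_regions, provenance=prov)

    def edge_indices(self, edge_map: EdgeIndexMap) -> np.ndarray:
        """Edge-vector indices of this mask under ``edge_map``."""
        if edge_map.n_regions != self.n_regions:
            raise ValueError("edge map size does not match mask")
        return np.array([edge_map.index_of(int(i), int(j))
                         for i, j in zip(self.table["region_i"],
                                         self.table["region_j"])], dtype=int)

    def boolean_mask(self, edge_map: EdgeIndexMap) -> np.ndarray:
        out = np.zeros(edge_map.n_edges, dtype=bool)
        out[self.edge_indices(edge_map)] = True
        return out

    def to_csv(self, path: str | Path) -> None:
        """Write the mask (1-based region ids) plus a JSON sidecar."""
        path = Path(path)
        out = self.table.copy()
        out["region_i"] = out["region_i"] + 1
        out["region_j"] = out["region_j"] + 1
        with open(path, "w") as fh:
            fh.write("# region ids are 1-based in this file\n")
            out.to_csv(fh, index=False)
        sidecar = dict(n_regions=self.n_regions, **self.provenance)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1, default=str))

    @classmethod
    def from_csv(cls, path: str | Path) -> "NetworkMask":
        path = Path(path)
        df = pd.read_csv(path, comment="#")
        df["region_i"] = df["region_i"].astype(int) - 1
        df["region_j"] = df["region_j"].astype(int) - 1
        sidecar_path = path.with_suffix(path.suffix + ".json")
        prov: dict = {}
        n_regions = int(df[["region_i", "region_j"]].to_numpy().max()) + 1 \
            if len(df) else 0
        if sidecar_path.exists():
            prov = json.loads(sidecar_path.read_text())
            n_regions = int(prov.pop("n_regions", n_regions))
        return cls(table=df, n_regions=n_regions, provenance=prov)
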