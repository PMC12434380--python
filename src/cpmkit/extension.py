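"""External validation of a fixed edge set in an independent cohort.

The discovery cohort's selected-edge set is applied, unchanged, to every
participant of an extension cohort: per-participant network strengths are
the sum of absolute Fisher-z values over the mask's edges.  Generalization
is the Spearman correlation between those strengths and the follow-up
severity score — plain, and partial with respect to the standard
covariates.  MAE/RMSE are computed from predicted scores through a
strength -> outcome calibration line; by default that line is refit on
the extension cohort (and the result records which model was used).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import AlignedCohort
from .cpm import (NetworkMask, StrengthModel, cohort_strengths,
                  fit_strength_model, partial_spearman)

log = logging.getLogger("cpmkit")


@dataclass
class ExtensionResult:
    """Generalization metrics of a fixed network in a new cohort."""

    rho_plain: float
    p_plain: float
    rho_partial: float
    p_partial: float
    mae: float
    rmse: float
    n: int
    calibration: str      # "supplied" or "refit_on_extension"

    def to_dict(self) -> dict:
        return dict(rho_plain=self.rho_plain, p_plain=self.p_plain,
                    rho_partial=self.rho_partial, p_partial=self.p_partial,
                    mae=self.mae, rmse=self.rmse, n=self.n,
                    calibration=self.calibration)


def apply_network(mask: NetworkMask, cohort: AlignedCohort) -> np.ndarray:
    """Per-participant network strength over the mask's edges."""
    edge_map = cohort.edges.edge_map
    if len(mask) and int(mask.table[["region_i", "region_j"]].to_numpy().max()) \
            >= edge_map.n_regions:
        raise ValueError("mask references regions outside the cohort's "
                         "parcellation")
    if len(mask) == 0:
        return np.zeros(cohort.n)
    bool_mask = mask.boolean_mask(edge_map)
    return cohort_strengths(cohort.edges.X, bool_mask)


def evaluate_extension(strengths: np.ndarray, cohort: AlignedCohort,
                       calibration: StrengthModel | None = None,
                       ) -> ExtensionResult:
    """Correlate strengths with score_y1, plain and covariate-partial.

    MAE/RMSE use predicted scores from ``calibration`` when supplied,
    otherwise from a line refit on this cohort (recorded in the result).
    """
    strengths = np.asarray(strengths, dtype=float)
    n = cohort.n
    if n <= 6:
        raise ValueError("extension cohort too small (need n > 6)")
    y = cohort.outcome
    cov = cohort.covariates()
    if not np.isfinite(cov).all():
        raise ValueError("missing/non-finite covariates in extension cohort")
    rho_plain, p_plain = partial_spearman(strengths, y, None)
    rho_partial, p_partial = partial_spearman(strengths, y, cov)
    if calibration is None:
        model = fit_strength_model(strengths, y)
        cal = "refit_on_extension"
    else:
        model, cal = calibration, "supplied"
    pred = np.asarray(model.predict(strengths))
    err = pred - y
    return ExtensionResult(
        rho_plain=rho_plain, p_plain=p_plain,
        rho_partial=rho_partial, p_partial=p_partial,
        mae=float(np.abs(err).mean()),
        rmse=float(np.sqrt((err ** 2).mean())),
        n=n, calibration=cal)


def specificity_scan(strengths: np.ndarray, outcome_table: pd.DataFrame,
                     covariates: np.ndarray) -> pd.DataFrame:
    """Rank alternative outcomes by |partial Spearman| with the strengths.

    Returns a frame (outcome, rho_partial, p, flag) sorted by descending
    |rho_partial|.  No multiplicity correction — this is a descriptive
    ranking.  Constant outcome columns are flagged, not fatal.
    """
    if outcome_table.shape[1] < 2:
        raise ValueError("need at least 2 outcome columns to rank")
    strengths = np.asarray(strengths, dtype=float)
    rows = []
    for name in outcome_table.columns:
        col = outcome_table[name].to_numpy(float)
        try:
            rho, p = partial_spearman(strengths, col, covariates)
            rows.append(dict(outcome=name, rho_partial=rho, p=p, flag=""))
        except ValueError as exc:
            log.warning("specificity: outcome %r skipped (%s)", name, exc)
            rows.append(dict(outcome=name, rho_partial=np.nan, p=np.nan,
                             flag=str(exc)))
    out = pd.DataFrame(rows)
    return (out.reindex(out["rho_partial"].abs()
                        .sort_values(ascending=False, na_position="last").index)
            .reset_index(drop=True))
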