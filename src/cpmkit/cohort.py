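"""Phenotype records and their alignment with connectome rows.

The outcome is the 1-year follow-up severity score (``score_y1``); the
covariates partialled out everywhere downstream are baseline severity,
sex at birth, age, and mean head motion (framewise displacement), in that
fixed order.  Sex is coded F=1 / M=0 — an arbitrary but fixed convention;
partial correlation is invariant to affine recoding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import CohortEdgeMatrix

log = logging.getLogger("cpmkit")

REQUIRED_COLUMNS = (
    "participant_id", "site_id", "family_id", "sex", "age", "mean_fd",
    "score_base", "score_y1",
)

#: fixed covariate order used for every partial correlation
COVARIATE_COLUMNS = ("score_base", "sex_coded", "age", "mean_fd")


@dataclass
class PhenotypeTable:
    """Validated phenotype records, one row per participant."""

    df: pd.DataFrame
    drop_log: dict[str, int] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.df)

    def covariates(self) -> np.ndarray:
        """(n, 4) matrix in the order (score_base, sex F=1, age, mean_fd)."""
        d = self.df
        return np.column_stack([
            d["score_base"].to_numpy(float),
            (d["sex"].astype(str).str.upper() == "F").to_numpy(float),
            d["age"].to_numpy(float),
            d["mean_fd"].to_numpy(float),
        ])

    @property
    def outcome(self) -> np.ndarray:
        return self.df["score_y1"].to_numpy(float)

    @property
    def sites(self) -> np.ndarray:
        return self.df["site_id"].astype(str).to_numpy()

    @property
    def families(self) -> np.ndarray:
        return self.df["family_id"].astype(str).to_numpy()


def validate_phenotypes(df: pd.DataFrame,
                        max_mean_fd: float | None = None) -> PhenotypeTable:
    """Validate a raw phenotype frame, dropping incomplete records.

    Records missing any required field are dropped with a logged count;
    structural problems (missing columns, duplicate ids) raise.  An
    optional ``max_mean_fd`` filter mirrors upstream motion-based sample
    selection.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing required column(s): {missing}")
    df = df.copy()
    drop_log: dict[str, int] = {}

    n0 = len(df)
    df = df.dropna(subset=list(REQUIRED_COLUMNS))
    if n0 - len(df):
        drop_log["missing_required_field"] = n0 - len(df)

    sex = df["sex"].astype(str).str.upper()
    bad_sex = ~sex.isin(["F", "M"])
    if bad_sex.any():
        drop_log["invalid_sex"] = int(bad_sex.sum())
        df = df[~bad_sex]

    bad = (df["mean_fd"].astype(float) < 0) | (df["age"].astype(float) <= 0)
    if bad.any():
        drop_log["invalid_age_or_motion"] = int(bad.sum())
        df = df[~bad]

    if max_mean_fd is not None:
        high = df["mean_fd"].astype(float) >= max_mean_fd
        if high.any():
            drop_log["mean_fd_filter"] = int(high.sum())
            df = df[~high]

    ids = df["participant_id"].astype(str)
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate participant_id(s): {dupes}")
    df["participant_id"] = ids

    if "group" not in df.columns:
        df["group"] = "none"

    for reason, count in drop_log.items():
        log.info("phenotype validation dropped %d record(s): %s", count, reason)
    return PhenotypeTable(df=df.reset_index(drop=True), drop_log=drop_log)


def load_phenotypes(path: str | Path,
                    max_mean_fd: float | None = None) -> PhenotypeTable:
    """Load and validate a phenotype CSV."""
    return validate_phenotypes(pd.read_csv(path), max_mean_fd=max_mean_fd)


@dataclass
class AlignedCohort:
    """Edge matrix and phenotypes in one-to-one row correspondence."""

    edges: CohortEdgeMatrix
    phenotypes: PhenotypeTable

    def __post_init__(self) -> None:
        ids_x = self.edges.participant_ids
        ids_p = list(self.phenotypes.df["participant_id"])
        if ids_x != ids_p:
            raise ValueError("edge matrix and phenotype rows are not aligned")

    @property
    def n(self) -> int:
        return self.edges.n_participants

    @property
    def participant_ids(self) -> list[str]:
        return self.edges.participant_ids

    def covariates(self) -> np.ndarray:
        return self.phenotypes.covariates()

    @property
    def outcome(self) -> np.ndarray:
        return self.phenotypes.outcome

    @property
    def sites(self) -> np.ndarray:
        return self.phenotypes.sites


def align(edges: CohortEdgeMatrix, phenotypes: PhenotypeTable) -> AlignedCohort:
    """Restrict both sides to the id intersection, identically ordered.

    Order follows the edge matrix.  Raises if the intersection is empty;
    logs counts kept/dropped on each side.
    """
    ids_x = edges.participant_ids
    pheno_ids = set(phenotypes.df["participant_id"])
    keep = [i for i, pid in enumerate(ids_x) if pid in pheno_ids]
    if not keep:
        raise ValueError("no participant ids shared between edges and phenotypes")
    kept_ids = [ids_x[i] for i in keep]
    log.info("align: kept %d of %d edge rows, %d of %d phenotype rows",
             len(keep), len(ids_x), len(keep), phenotypes.n)
    sub_edges = CohortEdgeMatrix(
        X=edges.X[keep], participant_ids=kept_ids, edge_map=edges.edge_map)
    pdf = (phenotypes.df.set_index("participant_id")
           .loc[kept_ids].reset_index())
    return AlignedCohort(edges=sub_edges,
                         phenotypes=PhenotypeTable(df=pdf))
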