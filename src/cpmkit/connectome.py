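"""Functional connectomes and their edge-vector representation.

A connectome is the symmetric matrix of Fisher r-to-z transformed Pearson
correlations between the activity time series of every pair of brain
regions.  Downstream predictive modeling treats the upper triangle of that
matrix as a flat feature vector ("edges"), so this module owns the
bookkeeping that makes the matrix <-> vector mapping unambiguous:

* :class:`Parcellation` — the region table (labels, hemisphere, lobe,
  canonical-network assignment, cortical/subcortical flag),
* :func:`build_connectome` — time series -> Fisher-z matrix,
* :class:`EdgeIndexMap` — the row-major upper-triangle edge ordering,
* :func:`vectorize` / :func:`devectorize` — the bijection itself,
* :class:`CohortEdgeMatrix` — participants x edges, the predictor matrix.

Edge order is row-major over the upper triangle with i < j, 0-based
internally.  Files that expose region indices write 1-based ids and say so
in a sidecar/header.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: correlations are clipped to +/- (1 - CLIP_EPS) before atanh so that
#: perfectly (anti)correlated series still yield finite z-values.
CLIP_EPS = 1e-7

CANONICAL_NETWORKS = (
    "DMN", "FPN", "DAN", "VAN", "SMN", "limbic", "visual", "subcortical",
)

_PARCELLATION_COLUMNS = (
    "region_id", "label", "hemisphere", "lobe", "canonical_network",
    "is_cortical",
)


# ---------------------------------------------------------------------------
# Parcellation
# ---------------------------------------------------------------------------

@dataclass
class Parcellation:
    """Region table for an N-region brain parcellation.

    ``table`` has one row per region with columns ``region_id`` (0-based,
    contiguous), ``label``, ``hemisphere`` ({L, R, none}), ``lobe``,
    ``canonical_network`` and ``is_cortical``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _PARCELLATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"parcellation table missing columns: {missing}")
        ids = np.asarray(self.table["region_id"])
        if not np.array_equal(ids, np.arange(len(ids))):
            raise ValueError("region_ids must be 0..N-1 with no gaps")
        self.table = self.table.reset_index(drop=True)

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def networks(self) -> np.ndarray:
        return np.asarray(self.table["canonical_network"], dtype=object)

    @property
    def n_cortical(self) -> int:
        return int(self.table["is_cortical"].sum())

    @classmethod
    def synthetic(cls, n_regions: int = 352) -> "Parcellation":
        """Deterministic stand-in atlas with the default 352-region layout.

        333 cortical regions cycle through the seven canonical cortical
        networks and four lobes; 19 subcortical regions form the eighth
        class.  For other sizes the cortical/subcortical split scales
        proportionally (19/352).  Labels are synthetic — this is a
        structural stand-in for a real atlas table, not a reproduction of
        one.
        """
        if n_regions < 2:
            raise ValueError("need at least 2 regions")
        n_sub = max(1, round(n_regions * 19 / 352)) if n_regions >= 8 else 0
        n_ctx = n_regions - n_sub
        cortical_nets = [n for n in CANONICAL_NETWORKS if n != "subcortical"]
        lobes = ["frontal", "parietal", "temporal", "occipital"]
        rows = []
        for r in range(n_ctx):
            net = cortical_nets[r % len(cortical_nets)]
            rows.append(dict(
                region_id=r,
                label=f"ctx_{net}_{r:03d}",
                hemisphere="L" if r % 2 == 0 else "R",
                lobe=lobes[(r // 2) % len(lobes)],
                canonical_network=net,
                is_cortical=True,
            ))
        for s in range(n_sub):
            r = n_ctx + s
            rows.append(dict(
                region_id=r,
                label=f"subctx_{s:03d}",
                hemisphere="L" if s % 2 == 0 else "R",
                lobe="subcortical",
                canonical_network="subcortical",
                is_cortical=False,
            ))
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Parcellation":
        """Read a parcellation TSV (region_id 1-based in the file)."""
        df = pd.read_csv(path, sep="\t", comment="#")
        df["region_id"] = df["region_id"].astype(int) - 1
        df["is_cortical"] = df["is_cortical"].astype(bool)
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["region_id"] = out["region_id"] + 1
        with open(path, "w") as fh:
            fh.write("# region_id is 1-based in this file\n")
            out.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Time series -> connectome
# ---------------------------------------------------------------------------

@dataclass
class TimeSeriesMatrix:
    """Regions x timepoints activity matrix for one participant."""

    values: np.ndarray
    participant_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D regions x time matrix")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 timepoints")
        if not np.isfinite(self.values).all():
            raise ValueError("time series contains non-finite values")


@dataclass
class Connectome:
    """Symmetric N x N Fisher-z functional-connectivity matrix."""

    z: np.ndarray
    participant_id: str

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise ValueError("connectome must be square")
        if not np.allclose(self.z, self.z.T, atol=1e-12):
            raise ValueError("connectome must be symmetric")

    @property
    def n_regions(self) -> int:
        return self.z.shape[0]


def build_connectome(ts: TimeSeriesMatrix) -> Connectome:
    """Fisher r-to-z connectome from one participant's time series.

    z[i, j] = atanh(clip(pearson(ts_i, ts_j), +/-(1 - 1e-7))); the diagonal
    is stored as 0 and excluded from all downstream use.

    Raises
    ------
    ValueError
        If fewer than 3 timepoints, any region has zero variance, or the
        input is non-finite.
    """
    x = ts.values
    if x.shape[1] < 3:
        raise ValueError("need at least 3 timepoints to correlate")
    sd = x.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance region(s): {dead.tolist()}")
    r = np.corrcoef(x)
    np.clip(r, -(1 - CLIP_EPS), 1 - CLIP_EPS, out=r)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return Connectome(z=z, participant_id=ts.participant_id)


def load_time_series(path: str | Path, participant_id: str | None = None,
                     header: bool = False, delimiter: str | None = None,
                     ) -> TimeSeriesMatrix:
    """Read a regions-in-rows delimited text file of time series."""
    path = Path(path)
    values = np.loadtxt(path, delimiter=delimiter,
                        skiprows=1 if header else 0, ndmin=2)
    pid = participant_id if participant_id is not None else path.stem
    return TimeSeriesMatrix(values=values, participant_id=pid)


# ---------------------------------------------------------------------------
# Edge indexing
# ---------------------------------------------------------------------------

def n_edges(n_regions: int) -> int:
    """Number of unique region pairs: N(N-1)/2."""
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    return n_regions * (n_regions - 1) // 2


@dataclass
class EdgeIndexMap:
    """Bijection between edge index and unordered region pair (i < j).

    Ordering is row-major over the strict upper triangle:
    (0,1), (0,2), ..., (0,N-1), (1,2), ...
    """

    n_regions: int
    rows: np.ndarray = field(init=False)
    cols: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        iu = np.triu_indices(self.n_regions, k=1)
        self.rows, self.cols = iu[0].astype(np.int64), iu[1].astype(np.int64)

    def __len__(self) -> int:
        return self.rows.size

    @property
    def n_edges(self) -> int:
        return self.rows.size

    def index_of(self, i: int, j: int) -> int:
        """Edge index of the unordered pair (i, j), 0-based regions."""
        if i == j:
            raise ValueError("diagonal pairs have no edge index")
        if i > j:
            i, j = j, i
        n = self.n_regions
        if not (0 <= i < j < n):
            raise ValueError(f"region pair ({i}, {j}) out of range for N={n}")
        # edges before row i: sum_{r<i} (n-1-r); offset within row: j-i-1
        return i * (n - 1) - i * (i - 1) // 2 + (j - i - 1)

    def pairs(self) -> np.ndarray:
        return np.column_stack([self.rows, self.cols])


def vectorize(conn: Connectome, edge_map: EdgeIndexMap) -> np.ndarray:
    """Upper-triangle edge vector (length E) of a connectome."""
    if conn.n_regions != edge_map.n_regions:
        raise ValueError(
            f"connectome has {conn.n_regions} regions, edge map expects "
            f"{edge_map.n_regions}")
    return conn.z[edge_map.rows, edge_map.cols].copy()


def devectorize(edges: np.ndarray, edge_map: EdgeIndexMap,
                participant_id: str = "") -> Connectome:
    """Rebuild the symmetric zero-diagonal matrix from an edge vector."""
    edges = np.asarray(edges, dtype=float)
    if edges.shape != (edge_map.n_edges,):
        raise ValueError(
            f"edge vector has length {edges.size}, expected {edge_map.n_edges}")
    n = edge_map.n_regions
    z = np.zeros((n, n))
    z[edge_map.rows, edge_map.cols] = edges
    z = z + z.T
    return Connectome(z=z, participant_id=participant_id)


# ---------------------------------------------------------------------------
# Cohort edge matrix
# ---------------------------------------------------------------------------

@dataclass
class CohortEdgeMatrix:
    """Participants x edges predictor matrix with its edge-order contract."""

    X: np.ndarray
    participant_ids: list[str]
    edge_map: EdgeIndexMap

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("edge matrix must be 2-D")
        if self.X.shape[0] != len(self.participant_ids):
            raise ValueError("row count does not match participant_ids")
        if self.X.shape[1] != self.edge_map.n_edges:
            raise ValueError("column count does not match edge map")
        self.participant_ids = [str(p) for p in self.participant_ids]

    @property
    def n_participants(self) -> int:
        return self.X.shape[0]

    @classmethod
    def from_connectomes(cls, conns: Sequence[Connectome],
                         edge_map: EdgeIndexMap | None = None,
                         ) -> "CohortEdgeMatrix":
        if not conns:
            raise ValueError("no connectomes given")
        if edge_map is None:
            edge_map = EdgeIndexMap(conns[0].n_regions)
        X = np.stack([vectorize(c, edge_map) for c in conns])
        return cls(X=X, participant_ids=[c.participant_id for c in conns],
                   edge_map=edge_map)

    # -- persistence: .npy payload + JSON sidecar, CSV fallback for small N

    def save(self, prefix: str | Path, fmt: str = "npy") -> None:
        """Write ``<prefix>.npy`` (or ``.csv``) plus ``<prefix>.json``."""
        prefix = Path(prefix)
        sidecar = dict(
            n_regions=self.edge_map.n_regions,
            n_edges=self.edge_map.n_edges,
            participant_ids=self.participant_ids,
            edge_order="row-major upper triangle, i<j, 0-based regions",
            format=fmt,
        )
        prefix.parent.mkdir(parents=True, exist_ok=True)
        if fmt == "npy":
            np.save(prefix.with_suffix(".npy"), self.X)
        elif fmt == "csv":
            np.savetxt(prefix.with_suffix(".csv"), self.X, delimiter=",")
        else:
            raise ValueError(f"unknown format {fmt!r}")
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, prefix: str | Path) -> "CohortEdgeMatrix":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        if meta["format"] == "npy":
            X = np.load(prefix.with_suffix(".npy"))
        else:
            X = np.loadtxt(prefix.with_suffix(".csv"), delimiter=",", ndmin=2)
        return cls(X=X, participant_ids=list(meta["participant_ids"]),
                   edge_map=EdgeIndexMap(int(meta["n_regions"])))
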