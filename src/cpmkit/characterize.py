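"""Canonical-network characterization of a selected edge set.

Selected edges are grouped by the canonical-network membership of their
two endpoint regions (seven cortical systems plus subcortex).  For every
unordered network pair the observed edge count is compared with the
number of possible edges in that pair; the normalized count is the
ratio of proportions

    normalized = (observed / |mask|) / (possible / E),

so values above 1 mark pairs holding more selected edges than their share
of the edge space predicts ("overrepresented").  The raw observed/possible
ratio is emitted alongside.  Region degree (selected edges incident to a
region) and per-participant mean-FC profiles split by the sign of each
edge's outcome association complete the summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import AlignedCohort
from .connectome import Parcellation, n_edges
from .cpm import NetworkMask

#: display threshold used for brain renderings; recorded as metadata only
DEGREE_DISPLAY_THRESHOLD = 8


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _mask_networks(mask: NetworkMask, parcellation: Parcellation,
                   ) -> tuple[np.ndarray, np.ndarray]:
    nets = parcellation.networks
    ri = mask.table["region_i"].to_numpy(int)
    rj = mask.table["region_j"].to_numpy(int)
    if len(mask) and max(ri.max(), rj.max()) >= parcellation.n_regions:
        raise ValueError("mask references regions beyond the parcellation")
    unassigned = sorted({int(r) for r in np.concatenate([ri, rj])
                         if nets[r] in ("none", "", None)})
    if unassigned:
        raise ValueError(
            f"regions without canonical-network assignment: {unassigned}")
    return nets[ri], nets[rj]


def pair_counts(mask: NetworkMask, parcellation: Parcellation) -> pd.DataFrame:
    """Observed/possible/normalized edge counts per canonical-network pair.

    Rows cover every unordered pair of networks present in the
    parcellation, so observed counts total |mask| and possible counts
    total E.
    """
    nets = parcellation.networks
    net_names, net_sizes = np.unique(nets, return_counts=True)
    size = dict(zip(net_names, net_sizes))

    observed: dict[tuple[str, str], int] = {}
    ni, nj = _mask_networks(mask, parcellation)
    for a, b in zip(ni, nj):
        key = _pair_key(a, b)
        observed[key] = observed.get(key, 0) + 1

    E = n_edges(parcellation.n_regions)
    m = len(mask)
    rows = []
    for ia, a in enumerate(net_names):
        for b in net_names[ia:]:
            possible = (size[a] * (size[a] - 1) // 2 if a == b
                        else size[a] * size[b])
            obs = observed.get(_pair_key(a, b), 0)
            normalized = (obs / m) / (possible / E) if m and possible else np.nan
            rows.append(dict(
                network_a=a, network_b=b, observed=obs, possible=possible,
                normalized=normalized,
                raw_ratio=obs / possible if possible else np.nan,
                overrepresented=bool(normalized > 1) if m else False,
            ))
    return pd.DataFrame(rows)


def region_degree(mask: NetworkMask, parcellation: Parcellation,
                  ) -> pd.DataFrame:
    """Selected-edge count incident to each region (handshake: sums to 2|mask|)."""
    deg = np.zeros(parcellation.n_regions, dtype=int)
    for col in ("region_i", "region_j"):
        idx, cnt = np.unique(mask.table[col].to_numpy(int), return_counts=True)
        deg[idx] += cnt
    out = parcellation.table[["region_id", "label", "canonical_network"]].copy()
    out["degree"] = deg
    out.attrs["display_threshold"] = DEGREE_DISPLAY_THRESHOLD
    return out


def fc_profiles(cohort: AlignedCohort, mask: NetworkMask,
                parcellation: Parcellation) -> pd.DataFrame:
    """Per-participant mean FC by (network pair, association sign).

    Long format: participant_id, network_a, network_b, sign, mean_z,
    n_edges.  Cells with no edges are absent, not zero.
    """
    if "sign" not in mask.table.columns:
        raise ValueError("mask has no per-edge association signs")
    ni, nj = _mask_networks(mask, parcellation)
    edge_idx = mask.edge_indices(cohort.edges.edge_map)
    signs = mask.table["sign"].to_numpy(int)

    cells: dict[tuple[str, str, int], list[int]] = {}
    for e, (a, b, s) in enumerate(zip(ni, nj, signs)):
        cells.setdefault((*_pair_key(a, b), int(s)), []).append(edge_idx[e])

    X = cohort.edges.X
    rows = []
    for (a, b, s), cols in sorted(cells.items()):
        means = X[:, cols].mean(axis=1)
        for pid, mz in zip(cohort.participant_ids, means):
            rows.append(dict(participant_id=pid, network_a=a, network_b=b,
                             sign=s, mean_z=float(mz), n_edges=len(cols)))
    return pd.DataFrame(rows)
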