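"""Full-study orchestration: simulate -> discover -> permute -> extend ->
characterize, with a reproducibility manifest in every output directory.

The study config is a YAML mapping with blocks:

    seed: 7
    discovery:            # SimulationConfig fields, or {edges:, phenotypes:}
      preset: abcd_like   # optional; explicit fields override preset values
      n_participants: 800
    cv:                   # CVConfig fields
      n_iterations: 20
      n_permutations: 200
    extension:            # optional; same shape as discovery
      preset: banda_like
    characterize: true    # optional

Any stage failure aborts with the stage name; outputs written so far are
left in place.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .characterize import fc_profiles, pair_counts, region_degree
from .cohort import AlignedCohort, PhenotypeTable, align, load_phenotypes
from .connectome import CohortEdgeMatrix, Parcellation
from .cpm import NetworkMask
from .extension import apply_network, evaluate_extension
from .simulate import SimulationConfig, preset, simulate_cohort
from .validation import CVConfig, consensus_network, permutation_test, run_cv

log = logging.getLogger("cpmkit")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(out_dir: Path, config: dict, seed: int,
                   inputs: list[Path] | None = None) -> None:
    manifest = dict(
        config=config,
        master_seed=seed,
        software_version=__version__,
        input_digests={str(p): _digest(p) for p in (inputs or [])},
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, default=str))


def _build_cohort(block: dict, seed: int) -> AlignedCohort:
    """A cohort from files (edges+phenotypes) or from the simulator."""
    if "edges" in block:
        edges = CohortEdgeMatrix.load(Path(block["edges"]).with_suffix(""))
        pheno = load_phenotypes(block["phenotypes"])
        return align(edges, pheno)
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    cfg = preset(block["preset"], seed=seed) if "preset" in block \
        else SimulationConfig(seed=seed)
    overrides = {k: v for k, v in block.items() if k in fields}
    cfg = dataclasses.replace(cfg, **overrides, seed=seed)
    return simulate_cohort(cfg).cohort


def _save_cv(result, perm, out_dir: Path) -> None:
    payload = dict(
        per_iteration_rho=[None if np.isnan(r) else float(r)
                           for r in result.rhos],
        mean_rho=result.mean_rho,
        n_zero_edge_iterations=result.n_zero_edge,
        alpha=result.alpha, adjusted=result.adjusted, seed=result.seed,
    )
    if perm is not None:
        payload["p_perm"] = perm.p_perm
        pd.DataFrame({"null_mean_rho": perm.null_rhos}).to_csv(
            out_dir / "permutation_null.csv", index=False)
    (out_dir / "cv_result.json").write_text(json.dumps(payload, indent=1))


def run_full_study(config: dict, out_dir: str | Path) -> dict:
    """Execute the configured stages; returns a summary dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    summary: dict = {}
    stage = "setup"
    try:
        stage = "discovery-cohort"
        discovery = _build_cohort(config["discovery"], seed)

        stage = "cross-validation"
        cv_cfg = CVConfig(seed=seed, **config.get("cv", {}))
        t0 = time.time()
        cv = run_cv(discovery, cv_cfg)
        log.info("stage %s: %.1fs, mean_rho=%.4f (%d zero-edge iterations)",
                 stage, time.time() - t0, cv.mean_rho, cv.n_zero_edge)
        summary["mean_rho"] = cv.mean_rho

        perm = None
        if cv_cfg.n_permutations:
            stage = "permutation-test"
            t0 = time.time()
            perm = permutation_test(discovery, cv_cfg, cv)
            log.info("stage %s: %.1fs, p_perm=%.4f", stage,
                     time.time() - t0, perm.p_perm)
            summary["p_perm"] = perm.p_perm
        _save_cv(cv, perm, out_dir)

        stage = "consensus-network"
        network = consensus_network(discovery, alpha=cv_cfg.alpha,
                                    adjust=cv_cfg.adjust)
        network.to_csv(out_dir / "network_mask.csv")
        summary["n_network_edges"] = len(network)

        if "extension" in config:
            stage = "extension-cohort"
            ext_cohort = _build_cohort(config["extension"], seed + 1)
            stage = "extension-evaluation"
            strengths = apply_network(network, ext_cohort)
            ext = evaluate_extension(strengths, ext_cohort)
            (out_dir / "extension_result.json").write_text(
                json.dumps(ext.to_dict(), indent=1))
            summary["extension_rho_partial"] = ext.rho_partial

        if config.get("characterize", True) and len(network):
            stage = "characterization"
            parc = Parcellation.synthetic(network.n_regions)
            pair_counts(network, parc).to_csv(
                out_dir / "pair_counts.csv", index=False)
            region_degree(network, parc).to_csv(
                out_dir / "region_degree.csv", index=False)
            fc_profiles(discovery, network, parc).to_csv(
                out_dir / "fc_profiles.csv", index=False)

        stage = "manifest"
        write_manifest(out_dir, config, seed)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed in stage '{stage}': {exc}") from exc
    return summary


def load_study_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
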