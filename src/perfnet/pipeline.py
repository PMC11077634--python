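"""One-command reproducible runs of the full network comparison design.

``run_full_comparison`` ties the stages together: load (or simulate) the
per-group regional CBF tables, build each group's correlation network,
compute global metrics over the sparsity grid and nodal betweenness at the
nodal sparsity, detect hubs, then run every pairwise group comparison
(global-metric permutation tests across the grid, nodal BC permutation test,
Fisher-z edge comparison, regional t-tests).  The effective configuration,
seeds and a config hash are archived inside the JSON report so any run can
be reproduced bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as gm
from . import stats as st
from .network import SparsityGrid, normalize_regional_cbf, pearson_network, threshold_by_sparsity
from .parcellate import RegionalCBFMatrix, read_matrix_tsv, write_matrix_tsv
from .synthetic import make_default_models, sample_regional_cbf

log = logging.getLogger("perfnet")

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """All stage parameters of a full comparison run."""

    sparsity_grid: list[float] = field(default_factory=lambda: SparsityGrid().values)
    normalize: str = "global-mean"
    use_absolute: bool = False
    edge_family: str = "union"
    edge_sparsity: float = 0.83
    nodal_sparsity: float = 0.83
    n_perm: int = 1000
    n_refs: int = 100
    alpha_regions: float = 0.05
    alpha_edges: float = 0.001
    alpha_nodal: float = 0.05
    alpha_global: float = 0.05
    seed: int = 0
    metrics: list[str] = field(default_factory=lambda: list(st.GLOBAL_METRICS))
    # inputs: either a matrix TSV or simulation settings
    matrix_tsv: str | None = None
    simulate_regions: int = 246
    simulate_seed: int = 1
    out_dir: str | None = None

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _load_inputs(config: RunConfig) -> dict[str, RegionalCBFMatrix]:
    if config.matrix_tsv is not None:
        return read_matrix_tsv(config.matrix_tsv)
    truth = make_default_models(R=config.simulate_regions, seed=config.simulate_seed)
    return {
        name: sample_regional_cbf(model, seed=config.simulate_seed + 1000 * (k + 1))
        for k, (name, model) in enumerate(truth.models.items())
    }


def run_full_comparison(
    config: RunConfig,
    matrices: dict[str, RegionalCBFMatrix] | None = None,
) -> dict:
    """Execute the whole comparison design; returns (and optionally writes) the report."""
    t0 = time.time()
    if matrices is None:
        matrices = _load_inputs(config)
    groups = list(matrices.keys())
    grid = SparsityGrid(list(config.sparsity_grid))

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": asdict(config),
        "config_hash": config.hash(),
        "groups": {g: {"n_subjects": matrices[g].n_subjects} for g in groups},
        "global_metrics": [],
        "nodal_bc": {},
        "hubs": {},
        "hub_bc_lookup": {},
        "comparisons": {},
        "timings": {},
    }

    networks = {}
    nodal = {}
    for stage_group in groups:
        try:
            norm = normalize_regional_cbf(matrices[stage_group], mode=config.normalize)
            networks[stage_group] = pearson_network(norm)
        except Exception as err:
            raise RuntimeError(f"network construction failed for group {stage_group}: {err}") from err

    t1 = time.time()
    report["timings"]["networks_s"] = round(t1 - t0, 3)

    for gi, grp in enumerate(groups):
        for si, s in enumerate(grid):
            graph = threshold_by_sparsity(networks[grp], s, use_absolute=config.use_absolute)
            rec = gm.compute_global_metrics(
                graph, n_refs=config.n_refs, seed=config.seed + 101 * gi + si
            )
            report["global_metrics"].append(
                {
                    "group": grp,
                    "sparsity": s,
                    "global_efficiency": rec.global_efficiency,
                    "clustering_coefficient": rec.clustering_coefficient,
                    "characteristic_path_length": rec.characteristic_path_length,
                    "small_world_sigma": rec.small_world_sigma,
                }
            )
        graph = threshold_by_sparsity(networks[grp], config.nodal_sparsity, use_absolute=config.use_absolute)
        nodal[grp] = gm.betweenness_centrality(graph)
        report["nodal_bc"][grp] = {str(r): v for r, v in zip(nodal[grp].region_ids, nodal[grp].bc.tolist())}
        hubs = gm.detect_hubs(nodal[grp])
        report["hubs"][grp] = {"region_ids": hubs.region_ids, "threshold": hubs.threshold}
        log.info("group %s: %d hubs at sparsity %.2f", grp, len(hubs.region_ids), config.nodal_sparsity)

    # BC of the first (reference) group's hubs looked up in every group
    ref_hubs = gm.detect_hubs(nodal[groups[0]])
    report["hub_bc_lookup"] = {
        "reference_group": groups[0],
        "values": gm.hub_bc_across_groups(ref_hubs, nodal),
    }
    t2 = time.time()
    report["timings"]["metrics_s"] = round(t2 - t1, 3)

    for a, b in combinations(groups, 2):
        key = f"{a}_vs_{b}"
        comp: dict = {}
        pair_seed = config.seed + zlib.crc32(key.encode()) % 100000
        for metric in config.metrics:
            results = st.permutation_test_global(
                matrices[a], matrices[b], metric=metric, grid=grid,
                n_perm=config.n_perm, seed=pair_seed, normalize=config.normalize,
            )
            comp[metric] = [
                {"sparsity": r.sparsity, "observed_difference": r.observed_difference, "p_value": r.p_value}
                for r in results
            ]
        nod = st.permutation_test_nodal(
            matrices[a], matrices[b], sparsity=config.nodal_sparsity,
            n_perm=config.n_perm, seed=pair_seed + 1, normalize=config.normalize,
        )
        comp["nodal_bc"] = {
            "sparsity": nod.sparsity,
            "significant_regions": [
                r for r, p in zip(nod.region_ids, nod.p_values) if p < config.alpha_nodal
            ],
            "p_values": {str(r): float(p) for r, p in zip(nod.region_ids, nod.p_values)},
        }
        edge = st.edge_z_comparison(
            networks[a], networks[b], sparsity=config.edge_sparsity,
            alpha=config.alpha_edges, family=config.edge_family,
        )
        comp["edges"] = {
            "n_tested": len(edge.edges),
            "surviving": [list(e) for e in edge.surviving],
            "direction": {f"{i}-{j}": d for (i, j), d in edge.direction.items()},
            "alpha": edge.alpha,
        }
        reg = st.regional_ttests(matrices[a], matrices[b], alpha=config.alpha_regions)
        comp["regional_ttests"] = {
            "significant_regions": [r for r, f in zip(reg.region_ids, reg.significant) if f],
            "alpha": reg.alpha,
        }
        comp["seed"] = pair_seed
        report["comparisons"][key] = comp
        log.info("comparison %s done", key)

    report["timings"]["comparisons_s"] = round(time.time() - t2, 3)
    report["timings"]["total_s"] = round(time.time() - t0, 3)

    if config.out_dir is not None:
        _write_bundle(report, matrices, networks, config)
    return report


def _write_bundle(report: dict, matrices, networks, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=1))
    config.to_yaml(out / "config.yaml")
    write_matrix_tsv(matrices, out / "regional_cbf.tsv")
    for grp, net in networks.items():
        df = pd.DataFrame(net.r, index=net.region_ids, columns=net.region_ids)
        df.to_csv(out / f"network_{grp}.tsv", sep="\t")
    pd.DataFrame(report["global_metrics"]).to_csv(out / "global_metrics.tsv", sep="\t", index=False)
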