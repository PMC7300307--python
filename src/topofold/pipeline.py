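"""End-to-end analysis pipeline: persistence -> TFV -> reduction -> flow.

``run_pipeline`` sequences the three analysis stages over a trajectory
and writes every intermediate artifact (persistence CSV, TFV matrix,
factor models, rank-scan curve, flow field, fixed-point summary) plus a
JSON log recording versions, seeds and the decisions taken, so a run is
reproducible and auditable from its output directory alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .decompose import (basis_report, nmf_decompose, pca_decompose,
                        rank_scan)
from .features import TopologicalFeaturizer, edge_labels
from .flow import ReducedTrajectory, fixed_point_summary, flow_field

logger = logging.getLogger("topofold")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_path: str
    output_dir: str
    input_format: str | None = None       # pdb | xyz | None (infer)
    selection: str = "CA"
    weight_mode: str = "death"            # death | birth | lifetime
    rank: int | str = "auto"              # int or "auto"
    rank_scan_max: int = 10
    rank_scan_subsample: int = 1000
    seed: int = 0
    flow_cell: float = 1.5                # Angstrom
    flow_min_count: int = 10
    frame_interval: float = 10.0          # ps, used if input lacks times

    def validate(self) -> None:
        if self.weight_mode not in ("death", "birth", "lifetime"):
            raise ValueError(f"invalid weight mode {self.weight_mode!r}")
        if not (self.rank == "auto"
                or (isinstance(self.rank, int) and self.rank >= 1)):
            raise ValueError(f"invalid rank {self.rank!r}")
        if not Path(self.input_path).exists():
            raise FileNotFoundError(self.input_path)


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages and return the artifact directory.

    Stage order: read frames, per-frame persistence + volume-optimal
    cycles, TFV matrix, rank selection (if "auto"), NMF and PCA of the
    TFVs, reduced-space flow field and fixed-point summary.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"weight_mode": config.weight_mode, "seed": config.seed,
            "selection": config.selection}
    log: dict = {"config": asdict(config), "stages": {}}

    frames = tio.read_trajectory(config.input_path, config.input_format,
                                 selection=config.selection)
    n = frames[0].n
    times = np.arange(len(frames)) * config.frame_interval
    log["stages"]["read"] = {"n_frames": len(frames), "n_atoms": n}

    feat = TopologicalFeaturizer(mode=config.weight_mode)
    gens_per_frame = [feat.frame_generators(c) for c in frames]
    tio.write_persistence_csv(out / "persistence.csv", gens_per_frame, meta)
    from .features import build_tfv
    X = np.array([build_tfv(g, n, mode=config.weight_mode).values
                  for g in gens_per_frame])
    tio.write_feature_csv(out / "tfv.csv", X, n, times, meta)
    tio.write_matrix_npz(out / "tfv.npz", tfv=X, times=times)
    log["stages"]["tfv"] = {"shape": list(X.shape)}

    V = X.T
    if config.rank == "auto":
        scan = rank_scan(V, L_max=config.rank_scan_max,
                         subsample=config.rank_scan_subsample,
                         seed=config.seed)
        rank = scan.selected_rank
        tio._write_csv(out / "rank_scan.csv",
                       pd.DataFrame({"rank": scan.ranks, "rss": scan.rss}),
                       meta | {"selected_rank": rank})
        log["stages"]["rank_scan"] = {"selected_rank": rank,
                                      "rss": scan.rss.tolist()}
        logger.info("rank scan selected L = %d", rank)
    else:
        rank = int(config.rank)

    model = nmf_decompose(V, rank)
    labels = edge_labels(n)
    tio._write_csv(out / "nmf_W.csv",
                   pd.DataFrame(model.W, columns=[f"w{k+1}" for k in
                                                  range(rank)])
                   .assign(edge=labels)[["edge"] + [f"w{k+1}" for k in
                                                    range(rank)]],
                   meta | {"rank": rank, "rss": model.rss})
    tio._write_csv(out / "nmf_H.csv",
                   pd.DataFrame(model.H.T,
                                columns=[f"h{k+1}" for k in range(rank)])
                   .assign(time_ps=times)[["time_ps"] + [f"h{k+1}" for k in
                                                         range(rank)]],
                   meta | {"rank": rank})
    report = basis_report(model, n)
    with open(out / "basis_report.json", "w") as fh:
        json.dump([[{"edge": f"{i}-{j}", "weight": w}
                    for (i, j), w in entries] for entries in report], fh,
                  indent=1)
    log["stages"]["nmf"] = {"rank": rank, "rss": model.rss}

    pca = pca_decompose(X, n_components=min(3, min(X.shape)))
    tio._write_csv(out / "pca_scores.csv",
                   pd.DataFrame(pca.scores,
                                columns=[f"pc{k+1}" for k in
                                         range(pca.scores.shape[1])])
                   .assign(time_ps=times),
                   meta | {"explained_variance_ratio":
                           pca.explained_variance_ratio.tolist()})
    log["stages"]["pca"] = {
        "explained_variance_ratio": pca.explained_variance_ratio.tolist()}

    if rank >= 2:
        traj = ReducedTrajectory(times=times, h=model.H.T)
        fld = flow_field(traj, cell=config.flow_cell,
                         min_count=config.flow_min_count)
        rows = [{"cell_x": ix, "cell_y": iy,
                 "mean_dx": fld.mean[ix, iy, 0],
                 "mean_dy": fld.mean[ix, iy, 1],
                 "count": int(fld.counts[ix, iy])}
                for ix in range(fld.counts.shape[0])
                for iy in range(fld.counts.shape[1])
                if fld.counts[ix, iy] > 0]
        tio._write_csv(out / "flow.csv", pd.DataFrame(rows),
                       meta | {"cell_A": config.flow_cell,
                               "min_count": config.flow_min_count})
        fps = fixed_point_summary(fld)
        tio._write_csv(out / "fixed_points.csv",
                       pd.DataFrame([{"h1_A": loc[0], "h2_A": loc[1],
                                      "type": kind} for loc, kind in fps]),
                       meta)
        log["stages"]["flow"] = {"n_fixed_points": len(fps)}

    import sklearn
    import scipy
    log["versions"] = {"numpy": np.__version__, "scipy": scipy.__version__,
                       "sklearn": sklearn.__version__}
    log["convention"] = tio.HEADER_CONVENTION
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1)
    return out
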