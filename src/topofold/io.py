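"""Trajectory/structure readers and result writers.

Structures come in as multi-model PDB (read through biotite, with
occupancy-based alternate-location resolution) or multi-frame XYZ (a
simple fixed format parsed here).  By default the C-alpha trace is
selected by atom name.  Result writers emit CSV with headers recording
the edge-index convention, the weight mode and the units, plus a
compact NumPy ``.npz`` container for feature matrices.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cloud import PointCloud
from .features import edge_labels

logger = logging.getLogger("topofold")

HEADER_CONVENTION = ("edge_index: slot(i,j) = i*n - i(i+1)/2 + (j-i-1), "
                     "0-based, i<j; units: Angstrom, ps")


# ---------------------------------------------------------------------------
# readers

def read_xyz(path) -> list[PointCloud]:
    """Read a multi-frame XYZ file (all frames must share atom count)."""
    frames: list[PointCloud] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"{path}: expected atom count at line {i + 1}"
                             ) from exc
        block = lines[i + 2: i + 2 + count]
        if len(block) < count:
            raise ValueError(f"{path}: truncated frame at line {i + 1}")
        names, coords = [], []
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise ValueError(
                    f"{path}: unparseable atom record at line {i + 3 + j}")
            names.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        frames.append(PointCloud(np.array(coords), labels=tuple(names)))
        i += 2 + count
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return frames


def read_pdb(path, selection: str = "CA") -> list[PointCloud]:
    """Read a (multi-model) PDB, selecting atoms by name.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties: the first); the event is logged.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    pdbfile = pdb.PDBFile.read(str(path))
    stack = pdbfile.get_structure(altloc="occupancy")
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    first_all = pdbfile.get_structure(model=1, altloc="all")
    if first_all.array_length() > stack[0].array_length():
        logger.info("%s: alternate locations resolved to the highest-"
                    "occupancy conformer", path)
    frames = []
    for model in stack:
        sel = model[model.atom_name == selection]
        if sel.array_length() == 0:
            raise ValueError(f"{path}: no atoms named {selection!r}")
        labels = tuple(f"{rn}{ri}" for rn, ri in
                       zip(sel.res_name, sel.res_id))
        frames.append(PointCloud(sel.coord.astype(float), labels=labels))
    return frames


def read_trajectory(path, fmt: str | None = None,
                    selection: str = "CA") -> list[PointCloud]:
    """Read a trajectory in PDB or XYZ format (inferred from the
    extension when ``fmt`` is None)."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "pdb":
        return read_pdb(path, selection=selection)
    if fmt == "xyz":
        return read_xyz(path)
    raise ValueError(f"unsupported trajectory format {fmt!r}")


# ---------------------------------------------------------------------------
# writers

def write_xyz(path, frames: list[PointCloud], comment: str = "") -> None:
    with open(path, "w") as fh:
        for k, cloud in enumerate(frames):
            names = cloud.labels or tuple("C" for _ in range(cloud.n))
            fh.write(f"{cloud.n}\n{comment} frame {k}\n")
            for name, (x, y, z) in zip(names, cloud.coords):
                fh.write(f"{name.split()[0]} {x:.6f} {y:.6f} {z:.6f}\n")


def write_pdb(path, frames: list[PointCloud]) -> None:
    """Write frames as a multi-model PDB of C-alpha pseudo-residues."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = frames[0].n
    arrays = []
    for cloud in frames:
        arr = struc.AtomArray(n)
        arr.coord = cloud.coords.astype(np.float32)
        arr.atom_name = np.array(["CA"] * n)
        arr.res_name = np.array(["GLY"] * n)
        arr.res_id = np.arange(1, n + 1)
        arr.chain_id = np.array(["A"] * n)
        arr.element = np.array(["C"] * n)
        arrays.append(arr)
    pdbfile = pdb.PDBFile()
    pdbfile.set_structure(struc.stack(arrays))
    pdbfile.write(str(path))


def _write_csv(path, df: pd.DataFrame, meta: dict | None = None) -> None:
    """CSV with '#' header lines naming conventions and units."""
    with open(path, "w") as fh:
        fh.write(f"# {HEADER_CONVENTION}\n")
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_persistence_csv(path, per_frame_generators, meta=None) -> None:
    """Rows: (frame, birth_A, death_A, birth_edge_i, birth_edge_j,
    cycle_edges) with cycle edges ';'-joined as 'i-j', 0-based."""
    rows = []
    for frame, gens in enumerate(per_frame_generators):
        for g in gens:
            p = g.pair
            rows.append({
                "frame": frame,
                "birth_A": p.birth,
                "death_A": p.death,
                "birth_edge_i": p.birth_edge[0],
                "birth_edge_j": p.birth_edge[1],
                "cycle_edges": ";".join(f"{i}-{j}"
                                        for i, j in sorted(g.cycle)),
            })
    _write_csv(path, pd.DataFrame(rows), meta)


def write_feature_csv(path, X, n_atoms: int, times=None, meta=None) -> None:
    """Feature matrix as CSV: rows = edges labeled 'i-j', columns =
    frame times in ps."""
    X = np.asarray(X)
    cols = [f"{t:g}" for t in (times if times is not None
                               else np.arange(X.shape[0]) * 10.0)]
    df = pd.DataFrame(X.T, columns=cols)
    df.insert(0, "edge", edge_labels(n_atoms))
    _write_csv(path, df, meta)


def write_matrix_npz(path, **arrays) -> None:
    """Compact binary matrix container (NumPy .npz, documented in the
    README); stores the edge-index convention alongside the data."""
    np.savez_compressed(path, convention=np.array(HEADER_CONVENTION),
                        **arrays)


def write_labels_csv(path, labels, meta=None) -> None:
    df = pd.DataFrame({"frame": np.arange(len(labels)), "state": labels})
    _write_csv(path, df, meta)
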