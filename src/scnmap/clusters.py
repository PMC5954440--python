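"""Cluster extraction from thresholded statistic maps and report writing."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GeometryError
from .glm import connectivity_structure

__all__ = [
    "ClusterRecord",
    "extract_clusters",
    "clusters_to_frame",
    "frame_to_clusters",
    "write_report",
]

log = logging.getLogger("scnmap")

CLUSTER_COLUMNS = ["seed", "contrast", "x_mm", "y_mm", "z_mm", "k_voxels", "max_t"]


@dataclass
class ClusterRecord:
    """One suprathreshold cluster: peak location, extent and peak statistic.

    ``peak_world_mm`` is the world coordinate of the voxel attaining the
    maximum t within the cluster (ties broken by smallest (x, y, z)
    lexicographically).
    """

    seed_name: str
    contrast: str
    peak_world_mm: tuple[float, float, float]
    size: int
    max_t: float


def extract_clusters(
    thresholded_map: np.ndarray,
    affine: np.ndarray,
    connectivity: int = 18,
    seed_name: str = "",
    contrast: str = "",
) -> list[ClusterRecord]:
    """Connected components of nonzero voxels, one record per component.

    Records are sorted by size descending, ties broken by max_t descending.
    Default 18-connectivity (faces + edges), the dominant neuroimaging
    convention.
    """
    tmap = np.asarray(thresholded_map, dtype=np.float64)
    affine = np.asarray(affine, dtype=np.float64)
    if tmap.ndim != 3:
        raise GeometryError("thresholded map must be 3D")
    if affine.shape != (4, 4):
        raise GeometryError("affine must be 4x4")
    structure = connectivity_structure(connectivity)
    nonzero = tmap != 0
    if not nonzero.any():
        return []
    labels, n_lab = ndimage.label(nonzero, structure=structure)
    records: list[ClusterRecord] = []
    for lab in range(1, n_lab + 1):
        member = labels == lab
        size = int(member.sum())
        vals = np.where(member, tmap, -np.inf)
        max_t = float(vals.max())
        peak_idx = np.argwhere(member & (tmap == max_t))
        homog = np.column_stack([peak_idx, np.ones(len(peak_idx))])
        worlds = homog @ affine[:3].T
        order = np.lexsort((worlds[:, 2], worlds[:, 1], worlds[:, 0]))
        peak = tuple(float(v) for v in worlds[order[0]])
        records.append(
            ClusterRecord(
                seed_name=seed_name,
                contrast=contrast,
                peak_world_mm=peak,
                size=size,
                max_t=max_t,
            )
        )
    records.sort(key=lambda r: (-r.size, -r.max_t))
    return records


def clusters_to_frame(records: list[ClusterRecord], round_mm: bool = False) -> pd.DataFrame:
    """Tabulate cluster records; ``round_mm`` rounds peak coordinates to
    integer millimetres (the convention of printed coordinate tables)."""
    rows = []
    for r in records:
        x, y, z = r.peak_world_mm
        if round_mm:
            x, y, z = (float(round(v)) for v in (x, y, z))
        rows.append(
            {
                "seed": r.seed_name,
                "contrast": r.contrast,
                "x_mm": x,
                "y_mm": y,
                "z_mm": z,
                "k_voxels": r.size,
                "max_t": r.max_t,
            }
        )
    return pd.DataFrame(rows, columns=CLUSTER_COLUMNS)


def frame_to_clusters(frame: pd.DataFrame) -> list[ClusterRecord]:
    return [
        ClusterRecord(
            seed_name=str(row["seed"]),
            contrast=str(row["contrast"]),
            peak_world_mm=(float(row["x_mm"]), float(row["y_mm"]), float(row["z_mm"])),
            size=int(row["k_voxels"]),
            max_t=float(row["max_t"]),
        )
        for _, row in frame.iterrows()
    ]


def write_report(
    outdir,
    clusters: list[ClusterRecord],
    config: dict,
    rng_seeds: dict[str, int],
    version: str | None = None,
    input_checksums: dict[str, str] | None = None,
) -> dict:
    """Write the run report: clusters.tsv, manifest.json, run.log.

    Identical inputs and config produce byte-identical outputs apart from
    the timestamp recorded in the log.  Returns the manifest dict.
    """
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = clusters_to_frame(clusters)
    frame.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    manifest = {
        "software": "scnmap",
        "version": version or __version__,
        "config": config,
        "rng_seeds": dict(rng_seeds),
        "input_checksums": dict(input_checksums or {}),
        "n_clusters": len(clusters),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    import datetime

    with open(outdir / "run.log", "a") as fh:
        fh.write(
            f"{datetime.datetime.now().isoformat()} wrote {len(clusters)} "
            f"cluster record(s) to {outdir / 'clusters.tsv'}\n"
        )
    return manifest
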