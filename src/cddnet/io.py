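"""Data ingestion, ROI extraction, and the end-to-end pipeline.

Multivariate series travel as plain CSV/TSV tables: one header row of
region labels, one body row per scan.  Optionally, a preprocessed 4-D
NIfTI volume plus a table of MNI coordinates can be reduced to such a
series by cube-averaged ROI extraction (default 5x5x5 voxels per region).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cdd import estimate_all_pairs
from .network import build_network, degree_table, write_edge_list, write_graphml

__all__ = [
    "read_series",
    "write_series",
    "default_roi_table",
    "extract_roi",
    "drop_initial_scans",
    "PipelineConfig",
    "run_pipeline",
    "load_config",
]

logger = logging.getLogger(__name__)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_series(path) -> pd.DataFrame:
    """Read a labeled multivariate series from CSV/TSV.

    Column order is preserved.  NaN or non-numeric cells raise with the
    offending row and column named; an empty body raises.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path))
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table ({exc})") from exc
    if df.shape[0] == 0:
        raise ValueError(f"{path}: header-only file, no data rows")
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no columns")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric or missing value at row {row}, column {col!r}"
            )
        df[col] = numeric.astype(float)
    return df


def write_series(df: pd.DataFrame, path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# ROI extraction

#: seven bilateral cortical regions (Brodmann-area landmarks in MNI mm)
_DEFAULT_ROIS = [
    ("A", "BA04", "M1", "Primary Motor Cortex", (-36, -17, 44), (38, -18, 45)),
    ("B", "BA08", "FEF", "Frontal Eye Fields", (-23, 24, 44), (22, 26, 45)),
    ("C", "BA10", "aPFC", "Anterior Prefrontal Cortex", (-23, 55, 4), (23, 55, 7)),
    ("D", "BA18", "V2", "Visual Association Area", (-19, -92, 2), (29, -92, 2)),
    ("E", "BA20", "ITG", "Inferior Temporal Gyrus", (-47, -14, -34), (48, -17, -31)),
    ("F", "BA23", "vPCC", "Ventral Posterior Cingulate Cortex", (-10, -45, 24), (9, -45, 24)),
    ("G", "BA38", "TP", "Temporopolar Area", (-43, 13, -30), (40, 11, -30)),
]


def default_roi_table() -> pd.DataFrame:
    """The default fourteen-region ROI table (7 bilateral cortical landmarks)."""
    rows = []
    for node, ba, name, desc, left, right in _DEFAULT_ROIS:
        for side, (x, y, z) in (("L", left), ("R", right)):
            rows.append(
                {
                    "label": f"{side}.{node} {name}",
                    "node": node,
                    "side": side,
                    "ba": ba,
                    "name": name,
                    "description": desc,
                    "x": float(x),
                    "y": float(y),
                    "z": float(z),
                }
            )
    return pd.DataFrame(rows)


def extract_roi(volume, roi_table: pd.DataFrame | None = None, cube: int = 5) -> pd.DataFrame:
    """Average ``cube``-sized voxel neighborhoods around each ROI center.

    ``volume`` is a 4-D NIfTI path or image whose affine maps voxel indices
    to world (MNI) millimeters; each ROI center is mapped to the nearest
    voxel (no interpolation).  Raises if any cube leaves the field of view
    or if two cubes overlap.
    """
    import nibabel as nib

    if cube < 1 or cube % 2 == 0:
        raise ValueError("cube edge length must be a positive odd integer")
    if roi_table is None:
        roi_table = default_roi_table()
    img = nib.load(str(volume)) if not hasattr(volume, "affine") else volume
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError("expected a 4-D volume (x, y, z, time)")
    inv = np.linalg.inv(img.affine)
    half = cube // 2

    centers = {}
    for row in roi_table.itertuples(index=False):
        world = np.array([row.x, row.y, row.z, 1.0])
        idx = np.round(inv @ world)[:3].astype(int)
        lo = idx - half
        hi = idx + half
        if np.any(lo < 0) or np.any(hi >= data.shape[:3]):
            raise ValueError(f"ROI {row.label!r}: {cube}^3 cube falls outside the volume")
        centers[row.label] = idx

    labels = list(centers)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            if np.all(np.abs(centers[a] - centers[b]) <= cube - 1):
                raise ValueError(f"ROI cubes overlap: {a!r} and {b!r}")

    out = {}
    for label, idx in centers.items():
        block = data[
            idx[0] - half : idx[0] + half + 1,
            idx[1] - half : idx[1] + half + 1,
            idx[2] - half : idx[2] + half + 1,
            :,
        ]
        out[label] = block.mean(axis=(0, 1, 2))
    return pd.DataFrame(out)


def drop_initial_scans(series: pd.DataFrame, n_drop: int) -> pd.DataFrame:
    """Remove the first ``n_drop`` rows (pre-movie rest / onset transient)."""
    if n_drop < 0:
        raise ValueError("n_drop must be nonnegative")
    if n_drop >= len(series):
        raise ValueError(f"cannot drop {n_drop} of {len(series)} scans")
    return series.iloc[n_drop:].reset_index(drop=True)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end run.

    Defaults mirror the standard protocol: 100 bootstrap replicates, local
    FDR threshold 0.2, 5x5x5 ROI cubes, 5 initial scans dropped when the
    input comes from imaging.
    """

    input_csv: str
    out_dir: str
    n_drop: int = 0
    serial: str = "none"
    n_boot: int = 100
    fdr_threshold: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.input_csv).exists():
            raise FileNotFoundError(f"input file not found: {self.input_csv}")
        if self.serial not in ("none", "ar1"):
            raise ValueError("serial must be 'none' or 'ar1'")
        if not (0.0 < self.fdr_threshold < 1.0):
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if self.n_boot < 2:
            raise ValueError("n_boot must be >= 2")


def load_config(path, **overrides) -> PipelineConfig:
    """Parse a flat ``key = value`` config file, with keyword overrides."""
    values: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        values[key] = val
    values.update({k: v for k, v in overrides.items() if v is not None})
    fields = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}
    unknown = set(values) - set(fields)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("n_drop", "n_boot", "seed"):
        if key in values:
            values[key] = int(values[key])
    if "fdr_threshold" in values:
        values["fdr_threshold"] = float(values["fdr_threshold"])
    return PipelineConfig(**values)


def run_pipeline(config: PipelineConfig) -> dict:
    """Read -> estimate all pairs -> prune network -> degrees -> manifest.

    Writes ``cdd.csv``, ``edges.tsv``, ``net.graphml``, ``degrees.csv`` and
    ``manifest.json`` into ``config.out_dir`` and returns their paths.  Any
    stage failure removes files written so far and re-raises with the stage
    named.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "read"
    try:
        series = read_series(config.input_csv)
        if config.n_drop:
            series = drop_initial_scans(series, config.n_drop)

        stage = "estimate"
        pairs = estimate_all_pairs(
            series, serial=config.serial, n_boot=config.n_boot, seed=config.seed
        )
        cdd_path = out_dir / "cdd.csv"
        pairs.to_csv(cdd_path, index=False, float_format="%.10g")
        written.append(cdd_path)

        stage = "network"
        labels = list(series.columns)
        mat = pd.DataFrame(np.nan, index=labels, columns=labels)
        for row in pairs.itertuples(index=False):
            mat.loc[row.region_u, row.region_v] = row.rho2_uv
            mat.loc[row.region_v, row.region_u] = row.rho2_vu
        net = build_network(mat, pair_results=pairs, fdr_threshold=config.fdr_threshold)
        edges_path = out_dir / "edges.tsv"
        write_edge_list(net, edges_path)
        written.append(edges_path)
        graphml_path = out_dir / "net.graphml"
        write_graphml(net, graphml_path)
        written.append(graphml_path)

        stage = "degrees"
        degrees_path = out_dir / "degrees.csv"
        degree_table(net).to_csv(degrees_path, index=False)
        written.append(degrees_path)

        stage = "manifest"
        manifest = {
            "package": "cddnet",
            "version": __version__,
            "seed": config.seed,
            "input": str(config.input_csv),
            "n_scans_used": int(len(series)),
            "n_regions": len(labels),
            "n_pairs": len(pairs),
            "parameters": {
                "serial": config.serial,
                "n_boot": config.n_boot,
                "fdr_threshold": config.fdr_threshold,
                "n_drop": config.n_drop,
            },
            "fdr_fit": {"eta": net.fdr_fit.eta, "sigma": net.fdr_fit.sigma},
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
        written.append(manifest_path)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return {p.stem: p for p in written}
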