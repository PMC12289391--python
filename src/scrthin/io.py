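"""Dataset and result serialization: headered CSV, JSON, run manifests.

Tabular data is plain UTF-8 CSV with '.' decimal; encounter data uses a
long format (individual_id, detector_id, count) with K and geometry carried
in a JSON sidecar (``truth.json`` inside a replicate bundle).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from scrthin.geometry import DetectorGrid, build_detector_grid
from scrthin.simulate import ColonySet, EncounterData, Population, ScenarioConfig


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json(data: dict, path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, default=_jsonable) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


# -- coordinates ------------------------------------------------------------


def write_points(coords: np.ndarray, path) -> None:
    """Write (id, x, y) CSV for detectors or colonies."""
    df = pd.DataFrame(
        {"id": np.arange(len(coords)), "x": coords[:, 0], "y": coords[:, 1]}
    )
    df.to_csv(path, index=False)


def read_points(path) -> np.ndarray:
    df = pd.read_csv(path)
    for col in ("id", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"{path}: expected columns id,x,y")
    return df.sort_values("id")[["x", "y"]].to_numpy(dtype=float)


# -- encounters -------------------------------------------------------------


def write_encounters(y: EncounterData, path) -> None:
    """Long-format CSV (individual_id, detector_id, count), nonzero cells."""
    ii, jj = np.nonzero(y.counts)
    df = pd.DataFrame(
        {"individual_id": ii, "detector_id": jj, "count": y.counts[ii, jj]}
    )
    df.to_csv(path, index=False)


def read_encounters(path, n_individuals: int, n_detectors: int, K: int) -> EncounterData:
    df = pd.read_csv(path)
    for col in ("individual_id", "detector_id", "count"):
        if col not in df.columns:
            raise ValueError(f"{path}: expected columns individual_id,detector_id,count")
    counts = np.zeros((n_individuals, n_detectors), dtype=int)
    counts[df["individual_id"], df["detector_id"]] = df["count"]
    return EncounterData(counts=counts, K=K)


# -- replicate bundles ------------------------------------------------------


def export_bundle(
    out_dir,
    config: ScenarioConfig,
    replicate_index: int,
    pop: Population,
    colonies: ColonySet,
    control: EncounterData,
    removed: EncounterData,
) -> Path:
    """Write one replicate as detectors/colonies/encounters CSVs + truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = config.detector_grid()
    write_points(grid.coords, out / "detectors.csv")
    write_points(colonies.coords, out / "colonies.csv")
    write_encounters(control, out / "encounters_control.csv")
    write_encounters(removed, out / "encounters_removed.csv")
    write_json(
        {
            "replicate_index": replicate_index,
            "n_true": pop.n,
            "centers": pop.centers,
            "K": config.K,
            "lam0": config.lam0,
            "sigma": config.sigma,
            "nx": config.nx,
            "ny": config.ny,
            "spacing": config.spacing,
            "buffer": config.buffer,
            "colony_radius": colonies.radius,
            "removal_fraction": colonies.removal_fraction,
            "master_seed": config.master_seed,
        },
        out / "truth.json",
    )
    return out


def import_bundle(bundle_dir) -> dict:
    """Read a replicate bundle back into domain objects."""
    b = Path(bundle_dir)
    truth = read_json(b / "truth.json")
    det = read_points(b / "detectors.csv")
    grid = build_detector_grid(truth["nx"], truth["ny"], truth["spacing"], origin=tuple(det[0]))
    n, J = truth["n_true"], grid.n_detectors
    return {
        "truth": truth,
        "grid": grid,
        "colonies": read_points(b / "colonies.csv"),
        "control": read_encounters(b / "encounters_control.csv", n, J, truth["K"]),
        "removed": read_encounters(b / "encounters_removed.csv", n, J, truth["K"]),
    }


# -- run manifest -----------------------------------------------------------


@dataclass(frozen=True)
class RunManifest:
    """Reproducibility metadata: config hash, seed, version, seed table."""

    config_hash: str
    master_seed: int
    package_version: str
    timestamp: str
    replicate_seeds: dict

    @classmethod
    def create(cls, config_dict: dict, master_seed: int, n_replicates: int) -> "RunManifest":
        from scrthin import __version__
        from scrthin.simulate import replicate_seed

        blob = json.dumps(config_dict, sort_keys=True).encode()
        seeds = {
            str(i): int(replicate_seed(master_seed, i, 0).generate_state(1)[0])
            for i in range(n_replicates)
        }
        return cls(
            config_hash=hashlib.sha256(blob).hexdigest(),
            master_seed=int(master_seed),
            package_version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
            replicate_seeds=seeds,
        )

    def write(self, path) -> None:
        write_json(self.__dict__, path)
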