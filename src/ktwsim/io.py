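"""File outputs of a run: event TSV, snapshot CSV, config echo, manifest.

All formats are plain text.  The event log is a TSV with ``#``-prefixed
header comments carrying the parameters and seed; snapshots are a CSV matrix
(rows: recorded events; columns: per-species log10 relative abundance plus
the event index, model time and preceding interval).  The JSON manifest
records the seed, library versions and SHA-256 checksums of every file, so a
config plus seed regenerates every output byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, save_config
from .model import SimulationResult
from .state import EventLog, Snapshots

EVENT_COLUMNS = [
    "event_index",
    "model_time",
    "dt",
    "species_id",
    "extra_victims",
    "log10_before",
    "log10_after",
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_event_log(event_log: EventLog, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# params: " + json.dumps(event_log.params_dict, sort_keys=True) + "\n")
        seed = event_log.params_dict.get("seed")
        fh.write(f"# seed: {seed}\n# generator: numpy.random.default_rng\n")
        event_log.to_dataframe().to_csv(fh, sep="\t", index=False)
    return path


def read_event_log(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype={"extra_victims": str},
        keep_default_na=False,
        float_precision="round_trip",
    )


def write_snapshots(snapshots: Snapshots, path: str | Path) -> Path:
    path = Path(path)
    snapshots.to_dataframe().to_csv(path, index=False)
    return path


def read_snapshots(path: str | Path) -> Snapshots:
    return Snapshots.from_dataframe(
        pd.read_csv(path, float_precision="round_trip")
    )


def write_outputs(
    result: SimulationResult,
    config: RunConfig | None = None,
    outdir: str | Path = ".",
) -> dict[str, Path]:
    """Write all artifacts of a finished run; returns the file paths.

    Files: ``events.tsv``, ``snapshots.csv`` (if recorded), ``config.yaml``
    and ``manifest.json`` (seed, versions, checksums).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["events"] = write_event_log(result.event_log, outdir / "events.tsv")
    if result.snapshots is not None:
        paths["snapshots"] = write_snapshots(result.snapshots, outdir / "snapshots.csv")
    if config is None:
        config = RunConfig(params=result.params, outdir=str(outdir))
    paths["config"] = save_config(config, outdir / "config.yaml")

    manifest = {
        "seed": result.params.seed,
        "label": config.label,
        "n_events_run": len(result.event_log),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "checksums": {name: _sha256(p) for name, p in paths.items()},
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = mpath
    return paths
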