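"""Flat-file persistence of study results: CSV stores plus a JSON manifest.

Everything is plain text (CSV/JSON) so a run is auditable and diffable; the
manifest records the config hash, master seed, and library versions, making
every output row traceable to (condition, criterion, replication).
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .simulation import ReplicationSet

__all__ = [
    "save_results",
    "load_results",
    "write_manifest",
    "read_manifest",
    "MissingResultsError",
]

MANIFEST = "manifest.json"


class MissingResultsError(FileNotFoundError):
    pass


def _cell_key(key) -> str:
    design, sim, n, L = key
    return f"{design}_{sim}_{n}_{L}"


def save_results(results: dict, outdir) -> None:
    """Persist a ``run_study`` result dict as long-format CSVs per cell."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for key, rs in results.items():
        stem = _cell_key(key)
        frames = []
        for kind, store in (("method", rs.methods), ("criterion", rs.criteria)):
            for name, arr in store.items():
                R, P = arr.shape
                frames.append(pd.DataFrame({
                    "kind": kind,
                    "name": name,
                    "replication": np.repeat(np.arange(R), P),
                    "x": np.tile(rs.x, R),
                    "value": arr.ravel(),
                }))
        pd.concat(frames, ignore_index=True).to_csv(
            out / f"replications_{stem}.csv", index=False)
        pd.DataFrame({"x": rs.x, "count": rs.x_counts}).to_csv(
            out / f"xcounts_{stem}.csv", index=False)


def load_results(indir) -> dict:
    """Rebuild the result dict from a results directory."""
    indir = Path(indir)
    files = sorted(indir.glob("replications_*.csv"))
    if not files:
        raise MissingResultsError(
            f"no replication stores found in {indir}; run the study first")
    results = {}
    for f in files:
        design, sim, n, L = f.stem.split("_")[1:]
        n, L = int(n), int(L)
        df = pd.read_csv(f)
        x = np.sort(df["x"].unique()).astype(float)
        rs = ReplicationSet(design, sim, n, L, x)
        for kind, store in (("method", rs.methods), ("criterion", rs.criteria)):
            sub = df[df["kind"] == kind]
            for name, g in sub.groupby("name", sort=False):
                R = g["replication"].nunique()
                store[name] = (
                    g.sort_values(["replication", "x"])["value"]
                    .to_numpy().reshape(R, x.size)
                )
        counts = pd.read_csv(indir / f"xcounts_{f.stem.removeprefix('replications_')}.csv")
        rs.x_counts = counts["count"].to_numpy(dtype=float)
        results[(design, sim, n, L)] = rs
    return results


def write_manifest(outdir, config, extra: dict | None = None) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "created": datetime.now(timezone.utc).isoformat(),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    try:
        from importlib.metadata import version
        manifest["versions"]["equatesim"] = version("equatesim")
    except Exception:  # pragma: no cover
        pass
    if extra:
        manifest.update(extra)
    (out / MANIFEST).write_text(json.dumps(manifest, indent=2, default=list))


def read_manifest(indir) -> dict:
    path = Path(indir) / MANIFEST
    if not path.exists():
        raise MissingResultsError(f"no {MANIFEST} in {indir}")
    return json.loads(path.read_text())
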