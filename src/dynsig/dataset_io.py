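"""Readers and writers for the published dataset layout.

One CSV file per run: comma-separated, LF line ends, no header, no time
column; one row per sample, one column per state variable.  Values are
written in the shortest decimal form that round-trips to the same float64,
so files are diff-stable across platforms and ``read(write(x)) == x``
exactly.  Per-model archives are plain zips of the run files plus the
model's manifest slice; times are implied by (samples, T_max) recorded in
the manifest.
"""

from __future__ import annotations

import csv
import json
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .simulate import GenerationManifest, ManifestEntry, Trajectory

__all__ = ["RunFile", "DatasetWriter", "run_filename", "write_run", "read_run",
           "package_model", "write_manifest", "read_manifest"]

MANIFEST_NAME = "manifest.json"


@dataclass(frozen=True)
class RunFile:
    path: Path
    model_symbol: str
    run_index: int
    table: np.ndarray  # (s, dim)


def run_filename(model_symbol: str, run_index: int) -> str:
    """Deterministic file name: symbol plus zero-padded run index."""
    return f"{model_symbol}_{run_index:04d}.csv"


def _parse_run_name(path: Path) -> tuple[str, int]:
    stem = path.stem
    symbol, _, idx = stem.rpartition("_")
    try:
        return symbol, int(idx)
    except ValueError:
        return stem, -1


def write_run(trajectory: Trajectory, directory) -> RunFile:
    """Write one trajectory as a headerless CSV of state values."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / run_filename(trajectory.model_symbol, trajectory.run_index)
    values = np.asarray(trajectory.values, dtype=float)
    try:
        lines = [",".join(repr(v) for v in row) for row in values.tolist()]
        path.write_text("\n".join(lines) + "\n", encoding="ascii")
    except OSError as exc:
        raise OSError(f"failed writing run file {path}: {exc}") from exc
    return RunFile(path, trajectory.model_symbol, trajectory.run_index, values)


def read_run(path, expected_dim: int | None = None) -> RunFile:
    """Read a run CSV back; tolerant of trailing-newline variants, strict on ragged rows."""
    path = Path(path)
    rows: list[list[float]] = []
    with path.open(newline="") as fh:
        for lineno, rec in enumerate(csv.reader(fh), start=1):
            if not rec:
                continue  # blank line (trailing newline variants)
            try:
                rows.append([float(v) for v in rec])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value ({exc})") from None
            if len(rows[-1]) != len(rows[0]):
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(rows[-1])} columns, expected {len(rows[0])})"
                )
    if not rows:
        raise ValueError(f"{path}: empty run file")
    table = np.asarray(rows, dtype=float)
    if expected_dim is not None and table.shape[1] != expected_dim:
        raise ValueError(f"{path}: {table.shape[1]} columns, expected {expected_dim}")
    symbol, idx = _parse_run_name(path)
    return RunFile(path, symbol, idx, table)


def write_manifest(manifest: GenerationManifest, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / MANIFEST_NAME
    doc = {
        "master_seed": manifest.master_seed,
        "runs_per_model": manifest.runs_per_model,
        "samples": manifest.samples,
        "entries": manifest.to_records(),
    }
    path.write_text(json.dumps(doc, indent=1) + "\n")
    return path


def read_manifest(path) -> GenerationManifest:
    doc = json.loads(Path(path).read_text())
    manifest = GenerationManifest(doc["master_seed"], doc["runs_per_model"], doc["samples"])
    for r in doc["entries"]:
        manifest.entries.append(ManifestEntry(
            r["model"], r["run"], r["seed"], tuple(r["ic"]), r["path"], r["dim"],
            r.get("retries", 0),
        ))
    return manifest


def package_model(symbol: str, directory, manifest: GenerationManifest | None = None) -> Path:
    """Zip one model's run files (plus its manifest slice) into <symbol>.zip."""
    directory = Path(directory)
    files = sorted(directory.glob(f"{symbol}_*.csv"))
    if not files:
        raise FileNotFoundError(f"no run files for {symbol} under {directory}")
    archive = directory / f"{symbol}.zip"
    with zipfile.ZipFile(archive, "w", zipfile.ZIP_DEFLATED) as zf:
        for f in files:
            zf.write(f, arcname=f.name)
        if manifest is not None:
            entries = [r for r in manifest.to_records() if r["model"] == symbol]
            zf.writestr(f"{symbol}_manifest.json", json.dumps(entries, indent=1))
    return archive


class DatasetWriter:
    """Directory-backed sink used by :func:`dynsig.simulate.generate_dataset`."""

    def __init__(self, directory) -> None:
        self.directory = Path(directory)

    def run_path(self, symbol: str, run_index: int) -> Path:
        return self.directory / run_filename(symbol, run_index)

    def write_run(self, trajectory: Trajectory) -> RunFile:
        return write_run(trajectory, self.directory)

    def write_manifest(self, manifest: GenerationManifest) -> Path:
        return write_manifest(manifest, self.directory)
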