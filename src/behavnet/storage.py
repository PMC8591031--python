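"""Run bookkeeping: per-run folders, array/parameter persistence, comparison.

Every experiment lives under ``Data/<experiment>/run_<k>/`` with strictly
increasing run indices; a run folder is never overwritten.  Arrays go into a
single self-describing HDF5 container per run, parameters and free-form
results into JSON (lossless round-trip), and run comparison produces a
pandas table with one row per run.
"""
from __future__ import annotations

import json
import re
from pathlib import Path

import h5py
import numpy as np
import pandas as pd


class StorageError(Exception):
    pass


_RUN_RE = re.compile(r"^run_(\d+)$")
_NAME_RE = re.compile(r"^[\w.\-]+$")


class RunFolder:
    """One simulation run's folder: arrays, parameters, results."""

    def __init__(self, path: Path, index: int):
        self.path = Path(path)
        self.index = index

    # -- arrays -----------------------------------------------------------
    @property
    def _h5path(self) -> Path:
        return self.path / "arrays.h5"

    def save_array(self, name: str, data):
        if not _NAME_RE.match(name):
            raise StorageError(f"array name {name!r} is not filesystem-safe")
        data = np.asarray(data)
        with h5py.File(self._h5path, "a") as fh:
            if name in fh:
                del fh[name]
            fh.create_dataset(name, data=data)

    def load_array(self, name: str) -> np.ndarray:
        if not self._h5path.exists():
            raise StorageError(f"run {self.index} has no saved arrays")
        with h5py.File(self._h5path, "r") as fh:
            if name not in fh:
                raise StorageError(
                    f"no array {name!r} in run {self.index}; available: "
                    + ", ".join(sorted(fh.keys())))
            return fh[name][()]

    def array_names(self) -> list[str]:
        if not self._h5path.exists():
            return []
        with h5py.File(self._h5path, "r") as fh:
            return sorted(fh.keys())

    # -- parameters / results ----------------------------------------------
    def _save_json(self, filename: str, mapping: dict):
        path = self.path / filename
        data = json.loads(path.read_text()) if path.exists() else {}
        data.update(mapping)
        path.write_text(json.dumps(data, indent=2, sort_keys=True))

    def _load_json(self, filename: str) -> dict:
        path = self.path / filename
        return json.loads(path.read_text()) if path.exists() else {}

    def save_parameters(self, **params):
        self._save_json("parameters.json", params)

    def load_parameters(self) -> dict:
        return self._load_json("parameters.json")

    def save_result(self, name: str, value):
        self._save_json("results.json", {name: value})

    def load_results(self) -> dict:
        return self._load_json("results.json")


class StorageManager:
    """Allocates run folders under ``<root>/<experiment>/``."""

    def __init__(self, experiment: str, root="Data"):
        self.experiment = experiment
        self.root = Path(root)

    @property
    def experiment_path(self) -> Path:
        return self.root / self.experiment

    def runs(self) -> list[RunFolder]:
        if not self.experiment_path.exists():
            return []
        found = []
        for child in self.experiment_path.iterdir():
            m = _RUN_RE.match(child.name)
            if m and child.is_dir():
                found.append(RunFolder(child, int(m.group(1))))
        return sorted(found, key=lambda r: r.index)

    def create_run(self) -> RunFolder:
        """Atomically allocate the next free run index (concurrency-safe)."""
        self.experiment_path.mkdir(parents=True, exist_ok=True)
        existing = [r.index for r in self.runs()]
        index = max(existing, default=-1) + 1
        while True:
            path = self.experiment_path / f"run_{index}"
            try:
                path.mkdir(exist_ok=False)
                return RunFolder(path, index)
            except FileExistsError:
                index += 1
            except OSError as exc:
                raise StorageError(f"cannot create run folder {path}: {exc}") from exc


def create_run(experiment: str, root="Data") -> RunFolder:
    return StorageManager(experiment, root).create_run()


def compare_runs(experiment: str, parameters=(), root="Data",
                 sort_by: str | None = None) -> pd.DataFrame:
    """One row per run with the requested parameters and saved scalar results.

    Missing values are flagged as NaN rather than raising; with no matching
    parameters the table still lists the run indices.
    """
    manager = StorageManager(experiment, root)
    runs = manager.runs()
    if not runs:
        raise StorageError(f"experiment {experiment!r} has no runs under {root}")
    rows = []
    for run in runs:
        record: dict = {"run": run.index}
        merged = {**run.load_parameters(), **run.load_results()}
        for name in parameters:
            record[name] = merged.get(name, np.nan)
        rows.append(record)
    df = pd.DataFrame(rows)
    if sort_by is not None and sort_by in df.columns:
        df = df.sort_values(sort_by).reset_index(drop=True)
    return df
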