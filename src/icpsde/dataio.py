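"""Trajectory CSV I/O.

Declared dialect: UTF-8 CSV with header exactly ``time_min,icp_mmHg``,
decimal point, one row per grid time.  Provenance (parameters, scheme,
seed) travels in a sidecar JSON file with the same basename and a
``.json`` suffix.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .exceptions import TrajectoryFormatError
from .model import CSFModelParams
from .sde import ICPTrajectory, TimeGrid

__all__ = ["write_trajectory", "read_trajectory", "HEADER"]

logger = logging.getLogger(__name__)

HEADER = "time_min,icp_mmHg"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trajectory(path, traj: ICPTrajectory) -> Path:
    """Write a trajectory CSV plus its metadata sidecar; returns the CSV path."""
    path = Path(path)
    lines = [HEADER]
    lines += [f"{float(t)!r},{float(p)!r}" for t, p in zip(traj.grid.t, traj.p)]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    meta = {
        "scheme": traj.scheme,
        "seed": traj.seed,
        "params": traj.params.to_dict() if traj.params is not None else None,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2) + "\n", encoding="utf-8")
    return path


def read_trajectory(path) -> ICPTrajectory:
    """Read a trajectory CSV (and sidecar metadata, when present).

    Round-trips :func:`write_trajectory` output exactly.  Malformed
    headers, non-numeric cells and non-monotone times are reported with
    their row number.  Rows with non-positive pressures are accepted —
    clinical recordings may contain artifacts — but logged as a
    flagged-row report.
    """
    path = Path(path)
    raw = path.read_text(encoding="utf-8").splitlines()
    if not raw or raw[0].strip() != HEADER:
        raise TrajectoryFormatError(
            f"{path}: row 1: header must be exactly {HEADER!r}, got "
            f"{(raw[0].strip() if raw else '')!r}"
        )
    times, pressures, flagged = [], [], []
    for row_no, line in enumerate(raw[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(",")
        if len(cells) != 2:
            raise TrajectoryFormatError(f"{path}: row {row_no}: expected 2 cells")
        try:
            t, p = float(cells[0]), float(cells[1])
        except ValueError:
            raise TrajectoryFormatError(
                f"{path}: row {row_no}: non-numeric cell in {line!r}"
            ) from None
        if times and t <= times[-1]:
            raise TrajectoryFormatError(
                f"{path}: row {row_no}: times must be strictly increasing"
            )
        if p <= 0:
            flagged.append(row_no)
        times.append(t)
        pressures.append(p)
    if flagged:
        logger.warning(
            "%s: %d row(s) with non-positive pressure flagged: rows %s",
            path, len(flagged), flagged,
        )
    meta_path = _sidecar(path)
    scheme, seed, params = "external", None, None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text(encoding="utf-8"))
        scheme = meta.get("scheme", "external")
        seed = meta.get("seed")
        if meta.get("params") is not None:
            params = CSFModelParams.from_dict(meta["params"])
    if flagged and scheme in ("log-euler", "exact-path", "deterministic"):
        # positivity-guaranteed provenance contradicts the data; keep the
        # file readable but mark it as externally modified
        logger.warning("%s: non-positive pressures under scheme %r; "
                       "treating as external data", path, scheme)
        scheme = "external"
    grid = TimeGrid(np.asarray(times))
    return ICPTrajectory(grid=grid, p=np.asarray(pressures), scheme=scheme,
                         seed=seed, params=params)
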