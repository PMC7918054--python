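"""File round-tripping: result CSVs, manifests, lattice snapshots (grid/PGM)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .lattice import Lattice
from .params import ParameterError
from .scenarios import SimulationResult

__all__ = [
    "write_result_csv",
    "write_manifest",
    "read_manifest",
    "write_snapshot_grid",
    "read_snapshot_grid",
    "write_snapshot_pgm",
]

# Snapshot integer coding: occupancy code plus 10 when the occupant is
# resistant (0 empty, 1 SF, 2 HA, 11 resistant SF, 12 resistant HA).
_RESISTANT_OFFSET = 10


def write_result_csv(result: SimulationResult, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    result.to_dataframe().to_csv(path, index=False)
    return path


def write_manifest(path: str | Path, **entries) -> Path:
    """YAML manifest with everything needed to re-run a command."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(entries, sort_keys=True))
    return path


def read_manifest(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def snapshot_codes(lat: Lattice) -> np.ndarray:
    return lat.occ.astype(np.int16) + _RESISTANT_OFFSET * lat.res


def write_snapshot_grid(lat: Lattice, path: str | Path, delimiter: str = "\t") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, snapshot_codes(lat), fmt="%d", delimiter=delimiter)
    return path


def read_snapshot_grid(path: str | Path, delimiter: str = "\t") -> Lattice:
    codes = np.loadtxt(path, dtype=np.int16, delimiter=delimiter, ndmin=2)
    res = codes >= _RESISTANT_OFFSET
    occ = codes - _RESISTANT_OFFSET * res
    if not np.isin(occ, (0, 1, 2)).all():
        raise ParameterError(f"invalid snapshot codes in {path}")
    return Lattice(occ.astype(np.int8), res)


def write_snapshot_pgm(lat: Lattice, path: str | Path) -> Path:
    """Plain (P2) portable graymap; gray levels 0=empty, 1=SF, 2=HA (+10 resistant)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    codes = snapshot_codes(lat)
    lines = [f"P2\n{lat.cols} {lat.rows}\n{int(codes.max(initial=1))}\n"]
    for row in codes:
        lines.append(" ".join(str(v) for v in row) + "\n")
    path.write_text("".join(lines))
    return path
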