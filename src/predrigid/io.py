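"""File formats: extended XYZ structures and the feature container.

The feature container is the package's interchange format for
per-environment features, the structure map, component blocks, optional
coordinate gradients and a target table.  The primary layout is a single
HDF5 file (bit-exact round trips); a plain-text CSV fallback (a
directory holding features.csv / envmap.csv / targets.csv and optionally
blocks.csv) covers environments without HDF5 tooling.  All indices in
both layouts are 0-based, recorded in the container metadata.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .core import FeatureSet

__all__ = [
    "Structure",
    "XYZParseError",
    "read_xyz",
    "write_xyz",
    "read_container",
    "write_container",
]

FORMAT_VERSION = 1


@dataclass
class Structure:
    """A molecular structure: species, positions (length units, Å-like),
    optional 3x3 cell, free-form comment properties."""

    symbols: list[str]
    positions: np.ndarray
    cell: np.ndarray | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n_atoms, 3)")
        if len(self.symbols) != len(self.positions):
            raise ValueError("one symbol per atom required")
        if len(self.symbols) == 0:
            raise ValueError("empty structure")
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float).reshape(3, 3)

    def __len__(self) -> int:
        return len(self.symbols)


class XYZParseError(ValueError):
    def __init__(self, path, line_no: int, message: str) -> None:
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


_KV_RE = re.compile(r'(\S+?)=(?:"([^"]*)"|(\S+))')


def _parse_comment(comment: str) -> dict:
    props = {}
    for m in _KV_RE.finditer(comment):
        key = m.group(1)
        props[key] = m.group(2) if m.group(2) is not None else m.group(3)
    return props


def read_xyz(path) -> list[Structure]:
    """Read a (multi-frame) extended-XYZ file; frames in file order."""
    path = Path(path)
    structures: list[Structure] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise XYZParseError(path, i + 1, f"expected atom count, got {lines[i]!r}")
        if natoms <= 0:
            raise XYZParseError(path, i + 1, f"invalid atom count {natoms}")
        if i + 1 + natoms >= len(lines) + 1 and i + 1 >= len(lines):
            raise XYZParseError(path, i + 1, "missing comment line")
        props = _parse_comment(lines[i + 1])
        cell = None
        if "Lattice" in props:
            vals = np.fromstring(props.pop("Lattice"), sep=" ")
            if vals.size != 9:
                raise XYZParseError(path, i + 2, "Lattice must hold 9 numbers")
            cell = vals.reshape(3, 3)
        props.pop("Properties", None)
        symbols, positions = [], []
        for a in range(natoms):
            ln = i + 2 + a
            if ln >= len(lines) or not lines[ln].strip():
                raise XYZParseError(
                    path, ln + 1, f"frame declares {natoms} atoms but file ends early"
                )
            parts = lines[ln].split()
            if len(parts) < 4:
                raise XYZParseError(path, ln + 1, f"need 'symbol x y z', got {lines[ln]!r}")
            symbols.append(parts[0])
            try:
                positions.append([float(x) for x in parts[1:4]])
            except ValueError:
                raise XYZParseError(path, ln + 1, f"non-numeric coordinate in {lines[ln]!r}")
        structures.append(
            Structure(symbols=symbols, positions=np.array(positions), cell=cell, info=props)
        )
        i += 2 + natoms
    return structures


def _fmt_value(v) -> str:
    s = str(v)
    return f'"{s}"' if " " in s else s


def write_xyz(structures: Sequence[Structure], path) -> None:
    """Write structures as extended XYZ (deterministic output)."""
    with open(path, "w") as fh:
        for s in structures:
            fh.write(f"{len(s)}\n")
            fields = []
            if s.cell is not None:
                lattice = " ".join(f"{x:.10g}" for x in s.cell.ravel())
                fields.append(f'Lattice="{lattice}"')
            fields.append("Properties=species:S:1:pos:R:3")
            for k in sorted(s.info):
                fields.append(f"{k}={_fmt_value(s.info[k])}")
            fh.write(" ".join(fields) + "\n")
            for sym, pos in zip(s.symbols, s.positions):
                fh.write(f"{sym} {pos[0]:.12f} {pos[1]:.12f} {pos[2]:.12f}\n")


# ---------------------------------------------------------------------------
# feature container


class ContainerSchemaError(ValueError):
    pass


def write_container(
    path,
    fs: FeatureSet,
    targets: pd.DataFrame | None = None,
    metadata: dict | None = None,
) -> None:
    """Write a feature container.

    ``path`` ending in ``.h5``/``.hdf5`` selects the HDF5 layout;
    anything else is treated as a directory for the CSV fallback.
    ``targets`` is a table with columns (structure, kind, weight, value).
    """
    path = Path(path)
    meta = dict(metadata or {})
    meta.setdefault("format_version", FORMAT_VERSION)
    meta.setdefault("indexing", "0-based")
    if path.suffix in {".h5", ".hdf5"}:
        _write_h5(path, fs, targets, meta)
    else:
        _write_csv(path, fs, targets, meta)


def read_container(path) -> tuple[FeatureSet, pd.DataFrame | None, dict]:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        return _read_h5(path)
    return _read_csv(path)


def _write_h5(path, fs, targets, meta) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("env_features", data=fs.env_features, track_times=False)
        f.create_dataset("structure_of_env", data=fs.structure_of_env, track_times=False)
        if fs.env_gradients is not None:
            f.create_dataset("env_gradients", data=fs.env_gradients, track_times=False)
        if fs.blocks:
            grp = f.create_group("blocks")
            labels = list(fs.blocks)
            grp.create_dataset("label", data=[l.encode() for l in labels], track_times=False)
            grp.create_dataset("start", data=[fs.blocks[l][0] for l in labels], track_times=False)
            grp.create_dataset("stop", data=[fs.blocks[l][1] for l in labels], track_times=False)
        if targets is not None:
            grp = f.create_group("targets")
            grp.create_dataset("structure", data=targets["structure"].to_numpy(dtype=np.intp), track_times=False)
            grp.create_dataset("kind", data=[k.encode() for k in targets["kind"]], track_times=False)
            grp.create_dataset("weight", data=targets["weight"].to_numpy(dtype=float), track_times=False)
            grp.create_dataset("value", data=targets["value"].to_numpy(dtype=float), track_times=False)
        for k, v in meta.items():
            f.attrs[k] = v


def _read_h5(path):
    with h5py.File(path, "r") as f:
        for name in ("env_features", "structure_of_env"):
            if name not in f:
                raise ContainerSchemaError(f"missing mandatory dataset {name!r} in {path}")
        meta = dict(f.attrs)
        version = int(meta.get("format_version", -1))
        if version != FORMAT_VERSION:
            raise ContainerSchemaError(
                f"container format version {version} != supported {FORMAT_VERSION}"
            )
        blocks = {}
        if "blocks" in f:
            for label, start, stop in zip(
                f["blocks/label"][:], f["blocks/start"][:], f["blocks/stop"][:]
            ):
                blocks[label.decode()] = (int(start), int(stop))
        fs = FeatureSet(
            env_features=f["env_features"][:],
            structure_of_env=f["structure_of_env"][:],
            blocks=blocks,
            env_gradients=f["env_gradients"][:] if "env_gradients" in f else None,
        )
        targets = None
        if "targets" in f:
            targets = pd.DataFrame(
                {
                    "structure": f["targets/structure"][:],
                    "kind": [k.decode() for k in f["targets/kind"][:]],
                    "weight": f["targets/weight"][:],
                    "value": f["targets/value"][:],
                }
            )
    return fs, targets, meta


def _write_csv(path: Path, fs, targets, meta) -> None:
    path.mkdir(parents=True, exist_ok=True)
    feat = pd.DataFrame(fs.env_features, columns=[f"f{i}" for i in range(fs.d)])
    feat.insert(0, "env", np.arange(fs.n_env))
    feat.to_csv(path / "features.csv", index=False, float_format="%.17g")
    envmap = pd.DataFrame(
        {"env": np.arange(fs.n_env), "structure": fs.structure_of_env}
    )
    envmap.to_csv(path / "envmap.csv", index=False)
    if fs.blocks:
        pd.DataFrame(
            [(l, a, b) for l, (a, b) in fs.blocks.items()],
            columns=["label", "start", "stop"],
        ).to_csv(path / "blocks.csv", index=False)
    if targets is not None:
        targets.to_csv(path / "targets.csv", index=False, float_format="%.17g")
    with open(path / "metadata.json", "w") as fh:
        json.dump({k: _jsonable(v) for k, v in meta.items()}, fh, indent=2)


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def _read_csv(path: Path):
    path = Path(path)
    feat_path = path / "features.csv"
    map_path = path / "envmap.csv"
    if not feat_path.exists():
        raise ContainerSchemaError(f"missing mandatory file {feat_path}")
    if not map_path.exists():
        raise ContainerSchemaError(f"missing mandatory file {map_path} (structure map)")
    feat = pd.read_csv(feat_path)
    envmap = pd.read_csv(map_path)
    meta_path = path / "metadata.json"
    meta = json.load(open(meta_path)) if meta_path.exists() else {}
    version = int(meta.get("format_version", FORMAT_VERSION))
    if version != FORMAT_VERSION:
        raise ContainerSchemaError(
            f"container format version {version} != supported {FORMAT_VERSION}"
        )
    blocks = {}
    blocks_path = path / "blocks.csv"
    if blocks_path.exists():
        for _, row in pd.read_csv(blocks_path).iterrows():
            blocks[str(row["label"])] = (int(row["start"]), int(row["stop"]))
    fs = FeatureSet(
        env_features=feat.drop(columns=["env"]).to_numpy(dtype=float),
        structure_of_env=envmap["structure"].to_numpy(dtype=np.intp),
        blocks=blocks,
    )
    targets_path = path / "targets.csv"
    targets = pd.read_csv(targets_path) if targets_path.exists() else None
    return fs, targets, meta
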