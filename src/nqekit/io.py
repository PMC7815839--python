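"""File formats: extended XYZ, z/R/E/F dataset archives, trajectories, tables.

The dataset archive is a compressed NumPy .npz holding arrays named
``z`` (atomic numbers), ``R`` (M×N×3 coordinates, Å), ``E`` (M energies,
kcal/mol) and ``F`` (M×N×3 forces, kcal/mol/Å) — the dialect of the
published gradient-domain training sets, accepted unchanged.

All floating-point text output uses 17 significant digits so that
write→read round-trips are lossless.
"""

from __future__ import annotations

import json
from typing import Optional, Sequence

import numpy as np
import yaml

from .data import Dataset, MolecularConfiguration
from .dynamics import Trajectory
from .units import NUMBERS_TO_SYMBOLS

__all__ = [
    "read_extxyz", "write_extxyz", "read_dataset", "write_dataset",
    "write_trajectory", "read_trajectory", "write_table",
    "load_config", "save_config", "ParseError",
]

_FMT = "%.17g"


class ParseError(ValueError):
    """Malformed file; the message names the offending line."""


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return _FMT % x


def write_extxyz(path, configs) -> None:
    """Write configurations in extended-XYZ (energy key, force columns)."""
    if isinstance(configs, MolecularConfiguration):
        configs = [configs]
    with open(path, "w") as fh:
        for c in configs:
            fh.write(f"{c.n_atoms}\n")
            props = "species:S:1:pos:R:3"
            if c.forces is not None:
                props += ":forces:R:3"
            comment = f'Properties={props}'
            if c.energy is not None:
                comment += f" energy={_fmt(c.energy)}"
            fh.write(comment + "\n")
            for a in range(c.n_atoms):
                row = [c.species[a]] + [_fmt(v) for v in c.coordinates[a]]
                if c.forces is not None:
                    row += [_fmt(v) for v in c.forces[a]]
                fh.write(" ".join(row) + "\n")


def _parse_comment(line: str) -> dict:
    out = {}
    for tok in line.split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            out[k] = v.strip('"')
    return out


def read_extxyz(path) -> list[MolecularConfiguration]:
    """Read one or more configurations from an extended-XYZ file."""
    configs = []
    with open(path) as fh:
        lines = fh.readlines()
    ln = 0
    nlines = len(lines)
    while ln < nlines:
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            nat = int(lines[ln].strip())
        except ValueError:
            raise ParseError(
                f"{path}:{ln + 1}: expected atom count, got {lines[ln]!r}"
            ) from None
        if ln + 1 + nat >= nlines + 1 or ln + 1 >= nlines:
            raise ParseError(
                f"{path}:{ln + 1}: truncated file, {nat} atoms declared but "
                f"only {nlines - ln - 2} atom lines remain"
            )
        keys = _parse_comment(lines[ln + 1])
        energy = float(keys["energy"]) if "energy" in keys else None
        has_forces = "forces" in keys.get("Properties", "")
        species, coords, forces = [], [], []
        for a in range(nat):
            idx = ln + 2 + a
            if idx >= nlines:
                raise ParseError(
                    f"{path}:{idx + 1}: truncated file inside atom block"
                )
            parts = lines[idx].split()
            want = 7 if has_forces else 4
            if len(parts) < want:
                raise ParseError(
                    f"{path}:{idx + 1}: expected {want} columns, got {len(parts)}"
                )
            species.append(parts[0])
            try:
                coords.append([float(v) for v in parts[1:4]])
                if has_forces:
                    forces.append([float(v) for v in parts[4:7]])
            except ValueError:
                raise ParseError(
                    f"{path}:{idx + 1}: non-numeric coordinate/force field"
                ) from None
        configs.append(MolecularConfiguration(
            tuple(species), np.array(coords), energy,
            np.array(forces) if has_forces else None,
        ))
        ln += 2 + nat
    if not configs:
        raise ParseError(f"{path}: no configurations found")
    return configs


# ---------------------------------------------------------------------------
# z/R/E/F dataset archives
# ---------------------------------------------------------------------------

def write_dataset(path, dataset: Dataset) -> None:
    z = dataset.configurations[0].atomic_numbers
    np.savez_compressed(
        path, z=z, R=dataset.coordinates_array(),
        E=dataset.energies_array() if dataset.has_energies else np.full(len(dataset), np.nan),
        F=dataset.forces_array(),
        units=json.dumps(dataset.units),
        provenance=json.dumps(dataset.provenance, default=str),
    )


def read_dataset(path, species: Optional[Sequence[str]] = None) -> Dataset:
    """Load a z/R/E/F archive, validating shapes and finiteness.

    Every violation found is listed in a single error. Unknown atomic
    numbers may be resolved by passing ``species`` explicitly.
    """
    with np.load(path, allow_pickle=False) as f:
        problems = []
        for name in ("z", "R", "E", "F"):
            if name not in f:
                problems.append(f"missing array {name!r}")
        if problems:
            raise ValueError(f"{path}: " + "; ".join(problems))
        z, R, E, F = f["z"], f["R"], f["E"], f["F"]
        units = json.loads(str(f["units"])) if "units" in f else None
        prov = json.loads(str(f["provenance"])) if "provenance" in f else {}
    n = len(z)
    if R.ndim != 3 or R.shape[1:] != (n, 3):
        problems.append(f"R has shape {R.shape}, expected (M, {n}, 3)")
    if F.shape != R.shape:
        problems.append(f"F has shape {F.shape}, expected {R.shape}")
    if E.shape != (R.shape[0],):
        problems.append(f"E has shape {E.shape}, expected ({R.shape[0]},)")
    if not problems:
        for arr, name in ((R, "R"), (F, "F")):
            bad = np.nonzero(~np.isfinite(arr).all(axis=(1, 2)))[0]
            if bad.size:
                problems.append(f"non-finite {name} at record(s) {bad.tolist()}")
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))

    has_e = bool(np.all(np.isfinite(E)))
    if not has_e and not np.all(np.isnan(E)):
        bad = np.nonzero(~np.isfinite(E))[0]
        raise ValueError(f"{path}: non-finite E at record(s) {bad.tolist()}")
    if species is None:
        species = tuple(NUMBERS_TO_SYMBOLS.get(int(v), "X") for v in z)
    configs = [
        MolecularConfiguration(tuple(species), R[i],
                               float(E[i]) if has_e else None, F[i])
        for i in range(R.shape[0])
    ]
    ds = Dataset(configs, provenance={"source": str(path), **prov})
    if units:
        ds.units = units
    return ds


# ---------------------------------------------------------------------------
# trajectory container
# ---------------------------------------------------------------------------

def write_trajectory(path, traj: Trajectory) -> None:
    payload = {
        "dt": traj.dt, "stride": traj.stride, "frames": traj.frames,
        "status": traj.status,
        "provenance": json.dumps(traj.provenance, default=str),
    }
    for k, v in traj.records.items():
        payload[f"rec_{k}"] = v
    if traj.beads is not None:
        payload["beads"] = traj.beads
    np.savez_compressed(path, **payload)


def read_trajectory(path) -> Trajectory:
    with np.load(path, allow_pickle=False) as f:
        records = {k[4:]: f[k].copy() for k in f.files if k.startswith("rec_")}
        return Trajectory(
            dt=float(f["dt"]), stride=int(f["stride"]),
            frames=f["frames"].copy(), records=records,
            beads=(f["beads"].copy() if "beads" in f.files else None),
            status=str(f["status"]),
            provenance=json.loads(str(f["provenance"])),
        )


# ---------------------------------------------------------------------------
# text tables and config files
# ---------------------------------------------------------------------------

def write_table(path, columns: dict) -> None:
    """Tab-delimited text table with a # header, 17 significant digits."""
    names = list(columns)
    cols = [np.atleast_1d(np.asarray(columns[k])) for k in names]
    n = len(cols[0])
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(names) + "\n")
        for i in range(n):
            fh.write("\t".join(
                _fmt(float(c[i])) if np.issubdtype(c.dtype, np.floating)
                else str(c[i]) for c in cols) + "\n")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping of flat keys")
    return cfg


def save_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
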