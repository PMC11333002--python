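"""Readers and writers for the package's interchange formats.

Tab-separated values with ``#`` comment lines are the universal tabular
dialect: trajectories (time_ns, e2e_nm, states), force-extension traces
(time_ns, ext_nm, force_pN), free-energy profiles (xi_nm, A_kJ_mol,
n_samples), and umbrella-window archives (one TSV per window plus a YAML
manifest).  Coordinates travel as single-chain PDB files with N, H, CA, C,
O atoms per residue.  Every stochastic run can record a JSON run manifest
from which the output is reproducible bit for bit.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import yaml

from .errors import EmptyAnalysisError, ParseError
from .geometry import BackboneCoordinates
from .helicity import StateTrajectory
from .pulling import ForceExtensionTrace
from .umbrella import PMFProfile, UmbrellaWindow

__all__ = [
    "read_trajectory", "write_trajectory",
    "read_trace", "write_trace",
    "read_pmf", "write_pmf",
    "read_windows", "write_windows",
    "read_pdb", "write_pdb",
    "write_manifest", "read_manifest",
]

_TRAJ_COLUMNS = ("time_ns", "e2e_nm", "states")
_TRACE_COLUMNS = ("time_ns", "ext_nm", "force_pN")
_PMF_COLUMNS = ("xi_nm", "A_kJ_mol", "n_samples")


def _data_lines(path: Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def write_trajectory(path, traj: StateTrajectory) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {traj.label}\n")
        fh.write(f"# force_pN={traj.force_pn:g} "
                 f"production={int(traj.production)}\n")
        fh.write("\t".join(_TRAJ_COLUMNS) + "\n")
        for t, e, s in zip(traj.times_ns, traj.e2e_nm, traj.state_strings()):
            fh.write(f"{t:.6f}\t{e:.6f}\t{s}\n")


def read_trajectory(path) -> StateTrajectory:
    """Read a trajectory TSV, validating layout and reporting the line
    number of any malformed row."""
    path = Path(path)
    lines = _data_lines(path)
    try:
        _, header = next(lines)
    except StopIteration:
        raise ParseError(f"{path}: empty file") from None
    cols = tuple(header.split("\t"))
    if cols != _TRAJ_COLUMNS:
        raise ParseError(
            f"{path}: expected header {'	'.join(_TRAJ_COLUMNS)!r}, "
            f"got {header!r}")
    times, e2es, states = [], [], []
    n_res = None
    for lineno, line in lines:
        parts = line.split("\t")
        if len(parts) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 columns")
        try:
            times.append(float(parts[0]))
            e2es.append(float(parts[1]))
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: non-numeric time or distance") from None
        s = parts[2]
        if set(s) - {"H", "C"} or not s:
            raise ParseError(f"{path}:{lineno}: invalid state string {s!r}")
        if n_res is None:
            n_res = len(s)
        elif len(s) != n_res:
            raise ParseError(
                f"{path}:{lineno}: state string length {len(s)} != "
                f"{n_res} residues of earlier rows")
        states.append(s)
    if not times:
        raise EmptyAnalysisError(f"{path}: header-only file, no frames")
    meta = _read_traj_meta(path)
    try:
        return StateTrajectory.from_strings(times, states, e2es, **meta)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _read_traj_meta(path: Path) -> dict:
    meta = {"force_pn": 0.0, "label": "", "production": False}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                for tok in body.split():
                    if tok.startswith("force_pN="):
                        meta["force_pn"] = float(tok.split("=", 1)[1])
                    elif tok.startswith("production="):
                        meta["production"] = bool(int(tok.split("=", 1)[1]))
            elif body:
                meta["label"] = body
    return meta


def write_trace(path, trace: ForceExtensionTrace) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {trace.label}\n")
        fh.write("\t".join(_TRACE_COLUMNS) + "\n")
        for t, e, f in zip(trace.times_ns, trace.extension_nm, trace.force_pn):
            fh.write(f"{t:.6f}\t{e:.6f}\t{f:.6f}\n")


def read_trace(path) -> ForceExtensionTrace:
    path = Path(path)
    rows = _read_numeric_tsv(path, _TRACE_COLUMNS)
    return ForceExtensionTrace(rows[:, 0], rows[:, 1], rows[:, 2],
                               label=path.stem)


def write_pmf(path, profile: PMFProfile) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# reference={profile.reference:g}\n")
        fh.write("\t".join(_PMF_COLUMNS) + "\n")
        for x, a, c in zip(profile.grid, profile.free_energy, profile.counts):
            fh.write(f"{x:.6f}\t{a if np.isfinite(a) else 'nan'}\t{int(c)}\n")


def read_pmf(path) -> PMFProfile:
    path = Path(path)
    rows = _read_numeric_tsv(path, _PMF_COLUMNS, allow_nan=True)
    reference = 0.0
    with open(path) as fh:
        first = fh.readline().strip()
        if first.startswith("#") and "reference=" in first:
            reference = float(first.split("reference=")[1])
    return PMFProfile(rows[:, 0], rows[:, 1], rows[:, 2].astype(int),
                      reference=reference)


def _read_numeric_tsv(path: Path, columns: tuple[str, ...],
                      allow_nan: bool = False) -> np.ndarray:
    lines = _data_lines(path)
    try:
        _, header = next(lines)
    except StopIteration:
        raise ParseError(f"{path}: empty file") from None
    if tuple(header.split("\t")) != columns:
        raise ParseError(f"{path}: expected header {'	'.join(columns)!r}")
    data = []
    for lineno, line in lines:
        parts = line.split("\t")
        if len(parts) != len(columns):
            raise ParseError(
                f"{path}:{lineno}: expected {len(columns)} columns")
        try:
            data.append([float(p) for p in parts])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric value") from None
    if not data:
        raise EmptyAnalysisError(f"{path}: header-only file, no rows")
    arr = np.asarray(data)
    if not allow_nan and not np.all(np.isfinite(arr)):
        raise ParseError(f"{path}: non-finite values")
    return arr


def write_windows(directory, windows: list[UmbrellaWindow]) -> None:
    """Write an umbrella-window archive: window_NN.tsv files plus
    windows.yaml manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, w in enumerate(windows):
        name = f"window_{i:02d}.tsv"
        with open(directory / name, "w") as fh:
            fh.write("sample_index\txi_nm\n")
            for j, x in enumerate(w.samples):
                fh.write(f"{j}\t{x:.8f}\n")
        manifest.append({
            "file": name,
            "center_nm": float(w.center),
            "k_kJ_mol_nm2": float(w.spring_constant),
            "discard_ns": float(w.equilibration_discard_ns),
        })
    with open(directory / "windows.yaml", "w") as fh:
        yaml.safe_dump({"windows": manifest}, fh, sort_keys=False)


def read_windows(directory) -> list[UmbrellaWindow]:
    directory = Path(directory)
    manifest_path = directory / "windows.yaml"
    if not manifest_path.exists():
        raise ParseError(f"{manifest_path}: missing window manifest")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    windows = []
    for entry in manifest["windows"]:
        rows = _read_numeric_tsv(directory / entry["file"],
                                 ("sample_index", "xi_nm"))
        windows.append(UmbrellaWindow(
            center=entry["center_nm"],
            spring_constant=entry["k_kJ_mol_nm2"],
            samples=rows[:, 1],
            equilibration_discard_ns=entry.get("discard_ns", 0.0)))
    return windows


# ---------------------------------------------------------------- PDB I/O

def write_pdb(path, coords: BackboneCoordinates) -> None:
    """Write a one-chain PDB with N, H, CA, C, O atoms per residue."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    names, elements, res_ids, positions = [], [], [], []
    three = {"A": "ALA"}
    for i in range(coords.residue_count):
        for name, arr, elem in (("N", coords.n, "N"), ("H", coords.h, "H"),
                                ("CA", coords.ca, "C"), ("C", coords.c, "C"),
                                ("O", coords.o, "O")):
            pos = arr[i]
            if not np.all(np.isfinite(pos)):
                continue
            names.append(name)
            elements.append(elem)
            res_ids.append(i + 1)
            positions.append(pos)
    atoms = struc.AtomArray(len(names))
    atoms.coord = np.asarray(positions, dtype=np.float32)
    atoms.atom_name = np.asarray(names)
    atoms.element = np.asarray(elements)
    atoms.res_id = np.asarray(res_ids)
    atoms.res_name = np.asarray(
        [three.get(coords.sequence[r - 1], "ALA") for r in res_ids])
    atoms.chain_id = np.asarray(["A"] * len(names))
    atoms.hetero = np.zeros(len(names), dtype=bool)
    f = pdb.PDBFile()
    f.set_structure(atoms)
    f.write(str(path))


def read_pdb(path) -> BackboneCoordinates:
    """Read backbone coordinates from the first model/chain of a PDB file."""
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(str(path))
    atoms = f.get_structure(model=1)
    atoms = atoms[atoms.chain_id == atoms.chain_id[0]]
    res_ids = np.unique(atoms.res_id)
    m = len(res_ids)
    out = {k: np.full((m, 3), np.nan) for k in ("N", "H", "CA", "C", "O")}
    for i, rid in enumerate(res_ids):
        sel = atoms[atoms.res_id == rid]
        for name in out:
            hit = sel[sel.atom_name == name]
            if len(hit):
                out[name][i] = hit.coord[0]
    for name in ("N", "CA", "C", "O"):
        if not np.all(np.isfinite(out[name])):
            raise ParseError(f"{path}: missing backbone {name} atoms")
    return BackboneCoordinates(out["N"], out["CA"], out["C"], out["O"],
                               out["H"])


# ------------------------------------------------------------- manifests

def write_manifest(path, command: str, parameters: dict,
                   outputs: list[str], seed: int | None = None,
                   inputs: list[str] | None = None) -> None:
    """Record a reproducible run description next to its outputs."""
    from . import __version__
    doc = {
        "command": command,
        "parameters": parameters,
        "seed": seed,
        "inputs": inputs or [],
        "outputs": outputs,
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("command", "parameters", "outputs"):
        if key not in doc:
            raise ParseError(f"{path}: manifest missing {key!r}")
    return doc
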