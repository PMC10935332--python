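"""Structure, trajectory and table I/O.

PDB is the interchange format for single conformations (read through
gemmi, with an atom-name alias table and waters skipped); multi-frame XYZ
is the canonical trajectory format (atom names in the symbol column, so a
trajectory round-trips losslessly against a topology); DCD ingestion
delegates to MDAnalysis.  Tabular inputs (couplings, EXSY volumes,
variable-temperature shifts) are comma-separated with a header row.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable

import gemmi
import numpy as np
import pandas as pd

from .geometry import AlditolTopology, Conformation, GeometryError, Trajectory
from .jcoupling import CouplingSet
from .nmr_exchange import ExsyDataset, TempShiftSeries

__all__ = [
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "read_couplings_csv",
    "read_exsy_csv",
    "read_tempshift_csv",
]

#: residue names treated as solvent and skipped on input
WATER_RESIDUES = {"HOH", "WAT", "TIP3", "TIP", "SOL", "SPC"}

#: PDB atom-name aliases -> canonical names
ATOM_ALIASES = {
    "H11": "H1R", "H12": "H1S", "1H1": "H1R", "2H1": "H1S",
    "H51": "H5R", "H52": "H5S", "1H5": "H5R", "2H5": "H5S",
    "HO1": "HO1", "HO2": "HO2", "HO3": "HO3", "HO4": "HO4", "HO5": "HO5",
    "H1O": "HO1", "H2O": "HO2", "H3O": "HO3", "H4O": "HO4", "H5O": "HO5",
    "O1H": "HO1", "O2H": "HO2", "O3H": "HO3", "O4H": "HO4", "O5H": "HO5",
}


class IOError_(ValueError):
    """Raised for malformed input files."""


def _canonical(name: str) -> str:
    name = name.strip()
    return ATOM_ALIASES.get(name, name)


def read_structure(
    path: str | Path,
    molecule: str | AlditolTopology,
    strict: bool = True,
) -> Conformation:
    """Read a single pentitol conformation from a PDB file.

    Atom names are matched to the topology through an alias table; water
    residues are skipped.  With `strict` every topology atom must be
    present; otherwise missing hydrogens are rejected only if backbone
    atoms are absent.
    """
    topo = (
        molecule
        if isinstance(molecule, AlditolTopology)
        else AlditolTopology.from_name(molecule)
    )
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise IOError_(f"cannot parse PDB file {path}: {exc}") from exc
    found: dict[str, np.ndarray] = {}
    unmatched: list[str] = []
    for model in st:
        for chain in model:
            for res in chain:
                if res.name.strip().upper() in WATER_RESIDUES:
                    continue
                for atom in res:
                    name = _canonical(atom.name)
                    if name in topo.atom_names:
                        found[name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    else:
                        unmatched.append(atom.name)
        break  # first model only
    missing = [a for a in topo.atom_names if a not in found]
    if missing:
        raise IOError_(
            f"PDB file {path} lacks atoms {missing}"
            + (f" (unmatched names: {unmatched})" if unmatched else "")
        )
    coords = np.stack([found[a] for a in topo.atom_names])
    return Conformation(topo, coords)


def write_structure(conf: Conformation, path: str | Path, resname: str = "ALD") -> None:
    """Write a conformation as a one-residue PDB (HETATM records)."""
    st = gemmi.Structure()
    st.name = conf.topology.name
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    res = gemmi.Residue()
    res.name = resname
    res.seqid = gemmi.SeqId(1, " ")
    res.het_flag = "H"
    for (name, element), xyz in zip(conf.topology.atoms, conf.coords):
        atom = gemmi.Atom()
        atom.name = name
        atom.element = gemmi.Element(element)
        atom.pos = gemmi.Position(*map(float, xyz))
        res.add_atom(atom)
    chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def read_trajectory(
    path: str | Path,
    molecule: str | AlditolTopology,
    fmt: str | None = None,
) -> Trajectory:
    """Read an ordered multi-frame trajectory (XYZ, or DCD via MDAnalysis).

    XYZ frames must all carry the same atoms; atom names are matched to
    the topology (aliases allowed), so column order need not match.
    """
    topo = (
        molecule
        if isinstance(molecule, AlditolTopology)
        else AlditolTopology.from_name(molecule)
    )
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        return _read_xyz(path, topo)
    if fmt == "dcd":
        import MDAnalysis as mda

        u = mda.Universe(str(path), format="DCD", to_guess=())
        if u.atoms.n_atoms != len(topo.atoms):
            raise IOError_(
                f"DCD atom count {u.atoms.n_atoms} != topology ({len(topo.atoms)})"
            )
        coords = np.stack([u.atoms.positions.copy() for _ in u.trajectory])
        return Trajectory(topo, coords.astype(float))
    raise IOError_(f"unsupported trajectory format {fmt!r}")


def _read_xyz(path: Path, topo: AlditolTopology) -> Trajectory:
    text = Path(path).read_text().strip()
    if not text:
        raise IOError_(f"empty trajectory file {path}")
    lines = text.split("\n")
    frames = []
    i = 0
    n_expect = None
    while i < len(lines):
        try:
            n = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise IOError_(f"{path}:{i+1}: expected an atom count") from None
        if n_expect is None:
            n_expect = n
        elif n != n_expect:
            raise IOError_(f"{path}:{i+1}: inconsistent frame size {n} != {n_expect}")
        if i + 1 + n >= len(lines) + 1 and i + 2 + n > len(lines):
            raise IOError_(f"{path}:{i+1}: truncated frame")
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise IOError_(f"{path}:{i+1}: truncated frame")
        coords: dict[str, np.ndarray] = {}
        for k, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise IOError_(f"{path}:{i+3+k}: expected 'name x y z'")
            name = _canonical(parts[0])
            try:
                coords[name] = np.array([float(x) for x in parts[1:4]])
            except ValueError:
                raise IOError_(f"{path}:{i+3+k}: bad coordinate") from None
        missing = [a for a in topo.atom_names if a not in coords]
        if missing:
            raise IOError_(f"{path}:{i+1}: frame lacks atoms {missing}")
        frames.append(np.stack([coords[a] for a in topo.atom_names]))
        i += 2 + n
    return Trajectory(topo, np.stack(frames))


def write_trajectory(traj: Trajectory, path: str | Path, comment: str = "") -> None:
    """Write a trajectory as multi-frame XYZ with atom names."""
    names = traj.topology.atom_names
    with open(path, "w") as fh:
        for f, frame in enumerate(traj.coords):
            fh.write(f"{len(names)}\n")
            fh.write(f"{comment or traj.topology.name} frame {f}\n")
            for name, (x, y, z) in zip(names, frame):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


# --------------------------------------------------------------------------
# tables
# --------------------------------------------------------------------------

def read_couplings_csv(path: str | Path) -> dict[str, CouplingSet]:
    """Read coupling sets: columns molecule, coupling_name, hertz, available."""
    df = pd.read_csv(path)
    required = {"molecule", "coupling_name", "hertz", "available"}
    if not required <= set(df.columns):
        raise IOError_(f"couplings CSV needs columns {sorted(required)}")
    out: dict[str, CouplingSet] = {}
    for mol, grp in df.groupby("molecule", sort=False):
        values = {
            str(r["coupling_name"]): (
                float(r["hertz"]) if str(r["available"]).lower() in ("yes", "true", "1") else None
            )
            for _, r in grp.iterrows()
        }
        out[str(mol)] = CouplingSet(str(mol), values)
    return out


def read_exsy_csv(path: str | Path, site: str = "OH") -> ExsyDataset:
    """Read an EXSY build-up table: mixing_time_s, diagonal, cross[, sigma]."""
    df = pd.read_csv(path)
    required = {"mixing_time_s", "diagonal", "cross"}
    if not required <= set(df.columns):
        raise IOError_(f"EXSY CSV needs columns {sorted(required)}")
    sigma = df["sigma"].to_numpy(float) if "sigma" in df.columns else None
    return ExsyDataset(
        site,
        df["mixing_time_s"].to_numpy(float),
        df["diagonal"].to_numpy(float),
        df["cross"].to_numpy(float),
        sigma,
    )


def read_tempshift_csv(path: str | Path, site: str = "OH") -> TempShiftSeries:
    """Read a variable-temperature shift table: temperature_K, shift_ppm."""
    df = pd.read_csv(path)
    required = {"temperature_K", "shift_ppm"}
    if not required <= set(df.columns):
        raise IOError_(f"temperature CSV needs columns {sorted(required)}")
    return TempShiftSeries(
        site, df["temperature_K"].to_numpy(float), df["shift_ppm"].to_numpy(float)
    )
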