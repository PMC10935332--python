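"""Molecular representation and geometric measurement for acyclic pentitols.

Five-carbon sugar alcohols (ribitol, arabitol, xylitol) share the backbone
HOCH2-(CHOH)3-CH2OH.  Their shape is described by four main-chain dihedral
angles::

    phi1 = O1-C1-C2-C3    phi2 = C1-C2-C3-C4
    phi3 = C2-C3-C4-C5    phi4 = C3-C4-C5-O5

This module provides the :class:`AlditolTopology` (atom graph, stereocentre
configurations, dihedral definitions), an idealized internal-to-Cartesian
conformer builder (sequential NeRF placement), and the geometric
measurements used throughout the package: dihedral angles in the IUPAC sign
convention, distances, angles, and least-squares (Kabsch) superposition
RMSD.

All array routines are batched: coordinate arguments may carry arbitrary
leading axes, so a whole trajectory can be measured in one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GeometryParams",
    "AlditolTopology",
    "Conformation",
    "Trajectory",
    "BUILTIN_MOLECULES",
    "PHI_NAMES",
    "build_conformer",
    "measure_dihedral",
    "measure_distance",
    "measure_angle",
    "superpose_rmsd",
    "dihedral",
    "vector_angle",
    "nerf_place",
    "wrap_angle",
    "kabsch",
    "chirality_label",
    "stereo_configuration",
]

PHI_NAMES = ("phi1", "phi2", "phi3", "phi4")


class GeometryError(ValueError):
    """Raised for degenerate or invalid geometric input."""


# --------------------------------------------------------------------------
# low-level vector geometry (batched over leading axes)
# --------------------------------------------------------------------------

def _unit(v: np.ndarray, axis: int = -1) -> np.ndarray:
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    if np.any(n < 1e-12):
        raise GeometryError("zero-length vector in geometric computation")
    return v / n


def wrap_angle(angle_deg):
    """Wrap an angle (degrees) into the interval (-180, 180]."""
    a = np.asarray(angle_deg, dtype=float)
    w = -np.remainder(-a + 180.0, 360.0) + 180.0  # (-180, 180]
    return w if w.ndim else float(w)


def dihedral(p0, p1, p2, p3) -> np.ndarray | float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC convention.

    Looking from p1 towards p2, a clockwise rotation of the far bond
    relative to the near bond is positive.  Returned values lie in
    (-180, 180].
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.any(np.linalg.norm(n1, axis=-1) < 1e-10) or np.any(
        np.linalg.norm(n2, axis=-1) < 1e-10
    ):
        raise GeometryError("collinear atoms: dihedral angle is undefined")
    m1 = np.cross(n1, _unit(b2))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    return wrap_angle(ang)


def vector_angle(p0, p1, p2) -> np.ndarray | float:
    """Angle at p1 between p0 and p2, in degrees, in [0, 180]."""
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    u = _unit(p0 - p1)
    v = _unit(p2 - p1)
    c = np.clip(np.sum(u * v, axis=-1), -1.0, 1.0)
    ang = np.degrees(np.arccos(c))
    return ang if ang.ndim else float(ang)


def nerf_place(a, b, c, bond, angle_deg, torsion_deg) -> np.ndarray:
    """Place atom D bonded to C such that angle(B,C,D) = `angle_deg` and
    dihedral(A,B,C,D) = `torsion_deg` (natural extension reference frame).

    `a`, `b`, `c` may have leading batch axes; `bond`, `angle_deg` and
    `torsion_deg` broadcast against them.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    batch = np.broadcast_shapes(
        a.shape[:-1], np.shape(bond), np.shape(angle_deg), np.shape(torsion_deg)
    )
    bond = np.broadcast_to(np.asarray(bond, dtype=float), batch)[..., None]
    theta = np.radians(np.broadcast_to(np.asarray(angle_deg, dtype=float), batch))[..., None]
    tau = np.radians(np.broadcast_to(np.asarray(torsion_deg, dtype=float), batch))[..., None]
    a, b, c = (np.broadcast_to(p, batch + (3,)) for p in (a, b, c))

    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    # local displacement in the (bc, m, n) frame
    d_local = bond * np.concatenate(
        [-np.cos(theta), np.sin(theta) * np.cos(tau), -np.sin(theta) * np.sin(tau)],
        axis=-1,
    )
    # assemble: d = c + x*bc + y*m + z*n
    return (
        c
        + d_local[..., 0:1] * bc
        + d_local[..., 1:2] * m
        + d_local[..., 2:3] * n
    )


def kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rigid superposition of `mobile` onto `reference`.

    Returns ``(rmsd, rotation, translation)`` such that
    ``mobile @ rotation.T + translation`` is least-squares closest to
    `reference`.  Both inputs are (n, 3) arrays over the same atoms.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError("superposition requires matching (n, 3) arrays")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    t = qc - pc @ R.T
    return rmsd, R, t


# --------------------------------------------------------------------------
# parameters and topology
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GeometryParams:
    """Idealized internal coordinates used to realize conformers in 3D.

    Crystal structures of pentitols are not redetermined here; standard
    bond lengths and angles stand in for them.  All lengths in Angstrom,
    angles in degrees.
    """

    r_cc: float = 1.53
    r_co: float = 1.43
    r_oh: float = 0.97
    r_ch: float = 1.09
    ang_ccc: float = 112.0
    ang_cco: float = 109.5
    ang_cch: float = 109.5
    ang_coh: float = 109.5
    ang_hch: float = 109.5  # retained for completeness; methylene H's are
    # placed at +/-120 deg torsions, which fixes H-C-H implicitly

    def __post_init__(self):
        for name in ("r_cc", "r_co", "r_oh", "r_ch"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"bond length {name} must be positive")
        for name in ("ang_ccc", "ang_cco", "ang_cch", "ang_coh", "ang_hch"):
            v = getattr(self, name)
            if not 0.0 < v < 180.0:
                raise GeometryError(f"angle {name} must lie in (0, 180)")


#: canonical atom order for pentitols (backbone, oxygens, CH hydrogens, OH hydrogens)
PENTITOL_ATOMS: tuple[tuple[str, str], ...] = tuple(
    [(f"C{i}", "C") for i in range(1, 6)]
    + [(f"O{i}", "O") for i in range(1, 6)]
    + [
        ("H1R", "H"),
        ("H1S", "H"),
        ("H2", "H"),
        ("H3", "H"),
        ("H4", "H"),
        ("H5R", "H"),
        ("H5S", "H"),
    ]
    + [(f"HO{i}", "H") for i in range(1, 6)]
)

PENTITOL_BONDS: tuple[tuple[str, str], ...] = tuple(
    [(f"C{i}", f"C{i+1}") for i in range(1, 5)]
    + [(f"C{i}", f"O{i}") for i in range(1, 6)]
    + [(f"O{i}", f"HO{i}") for i in range(1, 6)]
    + [
        ("C1", "H1R"),
        ("C1", "H1S"),
        ("C2", "H2"),
        ("C3", "H3"),
        ("C4", "H4"),
        ("C5", "H5R"),
        ("C5", "H5S"),
    ]
)

DIHEDRAL_DEFS: dict[str, tuple[str, str, str, str]] = {
    "phi1": ("O1", "C1", "C2", "C3"),
    "phi2": ("C1", "C2", "C3", "C4"),
    "phi3": ("C2", "C3", "C4", "C5"),
    "phi4": ("C3", "C4", "C5", "O5"),
}

#: hydroxyl torsion reference atoms: torsion(ref, C, O, HO) is the input value
HYDROXYL_REFS = {"O1": "C2", "O2": "C3", "O3": "C4", "O4": "C3", "O5": "C4"}

#: Fischer-projection configurations of the built-in molecules at C2-C4.
#: d-arabitol carries the standard numbering (C1 = the former aldehyde
#: carbon of d-arabinose).  Ribitol and xylitol are meso, so the two chain
#: ends are interchangeable; here they are numbered from the end that makes
#: C2 Fischer-'l', which is the frame the solution-NMR work on these
#: compounds uses (it pairs the printed prochiral couplings with the
#: backbone rotamer states as published).  The opposite numbering describes
#: the same molecule with all backbone torsions negated.
BUILTIN_MOLECULES: dict[str, dict[str, str]] = {
    "ribitol": {"C2": "l", "C3": "l", "C4": "l"},
    "d-arabitol": {"C2": "l", "C3": "d", "C4": "d"},
    "l-arabitol": {"C2": "d", "C3": "l", "C4": "l"},
    "xylitol": {"C2": "l", "C3": "d", "C4": "l"},
}


@dataclass(frozen=True)
class AlditolTopology:
    """Atom graph, stereochemistry and dihedral definitions of a pentitol."""

    name: str
    stereo: Mapping[str, str]
    atoms: tuple[tuple[str, str], ...] = PENTITOL_ATOMS
    bonds: tuple[tuple[str, str], ...] = PENTITOL_BONDS
    dihedral_defs: Mapping[str, tuple[str, str, str, str]] = field(
        default_factory=lambda: dict(DIHEDRAL_DEFS)
    )
    prochiral_labels: Mapping[str, str] = field(
        default_factory=lambda: {
            "H1R": "pro-R",
            "H1S": "pro-S",
            "H5R": "pro-R",
            "H5S": "pro-S",
        }
    )

    def __post_init__(self):
        names = [a for a, _ in self.atoms]
        if len(set(names)) != len(names):
            raise GeometryError("duplicate atom names in topology")
        carbons = [n for n in names if n.startswith("C")]
        oxygens = [n for n in names if n.startswith("O")]
        if len(carbons) != 5 or len(oxygens) != 5:
            raise GeometryError("pentitol topology requires 5 C and 5 O atoms")
        for centre in ("C2", "C3", "C4"):
            cfg = self.stereo.get(centre)
            if cfg not in ("d", "l"):
                raise GeometryError(
                    f"stereo configuration for {centre} must be 'd' or 'l'"
                )
        nameset = set(names)
        for phi, quad in self.dihedral_defs.items():
            missing = [a for a in quad if a not in nameset]
            if missing:
                raise GeometryError(f"{phi} references unknown atoms {missing}")

    @classmethod
    def from_name(cls, name: str) -> "AlditolTopology":
        key = name.lower().replace("_", "-")
        if key not in BUILTIN_MOLECULES:
            raise GeometryError(
                f"unknown molecule {name!r}; built-ins: {sorted(BUILTIN_MOLECULES)}"
            )
        return cls(name=key, stereo=dict(BUILTIN_MOLECULES[key]))

    @property
    def atom_names(self) -> tuple[str, ...]:
        return tuple(a for a, _ in self.atoms)

    def index(self, atom: str) -> int:
        try:
            return self.atom_names.index(atom)
        except ValueError:
            raise GeometryError(f"unknown atom name {atom!r}") from None

    def mirror(self) -> "AlditolTopology":
        """Topology of the enantiomer (all stereocentres inverted)."""
        flipped = {c: ("l" if s == "d" else "d") for c, s in self.stereo.items()}
        return replace(self, name=f"ent-{self.name}", stereo=flipped)


@dataclass
class Conformation:
    """Single 3D realization of a topology (coordinates in Angstrom)."""

    topology: AlditolTopology
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.topology.atoms), 3):
            raise GeometryError(
                f"coordinate array must be ({len(self.topology.atoms)}, 3)"
            )
        if not np.all(np.isfinite(self.coords)):
            raise GeometryError("non-finite coordinates")

    def xyz(self, atom: str) -> np.ndarray:
        return self.coords[self.topology.index(atom)]


@dataclass
class Trajectory:
    """Ordered frames sharing one topology.

    `coords` has shape (n_frames, n_atoms, 3); `frame_interval` is an
    arbitrary time unit and is optional metadata.
    """

    topology: AlditolTopology
    coords: np.ndarray
    frame_interval: float | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if (
            self.coords.ndim != 3
            or self.coords.shape[0] < 1
            or self.coords.shape[1:] != (len(self.topology.atoms), 3)
        ):
            raise GeometryError(
                "trajectory coordinates must be (n_frames >= 1, n_atoms, 3)"
            )

    def __len__(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Conformation:
        return Conformation(self.topology, self.coords[i])

    def __iter__(self):
        for i in range(len(self)):
            yield self.frame(i)


# --------------------------------------------------------------------------
# conformer construction
# --------------------------------------------------------------------------

# Sign conventions fixed by calibration against CIP assignments (see tests):
# a stereocentre Ci carries its oxygen at torsion phi +/- 120 deg from the
# backbone reference; _STEREO_PARITY maps the Fischer 'd' label to that sign
# in each centre's local placement frame so that same-Fischer-side oxygens
# at Ci/Ci+2 are parallel in the all-trans chain (Jeffrey's rule geometry).
_STEREO_PARITY = {"C2": 1.0, "C3": 1.0, "C4": -1.0}
_GLOBAL_HAND = 1.0
# The methylene hydrogen named H1R (H5R) sits at this multiple of +120 deg
# from the terminal oxygen within the C1 (C5) rotor frame.  The R/S naming
# follows the stereospecific assignments of the alditol solution-NMR
# literature, whose published coupling analyses these positions reproduce
# quantitatively; note that CIP software applied to the idealized
# geometries labels the two positions the other way around (see the methods
# note and the stereochemistry tests, which pin both facts).
_PROCHIRAL_SIGN = {"C1": -1.0, "C5": -1.0}


def _stereo_sign(topology: AlditolTopology, centre: str) -> float:
    cfg = 1.0 if topology.stereo[centre] == "d" else -1.0
    return _GLOBAL_HAND * _STEREO_PARITY[centre] * cfg


def build_frames(
    topology: AlditolTopology,
    phis: np.ndarray,
    hydroxyl_torsions: np.ndarray | None = None,
    params: GeometryParams | None = None,
) -> np.ndarray:
    """Vectorized internal-to-Cartesian construction.

    `phis` is (..., 4) in degrees, ordered phi1..phi4; `hydroxyl_torsions`
    is (..., 5) for HO1..HO5 (default: all anti, 180 deg).  Returns
    coordinates of shape (..., 22, 3) in the canonical atom order.
    """
    p = params or GeometryParams()
    phis = np.asarray(phis, dtype=float)
    if phis.shape[-1] != 4:
        raise GeometryError("phis must have last dimension 4 (phi1..phi4)")
    batch = phis.shape[:-1]
    if hydroxyl_torsions is None:
        oh = np.full(batch + (5,), 180.0)
    else:
        oh = np.asarray(hydroxyl_torsions, dtype=float)
        if oh.shape != batch + (5,):
            raise GeometryError("hydroxyl_torsions must be (..., 5)")

    phi1, phi2, phi3, phi4 = (phis[..., i] for i in range(4))
    pos: dict[str, np.ndarray] = {}

    zeros = np.zeros(batch + (3,))
    pos["C1"] = zeros
    pos["C2"] = zeros + np.array([p.r_cc, 0.0, 0.0])
    a = np.radians(180.0 - p.ang_ccc)
    pos["C3"] = pos["C2"] + p.r_cc * np.array([np.cos(a), np.sin(a), 0.0])

    pos["C4"] = nerf_place(pos["C1"], pos["C2"], pos["C3"], p.r_cc, p.ang_ccc, phi2)
    pos["C5"] = nerf_place(pos["C2"], pos["C3"], pos["C4"], p.r_cc, p.ang_ccc, phi3)

    pos["O1"] = nerf_place(pos["C3"], pos["C2"], pos["C1"], p.r_co, p.ang_cco, phi1)
    pos["O5"] = nerf_place(pos["C3"], pos["C4"], pos["C5"], p.r_co, p.ang_cco, phi4)

    s2 = _stereo_sign(topology, "C2")
    s3 = _stereo_sign(topology, "C3")
    s4 = _stereo_sign(topology, "C4")

    # C2 substituents, placed via torsion(X, C2, C3, C4) == torsion(C4,C3,C2,X)
    pos["O2"] = nerf_place(
        pos["C4"], pos["C3"], pos["C2"], p.r_co, p.ang_cco, phi2 + s2 * 120.0
    )
    pos["H2"] = nerf_place(
        pos["C4"], pos["C3"], pos["C2"], p.r_ch, p.ang_cch, phi2 - s2 * 120.0
    )
    # C3 substituents via torsion(C5, C4, C3, X)
    pos["O3"] = nerf_place(
        pos["C5"], pos["C4"], pos["C3"], p.r_co, p.ang_cco, phi3 + s3 * 120.0
    )
    pos["H3"] = nerf_place(
        pos["C5"], pos["C4"], pos["C3"], p.r_ch, p.ang_cch, phi3 - s3 * 120.0
    )
    # C4 substituents via torsion(C2, C3, C4, X); torsion(C2,C3,C4,C5) = phi3
    pos["O4"] = nerf_place(
        pos["C2"], pos["C3"], pos["C4"], p.r_co, p.ang_cco, phi3 + s4 * 120.0
    )
    pos["H4"] = nerf_place(
        pos["C2"], pos["C3"], pos["C4"], p.r_ch, p.ang_cch, phi3 - s4 * 120.0
    )

    # terminal methylene hydrogens share the O1 (O5) rotor frame
    pr1 = _PROCHIRAL_SIGN["C1"]
    pr5 = _PROCHIRAL_SIGN["C5"]
    pos["H1R"] = nerf_place(
        pos["C3"], pos["C2"], pos["C1"], p.r_ch, p.ang_cch, phi1 + pr1 * 120.0
    )
    pos["H1S"] = nerf_place(
        pos["C3"], pos["C2"], pos["C1"], p.r_ch, p.ang_cch, phi1 - pr1 * 120.0
    )
    pos["H5R"] = nerf_place(
        pos["C3"], pos["C4"], pos["C5"], p.r_ch, p.ang_cch, phi4 + pr5 * 120.0
    )
    pos["H5S"] = nerf_place(
        pos["C3"], pos["C4"], pos["C5"], p.r_ch, p.ang_cch, phi4 - pr5 * 120.0
    )

    for i, oxy in enumerate(("O1", "O2", "O3", "O4", "O5")):
        ref = HYDROXYL_REFS[oxy]
        carbon = f"C{i+1}"
        pos[f"HO{i+1}"] = nerf_place(
            pos[ref], pos[carbon], pos[oxy], p.r_oh, p.ang_coh, oh[..., i]
        )

    order = [a for a, _ in topology.atoms]
    return np.stack([pos[a] for a in order], axis=-2)


def build_conformer(
    topology: AlditolTopology,
    dihedrals: Mapping[str, float],
    hydroxyl_torsions: Mapping[str, float] | None = None,
    params: GeometryParams | None = None,
) -> Conformation:
    """Build one idealized conformer from main-chain dihedrals.

    `dihedrals` must supply phi1..phi4 (degrees, in (-180, 180]);
    `hydroxyl_torsions` optionally overrides per-hydroxyl H torsions
    (keys 'O1'..'O5'; default anti, 180 deg).
    """
    missing = [k for k in PHI_NAMES if k not in dihedrals]
    if missing:
        raise GeometryError(f"missing dihedral(s): {', '.join(missing)}")
    phis = np.array([float(dihedrals[k]) for k in PHI_NAMES])
    oh = np.full(5, 180.0)
    if hydroxyl_torsions:
        for key, val in hydroxyl_torsions.items():
            if key not in ("O1", "O2", "O3", "O4", "O5"):
                raise GeometryError(f"unknown hydroxyl key {key!r}")
            oh[int(key[1]) - 1] = float(val)
    coords = build_frames(topology, phis, oh, params)
    return Conformation(topology, coords)


# --------------------------------------------------------------------------
# measurements
# --------------------------------------------------------------------------

def measure_dihedral(conf: Conformation, quad: Sequence[str]) -> float:
    """Dihedral angle (degrees, (-180, 180]) over four named atoms."""
    if len(quad) != 4:
        raise GeometryError("dihedral requires exactly four atom names")
    pts = [conf.xyz(a) for a in quad]
    return float(dihedral(*pts))


def measure_distance(conf: Conformation, pair: Sequence[str]) -> float:
    """Euclidean distance (Angstrom) between two named atoms."""
    if len(pair) != 2:
        raise GeometryError("distance requires exactly two atom names")
    return float(np.linalg.norm(conf.xyz(pair[0]) - conf.xyz(pair[1])))


def measure_angle(conf: Conformation, triple: Sequence[str]) -> float:
    """Bond angle (degrees) over three named atoms."""
    if len(triple) != 3:
        raise GeometryError("angle requires exactly three atom names")
    return float(vector_angle(*(conf.xyz(a) for a in triple)))


def superpose_rmsd(
    mobile: Conformation,
    reference: Conformation,
    selection: Iterable[str] | None = None,
):
    """Least-squares RMSD after optimal rigid (Kabsch) superposition.

    Returns ``(rmsd, rotation, translation)``.  `selection` restricts the
    fit and the deviation to the named atoms (default: all atoms).
    """
    if mobile.topology.atom_names != reference.topology.atom_names:
        raise GeometryError("superposition requires identical atom sets")
    if selection is None:
        idx = slice(None)
    else:
        names = list(selection)
        if not names:
            raise GeometryError("empty atom selection")
        idx = [mobile.topology.index(a) for a in names]
    return kabsch(mobile.coords[idx], reference.coords[idx])


# --------------------------------------------------------------------------
# chirality
# --------------------------------------------------------------------------

def chirality_label(centre, p1, p2, p3, p4) -> str:
    """CIP rotation label from 3D positions given priority order p1 > p2 > p3 > p4.

    Returns 'R' or 'S'.  Calibrated against reference CIP assignments of
    small chiral molecules (see test suite).
    """
    centre, p1, p2, p3, p4 = (np.asarray(x, dtype=float) for x in (centre, p1, p2, p3, p4))
    v = np.cross(p1 - p4, p2 - p4) @ (p3 - p4)
    if abs(v) < 1e-10:
        raise GeometryError("degenerate (planar) stereocentre")
    return "R" if v < 0 else "S"


_CENTRE_NEIGHBOURS = {
    "C2": ("O2", "C3", "C1", "H2"),
    "C3": ("O3", "C2", "C4", "H3"),  # C2/C4 priority resolved geometrically below
    "C4": ("O4", "C3", "C5", "H4"),
}


def stereo_configuration(conf: Conformation) -> dict[str, str]:
    """Re-derive Fischer d/l labels of C2-C4 from 3D coordinates.

    Inverse of the builder's placement rule; used to verify that a built
    conformer carries the chirality its topology declares.
    """
    out: dict[str, str] = {}
    for centre in ("C2", "C3", "C4"):
        i = int(centre[1])
        # improper torsion O(i)-C(i) | C(i+1)->C(i-1): +120 deg for a Fischer
        # 'd' centre, -120 deg for 'l', independent of the backbone conformation
        tau = dihedral(
            conf.xyz(f"O{i}"),
            conf.xyz(centre),
            conf.xyz(f"C{i+1}"),
            conf.xyz(f"C{i-1}"),
        )
        out[centre] = "d" if tau > 0 else "l"
    return out
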