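"""Vicinal coupling prediction and three-state rotamer population inversion.

A C-C bond of an acyclic polyol is modelled as hopping between the three
staggered rotamers (trans = 180 deg, gauche- = -60 deg, gauche+ = +60 deg).
Observed vicinal couplings are population-weighted averages over those
states, so with predicted per-state couplings J_s the populations p solve

    min || M p - J_obs ||^2   subject to   p >= 0,  sum p = 1

where M[i, s] is the coupling of observable i in state s.

Per-state couplings are predicted with generalized Karplus equations:

* 3J(H,H): the Haasnoot-Leeuw-Altona (HLA) equation with substituent
  electronegativity and orientation corrections,

      J = P1 cos^2(phi) + P2 cos(phi) + P3
          + sum_i dchi_i [ P4 + P5 cos^2(xi_i phi + P6 |dchi_i|) ]

* 3J(C,H): a plain cosine Karplus form  A cos^2(theta) + B cos(theta) + C.

Crucially, the dihedral angle entering each Karplus form is *measured on an
idealized 3D conformer* built with the backbone dihedral fixed at the state
centre, so all stereochemical offsets between the oxygen-defined backbone
angle and the H-C-C-H / C-C-C-H coupling paths come from geometry, never
from hardcoded tables.  Substituent orientation factors xi are likewise
read off the conformer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .geometry import (
    AlditolTopology,
    Conformation,
    GeometryParams,
    PHI_NAMES,
    build_conformer,
    dihedral,
    wrap_angle,
)

__all__ = [
    "KarplusParams",
    "CouplingSet",
    "RotamerPopulations",
    "StateCouplingMatrix",
    "ROTAMER_STATES",
    "haasnoot_j",
    "ch_karplus_j",
    "predict_state_couplings",
    "invert_populations",
    "phi_populations",
    "NotDeterminableError",
]

#: rotamer state centres in degrees, fixed column order used everywhere
ROTAMER_STATES: tuple[float, float, float] = (180.0, -60.0, 60.0)
STATE_LABELS = ("trans", "gauche-", "gauche+")


class CouplingError(ValueError):
    pass


class NotDeterminableError(CouplingError):
    """Raised when the couplings needed for a site are unavailable (N.D.)."""


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

#: HLA coefficient sets (P1..P6) keyed by the number of non-hydrogen
#: substituents on the H-C-C-H fragment (Haasnoot/de Leeuw/Altona fits).
_HLA_SETS: dict[int, tuple[float, ...]] = {
    2: (13.70, -0.73, 0.0, 0.56, -2.47, 16.9),
    3: (13.22, -0.99, 0.0, 0.87, -2.46, 19.9),
    4: (13.24, -0.91, 0.0, 0.53, -2.41, 15.5),
}

#: Huggins electronegativity differences vs hydrogen for alpha atoms
_HUGGINS_DCHI: dict[str, float] = {"H": 0.0, "C": 0.40, "N": 0.85, "O": 1.30}


@dataclass(frozen=True)
class KarplusParams:
    """Coefficients for the HLA 3J(H,H) and cosine 3J(C,H) equations.

    ``hh_sets`` maps substituent count (2-4) to (P1..P6).  ``dchi`` holds
    per-element Huggins electronegativity differences versus H, and
    ``beta_correction`` is the group-electronegativity attenuation
    dchi_group = dchi_alpha - beta_correction * sum(dchi_beta).

    ``ch`` holds (A, B, C) of 3J(C,H) = A cos^2 + B cos + C along a
    C-C-C-H path.  The default is an aliphatic-carbohydrate
    parameterization with a trans coupling near 9 Hz.
    """

    hh_sets: Mapping[int, tuple[float, ...]] = field(
        default_factory=lambda: dict(_HLA_SETS)
    )
    dchi: Mapping[str, float] = field(default_factory=lambda: dict(_HUGGINS_DCHI))
    beta_correction: float = 0.14
    ch: tuple[float, float, float] = (8.06, -0.87, 0.47)
    provenance: str = "HLA 1980 sets; Huggins electronegativities; CCCH cosine fit"

    def __post_init__(self):
        if not self.provenance:
            raise CouplingError("provenance label must be non-empty")
        for n, coeffs in self.hh_sets.items():
            if len(coeffs) != 6:
                raise CouplingError(f"HLA set for {n} substituents needs P1..P6")
        if len(self.ch) != 3:
            raise CouplingError("ch coefficients must be (A, B, C)")

    def hh_coefficients(self, n_substituents: int) -> tuple[float, ...]:
        try:
            return tuple(self.hh_sets[n_substituents])
        except KeyError:
            raise CouplingError(
                f"no HLA parameter set for {n_substituents} substituents"
            ) from None

    @classmethod
    def from_file(cls, path) -> "KarplusParams":
        """Load coefficients from a key-value text file.

        Lines are ``key = values`` with ``#`` comments; recognized keys:
        ``ch`` (A B C), ``hh2``/``hh3``/``hh4`` (P1..P6), ``dchi_<El>``,
        ``beta_correction``, ``provenance``.  Unspecified keys keep their
        defaults.
        """
        hh = dict(_HLA_SETS)
        dchi = dict(_HUGGINS_DCHI)
        ch = cls.ch
        beta = cls.beta_correction
        provenance = None
        for raw in open(path):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise CouplingError(f"malformed parameter line: {raw.rstrip()!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key == "provenance":
                provenance = val
            elif key == "ch":
                ch = tuple(float(x) for x in val.split())
            elif key.startswith("hh") and key[2:].isdigit():
                hh[int(key[2:])] = tuple(float(x) for x in val.split())
            elif key.startswith("dchi_"):
                dchi[key[5:]] = float(val)
            elif key == "beta_correction":
                beta = float(val)
            else:
                raise CouplingError(f"unknown parameter key {key!r}")
        return cls(
            hh_sets=hh,
            dchi=dchi,
            beta_correction=beta,
            ch=ch,
            provenance=provenance or f"loaded from {path}",
        )

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# provenance: {self.provenance}\n")
            fh.write(f"provenance = {self.provenance}\n")
            fh.write("ch = " + " ".join(f"{x:g}" for x in self.ch) + "\n")
            for n, coeffs in sorted(self.hh_sets.items()):
                fh.write(f"hh{n} = " + " ".join(f"{x:g}" for x in coeffs) + "\n")
            for el, v in sorted(self.dchi.items()):
                fh.write(f"dchi_{el} = {v:g}\n")
            fh.write(f"beta_correction = {self.beta_correction:g}\n")


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

KNOWN_COUPLINGS = (
    "3J(H1R,H2)",
    "3J(H1S,H2)",
    "3J(H2,H3)",
    "3J(H3,H4)",
    "3J(H4,H5R)",
    "3J(H4,H5S)",
    "2J(H1R,H1S)",
    "2J(H5R,H5S)",
    "3J(C1,H3)",
    "3J(C3,H1S)",
    "3J(C3,H1R)",
    "3J(C3,H5)",
    "3J(C5,H2)",
)


@dataclass
class CouplingSet:
    """Named J-couplings (Hz) of one molecule; ``None`` marks N.D. entries."""

    molecule: str
    values: dict[str, float | None]

    def __post_init__(self):
        for name, v in self.values.items():
            if v is None:
                continue
            if name.startswith("3J") and not 0.0 <= v <= 15.0:
                raise CouplingError(f"{name}={v} Hz outside [0, 15]")
            if name.startswith("2J") and v >= 0.0:
                raise CouplingError(f"geminal {name}={v} Hz must be negative")

    def get(self, name: str) -> float | None:
        return self.values.get(name)

    def require(self, name: str) -> float:
        v = self.values.get(name)
        if v is None:
            raise NotDeterminableError(
                f"{self.molecule}: coupling {name} not determined"
            )
        return v


@dataclass
class RotamerPopulations:
    """Probabilities of the trans / gauche- / gauche+ states of one bond."""

    p_trans: float
    p_gauche_minus: float
    p_gauche_plus: float
    residual: float | None = None

    def __post_init__(self):
        arr = self.as_array()
        if np.any(arr < -1e-9) or np.any(arr > 1 + 1e-9):
            raise CouplingError("populations must lie in [0, 1]")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise CouplingError("populations must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_trans, self.p_gauche_minus, self.p_gauche_plus])

    def percentages(self) -> tuple[int, int, int]:
        """Integer percentages for reporting (rounded, as printed in tables)."""
        return tuple(int(round(100 * p)) for p in self.as_array())


@dataclass
class StateCouplingMatrix:
    """Predicted couplings (Hz): rows = observables, columns = rotamer states."""

    observables: tuple[str, ...]
    matrix: np.ndarray  # shape (n_obs, 3), column order ROTAMER_STATES

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.observables), 3):
            raise CouplingError("matrix shape must be (n_observables, 3)")
        if not np.all(np.isfinite(self.matrix)):
            raise CouplingError("non-finite predicted couplings")

    def forward(self, populations: np.ndarray | RotamerPopulations) -> np.ndarray:
        p = (
            populations.as_array()
            if isinstance(populations, RotamerPopulations)
            else np.asarray(populations, dtype=float)
        )
        return self.matrix @ p


# --------------------------------------------------------------------------
# Karplus equations
# --------------------------------------------------------------------------

def haasnoot_j(
    dihedral_hh: float,
    substituents: Sequence[tuple[float, float]],
    params: KarplusParams | None = None,
) -> float:
    """HLA generalized Karplus 3J(H,H) in Hz.

    `substituents` lists (dchi, xi) for every non-hydrogen substituent on
    the H-C-C-H fragment; xi is +1 or -1 (orientation sign factor).
    """
    params = params or KarplusParams()
    p1, p2, p3, p4, p5, p6 = params.hh_coefficients(max(len(substituents), 2))
    phi = np.radians(float(dihedral_hh))
    j = p1 * np.cos(phi) ** 2 + p2 * np.cos(phi) + p3
    for dchi, xi in substituents:
        if xi not in (-1.0, 1.0, -1, 1):
            raise CouplingError("xi orientation factors must be +1 or -1")
        j += dchi * (
            p4 + p5 * np.cos(np.radians(xi * float(dihedral_hh) + p6 * abs(dchi))) ** 2
        )
    return float(j)


def ch_karplus_j(dihedral_ch: float, params: KarplusParams | None = None) -> float:
    """Cosine Karplus 3J(C,H) in Hz along a C-C-C-H path."""
    params = params or KarplusParams()
    a, b, c = params.ch
    th = np.radians(float(dihedral_ch))
    return float(a * np.cos(th) ** 2 + b * np.cos(th) + c)


# --------------------------------------------------------------------------
# fragment analysis on built conformers
# --------------------------------------------------------------------------

def _parse_coupling(name: str) -> tuple[str, str, str]:
    """Return (kind, atom_a, atom_b) for a name like '3J(H1R,H2)'."""
    if not (name.startswith(("2J(", "3J(")) and name.endswith(")")):
        raise CouplingError(f"cannot parse coupling name {name!r}")
    kind = name[:2]
    a, b = name[3:-1].split(",")
    return kind, a.strip(), b.strip()


def _host_carbon(topology: AlditolTopology, atom: str) -> str:
    """Backbone carbon bonded to the given H (or the atom itself if a carbon)."""
    if atom.startswith("C"):
        return atom
    for b1, b2 in topology.bonds:
        if b1 == atom and b2.startswith("C"):
            return b2
        if b2 == atom and b1.startswith("C"):
            return b1
    raise CouplingError(f"no backbone carbon bonded to {atom}")


def _neighbours(topology: AlditolTopology, atom: str) -> list[str]:
    out = []
    for b1, b2 in topology.bonds:
        if b1 == atom:
            out.append(b2)
        elif b2 == atom:
            out.append(b1)
    return out


def _element(topology: AlditolTopology, atom: str) -> str:
    for name, el in topology.atoms:
        if name == atom:
            return el
    raise CouplingError(f"unknown atom {atom!r}")


def _group_dchi(topology: AlditolTopology, sub: str, host: str, params: KarplusParams) -> float:
    """Group electronegativity: alpha atom minus attenuated beta atoms."""
    alpha = params.dchi.get(_element(topology, sub), 0.0)
    beta = sum(
        params.dchi.get(_element(topology, b), 0.0)
        for b in _neighbours(topology, sub)
        if b != host
    )
    return alpha - params.beta_correction * beta


def _hh_coupling_from_conformer(
    conf: Conformation, h_a: str, h_b: str, params: KarplusParams
) -> float:
    """Evaluate the HLA equation for an H-C-C-H fragment of a 3D conformer.

    The coupling dihedral, the substituent list and every orientation sign
    xi are measured from the coordinates.
    """
    topo = conf.topology
    c_a = _host_carbon(topo, h_a)
    c_b = _host_carbon(topo, h_b)
    theta = float(
        dihedral(conf.xyz(h_a), conf.xyz(c_a), conf.xyz(c_b), conf.xyz(h_b))
    )
    subs: list[tuple[float, float]] = []
    for host, path_atom, on_first in (
        (c_a, h_a, True),
        (c_b, h_b, False),
    ):
        other_c = c_b if on_first else c_a
        for sub in _neighbours(topo, host):
            if sub in (path_atom, other_c):
                continue
            if _element(topo, sub) == "H":
                continue  # dchi = 0, no contribution
            if on_first:
                tau = float(
                    dihedral(conf.xyz(sub), conf.xyz(c_a), conf.xyz(c_b), conf.xyz(h_b))
                )
            else:
                tau = float(
                    dihedral(conf.xyz(h_a), conf.xyz(c_a), conf.xyz(c_b), conf.xyz(sub))
                )
            delta = wrap_angle(tau - theta)
            xi = 1.0 if delta < 0 else -1.0
            subs.append((_group_dchi(topo, sub, host, params), xi))
    return haasnoot_j(theta, subs, params)


def _ch_coupling_from_conformer(
    conf: Conformation, carbon: str, proton: str, params: KarplusParams
) -> float:
    """3J(C,H) over C-C-C-H measured on the conformer."""
    topo = conf.topology
    c_h = _host_carbon(topo, proton)
    # middle carbon: backbone neighbour shared by `carbon` and c_h
    shared = [
        n
        for n in _neighbours(topo, carbon)
        if n.startswith("C") and c_h in _neighbours(topo, n)
    ]
    if not shared:
        raise CouplingError(f"no three-bond C-C-C-H path {carbon}..{proton}")
    mid = shared[0]
    theta = float(
        dihedral(conf.xyz(carbon), conf.xyz(mid), conf.xyz(c_h), conf.xyz(proton))
    )
    return ch_karplus_j(theta, params)


#: observables usable for each backbone site
SITE_OBSERVABLES = {
    "phi1": ("3J(H1R,H2)", "3J(H1S,H2)"),
    "phi2": ("3J(H2,H3)", "3J(C1,H3)"),
}


def predict_state_couplings(
    topology: AlditolTopology,
    phi: str,
    observables: Sequence[str],
    params: KarplusParams | None = None,
    geometry_params: GeometryParams | None = None,
) -> StateCouplingMatrix:
    """Predict each observable in the three staggered rotamers of one bond.

    For every state the idealized conformer is built with the site dihedral
    at the state centre (other backbone dihedrals anti) and the matching
    Karplus form is evaluated on the measured coupling-path dihedral.
    """
    params = params or KarplusParams()
    if phi not in ("phi1", "phi2"):
        raise CouplingError("population analysis supports phi1 or phi2 sites")
    if len(observables) < 1:
        raise CouplingError("at least one observable required")
    rows = []
    for state in ROTAMER_STATES:
        phis = {name: 180.0 for name in PHI_NAMES}
        phis[phi] = state
        conf = build_conformer(topology, phis, params=geometry_params)
        col = []
        for obs in observables:
            kind, a, b = _parse_coupling(obs)
            if kind != "3J":
                raise CouplingError(f"{obs}: only vicinal couplings are predicted")
            if a.startswith("H") and b.startswith("H"):
                col.append(_hh_coupling_from_conformer(conf, a, b, params))
            elif a.startswith("C") and b.startswith("H"):
                col.append(_ch_coupling_from_conformer(conf, a, b, params))
            else:
                raise CouplingError(f"unsupported coupling type {obs!r}")
        rows.append(col)
    matrix = np.array(rows).T  # (n_obs, 3)
    return StateCouplingMatrix(tuple(observables), matrix)


# --------------------------------------------------------------------------
# inversion
# --------------------------------------------------------------------------

def invert_populations(
    observed: Sequence[float] | Mapping[str, float],
    matrix: StateCouplingMatrix,
) -> RotamerPopulations:
    """Simplex-constrained least-squares inversion of observed couplings.

    Solves min ||M p - J||^2 with p on the probability simplex by exact
    enumeration of active sets (all faces of the 2-simplex); boundary
    solutions therefore come out exactly 0 rather than epsilon-negative.
    Ties are broken towards the trans state.
    """
    if isinstance(observed, Mapping):
        try:
            j_obs = np.array([float(observed[o]) for o in matrix.observables])
        except KeyError as exc:
            raise CouplingError(f"observed couplings missing {exc}") from None
    else:
        j_obs = np.asarray(observed, dtype=float)
    if j_obs.shape != (len(matrix.observables),):
        raise CouplingError("observed couplings must match matrix rows")
    if len(j_obs) < 2:
        raise CouplingError(
            "at least two observed couplings are needed for a three-state inversion"
        )
    M = matrix.matrix
    if np.linalg.matrix_rank(np.vstack([M, np.ones(3)]), tol=1e-8) < 3:
        # all-equal columns cannot distinguish states; report rather than guess
        if np.allclose(M, M[:, [0]]):
            raise CouplingError("state-coupling matrix is rank deficient")

    best: tuple[float, np.ndarray] | None = None
    # subsets ordered so that trans-containing faces win exact ties
    for size in (3, 2, 1):
        for subset in itertools.combinations(range(3), size):
            Ms = M[:, subset]
            # minimize ||Ms q - J|| s.t. sum q = 1 via KKT system
            k = len(subset)
            A = np.zeros((k + 1, k + 1))
            A[:k, :k] = 2.0 * Ms.T @ Ms
            A[:k, k] = 1.0
            A[k, :k] = 1.0
            rhs = np.concatenate([2.0 * Ms.T @ j_obs, [1.0]])
            sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            q = sol[:k]
            if np.any(q < -1e-10):
                continue
            q = np.clip(q, 0.0, None)
            q = q / q.sum()
            p = np.zeros(3)
            p[list(subset)] = q
            res = float(np.linalg.norm(M @ p - j_obs))
            if best is None or res < best[0] - 1e-12:
                best = (res, p)
    assert best is not None  # the full simplex face always yields a candidate
    res, p = best
    return RotamerPopulations(p[0], p[1], p[2], residual=res)


def phi_populations(
    molecule: str | AlditolTopology,
    site: str,
    couplings: CouplingSet,
    params: KarplusParams | None = None,
    geometry_params: GeometryParams | None = None,
) -> RotamerPopulations:
    """Rotamer populations of phi1 or phi2 from a molecule's coupling set.

    phi1 uses the two prochiral 3J(H1R,H2)/3J(H1S,H2) couplings; phi2 uses
    3J(H2,H3) together with 3J(C1,H3).  Missing couplings raise
    :class:`NotDeterminableError` naming the absent observable.
    """
    topology = (
        molecule
        if isinstance(molecule, AlditolTopology)
        else AlditolTopology.from_name(molecule)
    )
    if site not in SITE_OBSERVABLES:
        raise CouplingError(f"unsupported site {site!r}; use phi1 or phi2")
    observables = SITE_OBSERVABLES[site]
    j_obs = [couplings.require(o) for o in observables]
    matrix = predict_state_couplings(
        topology, site, observables, params, geometry_params
    )
    return invert_populations(j_obs, matrix)
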