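"""Synthetic inputs with known ground truth for every pipeline stage.

The study this package models consumed instrument output (NMR spectra) and
100 ns solvated MD trajectories.  At desk scale those are replaced by
generators whose ground truth is exact:

* rotamer-jump trajectories - per-dihedral discrete-state Markov chains
  realized as Cartesian frames through the idealized conformer builder,
  with truncated libration noise so the planted state sequence equals the
  classified sequence by construction;
* planted hydrogen-bond trajectories - frames engineered so that exactly a
  scheduled set of donor->acceptor pairs satisfies the three geometric
  criteria;
* two-site EXSY build-up curves from the exact matrix-exponential solution
  of the magnetization-exchange equations;
* forward-modelled coupling sets (the exact inverse of the population
  inversion);
* the packaged in-study tables (crystal dihedral survey and coupling
  constants) as typed records.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.stats import truncnorm

from .crystal_survey import CrystalRecord, RotamerState, load_crystal_table
from .geometry import (
    AlditolTopology,
    GeometryParams,
    PHI_NAMES,
    Trajectory,
    build_conformer,
    build_frames,
)
from .jcoupling import CouplingSet, RotamerPopulations, StateCouplingMatrix
from .nmr_exchange import ExsyDataset
from .trajectory import HBondCriteria, detect_hbonds

__all__ = [
    "RotamerJumpModel",
    "ExsyModel",
    "simulate_rotamer_trajectory",
    "plant_hbond_frames",
    "simulate_exsy",
    "forward_couplings",
    "packaged_fixtures",
]

#: state order used throughout: trans, gauche-, gauche+
STATE_ORDER = (RotamerState.TRANS, RotamerState.GAUCHE_MINUS, RotamerState.GAUCHE_PLUS)
STATE_CENTRES = np.array([180.0, -60.0, 60.0])
# half-open classification bins, expressed in an unwrapped coordinate per state
_STATE_BOUNDS = {0: (120.0, 240.0), 1: (-120.0, 0.0), 2: (0.0, 120.0)}


@dataclass(frozen=True)
class RotamerJumpModel:
    """Markov rotamer-jump dynamics of the four backbone dihedrals.

    `stationary` maps each dihedral to its target stationary distribution
    over (trans, gauche-, gauche+).  Jumps are resampled from the
    stationary law with probability `jump_probability` per frame, which
    makes the stationary distribution exact by construction.  `sigma_deg`
    is the libration width; samples are truncated to the state's
    classification bin so the planted state is always recovered.
    """

    stationary: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {p: (1 / 3, 1 / 3, 1 / 3) for p in PHI_NAMES}
    )
    jump_probability: float = 0.1
    sigma_deg: float = 10.0
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self):
        for phi in PHI_NAMES:
            pi = np.asarray(self.stationary.get(phi, (1 / 3, 1 / 3, 1 / 3)), dtype=float)
            if pi.shape != (3,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
                raise ValueError(f"stationary law for {phi} must be on the 3-simplex")
        if not 0.0 <= self.jump_probability <= 1.0:
            raise ValueError("jump probability must lie in [0, 1]")
        if self.sigma_deg < 0:
            raise ValueError("libration width must be non-negative")
        if self.sigma_deg > 40.0:
            raise ValueError(
                "libration width too large: truncation to the rotamer bin would "
                "dominate; use sigma_deg <= 40"
            )
        if self.n_frames < 1:
            raise ValueError("need at least one frame")

    def pi(self, phi: str) -> np.ndarray:
        return np.asarray(self.stationary.get(phi, (1 / 3, 1 / 3, 1 / 3)), dtype=float)


def _sample_states(pi: np.ndarray, n: int, jump_p: float, rng: np.random.Generator) -> np.ndarray:
    """Markov chain: with prob jump_p resample the state from pi."""
    draws = rng.choice(3, size=n, p=pi)
    jump = rng.random(n) < jump_p
    jump[0] = True  # initial state from the stationary law
    states = np.empty(n, dtype=np.int64)
    current = draws[0]
    for i in range(n):
        if jump[i]:
            current = draws[i]
        states[i] = current
    return states


def _noisy_angles(states: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """State centres plus truncated-Gaussian libration, wrapped to (-180, 180]."""
    if sigma == 0.0:
        return STATE_CENTRES[states].copy()
    angles = np.empty(len(states))
    for s in range(3):
        idx = states == s
        k = int(idx.sum())
        if k == 0:
            continue
        lo, hi = _STATE_BOUNDS[s]
        centre = STATE_CENTRES[s] if s != 0 else 180.0
        a = (lo - centre) / sigma
        b = (hi - centre) / sigma
        vals = truncnorm.rvs(a, b, loc=centre, scale=sigma, size=k, random_state=rng)
        angles[idx] = vals
    # wrap the trans samples that exceeded 180 into (-180, 180]
    angles = np.where(angles > 180.0, angles - 360.0, angles)
    return angles


def simulate_rotamer_trajectory(
    topology: AlditolTopology,
    model: RotamerJumpModel,
    params: GeometryParams | None = None,
) -> tuple[Trajectory, dict[str, np.ndarray]]:
    """Sample a rotamer-jump trajectory and realize it in Cartesian space.

    Returns the trajectory and the planted ground truth: a map
    phi -> integer state sequence (0 = trans, 1 = gauche-, 2 = gauche+).
    """
    rng = np.random.default_rng(model.seed)
    phis = np.empty((model.n_frames, 4))
    truth: dict[str, np.ndarray] = {}
    for j, phi in enumerate(PHI_NAMES):
        states = _sample_states(model.pi(phi), model.n_frames, model.jump_probability, rng)
        truth[phi] = states
        phis[:, j] = _noisy_angles(states, model.sigma_deg, rng)
    coords = build_frames(topology, phis, None, params)
    return Trajectory(topology, coords), truth


# --------------------------------------------------------------------------
# planted hydrogen bonds
# --------------------------------------------------------------------------

#: coarse backbone candidates tried when searching for a feasible geometry
_BACKBONE_CANDIDATES = [
    (180.0, 180.0, 180.0, 180.0),
    (60.0, 180.0, 180.0, 60.0),
    (-60.0, 180.0, 180.0, -60.0),
    (180.0, -60.0, 180.0, 60.0),
    (180.0, 60.0, 180.0, -60.0),
    (180.0, 60.0, -60.0, 180.0),
    (180.0, -60.0, 60.0, 180.0),
    (60.0, 60.0, 180.0, 180.0),
    (180.0, 180.0, 60.0, 60.0),
    (60.0, -60.0, -60.0, 60.0),
    (-60.0, 60.0, 60.0, -60.0),
]

_TORSION_GRID = np.arange(-180.0, 180.0, 2.0)


def _frame_with_torsions(topology, phis, oh, params):
    return build_conformer(
        topology,
        dict(zip(PHI_NAMES, phis)),
        {f"O{i+1}": oh[i] for i in range(5)},
        params,
    )


def _solve_frame(
    topology: AlditolTopology,
    pairs: frozenset[tuple[str, str]],
    criteria: HBondCriteria,
    params: GeometryParams | None,
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Find backbone dihedrals and hydroxyl torsions realizing exactly `pairs`.

    Donor hydroxyl torsions are grid-searched to satisfy the bond criteria
    towards the scheduled acceptor; all other hydroxyls are oriented to
    violate the donor-angle criterion towards every nearby oxygen.  The
    frame is verified by re-detection before being returned.
    """
    from .geometry import measure_distance, vector_angle as vangle

    donors = {d: a for d, a in pairs}
    if len(donors) != len(pairs):
        raise ValueError("at most one scheduled acceptor per donor")
    for cand in _BACKBONE_CANDIDATES:
        base = build_conformer(topology, dict(zip(PHI_NAMES, cand)), params=params)
        if any(
            measure_distance(base, (d, a)) > criteria.max_oo_distance - 0.05
            for d, a in pairs
        ):
            continue
        oh = [180.0] * 5
        ok = True
        for i, oxy in enumerate(("O1", "O2", "O3", "O4", "O5")):
            target = donors.get(oxy)
            best, best_val = None, None
            for tor in _TORSION_GRID:
                oh_try = list(oh)
                oh_try[i] = float(tor)
                conf = _frame_with_torsions(topology, cand, oh_try, params)
                h = conf.xyz(f"HO{i+1}")
                o = conf.xyz(oxy)
                if target is not None:
                    # minimize the donor angle towards the scheduled acceptor
                    val = vangle(h, o, conf.xyz(target))
                    if best_val is None or val < best_val:
                        best, best_val = tor, val
                else:
                    # maximize the smallest donor angle towards any oxygen in range
                    worst = 180.0
                    for other in ("O1", "O2", "O3", "O4", "O5"):
                        if other == oxy:
                            continue
                        if measure_distance(conf, (oxy, other)) <= criteria.max_oo_distance:
                            worst = min(worst, vangle(h, o, conf.xyz(other)))
                    if best_val is None or worst > best_val:
                        best, best_val = tor, worst
            oh[i] = float(best)
            if target is not None and best_val > criteria.max_donor_angle - 2.0:
                ok = False
                break
            if target is None and best_val < criteria.max_donor_angle + 5.0:
                ok = False
                break
        if not ok:
            continue
        conf = _frame_with_torsions(topology, cand, oh, params)
        found = {(d, a) for d, _, a in detect_hbonds(conf, criteria)}
        if found == set(pairs):
            return tuple(cand), tuple(oh)
    raise ValueError(
        f"no feasible idealized geometry found for scheduled bonds {sorted(pairs)}"
    )


def plant_hbond_frames(
    topology: AlditolTopology,
    schedule: Sequence[Sequence[tuple[str, str]]],
    criteria: HBondCriteria | None = None,
    params: GeometryParams | None = None,
) -> Trajectory:
    """Build a trajectory whose detected H-bonds equal the schedule exactly.

    `schedule` lists, per frame, the (donor oxygen, acceptor oxygen) pairs
    that must be present; every unscheduled pair violates at least one
    criterion.  Raises if a scheduled set is geometrically infeasible.
    """
    criteria = criteria or HBondCriteria()
    cache: dict[frozenset, tuple] = {}
    frames = []
    for fr in schedule:
        key = frozenset(tuple(p) for p in fr)
        if key not in cache:
            cache[key] = _solve_frame(topology, key, criteria, params)
        phis, oh = cache[key]
        frames.append(
            _frame_with_torsions(topology, phis, list(oh), params).coords
        )
    return Trajectory(topology, np.stack(frames))


# --------------------------------------------------------------------------
# EXSY
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ExsyModel:
    """Two-site magnetization exchange ground truth.

    Site a is the observed hydroxyl proton, site b the exchange partner
    (water).  `k_ex` is the forward rate a->b in 1/s; the backward rate is
    k_ex * p_a / p_b (detailed balance).  `r1` are longitudinal relaxation
    rates per site.
    """

    k_ex: float = 200.0
    r1: tuple[float, float] = (1.0, 1.0)
    populations: tuple[float, float] = (0.5, 0.5)
    mixing_times: tuple[float, ...] = tuple(0.003 * i for i in range(1, 9))
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.k_ex < 0 or any(r < 0 for r in self.r1):
            raise ValueError("rates must be non-negative")
        pa, pb = self.populations
        if pa <= 0 or pb <= 0 or abs(pa + pb - 1.0) > 1e-9:
            raise ValueError("site populations must be positive and sum to 1")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")


def simulate_exsy(model: ExsyModel, site: str = "OH") -> ExsyDataset:
    """Exact two-site EXSY volumes: M(t) = expm(-R t) M(0) with M(0) on a.

    R couples longitudinal relaxation and exchange; the diagonal volume is
    the magnetization remaining on site a, the cross volume the part
    transferred to b.  As t -> 0, cross/diagonal -> k_ex * t.
    """
    pa, pb = model.populations
    k_ab = model.k_ex
    k_ba = model.k_ex * pa / pb
    r1a, r1b = model.r1
    R = np.array([[r1a + k_ab, -k_ba], [-k_ab, r1b + k_ba]])
    rng = np.random.default_rng(model.seed)
    diag, cross = [], []
    for t in model.mixing_times:
        m = expm(-R * t) @ np.array([1.0, 0.0])
        diag.append(m[0])
        cross.append(m[1])
    diag = np.array(diag)
    cross = np.array(cross)
    if model.noise_sigma > 0:
        diag = np.clip(diag + rng.normal(0, model.noise_sigma, diag.shape), 1e-12, None)
        cross = np.clip(cross + rng.normal(0, model.noise_sigma, cross.shape), 0.0, None)
    return ExsyDataset(site, np.array(model.mixing_times), diag, cross)


# --------------------------------------------------------------------------
# forward couplings and packaged tables
# --------------------------------------------------------------------------

def forward_couplings(
    populations: RotamerPopulations | Sequence[float],
    matrix: StateCouplingMatrix,
    molecule: str = "synthetic",
) -> CouplingSet:
    """Population-weighted couplings J = M p (exact inverse of inversion)."""
    p = (
        populations.as_array()
        if isinstance(populations, RotamerPopulations)
        else np.asarray(populations, dtype=float)
    )
    if p.shape != (3,):
        raise ValueError("populations must have three entries")
    j = matrix.matrix @ p
    return CouplingSet(molecule, dict(zip(matrix.observables, (float(x) for x in j))))


def packaged_fixtures() -> tuple[list[CrystalRecord], dict[str, CouplingSet]]:
    """The in-study tables as typed records.

    Returns the crystal dihedral survey (3 ribitol + 4 d-arabitol +
    45 xylitol conformers) and the per-molecule coupling sets with their
    not-determined entries flagged as ``None``.
    """
    from importlib.resources import files

    import pandas as pd

    records = load_crystal_table()
    df = pd.read_csv((files("pentitol.data") / "couplings.csv").open())
    couplings: dict[str, CouplingSet] = {}
    for mol, grp in df.groupby("molecule", sort=False):
        values = {
            row["coupling_name"]: (float(row["hertz"]) if row["available"] == "yes" else None)
            for _, row in grp.iterrows()
        }
        couplings[mol] = CouplingSet(mol, values)
    return records, couplings
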