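"""Per-frame and aggregate statistics of pentitol trajectories.

Post-processing of multi-frame coordinates the way an MD study of a small
solute is analysed: backbone dihedral time series and their three-state
rotamer populations, joint phi2/phi3 probabilities, state-transition
counts, end-to-end C1-C5 distance and extended/bent shape flips, geometric
intramolecular hydrogen-bond detection with per-oxygen bonding
frequencies, and an all-atom superposed RMSD series.

Hydrogen bonds follow three geometric criteria on a donor hydroxyl
O-H ... acceptor O pair:

1. donor-acceptor oxygen distance <= 3.4 Angstrom;
2. angle at the donor oxygen between the O-H bond and the O...O vector
   <= 30 degrees;
3. angle at the hydrogen (donor O - H - acceptor O) > 120 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .crystal_survey import (
    STATE_BY_CODE,
    RotamerState,
    classify_codes,
    classify_state,
    classify_states,
)
from .geometry import (
    AlditolTopology,
    Conformation,
    GeometryError,
    PHI_NAMES,
    Trajectory,
    dihedral,
    kabsch,
    vector_angle,
)

__all__ = [
    "DihedralSeries",
    "HBondCriteria",
    "HBondStats",
    "ShapeSeries",
    "dihedral_series",
    "state_populations",
    "joint_probability",
    "transition_count",
    "shape_series",
    "detect_hbonds",
    "hbond_frequencies",
    "rmsd_series",
]

HYDROXYL_OXYGENS = ("O1", "O2", "O3", "O4", "O5")


@dataclass
class DihedralSeries:
    """Backbone dihedral values per frame; columns ordered phi1..phi4."""

    values: np.ndarray  # (n_frames, 4) degrees in (-180, 180]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 4:
            raise ValueError("dihedral series must be (n_frames, 4)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("missing values in dihedral series")

    def __len__(self) -> int:
        return self.values.shape[0]

    def phi(self, name: str) -> np.ndarray:
        return self.values[:, PHI_NAMES.index(name)]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric thresholds for an intramolecular O-H...O hydrogen bond."""

    max_oo_distance: float = 3.4  # Angstrom, donor O to acceptor O
    max_donor_angle: float = 30.0  # deg, H-Od-Oa angle at the donor oxygen
    min_hydrogen_angle: float = 120.0  # deg, Od-H-Oa angle at the hydrogen

    def __post_init__(self):
        if self.max_oo_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        for a in (self.max_donor_angle, self.min_hydrogen_angle):
            if not 0.0 < a < 180.0:
                raise ValueError("angle thresholds must lie in (0, 180)")


@dataclass
class HBondStats:
    """Per-oxygen and per-directed-pair hydrogen-bond frequencies.

    `oxygen_fraction[o]` is the fraction of frames in which oxygen `o`
    participates (as donor or acceptor) in at least one intramolecular
    bond; `pair_fraction[(donor, acceptor)]` the fraction of frames where
    that directed bond is present.
    """

    n_frames: int
    oxygen_fraction: dict[str, float]
    pair_fraction: dict[tuple[str, str], float]

    def filtered_pairs(self, cutoff: float = 0.10) -> dict[tuple[str, str], float]:
        """Directed pairs at or above the reporting cutoff (default 10%)."""
        return {k: v for k, v in self.pair_fraction.items() if v >= cutoff}

    def bonding_oxygens(self, cutoff: float = 0.20) -> list[str]:
        """Oxygens whose bonding frequency reaches the cutoff (default 20%)."""
        return [o for o, f in self.oxygen_fraction.items() if f >= cutoff]


@dataclass
class ShapeSeries:
    """Per-frame C1-C5 distance and extended/bent/intermediate labels."""

    distances: np.ndarray
    labels: list[str]
    flips: int
    thresholds: tuple[float, float]  # (bent_max, extended_min)


# --------------------------------------------------------------------------
# dihedral statistics
# --------------------------------------------------------------------------

def dihedral_series(traj: Trajectory, topology: AlditolTopology | None = None) -> DihedralSeries:
    """Measure phi1..phi4 in every frame (vectorized over the trajectory)."""
    topo = topology or traj.topology
    cols = []
    for phi in PHI_NAMES:
        quad = topo.dihedral_defs[phi]
        idx = [topo.index(a) for a in quad]
        p = traj.coords[:, idx, :]
        cols.append(dihedral(p[:, 0], p[:, 1], p[:, 2], p[:, 3]))
    return DihedralSeries(np.stack(cols, axis=1))


def state_populations(series: DihedralSeries) -> dict[str, dict[RotamerState, float]]:
    """Percentage of frames in each rotamer state, per backbone dihedral."""
    if len(series) < 1:
        raise ValueError("empty series")
    out: dict[str, dict[RotamerState, float]] = {}
    for phi in PHI_NAMES:
        codes = classify_codes(series.phi(phi))
        n = len(codes)
        out[phi] = {
            s: 100.0 * float(np.sum(codes == c)) / n
            for c, s in enumerate(STATE_BY_CODE)
        }
    return out


def joint_probability(
    series: DihedralSeries,
    pair: tuple[str, str],
    states: tuple[RotamerState | str, RotamerState | str],
) -> float:
    """Percentage of frames with both dihedrals in the requested states."""
    want = tuple(STATE_BY_CODE.index(RotamerState(s)) for s in states)
    a = classify_codes(series.phi(pair[0]))
    b = classify_codes(series.phi(pair[1]))
    both = (a == want[0]) & (b == want[1])
    return 100.0 * float(np.sum(both)) / len(series)


def transition_count(
    series: DihedralSeries,
) -> dict[str, dict[tuple[RotamerState, RotamerState], int]]:
    """Counts of state changes between consecutive frames, per dihedral."""
    if len(series) < 2:
        raise ValueError("transition counting needs at least two frames")
    out: dict[str, dict[tuple[RotamerState, RotamerState], int]] = {}
    for phi in PHI_NAMES:
        codes = classify_codes(series.phi(phi))
        counts: dict[tuple[RotamerState, RotamerState], int] = {}
        prev, nxt = codes[:-1], codes[1:]
        changed = prev != nxt
        for a, b in zip(prev[changed], nxt[changed]):
            key = (STATE_BY_CODE[a], STATE_BY_CODE[b])
            counts[key] = counts.get(key, 0) + 1
        out[phi] = counts
    return out


# --------------------------------------------------------------------------
# chain shape
# --------------------------------------------------------------------------

def shape_series(
    traj: Trajectory,
    thresholds: tuple[float, float] = (4.7, 4.9),
) -> ShapeSeries:
    """C1-C5 distance per frame with hysteresis-based flip counting.

    A frame is `bent` if the distance is <= bent_max, `extended` if
    >= extended_min, else `intermediate`.  A flip is a bent->extended or
    extended->bent change, ignoring intermediate frames in between
    (hysteresis: intermediates neither trigger nor reset a flip).
    """
    bent_max, extended_min = thresholds
    if extended_min <= bent_max:
        raise ValueError("extended_min must exceed bent_max")
    i1 = traj.topology.index("C1")
    i5 = traj.topology.index("C5")
    d = np.linalg.norm(traj.coords[:, i1, :] - traj.coords[:, i5, :], axis=-1)
    labels = np.where(d <= bent_max, "bent", np.where(d >= extended_min, "extended", "intermediate"))
    flips = 0
    last = None
    for lab in labels:
        if lab == "intermediate":
            continue
        if last is not None and lab != last:
            flips += 1
        last = lab
    return ShapeSeries(d, labels.tolist(), flips, (bent_max, extended_min))


# --------------------------------------------------------------------------
# hydrogen bonds
# --------------------------------------------------------------------------

def _hbond_mask(
    coords: np.ndarray,
    o_idx: np.ndarray,
    h_idx: np.ndarray,
    criteria: HBondCriteria,
) -> np.ndarray:
    """Boolean (n_frames, 5, 5) donor x acceptor bond matrix (vectorized)."""
    O = coords[:, o_idx, :]  # (n, 5, 3)
    H = coords[:, h_idx, :]  # (n, 5, 3)
    oo = O[:, None, :, :] - O[:, :, None, :]  # donor -> acceptor (n, 5d, 5a, 3)
    dist = np.linalg.norm(oo, axis=-1)
    oh = H - O  # donor O -> its H (n, 5, 3)
    # angle at donor oxygen between O-H and O->Oacc
    oh_n = oh / np.linalg.norm(oh, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        oo_n = oo / np.where(dist[..., None] > 0, dist[..., None], np.inf)
    cos_don = np.clip(np.einsum("nda,ndxa->ndx", oh_n, oo_n), -1.0, 1.0)
    ang_donor = np.degrees(np.arccos(cos_don))
    # angle at hydrogen: H->Odonor vs H->Oacceptor
    ho = -oh  # H -> donor O
    ha = O[:, None, :, :] - H[:, :, None, :]  # H(donor) -> acceptor O
    ho_n = ho / np.linalg.norm(ho, axis=-1, keepdims=True)
    ha_len = np.linalg.norm(ha, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        ha_n = ha / np.where(ha_len > 0, ha_len, np.inf)
    cos_h = np.clip(np.einsum("nda,ndxa->ndx", ho_n, ha_n), -1.0, 1.0)
    ang_h = np.degrees(np.arccos(cos_h))

    mask = (
        (dist <= criteria.max_oo_distance)
        & (ang_donor <= criteria.max_donor_angle)
        & (ang_h > criteria.min_hydrogen_angle)
    )
    # a pair is donor != acceptor
    eye = np.eye(len(o_idx), dtype=bool)
    mask &= ~eye[None, :, :]
    return mask


def detect_hbonds(
    conf: Conformation,
    criteria: HBondCriteria | None = None,
) -> list[tuple[str, str, str]]:
    """Intramolecular hydrogen bonds of one frame.

    Returns (donor O, donor H, acceptor O) triples satisfying all three
    geometric criteria, ordered by donor then acceptor index.
    """
    criteria = criteria or HBondCriteria()
    topo = conf.topology
    names = set(topo.atom_names)
    for i, o in enumerate(HYDROXYL_OXYGENS, start=1):
        if f"HO{i}" not in names:
            raise GeometryError(f"hydroxyl hydrogen missing for {o}")
    o_idx = np.array([topo.index(o) for o in HYDROXYL_OXYGENS])
    h_idx = np.array([topo.index(f"HO{i}") for i in range(1, 6)])
    mask = _hbond_mask(conf.coords[None], o_idx, h_idx, criteria)[0]
    out = []
    for d in range(5):
        for a in range(5):
            if mask[d, a]:
                out.append(
                    (HYDROXYL_OXYGENS[d], f"HO{d+1}", HYDROXYL_OXYGENS[a])
                )
    return out


def hbond_frequencies(
    traj: Trajectory,
    criteria: HBondCriteria | None = None,
) -> HBondStats:
    """Per-oxygen and per-pair hydrogen-bond frequencies over a trajectory.

    An oxygen counts once per frame if it takes part in any bond, as donor
    or acceptor, regardless of how many bonds it forms in that frame.
    """
    criteria = criteria or HBondCriteria()
    topo = traj.topology
    o_idx = np.array([topo.index(o) for o in HYDROXYL_OXYGENS])
    h_idx = np.array([topo.index(f"HO{i}") for i in range(1, 6)])
    mask = _hbond_mask(traj.coords, o_idx, h_idx, criteria)  # (n, 5, 5)
    n = mask.shape[0]
    involved = mask.any(axis=2) | mask.any(axis=1)  # donor or acceptor
    oxygen_fraction = {
        o: float(involved[:, i].sum()) / n for i, o in enumerate(HYDROXYL_OXYGENS)
    }
    pair_fraction = {
        (HYDROXYL_OXYGENS[d], HYDROXYL_OXYGENS[a]): float(mask[:, d, a].sum()) / n
        for d in range(5)
        for a in range(5)
        if d != a
    }
    return HBondStats(n, oxygen_fraction, pair_fraction)


# --------------------------------------------------------------------------
# RMSD
# --------------------------------------------------------------------------

def rmsd_series(
    traj: Trajectory,
    reference: Conformation,
    fit: bool = True,
) -> np.ndarray:
    """All-atom RMSD of every frame against a reference conformation.

    With `fit` (default) each frame is first superposed onto the reference
    by the optimal rigid (Kabsch) transformation; without it the raw
    deviation is reported.
    """
    if traj.topology.atom_names != reference.topology.atom_names:
        raise GeometryError("trajectory and reference topologies differ")
    out = np.empty(len(traj))
    for i in range(len(traj)):
        if fit:
            out[i] = kabsch(traj.coords[i], reference.coords)[0]
        else:
            diff = traj.coords[i] - reference.coords
            out[i] = float(np.sqrt((diff**2).sum() / diff.shape[0]))
    return out
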