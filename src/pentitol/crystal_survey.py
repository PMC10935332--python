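"""Survey of pentitol crystal conformers: rotamer binning and chain shape.

Deposited small-molecule crystal structures of ribitol, d-arabitol and
xylitol populate only a handful of backbone conformations.  This module
classifies tabulated main-chain dihedrals into the three staggered rotamer
states, counts joint phi2/phi3 patterns, recomputes the end-to-end C1-C5
distance from idealized internal coordinates, and applies Jeffrey's
configurational rule (an alditol extends when the C2 and C4 configurations
differ, and bends when they match, because matching configurations place
the two C-O bonds parallel 1,3 to each other in the extended chain).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    AlditolTopology,
    GeometryParams,
    PHI_NAMES,
    build_conformer,
    measure_distance,
    wrap_angle,
)

__all__ = [
    "RotamerState",
    "CrystalRecord",
    "classify_state",
    "count_patterns",
    "c1c5_from_dihedrals",
    "jeffrey_predict",
    "load_crystal_table",
]


class RotamerState(str, Enum):
    """The three staggered rotamer states of a backbone dihedral."""

    TRANS = "trans"  # 180 deg bin
    GAUCHE_MINUS = "gauche-"  # -60 deg bin
    GAUCHE_PLUS = "gauche+"  # +60 deg bin

    @property
    def centre(self) -> float:
        return {"trans": 180.0, "gauche-": -60.0, "gauche+": 60.0}[self.value]


@dataclass(frozen=True)
class CrystalRecord:
    """One deposited conformer: CCDC id, molecule, phi1..phi4, printed C1-C5."""

    deposition_id: str
    molecule: str
    phi: tuple[float, float, float, float]
    c1c5: float | None = None

    def __post_init__(self):
        if len(self.phi) != 4:
            raise ValueError("four backbone dihedrals required")
        object.__setattr__(self, "phi", tuple(wrap_angle(p) for p in self.phi))


def classify_state(angle_deg: float) -> RotamerState:
    """Bin one dihedral into trans / gauche- / gauche+.

    Bins: trans for angle < -120 or angle > 120 (strict, so the boundary
    -120 belongs to gauche-), gauche- for -120 <= angle < 0, gauche+ for
    0 <= angle <= 120.  Angles outside (-180, 180] are wrapped first,
    never rejected.
    """
    a = wrap_angle(float(angle_deg))
    if a < -120.0 or a > 120.0:
        return RotamerState.TRANS
    if a < 0.0:
        return RotamerState.GAUCHE_MINUS
    return RotamerState.GAUCHE_PLUS


#: fixed state order used for integer codes throughout the package
STATE_BY_CODE: tuple[RotamerState, ...] = (
    RotamerState.TRANS,
    RotamerState.GAUCHE_MINUS,
    RotamerState.GAUCHE_PLUS,
)


def classify_codes(angles_deg) -> np.ndarray:
    """Vectorized binning to integer codes 0=trans, 1=gauche-, 2=gauche+."""
    a = np.atleast_1d(wrap_angle(np.asarray(angles_deg, dtype=float)))
    trans = (a < -120.0) | (a > 120.0)
    gminus = (~trans) & (a < 0.0)
    out = np.full(a.shape, 2, dtype=np.int64)
    out[trans] = 0
    out[gminus] = 1
    return out


def classify_states(angles_deg) -> np.ndarray:
    """Vectorized :func:`classify_state`; returns an object array of states."""
    codes = classify_codes(angles_deg)
    out = np.empty(codes.shape, dtype=object)
    for c, s in enumerate(STATE_BY_CODE):
        out[codes == c] = s
    return out


def count_patterns(
    records: Sequence[CrystalRecord],
    pair: tuple[str, str] = ("phi2", "phi3"),
) -> dict[tuple[RotamerState, RotamerState], int]:
    """Count joint rotamer patterns of a dihedral pair over crystal records.

    Every record lands in exactly one (state, state) cell, so the counts sum
    to ``len(records)``.  An empty selection yields an empty map.
    """
    for name in pair:
        if name not in PHI_NAMES:
            raise ValueError(f"unknown dihedral {name!r}")
    i, j = (PHI_NAMES.index(p) for p in pair)
    counts: Counter = Counter()
    for rec in records:
        counts[(classify_state(rec.phi[i]), classify_state(rec.phi[j]))] += 1
    return dict(counts)


def c1c5_from_dihedrals(
    topology: AlditolTopology,
    phi: Mapping[str, float] | Sequence[float],
    params: GeometryParams | None = None,
) -> float:
    """C1-C5 distance (Angstrom) of the idealized conformer with given phis.

    The value depends only on phi2/phi3 and the backbone internal
    coordinates; phi1 and phi4 merely rotate the terminal oxygens.
    """
    if not isinstance(phi, Mapping):
        phi = dict(zip(PHI_NAMES, phi))
    conf = build_conformer(topology, phi, params=params)
    return measure_distance(conf, ("C1", "C5"))


def jeffrey_predict(topology: AlditolTopology) -> str:
    """'extended' if the C2 and C4 configurations differ, else 'bent'."""
    try:
        c2, c4 = topology.stereo["C2"], topology.stereo["C4"]
    except KeyError as exc:
        raise ValueError(f"missing stereo label for {exc}") from None
    return "extended" if c2 != c4 else "bent"


def load_crystal_table(path_or_frame=None, molecule: str | None = None) -> list[CrystalRecord]:
    """Load crystal records from a CSV (default: the packaged survey table).

    Expected columns: ccdc_id, molecule, phi1..phi4, optionally c1c5_printed.
    `molecule` filters by name; unknown molecules simply yield no records.
    """
    if path_or_frame is None:
        from importlib.resources import files

        path_or_frame = files("pentitol.data") / "crystal_dihedrals.csv"
        df = pd.read_csv(path_or_frame.open())
    elif isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame
    else:
        df = pd.read_csv(path_or_frame)
    required = {"ccdc_id", "molecule", "phi1", "phi2", "phi3", "phi4"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"crystal table missing columns {sorted(missing)}")
    if molecule is not None:
        df = df[df["molecule"] == molecule.lower()]
    records = []
    for _, row in df.iterrows():
        c1c5 = row.get("c1c5_printed")
        records.append(
            CrystalRecord(
                deposition_id=str(row["ccdc_id"]),
                molecule=str(row["molecule"]),
                phi=(row["phi1"], row["phi2"], row["phi3"], row["phi4"]),
                c1c5=None if pd.isna(c1c5) else float(c1c5),
            )
        )
    return records
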