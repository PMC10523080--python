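"""Running load sets: ankle joint contact force plus 16 muscle forces.

A versioned generic load table ships with the package
(``data/running_loads.csv``; columns ``speed_m_s, entity, fx_n_per_kg,
fy_n_per_kg, fz_n_per_kg`` in the mesh coordinate frame, fixed order).  The
table is synthetic: it reproduces the structure and ordering of peak-stance
running loads — ankle joint contact force around 8-13 bodyweights growing
with speed from 3 to 5 m/s, soleus the largest muscle force, plantarflexors
pulling distally — not any measured dataset.  Per-kg entries are scaled by
each subject's body mass to obtain forces in newtons.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .synthgeom import MUSCLE_NAMES, SubjectCovariates

SPEEDS = (3, 4, 5)


class UnsupportedSpeedError(ValueError):
    """Speed not in the packaged 3/4/5 m/s table."""


@dataclass
class LoadSet:
    """Forces for one subject at one speed.

    ``ankle_jcf`` is the full force vector (N); ``muscle_forces`` maps each of
    the 16 muscle names to ``(magnitude N, unit line-of-action vector)``.
    """

    speed: int
    ankle_jcf: np.ndarray
    muscle_forces: dict[str, tuple[float, np.ndarray]]

    def total_force(self) -> np.ndarray:
        total = self.ankle_jcf.copy()
        for mag, d in self.muscle_forces.values():
            total = total + mag * d
        return total

    def scaled(self, factor: float) -> "LoadSet":
        return LoadSet(self.speed, self.ankle_jcf * factor,
                       {k: (m * factor, d.copy())
                        for k, (m, d) in self.muscle_forces.items()})


def load_reference_table() -> pd.DataFrame:
    """Read the packaged per-kg load table."""
    with resources.files("tibstrain.data").joinpath("running_loads.csv").open() as fh:
        return pd.read_csv(fh)


def per_kg_loadset(speed: int, table: pd.DataFrame | None = None) -> LoadSet:
    """Per-kg load set (N/kg magnitudes) for one running speed."""
    if speed not in SPEEDS:
        raise UnsupportedSpeedError(f"speed {speed} m/s not in packaged table {SPEEDS}")
    table = table if table is not None else load_reference_table()
    sub = table[table["speed_m_s"] == speed]
    vecs = {row.entity: np.array([row.fx_n_per_kg, row.fy_n_per_kg, row.fz_n_per_kg])
            for row in sub.itertuples()}
    missing = set(MUSCLE_NAMES) - set(vecs)
    if missing or "ankle_jcf" not in vecs:
        raise ValueError(f"load table incomplete for speed {speed}: missing {sorted(missing)}")
    muscles = {}
    for name in MUSCLE_NAMES:
        v = vecs[name]
        mag = float(np.linalg.norm(v))
        muscles[name] = (mag, v / mag if mag > 0 else np.zeros(3))
    return LoadSet(speed=speed, ankle_jcf=vecs["ankle_jcf"], muscle_forces=muscles)


def generate_loadset(speed: int, covariates: SubjectCovariates,
                     table: pd.DataFrame | None = None) -> LoadSet:
    """Body-mass-scaled load set (forces in N) for one subject and speed."""
    base = per_kg_loadset(speed, table)
    return base.scaled(covariates.body_mass)
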