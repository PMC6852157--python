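"""Trial-level feeding data container and CSV round-tripping.

A :class:`TrialSet` holds every replicate of a non-replacement feeding
experiment for one consumer-resource pair: initial resource densities,
numbers eaten, trial duration and the covariates (masses, temperature,
arena geometry, encounter strategy, taxonomic group) that the
meta-analysis stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["TrialSet", "STRATEGIES", "trials_to_frame", "frame_to_trials",
           "write_trials_csv", "read_trials_csv", "TRIALS_COLUMNS"]

#: Encounter-strategy taxonomy: active searchers for mobile or static
#: resources, grazers, and the passive modes (filter feeding, deposit
#: feeding, obligate sit-and-wait predation).
STRATEGIES = (
    "active-mobile",
    "active-static",
    "grazer",
    "filter",
    "sit-and-wait",
    "deposit",
)

TRIALS_COLUMNS = [
    "pair_id", "N0", "eaten", "T", "arena", "arena_dim",
    "consumer_mass_g", "resource_mass_g", "temp_C", "strategy", "taxon_group",
]


@dataclass
class TrialSet:
    """Replicated feeding trials for one consumer-resource pair.

    ``N0`` and ``eaten`` are parallel per-replicate arrays: row i records
    that of ``N0[i]`` initial resource individuals, ``eaten[i]`` were
    consumed over duration ``T``.  Densities are individuals per arena;
    ``arena`` is the footprint (m^2, ``arena_dim=2``) or volume (m^3,
    ``arena_dim=3``).
    """

    pair_id: str
    N0: np.ndarray
    eaten: np.ndarray
    T: float
    arena: float = 1.0
    arena_dim: int = 2
    consumer_mass: float = 1.0
    resource_mass: float = 1.0
    temperature: float = 15.0
    strategy: str = "active-mobile"
    taxon_group: str = "unassigned"
    time_unit: str = "s"

    def __post_init__(self) -> None:
        self.N0 = np.asarray(self.N0, dtype=int)
        self.eaten = np.asarray(self.eaten, dtype=int)
        if self.N0.shape != self.eaten.shape or self.N0.ndim != 1:
            raise ValueError("N0 and eaten must be 1-D arrays of equal length")
        if np.any(self.N0 < 0) or np.any(self.eaten < 0):
            raise ValueError("densities and counts must be non-negative")
        if np.any(self.eaten > self.N0):
            raise ValueError("eaten cannot exceed initial density in any replicate")
        if not self.T > 0:
            raise ValueError("trial duration T must be positive")
        if not self.arena > 0:
            raise ValueError("arena footprint/volume must be positive")
        if self.arena_dim not in (2, 3):
            raise ValueError("arena_dim must be 2 or 3")
        if not (self.consumer_mass > 0 and self.resource_mass > 0):
            raise ValueError("masses must be positive")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.time_unit not in ("s", "d"):
            raise ValueError("time_unit must be 's' or 'd'")

    @property
    def n(self) -> int:
        """Number of replicate rows."""
        return int(self.N0.size)

    @property
    def n_levels(self) -> int:
        """Number of distinct initial densities."""
        return int(np.unique(self.N0).size)

    @property
    def seconds_per_time_unit(self) -> float:
        return 86400.0 if self.time_unit == "d" else 1.0

    def proportions(self) -> np.ndarray:
        """Proportional consumption eaten/N0 per replicate (0 where N0=0)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(self.N0 > 0, self.eaten / np.maximum(self.N0, 1), 0.0)
        return p


def trials_to_frame(trial_sets: Iterable[TrialSet]) -> pd.DataFrame:
    """Stack trial sets into one tidy frame (one row per replicate)."""
    rows = []
    for ts in trial_sets:
        for n0, ne in zip(ts.N0, ts.eaten):
            rows.append({
                "pair_id": ts.pair_id, "N0": int(n0), "eaten": int(ne),
                "T": ts.T, "arena": ts.arena, "arena_dim": ts.arena_dim,
                "consumer_mass_g": ts.consumer_mass,
                "resource_mass_g": ts.resource_mass,
                "temp_C": ts.temperature, "strategy": ts.strategy,
                "taxon_group": ts.taxon_group,
            })
    return pd.DataFrame(rows, columns=TRIALS_COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> list[TrialSet]:
    """Rebuild TrialSet objects from a tidy trials frame."""
    out = []
    for pair_id, grp in df.groupby("pair_id", sort=False):
        first = grp.iloc[0]
        out.append(TrialSet(
            pair_id=str(pair_id),
            N0=grp["N0"].to_numpy(),
            eaten=grp["eaten"].to_numpy(),
            T=float(first["T"]),
            arena=float(first["arena"]),
            arena_dim=int(first["arena_dim"]),
            consumer_mass=float(first["consumer_mass_g"]),
            resource_mass=float(first["resource_mass_g"]),
            temperature=float(first["temp_C"]),
            strategy=str(first["strategy"]),
            taxon_group=str(first["taxon_group"]),
        ))
    return out


def write_trials_csv(trial_sets: Sequence[TrialSet], path) -> pd.DataFrame:
    df = trials_to_frame(trial_sets)
    df.to_csv(path, index=False)
    return df


def read_trials_csv(path) -> list[TrialSet]:
    return frame_to_trials(pd.read_csv(path))
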