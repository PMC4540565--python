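"""Tabular container for concentration profiles on an (r, t) grid."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DomainError

__all__ = ["RadialProfile"]

#: Text precision for CSV output: 17 significant digits round-trips doubles
#: bit-exactly.
CSV_FLOAT_FORMAT = "%.17g"

TIME_SCALES = ("t", "alpha_t", "k_t")
NORMALIZATIONS = ("none", "/c_t0", "/c_r1", "/(c_t0+c_E)")


@dataclass
class RadialProfile:
    """Concentrations sampled on an (r, t) grid.

    Attributes
    ----------
    r_grid : ndarray
        Dimensionless radii in [0, 1].
    t_grid : ndarray
        Raw times.  ``time_scale`` records which scaled axis (``alpha_t`` or
        ``k_t``) the grid was specified on, if any; the stored values are
        always raw ``t`` so profiles from different solvers compare directly.
    values : ndarray, shape (len(t_grid), len(r_grid))
        Concentrations, scaled according to ``normalization``.
    time_scale : str
        One of ``"t"``, ``"alpha_t"``, ``"k_t"``.
    normalization : str
        One of ``"none"``, ``"/c_t0"``, ``"/c_r1"``, ``"/(c_t0+c_E)"``.
    solver : str
        ``"analytic"`` or ``"mol"``.
    provenance : dict
        Parameter bundle and solver settings that produced the profile.
    """

    r_grid: np.ndarray
    t_grid: np.ndarray
    values: np.ndarray
    time_scale: str = "t"
    normalization: str = "none"
    solver: str = "analytic"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.t_grid.size, self.r_grid.size):
            raise DomainError(
                f"values shape {self.values.shape} does not match "
                f"(|t_grid|, |r_grid|) = ({self.t_grid.size}, {self.r_grid.size})"
            )
        if self.time_scale not in TIME_SCALES:
            raise DomainError(f"unknown time scale {self.time_scale!r}")
        if self.normalization not in NORMALIZATIONS:
            raise DomainError(f"unknown normalization {self.normalization!r}")

    def to_frame(self) -> pd.DataFrame:
        """Long/tidy frame with columns ``time``, ``r``, ``concentration``."""
        tt, rr = np.meshgrid(self.t_grid, self.r_grid, indexing="ij")
        return pd.DataFrame(
            {
                "time": tt.ravel(),
                "r": rr.ravel(),
                "concentration": self.values.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        """Write the tidy table as CSV at 17 significant digits (bit-exact
        round trip for doubles)."""
        self.to_frame().to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)

    @classmethod
    def from_csv(cls, path, **metadata) -> "RadialProfile":
        """Rebuild a profile from a tidy CSV written by :meth:`to_csv`."""
        df = pd.read_csv(path, float_precision="round_trip")
        t_grid = np.unique(df["time"].to_numpy())
        r_grid = np.unique(df["r"].to_numpy())
        pivot = df.pivot(index="time", columns="r", values="concentration")
        values = pivot.loc[t_grid, r_grid].to_numpy()
        return cls(r_grid=r_grid, t_grid=t_grid, values=values, **metadata)
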