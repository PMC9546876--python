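"""Per-cell mechanical and E-Cadherin fields on the island.

Micropatterned colonies on soft hydrogel exert high substrate traction at the
rim and high cell-cell tension in the interior; E-Cadherin expression is flat
in the interior and rises sharply at the rim. These three per-cell fields feed
the Notch model through two coupling terms:

    S_i        = ECAD_i * Traction_i           (facilitates trans-activation)
    C_neighbor = sum_j ECAD_j * CellCellForce_j (neighbors j; inhibits it)

The analytic profiles are exponentials in normalized radius with short decay
lengths, so the transition occupies the rim band r in [~0.9, 1] where the
fate bifurcation is observed. A measured per-cell traction table (CSV) can
replace the analytic traction profile.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .lattice import Lattice


@dataclass(frozen=True)
class FieldParams:
    """Shape parameters of the analytic radial field profiles.

    All values are dimensionless; decay lengths are in normalized-radius
    units and kept <= 0.2 so the rise/fall is localized to the rim band.

    t_interior : interior traction plateau (rim value is 1 by construction)
    lam_t      : traction rise length at the rim
    e_interior : interior E-Cadherin plateau (rim adds +1 on top)
    lam_e      : E-Cadherin rise length
    c_max      : interior cell-cell force plateau
    lam_c      : nominal cell-cell decay length (the decay is inherited from
                 the traction profile through the inverse relation)
    """

    t_interior: float = 0.2
    lam_t: float = 0.05
    e_interior: float = 1.0
    lam_e: float = 0.05
    c_max: float = 1.0
    lam_c: float = 0.05

    def __post_init__(self):
        for name in ("t_interior", "lam_t", "e_interior", "lam_e", "c_max", "lam_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"FieldParams.{name} must be positive")
        if self.lam_t > 0.2 or self.lam_e > 0.2 or self.lam_c > 0.2:
            raise ValueError("decay lengths must be <= 0.2 (rim-band localization)")


@dataclass
class MechanicalFields:
    """Per-cell traction, cell-cell force and E-Cadherin level.

    traction is max-normalized (max = 1 for the analytic profile);
    provenance records whether the traction came from the analytic profile
    or a measured CSV.
    """

    traction: np.ndarray
    cellcell: np.ndarray
    ecad: np.ndarray
    provenance: str = "analytic"
    #: neutral mechanics: the model replaces S/(soft+C) by 1 and C by 0,
    #: recovering the unmodulated lateral-inhibition limit.
    neutral: bool = False

    def __post_init__(self):
        for name in ("traction", "cellcell", "ecad"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if np.any(arr < 0):
                raise ValueError(f"{name} field must be nonnegative")
            setattr(self, name, arr)

    def scaled_ecad(self, factor: float) -> "MechanicalFields":
        """Copy with the E-Cadherin field scaled uniformly (knockdowns)."""
        return MechanicalFields(
            traction=self.traction.copy(),
            cellcell=self.cellcell.copy(),
            ecad=self.ecad * factor,
            provenance=self.provenance,
            neutral=self.neutral,
        )


def traction_profile(r, fp: FieldParams):
    """Analytic normalized traction: interior plateau, exponential rim rise."""
    r = np.asarray(r, dtype=float)
    return fp.t_interior + (1.0 - fp.t_interior) * np.exp((r - 1.0) / fp.lam_t)


def analytic_fields(lattice: Lattice, fp: FieldParams | None = None) -> MechanicalFields:
    """Evaluate the analytic radial field profiles at each cell's radius.

    traction(r) = t_interior + (1 - t_interior) * exp((r-1)/lam_t)
    ecad(r)     = e_interior + exp((r-1)/lam_e)
    cellcell(r) = c_max * (1 - traction(r))

    The cell-cell force is the inverse of traction: high where traction is
    low (interior) and vanishing at the rim where traction peaks.
    """
    fp = fp or FieldParams()
    r = lattice.radius
    traction = traction_profile(r, fp)
    ecad = fp.e_interior + np.exp((r - 1.0) / fp.lam_e)
    cellcell = fp.c_max * (1.0 - traction)
    return MechanicalFields(traction=traction, cellcell=cellcell, ecad=ecad)


def force_free_fields(lattice: Lattice) -> MechanicalFields:
    """Mechanics-neutral fields: the base lateral-inhibition model.

    Zero traction/cell-cell/E-Cadherin influence is represented by a neutral
    coupling (A_i = 1, C_neighbor = 0), recovering the classic
    Notch-Delta-Jagged model without mechanical modulation.
    """
    n = lattice.n_cells
    return MechanicalFields(
        traction=np.zeros(n),
        cellcell=np.zeros(n),
        ecad=np.zeros(n),
        provenance="force-free",
        neutral=True,
    )


def normalize_traction(groups) -> list:
    """Max-normalize replicate traction measurements.

    ``groups`` is a sequence of per-replicate arrays of raw stresses (Pa).
    Each value is divided by the mean over replicates of the per-replicate
    maximum stress, so the averaged profile peaks near 1. Scale-equivariant:
    multiplying all raw stresses by k leaves the output unchanged.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) == 0 or any(len(g) == 0 for g in groups):
        raise ValueError("normalize_traction requires at least one non-empty replicate")
    if any(np.any(g < 0) for g in groups):
        raise ValueError("stresses must be nonnegative")
    mean_max = float(np.mean([g.max() for g in groups]))
    if mean_max == 0.0:
        return [np.zeros_like(g) for g in groups]
    return [g / mean_max for g in groups]


def fields_from_traction_csv(
    lattice: Lattice, path, fp: FieldParams | None = None, n_bins: int = 20
) -> MechanicalFields:
    """Replace the analytic traction with a measured radial traction table.

    The CSV needs columns ``replicate_id``, ``radius`` (normalized) and
    ``stress_pa``. Stresses are max-normalized per the replicate rule of
    :func:`normalize_traction`, binned into ``n_bins`` equal radius bins,
    replicate-averaged per bin, and linearly interpolated to the lattice's
    per-cell radii. E-Cadherin keeps its analytic profile; cell-cell force is
    derived from the measured traction through the inverse relation.
    """
    fp = fp or FieldParams()
    df = pd.read_csv(path)
    required = {"replicate_id", "radius", "stress_pa"}
    if not required.issubset(df.columns):
        raise ValueError(f"traction CSV must have columns {sorted(required)}")
    groups = [g["stress_pa"].to_numpy() for _, g in df.groupby("replicate_id")]
    normed = normalize_traction(groups)
    df = df.copy()
    df["stress_norm"] = np.nan
    for (rep, g), nv in zip(df.groupby("replicate_id"), normed):
        df.loc[g.index, "stress_norm"] = nv
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    df["bin"] = np.clip(np.digitize(df["radius"], edges) - 1, 0, n_bins - 1)
    per_rep_bin = df.groupby(["replicate_id", "bin"])["stress_norm"].mean()
    per_bin = per_rep_bin.groupby("bin").mean()
    prof = per_bin.reindex(range(n_bins)).interpolate(limit_direction="both").to_numpy()
    traction = np.interp(lattice.radius, centers, prof)
    traction = np.maximum(traction, 0.0)
    ecad = fp.e_interior + np.exp((lattice.radius - 1.0) / fp.lam_e)
    cellcell = np.maximum(fp.c_max * (1.0 - traction), 0.0)
    return MechanicalFields(
        traction=traction, cellcell=cellcell, ecad=ecad, provenance="csv"
    )


def compute_S(fields: MechanicalFields, i: int | None = None):
    """Traction facilitation term S_i = ECAD_i * Traction_i.

    With ``i=None`` returns the full per-cell vector.
    """
    s = fields.ecad * fields.traction
    return s if i is None else float(s[i])


def compute_C_neighbor(lattice: Lattice, fields: MechanicalFields, i: int | None = None):
    """Neighbor cell-cell inhibition term C_i = sum_{j in N(i)} ECAD_j * Force_j."""
    per_cell = fields.ecad * fields.cellcell
    c = lattice.neighbor_matrix() @ per_cell
    return c if i is None else float(c[i])
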