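"""Shrake-Rupley solvent-accessible surface area.

A probe sphere (default radius 0.14 nm, a water molecule) rolls over the
van der Waals surface: each atom's sphere is expanded by the probe radius
and covered with a deterministic quasi-uniform test-point set (golden
spiral, so results are exactly reproducible); a test point is accessible
iff it lies outside every other expanded sphere, and the atom contributes
its accessible point fraction times 4 pi (r_vdw + r_probe)^2.

Periodic images are ignored: the micelle is assumed whole and far from
its images, which holds for the dilute study systems (box edge an order
of magnitude above the micelle diameter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import chemistry
from .model import AtomSet

__all__ = ["SASAResult", "compute_sasa", "sasa_rg_ratio_table",
           "sphere_points"]


def sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral lattice, no RNG)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


@dataclass
class SASAResult:
    """Areas in nm^2; ``per_chain`` is total divided by the aggregation
    number (count of distinct non-solvent chains present)."""

    total: float
    per_atom: np.ndarray
    per_chain: float
    probe_radius: float
    n_sphere_points: int
    n_chains: int


def compute_sasa(atoms: AtomSet, probe_radius: float = 0.14,
                 n_sphere_points: int = 960,
                 radii: dict | None = None) -> SASAResult:
    """Shrake-Rupley SASA of ``atoms`` (solute only: pre-select the
    micelle; water and ions are not excluded here).

    ``radii`` overrides the element -> van der Waals radius table
    (defaults to Bondi radii, nm).
    """
    if n_sphere_points < 64:
        raise ValueError("n_sphere_points must be >= 64")
    table = chemistry.VDW_RADII_NM if radii is None else radii
    try:
        r_vdw = np.array([table[e] for e in atoms.elements], float)
    except KeyError as exc:
        raise ValueError(
            f"no van der Waals radius for element {exc.args[0]!r}")
    r_exp = r_vdw + probe_radius
    coords = atoms.coords
    n = len(atoms)
    unit = sphere_points(n_sphere_points)
    tree = cKDTree(coords)
    reach = 2.0 * r_exp.max()
    per_atom = np.empty(n)
    for i in range(n):
        pts = coords[i] + r_exp[i] * unit
        neigh = [j for j in tree.query_ball_point(coords[i], reach)
                 if j != i]
        if neigh:
            nb = np.asarray(neigh, int)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(-1)
            buried = (d2 < (r_exp[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * np.pi * r_exp[i] ** 2
    chains = np.unique(atoms.chain_ids[atoms.chain_ids >= 0])
    n_chains = max(len(chains), 1)
    total = float(per_atom.sum())
    return SASAResult(
        total=total,
        per_atom=per_atom,
        per_chain=total / n_chains,
        probe_radius=probe_radius,
        n_sphere_points=n_sphere_points,
        n_chains=n_chains,
    )


def sasa_rg_ratio_table(results_by_system: dict, reference: str):
    """Compare SASA ratios with Rg^2 ratios across systems.

    ``results_by_system`` maps a system label to a ``(SASAResult,
    GyrationResult)`` pair.  For a perfect sphere the surface area is
    proportional to Rg^2, so for near-spherical micelles
    SASA_ref / SASA_sys should track Rg_ref^2 / Rg_sys^2; the returned
    table reports both ratios (reference in the numerator) and their
    difference as a sphericity diagnostic.
    """
    import pandas as pd

    if reference not in results_by_system:
        raise KeyError(f"reference system {reference!r} missing")
    ref_sasa, ref_gyr = results_by_system[reference]
    if ref_gyr.rg == 0:
        raise ValueError("reference Rg is zero")
    rows = []
    for label, (s, g) in results_by_system.items():
        if g.rg == 0:
            raise ValueError(f"zero Rg for system {label!r}")
        sasa_ratio = ref_sasa.total / s.total
        rg2_ratio = ref_gyr.rg ** 2 / g.rg ** 2
        rows.append({
            "system": label,
            "sasa": s.total,
            "rg": g.rg,
            "sasa_ratio": sasa_ratio,
            "rg2_ratio": rg2_ratio,
            "ratio_difference": sasa_ratio - rg2_ratio,
        })
    return pd.DataFrame(rows).set_index("system")
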