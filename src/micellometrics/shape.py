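"""Gyration-tensor shape descriptors.

The gyration tensor is the weighted second-moment tensor of positions
about the weighted center,

    G_ab = (1/W) sum_i w_i (r_ia - <r_a>) (r_ib - <r_b>),

whose eigenvalues l1 >= l2 >= l3 (nm^2) satisfy Rg^2 = l1 + l2 + l3.
Weights are atomic masses or coherent neutron scattering lengths (the
latter giving the SANS-comparable Rgb; negative 1H lengths are allowed).

Two scalar descriptors condense the spectrum: the asphericity

    b = 1 - 3 (l1 l2 + l2 l3 + l3 l1) / (l1 + l2 + l3)^2,

zero for a sphere and one for a line, and the shape (prolateness)
parameter

    S = 27 (l1 - lm)(l2 - lm)(l3 - lm) / (l1 + l2 + l3)^3,

with lm the eigenvalue mean; S ranges from -0.25 (perfect oblate,
l1 = l2, l3 = 0) through 0 (sphere) to 2 (perfect prolate, l2 = l3 = 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import chemistry
from .model import AtomSet, MicelleSystem, select, solvation_shell, \
    unwrap_frame

logger = logging.getLogger(__name__)

__all__ = ["GyrationResult", "gyration_tensor", "shape_metrics",
           "shape_metrics_array", "analyze_frames"]


def _weights(atoms: AtomSet, weighting: str,
             blengths: dict | None = None) -> np.ndarray:
    if weighting == "mass":
        w = atoms.masses
        if np.any(w <= 0):
            raise ValueError("non-positive mass weight")
        return w
    if weighting in ("scattering_length", "blength"):
        table = chemistry.COHERENT_B_FM if blengths is None else blengths
        try:
            w = np.array([table[e] for e in atoms.elements], float)
        except KeyError as exc:
            raise ValueError(
                f"no scattering length for element {exc.args[0]!r}")
        if abs(w.sum()) < 1.0:
            logger.warning(
                "net scattering length of selection is %.3g fm (near zero); "
                "the weighted center is ill-conditioned", w.sum())
        return w
    raise ValueError(f"unknown weighting {weighting!r}")


def gyration_tensor(atoms: AtomSet, weighting: str = "mass",
                    blengths: dict | None = None) -> np.ndarray:
    """Weighted second-moment (gyration) tensor, nm^2."""
    if len(atoms) == 0:
        raise ValueError("empty selection")
    w = _weights(atoms, weighting, blengths)
    total = w.sum()
    if total == 0:
        raise ValueError("zero total weight")
    center = (w[:, None] * atoms.coords).sum(axis=0) / total
    d = atoms.coords - center
    return (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0) \
        / total


def shape_metrics(eigenvalues) -> tuple[float, float]:
    """(asphericity, shape) from a descending non-negative spectrum."""
    lam = np.asarray(eigenvalues, float)
    if lam.shape != (3,):
        raise ValueError("expected three eigenvalues")
    if np.any(lam < -1e-12 * max(lam.max(), 1.0)):
        raise ValueError("negative eigenvalue")
    lam = np.clip(lam, 0.0, None)
    if not (lam[0] >= lam[1] >= lam[2]):
        raise ValueError("eigenvalues must be sorted descending")
    total = lam.sum()
    if total == 0:
        raise ValueError("all eigenvalues zero")
    # elementary-symmetric form: b = 1 - 3 e2/e1^2 and
    # S = 27 e3/e1^3 - 9 e2/e1^2 + 2, algebraically identical to the
    # product form 27 prod(l_i - lmean)/e1^3 but exact in floating point
    # for the ideal oblate/prolate/sphere spectra
    e2 = lam[0] * lam[1] + lam[1] * lam[2] + lam[2] * lam[0]
    e3 = lam[0] * lam[1] * lam[2]
    asphericity = 1.0 - 3.0 * e2 / total ** 2
    shape = 27.0 * e3 / total ** 3 - 9.0 * e2 / total ** 2 + 2.0
    return (float(np.clip(asphericity, 0.0, 1.0)),
            float(np.clip(shape, -0.25, 2.0)))


def shape_metrics_array(eigenvalues: np.ndarray) -> tuple[np.ndarray,
                                                          np.ndarray]:
    """Vectorized :func:`shape_metrics` over an (n, 3) array of
    descending non-negative spectra."""
    lam = np.asarray(eigenvalues, float)
    if lam.ndim != 2 or lam.shape[1] != 3:
        raise ValueError("expected an (n, 3) array")
    if np.any(lam < 0) or np.any(np.diff(lam, axis=1) > 0):
        raise ValueError("spectra must be non-negative and descending")
    total = lam.sum(axis=1)
    if np.any(total == 0):
        raise ValueError("all-zero spectrum present")
    e2 = lam[:, 0] * lam[:, 1] + lam[:, 1] * lam[:, 2] \
        + lam[:, 2] * lam[:, 0]
    e3 = lam.prod(axis=1)
    asph = 1.0 - 3.0 * e2 / total ** 2
    shape = 27.0 * e3 / total ** 3 - 9.0 * e2 / total ** 2 + 2.0
    return np.clip(asph, 0.0, 1.0), np.clip(shape, -0.25, 2.0)


@dataclass
class GyrationResult:
    """Per-frame gyration spectrum and derived descriptors (nm, nm^2)."""

    eigenvalues: tuple[float, float, float]
    rg: float
    asphericity: float
    shape: float
    ratios: tuple[float, float]         # (l2/l1, l3/l1)
    rgb: float | None = None
    frame_index: int = 0

    @property
    def lambda_mean(self) -> float:
        return sum(self.eigenvalues) / 3.0

    @classmethod
    def from_atoms(cls, atoms: AtomSet, weighting: str = "mass",
                   include_rgb: bool = False,
                   blengths: dict | None = None) -> "GyrationResult":
        tensor = gyration_tensor(atoms, weighting, blengths)
        lam = np.sort(np.linalg.eigvalsh(tensor))[::-1]
        lam = np.clip(lam, 0.0, None)
        asph, shp = shape_metrics(lam)
        rgb = None
        if include_rgb:
            tb = gyration_tensor(atoms, "scattering_length", blengths)
            tr = np.trace(tb)
            rgb = float(np.sqrt(tr)) if tr >= 0 else float("nan")
        return cls(
            eigenvalues=tuple(float(x) for x in lam),
            rg=float(np.sqrt(lam.sum())),
            asphericity=asph,
            shape=shp,
            ratios=(float(lam[1] / lam[0]), float(lam[2] / lam[0])),
            rgb=rgb,
            frame_index=atoms.frame_index,
        )


def analyze_frames(system: MicelleSystem, selection: str = "micelle",
                   weighting: str = "mass", include_shell: bool = False,
                   shell_cutoff: float = 0.35,
                   shell_oxygens_only: bool = False,
                   include_rgb: bool = False,
                   unwrap: bool = True) -> list[GyrationResult]:
    """Gyration descriptors for every frame of ``system``.

    ``include_shell`` augments the selection with all water molecules whose
    oxygen lies within ``shell_cutoff`` nm of it before building the tensor
    (the hydration-shell Rg convention); ``shell_oxygens_only`` drops the
    water hydrogens from the augmented set.  Frames are unwrapped across
    periodic boundaries by default.
    """
    results = []
    for k, frame in enumerate(system.frames):
        work = unwrap_frame(frame) if unwrap else frame
        if include_shell:
            shell = solvation_shell(work, solute_query=selection,
                                    cutoff=shell_cutoff)
            if shell_oxygens_only:
                shell = shell.subset(shell.atom_roles != "water_hydrogen")
            picked = shell
        else:
            picked = select(work, selection)
        if len(picked) == 0:
            raise ValueError(
                f"selection {selection!r} empty in frame {k}")
        res = GyrationResult.from_atoms(picked, weighting,
                                        include_rgb=include_rgb)
        res.frame_index = k
        results.append(res)
    return results
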