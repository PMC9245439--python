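"""Core domain model: atom containers, selections, periodic geometry.

An :class:`AtomSet` is a column-oriented snapshot (numpy arrays, nm units)
of one configuration; :class:`MicelleSystem` holds an ordered sequence of
frames together with the chain architecture.  Selections are expressed
either as named shortcuts ("micelle", "core", ...) or as ANDed
``field=value`` tokens over residue name, atom role, chain id and atom
name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord", "AtomSet", "ChainSequence", "MicelleSystem",
    "select", "solvation_shell", "unwrap_frame",
    "minimum_image", "pairwise_distances",
]


@dataclass(frozen=True)
class AtomRecord:
    """Single-atom view; ``coords`` in nm, ``mass`` in amu."""

    id: int
    element: str
    mass: float
    coords: tuple[float, float, float]
    chain_id: int
    residue_name: str
    residue_index: int
    atom_role: str
    name: str


@dataclass
class AtomSet:
    """One frame of coordinates plus per-atom annotation (units: nm, amu).

    ``chain_id`` is -1 for solvent and ions.  ``box`` is an orthorhombic
    periodic box edge vector or ``None`` for an isolated configuration.
    """

    coords: np.ndarray                  # (n, 3) nm
    masses: np.ndarray                  # (n,) amu
    elements: np.ndarray                # (n,) str
    chain_ids: np.ndarray               # (n,) int
    residue_names: np.ndarray           # (n,) str
    residue_indices: np.ndarray         # (n,) int, 0-based
    atom_roles: np.ndarray              # (n,) str
    names: np.ndarray                   # (n,) str
    box: np.ndarray | None = None       # (3,) nm
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.masses = np.asarray(self.masses, dtype=float)
        for attr in ("elements", "chain_ids", "residue_names",
                     "residue_indices", "atom_roles", "names"):
            setattr(self, attr, np.asarray(getattr(self, attr)))
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    def validate(self) -> None:
        """Check the container invariants; raises ``ValueError`` on breach."""
        n = len(self)
        if n == 0:
            raise ValueError("empty AtomSet")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.masses <= 0):
            raise ValueError("non-positive atomic mass")
        if self.total_mass <= 0:
            raise ValueError("non-positive total mass")
        if self.box is not None and np.any(self.box <= 0):
            raise ValueError("box edges must be positive")

    def center_of_mass(self, weights: np.ndarray | None = None) -> np.ndarray:
        w = self.masses if weights is None else np.asarray(weights, float)
        total = w.sum()
        if total == 0:
            raise ValueError("zero total weight")
        return (w[:, None] * self.coords).sum(axis=0) / total

    def subset(self, mask: np.ndarray) -> "AtomSet":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = mask
        else:
            idx = np.flatnonzero(mask)
        return AtomSet(
            coords=self.coords[idx].copy(),
            masses=self.masses[idx].copy(),
            elements=self.elements[idx].copy(),
            chain_ids=self.chain_ids[idx].copy(),
            residue_names=self.residue_names[idx].copy(),
            residue_indices=self.residue_indices[idx].copy(),
            atom_roles=self.atom_roles[idx].copy(),
            names=self.names[idx].copy(),
            box=None if self.box is None else self.box.copy(),
            frame_index=self.frame_index,
        )

    def copy(self) -> "AtomSet":
        return self.subset(np.ones(len(self), dtype=bool))

    def translated(self, shift: np.ndarray) -> "AtomSet":
        out = self.copy()
        out.coords = out.coords + np.asarray(shift, float)
        return out

    def atoms(self) -> Iterator[AtomRecord]:
        for i in range(len(self)):
            yield AtomRecord(
                id=i,
                element=str(self.elements[i]),
                mass=float(self.masses[i]),
                coords=tuple(self.coords[i]),
                chain_id=int(self.chain_ids[i]),
                residue_name=str(self.residue_names[i]),
                residue_index=int(self.residue_indices[i]),
                atom_role=str(self.atom_roles[i]),
                name=str(self.names[i]),
            )

    @classmethod
    def from_records(cls, records: Sequence[AtomRecord],
                     box: np.ndarray | None = None,
                     frame_index: int = 0) -> "AtomSet":
        return cls(
            coords=np.array([r.coords for r in records], float),
            masses=np.array([r.mass for r in records], float),
            elements=np.array([r.element for r in records]),
            chain_ids=np.array([r.chain_id for r in records], int),
            residue_names=np.array([r.residue_name for r in records]),
            residue_indices=np.array([r.residue_index for r in records], int),
            atom_roles=np.array([r.atom_role for r in records]),
            names=np.array([r.name for r in records]),
            box=box,
            frame_index=frame_index,
        )

    @classmethod
    def concatenate(cls, parts: Sequence["AtomSet"],
                    box: np.ndarray | None = None,
                    frame_index: int = 0) -> "AtomSet":
        return cls(
            coords=np.vstack([p.coords for p in parts]),
            masses=np.concatenate([p.masses for p in parts]),
            elements=np.concatenate([p.elements for p in parts]),
            chain_ids=np.concatenate([p.chain_ids for p in parts]),
            residue_names=np.concatenate([p.residue_names for p in parts]),
            residue_indices=np.concatenate(
                [p.residue_indices for p in parts]),
            atom_roles=np.concatenate([p.atom_roles for p in parts]),
            names=np.concatenate([p.names for p in parts]),
            box=box,
            frame_index=frame_index,
        )


@dataclass(frozen=True)
class ChainSequence:
    """Residue sequence of one amphiphilic chain.

    The default architecture is a block of 5 hydrophobic DEC residues
    followed by 20 hydrophilic residues (MOE with COE at the charged
    positions).  ``charge_positions`` is derived: exactly the 0-based
    indices holding COE.
    """

    residues: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = [r for r in self.residues if r not in ("DEC", "MOE", "COE")]
        if bad:
            raise ValueError(f"unknown residue token(s): {sorted(set(bad))}")

    @property
    def charge_positions(self) -> tuple[int, ...]:
        return tuple(i for i, r in enumerate(self.residues) if r == "COE")

    @property
    def n_charges(self) -> int:
        return len(self.charge_positions)

    def __len__(self) -> int:
        return len(self.residues)

    @classmethod
    def from_charge_positions(cls, charge_positions: Sequence[int],
                              n_residues: int = 25,
                              block_length: int = 5,
                              one_based: bool = False) -> "ChainSequence":
        """Build the standard diblock: ``block_length`` DEC then MOE with COE
        substituted at ``charge_positions`` (0-based unless ``one_based``).
        """
        pos = {p - 1 if one_based else p for p in charge_positions}
        if any(p < block_length or p >= n_residues for p in pos):
            raise ValueError(
                "charge positions must fall in the hydrophilic block "
                f"[{block_length}, {n_residues})")
        residues = tuple(
            "DEC" if i < block_length else ("COE" if i in pos else "MOE")
            for i in range(n_residues))
        return cls(residues)


@dataclass
class MicelleSystem:
    """Multi-frame micelle: frames, aggregation number and chain sequence."""

    frames: list[AtomSet]
    n_chains: int
    sequence: ChainSequence
    concentration: float = 0.0          # weight percent
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @classmethod
    def from_frames(cls, frames: list[AtomSet]) -> "MicelleSystem":
        """Reconstruct system-level structure from parsed frames: the
        aggregation number from the chain ids and the sequence from the
        residues of the first chain."""
        if not frames:
            raise ValueError("no frames")
        f0 = frames[0]
        chain_ids = np.unique(f0.chain_ids[f0.chain_ids >= 0])
        if chain_ids.size == 0:
            raise ValueError("no peptoid chains in input")
        first = f0.subset(f0.chain_ids == chain_ids[0])
        order = np.argsort(first.residue_indices, kind="stable")
        residues = []
        for i in order:
            ridx = int(first.residue_indices[i])
            if len(residues) <= ridx:
                residues.extend([None] * (ridx + 1 - len(residues)))
            residues[ridx] = str(first.residue_names[i])
        sequence = ChainSequence(tuple(r for r in residues if r))
        solute = f0.chain_ids >= 0
        concentration = 100.0 * f0.masses[solute].sum() / f0.total_mass
        return cls(frames=list(frames), n_chains=int(chain_ids.size),
                   sequence=sequence, concentration=float(concentration))

    def validate(self) -> None:
        for f in self.frames:
            f.validate()
            solute = (f.residue_names != "WAT") & (f.residue_names != "NA")
            chains = f.chain_ids[solute]
            if np.any(chains < 0) or np.any(chains >= self.n_chains):
                raise ValueError("solute atom outside the declared chains")
            if len(np.unique(chains)) != self.n_chains:
                raise ValueError("missing chain among solute atoms")
            n_na = int(np.sum(f.atom_roles == "sodium"))
            expected = self.n_chains * self.sequence.n_charges
            if n_na != expected:
                raise ValueError(
                    f"sodium count {n_na} != chains x charges {expected}")


# ---------------------------------------------------------------------------
# periodic geometry helpers (orthorhombic boxes only)

def minimum_image(disp: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    if box is None:
        return disp
    return disp - box * np.round(disp / box)


def pairwise_distances(a: np.ndarray, b: np.ndarray,
                       box: np.ndarray | None = None,
                       chunk: int = 2048) -> np.ndarray:
    """Dense (len(a), len(b)) minimum-image distance matrix, chunked."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    out = np.empty((a.shape[0], b.shape[0]))
    for lo in range(0, a.shape[0], chunk):
        hi = min(lo + chunk, a.shape[0])
        d = a[lo:hi, None, :] - b[None, :, :]
        d = minimum_image(d, box)
        out[lo:hi] = np.sqrt((d * d).sum(axis=-1))
    return out


def _wrapped(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    # cKDTree with boxsize requires coordinates strictly inside [0, box)
    w = np.mod(coords, box)
    return np.where(w >= box, 0.0, w)


def neighbor_pairs(a: np.ndarray, b: np.ndarray, cutoff: float,
                   box: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Indices (ia, ib) of pairs with minimum-image distance < cutoff."""
    if box is not None:
        ta = cKDTree(_wrapped(a, box), boxsize=box)
        tb = cKDTree(_wrapped(b, box), boxsize=box)
    else:
        ta, tb = cKDTree(a), cKDTree(b)
    pairs = ta.query_ball_tree(tb, cutoff)
    ia = np.concatenate([[i] * len(js) for i, js in enumerate(pairs)]) \
        if any(pairs) else np.empty(0, int)
    ib = np.concatenate([js for js in pairs if js]) \
        if any(pairs) else np.empty(0, int)
    ia, ib = np.asarray(ia, int), np.asarray(ib, int)
    if len(ia):
        d = np.linalg.norm(minimum_image(a[ia] - b[ib], box), axis=1)
        keep = d < cutoff          # strict <; tree query is <=
        ia, ib = ia[keep], ib[keep]
    return ia, ib


# ---------------------------------------------------------------------------
# selections

_NAMED_QUERIES = {
    "all": lambda a: np.ones(len(a), bool),
    "micelle": lambda a: (a.residue_names != "WAT") & (a.residue_names != "NA"),
    "core": lambda a: a.residue_names == "DEC",
    "corona": lambda a: (a.residue_names == "MOE") | (a.residue_names == "COE"),
    "water": lambda a: a.residue_names == "WAT",
    "sodium": lambda a: a.atom_roles == "sodium",
    "carboxylate": lambda a: np.isin(
        a.atom_roles, ("carboxylate_carbon", "carboxylate_oxygen")),
    "heavy": lambda a: a.elements != "H",
}


def selection_mask(atoms: AtomSet, query: str) -> np.ndarray:
    """Boolean mask for a selection expression.

    ``query`` is a named shortcut or whitespace-separated ``field=value``
    tokens combined with AND; fields: ``residue``, ``role``, ``chain``,
    ``name``, ``element``.  Named shortcuts may be mixed in as bare tokens.
    """
    mask = np.ones(len(atoms), bool)
    for token in query.split():
        if token.lower() == "and":
            continue
        if token in _NAMED_QUERIES:
            mask &= _NAMED_QUERIES[token](atoms)
            continue
        if "=" not in token:
            raise ValueError(f"unknown selection token: {token!r}")
        key, value = token.split("=", 1)
        key = key.lower()
        if key in ("residue", "residue_name", "resname"):
            mask &= atoms.residue_names == value.upper()
        elif key in ("role", "atom_role"):
            mask &= atoms.atom_roles == value
        elif key in ("chain", "chain_id"):
            mask &= atoms.chain_ids == int(value)
        elif key == "name":
            mask &= atoms.names == value
        elif key == "element":
            mask &= atoms.elements == value
        else:
            raise ValueError(f"unknown selection field: {key!r}")
    return mask


def select(atoms: AtomSet, query: str) -> AtomSet:
    """Subset of ``atoms`` matching ``query``, order preserved."""
    mask = selection_mask(atoms, query)
    if not mask.any():
        logger.warning("selection %r matched no atoms", query)
    return atoms.subset(mask)


# ---------------------------------------------------------------------------
# solvation shell

def solvation_shell(atoms: AtomSet, solute_query: str = "micelle",
                    cutoff: float = 0.35,
                    heavy_only: bool = False) -> AtomSet:
    """Solute plus every water molecule whose oxygen lies within ``cutoff``
    (nm, strict <) of any solute atom.

    Whole water molecules are included: the oxygen decides membership and
    its hydrogens follow, so mass-weighted descriptors of the augmented set
    stay physical.  Minimum-image distances are used when a box is present.
    ``heavy_only`` restricts the solute side of the distance test to
    non-hydrogen atoms.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    solute_mask = selection_mask(atoms, solute_query)
    if not solute_mask.any():
        raise ValueError(f"solute selection {solute_query!r} is empty")
    probe_mask = solute_mask & (atoms.elements != "H") if heavy_only \
        else solute_mask
    ow_mask = atoms.atom_roles == "water_oxygen"
    if not ow_mask.any():
        raise ValueError("no water oxygens present")
    if atoms.box is None:
        span = atoms.coords.max(axis=0) - atoms.coords.min(axis=0)
        logger.debug("non-periodic solvation shell, extent %s nm", span)
    ow_idx = np.flatnonzero(ow_mask)
    _, hit = neighbor_pairs(atoms.coords[probe_mask], atoms.coords[ow_idx],
                            cutoff, atoms.box)
    hit_oxygens = ow_idx[np.unique(hit)]
    # whole-molecule inclusion: a water molecule is one WAT residue
    keys = atoms.chain_ids * (atoms.residue_indices.max() + 2) \
        + atoms.residue_indices
    hit_keys = np.unique(keys[hit_oxygens])
    water_mask = (atoms.residue_names == "WAT") & np.isin(keys, hit_keys)
    return atoms.subset(solute_mask | water_mask)


# ---------------------------------------------------------------------------
# unwrapping (make the micelle whole across periodic boundaries)

def unwrap_frame(atoms: AtomSet) -> AtomSet:
    """Undo periodic wrapping so the micelle is geometrically whole.

    Within each chain, atoms are chained by minimum image from the chain's
    first atom; chains are then shifted as rigid units so their centers sit
    in the image nearest the first chain.  Waters and ions are moved to the
    image nearest the reassembled micelle's center of mass.  A no-op when
    the set has no box.
    """
    if atoms.box is None:
        return atoms
    out = atoms.copy()
    box = out.box
    chain_ids = np.unique(out.chain_ids[out.chain_ids >= 0])
    anchor_com = None
    for cid in chain_ids:
        idx = np.flatnonzero(out.chain_ids == cid)
        xyz = out.coords[idx]
        steps = minimum_image(np.diff(xyz, axis=0), box)
        xyz = np.vstack([xyz[0], xyz[0] + np.cumsum(steps, axis=0)])
        if anchor_com is None:
            anchor_com = xyz.mean(axis=0)
        else:
            com = xyz.mean(axis=0)
            xyz = xyz - box * np.round((com - anchor_com) / box)
        out.coords[idx] = xyz
    if anchor_com is not None:
        solute = out.chain_ids >= 0
        mic_com = out.subset(solute).center_of_mass()
        # shift each solvent/ion molecule to the image nearest the micelle
        other = np.flatnonzero(~solute)
        if other.size:
            keys = out.residue_indices[other] * 8 + np.where(
                out.residue_names[other] == "WAT", 0, 1)
            for key in np.unique(keys):
                idx = other[keys == key]
                ref = out.coords[idx[0]]
                shift = -box * np.round((ref - mic_com) / box)
                out.coords[idx] += shift
    return out
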