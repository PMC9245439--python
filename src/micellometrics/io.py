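"""Configuration readers and writers (PDB and GRO dialects).

Parsing and serialization are delegated to MDAnalysis; this module maps
between its Universe and the package's :class:`~micellometrics.model.AtomSet`
(nm units internally, PDB Angstrom converted on read), infers atom roles,
masses and elements from the documented residue/atom-name table, and
reconstructs chain membership.

Chain bookkeeping across formats: PDB files carry chains in the segment id
column (``C000``, ``C001``, ... for peptoid chains, ``SOL``/``ION`` for
solvent).  GRO files have no chain field, so chains are written with
residue numbers restarting at 1 per chain and recovered from those resets
on read; water and sodium residues (identified by name) are chain ``-1``.

Multi-frame input: PDB via MODEL records; GRO as concatenated single-frame
blocks, split on the atom-count header of each block.
"""

from __future__ import annotations

import os
import tempfile
import warnings

import numpy as np

from . import chemistry
from .model import AtomSet

__all__ = ["read_configuration", "read_trajectory", "write_configuration",
           "ConfigurationError"]

_ANGSTROM_PER_NM = 10.0


class ConfigurationError(ValueError):
    """Raised for unreadable or chemically unidentifiable input."""


def _guess_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in ("pdb", "gro"):
        return ext
    raise ConfigurationError(
        f"cannot infer format from {path!r}; pass format='pdb' or 'gro'")


def _annotate(resname_raw: str, atom_name: str,
              role_table: dict) -> tuple[str, str, str, float]:
    try:
        resname = chemistry.canonical_residue(resname_raw)
    except KeyError:
        raise ConfigurationError(
            f"unknown residue token {resname_raw!r}") from None
    key = (resname, atom_name)
    if key not in role_table:
        raise ConfigurationError(
            f"no role mapping for atom {atom_name!r} in residue {resname!r}")
    element, role, mass = role_table[key]
    return resname, element, role, mass


def _universe_to_atomsets(u, role_table: dict,
                          frame_offset: int = 0) -> list[AtomSet]:
    import MDAnalysis as mda  # noqa: F401  (loaded lazily with the module)

    n = u.atoms.n_atoms
    raw_resnames = u.atoms.resnames
    names = u.atoms.names
    resids = u.atoms.resids
    segids = u.atoms.segids if hasattr(u.atoms, "segids") else [""] * n

    resnames = np.empty(n, dtype=object)
    elements = np.empty(n, dtype=object)
    roles = np.empty(n, dtype=object)
    masses = np.empty(n, dtype=float)
    for i in range(n):
        resnames[i], elements[i], roles[i], masses[i] = _annotate(
            str(raw_resnames[i]), str(names[i]).strip(), role_table)

    # chain ids: segid C### when present, else resid resets among peptoid
    # residues (GRO); solvent and ions are chain -1
    chain_ids = np.full(n, -1, dtype=int)
    peptoid = np.isin(resnames.astype(str), ("DEC", "MOE", "COE"))
    seg_based = False
    for i in np.flatnonzero(peptoid):
        seg = str(segids[i]).strip()
        if seg.startswith("C") and seg[1:].isdigit():
            chain_ids[i] = int(seg[1:])
            seg_based = True
    if not seg_based and peptoid.any():
        chain = -1
        prev_resid = None
        for i in np.flatnonzero(peptoid):
            rid = int(resids[i])
            if prev_resid is None or rid < prev_resid:
                chain += 1
            chain_ids[i] = chain
            prev_resid = rid

    # residue indices: 0-based within a chain for peptoids; globally unique
    # (and disjoint from each other) for solvent/ion molecules
    residue_indices = np.zeros(n, dtype=int)
    prev = (None, None)
    counter = -1
    for i in range(n):
        if peptoid[i]:
            residue_indices[i] = int(resids[i]) - 1
            continue
        key = (str(resnames[i]), int(resids[i]))
        if key != prev:
            counter += 1
            prev = key
        residue_indices[i] = counter

    frames = []
    for ts in u.trajectory:
        box = None
        if ts.dimensions is not None and ts.dimensions[:3].min() > 0:
            box = np.asarray(ts.dimensions[:3], float) / _ANGSTROM_PER_NM
        frames.append(AtomSet(
            coords=u.atoms.positions.astype(float) / _ANGSTROM_PER_NM,
            masses=masses.copy(),
            elements=elements.astype(str),
            chain_ids=chain_ids.copy(),
            residue_names=resnames.astype(str),
            residue_indices=residue_indices.copy(),
            atom_roles=roles.astype(str),
            names=np.asarray([str(x).strip() for x in names]),
            box=box,
            frame_index=frame_offset + len(frames),
        ))
    return frames


def _pdb_header_box(path: str) -> np.ndarray | None:
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                edges = np.array([float(line[6:15]), float(line[15:24]),
                                  float(line[24:33])])
                if edges.min() > 1.0:     # ignore placeholder unit cells
                    return edges / _ANGSTROM_PER_NM
            if line.startswith(("ATOM", "HETATM")):
                break
    return None


def _split_gro_blocks(text: str) -> list[str]:
    lines = text.splitlines()
    blocks = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i + 1].strip())
        except (IndexError, ValueError):
            raise ConfigurationError("malformed GRO block header")
        end = i + n + 3
        if end > len(lines):
            raise ConfigurationError("truncated GRO frame")
        blocks.append("\n".join(lines[i:end]) + "\n")
        i = end
    return blocks


def read_trajectory(path: str, format: str | None = None,
                    role_table: dict | None = None) -> list[AtomSet]:
    """Read a single- or multi-frame configuration file into AtomSets."""
    import MDAnalysis as mda

    fmt = _guess_format(path, format)
    table = chemistry.ROLE_TABLE if role_table is None else role_table
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fmt == "pdb":
            u = mda.Universe(path)
            frames = _universe_to_atomsets(u, table)
            if any(f.box is None for f in frames):
                box = _pdb_header_box(path)
                if box is not None:
                    for f in frames:
                        f.box = box.copy()
            return frames
        if fmt == "gro":
            with open(path) as fh:
                blocks = _split_gro_blocks(fh.read())
            frames = []
            for k, block in enumerate(blocks):
                with tempfile.NamedTemporaryFile(
                        "w", suffix=".gro", delete=False) as tmp:
                    tmp.write(block)
                    tmp_path = tmp.name
                try:
                    u = mda.Universe(tmp_path)
                    frames.extend(_universe_to_atomsets(u, table,
                                                        frame_offset=k))
                finally:
                    os.remove(tmp_path)
            return frames
    raise ConfigurationError(f"unsupported format {fmt!r}")


def read_configuration(path: str, format: str | None = None,
                       frame: int = 0,
                       role_table: dict | None = None) -> AtomSet:
    """Read one frame (default the first) from a configuration file."""
    frames = read_trajectory(path, format=format, role_table=role_table)
    if not 0 <= frame < len(frames):
        raise ConfigurationError(
            f"frame {frame} out of range (file has {len(frames)})")
    return frames[frame]


def _atomset_to_universe(atoms: AtomSet):
    import MDAnalysis as mda

    n = len(atoms)
    # residues: consecutive runs of (chain, residue_index, resname)
    keys = list(zip(atoms.chain_ids.tolist(),
                    atoms.residue_indices.tolist(),
                    atoms.residue_names.tolist()))
    resindex = np.zeros(n, dtype=int)
    res_keys = []
    for i, key in enumerate(keys):
        if not res_keys or key != res_keys[-1]:
            res_keys.append(key)
        resindex[i] = len(res_keys) - 1

    def segid_for(chain_id: int, resname: str) -> str:
        if chain_id >= 0:
            return f"C{chain_id:03d}"
        return "ION" if resname == "NA" else "SOL"

    res_segids = [segid_for(c, rn) for c, _, rn in res_keys]
    seg_names = list(dict.fromkeys(res_segids))
    seg_index = {s: i for i, s in enumerate(seg_names)}
    residue_segindex = np.array([seg_index[s] for s in res_segids], int)

    # per-chain 1-based residue numbering (resets mark chain boundaries
    # in chain-less formats); solvent numbered per molecule
    resids = []
    counters: dict[str, int] = {}
    for (chain_id, _, resname), segid in zip(res_keys, res_segids):
        counters[segid] = counters.get(segid, 0) + 1
        resids.append((counters[segid] - 1) % 99999 + 1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n, n_residues=len(res_keys), n_segments=len(seg_names),
            atom_resindex=resindex, residue_segindex=residue_segindex,
            trajectory=True)
        u.add_TopologyAttr("names", atoms.names.tolist())
        u.add_TopologyAttr("resnames", [rn for _, _, rn in res_keys])
        u.add_TopologyAttr("resids", resids)
        u.add_TopologyAttr("segids", seg_names)
        u.add_TopologyAttr("elements", atoms.elements.tolist())
        u.add_TopologyAttr("masses", atoms.masses.tolist())
    return u


def write_configuration(frames: AtomSet | list[AtomSet], path: str,
                        format: str | None = None) -> None:
    """Write one or more frames to a PDB or GRO file (multi-frame PDB uses
    MODEL records; multi-frame GRO is concatenated blocks)."""
    import MDAnalysis as mda

    if isinstance(frames, AtomSet):
        frames = [frames]
    if not frames:
        raise ConfigurationError("nothing to write")
    fmt = _guess_format(path, format)
    u = _atomset_to_universe(frames[0])

    def load(frame: AtomSet) -> None:
        u.atoms.positions = frame.coords * _ANGSTROM_PER_NM
        if frame.box is not None:
            u.dimensions = [*(frame.box * _ANGSTROM_PER_NM), 90, 90, 90]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fmt == "pdb":
            with mda.Writer(path, multiframe=len(frames) > 1,
                            n_atoms=len(frames[0])) as w:
                for frame in frames:
                    load(frame)
                    w.write(u.atoms)
        elif fmt == "gro":
            load(frames[0])
            with mda.Writer(path, n_atoms=len(frames[0])) as w:
                w.write(u.atoms)
            if len(frames) > 1:
                buf = [open(path).read()]
                for frame in frames[1:]:
                    load(frame)
                    tmp = path + ".part.gro"
                    with mda.Writer(tmp, n_atoms=len(frame)) as w:
                        w.write(u.atoms)
                    buf.append(open(tmp).read())
                    os.remove(tmp)
                with open(path, "w") as fh:
                    fh.write("".join(buf))
        else:
            raise ConfigurationError(f"unsupported format {fmt!r}")
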