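"""Synthetic micelle configurations with planted ground truth.

The generator emulates the equilibrium morphology of a sequence-defined
amphiphilic peptoid micelle: an ellipsoidal hydrophobic core of DEC beads,
a hydrophilic MOE/COE corona with carboxylate groups biased to the outer
surface, one sodium counterion per carboxylate (a chosen fraction planted
inside the 0.35 nm condensation shell of a carboxylate oxygen, the rest
dispersed in the solvent region), an optional number of planted
COO-Na-COO salt bridges between chains, and an explicit hydration shell
of rigid three-site waters.  Everything is reproducible from the seed.

The planted quantities (condensed-ion count, bridge geometry) are exact
in the first frame; later frames add Gaussian jitter and are exact within
the jitter scale.  Geometry is placement, not physics: there is no force
field and no dynamics, so the configurations probe the analysis code, not
peptoid thermodynamics.

Ideal geometric bodies (solid sphere, rod, disk, ellipsoid) with known
closed-form descriptors are provided as fixtures for the shape machinery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import chemistry
from .model import AtomSet, ChainSequence, MicelleSystem

__all__ = ["SyntheticMicelleSpec", "IdealBodySpec", "generate_micelle",
           "generate_ideal_body", "CHAIN_PRESETS", "preset_spec"]

_MIN_SEPARATION = 0.25      # nm, hard floor between inserted beads
_CONDENSATION_CUTOFF = 0.35  # nm, Na-O(carboxylate) condensation shell
_BRIDGE_CUTOFF = 0.5        # nm, Na-C(carboxylate) salt-bridge shell
_CO_BOND = 0.125            # nm, carboxylate C-O distance


@dataclass(frozen=True)
class SyntheticMicelleSpec:
    """Parameters of one synthetic micelle system.

    Defaults correspond to the largest singly charged system of the study
    series: aggregation number 28, 25-mer chains with a 5-residue DEC
    block and a single terminal carboxylate.  Lengths in nm, water density
    in molecules/nm^3.
    """

    n_chains: int = 28
    sequence: ChainSequence = field(
        default_factory=lambda: ChainSequence.from_charge_positions(
            [25], one_based=True))
    core_radius: float = 1.5
    corona_thickness: float = 1.5
    water_shell_thickness: float = 0.6
    water_density: float = chemistry.WATER_NUMBER_DENSITY_NM3
    na_condensation_fraction: float = 0.0
    planted_salt_bridges: int = 0
    aspect_ratios: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_frames: int = 1
    jitter_sigma: float = 0.01
    box_edge: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.na_condensation_fraction <= 1.0:
            raise ValueError("na_condensation_fraction must be in [0, 1]")
        if min(self.aspect_ratios) <= 0:
            raise ValueError("aspect ratios must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if min(self.core_radius, self.corona_thickness,
               self.water_shell_thickness) <= 0:
            raise ValueError("geometry lengths must be positive")
        n_na = self.n_chains * self.sequence.n_charges
        n_cond = round(self.na_condensation_fraction * n_na)
        if n_cond + self.planted_salt_bridges > n_na:
            raise ValueError(
                "condensed ions plus planted bridges exceed the sodium count")
        if self.planted_salt_bridges > 0 and self.n_chains < 2:
            raise ValueError("planted bridges need at least two chains")
        if 2 * self.planted_salt_bridges > n_na:
            raise ValueError("not enough carboxylate groups for the bridges")


@dataclass(frozen=True)
class IdealBodySpec:
    """Monte-Carlo point cloud of an ideal geometric body.

    ``kind``: solid_sphere (radius), rod (length), disk (radius),
    ellipsoid (semi_axes).  Equal point masses.
    """

    kind: str
    radius: float = 1.0
    length: float = 1.0
    semi_axes: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_points: int = 1000
    mass_per_point: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in ("solid_sphere", "rod", "disk", "ellipsoid"):
            raise ValueError(f"unknown body kind {self.kind!r}")
        if self.n_points < 4:
            raise ValueError("n_points must be >= 4")
        if min(self.radius, self.length, *self.semi_axes) <= 0:
            raise ValueError("sizes must be positive")
        if self.mass_per_point <= 0:
            raise ValueError("mass_per_point must be positive")


# Study-series presets: aggregation number and Table-derived water counts
# per system.  The charge positions of chains 2-8 are published only as a
# sequence diagram, so the positions below are approximate placements
# consistent with the described trend (charges moving from the chain
# terminus toward the hydrophobic/hydrophilic junction).
CHAIN_PRESETS: dict[str, dict] = {
    "chain1": dict(n_chains=28, charge_positions=[25], n_waters=516703),
    "chain2": dict(n_chains=25, charge_positions=[20], n_waters=461503),
    "chain3": dict(n_chains=23, charge_positions=[15], n_waters=434591),
    "chain4": dict(n_chains=18, charge_positions=[10], n_waters=332282),
    "chain5": dict(n_chains=13, charge_positions=[6], n_waters=239960),
    "chain6": dict(n_chains=18, charge_positions=[21, 23, 25],
                   n_waters=369782),
    "chain7": dict(n_chains=17, charge_positions=[13, 15, 17],
                   n_waters=315291),
    "chain8": dict(n_chains=12, charge_positions=[6, 8, 10],
                   n_waters=206465),
}


def preset_spec(name: str, **overrides) -> SyntheticMicelleSpec:
    """Spec for one of the study-series systems ``chain1`` .. ``chain8``.

    Charge positions are 1-based along the 25-mer and approximate for the
    systems whose exact positions are published only graphically.
    """
    if name not in CHAIN_PRESETS:
        raise KeyError(f"unknown preset {name!r}; "
                       f"choose from {sorted(CHAIN_PRESETS)}")
    p = CHAIN_PRESETS[name]
    base = dict(
        n_chains=p["n_chains"],
        sequence=ChainSequence.from_charge_positions(
            p["charge_positions"], one_based=True),
    )
    base.update(overrides)
    return SyntheticMicelleSpec(**base)


# ---------------------------------------------------------------------------

def _fibonacci_directions(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def _orthonormal_frame(u: np.ndarray,
                       rng: np.random.Generator) -> tuple[np.ndarray,
                                                          np.ndarray]:
    """Two unit vectors spanning the plane orthogonal to u."""
    trial = rng.normal(size=3)
    t1 = trial - u * (trial @ u)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(u, t1)
    return t1, t2


class _Bead:
    __slots__ = ("pos", "element", "role", "mass", "chain", "resname",
                 "resindex", "name")

    def __init__(self, pos, element, role, mass, chain, resname, resindex,
                 name):
        self.pos = np.asarray(pos, float)
        self.element = element
        self.role = role
        self.mass = mass
        self.chain = chain
        self.resname = resname
        self.resindex = resindex
        self.name = name


def _place_chain(chain_id: int, direction: np.ndarray,
                 spec: SyntheticMicelleSpec,
                 rng: np.random.Generator) -> list[_Bead]:
    """Radial layout of one chain: DEC block inside the core ellipsoid,
    hydrophilic block spiralling outward through the corona, carboxylate
    residues bulged toward the outer surface.

    Backbone beads follow a helical path around the chain's radial
    direction so consecutive beads keep realistic ~0.2-0.3 nm spacing even
    though the corona is thinner than the chain contour length; side-chain
    beads alternate sides of the path.
    """
    aspect = np.asarray(spec.aspect_ratios, float)
    seq = spec.sequence.residues
    n_core = sum(1 for r in seq if r == "DEC")
    n_corona = len(seq) - n_core
    t1, t2 = _orthonormal_frame(direction, rng)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    omega = 0.55                   # helical advance per residue, rad
    beads: list[_Bead] = []
    corona_seen = 0
    for ridx, resname in enumerate(seq):
        if resname == "DEC":
            frac = 0.30 + 0.65 * (ridx + 0.5) / max(n_core, 1)
            radius = frac * spec.core_radius
            amplitude = 0.15
        else:
            frac = (corona_seen + 0.5) / max(n_corona, 1)
            radius = spec.core_radius + frac * spec.corona_thickness
            corona_seen += 1
            amplitude = 0.45
        if resname == "COE":
            # carboxylate sites biased to the outer corona surface
            radius = max(radius, spec.core_radius
                         + 0.80 * spec.corona_thickness)
        ang = phase + omega * ridx
        trans = amplitude * (np.cos(ang) * t1 + np.sin(ang) * t2)
        base = radius * direction * aspect + trans
        side = np.cos(ang + np.pi / 2) * t1 + np.sin(ang + np.pi / 2) * t2
        if resname == "COE":
            placement = {
                "BB": base,
                "SC": base + 0.15 * direction,
                "CG": base + 0.30 * direction,
                "OD1": base + 0.30 * direction
                + _CO_BOND * (0.55 * direction + 0.835 * side),
                "OD2": base + 0.30 * direction
                + _CO_BOND * (0.55 * direction - 0.835 * side),
            }
        else:
            sign = 1.0 if ridx % 2 else -1.0
            placement = {"BB": base, "SC": base + 0.28 * sign * side}
        for name, elem, role, mass in chemistry.BEAD_LAYOUT[resname]:
            beads.append(_Bead(placement[name], elem, role, mass,
                               chain_id, resname, ridx, name))
    return beads


def _relocate_bridge_groups(beads: list[_Bead],
                            spec: SyntheticMicelleSpec,
                            rng: np.random.Generator) -> list[np.ndarray]:
    """Move ``planted_salt_bridges`` pairs of carboxylate groups from
    different chains onto shared surface sites and return the sodium
    positions that bridge them.

    Geometry per bridge: the two carboxylate carbons sit 0.45 nm apart
    tangentially on the corona surface; the sodium sits 0.35 nm outward of
    their midpoint (0.416 nm from each carbon, inside the 0.5 nm bridge
    shell) while both carboxylates point their oxygens inward, keeping the
    sodium > 0.35 nm from every oxygen so a planted bridge never counts as
    a condensed ion.
    """
    k = spec.planted_salt_bridges
    if k == 0:
        return []
    groups: dict[tuple[int, int], list[_Bead]] = {}
    for b in beads:
        if b.role in ("carboxylate_carbon", "carboxylate_oxygen",
                      "backbone", "sidechain") and b.resname == "COE":
            groups.setdefault((b.chain, b.resindex), []).append(b)
    keys = sorted(groups)
    chains = sorted({c for c, _ in keys})
    # pair groups from distinct chains, each group used at most once
    pairs = []
    used = set()
    chain_cycle = [(c1, c2) for i, c1 in enumerate(chains)
                   for c2 in chains[i + 1:]]
    ci = 0
    while len(pairs) < k and ci < len(chain_cycle) * 4:
        c1, c2 = chain_cycle[ci % len(chain_cycle)]
        ci += 1
        g1 = next((g for g in keys if g[0] == c1 and g not in used), None)
        g2 = next((g for g in keys if g[0] == c2 and g not in used), None)
        if g1 and g2:
            used.update((g1, g2))
            pairs.append((g1, g2))
    if len(pairs) < k:
        raise ValueError("cannot pair enough carboxylate groups for the "
                         "requested planted bridges")
    r_site = spec.core_radius + spec.corona_thickness
    sites = _fibonacci_directions(max(2 * k, 8))[::2][:k]
    na_positions = []
    for (g1, g2), normal in zip(pairs, sites):
        t1, t2 = _orthonormal_frame(normal, rng)
        mid = r_site * normal
        for g, sign in ((g1, 1.0), (g2, -1.0)):
            carbon = mid + sign * 0.225 * t1
            placement = {
                "CG": carbon,
                "OD1": carbon + _CO_BOND * (-0.8 * normal + 0.6 * t2),
                "OD2": carbon + _CO_BOND * (-0.8 * normal - 0.6 * t2),
                "SC": carbon - 0.18 * normal + sign * 0.10 * t1,
                "BB": carbon - 0.36 * normal + sign * 0.20 * t1,
            }
            for b in groups[g]:
                b.pos = placement[b.name]
        na_positions.append(mid + 0.35 * normal)
    return na_positions


def _sample_shell(n: int, r_in: float, r_out: float,
                  aspect: np.ndarray, rng: np.random.Generator,
                  oversample: int = 1) -> np.ndarray:
    """Uniform points in the ellipsoidal shell scale*[r_in, r_out]."""
    m = max(int(n * oversample), n)
    u = rng.random(m)
    r = (r_in ** 3 + u * (r_out ** 3 - r_in ** 3)) ** (1.0 / 3.0)
    v = rng.normal(size=(m, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return r[:, None] * v * aspect


def _pack_waters(n_target: int, r_in: float, r_out: float,
                 aspect: np.ndarray, occupied: np.ndarray,
                 rng: np.random.Generator,
                 min_sep: float = _MIN_SEPARATION,
                 max_rounds: int = 60) -> np.ndarray:
    """Rejection-sample ``n_target`` oxygen sites in the hydration shell,
    keeping every site >= min_sep from occupied beads and from each other."""
    accepted: list[np.ndarray] = []
    occ_tree = cKDTree(occupied) if len(occupied) else None
    for _ in range(max_rounds):
        need = n_target - len(accepted)
        if need <= 0:
            break
        cand = _sample_shell(2 * need + 64, r_in, r_out, aspect, rng)
        if occ_tree is not None:
            bad = occ_tree.query_ball_point(cand, min_sep)
            cand = cand[[not b for b in bad]]
        if accepted:
            acc_tree = cKDTree(np.asarray(accepted))
            bad = acc_tree.query_ball_point(cand, min_sep)
            cand = cand[[not b for b in bad]]
        # greedy mutual acceptance within the candidate batch
        if len(cand):
            ctree = cKDTree(cand)
            conflict = ctree.query_pairs(min_sep, output_type="ndarray")
            drop = set()
            for i, j in conflict:
                if i not in drop:
                    drop.add(j)
            for i, c in enumerate(cand):
                if i not in drop and len(accepted) < n_target:
                    accepted.append(c)
    if len(accepted) < n_target:
        raise RuntimeError(
            f"water packing infeasible: placed {len(accepted)} of "
            f"{n_target} at density with {min_sep} nm separation")
    return np.asarray(accepted[:n_target])


def _water_molecules(oxygens: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """(n, 3, 3) rigid-water sites (O, H1, H2) with random orientation."""
    n = len(oxygens)
    half = np.deg2rad(chemistry.WATER_HOH_DEG / 2.0)
    out = np.empty((n, 3, 3))
    axes = rng.normal(size=(n, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    for i in range(n):
        t1, t2 = _orthonormal_frame(axes[i], rng)
        h1 = axes[i] * np.cos(half) + t1 * np.sin(half)
        h2 = axes[i] * np.cos(half) - t1 * np.sin(half)
        out[i, 0] = oxygens[i]
        out[i, 1] = oxygens[i] + chemistry.WATER_OH_NM * h1
        out[i, 2] = oxygens[i] + chemistry.WATER_OH_NM * h2
    return out


def generate_micelle(spec: SyntheticMicelleSpec) -> MicelleSystem:
    """Build a :class:`MicelleSystem` from ``spec`` (deterministic in the
    seed).  Planted ground truth is recorded in ``system.metadata``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    aspect = np.asarray(spec.aspect_ratios, float)

    directions = _fibonacci_directions(spec.n_chains)
    # random global rotation so different seeds give different geometry
    q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    directions = directions @ q.T

    beads: list[_Bead] = []
    for cid in range(spec.n_chains):
        beads.extend(_place_chain(cid, directions[cid], spec, rng))

    na_bridge = _relocate_bridge_groups(beads, spec, rng)

    # resolve residual inter-chain clashes by small jitters (pairs within
    # the same or bonded-neighbor residues of one chain are exempt: bonded
    # beads legitimately sit closer than the non-bonded floor)
    coords = np.array([b.pos for b in beads])
    frozen = {(b.chain, b.resindex) for b in beads if b.resname == "COE"} \
        if spec.planted_salt_bridges else set()
    for _ in range(40):
        tree = cKDTree(coords)
        close = tree.query_pairs(_MIN_SEPARATION, output_type="ndarray")
        if len(close) == 0:
            break
        bonded = np.array(
            [beads[i].chain == beads[j].chain
             and abs(beads[i].resindex - beads[j].resindex) <= 1
             for i, j in close], bool)
        clash = close[~bonded]
        if len(clash) == 0:
            break
        for i, j in clash:
            k = j if (beads[j].chain, beads[j].resindex) not in frozen \
                else i
            if (beads[k].chain, beads[k].resindex) in frozen:
                continue
            coords[k] += rng.normal(0.0, 0.05, size=3)
    for b, c in zip(beads, coords):
        b.pos = c

    oxygens = np.array([b.pos for b in beads
                        if b.role == "carboxylate_oxygen"])
    carbons = np.array([b.pos for b in beads
                        if b.role == "carboxylate_carbon"])
    n_na = spec.n_chains * spec.sequence.n_charges
    n_cond = round(spec.na_condensation_fraction * n_na)
    n_free = n_na - n_cond - len(na_bridge)

    na_positions: list[np.ndarray] = list(na_bridge)

    # condensed ions: 0.28 nm from a carboxylate oxygen of a non-bridge group
    if n_cond:
        group_oxy: dict[tuple[int, int], list[np.ndarray]] = {}
        for b in beads:
            if b.role == "carboxylate_oxygen":
                group_oxy.setdefault((b.chain, b.resindex), []).append(b.pos)
        candidates = sorted(group_oxy)
        if spec.planted_salt_bridges and na_bridge:
            na_arr = np.asarray(na_bridge)
            candidates = [
                g for g in candidates
                if np.min(np.linalg.norm(
                    na_arr - np.mean(group_oxy[g], axis=0), axis=1)) > 0.9]
        if not candidates:
            raise ValueError("no carboxylate groups free for condensation")
        for k in range(n_cond):
            g = candidates[k % len(candidates)]
            oxy = group_oxy[g][k % 2]
            for _ in range(200):
                d = rng.normal(size=3)
                d /= np.linalg.norm(d)
                pos = oxy + 0.28 * d
                d_all = np.linalg.norm(oxygens - pos, axis=1)
                if d_all.min() > 0.20 and d_all.min() < _CONDENSATION_CUTOFF:
                    break
            na_positions.append(pos)

    # free ions: dispersed in the hydration shell, outside every
    # condensation shell and away from bridge geometry
    r_cor = spec.core_radius + spec.corona_thickness
    r_out = r_cor + spec.water_shell_thickness
    placed = np.array([b.pos for b in beads])
    count = 0
    attempts = 0
    while count < n_free:
        attempts += 1
        if attempts > 200:
            raise RuntimeError(
                f"free-ion placement infeasible: placed {count} of {n_free}")
        cand = _sample_shell(8 * max(n_free, 4), r_cor + 0.1, r_out,
                             aspect, rng)
        for pos in cand:
            if count >= n_free:
                break
            if len(oxygens) and np.min(np.linalg.norm(
                    oxygens - pos, axis=1)) < _CONDENSATION_CUTOFF + 0.10:
                continue
            if len(carbons) and np.min(np.linalg.norm(
                    carbons - pos, axis=1)) < _BRIDGE_CUTOFF + 0.05:
                continue
            if np.min(np.linalg.norm(placed - pos, axis=1)) \
                    < _MIN_SEPARATION:
                continue
            if na_positions and np.min(np.linalg.norm(
                    np.asarray(na_positions) - pos, axis=1)) \
                    < _MIN_SEPARATION:
                continue
            na_positions.append(pos)
            count += 1

    # hydration shell waters
    shell_volume = 4.0 / 3.0 * np.pi * np.prod(aspect) \
        * (r_out ** 3 - r_cor ** 3)
    n_waters = int(round(spec.water_density * shell_volume))
    occupied = np.vstack([placed, np.asarray(na_positions)]) \
        if na_positions else placed
    ow = _pack_waters(n_waters, r_cor, r_out, aspect, occupied, rng)
    waters = _water_molecules(ow, rng)

    # assemble arrays; solvent/ion residue indices globally unique
    solvent_resindex = 0
    records: list[_Bead] = list(beads)
    for w in waters:
        for name, elem, role, mass in chemistry.BEAD_LAYOUT["WAT"]:
            pos = {"OW": w[0], "HW1": w[1], "HW2": w[2]}[name]
            records.append(_Bead(pos, elem, role, mass, -1, "WAT",
                                 solvent_resindex, name))
        solvent_resindex += 1
    for pos in na_positions:
        records.append(_Bead(pos, "Na", "sodium", chemistry.MASS_SODIUM,
                             -1, "NA", solvent_resindex, "NA"))
        solvent_resindex += 1

    edge = spec.box_edge if spec.box_edge is not None \
        else float(np.ceil(2.0 * r_out * max(aspect) + 2.0))
    box = np.array([edge, edge, edge])
    center = box / 2.0

    base = AtomSet(
        coords=np.array([r.pos for r in records]) + center,
        masses=np.array([r.mass for r in records]),
        elements=np.array([r.element for r in records]),
        chain_ids=np.array([r.chain for r in records], int),
        residue_names=np.array([r.resname for r in records]),
        residue_indices=np.array([r.resindex for r in records], int),
        atom_roles=np.array([r.role for r in records]),
        names=np.array([r.name for r in records]),
        box=box,
        frame_index=0,
    )
    frames = [base]
    for f in range(1, spec.n_frames):
        jit = base.copy()
        jit.coords = base.coords + rng.normal(
            0.0, spec.jitter_sigma, size=base.coords.shape)
        jit.frame_index = f
        frames.append(jit)

    peptoid_mass = sum(b.mass for b in beads)
    total_mass = float(base.masses.sum())
    system = MicelleSystem(
        frames=frames,
        n_chains=spec.n_chains,
        sequence=spec.sequence,
        concentration=100.0 * peptoid_mass / total_mass,
        metadata={
            "spec": dataclasses.asdict(spec) | {
                "sequence": list(spec.sequence.residues)},
            "planted": {
                "n_sodium": n_na,
                "n_condensed": n_cond,
                "n_free": n_free,
                "n_bridges": len(na_bridge),
            },
        },
    )
    system.validate()
    return system


# ---------------------------------------------------------------------------

def generate_ideal_body(spec: IdealBodySpec) -> AtomSet:
    """Equal-mass point cloud of an ideal body (all beads DEC side-chain
    beads so shape selections treat them as micelle material)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_points
    if spec.kind == "solid_sphere":
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = spec.radius * rng.random(n) ** (1.0 / 3.0)
        coords = r[:, None] * v
    elif spec.kind == "rod":
        t = rng.random(n) - 0.5
        coords = np.zeros((n, 3))
        coords[:, 0] = t * spec.length
    elif spec.kind == "disk":
        r = spec.radius * np.sqrt(rng.random(n))
        theta = 2.0 * np.pi * rng.random(n)
        coords = np.stack([r * np.cos(theta), r * np.sin(theta),
                           np.zeros(n)], axis=1)
    else:  # ellipsoid
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = rng.random(n) ** (1.0 / 3.0)
        coords = r[:, None] * v * np.asarray(spec.semi_axes)
    return AtomSet(
        coords=coords,
        masses=np.full(n, spec.mass_per_point),
        elements=np.full(n, "C", dtype=object).astype(str),
        chain_ids=np.zeros(n, int),
        residue_names=np.full(n, "DEC", dtype=object).astype(str),
        residue_indices=np.arange(n),
        atom_roles=np.full(n, "sidechain", dtype=object).astype(str),
        names=np.full(n, "SC", dtype=object).astype(str),
        box=None,
    )
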