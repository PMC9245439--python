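"""Coordination, salt-bridge and counterion-condensation statistics.

All cutoffs follow the solvation conventions of the study series: 0.35 nm
(the first minimum of the relevant radial distribution functions) defines
both sodium and water coordination of a carboxylate group and counterion
condensation; a sodium within 0.5 nm of two carboxylate groups on
different chains is a COO-Na-COO salt bridge.  Every distance test is a
strict ``<`` and uses minimum-image distances when a box is present.

A "carboxylate group" is the COO- unit of one COE residue: coordination
counts partners within the cutoff of either oxygen (group-level
counting), and the bridge test references the carboxylate carbon by
default (oxygen-based variant available).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .model import AtomSet, MicelleSystem, pairwise_distances

__all__ = ["CoordinationHistogram", "NeighborDistanceDistribution",
           "SaltBridgeReport", "coordination_histogram",
           "nearest_interchain_carboxylate", "salt_bridges",
           "condensed_sodium_fraction"]

_PARTNER_ROLES = {"sodium": "sodium", "water_oxygen": "water_oxygen"}


@dataclass
class CoordinationHistogram:
    """Distribution of coordination numbers N_c over (group, frame)."""

    partner: str
    cutoff: float
    counts: dict[int, int]
    n_samples: int

    @property
    def probabilities(self) -> dict[int, float]:
        return {k: v / self.n_samples for k, v in sorted(self.counts.items())}

    @property
    def mean(self) -> float:
        return sum(k * v for k, v in self.counts.items()) / self.n_samples


@dataclass
class NeighborDistanceDistribution:
    """Nearest interchain carboxylate-carbon distances, one per
    (carbon, frame), with a unit-area histogram and KDE density."""

    distances: np.ndarray
    bin_edges: np.ndarray
    density: np.ndarray            # histogram, unit area
    kde_grid: np.ndarray
    kde_density: np.ndarray        # unit area

    @classmethod
    def from_distances(cls, distances: np.ndarray, bin_width: float = 0.05,
                       bandwidth: str | float = "scott"
                       ) -> "NeighborDistanceDistribution":
        from scipy.stats import gaussian_kde

        distances = np.asarray(distances, float)
        if np.any(distances <= 0):
            raise ValueError("non-positive neighbor distance")
        hi = distances.max() * 1.2
        edges = np.arange(0.0, hi + bin_width, bin_width)
        hist, edges = np.histogram(distances, bins=edges, density=True)
        if len(distances) > 1 and distances.std() > 0:
            kde = gaussian_kde(distances, bw_method=bandwidth)
            grid = np.linspace(0.0, hi, 256)
            dens = kde(grid)
        else:
            grid = np.linspace(0.0, hi, 256)
            dens = np.zeros_like(grid)
        return cls(distances=distances, bin_edges=edges, density=hist,
                   kde_grid=grid, kde_density=dens)


@dataclass
class SaltBridgeReport:
    """Pooled-over-frames salt-bridge and condensation statistics.

    ``fraction_05``/``fraction_10``: percentage of (carbon, nearest
    interchain carbon) records below 0.5 / 1.0 nm whose pair is bridged by
    a sodium.  The two fractions are computed on different qualifying
    sets, so neither bounds the other.  ``condensed_fraction``: percentage
    of sodium ions within 0.35 nm of any carboxylate oxygen.
    """

    bridges: list[dict]
    fraction_05: float
    fraction_10: float
    condensed_fraction: float
    n_qualifying_05: int
    n_qualifying_10: int
    n_sodium: int
    bridge_cutoff: float
    site: str


def _carboxylate_groups(frame: AtomSet):
    """(group key, oxygen indices, carbon index) per COE carboxylate."""
    mask = np.isin(frame.atom_roles,
                   ("carboxylate_carbon", "carboxylate_oxygen"))
    idx = np.flatnonzero(mask)
    groups: dict[tuple[int, int], dict] = {}
    for i in idx:
        key = (int(frame.chain_ids[i]), int(frame.residue_indices[i]))
        slot = groups.setdefault(key, {"oxygens": [], "carbon": None})
        if frame.atom_roles[i] == "carboxylate_carbon":
            slot["carbon"] = i
        else:
            slot["oxygens"].append(i)
    return groups


def coordination_histogram(system: MicelleSystem, partner: str = "sodium",
                           cutoff: float = 0.35) -> CoordinationHistogram:
    """N_c histogram: distinct partner atoms within ``cutoff`` of either
    oxygen of each carboxylate group, pooled over (group, frame)."""
    if partner not in _PARTNER_ROLES:
        raise ValueError(f"partner must be one of {sorted(_PARTNER_ROLES)}")
    role = _PARTNER_ROLES[partner]
    counts: Counter[int] = Counter()
    n_samples = 0
    for frame in system.frames:
        groups = _carboxylate_groups(frame)
        if not groups:
            raise ValueError("no carboxylate (COE) groups in system")
        partner_idx = np.flatnonzero(frame.atom_roles == role)
        pcoords = frame.coords[partner_idx]
        for key in sorted(groups):
            oxy = groups[key]["oxygens"]
            if len(pcoords):
                d = pairwise_distances(frame.coords[oxy], pcoords,
                                       frame.box)
                n_c = int(np.sum((d < cutoff).any(axis=0)))
            else:
                n_c = 0
            counts[n_c] += 1
            n_samples += 1
    return CoordinationHistogram(partner=partner, cutoff=cutoff,
                                 counts=dict(counts), n_samples=n_samples)


def _nearest_records(frame: AtomSet):
    """Per carboxylate carbon: (carbon index, nearest interchain carbon
    index, distance)."""
    groups = _carboxylate_groups(frame)
    carbons = np.array([groups[k]["carbon"] for k in sorted(groups)], int)
    chains = frame.chain_ids[carbons]
    if len(np.unique(chains)) < 2:
        raise ValueError(
            "nearest interchain analysis needs >= 2 charged chains")
    coords = frame.coords[carbons]
    d = pairwise_distances(coords, coords, frame.box)
    same = chains[:, None] == chains[None, :]
    d[same] = np.inf
    j = np.argmin(d, axis=1)
    return [(int(carbons[i]), int(carbons[j[i]]), float(d[i, j[i]]))
            for i in range(len(carbons))]


def nearest_interchain_carboxylate(system: MicelleSystem,
                                   bin_width: float = 0.05,
                                   bandwidth: str | float = "scott"
                                   ) -> NeighborDistanceDistribution:
    """Distribution of the C-C_neighbor nearest distance: for every
    carboxylate carbon and frame, the distance to the closest carboxylate
    carbon on a different chain."""
    distances = []
    for frame in system.frames:
        distances.extend(d for _, _, d in _nearest_records(frame))
    return NeighborDistanceDistribution.from_distances(
        np.asarray(distances), bin_width=bin_width, bandwidth=bandwidth)


def condensed_sodium_fraction(system: MicelleSystem,
                              cutoff: float = 0.35) -> float:
    """Percentage of sodium ions within ``cutoff`` of any carboxylate
    oxygen, pooled over frames."""
    condensed = 0
    total = 0
    for frame in system.frames:
        na_idx = np.flatnonzero(frame.atom_roles == "sodium")
        oxy_idx = np.flatnonzero(frame.atom_roles == "carboxylate_oxygen")
        if not len(na_idx):
            raise ValueError("no sodium ions in system")
        total += len(na_idx)
        if len(oxy_idx):
            d = pairwise_distances(frame.coords[na_idx],
                                   frame.coords[oxy_idx], frame.box)
            condensed += int(np.sum((d < cutoff).any(axis=1)))
    return 100.0 * condensed / total


def salt_bridges(system: MicelleSystem, bridge_cutoff: float = 0.5,
                 neighbor_thresholds: tuple[float, float] = (0.5, 1.0),
                 site: str = "carbon",
                 condensation_cutoff: float = 0.35) -> SaltBridgeReport:
    """Detect COO-Na-COO bridges and report pooled bridge fractions.

    For each (carboxylate carbon, nearest interchain carbon) record with
    separation below a threshold, the pair is bridged if any sodium lies
    within ``bridge_cutoff`` of both carboxylate groups - of their carbons
    (``site="carbon"``, default) or of any oxygen of each group
    (``site="oxygen"``).
    """
    if site not in ("carbon", "oxygen"):
        raise ValueError("site must be 'carbon' or 'oxygen'")
    lo_thr, hi_thr = neighbor_thresholds
    qualifying = {lo_thr: 0, hi_thr: 0}
    bridged = {lo_thr: 0, hi_thr: 0}
    bridge_records: list[dict] = []
    for frame in system.frames:
        na_idx = np.flatnonzero(frame.atom_roles == "sodium")
        if not len(na_idx):
            raise ValueError("no sodium ions in system")
        na = frame.coords[na_idx]
        groups = _carboxylate_groups(frame)
        carbon_to_group = {g["carbon"]: k for k, g in groups.items()}

        def near_group(carbon_idx: int) -> np.ndarray:
            if site == "carbon":
                ref = frame.coords[[carbon_idx]]
            else:
                key = carbon_to_group[carbon_idx]
                ref = frame.coords[groups[key]["oxygens"]]
            d = pairwise_distances(na, ref, frame.box)
            return (d < bridge_cutoff).any(axis=1)

        for ci, cj, dist in _nearest_records(frame):
            both = near_group(ci) & near_group(cj)
            is_bridged = bool(both.any())
            for thr in (lo_thr, hi_thr):
                if dist < thr:
                    qualifying[thr] += 1
                    bridged[thr] += is_bridged
            if is_bridged and dist < hi_thr:
                for na_k in np.flatnonzero(both):
                    bridge_records.append({
                        "frame": frame.frame_index,
                        "sodium": int(na_idx[na_k]),
                        "carbon_a": ci,
                        "carbon_b": cj,
                        "chain_a": int(frame.chain_ids[ci]),
                        "chain_b": int(frame.chain_ids[cj]),
                        "cc_distance": dist,
                    })

    def frac(thr: float) -> float:
        return 100.0 * bridged[thr] / qualifying[thr] if qualifying[thr] \
            else 0.0

    return SaltBridgeReport(
        bridges=bridge_records,
        fraction_05=frac(lo_thr),
        fraction_10=frac(hi_thr),
        condensed_fraction=condensed_sodium_fraction(
            system, condensation_cutoff),
        n_qualifying_05=qualifying[lo_thr],
        n_qualifying_10=qualifying[hi_thr],
        n_sodium=sum(int(np.sum(f.atom_roles == "sodium"))
                     for f in system.frames),
        bridge_cutoff=bridge_cutoff,
        site=site,
    )
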