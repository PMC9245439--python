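"""Coordination, nearest-interchain distances, salt bridges,
condensation."""

import numpy as np
import pytest

from micellometrics import (ChainSequence, MicelleSystem,
                            SyntheticMicelleSpec,
                            condensed_sodium_fraction,
                            coordination_histogram, generate_micelle,
                            nearest_interchain_carboxylate, salt_bridges)
from micellometrics.model import AtomSet, pairwise_distances


def coo_group(chain, resindex, carbon_xyz, direction=(1.0, 0.0, 0.0)):
    """Beads of one carboxylate group: carbon plus two oxygens 0.125 nm
    away, oriented along ``direction``."""
    c = np.asarray(carbon_xyz, float)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    perp = np.array([-d[1], d[0], 0.0]) if abs(d[2]) < 0.9 \
        else np.array([1.0, 0.0, 0.0])
    o1 = c + 0.125 * (0.55 * d + 0.835 * perp)
    o2 = c + 0.125 * (0.55 * d - 0.835 * perp)
    return [
        (c, "C", "carboxylate_carbon", "CG", chain, "COE", resindex),
        (o1, "O", "carboxylate_oxygen", "OD1", chain, "COE", resindex),
        (o2, "O", "carboxylate_oxygen", "OD2", chain, "COE", resindex),
    ]


def build_system(groups, sodium_xyz=(), water_xyz=(), box=None,
                 n_chains=None):
    """Assemble a MicelleSystem from carboxylate groups plus free ions
    and waters (plus filler chains so invariants hold loosely)."""
    rows = []
    for g in groups:
        rows.extend(g)
    resi = max(r[6] for r in rows) + 1
    for w in water_xyz:
        rows.append((np.asarray(w, float), "O", "water_oxygen", "OW",
                     -1, "WAT", resi))
        resi += 1
    for s in sodium_xyz:
        rows.append((np.asarray(s, float), "Na", "sodium", "NA",
                     -1, "NA", resi))
        resi += 1
    atoms = AtomSet(
        coords=np.array([r[0] for r in rows]),
        masses=np.ones(len(rows)),
        elements=np.array([r[1] for r in rows]),
        chain_ids=np.array([r[4] for r in rows], int),
        residue_names=np.array([r[5] for r in rows]),
        residue_indices=np.array([r[6] for r in rows], int),
        atom_roles=np.array([r[2] for r in rows]),
        names=np.array([r[3] for r in rows]),
        box=None if box is None else np.asarray(box, float),
    )
    chains = int(atoms.chain_ids.max()) + 1 if n_chains is None \
        else n_chains
    return MicelleSystem(
        frames=[atoms], n_chains=chains,
        sequence=ChainSequence.from_charge_positions([25],
                                                     one_based=True))


class TestCoordination:
    def test_planted_single_sodium_counted(self):
        g = coo_group(0, 5, [0, 0, 0])
        oxy = g[1][0]
        system = build_system([g], sodium_xyz=[oxy + [0.30, 0, 0]])
        hist = coordination_histogram(system, "sodium", cutoff=0.35)
        assert hist.counts == {1: 1}

    def test_boundary_is_strict_less_than(self):
        g = coo_group(0, 5, [0, 0, 0])
        oxy = np.asarray(g[1][0])
        na = oxy + np.array([0.35, 0.0, 0.0])
        far_corner = np.asarray(g[2][0])
        assert np.linalg.norm(na - far_corner) > 0.35
        system = build_system([g], sodium_xyz=[na])
        hist = coordination_histogram(system, "sodium", cutoff=0.35)
        assert hist.counts == {0: 1}

    def test_group_level_counting_not_double(self):
        # one sodium within the cutoff of BOTH oxygens counts once
        g = coo_group(0, 5, [0, 0, 0])
        mid = 0.5 * (np.asarray(g[1][0]) + np.asarray(g[2][0]))
        system = build_system([g], sodium_xyz=[mid + [0.1, 0, 0]])
        hist = coordination_histogram(system, "sodium", cutoff=0.35)
        assert hist.counts == {1: 1}

    def test_water_histogram_matches_brute_force(self):
        rng = np.random.default_rng(23)
        groups = [coo_group(i, 5, rng.uniform(1, 3, 3)) for i in range(3)]
        waters = rng.uniform(0, 4, size=(100, 3))
        system = build_system(groups, water_xyz=waters,
                              box=[4.0, 4.0, 4.0])
        hist = coordination_histogram(system, "water_oxygen", cutoff=0.35)
        expected = {}
        box = np.array([4.0, 4.0, 4.0])
        for g in groups:
            oxys = np.array([g[1][0], g[2][0]])
            d = pairwise_distances(waters, oxys, box)
            n_c = int(np.sum(d.min(axis=1) < 0.35))
            expected[n_c] = expected.get(n_c, 0) + 1
        assert hist.counts == expected
        assert sum(hist.probabilities.values()) == pytest.approx(1.0)

    def test_no_carboxylates_rejected(self):
        spec = SyntheticMicelleSpec(
            n_chains=2, core_radius=0.8, corona_thickness=0.8,
            water_shell_thickness=0.3, seed=5)
        system = generate_micelle(spec)
        stripped = system.frames[0].subset(
            ~np.isin(system.frames[0].residue_names, ["COE"]))
        bad = MicelleSystem(frames=[stripped], n_chains=2,
                            sequence=system.sequence)
        with pytest.raises(ValueError, match="carboxylate"):
            coordination_histogram(bad)


class TestNearestInterchain:
    def test_two_groups_mutual_nearest(self):
        groups = [coo_group(0, 5, [0, 0, 0]),
                  coo_group(1, 5, [0.8, 0, 0])]
        dist = nearest_interchain_carboxylate(build_system(groups))
        np.testing.assert_allclose(sorted(dist.distances), [0.8, 0.8],
                                   atol=1e-12)

    def test_triangle_configuration(self):
        # chains at pairwise distances 0.5 / 0.7 / 0.9
        groups = [coo_group(0, 5, [0, 0, 0]),
                  coo_group(1, 5, [0.5, 0, 0]),
                  coo_group(2, 5, [-0.433, 0.566, 0])]
        d01 = 0.5
        d02 = np.linalg.norm([-0.433, 0.566])
        d12 = np.linalg.norm([0.933, -0.566])
        assert d02 == pytest.approx(0.712, abs=0.01)
        assert d12 == pytest.approx(1.091, abs=0.01)
        dist = nearest_interchain_carboxylate(build_system(groups))
        np.testing.assert_allclose(
            sorted(dist.distances), sorted([d01, d01, d02]), atol=1e-9)

    def test_same_chain_never_counted(self):
        groups = [coo_group(0, 5, [0, 0, 0]),
                  coo_group(0, 7, [0.3, 0, 0]),     # same chain, closer
                  coo_group(1, 5, [1.5, 0, 0])]
        dist = nearest_interchain_carboxylate(build_system(groups))
        assert dist.distances.min() > 1.0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(29)
        groups = []
        for chain in range(4):
            for k in range(3):          # triply charged
                groups.append(coo_group(chain, 5 + 2 * k,
                                        rng.uniform(0, 3, 3)))
        system = build_system(groups)
        dist = nearest_interchain_carboxylate(system)
        carbons = np.array([g[0][0] for g in groups])
        chains = np.array([g[0][4] for g in groups])
        expected = []
        for i in range(len(carbons)):
            d = [np.linalg.norm(carbons[i] - carbons[j])
                 for j in range(len(carbons)) if chains[j] != chains[i]]
            expected.append(min(d))
        np.testing.assert_allclose(sorted(dist.distances),
                                   sorted(expected), atol=1e-12)

    def test_single_charged_chain_rejected(self):
        system = build_system([coo_group(0, 5, [0, 0, 0])], n_chains=1)
        with pytest.raises(ValueError, match="2 charged chains"):
            nearest_interchain_carboxylate(system)

    def test_kde_density_has_unit_area(self):
        rng = np.random.default_rng(31)
        groups = [coo_group(c, 5, rng.uniform(0, 4, 3))
                  for c in range(6)]
        dist = nearest_interchain_carboxylate(build_system(groups))
        area = np.trapezoid(dist.kde_density, dist.kde_grid)
        assert area == pytest.approx(1.0, abs=0.05)
        hist_area = np.sum(dist.density * np.diff(dist.bin_edges))
        assert hist_area == pytest.approx(1.0, abs=1e-9)


class TestSaltBridges:
    def test_planted_bridge_counted(self):
        # carbons 0.45 nm apart on different chains, sodium equidistant
        groups = [coo_group(0, 5, [0, 0, 0], direction=[0, 0, -1]),
                  coo_group(1, 5, [0.45, 0, 0], direction=[0, 0, -1])]
        na = [0.225, 0.0, 0.35]
        report = salt_bridges(build_system(groups, sodium_xyz=[na]))
        assert report.fraction_05 == 100.0
        assert report.n_qualifying_05 == 2
        assert len(report.bridges) == 2     # one record per carbon side

    def test_one_sided_sodium_is_not_a_bridge(self):
        groups = [coo_group(0, 5, [0, 0, 0], direction=[0, 0, -1]),
                  coo_group(1, 5, [0.45, 0, 0], direction=[0, 0, -1])]
        na = [-0.4, 0.0, 0.0]       # 0.4 from carbon A, 0.85 from B
        report = salt_bridges(build_system(groups, sodium_xyz=[na]))
        assert report.fraction_05 == 0.0

    def test_fractions_use_different_qualifying_sets(self):
        # bridged close pair + unbridged far pair: the 0.5 nm fraction
        # exceeds the 1.0 nm fraction, as with real micelle statistics
        close = [coo_group(0, 5, [0, 0, 0], direction=[0, 0, -1]),
                 coo_group(1, 5, [0.45, 0, 0], direction=[0, 0, -1])]
        far = [coo_group(2, 5, [5.0, 5.0, 0]),
               coo_group(3, 5, [5.9, 5.0, 0])]
        na = [0.225, 0.0, 0.35]
        report = salt_bridges(build_system(close + far, sodium_xyz=[na]))
        assert report.n_qualifying_05 == 2
        assert report.n_qualifying_10 == 4
        assert report.fraction_05 == 100.0
        assert report.fraction_10 == 50.0
        assert report.fraction_05 > report.fraction_10

    def test_planted_generator_bridges_match_exhaustive_oracle(self):
        spec = SyntheticMicelleSpec(
            n_chains=6, core_radius=1.0, corona_thickness=1.0,
            water_shell_thickness=0.3, planted_salt_bridges=3, seed=33)
        system = generate_micelle(spec)
        report = salt_bridges(system)
        frame = system.frames[0]
        na = frame.coords[frame.atom_roles == "sodium"]
        cmask = frame.atom_roles == "carboxylate_carbon"
        carbons, chains = frame.coords[cmask], frame.chain_ids[cmask]
        # oracle: per carbon, nearest interchain carbon, then check all Na
        bridged_pairs = set()
        qualifying = 0
        bridged = 0
        for i in range(len(carbons)):
            dd = np.linalg.norm(carbons - carbons[i], axis=1)
            dd[chains == chains[i]] = np.inf
            j = int(np.argmin(dd))
            if dd[j] < 0.5:
                qualifying += 1
                ok = np.any(
                    (np.linalg.norm(na - carbons[i], axis=1) < 0.5)
                    & (np.linalg.norm(na - carbons[j], axis=1) < 0.5))
                bridged += ok
                if ok:
                    bridged_pairs.add(frozenset((i, j)))
        assert report.n_qualifying_05 == qualifying
        assert report.fraction_05 == pytest.approx(
            100.0 * bridged / qualifying)
        assert len(bridged_pairs) >= 3

    def test_chain_relabeling_invariance(self):
        rng = np.random.default_rng(37)
        groups = [coo_group(c, 5, rng.uniform(0, 2, 3))
                  for c in range(5)]
        na = [rng.uniform(0, 2, 3) for _ in range(5)]
        base = salt_bridges(build_system(groups, sodium_xyz=na))
        relabeled = [coo_group(4 - c, 5, np.asarray(g[0][0]))
                     for c, g in enumerate(groups)]
        perm = salt_bridges(build_system(relabeled, sodium_xyz=na))
        assert perm.fraction_05 == base.fraction_05
        assert perm.fraction_10 == base.fraction_10
        assert perm.condensed_fraction == base.condensed_fraction


class TestCondensation:
    @pytest.mark.parametrize("fraction", [0.0, 0.1, 0.3])
    def test_planted_fraction_recovered(self, fraction):
        spec = SyntheticMicelleSpec(
            n_chains=10, core_radius=1.0, corona_thickness=1.0,
            water_shell_thickness=0.3,
            na_condensation_fraction=fraction, seed=41)
        system = generate_micelle(spec)
        measured = condensed_sodium_fraction(system)
        tol = 100.0 / 10          # one ion out of ten
        assert abs(measured - 100.0 * fraction) <= tol

    def test_oxygen_rule_strictness(self):
        g = coo_group(0, 5, [0, 0, 0])
        oxy = np.asarray(g[1][0])
        system = build_system(
            [g, coo_group(1, 5, [3, 3, 3])],
            sodium_xyz=[oxy + [0.349, 0, 0], oxy + [0.55, 0, 0]])
        assert condensed_sodium_fraction(system) == pytest.approx(50.0)
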