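"""RDF, weighted totals, S(Q) and Guinier analysis."""

import numpy as np
import pytest

from micellometrics import (GyrationResult, IdealBodySpec,
                            ScatteringLengthTable, generate_ideal_body,
                            guinier_rg, partial_rdf, structure_factor,
                            total_weighted_rdf)
from micellometrics.scattering import (RDFProfile, StructureFactorProfile,
                                       element_partials)

from conftest import make_atoms


def flat_profile(g_value=1.0, r_max=3.0, n_bins=150):
    edges = np.linspace(0.0, r_max, n_bins + 1)
    return RDFProfile(bin_edges=edges, g=np.full(n_bins, g_value),
                      pair="total-weighted", densities={})


class TestPartialRDF:
    def test_ideal_gas_is_flat(self):
        rng = np.random.default_rng(12)
        box = [8.0, 8.0, 8.0]
        atoms = make_atoms(rng.uniform(0, 8, size=(1200, 3)), box=box)
        prof = partial_rdf(atoms, r_max=3.5, bin_width=0.1)
        # skip the first bins (tiny shell volumes, noisy)
        g = prof.g[5:]
        assert abs(g.mean() - 1.0) < 0.02
        assert g.std() < 0.2

    def test_fixed_pair_lands_in_single_bin(self):
        d = 0.73
        atoms = make_atoms([[0, 0, 0], [d, 0, 0]], box=[5.0, 5.0, 5.0])
        prof = partial_rdf(atoms, r_max=2.0, bin_width=0.05)
        nz = np.flatnonzero(prof.counts)
        assert len(nz) == 1
        assert prof.bin_edges[nz[0]] <= d < prof.bin_edges[nz[0] + 1]

    def test_counts_match_brute_force_oracle(self):
        rng = np.random.default_rng(13)
        box = np.array([4.0, 4.0, 4.0])
        coords = rng.uniform(0, 4, size=(200, 3))
        atoms = make_atoms(coords, box=box)
        prof = partial_rdf(atoms, r_max=1.9, bin_width=0.05)
        # exhaustive double loop with explicit minimum image
        edges = prof.bin_edges
        expected = np.zeros(len(edges) - 1)
        for i in range(200):
            for j in range(i + 1, 200):
                d = coords[i] - coords[j]
                d -= box * np.round(d / box)
                r = np.sqrt((d * d).sum())
                if r < edges[-1]:
                    expected[min(int(r // 0.05), len(expected) - 1)] += 1
        np.testing.assert_array_equal(prof.counts, expected)

    def test_cross_species_counts_match_oracle(self):
        rng = np.random.default_rng(14)
        box = np.array([4.0, 4.0, 4.0])
        a = make_atoms(rng.uniform(0, 4, (60, 3)), box=box)
        b = make_atoms(rng.uniform(0, 4, (80, 3)), box=box)
        prof = partial_rdf(a, b, r_max=1.9, bin_width=0.1)
        expected = np.zeros(len(prof.bin_edges) - 1)
        for i in range(60):
            for j in range(80):
                d = a.coords[i] - b.coords[j]
                d -= box * np.round(d / box)
                r = np.sqrt((d * d).sum())
                if r < 1.9:
                    expected[int(r // 0.1)] += 1
        np.testing.assert_array_equal(prof.counts, expected)

    def test_half_box_rule_enforced(self):
        atoms = make_atoms([[0, 0, 0]], box=[4.0, 4.0, 4.0])
        with pytest.raises(ValueError, match="half"):
            partial_rdf(atoms, r_max=2.5)

    def test_nonperiodic_requires_volume(self):
        atoms = make_atoms([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError, match="volume"):
            partial_rdf(atoms, r_max=2.0)


class TestWeightedTotal:
    def test_single_species_identity(self):
        rng = np.random.default_rng(15)
        atoms = make_atoms(rng.uniform(0, 5, (300, 3)),
                           elements=["C"] * 300, box=[5.0] * 3)
        parts = element_partials(atoms, r_max=2.0, bin_width=0.1)
        total = total_weighted_rdf(parts)
        np.testing.assert_allclose(total.g, parts[0].g, atol=1e-12)

    def test_equal_lengths_reduce_to_composition_weighting(self):
        rng = np.random.default_rng(16)
        n = 200
        elements = ["C"] * 120 + ["O"] * 80
        atoms = make_atoms(rng.uniform(0, 5, (n, 3)), elements=elements,
                           box=[5.0] * 3)
        parts = element_partials(atoms, r_max=2.0, bin_width=0.1)
        same_b = total_weighted_rdf(parts, {"C": 5.0, "O": 5.0})
        other_b = total_weighted_rdf(parts, {"C": 7.0, "O": 7.0})
        np.testing.assert_allclose(same_b.g, other_b.g, atol=1e-12)

    def test_two_species_hand_weighted_sum(self):
        rng = np.random.default_rng(17)
        elements = ["C"] * 50 + ["O"] * 30
        atoms = make_atoms(rng.uniform(0, 5, (80, 3)), elements=elements,
                           box=[5.0] * 3)
        parts = element_partials(atoms, r_max=2.0, bin_width=0.1)
        b = {"C": 6.646, "O": 5.803}
        total = total_weighted_rdf(parts, b)
        by_pair = {tuple(sorted(p.pair)): p.g for p in parts}
        vol = 125.0
        c = {"C": 50 / vol, "O": 30 / vol}
        num = (c["C"] ** 2 * b["C"] ** 2 * by_pair[("C", "C")]
               + 2 * c["C"] * c["O"] * b["C"] * b["O"]
               * by_pair[("C", "O")]
               + c["O"] ** 2 * b["O"] ** 2 * by_pair[("O", "O")])
        expected = num / (c["C"] * b["C"] + c["O"] * b["O"]) ** 2
        np.testing.assert_allclose(total.g, expected, atol=1e-12)

    def test_missing_pair_detected(self):
        rng = np.random.default_rng(18)
        a = make_atoms(rng.uniform(0, 5, (30, 3)), elements=["C"] * 30,
                       box=[5.0] * 3)
        p = partial_rdf(a, r_max=2.0, bin_width=0.1, labels=("C", "C"))
        p.densities["O"] = 0.1      # claim O exists but supply no O pairs
        with pytest.raises(ValueError, match="missing"):
            total_weighted_rdf([p])

    def test_deuteration_flips_hydrogen_sign(self):
        table = ScatteringLengthTable()
        assert table["H"] < 0
        assert table.deuterated()["H"] > 0


class TestStructureFactor:
    def test_flat_g_gives_unit_s(self):
        prof = structure_factor(flat_profile(1.0), rho=33.0,
                                q_grid=np.linspace(0.01, 0.3, 25))
        np.testing.assert_allclose(prof.s, 1.0, atol=1e-12)

    def test_gaussian_bump_matches_closed_form(self):
        """g(r) = 1 + A exp(-(r-r0)^2 / 2s^2) has an analytic transform:
        S(Q) = 1 + (4 pi rho A s sqrt(2 pi)/Q) e^{-s^2Q^2/2}
               (r0 sin(Qr0) + s^2 Q cos(Qr0))."""
        A, r0, s, rho = 0.5, 1.0, 0.08, 20.0
        edges = np.linspace(0.0, 4.0, 2001)
        r = 0.5 * (edges[:-1] + edges[1:])
        g = 1.0 + A * np.exp(-((r - r0) ** 2) / (2 * s ** 2))
        prof_in = RDFProfile(bin_edges=edges, g=g, pair="total-weighted",
                             densities={})
        q_invA = np.linspace(0.02, 0.5, 40)
        out = structure_factor(prof_in, rho, q_invA, window="none")
        q = q_invA * 10.0
        expected = 1.0 + (4 * np.pi * rho * A * s * np.sqrt(2 * np.pi)
                          / q) * np.exp(-(s * q) ** 2 / 2) \
            * (r0 * np.sin(q * r0) + s ** 2 * q * np.cos(q * r0))
        np.testing.assert_allclose(out.s, expected, rtol=0.01, atol=5e-3)

    def test_qr_underflow_uses_series_limit(self):
        prof = structure_factor(flat_profile(2.0), rho=1.0,
                                q_grid=np.array([1e-12, 0.1]))
        assert np.all(np.isfinite(prof.s))

    def test_decreasing_q_grid_rejected(self):
        with pytest.raises(ValueError):
            StructureFactorProfile(q=np.array([0.2, 0.1]),
                                   s=np.array([1.0, 1.0]), rho=1.0)


class TestGuinier:
    def test_exact_synthetic_guinier_curve(self):
        rg_nm = 3.0
        q = np.linspace(0.005, 0.05, 30)          # A^-1
        s = np.exp(-(q * 10) ** 2 * rg_nm ** 2 / 3.0)
        prof = StructureFactorProfile(q=q, s=s, rho=1.0)
        assert guinier_rg(prof, q_max=0.05) == pytest.approx(3.0,
                                                             rel=1e-10)

    def test_noisy_curve_recovered_within_two_percent(self):
        rng = np.random.default_rng(19)
        rg_nm = 3.0
        q = np.linspace(0.005, 0.05, 50)
        s = np.exp(-(q * 10) ** 2 * rg_nm ** 2 / 3.0) \
            * (1.0 + 0.01 * rng.normal(size=50))
        prof = StructureFactorProfile(q=q, s=s, rho=1.0)
        assert guinier_rg(prof, q_max=0.05) == pytest.approx(3.0,
                                                             rel=0.02)

    def test_rising_curve_rejected(self):
        q = np.linspace(0.01, 0.05, 20)
        prof = StructureFactorProfile(q=q, s=np.exp(+(q * 10) ** 2),
                                      rho=1.0)
        with pytest.raises(ValueError, match="Guinier"):
            guinier_rg(prof, q_max=0.05)

    def test_too_few_points_rejected(self):
        prof = StructureFactorProfile(q=np.array([0.01, 0.02, 0.3]),
                                      s=np.array([1.0, 0.9, 0.1]),
                                      rho=1.0)
        with pytest.raises(ValueError, match="5"):
            guinier_rg(prof, q_max=0.05)


@pytest.fixture(scope="module")
def sphere_profile():
    """Dilute-normalized S(Q) of a uniform solid sphere."""
    body = generate_ideal_body(IdealBodySpec(
        "solid_sphere", radius=3.0, n_points=5000, seed=4))
    edge = 50.0
    body.box = np.array([edge] * 3)
    body.coords += edge / 2
    parts = element_partials(body, r_max=7.0, bin_width=0.02)
    total = total_weighted_rdf(parts)
    rho = len(body) / edge ** 3
    prof = structure_factor(total, rho, np.linspace(0.008, 0.05, 40),
                            window="none")
    return prof, GyrationResult.from_atoms(body).rg


class TestSphereCrossCheck:
    def test_guinier_matches_direct_rg(self, sphere_profile):
        prof, rg_direct = sphere_profile
        rg = guinier_rg(prof, q_max=0.05)
        assert rg == pytest.approx(rg_direct, rel=0.05)

    def test_bin_refinement_stable_in_guinier_window(self):
        body = generate_ideal_body(IdealBodySpec(
            "solid_sphere", radius=3.0, n_points=3000, seed=5))
        edge = 50.0
        body.box = np.array([edge] * 3)
        body.coords += edge / 2
        rho = len(body) / edge ** 3
        q = np.linspace(0.008, 0.05, 20)
        s_vals = []
        for bw in (0.04, 0.02):
            total = total_weighted_rdf(
                element_partials(body, r_max=7.0, bin_width=bw))
            s_vals.append(structure_factor(total, rho, q,
                                           window="none").s)
        np.testing.assert_allclose(s_vals[1], s_vals[0], rtol=0.01)
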