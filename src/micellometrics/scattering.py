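"""Neutron-weighted pair correlations and the static structure factor.

Partial radial distribution functions g_ab(r) are combined with coherent
scattering lengths b_a in the Faber-Ziman convention,

    g(r) = sum_ab c_a c_b b_a b_b g_ab(r) / (sum_a c_a b_a)^2,

and Fourier-transformed with the isotropic kernel to the static structure
factor

    S(Q) = 1 + 4 pi rho int_0^rmax r^2 (g(r) - 1) sin(Qr)/(Qr) W(r) dr,

where W is a Lorch truncation window by default.  S(Q) is proportional to
the coherent neutron scattering intensity; its low-Q (Guinier) region,
ln S linear in Q^2 with slope -Rg^2/3, yields the scattering-weighted
radius of gyration that SANS experiments report.

Conventions: r and densities in nm, Q reported in inverse Angstrom to
match scattering practice; the analyzed selection defaults to the micelle
without solvent (water is excluded from the experimentally compared
S(Q)); hydrogens carry the 1H scattering length unless a deuteration
substitution is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chemistry
from .model import AtomSet

__all__ = ["ScatteringLengthTable", "RDFProfile", "StructureFactorProfile",
           "partial_rdf", "total_weighted_rdf", "structure_factor",
           "guinier_rg", "element_partials", "micelle_structure_factor"]

_NM_PER_INV_ANGSTROM = 10.0      # Q[nm^-1] = 10 * Q[A^-1]


@dataclass(frozen=True)
class ScatteringLengthTable:
    """Element/isotope -> coherent scattering length b (fm)."""

    values: dict = field(default_factory=lambda: dict(chemistry.COHERENT_B_FM))
    source: str = "Sears, Neutron News 3 (1992) 26"

    def __getitem__(self, element: str) -> float:
        try:
            return self.values[element]
        except KeyError:
            raise KeyError(
                f"no scattering length for element {element!r}") from None

    def deuterated(self, elements: tuple[str, ...] = ("H",)) \
            -> "ScatteringLengthTable":
        """Copy with the listed (exchangeable/solvent) hydrogen entries
        replaced by the deuterium scattering length."""
        vals = dict(self.values)
        for e in elements:
            vals[e] = self.values["D"]
        return ScatteringLengthTable(vals, self.source + " (deuterated)")


@dataclass
class RDFProfile:
    """Binned g(r): uniform half-open bins [lo, hi) in nm."""

    bin_edges: np.ndarray
    g: np.ndarray
    pair: tuple[str, str] | str
    densities: dict                       # label -> number density, nm^-3
    counts: np.ndarray | None = None      # raw pair counts per bin

    @property
    def r_mid(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class StructureFactorProfile:
    """S(Q) on a strictly increasing positive Q grid (inverse Angstrom)."""

    q: np.ndarray
    s: np.ndarray
    rho: float                            # nm^-3
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, float)
        self.s = np.asarray(self.s, float)
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("Q grid must be positive and increasing")
        if not np.all(np.isfinite(self.s)):
            raise ValueError("non-finite S(Q)")


def _pair_distance_histogram(a: np.ndarray, b: np.ndarray,
                             edges: np.ndarray, box: np.ndarray | None,
                             same: bool, chunk: int = 1024) -> np.ndarray:
    """Exact unordered pair-count histogram with minimum image (chunked)."""
    counts = np.zeros(len(edges) - 1)
    r_max = edges[-1]
    for lo in range(0, a.shape[0], chunk):
        hi = min(lo + chunk, a.shape[0])
        d = a[lo:hi, None, :] - b[None, :, :]
        if box is not None:
            d -= box * np.round(d / box)
        dist = np.sqrt((d * d).sum(-1))
        if same:
            # exclude self pairs and count each unordered pair once
            rows, cols = np.indices(dist.shape)
            mask = (cols > rows + lo)
            dist = dist[mask]
        dist = dist[dist < r_max]
        counts += np.histogram(dist, bins=edges)[0]
    return counts


def partial_rdf(atoms_a: AtomSet, atoms_b: AtomSet | None = None,
                r_max: float = 3.0, bin_width: float = 0.02,
                volume: float | None = None,
                labels: tuple[str, str] | None = None) -> RDFProfile:
    """Partial radial distribution function g_ab(r).

    ``atoms_b=None`` means the a==b case (self pairs excluded).  For
    periodic sets ``r_max`` must not exceed half the smallest box edge;
    for isolated sets an explicit normalization ``volume`` (nm^3) is
    required.  Normalization is the standard ideal-gas shell count.
    """
    same = atoms_b is None
    b_set = atoms_a if same else atoms_b
    box = atoms_a.box
    if box is not None:
        if r_max > box.min() / 2.0 + 1e-12:
            raise ValueError(
                f"r_max {r_max} exceeds half the smallest box edge "
                f"{box.min() / 2.0}")
        vol = float(np.prod(box))
    else:
        if volume is None:
            raise ValueError("non-periodic RDF needs an explicit volume")
        vol = float(volume)
    n_bins = int(round(r_max / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    counts = _pair_distance_histogram(atoms_a.coords, b_set.coords, edges,
                                      box, same)
    n_a, n_b = len(atoms_a), len(b_set)
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    n_pairs = n_a * (n_a - 1) / 2.0 if same else float(n_a * n_b)
    ideal = n_pairs * shell / vol
    g = np.divide(counts, ideal, out=np.zeros_like(counts),
                  where=ideal > 0)
    la = labels[0] if labels else "a"
    lb = labels[1] if labels else ("a" if same else "b")
    return RDFProfile(
        bin_edges=edges, g=g, pair=(la, lb),
        densities={la: n_a / vol, lb: n_b / vol},
        counts=counts,
    )


def element_partials(atoms: AtomSet, r_max: float = 3.0,
                     bin_width: float = 0.02,
                     volume: float | None = None) -> list[RDFProfile]:
    """All element-pair partial RDFs of a selection."""
    species = sorted(set(atoms.elements.tolist()))
    out = []
    for i, ea in enumerate(species):
        sub_a = atoms.subset(atoms.elements == ea)
        for eb in species[i:]:
            if ea == eb:
                out.append(partial_rdf(sub_a, None, r_max, bin_width,
                                       volume, labels=(ea, ea)))
            else:
                sub_b = atoms.subset(atoms.elements == eb)
                out.append(partial_rdf(sub_a, sub_b, r_max, bin_width,
                                       volume, labels=(ea, eb)))
    return out


def total_weighted_rdf(partials: list[RDFProfile],
                       blengths: ScatteringLengthTable | dict | None = None
                       ) -> RDFProfile:
    """Faber-Ziman neutron-weighted total g(r) from element partials.

    Requires one profile per unordered species pair on identical bins.
    """
    if not partials:
        raise ValueError("no partial profiles")
    table = blengths if blengths is not None else ScatteringLengthTable()
    if isinstance(table, dict):
        table = ScatteringLengthTable(dict(table))
    edges = partials[0].bin_edges
    for p in partials[1:]:
        if len(p.bin_edges) != len(edges) or \
                not np.allclose(p.bin_edges, edges):
            raise ValueError("partials have mismatched bins")
    densities: dict[str, float] = {}
    for p in partials:
        densities.update(p.densities)
    species = sorted(densities)
    provided = {tuple(sorted(p.pair)) for p in partials}
    needed = {tuple(sorted((a, b))) for i, a in enumerate(species)
              for b in species[i:]}
    missing = needed - provided
    if missing:
        raise ValueError(f"missing species pairs: {sorted(missing)}")
    denom = sum(densities[s] * table[s] for s in species) ** 2
    if denom == 0:
        raise ValueError("zero net scattering length density")
    g_total = np.zeros(len(edges) - 1)
    for p in partials:
        a, b = p.pair
        w = densities[a] * densities[b] * table[a] * table[b]
        if a != b:
            w *= 2.0        # unordered pair provided once
        g_total += w * p.g
    g_total /= denom
    return RDFProfile(bin_edges=edges.copy(), g=g_total,
                      pair="total-weighted", densities=densities)


def _lorch(r: np.ndarray, r_max: float) -> np.ndarray:
    x = np.pi * r / r_max
    return np.where(x > 0, np.sin(np.maximum(x, 1e-300)) / np.maximum(x, 1e-300), 1.0)


def structure_factor(g_total: RDFProfile, rho: float,
                     q_grid: np.ndarray,
                     window: str = "lorch",
                     scale: float = 1.0) -> StructureFactorProfile:
    """S(Q) from the total g(r) by quadrature over the bins.

    ``rho`` is the number density (nm^-3) consistent with the RDF
    normalization; ``q_grid`` in inverse Angstrom.  ``window`` is "lorch"
    (default, damps truncation ringing) or "none".  ``scale`` applies the
    optional vertical alignment constant (does not change the Guinier
    slope).
    """
    q_grid = np.asarray(q_grid, float)
    r = g_total.r_mid
    dr = g_total.bin_width
    r_max = g_total.bin_edges[-1]
    if window == "lorch":
        w = _lorch(r, r_max)
    elif window in ("none", None):
        w = np.ones_like(r)
    else:
        raise ValueError(f"unknown window {window!r}")
    integrand = r ** 2 * (g_total.g - 1.0) * w * dr
    q_nm = q_grid * _NM_PER_INV_ANGSTROM
    # sinc(Qr) with the series limit sinc -> 1 as Qr -> 0
    qr = np.outer(q_nm, r)
    kernel = np.sinc(qr / np.pi)
    s = 1.0 + 4.0 * np.pi * rho * kernel @ integrand
    return StructureFactorProfile(q=q_grid, s=scale * s, rho=rho,
                                  scale=scale)


def guinier_rg(profile: StructureFactorProfile,
               q_max: float = 0.1) -> float:
    """Radius of gyration (nm) from the Guinier region Q <= q_max (A^-1).

    Least-squares slope of ln S versus Q^2; Rg = sqrt(-3 slope).  Raises
    if fewer than 5 usable points or if the slope is non-negative (no
    Guinier decay).
    """
    mask = (profile.q <= q_max) & (profile.s > 0)
    if mask.sum() < 5:
        raise ValueError(
            f"need >= 5 points with Q <= {q_max} and S > 0; "
            f"have {int(mask.sum())}")
    q2 = (profile.q[mask] * _NM_PER_INV_ANGSTROM) ** 2     # nm^-2
    slope = np.polyfit(q2, np.log(profile.s[mask]), 1)[0]  # nm^2
    if slope >= 0:
        raise ValueError("non-decaying S(Q): input has no Guinier regime")
    return float(np.sqrt(-3.0 * slope))


def micelle_structure_factor(atoms: AtomSet, r_max: float,
                             bin_width: float = 0.02,
                             q_grid: np.ndarray | None = None,
                             volume: float | None = None,
                             blengths: ScatteringLengthTable | None = None,
                             window: str = "lorch") -> StructureFactorProfile:
    """Convenience chain: element partials -> weighted total -> S(Q) for a
    single selection (pass the micelle without water, the experimental
    comparison convention)."""
    partials = element_partials(atoms, r_max, bin_width, volume)
    total = total_weighted_rdf(partials, blengths)
    if atoms.box is not None:
        vol = float(np.prod(atoms.box))
    else:
        vol = float(volume)
    rho = len(atoms) / vol
    if q_grid is None:
        q_grid = np.linspace(0.005, 0.3, 120)
    return structure_factor(total, rho, q_grid, window=window)
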