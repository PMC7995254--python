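"""Frenkel exciton models of chlorophyll assemblies.

This module builds the site (Frenkel) Hamiltonian of a small set of coupled
chlorophylls from structural geometry: each pigment contributes a Qy
transition dipole (a unit direction times a magnitude in Debye) located at
its central Mg atom, pairwise electronic couplings are evaluated in the
point-dipole approximation, and the resulting N x N Hamiltonian is
diagonalized to obtain exciton energies, eigenvectors and exciton transition
dipoles.

Conventions
-----------
* Energies and couplings in cm^-1, distances in Angstrom, dipoles in Debye.
* The Qy direction is taken as the unit vector from ring atom NB to ring
  atom ND (configurable), a widely used convention for chlorophylls.
* Couplings are unscreened vacuum dipole-dipole couplings by default; an
  optional multiplicative screening factor is accepted.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Unit constant C in V = C * kappa * mu_a * mu_b / R^3.
#: Derivation: V = mu_a mu_b kappa / (4 pi eps0 R^3) with mu in Debye
#: (1 D = 3.33564e-30 C m) and R in Angstrom gives an energy of
#: (3.33564e-30)^2 / (4 pi eps0 (1e-10)^3) J = 1.10485e-21 J, which divided
#: by h*c = 1.98645e-23 J cm equals 5034.1 cm^-1 per D^2/A^3 (vacuum).
DIPOLE_COUPLING_CONSTANT = 5034.1  # cm^-1 A^3 D^-2

#: Literature Qy transition-dipole magnitudes of the monomeric pigments.
CHL_A_DIPOLE = 4.58  # Debye
CHL_B_DIPOLE = 3.83  # Debye

#: Per-residue-name defaults used by :func:`parse_structure`:
#: (dipole magnitude / D, site energy / cm^-1).  CLA is chlorophyll a,
#: CHL chlorophyll b in standard PDB chemical-component naming.  The site
#: energies are typical Qy positions (Chl a ~671 nm, Chl b ~656 nm) and are
#: meant as degenerate per-species placeholders; refine per complex.
DEFAULT_SPECIES_PARAMS: Mapping[str, tuple[float, float]] = {
    "CLA": (CHL_A_DIPOLE, 14900.0),
    "CHL": (CHL_B_DIPOLE, 15250.0),
}

#: Minimum center-center distance (A) below which the point-dipole
#: approximation is flagged as invalid.
POINT_DIPOLE_MIN_R = 2.0


class StructureError(ValueError):
    """A macromolecular structure is missing required pigment atoms."""


@dataclass
class Chromophore:
    """One pigment site: position, Qy direction, dipole magnitude, energy.

    Parameters
    ----------
    label : str
        Short identifier, unique within a model.
    center : (3,) array_like
        Position of the dipole origin (central Mg atom), Angstrom.
    qy_unit : (3,) array_like
        Unit vector along the Qy transition dipole.
    dipole_magnitude : float
        Transition dipole magnitude, Debye.
    site_energy : float
        Site transition energy, cm^-1.
    """

    label: str
    center: np.ndarray
    qy_unit: np.ndarray
    dipole_magnitude: float
    site_energy: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.qy_unit = np.asarray(self.qy_unit, dtype=float)
        if self.center.shape != (3,) or self.qy_unit.shape != (3,):
            raise ValueError("center and qy_unit must be 3-vectors")
        norm = float(np.linalg.norm(self.qy_unit))
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(
                f"qy_unit of {self.label!r} is not normalized (|v| = {norm:.6g}); "
                "divide by its norm first"
            )
        self.qy_unit = self.qy_unit / norm
        if not self.dipole_magnitude > 0:
            raise ValueError(f"dipole_magnitude of {self.label!r} must be > 0")
        if not self.site_energy > 0:
            raise ValueError(f"site_energy of {self.label!r} must be > 0")

    @property
    def dipole_vector(self) -> np.ndarray:
        """Full transition-dipole vector, Debye."""
        return self.dipole_magnitude * self.qy_unit


@dataclass
class CouplingTerm:
    """Point-dipole coupling between one unordered pair of chromophores."""

    pair: tuple[str, str]
    distance_R: float  # Angstrom
    kappa: float  # orientation factor, in [-2, 2]
    V: float  # cm^-1
    point_dipole_valid: bool = True


@dataclass
class ExcitonModel:
    """Site Hamiltonian of N coupled pigments and (after diagonalization)
    its exciton states.

    ``exciton_vectors[:, k]`` is the k-th eigenvector (site amplitudes);
    ``exciton_dipoles[k]`` is the corresponding exciton transition dipole
    (Debye), the eigenvector-weighted sum of the site dipole vectors.
    """

    chromophores: list[Chromophore]
    hamiltonian: np.ndarray  # (N, N), cm^-1
    exciton_energies: np.ndarray | None = None  # (N,), ascending
    exciton_vectors: np.ndarray | None = None  # (N, N), orthonormal columns
    exciton_dipoles: np.ndarray | None = None  # (N, 3), Debye

    @property
    def n_sites(self) -> int:
        return len(self.chromophores)

    @property
    def is_diagonalized(self) -> bool:
        return self.exciton_energies is not None

    @property
    def gaps(self) -> np.ndarray:
        """Pairwise exciton-energy differences ``gaps[i, j] = E_j - E_i`` (cm^-1)."""
        if self.exciton_energies is None:
            raise ValueError("model not diagonalized; call diagonalize() first")
        e = self.exciton_energies
        return e[None, :] - e[:, None]

    @property
    def dipole_strengths(self) -> np.ndarray:
        """|exciton dipole|^2 per state, D^2 (proportional to oscillator strength)."""
        if self.exciton_dipoles is None:
            raise ValueError("model not diagonalized; call diagonalize() first")
        return np.sum(self.exciton_dipoles**2, axis=1)


def point_dipole_coupling(
    a: Chromophore,
    b: Chromophore,
    screening: float = 1.0,
) -> CouplingTerm:
    """Dipole-dipole coupling V = C * s * kappa * mu_a * mu_b / R^3.

    ``kappa = mu_a . mu_b - 3 (mu_a . R)(mu_b . R)`` with unit vectors, the
    standard mutual-orientation factor; ``s`` is an optional screening
    multiplier (1 = vacuum).  Emits a warning and flags the term when
    R < 2 A, where the point-dipole approximation breaks down.
    """
    if a is b or a.label == b.label:
        raise ValueError("coupling requires two distinct chromophores")
    rvec = b.center - a.center
    R = float(np.linalg.norm(rvec))
    if R == 0.0:
        raise ValueError(
            f"chromophores {a.label!r} and {b.label!r} have coincident centers"
        )
    rhat = rvec / R
    kappa = float(
        np.dot(a.qy_unit, b.qy_unit)
        - 3.0 * np.dot(a.qy_unit, rhat) * np.dot(b.qy_unit, rhat)
    )
    V = (
        screening
        * DIPOLE_COUPLING_CONSTANT
        * kappa
        * a.dipole_magnitude
        * b.dipole_magnitude
        / R**3
    )
    valid = R >= POINT_DIPOLE_MIN_R
    if not valid:
        warnings.warn(
            f"center-center distance {R:.2f} A between {a.label!r} and "
            f"{b.label!r} is below {POINT_DIPOLE_MIN_R} A; the point-dipole "
            "approximation is not valid at this separation",
            stacklevel=2,
        )
    return CouplingTerm(
        pair=(a.label, b.label),
        distance_R=R,
        kappa=kappa,
        V=V,
        point_dipole_valid=valid,
    )


def all_couplings(
    chromophores: Sequence[Chromophore], screening: float = 1.0
) -> list[CouplingTerm]:
    """Couplings for every unordered pair, in lexicographic pair order."""
    return [
        point_dipole_coupling(a, b, screening=screening)
        for a, b in itertools.combinations(chromophores, 2)
    ]


def build_hamiltonian(
    chromophores: Sequence[Chromophore],
    couplings: Iterable[CouplingTerm] | None = None,
) -> ExcitonModel:
    """Assemble the site Hamiltonian (diagonal = site energies, off-diagonal
    = couplings).

    Pairs absent from ``couplings`` default to 0 with a logged notice; if
    ``couplings`` is None, all point-dipole couplings are computed.
    """
    labels = [c.label for c in chromophores]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate chromophore labels: {dupes}")
    if couplings is None:
        couplings = all_couplings(chromophores)
    n = len(chromophores)
    index = {lab: i for i, lab in enumerate(labels)}
    H = np.zeros((n, n))
    for i, c in enumerate(chromophores):
        H[i, i] = c.site_energy
    seen: set[frozenset[str]] = set()
    for term in couplings:
        la, lb = term.pair
        if la not in index or lb not in index:
            raise ValueError(f"coupling pair {term.pair} references unknown labels")
        i, j = index[la], index[lb]
        H[i, j] = H[j, i] = term.V
        seen.add(frozenset(term.pair))
    for a, b in itertools.combinations(labels, 2):
        if frozenset((a, b)) not in seen:
            logger.info("no coupling supplied for pair (%s, %s); defaulting to 0", a, b)
    return ExcitonModel(chromophores=list(chromophores), hamiltonian=H)


def diagonalize(model: ExcitonModel) -> ExcitonModel:
    """Solve the exciton eigenproblem; returns a completed copy of the model.

    Eigenvalues ascend; each eigenvector's first nonzero component is made
    positive (reproducible sign convention).  Exciton dipoles satisfy the
    dipole-strength sum rule sum_k |d_k|^2 = sum_i mu_i^2.
    """
    H = np.asarray(model.hamiltonian, dtype=float)
    if H.shape != (model.n_sites, model.n_sites):
        raise ValueError("hamiltonian shape does not match chromophore count")
    if not np.allclose(H, H.T, rtol=0, atol=1e-8 * max(1.0, np.abs(H).max())):
        raise ValueError("hamiltonian must be symmetric")
    energies, vectors = np.linalg.eigh(H)
    for k in range(vectors.shape[1]):
        col = vectors[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            vectors[:, k] = -col
    site_dipoles = np.array([c.dipole_vector for c in model.chromophores])  # (N, 3)
    exciton_dipoles = vectors.T @ site_dipoles  # (N, 3)
    return replace(
        model,
        exciton_energies=energies,
        exciton_vectors=vectors,
        exciton_dipoles=exciton_dipoles,
    )


def exciton_gap(model: ExcitonModel, i: int, j: int) -> float:
    """Signed energy gap ``E_j - E_i`` between exciton states (cm^-1).

    For a degenerate dimer with coupling V this is 2|V| for (i, j) = (0, 1).
    """
    if model.exciton_energies is None:
        raise ValueError("model not diagonalized; call diagonalize() first")
    n = model.n_sites
    for k in (i, j):
        if not 0 <= k < n:
            raise IndexError(f"exciton index {k} out of range for {n} states")
    if i == j:
        raise ValueError("gap requires two distinct exciton indices")
    return float(model.exciton_energies[j] - model.exciton_energies[i])


def stick_absorption(
    model: ExcitonModel,
    broadening_fwhm: float,
    axis: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-broadened stick absorption spectrum.

    Each exciton contributes a normalized Gaussian at its energy with area
    proportional to its dipole strength, so the integrated area is
    independent of the broadening.

    Returns ``(axis_cm1, intensity)``.
    """
    if model.exciton_energies is None:
        raise ValueError("model not diagonalized; call diagonalize() first")
    if not broadening_fwhm > 0:
        raise ValueError("broadening_fwhm must be > 0")
    sigma = broadening_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    if axis is None:
        lo = model.exciton_energies.min() - 5 * broadening_fwhm
        hi = model.exciton_energies.max() + 5 * broadening_fwhm
        axis = np.linspace(lo, hi, 2000)
    axis = np.asarray(axis, dtype=float)
    intensity = np.zeros_like(axis)
    for e, strength in zip(model.exciton_energies, model.dipole_strengths):
        intensity += (
            strength
            / (sigma * np.sqrt(2.0 * np.pi))
            * np.exp(-((axis - e) ** 2) / (2.0 * sigma**2))
        )
    return axis, intensity


# ---------------------------------------------------------------------------
# Structure parsing
# ---------------------------------------------------------------------------

def parse_structure(
    path,
    pigment_selector: Iterable[str] = ("CLA", "CHL"),
    species_params: Mapping[str, tuple[float, float]] | None = None,
    center_atom: str = "MG",
    qy_atoms: tuple[str, str] = ("NB", "ND"),
) -> list[Chromophore]:
    """Extract chlorophyll chromophores from a PDB/mmCIF structure.

    One :class:`Chromophore` per selected residue: the dipole origin is the
    central Mg atom and the Qy direction the normalized vector between the
    two named ring nitrogens (NB -> ND by default).  Dipole magnitude and
    site energy come from ``species_params`` keyed by residue name.
    """
    import gemmi  # local import: only needed when structures are used

    selector = {s.upper() for s in pigment_selector}
    params = dict(DEFAULT_SPECIES_PARAMS if species_params is None else species_params)
    structure = gemmi.read_structure(str(path))
    chromophores: list[Chromophore] = []
    for model in structure:
        for chain in model:
            for res in chain:
                if res.name.upper() not in selector:
                    continue
                atoms = {a.name.strip().upper(): a.pos for a in res}
                missing = [
                    name
                    for name in (center_atom, *qy_atoms)
                    if name.upper() not in atoms
                ]
                if missing:
                    raise StructureError(
                        f"residue {res.name} {res.seqid.num} in chain "
                        f"{chain.name} is missing atom(s) {', '.join(missing)}"
                    )
                if res.name.upper() not in params:
                    raise StructureError(
                        f"no dipole/site-energy defaults for residue name "
                        f"{res.name!r}; supply species_params"
                    )
                mg = atoms[center_atom.upper()]
                nb = atoms[qy_atoms[0].upper()]
                nd = atoms[qy_atoms[1].upper()]
                direction = np.array(
                    [nd.x - nb.x, nd.y - nb.y, nd.z - nb.z], dtype=float
                )
                norm = np.linalg.norm(direction)
                if norm == 0:
                    raise StructureError(
                        f"residue {res.name} {res.seqid.num} in chain {chain.name}: "
                        f"atoms {qy_atoms[0]} and {qy_atoms[1]} coincide"
                    )
                mu, e_site = params[res.name.upper()]
                chromophores.append(
                    Chromophore(
                        label=f"{chain.name}{res.seqid.num}-{res.name}",
                        center=np.array([mg.x, mg.y, mg.z]),
                        qy_unit=direction / norm,
                        dipole_magnitude=mu,
                        site_energy=e_site,
                    )
                )
        break  # first model only
    if not chromophores:
        raise StructureError(
            f"no pigments found in {path} for residue names {sorted(selector)}"
        )
    return chromophores


# ---------------------------------------------------------------------------
# Delimited-text output
# ---------------------------------------------------------------------------

def write_coupling_table(couplings: Sequence[CouplingTerm], path) -> None:
    """Write couplings as tab-separated text with a unit-bearing header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# point-dipole couplings\n")
        fh.write("site_a\tsite_b\tR_angstrom\tkappa\tV_cm-1\tpoint_dipole_valid\n")
        for t in couplings:
            fh.write(
                f"{t.pair[0]}\t{t.pair[1]}\t{t.distance_R:.6g}\t"
                f"{t.kappa:.6g}\t{t.V:.6g}\t{t.point_dipole_valid}\n"
            )


def write_hamiltonian(model: ExcitonModel, path) -> None:
    """Write the site Hamiltonian (cm^-1) as tab-separated text."""
    labels = "\t".join(c.label for c in model.chromophores)
    header = f"site Hamiltonian, cm^-1; rows/cols: {labels}"
    np.savetxt(path, model.hamiltonian, fmt="%.9g", delimiter="\t", header=header)
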