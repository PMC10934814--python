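"""Molecular polarizability from the Thole interactive induced-dipole model.

Each atom *i* carries an isotropic point polarizability ``alpha_i``.  An
external field induces dipoles that polarize each other through the damped
dipole-dipole interaction tensor, giving the 3N x 3N relay matrix

    A = [ alpha_i^{-1} I   on 3x3 diagonal blocks
          -T_ij            off-diagonal ]

with T_ij = lambda5 * 3 r r^T / r^5 - lambda3 * I / r^3 and r the
interatomic vector.  The molecular polarizability tensor is the sum of all
3x3 blocks of A^{-1}; the isotropic polarizability is its trace / 3.

Damping screens the interaction at short range to avoid the polarization
catastrophe.  Supported forms (``u = r / (alpha_i alpha_j)^{1/6}``,
dimensionless damping factor ``a``):

* ``exponential``: the exponentially decaying charge-density form; with
  ``w = a u``, lambda3 = 1 - (1 + w + w^2/2) e^{-w} and
  lambda5 = lambda3 - (w^3/6) e^{-w}
* ``linear``: the original piecewise-linear charge-density form with
  v = u / a: for v < 1, lambda3 = 4 v^3 - 3 v^4, lambda5 = v^4; else 1
* ``none``: bare point dipoles (useful for closed-form checks, but
  unphysical at short range)

The computation runs internally in atomic units (bohr, bohr^3) for sane
conditioning of the relay matrix, with the Å/Å³ conversion applied at the
boundary.  The shipped default parameter file uses a published
exponential-damping parameterization (damping factor 2.1304 with per-element
polarizabilities fitted to molecular data); the ionic charge of an adduct
does not enter the induced-dipole model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Structure3D",
    "TholeParams",
    "PolarizabilityResult",
    "XYZParseError",
    "read_xyz",
    "write_xyz",
    "default_thole_params",
    "load_thole_params",
    "molecular_polarizability",
]

BOHR_PER_ANGSTROM = 1.0 / 0.52917721092
ANG3_PER_BOHR3 = 0.52917721092**3

_KNOWN_ELEMENTS = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Br", "I", "Fe", "Zn", "Se",
}


class XYZParseError(ValueError):
    """Malformed XYZ file (bad counts, element symbols or coordinates)."""


@dataclass(frozen=True)
class Structure3D:
    """Atoms as (element, x, y, z) with coordinates in Å."""

    atoms: tuple[tuple[str, float, float, float], ...]
    charge: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.atoms) < 1:
            raise ValueError("structure needs at least one atom")
        coords = self.coordinates()
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        if len(self.atoms) > 1:
            from scipy.spatial.distance import pdist

            if pdist(coords).min() < 0.1:
                raise ValueError("two atoms closer than 0.1 Å; geometry is unphysical")

    def elements(self) -> list[str]:
        return [a[0] for a in self.atoms]

    def coordinates(self) -> np.ndarray:
        return np.asarray([[a[1], a[2], a[3]] for a in self.atoms], dtype=float)


@dataclass(frozen=True)
class TholeParams:
    """Element polarizabilities (Å³) and the damping scheme."""

    atomic_polarizabilities: Mapping[str, float]
    damping_form: str = "exponential"
    damping_factor: float = 2.1304

    def __post_init__(self) -> None:
        if self.damping_form not in ("exponential", "linear", "none"):
            raise ValueError(f"unknown damping_form {self.damping_form!r}")
        if self.damping_factor <= 0:
            raise ValueError("damping_factor must be > 0")
        for el, a in self.atomic_polarizabilities.items():
            if a <= 0:
                raise ValueError(f"atomic polarizability of {el} must be > 0, got {a}")


@dataclass(frozen=True)
class PolarizabilityResult:
    """Molecular polarizability tensor (Å³), its eigenvalues and mean."""

    tensor: np.ndarray
    isotropic: float
    eigenvalues: tuple[float, float, float]

    def to_dict(self) -> dict:
        return {
            "tensor_A3": self.tensor.tolist(),
            "isotropic_A3": self.isotropic,
            "eigenvalues_A3": list(self.eigenvalues),
        }


def read_xyz(path) -> Structure3D:
    """Parse a standard XYZ file (count line, comment line, atom rows)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise XYZParseError(f"{path}: empty file")
    try:
        n = int(lines[0].strip())
    except ValueError:
        raise XYZParseError(f"{path}: line 1: expected atom count, got {lines[0]!r}") from None
    comment = lines[1] if len(lines) > 1 else ""
    rows = [ln for ln in lines[2:] if ln.strip()]
    if len(rows) < n:
        raise XYZParseError(f"{path}: count line says {n} atoms but only {len(rows)} rows follow")
    atoms = []
    for k, ln in enumerate(rows[:n]):
        parts = ln.split()
        if len(parts) < 4:
            raise XYZParseError(f"{path}: line {k + 3}: expected 'element x y z', got {ln!r}")
        el = parts[0].capitalize()
        if el not in _KNOWN_ELEMENTS:
            raise XYZParseError(f"{path}: line {k + 3}: unknown element symbol {parts[0]!r}")
        try:
            x, y, z = (float(p) for p in parts[1:4])
        except ValueError:
            raise XYZParseError(f"{path}: line {k + 3}: bad coordinate in {ln!r}") from None
        atoms.append((el, x, y, z))
    return Structure3D(atoms=tuple(atoms), name=comment)


def write_xyz(s: Structure3D, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(s.atoms)}\n{s.name}\n")
        for el, x, y, z in s.atoms:
            fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def load_thole_params(path) -> TholeParams:
    with open(path) as fh:
        doc = json.load(fh)
    return TholeParams(
        atomic_polarizabilities=doc["atomic_polarizabilities"],
        damping_form=doc.get("damping_form", "exponential"),
        damping_factor=float(doc.get("damping_factor", 2.1304)),
    )


def default_thole_params() -> TholeParams:
    """Parameter set shipped with the package (exponential damping)."""
    text = resources.files("polarccs").joinpath("data/thole_params.json").read_text()
    doc = json.loads(text)
    return TholeParams(
        atomic_polarizabilities=doc["atomic_polarizabilities"],
        damping_form=doc["damping_form"],
        damping_factor=float(doc["damping_factor"]),
    )


def _damping_factors(u: float, a: float, form: str) -> tuple[float, float]:
    """(lambda3, lambda5) screening for one atom pair at reduced distance u."""
    if form == "none":
        return 1.0, 1.0
    if form == "exponential":
        w = a * u
        e = np.exp(-w)
        lam3 = 1.0 - (1.0 + w + 0.5 * w**2) * e
        lam5 = lam3 - (w**3 / 6.0) * e
        return lam3, lam5
    # linear: piecewise charge density, v = u / a
    v = u / a
    if v >= 1.0:
        return 1.0, 1.0
    return 4.0 * v**3 - 3.0 * v**4, v**4


def molecular_polarizability(s: Structure3D, p: TholeParams | None = None) -> PolarizabilityResult:
    """Molecular polarizability tensor of a structure via the relay matrix.

    Raises ``KeyError`` naming the element if a parameter is missing, and a
    ``numpy.linalg.LinAlgError``-derived error advising damping when the
    relay matrix is singular (polarization catastrophe with undamped
    interactions at short range).
    """
    params = p if p is not None else default_thole_params()
    elements = s.elements()
    missing = sorted({el for el in elements if el not in params.atomic_polarizabilities})
    if missing:
        raise KeyError(f"no Thole polarizability parameter for element(s) {missing}")
    n = len(elements)
    alpha = np.array(
        [params.atomic_polarizabilities[el] / ANG3_PER_BOHR3 for el in elements]
    )  # bohr^3
    coords = s.coordinates() * BOHR_PER_ANGSTROM  # bohr

    A = np.zeros((3 * n, 3 * n))
    for i in range(n):
        A[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] = np.eye(3) / alpha[i]
    a = params.damping_factor
    for i in range(n):
        for j in range(i + 1, n):
            rvec = coords[j] - coords[i]
            r = np.linalg.norm(rvec)
            u = r / (alpha[i] * alpha[j]) ** (1.0 / 6.0)
            lam3, lam5 = _damping_factors(u, a, params.damping_form)
            T = lam5 * 3.0 * np.outer(rvec, rvec) / r**5 - lam3 * np.eye(3) / r**3
            A[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = -T
            A[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = -T
    try:
        # a physical induced-dipole solution needs a positive-definite relay
        # matrix; Cholesky detects the polarization catastrophe cleanly
        np.linalg.cholesky(A)
        B = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "relay matrix is not positive definite (polarization catastrophe "
            "at short interatomic distance); use damping_form='exponential' "
            "or 'linear'"
        ) from exc
    tensor_au = B.reshape(n, 3, n, 3).sum(axis=(0, 2))
    tensor_au = 0.5 * (tensor_au + tensor_au.T)
    tensor = tensor_au * ANG3_PER_BOHR3
    eig = np.sort(np.linalg.eigvalsh(tensor))
    return PolarizabilityResult(
        tensor=tensor,
        isotropic=float(np.trace(tensor) / 3.0),
        eigenvalues=tuple(float(e) for e in eig),
    )
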