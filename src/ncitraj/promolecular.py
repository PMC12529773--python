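"""Promolecular electron densities and their analytic derivatives.

The promolecular density of a molecular fragment is the plain sum of
precomputed isolated-atom densities placed at the nuclear positions — no
self-consistency, no response to the chemical environment.  Each atomic
density is a sum of decaying exponentials

    rho_atom(r) = sum_j c_j * exp(-r / zeta_j)        (atomic units)

which makes the density, its gradient and its Hessian available in closed
form at any point.  These fields feed the noncovalent-interaction (NCI)
analysis: the reduced density gradient

    s = |grad rho| / (2 (3 pi^2)^{1/3} rho^{4/3})

is small where noncovalent contacts live, and the second Hessian eigenvalue
lambda2 signs the density into attractive (lambda2 < 0) versus repulsive
(lambda2 > 0) character.

All internal math is in atomic units; user-facing coordinates are in
angstrom.  The per-element coefficient table ships with the package
(``data/atomic_densities.json``) and can be overridden by path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BOHR_PER_ANGSTROM",
    "RDG_PREFACTOR",
    "AtomicDensityModel",
    "FieldSample",
    "UnsupportedElementError",
    "CuspError",
    "DegenerateDensityError",
    "load_density_table",
    "default_density_table",
    "atomic_density",
    "evaluate_field",
    "evaluate_field_many",
    "reduced_density_gradient",
]

BOHR_PER_ANGSTROM = 1.8897259886
#: 2 (3 pi^2)^(1/3), the denominator constant of the reduced density gradient
RDG_PREFACTOR = 2.0 * (3.0 * np.pi**2) ** (1.0 / 3.0)

#: points closer than this to a nucleus hit the exponential cusp
CUSP_RADIUS_BOHR = 1e-6


class UnsupportedElementError(KeyError):
    """No atomic density model is available for the requested element."""


class CuspError(ValueError):
    """Evaluation point coincides with a nuclear position."""


class DegenerateDensityError(ValueError):
    """The reduced density gradient is undefined for rho <= 0."""


@dataclass(frozen=True)
class AtomicDensityModel:
    """Isolated-atom density as a sum of exponential terms.

    ``terms`` is a sequence of (coefficient, decay_length) pairs with the
    coefficient in e/bohr^3 and the decay length in bohr.  Both must be
    strictly positive, which guarantees a strictly decreasing radial density.
    """

    element: str
    terms: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError(f"{self.element}: empty density model")
        for c, zeta in self.terms:
            if c <= 0 or zeta <= 0:
                raise ValueError(
                    f"{self.element}: coefficients and decay lengths must be > 0, got ({c}, {zeta})"
                )

    def rho(self, r):
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        for c, zeta in self.terms:
            out += c * np.exp(-r / zeta)
        return out

    def drho(self, r):
        """d(rho)/dr — strictly negative for r finite."""
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        for c, zeta in self.terms:
            out -= (c / zeta) * np.exp(-r / zeta)
        return out

    def d2rho(self, r):
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        for c, zeta in self.terms:
            out += (c / zeta**2) * np.exp(-r / zeta)
        return out


@dataclass
class FieldSample:
    """Density, gradient, Hessian and sorted Hessian eigenvalues at a point.

    Units: rho e/bohr^3, gradient e/bohr^4, hessian e/bohr^5.
    ``lambdas`` are sorted ascending, lambda1 <= lambda2 <= lambda3.
    """

    rho: float
    gradient: np.ndarray
    hessian: np.ndarray
    lambdas: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.gradient = np.asarray(self.gradient, dtype=float)
        self.hessian = np.asarray(self.hessian, dtype=float)
        if self.lambdas is None:
            self.lambdas = np.linalg.eigvalsh(self.hessian)
        if self.rho < 0:
            raise ValueError("rho must be >= 0")

    @property
    def grad_norm(self) -> float:
        return float(np.linalg.norm(self.gradient))

    @property
    def signed_rho(self) -> float:
        """sign(lambda2) * rho, the NCI classification variable."""
        return float(np.where(self.lambdas[1] < 0, -1.0, 1.0) * self.rho)


_DEFAULT_TABLE: dict[str, AtomicDensityModel] | None = None


def load_density_table(path: str | None = None) -> dict[str, AtomicDensityModel]:
    """Load an element -> AtomicDensityModel mapping from a JSON table.

    With ``path=None`` the packaged table is used.  The JSON layout is
    ``{"elements": {"C": [[c, zeta], ...], ...}}``.
    """
    if path is None:
        raw = resources.files("ncitraj.data").joinpath("atomic_densities.json").read_text()
    else:
        with open(path) as fh:
            raw = fh.read()
    data = json.loads(raw)
    elements = data["elements"] if "elements" in data else data
    return {
        el: AtomicDensityModel(el, tuple((float(c), float(z)) for c, z in terms))
        for el, terms in elements.items()
    }


def default_density_table() -> dict[str, AtomicDensityModel]:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_density_table()
    return _DEFAULT_TABLE


def atomic_density(model: AtomicDensityModel, r) -> np.ndarray | float:
    """rho_atom(r) = sum_j c_j exp(-r/zeta_j) for radial distance r in bohr."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radial distance must be >= 0")
    out = model.rho(r)
    return float(out) if out.ndim == 0 else out


def _resolve_atoms(
    atoms: Iterable[tuple[str, Sequence[float]]],
    table: dict[str, AtomicDensityModel],
) -> tuple[list[AtomicDensityModel], np.ndarray]:
    models = []
    positions = []
    for element, pos in atoms:
        el = element.capitalize()
        if el not in table:
            raise UnsupportedElementError(
                f"no atomic density model for element {element!r}; available: {sorted(table)}"
            )
        models.append(table[el])
        positions.append(pos)
    if not models:
        raise ValueError("at least one atom is required")
    return models, np.asarray(positions, dtype=float)


def evaluate_field_many(
    atoms: Iterable[tuple[str, Sequence[float]]],
    points_angstrom: np.ndarray,
    *,
    table: dict[str, AtomicDensityModel] | None = None,
    want_hessian: bool = True,
    cusp_check: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Vectorised promolecular rho / gradient / Hessian at many points.

    ``atoms`` are (element, position-in-angstrom) pairs, ``points_angstrom``
    is (N, 3).  Returns (rho (N,), gradient (N, 3), hessian (N, 3, 3) or
    None), everything in atomic units.  For a spherical term the Hessian is
    (f'' - f'/r) r_hat r_hat^T + (f'/r) I.
    """
    table = table or default_density_table()
    models, positions = _resolve_atoms(atoms, table)
    pts = np.atleast_2d(np.asarray(points_angstrom, dtype=float)) * BOHR_PER_ANGSTROM
    pos_b = positions * BOHR_PER_ANGSTROM

    n = pts.shape[0]
    rho = np.zeros(n)
    grad = np.zeros((n, 3))
    hess = np.zeros((n, 3, 3)) if want_hessian else None
    eye = np.eye(3)

    for model, center in zip(models, pos_b):
        d = pts - center
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        if cusp_check and np.any(r < CUSP_RADIUS_BOHR):
            raise CuspError(
                f"evaluation point within {CUSP_RADIUS_BOHR} bohr of a nucleus of {model.element}"
            )
        r_safe = np.maximum(r, CUSP_RADIUS_BOHR)
        rhat = d / r_safe[:, None]
        f = model.rho(r)
        fp = model.drho(r)
        fpp = model.d2rho(r)
        rho += f
        grad += fp[:, None] * rhat
        if want_hessian:
            radial = fpp - fp / r_safe
            hess += (
                radial[:, None, None] * rhat[:, :, None] * rhat[:, None, :]
                + (fp / r_safe)[:, None, None] * eye
            )
    return rho, grad, hess


def evaluate_field(
    fragments: Iterable[tuple[str, Sequence[float]]],
    point: Sequence[float],
    *,
    table: dict[str, AtomicDensityModel] | None = None,
) -> FieldSample:
    """Evaluate the promolecular field of a set of atoms at one point (angstrom)."""
    rho, grad, hess = evaluate_field_many(fragments, np.asarray(point, dtype=float)[None, :], table=table)
    return FieldSample(rho=float(rho[0]), gradient=grad[0], hessian=hess[0])


def reduced_density_gradient(rho, grad_norm):
    """Dimensionless s = |grad rho| / (2 (3 pi^2)^{1/3} rho^{4/3}).

    Scalar or array; raises for rho <= 0 (callers mask such voxels).
    """
    rho_arr = np.asarray(rho, dtype=float)
    gn = np.asarray(grad_norm, dtype=float)
    if np.any(rho_arr <= 0):
        raise DegenerateDensityError("reduced density gradient undefined for rho <= 0")
    s = gn / (RDG_PREFACTOR * rho_arr ** (4.0 / 3.0))
    return float(s) if s.ndim == 0 else s
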