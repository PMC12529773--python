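"""Regenerate the promolecular atomic-density coefficient table.

Each element is modelled as rho_atom(r) = sum_j c_j * exp(-r / zeta_j) in atomic
units (c in e/bohr^3, zeta in bohr).  The reference densities are spherically
averaged Slater-type-orbital atoms built from Clementi-Raimondi effective
exponents.  The 1s shell of an STO atom is itself a single exponential, so the
core term is exact; the remaining shells are fitted by minimising the maximum
relative error over the noncovalent contact shell r in [1.5, 4.5] bohr
(differential evolution over decay lengths, non-negative least squares for the
coefficients).  Hydrogen is the exact ground-state density e^{-2r}/pi.

A sum of positive exponentials is log-convex while the valence STO density
(~ r^2 e^{-2 zeta r}) is log-concave, so no coefficient choice can be accurate
everywhere; the fit window is placed where noncovalent contacts live.  Outside
it the core is overestimated (harmlessly, it is removed by the density cutoff)
and the far tail is negligible.

Usage:  python scripts/fit_atomic_densities.py [out.json]
Writes src/ncitraj/data/atomic_densities.json by default.
"""

from __future__ import annotations

import json
import sys
from math import factorial, pi
from pathlib import Path

import numpy as np
from scipy.optimize import differential_evolution, nnls

# (principal quantum number, Clementi-Raimondi effective exponent, occupancy)
STO_SHELLS = {
    "H": [(1, 1.0, 1)],
    "C": [(1, 5.6727, 2), (2, 1.6083, 2), (2, 1.5679, 2)],
    "N": [(1, 6.6651, 2), (2, 1.9237, 2), (2, 1.9170, 3)],
    "O": [(1, 7.6579, 2), (2, 2.2458, 2), (2, 2.2266, 4)],
    "S": [(1, 15.5409, 2), (2, 5.3144, 2), (2, 5.9885, 6), (3, 2.1223, 2), (3, 1.8273, 4)],
}

FIT_WINDOW = (1.5, 4.5)  # bohr; where noncovalent contacts live
N_VALENCE_TERMS = 2      # upper bound; NNLS prunes redundant terms


def sto_density(shells, r):
    """Spherically averaged density of an STO atom (e/bohr^3)."""
    rho = np.zeros_like(r)
    for n, zeta, occ in shells:
        norm2 = (2.0 * zeta) ** (2 * n + 1) / factorial(2 * n)
        rho += occ * norm2 * r ** (2 * n - 2) * np.exp(-2.0 * zeta * r) / (4.0 * pi)
    return rho


def fit_element(shells):
    n1, z1, occ1 = shells[0]
    core = [occ1 * (2.0 * z1) ** 3 / (8.0 * pi), 1.0 / (2.0 * z1)]  # exact 1s term
    if len(shells) == 1:
        return [core]
    r = np.geomspace(*FIT_WINDOW, 200)
    resid = sto_density(shells, r) - sto_density(shells[:1], r)

    def solve(zetas):
        basis = np.exp(-r[:, None] / zetas[None, :]) / resid[:, None]
        coeffs, _ = nnls(basis, np.ones_like(r))
        fit = np.exp(-r[:, None] / zetas[None, :]) @ coeffs
        return coeffs, np.abs(fit / resid - 1.0).max()

    bounds = [(np.log(0.05), np.log(1.0))] * N_VALENCE_TERMS
    res = differential_evolution(lambda lz: solve(np.exp(lz))[1], bounds,
                                 seed=6, tol=1e-14, maxiter=600, popsize=40)
    coeffs, err = solve(np.exp(res.x))
    keep = coeffs > 1e-12
    terms = sorted(zip(coeffs[keep].tolist(), np.exp(res.x)[keep].tolist()),
                   key=lambda t: t[1])
    print(f"  valence max relative error in {FIT_WINDOW} bohr: {err:.4f}")
    return [core] + [[c, z] for c, z in terms]


def main(out_path: Path):
    table = {}
    for el, shells in STO_SHELLS.items():
        print(el)
        table[el] = fit_element(shells)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with open(out_path, "w") as fh:
        json.dump({"version": 1, "units": {"coefficient": "e/bohr^3", "decay_length": "bohr"},
                   "elements": table}, fh, indent=1)
    print("wrote", out_path)


if __name__ == "__main__":
    default = Path(__file__).resolve().parents[1] / "src" / "ncitraj" / "data" / "atomic_densities.json"
    main(Path(sys.argv[1]) if len(sys.argv) > 1 else default)
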