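"""Deterministic rigid-water solvation fixtures (TIP3P-like / TIP4P-like).

Molecules are placed with rejection sampling inside a sphere; the same
seed yields byte-identical output.  Monomer geometries are exact rigid
bodies of the chosen model.
"""

from __future__ import annotations

import numpy as np

from ..constants import BOHR_PER_ANGSTROM
from ..qmmm_coupling import MMRegion

# model parameters: charges (e), LJ on oxygen (kcal/mol, Angstrom)
WATER_MODELS = {
    "tip3p": {
        "r_oh": 0.9572, "theta_deg": 104.52,
        "q": {"O": -0.834, "H": 0.417},
        "eps_o": 0.1521, "sigma_o": 3.1507,
        "msite": None,
    },
    "tip4p": {
        "r_oh": 0.9572, "theta_deg": 104.52,
        "q": {"O": 0.0, "H": 0.52, "M": -1.04},
        "eps_o": 0.1550, "sigma_o": 3.15365,
        "msite": 0.15,  # O-M distance along the bisector, Angstrom
    },
}

MIN_OO_ANGSTROM = 2.5
MIN_SOLUTE_ANGSTROM = 2.2


def water_monomer(model: str = "tip3p"):
    """Site coordinates (Angstrom), symbols, charges, eps, sigma of one
    rigid monomer with O at the origin, bisector along +z."""
    if model not in WATER_MODELS:
        raise ValueError(f"unknown water model {model!r}; options {sorted(WATER_MODELS)}")
    p = WATER_MODELS[model]
    th = np.deg2rad(p["theta_deg"]) / 2.0
    h1 = p["r_oh"] * np.array([np.sin(th), 0.0, np.cos(th)])
    h2 = p["r_oh"] * np.array([-np.sin(th), 0.0, np.cos(th)])
    coords = [np.zeros(3), h1, h2]
    symbols = ["O", "H", "H"]
    charges = [p["q"]["O"], p["q"]["H"], p["q"]["H"]]
    eps = [p["eps_o"], 0.0, 0.0]
    sigma = [p["sigma_o"], 1.0, 1.0]
    if p["msite"] is not None:
        coords.append(np.array([0.0, 0.0, p["msite"]]))
        symbols.append("M")
        charges.append(p["q"]["M"])
        eps.append(0.0)
        sigma.append(1.0)
    return np.array(coords), symbols, charges, eps, sigma


def _random_rotation(rng) -> np.ndarray:
    # uniform rotation via normalized quaternion
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def gen_water_box(n_molecules: int, radius: float, model: str = "tip3p",
                  seed: int = 0, solute_coords_bohr=None,
                  max_attempts: int = 200000) -> MMRegion:
    """Random rigid waters in a sphere of ``radius`` Angstrom.

    Guarantees no O-O pair closer than 2.5 Angstrom and no O closer than
    2.2 Angstrom to any solute atom.
    """
    monomer, symbols, charges, eps, sigma = water_monomer(model)
    rng = np.random.default_rng(seed)
    solute = (
        np.asarray(solute_coords_bohr, dtype=float).reshape(-1, 3) / BOHR_PER_ANGSTROM
        if solute_coords_bohr is not None else None
    )
    placed_o = []
    frames = []
    attempts = 0
    while len(frames) < n_molecules:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n_molecules} waters in radius {radius} A "
                f"after {max_attempts} attempts"
            )
        # uniform point in sphere
        pos = rng.standard_normal(3)
        pos *= radius * rng.random() ** (1.0 / 3.0) / np.linalg.norm(pos)
        if placed_o and np.min(np.linalg.norm(np.array(placed_o) - pos, axis=1)) < MIN_OO_ANGSTROM:
            continue
        if solute is not None and np.min(np.linalg.norm(solute - pos, axis=1)) < MIN_SOLUTE_ANGSTROM:
            continue
        R = _random_rotation(rng)
        frames.append(monomer @ R.T + pos)
        placed_o.append(pos)
    nsite = monomer.shape[0]
    if n_molecules == 0:
        return MMRegion.empty()
    coords = np.concatenate(frames)
    return MMRegion.from_user_units(
        coords,
        np.tile(charges, n_molecules),
        np.tile(eps, n_molecules),
        np.tile(sigma, n_molecules),
        np.repeat(np.arange(n_molecules), nsite),
        symbols=symbols * n_molecules,
    )
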