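"""Atom-centered integration grids: Becke fuzzy-cell partition over
Gauss-Chebyshev radial shells and Lebedev angular shells.

The angular grids are oriented along the molecule's principal axes so
that the quadrature rotates rigidly with the atoms (total energies are
then invariant under rigid rotation to machine precision of the SCF, not
merely to grid accuracy).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files

import numpy as np

from ..geometry import QMGeometry

LEBEDEV_ORDERS = (
    6, 14, 26, 38, 50, 74, 86, 110, 146, 170, 194, 302, 434, 590, 770, 974, 1202
)

# Bragg-Slater radii (bohr) used for the radial mapping scale
_BRAGG_ANGSTROM = {
    1: 0.35, 2: 0.31, 3: 1.45, 4: 1.05, 5: 0.85, 6: 0.70, 7: 0.65, 8: 0.60,
    9: 0.50, 10: 0.38, 11: 1.80, 12: 1.50, 13: 1.25, 14: 1.10, 15: 1.00,
    16: 1.00, 17: 1.00, 18: 0.71,
}
_BOHR = 1.8897261254578281

GRID_PRESETS = {
    "coarse": (35, 110),
    "default": (75, 302),
    "fine": (99, 590),
    "reference": (150, 1202),
}


@dataclass
class DFTGrid:
    points: np.ndarray  # (npts, 3) bohr
    weights: np.ndarray  # (npts,) includes Becke partition weights
    owning_atom: np.ndarray  # (npts,)
    radial_order: int
    angular_order: int


def load_lebedev(order: int) -> np.ndarray:
    """(n, 4) array of unit-sphere points and weights (weights sum to 1)."""
    if order not in LEBEDEV_ORDERS:
        raise ValueError(
            f"unsupported angular order {order}; supported: {LEBEDEV_ORDERS}"
        )
    path = files("qmmkit").joinpath("data", "lebedev", f"lebedev_{order:04d}.txt")
    return np.loadtxt(str(path))


def radial_shells(n: int, rm: float) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Chebyshev (2nd kind) nodes mapped onto r in (0, inf).

    Mapping r = rm (1+x)/(1-x); returns radii and quadrature weights that
    already include the r^2 volume factor.
    """
    i = np.arange(1, n + 1)
    theta = i * np.pi / (n + 1)
    x = np.cos(theta)
    w_cheb = np.pi / (n + 1) * np.sin(theta) ** 2  # weight fn sqrt(1-x^2)
    r = rm * (1.0 + x) / (1.0 - x)
    jac = 2.0 * rm / (1.0 - x) ** 2
    w = w_cheb / np.sqrt(1.0 - x**2) * jac * r**2
    return r, w


def _becke_smooth(mu: np.ndarray, k: int = 3) -> np.ndarray:
    f = mu
    for _ in range(k):
        f = 0.5 * f * (3.0 - f**2)
    return 0.5 * (1.0 - f)


def becke_weights(points: np.ndarray, centers: np.ndarray, owner: np.ndarray) -> np.ndarray:
    """Fuzzy-cell partition weight of each point w.r.t. its owning atom."""
    natoms = centers.shape[0]
    if natoms == 1:
        return np.ones(points.shape[0])
    dist = np.linalg.norm(points[:, None, :] - centers[None, :, :], axis=2)
    rij = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
    cell = np.ones((points.shape[0], natoms))
    for i in range(natoms):
        for j in range(natoms):
            if i == j:
                continue
            mu = (dist[:, i] - dist[:, j]) / rij[i, j]
            cell[:, i] *= _becke_smooth(mu)
    total = cell.sum(axis=1)
    return cell[np.arange(points.shape[0]), owner] / total


def _principal_frame(geometry: QMGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Rotation matrix (rows = axes) and centroid defining a body frame."""
    x = geometry.coordinates
    c = x.mean(axis=0)
    y = x - c
    if len(y) == 1:
        return np.eye(3), c
    gyr = y.T @ y
    _, vecs = np.linalg.eigh(gyr)
    axes = vecs[:, ::-1].T  # descending variance
    # fix signs deterministically: largest-magnitude projection positive
    for k in range(3):
        proj = y @ axes[k]
        j = np.argmax(np.abs(proj))
        if proj[j] < 0:
            axes[k] = -axes[k]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return axes, c


def build_grid(
    geometry: QMGeometry,
    radial_order: int = 75,
    angular_order: int = 302,
) -> DFTGrid:
    """Becke-partitioned molecular grid."""
    leb = load_lebedev(angular_order)
    ang_pts = leb[:, :3]
    ang_w = leb[:, 3] * 4.0 * np.pi
    axes, _ = _principal_frame(geometry)
    ang_pts = ang_pts @ axes  # orient with the molecule

    pts_all, w_all, owner_all = [], [], []
    for iatom, z in enumerate(geometry.atomic_numbers):
        rb = _BRAGG_ANGSTROM.get(int(z), 1.0) * _BOHR
        rm = rb if z == 1 else rb / 2.0
        radii, wrad = radial_shells(radial_order, rm)
        pts = (
            geometry.coordinates[iatom][None, None, :]
            + radii[:, None, None] * ang_pts[None, :, :]
        ).reshape(-1, 3)
        w = (wrad[:, None] * ang_w[None, :]).reshape(-1)
        pts_all.append(pts)
        w_all.append(w)
        owner_all.append(np.full(len(w), iatom))
    points = np.concatenate(pts_all)
    weights = np.concatenate(w_all)
    owner = np.concatenate(owner_all)
    weights = weights * becke_weights(points, geometry.coordinates, owner)
    keep = weights > 1e-16
    return DFTGrid(points[keep], weights[keep], owner[keep], radial_order, angular_order)


def grid_from_preset(geometry: QMGeometry, preset: str = "default") -> DFTGrid:
    if preset not in GRID_PRESETS:
        raise ValueError(f"unknown grid preset {preset!r}; options: {sorted(GRID_PRESETS)}")
    nrad, nang = GRID_PRESETS[preset]
    return build_grid(geometry, nrad, nang)


def eval_basis(basis, points: np.ndarray, gradients: bool = True):
    """Basis function values (npts, nbf) and gradients (3, npts, nbf)."""
    npts = points.shape[0]
    phi = np.zeros((npts, basis.nbf))
    dphi = np.zeros((3, npts, basis.nbf)) if gradients else None
    from ..basis_integrals.shells import cart_components

    for ish, sh in enumerate(basis.shells):
        A = basis.shell_center(ish)
        d = points - A
        r2 = np.einsum("pi,pi->p", d, d)
        rad = np.zeros(npts)
        drad = np.zeros(npts)
        for a, c in zip(sh.exponents, sh.coefs_normalized):
            e = c * np.exp(-a * r2)
            rad += e
            drad += -2.0 * a * e
        i0 = basis.offsets[ish]
        for ic, (lx, ly, lz) in enumerate(cart_components(sh.angular_momentum)):
            nrm = sh.angular_norms[ic]
            poly = d[:, 0] ** lx * d[:, 1] ** ly * d[:, 2] ** lz
            phi[:, i0 + ic] = nrm * poly * rad
            if gradients:
                for ax, l in enumerate((lx, ly, lz)):
                    grad = poly * drad * d[:, ax]
                    if l > 0:
                        lower = [lx, ly, lz]
                        lower[ax] -= 1
                        dpoly = (
                            l
                            * d[:, 0] ** lower[0]
                            * d[:, 1] ** lower[1]
                            * d[:, 2] ** lower[2]
                        )
                        grad = grad + dpoly * rad
                    dphi[ax, :, i0 + ic] = nrm * grad
    return (phi, dphi) if gradients else phi
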