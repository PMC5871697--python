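"""Independent numerical oracles for the analytic integral routines.

These deliberately avoid the Obara-Saika recursion: primitive products
are integrated by Gauss-Hermite quadrature (exact for polynomial *
Gaussian integrands), the 1/r kernel via its Gaussian-transform
1/r = (2/sqrt(pi)) \\int_0^inf exp(-u^2 r^2) du with an outer adaptive
quadrature, and (ss|ss) repulsion by Monte-Carlo importance sampling.
"""

import numpy as np
from scipy.integrate import quad

# 24 nodes: exact for the (low-degree polynomial) x Gaussian integrands
# here, and better conditioned than larger rules under the e^{t^2} trick
_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(24)


class PrimitiveCart:
    """One Cartesian Gaussian primitive c * (x-A)^lx (y-A)^ly (z-A)^lz e^{-a r^2}."""

    def __init__(self, alpha, center, powers, coef=1.0):
        self.alpha = float(alpha)
        self.center = np.asarray(center, dtype=float)
        self.powers = tuple(int(p) for p in powers)
        self.coef = float(coef)

    def __call__(self, pts):
        d = pts - self.center
        r2 = np.einsum("pi,pi->p", d, d)
        poly = d[:, 0] ** self.powers[0] * d[:, 1] ** self.powers[1] * d[:, 2] ** self.powers[2]
        return self.coef * poly * np.exp(-self.alpha * r2)

    def laplacian(self, pts):
        """Analytic Laplacian by direct polynomial differentiation."""
        d = pts - self.center
        r2 = np.einsum("pi,pi->p", d, d)
        a = self.alpha
        out = np.zeros(pts.shape[0])
        lx, ly, lz = self.powers
        base = np.exp(-a * r2)
        for ax, l in enumerate((lx, ly, lz)):
            x = d[:, ax]
            others = [d[:, k] ** p for k, p in enumerate(self.powers) if k != ax]
            oth = others[0] * others[1]
            term = (
                (l * (l - 1) * x ** (l - 2) if l >= 2 else 0.0)
                - 2.0 * a * (2 * l + 1) * x**l
                + 4.0 * a * a * x ** (l + 2)
            )
            out += oth * term * base
        return self.coef * out


def _gh_grid(p, mu):
    """Tensor Gauss-Hermite nodes for weight e^{-p (r-mu)^2}, with the
    inverse weight folded in so any extra polynomial factor integrates
    exactly."""
    t = _GH_NODES / np.sqrt(p)
    X, Y, Z = np.meshgrid(t + mu[0], t + mu[1], t + mu[2], indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    w1 = _GH_WEIGHTS * np.exp(_GH_NODES**2) / np.sqrt(p)
    W = np.einsum("i,j,k->ijk", w1, w1, w1).ravel()
    d = pts - mu
    W = W * np.exp(-p * np.einsum("pi,pi->p", d, d))
    return pts, W


def quad_product(pa: PrimitiveCart, pb: PrimitiveCart, extra=None):
    """\\int pa(r) pb(r) [extra(r)] dr by Gauss-Hermite quadrature."""
    p = pa.alpha + pb.alpha
    mu = (pa.alpha * pa.center + pb.alpha * pb.center) / p
    pts, W = _gh_grid(p, mu)
    vals = pa(pts) * pb(pts) / np.exp(
        -p * np.einsum("pi,pi->p", pts - mu, pts - mu)
    )
    if extra is not None:
        vals = vals * extra(pts)
    return float(np.sum(W * vals))


def overlap_oracle(pa, pb):
    return quad_product(pa, pb)


def kinetic_oracle(pa, pb):
    p = pa.alpha + pb.alpha
    mu = (pa.alpha * pa.center + pb.alpha * pb.center) / p
    pts, W = _gh_grid(p, mu)
    gauss = np.exp(-p * np.einsum("pi,pi->p", pts - mu, pts - mu))
    vals = pa(pts) * (-0.5) * pb.laplacian(pts) / gauss
    return float(np.sum(W * vals))


def dipole_oracle(pa, pb, axis, origin):
    return quad_product(
        pa, pb, extra=lambda pts: pts[:, axis] - origin[axis]
    )


def attraction_oracle(pa, pb, charge_pos):
    """-<a| 1/|r-C| |b> via the Gaussian transform of 1/r.

    The semi-infinite u-integral is mapped to t in [0,1) via u=t/(1-t)
    (the integrand tail decays only as u^-3, so truncation would bite).
    """
    C = np.asarray(charge_pos, dtype=float)

    def inner(u):
        # combine three Gaussians: pa, pb, e^{-u^2 |r-C|^2}
        p = pa.alpha + pb.alpha + u * u
        mu = (pa.alpha * pa.center + pb.alpha * pb.center + u * u * C) / p
        pts, W = _gh_grid(p, mu)
        gauss = np.exp(-p * np.einsum("pi,pi->p", pts - mu, pts - mu))
        dC = pts - C
        vals = pa(pts) * pb(pts) * np.exp(-u * u * np.einsum("pi,pi->p", dC, dC)) / gauss
        return float(np.sum(W * vals))

    def mapped(t):
        u = t / (1.0 - t)
        return inner(u) / (1.0 - t) ** 2

    # the mapped integrand is smooth on [0,1]; a fixed high-order
    # Gauss-Legendre rule reaches ~1e-10 and is much cheaper than
    # adaptive quadrature here
    nodes, weights = np.polynomial.legendre.leggauss(96)
    t = 0.5 * (nodes + 1.0)
    val = 0.5 * float(np.sum(weights * [mapped(ti) for ti in t]))
    return -2.0 / np.sqrt(np.pi) * val


def eri_ssss_closed_form(alpha, norm=True):
    """(ss|ss) for four identical s primitives on one center."""
    n = (2.0 * alpha / np.pi) ** 0.75 if norm else 1.0
    zeta = 2.0 * alpha
    # F0(0) = 1
    return n**4 * 2.0 * np.pi**2.5 / (zeta * zeta * np.sqrt(2.0 * zeta))


def eri_ssss_montecarlo(alpha, nsamples=4_000_000, seed=7):
    """MC estimate of <1/r12> over two normalized s-primitive densities."""
    rng = np.random.default_rng(seed)
    std = 1.0 / np.sqrt(2.0 * (2.0 * alpha))  # density ~ e^{-2 a r^2}
    r1 = rng.normal(0.0, std, size=(nsamples, 3))
    r2 = rng.normal(0.0, std, size=(nsamples, 3))
    inv = 1.0 / np.linalg.norm(r1 - r2, axis=1)
    return float(inv.mean()), float(inv.std() / np.sqrt(nsamples))
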