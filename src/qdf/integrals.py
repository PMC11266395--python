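"""McMurchie-Davidson evaluation of Gaussian one- and two-electron integrals.

Implements overlap, kinetic, point-charge (nuclear attraction / MM
embedding / cavity potential) and electron-repulsion integrals over
contracted Cartesian Gaussians, plus analytic derivatives with respect to
basis-function centers via the raise/lower identity

    d/dA_x phi(i) = 2a phi(i+1) - i phi(i-1).

Two-electron integrals are stored in chemists' notation (mu nu|lambda
sigma) = integral of mu(1) nu(1) r12^-1 lambda(2) sigma(2).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammainc, gammaln

from .basis import BasisFunction


def boys(n: int, x):
    """Boys function F_n(x), vectorized over x."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    out = np.empty_like(x)
    small = x < 1e-13
    out[small] = 1.0 / (2 * n + 1) - x[small] / (2 * n + 3)
    xb = x[~small]
    a = n + 0.5
    # F_n(x) = Gamma(a) * P(a, x) / (2 x^a)
    out[~small] = np.exp(gammaln(a)) * gammainc(a, xb) / (2.0 * xb**a)
    return out[0] if scalar else out


def boys_all(nmax: int, x):
    """F_0..F_nmax at points x via stable downward recursion."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.empty((nmax + 1, len(x)))
    out[nmax] = boys(nmax, x)
    ex = np.exp(-x)
    for n in range(nmax, 0, -1):
        out[n - 1] = (2.0 * x * out[n] + ex) / (2 * n - 1)
    return out


_E1D_CACHE: dict = {}


def _E1d(i: int, j: int, a: float, b: float, AB: float) -> np.ndarray:
    key = (i, j, a, b, AB)
    cached = _E1D_CACHE.get(key)
    if cached is not None:
        return cached
    out = _E1d_compute(i, j, a, b, AB)
    if len(_E1D_CACHE) > 500000:
        _E1D_CACHE.clear()
    _E1D_CACHE[key] = out
    return out


def _E1d_compute(i: int, j: int, a: float, b: float, AB: float) -> np.ndarray:
    """Hermite expansion coefficients E_t^{ij} for one Cartesian direction."""
    p = a + b
    mu = a * b / p
    # table[(i,j)] -> array over t = 0..i+j
    E = {(0, 0): np.array([np.exp(-mu * AB * AB)])}
    XPA = -b * AB / p   # P - A with AB = A - B
    XPB = a * AB / p    # P - B

    def get(ii, jj):
        if (ii, jj) in E:
            return E[(ii, jj)]
        if ii > 0:
            prev = get(ii - 1, jj)
            X = XPA
        else:
            prev = get(ii, jj - 1)
            X = XPB
        n = len(prev)
        out = np.zeros(n + 1)
        # E_t^{i+1,j} = 1/(2p) E_{t-1} + X_PA E_t + (t+1) E_{t+1}
        out[1:] += prev / (2.0 * p)
        out[:n] += X * prev
        out[:n - 1] += np.arange(1, n) * prev[1:]
        E[(ii, jj)] = out
        return out

    return get(i, j)


def _hermite_coulomb(t_max, u_max, v_max, p, PC, n_extra=0):
    """R_{tuv} Hermite Coulomb integrals for a single composite center.

    Returns array R[t, u, v] (auxiliary order 0).  PC may be shape (3,) or
    (npts, 3); in the latter case the result has a leading points axis.
    """
    PC = np.asarray(PC, dtype=float)
    batched = PC.ndim == 2
    if not batched:
        PC = PC[None, :]
    npts = PC.shape[0]
    nmax = t_max + u_max + v_max + n_extra
    R2 = np.einsum("pi,pi->p", PC, PC)
    Fns = boys_all(nmax, p * R2)  # (nmax+1, npts)
    base = ((-2.0 * p) ** np.arange(nmax + 1))[:, None] * Fns
    # R^n_{tuv} built by recursion, memoized
    memo: dict[tuple[int, int, int], np.ndarray] = {}

    def R(t, u, v):
        # returns array over n axis trimmed appropriately: we store full
        # n-indexed arrays R^n for n = 0..nmax-(t+u+v)
        key = (t, u, v)
        if key in memo:
            return memo[key]
        if t == u == v == 0:
            memo[key] = base
            return base
        if t > 0:
            r1 = R(t - 1, u, v)
            out = PC[None, :, 0] * r1[1:]
            if t > 1:
                out = out + (t - 1) * R(t - 2, u, v)[1:1 + out.shape[0]]
        elif u > 0:
            r1 = R(t, u - 1, v)
            out = PC[None, :, 1] * r1[1:]
            if u > 1:
                out = out + (u - 1) * R(t, u - 2, v)[1:1 + out.shape[0]]
        else:
            r1 = R(t, u, v - 1)
            out = PC[None, :, 2] * r1[1:]
            if v > 1:
                out = out + (v - 1) * R(t, u, v - 2)[1:1 + out.shape[0]]
        memo[key] = out
        return out

    res = np.empty((t_max + 1, u_max + 1, v_max + 1, npts))
    for t in range(t_max + 1):
        for u in range(u_max + 1):
            for v in range(v_max + 1):
                res[t, u, v] = R(t, u, v)[0]
    if not batched:
        res = res[..., 0]
    return res


# ---------------------------------------------------------------------------
# primitive-level integrals
# ---------------------------------------------------------------------------

def _prim_overlap(a, la, A, b, lb, B):
    p = a + b
    s = (np.pi / p) ** 1.5
    for ax in range(3):
        E = _E1d(la[ax], lb[ax], a, b, A[ax] - B[ax])
        s *= E[0]
    return s


def _prim_kinetic(a, la, A, b, lb, B):
    # T = -1/2 <a|lap|b>; apply derivative to ket
    def S1d(i, j, ax):
        if i < 0 or j < 0:
            return 0.0
        return _E1d(i, j, a, b, A[ax] - B[ax])[0]

    p = a + b
    pref = (np.pi / p) ** 1.5
    terms = []
    for ax in range(3):
        j = lb[ax]
        d2 = 4 * b * b * S1d(la[ax], j + 2, ax) \
            - 2 * b * (2 * j + 1) * S1d(la[ax], j, ax)
        if j >= 2:
            d2 += j * (j - 1) * S1d(la[ax], j - 2, ax)
        others = 1.0
        for ax2 in range(3):
            if ax2 != ax:
                others *= S1d(la[ax2], lb[ax2], ax2)
        terms.append(d2 * others)
    return -0.5 * pref * sum(terms)


def _prim_potential(a, la, A, b, lb, B, points):
    """(a|1/|r-P||b) for each P in points (npts, 3)."""
    p = a + b
    P = (a * A + b * B) / p
    Ex = _E1d(la[0], lb[0], a, b, A[0] - B[0])
    Ey = _E1d(la[1], lb[1], a, b, A[1] - B[1])
    Ez = _E1d(la[2], lb[2], a, b, A[2] - B[2])
    Rt = _hermite_coulomb(len(Ex) - 1, len(Ey) - 1, len(Ez) - 1, p,
                          P[None, :] - points)
    val = np.einsum("t,u,v,tuvp->p", Ex, Ey, Ez, Rt)
    return 2.0 * np.pi / p * val


def _prim_eri(a, la, A, b, lb, B, c, lc, C, d, ld, D):
    p = a + b
    q = c + d
    P = (a * A + b * B) / p
    Q = (c * C + d * D) / q
    alpha = p * q / (p + q)
    E1 = [_E1d(la[ax], lb[ax], a, b, A[ax] - B[ax]) for ax in range(3)]
    E2 = [_E1d(lc[ax], ld[ax], c, d, C[ax] - D[ax]) for ax in range(3)]
    tmax = len(E1[0]) + len(E2[0]) - 2
    umax = len(E1[1]) + len(E2[1]) - 2
    vmax = len(E1[2]) + len(E2[2]) - 2
    Rt = _hermite_coulomb(tmax, umax, vmax, alpha, P - Q)
    val = 0.0
    for t1, e1x in enumerate(E1[0]):
        for u1, e1y in enumerate(E1[1]):
            for v1, e1z in enumerate(E1[2]):
                c1 = e1x * e1y * e1z
                if c1 == 0.0:
                    continue
                for t2, e2x in enumerate(E2[0]):
                    for u2, e2y in enumerate(E2[1]):
                        for v2, e2z in enumerate(E2[2]):
                            c2 = e2x * e2y * e2z
                            if c2 == 0.0:
                                continue
                            sign = (-1.0) ** (t2 + u2 + v2)
                            val += c1 * c2 * sign * Rt[t1 + t2, u1 + u2, v1 + v2]
    return 2.0 * np.pi**2.5 / (p * q * np.sqrt(p + q)) * val


# ---------------------------------------------------------------------------
# contracted-pair machinery (works for derivative pseudo-functions too)
# ---------------------------------------------------------------------------

def _pair_integral(f, g, prim_func):
    acc = 0.0
    for a, ca in zip(f.exps, f.coefs):
        for b, cb in zip(g.exps, g.coefs):
            acc += ca * cb * prim_func(a, f.powers, f.center, b, g.powers, g.center)
    return acc


def _derivative_parts(f: BasisFunction, axis: int):
    """Return pseudo-functions representing d f / d(center[axis])."""
    parts = []
    up = list(f.powers)
    up[axis] += 1
    parts.append(BasisFunction(f.center, tuple(up), f.exps,
                               2.0 * f.exps * f.coefs, f.atom_index))
    if f.powers[axis] > 0:
        dn = list(f.powers)
        dn[axis] -= 1
        parts.append(BasisFunction(f.center, tuple(dn), f.exps,
                                   -f.powers[axis] * f.coefs, f.atom_index))
    return parts


# ---------------------------------------------------------------------------
# matrix / tensor builders
# ---------------------------------------------------------------------------

def overlap_matrix(basis):
    n = len(basis)
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            S[i, j] = S[j, i] = _pair_integral(basis[i], basis[j], _prim_overlap)
    return S


def kinetic_matrix(basis):
    n = len(basis)
    T = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            T[i, j] = T[j, i] = _pair_integral(basis[i], basis[j], _prim_kinetic)
    return T


def potential_matrices(basis, points):
    """(mu|1/|r-P||nu) for every P: array of shape (npts, nao, nao)."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    n = len(basis)
    out = np.zeros((len(points), n, n))
    for i in range(n):
        for j in range(i + 1):
            f, g = basis[i], basis[j]
            acc = np.zeros(len(points))
            for a, ca in zip(f.exps, f.coefs):
                for b, cb in zip(g.exps, g.coefs):
                    acc += ca * cb * _prim_potential(
                        a, f.powers, f.center, b, g.powers, g.center, points)
            out[:, i, j] = out[:, j, i] = acc
    return out


def nuclear_attraction_matrix(basis, charges, centers):
    """V_mu_nu = -sum_k q_k (mu|1/|r-C_k||nu)  (centers in Bohr)."""
    pots = potential_matrices(basis, centers)
    return -np.einsum("k,kij->ij", np.asarray(charges, float), pots)


def eri_tensor(basis):
    """Full (mu nu|lambda sigma) tensor, chemists' notation, 8-fold symmetric."""
    n = len(basis)
    eri = np.zeros((n, n, n, n))
    pair_index = [(i, j) for i in range(n) for j in range(i + 1)]
    for ij, (i, j) in enumerate(pair_index):
        for kl in range(ij + 1):
            k, l = pair_index[kl]
            val = 0.0
            bi, bj, bk, bl = basis[i], basis[j], basis[k], basis[l]
            for a, ca in zip(bi.exps, bi.coefs):
                for b, cb in zip(bj.exps, bj.coefs):
                    for c, cc in zip(bk.exps, bk.coefs):
                        for d, cd in zip(bl.exps, bl.coefs):
                            val += ca * cb * cc * cd * _prim_eri(
                                a, bi.powers, bi.center, b, bj.powers, bj.center,
                                c, bk.powers, bk.center, d, bl.powers, bl.center)
            for (p, q) in ((i, j), (j, i)):
                for (r, s) in ((k, l), (l, k)):
                    eri[p, q, r, s] = eri[r, s, p, q] = val
    return eri


# ---------------------------------------------------------------------------
# derivatives with respect to an atom's position
# ---------------------------------------------------------------------------

def overlap_derivative_bra(basis, atom, axis):
    """dS[mu,nu] with the derivative applied to the bra function only and
    restricted to bra functions centered on ``atom``."""
    n = len(basis)
    dS = np.zeros((n, n))
    for i in range(n):
        if basis[i].atom_index != atom:
            continue
        for part in _derivative_parts(basis[i], axis):
            for j in range(n):
                dS[i, j] += _pair_integral(part, basis[j], _prim_overlap)
    return dS


def core_derivative_bra(basis, atom, axis, charges, centers):
    """d(mu|T+V|nu) bra-derivative only (operator centers held fixed)."""
    n = len(basis)
    dH = np.zeros((n, n))
    centers = np.asarray(centers, float).reshape(-1, 3)
    charges = np.asarray(charges, float)
    for i in range(n):
        if basis[i].atom_index != atom:
            continue
        for part in _derivative_parts(basis[i], axis):
            for j in range(n):
                g = basis[j]
                val = _pair_integral(part, g, _prim_kinetic)
                for a, ca in zip(part.exps, part.coefs):
                    for b, cb in zip(g.exps, g.coefs):
                        pots = _prim_potential(a, part.powers, part.center,
                                               b, g.powers, g.center, centers)
                        val -= ca * cb * float(charges @ pots)
                dH[i, j] += val
    return dH


def operator_center_derivative(basis, center, axis):
    """d(mu|1/|r-C||nu)/dC_axis via translational invariance:
    dC = -(d_bra + d_ket)."""
    n = len(basis)
    dV = np.zeros((n, n))
    pt = np.asarray(center, float).reshape(1, 3)

    def pair_pot(f, g):
        acc = 0.0
        for a, ca in zip(f.exps, f.coefs):
            for b, cb in zip(g.exps, g.coefs):
                acc += ca * cb * _prim_potential(a, f.powers, f.center,
                                                 b, g.powers, g.center, pt)[0]
        return acc

    for i in range(n):
        for j in range(i + 1):
            val = 0.0
            for part in _derivative_parts(basis[i], axis):
                val -= pair_pot(part, basis[j])
            for part in _derivative_parts(basis[j], axis):
                val -= pair_pot(basis[i], part)
            dV[i, j] = dV[j, i] = val
    return dV


def eri_derivative_bra(basis, atom, axis):
    """d(mu nu|lambda sigma) with derivative applied to the first slot only,
    zero rows for mu not on ``atom``."""
    n = len(basis)
    out = np.zeros((n, n, n, n))
    for i in range(n):
        if basis[i].atom_index != atom:
            continue
        for part in _derivative_parts(basis[i], axis):
            for j in range(n):
                bj = basis[j]
                for k in range(n):
                    for l in range(k + 1):
                        bk, bl = basis[k], basis[l]
                        val = 0.0
                        for a, ca in zip(part.exps, part.coefs):
                            for b, cb in zip(bj.exps, bj.coefs):
                                for c, cc in zip(bk.exps, bk.coefs):
                                    for d, cd in zip(bl.exps, bl.coefs):
                                        val += ca * cb * cc * cd * _prim_eri(
                                            a, part.powers, part.center,
                                            b, bj.powers, bj.center,
                                            c, bk.powers, bk.center,
                                            d, bl.powers, bl.center)
                        out[i, j, k, l] += val
                        if k != l:
                            out[i, j, l, k] += val
    return out
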