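"""Independent reference implementations used only by the tests.

These deliberately avoid the code paths they check: the CPMG oracle is a
discrete-isochromat Bloch simulation, the bSSFP oracle reaches steady
state by brute-force pulse-by-pulse iteration with scipy matrix
exponentials, NNLS is solved by exhaustive support enumeration, and the
paired test by exact sign-flip enumeration.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm


def isochromat_cpmg(t2, t1, alpha_deg, delta_te, n_echoes, n_iso=2001):
    """CPMG echo train by brute-force Bloch rotation of discrete spins.

    90deg excitation about y, refocusing about x, crusher dephasing of one
    full cycle per half echo spacing distributed uniformly over the spins
    (exact quadrature for the finite dephasing-order spectrum), T2/T1
    relaxation with equilibrium regrowth.
    """
    phis = 2 * np.pi * (np.arange(n_iso) + 0.5) / n_iso
    M = np.zeros((3, n_iso))
    M[0] = 1.0
    a = np.deg2rad(alpha_deg)
    tau = delta_te / 2.0
    E2, E1 = np.exp(-tau / t2), np.exp(-tau / t1)
    c, s = np.cos(phis), np.sin(phis)
    ca, sa = np.cos(a), np.sin(a)

    def free(M):
        x = c * M[0] + s * M[1]
        y = -s * M[0] + c * M[1]
        z = 1.0 + (M[2] - 1.0) * E1
        return np.array([E2 * x, E2 * y, z])

    def pulse(M):
        return np.array([
            M[0],
            ca * M[1] + sa * M[2],
            -sa * M[1] + ca * M[2],
        ])

    echoes = np.zeros(n_echoes)
    for n in range(n_echoes):
        M = free(M)
        M = pulse(M)
        M = free(M)
        echoes[n] = M[0].mean()
    return echoes


def bloch_bssfp(pools, tr, te, fa_deg, phase_cycle_deg, delta_f, kappa=1.0,
                n_iter=20000, tol=1e-14):
    """Steady-state bSSFP magnitude by pulse-by-pulse fixed-point iteration.

    ``pools`` is a list of dicts with keys f, t1, t2 and optionally
    exchange ("k_to_next"/"k_from_next" couple pool i and i+1). Uses scipy
    ``expm`` of the full real relaxation-exchange-precession generator —
    an implementation route disjoint from the closed-form model.
    """
    n = len(pools)
    dim = 3 * n
    omega = 2 * np.pi * delta_f / 1000.0 + np.deg2rad(phase_cycle_deg) / tr
    A = np.zeros((dim, dim))
    meq = np.zeros(dim)
    for i, p in enumerate(pools):
        o = 3 * i
        A[o, o] = -1.0 / p["t2"]
        A[o, o + 1] = omega
        A[o + 1, o] = -omega
        A[o + 1, o + 1] = -1.0 / p["t2"]
        A[o + 2, o + 2] = -1.0 / p["t1"]
        meq[o + 2] = p["f"]
    for i, p in enumerate(pools):
        k_out = p.get("k_to_next", 0.0)
        k_in = p.get("k_from_next", 0.0)
        if k_out or k_in:
            o, q = 3 * i, 3 * (i + 1)
            for d in range(3):
                A[o + d, o + d] -= k_out
                A[q + d, o + d] += k_out
                A[q + d, q + d] -= k_in
                A[o + d, q + d] += k_in

    E_tr = expm(A * tr)
    b_tr = meq - E_tr @ meq
    theta = kappa * np.deg2rad(fa_deg)
    ca, sa = np.cos(theta), np.sin(theta)
    R = np.zeros((dim, dim))
    for i in range(n):
        o = 3 * i
        R[o, o] = 1.0
        R[o + 1, o + 1] = ca
        R[o + 1, o + 2] = sa
        R[o + 2, o + 1] = -sa
        R[o + 2, o + 2] = ca

    M = meq.copy()
    for _ in range(n_iter):
        M_new = E_tr @ (R @ M) + b_tr
        if np.max(np.abs(M_new - M)) < tol:
            M = M_new
            break
        M = M_new
    E_te = expm(A * te)
    M_te = E_te @ (R @ M) + (meq - E_te @ meq)
    tx = sum(M_te[3 * i] for i in range(n))
    ty = sum(M_te[3 * i + 1] for i in range(n))
    return float(np.hypot(tx, ty))


def nnls_bruteforce(basis, signal):
    """Global NNLS optimum by exhaustive support-set enumeration (small n)."""
    basis = np.asarray(basis, dtype=float)
    signal = np.asarray(signal, dtype=float)
    n = basis.shape[1]
    best_x = np.zeros(n)
    best_r = float(signal @ signal)
    for r in range(1, n + 1):
        for support in itertools.combinations(range(n), r):
            sub = basis[:, support]
            x, *_ = np.linalg.lstsq(sub, signal, rcond=None)
            if np.any(x < -1e-12):
                continue
            resid = signal - sub @ np.clip(x, 0, None)
            rr = float(resid @ resid)
            if rr < best_r - 1e-15:
                best_r = rr
                best_x = np.zeros(n)
                best_x[list(support)] = np.clip(x, 0, None)
    return best_x, best_r


def signflip_pvalue(values_a, values_b):
    """Exact two-sided sign-flip p-value for paired data (n <= ~16).

    Under the null the signs of the paired differences are exchangeable;
    because sum(d^2) is flip-invariant, the t statistic is monotone in
    |mean|, so the exact p is the fraction of sign patterns whose |mean|
    reaches the observed one.
    """
    d = np.asarray(values_b, dtype=float) - np.asarray(values_a, dtype=float)
    n = len(d)
    obs = abs(d.mean())
    signs = np.array(list(itertools.product([-1.0, 1.0], repeat=n)))
    means = np.abs((signs * d).mean(axis=1))
    return float(np.mean(means >= obs - 1e-12))
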