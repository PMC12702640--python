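"""Brute-force Mie oracle, independent of the package implementation.

Computes partial-wave coefficients directly from SciPy's spherical Bessel
functions (Bohren & Huffman closed forms, no logarithmic-derivative
recurrence) and sums the amplitude series with its own angular-function
recurrence.  Real relative refractive index only.
"""

import numpy as np
from scipy.special import spherical_jn, spherical_yn


def coefficients(x: float, m: float, nmax: int | None = None):
    if nmax is None:
        nmax = int(np.ceil(x + 4.05 * x ** (1.0 / 3.0) + 2.0))
    n = np.arange(1, nmax + 1)

    jx = spherical_jn(n, x)
    jxp = spherical_jn(n, x, derivative=True)
    yx = spherical_yn(n, x)
    yxp = spherical_yn(n, x, derivative=True)
    psi = x * jx
    psip = jx + x * jxp
    chi = -x * yx
    chip = -(yx + x * yxp)
    xi = psi - 1j * chi
    xip = psip - 1j * chip

    mx = m * x
    jm = spherical_jn(n, mx)
    jmp = spherical_jn(n, mx, derivative=True)
    psim = mx * jm
    psimp = jm + mx * jmp

    an = (m * psim * psip - psi * psimp) / (m * psim * xip - xi * psimp)
    bn = (psim * psip - m * psi * psimp) / (psim * xip - m * xi * psimp)
    return an, bn


def amplitudes(x: float, m: float, theta):
    """S1(theta), S2(theta) by direct term-by-term summation."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    an, bn = coefficients(x, m)
    S1 = np.zeros(theta.size, dtype=complex)
    S2 = np.zeros(theta.size, dtype=complex)
    for j, mu in enumerate(np.cos(theta)):
        pi_prev, pi_cur = 0.0, 1.0  # pi_0, pi_1
        s1 = 0.0 + 0.0j
        s2 = 0.0 + 0.0j
        for k in range(1, an.size + 1):
            tau = k * mu * pi_cur - (k + 1) * pi_prev
            f = (2 * k + 1) / (k * (k + 1))
            s1 += f * (an[k - 1] * pi_cur + bn[k - 1] * tau)
            s2 += f * (an[k - 1] * tau + bn[k - 1] * pi_cur)
            pi_prev, pi_cur = pi_cur, ((2 * k + 1) * mu * pi_cur - (k + 1) * pi_prev) / k
        S1[j] = s1
        S2[j] = s2
    return S1, S2
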