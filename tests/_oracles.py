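"""Independent brute-force oracles for the covariance and weighting math.

Everything here is written as plain loops over the defining formulas and is
deliberately independent of the library implementations it checks.
"""

import numpy as np


def mv_covariance_loops(x_stack, L):
    """Triple-loop covariance: temporal x spatial average of outer products."""
    x_stack = [np.asarray(x) for x in x_stack]
    n = x_stack[0].size
    n_sub = n - L + 1
    R = np.zeros((L, L), dtype=complex)
    for x in x_stack:
        for l in range(n_sub):
            for a in range(L):
                for b in range(L):
                    R[a, b] += x[l + a] * np.conj(x[l + b])
    return R / (len(x_stack) * n_sub)


def smooth_covariance_loops(x, L):
    return mv_covariance_loops([x], L)


def rotary_average_terms(R):
    """Term-by-term evaluation with an explicit exchange matrix."""
    R = np.asarray(R)
    n = R.shape[0]
    J = np.zeros((n, n))
    for i in range(n):
        J[i, n - 1 - i] = 1.0
    return (R + J @ R.T + J @ R @ J + R.T @ J) / 4.0


def msr_loops(M):
    """Double-loop mean / population-std of the real parts of all entries."""
    A = np.asarray(M).real
    n = A.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += A[i, j]
    mean = total / n**2
    acc = 0.0
    for i in range(n):
        for j in range(n):
            acc += (A[i, j] - mean) ** 2
    std = np.sqrt(acc / n**2)
    return mean, std


def capon_weights_inverse(R):
    """Capon weights via explicit matrix inversion (oracle path)."""
    a = np.ones(R.shape[0])
    Ri = np.linalg.inv(R)
    w = Ri @ a
    return w / (a.conj() @ Ri @ a)


def random_hpd(rng, n, load=0.1):
    """Random Hermitian positive-definite matrix."""
    A = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
    R = A @ A.conj().T / n
    return R + load * np.trace(R).real / n * np.eye(n)
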