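"""Independent reference implementations used only as test oracles."""

import numpy as np


def grid_search_slope(x, y, lo=-10.0, hi=10.0):
    """Brute-force maximizer of the standardized logistic likelihood:
    three-stage grid over (intercept, slope), final step 5e-4."""
    z = (x - x.mean()) / x.std(ddof=1)

    def ll(b0, b1):
        eta = b0 + b1 * z
        return np.sum(y * eta - np.logaddexp(0.0, eta))

    b0s = np.linspace(-5, 5, 101)
    b1s = np.linspace(lo, hi, 201)
    best = max(((ll(b0, b1), b0, b1) for b0 in b0s for b1 in b1s))
    for width in (0.2, 0.01):
        _, b0c, b1c = best
        b0s = np.linspace(b0c - width, b0c + width, 81)
        b1s = np.linspace(b1c - width, b1c + width, 81)
        best = max(((ll(b0, b1), b0, b1) for b0 in b0s for b1 in b1s))
    return best[2]


def oracle_epg_train(alpha_ex, alpha_ref, n_echo, esp, t1, t2):
    """Dense-matrix extended-phase-graph simulation: every operator is an
    explicit matrix over the stacked (F+, F-, Z) state vector.  Slow and
    direct; independent of the production recursion."""
    N = 2 * n_echo + 2
    dim = 3 * N

    def idx(row, k):
        return row * N + k

    def rf_mat(a, phase):
        T = np.array([
            [np.cos(a / 2) ** 2, np.exp(2j * phase) * np.sin(a / 2) ** 2,
             -1j * np.exp(1j * phase) * np.sin(a)],
            [np.exp(-2j * phase) * np.sin(a / 2) ** 2, np.cos(a / 2) ** 2,
             1j * np.exp(-1j * phase) * np.sin(a)],
            [-0.5j * np.exp(-1j * phase) * np.sin(a),
             0.5j * np.exp(1j * phase) * np.sin(a), np.cos(a)],
        ])
        M = np.zeros((dim, dim), complex)
        for k in range(N):
            for r in range(3):
                for c in range(3):
                    M[idx(r, k), idx(c, k)] = T[r, c]
        return M

    def relax(v, tau):
        e2, e1 = np.exp(-tau / t2), np.exp(-tau / t1)
        v = v.copy()
        v[0:N] *= e2
        v[N:2 * N] *= e2
        v[2 * N:] *= e1
        v[idx(2, 0)] += 1 - e1
        return v

    def shift(v):
        v = v.copy()
        Fp, Fm = v[0:N].copy(), v[N:2 * N].copy()
        Fp[1:] = Fp[:-1]
        Fm[:-1] = Fm[1:]
        Fm[-1] = 0
        Fp[0] = np.conj(Fm[0])
        v[0:N], v[N:2 * N] = Fp, Fm
        return v

    v = np.zeros(dim, complex)
    v[idx(2, 0)] = 1.0
    v = rf_mat(alpha_ex, 0.0) @ v
    R = rf_mat(alpha_ref, np.pi / 2)
    out = []
    for _ in range(n_echo):
        v = shift(relax(v, esp / 2))
        v = R @ v
        v = shift(relax(v, esp / 2))
        out.append(abs(v[idx(0, 0)]))
    return np.array(out)
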