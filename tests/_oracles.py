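"""Independent reference implementations used only as test oracles."""

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import linprog


def barrier_recruitment_oracle(C, d, v, N, n_m, mu_end=1e-14):
    """Independent convex solver for the volume-normalised cubic recruitment
    problem: log-barrier path following with null-space Newton, strictly
    feasible start from an LP on the muscle margin.  Shares no code with the
    package solver."""
    n = C.shape[1]
    scale = max(1.0, np.linalg.norm(d))
    col = np.concatenate([N, np.full(n - n_m, scale)])
    Cx = C * col[None, :]
    vv = v / v.mean()

    cobj = np.zeros(n + 1)
    cobj[-1] = -1.0
    A_eq = np.hstack([Cx, np.zeros((Cx.shape[0], 1))])
    A_ub = np.zeros((n_m, n + 1))
    for i in range(n_m):
        A_ub[i, i] = -1.0
        A_ub[i, -1] = 1.0
    lp = linprog(cobj, A_ub=A_ub, b_ub=np.zeros(n_m), A_eq=A_eq, b_eq=d,
                 bounds=[(None, None)] * n + [(None, 10.0)])
    if not (lp.success and lp.x[-1] > 0):
        raise RuntimeError("oracle: no strictly feasible start")
    x = lp.x[:n]
    Z = null_space(Cx)
    mu = 1e-1
    while mu > mu_end:
        for _ in range(200):
            xm = x[:n_m]
            g = np.zeros(n)
            Hd = np.zeros(n)
            g[:n_m] = 3 * vv * xm**2 - mu / xm
            Hd[:n_m] = 6 * vv * xm + mu / xm**2
            gz = Z.T @ g
            Hz = (Z * Hd[:, None]).T @ Z
            dy = np.linalg.solve(Hz, -gz)
            step = Z @ dy
            neg = step[:n_m] < 0
            alpha = 1.0
            if neg.any():
                alpha = min(1.0, 0.99 * np.min(-xm[neg] / step[:n_m][neg]))
            x = x + alpha * step
            if float(-gz @ dy) < 1e-16:
                break
        mu *= 0.2
    return x * col


def random_recruitment_instance(rng, max_muscles=5, max_dofs=2):
    """A feasible random moment-arm instance with antagonist coverage."""
    n_m = int(rng.integers(2, max_muscles + 1))
    n_dof = int(rng.integers(1, max_dofs + 1))
    r = rng.uniform(0.02, 0.08, size=(n_dof, n_m)) * rng.choice([-1, 1], size=(n_dof, n_m))
    for k in range(n_dof):
        if np.all(r[k] > 0) or np.all(r[k] < 0):
            r[k, rng.integers(n_m)] *= -1
    v = rng.uniform(1e-4, 1e-3, n_m)
    N = rng.uniform(500, 4000, n_m)
    d = r @ (rng.uniform(0, 1, n_m) * N * 0.3)
    return r, d, v, N, n_m


def terzaghi_pressure(z_from_drained, drainage_path, cv, t, sigma0, n_terms=300):
    """Series solution of 1-D consolidation with one drained face."""
    Z = np.asarray(z_from_drained, dtype=float) / drainage_path
    T = cv * t / drainage_path**2
    p = np.zeros_like(Z)
    for m in range(n_terms):
        M = (2 * m + 1) * np.pi / 2
        p += 2.0 / M * np.sin(M * Z) * np.exp(-M * M * T)
    return sigma0 * p
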