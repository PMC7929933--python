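"""Numba kernels for Euler-Maruyama integration of the chemical-Langevin model.

All kernels are seeded explicitly and run single-threaded, so results are
bitwise reproducible for a given (seed, dt, duration).  Non-negativity is
enforced by reflection at zero (absolute value after each step).  Hill
thresholds are raised to their exponents once per kernel call, and integer
Hill exponents use repeated multiplication instead of ``pow``.
"""

import numba as nb
import numpy as np


@nb.njit(cache=True)
def _xpow(x, n):
    ni = int(n)
    if ni == n and 0 < ni < 8:
        r = x
        for _ in range(ni - 1):
            r *= x
        return r
    return x ** n


@nb.njit(cache=True)
def _premats(K, n, K_s, m_s):
    N = K.shape[0]
    Km = np.empty((N, N))
    for i in range(N):
        for j in range(N):
            Km[i, j] = _xpow(K[i, j], n[i, j])
    Ksm = np.empty(N)
    for i in range(N):
        Ksm[i] = _xpow(K_s[i], m_s[i])
    return Km, Ksm


@nb.njit(cache=True)
def _gain_pre(x, s, sign, Km, n, w, ssign, Ksm, m_s, w_s, w_b, G):
    N = x.shape[0]
    for i in range(N):
        g = w_b[i] + w_s[i]
        if ssign[i] > 0:
            sm = _xpow(s, m_s[i])
            g = w_b[i] + w_s[i] * sm / (sm + Ksm[i])
        elif ssign[i] < 0:
            g = w_b[i] + w_s[i] * Ksm[i] / (Ksm[i] + _xpow(s, m_s[i]))
        for j in range(N):
            if sign[i, j] != 0:
                xm = _xpow(x[j], n[i, j])
                if sign[i, j] > 0:
                    h = xm / (xm + Km[i, j])
                else:
                    h = Km[i, j] / (Km[i, j] + xm)
                g *= 1.0 - w[i, j] + w[i, j] * h
        G[i] = g


@nb.njit(cache=True)
def gain(x, s, sign, K, n, w, ssign, K_s, m_s, w_s, w_b):
    Km, Ksm = _premats(K, n, K_s, m_s)
    G = np.empty(x.shape[0])
    _gain_pre(x, s, sign, Km, n, w, ssign, Ksm, m_s, w_s, w_b, G)
    return G


@nb.njit(cache=True)
def em_trajectory(
    x0, s, n_steps, stride, dt, omega, seed,
    alpha, delta, sign, K, n, w, ssign, K_s, m_s, w_s, w_b,
):
    """Single-cell trajectory; states recorded every ``stride`` steps.

    Returns (states, ok): states has shape (n_steps//stride + 1, N);
    ok = False signals numerical blow-up.
    """
    np.random.seed(seed)
    Km, Ksm = _premats(K, n, K_s, m_s)
    N = x0.shape[0]
    n_rec = n_steps // stride + 1
    out = np.empty((n_rec, N))
    G = np.empty(N)
    x = x0.copy()
    out[0] = x
    cap = 0.0
    for i in range(N):
        cap = max(cap, alpha[i] / delta[i])
    cap = 1e6 * max(cap, 1.0)
    k = 1
    for t in range(1, n_steps + 1):
        _gain_pre(x, s, sign, Km, n, w, ssign, Ksm, m_s, w_s, w_b, G)
        for i in range(N):
            prod = alpha[i] * G[i]
            deg = delta[i] * x[i]
            amp = np.sqrt((prod + deg) * dt / omega)
            x[i] = abs(x[i] + (prod - deg) * dt + amp * np.random.standard_normal())
            if not np.isfinite(x[i]) or x[i] > cap:
                return out, False
        if t % stride == 0:
            out[k] = x
            k += 1
    return out, True


@nb.njit(cache=True)
def em_endstates(
    x0, svals, n_steps, dt, omega, seed,
    alpha, delta, sign, K, n, w, ssign, K_s, m_s, w_s, w_b,
):
    """Ensemble of independent cells; returns end states and an ok flag.

    x0: (cells, N) initial states; svals: (cells,) per-cell signal levels.
    """
    np.random.seed(seed)
    Km, Ksm = _premats(K, n, K_s, m_s)
    cells, N = x0.shape
    x = x0.copy()
    G = np.empty(N)
    cap = 0.0
    for i in range(N):
        cap = max(cap, alpha[i] / delta[i])
    cap = 1e6 * max(cap, 1.0)
    for c in range(cells):
        for t in range(n_steps):
            _gain_pre(x[c], svals[c], sign, Km, n, w, ssign, Ksm, m_s, w_s, w_b, G)
            for i in range(N):
                prod = alpha[i] * G[i]
                deg = delta[i] * x[c, i]
                amp = np.sqrt((prod + deg) * dt / omega)
                x[c, i] = abs(x[c, i] + (prod - deg) * dt + amp * np.random.standard_normal())
                if not np.isfinite(x[c, i]) or x[c, i] > cap:
                    return x, False
    return x, True


@nb.njit(cache=True)
def em_first_passage(
    x0, s, target, radius2, inv_scale, n_cells, t_max, dt, omega, seed,
    alpha, delta, sign, K, n, w, ssign, K_s, m_s, w_s, w_b,
):
    """First-passage times into a ball around ``target`` (scaled metric).

    Returns (times, censored): censored runs carry time == t_max.
    """
    np.random.seed(seed)
    Km, Ksm = _premats(K, n, K_s, m_s)
    N = x0.shape[0]
    n_steps = int(t_max / dt)
    times = np.empty(n_cells)
    censored = np.zeros(n_cells, dtype=np.bool_)
    G = np.empty(N)
    for c in range(n_cells):
        x = x0.copy()
        hit = False
        for t in range(1, n_steps + 1):
            _gain_pre(x, s, sign, Km, n, w, ssign, Ksm, m_s, w_s, w_b, G)
            for i in range(N):
                prod = alpha[i] * G[i]
                deg = delta[i] * x[i]
                amp = np.sqrt((prod + deg) * dt / omega)
                x[i] = abs(x[i] + (prod - deg) * dt + amp * np.random.standard_normal())
            d2 = 0.0
            for i in range(N):
                u = (x[i] - target[i]) * inv_scale[i]
                d2 += u * u
            if d2 < radius2:
                times[c] = t * dt
                hit = True
                break
        if not hit:
            times[c] = t_max
            censored[c] = True
    return times, censored


@nb.njit(cache=True)
def relax(x0, s, n_steps, dt, alpha, delta, sign, K, n, w, ssign, K_s, m_s, w_s, w_b):
    """Deterministic (noise-free) Euler relaxation toward an attractor."""
    Km, Ksm = _premats(K, n, K_s, m_s)
    N = x0.shape[0]
    x = x0.copy()
    G = np.empty(N)
    for t in range(n_steps):
        _gain_pre(x, s, sign, Km, n, w, ssign, Ksm, m_s, w_s, w_b, G)
        for i in range(N):
            v = x[i] + (alpha[i] * G[i] - delta[i] * x[i]) * dt
            x[i] = v if v > 0.0 else 0.0
    return x


# ---------------------------------------------------------------------------
# 1D benchmark: quartic double well V = x^4/4 - x^2/2 (drift x - x^3)


@nb.njit(cache=True)
def double_well_fpt(n_runs, amp2, dt, t_max, seed, x_start, x_target, radius):
    """First-passage times for dx = (x - x^3) dt + sqrt(amp2) dW.

    ``amp2`` is the squared noise amplitude (2*eps for a well of
    temperature eps, or 1/omega in system-size form).
    """
    np.random.seed(seed)
    n_steps = int(t_max / dt)
    times = np.empty(n_runs)
    censored = np.zeros(n_runs, dtype=np.bool_)
    g = np.sqrt(amp2 * dt)
    for c in range(n_runs):
        x = x_start
        hit = False
        for t in range(1, n_steps + 1):
            x = x + (x - x * x * x) * dt + g * np.random.standard_normal()
            if abs(x - x_target) < radius:
                times[c] = t * dt
                hit = True
                break
        if not hit:
            times[c] = t_max
            censored[c] = True
    return times, censored
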