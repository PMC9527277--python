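"""Numba photon-transport kernels for layered media.

Single-wavelength MCML-style random walk: implicit capture (weight decays by
the single-scattering albedo), Henyey–Greenstein scattering, probabilistic
Fresnel boundaries, survival roulette.  Because the media are laterally
homogeneous and only total diffuse reflectance/transmittance is needed, the
walk tracks depth and direction only.

A separate scattering-only ("white") kernel records per-photon path lengths
in each layer for escaping photons, so that reflectance for any absorption
spectrum can be evaluated after the fact as E[exp(-sum mu_a,l * L_l)].
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MIN_WEIGHT_DEFAULT = 1e-4
_SURVIVE_P_DEFAULT = 0.1


@njit(cache=True, fastmath=True, inline="always")
def _splitmix64(x):
    x = np.uint64(x) + np.uint64(0x9E3779B97F4A7C15)
    z = x
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, fastmath=True, inline="always")
def _rand(state):
    # xorshift64* in a 1-element array holding the state
    x = state[0]
    x ^= x >> np.uint64(12)
    x ^= x << np.uint64(25)
    x ^= x >> np.uint64(27)
    state[0] = x
    return np.float64(
        (x * np.uint64(0x2545F4914F6CDD1D)) >> np.uint64(11)
    ) * 1.1102230246251565e-16  # 2**-53


@njit(cache=True, fastmath=True, inline="always")
def _fresnel(cos_i, n_i, n_t):
    if n_i == n_t:
        return 0.0
    if cos_i > 0.99999999:
        r = (n_i - n_t) / (n_i + n_t)
        return r * r
    sin_i = np.sqrt(max(0.0, 1.0 - cos_i * cos_i))
    sin_t = n_i / n_t * sin_i
    if sin_t >= 1.0:
        return 1.0
    cos_t = np.sqrt(1.0 - sin_t * sin_t)
    rs = (n_i * cos_i - n_t * cos_t) / (n_i * cos_i + n_t * cos_t)
    rp = (n_i * cos_t - n_t * cos_i) / (n_i * cos_t + n_t * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, fastmath=True, inline="always")
def _spin(ux, uy, uz, g, state):
    if g == 0.0:
        cost = 2.0 * _rand(state) - 1.0
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * _rand(state))
        cost = (1.0 + g * g - tmp * tmp) / (2.0 * g)
        if cost > 1.0:
            cost = 1.0
        elif cost < -1.0:
            cost = -1.0
    sint = np.sqrt(1.0 - cost * cost)
    phi = 2.0 * np.pi * _rand(state)
    cosp = np.cos(phi)
    sinp = np.sin(phi)
    if abs(uz) > 0.99999:
        nux = sint * cosp
        nuy = sint * sinp
        nuz = cost * (1.0 if uz >= 0.0 else -1.0)
    else:
        temp = np.sqrt(1.0 - uz * uz)
        nux = sint * (ux * uz * cosp - uy * sinp) / temp + ux * cost
        nuy = sint * (uy * uz * cosp + ux * sinp) / temp + uy * cost
        nuz = -sint * cosp * temp + uz * cost
    norm = np.sqrt(nux * nux + nuy * nuy + nuz * nuz)
    return nux / norm, nuy / norm, nuz / norm


@njit(cache=True, fastmath=True)
def run_layered(
    mu_a,
    mu_s,
    g,
    n_layer,
    thickness,
    n_ambient,
    semi_infinite,
    n_photons,
    seed,
    w_min,
    p_survive,
):
    """Monte Carlo walk at one wavelength.

    Returns (refl, trans, absorbed, refl_sq_sum) as photon-weight fractions
    of the launched (post-specular) weight; refl_sq_sum is the sum of squared
    per-photon reflected weights for standard-error estimation.
    """
    n_lay = mu_a.shape[0]
    bounds = np.empty(n_lay + 1)
    bounds[0] = 0.0
    for i in range(n_lay):
        bounds[i + 1] = bounds[i] + thickness[i]
    albedo = np.empty(n_lay)
    inv_mu_t = np.empty(n_lay)
    for i in range(n_lay):
        mt = mu_a[i] + mu_s[i]
        inv_mu_t[i] = 1.0 / mt if mt > 0.0 else 1e30
        albedo[i] = mu_a[i] * inv_mu_t[i]
    iso = True
    for i in range(n_lay):
        if g[i] != 0.0:
            iso = False

    state = np.empty(1, dtype=np.uint64)
    state[0] = _splitmix64(seed)
    if state[0] == 0:
        state[0] = np.uint64(0x853C49E6748FEA9B)

    refl = 0.0
    trans = 0.0
    absorbed = 0.0
    refl_sq = 0.0

    for _ in range(n_photons):
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        lay = 0
        r_photon = 0.0
        alive = True
        s_ = 0.0  # dimensionless step remaining

        while alive:
            if s_ <= 0.0:
                xi = _rand(state)
                while xi <= 0.0:
                    xi = _rand(state)
                s_ = -np.log(xi)
            mu_t = mu_a[lay] + mu_s[lay]
            # distance to the boundary ahead
            if uz > 0.0:
                d_b = (bounds[lay + 1] - z) / uz
            elif uz < 0.0:
                d_b = (bounds[lay] - z) / uz
            else:
                d_b = 1e30
            if d_b * mu_t <= s_:
                # hit boundary
                z += d_b * uz
                s_ -= d_b * mu_t
                if uz < 0.0:
                    # upward crossing
                    if lay == 0:
                        r_f = _fresnel(-uz, n_layer[0], n_ambient)
                        if _rand(state) < r_f:
                            uz = -uz
                        else:
                            refl += w
                            r_photon += w
                            alive = False
                    else:
                        r_f = _fresnel(-uz, n_layer[lay], n_layer[lay - 1])
                        if _rand(state) < r_f:
                            uz = -uz
                        else:
                            # refract
                            ni = n_layer[lay]
                            nt = n_layer[lay - 1]
                            if ni != nt:
                                sin_i = np.sqrt(max(0.0, 1.0 - uz * uz))
                                sin_t = ni / nt * sin_i
                                cos_t = np.sqrt(max(0.0, 1.0 - sin_t * sin_t))
                                scale = ni / nt
                                ux *= scale
                                uy *= scale
                                uz = -cos_t
                            lay -= 1
                else:
                    # downward crossing
                    if lay == n_lay - 1:
                        if semi_infinite:
                            trans += w
                            alive = False
                        else:
                            r_f = _fresnel(uz, n_layer[lay], n_ambient)
                            if _rand(state) < r_f:
                                uz = -uz
                            else:
                                trans += w
                                alive = False
                    else:
                        r_f = _fresnel(uz, n_layer[lay], n_layer[lay + 1])
                        if _rand(state) < r_f:
                            uz = -uz
                        else:
                            ni = n_layer[lay]
                            nt = n_layer[lay + 1]
                            if ni != nt:
                                sin_i = np.sqrt(max(0.0, 1.0 - uz * uz))
                                sin_t = ni / nt * sin_i
                                cos_t = np.sqrt(max(0.0, 1.0 - sin_t * sin_t))
                                scale = ni / nt
                                ux *= scale
                                uy *= scale
                                uz = cos_t
                            lay += 1
            else:
                # interaction inside the layer
                z += s_ * inv_mu_t[lay] * uz
                s_ = 0.0
                d_w = w * albedo[lay]
                absorbed += d_w
                w -= d_w
                if iso:
                    uz = 2.0 * _rand(state) - 1.0
                else:
                    ux, uy, uz = _spin(ux, uy, uz, g[lay], state)
                if w < w_min:
                    if _rand(state) < p_survive:
                        gain = w / p_survive - w
                        absorbed -= gain
                        w /= p_survive
                    else:
                        absorbed += w
                        alive = False
        refl_sq += r_photon * r_photon

    inv = 1.0 / n_photons
    return refl * inv, trans * inv, absorbed * inv, refl_sq * inv


@njit(cache=True, fastmath=True)
def run_white(
    mu_s,
    g,
    n_layer,
    thickness,
    n_ambient,
    n_photons,
    seed,
):
    """Scattering-only walk; records per-layer path lengths of photons that
    escape through the top surface.

    Returns (paths, n_escaped) where paths has shape (n_photons, n_layers)
    and only the first n_escaped rows are valid.
    """
    n_lay = mu_s.shape[0]
    bounds = np.empty(n_lay + 1)
    bounds[0] = 0.0
    for i in range(n_lay):
        bounds[i + 1] = bounds[i] + thickness[i]
    iso = True
    for i in range(n_lay):
        if g[i] != 0.0:
            iso = False

    state = np.empty(1, dtype=np.uint64)
    state[0] = _splitmix64(seed)
    if state[0] == 0:
        state[0] = np.uint64(0x853C49E6748FEA9B)

    paths = np.zeros((n_photons, n_lay))
    n_escaped = 0
    path = np.zeros(n_lay)

    for _ in range(n_photons):
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        lay = 0
        for i in range(n_lay):
            path[i] = 0.0
        alive = True
        escaped = False
        s_ = 0.0

        while alive:
            if s_ <= 0.0:
                xi = _rand(state)
                while xi <= 0.0:
                    xi = _rand(state)
                s_ = -np.log(xi)
            mu_t = mu_s[lay]
            if uz > 0.0:
                d_b = (bounds[lay + 1] - z) / uz
            elif uz < 0.0:
                d_b = (bounds[lay] - z) / uz
            else:
                d_b = 1e30
            if d_b * mu_t <= s_:
                z += d_b * uz
                path[lay] += d_b
                s_ -= d_b * mu_t
                if uz < 0.0:
                    if lay == 0:
                        r_f = _fresnel(-uz, n_layer[0], n_ambient)
                        if _rand(state) < r_f:
                            uz = -uz
                        else:
                            alive = False
                            escaped = True
                    else:
                        r_f = _fresnel(-uz, n_layer[lay], n_layer[lay - 1])
                        if _rand(state) < r_f:
                            uz = -uz
                        else:
                            ni = n_layer[lay]
                            nt = n_layer[lay - 1]
                            if ni != nt:
                                sin_i = np.sqrt(max(0.0, 1.0 - uz * uz))
                                sin_t = ni / nt * sin_i
                                cos_t = np.sqrt(max(0.0, 1.0 - sin_t * sin_t))
                                scale = ni / nt
                                ux *= scale
                                uy *= scale
                                uz = -cos_t
                            lay -= 1
                else:
                    if lay == n_lay - 1:
                        alive = False
                    else:
                        r_f = _fresnel(uz, n_layer[lay], n_layer[lay + 1])
                        if _rand(state) < r_f:
                            uz = -uz
                        else:
                            ni = n_layer[lay]
                            nt = n_layer[lay + 1]
                            if ni != nt:
                                sin_i = np.sqrt(max(0.0, 1.0 - uz * uz))
                                sin_t = ni / nt * sin_i
                                cos_t = np.sqrt(max(0.0, 1.0 - sin_t * sin_t))
                                scale = ni / nt
                                ux *= scale
                                uy *= scale
                                uz = cos_t
                            lay += 1
            else:
                step = s_ / mu_t
                z += step * uz
                path[lay] += step
                s_ = 0.0
                if iso:
                    uz = 2.0 * _rand(state) - 1.0
                else:
                    ux, uy, uz = _spin(ux, uy, uz, g[lay], state)

        if escaped:
            for i in range(n_lay):
                paths[n_escaped, i] = path[i]
            n_escaped += 1

    return paths, n_escaped
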