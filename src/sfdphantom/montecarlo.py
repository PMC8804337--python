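"""Monte Carlo photon-transport oracle for the diffusion forward model.

A pencil beam enters a homogeneous semi-infinite medium at the origin; photons
random-walk with Henyey–Greenstein scattering (g = 0.8, mu_s = mu_s'/(1-g)),
lose the absorbed fraction of their weight at every interaction, and face the
refractive-index-mismatched Fresnel boundary on every upward crossing.  The
spatially resolved diffuse reflectance is carried as (exit weight, exit
radius) pairs and transformed to spatial frequency by the zeroth-order Hankel
transform, Rd(fx) = (1/N) sum_i w_i J0(2 pi fx r_i); at fx = 0 this is
identically the plain diffuse-reflectance tally.  Used as an independent check
on the diffusion closed form, never as the production inverse model.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.special import j0

HG_ANISOTROPY = 0.8
#: photons below this weight enter Russian roulette; in the nearly
#: conservative media simulated here (albedo ~ 0.999) weight decays over
#: thousands of events, so the threshold bounds the walk length
WEIGHT_THRESHOLD = 1e-3
ROULETTE_SURVIVAL = 0.1
_MAX_EXITS_FACTOR = 1  # one exit record max per photon


@njit(cache=True)
def _mc_walk(mu_a, mu_s, g, n_rel, photons, seed, exit_w, exit_r):  # pragma: no cover
    """Photon loop; fills exit weight/radius arrays, returns number of exits."""
    np.random.seed(seed)
    mu_t = mu_a + mu_s
    albedo = mu_s / mu_t
    n_exit = 0
    for _ in range(photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        alive = True
        while alive:
            s = -np.log(np.random.random()) / mu_t
            while True:
                if uz < 0.0 and z + uz * s < 0.0:
                    # transport to the boundary and attempt escape
                    s_b = -z / uz
                    x += ux * s_b
                    y += uy * s_b
                    z = 0.0
                    s -= s_b
                    cos_i = -uz
                    # Fresnel reflectance, internal incidence (n_rel = n_in/n_out)
                    sin_t2 = n_rel * n_rel * (1.0 - cos_i * cos_i)
                    if sin_t2 >= 1.0:
                        refl = 1.0
                    else:
                        cos_t = np.sqrt(1.0 - sin_t2)
                        rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
                        rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
                        refl = 0.5 * (rs * rs + rp * rp)
                    if np.random.random() < refl:
                        uz = -uz  # specular re-entry, continue remaining step
                    else:
                        exit_w[n_exit] = w
                        exit_r[n_exit] = np.sqrt(x * x + y * y)
                        n_exit += 1
                        alive = False
                        break
                else:
                    x += ux * s
                    y += uy * s
                    z += uz * s
                    break
            if not alive:
                break
            # absorption and scattering at the interaction site
            w *= albedo
            if g == 0.0:
                cos_s = 2.0 * np.random.random() - 1.0
            else:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
                cos_s = (1.0 + g * g - tmp * tmp) / (2.0 * g)
            sin_s = np.sqrt(max(0.0, 1.0 - cos_s * cos_s))
            phi = 2.0 * np.pi * np.random.random()
            cos_p = np.cos(phi)
            sin_p = np.sin(phi)
            if abs(uz) > 0.99999:
                ux = sin_s * cos_p
                uy = sin_s * sin_p
                uz = cos_s * (1.0 if uz >= 0.0 else -1.0)
            else:
                denom = np.sqrt(1.0 - uz * uz)
                ux_new = sin_s * (ux * uz * cos_p - uy * sin_p) / denom + ux * cos_s
                uy_new = sin_s * (uy * uz * cos_p + ux * sin_p) / denom + uy * cos_s
                uz_new = -sin_s * cos_p * denom + uz * cos_s
                norm = np.sqrt(ux_new**2 + uy_new**2 + uz_new**2)
                ux = ux_new / norm
                uy = uy_new / norm
                uz = uz_new / norm
            if w < WEIGHT_THRESHOLD:
                if np.random.random() < ROULETTE_SURVIVAL:
                    w /= ROULETTE_SURVIVAL
                else:
                    alive = False
    return n_exit


def simulate_exits(
    mu_a: float,
    mu_s_prime: float,
    n: float = 1.4,
    photons: int = 100_000,
    seed: int = 0,
    g: float = HG_ANISOTROPY,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw (exit weight, exit radius) records of the diffusely reflected photons."""
    if mu_a <= 0 or mu_s_prime <= 0:
        raise ValueError("optical properties must be strictly positive")
    mu_s = mu_s_prime / (1.0 - g)
    exit_w = np.zeros(photons)
    exit_r = np.zeros(photons)
    n_exit = _mc_walk(
        float(mu_a), float(mu_s), float(g), float(n), int(photons), int(seed) & 0x7FFFFFFF,
        exit_w, exit_r,
    )
    return exit_w[:n_exit], exit_r[:n_exit]


def mc_reflectance_oracle(
    mu_a: float,
    mu_s_prime: float,
    fx: np.ndarray,
    n: float = 1.4,
    photons: int = 100_000,
    seed: int = 0,
    g: float = HG_ANISOTROPY,
) -> tuple[np.ndarray, np.ndarray]:
    """Spatial-frequency diffuse reflectance by photon transport.

    Returns ``(rd, se)``: the Hankel-transformed diffuse reflectance at each
    spatial frequency and its Monte Carlo standard error.  Deterministic for a
    given seed.  Standard errors are reported as-is; at high fx they can be a
    large fraction of the estimate.
    """
    if photons < 10_000:
        raise ValueError("oracle requires >= 1e4 photons")
    fx = np.atleast_1d(np.asarray(fx, dtype=float))
    if np.any(fx < 0):
        raise ValueError("spatial frequencies must be non-negative")
    w, r = simulate_exits(mu_a, mu_s_prime, n=n, photons=photons, seed=seed, g=g)
    rd = np.empty(fx.size)
    se = np.empty(fx.size)
    for k, f in enumerate(fx):
        contrib = w * j0(2.0 * np.pi * f * r)
        total = contrib.sum()
        rd[k] = total / photons
        # per-photon variance including the zero contribution of absorbed photons
        mean = rd[k]
        var = (contrib @ contrib) / photons - mean * mean
        se[k] = np.sqrt(max(var, 0.0) / photons)
    return rd, se
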