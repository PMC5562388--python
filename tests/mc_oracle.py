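"""Test-only Monte-Carlo photon-transport oracle for a semi-infinite medium.

Independent of the diffusion solver under test: weighted photon packets are
injected normally at the origin, random-walked with exponential free paths
and isotropic scattering at the reduced scattering coefficient (similarity
relation), absorbed fractionally at each interaction, Fresnel-reflected at
the refractive-index-mismatched surface, and scored into annular detection
bins when they escape.  Returns the spatially resolved diffuse reflectance
(mm^-2) at the requested radii.
"""

from __future__ import annotations

import numpy as np


def _fresnel_reflectance(cos_i: np.ndarray, n_rel: float) -> np.ndarray:
    """Unpolarized Fresnel reflectance, tissue (n_rel) -> air (1)."""
    sin_i = np.sqrt(np.clip(1.0 - cos_i**2, 0.0, 1.0))
    sin_t = n_rel * sin_i
    tir = sin_t >= 1.0
    sin_t = np.clip(sin_t, 0.0, 1.0 - 1e-12)
    cos_t = np.sqrt(1.0 - sin_t**2)
    rs = ((n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)) ** 2
    rp = ((n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)) ** 2
    R = 0.5 * (rs + rp)
    R[tir] = 1.0
    return R


def mc_diffuse_reflectance(
    radii_mm,
    mua: float,
    musp: float,
    n_rel: float = 1.4,
    n_photons: int = 200_000,
    bin_halfwidth_mm: float = 1.0,
    seed: int = 20170818,
) -> np.ndarray:
    """Diffuse reflectance R(rho) (mm^-2) at the given radii."""
    radii = np.asarray(radii_mm, dtype=float)
    rng = np.random.default_rng(seed)
    mut = mua + musp
    albedo = musp / mut

    pos = np.zeros((n_photons, 3))
    direc = np.zeros((n_photons, 3))
    direc[:, 2] = 1.0  # downward into the medium
    w = np.ones(n_photons)
    escaped_r: list[np.ndarray] = []
    escaped_w: list[np.ndarray] = []

    alive = np.ones(n_photons, dtype=bool)
    while alive.any():
        idx = np.nonzero(alive)[0]
        step = -np.log(rng.random(idx.size)) / mut
        newz = pos[idx, 2] + direc[idx, 2] * step
        hits = newz < 0.0

        # photons reaching the surface: Fresnel reflect or escape
        hi = idx[hits]
        if hi.size:
            t_hit = -pos[hi, 2] / direc[hi, 2]
            pos[hi, 0] += direc[hi, 0] * t_hit
            pos[hi, 1] += direc[hi, 1] * t_hit
            pos[hi, 2] = 0.0
            cos_i = np.abs(direc[hi, 2])
            refl = _fresnel_reflectance(cos_i, n_rel)
            bounce = rng.random(hi.size) < refl
            direc[hi[bounce], 2] *= -1.0
            out = hi[~bounce]
            if out.size:
                escaped_r.append(np.hypot(pos[out, 0], pos[out, 1]))
                escaped_w.append(w[out].copy())
                alive[out] = False

        # interior interactions: move, absorb, scatter isotropically
        ii = idx[~hits]
        if ii.size:
            pos[ii] += direc[ii] * step[~hits, None]
            w[ii] *= albedo
            cost = 2.0 * rng.random(ii.size) - 1.0
            sint = np.sqrt(1.0 - cost**2)
            phi = 2.0 * np.pi * rng.random(ii.size)
            direc[ii, 0] = sint * np.cos(phi)
            direc[ii, 1] = sint * np.sin(phi)
            direc[ii, 2] = cost

            # Russian roulette on low-weight packets
            low = ii[w[ii] < 1e-4]
            if low.size:
                lucky = rng.random(low.size) < 0.1
                w[low[lucky]] /= 0.1
                alive[low[~lucky]] = False

    r_esc = np.concatenate(escaped_r) if escaped_r else np.empty(0)
    w_esc = np.concatenate(escaped_w) if escaped_w else np.empty(0)
    out = np.empty(radii.shape)
    for k, rho in enumerate(radii):
        lo, hi_ = rho - bin_halfwidth_mm, rho + bin_halfwidth_mm
        area = np.pi * (hi_**2 - lo**2)
        sel = (r_esc >= lo) & (r_esc < hi_)
        out[k] = w_esc[sel].sum() / (n_photons * area)
    return out
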