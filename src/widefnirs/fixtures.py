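"""Synthetic media and independent oracles for validating the transport engine.

Every fixture is generated in code; the analytic or brute-force reference it
carries is deliberately a separate code path from the engine (the half-space
oracle uses analog survival-sampling absorption, not continuous weighting),
so agreement is a physics check rather than a tautology.
"""

from __future__ import annotations

import math

import numpy as np

from .head_model import (
    HeadModel,
    HeadModelConfig,
    OpticalProperties,
    RegionLabel,
    TISSUE_REGIONS,
    build_head_model,
)

__all__ = [
    "make_ballistic_slab",
    "make_homogeneous_halfspace",
    "make_perturbation_pair",
    "analog_reflectance",
]


def _uniform_properties(props: OpticalProperties) -> dict[RegionLabel, OpticalProperties]:
    return {r: props for r in TISSUE_REGIONS}


def make_ballistic_slab(mua: float, thickness: float) -> HeadModel:
    """Single-region non-scattering slab; straight-line transport applies.

    A normally launched packet crosses the slab ballistically and reaches the
    absorbing bottom face with weight ``exp(-mua * thickness)`` and total path
    equal to the thickness (Beer-Lambert).
    """
    props = OpticalProperties(mua=mua, mus=0.0, g=0.0, n=1.0)
    cfg = HeadModelConfig(
        depth=thickness,
        lateral_x=100.0,
        lateral_y=100.0,
        slab_thicknesses=(thickness, 0.0, 0.0, 0.0, 0.0),
        dgm_width=0.0,
    )
    return build_head_model(cfg, _uniform_properties(props))


def make_homogeneous_halfspace(
    props: OpticalProperties, depth: float = 90.0, lateral: float = 150.0
) -> HeadModel:
    """Homogeneous medium filling the whole volume (index-matched by default).

    With the standard tissue properties the volume is several transport mean
    free paths deep, so it stands in for a semi-infinite half-space; compare
    its total diffuse reflectance against :func:`analog_reflectance`.
    """
    cfg = HeadModelConfig(
        depth=depth,
        lateral_x=lateral,
        lateral_y=lateral,
        slab_thicknesses=(depth, 0.0, 0.0, 0.0, 0.0),
        dgm_width=0.0,
    )
    return build_head_model(cfg, _uniform_properties(props))


def make_perturbation_pair(
    model: HeadModel, region: RegionLabel, factor: float, seed: int = 0
):
    """(baseline, perturbed, seed) wired for the reweighting-vs-rerun test."""
    from .head_model import scale_absorption

    if factor <= 0:
        raise ValueError("factor must be > 0")
    return model, scale_absorption(model, region, factor), seed


def analog_reflectance(
    props: OpticalProperties,
    n_packets: int = 100_000,
    seed: int = 0,
    max_path: float = 5000.0,
    batch: int = 20_000,
):
    """Total diffuse reflectance of an index-matched homogeneous half-space.

    Independent brute-force Monte Carlo with *analog* absorption: photons step
    by ``-ln(u)/mut``, survive each interaction with probability ``mus/mut``
    (killed outright otherwise), and scatter through Henyey-Greenstein angles.
    Photons crossing z < 0 escape and count toward reflectance (the top is
    index-matched, so there is no internal reflection).

    Returns ``(reflectance, standard_error)``.
    """
    mua, mus, g = props.mua, props.mus, props.g
    mut = mua + mus
    if mut <= 0:
        raise ValueError("need mua + mus > 0")
    survive = mus / mut
    rng = np.random.default_rng(seed)
    escaped = 0
    done = 0
    while done < n_packets:
        nb = min(batch, n_packets - done)
        done += nb
        x = np.zeros(nb)
        y = np.zeros(nb)
        z = np.zeros(nb)
        ux = np.zeros(nb)
        uy = np.zeros(nb)
        uz = np.ones(nb)
        path = np.zeros(nb)
        alive = np.ones(nb, dtype=bool)
        while alive.any():
            idx = np.flatnonzero(alive)
            step = -np.log(rng.random(idx.size)) / mut
            zn = z[idx] + uz[idx] * step
            # photons crossing the surface escape before their next interaction
            esc = zn < 0
            escaped += int(esc.sum())
            alive[idx[esc]] = False
            keep = idx[~esc]
            step = step[~esc]
            x[keep] += ux[keep] * step
            y[keep] += uy[keep] * step
            z[keep] += uz[keep] * step
            path[keep] += step
            over = path[keep] > max_path
            alive[keep[over]] = False
            keep = keep[~over]
            # analog absorption: kill at the interaction site
            dead = rng.random(keep.size) >= survive
            alive[keep[dead]] = False
            keep = keep[~dead]
            if keep.size == 0:
                continue
            # Henyey-Greenstein scatter (independent vectorised implementation)
            u = rng.random(keep.size)
            if abs(g) < 1e-6:
                ct = 2.0 * u - 1.0
            else:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
                ct = np.clip((1.0 + g * g - tmp * tmp) / (2.0 * g), -1.0, 1.0)
            st = np.sqrt(1.0 - ct * ct)
            phi = 2.0 * math.pi * rng.random(keep.size)
            cp, sp = np.cos(phi), np.sin(phi)
            kx, ky, kz = ux[keep], uy[keep], uz[keep]
            near_pole = np.abs(kz) > 0.99999
            denom = np.sqrt(np.maximum(1e-30, 1.0 - kz * kz))
            nx = np.where(
                near_pole, st * cp, st * (kx * kz * cp - ky * sp) / denom + kx * ct
            )
            ny = np.where(
                near_pole, st * sp, st * (ky * kz * cp + kx * sp) / denom + ky * ct
            )
            nz = np.where(near_pole, np.sign(kz) * ct, -denom * st * cp + kz * ct)
            norm = np.sqrt(nx * nx + ny * ny + nz * nz)
            ux[keep], uy[keep], uz[keep] = nx / norm, ny / norm, nz / norm
    refl = escaped / n_packets
    se = math.sqrt(max(refl * (1.0 - refl), 1e-30) / n_packets)
    return refl, se
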