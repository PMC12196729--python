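"""Photon-packet Monte Carlo transport through the slab head model.

The engine follows the standard voxel/layer Monte Carlo convention for packet
transport in tissue: step lengths are sampled from the scattering coefficient
alone (dimensionless scattering length ``s = -ln(xi)`` consumed as
``sum(mus * l)`` across traversed segments), absorption attenuates the packet
weight continuously as ``exp(-mua * l)`` per segment, scattering directions are
drawn from the Henyey-Greenstein phase function, and the top surface applies
unpolarized Fresnel reflection against air.  Lateral and bottom faces absorb.

Because step sampling never consults the absorption coefficient, a packet's
trajectory — and therefore its per-region partial path lengths — is exactly
invariant under any change of ``mua``.  This is the property that makes
common-random-number reweighting of detected energies exact (see
:mod:`widefnirs.detection_metrics`).

Randomness is a counter-style per-packet substream keyed by ``(seed, packet
index)``, so results are bit-reproducible and independent of execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .head_model import HeadModel, N_REGIONS

__all__ = [
    "SourceSpec",
    "DetectorSpec",
    "SimulationResult",
    "packets_for_emitter",
    "launch_packet",
    "sample_scatter_direction",
    "fresnel_top_boundary",
    "run_simulation",
]

#: Default maximum total path length per packet, mm.
DEFAULT_MAX_PATH = 5000.0

# Record modes for the kernel.
RECORD_DETECTED = 0
RECORD_TOP_EXITS = 1
RECORD_ALL = 2


@dataclass(frozen=True)
class SourceSpec:
    """Disk emitter on the top surface, emitting normally into the head.

    ``center`` is the (x, y) disk centre in mm; ``diameter`` in mm.  Packets
    launch uniformly over the disk at the surface with direction (0, 0, +1)
    and weight 1 (no specular launch loss; source coupling is not modelled).
    """

    center: tuple[float, float]
    diameter: float

    def __post_init__(self) -> None:
        if self.diameter < 0:
            raise ValueError("source diameter must be >= 0")


@dataclass(frozen=True)
class DetectorSpec:
    """Disk detector on the top surface; accepts all exit angles."""

    center: tuple[float, float]
    diameter: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("detector diameter must be > 0")


def packets_for_emitter(diameter: float, base_count: float = 5e7) -> int:
    """Packet count for an emitter: ``round(base_count * diameter**2)``.

    Emitters launch a constant number of packets per unit area, so the count
    scales with the disk area (diameter squared); ``base_count`` is the count
    for a 1 mm emitter.
    """
    if diameter <= 0:
        raise ValueError("emitter diameter must be > 0")
    if base_count <= 0:
        raise ValueError("base_count must be > 0")
    return round(base_count * diameter * diameter)


# ---------------------------------------------------------------------------
# numba physics primitives (shared by the kernel and the public wrappers)
# ---------------------------------------------------------------------------

_U64_PHI = np.uint64(0x9E3779B97F4A7C15)
_U64_M1 = np.uint64(0xBF58476D1CE4E5B9)
_U64_M2 = np.uint64(0x94D049BB133111EB)
_U64_K2 = np.uint64(0xD1B54A32D192ED03)
_INV_2_53 = 1.0 / 9007199254740992.0


@njit(cache=True, inline="always")
def _rng_next(state):
    """splitmix64 step: returns (new_state, uniform double in [0, 1))."""
    state = state + _U64_PHI
    z = state
    z = (z ^ (z >> np.uint64(30))) * _U64_M1
    z = (z ^ (z >> np.uint64(27))) * _U64_M2
    z = z ^ (z >> np.uint64(31))
    return state, float(z >> np.uint64(11)) * _INV_2_53


@njit(cache=True, inline="always")
def _rng_init(seed, index):
    """Per-packet substream state keyed by (seed, packet index)."""
    state = (np.uint64(seed) * _U64_PHI) ^ ((np.uint64(index) + np.uint64(1)) * _U64_K2)
    state, _ = _rng_next(state)
    state, _ = _rng_next(state)
    return state


@njit(cache=True, inline="always")
def _hg_cos_theta(g, u):
    """Henyey-Greenstein inverse-CDF sample of the scattering cosine."""
    if abs(g) < 1e-6:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True, inline="always")
def _rotate_direction(ux, uy, uz, ct, phi):
    """New unit direction at polar angle acos(ct), azimuth phi, about (ux,uy,uz)."""
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(uz) > 0.99999:
        nx = st * cp
        ny = st * sp
        nz = ct if uz > 0.0 else -ct
    else:
        denom = math.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / denom + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / denom + uy * ct
        nz = -denom * st * cp + uz * ct
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, inline="always")
def _fresnel_reflectance(n1, n2, cos_i):
    """Unpolarized Fresnel reflectance for incidence cosine cos_i; 1.0 on TIR."""
    if n1 == n2:
        return 0.0
    sin_i = math.sqrt(max(0.0, 1.0 - cos_i * cos_i))
    sin_t = n1 / n2 * sin_i
    if sin_t >= 1.0:
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t * sin_t)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, inline="always")
def _region_index(x, y, z, zb, dgm):
    """Region index at (x, y, z); assumes the point is inside the volume.

    ``zb`` are the six cumulative slab depth bounds; ``dgm`` packs
    (x0, x1, y0, y1, z0, z1, z2, z3, z4) of the sulcal prism (x0 == x1
    disables it).
    """
    if dgm[0] < dgm[1] and dgm[0] <= x < dgm[1] and dgm[2] <= y < dgm[3]:
        if dgm[4] <= z < dgm[8]:
            if z < dgm[5]:
                return 5  # DGM1
            elif z < dgm[6]:
                return 6
            elif z < dgm[7]:
                return 7
            else:
                return 8
    for i in range(5):
        if zb[i] <= z < zb[i + 1]:
            return i
    return 4 if z >= zb[5] else 0  # clamp fp edge cases to nearest slab


@njit(cache=True, inline="always")
def _next_plane_distance(v, d, planes):
    """Distance along one axis to the nearest candidate plane strictly ahead.

    Planes closer than 1e-7 mm are treated as the one we are standing on.
    Returns (distance, plane_value); distance is inf if no plane lies ahead.
    """
    best = np.inf
    pv = 0.0
    if d > 1e-12:
        for k in range(planes.shape[0]):
            p = planes[k]
            if p > v:
                t = (p - v) / d
                if t > 1e-7:
                    best = t
                    pv = p
                    break
    elif d < -1e-12:
        for k in range(planes.shape[0] - 1, -1, -1):
            p = planes[k]
            if p < v:
                t = (p - v) / d
                if t > 1e-7:
                    best = t
                    pv = p
                    break
    return best, pv


@njit(cache=True, inline="always")
def _transport(
    state, x, y, z, ux, uy, uz, xp, yp, zp, zb, dgm, mus, gg, nn, n_ambient,
    max_path, paths,
):
    """Transport one packet from its current state until it leaves the volume.

    ``paths`` (per-region, mm) is accumulated in place.  Returns
    (rng_state, status, x, y, ux, uy, uz, nscat, total_path) with status
    0 top exit, 1 bottom, 2 lateral, 3 max-path terminated.  The trajectory
    consults only mus, g and n — never the absorption coefficients.
    """
    depth = zb[5]
    lx = xp[xp.shape[0] - 1]
    ly = yp[yp.shape[0] - 1]
    total_path = 0.0
    nscat = 0
    state, u = _rng_next(state)
    s = -math.log(1.0 - u)  # dimensionless scattering length
    status = -1

    while status < 0:
        dx, px = _next_plane_distance(x, ux, xp)
        dy, py = _next_plane_distance(y, uy, yp)
        dz, pz = _next_plane_distance(z, uz, zp)
        db = dx
        axis = 0
        pv = px
        if dy < db:
            db = dy
            axis = 1
            pv = py
        if dz < db:
            db = dz
            axis = 2
            pv = pz
        # the segment [0, db) lies in a single region; sample its midpoint
        reg = _region_index(
            x + ux * db * 0.5, y + uy * db * 0.5, z + uz * db * 0.5, zb, dgm
        )
        mus_r = mus[reg]
        ds = s / mus_r if mus_r > 0.0 else np.inf
        if ds < db:
            # scattering event inside the region
            x += ux * ds
            y += uy * ds
            z += uz * ds
            paths[reg] += ds
            total_path += ds
            if total_path > max_path:
                status = 3
                break
            state, u1 = _rng_next(state)
            state, u2 = _rng_next(state)
            ct = _hg_cos_theta(gg[reg], u1)
            ux, uy, uz = _rotate_direction(ux, uy, uz, ct, 2.0 * math.pi * u2)
            nscat += 1
            state, u = _rng_next(state)
            s = -math.log(1.0 - u)
        else:
            # advance to the boundary plane
            x += ux * db
            y += uy * db
            z += uz * db
            paths[reg] += db
            total_path += db
            s -= mus_r * db
            if total_path > max_path:
                status = 3
                break
            if axis == 2:
                if pv <= 0.0 and uz < 0.0:
                    # top face: Fresnel against the ambient medium
                    refl = _fresnel_reflectance(nn[reg], n_ambient, -uz)
                    if refl > 0.0:
                        state, u = _rng_next(state)
                    else:
                        u = 1.0
                    if u < refl:
                        uz = -uz
                    else:
                        status = 0
                elif pv >= depth and uz > 0.0:
                    status = 1
            elif axis == 0:
                if (pv <= 0.0 and ux < 0.0) or (pv >= lx and ux > 0.0):
                    status = 2
            else:
                if (pv <= 0.0 and uy < 0.0) or (pv >= ly and uy > 0.0):
                    status = 2

    return state, status, x, y, ux, uy, uz, nscat, total_path


@njit(cache=True)
def _run_kernel(
    n_packets,
    seed,
    xp,
    yp,
    zp,
    zb,
    dgm,
    mua,
    mus,
    gg,
    nn,
    n_ambient,
    src_cx,
    src_cy,
    src_r,
    det_cx,
    det_cy,
    det_r,
    max_path,
    record_mode,
    rec_weight,
    rec_x,
    rec_y,
    rec_nscat,
    rec_status,
    rec_paths,
):
    """Transport ``n_packets`` packets; fill record arrays, return tallies.

    Returns (n_recorded, n_detected, n_terminated, w_top, w_bottom,
    w_lateral, w_terminated, w_absorbed).  Status codes: 0 top exit,
    1 bottom, 2 lateral, 3 max-path terminated.
    """
    det_r2 = det_r * det_r
    paths = np.zeros(N_REGIONS, dtype=np.float64)

    n_rec = 0
    n_det = 0
    n_term = 0
    w_top = 0.0
    w_bottom = 0.0
    w_lateral = 0.0
    w_terminated = 0.0
    w_absorbed = 0.0

    for ip in range(n_packets):
        state = _rng_init(seed, ip)
        # launch uniformly over the source disk, normal incidence
        state, u1 = _rng_next(state)
        state, u2 = _rng_next(state)
        r = src_r * math.sqrt(u1)
        phi = 2.0 * math.pi * u2
        x = src_cx + r * math.cos(phi)
        y = src_cy + r * math.sin(phi)
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        for k in range(N_REGIONS):
            paths[k] = 0.0
        state, status, x, y, ux, uy, uz, nscat, total_path = _transport(
            state, x, y, z, ux, uy, uz, xp, yp, zp, zb, dgm, mus, gg, nn,
            n_ambient, max_path, paths,
        )

        # weight bookkeeping from the accumulated per-region paths
        tau = 0.0
        for k in range(N_REGIONS):
            tau += mua[k] * paths[k]
        w = math.exp(-tau)
        w_absorbed += 1.0 - w
        detected = False
        if status == 0:
            w_top += w
            ddx = x - det_cx
            ddy = y - det_cy
            detected = ddx * ddx + ddy * ddy <= det_r2
            if detected:
                n_det += 1
        elif status == 1:
            w_bottom += w
        elif status == 2:
            w_lateral += w
        else:
            w_terminated += w
            n_term += 1

        record = (
            (record_mode == RECORD_DETECTED and detected)
            or (record_mode == RECORD_TOP_EXITS and status == 0)
            or record_mode == RECORD_ALL
        )
        if record:
            rec_weight[n_rec] = w
            rec_x[n_rec] = x
            rec_y[n_rec] = y
            rec_nscat[n_rec] = nscat
            rec_status[n_rec] = status
            for k in range(N_REGIONS):
                rec_paths[n_rec, k] = paths[k]
            n_rec += 1

    return n_rec, n_det, n_term, w_top, w_bottom, w_lateral, w_terminated, w_absorbed


# ---------------------------------------------------------------------------
# public single-packet API (unit-testable views of the kernel physics)
# ---------------------------------------------------------------------------


@dataclass
class PacketState:
    """One photon packet in flight.

    Weight starts at 1 and is non-increasing; ``paths`` accumulates the
    partial path length per region (mm).
    """

    position: np.ndarray
    direction: np.ndarray
    weight: float = 1.0
    paths: np.ndarray = field(default_factory=lambda: np.zeros(N_REGIONS))
    scatter_count: int = 0
    total_path: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("packet weight must be in [0, 1]")


@dataclass(frozen=True)
class PacketRecord:
    """Terminal record of one packet: exit weight, exit point, paths, status.

    ``exit_weight = weight_at_launch * exp(-sum_r mua_r * path_r)``; status 0
    means a top-face exit (candidate for detection), 1/2 absorbing bottom or
    lateral faces, 3 max-path termination (weight discarded by callers).
    """

    exit_weight: float
    exit_position: tuple[float, float]
    paths: np.ndarray
    scatter_count: int
    status: int


def launch_packet(source: SourceSpec, rng: np.random.Generator) -> PacketState:
    """Sample one launch from the source disk.

    Position is uniform over the disk at the surface (z = 0, just inside the
    tissue — no specular launch loss); direction is (0, 0, 1); weight is 1.
    """
    u1, u2 = rng.random(2)
    r = (source.diameter / 2.0) * math.sqrt(u1)
    phi = 2.0 * math.pi * u2
    position = np.array(
        [source.center[0] + r * math.cos(phi), source.center[1] + r * math.sin(phi), 0.0]
    )
    return PacketState(position=position, direction=np.array([0.0, 0.0, 1.0]))


def propagate_packet(
    state: PacketState,
    model: HeadModel,
    seed: int,
    packet_index: int = 0,
    max_path: float = DEFAULT_MAX_PATH,
    n_ambient: float = 1.0,
) -> PacketRecord:
    """Transport one packet until it exits or exhausts the path limit.

    Scattering lengths are sampled from the scattering coefficient only and
    consumed across region segments; the weight attenuates continuously by
    the absorption accumulated along the trajectory, so the trajectory is
    exactly invariant under absorption changes.  Randomness comes from the
    ``(seed, packet_index)`` substream.
    """
    mua, mus, g, n = model.property_arrays()
    xp, yp, zp, zb, dgm = _geometry_arrays(model)
    paths = state.paths.astype(float).copy()
    x, y, z = state.position
    ux, uy, uz = state.direction
    rng_state = np.uint64(_rng_init(seed, packet_index))
    rng_state, status, x, y, ux, uy, uz, nscat, total = _transport(
        rng_state, x, y, z, ux, uy, uz, xp, yp, zp, zb, dgm, mus, g, n,
        float(n_ambient), float(max_path), paths,
    )
    weight = state.weight * math.exp(-float(mua @ paths))
    return PacketRecord(
        exit_weight=weight,
        exit_position=(x, y),
        paths=paths,
        scatter_count=state.scatter_count + nscat,
        status=status,
    )


def sample_scatter_direction(g: float, incoming, rng: np.random.Generator):
    """Draw a scattered unit direction from the Henyey-Greenstein phase function."""
    if not -1 < g < 1:
        raise ValueError("anisotropy g must be in (-1, 1)")
    ux, uy, uz = incoming
    u1, u2 = rng.random(2)
    ct = _hg_cos_theta(g, u1)
    return np.array(_rotate_direction(ux, uy, uz, ct, 2.0 * math.pi * u2))


def fresnel_top_boundary(direction, n_in: float, n_out: float, rng: np.random.Generator):
    """Resolve a packet crossing the top surface upward.

    Returns ``("reflect", new_direction)`` or ``("transmit", refracted)``;
    the choice is stochastic with unpolarized Fresnel reflectance, and always
    reflects beyond the critical angle.
    """
    ux, uy, uz = direction
    if uz >= 0:
        raise ValueError("packet must be moving upward (uz < 0) at the top face")
    cos_i = -uz
    refl = _fresnel_reflectance(n_in, n_out, cos_i)
    if rng.random() < refl:
        return "reflect", np.array([ux, uy, -uz])
    sin_i = math.sqrt(max(0.0, 1.0 - cos_i * cos_i))
    ratio = n_in / n_out
    cos_t = math.sqrt(max(0.0, 1.0 - (ratio * sin_i) ** 2))
    return "transmit", np.array([ux * ratio, uy * ratio, -cos_t])


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Aggregate output of one run: detected-packet records plus tallies.

    ``paths`` has one row per recorded packet and one column per
    :class:`~widefnirs.head_model.RegionLabel` (mm).  ``exit_weight`` is
    ``exp(-sum(mua * path))`` per packet.  The weight ledger closes:
    launched count = top + bottom + lateral + terminated + absorbed weight.
    """

    n_launched: int
    seed: int
    n_detected: int
    n_terminated: int
    exit_weight: np.ndarray
    exit_x: np.ndarray
    exit_y: np.ndarray
    scatter_count: np.ndarray
    status: np.ndarray
    paths: np.ndarray
    w_top: float
    w_bottom: float
    w_lateral: float
    w_terminated: float
    w_absorbed: float
    mua: np.ndarray
    record_mode: int = RECORD_DETECTED
    meta: dict = field(default_factory=dict)

    def detected_mask(self) -> np.ndarray:
        """Boolean mask over recorded packets: transmitted into the detector."""
        if self.record_mode == RECORD_DETECTED:
            return np.ones(len(self.exit_weight), dtype=bool)
        (dcx, dcy), dd = self.meta["detector"]
        inside = (self.exit_x - dcx) ** 2 + (self.exit_y - dcy) ** 2 <= (dd / 2.0) ** 2
        return (self.status == 0) & inside

    @property
    def detected_energy(self) -> float:
        """Sum of detected-packet exit weights."""
        return float(np.sum(self.exit_weight[self.detected_mask()]))

    def traversal_counts(self) -> np.ndarray:
        """Number of detected packets with positive path in each region."""
        return (self.paths[self.detected_mask()] > 0).sum(axis=0)

    def appl(self) -> np.ndarray:
        """Average partial path length per region over traversing detected packets (mm)."""
        counts = self.traversal_counts()
        sums = self.paths[self.detected_mask()].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)


def _geometry_arrays(model: HeadModel):
    cfg = model.config
    zb = np.asarray(cfg.slab_bounds, dtype=np.float64)
    if cfg.dgm_width > 0:
        x0, x1 = cfg.dgm_x_bounds
        y0, y1 = cfg.dgm_y_bounds
        dgm = np.array([x0, x1, y0, y1, *cfg.dgm_depth_breaks], dtype=np.float64)
    else:
        dgm = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
    xp = np.unique(np.array([0.0, dgm[0], dgm[1], cfg.lateral_x]))
    yp = np.unique(np.array([0.0, dgm[2], dgm[3], cfg.lateral_y]))
    zp = np.unique(np.concatenate([zb, dgm[4:9]])) if cfg.dgm_width > 0 else np.unique(zb)
    xp = xp[(xp >= 0) & (xp <= cfg.lateral_x)]
    yp = yp[(yp >= 0) & (yp <= cfg.lateral_y)]
    zp = zp[(zp >= 0) & (zp <= cfg.depth)]
    return xp, yp, zp, zb, dgm


def run_simulation(
    model: HeadModel,
    source: SourceSpec,
    detector: DetectorSpec,
    n_packets: int,
    seed: int,
    max_path: float = DEFAULT_MAX_PATH,
    record_mode: int = RECORD_DETECTED,
    n_ambient: float = 1.0,
) -> SimulationResult:
    """Run a full simulation; bit-reproducible from (inputs, seed).

    A packet is detected iff it transmits through the top face with its exit
    point inside the detector disk.  ``record_mode`` selects which packets get
    per-packet records: detected only (default), all top exits, or all.
    """
    if n_packets < 1:
        raise ValueError("n_packets must be >= 1")
    if seed < 0:
        raise ValueError("seed must be non-negative")
    mua, mus, g, n = model.property_arrays()
    xp, yp, zp, zb, dgm = _geometry_arrays(model)

    cap = int(n_packets)
    rec_weight = np.empty(cap)
    rec_x = np.empty(cap)
    rec_y = np.empty(cap)
    rec_nscat = np.empty(cap, dtype=np.int64)
    rec_status = np.empty(cap, dtype=np.int8)
    rec_paths = np.empty((cap, N_REGIONS))

    (n_rec, n_det, n_term, w_top, w_bottom, w_lateral, w_terminated, w_absorbed) = (
        _run_kernel(
            int(n_packets),
            int(seed),
            xp,
            yp,
            zp,
            zb,
            dgm,
            mua,
            mus,
            g,
            n,
            float(n_ambient),
            float(source.center[0]),
            float(source.center[1]),
            source.diameter / 2.0,
            float(detector.center[0]),
            float(detector.center[1]),
            detector.diameter / 2.0,
            float(max_path),
            int(record_mode),
            rec_weight,
            rec_x,
            rec_y,
            rec_nscat,
            rec_status,
            rec_paths,
        )
    )
    return SimulationResult(
        n_launched=int(n_packets),
        seed=int(seed),
        n_detected=n_det,
        n_terminated=n_term,
        exit_weight=rec_weight[:n_rec].copy(),
        exit_x=rec_x[:n_rec].copy(),
        exit_y=rec_y[:n_rec].copy(),
        scatter_count=rec_nscat[:n_rec].copy(),
        status=rec_status[:n_rec].copy(),
        paths=rec_paths[:n_rec].copy(),
        w_top=w_top,
        w_bottom=w_bottom,
        w_lateral=w_lateral,
        w_terminated=w_terminated,
        w_absorbed=w_absorbed,
        mua=mua,
        record_mode=record_mode,
        meta={
            "source": (tuple(source.center), source.diameter),
            "detector": (tuple(detector.center), detector.diameter),
            "max_path": max_path,
        },
    )
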