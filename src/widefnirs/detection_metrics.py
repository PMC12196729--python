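"""Metrics over detected photon packets.

Detected energy, common-random-number reweighting of absorption
perturbations, percent signal change, the grey-matter-to-scalp path ratio
(GSPR), and replicate summaries.

Reweighting exploits the engine's trajectory invariance: packet trajectories
never depend on the absorption coefficient, so the detected energy of a model
whose region absorptions are shifted by ``delta_mua`` equals exactly

    sum_i  w_i * exp(-sum_r delta_mua[r] * path[i, r])

over the same detected packets — an exact common-random-number estimate,
equal to a full rerun with the perturbed model and the same seed.

All metrics here operate on the *detected* packets of a
:class:`~widefnirs.mc_engine.SimulationResult`, or on a
:class:`DetectedPackets` selection built from top-exit records with a
post-hoc virtual detector (disk or annulus).  GSPR path sums are unweighted,
matching the detected-photon partial-path outputs its definition consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .head_model import N_REGIONS, RegionLabel
from .mc_engine import DetectorSpec, SimulationResult

__all__ = [
    "DetectedPackets",
    "PerturbationSpec",
    "SensitivityCurve",
    "GsprValue",
    "ReplicateSummary",
    "select_detected",
    "select_annulus",
    "detected_energy",
    "reweight_energy",
    "percent_change",
    "gspr",
    "sensitivity_curve",
    "replicate_summary",
]


@dataclass(frozen=True)
class DetectedPackets:
    """Exit weights and per-region partial paths of a set of detected packets.

    ``n_launched`` is the launched count behind the selection, so energies can
    be normalised to full-scale equivalents.
    """

    exit_weight: np.ndarray
    paths: np.ndarray  # (n, N_REGIONS), mm
    n_launched: int
    mua: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.exit_weight)

    @staticmethod
    def concat(parts: list["DetectedPackets"]) -> "DetectedPackets":
        if not parts:
            raise ValueError("nothing to concatenate")
        return DetectedPackets(
            exit_weight=np.concatenate([p.exit_weight for p in parts]),
            paths=np.vstack([p.paths for p in parts]),
            n_launched=sum(p.n_launched for p in parts),
            mua=parts[0].mua,
        )


def _as_detected(result) -> DetectedPackets:
    if isinstance(result, DetectedPackets):
        return result
    mask = result.detected_mask()
    return DetectedPackets(
        exit_weight=result.exit_weight[mask],
        paths=result.paths[mask],
        n_launched=result.n_launched,
        mua=result.mua,
    )


def select_detected(result: SimulationResult, detector: DetectorSpec) -> DetectedPackets:
    """Packets from top-exit records that land inside a (virtual) detector disk."""
    if result.record_mode == 0:
        raise ValueError(
            "virtual detectors need top-exit records (record_mode RECORD_TOP_EXITS/ALL)"
        )
    (dcx, dcy), dd = detector.center, detector.diameter
    inside = (result.exit_x - dcx) ** 2 + (result.exit_y - dcy) ** 2 <= (dd / 2) ** 2
    mask = (result.status == 0) & inside
    return DetectedPackets(
        exit_weight=result.exit_weight[mask],
        paths=result.paths[mask],
        n_launched=result.n_launched,
        mua=result.mua,
    )


def select_annulus(
    result: SimulationResult, center: tuple[float, float], radius: float, width: float = 1.0
) -> DetectedPackets:
    """Packets exiting the top face within a thin ring around ``center``.

    A ring detector at the true emitter-detector separation pools all
    azimuths, standing in for a small disk detector at that separation with
    far lower variance; energies are comparable after area normalisation.
    """
    r = np.hypot(result.exit_x - center[0], result.exit_y - center[1])
    mask = (result.status == 0) & (np.abs(r - radius) <= width / 2.0)
    return DetectedPackets(
        exit_weight=result.exit_weight[mask],
        paths=result.paths[mask],
        n_launched=result.n_launched,
        mua=result.mua,
    )


@dataclass(frozen=True)
class PerturbationSpec:
    """Absorption scale factors to sweep for one region; 1.0 is baseline."""

    region: RegionLabel
    factors: tuple[float, ...] = (1.0, 1.05, 1.10, 1.15, 1.20, 1.25)

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.factors):
            raise ValueError("all scale factors must be > 0")
        if not any(math.isclose(f, 1.0) for f in self.factors):
            raise ValueError("factors must include the 1.0 baseline")


@dataclass(frozen=True)
class SensitivityCurve:
    """Detected energy and percent change vs a region's absorption scale."""

    region: RegionLabel
    factors: tuple[float, ...]
    energy: tuple[float, ...]
    pct_change: tuple[float, ...]

    @property
    def max_abs_pct_change(self) -> float:
        return max(abs(p) for p in self.pct_change)


@dataclass(frozen=True)
class GsprValue:
    """Total detected-packet path in superficial grey matter vs scalp."""

    sgm_path: float
    scalp_path: float

    @property
    def ratio(self) -> float:
        return self.sgm_path / self.scalp_path


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean and sample standard deviation over replicate runs."""

    values: tuple[float, ...]
    mean: float
    sd: float

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def se(self) -> float:
        return self.sd / math.sqrt(self.n)


def detected_energy(result) -> float:
    """Sum of detected-packet exit weights (0 for empty detection)."""
    det = _as_detected(result)
    return float(det.exit_weight.sum())


def _delta_array(perturbation, mua: np.ndarray | None) -> np.ndarray:
    """Normalise a perturbation description into a per-region delta-mua array.

    Accepts a mapping RegionLabel -> delta mua (mm^-1), or a full-length
    array.  Rejects perturbations that would make any absorption negative.
    """
    if isinstance(perturbation, dict):
        delta = np.zeros(N_REGIONS)
        for region, d in perturbation.items():
            delta[int(region)] = d
    else:
        delta = np.asarray(perturbation, dtype=float)
        if delta.shape != (N_REGIONS,):
            raise ValueError(f"expected {N_REGIONS} per-region deltas")
    if mua is not None and np.any(mua + delta < 0):
        raise ValueError("perturbation would make an absorption coefficient negative")
    return delta


def reweight_energy(result, perturbation) -> float:
    """Detected energy under shifted absorption, from the same trajectories.

    ``perturbation`` maps regions to delta-mua in mm^-1.  Exactly equals a
    same-seed rerun with the perturbed model (trajectories are
    mua-independent).
    """
    det = _as_detected(result)
    delta = _delta_array(perturbation, det.mua)
    if det.n == 0:
        return 0.0
    return float(np.sum(det.exit_weight * np.exp(-det.paths @ delta)))


def percent_change(baseline_energy: float, perturbed_energy: float) -> float:
    """Relative deviation from baseline, in percent (negative for losses)."""
    if baseline_energy <= 0:
        raise ValueError("baseline energy must be > 0")
    return 100.0 * (perturbed_energy - baseline_energy) / baseline_energy


def gspr(result) -> GsprValue:
    """Grey-matter-to-scalp path ratio over detected packets.

    Total layer path = sum of detected-packet partial paths in the layer
    (equivalently APPL times the number of traversing packets), unweighted;
    the ratio is SGM over scalp.  Errors if no detected packet crossed the
    scalp.
    """
    det = _as_detected(result)
    sgm = float(det.paths[:, int(RegionLabel.SGM)].sum())
    scalp = float(det.paths[:, int(RegionLabel.SCALP)].sum())
    if scalp == 0:
        raise ValueError("GSPR undefined: no detected path in the scalp")
    return GsprValue(sgm_path=sgm, scalp_path=scalp)


def sensitivity_curve(result, spec: PerturbationSpec) -> SensitivityCurve:
    """Detected energy and percent change across a region's mua scale factors.

    Computed by common-random-number reweighting; the percent change at the
    1.0 factor is exactly zero.
    """
    det = _as_detected(result)
    if det.mua is None:
        raise ValueError("baseline mua unknown; cannot convert factors to deltas")
    base_mua = det.mua[int(spec.region)]
    baseline = detected_energy(det)
    energies = []
    pcts = []
    for f in spec.factors:
        if f == 1.0:
            e = baseline
        else:
            e = reweight_energy(det, {spec.region: base_mua * (f - 1.0)})
        energies.append(e)
        pcts.append(percent_change(baseline, e))
    return SensitivityCurve(
        region=spec.region,
        factors=tuple(spec.factors),
        energy=tuple(energies),
        pct_change=tuple(pcts),
    )


def replicate_summary(values) -> ReplicateSummary:
    """Mean and sample (ddof=1) standard deviation of replicate values."""
    vals = tuple(float(v) for v in values)
    if len(vals) < 2:
        raise ValueError("need at least two replicate values")
    arr = np.asarray(vals)
    return ReplicateSummary(values=vals, mean=float(arr.mean()), sd=float(arr.std(ddof=1)))
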