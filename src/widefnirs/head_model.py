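"""Layered slab head model with sulcal deep grey matter, and its optics.

The geometry is a 90 x 150 x 150 mm^3 rectilinear volume of five horizontal
slabs (scalp, skull, CSF, superficial grey matter, white matter) plus a
rectangular prism of deep sulcal grey matter embedded in the white matter and
segmented into four depth bands (DGM1-4).  The coordinate convention is

* ``z``: depth from the outer scalp surface, 0 at the surface, +z into the head
* ``y``: the optode axis and the long axis of the sulcal prism
* ``x``: the width axis of the sulcal prism

All regions are axis-aligned boxes, so the model is represented by continuous
region functions rather than a voxel grid; labelling uses half-open ``[low,
high)`` depth bands (lower bound inclusive) so every in-volume point maps to
exactly one region.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RegionLabel",
    "OpticalProperties",
    "HeadModelConfig",
    "HeadModel",
    "default_optical_properties",
    "build_head_model",
    "region_at",
    "scale_absorption",
    "save_head_model_config",
    "load_head_model_config",
]


class RegionLabel(enum.IntEnum):
    """Tissue regions of the head model; EXTERIOR marks out-of-volume points."""

    SCALP = 0
    SKULL = 1
    CSF = 2
    SGM = 3
    WM = 4
    DGM1 = 5
    DGM2 = 6
    DGM3 = 7
    DGM4 = 8
    EXTERIOR = 9


#: Region labels that carry tissue optical properties (everything but EXTERIOR).
TISSUE_REGIONS = tuple(r for r in RegionLabel if r is not RegionLabel.EXTERIOR)
N_REGIONS = len(TISSUE_REGIONS)


@dataclass(frozen=True)
class OpticalProperties:
    """Single-wavelength optical properties of one tissue region.

    Parameters
    ----------
    mua : float
        Absorption coefficient, mm^-1.
    mus : float
        Scattering coefficient, mm^-1.
    g : float
        Scattering anisotropy (mean cosine of the Henyey-Greenstein phase
        function), dimensionless, in (-1, 1).
    n : float
        Refractive index, dimensionless, >= 1.
    """

    mua: float
    mus: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.mua < 0:
            raise ValueError(f"mua must be >= 0, got {self.mua}")
        if self.mus < 0:
            raise ValueError(f"mus must be >= 0, got {self.mus}")
        if not -1 < self.g < 1:
            raise ValueError(f"g must be in (-1, 1), got {self.g}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")

    @property
    def mus_reduced(self) -> float:
        """Reduced scattering coefficient mus' = mus * (1 - g), mm^-1."""
        return self.mus * (1.0 - self.g)


def default_optical_properties() -> dict[RegionLabel, OpticalProperties]:
    """Per-region optical properties at 630 nm.

    Scalp and skull share one property set; the superficial grey-matter slab
    and all four deep grey-matter bands share the grey-matter set.
    """
    scalp = OpticalProperties(mua=0.019, mus=7.8, g=0.89, n=1.37)
    csf = OpticalProperties(mua=0.004, mus=0.009, g=0.89, n=1.37)
    gm = OpticalProperties(mua=0.02, mus=9.0, g=0.89, n=1.37)
    wm = OpticalProperties(mua=0.08, mus=8.5, g=0.9, n=1.37)
    return {
        RegionLabel.SCALP: scalp,
        RegionLabel.SKULL: scalp,
        RegionLabel.CSF: csf,
        RegionLabel.SGM: gm,
        RegionLabel.WM: wm,
        RegionLabel.DGM1: gm,
        RegionLabel.DGM2: gm,
        RegionLabel.DGM3: gm,
        RegionLabel.DGM4: gm,
    }


@dataclass(frozen=True)
class HeadModelConfig:
    """Geometry of the slab head model, all lengths in mm.

    ``slab_thicknesses`` are the scalp/skull/CSF/SGM/WM thicknesses from the
    surface down and must sum to ``depth``.  The sulcal prism is centred
    laterally: ``dgm_width`` along x, ``dgm_length`` along y, with depth bands
    given by ``dgm_depth_breaks`` (band i spans ``[breaks[i], breaks[i+1])``).
    Set ``dgm_width=0`` to disable the prism (plain five-slab model).
    """

    depth: float = 90.0
    lateral_x: float = 150.0
    lateral_y: float = 150.0
    slab_thicknesses: tuple[float, ...] = (6.0, 8.0, 4.0, 10.0, 62.0)
    dgm_width: float = 10.0
    dgm_length: float = 100.0
    dgm_depth_breaks: tuple[float, ...] = (28.0, 38.0, 48.0, 58.0, 90.0)
    region_overrides: dict[RegionLabel, OpticalProperties] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if len(self.slab_thicknesses) != 5:
            raise ValueError("expected five slab thicknesses (scalp..WM)")
        if any(t < 0 for t in self.slab_thicknesses):
            raise ValueError("slab thicknesses must be >= 0")
        total = sum(self.slab_thicknesses)
        if abs(total - self.depth) > 1e-9:
            raise ValueError(
                f"slab thicknesses sum to {total} mm, volume depth is {self.depth} mm"
            )
        if self.dgm_width < 0 or self.dgm_length < 0:
            raise ValueError("dgm_width and dgm_length must be >= 0")
        if self.dgm_width > 0:
            if self.dgm_width > self.lateral_x or self.dgm_length > self.lateral_y:
                raise ValueError("DGM prism exceeds the lateral volume")
            breaks = self.dgm_depth_breaks
            if len(breaks) != 5:
                raise ValueError("expected five DGM depth breaks (four bands)")
            if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
                raise ValueError("DGM depth breaks must be strictly increasing")
            sgm_bottom = sum(self.slab_thicknesses[:4])
            if breaks[0] < sgm_bottom - 1e-9 or breaks[-1] > self.depth + 1e-9:
                raise ValueError(
                    "DGM depth breaks must lie within [SGM bottom, volume depth]"
                )

    @property
    def slab_bounds(self) -> tuple[float, ...]:
        """Cumulative depth bounds (0, scalp_bottom, ..., depth)."""
        return tuple(np.concatenate([[0.0], np.cumsum(self.slab_thicknesses)]))

    @property
    def dgm_x_bounds(self) -> tuple[float, float]:
        half = self.dgm_width / 2.0
        c = self.lateral_x / 2.0
        return (c - half, c + half)

    @property
    def dgm_y_bounds(self) -> tuple[float, float]:
        half = self.dgm_length / 2.0
        c = self.lateral_y / 2.0
        return (c - half, c + half)


_SLAB_LABELS = (
    RegionLabel.SCALP,
    RegionLabel.SKULL,
    RegionLabel.CSF,
    RegionLabel.SGM,
    RegionLabel.WM,
)
_DGM_LABELS = (
    RegionLabel.DGM1,
    RegionLabel.DGM2,
    RegionLabel.DGM3,
    RegionLabel.DGM4,
)


@dataclass(frozen=True)
class HeadModel:
    """A built head model: geometry plus per-region optical properties."""

    config: HeadModelConfig
    properties: dict[RegionLabel, OpticalProperties]

    def region_at(self, position) -> RegionLabel:
        """Region label at a continuous (x, y, z) point in mm.

        Half-open bands, lower bound inclusive in z; EXTERIOR for points
        outside the volume.
        """
        x, y, z = position
        cfg = self.config
        if not (0.0 <= x < cfg.lateral_x and 0.0 <= y < cfg.lateral_y):
            return RegionLabel.EXTERIOR
        if not (0.0 <= z < cfg.depth):
            return RegionLabel.EXTERIOR
        if cfg.dgm_width > 0:
            x0, x1 = cfg.dgm_x_bounds
            y0, y1 = cfg.dgm_y_bounds
            breaks = cfg.dgm_depth_breaks
            if x0 <= x < x1 and y0 <= y < y1 and breaks[0] <= z < breaks[-1]:
                for i in range(4):
                    if breaks[i] <= z < breaks[i + 1]:
                        return _DGM_LABELS[i]
        bounds = self.config.slab_bounds
        for i in range(5):
            if bounds[i] <= z < bounds[i + 1]:
                return _SLAB_LABELS[i]
        return RegionLabel.EXTERIOR  # pragma: no cover - unreachable in-volume

    def property_arrays(self):
        """(mua, mus, g, n) float64 arrays indexed by RegionLabel value."""
        mua = np.zeros(N_REGIONS)
        mus = np.zeros(N_REGIONS)
        g = np.zeros(N_REGIONS)
        n = np.ones(N_REGIONS)
        for r in TISSUE_REGIONS:
            p = self.properties[r]
            mua[r], mus[r], g[r], n[r] = p.mua, p.mus, p.g, p.n
        return mua, mus, g, n

    def voxelize(self, resolution: float = 1.0) -> np.ndarray:
        """Integer label grid sampled at voxel centres, for visual checks only.

        Returns an array of shape (nx, ny, nz) of RegionLabel values.
        """
        cfg = self.config
        xs = np.arange(resolution / 2, cfg.lateral_x, resolution)
        ys = np.arange(resolution / 2, cfg.lateral_y, resolution)
        zs = np.arange(resolution / 2, cfg.depth, resolution)
        out = np.empty((len(xs), len(ys), len(zs)), dtype=np.int8)
        for i, x in enumerate(xs):
            for j, y in enumerate(ys):
                for k, z in enumerate(zs):
                    out[i, j, k] = int(self.region_at((x, y, z)))
        return out


def build_head_model(
    config: HeadModelConfig | None = None,
    properties: dict[RegionLabel, OpticalProperties] | None = None,
) -> HeadModel:
    """Build a head model from a geometry config and optical properties.

    ``config.region_overrides`` (and the ``properties`` argument, which takes
    precedence region-by-region) replace the default per-region optics.
    """
    if config is None:
        config = HeadModelConfig()
    props = default_optical_properties()
    props.update(config.region_overrides)
    if properties:
        props.update(properties)
    missing = [r for r in TISSUE_REGIONS if r not in props]
    if missing:
        raise ValueError(f"missing optical properties for {missing}")
    return HeadModel(config=config, properties=dict(props))


def save_head_model_config(config: HeadModelConfig, path) -> None:
    """Serialize a geometry config (and any optics overrides) to YAML."""
    import yaml

    data = {
        "depth": config.depth,
        "lateral_x": config.lateral_x,
        "lateral_y": config.lateral_y,
        "slab_thicknesses": list(config.slab_thicknesses),
        "dgm_width": config.dgm_width,
        "dgm_length": config.dgm_length,
        "dgm_depth_breaks": list(config.dgm_depth_breaks),
        "region_overrides": {
            r.name: {"mua": p.mua, "mus": p.mus, "g": p.g, "n": p.n}
            for r, p in config.region_overrides.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_head_model_config(path) -> HeadModelConfig:
    """Load a geometry config from YAML; unknown keys are rejected."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {
        "depth", "lateral_x", "lateral_y", "slab_thicknesses", "dgm_width",
        "dgm_length", "dgm_depth_breaks", "region_overrides",
    }
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown head-model keys: {sorted(unknown)}")
    overrides = {
        RegionLabel[name]: OpticalProperties(**props)
        for name, props in (data.pop("region_overrides", {}) or {}).items()
    }
    for key in ("slab_thicknesses", "dgm_depth_breaks"):
        if key in data:
            data[key] = tuple(float(v) for v in data[key])
    return HeadModelConfig(region_overrides=overrides, **data)


def region_at(model: HeadModel, position) -> RegionLabel:
    """Region label at a continuous point; EXTERIOR outside the volume."""
    return model.region_at(position)


def scale_absorption(
    model: HeadModel, region: RegionLabel, factor: float
) -> HeadModel:
    """Return a model with ``region``'s absorption coefficient scaled.

    Only mua of the named region changes; every other field is shared
    unchanged.  ``factor`` must be > 0.
    """
    if factor <= 0:
        raise ValueError(f"absorption scale factor must be > 0, got {factor}")
    if region not in model.properties:
        raise ValueError(f"no properties for region {region!r}")
    old = model.properties[region]
    props = dict(model.properties)
    props[region] = replace(old, mua=old.mua * factor)
    return HeadModel(config=model.config, properties=props)
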