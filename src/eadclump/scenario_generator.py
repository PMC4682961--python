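"""Deterministic, seeded construction of every study configuration.

All generators are pure functions of their arguments (including the seed):
identical inputs give identical outputs.  Percentage-to-count conversion
uses round-half-up throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from . import constants
from .cell_models import FibroblastParams, MyocyteParams, make_ead_parameters
from .tissue_solver import TissueGrid

__all__ = [
    "ScenarioSpec", "ConfigurationError", "circular_clump", "fibrosis_mask",
    "fibroblast_attachment", "cable_pattern", "reduced_coupling_clump",
    "build_grid", "CABLE_LENGTH", "EAD_SEGMENT", "PATTERN_C_BLOCK",
]

log = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Scenario parameters outside their physical/geometric ranges."""


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


# cell-type codes used in generated maps
NORMAL = 0
EAD = 1

#: 1D cable studies: 280 cells with a 160-cell EAD segment.  The stated
#: index ranges are interpreted as half-open 0-based ranges [60, 220) and
#: [120, 160) so the stated counts (160 EAD cells, 40 fibroblasts) hold.
CABLE_LENGTH = 280
EAD_SEGMENT = (60, 220)
PATTERN_C_BLOCK = (120, 160)


def circular_clump(grid_shape: Tuple[int, int], dx: float,
                   center_cm: Optional[Tuple[float, float]] = None,
                   radius_cm: float = 0.0) -> np.ndarray:
    """Cell-type map with an EAD disc: 1 inside radius R, 0 outside.

    Membership uses the Euclidean distance from the site center to the
    clump center; the default center is the domain center.
    """
    ny, nx = grid_shape
    if radius_cm < 0:
        raise ConfigurationError("clump radius must be non-negative")
    if center_cm is None:
        center_cm = (nx * dx / 2.0, ny * dx / 2.0)
    cx, cy = center_cm
    if radius_cm > 0 and (cx - radius_cm < 0 or cx + radius_cm > nx * dx
                          or cy - radius_cm < 0 or cy + radius_cm > ny * dx):
        raise ConfigurationError(
            f"clump of radius {radius_cm} cm at {center_cm} exceeds the "
            f"{nx * dx:g} x {ny * dx:g} cm domain")
    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dx
    r2 = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2
    return np.where(r2 <= radius_cm ** 2, EAD, NORMAL).astype(np.int64)


def band_clump(grid_shape: Tuple[int, int], dx: float, x_center_cm: float,
               half_length_cm: float) -> np.ndarray:
    """EAD band spanning the full strip height: |x - xc| <= half length.

    The cross-strip analog of a circular clump, used by the reduced-scale
    (narrow 2D strip) experiment proxies.
    """
    ny, nx = grid_shape
    if half_length_cm < 0:
        raise ConfigurationError("band half-length must be non-negative")
    xs = (np.arange(nx) + 0.5) * dx
    in_band = np.abs(xs - x_center_cm) <= half_length_cm
    return np.where(np.tile(in_band, (ny, 1)), EAD, NORMAL).astype(np.int64)


def fibrosis_mask(region_map: np.ndarray, p_f: float, seed: int) -> np.ndarray:
    """Obstacle mask: exactly round(P_f% of region sites), sampled uniformly
    without replacement inside the region (sites where ``region_map`` is
    nonzero)."""
    if not 0 <= p_f < 100:
        raise ConfigurationError("P_f must lie in [0, 100)")
    region_map = np.asarray(region_map)
    mask = np.zeros(region_map.shape, dtype=bool)
    sites = np.flatnonzero(region_map)
    n = _round_half_up(p_f / 100.0 * sites.size)
    if n:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(sites, size=n, replace=False)
        mask.ravel()[chosen] = True
    return mask


def fibroblast_attachment(region_map: np.ndarray, mode: str, p_a: float = 0.0,
                          seed: Optional[int] = None) -> np.ndarray:
    """Attachment mask over the region: all sites (``uniform``) or exactly
    round(P_a% of region sites) seeded-random sites (``random``)."""
    region_map = np.asarray(region_map)
    mask = np.zeros(region_map.shape, dtype=bool)
    if mode == "none":
        return mask
    if mode == "uniform":
        if p_a:
            log.warning("P_a=%s ignored for uniform attachment", p_a)
        mask[region_map != 0] = True
        return mask
    if mode == "random":
        if not 0 <= p_a < 100:
            raise ConfigurationError("P_a must lie in [0, 100)")
        if seed is None:
            raise ConfigurationError("random attachment requires a seed")
        sites = np.flatnonzero(region_map)
        n = _round_half_up(p_a / 100.0 * sites.size)
        if n:
            rng = np.random.default_rng(seed)
            chosen = rng.choice(sites, size=n, replace=False)
            mask.ravel()[chosen] = True
        return mask
    raise ConfigurationError(f"unknown attachment mode: {mode!r}")


def cable_pattern(pattern_id: str, p_a: float = 40.0,
                  seed: Optional[int] = None) -> Tuple[np.ndarray, np.ndarray]:
    """Cell-type and fibroblast-attachment maps for the four cable studies.

    A: EAD segment, no fibroblasts; B: fibroblasts on the whole segment;
    C: fibroblasts on the middle 40-cell block; D: seeded random
    attachment (P_a%) within the segment.  Returns (cell_types,
    attachment), both of length 280.
    """
    types = np.zeros((1, CABLE_LENGTH), dtype=np.int64)
    types[0, EAD_SEGMENT[0]:EAD_SEGMENT[1]] = EAD
    if pattern_id == "A":
        attach = np.zeros_like(types, dtype=bool)
    elif pattern_id == "B":
        attach = fibroblast_attachment(types, "uniform")
    elif pattern_id == "C":
        attach = np.zeros_like(types, dtype=bool)
        attach[0, PATTERN_C_BLOCK[0]:PATTERN_C_BLOCK[1]] = True
    elif pattern_id == "D":
        attach = fibroblast_attachment(types, "random", p_a=p_a, seed=seed)
    else:
        raise ConfigurationError(f"unknown cable pattern: {pattern_id!r}")
    return types, attach


def reduced_coupling_clump(grid_shape: Tuple[int, int], dx: float,
                           radius_cm: float, d_ratio: float,
                           center_cm: Optional[Tuple[float, float]] = None,
                           ) -> np.ndarray:
    """Diffusion-scale field: ``d_ratio`` inside the clump disc, 1 outside."""
    if not 0 < d_ratio <= 1:
        raise ConfigurationError("D/D0 must lie in (0, 1]")
    clump = circular_clump(grid_shape, dx, center_cm, radius_cm)
    return np.where(clump == EAD, d_ratio, 1.0)


@dataclass
class ScenarioSpec:
    """Complete description of one tissue configuration."""

    nx: int = 448
    ny: int = 448
    dx: float = constants.DX
    clump_radius_cm: float = 0.0
    clump_center_cm: Optional[Tuple[float, float]] = None
    clump_type: str = "type-I"             # type-I | type-II
    clump_d_ratio: float = 1.0
    fibrosis_pct: float = 0.0
    attachment_mode: str = "none"          # none | uniform | random
    attachment_pct: float = 0.0
    fibroblast: Optional[FibroblastParams] = None
    g_gap: float = constants.GGAP_DEFAULT
    cable_pattern_id: Optional[str] = None  # A|B|C|D (1D studies)
    seed: int = 0
    normal_params: MyocyteParams = field(default_factory=MyocyteParams)

    def __post_init__(self) -> None:
        if self.cable_pattern_id is not None and self.ny != 1:
            raise ConfigurationError("cable patterns require ny = 1")
        if not 0 <= self.fibrosis_pct < 100:
            raise ConfigurationError("P_f must lie in [0, 100)")
        if self.attachment_mode == "random" and not 0 <= self.attachment_pct < 100:
            raise ConfigurationError("P_a must lie in [0, 100)")

    def describe(self) -> dict:
        d = {k: v for k, v in vars(self).items()
             if k not in ("fibroblast", "normal_params")}
        if self.fibroblast is not None:
            d["fibroblast"] = vars(self.fibroblast)
        return d


def load_scenario(path) -> ScenarioSpec:
    """Read a :class:`ScenarioSpec` from a YAML/JSON config file.

    Recognized keys mirror the dataclass fields; a ``fibroblast`` mapping
    accepts ``e_rest`` plus either ``gf`` (constant) or ``piecewise: true``.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    fib = raw.pop("fibroblast", None)
    if fib is not None:
        if fib.pop("piecewise", False):
            fib_params = FibroblastParams.piecewise(e_rest=fib["e_rest"])
        else:
            fib_params = FibroblastParams.constant(
                e_rest=fib["e_rest"], gf=fib.get("gf", constants.GF_FIBROBLAST))
        raw["fibroblast"] = fib_params
    if "clump_center_cm" in raw and raw["clump_center_cm"] is not None:
        raw["clump_center_cm"] = tuple(raw["clump_center_cm"])
    return ScenarioSpec(**raw)


def build_grid(spec: ScenarioSpec) -> TissueGrid:
    """Materialize a :class:`TissueGrid` from a scenario description."""
    shape = (spec.ny, spec.nx)
    ead_params = make_ead_parameters(spec.clump_type)

    if spec.cable_pattern_id is not None:
        types, attach = cable_pattern(spec.cable_pattern_id,
                                      p_a=spec.attachment_pct, seed=spec.seed)
        grid = TissueGrid(ny=1, nx=types.shape[1], dx=spec.dx,
                          cell_types=[spec.normal_params, ead_params],
                          type_id=types)
        if attach.any():
            if spec.fibroblast is None:
                raise ConfigurationError("pattern requires fibroblast params")
            grid.attach_fibroblasts(attach, spec.fibroblast, spec.g_gap)
        return grid

    types = circular_clump(shape, spec.dx, spec.clump_center_cm,
                           spec.clump_radius_cm)
    dscale = np.where(types == EAD, spec.clump_d_ratio, 1.0)
    obstacle = fibrosis_mask(types, spec.fibrosis_pct, spec.seed) \
        if spec.fibrosis_pct else None
    grid = TissueGrid(ny=spec.ny, nx=spec.nx, dx=spec.dx,
                      cell_types=[spec.normal_params, ead_params],
                      type_id=types, diffusion_scale=dscale, obstacle=obstacle)
    if spec.attachment_mode != "none":
        if spec.fibroblast is None:
            raise ConfigurationError("fibroblast attachment requires params")
        region = types.copy()
        if obstacle is not None:
            region[obstacle] = 0   # obstacle sites never carry fibroblasts
        attach = fibroblast_attachment(region, spec.attachment_mode,
                                       p_a=spec.attachment_pct, seed=spec.seed)
        grid.attach_fibroblasts(attach, spec.fibroblast, spec.g_gap)
    return grid
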