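"""Closed-form diffusion-theory references for validating the transport kernel.

For a homogeneous infinite medium with absorption μa and reduced
scattering μs′ = μs(1−g), the steady-state (CW) fluence at distance r
from an isotropic unit-power point source is the diffusion Green's
function

    phi(r) = exp(-mueff r) / (4 pi D r),   D = 1/(3(mua+mus')),
    mueff = sqrt(3 mua (mua + mus'))

valid a few transport mean free paths ltr = 1/(mua+mus') away from the
source.  ``compare_to_oracle`` shell-averages an MC fluence volume around
the source and reports the relative-error profile against this form.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = ["DiffusionParams", "infinite_cw_fluence", "compare_to_oracle"]


@dataclasses.dataclass
class DiffusionParams:
    """Homogeneous-medium diffusion parameters (lengths in mm)."""

    mua: float
    musp: float
    n: float = 1.0

    @property
    def D(self) -> float:
        return 1.0 / (3.0 * (self.mua + self.musp))

    @property
    def mueff(self) -> float:
        return math.sqrt(3.0 * self.mua * (self.mua + self.musp))

    @property
    def ltr(self) -> float:
        """Transport mean free path 1/(mua+mus')."""
        return 1.0 / (self.mua + self.musp)


def infinite_cw_fluence(r, p: DiffusionParams):
    """CW fluence (mm^-2) of a unit point source in an infinite medium."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(r <= 0):
        raise ValueError("r must be > 0")
    return np.exp(-p.mueff * r) / (4.0 * math.pi * p.D * r)


@dataclasses.dataclass
class OracleComparison:
    radii: np.ndarray          # shell-center radii, mm
    mc: np.ndarray             # shell-averaged MC CW fluence
    analytic: np.ndarray       # oracle at shell centers
    rel_err: np.ndarray
    adequate: np.ndarray       # shells with sufficient statistics
    insufficient: bool         # no usable shell at all

    @property
    def max_rel_err(self) -> float:
        if self.insufficient:
            return math.nan
        return float(np.max(np.abs(self.rel_err[self.adequate])))


def compare_to_oracle(
    cw_fluence: np.ndarray,
    params: DiffusionParams,
    source_pos,
    length_unit: float = 1.0,
    r_min: float = 5.0,
    r_max: float = 15.0,
    shell_width: float = 1.0,
    min_fill: float = 0.99,
) -> OracleComparison:
    """Shell-averaged relative error of an MC CW fluence volume.

    Shells of *shell_width* mm are centred on *source_pos* (grid units);
    the first three transport mean free paths are always excluded, where
    diffusion theory itself is invalid.  A shell counts as statistically
    adequate when at least *min_fill* of its voxels received deposition;
    if no shell qualifies the comparison is flagged insufficient rather
    than failed.
    """
    dim = cw_fluence.shape
    src = np.asarray(source_pos, dtype=np.float64)
    cx, cy, cz = np.meshgrid(
        (np.arange(dim[0]) + 0.5 - src[0]) * length_unit,
        (np.arange(dim[1]) + 0.5 - src[1]) * length_unit,
        (np.arange(dim[2]) + 0.5 - src[2]) * length_unit,
        indexing="ij",
    )
    r = np.sqrt(cx * cx + cy * cy + cz * cz)
    lo = max(r_min, 3.0 * params.ltr)
    edges = np.arange(lo, r_max + shell_width * 0.5, shell_width)
    radii, mc, analytic, adequate = [], [], [], []
    for e0, e1 in zip(edges[:-1], edges[1:]):
        mask = (r >= e0) & (r < e1)
        nvox = int(mask.sum())
        if nvox == 0:
            continue
        vals = cw_fluence[mask]
        rc = 0.5 * (e0 + e1)
        radii.append(rc)
        mc.append(float(vals.mean()))
        analytic.append(float(infinite_cw_fluence(rc, params)))
        adequate.append((vals > 0).mean() >= min_fill and vals.mean() > 0)
    radii = np.asarray(radii)
    mc = np.asarray(mc)
    analytic = np.asarray(analytic)
    adequate = np.asarray(adequate, dtype=bool)
    rel = np.where(analytic > 0, (mc - analytic) / np.where(analytic > 0, analytic, 1.0), np.nan)
    return OracleComparison(
        radii=radii,
        mc=mc,
        analytic=analytic,
        rel_err=rel,
        adequate=adequate,
        insufficient=not bool(adequate.any()),
    )
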