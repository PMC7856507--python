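"""Luxton gEUD, Kutcher-Burman DVH reduction and Lyman NTCP for skin.

The Lyman model gives the complication probability of a uniformly
irradiated reference organ as

    NTCP = Phi((D - TD50) / (m * TD50)),

with Phi the standard normal CDF, TD50 the uniform dose producing 50%
complications and m the relative slope. An inhomogeneous dose to part of
the organ is reduced to an equivalent uniform exposure in either of two
strictly equivalent ways:

* the generalized equivalent uniform dose (power mean with exponent 1/n
  over partial volumes taken relative to the reference organ),
      gEUD = ( sum_i (v_i / V_ref) * D_i^(1/n) )^n,
  entered into the Lyman model at the whole-organ TD50; or
* the Kutcher-Burman effective volume
      v_eff = sum_i (v_i / V_ref) * (D_i / D_max)^(1/n)
  at the maximum dose, with the volume-scaled tolerance
  TD50(v) = TD50 * v^(-n).

Because gEUD = D_max * v_eff^n both routes give identical NTCP.

The skin endpoint used throughout is necrosis/ulceration of a 100 cm^2
reference area of skin, with TD50 = 70 Gy at conventional fractionation
and the Burman fit of the Emami tolerance data for the slope (m = 0.12)
and volume exponent (n = 0.10). The small n encodes a strong volume
effect: skin tolerates high doses to small areas, so the gEUD of a scalp
shell is dominated by its hot spots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .dvh import CumulativeDVH

__all__ = [
    "LKBParameters",
    "SKIN_EMAMI_BURMAN",
    "RadiobiologyResult",
    "geud",
    "geud_from_differential",
    "kutcher_burman_veff",
    "lyman_ntcp",
    "evaluate_dvh",
    "depth_gradient",
    "eqd2",
]


@dataclass(frozen=True)
class LKBParameters:
    """Lyman-Kutcher-Burman parameter set for one organ/endpoint.

    Attributes
    ----------
    td50_ref
        Uniform dose (Gy) producing 50% complications in the whole
        reference organ.
    m
        Relative slope of the dose-response curve (dimensionless).
    n
        Volume-effect exponent; n -> 0 is serial (max-dose driven),
        n = 1 is parallel (mean-dose driven).
    reference_area_cm2
        Area of the reference organ when it is a sheet-like structure
        (skin); partial volumes are taken relative to it.
    reference_thickness_mm
        Layer thickness used to convert the reference area to a volume.
    name
        Label for reports.
    """

    td50_ref: float
    m: float
    n: float
    reference_area_cm2: float
    reference_thickness_mm: float = 2.0
    name: str = ""

    def __post_init__(self):
        if self.td50_ref <= 0:
            raise ValueError("td50_ref must be positive")
        if not 0 < self.m < 1:
            raise ValueError("m must lie in (0, 1)")
        if not 0 < self.n <= 1:
            raise ValueError("n must lie in (0, 1]")
        if self.reference_area_cm2 <= 0 or self.reference_thickness_mm <= 0:
            raise ValueError("reference organ dimensions must be positive")

    @property
    def reference_volume_cc(self) -> float:
        """Reference organ volume (cm^3) = area x thickness."""
        return self.reference_area_cm2 * self.reference_thickness_mm / 10.0


#: Burman's fit of the Emami skin tolerance data (endpoint necrosis/
#: ulceration): TD50 = 70 Gy for a 100 cm^2 reference area of skin,
#: m = 0.12, n = 0.10; evaluated on a 2 mm layer.
SKIN_EMAMI_BURMAN = LKBParameters(
    td50_ref=70.0, m=0.12, n=0.10,
    reference_area_cm2=100.0, reference_thickness_mm=2.0,
    name="skin_emami_burman",
)

PARAMETER_SETS = {"skin_emami_burman": SKIN_EMAMI_BURMAN}


@dataclass(frozen=True)
class RadiobiologyResult:
    """gEUD, effective volume and NTCP for one structure DVH."""

    geud_gy: float
    ntcp: float
    veff: float
    dmax_gy: float


def _differential(dvh: CumulativeDVH) -> tuple[np.ndarray, np.ndarray]:
    doses, vols = dvh.differential()
    if np.any(doses < 0):
        raise ValueError("negative dose in DVH")
    keep = vols > 0
    return doses[keep], vols[keep]


def geud_from_differential(
    doses_gy: np.ndarray, volumes_cc: np.ndarray, params: LKBParameters
) -> float:
    """gEUD (Gy) from differential DVH bins.

    Partial volumes are taken relative to the reference organ volume;
    dose outside the structure contributes zero, so a structure smaller
    than the reference organ is implicitly padded with unirradiated
    tissue. Homogeneous of degree 1 in dose.
    """
    v_ref = params.reference_volume_cc
    if v_ref <= 0:
        raise ValueError("reference volume must be positive")
    doses = np.asarray(doses_gy, dtype=np.float64)
    vols = np.asarray(volumes_cc, dtype=np.float64)
    if np.any(doses < 0):
        raise ValueError("negative dose in DVH")
    inv_n = 1.0 / params.n
    # factor out dmax for numerical stability of the large power
    dmax = doses.max(initial=0.0)
    if dmax == 0.0:
        return 0.0
    s = np.sum((vols / v_ref) * (doses / dmax) ** inv_n)
    return float(dmax * s**params.n)


def geud(dvh: CumulativeDVH, params: LKBParameters) -> float:
    """Generalized equivalent uniform dose (Gy) of a cumulative DVH."""
    return geud_from_differential(*_differential(dvh), params)


def kutcher_burman_veff(dvh: CumulativeDVH, params: LKBParameters) -> float:
    """Kutcher-Burman effective partial volume (fraction of the reference organ).

    The DVH is reduced to the fraction ``v_eff`` of the reference organ
    that, uniformly irradiated at the maximum structure dose, is
    isoeffective with the inhomogeneous distribution.
    """
    doses, vols = _differential(dvh)
    dmax = doses.max(initial=0.0)
    if dmax <= 0:
        raise ValueError("maximum dose must be positive for the volume reduction")
    return float(np.sum((vols / params.reference_volume_cc)
                        * (doses / dmax) ** (1.0 / params.n)))


def lyman_ntcp(geud_gy: float, params: LKBParameters) -> float:
    """Lyman NTCP (probability in [0, 1]) at a given gEUD.

    NTCP = Phi(t) with t = (gEUD - TD50) / (m * TD50). Strictly
    increasing in gEUD; 0.5 at TD50.
    """
    geud_gy = np.asarray(geud_gy, dtype=np.float64)
    if np.any(geud_gy < 0):
        raise ValueError("gEUD must be non-negative")
    t = (geud_gy - params.td50_ref) / (params.m * params.td50_ref)
    out = norm.cdf(t)
    return float(out) if out.ndim == 0 else out


def lyman_ntcp_from_veff(dmax_gy: float, veff: float, params: LKBParameters) -> float:
    """Lyman NTCP via the volume-scaled tolerance TD50(v) = TD50 * v^(-n).

    Equals :func:`lyman_ntcp` at gEUD = dmax * veff^n; kept as the
    independent second route of the Kutcher-Burman reduction.
    """
    if veff <= 0:
        raise ValueError("effective volume must be positive")
    td50_v = params.td50_ref * veff ** (-params.n)
    return float(norm.cdf((dmax_gy - td50_v) / (params.m * td50_v)))


def evaluate_dvh(dvh: CumulativeDVH, params: LKBParameters) -> RadiobiologyResult:
    """gEUD, v_eff, D_max and NTCP of one structure DVH in one pass."""
    doses, vols = _differential(dvh)
    dmax = float(doses.max(initial=0.0))
    g = geud_from_differential(doses, vols, params)
    veff = (g / dmax) ** (1.0 / params.n) if dmax > 0 else 0.0
    return RadiobiologyResult(geud_gy=g, ntcp=lyman_ntcp(g, params),
                              veff=float(veff), dmax_gy=dmax)


def depth_gradient(
    geud_superficial_gy: float,
    geud_deep_gy: float,
    layer_center_separation_mm: float = 2.0,
) -> float:
    """gEUD depth gradient (Gy/mm) between two layers.

    For adjacent 2 mm layers (0-2 mm and 2-4 mm) the centers sit at 1 mm
    and 3 mm depth, 2 mm apart. Positive when dose builds up with depth,
    as it does below the surface of megavoltage beams.
    """
    if layer_center_separation_mm <= 0:
        raise ValueError("layer separation must be positive")
    return (geud_deep_gy - geud_superficial_gy) / layer_center_separation_mm


def eqd2(total_dose_gy, dose_per_fraction_gy: float, alpha_beta_gy: float):
    """Equi-effective dose in 2-Gy fractions (linear-quadratic model).

    EQD2 = D * (d + a/b) / (2 + a/b). Optional transform for
    hypofractionated courses; the accumulation and NTCP pipeline uses
    physical dose unless this is applied explicitly.
    """
    if dose_per_fraction_gy <= 0 or alpha_beta_gy <= 0:
        raise ValueError("dose per fraction and alpha/beta must be positive")
    d = np.asarray(total_dose_gy, dtype=np.float64)
    return d * (dose_per_fraction_gy + alpha_beta_gy) / (2.0 + alpha_beta_gy)
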