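"""Physical transport metrics derived from fitted effective diffusivities.

Conventions (all diffusivities in mm²/min):

* apparent diffusivity  D_app = D_free / lambda²
* Peclet number         Pe = (Deff - D_ref - D_disp) / D_ref, with
  D_ref = D_app for porous media and D_ref = D_free for open channels;
  the dispersion coefficient defaults to D_app.
* mean velocity         v = Deff / L for a subdomain characteristic
  length L (the Pe * D_ref / L composition differs only by the small
  D_ref correction and is available as an option).
* enhancement ratio     Deff / D_app
* small-PVS decomposition: the brain-tissue Deff minus an interstitial-
  convection term and a dispersion term (each of size D_app), divided by
  the PVS volume fraction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .subdomains import Subdomain

__all__ = [
    "TransportConstants",
    "MetricsReport",
    "apparent_diffusivity",
    "peclet",
    "mean_velocity",
    "small_pvs_deff",
    "enhancement_ratio",
    "round_sig",
    "report_round",
    "build_report",
]


@dataclass
class TransportConstants:
    d_free: float = 0.016  # mm²/min, free diffusivity of the tracer
    tortuosity: float = 1.73  # lambda; 1.6 and 1.85 also appear in sources
    porosity: float = 0.20
    d_disp: float | None = None  # defaults to D_app
    pvs_volume_fraction: float = 0.03
    characteristic_length: dict[int, float] = field(
        default_factory=lambda: {
            int(Subdomain.PAS_SURF): 12.0,  # caudal-rostral extent, mm
            int(Subdomain.PAS_BRANCH): 5.0,  # ventral-dorsal extent, mm
            int(Subdomain.BT): 0.5,  # inter-vessel spacing scale, mm
        }
    )

    def __post_init__(self) -> None:
        if self.d_free <= 0 or self.porosity <= 0 or self.pvs_volume_fraction <= 0:
            raise ValueError("constants must be positive")
        if self.tortuosity < 1:
            raise ValueError("tortuosity must be >= 1")

    @property
    def d_app(self) -> float:
        return apparent_diffusivity(self.d_free, self.tortuosity)

    @property
    def dispersion(self) -> float:
        return self.d_app if self.d_disp is None else self.d_disp


def round_sig(x: float, sig: int = 1) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0 or not np.isfinite(x):
        return x
    return float(round(x, -int(np.floor(np.log10(abs(x)))) + sig - 1))


def report_round(x: float) -> float:
    """Table-style rounding: nearest thousand when >= 1000, nearest
    integer when >= 1, else one significant figure."""
    if not np.isfinite(x):
        return x
    if abs(x) >= 1000:
        return float(round(x, -3))
    if abs(x) >= 1:
        return float(round(x))
    return round_sig(x, 1)


def apparent_diffusivity(d_free: float, tortuosity: float) -> float:
    """D_app = D / lambda²."""
    if tortuosity < 1:
        raise ValueError("tortuosity must be >= 1")
    return d_free / tortuosity ** 2


def peclet(deff: float, d_ref: float, d_disp: float) -> float:
    """Pe = (Deff - D_ref - D_disp) / D_ref; negative values indicate a
    Deff smaller than the diffusion-scale terms and are flagged."""
    if d_ref <= 0:
        raise ValueError("reference diffusivity must be positive")
    pe = (deff - d_ref - d_disp) / d_ref
    if pe < 0:
        warnings.warn(f"negative Peclet number {pe:.3g}: Deff below diffusion scale")
    return pe


def mean_velocity(deff: float, length: float, d_ref: float | None = None) -> float:
    """v = Deff / L; with ``d_ref`` given, the Pe-based variant
    (Deff - 2*d_ref)/L is used instead."""
    if length <= 0:
        raise ValueError("characteristic length must be positive")
    if d_ref is None:
        return deff / length
    return peclet(deff, d_ref, d_ref) * d_ref / length


def small_pvs_deff(deff_bt: float, d_app: float, pvs_fraction: float) -> float:
    """Deff attributable to small-PVS convection inside brain tissue.

    Subtracts an interstitial-convection and a dispersion contribution
    (each equal to D_app) and rescales by the PVS volume fraction.  A
    non-positive numerator returns 0 with a warning.
    """
    if not 0 < pvs_fraction < 1:
        raise ValueError("PVS volume fraction must be in (0, 1)")
    num = deff_bt - 2.0 * d_app
    if num <= 0:
        warnings.warn("brain-tissue Deff fully explained by diffusion-scale terms")
        return 0.0
    return num / pvs_fraction


def enhancement_ratio(deff: float, d_app: float) -> float:
    """Deff / D_app."""
    if d_app <= 0:
        raise ValueError("D_app must be positive")
    return deff / d_app


@dataclass
class MetricsReport:
    per_subdomain: dict[str, dict]
    small_pvs: dict
    constants: dict

    def to_json(self, path=None) -> str:
        s = json.dumps(
            {
                "per_subdomain": self.per_subdomain,
                "small_pvs": self.small_pvs,
                "constants": self.constants,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, s: str) -> "MetricsReport":
        d = json.loads(s)
        return cls(d["per_subdomain"], d["small_pvs"], d["constants"])

    def to_table(self) -> str:
        lines = [
            f"{'subdomain':<12}{'Deff':>8}{'Pe open':>10}{'Pe porous':>11}"
            f"{'L (mm)':>8}{'v (mm/min)':>12}{'Deff/Dapp':>11}"
        ]
        for name, m in self.per_subdomain.items():
            lines.append(
                f"{name:<12}{m['deff']:>8g}{m['pe_open_rounded']:>10g}"
                f"{m['pe_porous_rounded']:>11g}{m['characteristic_length']:>8g}"
                f"{m['velocity_rounded']:>12g}{m['enhancement']:>11g}"
            )
        lines.append(
            f"small-PVS Deff = {self.small_pvs['deff']:g} mm^2/min "
            f"({self.small_pvs['enhancement']:g}x apparent diffusivity)"
        )
        return "\n".join(lines)


def build_report(
    deff_by_subdomain: dict[int, float],
    constants: TransportConstants | None = None,
) -> MetricsReport:
    """Full metrics table from a fitted Deff set.

    Both raw and table-rounded values are retained for every quantity.
    """
    k = constants or TransportConstants()
    # table arithmetic uses the 1-significant-figure apparent diffusivity
    # (0.005), matching how the printed Pe and enhancement values are formed
    d_app = round_sig(k.d_app, 1)
    d_disp = d_app if k.d_disp is None else k.d_disp
    per: dict[str, dict] = {}
    for tag, deff in deff_by_subdomain.items():
        tag = int(tag)
        name = Subdomain(tag).name
        L = k.characteristic_length.get(tag)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pe_open = peclet(deff, k.d_free, d_disp)
            pe_porous = peclet(deff, d_app, d_disp)
        v = mean_velocity(deff, L) if L else float("nan")
        per[name] = {
            "deff": deff,
            "pe_open": pe_open,
            "pe_open_rounded": report_round(pe_open),
            "pe_open_ratio": deff / k.d_free,  # alternative open-channel reading
            "pe_porous": pe_porous,
            "pe_porous_rounded": report_round(pe_porous),
            "characteristic_length": L,
            "velocity": v,
            "velocity_rounded": report_round(v),
            "enhancement": enhancement_ratio(deff, d_app),
            "negative_pe_flag": bool(pe_open < 0 or pe_porous < 0),
        }
    deff_bt = deff_by_subdomain.get(int(Subdomain.BT))
    small = {}
    if deff_bt is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d_small = small_pvs_deff(deff_bt, d_app, k.pvs_volume_fraction)
        small = {
            "deff": d_small,
            "enhancement": d_small / d_app,
            "pvs_volume_fraction": k.pvs_volume_fraction,
        }
    const = {
        "d_free": k.d_free,
        "tortuosity": k.tortuosity,
        "d_app": k.d_app,
        "d_app_reported": d_app,
        "d_disp": d_disp,
        "porosity": k.porosity,
        "pvs_volume_fraction": k.pvs_volume_fraction,
    }
    return MetricsReport(per_subdomain=per, small_pvs=small, constants=const)
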