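"""Crystallinity from DSC melting endotherms.

Polydioxanone is semi-crystalline; hydrolysis preferentially removes the
amorphous phase, so the crystalline fraction rises during early
degradation.  The crystalline fraction is read from the first-heating
thermogram as

    X_c [%] = 100 * dH_m / dH_ref

where dH_m is the specific melting enthalpy (J/g) obtained by
integrating the baseline-subtracted endotherm over the melting window
and dH_ref is the melting enthalpy of a hypothetically 100%-crystalline
sample.  dH_ref is a required analysis constant: the packaged default of
141 J/g is a literature convention for PPDX, not a measured value, and
should be overridden when a better reference is available.

With heat flow in W/g and temperature scanned at ``scan_rate`` deg C/min,

    dH_m = (1 / scan_rate[degC/s]) * integral (q(T) - baseline(T)) dT
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Thermogram",
    "CrystallinityResult",
    "integrate_endotherm",
    "crystallinity",
    "replicate_crystallinity",
    "read_thermogram_csv",
    "write_thermogram_csv",
    "DH_REF_PPDX_J_PER_G",
]

#: Conventional 100%-crystalline PPDX melting enthalpy (J/g). A literature
#: convention packaged as default, exposed so users can override it.
DH_REF_PPDX_J_PER_G = 141.0


@dataclass(frozen=True)
class Thermogram:
    """Specific heat flow vs temperature at fixed scan rate.

    ``endo_up=True`` means endothermic transitions are positive in
    ``heat_flow`` (the sign convention is explicit; it is never guessed).
    """

    temperature: np.ndarray      # deg C, strictly ascending
    heat_flow: np.ndarray        # W/g
    scan_rate: float = 5.0       # deg C / min
    endo_up: bool = True
    sample_mass_mg: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.temperature, dtype=float)
        q = np.asarray(self.heat_flow, dtype=float)
        if t.size < 2 or t.size != q.size:
            raise ValueError("thermogram needs >= 2 matching (T, q) points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.scan_rate <= 0:
            raise ValueError("scan_rate must be positive")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "heat_flow", q)


@dataclass(frozen=True)
class CrystallinityResult:
    delta_H: float               # J/g
    dH_ref: float                # J/g
    crystallinity_pct: float     # %
    window: tuple[float, float]  # deg C


def integrate_endotherm(
    thermogram: Thermogram,
    T_lo: float,
    T_hi: float,
    *,
    baseline_fraction: float = 0.15,
    sign_tolerance: float = 0.25,
) -> float:
    """Specific melting enthalpy (J/g) over [T_lo, T_hi].

    A linear instrumental baseline is subtracted, the excess heat flow is
    trapezoid-integrated over temperature and divided by the scan rate
    (converted to deg C/s).  The baseline line is least-squares fitted to
    the outer ``baseline_fraction`` of the window at each end (those
    flanks are expected to be transition-free; a peak +- 3 FWHM window
    leaves them so), which keeps point noise at the window edges from
    tilting the whole baseline; ``baseline_fraction=0`` degenerates to
    the line through the two endpoint samples.  A net negative area
    exceeding ``sign_tolerance`` of the gross (absolute) excess area — a
    substantial inverted transition rather than noise around zero —
    signals a wrong endotherm sign convention and raises.
    """
    t, q = thermogram.temperature, thermogram.heat_flow
    if not (t[0] <= T_lo < T_hi <= t[-1]):
        raise ValueError(
            f"integration window [{T_lo}, {T_hi}] outside scan range "
            f"[{t[0]}, {t[-1]}]"
        )
    if not 0 <= baseline_fraction < 0.5:
        raise ValueError("baseline_fraction must be in [0, 0.5)")
    if not thermogram.endo_up:
        q = -q
    inside = (t > T_lo) & (t < T_hi)
    tt = np.concatenate(([T_lo], t[inside], [T_hi]))
    qq = np.concatenate(([np.interp(T_lo, t, q)], q[inside], [np.interp(T_hi, t, q)]))
    flank = baseline_fraction * (T_hi - T_lo)
    edge = (tt <= T_lo + flank) | (tt >= T_hi - flank)
    if baseline_fraction > 0 and edge.sum() >= 4:
        coef = np.polynomial.polynomial.polyfit(tt[edge], qq[edge], 1)
        baseline = np.polynomial.polynomial.polyval(tt, coef)
    else:
        baseline = np.interp(tt, [tt[0], tt[-1]], [qq[0], qq[-1]])
    area = float(np.trapezoid(qq - baseline, tt))  # W/g * degC
    rate_c_per_s = thermogram.scan_rate / 60.0
    delta_H = area / rate_c_per_s
    gross = float(np.trapezoid(np.abs(qq - baseline), tt)) / rate_c_per_s
    if delta_H < 0 and abs(delta_H) > sign_tolerance * max(gross, 1e-12):
        raise ValueError(
            f"net endotherm area is negative ({delta_H:.3g} J/g): "
            "check the endo_up sign convention"
        )
    return delta_H


def crystallinity(
    delta_H: float,
    dH_ref: float = DH_REF_PPDX_J_PER_G,
    window: tuple[float, float] = (float("nan"), float("nan")),
) -> CrystallinityResult:
    """Percent crystallinity, 100 * delta_H / dH_ref."""
    if dH_ref <= 0:
        raise ValueError("dH_ref must be positive")
    pct = 100.0 * delta_H / dH_ref
    return CrystallinityResult(
        delta_H=float(delta_H),
        dH_ref=float(dH_ref),
        crystallinity_pct=float(pct),
        window=tuple(window),
    )


def auto_window(
    thermogram: Thermogram, fwhm_factor: float = 3.0
) -> tuple[float, float]:
    """Peak +- fwhm_factor * FWHM window around the largest endotherm.

    Offered for convenience; explicit windows are the recommended (and
    tested) path, since auto-detection is fragile on noisy baselines.
    """
    t = thermogram.temperature
    q = thermogram.heat_flow if thermogram.endo_up else -thermogram.heat_flow
    i = int(np.argmax(q))
    half = (q[i] + np.median(q)) / 2.0
    above = np.nonzero(q >= half)[0]
    left = above[above <= i]
    right = above[above >= i]
    fwhm = t[right[-1]] - t[left[0]]
    fwhm = max(fwhm, 2 * np.median(np.diff(t)))
    lo = max(t[0], t[i] - fwhm_factor * fwhm)
    hi = min(t[-1], t[i] + fwhm_factor * fwhm)
    return float(lo), float(hi)


def replicate_crystallinity(
    thermograms: Sequence[Thermogram],
    window: tuple[float, float],
    dH_ref: float = DH_REF_PPDX_J_PER_G,
) -> dict:
    """Per-replicate crystallinity plus mean and SD (the measurement
    protocol averages three replicate scans).

    SD is the sample SD (ddof=1); for a single replicate it is reported
    as None, not 0.
    """
    if not thermograms:
        raise ValueError("no thermograms given")
    results = [
        crystallinity(integrate_endotherm(tg, *window), dH_ref, window)
        for tg in thermograms
    ]
    vals = np.asarray([r.crystallinity_pct for r in results])
    return {
        "replicates": results,
        "mean": float(np.mean(vals)),
        "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else None,
        "n": len(vals),
    }


# ---------------------------------------------------------------------------
# I/O: 2-column CSV + JSON metadata
# ---------------------------------------------------------------------------


def write_thermogram_csv(tg: Thermogram, path: str | Path) -> None:
    np.savetxt(
        path,
        np.column_stack([tg.temperature, tg.heat_flow]),
        delimiter=",",
        header="temperature_C,heat_flow_W_per_g",
        comments="",
    )
    Path(str(path) + ".json").write_text(
        json.dumps(
            {
                "scan_rate_C_per_min": tg.scan_rate,
                "endo_up": tg.endo_up,
                "sample_mass_mg": tg.sample_mass_mg,
                "meta": tg.meta,
            }
        )
    )


def read_thermogram_csv(path: str | Path) -> Thermogram:
    path = Path(path)
    try:
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
    except ValueError as exc:
        raise ValueError(f"malformed thermogram file {path}: {exc}") from exc
    meta = {}
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return Thermogram(
        temperature=arr[:, 0],
        heat_flow=arr[:, 1],
        scan_rate=meta.get("scan_rate_C_per_min", 5.0),
        endo_up=meta.get("endo_up", True),
        sample_mass_mg=meta.get("sample_mass_mg"),
        meta=meta.get("meta", {}),
    )
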