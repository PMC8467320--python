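"""Synthetic instrument data with known ground truth.

The analysis stages (baseline correction, shoulder integration, crack
morphometry, endotherm integration, statistics) are exercised against
simulated data whose ground truth is known by construction:

* **Raman / FT-IR spectra** are sums of pseudo-Voigt peaks
  (``shape_mix`` blends Gaussian and Lorentzian sharing center and FWHM)
  on a smooth polynomial background with additive Gaussian noise.  The
  polydioxanone (PPDX) skeleton bands sit at 870 (strongest, C-O-C), 1048
  (C-C), 1451 (CH2) and 1732 cm^-1 (ester C=O); the amorphous-phase
  carbonyl contribution is one broad Gaussian shoulder at 1742 cm^-1
  (midpoint of the 1736-1749 cm^-1 integration window, FWHM 14 cm^-1)
  whose amplitude scales with the degradation state.  Five Solvent
  Violet 13 dye bands (483, 1242, 1403, 1610, 1638 cm^-1) shrink with
  degradation as the dye is eluted.
* **Degradation series** reproduce the measurement protocol: an 8 x 8
  grid of spectra per period (12.9 um x 11.4 um spacing) with lognormal
  per-spot amplitude variability.
* **Crack masks** are rasterized filled ellipses with non-overlapping
  placement (or end-to-end chaining to emulate crack merging), plus the
  drawn length/orientation/aspect ground truth.
* **Thermograms** are Gaussian melting endotherms whose integrated
  specific enthalpy encodes a chosen percent crystallinity.

The shoulder amplitudes of the default degradation profiles are
calibrated (by root finding on the actual metric pipeline) so the
noiseless reference spectra reproduce the published per-period
normalized shoulder areas; the published crystallinities parameterise
the thermogram profiles the same way.  Everything is deterministic for
a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .crackmorph import BinaryMask
from .dsc import Thermogram
from .specquant import Spectrum, SpectrumGrid, shoulder_area

__all__ = [
    "PeakModel",
    "DegradationProfile",
    "CrackPopulationSpec",
    "CrackTruth",
    "pseudo_voigt",
    "generate_spectrum",
    "generate_degradation_series",
    "generate_crack_mask",
    "generate_thermogram",
    "reference_spectrum",
    "reference_shoulder_metric",
    "calibrate_shoulder_level",
    "default_degradation_profiles",
    "table2_crack_spec",
    "ppdx_raman_peaks",
    "dye_raman_peaks",
    "DEFAULT_BASELINE_COEFFS",
    "TABLE_SHOULDER_AREAS",
    "TABLE_CRYSTALLINITY",
]

# Published per-period ground truths used to parameterise the generator
# (normalized shoulder area, cm^-1; percent crystallinity).
TABLE_SHOULDER_AREAS = {0: 9.83, 4: 9.24, 8: 7.97, 16: 6.65, 24: 6.30}
TABLE_CRYSTALLINITY = {0: 47.6, 4: 54.8, 8: 60.9, 16: 69.7, 24: 59.2}

#: Gentle fluorescence-like background, evaluated as a polynomial in the
#: raw wavenumber (ascending coefficients); ~10% of the 870 cm^-1 peak.
DEFAULT_BASELINE_COEFFS = (120.0, -0.05, 1.2e-5)

_SHOULDER_CENTER = 1742.0  # midpoint of the 1736-1749 cm^-1 window
_SHOULDER_FWHM = 14.0
_CARBONYL_AMP = 320.0


@dataclass(frozen=True)
class PeakModel:
    """One pseudo-Voigt band: shape_mix 0 = Gaussian, 1 = Lorentzian."""

    center: float       # cm^-1
    amplitude: float    # counts (peak height)
    fwhm: float         # cm^-1
    shape_mix: float = 0.0

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if not 0 <= self.shape_mix <= 1:
            raise ValueError("shape_mix must be in [0, 1]")


@dataclass(frozen=True)
class DegradationProfile:
    """Ground-truth state of one degradation period."""

    week: int
    shoulder_level: float        # amorphous shoulder amp / carbonyl amp
    dye_level: float             # scale of the five dye bands
    crystallinity_pct: float
    noise_sd_rel: float = 0.02   # additive noise, fraction of carbonyl amp

    def __post_init__(self):
        if self.week < 0:
            raise ValueError("week must be >= 0")
        if self.shoulder_level < 0 or self.dye_level < 0:
            raise ValueError("shoulder_level and dye_level must be >= 0")
        if not 0 <= self.crystallinity_pct <= 100:
            raise ValueError("crystallinity_pct must be in [0, 100]")
        if self.noise_sd_rel < 0:
            raise ValueError("noise_sd_rel must be >= 0")


def ppdx_raman_peaks() -> list[PeakModel]:
    """The degradation-stable PPDX skeleton bands (Raman)."""
    return [
        PeakModel(870.0, 1000.0, 10.0, 0.3),
        PeakModel(1048.0, 420.0, 10.0, 0.3),
        PeakModel(1451.0, 380.0, 12.0, 0.3),
        PeakModel(1732.0, _CARBONYL_AMP, 9.0, 0.3),
    ]


def dye_raman_peaks(dye_level: float = 1.0) -> list[PeakModel]:
    """Solvent Violet 13 bands at full (non-degraded) strength x level."""
    base = [
        PeakModel(483.0, 60.0, 9.0, 0.3),
        PeakModel(1242.0, 45.0, 9.0, 0.3),
        PeakModel(1403.0, 40.0, 9.0, 0.3),
        PeakModel(1610.0, 50.0, 8.0, 0.3),
        PeakModel(1638.0, 55.0, 8.0, 0.3),
    ]
    return [
        PeakModel(p.center, p.amplitude * dye_level, p.fwhm, p.shape_mix)
        for p in base
    ]


def _shoulder_peak(shoulder_level: float) -> PeakModel:
    return PeakModel(
        _SHOULDER_CENTER, shoulder_level * _CARBONYL_AMP, _SHOULDER_FWHM, 0.0
    )


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def pseudo_voigt(
    w: np.ndarray, center: float, amplitude: float, fwhm: float, shape_mix: float
) -> np.ndarray:
    """Height-normalised pseudo-Voigt profile: a shape_mix-weighted sum of
    a Lorentzian and a Gaussian sharing center and FWHM."""
    d = w - center
    gauss = np.exp(-4.0 * np.log(2.0) * (d / fwhm) ** 2)
    lorentz = 1.0 / (1.0 + 4.0 * (d / fwhm) ** 2)
    return amplitude * ((1.0 - shape_mix) * gauss + shape_mix * lorentz)


def generate_spectrum(
    peaks: Sequence[PeakModel],
    baseline_coeffs: Sequence[float] = (0.0,),
    noise_sd: float = 0.0,
    seed: int = 0,
    grid: tuple[float, float, float] = (200.0, 1800.0, 1.0),
    kind: Literal["raman", "ftir"] = "raman",
    meta: dict | None = None,
) -> Spectrum:
    """Sum of pseudo-Voigt peaks + polynomial baseline + Gaussian noise.

    ``grid`` is (lo, hi, step) in cm^-1; ``baseline_coeffs`` are ascending
    polynomial coefficients evaluated at the raw wavenumber.  Reproducible
    for a fixed seed.
    """
    lo, hi, step = grid
    if step <= 0 or hi <= lo:
        raise ValueError("empty wavenumber grid")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    w = np.arange(lo, hi + step / 2, step)
    y = np.polynomial.polynomial.polyval(w, np.asarray(baseline_coeffs, float))
    y = np.broadcast_to(y, w.shape).astype(float).copy()
    for p in peaks:
        y += pseudo_voigt(w, p.center, p.amplitude, p.fwhm, p.shape_mix)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=w.size)
    return Spectrum(w, y, kind=kind, meta=meta or {})


def _profile_peaks(profile: DegradationProfile) -> list[PeakModel]:
    return (
        ppdx_raman_peaks()
        + [_shoulder_peak(profile.shoulder_level)]
        + dye_raman_peaks(profile.dye_level)
    )


def reference_spectrum(
    profile: DegradationProfile, grid: tuple[float, float, float] = (200.0, 1800.0, 1.0)
) -> Spectrum:
    """Noiseless, baseline-free, perturbation-free spectrum of a profile —
    the ground truth the grid statistics should recover."""
    return generate_spectrum(
        _profile_peaks(profile), (0.0,), 0.0, 0, grid, meta={"week": profile.week}
    )


def reference_shoulder_metric(profile: DegradationProfile) -> float:
    """Ground-truth normalized shoulder area (cm^-1) of a profile."""
    return shoulder_area(reference_spectrum(profile)).normalized_area


def calibrate_shoulder_level(
    target_area: float, dye_level: float = 0.0, s_max: float = 3.0
) -> float:
    """Shoulder level whose noiseless reference metric equals
    ``target_area`` (cm^-1), by root finding; the metric is monotone in
    the level, so the root is unique.  ``dye_level`` should match the
    profile the level is destined for (dye band tails contribute a tiny
    amount to the integration window)."""

    def f(s: float) -> float:
        prof = DegradationProfile(0, s, dye_level, 50.0)
        return reference_shoulder_metric(prof) - target_area

    if f(0.0) > 0:
        raise ValueError(
            f"target area {target_area} below the carbonyl tail contribution"
        )
    return float(brentq(f, 0.0, s_max, xtol=1e-10))


def default_degradation_profiles(
    noise_sd_rel: float = 0.02,
) -> list[DegradationProfile]:
    """The five study periods, shoulder levels calibrated to the published
    per-period normalized areas and crystallinities set to the published
    DSC values.  Dye levels decline monotonically (the publication reports
    the decline only qualitatively; the values here are a chosen emulation)."""
    dye = {0: 1.0, 4: 0.75, 8: 0.55, 16: 0.35, 24: 0.2}
    return [
        DegradationProfile(
            week=wk,
            shoulder_level=calibrate_shoulder_level(
                TABLE_SHOULDER_AREAS[wk], dye_level=dye[wk]
            ),
            dye_level=dye[wk],
            crystallinity_pct=TABLE_CRYSTALLINITY[wk],
            noise_sd_rel=noise_sd_rel,
        )
        for wk in sorted(TABLE_SHOULDER_AREAS)
    ]


def generate_degradation_series(
    profiles: Sequence[DegradationProfile],
    layout: tuple[int, int, float, float] = (8, 8, 12.9, 11.4),
    seed: int = 0,
    amplitude_cv: float = 0.05,
    baseline_coeffs: Sequence[float] = DEFAULT_BASELINE_COEFFS,
    grid: tuple[float, float, float] = (200.0, 1800.0, 1.0),
) -> dict[int, SpectrumGrid]:
    """One spectrum grid per degradation period.

    Every spot draws an independent lognormal multiplicative factor
    (coefficient of variation ``amplitude_cv``, unit mean) per peak and
    additive Gaussian noise of ``profile.noise_sd_rel`` x the carbonyl
    amplitude.  The PPDX peak set is fixed across periods; only the
    shoulder and dye amplitudes follow the profile.
    """
    n_rows, n_cols, dx, dy = layout
    if dx <= 0 or dy <= 0:
        raise ValueError("grid spacings must be positive")
    weeks = [p.week for p in profiles]
    if len(set(weeks)) != len(weeks):
        raise ValueError(f"duplicate week values in profiles: {sorted(weeks)}")
    sigma = float(np.sqrt(np.log1p(amplitude_cv**2)))
    mu = -0.5 * sigma**2  # unit-mean lognormal
    rng = np.random.default_rng(seed)
    out: dict[int, SpectrumGrid] = {}
    for prof in profiles:
        peaks = _profile_peaks(prof)
        noise_sd = prof.noise_sd_rel * _CARBONYL_AMP
        spectra = []
        for i in range(n_rows * n_cols):
            factors = rng.lognormal(mu, sigma, size=len(peaks)) if sigma > 0 else np.ones(len(peaks))
            jittered = [
                PeakModel(p.center, p.amplitude * f, p.fwhm, p.shape_mix)
                for p, f in zip(peaks, factors)
            ]
            spot_seed = int(rng.integers(0, 2**31 - 1))
            r, c = divmod(i, n_cols)
            spectra.append(
                generate_spectrum(
                    jittered,
                    baseline_coeffs,
                    noise_sd,
                    spot_seed,
                    grid,
                    meta={"week": prof.week, "row": r, "col": c},
                )
            )
        out[prof.week] = SpectrumGrid(
            spectra, n_rows=n_rows, n_cols=n_cols, dx_um=dx, dy_um=dy,
            meta={"week": prof.week},
        )
    return out


# ---------------------------------------------------------------------------
# crack masks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrackPopulationSpec:
    """Population of elliptical cracks to rasterize into one field.

    Distribution specs are dicts: ``{"kind": "lognormal", "median": m,
    "sigma": s}``, ``{"kind": "normal", "mean": m, "sd": s}`` or
    ``{"kind": "fixed", "value": v}``.  Angles are wrapped to [0, 180).
    """

    n_cracks: int
    length_dist: Mapping          # major axis, um
    aspect_dist: Mapping          # major/minor, >= 1
    angle_dist: Mapping           # degrees
    merge_prob: float = 0.0
    pixel_size: float = 0.066     # um / px
    field_size: tuple[float, float] = (84.0, 63.0)  # (width, height) um

    def __post_init__(self):
        if self.n_cracks < 0:
            raise ValueError("n_cracks must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not 0 <= self.merge_prob <= 1:
            raise ValueError("merge_prob must be in [0, 1]")


@dataclass(frozen=True)
class CrackTruth:
    """Ground truth of one drawn crack."""

    index: int
    length_um: float
    aspect: float
    angle_deg: float
    center_um: tuple[float, float]
    merged_with: int | None = None


def _draw(dist: Mapping, rng: np.random.Generator, lo: float | None = None) -> float:
    kind = dist["kind"]
    if kind == "lognormal":
        v = float(np.exp(rng.normal(np.log(dist["median"]), dist["sigma"])))
    elif kind == "normal":
        v = float(rng.normal(dist["mean"], dist["sd"]))
    elif kind == "fixed":
        v = float(dist["value"])
    else:
        raise ValueError(f"unknown distribution kind {kind!r}")
    if lo is not None and kind != "fixed":
        while v < lo:
            v = _draw(dist, rng)
    return v


def _raster_ellipse(
    occ_shape: tuple[int, int],
    center_px: tuple[float, float],
    a_px: float,
    b_px: float,
    angle_deg: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of pixels whose centers fall inside the rotated
    ellipse.  y-up angle convention; rows increase downward."""
    n_rows, n_cols = occ_shape
    cx, cy = center_px  # (col, row) in px
    hx = abs(a_px * np.cos(np.radians(angle_deg))) + abs(
        b_px * np.sin(np.radians(angle_deg))
    )
    hy = abs(a_px * np.sin(np.radians(angle_deg))) + abs(
        b_px * np.cos(np.radians(angle_deg))
    )
    r0 = max(0, int(np.floor(cy - hy - 1)))
    r1 = min(n_rows, int(np.ceil(cy + hy + 2)))
    c0 = max(0, int(np.floor(cx - hx - 1)))
    c1 = min(n_cols, int(np.ceil(cx + hx + 2)))
    if r1 <= r0 or c1 <= c0:
        return np.empty(0, int), np.empty(0, int)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dx = cc + 0.5 - cx
    dy = -(rr + 0.5 - cy)  # flip to y-up
    th = np.radians(angle_deg)
    u = dx * np.cos(th) + dy * np.sin(th)
    v = -dx * np.sin(th) + dy * np.cos(th)
    inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    return rr[inside], cc[inside]


def generate_crack_mask(
    spec: CrackPopulationSpec, seed: int = 0, max_tries: int = 500
) -> tuple[BinaryMask, list[CrackTruth]]:
    """Rasterize a crack population into a binary mask.

    Cracks are filled ellipses placed without touching each other
    (8-neighbourhood separation), except that with probability
    ``merge_prob`` a crack is chained end-to-end onto a previously placed
    one along its major axis, forming a single merged component — the
    longitudinal crack-merging mode seen late in degradation.
    """
    rng = np.random.default_rng(seed)
    w_um, h_um = spec.field_size
    n_cols = int(round(w_um / spec.pixel_size))
    n_rows = int(round(h_um / spec.pixel_size))
    occ = np.zeros((n_rows, n_cols), dtype=bool)
    truths: list[CrackTruth] = []
    if spec.n_cracks == 0:
        return BinaryMask(occ.astype(np.uint8), spec.pixel_size), truths

    for i in range(spec.n_cracks):
        length = _draw(spec.length_dist, rng, lo=2 * spec.pixel_size)
        aspect = max(1.0, _draw(spec.aspect_dist, rng, lo=1.0))
        angle = _draw(spec.angle_dist, rng) % 180.0
        if length >= min(w_um, h_um):
            raise ValueError(
                f"drawn crack length {length:.1f} um does not fit in the "
                f"{w_um} x {h_um} um field"
            )
        if length / spec.pixel_size < 5:
            warnings.warn(
                f"crack of {length:.2f} um spans fewer than 5 pixels at "
                f"pixel size {spec.pixel_size} um",
                stacklevel=2,
            )
        a_px = length / 2 / spec.pixel_size
        b_px = max(0.55, a_px / aspect)  # keep at least ~1 px of thickness
        th = np.radians(angle)
        hx = abs(a_px * np.cos(th)) + abs(b_px * np.sin(th))
        hy = abs(a_px * np.sin(th)) + abs(b_px * np.cos(th))
        if 2 * hx >= n_cols - 2 or 2 * hy >= n_rows - 2:
            raise ValueError(
                f"crack bounding box ({2*hx:.0f} x {2*hy:.0f} px) does not "
                f"fit in the {n_cols} x {n_rows} px field"
            )

        merge_target: int | None = None
        if truths and rng.random() < spec.merge_prob:
            merge_target = int(rng.integers(0, len(truths)))

        placed = False
        for _ in range(max_tries):
            if merge_target is not None:
                t = truths[merge_target]
                ta = np.radians(t.angle_deg)
                # continue along the partner's major axis, overlapping ~1 px
                sign = rng.choice([-1.0, 1.0])
                step = (
                    t.length_um / 2 + length / 2 - 1.5 * spec.pixel_size
                ) * sign
                cx_um = t.center_um[0] + step * np.cos(ta)
                cy_um = t.center_um[1] + step * np.sin(ta)
                angle = t.angle_deg
                th = np.radians(angle)
                cx = cx_um / spec.pixel_size
                cy = n_rows - cy_um / spec.pixel_size
            else:
                cx = rng.uniform(hx + 1, n_cols - hx - 1)
                cy = rng.uniform(hy + 1, n_rows - hy - 1)
                cx_um = cx * spec.pixel_size
                cy_um = (n_rows - cy) * spec.pixel_size
            rr, cc = _raster_ellipse((n_rows, n_cols), (cx, cy), a_px, b_px, angle)
            if rr.size == 0:
                continue
            if merge_target is None:
                # candidate plus 1-px halo must be free of existing cracks
                r0, r1 = rr.min(), rr.max() + 1
                c0, c1 = cc.min(), cc.max() + 1
                cand = np.zeros((r1 - r0 + 2, c1 - c0 + 2), dtype=bool)
                cand[rr - r0 + 1, cc - c0 + 1] = True
                halo = cand.copy()
                halo[1:, :] |= cand[:-1, :]
                halo[:-1, :] |= cand[1:, :]
                halo[:, 1:] |= cand[:, :-1]
                halo[:, :-1] |= cand[:, 1:]
                halo[1:, 1:] |= cand[:-1, :-1]
                halo[:-1, :-1] |= cand[1:, 1:]
                halo[1:, :-1] |= cand[:-1, 1:]
                halo[:-1, 1:] |= cand[1:, :-1]
                rs = slice(max(0, r0 - 1), min(n_rows, r1 + 1))
                cs = slice(max(0, c0 - 1), min(n_cols, c1 + 1))
                hr0 = rs.start - (r0 - 1)
                hc0 = cs.start - (c0 - 1)
                window = halo[
                    hr0 : hr0 + (rs.stop - rs.start),
                    hc0 : hc0 + (cs.stop - cs.start),
                ]
                if np.any(occ[rs, cs] & window):
                    continue
            occ[rr, cc] = True
            truths.append(
                CrackTruth(
                    index=i,
                    length_um=length,
                    aspect=aspect,
                    angle_deg=angle,
                    center_um=(float(cx_um), float(cy_um)),
                    merged_with=merge_target,
                )
            )
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place crack {i} after {max_tries} tries: "
                "field too small or too crowded for the requested population"
            )
    return BinaryMask(occ.astype(np.uint8), spec.pixel_size), truths


def table2_crack_spec(
    week: int, n_cracks: int = 200, field_scale: float | None = None
) -> CrackPopulationSpec:
    """Crack population emulating the published per-period morphology.

    Major-axis lengths are lognormal with the published median Feret
    diameter (sigma 0.6), orientations normal with the published
    mean +- SD (wrapped to [0, 180)), aspect ratios lognormal with the
    published median.  The field is enlarged relative to the 84 x 63 um
    imaging field when needed so the requested number of cracks can be
    placed without overlap (``field_scale`` defaults to 1, 1, 2 for
    weeks 8, 16, 24).
    """
    params = {
        8: {"len_med": 0.85, "angle": (87.3, 28.5), "ar_med": 3.61, "scale": 1.0},
        16: {"len_med": 1.87, "angle": (89.6, 27.0), "ar_med": 3.45, "scale": 1.0},
        24: {"len_med": 5.21, "angle": (89.0, 19.1), "ar_med": 5.48, "scale": 2.0},
    }
    if week not in params:
        raise ValueError(f"cracks are observed at weeks 8, 16, 24; got {week}")
    p = params[week]
    scale = p["scale"] if field_scale is None else field_scale
    return CrackPopulationSpec(
        n_cracks=n_cracks,
        length_dist={"kind": "lognormal", "median": p["len_med"], "sigma": 0.6},
        aspect_dist={"kind": "lognormal", "median": p["ar_med"], "sigma": 0.3},
        angle_dist={"kind": "normal", "mean": p["angle"][0], "sd": p["angle"][1]},
        merge_prob=0.0,
        pixel_size=0.066,
        field_size=(84.0 * scale, 63.0 * scale),
    )


# ---------------------------------------------------------------------------
# thermograms
# ---------------------------------------------------------------------------


def generate_thermogram(
    crystallinity_pct: float,
    dH_ref: float = 141.0,
    melt_center: float = 105.0,
    melt_fwhm: float = 8.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    temp_range: tuple[float, float, float] = (-30.0, 150.0, 0.1),
    scan_rate: float = 5.0,
    baseline_offset: float = 0.0,
    baseline_slope: float = 0.0,
) -> Thermogram:
    """Gaussian melting endotherm whose integrated specific enthalpy is
    ``crystallinity_pct/100 * dH_ref`` (J/g), on a flat or gently sloped
    instrumental baseline, endo-up convention."""
    if not 0 <= crystallinity_pct <= 100:
        raise ValueError("crystallinity_pct must be in [0, 100]")
    if dH_ref <= 0:
        raise ValueError("dH_ref must be positive")
    lo, hi, step = temp_range
    if not (lo + 3 * melt_fwhm <= melt_center <= hi - 3 * melt_fwhm):
        raise ValueError("melting peak must lie fully inside the scan range")
    t = np.arange(lo, hi + step / 2, step)
    sigma = melt_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    delta_H = crystallinity_pct / 100.0 * dH_ref
    rate_c_per_s = scan_rate / 60.0
    amp = delta_H * rate_c_per_s / (sigma * np.sqrt(2.0 * np.pi))
    q = baseline_offset + baseline_slope * (t - lo)
    q = q + amp * np.exp(-((t - melt_center) ** 2) / (2 * sigma**2))
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd > 0:
        q = q + np.random.default_rng(seed).normal(0.0, noise_sd, size=t.size)
    return Thermogram(
        temperature=t,
        heat_flow=q,
        scan_rate=scan_rate,
        endo_up=True,
        meta={"true_crystallinity_pct": crystallinity_pct, "dH_ref": dH_ref},
    )
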