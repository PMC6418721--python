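"""Seeded generators emulating trough recordings: lipid, polymer and mixed
isotherms, adsorption traces, and domain micrographs, each returned with a
ground-truth record sufficient to score downstream analyses.

The liquid-expanded branch follows a Volmer equation of state
``Π = kT/(A − ω) − Π_coh`` (kT expressed in Å²·mN/m), joined to a gently
sloped LE-LC plateau and a steep condensed branch.  Polymer films go from
a large pancake area through a brush regime and a sigmoidal squeeze-out to
a small residual area.  These functional forms are modelling choices of
this package, tuned so the default presets reproduce the landmark values
of the emulated system (lift-off near 110 Å²/molecule, transition onset
near 9 mN/m, exclusion pressures of 32.5 and 42.4 mN/m).

Every generator is a pure function of (parameters, seed): identical inputs
give bitwise-identical outputs.  No global random state is touched.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .adsorption import AdsorptionTrace
from .errors import PackingError, PressureOutOfRangeError, SimulationParameterError
from .imaging import Micrograph
from .isotherm import PER_LIPID, IsothermCurve, area_at_pressure, monotonize
from .mixing import MixtureSpec

#: Boltzmann constant in Å²·mN/m per kelvin (1 Å²·mN/m = 1e-23 J).
BOLTZMANN_A2_MN_PER_M = 1.380649

#: Pressure level of the faint gas-phase tail, mN/m.  Kept strictly
#: positive (and well under the 0.5 mN/m lift-off threshold) so noiseless
#: curves are strictly monotone and survive monotonize() unchanged.
GAS_TAIL_LEVEL = 0.05


def thermal_energy(temperature_c: float) -> float:
    """kT in Å²·mN/m at the given temperature in °C (404.7 at 20 °C)."""
    return BOLTZMANN_A2_MN_PER_M * (temperature_c + 273.15)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually produced, for scoring analyses."""

    generator: str
    params: dict
    truth: dict


# ---------------------------------------------------------------------------
# lipid isotherms


@dataclass(frozen=True)
class LipidEoSParams:
    """Piecewise equation-of-state parameters for a phospholipid isotherm.

    omega: excluded area (Å²); pi_coh: cohesion offset of the Volmer
    branch (mN/m); transition_pressure: plateau onset Π_t (mN/m);
    plateau_slope: small positive dΠ/d(−A) on the plateau so A(Π) stays
    invertible; lc_slope: steep condensed-branch slope; lc_onset_area:
    area where the condensed branch begins; collapse_pressure: where the
    generated curve ends.
    """

    omega: float = 40.0
    pi_coh: float = 5.0
    temperature: float = 20.0
    transition_pressure: float = 9.0
    plateau_slope: float = 0.02
    lc_slope: float = 3.0
    lc_onset_area: float = 50.0
    collapse_pressure: float = 55.0

    def __post_init__(self):
        if self.omega <= 0 or self.pi_coh <= 0:
            raise SimulationParameterError("omega and pi_coh must be positive")
        if not 0 < self.plateau_slope < self.lc_slope:
            raise SimulationParameterError(
                "need 0 < plateau_slope < lc_slope"
            )
        if self.transition_pressure >= self.collapse_pressure:
            raise SimulationParameterError(
                "transition pressure must be below collapse pressure"
            )

    @property
    def kt(self) -> float:
        return thermal_energy(self.temperature)

    @property
    def zero_pressure_area(self) -> float:
        """Area where the Volmer branch crosses Π = 0."""
        return self.omega + self.kt / self.pi_coh

    @property
    def transition_onset_area(self) -> float:
        return self.omega + self.kt / (self.pi_coh + self.transition_pressure)

    @property
    def plateau_end_pressure(self) -> float:
        return self.transition_pressure + self.plateau_slope * (
            self.transition_onset_area - self.lc_onset_area
        )

    @property
    def collapse_area(self) -> float:
        return self.lc_onset_area - (
            self.collapse_pressure - self.plateau_end_pressure
        ) / self.lc_slope

    def lift_off_area(self, threshold: float = 0.5) -> float:
        """Closed-form area where the Volmer branch reaches ``threshold``."""
        return self.omega + self.kt / (self.pi_coh + threshold)

    def pressure_of_area(self, areas: np.ndarray) -> np.ndarray:
        """Noiseless piecewise Π(A) over the full construction."""
        a = np.asarray(areas, dtype=float)
        a_tail = self.omega + self.kt / (self.pi_coh + GAS_TAIL_LEVEL)
        a_max = 1.15 * self.zero_pressure_area
        a_t = self.transition_onset_area
        pi = np.empty_like(a)
        tail = a >= a_tail
        pi[tail] = GAS_TAIL_LEVEL * (a_max - a[tail]) / (a_max - a_tail)
        volmer = (a < a_tail) & (a >= a_t)
        pi[volmer] = self.kt / (a[volmer] - self.omega) - self.pi_coh
        plateau = (a < a_t) & (a >= self.lc_onset_area)
        pi[plateau] = self.transition_pressure + self.plateau_slope * (
            a_t - a[plateau]
        )
        lc = a < self.lc_onset_area
        pi[lc] = self.plateau_end_pressure + self.lc_slope * (
            self.lc_onset_area - a[lc]
        )
        return pi

    def validate_construction(self) -> None:
        a_t = self.transition_onset_area
        if not (self.omega < self.lc_onset_area < a_t < self.zero_pressure_area):
            raise SimulationParameterError(
                "branch junctions out of order: need "
                "omega < lc_onset_area < transition area < zero-pressure area"
            )
        if self.collapse_pressure <= self.plateau_end_pressure:
            raise SimulationParameterError(
                "collapse pressure must exceed the plateau end pressure"
            )
        if self.collapse_area <= 0:
            raise SimulationParameterError("collapse area is non-positive")


def fdppc_like_params(
    lift_off_area: float = 110.0,
    lift_off_threshold: float = 0.5,
    omega: float = 40.0,
    temperature: float = 20.0,
    **overrides,
) -> LipidEoSParams:
    """Fluorinated-DPPC-like preset: pi_coh solved so the Volmer branch
    reaches ``lift_off_threshold`` exactly at ``lift_off_area``."""
    kt = thermal_energy(temperature)
    pi_coh = kt / (lift_off_area - omega) - lift_off_threshold
    return LipidEoSParams(
        omega=omega, pi_coh=pi_coh, temperature=temperature, **overrides
    )


def simulate_lipid_isotherm(
    params: LipidEoSParams,
    n_points: int = 400,
    noise_sd_pressure: float = 0.0,
    seed: int | None = None,
) -> tuple[IsothermCurve, GroundTruth]:
    """Generate one lipid compression isotherm plus its ground truth."""
    if n_points < 2:
        raise SimulationParameterError("need at least 2 points")
    if noise_sd_pressure > 0 and seed is None:
        raise SimulationParameterError("a seed is required when noise_sd > 0")
    params.validate_construction()
    a_max = 1.15 * params.zero_pressure_area
    areas = np.linspace(a_max, params.collapse_area, n_points)
    pressures = params.pressure_of_area(areas)
    if (np.diff(pressures) <= 0).any():
        raise SimulationParameterError("constructed pressures are not monotone")
    if noise_sd_pressure > 0:
        rng = np.random.default_rng(seed)
        pressures = pressures + rng.normal(0.0, noise_sd_pressure, n_points)
        pressures = np.maximum(pressures, -0.49)
    curve = IsothermCurve(
        areas=areas,
        pressures=pressures,
        convention="per_molecule",
        temperature=params.temperature,
        label="simulated lipid",
    )
    truth = GroundTruth(
        generator="simulate_lipid_isotherm",
        params={**dataclasses.asdict(params), "n_points": n_points,
                "noise_sd_pressure": noise_sd_pressure, "seed": seed},
        truth={
            "lift_off_area": params.lift_off_area(0.5),
            "transition_pressure": params.transition_pressure,
            "transition_onset_area": params.transition_onset_area,
            "plateau_end_pressure": params.plateau_end_pressure,
            "collapse_pressure": params.collapse_pressure,
        },
    )
    return curve, truth


# ---------------------------------------------------------------------------
# polymer isotherms


@dataclass(frozen=True)
class PolymerFilmParams:
    """Pancake -> brush -> squeeze-out construction for a polymer film.

    The area per molecule decays from ``pancake_area`` as
    ``pancake_area / (1 + Π/brush_transition_pressure)²`` and is driven to
    ``residual_area`` by a logistic squeeze-out centred at
    ``squeeze_out_pressure`` with width ``squeeze_width``.
    """

    pancake_area: float = 1500.0
    brush_transition_pressure: float = 8.0
    squeeze_out_pressure: float = 32.5
    squeeze_width: float = 0.5
    residual_area: float = 4.0

    def __post_init__(self):
        if min(self.pancake_area, self.brush_transition_pressure,
               self.squeeze_out_pressure, self.squeeze_width,
               self.residual_area) <= 0:
            raise SimulationParameterError("all parameters must be positive")
        if self.pancake_area <= 5 * self.residual_area:
            raise SimulationParameterError(
                "pancake_area must be much larger than residual_area"
            )
        if self.squeeze_out_pressure <= self.brush_transition_pressure:
            raise SimulationParameterError(
                "squeeze-out must occur above the brush transition"
            )

    def area_of_pressure(self, pressures: np.ndarray) -> np.ndarray:
        p = np.asarray(pressures, dtype=float)
        brush = self.pancake_area / (1.0 + p / self.brush_transition_pressure) ** 2
        keep = 1.0 / (1.0 + np.exp(-(self.squeeze_out_pressure - p) / self.squeeze_width))
        return self.residual_area + (brush - self.residual_area) * keep

    def retained_fraction(self, pressures: np.ndarray) -> np.ndarray:
        """Logistic squeeze profile f_keep(Π) in [0, 1]."""
        p = np.asarray(pressures, dtype=float)
        return 1.0 / (1.0 + np.exp(-(self.squeeze_out_pressure - p) / self.squeeze_width))


def gp_like_params(**overrides) -> PolymerFilmParams:
    """Plain triblock-copolymer preset (exclusion pressure 32.5 mN/m)."""
    defaults = dict(pancake_area=1500.0, brush_transition_pressure=8.0,
                    squeeze_out_pressure=32.5, squeeze_width=0.5,
                    residual_area=4.0)
    defaults.update(overrides)
    return PolymerFilmParams(**defaults)


def fgp_like_params(**overrides) -> PolymerFilmParams:
    """Perfluoro-capped copolymer preset (exclusion pressure 42.4 mN/m)."""
    defaults = dict(pancake_area=1600.0, brush_transition_pressure=8.0,
                    squeeze_out_pressure=42.4, squeeze_width=0.5,
                    residual_area=4.0)
    defaults.update(overrides)
    return PolymerFilmParams(**defaults)


def simulate_polymer_isotherm(
    params: PolymerFilmParams,
    n_points: int = 300,
    noise_sd_pressure: float = 0.0,
    seed: int | None = None,
    max_pressure: float | None = None,
) -> tuple[IsothermCurve, GroundTruth]:
    """Generate one polymer compression isotherm plus its ground truth."""
    if n_points < 2:
        raise SimulationParameterError("need at least 2 points")
    if noise_sd_pressure > 0 and seed is None:
        raise SimulationParameterError("a seed is required when noise_sd > 0")
    if max_pressure is None:
        max_pressure = params.squeeze_out_pressure + 10 * params.squeeze_width
    pressures = np.linspace(0.0, max_pressure, n_points)
    areas = params.area_of_pressure(pressures)
    if (np.diff(areas) >= 0).any():
        raise SimulationParameterError("constructed areas are not monotone")
    if noise_sd_pressure > 0:
        rng = np.random.default_rng(seed)
        pressures = pressures + rng.normal(0.0, noise_sd_pressure, n_points)
        pressures = np.maximum(pressures, -0.49)
    curve = IsothermCurve(
        areas=areas,
        pressures=pressures,
        convention="per_molecule",
        label="simulated polymer",
    )
    truth = GroundTruth(
        generator="simulate_polymer_isotherm",
        params={**dataclasses.asdict(params), "n_points": n_points,
                "noise_sd_pressure": noise_sd_pressure, "seed": seed,
                "max_pressure": max_pressure},
        truth={
            "squeeze_out_pressure": params.squeeze_out_pressure,
            "pancake_area": params.pancake_area,
            "residual_area": params.residual_area,
        },
    )
    return curve, truth


# ---------------------------------------------------------------------------
# mixed films


def gaussian_excess(amplitude: float, center: float, width: float) -> Callable:
    """Excess-area profile E(Π): a Gaussian bump (amplitude in Å²/lipid)."""

    def profile(p):
        p = np.asarray(p, dtype=float)
        return amplitude * np.exp(-((p - center) ** 2) / (2.0 * width**2))

    profile.description = {
        "shape": "gaussian", "amplitude": amplitude,
        "center": center, "width": width,
    }
    return profile


def simulate_mixed_isotherm(
    lipid: IsothermCurve,
    polymer: IsothermCurve,
    mix: MixtureSpec,
    excess_profile: Callable | None = None,
    n_points: int = 300,
    noise_sd_pressure: float = 0.0,
    seed: int | None = None,
) -> tuple[IsothermCurve, GroundTruth]:
    """Generate a per-lipid mixed-film isotherm from pure-component curves.

    A_mix_per_lipid(Π) = A_lipid(Π) + (x_p/x_l)·A_polymer(Π) + E(Π); the
    polymer term already carries the squeeze-out, so the mixture converges
    to the pure lipid (up to the tiny residual term) above the polymer's
    squeeze-out pressure.
    """
    if noise_sd_pressure > 0 and seed is None:
        raise SimulationParameterError("a seed is required when noise_sd > 0")
    lipid = monotonize(lipid)
    polymer = monotonize(polymer)
    lo = max(lipid.pressures[0], polymer.pressures[0])
    hi = min(lipid.pressures[-1], polymer.pressures[-1])
    if lo >= hi:
        raise PressureOutOfRangeError("pure curves share no pressure range")
    grid = np.linspace(lo, hi, n_points)
    r = mix.x_polymer / mix.x_lipid
    a_lip = area_at_pressure(lipid, grid)
    a_pol = area_at_pressure(polymer, grid)
    excess = excess_profile(grid) if excess_profile is not None else np.zeros_like(grid)
    areas = a_lip + r * a_pol + excess
    pressures = grid.copy()
    if noise_sd_pressure > 0:
        rng = np.random.default_rng(seed)
        pressures = pressures + rng.normal(0.0, noise_sd_pressure, n_points)
        pressures = np.maximum(pressures, -0.49)
    # compression order: decreasing area
    curve = IsothermCurve(
        areas=areas[::-1],
        pressures=pressures[::-1],
        convention=PER_LIPID,
        temperature=lipid.temperature,
        label=f"simulated mixture {mix.ratio_label}",
    )
    truth = GroundTruth(
        generator="simulate_mixed_isotherm",
        params={
            "lipid_to_polymer": [mix.lipid_count, mix.polymer_count],
            "n_points": n_points, "noise_sd_pressure": noise_sd_pressure,
            "seed": seed,
            "excess": getattr(excess_profile, "description", None)
            if excess_profile is not None else None,
        },
        truth={
            "pressure_grid": grid,
            "excess_profile": excess,
            "polymer_term_per_lipid": r * a_pol,
            "ideal_per_lipid": a_lip + r * a_pol,
            "polymer_to_lipid_ratio": r,
        },
    )
    return curve, truth


# ---------------------------------------------------------------------------
# adsorption traces


def simulate_adsorption_trace(
    pi_ini: float,
    exclusion_pressure: float,
    slope_magnitude: float = 0.5,
    tau_fast: float = 30.0,
    tau_slow: float = 600.0,
    fast_share: float = 0.5,
    noise_sd: float = 0.0,
    duration: float = 2000.0,
    n_points: int = 200,
    seed: int | None = None,
) -> tuple[AdsorptionTrace, GroundTruth]:
    """Two-regime adsorption trace with a linear ΔΠ_eq(Π_ini) law.

    ΔΠ_eq = max(0, slope_magnitude·(exclusion_pressure − pi_ini)), split
    into a fast and a slow first-order component.  Above the exclusion
    pressure the trace is flat at pi_ini (plus noise).
    """
    if min(pi_ini, exclusion_pressure, slope_magnitude, tau_fast, tau_slow,
           noise_sd, duration) < 0 or pi_ini < 0:
        raise ValueError("negative parameters are not allowed")
    if not 0.0 <= fast_share <= 1.0:
        raise ValueError("fast_share must lie in [0, 1]")
    if tau_fast >= tau_slow:
        raise ValueError("tau_fast must be smaller than tau_slow")
    if noise_sd > 0 and seed is None:
        raise ValueError("a seed is required when noise_sd > 0")
    delta_eq = max(0.0, slope_magnitude * (exclusion_pressure - pi_ini))
    t = np.linspace(0.0, duration, n_points)
    rise = fast_share * (1.0 - np.exp(-t / tau_fast)) + (1.0 - fast_share) * (
        1.0 - np.exp(-t / tau_slow)
    )
    p = pi_ini + delta_eq * rise
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        p = p + rng.normal(0.0, noise_sd, n_points)
    trace = AdsorptionTrace(
        times=t, pressures=p, pi_ini=pi_ini,
        label=f"simulated adsorption pi_ini={pi_ini:g}",
    )
    truth = GroundTruth(
        generator="simulate_adsorption_trace",
        params={
            "pi_ini": pi_ini, "exclusion_pressure": exclusion_pressure,
            "slope_magnitude": slope_magnitude, "tau_fast": tau_fast,
            "tau_slow": tau_slow, "fast_share": fast_share,
            "noise_sd": noise_sd, "duration": duration,
            "n_points": n_points, "seed": seed,
        },
        truth={
            "delta_pi_eq": delta_eq,
            "tau_fast": tau_fast,
            "tau_slow": tau_slow,
            "exclusion_pressure": exclusion_pressure,
        },
    )
    return trace, truth


# ---------------------------------------------------------------------------
# micrographs


def _domain_shapes(n: int, rng: np.random.Generator, irregularity: float):
    """Per-domain ellipse ratio, orientation, and harmonic perturbation."""
    shapes = []
    for _ in range(n):
        q = rng.uniform(0.85, 1.0)
        phi0 = rng.uniform(0, 2 * np.pi)
        k = np.array([2, 3, 4])
        weights = rng.dirichlet(np.ones(3))
        amps = irregularity * weights
        phases = rng.uniform(0, 2 * np.pi, 3)
        shapes.append((q, phi0, k, amps, phases))
    return shapes


def _raster_mask(
    width: int, height: int, centers, rmax, shapes, scale: float
) -> np.ndarray:
    mask = np.zeros((height, width), dtype=bool)
    for (cx, cy), rm, (q, phi0, k, amps, phases) in zip(centers, rmax, shapes):
        reach = int(np.ceil(scale * rm)) + 1
        x0, x1 = max(0, int(cx) - reach), min(width, int(cx) + reach + 1)
        y0, y1 = max(0, int(cy) - reach), min(height, int(cy) + reach + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dx = xx - cx
        dy = yy - cy
        u = np.cos(phi0) * dx + np.sin(phi0) * dy
        v = -np.sin(phi0) * dx + np.cos(phi0) * dy
        rr = np.hypot(u, v)
        theta = np.arctan2(v, u)
        ellipse = q / np.sqrt(q**2 * np.cos(theta) ** 2 + np.sin(theta) ** 2)
        harmonic = 1.0 + sum(
            a * np.cos(kk * theta + ph) for kk, a, ph in zip(k, amps, phases)
        )
        radial = np.clip(harmonic, 0.5, 1.0) * ellipse
        mask[y0:y1, x0:x1] |= rr <= scale * rm * radial
    return mask


def simulate_micrograph(
    width: int = 256,
    height: int = 256,
    target_phi: float = 0.5,
    n_domains: int = 16,
    shape_irregularity: float = 0.15,
    contrast: float = 180.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    background: float = 200.0,
    phi_tolerance: float = 0.005,
) -> tuple[Micrograph, GroundTruth]:
    """Binary-contrast micrograph with dark domains of known area fraction.

    Non-overlapping harmonically perturbed elliptical domains are placed
    on a jittered grid and scaled by bisection until the realized mask
    fraction is within ``phi_tolerance`` of ``target_phi`` (the realized
    value is recorded exactly in the ground truth).
    """
    if not 0.0 <= target_phi <= 0.9:
        raise ValueError("target_phi must lie in [0, 0.9]")
    if n_domains < 0:
        raise ValueError("n_domains must be non-negative")
    if noise_sd > 0 and seed is None:
        raise ValueError("a seed is required when noise_sd > 0")
    rng = np.random.default_rng(seed)

    if target_phi <= phi_tolerance or n_domains == 0:
        if target_phi > phi_tolerance:
            raise PackingError("cannot reach a positive phi with 0 domains")
        mask = np.zeros((height, width), dtype=bool)
        centers = []
    else:
        g = int(np.ceil(np.sqrt(n_domains)))
        cell_w, cell_h = width / g, height / g
        cells = rng.permutation(g * g)[:n_domains]
        centers = []
        for c in cells:
            ci, cj = divmod(int(c), g)
            jx = rng.uniform(-0.02, 0.02) * cell_w
            jy = rng.uniform(-0.02, 0.02) * cell_h
            centers.append(((cj + 0.5) * cell_w + jx, (ci + 0.5) * cell_h + jy))
        rmax = [0.47 * min(cell_w, cell_h)] * n_domains
        shapes = _domain_shapes(n_domains, rng, shape_irregularity)

        def phi_of(scale: float) -> tuple[float, np.ndarray]:
            m = _raster_mask(width, height, centers, rmax, shapes, scale)
            return m.mean(), m

        phi_hi, mask = phi_of(1.0)
        if phi_hi < target_phi - phi_tolerance:
            raise PackingError(
                f"max attainable phi {phi_hi:.3f} with {n_domains} "
                f"non-overlapping domains is below target {target_phi:.3f}"
            )
        lo_s, hi_s = 0.0, 1.0
        for _ in range(50):
            mid = 0.5 * (lo_s + hi_s)
            phi_mid, m = phi_of(mid)
            if abs(phi_mid - target_phi) <= phi_tolerance:
                mask = m
                break
            if phi_mid < target_phi:
                lo_s = mid
            else:
                hi_s = mid
        else:
            raise PackingError("bisection failed to reach the target phi")

    image = np.full((height, width), background, dtype=float)
    image[mask] = background - contrast
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, image.shape)
        image = np.clip(image, 0.0, None)
    micrograph = Micrograph(intensities=image, label="simulated micrograph")
    truth = GroundTruth(
        generator="simulate_micrograph",
        params={
            "width": width, "height": height, "target_phi": target_phi,
            "n_domains": n_domains, "shape_irregularity": shape_irregularity,
            "contrast": contrast, "noise_sd": noise_sd, "seed": seed,
            "background": background,
        },
        truth={
            "mask": mask,
            "phi": float(mask.mean()),
            "n_domains_placed": len(centers),
        },
    )
    return micrograph, truth


# ---------------------------------------------------------------------------
# preset registry

LIPID_PRESETS = {"fdppc_like": fdppc_like_params}
POLYMER_PRESETS = {"gp_like": gp_like_params, "fgp_like": fgp_like_params}


def isotherm_preset(name: str):
    """Look up a named preset; returns ('lipid'|'polymer', params)."""
    if name in LIPID_PRESETS:
        return "lipid", LIPID_PRESETS[name]()
    if name in POLYMER_PRESETS:
        return "polymer", POLYMER_PRESETS[name]()
    known = sorted(LIPID_PRESETS) + sorted(POLYMER_PRESETS)
    raise KeyError(f"unknown preset {name!r}; known presets: {known}")
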