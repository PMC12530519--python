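"""Sedimentation-equilibrium forward model and global self-association fitting.

At sedimentation equilibrium the concentration of an ideal species of molar
mass M follows a single exponential in r^2,

    c(r) = c(r_ref) * exp[ sigma * (r^2 - r_ref^2) / 2 ],
    sigma = M * (1 - vbar*rho) * omega^2 / (R*T)      [cm^-2],

and for a self-associating monomer-dimer-tetramer system mass action links
the species at every radius: c2 = c1^2/Kd12, c4 = c2^2/Kd24, with the n-mer
reduced buoyant coefficient n*sigma_1.  Because the n-mer exponential is the
n-th power of the monomer exponential, chemical equilibrium established at
the reference radius holds at all radii.

Global fitting shares Kd12 and Kd24 across speeds, loadings and detectors
(absorbance and Rayleigh interference).  By default one loading
concentration is floated per cell and the meniscus concentration of every
speed column follows from mass conservation over the solution column;
baselines are shared per cell and optical system.  Fully local
per-column parameterization is available for data where conservation
cannot be assumed.  Kd values are optimised as log10 to enforce
positivity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

#: gas constant in CGS units, erg mol^-1 K^-1 (matches cm/g/s profile units)
R_GAS_CGS = 8.31446e7

#: laser wavelength of the interference optics, cm (675 nm)
INTERFERENCE_WAVELENGTH_CM = 675e-7


@dataclass
class AssociationModel:
    """Physical constants of a monomer-dimer-tetramer self-association.

    kd12 and kd24 are molar dissociation constants (c1^2/c2 and c2^2/c4);
    ``numpy.inf`` disables the corresponding species.  vbar is the partial
    specific volume (mL/g), rho the solvent density (g/mL); their product
    must stay below 1 (the protein sediments rather than floats).
    """

    monomer_mass: float  # Da
    vbar: float = 0.73  # mL/g
    rho: float = 1.005  # g/mL
    epsilon_280: float = 9970.0  # M^-1 cm^-1 per monomer
    dndc: float = 0.185  # mL/g
    kd12: float = np.inf  # M
    kd24: float = np.inf  # M
    temperature: float = 293.0  # K

    def __post_init__(self) -> None:
        if self.monomer_mass <= 0:
            raise ValueError("monomer mass must be positive")
        if not 0 < self.vbar * self.rho < 1:
            raise ValueError("vbar*rho must lie in (0, 1): floating species unsupported")
        if self.kd12 <= 0 or self.kd24 <= 0:
            raise ValueError("dissociation constants must be positive (inf allowed)")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class EquilibriumProfile:
    """One radial equilibrium scan: signal versus radius at a single speed."""

    radius: np.ndarray  # cm, strictly increasing
    signal: np.ndarray
    speed: float  # rpm
    detector: str = "absorbance"  # or "interference"
    cell_id: str = "cell1"
    pathlength: float = 1.2  # cm
    loading_uM: float | None = None

    def __post_init__(self) -> None:
        self.radius = np.asarray(self.radius, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(np.diff(self.radius) <= 0):
            raise ValueError("radius must be strictly increasing")
        if self.radius.shape != self.signal.shape:
            raise ValueError("radius and signal must have the same shape")
        if self.speed <= 0:
            raise ValueError("rotor speed must be positive")
        if self.detector not in ("absorbance", "interference"):
            raise ValueError("detector must be 'absorbance' or 'interference'")


@dataclass
class GlobalFitResult:
    """Shared dissociation constants plus per-column nuisance parameters."""

    kd12_hat: float  # M
    kd24_hat: float  # M
    c_refs: dict  # (cell_id, speed) -> monomer reference concentration, M
    baselines: list  # per profile, signal units
    reduced_chi2: float
    n_obs: int
    n_params: int
    success: bool
    message: str = ""
    detector_weights: dict | None = None
    loadings: dict | None = None  # per-cell loading (M) when conserved


def reduced_buoyant_coefficient(model: AssociationModel, speed_rpm: float) -> float:
    """Monomer reduced buoyant coefficient sigma = M(1-vbar rho)omega^2/RT, cm^-2.

    The n-mer coefficient is n times the monomer value.
    """
    if speed_rpm < 0:
        raise ValueError("speed must be non-negative")
    omega = 2.0 * np.pi * speed_rpm / 60.0
    return (
        model.monomer_mass
        * (1.0 - model.vbar * model.rho)
        * omega**2
        / (R_GAS_CGS * model.temperature)
    )


def signal_coefficient(
    model: AssociationModel, detector: str, pathlength: float = 1.2
) -> float:
    """Signal per molar monomer-equivalent concentration for a detector.

    Absorbance: epsilon_280 * pathlength (AU per M monomer).  Interference:
    dndc * M * pathlength / (1000 * lambda) fringes per M monomer, i.e. the
    fringe shift produced by the mass concentration M*c/1000 g/mL.
    """
    if detector == "absorbance":
        return model.epsilon_280 * pathlength
    if detector == "interference":
        return (
            model.dndc
            * model.monomer_mass
            * pathlength
            / (1000.0 * INTERFERENCE_WAVELENGTH_CM)
        )
    raise ValueError(f"unknown detector {detector!r}")


def species_concentrations(
    model: AssociationModel, c1: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dimer and tetramer concentrations in mass-action equilibrium with c1."""
    c1 = np.asarray(c1, dtype=float)
    c2 = np.zeros_like(c1) if np.isinf(model.kd12) else c1**2 / model.kd12
    c4 = np.zeros_like(c1) if np.isinf(model.kd24) else c2**2 / model.kd24
    return c1, c2, c4


def total_monomer_concentration(
    model: AssociationModel, c1: np.ndarray | float
) -> np.ndarray:
    """Total concentration in monomer units: c1 + 2*c2 + 4*c4."""
    c1, c2, c4 = species_concentrations(model, c1)
    return c1 + 2.0 * c2 + 4.0 * c4


def monomer_radial_distribution(
    model: AssociationModel,
    c1_ref: float,
    radii: np.ndarray,
    speed_rpm: float,
    r_ref: float | None = None,
) -> np.ndarray:
    """Monomer concentration c1(r); exponent evaluated in log space."""
    radii = np.asarray(radii, dtype=float)
    if c1_ref <= 0:
        raise ValueError("reference monomer concentration must be positive")
    if r_ref is None:
        r_ref = radii[0]
    sigma1 = reduced_buoyant_coefficient(model, speed_rpm)
    log_c1 = np.log(c1_ref) + sigma1 * (radii**2 - r_ref**2) / 2.0
    return np.exp(log_c1)


def equilibrium_profile(
    model: AssociationModel,
    c1_ref: float,
    radii: np.ndarray,
    speed_rpm: float,
    detector: str = "absorbance",
    baseline: float = 0.0,
    r_ref: float | None = None,
    pathlength: float = 1.2,
) -> np.ndarray:
    """Noise-free equilibrium signal for the monomer-dimer-tetramer model."""
    c1 = monomer_radial_distribution(model, c1_ref, radii, speed_rpm, r_ref)
    coef = signal_coefficient(model, detector, pathlength)
    return coef * total_monomer_concentration(model, c1) + baseline


def solve_c1_from_total(model: AssociationModel, c_total: float) -> float:
    """Invert c_total = c1 + 2 c1^2/Kd12 + 4 (c1^2/Kd12)^2/Kd24 for c1."""
    if c_total <= 0:
        raise ValueError("total concentration must be positive")

    def g(log_c1: float) -> float:
        return float(total_monomer_concentration(model, np.exp(log_c1))) - c_total

    hi = np.log(c_total)
    lo = hi - 45.0  # generous bracket: monomer fraction >= e^-45
    return float(np.exp(brentq(g, lo, hi, xtol=1e-14)))


def loading_c1_ref(
    model: AssociationModel,
    loading_molar: float,
    radii: np.ndarray,
    speed_rpm: float,
) -> float:
    """Reference (meniscus) monomer concentration conserving the loading.

    Chooses c1 at the meniscus so that the sector-weighted column average of
    the total monomer-equivalent concentration equals ``loading_molar``.
    """
    radii = np.asarray(radii, dtype=float)
    if speed_rpm == 0:
        return solve_c1_from_total(model, loading_molar)
    weights = radii  # sector-shaped cell: volume element proportional to r dr

    def column_average(log_c1_ref: float) -> float:
        c1 = monomer_radial_distribution(model, np.exp(log_c1_ref), radii, speed_rpm)
        ctot = total_monomer_concentration(model, c1)
        return float(np.trapezoid(ctot * weights, radii) / np.trapezoid(weights, radii))

    hi = np.log(loading_molar) + 1.0
    lo = np.log(loading_molar) - 60.0
    f = lambda x: column_average(x) - loading_molar
    return float(np.exp(brentq(f, lo, hi, xtol=1e-13)))


@dataclass
class SingleSpeciesFit:
    """Apparent single-species mass fit of one or more profiles."""

    apparent_mass: float  # Da
    amplitudes: list
    baselines: list
    reduced_chi2: float
    success: bool
    message: str = ""


def fit_single_species(
    profiles: Sequence[EquilibriumProfile],
    model: AssociationModel,
    mass_guess: float | None = None,
) -> SingleSpeciesFit:
    """Fit an ideal single-species model sharing one effective molar mass.

    Each profile gets a free reference amplitude (in signal units) and
    baseline; the shared mass reports the apparent weight-average mass of
    the sedimenting material.  Used as the first-pass diagnostic whose
    concentration-dependent mass reveals self-association.
    """
    if not profiles:
        raise ValueError("at least one profile is required")
    if mass_guess is None:
        mass_guess = model.monomer_mass

    n = len(profiles)

    def residuals(params: np.ndarray) -> np.ndarray:
        mass = 10.0 ** params[0]
        out = []
        for k, p in enumerate(profiles):
            eff = replace(model, monomer_mass=mass, kd12=np.inf, kd24=np.inf)
            sigma = reduced_buoyant_coefficient(eff, p.speed)
            # amplitude folded into the exponent, clipped against overflow
            # when the optimizer probes very large masses
            exponent = params[1 + k] + sigma * (p.radius**2 - p.radius[0] ** 2) / 2.0
            pred = np.exp(np.minimum(exponent, 700.0)) + params[1 + n + k]
            out.append(pred - p.signal)
        return np.concatenate(out)

    x0 = np.concatenate(
        (
            [np.log10(mass_guess)],
            [
                np.log(max(float(p.signal[0]), float(p.signal.max()) / 50.0, 1e-12))
                for p in profiles
            ],
            [0.0 for _ in profiles],
        )
    )
    sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
    n_obs = sum(p.signal.size for p in profiles)
    dof = max(n_obs - sol.x.size, 1)
    return SingleSpeciesFit(
        apparent_mass=float(10.0 ** sol.x[0]),
        amplitudes=[float(np.exp(v)) for v in sol.x[1 : 1 + n]],
        baselines=[float(v) for v in sol.x[1 + n :]],
        reduced_chi2=float(2.0 * sol.cost / dof),
        success=bool(sol.success),
        message=str(sol.message),
    )


def _column_average_total(
    model: AssociationModel, c1_ref: float, radii: np.ndarray, speed: float
) -> float:
    """Sector-weighted column average of the total monomer concentration."""
    c1 = monomer_radial_distribution(model, c1_ref, radii, speed)
    ctot = total_monomer_concentration(model, c1)
    return float(np.trapezoid(ctot * radii, radii) / np.trapezoid(radii, radii))


def _mdt_residuals(
    params: np.ndarray,
    profiles: Sequence[EquilibriumProfile],
    model: AssociationModel,
    groups: list,
    group_of: list,
    cells: list,
    cell_of_group: list,
    baseline_of: list,
    n_baselines: int,
    weights: np.ndarray,
    include_tetramer: bool,
    conserve_loading: bool,
    mass_conservation: float,
    group_radii: list,
) -> np.ndarray:
    kd12 = 10.0 ** params[0]
    kd24 = 10.0 ** params[1] if include_tetramer else np.inf
    eff = replace(model, kd12=kd12, kd24=kd24)
    nc = len(cells) if conserve_loading else len(groups)
    off = 2
    if conserve_loading:
        # one loading per cell; the meniscus concentration of each speed
        # column follows from conservation of the sector-weighted average
        c1_refs = []
        for g, (cell, speed) in enumerate(groups):
            loading = 10.0 ** params[off + cell_of_group[g]]
            c1_refs.append(loading_c1_ref(eff, loading, group_radii[g], speed))
    else:
        c1_refs = [10.0 ** params[off + g] for g in range(len(groups))]
    out = []
    for k, p in enumerate(profiles):
        b_idx = baseline_of[k]
        baseline = 0.0 if b_idx is None else params[off + nc + b_idx]
        pred = equilibrium_profile(
            eff, c1_refs[group_of[k]], p.radius, p.speed, p.detector, baseline,
            pathlength=p.pathlength,
        )
        out.append((pred - p.signal) / weights[k])
    if mass_conservation > 0.0 and not conserve_loading:
        # soft constraint: each speed column of a cell must carry the same
        # total loading (equilibrium redistributes, it does not lose, mass)
        by_cell: dict = {}
        for g, (cell, speed) in enumerate(groups):
            avg = _column_average_total(eff, c1_refs[g], group_radii[g], speed)
            by_cell.setdefault(cell, []).append(avg)
        for avgs in by_cell.values():
            avgs = np.asarray(avgs)
            mean = avgs.mean()
            out.append(mass_conservation * (avgs - mean) / mean)
    return np.concatenate(out)


def fit_global_mdt(
    profiles: Sequence[EquilibriumProfile],
    model: AssociationModel,
    include_tetramer: bool = True,
    kd12_starts: Sequence[float] = (1e-7, 1e-6, 1e-5),
    kd24_starts: Sequence[float] = (1e-6, 1e-5, 1e-4),
    reweight: bool = True,
    conserve_loading: bool = True,
    baseline_per: str = "cell-detector",
    mass_conservation: float = 0.0,
) -> GlobalFitResult:
    """Global monomer-dimer(-tetramer) fit across speeds and detectors.

    Kd12 (and Kd24 when ``include_tetramer``) are shared across all data.
    With the default ``conserve_loading=True`` each cell contributes a single
    free loading concentration; the reference (meniscus) monomer
    concentration of every speed column follows from conservation of the
    sector-weighted column average, which is what couples the speeds and
    makes the small monomer amplitude identifiable against the baselines.
    ``conserve_loading=False`` floats an independent reference concentration
    per (cell, speed) column instead (optionally tied together by the soft
    ``mass_conservation`` penalty weight).

    ``baseline_per`` is ``"cell-detector"`` (one baseline shared by the
    speeds of a cell recorded with one optical system, the default) or
    ``"profile"`` (fully free baselines).

    The fit restarts from a coarse log-spaced grid of Kd pairs and keeps the
    lowest-SSR solution; per-detector noise is then estimated from the
    residuals and a single re-weighted pass is run.
    """
    if len(profiles) < 1:
        raise ValueError("at least one profile is required")
    if baseline_per not in ("profile", "cell-detector", "none"):
        raise ValueError(
            "baseline_per must be 'profile', 'cell-detector' or 'none'"
        )

    group_keys = sorted({(p.cell_id, p.speed) for p in profiles})
    group_of = [group_keys.index((p.cell_id, p.speed)) for p in profiles]
    cells = sorted({p.cell_id for p in profiles})
    cell_of_group = [cells.index(cell) for cell, _ in group_keys]
    group_radii = [None] * len(group_keys)
    for k, p in enumerate(profiles):
        if group_radii[group_of[k]] is None:
            group_radii[group_of[k]] = p.radius
    if baseline_per == "profile":
        baseline_of = list(range(len(profiles)))
        n_baselines = len(profiles)
    elif baseline_per == "none":
        baseline_of = [None] * len(profiles)
        n_baselines = 0
    else:
        baseline_keys = sorted({(p.cell_id, p.detector) for p in profiles})
        baseline_of = [baseline_keys.index((p.cell_id, p.detector)) for p in profiles]
        n_baselines = len(baseline_keys)
    nc = len(cells) if conserve_loading else len(group_keys)
    n_obs = sum(p.signal.size for p in profiles)
    fit_args = (
        profiles, model, group_keys, group_of, cells, cell_of_group,
        baseline_of, n_baselines,
    )

    def initial_params(kd12: float, kd24: float) -> np.ndarray:
        eff = replace(model, kd12=kd12, kd24=kd24 if include_tetramer else np.inf)
        c0 = np.zeros(nc)
        if conserve_loading:
            # column-average signal over the optical coefficient estimates
            # the loading directly
            sums = np.zeros(nc)
            counts = np.zeros(nc)
            for k, p in enumerate(profiles):
                coef = signal_coefficient(model, p.detector, p.pathlength)
                idx = cell_of_group[group_of[k]]
                sums[idx] += max(float(p.signal.mean()) / coef, 1e-12)
                counts[idx] += 1
            c0 = np.log10(sums / counts)
        else:
            for k, p in enumerate(profiles):
                coef = signal_coefficient(model, p.detector, p.pathlength)
                c_tot_men = max(
                    float(p.signal[0]) / coef,
                    float(p.signal.max()) / (50.0 * coef),
                    1e-12,
                )
                c0[group_of[k]] = np.log10(solve_c1_from_total(eff, c_tot_men))
        return np.concatenate(
            ([np.log10(kd12), np.log10(kd24)], c0, np.zeros(n_baselines))
        )

    def run(weights: np.ndarray, starts) -> object:
        best = None
        for kd12_0, kd24_0 in starts:
            x0 = initial_params(kd12_0, kd24_0)
            sol = least_squares(
                _mdt_residuals,
                x0,
                args=fit_args + (
                    weights, include_tetramer, conserve_loading,
                    mass_conservation, group_radii,
                ),
                bounds=(
                    [-12.0, -12.0] + [-15.0] * nc + [-np.inf] * n_baselines,
                    [0.0, 0.0] + [0.0] * nc + [np.inf] * n_baselines,
                ),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        return best

    unit_weights = np.ones(len(profiles))
    starts = list(itertools.product(kd12_starts, kd24_starts))
    best = run(unit_weights, starts)

    detector_weights = None
    if reweight:
        # per-detector noise SD from first-pass residuals, then one re-fit
        res = _mdt_residuals(
            best.x, *fit_args, unit_weights, include_tetramer,
            conserve_loading, 0.0, group_radii,
        )
        detector_weights = {}
        offsets = np.cumsum([0] + [p.signal.size for p in profiles])
        for det in {p.detector for p in profiles}:
            chunks = [
                res[offsets[k] : offsets[k + 1]]
                for k, p in enumerate(profiles)
                if p.detector == det
            ]
            sd = float(np.std(np.concatenate(chunks)))
            detector_weights[det] = max(sd, 1e-12)
        w = np.array([detector_weights[p.detector] for p in profiles])
        best = run(w, [(10.0 ** best.x[0], 10.0 ** best.x[1])])

    n_params = best.x.size if include_tetramer else best.x.size - 1
    dof = max(n_obs - n_params, 1)
    at_bound = bool(
        np.any(np.isclose(best.x[:2], -12.0)) or np.any(np.isclose(best.x[:2], 0.0))
    )
    message = str(best.message) + (" [Kd at bound]" if at_bound else "")
    kd12_hat = float(10.0 ** best.x[0])
    kd24_hat = float(10.0 ** best.x[1]) if include_tetramer else np.inf
    eff = replace(model, kd12=kd12_hat, kd24=kd24_hat)
    if conserve_loading:
        loadings = {
            cell: float(10.0 ** best.x[2 + i]) for i, cell in enumerate(cells)
        }
        c_refs = {
            key: loading_c1_ref(
                eff, loadings[key[0]], group_radii[g], key[1]
            )
            for g, key in enumerate(group_keys)
        }
    else:
        loadings = None
        c_refs = {
            key: float(10.0 ** best.x[2 + g]) for g, key in enumerate(group_keys)
        }
    return GlobalFitResult(
        kd12_hat=kd12_hat,
        kd24_hat=kd24_hat,
        c_refs=c_refs,
        baselines=[float(v) for v in best.x[2 + nc :]],
        reduced_chi2=float(2.0 * best.cost / dof),
        n_obs=n_obs,
        n_params=n_params,
        success=bool(best.success) and not at_bound,
        message=message,
        detector_weights=detector_weights,
        loadings=loadings,
    )
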