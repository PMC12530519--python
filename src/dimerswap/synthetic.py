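"""Synthetic generators for every input the analysis pipeline consumes.

The generators emulate the statistical structure of the study's measurement
types so that each downstream stage is testable without instrument data:

* SEC elution traces as Gaussian peaks in time whose area is proportional
  to mass concentration (differential-refractometer physics), with an
  optional weight-average molar-mass trace masked below 5 % of the peak;
* subunit-exchange experiments with a tunable heterodimer fraction;
* multi-speed sedimentation-equilibrium gradients from the exact
  monomer-dimer-tetramer forward model;
* Poisson colony counts for his3-AI retromobility plating;
* protein sequence families with fixed diagnostic positions;
* rigid-body-perturbed coordinate sets for superposition tests.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from dimerswap import sedeq
from dimerswap.exchange import Chromatogram
from dimerswap.mobility import MobilityExperiment
from dimerswap.sedeq import AssociationModel, EquilibriumProfile

#: 20-letter amino-acid alphabet
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: default SEC retention-time calibration t_R = a - b*log10(M), minutes
RETENTION_A_MIN = 26.0
RETENTION_B_MIN_PER_DECADE = 2.3

#: mask the molar-mass trace where the signal drops below this peak fraction
MASS_TRACE_MASK_FRACTION = 0.05


def retention_time_from_mass(molar_mass: float) -> float:
    """SEC calibration: retention time in minutes from molar mass in Da.

    The defaults place a ~23 kDa dimer near 16 min and a ~42 kDa dimer near
    15.4 min, inside the 14-18 min integration window of the exchange
    analysis.
    """
    return RETENTION_A_MIN - RETENTION_B_MIN_PER_DECADE * np.log10(molar_mass)


@dataclass
class SpeciesSpec:
    """One eluting species: a homodimer or heterodimer of capsid domains."""

    name: str
    molar_mass: float  # Da
    loading_conc: float  # µM, dimer-equivalent
    retention_time: float | None = None  # minutes; from calibration if None
    peak_width: float = 0.2  # minutes (SD of the Gaussian elution peak)

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError("molar mass must be positive")
        if self.peak_width <= 0:
            raise ValueError("peak width must be positive")
        if self.loading_conc < 0:
            raise ValueError("loading concentration must be non-negative")
        if self.retention_time is None:
            self.retention_time = retention_time_from_mass(self.molar_mass)


@dataclass
class ExchangeScenario:
    """A mixing experiment of two homodimer species with partial exchange.

    ``hetero_fraction`` f is the fraction of all dimers that are heterodimers
    after incubation; complete statistical exchange of an equimolar mixture
    corresponds to f = 0.5.  The heterodimer molar mass is the mean of the
    two homodimer masses.
    """

    species_a: SpeciesSpec
    species_b: SpeciesSpec
    hetero_fraction: float
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hetero_fraction <= 0.5:
            raise ValueError("hetero_fraction must lie in [0, 0.5]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class AUCScenario:
    """Multi-speed, multi-loading sedimentation-equilibrium experiment."""

    model: AssociationModel
    speeds: Sequence[float] = (20000.0, 23000.0, 26000.0)  # rpm
    loading_concs: Sequence[float] = (45.0,)  # µM, monomer-equivalent
    radii: np.ndarray | None = None  # cm; default meniscus 6.90 to base 7.15
    noise_sd: float = 0.01  # fraction of each profile's maximum signal
    detectors: Sequence[str] = ("absorbance", "interference")
    temperature: float | None = None  # K; overrides the model's if given
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.speeds):
            raise ValueError("all speeds must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.radii is None:
            # 0.25 cm solution column sampled at the 0.001 cm radial
            # resolution of modern equilibrium optics
            self.radii = np.linspace(6.90, 7.15, 251)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.radii[0] >= self.radii[-1]:
            raise ValueError("meniscus must lie below the cell base")


def default_time_grid(step_min: float = 1.0 / 240.0) -> np.ndarray:
    """Elution time grid covering the 14-18 min integration window."""
    return np.arange(12.0, 20.0, step_min)


def resolved_exchange_scenario(
    hetero_fraction: float, noise_sd: float = 0.0, seed: int = 0
) -> ExchangeScenario:
    """Equimolar 50 µM mixing scenario with fully resolved elution peaks.

    A 23 kDa and a 42 kDa homodimer elute ~0.6 min apart; with 0.03-min
    peak widths all three peaks (including the intermediate heterodimer)
    are baseline-resolved, so the fraction sum residual equals 100 times
    the heterodimer fraction.
    """
    species_a = SpeciesSpec("rf_dimer", 23000.0, 50.0, peak_width=0.03)
    species_b = SpeciesSpec("ca_dimer", 42000.0, 50.0, peak_width=0.03)
    return ExchangeScenario(species_a, species_b, hetero_fraction, noise_sd, seed)


def simulate_chromatogram(
    species: Sequence[SpeciesSpec],
    time_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Chromatogram:
    """Simulate a dRI trace as a sum of area-normalised Gaussian peaks.

    Each species contributes an area of ``loading_conc * molar_mass``
    (refractive signal proportional to mass concentration, equal dn/dc
    assumed).  The molar-mass trace is the signal-weighted average of the
    species masses, masked (NaN) where the noise-free signal falls below
    5 % of its maximum.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    if np.any(np.diff(time_grid) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    for sp in species:
        if not (
            time_grid[0] <= sp.retention_time - 4 * sp.peak_width
            and sp.retention_time + 4 * sp.peak_width <= time_grid[-1]
        ):
            raise ValueError(
                f"time grid does not cover species {sp.name!r} "
                "retention time +/- 4 peak widths"
            )
    total = np.zeros_like(time_grid)
    mass_weighted = np.zeros_like(time_grid)
    for sp in species:
        peak = (
            sp.loading_conc
            * sp.molar_mass
            / (sp.peak_width * np.sqrt(2.0 * np.pi))
            * np.exp(-0.5 * ((time_grid - sp.retention_time) / sp.peak_width) ** 2)
        )
        total += peak
        mass_weighted += peak * sp.molar_mass
    with np.errstate(invalid="ignore", divide="ignore"):
        mass_trace = mass_weighted / total
    if total.max() > 0:
        mass_trace[total <= MASS_TRACE_MASK_FRACTION * total.max()] = np.nan
    else:
        mass_trace[:] = np.nan
    rng = np.random.default_rng(seed)
    signal = total + rng.normal(0.0, noise_sd, size=time_grid.shape) if noise_sd else total
    return Chromatogram(
        time=time_grid.copy(),
        signal=signal,
        molar_mass=mass_trace,
        label="+".join(sp.name for sp in species),
    )


def heterodimer_species(
    species_a: SpeciesSpec, species_b: SpeciesSpec, loading_conc: float
) -> SpeciesSpec:
    """Heterodimer species of two homodimers.

    Mass is the mean of the homodimer masses.  The retention time is
    interpolated between the two homodimers' retention times linearly in
    log10(mass) — a local SEC calibration through the two observed peaks —
    which guarantees elution strictly between them.
    """
    mass = 0.5 * (species_a.molar_mass + species_b.molar_mass)
    la, lb = np.log10(species_a.molar_mass), np.log10(species_b.molar_mass)
    if np.isclose(la, lb):
        t_r = 0.5 * (species_a.retention_time + species_b.retention_time)
    else:
        frac = (np.log10(mass) - la) / (lb - la)
        t_r = species_a.retention_time + frac * (
            species_b.retention_time - species_a.retention_time
        )
    return SpeciesSpec(
        name=f"{species_a.name}-{species_b.name}",
        molar_mass=mass,
        loading_conc=loading_conc,
        retention_time=float(t_r),
        peak_width=0.5 * (species_a.peak_width + species_b.peak_width),
    )


def simulate_exchange_pair(
    scenario: ExchangeScenario, time_grid: np.ndarray
) -> tuple[Chromatogram, Chromatogram, Chromatogram]:
    """Simulate (mixture, component A, component B) chromatograms.

    The mixture contains each homodimer at its full loading minus the
    material consumed by exchange and the heterodimer at
    ``f * (c_A + c_B)`` (each heterodimer consumes half a homodimer of each
    kind), so total injected refractive signal is conserved exactly.
    """
    a, b, f = scenario.species_a, scenario.species_b, scenario.hetero_fraction
    hetero_conc = f * (a.loading_conc + b.loading_conc)
    rem_a = a.loading_conc - hetero_conc / 2.0
    rem_b = b.loading_conc - hetero_conc / 2.0
    if rem_a < 0 or rem_b < 0:
        raise ValueError(
            "hetero_fraction too large for the smaller loading concentration"
        )
    rng = np.random.default_rng(scenario.seed)
    seeds = rng.integers(0, 2**31 - 1, size=3)
    mix_species = [
        replace(a, loading_conc=rem_a),
        replace(b, loading_conc=rem_b),
    ]
    if hetero_conc > 0:
        mix_species.append(heterodimer_species(a, b, hetero_conc))
    mix = simulate_chromatogram(mix_species, time_grid, scenario.noise_sd, seeds[0])
    mix.label = f"mix({a.name},{b.name})"
    comp_a = simulate_chromatogram([a], time_grid, scenario.noise_sd, seeds[1])
    comp_b = simulate_chromatogram([b], time_grid, scenario.noise_sd, seeds[2])
    return mix, comp_a, comp_b


def simulate_se_profiles(scenario: AUCScenario) -> list[EquilibriumProfile]:
    """Simulate sedimentation-equilibrium scans for all speed/loading/detector
    combinations of an AUC scenario.

    Reference concentrations are chosen so total loading is conserved over
    the solution column (sector-weighted average); noise is additive
    Gaussian with SD equal to ``noise_sd`` times each profile's maximum
    noise-free signal.
    """
    model = scenario.model
    if scenario.temperature is not None:
        model = replace(model, temperature=scenario.temperature)
    rng = np.random.default_rng(scenario.seed)
    profiles: list[EquilibriumProfile] = []
    for i_load, loading_uM in enumerate(scenario.loading_concs):
        loading_molar = loading_uM * 1e-6
        cell_id = f"cell{i_load + 1}"
        for speed in scenario.speeds:
            if speed == 0:
                c1_ref = sedeq.solve_c1_from_total(model, loading_molar)
            else:
                c1_ref = sedeq.loading_c1_ref(
                    model, loading_molar, scenario.radii, speed
                )
            for detector in scenario.detectors:
                clean = sedeq.equilibrium_profile(
                    model, c1_ref, scenario.radii, max(speed, 1e-12), detector
                )
                noise = (
                    rng.normal(0.0, scenario.noise_sd * clean.max(), clean.shape)
                    if scenario.noise_sd
                    else 0.0
                )
                profiles.append(
                    EquilibriumProfile(
                        radius=scenario.radii.copy(),
                        signal=clean + noise,
                        speed=speed,
                        detector=detector,
                        cell_id=cell_id,
                        loading_uM=loading_uM,
                    )
                )
    return profiles


def simulate_mobility_counts(
    true_frequency: float,
    n_cultures: int = 4,
    dilution_his: float = 1.0,
    dilution_viable: float = 1e5,
    plated_volume: float = 0.1,
    cells_per_culture: float = 2e8,
    seed: int = 0,
    label: str = "",
) -> MobilityExperiment:
    """Simulate a quadruplicate his3-AI plating experiment.

    Cultures of ``cells_per_culture`` cells (per mL of culture) are plated at
    the stated dilutions and volumes (mL); His+ and viable colony counts are
    Poisson around the expectations implied by the true retromobility
    frequency.
    """
    if not 0.0 <= true_frequency <= 1.0:
        raise ValueError("true_frequency must lie in [0, 1]")
    if min(n_cultures, dilution_his, dilution_viable, plated_volume,
           cells_per_culture) <= 0:
        raise ValueError("all experimental quantities must be positive")
    rng = np.random.default_rng(seed)
    lam_his = true_frequency * cells_per_culture * plated_volume / dilution_his
    lam_viable = cells_per_culture * plated_volume / dilution_viable
    his = rng.poisson(lam_his, size=n_cultures)
    viable = rng.poisson(lam_viable, size=n_cultures)
    return MobilityExperiment(
        his_counts=his,
        viable_counts=viable,
        his_dilution=dilution_his,
        viable_dilution=dilution_viable,
        his_volume=plated_volume,
        viable_volume=plated_volume,
        label=label,
    )


def simulate_sequence_family(
    consensus: str,
    n_seqs: int,
    per_site_sub_rate: float,
    fixed_positions: Mapping[int, str] | None = None,
    seed: int = 0,
    offset: int = 0,
) -> list[str]:
    """Simulate a family of sequences around a consensus.

    Each site mutates independently with probability ``per_site_sub_rate``
    to one of the 19 other residues (uniformly).  ``fixed_positions`` maps
    positions in the ``offset`` coordinate frame (e.g. Gag numbering with
    offset 259) to residues carried by every sequence.
    """
    consensus = consensus.upper()
    if any(c not in AMINO_ACIDS for c in consensus):
        raise ValueError("consensus contains non-standard residues")
    if not 0.0 <= per_site_sub_rate <= 1.0:
        raise ValueError("substitution rate must lie in [0, 1]")
    fixed_positions = dict(fixed_positions or {})
    fixed_cols: dict[int, str] = {}
    for pos, res in fixed_positions.items():
        col = pos - offset
        if not 0 <= col < len(consensus):
            raise ValueError(f"fixed position {pos} outside the consensus")
        if res not in AMINO_ACIDS:
            raise ValueError(f"fixed residue {res!r} not in the 20-letter alphabet")
        fixed_cols[col] = res
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    cons = np.frombuffer(consensus.encode(), dtype="S1")
    seqs = []
    for _ in range(n_seqs):
        seq = cons.copy()
        mutate = rng.random(len(consensus)) < per_site_sub_rate
        for col in np.flatnonzero(mutate):
            choices = alphabet[alphabet != seq[col]]
            seq[col] = rng.choice(choices)
        for col, res in fixed_cols.items():
            seq[col] = res.encode()
        seqs.append(seq.tobytes().decode())
    return seqs


def perturb_structure(
    coords: np.ndarray,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
    per_atom_noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Apply a rigid motion R.x + t plus isotropic Gaussian noise per atom."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] == 0:
        raise ValueError("coords must be a non-empty (N, 3) array")
    rotation = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-8):
        raise ValueError("rotation matrix is not orthonormal")
    translation = (
        np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
    )
    out = coords @ rotation.T + translation
    if per_atom_noise_sd:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, per_atom_noise_sd, size=out.shape)
    return out
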