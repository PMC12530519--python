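"""SEC-MALLS dimer subunit-exchange analysis.

When two homodimeric capsid-domain proteins are incubated together and the
mixture is resolved by size-exclusion chromatography, heterodimer formation
appears as an intermediate elution peak that is absent from the sum of the
individually-run component chromatograms.  The analysis quantifies this as a
residual chromatogram,

    S_res(t) = S_exp(t) - (S_calc(t)_A + S_calc(t)_B),

and summarises it as the fraction sum residual

    theta_res = 100 * integral |S_res| / (2 * integral |S_A + S_B|)

over a fixed integration window.  The denominator factor 2 corrects the
double counting of exchanged material: each unit of heterodimer signal
appears once as a positive lobe and once, in total, as negative homodimer
depletion.  For fully resolved peaks of equal-mass dimers, theta_res equals
the heterodimer signal fraction, so complete statistical exchange of an
equimolar mixture (25/50/25 homodimer/heterodimer/homodimer) gives 50 %.

Pairs whose hydrophobic Dimer-1 interfaces are mismatched do not exchange
and define a background level; exchange is then scored 0-3 against strict
multiples (1.3x, 2x, 5x) of the background mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass
class Chromatogram:
    """A baseline-subtracted elution trace on a strictly increasing time grid.

    Parameters
    ----------
    time : array of float
        Retention time in minutes, strictly increasing.
    signal : array of float
        Differential refractive index (arbitrary units).
    molar_mass : array of float, optional
        Weight-average molar mass (Da) per time point; NaN where the signal
        is below the detector masking threshold.
    label : str
        Free-text sample identifier.
    """

    time: np.ndarray
    signal: np.ndarray
    molar_mass: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValueError("time grid must be 1-D with at least 2 points")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.signal.shape != self.time.shape:
            raise ValueError("signal and time must have the same shape")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite everywhere")
        if self.molar_mass is not None:
            self.molar_mass = np.asarray(self.molar_mass, dtype=float)
            if self.molar_mass.shape != self.time.shape:
                raise ValueError("molar_mass and time must have the same shape")
            defined = self.molar_mass[~np.isnan(self.molar_mass)]
            if np.any(defined <= 0):
                raise ValueError("molar_mass must be positive where defined")


@dataclass
class ExchangeConfig:
    """Integration window and scoring thresholds for the exchange analysis."""

    integration_limits: tuple[float, float] = (14.0, 18.0)
    residual_denominator_factor: float = 2.0
    score_thresholds: tuple[float, float, float] = (1.3, 2.0, 5.0)

    def __post_init__(self) -> None:
        i, j = self.integration_limits
        if not i < j:
            raise ValueError("integration limits must satisfy i < j")
        if self.residual_denominator_factor <= 0:
            raise ValueError("residual denominator factor must be positive")
        t = self.score_thresholds
        if not (t[0] < t[1] < t[2]):
            raise ValueError("score thresholds must be strictly increasing")


@dataclass
class ExchangeResult:
    """theta_res and its exchange score for one restriction-factor/CA pair."""

    theta_res: float
    background_mean: float
    background_sd: float
    score: int
    pair: tuple[str, str]  # (restriction-factor label, CA label)


@dataclass
class PairRecord:
    """One mixture experiment: chromatograms, labels and background status.

    ``dimer1_motif_*`` annotate the three-residue Dimer-1 interface motif
    (e.g. ``"AVL"`` or ``"VTF"``) of each component; pairs with mismatched
    motifs are non-exchanging by construction and define the background
    unless ``is_background`` overrides that default.
    """

    mix: Chromatogram
    comp_a: Chromatogram
    comp_b: Chromatogram
    ca_label: str
    rf_label: str
    dimer1_motif_a: str | None = None
    dimer1_motif_b: str | None = None
    is_background: bool | None = None

    @property
    def background(self) -> bool:
        if self.is_background is not None:
            return self.is_background
        if self.dimer1_motif_a is None or self.dimer1_motif_b is None:
            return False
        return self.dimer1_motif_a != self.dimer1_motif_b


def resample_to_common_grid(
    a: Chromatogram, b: Chromatogram, c: Chromatogram
) -> tuple[Chromatogram, Chromatogram, Chromatogram]:
    """Interpolate three chromatograms onto the first one's grid.

    The output grid is ``a.time`` restricted to the range covered by all
    three inputs; signals of ``b`` and ``c`` are linearly interpolated.
    """
    lo = max(a.time[0], b.time[0], c.time[0])
    hi = min(a.time[-1], b.time[-1], c.time[-1])
    if lo >= hi:
        raise ValueError("chromatogram time ranges do not overlap")
    keep = (a.time >= lo) & (a.time <= hi)
    grid = a.time[keep]
    if grid.size < 2:
        raise ValueError("fewer than 2 grid points in the common range")

    def onto(ch: Chromatogram) -> Chromatogram:
        return Chromatogram(
            time=grid.copy(),
            signal=np.interp(grid, ch.time, ch.signal),
            label=ch.label,
        )

    return Chromatogram(grid.copy(), a.signal[keep], label=a.label), onto(b), onto(c)


def _check_common_grid(*chroms: Chromatogram) -> None:
    ref = chroms[0].time
    for ch in chroms[1:]:
        if ch.time.shape != ref.shape or not np.allclose(ch.time, ref):
            raise ValueError(
                "chromatograms are not on a common grid; call "
                "resample_to_common_grid first"
            )


def residual_chromatogram(
    mix: Chromatogram, comp_a: Chromatogram, comp_b: Chromatogram
) -> Chromatogram:
    """Pointwise residual: mixture minus the calculated sum chromatogram."""
    _check_common_grid(mix, comp_a, comp_b)
    return Chromatogram(
        time=mix.time.copy(),
        signal=mix.signal - (comp_a.signal + comp_b.signal),
        label=f"residual({mix.label})",
    )


def sum_chromatogram(comp_a: Chromatogram, comp_b: Chromatogram) -> Chromatogram:
    """Calculated sum chromatogram of the two individually-run components."""
    _check_common_grid(comp_a, comp_b)
    return Chromatogram(
        time=comp_a.time.copy(),
        signal=comp_a.signal + comp_b.signal,
        label=f"sum({comp_a.label},{comp_b.label})",
    )


def theta_res(
    residual: Chromatogram,
    sum_calc: Chromatogram,
    config: ExchangeConfig | None = None,
) -> float:
    """Fraction sum residual in percent.

    Trapezoidal quadrature of ``|S_res|`` over the integration window,
    normalised by ``factor *`` the quadrature of ``|S_sum|`` over the same
    window.  Window limits falling outside the grid are clipped.
    """
    config = config or ExchangeConfig()
    _check_common_grid(residual, sum_calc)
    i, j = config.integration_limits
    lo = max(i, residual.time[0])
    hi = min(j, residual.time[-1])
    if lo >= hi:
        raise ValueError("integration window does not intersect the time grid")
    # refine the window edges so clipped limits land exactly on i and j
    inside = (residual.time > lo) & (residual.time < hi)
    grid = np.concatenate(([lo], residual.time[inside], [hi]))
    res = np.interp(grid, residual.time, np.abs(residual.signal))
    tot = np.interp(grid, sum_calc.time, np.abs(sum_calc.signal))
    denom = config.residual_denominator_factor * np.trapezoid(tot, grid)
    if denom == 0:
        raise ValueError("sum chromatogram integrates to zero over the window")
    return 100.0 * np.trapezoid(res, grid) / denom


def background_estimate(theta_values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1) of background theta_res values."""
    values = np.asarray(theta_values, dtype=float)
    if values.size < 2:
        raise ValueError("background estimation needs at least 2 values")
    return float(values.mean()), float(values.std(ddof=1))


def classify_exchange(
    theta: float, background_mean: float, config: ExchangeConfig | None = None
) -> int:
    """Score exchange 0-3 against strict multiples of the background mean.

    3: largely exchanged (> 5x background); 2: appreciable (> 2x);
    1: weak (> 1.3x); 0: non-observable.  Exact ties fall to the lower score.
    """
    config = config or ExchangeConfig()
    if background_mean <= 0:
        raise ValueError("background mean must be positive")
    t1, t2, t3 = config.score_thresholds
    if theta > t3 * background_mean:
        return 3
    if theta > t2 * background_mean:
        return 2
    if theta > t1 * background_mean:
        return 1
    return 0


def score_records(
    records: Iterable[tuple[str, str, float, bool]],
    config: ExchangeConfig | None = None,
) -> tuple[list[ExchangeResult], float, float]:
    """Score (ca, rf, theta, is_background) records against their background.

    Returns the per-pair results together with the background mean and SD
    estimated from the flagged records.
    """
    config = config or ExchangeConfig()
    records = list(records)
    bg = [theta for _, _, theta, is_bg in records if is_bg]
    if not bg:
        raise ValueError("no background (non-exchanging) pairs flagged")
    bg_mean, bg_sd = background_estimate(bg)
    results = [
        ExchangeResult(
            theta_res=theta,
            background_mean=bg_mean,
            background_sd=bg_sd,
            score=classify_exchange(theta, bg_mean, config),
            pair=(rf, ca),
        )
        for ca, rf, theta, _ in records
    ]
    return results, bg_mean, bg_sd


def exchange_matrix(
    pairs: Sequence[PairRecord], config: ExchangeConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, float, float]:
    """Compute theta_res and scores for a panel of exchange experiments.

    Returns ``(per_pair, score_matrix, background_mean, background_sd)``:
    ``per_pair`` is a tidy table (one row per pair), ``score_matrix`` the
    CA x restriction-factor pivot of scores.
    """
    if not pairs:
        raise ValueError("at least one pair is required")
    config = config or ExchangeConfig()
    rows = []
    for p in pairs:
        mix, ca, cb = resample_to_common_grid(p.mix, p.comp_a, p.comp_b)
        res = residual_chromatogram(mix, ca, cb)
        total = sum_chromatogram(ca, cb)
        theta = theta_res(res, total, config)
        rows.append((p.ca_label, p.rf_label, theta, p.background))
    results, bg_mean, bg_sd = score_records(rows, config)
    per_pair = pd.DataFrame(
        {
            "ca": [r[0] for r in rows],
            "restriction_factor": [r[1] for r in rows],
            "theta_res_percent": [r[2] for r in rows],
            "is_background": [r[3] for r in rows],
            "score": [x.score for x in results],
        }
    )
    matrix = per_pair.pivot(
        index="ca", columns="restriction_factor", values="score"
    )
    return per_pair, matrix, bg_mean, bg_sd


def fit_linear_baseline(
    chrom: Chromatogram,
    pre_window: tuple[float, float],
    post_window: tuple[float, float],
) -> Chromatogram:
    """Subtract a straight line fitted through pre- and post-peak windows."""
    mask = ((chrom.time >= pre_window[0]) & (chrom.time <= pre_window[1])) | (
        (chrom.time >= post_window[0]) & (chrom.time <= post_window[1])
    )
    if mask.sum() < 2:
        raise ValueError("baseline windows contain fewer than 2 points")
    slope, intercept = np.polyfit(chrom.time[mask], chrom.signal[mask], 1)
    return Chromatogram(
        time=chrom.time.copy(),
        signal=chrom.signal - (slope * chrom.time + intercept),
        molar_mass=None if chrom.molar_mass is None else chrom.molar_mass.copy(),
        label=chrom.label,
    )
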