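"""Retromobility frequency and fold-restriction statistics.

Retromobility of a his3-AI-marked transposon is measured by plating
replicate cultures on His dropout media (selecting completed
retromobility events) and on viable-count media at a much higher dilution.
The per-replicate frequency is the ratio of the two recovered titres:

    frequency = (His+ count * dilution / volume) /
                (viable count * dilution / volume).

Restriction strength is expressed as fold restriction, the ratio of mean
frequencies without and with the restriction factor.  When a restricted
strain yields no events at all, the graphed value is the theoretical
maximum fold restriction had a single event been observed, flagged as a
lower bound.  Two-condition comparisons use the classical two-sided
equal-variance Student's t-test.

The module also implements the sucrose-gradient peak-fraction rule used
for VLP assembly profiles: the peak fractions are those carrying strictly
more than 1/n of the total densitometric signal across n fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats


@dataclass
class MobilityExperiment:
    """Colony counts for one condition, one row per replicate culture.

    Scalar dilutions/volumes broadcast over replicates.
    """

    his_counts: np.ndarray
    viable_counts: np.ndarray
    his_dilution: np.ndarray | float = 1.0
    viable_dilution: np.ndarray | float = 1.0
    his_volume: np.ndarray | float = 0.1  # mL plated
    viable_volume: np.ndarray | float = 0.1  # mL plated
    label: str = ""

    def __post_init__(self) -> None:
        self.his_counts = np.atleast_1d(np.asarray(self.his_counts))
        self.viable_counts = np.atleast_1d(np.asarray(self.viable_counts))
        n = self.his_counts.size
        if self.viable_counts.size != n:
            raise ValueError("His+ and viable counts must have equal replicates")
        if np.any(self.his_counts < 0) or np.any(self.viable_counts < 0):
            raise ValueError("colony counts must be non-negative")
        if np.any(self.his_counts % 1 != 0) or np.any(self.viable_counts % 1 != 0):
            raise ValueError("colony counts must be integers")
        for attr in ("his_dilution", "viable_dilution", "his_volume", "viable_volume"):
            value = np.broadcast_to(
                np.asarray(getattr(self, attr), dtype=float), (n,)
            ).copy()
            setattr(self, attr, value)
        if np.any(self.his_dilution < 1) or np.any(self.viable_dilution < 1):
            raise ValueError("dilution factors must be >= 1")
        if np.any(self.his_volume <= 0) or np.any(self.viable_volume <= 0):
            raise ValueError("plated volumes must be positive")

    @property
    def n_replicates(self) -> int:
        return self.his_counts.size


@dataclass
class FrequencyResult:
    per_replicate: np.ndarray
    mean: float
    sd: float
    zero_event: bool  # no His+ colonies in any replicate
    label: str = ""


@dataclass
class FoldRestriction:
    fold: float
    is_lower_bound: bool  # True when computed under the one-event substitution

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        prefix = ">= " if self.is_lower_bound else ""
        return f"{prefix}{self.fold:.3g}"


@dataclass
class GradientProfile:
    """Densitometric signal across sucrose-gradient fractions (1 = top)."""

    signals: np.ndarray

    def __post_init__(self) -> None:
        self.signals = np.atleast_1d(np.asarray(self.signals, dtype=float))
        if np.any(self.signals < 0):
            raise ValueError("fraction signals must be non-negative")
        if self.signals.size < 2:
            raise ValueError("a gradient needs at least 2 fractions")


def retromobility_frequency(exp: MobilityExperiment) -> FrequencyResult:
    """Per-replicate retromobility frequencies with mean and SD (n-1)."""
    if np.any(exp.viable_counts == 0):
        raise ValueError(
            "zero viable count in a replicate: frequency undefined"
        )
    his_titre = exp.his_counts * exp.his_dilution / exp.his_volume
    viable_titre = exp.viable_counts * exp.viable_dilution / exp.viable_volume
    freqs = his_titre / viable_titre
    sd = float(freqs.std(ddof=1)) if freqs.size > 1 else 0.0
    return FrequencyResult(
        per_replicate=freqs,
        mean=float(freqs.mean()),
        sd=sd,
        zero_event=bool(np.all(exp.his_counts == 0)),
        label=exp.label,
    )


def fold_restriction(
    control: MobilityExperiment, restricted: MobilityExperiment
) -> FoldRestriction:
    """Fold restriction as the ratio of mean frequencies, control/restricted.

    If the restricted condition produced no His+ colonies in any replicate,
    the theoretical maximum is computed by substituting a single event into
    the replicate with the highest viable titre (the most conservative
    choice) and the result is flagged as a lower bound.
    """
    control_freq = retromobility_frequency(control)
    if control_freq.mean <= 0:
        raise ValueError("control mean frequency must be positive")
    restricted_freq = retromobility_frequency(restricted)
    if not restricted_freq.zero_event:
        if restricted_freq.mean == 0:
            raise ValueError("restricted frequency is zero without zero-event flag")
        return FoldRestriction(control_freq.mean / restricted_freq.mean, False)
    viable_titre = (
        restricted.viable_counts * restricted.viable_dilution / restricted.viable_volume
    )
    idx = int(np.argmax(viable_titre))
    his = restricted.his_counts.copy()
    his[idx] = 1
    one_event = replace(restricted, his_counts=his)
    bound = retromobility_frequency(one_event)
    return FoldRestriction(control_freq.mean / bound.mean, True)


def fold_from_frequencies(
    control_freqs: np.ndarray, restricted_freqs: np.ndarray
) -> float:
    """Fold restriction from already-computed frequencies (ratio of means)."""
    control_freqs = np.atleast_1d(np.asarray(control_freqs, dtype=float))
    restricted_freqs = np.atleast_1d(np.asarray(restricted_freqs, dtype=float))
    if restricted_freqs.mean() <= 0:
        raise ValueError("restricted mean frequency must be positive")
    return float(control_freqs.mean() / restricted_freqs.mean())


def ttest_two_sided(
    freqs_a: np.ndarray, freqs_b: np.ndarray, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided Student's t-test (equal-variance by default; Welch via flag).

    Degenerate inputs with zero variance in both groups and equal means
    return (0.0, 1.0) rather than NaN.
    """
    a = np.atleast_1d(np.asarray(freqs_a, dtype=float))
    b = np.atleast_1d(np.asarray(freqs_b, dtype=float))
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 replicates")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def gradient_peak_fractions(
    profile: GradientProfile | np.ndarray,
) -> list[int]:
    """1-based indices of fractions carrying strictly more than 1/n of the
    total signal; a perfectly uniform profile therefore has no peak fractions."""
    signals = (
        profile.signals if isinstance(profile, GradientProfile) else
        GradientProfile(profile).signals
    )
    total = signals.sum()
    if total <= 0:
        raise ValueError("gradient profile carries no signal")
    shares = signals / total
    return [int(i) + 1 for i in np.flatnonzero(shares > 1.0 / signals.size)]
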