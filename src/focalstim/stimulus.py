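"""Charge-balanced biphasic pulse parameterization and stimulus grids.

Stimuli are anodic-first, charge-balanced current pulse trains delivered at
120 Hz for 5 s.  The cathodic phase is fixed at 100 µs; the "pulse type" is
the duration ratio of the anodic to the cathodic phase, one of
{1, 2, 5, 10, 20}, carried as an ordinal type index 1–5.  Charge balance
fixes the anodic amplitude to cathodic_amplitude / duration_ratio, and the
1 µA stimulator resolution requires that quotient to be an integer.

Amplitudes are cathodic-phase currents in µA.  The experimental grid steps
amplitude by 10 µA for ratios 1–10 (10 amplitudes per type in the default
20–110 µA window) and restricts ratio 20 to multiples of 20 µA in an
extended 20–130 µA window (6 amplitudes), for 46 combinations in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DURATION_RATIOS: tuple[int, ...] = (1, 2, 5, 10, 20)
CATHODIC_WIDTH_US = 100.0
INTERPHASE_GAP_US = 5.0
FREQUENCY_HZ = 120.0
TRAIN_DURATION_S = 5.0

DEFAULT_AMPLITUDE_WINDOW = (20.0, 110.0)
DEFAULT_RATIO20_WINDOW = (20.0, 130.0)


class InvalidRatioError(ValueError):
    """Duration ratio is not one of the five deliverable ratios."""


class ResolutionViolationError(ValueError):
    """Requested pulse needs a fractional-µA anodic phase (stimulator limit)."""


@dataclass(frozen=True)
class PulseParams:
    """One charge-balanced anodic-first biphasic stimulus setting.

    Only the cathodic amplitude and the duration ratio vary; the anodic phase
    is derived from charge balance and never stored independently.
    """

    cathodic_amplitude: float          # µA, cathodic-phase current
    duration_ratio: int                # anodic/cathodic phase-duration ratio
    cathodic_width: float = CATHODIC_WIDTH_US    # µs
    interphase_gap: float = INTERPHASE_GAP_US    # µs, metadata only
    frequency: float = FREQUENCY_HZ              # Hz
    train_duration: float = TRAIN_DURATION_S     # s
    polarity: str = "anodic-first"

    @property
    def type_index(self) -> int:
        """Ordinal 1–5 position of the duration ratio in ascending order."""
        return DURATION_RATIOS.index(self.duration_ratio) + 1

    @property
    def anodic_amplitude(self) -> float:
        """µA; charge balance: a_an * w_an = a_cat * w_cat."""
        return self.cathodic_amplitude / self.duration_ratio

    @property
    def anodic_width(self) -> float:
        """µs."""
        return self.duration_ratio * self.cathodic_width

    @property
    def phase_charge_nC(self) -> float:
        """Charge per phase (identical for both by construction)."""
        return self.cathodic_amplitude * self.cathodic_width * 1e-3

    def as_dict(self) -> dict:
        return {
            "type_index": self.type_index,
            "duration_ratio": self.duration_ratio,
            "cathodic_amplitude_uA": self.cathodic_amplitude,
            "anodic_amplitude_uA": self.anodic_amplitude,
            "cathodic_width_us": self.cathodic_width,
            "anodic_width_us": self.anodic_width,
            "interphase_gap_us": self.interphase_gap,
            "frequency_Hz": self.frequency,
            "train_duration_s": self.train_duration,
            "polarity": self.polarity,
        }


def make_pulse(cathodic_amplitude: float, duration_ratio: int) -> PulseParams:
    """Build a deliverable pulse, enforcing charge balance and resolution.

    The anodic amplitude is cathodic_amplitude / duration_ratio and must be a
    whole number of µA (1 µA stimulator resolution), so the cathodic
    amplitude must be a positive multiple of the ratio.

    Raises
    ------
    InvalidRatioError
        if ``duration_ratio`` is not in {1, 2, 5, 10, 20}.
    ResolutionViolationError
        if the anodic phase would need fractional-µA current.
    ValueError
        if ``cathodic_amplitude`` is not positive.
    """
    if duration_ratio not in DURATION_RATIOS:
        raise InvalidRatioError(
            f"duration_ratio must be one of {DURATION_RATIOS}, got {duration_ratio!r}"
        )
    if cathodic_amplitude <= 0:
        raise ValueError(f"cathodic_amplitude must be > 0 µA, got {cathodic_amplitude}")
    # exact integer-µA check in integer arithmetic where possible
    amp = float(cathodic_amplitude)
    if abs(amp - round(amp)) > 1e-9 or int(round(amp)) % duration_ratio != 0:
        raise ResolutionViolationError(
            f"{cathodic_amplitude} µA at ratio {duration_ratio} needs an anodic "
            f"phase of {amp / duration_ratio} µA; stimulator resolution is 1 µA"
        )
    return PulseParams(cathodic_amplitude=float(round(amp)), duration_ratio=duration_ratio)


def deliverable_amplitudes(
    duration_ratio: int,
    amplitude_window: tuple[float, float] = DEFAULT_AMPLITUDE_WINDOW,
    step: float = 10.0,
    ratio20_window: tuple[float, float] = DEFAULT_RATIO20_WINDOW,
) -> np.ndarray:
    """Grid amplitudes (µA) for one duration ratio.

    Ratios 1–10 step through ``amplitude_window`` in ``step``-µA increments;
    ratio 20 takes multiples of 20 µA in ``ratio20_window``.
    """
    if duration_ratio not in DURATION_RATIOS:
        raise InvalidRatioError(f"unknown ratio {duration_ratio}")
    if duration_ratio == 20:
        lo, hi = ratio20_window
        first = int(np.ceil(lo / 20.0)) * 20
        amps = np.arange(first, hi + 1e-9, 20.0)
    else:
        lo, hi = amplitude_window
        amps = np.arange(lo, hi + 1e-9, step)
    return amps[amps > 0]


@dataclass
class StimGrid:
    """The enumerated experimental grid of pulse settings for one region."""

    pulses: list[PulseParams]
    amplitude_window: tuple[float, float]
    ratio20_window: tuple[float, float] = DEFAULT_RATIO20_WINDOW
    step: float = 10.0

    def __len__(self) -> int:
        return len(self.pulses)

    def __iter__(self):
        return iter(self.pulses)

    @property
    def box(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """Continuous optimization box: amplitude window x type-index bounds.

        The search box follows the main amplitude window; ratio-20 settings
        outside it remain reachable through deliverable rounding.
        """
        return self.amplitude_window, (1.0, float(len(DURATION_RATIOS)))

    def by_type(self, type_index: int) -> list[PulseParams]:
        return [p for p in self.pulses if p.type_index == type_index]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "type_index": p.type_index,
                "duration_ratio": p.duration_ratio,
                "cathodic_amplitude_uA": p.cathodic_amplitude,
                "anodic_amplitude_uA": p.anodic_amplitude,
                "anodic_width_us": p.anodic_width,
            }
            for p in self.pulses
        ]
        return pd.DataFrame(rows)


def build_grid(
    amplitude_window: tuple[float, float] = DEFAULT_AMPLITUDE_WINDOW,
    step: float = 10.0,
    ratios: Sequence[int] = DURATION_RATIOS,
    ratio20_window: tuple[float, float] = DEFAULT_RATIO20_WINDOW,
) -> StimGrid:
    """Enumerate the stimulus grid, ratio-major, amplitude ascending.

    Defaults reproduce the 46-combination experimental grid: 10 amplitudes
    (20–110 µA, 10 µA steps) for each of ratios 1, 2, 5 and 10, plus the six
    multiples of 20 µA in 20–130 µA for ratio 20.
    """
    lo, hi = amplitude_window
    if not (lo < hi or lo == hi):
        raise ValueError(f"empty amplitude window {amplitude_window}")
    if lo > hi or step <= 0:
        raise ValueError(f"inconsistent window {amplitude_window} / step {step}")
    pulses: list[PulseParams] = []
    seen: set[tuple[int, float]] = set()
    for ratio in sorted(ratios, key=DURATION_RATIOS.index):
        for amp in deliverable_amplitudes(ratio, amplitude_window, step, ratio20_window):
            key = (ratio, float(amp))
            if key in seen:
                continue
            seen.add(key)
            pulses.append(make_pulse(float(amp), ratio))
    if not pulses:
        raise ValueError("grid is empty for the given window/step")
    return StimGrid(pulses=pulses, amplitude_window=amplitude_window,
                    ratio20_window=ratio20_window, step=step)


def round_to_deliverable(
    a: float,
    t: float,
    amplitude_window: tuple[float, float] = DEFAULT_AMPLITUDE_WINDOW,
    ratio20_window: tuple[float, float] = DEFAULT_RATIO20_WINDOW,
) -> PulseParams:
    """Round a continuous optimizer point to a stimulator-deliverable pulse.

    The type coordinate rounds to the nearest ordinal index; the amplitude
    rounds to the nearest integer µA divisible by the chosen duration ratio,
    clamped inside that ratio's amplitude window.  Idempotent on points that
    are already deliverable.
    """
    t_idx = int(np.clip(round(t), 1, len(DURATION_RATIOS)))
    ratio = DURATION_RATIOS[t_idx - 1]
    if ratio == 20:
        lo, hi = ratio20_window
    else:
        lo, hi = amplitude_window
    a = float(np.clip(a, lo, hi))
    # nearest multiple of the ratio, then clamp back into the window on the
    # deliverable lattice
    amp = round(a / ratio) * ratio
    lo_lattice = int(np.ceil(lo / ratio)) * ratio
    hi_lattice = int(np.floor(hi / ratio)) * ratio
    amp = int(np.clip(amp, lo_lattice, hi_lattice))
    return make_pulse(float(amp), ratio)


def grid_to_csv(grid: StimGrid, path) -> None:
    """Export the grid as CSV (type_index, ratio, amplitudes, widths)."""
    grid.to_frame().to_csv(path, index=False)
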