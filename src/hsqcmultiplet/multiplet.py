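"""First-order simulation of 13C multiplet components and their combinatorics.

A CH resonance with n one-bond 13C neighbours gives rise to 2^n isotopomer
components: each subset of neighbours that happens to be 13C-labelled splits
the detected carbon by the corresponding couplings (empty set = singlet, one
neighbour = doublet, two = doublet of doublets, ...).  One-bond 13C/13C
couplings (30-60 Hz) are far smaller than carbon shift differences at high
field, so the weak-coupling (first-order) stick pattern is used: all sign
combinations of +/- s*J_k/2, where s is the apparent-J scaling factor of the
acquisition.  Sticks are dressed with a Lorentzian of configurable FWHM and
the component trace is normalised to unit area, so that regression
amplitudes are proportional to isotopomer signal integrals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .config import logger
from .library import Coupling, ResonanceEntry


@dataclass(frozen=True)
class LineshapeParams:
    """13C lineshape: Lorentzian full width at half maximum, Hz."""

    linewidth_c: float = 4.5

    def __post_init__(self) -> None:
        if self.linewidth_c <= 0:
            raise ValueError("linewidth_c must be positive")


@dataclass
class MultipletComponent:
    """One isotopomer's contribution to a multiplet.

    ``isotopomer`` is the subset of coupling partners that are 13C-labelled;
    ``sticks`` are the first-order line positions (Hz offsets from the
    multiplet centre) and ``trace``, when simulated, the unit-area 1D
    intensity over a 13C ppm axis.
    """

    isotopomer: Tuple[Coupling, ...]
    sticks: Tuple[float, ...] = ()
    trace: Optional[np.ndarray] = None

    @property
    def label(self) -> str:
        if not self.isotopomer:
            return "s"
        return "d(" + ",".join(c.partner for c in self.isotopomer) + ")"


def stick_pattern(isotopomer: Sequence[Coupling], j_scaling: int = 1) -> Tuple[float, ...]:
    """First-order line positions: all sign combinations of +/- s*J_k/2."""
    if j_scaling < 1:
        raise ValueError("j_scaling must be >= 1")
    if not isotopomer:
        return (0.0,)
    halves = [j_scaling * c.j / 2.0 for c in isotopomer]
    offsets = [sum(signed) for signed in itertools.product(*[(-h, +h) for h in halves])]
    return tuple(sorted(offsets))


def enumerate_components(
    entry: ResonanceEntry, include_long_range: bool = False
) -> List[MultipletComponent]:
    """All 2^n isotopomer components of *entry*, singlet first.

    Order: by subset size, then lexically by partner labels — deterministic
    so that regression coefficient vectors are comparable across runs.
    """
    partners = [c for c in entry.couplings if c.one_bond or include_long_range]
    subsets: List[Tuple[Coupling, ...]] = []
    for size in range(len(partners) + 1):
        for combo in itertools.combinations(partners, size):
            subsets.append(combo)
    subsets.sort(key=lambda s: (len(s), tuple(c.partner for c in s)))
    return [MultipletComponent(isotopomer=s) for s in subsets]


def lorentzian(axis_hz: np.ndarray, center_hz: float, fwhm: float) -> np.ndarray:
    """Unit-area Lorentzian (continuous normalisation) sampled on *axis_hz*."""
    hwhm = fwhm / 2.0
    return (hwhm / np.pi) / ((axis_hz - center_hz) ** 2 + hwhm**2)


def simulate_component(
    component: MultipletComponent,
    center_c: float,
    axis_c: np.ndarray,
    lineshape: LineshapeParams,
    freq_c: float,
    j_scaling: int = 1,
) -> MultipletComponent:
    """Attach a unit-area trace over *axis_c* (ppm) to *component*.

    Each stick becomes a Lorentzian centred at ``center_c + offset/freq_c``
    (Hz-to-ppm conversion via the 13C carrier frequency); equal stick
    weights; the sampled trace is renormalised to unit area on the grid.
    """
    axis_c = np.asarray(axis_c, dtype=float)
    if not (axis_c.min() <= center_c <= axis_c.max()):
        raise ValueError(f"centre {center_c} ppm outside 13C axis")
    sticks = stick_pattern(component.isotopomer, j_scaling)
    axis_hz = axis_c * freq_c
    trace = np.zeros_like(axis_hz)
    lo, hi = axis_hz.min(), axis_hz.max()
    n_outside = 0
    for off in sticks:
        pos = center_c * freq_c + off
        if not lo <= pos <= hi:
            n_outside += 1
        trace += lorentzian(axis_hz, pos, lineshape.linewidth_c)
    if n_outside:
        logger.warning(
            "%d/%d sticks of %s fall outside the 13C axis; trace truncated",
            n_outside, len(sticks), component.label)
    area = float(np.trapezoid(trace, np.abs(axis_hz - axis_hz[0])))
    if area <= 0:
        raise ValueError("component trace has non-positive area (axis too narrow?)")
    return MultipletComponent(
        isotopomer=component.isotopomer, sticks=sticks, trace=trace / area
    )


def simulate_components(
    entry: ResonanceEntry,
    center_c: float,
    axis_c: np.ndarray,
    lineshape: LineshapeParams,
    freq_c: float,
    j_scaling: int = 1,
    include_long_range: bool = False,
) -> List[MultipletComponent]:
    """Enumerate and simulate every component of *entry* at *center_c*."""
    return [
        simulate_component(c, center_c, axis_c, lineshape, freq_c, j_scaling)
        for c in enumerate_components(entry, include_long_range)
    ]


def enumerate_subsets(
    components: Sequence, q_range: Optional[Iterable[int]] = None
) -> List[Tuple[int, ...]]:
    """Index subsets of *components* with sizes in *q_range* (default 1..p).

    This is the p! / ((p-q)! q!) candidate space searched during multiplet
    identification; returned in deterministic (size, lexical) order.
    """
    if len(components) == 0:
        raise ValueError("components must be nonempty")
    p = len(components)
    sizes = list(q_range) if q_range is not None else list(range(1, p + 1))
    subsets: List[Tuple[int, ...]] = []
    for q in sizes:
        subsets.extend(itertools.combinations(range(p), q))
    return subsets


def equal_intensity_multiplet(
    components: Sequence[MultipletComponent], subset: Sequence[int]
) -> np.ndarray:
    """Unit-area equal-weight sum of the subset's component traces.

    The identification step simulates the sought multiplet "assuming equal
    intensities for each of the multiplet components" since the actual
    isotopomer amounts are unknown until quantification.
    """
    traces = [components[i].trace for i in subset]
    if any(t is None for t in traces):
        raise ValueError("components must be simulated before combining")
    mix = np.mean(traces, axis=0)
    total = mix.sum()
    return mix / total if total > 0 else mix
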