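"""Analysis configuration.

All tunable parameters of the multiplet assignment pipeline live here, with
the standard values used when the user supplies nothing: search half-widths
of +/-0.15 ppm (1H) and +/-3.0 ppm (13C) around the library shift, a minimum
component/column correlation of 0.8, 50 % peak retention inside latent
components, and trust thresholds of 80 % / 70 % on the coefficient of
determination.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

logger = logging.getLogger("hsqcmultiplet")

#: gamma_H / gamma_C, ratio of gyromagnetic ratios (26.7522128 / 6.728284).
GYRO_RATIO_HC = 3.976256

#: Carbon-axis compression used inside the library-shift distance: the
#: product of the search-width ratio (3.0 / 0.15 = 20) and gamma_H/gamma_C.
GAMMA_ADJUSTED = 20.0 * GYRO_RATIO_HC

#: Apparent-J multipliers the detector considers.
J_SCALING_CANDIDATES = (1, 2, 4, 8)


@dataclass
class AnalysisConfig:
    """Parameters steering the whole per-resonance analysis.

    Attributes
    ----------
    max_width_1h, max_width_13c:
        Half-widths (ppm) of the search window centred on the library shift.
    min_corr:
        Minimum Pearson correlation between a latent component and its best
        spectrum column; components below it are discarded as noise.
    retention_fraction:
        Local maxima below this fraction of a latent component's global
        maximum are suppressed before matching.
    trust_high, trust_low:
        Coefficient-of-determination thresholds (percent) separating
        trustworthy / borderline / not-trustworthy results.
    linewidth_c:
        Lorentzian FWHM (Hz) used for simulated 13C multiplet components.
        The default of 4.5 Hz matches typical processed 13C linewidths
        (including apodisation) and spans ~2 grid points on a zero-filled
        high-field carbon axis; much narrower values under-sample the
        lineshape on realistic grids.
    epsilon:
        Guard term (ppm^2) in the shift-distance-adjusted score, preventing
        divergence when the assigned shift coincides with the library shift.
    gamma_adjusted:
        Carbon-axis scaling inside the library-shift distance.
    j_scaling:
        Apparent-J multiplier: an integer in {1, 2, 4, 8}, or None for
        automatic detection from reference metabolites.
    n_components:
        Number of ICA sources, or None to choose by PCA explained variance.
    variance_threshold, max_components:
        Explained-variance fraction and cap for the automatic source count.
    ica_max_iter, ica_tol:
        FastICA fixed-point iteration limit and convergence tolerance.
    align_candidates:
        Number of best cross-correlation lags evaluated per component
        subset during 13C alignment; None evaluates every grid position.
    seed:
        Seed for the ICA initialisation (and any other randomness).
    """

    max_width_1h: float = 0.15
    max_width_13c: float = 3.0
    min_corr: float = 0.8
    retention_fraction: float = 0.5
    trust_high: float = 80.0
    trust_low: float = 70.0
    linewidth_c: float = 4.5
    epsilon: float = 1e-4
    gamma_adjusted: float = GAMMA_ADJUSTED
    j_scaling: Optional[int] = None
    n_components: Optional[int] = None
    variance_threshold: float = 0.995
    max_components: int = 10
    ica_max_iter: int = 500
    ica_tol: float = 1e-5
    align_candidates: Optional[int] = 15
    min_rho_for_detection: float = 50.0
    include_long_range: bool = False
    seed: int = 0
    library_path: Optional[Path] = None
    metabolites: Sequence[str] = field(default_factory=tuple)
    report_format: str = "json"
    extra_parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.max_width_1h <= 0 or self.max_width_13c <= 0:
            raise ValueError("search half-widths must be positive")
        if not 0.0 < self.min_corr < 1.0:
            raise ValueError("min_corr must lie in (0, 1)")
        if not 0.0 < self.retention_fraction < 1.0:
            raise ValueError("retention_fraction must lie in (0, 1)")
        if self.trust_high <= self.trust_low:
            raise ValueError("trust_high must exceed trust_low")
        if self.linewidth_c <= 0:
            raise ValueError("linewidth_c must be positive")
        if self.j_scaling is not None and self.j_scaling < 1:
            raise ValueError("j_scaling must be >= 1")

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["library_path"] = str(d["library_path"]) if d["library_path"] else None
        d["metabolites"] = list(d["metabolites"])
        return d
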