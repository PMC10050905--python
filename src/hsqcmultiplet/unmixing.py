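"""Blind separation of a search region into independent 13C source traces.

The region's 1H columns (13C 1D sub-spectra) are the observations of the
linear mixing model Y = W S: every column is an unknown nonnegative blend
of the K multiplet traces present in the window, plus noise.  Because
signals at different 1H shifts come from chemically distinct CH pairs, the
sources are statistically independent and FastICA recovers them up to sign
and scale.  Each recovered source is then placed along the proton dimension
by Pearson correlation against every column; sources correlating with no
column above ``min_corr`` are discarded as noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from sklearn.decomposition import FastICA, PCA
from sklearn.exceptions import ConvergenceWarning

from .config import AnalysisConfig, logger
from .spectral_io import SpectrumRegion


@dataclass
class LatentComponent:
    """One ICA source: a candidate 13C multiplet trace.

    The trace is oriented so its largest-magnitude extremum is positive
    (absorption peaks point up) and scaled to unit maximum; ``correlation``
    records the best column correlation even when below threshold.
    """

    trace: np.ndarray
    index: int
    assigned_h_ppm: Optional[float] = None
    correlation: float = 0.0

    def normalised(self) -> "LatentComponent":
        trace = np.asarray(self.trace, dtype=float)
        extremum = trace[np.argmax(np.abs(trace))]
        if extremum < 0:
            trace = -trace
        # ICA centres its sources, but an absorption-mode sub-spectrum has a
        # zero baseline: restore it by shifting the median (the baseline
        # level, since peaks occupy a minority of points) back to zero
        trace = trace - np.median(trace)
        peak = trace.max()
        if peak > 0:
            trace = trace / peak
        return LatentComponent(trace, self.index, self.assigned_h_ppm, self.correlation)


def _observation_matrix(region: SpectrumRegion) -> np.ndarray:
    # samples = 13C points, features = 1H columns (the observations)
    return np.asarray(region.intensities, dtype=float)


def choose_n_components(
    region: SpectrumRegion, variance_threshold: float = 0.995, cap: int = 10
) -> int:
    """Smallest K whose top-K principal components explain the threshold
    fraction of the region's signal variance, capped by *cap* and the
    column count.

    Noise spreads its variance evenly over all principal components, so a
    raw explained-variance cut-off would keep growing with the noise
    floor.  The eigenvalue spectrum is therefore corrected by the floor
    estimated from the median of its trailing half before the threshold
    is applied; a noiseless rank-k region still yields exactly k.
    """
    matrix = _observation_matrix(region)
    n_cols = matrix.shape[1]
    if not np.any(matrix):
        logger.warning("all-zero region; using a single component")
        return 1
    max_k = min(cap, n_cols, matrix.shape[0])
    pca = PCA(n_components=min(n_cols, matrix.shape[0]))
    pca.fit(matrix.T)
    eig = pca.explained_variance_
    floor = float(np.median(eig[eig.size // 2:])) if eig.size > 2 else 0.0
    corrected = np.maximum(eig - floor, 0.0)
    # eigenvalues inside the noise band (below ~the Marchenko-Pastur edge,
    # taken conservatively as 2.5x the floor) carry no signal
    corrected[eig < 2.5 * floor] = 0.0
    total = corrected.sum()
    if total <= 0:
        return 1
    cumulative = np.cumsum(corrected) / total
    reached = np.nonzero(cumulative >= variance_threshold)[0]
    k = int(reached[0]) + 1 if reached.size else max_k
    return max(1, min(k, max_k))


def decompose(
    region: SpectrumRegion,
    n_components: Optional[int] = None,
    seed: int = 0,
    variance_threshold: float = 0.995,
    max_components: int = 10,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> List[LatentComponent]:
    """Run fixed-point ICA on the region's columns; deterministic per seed.

    Returns unlocalised sources, orientation/scale normalised.  When the
    region has fewer columns than requested components the count is reduced
    with a warning; non-convergence returns the current estimate.
    """
    matrix = _observation_matrix(region)
    if matrix.shape[1] < 2:
        raise ValueError("region must span at least 2 proton columns")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("region intensities must be finite")
    if n_components is None:
        n_components = choose_n_components(region, variance_threshold, max_components)
    if n_components > matrix.shape[1]:
        logger.warning(
            "requested %d components but region has %d columns; reducing",
            n_components, matrix.shape[1])
        n_components = matrix.shape[1]
    ica = FastICA(
        n_components=n_components,
        algorithm="parallel",
        fun="logcosh",
        max_iter=max_iter,
        tol=tol,
        whiten="unit-variance",
        random_state=seed,
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            sources = ica.fit_transform(matrix)  # (n_13C_points, K)
        degenerate = not np.all(np.isfinite(sources))
    except ValueError:
        degenerate = True
    if degenerate:
        # effectively noiseless, rank-deficient data: the whitening step
        # divides by a zero variance; the principal components are already
        # the independent sources in this degenerate case
        logger.debug("ICA whitening degenerate; falling back to PCA sources")
        pca = PCA(n_components=n_components)
        pca.fit(matrix.T)
        sources = pca.components_.T
    elif ica.n_iter_ >= max_iter:
        logger.debug("FastICA stopped at the %d-iteration limit; "
                     "using current estimate", max_iter)
    return [
        LatentComponent(trace=sources[:, k], index=k).normalised()
        for k in range(sources.shape[1])
    ]


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-lag Pearson correlation; 0 when either signal is constant."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    da, db = a - a.mean(), b - b.mean()
    na, nb = np.linalg.norm(da), np.linalg.norm(db)
    if na == 0 or nb == 0:
        return 0.0
    return float(da @ db / (na * nb))


def localize_component(
    component: LatentComponent, region: SpectrumRegion, min_corr: float = 0.8
) -> Optional[LatentComponent]:
    """Assign the 1H shift of the best-correlating column, or reject.

    The component and the columns share the 13C axis, so the cross-
    correlation reduces to the zero-lag Pearson correlation.  Ties go to
    the column with larger total intensity, then to the lower index.
    """
    matrix = region.intensities
    if component.trace.size != matrix.shape[0]:
        raise ValueError("component length does not match the region's 13C axis")
    corrs = np.array([pearson(component.trace, matrix[:, j])
                      for j in range(matrix.shape[1])])
    best = corrs.max()
    candidates = np.nonzero(corrs >= best - 1e-12)[0]
    if candidates.size > 1:
        totals = matrix[:, candidates].sum(axis=0)
        candidates = candidates[totals == totals.max()]
    j = int(candidates[0])
    localized = LatentComponent(
        trace=component.trace,
        index=component.index,
        assigned_h_ppm=float(region.axis_h[j]),
        correlation=float(best),
    )
    if best < min_corr:
        logger.debug("component %d rejected: max correlation %.3f < %.3f",
                     component.index, best, min_corr)
        return None
    return localized


def localize_components(
    components: List[LatentComponent], region: SpectrumRegion, min_corr: float = 0.8
) -> List[LatentComponent]:
    """Localise every component, dropping those below *min_corr*."""
    out = []
    for comp in components:
        loc = localize_component(comp, region, min_corr)
        if loc is not None:
            out.append(loc)
    return out
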