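"""Sequencing-saturation analysis: subsample, call peaks, fit, extrapolate.

Observed depth fractions (10%..100%) are subsampled by binomial thinning and
peaks are called at each depth.  A Michaelis-Menten curve
``N(f) = Vmax * f / (K + f)`` is fitted to the observed counts and evaluated
over the full grid including virtual fractions (110%..200%).  The saturation
fraction f* is the smallest grid fraction at which the marginal peak gain
over the next 10% step falls below 1%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .io_formats import ChromSizes
from .peak_calling import PeakCallConfig, call_peaks

__all__ = [
    "SaturationCurve",
    "subsample_tags",
    "fit_saturation_curve",
    "saturation_analysis",
    "OBSERVED_FRACTIONS",
    "VIRTUAL_FRACTIONS",
]

OBSERVED_FRACTIONS = tuple(round(0.1 * i, 1) for i in range(1, 11))
VIRTUAL_FRACTIONS = tuple(round(0.1 * i, 1) for i in range(11, 21))


def subsample_tags(tags, fraction: float, seed: int = 0, exact: bool = False):
    """Random subsample of a tag list.

    Default is binomial thinning (each tag kept independently with
    probability ``fraction``); ``exact`` draws exactly
    ``round(fraction * n)`` tags without replacement.  Deterministic given
    ``seed``.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    tags = list(tags)
    if fraction == 1.0:
        return tags
    rng = np.random.default_rng(seed)
    if exact:
        k = int(round(fraction * len(tags)))
        idx = np.sort(rng.choice(len(tags), size=k, replace=False))
        return [tags[i] for i in idx]
    keep = rng.random(len(tags)) < fraction
    return [t for t, k in zip(tags, keep) if k]


@dataclass
class SaturationCurve:
    fractions: np.ndarray           # full grid (observed + virtual)
    observed_fractions: np.ndarray
    observed_counts: np.ndarray
    vmax: float | None
    k: float | None
    predicted: np.ndarray | None    # N-hat over the full grid
    saturation_fraction: float | None
    saturated_at_observed: bool | None
    saturation_gb: float | None = None

    @property
    def fitted(self) -> bool:
        return self.vmax is not None


def _mm(f, vmax, k):
    return vmax * f / (k + f)


def fit_saturation_curve(
    observed_fractions,
    observed_counts,
    virtual_fractions=VIRTUAL_FRACTIONS,
    gain_threshold: float = 0.01,
    model: str = "mm",
) -> SaturationCurve:
    """Fit the saturation model to observed peak counts and locate f*.

    ``model`` is ``"mm"`` (Michaelis-Menten, default) or ``"exp"``
    (asymptotic exponential ``Vmax * (1 - exp(-f/K))``).
    """
    f_obs = np.asarray(observed_fractions, dtype=np.float64)
    n_obs = np.asarray(observed_counts, dtype=np.float64)
    grid = np.concatenate([f_obs, np.asarray(virtual_fractions, dtype=np.float64)])
    curve = SaturationCurve(
        fractions=grid,
        observed_fractions=f_obs,
        observed_counts=n_obs,
        vmax=None,
        k=None,
        predicted=None,
        saturation_fraction=None,
        saturated_at_observed=None,
    )
    if n_obs.max() <= 0:
        warnings.warn("saturation fit: all peak counts are zero", stacklevel=2)
        return curve
    if model == "mm":
        func = _mm
    elif model == "exp":
        def func(f, vmax, k):
            return vmax * (1.0 - np.exp(-f / k))
    else:
        raise ValueError(f"unknown model {model!r}")
    if np.allclose(n_obs, n_obs[0]):
        # constant counts: saturated from the first fraction on
        vmax, k = float(n_obs[0]), 1e-9
    else:
        try:
            (vmax, k), _ = curve_fit(
                func,
                f_obs,
                n_obs,
                p0=(n_obs.max() * 1.5, 0.5),
                bounds=((0, 1e-9), (np.inf, np.inf)),
                maxfev=20_000,
            )
        except RuntimeError as exc:
            warnings.warn(f"saturation fit failed: {exc}", stacklevel=2)
            return curve
    predicted = func(grid, vmax, k)
    curve.vmax = float(vmax)
    curve.k = float(k)
    curve.predicted = predicted
    # f*: smallest grid fraction with < gain_threshold relative gain per +0.1
    fstar = None
    for f in grid:
        nf = func(f, vmax, k)
        nf_next = func(f + 0.1, vmax, k)
        if nf > 0 and (nf_next - nf) / nf < gain_threshold:
            fstar = float(f)
            break
    if fstar is None:
        fstar = float(grid[-1])  # not reached anywhere on the grid: cap at grid max
    curve.saturation_fraction = fstar
    curve.saturated_at_observed = fstar <= 1.0
    if not curve.saturated_at_observed:
        warnings.warn("not saturated at observed depth (f* > 1.0)", stacklevel=2)
    return curve


def saturation_analysis(
    tags,
    peak_config: PeakCallConfig,
    chrom_sizes: ChromSizes,
    fractions=OBSERVED_FRACTIONS,
    seed: int = 0,
    read_length: int | None = None,
    gain_threshold: float = 0.01,
    model: str = "mm",
) -> SaturationCurve:
    """Subsample at each observed fraction, call peaks, fit and extrapolate.

    With ``read_length`` the saturation point is also reported in gigabases
    (f* x tags x read length / 1e9).
    """
    tags = list(tags)
    counts = []
    for i, f in enumerate(fractions):
        sub = subsample_tags(tags, f, seed=seed + i) if f < 1.0 else tags
        counts.append(len(call_peaks(sub, peak_config, chrom_sizes)))
    curve = fit_saturation_curve(
        fractions, counts, gain_threshold=gain_threshold, model=model
    )
    if read_length is not None and curve.saturation_fraction is not None:
        curve.saturation_gb = (
            curve.saturation_fraction * len(tags) * read_length / 1e9
        )
    return curve
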