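"""Maximal-flux decomposition and response metrics.

The headline quantities of the analysis: for each dephosphorylation route
the maximum instantaneous flux over the stimulation window, the ratios and
percentage contributions between routes, the post-inhibitor decay
half-life, and peak metrics of the observables.

"Maximal flux" is the per-route maximum of instantaneous flux over the
stimulated window (default [0, 900] s), read off the dense grid with local
quadratic refinement.  Routes sharing an enzyme (PTEN acts on both
PI(3,4,5)P3 and PI(3,4)P2) are reported separately per substrate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .model import Species
from .simulate import Trajectory

__all__ = [
    "PIP3_ROUTES",
    "PI34P2_ROUTES",
    "FluxDecomposition",
    "maximal_flux_decomposition",
    "flux_ratio",
    "percent_contribution",
    "half_life_after_inhibition",
    "peak_metrics",
    "HalfLifeError",
]

#: Route label -> reaction id.  PI(3,4,5)P3 dephosphorylation: PTEN back to
#: PI(4,5)P2; SHIP2 and the lumped 5-phosphatase pool X forward to PI(3,4)P2.
PIP3_ROUTES: dict[str, str] = {
    "PTEN->PI45P2": "pten_pip3",
    "SHIP2->PI34P2": "ship2_pip3",
    "X->PI34P2": "x_pip3",
}

#: PI(3,4)P2 dephosphorylation: INPP4B (4-phosphatase), PTEN (3-phosphatase)
#: and the unknown residual phosphatase Y.
PI34P2_ROUTES: dict[str, str] = {
    "INPP4B": "inpp4b_pi34p2",
    "PTEN": "pten_pi34p2",
    "Y": "y_pi34p2",
}

_ALL_ROUTES = {**PIP3_ROUTES, **PI34P2_ROUTES}


class HalfLifeError(RuntimeError):
    """Raised when a species never decays to its half level post-event."""


def _refined_max(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(t_max, y_max) from a grid, quadratically refined around the argmax."""
    i = int(np.argmax(y))
    if i == 0 or i == len(y) - 1:
        return float(t[i]), float(y[i])
    t0, t1, t2 = t[i - 1], t[i], t[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (t0 - t1) * (t0 - t2) * (t1 - t2)
    if denom == 0:
        return float(t1), float(y1)
    a = (t2 * (y1 - y0) + t1 * (y0 - y2) + t0 * (y2 - y1)) / denom
    b = (t2**2 * (y0 - y1) + t1**2 * (y2 - y0) + t0**2 * (y1 - y2)) / denom
    if a >= 0:  # not locally concave; keep the grid point
        return float(t1), float(y1)
    t_pk = -b / (2 * a)
    if not (t0 <= t_pk <= t2):
        return float(t1), float(y1)
    c = y1 - a * t1**2 - b * t1
    return float(t_pk), float(a * t_pk**2 + b * t_pk + c)


@dataclass(frozen=True)
class FluxDecomposition:
    """Per-route maximal dephosphorylation fluxes over a window (a.u./s)."""

    genotype: str
    maxima: Mapping[str, float]
    window: tuple[float, float]

    def __getitem__(self, route: str) -> float:
        return self.maxima[route]


def maximal_flux_decomposition(
    trajectory: Trajectory, genotype: str = "", window: tuple[float, float] | None = None
) -> FluxDecomposition:
    """Maximum instantaneous flux of each dephosphorylation route.

    A route whose enzyme activity is zero has maximal flux exactly 0.
    """
    if window is None:
        window = (float(trajectory.times[0]), float(trajectory.times[-1]))
    mask = (trajectory.times >= window[0]) & (trajectory.times <= window[1])
    t = trajectory.times[mask]
    maxima: dict[str, float] = {}
    for label, rx_id in _ALL_ROUTES.items():
        try:
            f = trajectory.flux(rx_id)[mask]
        except KeyError:
            continue
        rx = trajectory.model.reaction(rx_id)
        if trajectory.model.activity(rx.enzyme) == 0.0:
            maxima[label] = 0.0
            continue
        _, fmax = _refined_max(t, f)
        maxima[label] = max(fmax, 0.0)
    return FluxDecomposition(genotype=genotype, maxima=maxima, window=window)


def flux_ratio(
    decomp: FluxDecomposition,
    numerator: Sequence[str],
    denominator: Sequence[str],
    allow_infinite: bool = False,
) -> float:
    """Sum of numerator-route maxima over sum of denominator-route maxima."""
    num = sum(decomp.maxima[r] for r in numerator)
    den = sum(decomp.maxima[r] for r in denominator)
    if den == 0:
        if allow_infinite:
            return float("inf")
        raise ZeroDivisionError(
            f"denominator routes {list(denominator)} carry zero maximal flux"
        )
    return num / den


def percent_contribution(
    decomp: FluxDecomposition, route: str, route_set: Sequence[str]
) -> float:
    """Percentage of one route's maximal flux within a route set."""
    if route not in route_set:
        raise ValueError(f"route {route!r} not in route set {list(route_set)}")
    total = sum(decomp.maxima[r] for r in route_set)
    if total == 0:
        raise ZeroDivisionError("route set carries zero total maximal flux")
    return 100.0 * decomp.maxima[route] / total


def half_life_after_inhibition(
    trajectory: Trajectory, species: Species
) -> float:
    """Seconds after the inhibitor event for the observable to fall halfway
    from its event value to the post-event plateau.

    The plateau is the post-event minimum (basal/background signal
    persists, so zero is not assumed).  The crossing is located on the
    dense grid and refined by linear interpolation between grid points.
    """
    ev = trajectory.protocol.inhibitor
    if ev is None:
        raise ValueError("trajectory has no inhibitor event")
    t = trajectory.times
    y = trajectory.observable(species)
    mask = t >= ev.time
    if mask.sum() < 3:
        raise HalfLifeError("too few post-event samples")
    tp, yp = t[mask], y[mask]
    y_event = float(np.interp(ev.time, t, y))
    plateau = float(yp.min())
    half = 0.5 * (y_event + plateau)
    if y_event <= plateau or not np.any(yp <= half):
        raise HalfLifeError(
            f"{species.value} never falls to half level after the event "
            f"(event value {y_event:.4g}, plateau {plateau:.4g}); "
            "no decay — was the inhibition a sham event?"
        )
    i = int(np.argmax(yp <= half))
    if i == 0:
        return 0.0
    t_cross = float(
        np.interp(half, [yp[i], yp[i - 1]], [tp[i], tp[i - 1]])
    )
    return t_cross - ev.time


def peak_metrics(
    trajectory: Trajectory, species: Species
) -> tuple[float, float, float]:
    """(t_peak, peak, fold_over_basal) of the observable on the dense grid.

    The fold change is relative to the t = 0 observable (background-
    inclusive for PI(3,4)P2).  A flat trajectory reports its initial point.
    """
    t = trajectory.times
    y = trajectory.observable(species)
    basal = float(y[0])
    t_pk, y_pk = _refined_max(t, y)
    if np.allclose(y, basal, rtol=1e-12, atol=1e-12):
        return float(t[0]), basal, 1.0
    fold = y_pk / basal if basal > 0 else float("inf")
    return t_pk, y_pk, fold
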