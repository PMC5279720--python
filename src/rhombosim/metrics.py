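"""Boundary-sharpness quantification.

The transition region between two fate zones is delimited by the *anterior
edge* (leftmost cell of the posterior-zone fate) and the *posterior edge*
(rightmost cell of the anterior-zone fate); its width is

    TW = max(0, posterior_edge - anterior_edge + 1)   [cell diameters]

so a manually built half-half random band of width ITW (with both fates
present in its extreme columns) measures exactly ITW and a perfectly sorted
straight interface measures 0.

A cell is *mislocated* when its fate disagrees with the side it occupies of
the best vertical split x* (the split minimising the number of fate/side
disagreements).  The Sharpness Index is the population standard deviation of
the mislocated cells' center distances to the transition-region midline
(0 when at most one cell is mislocated).  Runs are classified at the final
time as boundary formed (0 mislocated), nearly formed (1-2) or failed to
form (>= 3, or a fate has vanished from its own zone).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .scem_mechanics import Fate, Tissue

__all__ = [
    "Boundary",
    "TWO_ZONE_BOUNDARY",
    "transition_edges",
    "transition_width",
    "mislocated_cells",
    "best_split",
    "sharpness_index",
    "classify_outcome",
    "MetricsSeries",
    "ensemble_summary",
    "EnsembleSummary",
]


@dataclass(frozen=True)
class Boundary:
    """One fate interface: ``left_fate`` occupies x < boundary < ``right_fate``.

    ``x_range`` restricts all metrics to cells whose center falls inside it
    (used to separate the two boundaries of three-zone runs); ``None`` means
    the whole domain.
    """

    name: str = "A|B"
    left_fate: Fate = Fate.A
    right_fate: Fate = Fate.B
    x_range: tuple[float, float] | None = None


TWO_ZONE_BOUNDARY = Boundary()


def _select(tissue: Tissue, boundary: Boundary) -> tuple[np.ndarray, np.ndarray]:
    """Center x positions and fates of the cells relevant to this boundary."""

    x = tissue.centers()[:, 0]
    fates = tissue.fate
    if boundary.x_range is not None:
        lo, hi = boundary.x_range
        keep = (x >= lo) & (x < hi)
        return x[keep], fates[keep]
    return x, fates.copy()


def transition_edges(tissue: Tissue, boundary: Boundary = TWO_ZONE_BOUNDARY):
    """(anterior_edge, posterior_edge) of the transition zone, in x.

    anterior edge: minimum center-x over right-zone-fate cells; posterior
    edge: maximum center-x over left-zone-fate cells.  Either is ``nan`` when
    its fate is absent from the (sub-)domain, e.g. after one zone overruns
    the other.
    """

    x, fates = _select(tissue, boundary)
    right = x[fates == int(boundary.right_fate)]
    left = x[fates == int(boundary.left_fate)]
    anterior = float(right.min()) if len(right) else float("nan")
    posterior = float(left.max()) if len(left) else float("nan")
    return anterior, posterior


def transition_width(tissue: Tissue, boundary: Boundary = TWO_ZONE_BOUNDARY) -> float:
    """Transition width TW in cell diameters; ``nan`` when edges are undefined."""

    anterior, posterior = transition_edges(tissue, boundary)
    if np.isnan(anterior) or np.isnan(posterior):
        return float("nan")
    return max(0.0, posterior - anterior + 1.0)


def best_split(x: np.ndarray, fates: np.ndarray, boundary: Boundary = TWO_ZONE_BOUNDARY) -> float:
    """Vertical split position x* minimising fate/side disagreements.

    Cells with center < x* should carry ``boundary.left_fate``; cells with
    center >= x* should carry ``boundary.right_fate``.  Candidate splits are
    the midpoints between consecutive distinct center positions plus the two
    outer positions; ties are resolved by the median of the minimising
    candidates.
    """

    if len(x) == 0:
        raise ValueError("no cells to split")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    fs = fates[order]
    uniq = np.unique(xs)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    is_left = fs == int(boundary.left_fate)
    # disagreements(c) = #left-fate cells right of c + #right-fate cells left of c
    n_right_fate_upto = np.cumsum(~is_left)
    total_left_fate = int(np.sum(is_left))
    counts = np.empty(len(candidates))
    for k, c in enumerate(candidates):
        n_before = int(np.searchsorted(xs, c, side="left"))
        right_fate_before = n_right_fate_upto[n_before - 1] if n_before else 0
        left_fate_before = n_before - right_fate_before
        counts[k] = (total_left_fate - left_fate_before) + right_fate_before
    minimal = candidates[counts == counts.min()]
    return float(np.median(minimal))


def mislocated_cells(
    tissue: Tissue, boundary: Boundary = TWO_ZONE_BOUNDARY
) -> tuple[np.ndarray, float]:
    """(indices of mislocated cells, best split x*).

    Indices refer to cell ids of the full tissue even when the boundary has a
    restricted ``x_range``.
    """

    x_all = tissue.centers()[:, 0]
    fates_all = tissue.fate
    if boundary.x_range is not None:
        lo, hi = boundary.x_range
        keep = np.flatnonzero((x_all >= lo) & (x_all < hi))
    else:
        keep = np.arange(tissue.n_cells)
    x = x_all[keep]
    fates = fates_all[keep]
    xstar = best_split(x, fates, boundary)
    left_side = x < xstar
    expected = np.where(left_side, int(boundary.left_fate), int(boundary.right_fate))
    return keep[fates != expected], xstar


def sharpness_index(tissue: Tissue, boundary: Boundary = TWO_ZONE_BOUNDARY) -> float:
    """Population std of mislocated-cell distances to the transition midline.

    0 when at most one cell is mislocated; ``nan`` when the midline is
    undefined because a fate is absent.
    """

    anterior, posterior = transition_edges(tissue, boundary)
    if np.isnan(anterior) or np.isnan(posterior):
        return float("nan")
    mis, _ = mislocated_cells(tissue, boundary)
    if len(mis) <= 1:
        return 0.0
    midline = 0.5 * (anterior + posterior)
    dist = np.abs(tissue.centers()[mis, 0] - midline)
    return float(dist.std())  # population (ddof=0) standard deviation


def classify_outcome(tissue: Tissue, boundary: Boundary = TWO_ZONE_BOUNDARY) -> str:
    """"formed" (0 mislocated), "nearly_formed" (1-2), else "failed"."""

    x_all = tissue.centers()[:, 0]
    fates_all = tissue.fate
    if boundary.x_range is not None:
        lo, hi = boundary.x_range
        keep = (x_all >= lo) & (x_all < hi)
        x, fates = x_all[keep], fates_all[keep]
    else:
        x, fates = x_all, fates_all
    if not np.any(fates == int(boundary.left_fate)) or not np.any(
        fates == int(boundary.right_fate)
    ):
        return "failed"
    mis, xstar = mislocated_cells(tissue, boundary)
    # each fate must still hold its own zone
    left_ok = np.any((x < xstar) & (fates == int(boundary.left_fate)))
    right_ok = np.any((x >= xstar) & (fates == int(boundary.right_fate)))
    if not (left_ok and right_ok):
        return "failed"
    n = len(mis)
    if n == 0:
        return "formed"
    if n <= 2:
        return "nearly_formed"
    return "failed"


# ---------------------------------------------------------------------------
# time series and ensembles


@dataclass
class MetricsSeries:
    """Per-run time series of the boundary metrics plus the final outcome."""

    boundary: Boundary
    times: list[float] = field(default_factory=list)
    anterior_edge: list[float] = field(default_factory=list)
    posterior_edge: list[float] = field(default_factory=list)
    TW: list[float] = field(default_factory=list)
    SI: list[float] = field(default_factory=list)
    mislocated_count: list[int] = field(default_factory=list)
    outcome: str | None = None

    def record(self, tissue: Tissue) -> None:
        anterior, posterior = transition_edges(tissue, self.boundary)
        self.times.append(tissue.time)
        self.anterior_edge.append(anterior)
        self.posterior_edge.append(posterior)
        if np.isnan(anterior) or np.isnan(posterior):
            self.TW.append(float("nan"))
        else:
            self.TW.append(max(0.0, posterior - anterior + 1.0))
        self.SI.append(sharpness_index(tissue, self.boundary))
        mis, _ = mislocated_cells(tissue, self.boundary)
        self.mislocated_count.append(len(mis))

    def finalize(self, tissue: Tissue) -> None:
        self.outcome = classify_outcome(tissue, self.boundary)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_hpf": self.times,
                "anterior_edge": self.anterior_edge,
                "posterior_edge": self.posterior_edge,
                "TW": self.TW,
                "SI": self.SI,
                "mislocated_count": self.mislocated_count,
            }
        )


@dataclass
class EnsembleSummary:
    times: np.ndarray
    mean_TW: np.ndarray
    sd_TW: np.ndarray
    mean_SI: np.ndarray
    sd_SI: np.ndarray
    mean_anterior: np.ndarray
    mean_posterior: np.ndarray
    outcome_counts: dict[str, int]
    density_profile: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_hpf": self.times,
                "mean_TW": self.mean_TW,
                "sd_TW": self.sd_TW,
                "mean_SI": self.mean_SI,
                "sd_SI": self.sd_SI,
                "mean_anterior_edge": self.mean_anterior,
                "mean_posterior_edge": self.mean_posterior,
            }
        )


def b_fraction_profile(tissues: Sequence[Tissue], bin_width: float = 1.0) -> pd.DataFrame:
    """Fraction of B-fate cells per x bin, pooled over tissues."""

    xs = np.concatenate([t.centers()[:, 0] for t in tissues])
    fb = np.concatenate([(t.fate == int(Fate.B)).astype(float) for t in tissues])
    x0 = min(t.domain[0] for t in tissues)
    x1 = max(t.domain[1] for t in tissues)
    edges = np.arange(x0, x1 + bin_width, bin_width)
    idx = np.clip(np.digitize(xs, edges) - 1, 0, len(edges) - 2)
    total = np.bincount(idx, minlength=len(edges) - 1)
    nb = np.bincount(idx, weights=fb, minlength=len(edges) - 1)
    with np.errstate(invalid="ignore"):
        frac = np.where(total > 0, nb / np.maximum(total, 1), np.nan)
    return pd.DataFrame(
        {"x": 0.5 * (edges[:-1] + edges[1:]), "n_cells": total, "B_fraction": frac}
    )


def ensemble_summary(
    runs: Iterable[MetricsSeries], final_tissues: Sequence[Tissue] | None = None
) -> EnsembleSummary:
    """Pointwise mean/sd of TW, SI and edges over replicate runs.

    All runs must share the same time grid.  Undefined values (a fate absent)
    are excluded pointwise via nan-aware means, and the outcome histogram
    counts each run's final classification.  When final tissues are supplied
    the pooled B-fraction density profile is attached.
    """

    runs = list(runs)
    if not runs:
        raise ValueError("ensemble_summary needs at least one run")
    times = np.asarray(runs[0].times)
    for r in runs[1:]:
        if len(r.times) != len(times) or not np.allclose(r.times, times):
            raise ValueError("inconsistent time grids across runs")
    tw = np.array([r.TW for r in runs])
    si = np.array([r.SI for r in runs])
    ant = np.array([r.anterior_edge for r in runs])
    post = np.array([r.posterior_edge for r in runs])
    counts = {"formed": 0, "nearly_formed": 0, "failed": 0}
    for r in runs:
        if r.outcome is not None:
            counts[r.outcome] += 1
    with np.errstate(invalid="ignore"):
        summary = EnsembleSummary(
            times=times,
            mean_TW=np.nanmean(tw, axis=0),
            sd_TW=np.nanstd(tw, axis=0),
            mean_SI=np.nanmean(si, axis=0),
            sd_SI=np.nanstd(si, axis=0),
            mean_anterior=np.nanmean(ant, axis=0),
            mean_posterior=np.nanmean(post, axis=0),
            outcome_counts=counts,
        )
    if final_tissues is not None:
        summary.density_profile = b_fraction_profile(final_tissues)
    return summary
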