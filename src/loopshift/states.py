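"""Loop conformational state labeling and population statistics.

Each frame is assigned to one of ``closed``, ``open``, ``wide_open`` or
``other`` from its loop-Cα RMSD to the three reference conformations:
the candidate state is the argmin of the three RMSDs, accepted if that RMSD
is at or below the state's cutoff, otherwise the frame is ``other``.
Ties are broken by the fixed priority closed > open > wide_open, so labeling
is deterministic.  ``other`` frames are excluded from state-conditioned
downstream statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import AlignmentError, EmptySeriesError, ConfigError

__all__ = [
    "STATE_NAMES",
    "StateLabelSeries",
    "RmsdHistogram",
    "label_states",
    "rmsd_histogram",
    "fraction_below",
    "FractionBelow",
    "state_populations",
    "StatePopulations",
    "closure_analysis",
]

#: Label vocabulary; array codes are indices into this tuple.
STATE_NAMES = ("closed", "open", "wide_open", "other")
OTHER = 3


@dataclass
class StateLabelSeries:
    """Per-(replica, frame) categorical loop-state assignment.

    ``labels`` holds integer codes into :data:`STATE_NAMES`.
    """

    labels: np.ndarray                    # (R, F) int8
    thresholds_used: Mapping[str, float]
    rmsd_inputs: Mapping[str, np.ndarray] | None = None

    @property
    def n_replicas(self) -> int:
        return self.labels.shape[0]

    @property
    def n_frames(self) -> int:
        return self.labels.shape[1]

    def as_names(self) -> np.ndarray:
        return np.asarray(STATE_NAMES)[self.labels]

    def to_frame(self) -> pd.DataFrame:
        r, f = np.meshgrid(np.arange(self.n_replicas),
                           np.arange(self.n_frames), indexing="ij")
        return pd.DataFrame({"replica": r.ravel(), "frame": f.ravel(),
                             "label": self.as_names().ravel()})


def label_states(rmsd_closed: np.ndarray, rmsd_open: np.ndarray,
                 rmsd_wide: np.ndarray,
                 cutoffs: Mapping[str, float]) -> StateLabelSeries:
    """Argmin-then-threshold state labeling.

    ``cutoffs`` maps ``closed``/``open``/``wide_open`` to Å values; a frame
    whose winning RMSD exceeds its state's cutoff becomes ``other``.
    """
    a, b, c = (np.asarray(x, dtype=float) for x in (rmsd_closed, rmsd_open, rmsd_wide))
    if not (a.shape == b.shape == c.shape):
        raise AlignmentError("RMSD series are not aligned on (replica, frame)")
    for s in ("closed", "open", "wide_open"):
        if s not in cutoffs or cutoffs[s] <= 0:
            raise ConfigError(f"positive cutoff required for state {s!r}")
    stacked = np.stack([a, b, c])                      # priority order
    winner = np.argmin(stacked, axis=0)                # first wins ties
    win_rmsd = np.take_along_axis(stacked, winner[None], axis=0)[0]
    cut = np.asarray([cutoffs["closed"], cutoffs["open"], cutoffs["wide_open"]])
    labels = np.where(win_rmsd <= cut[winner], winner, OTHER).astype(np.int8)
    return StateLabelSeries(labels=labels, thresholds_used=dict(cutoffs),
                            rmsd_inputs={"closed": a, "open": b, "wide_open": c})


@dataclass
class RmsdHistogram:
    """Uniform-width histogram of an RMSD series, edges anchored at 0 Å."""

    bin_edges: np.ndarray
    counts: np.ndarray
    normalized: np.ndarray   # probability per bin, sums to 1

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_lo": self.bin_edges[:-1],
                             "bin_hi": self.bin_edges[1:],
                             "count": self.counts,
                             "density": self.normalized})


def rmsd_histogram(series: np.ndarray, bin_width: float = 0.16) -> RmsdHistogram:
    """Histogram with edges at 0, w, 2w, ... covering max(series).

    The default bin width of 0.16 Å matches the loop-RMSD population
    histograms this package is built to reproduce; counts conserve frames.
    """
    values = np.asarray(series, dtype=float).ravel()
    if values.size == 0:
        raise EmptySeriesError("cannot histogram an empty series")
    if bin_width <= 0:
        raise ConfigError("bin_width must be positive")
    n_bins = max(1, int(np.ceil((values.max() + 1e-12) / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(values, bins=edges)
    return RmsdHistogram(bin_edges=edges, counts=counts,
                         normalized=counts / counts.sum())


@dataclass
class FractionBelow:
    """Fraction of frames with RMSD <= cutoff, pooled and per replica."""

    cutoff: float
    pooled: float
    per_replica: np.ndarray


def fraction_below(series: np.ndarray, cutoff: float) -> FractionBelow:
    """Proportion of frames at or below ``cutoff`` (inclusive).

    ``series`` may be 1-D (pooled only) or (replicas, frames).
    """
    if cutoff <= 0:
        raise ConfigError("cutoff must be positive")
    values = np.asarray(series, dtype=float)
    if values.size == 0:
        raise EmptySeriesError("cannot compute fraction of an empty series")
    hit = values <= cutoff
    per_replica = (hit.mean(axis=1) if values.ndim == 2
                   else np.array([hit.mean()]))
    return FractionBelow(cutoff=cutoff, pooled=float(hit.mean()),
                         per_replica=per_replica)


@dataclass
class StatePopulations:
    """Per-state occupancy fractions with between-replica uncertainty."""

    per_replica: pd.DataFrame   # replicas x states, rows sum to 1
    pooled: pd.Series           # frame-weighted mean over replicas
    se: pd.Series               # between-replica SD / sqrt(n_replicas)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"state": self.pooled.index,
                             "pooled_fraction": self.pooled.values,
                             "se": self.se.values})


def state_populations(labels: StateLabelSeries) -> StatePopulations:
    """Fraction of frames in each state, per replica and pooled.

    The pooled value is the frame-weighted mean (all replicas have equal
    frame counts, so it equals the replica mean); the standard error is the
    between-replica standard deviation over sqrt(n_replicas) — replicas,
    not frames, are the statistical unit.
    """
    if labels.labels.size == 0:
        raise EmptySeriesError("empty label series")
    lab = labels.labels
    n_rep = lab.shape[0]
    frac = np.stack([(lab == k).mean(axis=1) for k in range(4)], axis=1)
    per_replica = pd.DataFrame(frac, columns=list(STATE_NAMES))
    pooled = pd.Series([(lab == k).mean() for k in range(4)],
                       index=list(STATE_NAMES))
    if n_rep > 1:
        se = per_replica.std(axis=0, ddof=1) / np.sqrt(n_rep)
    else:
        se = pd.Series(np.zeros(4), index=list(STATE_NAMES))
    return StatePopulations(per_replica=per_replica, pooled=pooled, se=se)


def closure_analysis(rmsd_closed: np.ndarray, com_dist: np.ndarray,
                     window: int, rmsd_cut: float,
                     dist_cut: float) -> pd.DataFrame:
    """Terminal-window closure/productivity table, one row per replica.

    Over the last ``window`` frames of each replica: the mean RMSD to the
    closed reference and the mean catalytic-arginine-style COM distance.
    ``productive`` is True when the mean distance is at or below
    ``dist_cut``; ``closed`` when the mean RMSD is at or below ``rmsd_cut``.
    The joint table supports asking whether closure occurs only in
    productive replicas.
    """
    r = np.asarray(rmsd_closed, dtype=float)
    d = np.asarray(com_dist, dtype=float)
    if r.shape != d.shape:
        raise AlignmentError("RMSD and COM-distance series are not aligned")
    if not 1 <= window <= r.shape[1]:
        raise ConfigError(f"window {window} outside 1..{r.shape[1]}")
    mean_rmsd = r[:, -window:].mean(axis=1)
    mean_dist = d[:, -window:].mean(axis=1)
    df = pd.DataFrame({
        "replica": np.arange(r.shape[0]),
        "mean_rmsd": mean_rmsd,
        "mean_dist": mean_dist,
        "closed": mean_rmsd <= rmsd_cut,
        "productive": mean_dist <= dist_cut,
    })
    return df
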