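"""Per-replica RMSF, between-variant differences, and significance testing.

The statistical unit is the replica, never the frame: frames within a
replica are autocorrelated, so per-residue RMSF values are computed
independently for each replica and the two variants are compared with a
two-sided t-test over replicas (Welch by default), followed by
Benjamini–Hochberg control of the false discovery rate across all residues
tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ensemble_io import AtomIndexSet, ReplicaEnsemble, Topology, write_per_residue_scores
from .errors import AlignmentError, ConfigError, EmptySeriesError
from .geometry import _batched_rotations
from .states import StateLabelSeries, STATE_NAMES

__all__ = [
    "RmsfMatrix",
    "DeltaRmsfReport",
    "rmsf_per_replica",
    "delta_rmsf",
    "per_residue_ttest",
    "benjamini_hochberg",
    "significance_report",
]


@dataclass
class RmsfMatrix:
    """Per-(replica, residue) root-mean-square fluctuations in Å.

    ``values`` is a DataFrame with one row per retained replica and one
    column per residue_index carrying a Cα atom in the selection.
    ``alignment_spec`` records the fit used so downstream reports can echo
    it.
    """

    values: pd.DataFrame
    alignment_spec: str
    state_filter: str | None = None

    @property
    def residue_index(self) -> np.ndarray:
        return self.values.columns.to_numpy()


def _two_pass_rmsf(frames: np.ndarray, fit_pos: np.ndarray,
                   sel_pos: np.ndarray) -> np.ndarray:
    """Align frames to the replica mean structure (two passes), then RMSF.

    frames: (F, n_atoms, 3).  Returns per-selected-atom RMSF.
    """
    w = np.ones(len(fit_pos))
    aligned_sel = frames[:, sel_pos, :]
    mean_fit = frames[:, fit_pos, :].mean(axis=0)
    for _ in range(2):
        Pf = frames[:, fit_pos, :]
        cm = Pf.mean(axis=1)                       # (F, 3)
        cr = mean_fit.mean(axis=0)                 # (3,)
        R = _batched_rotations(Pf - cm[:, None, :], mean_fit - cr, w)
        shift = cr - np.einsum("fij,fj->fi", R, cm)
        aligned_fit = np.einsum("fij,fnj->fni", R, frames[:, fit_pos, :]) + shift[:, None, :]
        aligned_sel = np.einsum("fij,fnj->fni", R, frames[:, sel_pos, :]) + shift[:, None, :]
        mean_fit = aligned_fit.mean(axis=0)
    mean_sel = aligned_sel.mean(axis=0)
    dev = aligned_sel - mean_sel[None]
    return np.sqrt(np.einsum("fni,fni->n", dev, dev) / frames.shape[0])


def rmsf_per_replica(ensemble: ReplicaEnsemble, selection: AtomIndexSet,
                     fit: AtomIndexSet | None = None,
                     state_filter: tuple[StateLabelSeries, str] | None = None,
                     ) -> RmsfMatrix:
    """Per-replica, per-residue Cα RMSF.

    Parameters
    ----------
    selection : Cα atoms to report RMSF for (one per residue).
    fit : atoms used for the mean-structure superposition; defaults to the
        selection itself.  Fitting on a rigid scaffold (e.g. non-loop Cα)
        avoids the loop's own motion contaminating the global fit.
    state_filter : optional ``(labels, state_name)`` pair; only frames in
        that state contribute.  Replicas left with fewer than 2 frames are
        dropped with a warning; fewer than 2 surviving replicas is an error.
    """
    top = ensemble.topology
    sel_pos = selection.positions(top)
    fit_sel = fit or selection
    fit_pos = fit_sel.positions(top)
    res_idx = top.residue_indices[sel_pos]

    keep_mask = None
    if state_filter is not None:
        labels, state = state_filter
        if state not in STATE_NAMES:
            raise ConfigError(f"unknown state {state!r}")
        if labels.labels.shape[:2] != ensemble.coords.shape[:2]:
            raise AlignmentError("labels are not aligned with the ensemble")
        keep_mask = labels.as_names() == state

    rows, kept = [], []
    for r in range(ensemble.n_replicas):
        frames = ensemble.coords[r]
        if keep_mask is not None:
            frames = frames[keep_mask[r]]
        if frames.shape[0] < 2:
            warnings.warn(f"replica {r} has <2 frames after state filtering; dropped")
            continue
        rows.append(_two_pass_rmsf(frames, fit_pos, sel_pos))
        kept.append(r)
    if len(rows) < 2:
        raise EmptySeriesError("fewer than 2 replicas survive the state filter")
    values = pd.DataFrame(np.stack(rows), index=kept, columns=res_idx)
    spec = f"two-pass mean-structure fit on {fit_sel.label} ({len(fit_sel)} atoms)"
    return RmsfMatrix(values=values, alignment_spec=spec,
                      state_filter=None if state_filter is None else state_filter[1])


def _check_axes(mat_a: RmsfMatrix, mat_b: RmsfMatrix) -> None:
    if not np.array_equal(mat_a.residue_index, mat_b.residue_index):
        raise AlignmentError("RMSF matrices have different residue axes")


def delta_rmsf(mat_a: RmsfMatrix, mat_b: RmsfMatrix) -> pd.Series:
    """Per-residue mean RMSF difference, A minus B (positive = more
    flexible in A)."""
    _check_axes(mat_a, mat_b)
    return mat_a.values.mean(axis=0) - mat_b.values.mean(axis=0)


def per_residue_ttest(mat_a: RmsfMatrix, mat_b: RmsfMatrix,
                      variant: str = "welch") -> pd.Series:
    """Two-sided t-test per residue over replicate RMSF values.

    Welch's unequal-variance test is the default; ``variant="student"``
    gives the pooled-variance test.  Residues with zero variance in both
    groups and equal means get p = 1 by convention.
    """
    _check_axes(mat_a, mat_b)
    if variant not in ("welch", "student"):
        raise ConfigError(f"t-test variant must be welch or student, got {variant!r}")
    if len(mat_a.values) < 2 or len(mat_b.values) < 2:
        raise EmptySeriesError("t-test needs >=2 replicas per group")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(mat_a.values.to_numpy(), mat_b.values.to_numpy(),
                              axis=0, equal_var=(variant == "student"))
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    means_equal = np.isclose(mat_a.values.mean(axis=0), mat_b.values.mean(axis=0))
    p[degenerate & means_equal] = 1.0
    p[degenerate & ~means_equal] = 0.0
    return pd.Series(p, index=mat_a.residue_index)


def benjamini_hochberg(p_values, fdr: float = 0.05):
    """Benjamini–Hochberg step-up procedure.

    Returns ``(significant flags, adjusted q-values)``.  The flags realize
    the step-up rule (reject all p at or below the largest p_(k) with
    p_(k) <= k*fdr/m); q-values are the monotone-adjusted p*m/rank.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any(np.isnan(p)):
        raise ConfigError("NaN p-values are not allowed")
    if np.any((p < 0) | (p > 1)):
        raise ConfigError("p-values must lie in [0, 1]")
    if not 0 < fdr < 1:
        raise ConfigError("fdr must lie in (0, 1)")
    reject, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return reject, q


@dataclass
class DeltaRmsfReport:
    """Per-residue flexibility comparison between two variants."""

    table: pd.DataFrame   # residue_index, residue_name, mean_delta, p, q, significant
    fdr: float
    test_variant: str
    alignment_spec: str

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def significance_report(delta: pd.Series, p_values: pd.Series,
                        fdr: float = 0.05, test_variant: str = "welch",
                        topology: Topology | None = None,
                        alignment_spec: str = "") -> DeltaRmsfReport:
    """Assemble the per-residue ΔRMSF significance table.

    Non-significant residues keep their delta but carry a False flag; a
    structure projection (see :func:`write_projection`) writes 0 for them so
    they render white.
    """
    if not np.array_equal(delta.index.to_numpy(), p_values.index.to_numpy()):
        raise AlignmentError("delta and p-value residue axes differ")
    flags, q = benjamini_hochberg(p_values.to_numpy(), fdr=fdr)
    res_names = np.full(len(delta), "UNK", dtype="U4")
    if topology is not None:
        lut = dict(zip(topology.residue_indices.tolist(),
                       topology.residue_names.tolist()))
        res_names = np.array([lut.get(i, "UNK") for i in delta.index], dtype="U4")
    table = pd.DataFrame({
        "residue_index": delta.index.to_numpy(),
        "residue_name": res_names,
        "mean_delta_A_minus_B": delta.to_numpy(),
        "p": p_values.to_numpy(),
        "q": q,
        "significant": flags,
    })
    return DeltaRmsfReport(table=table, fdr=fdr, test_variant=test_variant,
                           alignment_spec=alignment_spec)


def write_projection(report: DeltaRmsfReport, topology: Topology,
                     coords: np.ndarray, path) -> None:
    """Write the significant ΔRMSF values into a PDB B-factor column."""
    scores = {int(r.residue_index): float(r.mean_delta_A_minus_B)
              for r in report.table.itertuples() if r.significant}
    write_per_residue_scores(topology, coords, scores, path)
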