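"""Rigid-body superposition, RMSD/COM series, and backbone dihedrals.

Conventions
-----------
* Superposition solves the weighted least-squares problem
  ``min over R, t of sum_n w_n |R x_n + t - y_n|^2`` with ``R`` restricted
  to proper rotations (reflections excluded).  The solution is the standard
  SVD construction.
* Loop RMSD follows the fit/measure split: frames are superposed on a *fit*
  selection (typically all non-loop Cα atoms, isolating loop motion from
  global tumbling) and RMSD is then measured over a possibly different
  *measure* selection (the loop Cα atoms).
* Superposition weights are unit by default (plain Cα-RMSD practice);
  mass weighting is opt-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble_io import AtomIndexSet, ReferenceState, ReplicaEnsemble
from .errors import DegenerateGeometryError, EmptySeriesError, SelectionError

__all__ = [
    "SuperpositionResult",
    "kabsch_superpose",
    "rmsd_series",
    "com_distance_series",
    "backbone_dihedrals",
    "DihedralSeries",
    "RamachandranMask",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal proper rotation/translation and the minimized RMSD (Å).

    Applying ``rotation @ x + translation`` to the mobile coordinates
    attains ``rmsd`` against the reference.
    """

    rotation: np.ndarray      # (3, 3), det = +1
    translation: np.ndarray   # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _check_superposable(x: np.ndarray) -> None:
    if x.shape[0] < 3:
        raise DegenerateGeometryError("superposition needs at least 3 atoms")
    centered = x - x.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError(
            "atoms are collinear; rotation is not uniquely determined")


def _batched_rotations(P: np.ndarray, Q: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Optimal proper rotations mapping centered mobile P -> centered ref Q.

    P: (F, n, 3) centered per frame; Q: (n, 3) or (F, n, 3) centered;
    w: (n,) weights.  Returns (F, 3, 3).
    """
    if Q.ndim == 2:
        H = np.einsum("fni,nj->fij", P * w[None, :, None], Q)
    else:
        H = np.einsum("fni,fnj->fij", P * w[None, :, None], Q)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("fij,fjk->fik", U, Vt)))
    # flip the smallest singular direction when an improper solution appears
    Vt = Vt.copy()
    Vt[:, -1, :] *= d[:, None]
    R = np.einsum("fji,fkj->fik", Vt, U)  # V @ diag-corrected @ U.T, transposed form
    return R


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None) -> SuperpositionResult:
    """Least-squares optimal proper rotation/translation (Kabsch via SVD).

    Parameters
    ----------
    mobile, reference : (n, 3) arrays on the same selection, Å.
    weights : optional (n,) positive weights (e.g. masses); unit if omitted.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise SelectionError("mobile and reference selections differ in length")
    _check_superposable(mobile)
    _check_superposable(reference)
    n = mobile.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w <= 0):
        raise SelectionError("weights must be positive, one per atom")
    wsum = w.sum()
    cm = (w[:, None] * mobile).sum(axis=0) / wsum
    cr = (w[:, None] * reference).sum(axis=0) / wsum
    P = (mobile - cm)[None]
    Q = reference - cr
    R = _batched_rotations(P, Q, w)[0]
    t = cr - R @ cm
    diff = mobile @ R.T + t - reference
    rmsd = float(np.sqrt((w * np.einsum("ni,ni->n", diff, diff)).sum() / wsum))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def _batched_rmsd(frames: np.ndarray, ref: np.ndarray,
                  fit_pos: np.ndarray, measure_pos: np.ndarray,
                  weights: np.ndarray | None) -> np.ndarray:
    """Per-frame fit/measure RMSD for a (F, n_atoms, 3) frame block."""
    w = (np.ones(len(fit_pos)) if weights is None
         else np.asarray(weights, dtype=float))
    wsum = w.sum()
    Pf = frames[:, fit_pos, :]
    Qf = ref[fit_pos, :]
    cm = (w[None, :, None] * Pf).sum(axis=1) / wsum         # (F, 3)
    cr = (w[:, None] * Qf).sum(axis=0) / wsum               # (3,)
    R = _batched_rotations(Pf - cm[:, None, :], Qf - cr, w)  # (F, 3, 3)
    Pm = frames[:, measure_pos, :] - cm[:, None, :]
    Qm = ref[measure_pos, :] - cr
    rotated = np.einsum("fij,fnj->fni", R, Pm)
    diff = rotated - Qm[None]
    return np.sqrt(np.einsum("fni,fni->f", diff, diff) / len(measure_pos))


def rmsd_series(ensemble: ReplicaEnsemble, reference: ReferenceState,
                fit: AtomIndexSet, measure: AtomIndexSet,
                mass_weighted: bool = False) -> np.ndarray:
    """Per-(replica, frame) RMSD in Å to a reference conformation.

    Frames are superposed on ``fit`` atoms and RMSD is computed over
    ``measure`` atoms.  Returns shape ``(n_replicas, n_frames)``.
    """
    if len(fit) == 0 or len(measure) == 0:
        raise EmptySeriesError("fit and measure selections must be non-empty")
    top = ensemble.topology
    fit_pos = fit.positions(top)
    meas_pos = measure.positions(top)
    weights = top.masses[fit_pos] if mass_weighted else None
    out = np.empty((ensemble.n_replicas, ensemble.n_frames))
    for r in range(ensemble.n_replicas):
        out[r] = _batched_rmsd(ensemble.coords[r], reference.coords,
                               fit_pos, meas_pos, weights)
    return out


def com_distance_series(ensemble: ReplicaEnsemble, sel_a: AtomIndexSet,
                        sel_b: AtomIndexSet) -> np.ndarray:
    """Distance in Å between the mass-weighted centroids of two selections."""
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise EmptySeriesError("COM selections must be non-empty")
    top = ensemble.topology
    pa, pb = sel_a.positions(top), sel_b.positions(top)
    ma, mb = top.masses[pa], top.masses[pb]
    ca = np.einsum("rfni,n->rfi", ensemble.coords[:, :, pa, :], ma) / ma.sum()
    cb = np.einsum("rfni,n->rfi", ensemble.coords[:, :, pb, :], mb) / mb.sum()
    return np.linalg.norm(ca - cb, axis=-1)


# ---------------------------------------------------------------------------
# backbone dihedrals
# ---------------------------------------------------------------------------

def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                   p3: np.ndarray) -> np.ndarray:
    """Signed dihedral in degrees, IUPAC convention, range (-180, 180].

    Inputs broadcast over leading axes; the last axis is xyz.
    """
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", np.cross(n1, n2), b2n)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> +180 so the range is (-180, 180]
    return np.where(ang <= -180.0, ang + 360.0, ang)


@dataclass(frozen=True)
class RamachandranMask:
    """Coarse rectangular favored/allowed partition of the (phi, psi) plane.

    ``favored`` is a list of ``(phi_lo, phi_hi, psi_lo, psi_hi)`` boxes;
    the allowed region is each box dilated by ``allowed_margin`` degrees.
    Anything else is disallowed.  This is deliberately coarse: downstream
    use only needs a disallowed / not-disallowed call, and the mask is
    swappable.
    """

    favored: tuple = (
        (-180.0, -45.0, 90.0, 180.0),    # beta region
        (-160.0, -45.0, -70.0, -5.0),    # right-handed alpha
        (45.0, 100.0, -20.0, 80.0),      # left-handed alpha
    )
    allowed_margin: float = 20.0

    def classify(self, phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
        phi = np.asarray(phi, dtype=float)
        psi = np.asarray(psi, dtype=float)
        region = np.full(phi.shape, "disallowed", dtype="U10")
        for lo, hi, plo, phi_hi in self.favored:
            m = self.allowed_margin
            in_allowed = ((phi >= lo - m) & (phi <= hi + m)
                          & (psi >= plo - m) & (psi <= phi_hi + m))
            region[in_allowed & (region == "disallowed")] = "allowed"
        for lo, hi, plo, phi_hi in self.favored:
            in_fav = (phi >= lo) & (phi <= hi) & (psi >= plo) & (psi <= phi_hi)
            region[in_fav] = "favored"
        region[~(np.isfinite(phi) & np.isfinite(psi))] = "undefined"
        return region


@dataclass
class DihedralSeries:
    """Per-(replica, frame) phi/psi for one residue, with region labels.

    Undefined angles (chain termini) are NaN and their region is
    ``"undefined"``.
    """

    residue_index: int
    phi: np.ndarray      # (R, F) degrees or NaN
    psi: np.ndarray
    region: np.ndarray   # (R, F) str


def _find_atom(top, residue_index: int, name: str) -> int | None:
    hits = np.nonzero((top.residue_indices == residue_index)
                      & (top.atom_names == name))[0]
    return int(hits[0]) if len(hits) else None


def backbone_dihedrals(ensemble: ReplicaEnsemble, residue_index: int,
                       mask: RamachandranMask | None = None) -> DihedralSeries:
    """Phi/psi series for one residue; termini give NaN, not an error."""
    top = ensemble.topology
    mask = mask or RamachandranMask()
    atoms = {
        "C_prev": _find_atom(top, residue_index - 1, "C"),
        "N": _find_atom(top, residue_index, "N"),
        "CA": _find_atom(top, residue_index, "CA"),
        "C": _find_atom(top, residue_index, "C"),
        "N_next": _find_atom(top, residue_index + 1, "N"),
    }
    if atoms["N"] is None or atoms["CA"] is None or atoms["C"] is None:
        raise SelectionError(
            f"residue {residue_index} lacks backbone N/CA/C atoms")
    shape = (ensemble.n_replicas, ensemble.n_frames)
    phi = np.full(shape, np.nan)
    psi = np.full(shape, np.nan)
    c = ensemble.coords
    if atoms["C_prev"] is not None:
        phi = dihedral_angle(c[:, :, atoms["C_prev"]], c[:, :, atoms["N"]],
                             c[:, :, atoms["CA"]], c[:, :, atoms["C"]])
    if atoms["N_next"] is not None:
        psi = dihedral_angle(c[:, :, atoms["N"]], c[:, :, atoms["CA"]],
                             c[:, :, atoms["C"]], c[:, :, atoms["N_next"]])
    region = mask.classify(phi, psi)
    return DihedralSeries(residue_index=residue_index, phi=phi, psi=psi,
                          region=region)
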