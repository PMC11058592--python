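"""Empirical valence bond (EVB) free-energy estimation and LRA group
contributions.

The reaction is modelled by two diabatic states with energies E1 (reactant)
and E2 (product) per frame.  Sampling is driven by the mapping potential

    E_m(x) = (1 - lambda_m) E1 + lambda_m (E2 + alpha),

over a ladder of lambda windows spanning 0..1 (51 windows in the protocol
this package mirrors).  Free-energy differences between adjacent windows
come from Zwanzig exponential averaging; the adiabatic ground-state profile
Delta g(x) along the energy-gap coordinate x = E1 - E2' is reconstructed by
the standard EVB umbrella correction, and activation/reaction free energies
are read off its extrema.

Per-residue electrostatic contributions to the activation barrier use the
linear response approximation: the half-sum of the endpoint-ensemble
averages of the charge-perturbation energy, scaled by an internal
dielectric constant (default 4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import ConfigError, EmptySeriesError, NoBarrierError

__all__ = [
    "KB_KCAL",
    "MappingSeries",
    "EvbParams",
    "FepLadder",
    "FreeEnergyProfile",
    "GroupEnergySeries",
    "LraReport",
    "mapping_energy",
    "evb_ground_energy",
    "fep_ladder",
    "umbrella_profile",
    "lra_group_contribution",
]

#: Boltzmann constant in kcal/mol/K.
KB_KCAL = 0.0019872041


@dataclass(frozen=True)
class EvbParams:
    """Constant off-diagonal coupling and gas-phase shift (kcal/mol)."""

    h12: float = 0.0
    alpha: float = 0.0

    def __post_init__(self):
        if self.h12 < 0:
            raise ConfigError("H12 must be non-negative")


@dataclass
class MappingSeries:
    """Per-window diabatic energies from an EVB mapping run.

    ``energies[m]`` is an ``(n_frames_m, 2)`` array of (E1, E2) in kcal/mol
    sampled under window m's mapping potential.
    """

    lambdas: np.ndarray
    energies: list
    temperature: float = 298.0

    def __post_init__(self):
        lam = np.asarray(self.lambdas, dtype=float)
        if len(lam) < 2 or np.any(np.diff(lam) <= 0):
            raise ConfigError("lambdas must be strictly increasing, >=2 windows")
        if not (np.isclose(lam[0], 0.0) and np.isclose(lam[-1], 1.0)):
            raise ConfigError("lambda ladder must span 0 and 1")
        if len(self.energies) != len(lam):
            raise ConfigError("one energy block per lambda window required")
        for m, e in enumerate(self.energies):
            e = np.asarray(e, dtype=float)
            if e.ndim != 2 or e.shape[1] != 2 or e.shape[0] == 0:
                raise ConfigError(f"window {m}: energies must be non-empty (n, 2)")
            if not np.all(np.isfinite(e)):
                raise ConfigError(f"window {m}: non-finite energies")
            self.energies[m] = e
        self.lambdas = lam

    @property
    def kT(self) -> float:
        return KB_KCAL * self.temperature

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m, (lam, e) in enumerate(zip(self.lambdas, self.energies)):
            for fr in range(e.shape[0]):
                rows.append((m, lam, fr, e[fr, 0], e[fr, 1]))
        return pd.DataFrame(rows, columns=["window", "lambda", "frame", "E1", "E2"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, temperature: float = 298.0) -> "MappingSeries":
        lambdas, blocks = [], []
        for m, sub in df.groupby("window", sort=True):
            lambdas.append(float(sub["lambda"].iloc[0]))
            blocks.append(sub[["E1", "E2"]].to_numpy(dtype=float))
        return cls(lambdas=np.asarray(lambdas), energies=blocks,
                   temperature=temperature)


def mapping_energy(e1, e2, lam: float):
    """Linear mapping potential: (1 - lam) E1 + lam E2."""
    if not 0.0 <= lam <= 1.0:
        raise ConfigError(f"lambda {lam} outside [0, 1]")
    return (1.0 - lam) * np.asarray(e1) + lam * np.asarray(e2)


def evb_ground_energy(e1, e2, params: EvbParams):
    """Lower eigenvalue of the 2x2 EVB Hamiltonian.

    E_g = (E1 + E2')/2 - sqrt((E1 - E2')^2/4 + H12^2), E2' = E2 + alpha.
    """
    e1 = np.asarray(e1, dtype=float)
    e2p = np.asarray(e2, dtype=float) + params.alpha
    return 0.5 * (e1 + e2p) - np.sqrt(0.25 * (e1 - e2p) ** 2 + params.h12 ** 2)


@dataclass
class FepLadder:
    """Window-to-window free-energy increments and cumulative profiles.

    ``dg_forward[m]`` is the cumulative Delta G(lambda_0 -> lambda_m) from
    forward (Zwanzig) increments; ``dg_reverse`` the same quantity built
    from reverse increments, so agreement between the two is a sampling
    diagnostic.
    """

    lambdas: np.ndarray
    increments_forward: np.ndarray   # (M-1,)
    increments_reverse: np.ndarray   # (M-1,), estimates of Delta G(m+1 -> m)
    temperature: float

    @property
    def dg_forward(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.increments_forward)])

    @property
    def dg_reverse(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(-self.increments_reverse)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lambda": self.lambdas,
                             "dG_forward": self.dg_forward,
                             "dG_reverse": self.dg_reverse})


def _zwanzig(delta_u: np.ndarray, kT: float) -> float:
    """-kT ln < exp(-dU/kT) >, overflow-safe via logsumexp."""
    n = delta_u.size
    return float(-kT * (logsumexp(-delta_u / kT) - np.log(n)))


def fep_ladder(series: MappingSeries, params: EvbParams = EvbParams()) -> FepLadder:
    """Bidirectional exponential-averaging free energies along the ladder."""
    kT = series.kT
    lam = series.lambdas
    M = len(lam)
    fwd = np.empty(M - 1)
    rev = np.empty(M - 1)
    for m in range(M - 1):
        for idx in (m, m + 1):
            if series.energies[idx].shape[0] < 10:
                warnings.warn(f"window {idx} has <10 frames; "
                              f"estimate may be unreliable")
        e1_m, e2_m = series.energies[m][:, 0], series.energies[m][:, 1] + params.alpha
        e1_n, e2_n = series.energies[m + 1][:, 0], series.energies[m + 1][:, 1] + params.alpha
        du_fwd = (mapping_energy(e1_m, e2_m, lam[m + 1])
                  - mapping_energy(e1_m, e2_m, lam[m]))
        du_rev = (mapping_energy(e1_n, e2_n, lam[m])
                  - mapping_energy(e1_n, e2_n, lam[m + 1]))
        fwd[m] = _zwanzig(du_fwd, kT)
        rev[m] = _zwanzig(du_rev, kT)
    return FepLadder(lambdas=lam, increments_forward=fwd,
                     increments_reverse=rev, temperature=series.temperature)


@dataclass
class FreeEnergyProfile:
    """Ground-state free energy along the energy gap x = E1 - E2'.

    The reactant basin sits at negative x (E1 below E2'), the product basin
    at positive x.  ``dg`` is shifted so the reactant minimum is 0.
    """

    gap_bin_centers: np.ndarray
    dg: np.ndarray
    bin_counts: np.ndarray
    dg_activation: float
    dg_reaction: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gap": self.gap_bin_centers, "dg": self.dg,
                             "count": self.bin_counts})


def _extract_barrier(x: np.ndarray, g: np.ndarray) -> tuple[float, float, int, int, int]:
    """Locate reactant minimum, the maximum between the basins, and the
    product minimum.

    The diabatic crossing sits at x = E1 - E2' = 0 by definition, so the
    reactant basin is the profile minimum over x < 0, the product basin
    the minimum over x >= 0, and the barrier top the maximum between them.
    Taking side-wise global minima (rather than local minima) keeps noisy,
    sparsely sampled tail bins from masquerading as basins.
    """
    n = len(g)
    if n < 3:
        raise NoBarrierError("profile has too few bins")
    left = np.nonzero(x < 0)[0]
    right = np.nonzero(x >= 0)[0]
    if len(left) == 0 or len(right) == 0:
        raise NoBarrierError("profile does not bracket the diabatic crossing")
    i_react = int(left[np.argmin(g[left])])
    i_prod = int(right[np.argmin(g[right])])
    if i_prod - i_react < 2:
        raise NoBarrierError("no interior maximum: profile is monotone")
    i_max = i_react + 1 + int(np.argmax(g[i_react + 1:i_prod]))
    if g[i_max] <= max(g[i_react], g[i_prod]):
        raise NoBarrierError("no barrier between the two minima")
    return (float(g[i_max] - g[i_react]), float(g[i_prod] - g[i_react]),
            i_react, i_max, i_prod)


def umbrella_profile(series: MappingSeries, params: EvbParams,
                     ladder: FepLadder, n_bins: int = 100,
                     min_bin_count: int = 10) -> FreeEnergyProfile:
    """EVB umbrella reconstruction of Delta g(x) along x = E1 - E2'.

    Per window m and gap bin b:

        dg(b; m) = dG_m - kT ln < 1{x in b} exp(-(E_g - E_m)/kT) >_m

    and overlapping windows are combined by weighting each window's
    estimate with its frame count in the bin.  Bins with fewer than
    ``min_bin_count`` total frames are dropped.
    """
    kT = series.kT
    lam = series.lambdas
    dG = ladder.dg_forward
    x_all = [e[:, 0] - (e[:, 1] + params.alpha) for e in series.energies]
    lo = min(x.min() for x in x_all)
    hi = max(x.max() for x in x_all)
    edges = np.linspace(lo, hi + 1e-9, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    est = np.full((len(lam), n_bins), np.nan)
    cnt = np.zeros((len(lam), n_bins))
    for m, e in enumerate(series.energies):
        e1, e2p = e[:, 0], e[:, 1] + params.alpha
        x = e1 - e2p
        eg = 0.5 * (e1 + e2p) - np.sqrt(0.25 * (e1 - e2p) ** 2 + params.h12 ** 2)
        em = (1.0 - lam[m]) * e1 + lam[m] * e2p
        w = -(eg - em) / kT                    # log-weights
        bins = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
        n_m = e.shape[0]
        for b in np.unique(bins):
            sel = bins == b
            cnt[m, b] = sel.sum()
            est[m, b] = dG[m] - kT * (logsumexp(w[sel]) - np.log(n_m))

    total = cnt.sum(axis=0)
    keep = total >= min_bin_count
    if keep.sum() < 3:
        raise NoBarrierError("too few adequately sampled gap bins")
    with np.errstate(invalid="ignore"):
        weights = np.where(np.isnan(est), 0.0, cnt)
        dg_bins = np.nansum(weights * np.nan_to_num(est), axis=0) / np.maximum(weights.sum(axis=0), 1e-300)
    x_keep = centers[keep]
    g_keep = dg_bins[keep]
    act, rxn, i_react, _, _ = _extract_barrier(x_keep, g_keep)
    g_keep = g_keep - g_keep[i_react]
    return FreeEnergyProfile(gap_bin_centers=x_keep, dg=g_keep,
                             bin_counts=total[keep],
                             dg_activation=act, dg_reaction=rxn)


# ---------------------------------------------------------------------------
# LRA group contributions
# ---------------------------------------------------------------------------

@dataclass
class GroupEnergySeries:
    """Per-frame residue-fragment electrostatic energies at both endpoints.

    For each ensemble ("RS" sampled at the reactant state, "TS" at the
    transition state) and each residue, the interaction energy of the
    residue with the reacting fragments is evaluated with both the RS and
    the TS charge set: ``u_rs[ens]`` and ``u_ts[ens]`` are
    ``(n_frames, n_residues)`` arrays.
    """

    residue_index: np.ndarray
    u_rs: Mapping[str, np.ndarray]
    u_ts: Mapping[str, np.ndarray]

    def __post_init__(self):
        for ens in ("RS", "TS"):
            if ens not in self.u_rs or ens not in self.u_ts:
                raise ConfigError(f"ensemble {ens!r} missing a charge-set column")
            for tab in (self.u_rs[ens], self.u_ts[ens]):
                if tab.shape[0] == 0 or tab.shape[1] != len(self.residue_index):
                    raise ConfigError(f"ensemble {ens!r}: bad energy table shape")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GroupEnergySeries":
        """Build from long-format rows (ensemble, frame, residue_index, u_RS, u_TS)."""
        res = np.sort(df["residue_index"].unique())
        u_rs, u_ts = {}, {}
        for ens, sub in df.groupby("ensemble"):
            piv_rs = sub.pivot(index="frame", columns="residue_index", values="u_RS")
            piv_ts = sub.pivot(index="frame", columns="residue_index", values="u_TS")
            u_rs[ens] = piv_rs[res].to_numpy(dtype=float)
            u_ts[ens] = piv_ts[res].to_numpy(dtype=float)
        return cls(residue_index=res, u_rs=u_rs, u_ts=u_ts)


@dataclass
class LraReport:
    """Per-residue electrostatic contributions to the barrier (kcal/mol)."""

    table: pd.DataFrame   # residue_index, ddg_elec
    epsilon_in: float

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["epsilon_in"] = self.epsilon_in
        out.to_csv(path, sep="\t", index=False)


def lra_group_contribution(series: GroupEnergySeries,
                           epsilon_in: float = 4.0) -> LraReport:
    """Linear-response estimate of each residue's electrostatic effect.

    ddG_i = 0.5 [ <u_i^TS - u_i^RS>_RS + <u_i^TS - u_i^RS>_TS ] / epsilon_in
    """
    if epsilon_in <= 0:
        raise ConfigError("epsilon_in must be positive")
    d_rs = (series.u_ts["RS"] - series.u_rs["RS"]).mean(axis=0)
    d_ts = (series.u_ts["TS"] - series.u_rs["TS"]).mean(axis=0)
    ddg = 0.5 * (d_rs + d_ts) / epsilon_in
    table = pd.DataFrame({"residue_index": series.residue_index,
                          "ddg_elec": ddg})
    return LraReport(table=table, epsilon_in=epsilon_in)
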