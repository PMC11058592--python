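"""Per-frame non-covalent interaction detection and network differencing.

Interactions (hydrogen bonds, salt bridges, generic sidechain contacts) are
detected geometrically per frame, accumulated into state-conditioned
occupancies (the fraction of a state's frames in which the interaction is
present), and occupancy tables of two variants are differenced to rank the
network changes that accompany a population shift.

Keys are canonical by residue *position* — ``(chain, residue_index)`` of
the lower-indexed partner first — so tables remain comparable across
variants that differ by loop substitutions (the residue names are carried
alongside, not inside, the key).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .ensemble_io import ReplicaEnsemble, Topology
from .errors import ConfigError, EmptySeriesError, SelectionError
from .states import StateLabelSeries, STATE_NAMES

__all__ = [
    "InteractionKey",
    "DetectorConfig",
    "HBondDetector",
    "ContactDetector",
    "detect_hbonds",
    "detect_contacts",
    "OccupancyTable",
    "interaction_occupancy",
    "network_difference",
    "residue_projection",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")

#: Sidechain hydrogen-bond donor heavy atoms per residue type.  Backbone N
#: is a donor for every residue except proline (no amide hydrogen).
SIDECHAIN_DONORS: Mapping[str, tuple[str, ...]] = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "CYS": ("SG",),
    "ASN": ("ND2",), "GLN": ("NE2",), "TRP": ("NE1",),
    "ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}

#: Sidechain acceptor heavy atoms per residue type.  Backbone O accepts for
#: every residue.
SIDECHAIN_ACCEPTORS: Mapping[str, tuple[str, ...]] = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "ASN": ("OD1",), "GLN": ("OE1",),
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"), "MET": ("SD",),
}

POSITIVE_GROUPS: Mapping[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",),
}
NEGATIVE_GROUPS: Mapping[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"),
}


class InteractionKey(NamedTuple):
    """Canonical, variant-comparable identity of one interaction.

    ``donor_side`` is ``"i"``/``"j"`` for hydrogen bonds (which partner
    donates) and ``""`` for contacts and salt bridges.
    """

    kind: str            # hbond | saltbridge | contact
    chain_i: str
    res_i: int
    atom_i: str
    chain_j: str
    res_j: int
    atom_j: str
    donor_side: str
    backbone: bool


def _canonical_key(kind, chain_d, res_d, atom_d, chain_a, res_a, atom_a,
                   donor: bool, backbone: bool) -> InteractionKey:
    """Order partners by (chain, residue_index); track the donor side."""
    if (chain_d, res_d) <= (chain_a, res_a):
        return InteractionKey(kind, chain_d, res_d, atom_d,
                              chain_a, res_a, atom_a,
                              "i" if donor else "", backbone)
    return InteractionKey(kind, chain_a, res_a, atom_a,
                          chain_d, res_d, atom_d,
                          "j" if donor else "", backbone)


def _is_donor(top: Topology, i: int) -> bool:
    name, res = top.atom_names[i], top.residue_names[i]
    if name == "N":                       # backbone amide
        return res != "PRO"               # proline N has no amide hydrogen
    if name in SIDECHAIN_DONORS.get(res, ()):
        return True
    # generic fallback for non-standard residues: sidechain nitrogens donate
    return top.elements[i].upper() == "N" and name not in BACKBONE_NAMES \
        and res not in SIDECHAIN_DONORS


def _is_acceptor(top: Topology, i: int) -> bool:
    name, res = top.atom_names[i], top.residue_names[i]
    if name == "O":                       # backbone carbonyl
        return True
    if name in SIDECHAIN_ACCEPTORS.get(res, ()):
        return True
    return top.elements[i].upper() == "O" and name not in BACKBONE_NAMES \
        and res not in SIDECHAIN_ACCEPTORS


def _pair_allowed(top: Topology, d: int, a: int) -> bool:
    """Exclude intra-residue pairs unless one side is backbone and the
    other sidechain."""
    if d == a:
        return False
    same_res = (top.chain_ids[d] == top.chain_ids[a]
                and top.residue_indices[d] == top.residue_indices[a])
    if same_res:
        d_bb = top.atom_names[d] in BACKBONE_NAMES
        a_bb = top.atom_names[a] in BACKBONE_NAMES
        return d_bb != a_bb
    return True


@dataclass(frozen=True)
class DetectorConfig:
    """Geometric criteria, echoed into every output table."""

    hbond_d_max: float = 3.5          # donor-acceptor heavy-atom distance, Å
    hbond_angle_min: float = 135.0    # D-H...A angle, degrees
    hbond_mode: str = "with_hydrogens"  # or "heavy_only" (no angle term)
    contact_d_max: float = 4.5        # sidechain-sidechain heavy atoms, Å
    saltbridge_d_max: float = 4.0
    detect_contact: bool = True

    def __post_init__(self):
        if self.hbond_mode not in ("with_hydrogens", "heavy_only"):
            raise ConfigError(f"unknown hbond_mode {self.hbond_mode!r}")


class HBondDetector:
    """Precomputes candidate donor/acceptor pairs for one topology.

    In ``with_hydrogens`` mode, hydrogens are resolved per frame as element-H
    atoms of the donor's residue within 1.25 Å of the donor heavy atom, and
    the D–H···A angle criterion applies.  In ``heavy_only`` mode (for
    hydrogen-free reduced models) only the heavy-atom distance is tested.
    """

    def __init__(self, topology: Topology, config: DetectorConfig = DetectorConfig()):
        self.top = topology
        self.config = config
        donors = [i for i in range(topology.n_atoms) if _is_donor(topology, i)]
        acceptors = [i for i in range(topology.n_atoms) if _is_acceptor(topology, i)]
        pairs = [(d, a) for d in donors for a in acceptors
                 if _pair_allowed(topology, d, a)]
        self.pair_d = np.array([p[0] for p in pairs], dtype=np.int64)
        self.pair_a = np.array([p[1] for p in pairs], dtype=np.int64)
        if config.hbond_mode == "with_hydrogens":
            self._hydrogen_lut = {
                d: np.nonzero((topology.residue_indices == topology.residue_indices[d])
                              & (topology.chain_ids == topology.chain_ids[d])
                              & (np.char.upper(topology.elements) == "H"))[0]
                for d in donors}

    def pair_mask(self, frames: np.ndarray) -> np.ndarray:
        """(F, n_pairs) boolean detection mask for a block of frames."""
        frames = np.atleast_3d(frames)
        if frames.ndim == 2:
            frames = frames[None]
        dvec = frames[:, self.pair_a, :] - frames[:, self.pair_d, :]
        dist = np.linalg.norm(dvec, axis=-1)
        mask = dist <= self.config.hbond_d_max
        if self.config.hbond_mode == "with_hydrogens":
            mask &= self._angle_mask(frames, dist)
        return mask

    def _angle_mask(self, frames: np.ndarray, dist: np.ndarray) -> np.ndarray:
        cos_min = np.cos(np.radians(self.config.hbond_angle_min))
        out = np.zeros_like(dist, dtype=bool)
        for k in range(len(self.pair_d)):
            d, a = self.pair_d[k], self.pair_a[k]
            hyds = self._hydrogen_lut.get(d, np.empty(0, dtype=np.int64))
            if len(hyds) == 0:
                continue
            dh = frames[:, hyds, :] - frames[:, d, :][:, None, :]
            bonded = np.linalg.norm(dh, axis=-1) <= 1.25
            ha = frames[:, a, :][:, None, :] - frames[:, hyds, :]
            v1 = -dh / np.maximum(np.linalg.norm(dh, axis=-1, keepdims=True), 1e-12)  # H->D
            v2 = ha / np.maximum(np.linalg.norm(ha, axis=-1, keepdims=True), 1e-12)  # H->A
            cos_dha = np.einsum("fhi,fhi->fh", v1, v2)
            # angle >= angle_min  <=>  cos(angle) <= cos(angle_min)
            ok = bonded & (cos_dha <= cos_min)
            out[:, k] = ok.any(axis=1)
        return out

    def key(self, pair_index: int) -> InteractionKey:
        top = self.top
        d, a = int(self.pair_d[pair_index]), int(self.pair_a[pair_index])
        backbone = (top.atom_names[d] in BACKBONE_NAMES
                    and top.atom_names[a] in BACKBONE_NAMES)
        return _canonical_key(
            "hbond", top.chain_ids[d], int(top.residue_indices[d]), top.atom_names[d],
            top.chain_ids[a], int(top.residue_indices[a]), top.atom_names[a],
            donor=True, backbone=backbone)

    def detect(self, coords: np.ndarray) -> set[InteractionKey]:
        mask = self.pair_mask(coords[None])[0]
        return {self.key(k) for k in np.nonzero(mask)[0]}


class ContactDetector:
    """Residue-level sidechain contacts and salt bridges."""

    def __init__(self, topology: Topology, config: DetectorConfig = DetectorConfig()):
        self.top = topology
        self.config = config
        heavy = np.char.upper(topology.elements) != "H"
        sidechain = ~np.isin(topology.atom_names, BACKBONE_NAMES) & heavy
        self.sc_idx = np.nonzero(sidechain)[0]
        res_key = list(zip(topology.chain_ids[self.sc_idx].tolist(),
                           topology.residue_indices[self.sc_idx].tolist()))
        self._res_of_sc = res_key
        charged = {}
        for i in range(topology.n_atoms):
            res, name = topology.residue_names[i], topology.atom_names[i]
            if name in POSITIVE_GROUPS.get(res, ()):
                charged[i] = +1
            elif name in NEGATIVE_GROUPS.get(res, ()):
                charged[i] = -1
        self.charged = charged

    def detect(self, coords: np.ndarray) -> set[InteractionKey]:
        top, cfg = self.top, self.config
        keys: set[InteractionKey] = set()
        idx = self.sc_idx
        if len(idx) == 0:
            return keys
        x = coords[idx]
        d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
        close = np.argwhere(d <= cfg.contact_d_max)
        seen_pairs: dict[tuple, str] = {}
        for a_k, b_k in close:
            if a_k >= b_k:
                continue
            ra, rb = self._res_of_sc[a_k], self._res_of_sc[b_k]
            if ra == rb:
                continue
            pair = (ra, rb) if ra <= rb else (rb, ra)
            ia, ib = int(idx[a_k]), int(idx[b_k])
            kind = "contact"
            qa = self.charged.get(ia, 0)
            qb = self.charged.get(ib, 0)
            if qa * qb < 0 and d[a_k, b_k] <= cfg.saltbridge_d_max:
                kind = "saltbridge"
            if pair not in seen_pairs or kind == "saltbridge":
                seen_pairs[pair] = kind
        for (ra, rb), kind in seen_pairs.items():
            keys.add(InteractionKey(kind, ra[0], int(ra[1]), "",
                                    rb[0], int(rb[1]), "", "", False))
        return keys


def detect_hbonds(coords: np.ndarray, topology: Topology,
                  d_max: float = 3.5, angle_min: float = 135.0,
                  mode: str = "with_hydrogens") -> set[InteractionKey]:
    """Hydrogen bonds in a single frame.

    A bond is reported when the donor–acceptor heavy-atom distance is at or
    below ``d_max`` and (in ``with_hydrogens`` mode) some covalent hydrogen
    of the donor makes a D–H···A angle of at least ``angle_min`` degrees.
    Proline backbone N is never a donor.
    """
    cfg = DetectorConfig(hbond_d_max=d_max, hbond_angle_min=angle_min,
                         hbond_mode=mode)
    return HBondDetector(topology, cfg).detect(np.asarray(coords, dtype=float))


def detect_contacts(coords: np.ndarray, topology: Topology,
                    d_max: float = 4.5,
                    saltbridge_d_max: float = 4.0) -> set[InteractionKey]:
    """Residue pairs with any sidechain heavy-atom distance <= ``d_max``;
    oppositely charged groups within ``saltbridge_d_max`` are flagged as
    salt bridges."""
    cfg = DetectorConfig(contact_d_max=d_max, saltbridge_d_max=saltbridge_d_max)
    return ContactDetector(topology, cfg).detect(np.asarray(coords, dtype=float))


# ---------------------------------------------------------------------------
# state-conditioned occupancy
# ---------------------------------------------------------------------------

@dataclass
class OccupancyTable:
    """Per-(interaction, state) occupancies with per-replica breakdown.

    ``pooled[(key, state)]`` is detected-frames / state-frames over all
    replicas; ``per_replica[(key, state)]`` holds each replica's occupancy
    (NaN where a replica has no frames in the state); ``state_frames``
    counts frames per (state, replica).
    """

    pooled: dict
    per_replica: dict
    state_frames: dict
    config: DetectorConfig
    variant: str = ""

    def states(self) -> set[str]:
        return {s for (_, s) in self.pooled}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (key, state), occ in sorted(self.pooled.items()):
            per = self.per_replica[(key, state)]
            rows.append({
                "kind": key.kind, "chain_i": key.chain_i, "res_i": key.res_i,
                "atom_i": key.atom_i, "chain_j": key.chain_j, "res_j": key.res_j,
                "atom_j": key.atom_j, "donor_side": key.donor_side,
                "backbone": key.backbone, "state": state, "variant": self.variant,
                "occupancy": occ,
                "n_frames": int(np.nansum(self.state_frames[state])),
                "replica_sd": float(np.nanstd(per, ddof=1)) if np.sum(~np.isnan(per)) > 1 else 0.0,
            })
        return pd.DataFrame(rows)


def interaction_occupancy(ensemble: ReplicaEnsemble, labels: StateLabelSeries,
                          config: DetectorConfig = DetectorConfig(),
                          variant: str = "") -> OccupancyTable:
    """State-conditioned occupancy of every interaction ever observed.

    Frames labeled ``other`` are discarded.  A state with zero frames is
    omitted with a warning.  Hydrogen bonds are always scanned; residue
    contacts are included when ``config.detect_contact`` is true.
    """
    if labels.labels.shape != ensemble.coords.shape[:2]:
        raise ConfigError("labels are not aligned with the ensemble")
    hb = HBondDetector(ensemble.topology, config)
    contact = ContactDetector(ensemble.topology, config) if config.detect_contact else None
    names = labels.as_names()
    states_used = [s for s in STATE_NAMES if s != "other"]

    n_rep = ensemble.n_replicas
    state_frames = {s: np.array([(names[r] == s).sum() for r in range(n_rep)], dtype=float)
                    for s in states_used}
    for s in list(state_frames):
        if state_frames[s].sum() == 0:
            warnings.warn(f"state {s!r} has zero frames; omitted from occupancy table")
            del state_frames[s]

    # detected counts per (key, state, replica)
    counts: dict = {}
    for r in range(n_rep):
        frames = ensemble.coords[r]
        mask = hb.pair_mask(frames)  # (F, P)
        for s in state_frames:
            fsel = names[r] == s
            if not fsel.any():
                continue
            per_pair = mask[fsel].sum(axis=0)
            for k in np.nonzero(per_pair)[0]:
                key = hb.key(int(k))
                counts.setdefault((key, s), np.zeros(n_rep))[r] += per_pair[k]
        if contact is not None:
            for f in np.nonzero(np.isin(names[r], list(state_frames)))[0]:
                s = names[r][f]
                for key in contact.detect(frames[f]):
                    counts.setdefault((key, s), np.zeros(n_rep))[r] += 1

    pooled, per_replica = {}, {}
    for (key, s), cnt in counts.items():
        nf = state_frames[s]
        pooled[(key, s)] = float(cnt.sum() / nf.sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            per_replica[(key, s)] = np.where(nf > 0, cnt / np.maximum(nf, 1), np.nan)
    return OccupancyTable(pooled=pooled, per_replica=per_replica,
                          state_frames=state_frames, config=config,
                          variant=variant)


def network_difference(tab_a: OccupancyTable, tab_b: OccupancyTable,
                       state: str) -> pd.DataFrame:
    """Occupancy deltas (A − B) within one state, ranked by |delta|.

    Keys are unioned; an interaction absent from one table counts as
    occupancy 0 there.  Ties in |delta| break on the canonical key so the
    ranking is deterministic.
    """
    keys_a = {k for (k, s) in tab_a.pooled if s == state}
    keys_b = {k for (k, s) in tab_b.pooled if s == state}
    keys = keys_a | keys_b
    if not keys:
        raise EmptySeriesError(f"state {state!r} absent from both occupancy tables")
    rows = []
    for key in keys:
        occ_a = tab_a.pooled.get((key, state), 0.0)
        occ_b = tab_b.pooled.get((key, state), 0.0)
        per_a = tab_a.per_replica.get((key, state))
        per_b = tab_b.per_replica.get((key, state))
        sd_a = float(np.nanstd(per_a, ddof=1)) if per_a is not None and np.sum(~np.isnan(per_a)) > 1 else 0.0
        sd_b = float(np.nanstd(per_b, ddof=1)) if per_b is not None and np.sum(~np.isnan(per_b)) > 1 else 0.0
        rows.append({"key": key, "kind": key.kind,
                     "chain_i": key.chain_i, "res_i": key.res_i, "atom_i": key.atom_i,
                     "chain_j": key.chain_j, "res_j": key.res_j, "atom_j": key.atom_j,
                     "occ_a": occ_a, "occ_b": occ_b, "delta": occ_a - occ_b,
                     "replica_sd_a": sd_a, "replica_sd_b": sd_b})
    df = pd.DataFrame(rows)
    df["abs_delta"] = df["delta"].abs()
    df = df.sort_values(["abs_delta", "key"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["direction"] = np.where(df["delta"] > 0, "favors_A",
                               np.where(df["delta"] < 0, "favors_B", "equal"))
    return df.drop(columns=["abs_delta"])


def residue_projection(diff: pd.DataFrame) -> dict[int, float]:
    """Per-residue summed |delta| for structure coloring.

    Each interaction contributes its |delta| to both participating
    residues, so the summed scores equal twice the total |delta|.
    """
    if len(diff) == 0:
        raise EmptySeriesError("empty network difference")
    scores: dict[int, float] = {}
    for row in diff.itertuples():
        for res in (int(row.res_i), int(row.res_j)):
            scores[res] = scores.get(res, 0.0) + abs(row.delta)
    return scores
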