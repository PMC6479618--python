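"""Cysteine-pair scanning for disulfide-bond engineering.

The screen follows the classic geometric feasibility rule — two residues are
candidate cysteine substitutions when their Cβ atoms are within 5 Å (Cα for
glycine) — and then models the putative bridge explicitly: a Sγ atom is placed
on each residue from its N/CA/CB frame at ideal stereochemistry over a grid of
χ1 rotamers, and the conformer with the lowest strain energy is kept.

Because published commercial scoring functions for this screen are
proprietary, the two scores used here are explicit, documented surrogates with
their zero point at ideal disulfide stereochemistry:

* strain energy ``ΔE`` — harmonic penalties on the S–S distance (ideal
  2.05 Å), the two CB–S–S angles (ideal 104.15°) and a two-fold torsion term
  on χ3 (ideal ±87°);
* interaction energy ``ΔEi`` — a soft-sphere clash penalty plus a weak
  favourable contact well between each modelled Sγ and surrounding heavy
  atoms (negative = favourable packing).

Candidates are classified Good / Medium / Bad from (ΔEi, ΔE) with the
screening rule: Good when ΔEi < 0 and ΔE < 20; Bad when ΔEi > 40 or ΔE > 40
or (ΔEi > 20 and ΔE > 20); Medium otherwise.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .geometry import GeometryError, angle_deg, dihedral_deg, place_atom
from .structure_io import (
    BACKBONE_ATOMS,
    Atom,
    DisorderedRegion,
    Residue,
    Structure,
    StructureError,
)

log = logging.getLogger(__name__)

__all__ = [
    "IDEAL_CB_SG",
    "IDEAL_SS",
    "IDEAL_CA_CB_SG",
    "IDEAL_CB_S_S",
    "IDEAL_CHI3",
    "Quality",
    "DesignConfig",
    "ModeledDisulfide",
    "DisulfideCandidate",
    "ConfigurationError",
    "detect_native_disulfides",
    "enumerate_pairs",
    "model_disulfide",
    "strain_energy",
    "interaction_energy",
    "classify_quality",
    "apply_filters",
    "rank_candidates",
    "mutate_to_cys",
    "scan_structure",
    "candidates_to_dataframe",
    "write_candidate_report",
    "virtual_cb",
]

# ideal disulfide stereochemistry (standard cystine values)
IDEAL_CB_SG = 1.81  # Å
IDEAL_SS = 2.05  # Å
IDEAL_CA_CB_SG = 114.0  # degrees
IDEAL_CB_S_S = 104.15  # degrees
IDEAL_CHI3 = 87.0  # degrees (two-fold: -93° is equivalent)


class ConfigurationError(ValueError):
    """A configuration value cannot be applied to the given structure."""


class Quality(str, Enum):
    GOOD = "Good"
    MEDIUM = "Medium"
    BAD = "Bad"

    @property
    def order(self) -> int:
        return {"Good": 0, "Medium": 1, "Bad": 2}[self.value]


@dataclass
class DesignConfig:
    """Tunable thresholds and constants of the cysteine scan.

    Distances in Å, angles in degrees, energies in arbitrary surrogate units.
    """

    max_cb_cb: float = 5.0
    min_seq_sep: int = 4
    active_site_residues: tuple[tuple[str, int], ...] = ()
    active_site_radius: float = 10.0
    native_ss_max: float = 2.3
    ss_ideal: float = IDEAL_SS
    ss_target_band: tuple[float, float] = (1.7, 2.3)  # "about 2 Å"
    chi1_grid_step: float = 5.0
    burial_neighbor_cutoff: float = 10.0
    burial_neighbor_max: int = 16
    # strain-energy surrogate constants
    k_ss: float = 100.0  # units/Å²
    k_ang: float = 0.02  # units/deg²
    k_tor: float = 2.0  # units
    # interaction-energy surrogate constants
    k_clash: float = 50.0  # units/Å²
    clash_dist: float = 3.0  # Å
    contact_range: tuple[float, float] = (3.5, 6.0)  # Å
    contact_eps: float = 0.1  # units per contact

    def __post_init__(self) -> None:
        for name in (
            "max_cb_cb",
            "active_site_radius",
            "native_ss_max",
            "ss_ideal",
            "chi1_grid_step",
            "burial_neighbor_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if 360.0 % self.chi1_grid_step != 0:
            raise ConfigurationError("chi1_grid_step must divide 360")


@dataclass(frozen=True)
class ModeledDisulfide:
    chi1_i: float
    chi1_j: float
    chi3: float
    d_ss: float
    sg_i: np.ndarray
    sg_j: np.ndarray
    theta_i: float
    theta_j: float
    e_strain: float


@dataclass
class DisulfideCandidate:
    """A residue pair evaluated as a potential engineered disulfide."""

    res_i: Residue
    res_j: Residue
    d_cb: float
    model: ModeledDisulfide | None = None
    e_strain: float = math.nan
    e_interaction: float = math.nan
    quality: Quality | None = None
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def pair_label(self) -> str:
        return f"{self.res_i.label}-{self.res_j.label}"

    @property
    def demoted(self) -> bool:
        return bool(self.flags.get("near_active_site") or self.flags.get("involves_native_cys"))


# ---------------------------------------------------------------------------
# geometric scaffolding


def _scan_coord(r: Residue) -> np.ndarray | None:
    """Cβ coordinate used by the distance screen (Cα fallback for glycine)."""
    cb = r.atom("CB")
    if cb is not None:
        return cb.coords
    if r.res_name == "GLY":
        ca = r.atom("CA")
        return None if ca is None else ca.coords
    return None


def virtual_cb(r: Residue) -> np.ndarray:
    """Cβ position; for glycine, an ideal virtual Cβ built from the N/CA/C frame."""
    cb = r.atom("CB")
    if cb is not None:
        return cb.coords
    if not r.has_atoms("N", "CA", "C"):
        raise StructureError(f"{r.label}: need N, CA, C to construct a Cβ")
    return place_atom(r.atom("C").coords, r.atom("N").coords, r.atom("CA").coords,
                      1.530, 110.6, -122.6)


def detect_native_disulfides(
    s: Structure, max_ss: float = 2.3
) -> list[tuple[Residue, Residue]]:
    """Cysteine pairs whose Sγ–Sγ distance indicates an existing disulfide.

    Each cysteine participates in at most one returned pair (closest wins).
    """
    cys = [(r, r.atom("SG")) for r in s.residues() if r.res_name == "CYS"]
    cys = [(r, sg) for r, sg in cys if sg is not None]
    hits = []
    for a in range(len(cys)):
        for b in range(a + 1, len(cys)):
            d = float(np.linalg.norm(cys[a][1].coords - cys[b][1].coords))
            if d <= max_ss:
                hits.append((d, a, b))
    hits.sort()
    used: set[int] = set()
    pairs = []
    for _, a, b in hits:
        if a in used or b in used:
            continue
        used.update((a, b))
        ri, rj = cys[a][0], cys[b][0]
        if (rj.chain_id, rj.auth_seq_num) < (ri.chain_id, ri.auth_seq_num):
            ri, rj = rj, ri
        pairs.append((ri, rj))
    pairs.sort(key=lambda p: (p[0].chain_id, p[0].auth_seq_num))
    return pairs


def enumerate_pairs(
    s: Structure, cfg: DesignConfig | None = None
) -> list[tuple[Residue, Residue, float]]:
    """All residue pairs passing the Cβ–Cβ feasibility screen.

    Pairs must be separated by at least ``cfg.min_seq_sep`` residues along the
    chain (pairs across different chains always qualify), have a Cβ–Cβ
    distance (Cα for glycine) of at most ``cfg.max_cb_cb``, and neither member
    may be proline.  Sorted by distance, ascending.
    """
    cfg = cfg or DesignConfig()
    residues, coords = [], []
    for r in s.residues():
        if r.res_name == "PRO":
            continue
        c = _scan_coord(r)
        if c is None:
            log.warning("%s: no CB/CA scan coordinate; skipped", r.label)
            continue
        residues.append(r)
        coords.append(c)
    if not residues:
        return []
    xyz = np.array(coords)
    dmat = cdist(xyz, xyz)
    out = []
    for a in range(len(residues)):
        for b in range(a + 1, len(residues)):
            ri, rj = residues[a], residues[b]
            if ri.chain_id == rj.chain_id:
                if abs(ri.auth_seq_num - rj.auth_seq_num) < cfg.min_seq_sep:
                    continue
            if dmat[a, b] <= cfg.max_cb_cb:
                if (rj.chain_id, rj.auth_seq_num) < (ri.chain_id, ri.auth_seq_num):
                    ri, rj = rj, ri
                out.append((ri, rj, float(dmat[a, b])))
    out.sort(key=lambda t: t[2])
    return out


# ---------------------------------------------------------------------------
# energies


def strain_energy(d_ss, theta_i, theta_j, chi3, cfg: DesignConfig | None = None):
    """Surrogate strain energy ΔE of a modelled disulfide (0 at ideal geometry).

    ``E = k_ss (d_ss − 2.05)² + k_ang [(θ_i − 104.15)² + (θ_j − 104.15)²]
    + k_tor (1 − cos 2(χ3 − 87°))`` with θ the CB–S–S angles. Accepts arrays.
    """
    cfg = cfg or DesignConfig()
    d_ss = np.asarray(d_ss, float)
    e = (
        cfg.k_ss * (d_ss - cfg.ss_ideal) ** 2
        + cfg.k_ang * ((np.asarray(theta_i, float) - IDEAL_CB_S_S) ** 2
                       + (np.asarray(theta_j, float) - IDEAL_CB_S_S) ** 2)
        + cfg.k_tor * (1.0 - np.cos(2.0 * np.radians(np.asarray(chi3, float) - IDEAL_CHI3)))
    )
    return float(e) if e.ndim == 0 else e


def interaction_energy(
    s: Structure,
    sg_i: np.ndarray,
    sg_j: np.ndarray,
    pair: tuple[Residue, Residue],
    cfg: DesignConfig | None = None,
) -> float:
    """Surrogate interaction energy ΔEi of the modelled Sγ atoms with their
    environment: soft-sphere clash penalty inside ``clash_dist`` minus a small
    reward per heavy-atom contact in ``contact_range``; the pair's own atoms
    are excluded.  Negative values indicate favourable packing.
    """
    cfg = cfg or DesignConfig()
    skip = {pair[0].key, pair[1].key}
    env = [a.coords for r in s.residues() if r.key not in skip for a in r.atoms]
    if not env:
        return 0.0
    env = np.array(env)
    lo, hi = cfg.contact_range
    total = 0.0
    for sg in (np.asarray(sg_i, float), np.asarray(sg_j, float)):
        d = np.linalg.norm(env - sg, axis=1)
        clash = np.clip(cfg.clash_dist - d, 0.0, None)
        total += cfg.k_clash * float(np.sum(clash**2))
        total -= cfg.contact_eps * float(np.count_nonzero((d >= lo) & (d <= hi)))
    return total


def classify_quality(e_interaction: float, e_strain: float) -> Quality:
    """Screening verdict from (ΔEi, ΔE): Good, Bad, else Medium (see module docs)."""
    ei, es = float(e_interaction), float(e_strain)
    if math.isnan(ei) or math.isnan(es):
        raise ValueError("classify_quality: NaN input")
    if ei < 0 and es < 20:
        return Quality.GOOD
    if ei > 40 or es > 40 or (ei > 20 and es > 20):
        return Quality.BAD
    return Quality.MEDIUM


# ---------------------------------------------------------------------------
# explicit disulfide modelling


def model_disulfide(
    s: Structure,
    pair: tuple[Residue, Residue],
    cfg: DesignConfig | None = None,
    chi1_values: np.ndarray | None = None,
) -> ModeledDisulfide:
    """Model the Sγ–Sγ bridge for a residue pair over a χ1 rotamer grid.

    Each Sγ is placed from its residue's N/CA/CB frame at ideal internal
    coordinates (CB–SG 1.81 Å, CA–CB–SG 114°) with the N–CA–CB–SG torsion χ1
    swept over the grid for both residues; the conformer minimising the strain
    energy is returned.  Glycine uses an ideal virtual Cβ.
    """
    cfg = cfg or DesignConfig()
    ri, rj = pair
    frames = []
    for r in (ri, rj):
        if not r.has_atoms("N", "CA"):
            raise StructureError(f"{r.label}: need N and CA to model a disulfide")
        frames.append((r.atom("N").coords, r.atom("CA").coords, virtual_cb(r)))
    if chi1_values is None:
        chi1_values = np.arange(-180.0, 180.0, cfg.chi1_grid_step)
    chi1_values = np.asarray(chi1_values, float)

    sg = []
    for n, ca, cb in frames:
        sg.append(place_atom(n, ca, cb, IDEAL_CB_SG, IDEAL_CA_CB_SG, chi1_values))
    sg_i = sg[0][:, None, :]  # (G, 1, 3)
    sg_j = sg[1][None, :, :]  # (1, G, 3)
    cb_i, cb_j = frames[0][2], frames[1][2]

    diff = sg_j - sg_i
    d_ss = np.linalg.norm(diff, axis=-1)
    with np.errstate(invalid="ignore"):
        theta_i = angle_deg(np.broadcast_to(cb_i, sg_i.shape), sg_i, sg_j)
        theta_j = angle_deg(np.broadcast_to(cb_j, sg_j.shape), sg_j, sg_i)
        chi3 = dihedral_deg(
            np.broadcast_to(cb_i, np.broadcast_shapes(sg_i.shape, sg_j.shape)),
            np.broadcast_to(sg_i, np.broadcast_shapes(sg_i.shape, sg_j.shape)),
            np.broadcast_to(sg_j, np.broadcast_shapes(sg_i.shape, sg_j.shape)),
            np.broadcast_to(cb_j, np.broadcast_shapes(sg_i.shape, sg_j.shape)),
        )
    e = strain_energy(d_ss, theta_i, theta_j, chi3, cfg)
    e = np.where(np.isfinite(e), e, np.inf)
    gi, gj = np.unravel_index(int(np.argmin(e)), e.shape)
    return ModeledDisulfide(
        chi1_i=float(chi1_values[gi]),
        chi1_j=float(chi1_values[gj]),
        chi3=float(chi3[gi, gj]),
        d_ss=float(d_ss[gi, gj]),
        sg_i=sg[0][gi],
        sg_j=sg[1][gj],
        theta_i=float(theta_i[gi, gj]),
        theta_j=float(theta_j[gi, gj]),
        e_strain=float(e[gi, gj]),
    )


# ---------------------------------------------------------------------------
# filtering and ranking


def apply_filters(
    cands: Sequence[DisulfideCandidate],
    s: Structure,
    cfg: DesignConfig | None = None,
    disordered: Sequence[DisorderedRegion] = (),
    native: Sequence[tuple[Residue, Residue]] = (),
) -> list[DisulfideCandidate]:
    """Annotate candidates with advisory flags; nothing is deleted.

    Flags: ``near_active_site`` (any atom within ``active_site_radius`` of a
    catalytic side chain), ``involves_native_cys`` (member of a detected native
    disulfide), ``buried_i``/``buried_j`` (Cβ-neighbour count above
    ``burial_neighbor_max``), ``in_disordered_region`` (member within ±2
    residues of a crystallographically disordered stretch).
    """
    cfg = cfg or DesignConfig()
    site_atoms = []
    for chain_id, num in cfg.active_site_residues:
        try:
            r = s.get_residue(chain_id, num)
        except KeyError as exc:
            raise ConfigurationError(f"active-site residue {chain_id}/{num} absent") from exc
        side = [a.coords for a in r.atoms if a.name not in BACKBONE_ATOMS]
        site_atoms.extend(side if side else [a.coords for a in r.atoms])
    site = np.array(site_atoms) if site_atoms else None

    native_keys = {r.key for p in native for r in p}
    cb_all = np.array([c for r in s.residues() if (c := _scan_coord(r)) is not None])

    def near_site(res: Residue) -> bool:
        if site is None:
            return False
        pts = np.array([a.coords for a in res.atoms])
        return bool(np.min(cdist(pts, site)) <= cfg.active_site_radius)

    def buried(res: Residue) -> bool:
        c = _scan_coord(res)
        if c is None:
            return False
        d = np.linalg.norm(cb_all - c, axis=1)
        return int(np.count_nonzero(d <= cfg.burial_neighbor_cutoff)) - 1 > cfg.burial_neighbor_max

    def near_disorder(res: Residue) -> bool:
        return any(
            reg.chain_id == res.chain_id and reg.covers(res.auth_seq_num, margin=2)
            for reg in disordered
        )

    for c in cands:
        c.flags = {
            "near_active_site": near_site(c.res_i) or near_site(c.res_j),
            "involves_native_cys": c.res_i.key in native_keys or c.res_j.key in native_keys,
            "in_disordered_region": near_disorder(c.res_i) or near_disorder(c.res_j),
            "buried_i": buried(c.res_i),
            "buried_j": buried(c.res_j),
        }
    return list(cands)


def rank_candidates(cands: Sequence[DisulfideCandidate]) -> list[DisulfideCandidate]:
    """Stable ranking: quality class, then flagged-demotion, then combined
    energy ``ΔE + max(ΔEi, 0)``, then Cβ–Cβ distance."""
    def key(c: DisulfideCandidate):
        q = c.quality.order if c.quality is not None else 3
        return (q, c.demoted, c.e_strain + max(c.e_interaction, 0.0), c.d_cb)

    return sorted(cands, key=key)


def mutate_to_cys(
    s: Structure,
    pair: tuple[Residue, Residue],
    model: ModeledDisulfide,
) -> Structure:
    """Return a copy of the structure with the pair mutated to cysteine.

    Side-chain atoms beyond Cβ are removed, Sγ is added at the modelled
    coordinates, and every other residue is untouched.
    """
    out = s.copy()
    for res, sg in ((pair[0], model.sg_i), (pair[1], model.sg_j)):
        r = out.get_residue(*res.key)
        cb = virtual_cb(res)
        r.res_name = "CYS"
        kept = [a for a in r.atoms if a.name in BACKBONE_ATOMS]
        kept.append(Atom(name="CB", element="C", coords=cb))
        kept.append(Atom(name="SG", element="S", coords=np.asarray(sg, float)))
        r.atoms = kept
    return out


# ---------------------------------------------------------------------------
# end-to-end scan


def scan_structure(
    s: Structure,
    cfg: DesignConfig | None = None,
    disordered: Sequence[DisorderedRegion] | None = None,
) -> tuple[list[DisulfideCandidate], list[tuple[Residue, Residue]]]:
    """Full screen: native disulfides, enumeration, modelling, scoring,
    classification, flagging and ranking.  Returns (ranked candidates,
    native disulfide pairs)."""
    cfg = cfg or DesignConfig()
    native = detect_native_disulfides(s, cfg.native_ss_max)
    if disordered is None:
        disordered = detect_missing_regions_or_empty(s)
    cands = []
    for ri, rj, d_cb in enumerate_pairs(s, cfg):
        try:
            m = model_disulfide(s, (ri, rj), cfg)
        except (GeometryError, StructureError) as exc:
            log.warning("pair %s-%s: modelling failed (%s); skipped", ri.label, rj.label, exc)
            continue
        ei = interaction_energy(s, m.sg_i, m.sg_j, (ri, rj), cfg)
        cand = DisulfideCandidate(
            res_i=ri,
            res_j=rj,
            d_cb=d_cb,
            model=m,
            e_strain=m.e_strain,
            e_interaction=ei,
            quality=classify_quality(ei, m.e_strain),
        )
        cands.append(cand)
    apply_filters(cands, s, cfg, disordered=disordered, native=native)
    return rank_candidates(cands), native


def detect_missing_regions_or_empty(s: Structure) -> list[DisorderedRegion]:
    from .structure_io import detect_missing_regions

    if not s.seqres:
        return []
    return detect_missing_regions(s)


# ---------------------------------------------------------------------------
# reporting


def candidates_to_dataframe(cands: Sequence[DisulfideCandidate]) -> pd.DataFrame:
    rows = []
    for rank, c in enumerate(cands, start=1):
        m = c.model
        rows.append(
            {
                "rank": rank,
                "chain_i": c.res_i.chain_id,
                "res_i": c.res_i.auth_seq_num,
                "aa_i": c.res_i.res_name,
                "chain_j": c.res_j.chain_id,
                "res_j": c.res_j.auth_seq_num,
                "aa_j": c.res_j.res_name,
                "d_cb": round(c.d_cb, 3),
                "d_ss": round(m.d_ss, 3) if m else None,
                "chi1_i": round(m.chi1_i, 1) if m else None,
                "chi1_j": round(m.chi1_j, 1) if m else None,
                "chi3": round(m.chi3, 1) if m else None,
                "e_strain": round(c.e_strain, 3),
                "e_interaction": round(c.e_interaction, 3),
                "quality": c.quality.value if c.quality else None,
                "flags": ";".join(k for k, v in sorted(c.flags.items()) if v),
            }
        )
    return pd.DataFrame(rows)


def write_candidate_report(
    cands: Sequence[DisulfideCandidate],
    cfg: DesignConfig,
    tsv_path: str | Path | None = None,
    json_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write the candidate table as TSV and/or JSON (with the config echoed)."""
    df = candidates_to_dataframe(cands)
    if tsv_path is not None:
        df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = {
            "config": dataclasses.asdict(cfg),
            "candidates": df.to_dict(orient="records"),
        }
        Path(json_path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return df
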