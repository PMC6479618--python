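"""Conformational-stability metrics over coordinate ensembles.

Given an ordered ensemble of frames (stand-ins for snapshots of a molecular
dynamics trajectory) the module computes the three observables used to judge
whether an engineered disulfide rigidified a structure:

* backbone RMSD per frame after optimal (Kabsch) superposition onto a
  reference — drift of this series indicates unfolding;
* radius of gyration per frame — loss of compactness;
* Sγ–Sγ distance per frame for each disulfide, and the fraction of frames in
  which the bond stays below a retention threshold (2.15 Å by default).  A
  bond is called stable only when retention is 1.0.

RMSD uses the {N, CA, C} backbone selection; Rg is mass-weighted by default.
Neither Rg nor S–S distances involve superposition (both are internal /
centre-of-mass-relative quantities).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import kabsch_superpose
from .structure_io import Ensemble, Structure, StructureError

log = logging.getLogger(__name__)

__all__ = [
    "ATOMIC_MASSES",
    "BACKBONE_SELECTION",
    "SS_RETENTION_THRESHOLD",
    "StabilityReport",
    "kabsch_superpose",
    "rmsd_series",
    "radius_of_gyration",
    "rg_series",
    "ss_distance_series",
    "ss_retention",
    "analyze_ensemble",
    "summarize",
    "write_report",
    "plot_report",
]

BACKBONE_SELECTION = ("N", "CA", "C")
SS_RETENTION_THRESHOLD = 2.15  # Å

ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
    "FE": 55.845,
    "ZN": 65.38,
}

BondKey = tuple[tuple[str, int], tuple[str, int]]


def _mass(element: str) -> float:
    m = ATOMIC_MASSES.get(element.upper())
    if m is None:
        log.warning("element %r has no tabulated mass; using 12.011", element)
        return 12.011
    return m


def rmsd_series(
    e: Ensemble,
    reference_mode: str = "first_frame",
    reference: Structure | None = None,
    backbone: Sequence[str] = BACKBONE_SELECTION,
) -> np.ndarray:
    """Per-frame backbone RMSD after Kabsch superposition onto the reference.

    ``reference_mode`` is ``"first_frame"`` or ``"external_reference"`` (the
    latter requires ``reference``, matched atom-by-atom by residue identity).
    """
    idx = e.atom_indices(backbone)
    if idx.size == 0:
        raise StructureError(f"backbone selection {tuple(backbone)} matches no ensemble atoms")
    sub = e.frames[:, idx, :]
    if reference_mode == "first_frame":
        ref = sub[0]
    elif reference_mode == "external_reference":
        if reference is None:
            raise ValueError("reference_mode='external_reference' requires a reference structure")
        wanted = [e.atoms[i] for i in idx]
        coords = []
        for aref in wanted:
            r = reference.get_residue(aref.chain_id, aref.auth_seq_num, aref.icode)
            a = r.atom(aref.atom_name)
            if a is None:
                raise StructureError(f"reference lacks atom {aref.atom_name} of {r.label}")
            coords.append(a.coords)
        ref = np.array(coords)
    else:
        raise ValueError(f"unknown reference_mode {reference_mode!r}")
    return np.array([kabsch_superpose(ref, frame)[2] for frame in sub])


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration, Å: sqrt(Σ m |r − r_com|² / Σ m)."""
    coords = np.asarray(coords, float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
        raise ValueError("coords must have shape (N, 3) with N >= 1")
    if masses is None:
        m = np.ones(coords.shape[0])
    else:
        m = np.asarray(masses, float)
        if m.shape != (coords.shape[0],) or np.any(m <= 0):
            raise ValueError("masses must be positive, one per atom")
    total = m.sum()
    if total <= 0:
        raise ValueError("zero total mass")
    com = (m @ coords) / total
    return float(np.sqrt(np.sum(m * np.sum((coords - com) ** 2, axis=1)) / total))


def rg_series(e: Ensemble, mass_weighted: bool = True) -> np.ndarray:
    masses = (
        np.array([_mass(a.element) for a in e.atoms]) if mass_weighted else None
    )
    return np.array([radius_of_gyration(f, masses) for f in e.frames])


def ss_distance_series(
    e: Ensemble, bonds: Sequence[BondKey]
) -> dict[BondKey, np.ndarray]:
    """Euclidean Sγ–Sγ distance per frame for each disulfide (no superposition).

    Bonds are given as ``((chain, resnum), (chain, resnum))`` pairs.
    """
    out: dict[BondKey, np.ndarray] = {}
    for bond in bonds:
        (ci, ni), (cj, nj) = bond
        try:
            ii = e.find_atom(ci, ni, "SG")
        except KeyError as exc:
            raise StructureError(f"residue {ci}/{ni}: no SG atom in ensemble") from exc
        try:
            jj = e.find_atom(cj, nj, "SG")
        except KeyError as exc:
            raise StructureError(f"residue {cj}/{nj}: no SG atom in ensemble") from exc
        out[bond] = np.linalg.norm(e.frames[:, ii, :] - e.frames[:, jj, :], axis=1)
    return out


def ss_retention(series: np.ndarray, threshold: float = SS_RETENTION_THRESHOLD) -> float:
    """Fraction of frames with S–S distance at or below the threshold."""
    series = np.asarray(series, float)
    if series.size == 0:
        raise ValueError("empty distance series")
    return float(np.count_nonzero(series <= threshold) / series.size)


@dataclass
class StabilityReport:
    """Stability observables of one ensemble under one temperature condition."""

    label: str
    temperature_label: float | None
    times: np.ndarray
    rmsd: np.ndarray
    rg: np.ndarray
    ss: dict[BondKey, np.ndarray] = field(default_factory=dict)
    ss_threshold: float = SS_RETENTION_THRESHOLD

    def __post_init__(self) -> None:
        n = len(self.times)
        if len(self.rmsd) != n or len(self.rg) != n:
            raise ValueError("all series must have one value per frame")
        for bond, ser in self.ss.items():
            if len(ser) != n:
                raise ValueError(f"S-S series for {bond} has wrong length")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def retention(self) -> dict[BondKey, float]:
        return {b: ss_retention(s, self.ss_threshold) for b, s in self.ss.items()}

    @property
    def unstable(self) -> bool:
        """Late-window drift heuristic: mean RMSD over the final 20% of frames
        exceeds 1.5x the mean over the first 20%."""
        k = max(1, int(0.2 * self.n_frames))
        first = float(np.mean(self.rmsd[:k]))
        last = float(np.mean(self.rmsd[-k:]))
        return last > 1.5 * first

    def summary_row(self) -> dict:
        row = {
            "label": self.label,
            "temperature_C": self.temperature_label,
            "n_frames": self.n_frames,
            "rmsd_mean": float(np.mean(self.rmsd)),
            "rmsd_sd": float(np.std(self.rmsd)),
            "rg_mean": float(np.mean(self.rg)),
            "rg_sd": float(np.std(self.rg)),
            "unstable": self.unstable,
        }
        ret = self.retention
        row["ss_retention"] = (
            ";".join(f"{ci}{ni}:{cj}{nj}={v:.3f}" for ((ci, ni), (cj, nj)), v in ret.items())
            or None
        )
        row["ss_retention_min"] = min(ret.values()) if ret else None
        row["ss_all_stable"] = all(v == 1.0 for v in ret.values()) if ret else None
        return row


def analyze_ensemble(
    e: Ensemble,
    bonds: Sequence[BondKey] = (),
    reference: Structure | None = None,
    ss_threshold: float = SS_RETENTION_THRESHOLD,
    backbone: Sequence[str] = BACKBONE_SELECTION,
    mass_weighted_rg: bool = True,
) -> StabilityReport:
    """Compute the full stability report for one ensemble."""
    mode = "external_reference" if reference is not None else "first_frame"
    return StabilityReport(
        label=e.identifier,
        temperature_label=e.temperature_label,
        times=e.times,
        rmsd=rmsd_series(e, mode, reference, backbone),
        rg=rg_series(e, mass_weighted_rg),
        ss=ss_distance_series(e, bonds),
        ss_threshold=ss_threshold,
    )


def summarize(reports: Sequence[StabilityReport]) -> pd.DataFrame:
    """Comparison table across ensembles/temperature conditions."""
    if not reports:
        raise ValueError("summarize needs at least one report")
    return pd.DataFrame([r.summary_row() for r in reports])


def write_report(
    report: StabilityReport,
    json_path: str | Path | None = None,
    tsv_path: str | Path | None = None,
) -> None:
    """Serialize per-frame series (TSV) and the summary with settings (JSON)."""
    if tsv_path is not None:
        cols = {"time_ps": report.times, "rmsd_A": report.rmsd, "rg_A": report.rg}
        for ((ci, ni), (cj, nj)), ser in report.ss.items():
            cols[f"ss_{ci}{ni}_{cj}{nj}_A"] = ser
        pd.DataFrame(cols).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = report.summary_row()
        payload["ss_threshold_A"] = report.ss_threshold
        Path(json_path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


def plot_report(report: StabilityReport, path: str | Path) -> None:
    """Optional per-series plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_panels = 2 + (1 if report.ss else 0)
    fig, axes = plt.subplots(n_panels, 1, figsize=(7, 2.4 * n_panels), sharex=True)
    axes = np.atleast_1d(axes)
    axes[0].plot(report.times / 1000.0, report.rmsd)
    axes[0].set_ylabel("RMSD (Å)")
    axes[1].plot(report.times / 1000.0, report.rg)
    axes[1].set_ylabel("Rg (Å)")
    if report.ss:
        for ((ci, ni), (cj, nj)), ser in report.ss.items():
            axes[2].plot(report.times / 1000.0, ser, label=f"{ci}{ni}-{cj}{nj}")
        axes[2].axhline(report.ss_threshold, ls="--", c="k", lw=0.8)
        axes[2].set_ylabel("S–S (Å)")
        axes[2].legend(fontsize=8)
    axes[-1].set_xlabel("time (ns)")
    title = report.label
    if report.temperature_label is not None:
        title += f" @ {report.temperature_label} °C"
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
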