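"""Checks against the endoglucanase II crystal structure (PDB 5L9C, chain A).

The engineered enzyme this package was written around is EGLII from
*Penicillium verruculosum* (glycoside hydrolase family 5).  Its crystal
structure is not distributed with the package; when a local copy of the
PDB entry is available these helpers verify the structural facts the design
workflow relies on:

* exactly one native disulfide, C221-C258;
* the chosen engineered pairs S127C-A165C and Y171C-L201C pass the 5 Å
  Cβ–Cβ feasibility screen;
* a crystallographically disordered mid-chain stretch covering residues
  212–219 (near the active site, hence excluded from mutagenesis);
* catalytic residues E142 and E249 present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dsb_design import detect_native_disulfides
from .structure_io import detect_missing_regions, read_structure

__all__ = ["ReferenceCheck", "validate_reference_structure", "EGLII_ACTIVE_SITE"]

EGLII_ACTIVE_SITE = (142, 249)  # catalytic glutamates
EGLII_NATIVE_DISULFIDE = (221, 258)
EGLII_ENGINEERED_PAIRS = ((127, 165), (171, 201))
EGLII_DISORDERED_MID = (212, 219)


@dataclass
class ReferenceCheck:
    checks: dict[str, bool] = field(default_factory=dict)
    details: dict[str, object] = field(default_factory=dict)

    @property
    def all_passed(self) -> bool:
        return all(self.checks.values())


def validate_reference_structure(path: str | Path, chain: str = "A") -> ReferenceCheck:
    """Validate a local copy of the EGLII crystal structure (see module docs)."""
    s = read_structure(path, chain_filter=chain)
    out = ReferenceCheck()

    native = [(a.auth_seq_num, b.auth_seq_num) for a, b in detect_native_disulfides(s)]
    out.checks["single_native_disulfide_221_258"] = native == [EGLII_NATIVE_DISULFIDE]
    out.details["native_disulfides"] = native

    for i, j in EGLII_ENGINEERED_PAIRS:
        key = f"pair_{i}_{j}_cb_within_5A"
        try:
            ri, rj = s.get_residue(chain, i), s.get_residue(chain, j)
            ci = (ri.atom("CB") or ri.atom("CA")).coords
            cj = (rj.atom("CB") or rj.atom("CA")).coords
            d = float(np.linalg.norm(ci - cj))
            out.checks[key] = d <= 5.0
            out.details[key] = d
        except KeyError:
            out.checks[key] = False
            out.details[key] = "residue missing"

    try:
        regions = detect_missing_regions(s)
        lo, hi = EGLII_DISORDERED_MID
        out.checks["mid_chain_disorder_covers_212_219"] = any(
            r.start <= lo and r.end >= hi for r in regions
        )
        out.details["missing_regions"] = [(r.start, r.end) for r in regions]
    except Exception as exc:  # no SEQRES in the local copy
        out.checks["mid_chain_disorder_covers_212_219"] = False
        out.details["missing_regions"] = f"not determinable: {exc}"

    present = {r.auth_seq_num: r.res_name for r in s.residues(chain)}
    out.checks["catalytic_glutamates_present"] = all(
        present.get(n) == "GLU" for n in EGLII_ACTIVE_SITE
    )
    return out
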