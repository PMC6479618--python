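"""Verification of mutagenic primer tables.

For each cysteine substitution, site-directed mutagenesis by overlap-extension
PCR uses a forward/reverse primer pair spanning the mutated codon.  The two
primers of a pair anneal to opposite strands over the same region, so the
reverse primer must match the reverse complement of the forward primer —
exactly, or up to a short terminal overhang when the two primers have
staggered ends (a common design; two of the published pairs verified here
differ by a single 3' base).

Verdicts are always recomputed from the sequences, never read from the input.
The cysteine-codon check (TGT/TGC) is substring-based: without the gene
sequence the reading frame is unknown, so a frame-aware check is impossible
and a rare false positive from a spanning codon is accepted as a documented
limitation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
import pandas as pd

__all__ = [
    "Primer",
    "MutagenicPair",
    "TableSummary",
    "PrimerError",
    "reverse_complement",
    "verify_pair",
    "check_table",
    "packaged_primer_table",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
CYS_CODONS = ("TGT", "TGC")


class PrimerError(ValueError):
    pass


def _validate(seq: str, name: str = "sequence") -> str:
    s = seq.strip().upper()
    if not s:
        raise PrimerError(f"{name}: empty sequence")
    for pos, ch in enumerate(s, start=1):
        if ch not in "ACGT":
            raise PrimerError(f"{name}: invalid character {ch!r} at position {pos}")
    return s


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str  # 5'->3', uppercase ACGT

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _validate(self.sequence, self.name or "primer"))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MutagenicPair:
    mutation: str  # e.g. "S127C"
    fwd: Primer
    rev: Primer
    is_exact_revcomp: bool | None = None
    is_revcomp_consistent: bool | None = None
    has_cys_codon: bool | None = None


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA sequence (involution; case-insensitive input)."""
    return _validate(seq)[::-1].translate(_COMPLEMENT)


def _overlap_consistent(a: str, b: str) -> bool:
    """True when the shorter sequence is a terminal-aligned substring of the
    longer (equal sequences included) — i.e. the pair differs only by a short
    single-stranded overhang at one end."""
    if len(a) > len(b):
        a, b = b, a
    return b.startswith(a) or b.endswith(a)


def verify_pair(p: MutagenicPair) -> MutagenicPair:
    """Recompute strand-consistency and cysteine-codon verdicts for a pair."""
    rc = reverse_complement(p.fwd.sequence)
    exact = rc == p.rev.sequence
    return replace(
        p,
        is_exact_revcomp=exact,
        is_revcomp_consistent=exact or _overlap_consistent(rc, p.rev.sequence),
        has_cys_codon=any(c in p.fwd.sequence for c in CYS_CODONS),
    )


@dataclass
class TableSummary:
    n_pairs: int
    n_consistent: int
    n_with_cys_codon: int
    pairs: list[MutagenicPair]

    @property
    def all_consistent(self) -> bool:
        return self.n_consistent == self.n_pairs

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_consistent": self.n_consistent,
            "n_with_cys_codon": self.n_with_cys_codon,
            "pairs": [
                {
                    "mutation": p.mutation,
                    "fwd": p.fwd.name,
                    "rev": p.rev.name,
                    "is_exact_revcomp": p.is_exact_revcomp,
                    "is_revcomp_consistent": p.is_revcomp_consistent,
                    "has_cys_codon": p.has_cys_codon,
                }
                for p in self.pairs
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def check_table(path: str | Path) -> TableSummary:
    """Verify a TSV primer table (columns: mutation, primer_name, sequence).

    Rows are paired by mutation label via ``-fwd``/``-rev`` primer-name
    suffixes; a blank mutation cell inherits the label above it (as in a
    printed table).  Unpaired primers are an error listing the orphans.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"mutation", "primer_name", "sequence"}
    if not required.issubset(df.columns):
        raise PrimerError(f"{path}: table must have columns {sorted(required)}")
    if df.empty:
        return TableSummary(0, 0, 0, [])
    df["mutation"] = df["mutation"].replace("", pd.NA).ffill()
    if df["mutation"].isna().any():
        raise PrimerError(f"{path}: leading rows lack a mutation label")

    groups: dict[str, dict[str, Primer]] = {}
    for _, row in df.iterrows():
        name = row["primer_name"].strip()
        if name.endswith("-fwd"):
            role = "fwd"
        elif name.endswith("-rev"):
            role = "rev"
        else:
            raise PrimerError(f"primer {name!r}: name must end in -fwd or -rev")
        slot = groups.setdefault(str(row["mutation"]).strip(), {})
        if role in slot:
            raise PrimerError(f"mutation {row['mutation']}: duplicate {role} primer")
        slot[role] = Primer(name=name, sequence=row["sequence"])

    orphans = [
        f"{mut} ({', '.join(p.name for p in slot.values())})"
        for mut, slot in groups.items()
        if set(slot) != {"fwd", "rev"}
    ]
    if orphans:
        raise PrimerError("unpaired primers: " + "; ".join(orphans))

    pairs = [
        verify_pair(MutagenicPair(mutation=m, fwd=slot["fwd"], rev=slot["rev"]))
        for m, slot in groups.items()
    ]
    pairs.sort(key=lambda p: p.mutation)
    return TableSummary(
        n_pairs=len(pairs),
        n_consistent=sum(bool(p.is_revcomp_consistent) for p in pairs),
        n_with_cys_codon=sum(bool(p.has_cys_codon) for p in pairs),
        pairs=pairs,
    )


def packaged_primer_table() -> Path:
    """Path to the packaged six-pair mutagenic primer table."""
    return Path(__file__).parent / "data" / "table2_primers.tsv"
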