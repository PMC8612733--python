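"""Residue-level sequence features of phase-separating proteins.

Intrinsically disordered regions (IDRs) that drive condensation are
characterized here by two simple profiles: net charge per residue (NCPR)
over a sliding window, and counts of the residue classes relevant to
condensation (aromatic Y, basic R/K, acidic D/E, polar Q/N, hydrophobic
V/M/F). The module also builds the standard mutant constructs used to
dissect IDR grammar: class substitutions over a region (e.g. "CTD-Y to S",
"CTD-RK to G" on YBX1's C-terminal domain, residues 128-324) and interval
deletions.

Charge convention: R and K are +1, D and E are -1, everything else 0.
Histidine is treated as uncharged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import CondquantError, FormatError

__all__ = [
    "CANONICAL_RESIDUES",
    "RESIDUE_CLASSES",
    "YBX1_CTD",
    "ProteinSequence",
    "NCPRProfile",
    "SubstitutionRule",
    "ncpr_profile",
    "residue_class_composition",
    "apply_substitution_rule",
    "deletion_variant",
    "ctd_rule",
    "read_fasta",
    "write_fasta",
]

CANONICAL_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

_CHARGE = {"R": 1, "K": 1, "D": -1, "E": -1}

#: Residue classes probed by the standard IDR substitution mutants.
RESIDUE_CLASSES = {
    "Y": "Y",
    "R/K": "RK",
    "D/E": "DE",
    "Q/N": "QN",
    "V/M/F": "VMF",
}

#: YBX1 C-terminal disordered domain, 1-based inclusive residue interval.
YBX1_CTD = (128, 324)


@dataclass
class ProteinSequence:
    """A protein sequence with 1-based residue positions."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise CondquantError("empty protein sequence")
        bad = set(self.residues) - CANONICAL_RESIDUES
        if bad:
            raise CondquantError(
                f"{self.id}: non-canonical residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class NCPRProfile:
    """Sliding-window net charge per residue.

    ``values[i]`` is the mean charge over the window centred at 1-based
    position ``center_positions[i]``; values lie in [-1, 1]. Terminal
    positions without a full window are omitted.
    """

    window: int
    center_positions: np.ndarray
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.center_positions, "ncpr": self.values}
        )


@dataclass
class SubstitutionRule:
    """Replace every residue matching a mapping key within a region.

    ``region`` is a 1-based inclusive interval; ``mapping`` maps single
    residues to single replacement residues (e.g. ``{"Y": "S"}`` for
    "Y to S", ``{"R": "G", "K": "G"}`` for "RK to G").
    """

    name: str
    region: tuple[int, int]
    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, val in self.mapping.items():
            if len(key) != 1 or key not in CANONICAL_RESIDUES:
                raise CondquantError(f"mapping key {key!r} is not a residue")
            if len(val) != 1 or val not in CANONICAL_RESIDUES:
                raise CondquantError(
                    f"replacement {val!r} is not a canonical residue"
                )
        if self.region[0] < 1 or self.region[1] < self.region[0]:
            raise CondquantError(f"invalid region {self.region}")


def _check_region(seq: ProteinSequence, region: tuple[int, int]) -> tuple[int, int]:
    start, end = int(region[0]), int(region[1])
    if start < 1 or end > len(seq) or end < start:
        raise CondquantError(
            f"region {region} out of bounds for length-{len(seq)} sequence"
        )
    return start, end


def ncpr_profile(seq: ProteinSequence, window: int = 5) -> NCPRProfile:
    """Net charge per residue over a sliding window (default 5 residues).

    Each window's value is (count of R/K - count of D/E) / window,
    reported at the window's centre position (``i + window//2`` for a
    window starting at 1-based position ``i``).
    """
    if window < 1:
        raise CondquantError("window must be >= 1")
    if len(seq) < window:
        raise CondquantError(
            f"sequence length {len(seq)} shorter than window {window}"
        )
    charges = np.array([_CHARGE.get(r, 0) for r in seq.residues], dtype=np.float64)
    kernel = np.ones(window)
    values = np.convolve(charges, kernel, mode="valid") / window
    centers = np.arange(1, len(seq) - window + 2) + window // 2
    return NCPRProfile(window=window, center_positions=centers, values=values)


def residue_class_composition(
    seq: ProteinSequence, region: tuple[int, int] | None = None
) -> pd.DataFrame:
    """Counts and fractions of the mutant-relevant residue classes.

    Classes: Y, R/K, D/E, Q/N, V/M/F, plus "other". ``region`` restricts
    the count to a 1-based inclusive interval (default: whole sequence).
    """
    if region is None:
        region = (1, len(seq))
    start, end = _check_region(seq, region)
    segment = seq.residues[start - 1 : end]
    n = len(segment)
    rows = []
    classified = 0
    for label, members in RESIDUE_CLASSES.items():
        count = sum(segment.count(m) for m in members)
        classified += count
        rows.append({"residue_class": label, "count": count, "fraction": count / n})
    rows.append(
        {
            "residue_class": "other",
            "count": n - classified,
            "fraction": (n - classified) / n,
        }
    )
    df = pd.DataFrame(rows)
    df.attrs["region"] = (start, end)
    return df


def apply_substitution_rule(
    seq: ProteinSequence, rule: SubstitutionRule
) -> ProteinSequence:
    """Apply a residue-class substitution over the rule's region.

    Residues outside the region are untouched; the output id is
    ``"<seq.id>|<rule.name>"``. Length never changes.
    """
    start, end = _check_region(seq, rule.region)
    chars = list(seq.residues)
    for i in range(start - 1, end):
        chars[i] = rule.mapping.get(chars[i], chars[i])
    return ProteinSequence(id=f"{seq.id}|{rule.name}", residues="".join(chars))


def deletion_variant(
    seq: ProteinSequence, interval: tuple[int, int]
) -> ProteinSequence:
    """Delete a 1-based inclusive residue interval.

    Deleting the whole sequence is an error (an empty protein is not a
    construct). The output id records the deletion, e.g. ``"P1|d1-127"``.
    """
    start, end = _check_region(seq, interval)
    if start == 1 and end == len(seq):
        raise CondquantError("deletion would remove the entire sequence")
    remaining = seq.residues[: start - 1] + seq.residues[end:]
    return ProteinSequence(id=f"{seq.id}|d{start}-{end}", residues=remaining)


def ctd_rule(
    classes: str, replacement: str, region: tuple[int, int] = YBX1_CTD
) -> SubstitutionRule:
    """Build a named class-substitution rule over the CTD.

    ``ctd_rule("Y", "S")`` is the "CTD-Y to S" construct;
    ``ctd_rule("RK", "G")`` is "CTD-RK to G"; the region defaults to
    YBX1's C-terminal domain (residues 128-324).
    """
    mapping = {c: replacement for c in classes}
    return SubstitutionRule(
        name=f"CTD-{'/'.join(classes)} to {replacement}",
        region=region,
        mapping=mapping,
    )


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read FASTA {path}: {exc}") from exc
    if not records:
        raise FormatError(f"no sequences in {path}")
    return [ProteinSequence(id=r.id, residues=str(r.seq)) for r in records]


def write_fasta(sequences: list[ProteinSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")
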