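"""Cross-assay tabular statistics: set overlaps and qPCR enrichment.

Two small but frequently reported statistics live here:

* overlap between gene/protein identifier sets (e.g. a condensate
  interactome vs a published P-body or stress-granule proteome), reported
  as an intersection count and a percentage of the *reference* set;
* exosomal miRNA enrichment from RT-qPCR cycle thresholds: fold change
  ``2^(Ct_cell - Ct_exo)`` and the relative enrichment of a condition
  over a control (ratio of their exosome/cell fold changes).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .exceptions import CondquantError

__all__ = [
    "GeneSet",
    "OverlapResult",
    "EnrichmentResult",
    "CtFoldChange",
    "normalize_ids",
    "overlap",
    "relative_enrichment",
    "fold_change_from_ct",
    "CT_NEGATIVE_CUTOFF",
]

logger = logging.getLogger(__name__)

#: Ct values above this are treated as "not detected".
CT_NEGATIVE_CUTOFF = 40.0


@dataclass(frozen=True)
class GeneSet:
    """A named set of normalized gene/protein identifiers."""

    name: str
    ids: frozenset[str]

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class OverlapResult:
    n_query: int
    n_reference: int
    n_intersect: int
    pct_of_reference: float
    shared: frozenset[str]


@dataclass(frozen=True)
class EnrichmentResult:
    fc_exo_over_cell_condition: float
    fc_exo_over_cell_control: float
    relative_enrichment: float


@dataclass(frozen=True)
class CtFoldChange:
    """Fold change from a Ct pair; ``negative=True`` means not detected."""

    fold_change: float | None
    negative: bool


def normalize_ids(raw: list[str], name: str = "") -> GeneSet:
    """Trim, upper-case and de-duplicate raw identifier strings.

    No alias or ortholog resolution is attempted — normalization is
    deterministic string cleanup only. Duplicates (after normalization)
    are logged at INFO level. All-empty input is an error.
    """
    if not raw:
        raise CondquantError("empty identifier list")
    seen: set[str] = set()
    duplicates = []
    for item in raw:
        ident = str(item).strip().upper()
        if not ident:
            continue
        if ident in seen:
            duplicates.append(ident)
        seen.add(ident)
    if not seen:
        raise CondquantError("no non-empty identifiers after normalization")
    if duplicates:
        logger.info("%s: %d duplicate id(s) dropped: %s",
                    name or "gene set", len(duplicates), sorted(set(duplicates)))
    return GeneSet(name=name, ids=frozenset(seen))


def overlap(query: GeneSet, reference: GeneSet) -> OverlapResult:
    """Exact intersection of two normalized sets.

    The percentage uses the *reference* set as denominator: "what fraction
    of the reference proteome is present in the query".
    """
    if len(reference) == 0:
        raise CondquantError("reference set is empty")
    shared = query.ids & reference.ids
    return OverlapResult(
        n_query=len(query),
        n_reference=len(reference),
        n_intersect=len(shared),
        pct_of_reference=100.0 * len(shared) / len(reference),
        shared=frozenset(shared),
    )


def fold_change_from_ct(ct_exo: float, ct_cell: float) -> CtFoldChange:
    """Fold change (exosome over cell) from RT-qPCR cycle thresholds.

    ``fold_change = 2 ** (ct_cell - ct_exo)``. A Ct above
    :data:`CT_NEGATIVE_CUTOFF` on either side means the species was not
    detected: the result is flagged negative with no numeric fold change.
    """
    for name, ct in (("ct_exo", ct_exo), ("ct_cell", ct_cell)):
        if not math.isfinite(ct):
            raise CondquantError(f"{name} must be finite, got {ct}")
        if ct <= 0:
            raise CondquantError(f"{name} must be positive, got {ct}")
    if ct_exo > CT_NEGATIVE_CUTOFF or ct_cell > CT_NEGATIVE_CUTOFF:
        return CtFoldChange(fold_change=None, negative=True)
    return CtFoldChange(fold_change=2.0 ** (ct_cell - ct_exo), negative=False)


def relative_enrichment(fc_condition: float, fc_control: float) -> EnrichmentResult:
    """Relative enrichment: condition fold change over control fold change."""
    if not (fc_condition > 0 and fc_control > 0):
        raise CondquantError(
            f"fold changes must be positive, got {fc_condition}, {fc_control}"
        )
    return EnrichmentResult(
        fc_exo_over_cell_condition=float(fc_condition),
        fc_exo_over_cell_control=float(fc_control),
        relative_enrichment=float(fc_condition) / float(fc_control),
    )
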