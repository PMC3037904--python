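"""Gene-set collection preparation: alias repair, platform pruning, keyword
selection.

Gene-set membership matching in GSEA is by exact approved-symbol string, so a
set listing an alias (e.g. TNFA for TNF) silently loses that gene unless the
alias is repaired first.  Pruning removes sets with too few members
represented on the annotated platform — such sets cannot yield a stable
enrichment score.  Keyword filtering selects a focused sub-collection (e.g.
liver-disease sets) by case-insensitive OR-matching over names and
descriptions.
"""

from __future__ import annotations

import logging
import warnings

from .io_formats import GeneSet, GeneSetCollection, ProbeAnnotation, SymbolTable

logger = logging.getLogger(__name__)

__all__ = ["resolve_aliases_in_sets", "prune_by_platform", "filter_by_keyword"]


def resolve_aliases_in_sets(
    collection: GeneSetCollection, symbol_table: SymbolTable
) -> tuple[GeneSetCollection, dict[str, int]]:
    """Replace alias members with their approved symbols.

    Members that are already approved stay; aliases become their approved
    symbol (duplicates created by the replacement are deduplicated by the set
    container); members that are neither approved nor a known alias are kept
    unchanged — GSEA will simply never encounter them in a ranked list — and
    counted in the returned report ``{"replaced": n, "unknown": n}``.
    Idempotent: a second pass changes nothing.
    """
    replaced = 0
    unknown = 0
    sets = []
    for s in collection:
        members = set()
        for m in s.members:
            if symbol_table.is_approved(m):
                members.add(m)
                continue
            approved = symbol_table.to_approved(m)
            if approved is not None:
                members.add(approved)
                replaced += 1
            else:
                members.add(m)
                unknown += 1
        sets.append(GeneSet(name=s.name, description=s.description, members=frozenset(members)))
    return GeneSetCollection(sets), {"replaced": replaced, "unknown": unknown}


def prune_by_platform(
    collection: GeneSetCollection,
    annotation: ProbeAnnotation,
    min_mapped: int = 10,
) -> tuple[GeneSetCollection, list[str]]:
    """Drop sets with fewer than ``min_mapped`` members on the platform.

    The platform is the set of approved symbols carried by the annotation's
    mapped probes.  Returns the pruned collection and the names removed.
    """
    platform = annotation.symbols
    if not platform:
        raise ValueError("annotation carries no symbols; nothing to intersect with")
    kept, removed = [], []
    for s in collection:
        n = len(s.members & platform)
        if n < min_mapped:
            removed.append(s.name)
            logger.info("pruning %s: only %d of %d members on platform", s.name, n, len(s))
        else:
            kept.append(s)
    return GeneSetCollection(kept), removed


def filter_by_keyword(collection: GeneSetCollection, terms: list[str]) -> GeneSetCollection:
    """Keep sets whose name or description contains any term (case-insensitive).

    Emulates an OR keyword search over a curated database (e.g.
    ``["liver", "hepatocellular", "hepatitis"]``).  An empty term list is an
    error; a search with no matches returns an empty collection with a
    warning.
    """
    if not terms:
        raise ValueError("at least one search term is required")
    lowered = [t.lower() for t in terms]
    kept = [
        s
        for s in collection
        if any(t in s.name.lower() or t in s.description.lower() for t in lowered)
    ]
    if not kept:
        warnings.warn(f"no gene set matches terms {terms}", stacklevel=2)
    return GeneSetCollection(kept)
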