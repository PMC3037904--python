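"""Homology annotation of a non-human array with approved human gene symbols.

The annotation procedure consumes pre-computed BLAST tabular output (the
package never runs BLAST itself): each array element's EST was searched,
six-frame translated, against the human RefSeq protein database with a
permissive reporting threshold (e-value 0.01, ten hits reported) so the full
range of hits is visible.  For annotation only hits with e-value strictly
below 1e-10 are considered.  Per element:

1. take the hit with the lowest e-value; break e-value ties (commonly both
   0.0) by the highest bit-score;
2. if best hits tie on both e-value and bit-score, assign a symbol only when
   every tied protein resolves to the same approved symbol — otherwise the
   element is queued for human curation (``ambiguous_tie``);
3. resolve the chosen protein accession to an approved HGNC symbol across one
   or more symbol sources, repairing disagreements that are merely
   alias-vs-approved and flagging true conflicts;
4. optionally cross-check against a second homology route (e.g. zebrafish
   best hits mapped to human symbols through an ortholog table), reporting —
   never auto-resolving — disagreements.

The result is written as a GSEA CHIP file in which elements without a symbol
are retained blank (GSEA ignores them), plus curation reports.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd

from .io_formats import BlastHit, ProbeAnnotation, SymbolTable

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationDecision",
    "OrthologyEvidence",
    "select_best_hit",
    "resolve_symbol",
    "annotate_platform",
    "crosscheck_orthology",
    "build_chip",
    "duplicate_symbol_report",
    "DEFAULT_EVALUE_MAX",
]

DEFAULT_EVALUE_MAX = 1e-10


@dataclass
class AnnotationDecision:
    """The outcome of best-hit selection and symbol resolution for one probe.

    ``status`` is one of ``annotated`` (a symbol was assigned),
    ``below_threshold`` (no hit passed the e-value filter), ``ambiguous_tie``
    (best hits tied on e-value and bit-score across different symbols),
    ``symbol_conflict`` (sources truly disagree) or ``unmapped`` (the chosen
    protein is in no symbol source).
    """

    query_id: str
    chosen_protein: str | None = None
    chosen_symbol: str | None = None
    status: str = "below_threshold"
    evalue: float | None = None
    bitscore: float | None = None
    detail: str = ""

    def __post_init__(self) -> None:
        if (self.status == "annotated") != (self.chosen_symbol is not None):
            raise ValueError(
                f"{self.query_id}: status {self.status!r} inconsistent with "
                f"chosen_symbol {self.chosen_symbol!r}"
            )


@dataclass
class OrthologyEvidence:
    """Agreement between the direct human annotation and the ortholog route.

    ``agrees`` is True/False when both routes produced a symbol, and None when
    the ortholog route has no qualifying hit (unknown)."""

    query_id: str
    zebrafish_protein: str | None
    zebrafish_mapped_symbol: str | None
    human_symbol: str | None
    agrees: bool | None


def select_best_hit(
    hits: list[BlastHit],
    evalue_threshold: float = DEFAULT_EVALUE_MAX,
    symbol_of=None,
) -> AnnotationDecision:
    """Pick the best BLAST hit for one query under the annotation rules.

    Hits with e-value >= ``evalue_threshold`` are discarded first; with no
    survivor the decision is ``below_threshold`` (never an exception — an
    empty hit list is a legitimate unannotated probe).  Among survivors the
    lowest e-value wins; equal e-values are broken by the highest bit-score.
    Hits still tied on both are resolved through ``symbol_of`` (a callable
    mapping protein accession to approved symbol or None): when every tied
    protein carries one shared symbol they collapse silently to it, otherwise
    the decision is ``ambiguous_tie`` with no assignment.

    The returned decision carries the winning protein but no symbol; symbol
    resolution is a separate step (see :func:`resolve_symbol`).
    """
    if hits:
        queries = {h.query_id for h in hits}
        if len(queries) != 1:
            raise ValueError(f"hits span multiple queries: {sorted(queries)}")
        query_id = hits[0].query_id
    else:
        query_id = ""
    passing = [h for h in hits if h.evalue < evalue_threshold]
    if not passing:
        best = min(hits, key=lambda h: h.evalue) if hits else None
        return AnnotationDecision(
            query_id=query_id,
            status="below_threshold",
            evalue=best.evalue if best else None,
            bitscore=best.bitscore if best else None,
            detail="no hit below e-value threshold" if hits else "no hits",
        )
    min_e = min(h.evalue for h in passing)
    at_min_e = [h for h in passing if h.evalue == min_e]
    max_s = max(h.bitscore for h in at_min_e)
    tied = [h for h in at_min_e if h.bitscore == max_s]
    if len(tied) > 1:
        proteins = sorted({h.subject_id for h in tied})
        if len(proteins) > 1 and symbol_of is not None:
            symbols = {symbol_of(p) for p in proteins}
            if len(symbols) == 1 and None not in symbols:
                # distinct accessions (isoforms, post-duplication paralogs)
                # sharing one approved symbol collapse silently
                return AnnotationDecision(
                    query_id=query_id,
                    chosen_protein=proteins[0],
                    status="candidate",
                    evalue=min_e,
                    bitscore=max_s,
                    detail=f"tie collapsed: {len(proteins)} accessions share one symbol",
                )
        if len(proteins) == 1:
            return AnnotationDecision(
                query_id=query_id,
                chosen_protein=proteins[0],
                status="candidate",
                evalue=min_e,
                bitscore=max_s,
            )
        return AnnotationDecision(
            query_id=query_id,
            status="ambiguous_tie",
            evalue=min_e,
            bitscore=max_s,
            detail="tied best hits: " + ",".join(proteins),
        )
    win = tied[0]
    return AnnotationDecision(
        query_id=query_id,
        chosen_protein=win.subject_id,
        status="candidate",
        evalue=win.evalue,
        bitscore=win.bitscore,
    )



def resolve_symbol(
    protein_id: str, sources: list[SymbolTable]
) -> tuple[str | None, str]:
    """Resolve a protein accession to one approved symbol across sources.

    Each source is consulted by protein accession, falling back to linked
    mRNA accessions.  Agreement after alias normalisation yields the symbol;
    a disagreement in which one source's answer is merely an alias of
    another's approved symbol resolves to the approved symbol with an empty
    conflict report.  A true disagreement returns ``(None, report)`` for the
    curation queue; a protein unknown to every source returns
    ``(None, "unmapped")``.
    """
    if not sources:
        raise ValueError("at least one symbol source is required")
    answers: list[str] = []
    for src in sources:
        rec = src.lookup_protein(protein_id) or src.lookup_mrna(protein_id)
        if rec is not None:
            answers.append(rec.approved_symbol)
    if not answers:
        return None, "unmapped"
    distinct = sorted(set(answers))
    if len(distinct) == 1:
        return distinct[0], ""
    # alias repair: map every answer to approved form in every source
    repaired = set()
    for sym in distinct:
        approved = None
        for src in sources:
            approved = src.to_approved(sym)
            if approved is not None:
                break
        repaired.add(approved if approved is not None else sym)
    if len(repaired) == 1:
        return repaired.pop(), ""
    return None, "conflict: " + " vs ".join(sorted(repaired))


def annotate_platform(
    blast_groups: dict[str, list[BlastHit]],
    sources: list[SymbolTable],
    evalue_threshold: float = DEFAULT_EVALUE_MAX,
    probe_ids: list[str] | None = None,
) -> list[AnnotationDecision]:
    """Produce one :class:`AnnotationDecision` per array element.

    ``probe_ids`` fixes the full platform (elements without any BLAST hit get
    ``below_threshold`` decisions); by default the platform is the set of
    queries present in the hit file, in file order.
    """

    def symbol_of(protein: str) -> str | None:
        sym, report = resolve_symbol(protein, sources)
        return sym

    if probe_ids is None:
        probe_ids = list(blast_groups)
    decisions: list[AnnotationDecision] = []
    for probe in probe_ids:
        hits = blast_groups.get(probe, [])
        dec = select_best_hit(hits, evalue_threshold, symbol_of=symbol_of)
        if not dec.query_id:
            dec.query_id = probe
        if dec.status == "candidate":
            sym, report = resolve_symbol(dec.chosen_protein, sources)
            if sym is not None:
                dec.chosen_symbol = sym
                dec.status = "annotated"
            elif report == "unmapped":
                dec.status = "unmapped"
                dec.detail = report
            else:
                dec.status = "symbol_conflict"
                dec.detail = report
        decisions.append(dec)
    return decisions


def crosscheck_orthology(
    decisions: list[AnnotationDecision],
    zebrafish_hits: dict[str, list[BlastHit]],
    ortholog_table: dict[str, str],
    sources: list[SymbolTable],
    evalue_threshold: float = DEFAULT_EVALUE_MAX,
) -> list[OrthologyEvidence]:
    """Cross-check annotated probes against the ortholog homology route.

    For each probe with a human symbol, the best zebrafish hit (same e-value
    filter and tie rules) is mapped to a human symbol through the ortholog
    table.  Symbols are compared after alias resolution; disagreements are
    reported for curation, never auto-resolved.  A probe with no qualifying
    zebrafish hit, or whose zebrafish protein is absent from the ortholog
    table, gets ``agrees=None`` (unknown).
    """

    def to_approved(sym: str) -> str:
        for src in sources:
            a = src.to_approved(sym)
            if a is not None:
                return a
        return sym.upper()

    evidence: list[OrthologyEvidence] = []
    for dec in decisions:
        if dec.status != "annotated":
            continue
        zhits = zebrafish_hits.get(dec.query_id, [])
        zdec = select_best_hit(zhits, evalue_threshold)
        if zdec.status != "candidate":
            evidence.append(
                OrthologyEvidence(dec.query_id, None, None, dec.chosen_symbol, None)
            )
            continue
        zprot = zdec.chosen_protein
        mapped = ortholog_table.get(zprot)
        if mapped is None:
            evidence.append(
                OrthologyEvidence(dec.query_id, zprot, None, dec.chosen_symbol, None)
            )
            continue
        agrees = to_approved(mapped) == to_approved(dec.chosen_symbol)
        evidence.append(
            OrthologyEvidence(dec.query_id, zprot, mapped, dec.chosen_symbol, agrees)
        )
    return evidence


def build_chip(decisions: list[AnnotationDecision]) -> ProbeAnnotation:
    """Assemble the platform annotation from per-probe decisions.

    Unannotated probes (below threshold, ambiguous, conflicted, unmapped) are
    kept with an empty symbol so the platform file is complete; GSEA ignores
    them.  Summary counts are logged; a platform with zero annotated probes
    is valid but warned about.
    """
    ids = [d.query_id for d in decisions]
    if len(set(ids)) != len(ids):
        dups = sorted({q for q in ids if ids.count(q) > 1})
        raise ValueError(f"duplicate query ids in decisions: {dups[:5]}")
    rows = {
        "symbol": [d.chosen_symbol or "" for d in decisions],
        "title": [
            f"{d.chosen_protein} e={d.evalue:g}" if d.status == "annotated" else d.status
            for d in decisions
        ],
    }
    annotation = ProbeAnnotation(
        table=pd.DataFrame(rows, index=pd.Index(ids, name="probe_id"))
    )
    n = len(decisions)
    k = annotation.n_annotated
    logger.info("annotated %d of %d elements (%.1f%%)", k, n, 100.0 * k / n if n else 0.0)
    if n and k == 0:
        warnings.warn("no array element received a symbol", stacklevel=2)
    return annotation


def duplicate_symbol_report(annotation: ProbeAnnotation) -> tuple[pd.DataFrame, int]:
    """Symbols mapped by two or more array elements.

    Returns a table of ``(symbol, probe_count)`` for shared symbols plus the
    total number of elements involved in any sharing — the statistic the
    duplicate structure of a platform is usually summarised by.  Duplicates
    arise either from one gene spotted on several elements or from lineage-
    specific gene duplication collapsing onto one human symbol; sequence data
    alone cannot distinguish the two, so both are kept for the probe-collapse
    step downstream.
    """
    counts = annotation.annotated["symbol"].value_counts()
    shared = counts[counts >= 2]
    report = pd.DataFrame(
        {"symbol": shared.index, "probe_count": shared.to_numpy()}
    ).reset_index(drop=True)
    total_elements = int(shared.sum())
    return report, total_elements


def curation_report(
    decisions: list[AnnotationDecision],
    orthology: list[OrthologyEvidence] | None = None,
) -> pd.DataFrame:
    """Tabulate every probe needing human attention.

    Rows: ambiguous ties, symbol conflicts, unmapped proteins, and (when
    orthology evidence is supplied) probes whose two homology routes disagree.
    """
    rows = []
    for d in decisions:
        if d.status in ("ambiguous_tie", "symbol_conflict", "unmapped"):
            rows.append(
                {"probe_id": d.query_id, "issue": d.status, "detail": d.detail}
            )
    for ev in orthology or []:
        if ev.agrees is False:
            rows.append(
                {
                    "probe_id": ev.query_id,
                    "issue": "orthology_disagreement",
                    "detail": f"human={ev.human_symbol} ortholog={ev.zebrafish_mapped_symbol}",
                }
            )
    return pd.DataFrame(rows, columns=["probe_id", "issue", "detail"])
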