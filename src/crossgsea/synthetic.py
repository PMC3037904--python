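"""Seed-deterministic synthetic fixtures with machine-readable answer keys.

Every stage of the pipeline can be exercised without any external download:

* two-class log-scale expression matrices with planted differentially
  expressed gene sets of controlled effect size (emulating a 12-vs-12
  treated/control microarray design with log-normal noise);
* BLAST hit tables with controlled fractions of e-value/score ties and
  below-threshold queries, plus the symbol table resolving their proteins;
* paired symbol/alias tables with planted alias indirections and true
  conflicts, and an ortholog table with planted disagreements.

Each generator returns its ground truth ("answer key") alongside the data so
tests compare pipeline output against the key rather than re-deriving it.
The defaults are the study conditions the pipeline targets: 12 samples per
class, unit log2 noise, a 2,000-gene universe that keeps full-pipeline tests
in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import count

import numpy as np
import pandas as pd

from .io_formats import (
    BlastHit,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    PhenotypeLabels,
    SymbolRecord,
    SymbolTable,
)

__all__ = [
    "PlantSpec",
    "gen_expression",
    "gen_gene_sets",
    "gen_blast_fixture",
    "gen_symbol_tables",
]


@dataclass
class PlantSpec:
    """A gene set to plant as differentially expressed.

    ``effect_size`` is the log-scale mean shift added to members in the
    positive (treatment) class; ``direction`` "up" adds it, "down" subtracts.
    """

    set_name: str
    member_symbols: list[str]
    effect_size: float
    direction: str = "up"

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")


def _symbols(n: int) -> list[str]:
    return [f"GENE{i:05d}" for i in range(n)]


def gen_expression(
    n_genes: int = 2000,
    n_per_class: int = 12,
    plants: list[PlantSpec] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    class_names: tuple[str, str] = ("treated", "control"),
    scale: str = "log",
) -> tuple[ExpressionMatrix, PhenotypeLabels, dict]:
    """Two-class expression with planted enriched sets.

    Background values are i.i.d. normal(0, ``noise_sd``) on the log scale per
    sample; each plant's members are shifted by ±``effect_size`` in the
    treatment class.  With ``scale="linear"`` the same matrix is exported as
    linear intensities (``100 * 2**x``) for exercising the normalization
    entry mode.  The truth dict records every planted membership, direction
    and effect size.
    """
    plants = plants or []
    symbols = _symbols(n_genes)
    universe = set(symbols)
    for p in plants:
        missing = set(p.member_symbols) - universe
        if missing:
            raise ValueError(
                f"plant {p.set_name!r} uses symbols outside the universe: "
                f"{sorted(missing)[:5]} (is the plant larger than n_genes?)"
            )
    rng = np.random.default_rng(seed)
    n_samples = 2 * n_per_class
    data = rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    sample_ids = [f"T{i + 1}" for i in range(n_per_class)] + [
        f"C{i + 1}" for i in range(n_per_class)
    ]
    index = {s: i for i, s in enumerate(symbols)}
    for p in plants:
        shift = p.effect_size if p.direction == "up" else -p.effect_size
        rows = [index[m] for m in p.member_symbols]
        data[np.ix_(rows, range(n_per_class))] += shift
    values = pd.DataFrame(data, index=pd.Index(symbols, name="NAME"), columns=sample_ids)
    if scale == "linear":
        values = 100.0 * np.power(2.0, values)
        matrix = ExpressionMatrix(values=values, scale="linear")
    elif scale == "log":
        matrix = ExpressionMatrix(values=values, scale="log")
    else:
        raise ValueError("scale must be 'log' or 'linear'")
    labels = PhenotypeLabels(
        sample_ids=sample_ids,
        class_names=class_names,
        assignment=[class_names[0]] * n_per_class + [class_names[1]] * n_per_class,
    )
    truth = {
        "seed": seed,
        "noise_sd": noise_sd,
        "plants": {
            p.set_name: {
                "members": sorted(p.member_symbols),
                "effect_size": p.effect_size,
                "direction": p.direction,
            }
            for p in plants
        },
    }
    return matrix, labels, truth


def gen_gene_sets(
    universe: list[str],
    n_sets: int,
    size_range: tuple[int, int] = (15, 60),
    seed: int = 0,
    prefix: str = "RANDOM_SET",
) -> GeneSetCollection:
    """Random (null) gene sets drawn without replacement from ``universe``."""
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    sets = []
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        sets.append(
            GeneSet(
                name=f"{prefix}_{i:04d}",
                description="synthetic null set",
                members=frozenset(members),
            )
        )
    return GeneSetCollection(sets)


def gen_blast_fixture(
    n_queries: int = 200,
    tie_fraction: float = 0.1,
    below_threshold_fraction: float = 0.1,
    seed: int = 0,
    duplicate_fraction: float = 0.1,
) -> tuple[dict[str, list[BlastHit]], SymbolTable, dict]:
    """Per-query BLAST hit lists with a known correct annotation.

    Query categories (answer key ``status``):

    * ``annotated`` — a unique best hit below the e-value threshold; within
      this category some queries get two equal-e-value hits resolved by
      bit-score, and some get an isoform tie (two accessions, equal e-value
      and score, sharing one symbol) that must collapse silently;
    * ``ambiguous_tie`` (``tie_fraction``) — two accessions tied on e-value
      and bit-score with *different* symbols: no assignment;
    * ``below_threshold`` (``below_threshold_fraction``) — every hit has
      e-value >= 1e-10.

    ``duplicate_fraction`` of annotated queries reuse an earlier query's
    symbol (a second probe for the same gene), planting the duplicate-symbol
    structure the reporting stage must recover.  The key maps each query to
    ``{"status": ..., "protein": ..., "symbol": ...}``.
    """
    if tie_fraction < 0 or below_threshold_fraction < 0:
        raise ValueError("fractions must be in [0, 1]")
    if tie_fraction + below_threshold_fraction > 1:
        raise ValueError("tie_fraction + below_threshold_fraction must be <= 1")
    rng = np.random.default_rng(seed)
    groups: dict[str, list[BlastHit]] = {}
    key: dict[str, dict] = {}
    records: list[SymbolRecord] = []
    next_acc = count(1)

    def new_protein(symbol: str) -> str:
        acc = f"NP_{next(next_acc):06d}"
        records.append(SymbolRecord(approved_symbol=symbol, protein_ids=frozenset({acc})))
        return acc

    def extra_isoform(symbol: str) -> str:
        acc = f"NP_{next(next_acc):06d}"
        # attach a second accession to the existing record for this symbol
        for r in records:
            if r.approved_symbol == symbol:
                r.protein_ids = frozenset(r.protein_ids | {acc})
                return acc
        raise KeyError(symbol)

    n_tie = int(round(tie_fraction * n_queries))
    n_below = int(round(below_threshold_fraction * n_queries))
    statuses = (
        ["ambiguous_tie"] * n_tie
        + ["below_threshold"] * n_below
        + ["annotated"] * (n_queries - n_tie - n_below)
    )
    rng.shuffle(statuses)
    annotated_symbols: list[str] = []
    sym_counter = count()

    def fresh_symbol() -> str:
        return f"SYM{next(sym_counter):05d}"

    for qi, status in enumerate(statuses):
        q = f"EST{qi:05d}"
        hits: list[BlastHit] = []

        def decoys(k: int) -> None:
            for _ in range(k):
                sym = fresh_symbol()
                hits.append(
                    BlastHit(q, new_protein(sym), 10.0 ** -rng.uniform(2, 9), float(rng.uniform(40, 80)))
                )

        if status == "below_threshold":
            decoys(int(rng.integers(1, 4)))
            key[q] = {"status": "below_threshold", "protein": None, "symbol": None}
        elif status == "ambiguous_tie":
            e = 0.0 if rng.random() < 0.5 else 10.0 ** -float(rng.integers(30, 150))
            score = float(rng.integers(300, 900))
            for _ in range(2):
                hits.append(BlastHit(q, new_protein(fresh_symbol()), e, score))
            decoys(int(rng.integers(0, 3)))
            key[q] = {"status": "ambiguous_tie", "protein": None, "symbol": None}
        else:
            if annotated_symbols and rng.random() < duplicate_fraction:
                symbol = str(rng.choice(annotated_symbols))
                best = extra_isoform(symbol)
            else:
                symbol = fresh_symbol()
                best = new_protein(symbol)
            flavour = rng.random()
            if flavour < 0.2:
                # e-value tie resolved by bit-score
                e = 0.0
                hits.append(BlastHit(q, best, e, 700.0))
                hits.append(BlastHit(q, new_protein(fresh_symbol()), e, 550.0))
            elif flavour < 0.3:
                # isoform tie: equal e-value and score, same symbol
                e = 10.0 ** -float(rng.integers(50, 150))
                score = float(rng.integers(300, 900))
                iso = extra_isoform(symbol)
                hits.append(BlastHit(q, best, e, score))
                hits.append(BlastHit(q, iso, e, score))
                best = min(best, iso)  # tie collapse picks the lexicographic first
            else:
                e = 10.0 ** -float(rng.integers(11, 180))
                hits.append(BlastHit(q, best, e, float(rng.integers(200, 900))))
            decoys(int(rng.integers(0, 3)))
            annotated_symbols.append(symbol)
            key[q] = {"status": "annotated", "protein": best, "symbol": symbol}
        rng.shuffle(hits)
        groups[q] = hits
    return groups, SymbolTable(records), key


def gen_symbol_tables(
    n_symbols: int = 100,
    alias_rate: float = 0.2,
    conflict_rate: float = 0.05,
    seed: int = 0,
    ortholog_disagree_rate: float = 0.1,
) -> tuple[SymbolTable, SymbolTable, dict[str, str], dict]:
    """Two symbol sources, an ortholog table, and their answer key.

    Source A is authoritative: every approved symbol with its aliases and
    accessions.  Source B agrees for most proteins, reports the *alias* as
    its approved symbol for an ``alias_rate`` fraction (reconciliation must
    recover the approved symbol), and reports an unrelated symbol for a
    ``conflict_rate`` fraction (reconciliation must flag, never guess).  The
    ortholog table maps a zebrafish accession per symbol to the human symbol
    — directly, via an alias (still agreement), or to a wrong symbol for an
    ``ortholog_disagree_rate`` fraction (planted disagreements).

    Key: ``key["protein"][accession] = approved symbol | "conflict"``;
    ``key["ortholog"][symbol] = (zebrafish accession, expected_agrees)``.
    """
    for r in (alias_rate, conflict_rate, ortholog_disagree_rate):
        if not 0 <= r <= 1:
            raise ValueError("rates must be in [0, 1]")
    if alias_rate + conflict_rate > 1:
        raise ValueError("alias_rate + conflict_rate must be <= 1")
    rng = np.random.default_rng(seed)
    a_records: list[SymbolRecord] = []
    b_records: list[SymbolRecord] = []
    ortholog: dict[str, str] = {}
    key: dict = {"protein": {}, "ortholog": {}}
    n_alias = int(round(alias_rate * n_symbols))
    n_conflict = int(round(conflict_rate * n_symbols))
    kinds = (
        ["alias"] * n_alias
        + ["conflict"] * n_conflict
        + ["agree"] * (n_symbols - n_alias - n_conflict)
    )
    rng.shuffle(kinds)
    for i, kind in enumerate(kinds):
        sym = f"SYM{i:04d}"
        alias = f"{sym}_ALT"
        prot = f"NP_{i:06d}"
        mrna = f"NM_{i:06d}"
        a_records.append(
            SymbolRecord(
                approved_symbol=sym,
                aliases=frozenset({alias}),
                protein_ids=frozenset({prot}),
                mrna_ids=frozenset({mrna}),
            )
        )
        if kind == "agree":
            b_records.append(
                SymbolRecord(approved_symbol=sym, protein_ids=frozenset({prot}))
            )
            key["protein"][prot] = sym
        elif kind == "alias":
            # B thinks the alias is the primary symbol
            b_records.append(
                SymbolRecord(approved_symbol=alias, protein_ids=frozenset({prot}))
            )
            key["protein"][prot] = sym
        else:  # true conflict: B reports an unrelated name
            b_records.append(
                SymbolRecord(
                    approved_symbol=f"WRONG{i:04d}", protein_ids=frozenset({prot})
                )
            )
            key["protein"][prot] = "conflict"
        zf = f"ZF_{i:06d}"
        u = rng.random()
        if u < ortholog_disagree_rate:
            ortholog[zf] = f"SYM{(i + 1) % n_symbols:04d}"  # a different gene
            key["ortholog"][sym] = (zf, False)
        elif u < ortholog_disagree_rate + 0.2:
            ortholog[zf] = alias  # agreement only after alias resolution
            key["ortholog"][sym] = (zf, True)
        else:
            ortholog[zf] = sym
            key["ortholog"][sym] = (zf, True)
    return SymbolTable(a_records), SymbolTable(b_records), ortholog, key
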