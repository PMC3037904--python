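"""Readers and writers for the GSEA file ecosystem and annotation inputs.

The formats handled here are the plain-text dialects consumed by the desktop
GSEA tool — GCT (#1.2 expression matrices), categorical CLS phenotype files,
GMX/GMT gene-set collections, and three-column CHIP platform annotations —
plus the tabular inputs needed to *build* a CHIP file for a non-human array:
BLAST tabular hit files, an approved-symbol/alias table, and a two-column
ortholog table.

All readers are strict: declared dimensions must match content, numeric cells
must parse, and missing expression values are rejected (upstream thresholding
is expected to have removed them).  Writers round-trip bit-exactly with the
readers up to numeric formatting.

Gene symbols are uppercased everywhere on ingest.  HGNC approved symbols are
uppercase, and case-normalising at the boundary prevents silent set-membership
mismatches deeper in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "PhenotypeLabels",
    "BlastHit",
    "SymbolRecord",
    "SymbolTable",
    "GeneSet",
    "GeneSetCollection",
    "ProbeAnnotation",
    "read_gct",
    "write_gct",
    "read_cls",
    "write_cls",
    "read_gene_sets",
    "write_gene_sets",
    "read_chip",
    "write_chip",
    "read_blast_table",
    "read_symbol_table",
    "write_symbol_table",
    "read_ortholog_table",
    "write_ortholog_table",
]


class FormatError(ValueError):
    """A file violated its format contract (bad dimensions, cells, headers)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A probes-x-samples expression table.

    ``values`` is a :class:`pandas.DataFrame` indexed by probe (or symbol,
    after collapse) with one column per sample.  ``scale`` records whether the
    numbers are linear intensities (as deposited) or log-scale (after
    preprocessing); operations that only make sense on one scale check it.
    """

    values: pd.DataFrame
    descriptions: pd.Series | None = None
    scale: str = "linear"  # "linear" | "log"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe identifiers: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dups[:5]}")
        if self.scale not in ("linear", "log"):
            raise ValueError(f"scale must be 'linear' or 'log', got {self.scale!r}")
        if self.descriptions is None:
            self.descriptions = pd.Series("", index=self.values.index, dtype=object)
        else:
            self.descriptions = self.descriptions.reindex(self.values.index).fillna("")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class PhenotypeLabels:
    """A two-class categorical phenotype assignment for an expression matrix.

    ``class_names`` preserves file order; by convention the first-listed class
    is the treatment/positive class, so a positive ranking metric means
    "up-regulated in treatment".
    """

    sample_ids: list[str]
    class_names: tuple[str, str]
    assignment: list[str]  # per-sample class name, aligned with sample_ids

    def __post_init__(self) -> None:
        if len(self.class_names) != 2:
            raise FormatError(
                f"exactly two phenotype classes are supported, got {len(self.class_names)}"
            )
        if len(self.assignment) != len(self.sample_ids):
            raise FormatError("assignment length does not match sample count")
        unknown = set(self.assignment) - set(self.class_names)
        if unknown:
            raise FormatError(f"labels not among declared classes: {sorted(unknown)}")
        for cls in self.class_names:
            if self.assignment.count(cls) < 2:
                raise FormatError(
                    f"class {cls!r} has fewer than 2 samples; "
                    "signal-to-noise needs a variance per class"
                )

    @property
    def positive_class(self) -> str:
        return self.class_names[0]

    @property
    def negative_class(self) -> str:
        return self.class_names[1]

    def class_indices(self, cls: str) -> np.ndarray:
        """Positions of samples assigned to ``cls``."""
        return np.array([i for i, a in enumerate(self.assignment) if a == cls])

    def swapped(self) -> "PhenotypeLabels":
        """The same assignment with the two class names in reversed roles."""
        return PhenotypeLabels(
            sample_ids=list(self.sample_ids),
            class_names=(self.class_names[1], self.class_names[0]),
            assignment=list(self.assignment),
        )


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_id: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"e-value must be non-negative, got {self.evalue}")
        if self.bitscore <= 0:
            raise ValueError(f"bit-score must be positive, got {self.bitscore}")


@dataclass
class SymbolRecord:
    """One approved human gene symbol with its aliases and linked accessions."""

    approved_symbol: str
    aliases: frozenset[str] = frozenset()
    protein_ids: frozenset[str] = frozenset()
    mrna_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.approved_symbol = self.approved_symbol.upper()
        self.aliases = frozenset(a.upper() for a in self.aliases) - {self.approved_symbol}
        self.protein_ids = frozenset(self.protein_ids)
        self.mrna_ids = frozenset(self.mrna_ids)


class SymbolTable:
    """A collection of :class:`SymbolRecord` with lookup indexes.

    Provides the three lookups annotation needs: protein accession -> record,
    mRNA accession -> record, and alias -> approved symbol.
    """

    def __init__(self, records: list[SymbolRecord]):
        self.records = list(records)
        seen: set[str] = set()
        for r in self.records:
            if r.approved_symbol in seen:
                raise FormatError(f"duplicate approved symbol {r.approved_symbol!r}")
            seen.add(r.approved_symbol)
        self._by_protein: dict[str, SymbolRecord] = {}
        self._by_mrna: dict[str, SymbolRecord] = {}
        self._alias_to_approved: dict[str, str] = {}
        for r in self.records:
            for p in r.protein_ids:
                self._by_protein[p] = r
            for m in r.mrna_ids:
                self._by_mrna[m] = r
            for a in r.aliases:
                # first writer wins on alias collisions between records
                self._alias_to_approved.setdefault(a, r.approved_symbol)
        self._approved = seen

    def __len__(self) -> int:
        return len(self.records)

    def lookup_protein(self, protein_id: str) -> SymbolRecord | None:
        return self._by_protein.get(protein_id)

    def lookup_mrna(self, mrna_id: str) -> SymbolRecord | None:
        return self._by_mrna.get(mrna_id)

    def is_approved(self, symbol: str) -> bool:
        return symbol.upper() in self._approved

    def to_approved(self, symbol: str) -> str | None:
        """Map a symbol or alias to its approved symbol; None when unknown."""
        s = symbol.upper()
        if s in self._approved:
            return s
        return self._alias_to_approved.get(s)


@dataclass
class GeneSet:
    """A named set of human gene symbols; members are uppercased and unique."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        self.members = frozenset(m.upper() for m in self.members if m)
        if not self.members:
            raise FormatError(f"gene set {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


class GeneSetCollection:
    """An ordered collection of uniquely named gene sets."""

    def __init__(self, sets: list[GeneSet]):
        names = [s.name for s in sets]
        dups = sorted({n for n in names if names.count(n) > 1})
        if dups:
            raise FormatError(f"duplicate gene set names: {dups}")
        self.sets = list(sets)
        self._by_name = {s.name: s for s in self.sets}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return [(s.name, s.members) for s in self.sets] == [
            (s.name, s.members) for s in other.sets
        ]


@dataclass
class ProbeAnnotation:
    """Mapping from array element to approved human gene symbol.

    Probes with an empty symbol are retained and flagged unannotated — the
    GSEA convention is that such elements are simply ignored downstream, but
    they must stay in the file so the platform stays complete.
    """

    table: pd.DataFrame  # index probe_id; columns: symbol, title

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe identifiers in annotation: {dups[:5]}")
        for col in ("symbol", "title"):
            if col not in self.table.columns:
                raise FormatError(f"annotation table missing column {col!r}")
        self.table = self.table.copy()
        self.table["symbol"] = self.table["symbol"].fillna("").astype(str).str.upper()
        self.table["title"] = self.table["title"].fillna("").astype(str)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def annotated(self) -> pd.DataFrame:
        return self.table[self.table["symbol"] != ""]

    @property
    def unannotated_probes(self) -> list[str]:
        return list(self.table.index[self.table["symbol"] == ""])

    @property
    def n_annotated(self) -> int:
        return int((self.table["symbol"] != "").sum())

    @property
    def annotated_fraction(self) -> float:
        return self.n_annotated / len(self.table) if len(self.table) else 0.0

    def symbol_of(self, probe_id: str) -> str:
        return str(self.table.at[probe_id, "symbol"])

    @property
    def symbols(self) -> set[str]:
        """The unique approved symbols represented on the platform."""
        return set(self.annotated["symbol"])


# ---------------------------------------------------------------------------
# GCT
# ---------------------------------------------------------------------------

_GCT_VERSION = "#1.2"


def read_gct(path) -> ExpressionMatrix:
    """Read a GCT #1.2 expression matrix.

    Layout: a version line, a ``<n_probes>\\t<n_samples>`` dimensions line,
    a header row (probe-name column, description column, one column per
    sample), then one data row per probe.  Any mismatch between the declared
    dimensions and the body, and any non-numeric or missing cell, raises
    :class:`FormatError` naming the offending line.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != _GCT_VERSION:
        raise FormatError(
            f"line 1: expected GCT version line {_GCT_VERSION!r}, "
            f"got {lines[0]!r}" if lines else "empty file"
        )
    try:
        n_probes_s, n_samples_s = lines[1].split("\t")[:2]
        n_probes, n_samples = int(n_probes_s), int(n_samples_s)
    except (IndexError, ValueError) as exc:
        raise FormatError(f"line 2: bad dimensions line {lines[1]!r}") from exc
    header = lines[2].split("\t")
    if len(header) < 2:
        raise FormatError("line 3: header must have probe-name and description columns")
    sample_ids = header[2:]
    if len(sample_ids) != n_samples:
        raise FormatError(
            f"line 3: header names {len(sample_ids)} samples but "
            f"dimensions line declares {n_samples}"
        )
    body = [ln for ln in lines[3:] if ln.strip() != ""]
    if len(body) != n_probes:
        raise FormatError(
            f"line 2: dimensions line declares {n_probes} probes but body has {len(body)} rows"
        )
    probe_ids: list[str] = []
    descriptions: list[str] = []
    data = np.empty((n_probes, n_samples), dtype=float)
    for i, ln in enumerate(body):
        cells = ln.split("\t")
        if len(cells) != n_samples + 2:
            raise FormatError(
                f"line {i + 4}: expected {n_samples + 2} columns, got {len(cells)}"
            )
        probe_ids.append(cells[0])
        descriptions.append(cells[1])
        for j, cell in enumerate(cells[2:]):
            if cell.strip() == "" or cell.strip().lower() in ("na", "nan", "null"):
                raise FormatError(
                    f"line {i + 4}, column {j + 3}: missing expression value "
                    "(thresholding upstream must remove missing values)"
                )
            try:
                data[i, j] = float(cell)
            except ValueError as exc:
                raise FormatError(
                    f"line {i + 4}, column {j + 3}: non-numeric cell {cell!r}"
                ) from exc
    values = pd.DataFrame(data, index=pd.Index(probe_ids, name="NAME"), columns=sample_ids)
    desc = pd.Series(descriptions, index=values.index, dtype=object)
    return ExpressionMatrix(values=values, descriptions=desc, scale="linear")


def _format_number(x: float) -> str:
    # shortest repr that round-trips through float()
    return repr(float(x))


def write_gct(matrix: ExpressionMatrix, path) -> None:
    """Write a GCT #1.2 file; ``read_gct`` recovers it value-for-value."""
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write(_GCT_VERSION + "\n")
        fh.write(f"{matrix.n_probes}\t{matrix.n_samples}\n")
        fh.write("NAME\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
        for probe, desc, row in zip(
            matrix.probe_ids, matrix.descriptions, matrix.values.to_numpy()
        ):
            fh.write(probe + "\t" + str(desc) + "\t")
            fh.write("\t".join(_format_number(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# CLS
# ---------------------------------------------------------------------------


def read_cls(path, sample_ids: list[str] | None = None) -> PhenotypeLabels:
    """Read a categorical CLS phenotype file.

    Line 1: ``<n_samples> <n_classes> 1``; line 2: ``#`` followed by the class
    names; line 3: one label per sample, either the class names themselves or
    integers which map to class names in order of first appearance (the
    reference tool's convention).  Only two-class designs are supported.

    ``sample_ids`` attaches sample identifiers from a companion expression
    matrix; otherwise positional identifiers ``S1..Sn`` are used.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh.read().splitlines() if ln.strip() != ""]
    if len(lines) < 3:
        raise FormatError("CLS file must have counts, class-name and label lines")
    counts = lines[0].split()
    try:
        n_samples, n_classes = int(counts[0]), int(counts[1])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"line 1: bad counts line {lines[0]!r}") from exc
    if n_classes != 2:
        raise FormatError(
            f"two-phenotype designs only: file declares {n_classes} classes"
        )
    name_line = lines[1]
    if not name_line.startswith("#"):
        raise FormatError("line 2: class-name line must start with '#'")
    class_names = name_line[1:].split()
    if len(class_names) != 2:
        raise FormatError(
            f"line 2: expected 2 class names, got {len(class_names)}"
        )
    raw_labels = lines[2].split()
    if len(raw_labels) != n_samples:
        raise FormatError(
            f"line 3: {len(raw_labels)} labels but line 1 declares {n_samples} samples"
        )
    if all(lbl in class_names for lbl in raw_labels):
        assignment = list(raw_labels)
    else:
        # numeric (or otherwise symbolic) labels: order of first appearance
        order: list[str] = []
        for lbl in raw_labels:
            if lbl not in order:
                order.append(lbl)
        if len(order) != 2:
            raise FormatError(
                f"line 3: labels take {len(order)} distinct values, expected 2"
            )
        mapping = dict(zip(order, class_names))
        assignment = [mapping[lbl] for lbl in raw_labels]
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n_samples)]
    elif len(sample_ids) != n_samples:
        raise FormatError(
            f"CLS declares {n_samples} samples but {len(sample_ids)} sample ids supplied"
        )
    return PhenotypeLabels(
        sample_ids=list(sample_ids),
        class_names=(class_names[0], class_names[1]),
        assignment=assignment,
    )


def write_cls(labels: PhenotypeLabels, path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{len(labels.sample_ids)} 2 1\n")
        fh.write("# " + " ".join(labels.class_names) + "\n")
        fh.write(" ".join(labels.assignment) + "\n")


# ---------------------------------------------------------------------------
# GMX / GMT
# ---------------------------------------------------------------------------


def read_gene_sets(path, dialect: str | None = None) -> GeneSetCollection:
    """Read a gene-set collection in GMX (one set per column) or GMT (one set
    per row) dialect.  ``dialect`` defaults to the file extension."""
    if dialect is None:
        dialect = str(path).rsplit(".", 1)[-1].lower()
    dialect = dialect.lower()
    if dialect not in ("gmx", "gmt"):
        raise ValueError(f"dialect must be 'gmx' or 'gmt', got {dialect!r}")
    with open(path, "rt", encoding="utf-8") as fh:
        rows = [ln.rstrip("\n").split("\t") for ln in fh.read().splitlines()]
    rows = [r for r in rows if any(c.strip() for c in r)]
    if dialect == "gmt":
        sets = []
        for r in rows:
            if len(r) < 3:
                raise FormatError(
                    f"GMT row for {r[0]!r} needs name, description and >=1 member"
                )
            members = [c.strip() for c in r[2:] if c.strip()]
            sets.append(GeneSet(name=r[0], description=r[1], members=frozenset(members)))
        return GeneSetCollection(sets)
    # GMX: transpose — row 1 names, row 2 descriptions, remaining rows members
    if len(rows) < 3:
        raise FormatError("GMX file needs a name row, a description row and member rows")
    width = max(len(r) for r in rows)
    grid = [r + [""] * (width - len(r)) for r in rows]
    names = grid[0]
    descriptions = grid[1]
    sets = []
    for col in range(width):
        name = names[col].strip()
        if not name:
            continue
        members = [grid[r][col].strip() for r in range(2, len(grid))]
        members = [m for m in members if m]
        sets.append(
            GeneSet(name=name, description=descriptions[col].strip(), members=frozenset(members))
        )
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path, dialect: str | None = None) -> None:
    """Write a collection in GMX or GMT dialect (default: file extension).

    Members are written in sorted order so output is deterministic.
    """
    if dialect is None:
        dialect = str(path).rsplit(".", 1)[-1].lower()
    dialect = dialect.lower()
    if dialect == "gmt":
        with open(path, "wt", encoding="utf-8", newline="\n") as fh:
            for s in collection:
                fh.write("\t".join([s.name, s.description] + sorted(s.members)) + "\n")
        return
    if dialect != "gmx":
        raise ValueError(f"dialect must be 'gmx' or 'gmt', got {dialect!r}")
    cols = [[s.name, s.description] + sorted(s.members) for s in collection.sets]
    depth = max((len(c) for c in cols), default=0)
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for r in range(depth):
            fh.write("\t".join(c[r] if r < len(c) else "" for c in cols) + "\n")


# ---------------------------------------------------------------------------
# CHIP
# ---------------------------------------------------------------------------

_CHIP_HEADER = ["Probe Set ID", "Gene Symbol", "Gene Title"]


def read_chip(path) -> ProbeAnnotation:
    """Read a three-column tab-delimited CHIP platform annotation."""
    with open(path, "rt", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError("empty CHIP file")
    header = lines[0].split("\t")
    if [h.strip() for h in header[:3]] != _CHIP_HEADER:
        raise FormatError(
            f"CHIP header must be {_CHIP_HEADER}, got {header[:3]}"
        )
    probes, symbols, titles = [], [], []
    for i, ln in enumerate(lines[1:]):
        if ln.strip() == "":
            continue
        cells = ln.split("\t")
        cells += [""] * (3 - len(cells))
        probes.append(cells[0])
        symbols.append(cells[1])
        titles.append(cells[2])
    table = pd.DataFrame(
        {"symbol": symbols, "title": titles}, index=pd.Index(probes, name="probe_id")
    )
    return ProbeAnnotation(table=table)


def write_chip(annotation: ProbeAnnotation, path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_CHIP_HEADER) + "\n")
        for probe, row in annotation.table.iterrows():
            fh.write(f"{probe}\t{row['symbol']}\t{row['title']}\n")


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------


def read_blast_table(path) -> dict[str, list[BlastHit]]:
    """Read a BLAST tabular hit file, grouped per query in file order.

    Accepts either the 12-column ``-outfmt 6`` layout (query, subject, then
    ten more fields with e-value in column 11 and bit-score in column 12) or a
    minimal 4-column ``query<TAB>subject<TAB>evalue<TAB>bitscore`` layout.
    Every hit in the file is kept — the reader never truncates per-query hit
    lists; any cap (e.g. "10 best hits") is whatever the upstream BLAST run
    chose to report.  An empty file yields an empty mapping.
    """
    groups: dict[str, list[BlastHit]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if ln.strip() == "" or ln.startswith("#"):
                continue
            cells = ln.split("\t")
            if len(cells) >= 12:
                q, s, ev, bs = cells[0], cells[1], cells[10], cells[11]
            elif len(cells) == 4:
                q, s, ev, bs = cells
            else:
                raise FormatError(
                    f"line {lineno}: expected 4 or >=12 tab-delimited fields, got {len(cells)}"
                )
            try:
                evalue = float(ev)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: unparseable e-value {ev!r}") from exc
            try:
                bitscore = float(bs)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: unparseable bit-score {bs!r}") from exc
            groups.setdefault(q, []).append(
                BlastHit(query_id=q, subject_id=s, evalue=evalue, bitscore=bitscore)
            )
    return groups


# ---------------------------------------------------------------------------
# symbol / alias table and ortholog table
# ---------------------------------------------------------------------------


def _split_pipe(cell: str) -> frozenset[str]:
    return frozenset(x.strip() for x in cell.split("|") if x.strip())


def read_symbol_table(path) -> SymbolTable:
    """Read an approved-symbol table.

    Tab-delimited with a header; columns: approved symbol, pipe-separated
    aliases, pipe-separated RefSeq protein accessions, pipe-separated RefSeq
    mRNA accessions (the last two may be empty).
    """
    records = []
    with open(path, "rt", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError("empty symbol table")
    for lineno, ln in enumerate(lines[1:], start=2):
        if ln.strip() == "":
            continue
        cells = ln.split("\t")
        cells += [""] * (4 - len(cells))
        if not cells[0].strip():
            raise FormatError(f"line {lineno}: empty approved symbol")
        records.append(
            SymbolRecord(
                approved_symbol=cells[0].strip(),
                aliases=_split_pipe(cells[1]),
                protein_ids=_split_pipe(cells[2]),
                mrna_ids=_split_pipe(cells[3]),
            )
        )
    return SymbolTable(records)


def write_symbol_table(table: SymbolTable, path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("approved_symbol\taliases\tprotein_ids\tmrna_ids\n")
        for r in table.records:
            fh.write(
                "\t".join(
                    [
                        r.approved_symbol,
                        "|".join(sorted(r.aliases)),
                        "|".join(sorted(r.protein_ids)),
                        "|".join(sorted(r.mrna_ids)),
                    ]
                )
                + "\n"
            )


def read_ortholog_table(path) -> dict[str, str]:
    """Read a two-column ortholog table: model-organism protein accession to
    human gene symbol (symbols uppercased)."""
    mapping: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, ln in enumerate(fh, start=1):
            if ln.strip() == "" or ln.startswith("#"):
                continue
            cells = ln.rstrip("\n").split("\t")
            if len(cells) < 2:
                raise FormatError(f"line {lineno}: expected 2 tab-delimited columns")
            mapping[cells[0].strip()] = cells[1].strip().upper()
    return mapping


def write_ortholog_table(mapping: dict[str, str], path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for k in mapping:
            fh.write(f"{k}\t{mapping[k]}\n")
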