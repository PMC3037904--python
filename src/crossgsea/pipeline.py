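"""End-to-end orchestration from a single declarative YAML config.

A run takes one or more phenotype comparisons (GCT + CLS pairs), a platform
annotation (a ready CHIP file, or the BLAST/symbol inputs to build one), and
one or more gene-set collections, and produces one results table per
(collection x comparison) plus a manifest recording input checksums,
parameters, the seed and the package version.  Re-running from the same
manifest reproduces the tables byte-for-byte.

Config schema (YAML, all paths relative to the config file)::

    comparisons:
      acute: {gct: acute.gct, cls: acute.cls, normalized: false}
    chip: platform.chip            # or: blast/symbols/... to build one
    collections:
      go_sets: {path: sets.gmx, comparisons: [acute]}
    symbols: hgnc.tsv              # optional, enables alias repair in sets
    params: {nperm: 1000, min_size: 10, max_size: 500, weight: 1, seed: 17,
             floor: 0.01, min_mapped: 10}
    out: run_dir

All thresholds default to the pipeline's standard values (floor 0.01,
e-value < 1e-10, set-size window 10..500, 1000 permutations, weight 1).
Missing inputs are all reported before any computation starts, and output
files are written atomically (temp file + rename) so a failed run leaves no
truncated tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from pathlib import Path

import yaml

from . import __version__
from .annotation import annotate_platform, build_chip
from .curation import prune_by_platform, resolve_aliases_in_sets
from .gsea import ESParams, results_table, run_gsea
from .io_formats import (
    read_blast_table,
    read_chip,
    read_cls,
    read_gct,
    read_gene_sets,
    read_symbol_table,
    write_chip,
)
from .preprocess import NormalizationConfig, collapse_probes, normalize

logger = logging.getLogger(__name__)

__all__ = ["load_config", "run_pipeline"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text, encoding="utf-8")
    os.replace(tmp, path)


def load_config(path) -> dict:
    """Load a YAML run config and resolve its paths against the config dir."""
    path = Path(path)
    cfg = yaml.safe_load(path.read_text(encoding="utf-8"))
    base = path.parent
    for comp in cfg.get("comparisons", {}).values():
        for k in ("gct", "cls"):
            if k in comp:
                comp[k] = str(base / comp[k])
    for coll in cfg.get("collections", {}).values():
        if "path" in coll:
            coll["path"] = str(base / coll["path"])
    for k in ("chip", "symbols", "blast"):
        if k in cfg:
            cfg[k] = str(base / cfg[k])
    if "out" in cfg:
        cfg["out"] = str(base / cfg["out"])
    return cfg


def _check_inputs(cfg: dict) -> list[str]:
    missing = []
    for name, comp in cfg.get("comparisons", {}).items():
        for k in ("gct", "cls"):
            if k not in comp:
                missing.append(f"comparison {name}: no {k} entry")
            elif not Path(comp[k]).is_file():
                missing.append(comp[k])
    for name, coll in cfg.get("collections", {}).items():
        if "path" not in coll:
            missing.append(f"collection {name}: no path entry")
        elif not Path(coll["path"]).is_file():
            missing.append(coll["path"])
    for k in ("chip", "symbols", "blast"):
        if k in cfg and not Path(cfg[k]).is_file():
            missing.append(cfg[k])
    return missing


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> Path:
    """Execute annotate -> curate -> normalize -> enrich for every
    (collection x comparison) pair named in the config.

    Returns the run directory, which contains one ``<collection>__
    <comparison>.tsv`` results table per pair, ``run.log``, and
    ``manifest.json``.  Raises before any computation if inputs are missing.
    """
    if not isinstance(config, dict):
        cfg = load_config(config)
    else:
        cfg = config
    missing = _check_inputs(cfg)
    if missing:
        raise FileNotFoundError("missing inputs: " + "; ".join(missing))
    out = Path(out_dir if out_dir is not None else cfg.get("out", "gsea_run"))
    out.mkdir(parents=True, exist_ok=True)

    p = cfg.get("params", {})
    params = ESParams(
        weight_p=float(p.get("weight", 1.0)),
        min_size=int(p.get("min_size", 10)),
        max_size=int(p.get("max_size", 500)),
        n_perm=int(p.get("nperm", 1000)),
        seed=int(p.get("seed", 0)),
    )
    norm_cfg = NormalizationConfig(floor=float(p.get("floor", 0.01)))
    min_mapped = int(p.get("min_mapped", 10))

    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    # --- platform annotation -------------------------------------------------
    symbol_table = read_symbol_table(cfg["symbols"]) if "symbols" in cfg else None
    if "chip" in cfg:
        annotation = read_chip(cfg["chip"])
        log(f"platform: {cfg['chip']} ({annotation.n_annotated}/"
            f"{len(annotation.table)} probes annotated)")
    elif "blast" in cfg:
        if symbol_table is None:
            raise ValueError("building a CHIP from BLAST hits requires 'symbols'")
        groups = read_blast_table(cfg["blast"])
        decisions = annotate_platform(groups, [symbol_table])
        annotation = build_chip(decisions)
        write_chip(annotation, out / "platform.chip")
        log(f"platform built from {cfg['blast']}: {annotation.n_annotated}/"
            f"{len(annotation.table)} probes annotated")
    else:
        raise ValueError("config needs either 'chip' or 'blast' (+'symbols')")

    # --- comparisons ---------------------------------------------------------
    prepared = {}
    for name, comp in cfg.get("comparisons", {}).items():
        matrix = read_gct(comp["gct"])
        labels = read_cls(comp["cls"], sample_ids=matrix.sample_ids)
        if comp.get("normalized", False):
            # deposited values already on the log/normalized scale
            matrix.scale = "log"
        else:
            matrix = normalize(matrix, norm_cfg)
        collapsed = collapse_probes(matrix, annotation)
        prepared[name] = (collapsed, labels)
        log(f"comparison {name}: {matrix.n_probes} probes -> "
            f"{collapsed.n_probes} symbols, {len(labels.sample_ids)} samples")

    # --- collections and enrichment ------------------------------------------
    tables = []
    for cname, coll_cfg in cfg.get("collections", {}).items():
        collection = read_gene_sets(coll_cfg["path"], coll_cfg.get("dialect"))
        if symbol_table is not None:
            collection, rep = resolve_aliases_in_sets(collection, symbol_table)
            log(f"collection {cname}: {rep['replaced']} aliases replaced, "
                f"{rep['unknown']} unknown members kept")
        collection, removed = prune_by_platform(collection, annotation, min_mapped)
        if removed:
            log(f"collection {cname}: pruned {len(removed)} sets below "
                f"{min_mapped} mapped genes: {', '.join(removed)}")
        for comp_name in coll_cfg.get("comparisons", list(prepared)):
            matrix, labels = prepared[comp_name]
            results = run_gsea(matrix, labels, collection, params)
            table = results_table(results)
            fname = f"{cname}__{comp_name}.tsv"
            _atomic_write_text(out / fname, table.to_csv(sep="\t", index=False))
            tables.append(fname)
            n_sig = int((table["p_nominal"] < 0.05).sum())
            log(f"{fname}: {len(table)} sets tested, {n_sig} at nominal p < 0.05")

    # --- manifest ------------------------------------------------------------
    input_paths = []
    for comp in cfg.get("comparisons", {}).values():
        input_paths += [comp["gct"], comp["cls"]]
    input_paths += [coll["path"] for coll in cfg.get("collections", {}).values()]
    input_paths += [cfg[k] for k in ("chip", "symbols", "blast") if k in cfg]
    manifest = {
        "version": __version__,
        "params": {
            "weight_p": params.weight_p,
            "min_size": params.min_size,
            "max_size": params.max_size,
            "n_perm": params.n_perm,
            "seed": params.seed,
            "floor": norm_cfg.floor,
            "min_mapped": min_mapped,
        },
        "inputs": {p: _sha256(Path(p)) for p in input_paths},
        "tables": tables,
    }
    _atomic_write_text(out / "manifest.json", json.dumps(manifest, indent=2, sort_keys=True))
    _atomic_write_text(out / "run.log", "\n".join(log_lines) + "\n")
    return out
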