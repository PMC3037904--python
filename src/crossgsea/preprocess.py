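"""Expression preprocessing: thresholding, normalization, probe collapse.

The normalization emulates the GeneSpring-style recipe used for two-colour
ratio data: intensities are floored at 0.01 (so the subsequent log transform
cannot produce huge negative values or blow up on non-positive cells),
log-transformed, percentile-shifted per sample (each sample's 50th percentile
is subtracted, putting all chips on a common centre), re-baselined per probe
(each probe's median across samples is subtracted, so values are relative to
the probe's own typical level), and finally re-centred on the overall median
— a near no-op after the per-probe step, kept for fidelity to the recipe's
"baseline = median of all data" wording.

Probe collapse maps a probe-level matrix to one row per approved human gene
symbol.  Probes with no symbol are dropped (GSEA would ignore them anyway);
for a symbol represented by several probes the probe with the largest
across-sample mean contributes all of that symbol's values (the max-probe
rule, the reference tool's default).  Ties on the mean go to the probe that
appears first in the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, ProbeAnnotation

__all__ = ["NormalizationConfig", "floor_values", "normalize", "collapse_probes"]


@dataclass
class NormalizationConfig:
    """Parameters of the normalization recipe.

    floor: intensity floor applied before the log transform (default 0.01).
    log_base: base of the log transform; 2 is the microarray convention.
    percentile: per-sample shift percentile, 50 (the median) by default.
    spot_baseline: what "each spot was normalized to the median of all
        spots" is taken to mean — ``"probe"`` (default: subtract each probe's
        median across samples) or ``"sample"`` (subtract each sample's median
        across probes a second time, i.e. a per-chip reading).
    """

    floor: float = 0.01
    log_base: float = 2.0
    percentile: float = 50.0
    spot_baseline: str = "probe"

    def __post_init__(self) -> None:
        if self.floor <= 0:
            raise ValueError("floor must be positive")
        if self.log_base <= 0 or self.log_base == 1:
            raise ValueError("log_base must be positive and != 1")
        if not (0 < self.percentile < 100):
            raise ValueError("percentile must lie in (0, 100)")
        if self.spot_baseline not in ("probe", "sample"):
            raise ValueError("spot_baseline must be 'probe' or 'sample'")


def floor_values(matrix: ExpressionMatrix, floor: float = 0.01) -> ExpressionMatrix:
    """Thresholding substitution: values below ``floor`` are set to ``floor``.

    Operates on linear-scale intensities only — its purpose is to remove very
    small or negative values before the log transform.
    """
    if matrix.scale != "linear":
        raise ValueError("floor_values applies to linear-scale matrices")
    values = matrix.values.clip(lower=floor)
    return ExpressionMatrix(
        values=values, descriptions=matrix.descriptions.copy(), scale="linear"
    )


def normalize(
    matrix: ExpressionMatrix, config: NormalizationConfig | None = None
) -> ExpressionMatrix:
    """Apply the full normalization: floor -> log -> per-sample percentile
    shift -> spot baseline -> global median re-centring.

    Input must be linear-scale; output is flagged log-scale.  A non-positive
    value surviving to the log step (possible only if flooring was bypassed
    with ``floor <= 0``) raises.
    """
    if config is None:
        config = NormalizationConfig()
    if matrix.scale != "linear":
        raise ValueError("normalize expects a linear-scale matrix")
    floored = floor_values(matrix, config.floor)
    vals = floored.values.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValueError("non-positive value reached the log step; floor first")
    logged = np.log(vals) / np.log(config.log_base)
    # per-sample percentile shift: columns share a common centre
    shift = np.percentile(logged, config.percentile, axis=0, keepdims=True)
    logged = logged - shift
    # spot baseline
    if config.spot_baseline == "probe":
        logged = logged - np.median(logged, axis=1, keepdims=True)
    else:
        logged = logged - np.median(logged, axis=0, keepdims=True)
    # global re-centring on the overall median
    logged = logged - np.median(logged)
    out = pd.DataFrame(logged, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values=out, descriptions=matrix.descriptions.copy(), scale="log")


def collapse_probes(
    matrix: ExpressionMatrix, annotation: ProbeAnnotation, mode: str = "max"
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to one row per gene symbol.

    Unannotated probes (and probes absent from the annotation) are dropped.
    ``mode="max"``: each symbol takes the entire per-sample row of the probe
    whose across-sample mean is maximal.  The collapsed matrix keeps the
    input's scale flag and records the winning probe id in the descriptions.
    """
    if mode != "max":
        raise ValueError(f"unsupported collapse mode {mode!r}")
    sym = annotation.table["symbol"]
    common = matrix.values.index.intersection(sym[sym != ""].index)
    if len(common) == 0:
        raise ValueError("no annotated probe overlaps the expression matrix")
    sub = matrix.values.loc[common]
    symbols = sym.loc[common]
    means = sub.mean(axis=1)
    # stable: keep first-in-matrix probe on mean ties
    order = pd.DataFrame(
        {"symbol": symbols.to_numpy(), "mean": means.to_numpy(), "probe": common},
    )
    order["pos"] = np.arange(len(order))
    # sort: by symbol, then descending mean, then original position
    order = order.sort_values(["symbol", "mean", "pos"], ascending=[True, False, True])
    winners = order.drop_duplicates("symbol", keep="first")
    collapsed = sub.loc[winners["probe"]]
    collapsed.index = pd.Index(winners["symbol"].to_numpy(), name="NAME")
    desc = pd.Series(winners["probe"].to_numpy(), index=collapsed.index, dtype=object)
    return ExpressionMatrix(values=collapsed, descriptions=desc, scale=matrix.scale)
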