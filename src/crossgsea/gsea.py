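"""Weighted Kolmogorov–Smirnov gene set enrichment with phenotype permutation.

Given a symbol-level log-scale expression matrix with a two-class phenotype,
genes are ranked by the signal-to-noise ratio

    s2n = (mu_pos - mu_neg) / (sd_pos + sd_neg)

with each class standard deviation floored at ``0.2 * |mu|`` (0.2 when the
mean is zero) — the variance floor keeps low-expression genes from dominating
the ranking.  For a gene set S of size N_H inside a ranked list of N genes,
a running sum walks the list: a gene in S ("hit") adds ``|s2n|^p`` divided by
the summed ``|s2n|^p`` over S, a gene outside S ("miss") subtracts
``1/(N - N_H)``.  The enrichment score ES is the running sum's extremum of
maximal absolute value (signed); positive ES means the set is concentrated
among genes up-regulated in the positive (treatment) class.  ``p = 1``
(weighted) is the default; ``p = 0`` recovers the classical two-sample KS
deviation between hit and miss positions.

Significance is assessed by phenotype permutation: class labels are
reassigned at random (class sizes preserved), the list re-ranked, and ES
recomputed, giving a per-set null distribution.  The nominal p-value is the
same-sign tail fraction; the normalized score NES divides ES by the mean of
same-sign permuted ES; the FDR q-value compares each |NES| against the pooled
same-sign permuted NES and the observed same-sign NES, with a step-up pass
making q monotone non-increasing in |NES|.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneSet, GeneSetCollection, PhenotypeLabels

logger = logging.getLogger(__name__)

__all__ = [
    "RankedList",
    "ESParams",
    "EnrichmentResult",
    "signal_to_noise",
    "enrichment_score",
    "permutation_null",
    "nominal_p",
    "normalized_es",
    "fdr_q",
    "run_gsea",
    "results_table",
]


@dataclass
class RankedList:
    """Genes ordered (descending) by a differential-expression metric."""

    symbols: list[str]
    metric: np.ndarray
    class_order: tuple[str, str]  # (positive, negative)

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.symbols) != len(self.metric):
            raise ValueError("symbols and metric lengths differ")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("ranked symbols must be unique")
        if np.any(np.diff(self.metric) > 0):
            raise ValueError("metric must be non-increasing")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class ESParams:
    """Knobs of an enrichment run.

    weight_p: exponent on |s2n| in hit increments (1 = weighted, 0 = classic KS).
    min_size/max_size: post-intersection gene set size window (10..500).
    n_perm: number of phenotype permutations (1000).
    seed: mandatory seed for the permutation generator.
    """

    weight_p: float = 1.0
    min_size: int = 10
    max_size: int = 500
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weight_p < 0:
            raise ValueError("weight_p must be >= 0")
        if self.min_size > self.max_size:
            raise ValueError("min_size must be <= max_size")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class EnrichmentResult:
    set_name: str
    size: int  # post-intersection with the ranked list
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    direction: str  # "up" | "down"

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.es <= 1.0 + 1e-12:
            raise ValueError(f"{self.set_name}: ES {self.es} outside [-1, 1]")
        if self.es != 0 and not np.isnan(self.nes):
            if np.sign(self.nes) != np.sign(self.es):
                raise ValueError(f"{self.set_name}: NES sign differs from ES sign")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------


def _s2n_metric(values: np.ndarray, pos_idx: np.ndarray, neg_idx: np.ndarray) -> np.ndarray:
    """Vectorised signal-to-noise with the reference variance floor."""
    pos = values[:, pos_idx]
    neg = values[:, neg_idx]
    mu_p = pos.mean(axis=1)
    mu_n = neg.mean(axis=1)
    sd_p = pos.std(axis=1, ddof=1)
    sd_n = neg.std(axis=1, ddof=1)
    floor_p = np.where(mu_p != 0, 0.2 * np.abs(mu_p), 0.2)
    floor_n = np.where(mu_n != 0, 0.2 * np.abs(mu_n), 0.2)
    sd_p = np.maximum(sd_p, floor_p)
    sd_n = np.maximum(sd_n, floor_n)
    return (mu_p - mu_n) / (sd_p + sd_n)


def _rank_order(symbols: np.ndarray, metric: np.ndarray) -> np.ndarray:
    """Indices sorting by metric descending, ties lexicographic by symbol."""
    # lexsort: last key is primary
    return np.lexsort((symbols, -metric))


def signal_to_noise(matrix: ExpressionMatrix, labels: PhenotypeLabels) -> RankedList:
    """Rank genes by signal-to-noise ratio, positive class first in CLS order.

    Requires a log-scale matrix whose samples match the phenotype file and at
    least two samples per class (the per-class standard deviation needs a
    degree of freedom).  Ties in the metric are broken lexicographically by
    symbol so runs are reproducible.
    """
    if matrix.scale != "log":
        raise ValueError("signal_to_noise expects a log-scale (normalized) matrix")
    if list(matrix.sample_ids) != list(labels.sample_ids):
        raise ValueError("matrix samples and phenotype samples differ")
    pos_idx = labels.class_indices(labels.positive_class)
    neg_idx = labels.class_indices(labels.negative_class)
    if len(pos_idx) < 2 or len(neg_idx) < 2:
        raise ValueError("each phenotype class needs >= 2 samples")
    values = matrix.values.to_numpy(dtype=float)
    metric = _s2n_metric(values, pos_idx, neg_idx)
    symbols = np.asarray(matrix.probe_ids, dtype=object)
    order = _rank_order(symbols, metric)
    return RankedList(
        symbols=list(symbols[order]),
        metric=metric[order],
        class_order=(labels.positive_class, labels.negative_class),
    )


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------


def _es_from_order(
    metric_sorted: np.ndarray, hit_mask: np.ndarray, weight_p: float
) -> float:
    """ES for one set given the sorted metric and a boolean hit mask."""
    n = metric_sorted.shape[0]
    n_hit = int(hit_mask.sum())
    if n_hit == 0:
        raise ValueError("gene set has empty intersection with the ranked list")
    if n_hit == n:
        raise ValueError("gene set covers the whole ranked list; no misses to contrast")
    weights = np.where(hit_mask, np.abs(metric_sorted) ** weight_p, 0.0)
    total = weights.sum()
    if total == 0:
        # all hit metrics are exactly zero: fall back to unweighted hits
        weights = hit_mask.astype(float)
        total = weights.sum()
    steps = weights / total - (~hit_mask) / (n - n_hit)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet | frozenset | set, weight_p: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score of one gene set on a ranked list.

    Returns ``(es, running_sum)``; the running sum is the full deviation
    profile, useful for plotting or leading-edge inspection.  The set is
    intersected with the ranked symbols first; an empty intersection is an
    error (callers filter sets before scoring).
    """
    members = gene_set.members if isinstance(gene_set, GeneSet) else frozenset(gene_set)
    symbols = np.asarray(ranked.symbols, dtype=object)
    hit_mask = np.isin(symbols, list(members))
    n = len(symbols)
    n_hit = int(hit_mask.sum())
    if n_hit == 0:
        raise ValueError("gene set has empty intersection with the ranked list")
    if n_hit == n:
        raise ValueError("gene set covers the whole ranked list; no misses to contrast")
    weights = np.where(hit_mask, np.abs(ranked.metric) ** weight_p, 0.0)
    total = weights.sum()
    if total == 0:
        weights = hit_mask.astype(float)
        total = weights.sum()
    steps = weights / total - (~hit_mask) / (n - n_hit)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------


def permutation_null(
    matrix: ExpressionMatrix,
    labels: PhenotypeLabels,
    sets: dict[str, frozenset],
    params: ESParams,
) -> dict[str, np.ndarray]:
    """Per-set null ES distributions under phenotype permutation.

    Each permutation reassigns class labels uniformly at random (class sizes
    preserved), re-ranks every gene by signal-to-noise under the permuted
    labels, and recomputes the ES of every set against that ranking.  All
    sets share the same permutations, as in the reference tool, so the pooled
    FDR construction is consistent.  Fully reproducible from ``params.seed``.

    Permutations are sampled with replacement; when ``n_perm`` exceeds the
    number of distinct label assignments a warning is emitted (the null then
    necessarily repeats assignments).
    """
    rng = np.random.default_rng(params.seed)
    values = matrix.values.to_numpy(dtype=float)
    symbols = np.asarray(matrix.probe_ids, dtype=object)
    n_samples = values.shape[1]
    pos_size = len(labels.class_indices(labels.positive_class))
    n_distinct = comb(n_samples, pos_size)
    if params.n_perm > n_distinct:
        warnings.warn(
            f"n_perm={params.n_perm} exceeds the {n_distinct} distinct label "
            "assignments; sampling with replacement",
            stacklevel=2,
        )
    hit_lists = {name: np.isin(symbols, list(members)) for name, members in sets.items()}
    null: dict[str, list[float]] = {name: [] for name in sets}
    all_idx = np.arange(n_samples)
    for _ in range(params.n_perm):
        perm = rng.permutation(all_idx)
        pos_idx, neg_idx = perm[:pos_size], perm[pos_size:]
        metric = _s2n_metric(values, pos_idx, neg_idx)
        order = _rank_order(symbols, metric)
        metric_sorted = metric[order]
        for name, base_mask in hit_lists.items():
            null[name].append(
                _es_from_order(metric_sorted, base_mask[order], params.weight_p)
            )
    return {name: np.asarray(v) for name, v in null.items()}


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------


def nominal_p(es: float, null_es: np.ndarray) -> float:
    """One-sided permutation p-value against the same-sign null tail.

    The fraction of same-sign null scores at least as extreme (in absolute
    value) as the observed ES.  No pseudocount is added, so an observed score
    beyond every permuted score reports exactly 0.0.
    """
    null_es = np.asarray(null_es, dtype=float)
    if null_es.size == 0:
        raise ValueError("empty null distribution")
    if es >= 0:
        same = null_es[null_es >= 0]
    else:
        same = null_es[null_es < 0]
    if same.size == 0:
        return 0.0
    return float(np.mean(np.abs(same) >= abs(es)))


def normalized_es(es: float, null_es: np.ndarray) -> float:
    """ES divided by the magnitude of the same-sign null mean (sign kept).

    NaN (with a log record) when the null contains no same-sign scores —
    the set's NES is then undefined and it is excluded from FDR pooling.
    """
    null_es = np.asarray(null_es, dtype=float)
    same = null_es[null_es >= 0] if es >= 0 else null_es[null_es < 0]
    if same.size == 0 or same.mean() == 0:
        logger.warning("NES undefined: no same-sign permutation scores")
        return float("nan")
    return float(es / abs(same.mean()))


def _norm_null(null_es: np.ndarray) -> np.ndarray:
    """Normalize a null ES array the same way observed ES are normalized:
    positive scores by the positive-side mean, negative by the negative-side
    mean magnitude."""
    null_es = np.asarray(null_es, dtype=float)
    out = np.full_like(null_es, np.nan)
    pos = null_es >= 0
    if pos.any() and null_es[pos].mean() != 0:
        out[pos] = null_es[pos] / abs(null_es[pos].mean())
    neg = ~pos
    if neg.any() and null_es[neg].mean() != 0:
        out[neg] = null_es[neg] / abs(null_es[neg].mean())
    return out


def fdr_q(
    observed_nes: dict[str, float], permuted_nes: dict[str, np.ndarray]
) -> dict[str, float]:
    """Permutation FDR q-values from pooled normalized null scores.

    For a set with observed NES*, q is the ratio of (fraction of pooled
    same-sign permuted NES at least as extreme as |NES*|) to (fraction of
    observed same-sign NES at least as extreme), clamped to [0, 1].  A
    step-up pass then enforces monotonicity: within each sign, a set's q is
    the minimum raw q over sets with |NES| no larger than its own, so q never
    increases with |NES|.
    """
    pool = np.concatenate([v for v in permuted_nes.values()]) if permuted_nes else np.array([])
    pool = pool[~np.isnan(pool)]
    obs_items = [(k, v) for k, v in observed_nes.items() if not np.isnan(v)]
    obs_vals = np.array([v for _, v in obs_items])
    raw: dict[str, float] = {}
    for name, nes in obs_items:
        if nes >= 0:
            pool_same = pool[pool >= 0]
            obs_same = obs_vals[obs_vals >= 0]
            num = np.mean(pool_same >= nes) if pool_same.size else 0.0
            den = np.mean(obs_same >= nes) if obs_same.size else 0.0
        else:
            pool_same = pool[pool < 0]
            obs_same = obs_vals[obs_vals < 0]
            num = np.mean(pool_same <= nes) if pool_same.size else 0.0
            den = np.mean(obs_same <= nes) if obs_same.size else 0.0
        raw[name] = float(min(1.0, num / den)) if den > 0 else 0.0
    # step-up: q monotone non-increasing in |NES| within each sign
    out = dict(raw)
    for sign in (1, -1):
        names = [k for k, v in obs_items if (v >= 0) == (sign > 0)]
        names.sort(key=lambda k: abs(observed_nes[k]))  # weakest first
        running = np.inf
        for k in names:  # q_k = min(raw over |NES| <= |NES_k|), BH-style
            running = min(running, raw[k])
            out[k] = running
    for k, v in observed_nes.items():
        if np.isnan(v):
            out[k] = float("nan")
    return out


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def run_gsea(
    matrix: ExpressionMatrix,
    labels: PhenotypeLabels,
    collection: GeneSetCollection,
    params: ESParams | None = None,
) -> list[EnrichmentResult]:
    """Full enrichment analysis of a gene-set collection.

    The matrix must already be symbol-level (collapsed) and log-scale.  Sets
    are intersected with the ranked symbols; sets smaller than ``min_size``
    or larger than ``max_size`` after intersection are excluded (logged).
    Results carry post-filter sizes and are ordered up-regulated sets first
    by decreasing NES, then down-regulated by increasing NES.
    """
    if params is None:
        params = ESParams()
    ranked = signal_to_noise(matrix, labels)
    universe = set(ranked.symbols)
    retained: dict[str, frozenset] = {}
    for s in collection:
        inter = frozenset(s.members & universe)
        if len(inter) < params.min_size or len(inter) > params.max_size:
            logger.info(
                "excluding %s: %d genes on platform (window %d..%d)",
                s.name, len(inter), params.min_size, params.max_size,
            )
            continue
        retained[s.name] = inter
    if not retained:
        raise ValueError(
            f"no gene set has between {params.min_size} and {params.max_size} "
            "members on the platform after intersection"
        )
    observed_es = {
        name: enrichment_score(ranked, members, params.weight_p)[0]
        for name, members in retained.items()
    }
    null = permutation_null(matrix, labels, retained, params)
    observed_nes = {name: normalized_es(observed_es[name], null[name]) for name in retained}
    permuted_nes = {name: _norm_null(null[name]) for name in retained}
    qvals = fdr_q(observed_nes, permuted_nes)
    results = []
    for name, members in retained.items():
        es = observed_es[name]
        results.append(
            EnrichmentResult(
                set_name=name,
                size=len(members),
                es=es,
                nes=observed_nes[name],
                p_nominal=nominal_p(es, null[name]),
                fdr_q=qvals[name],
                direction="up" if es > 0 else "down",
            )
        )
    ups = sorted((r for r in results if r.direction == "up"), key=lambda r: -r.nes)
    downs = sorted((r for r in results if r.direction == "down"), key=lambda r: r.nes)
    return ups + downs


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Results as a DataFrame with the conventional column order."""
    return pd.DataFrame(
        [
            {
                "set": r.set_name,
                "size": r.size,
                "es": r.es,
                "nes": r.nes,
                "p_nominal": r.p_nominal,
                "fdr_q": r.fdr_q,
                "direction": r.direction,
            }
            for r in results
        ],
        columns=["set", "size", "es", "nes", "p_nominal", "fdr_q", "direction"],
    )
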