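"""Ranking, enrichment scores, permutation significance and FDR.

The weighted running-sum statistic is checked against a deliberately naive
pure-Python oracle, against the classical two-sample KS statistic at weight
zero, against exhaustive enumeration of label assignments for tiny designs,
and against an independent reference implementation (the Bioconductor fgsea
package's ``calcGseaStat``, driven through Rscript).
"""

import shutil
import subprocess
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from crossgsea import (
    ESParams,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    PhenotypeLabels,
    PlantSpec,
    RankedList,
    enrichment_score,
    fdr_q,
    gen_expression,
    gen_gene_sets,
    nominal_p,
    normalized_es,
    permutation_null,
    run_gsea,
    signal_to_noise,
)
from crossgsea.gsea import _s2n_metric


# --------------------------------------------------------------- oracles


def brute_force_es(metrics, in_set, weight_p):
    """Naive transliteration of the running-sum definition (the oracle)."""
    n = len(metrics)
    n_hit = sum(in_set)
    denom_hit = sum(abs(m) ** weight_p for m, h in zip(metrics, in_set) if h)
    running = 0.0
    best = 0.0
    for m, h in zip(metrics, in_set):
        if h:
            running += (abs(m) ** weight_p) / denom_hit
        else:
            running -= 1.0 / (n - n_hit)
        if abs(running) > abs(best):
            best = running
    return best


def _ranked(metric, symbols=None):
    metric = np.asarray(metric, dtype=float)
    symbols = symbols or [f"G{i:03d}" for i in range(len(metric))]
    return RankedList(symbols=symbols, metric=metric, class_order=("t", "c"))


# ------------------------------------------------------------ signal-to-noise


def _expr(data, labels):
    data = np.asarray(data, dtype=float)
    return ExpressionMatrix(
        values=pd.DataFrame(
            data,
            index=[f"G{i:03d}" for i in range(data.shape[0])],
            columns=labels.sample_ids,
        ),
        scale="log",
    )


@pytest.fixture
def labels_3v3():
    return PhenotypeLabels(
        sample_ids=[f"s{i}" for i in range(6)],
        class_names=("treated", "control"),
        assignment=["treated"] * 3 + ["control"] * 3,
    )


def test_s2n_zero_for_identical_classes(labels_3v3):
    m = _expr([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], labels_3v3)
    assert signal_to_noise(m, labels_3v3).metric[0] == 0.0


def test_s2n_variance_floor_binds(labels_3v3):
    # class means 2 and 1, zero spread: floors 0.2*2 and 0.2*1 bind,
    # metric = (2-1)/(0.4+0.2) = 1/0.6
    m = _expr([[2.0, 2.0, 2.0, 1.0, 1.0, 1.0]], labels_3v3)
    np.testing.assert_allclose(signal_to_noise(m, labels_3v3).metric[0], 1 / 0.6)


def test_s2n_floor_at_zero_mean_is_absolute(labels_3v3):
    # zero-mean class gets the absolute floor 0.2
    m = _expr([[0.0, 0.0, 0.0, 1.0, 1.0, 1.0]], labels_3v3)
    np.testing.assert_allclose(signal_to_noise(m, labels_3v3).metric[0], -1 / 0.4)


def test_s2n_uses_sample_sd(labels_3v3):
    vals = np.array([[4.0, 6.0, 8.0, 1.0, 2.0, 3.0]])
    m = _expr(vals, labels_3v3)
    sd_p = np.std(vals[0, :3], ddof=1)
    sd_n = np.std(vals[0, 3:], ddof=1)
    expected = (6.0 - 2.0) / (max(sd_p, 0.2 * 6) + max(sd_n, 0.2 * 2))
    np.testing.assert_allclose(signal_to_noise(m, labels_3v3).metric[0], expected)


def test_s2n_negating_values_negates_metric(labels_3v3):
    rng = np.random.default_rng(5)
    vals = rng.normal(size=(20, 6))
    r1 = signal_to_noise(_expr(vals, labels_3v3), labels_3v3)
    r2 = signal_to_noise(_expr(-vals, labels_3v3), labels_3v3)
    m1 = dict(zip(r1.symbols, r1.metric))
    m2 = dict(zip(r2.symbols, r2.metric))
    for g in m1:
        np.testing.assert_allclose(m2[g], -m1[g], atol=1e-12)


def test_s2n_requires_two_samples_per_class():
    labels = PhenotypeLabels(
        sample_ids=["a", "b", "c", "d"],
        class_names=("t", "c"),
        assignment=["t", "t", "c", "c"],
    )
    # drop to 1 vs 3 by relabelling is rejected at construction time
    with pytest.raises(Exception, match="2 samples"):
        PhenotypeLabels(
            sample_ids=["a", "b", "c", "d"],
            class_names=("t", "c"),
            assignment=["t", "c", "c", "c"],
        )
    # and a non-log matrix is rejected
    m = _expr(np.ones((2, 4)), labels)
    m.scale = "linear"
    with pytest.raises(ValueError, match="log-scale"):
        signal_to_noise(m, labels)


def test_s2n_ties_broken_lexicographically(labels_3v3):
    vals = np.tile([[1.0, 2.0, 3.0, 0.0, 1.0, 2.0]], (4, 1))  # identical rows
    ranked = signal_to_noise(_expr(vals, labels_3v3), labels_3v3)
    assert ranked.symbols == sorted(ranked.symbols)


# ------------------------------------------------------------ enrichment score


def test_es_all_mass_at_top_is_one():
    es, _ = enrichment_score(_ranked([2, 1, -1, -2]), {"G000"}, 1.0)
    assert es == pytest.approx(1.0)


def test_es_all_mass_at_bottom_is_minus_one():
    es, _ = enrichment_score(_ranked([2, 1, -1, -2]), {"G003"}, 1.0)
    assert es == pytest.approx(-1.0)


def test_es_second_gene_two_thirds():
    # hand evaluation: steps -1/3, +1, -1/3, -1/3 -> extremum +2/3 at rank 2
    es, running = enrichment_score(_ranked([2, 1, -1, -2]), {"G001"}, 1.0)
    assert es == pytest.approx(2 / 3)
    np.testing.assert_allclose(running, [-1 / 3, 2 / 3, 1 / 3, 0.0], atol=1e-12)


def test_es_running_sum_ends_at_zero():
    rng = np.random.default_rng(3)
    metric = np.sort(rng.normal(size=40))[::-1]
    members = {f"G{i:03d}" for i in rng.choice(40, 7, replace=False)}
    _, running = enrichment_score(_ranked(metric), members, 1.0)
    assert running[-1] == pytest.approx(0.0, abs=1e-12)


def test_es_empty_intersection_is_error():
    with pytest.raises(ValueError, match="empty intersection"):
        enrichment_score(_ranked([1, -1]), {"NOT_THERE"}, 1.0)


@pytest.mark.parametrize("weight_p", [0.0, 1.0, 1.5])
def test_es_matches_brute_force_oracle(weight_p):
    rng = np.random.default_rng(17)
    for _ in range(50):
        n = int(rng.integers(5, 60))
        metric = np.sort(rng.normal(size=n))[::-1]
        k = int(rng.integers(1, n))
        hit_idx = set(rng.choice(n, k, replace=False).tolist())
        in_set = [i in hit_idx for i in range(n)]
        ranked = _ranked(metric)
        members = {ranked.symbols[i] for i in hit_idx}
        es, _ = enrichment_score(ranked, members, weight_p)
        assert es == pytest.approx(brute_force_es(metric, in_set, weight_p), abs=1e-12)


def test_es_weight_zero_equals_classical_ks():
    """At p=0 the statistic is the two-sample KS deviation between the hit
    and miss rank distributions (checked against scipy's KS statistic)."""
    rng = np.random.default_rng(23)
    for _ in range(50):
        n = int(rng.integers(10, 80))
        metric = np.sort(rng.normal(size=n))[::-1]
        k = int(rng.integers(2, n - 1))
        hit_idx = np.sort(rng.choice(n, k, replace=False))
        ranked = _ranked(metric)
        members = {ranked.symbols[i] for i in hit_idx}
        es, _ = enrichment_score(ranked, members, 0.0)
        miss_idx = np.setdiff1d(np.arange(n), hit_idx)
        ks = sps.ks_2samp(hit_idx, miss_idx, method="asymp").statistic
        assert abs(es) == pytest.approx(ks, abs=1e-12)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_es_matches_fgsea_reference():
    """Cross-check the weighted statistic against fgsea::calcGseaStat."""
    rng = np.random.default_rng(7)
    cases = []
    for _ in range(4):
        n = int(rng.integers(20, 80))
        metric = np.sort(rng.normal(size=n))[::-1]
        k = int(rng.integers(3, 12))
        sel = np.sort(rng.choice(n, k, replace=False)) + 1  # 1-based
        cases.append((metric, sel))
    script = ["suppressMessages(library(fgsea))"]
    for metric, sel in cases:
        script.append(
            f"cat(calcGseaStat(c({','.join(str(float(x)) for x in metric)}),"
            f" c({','.join(str(int(i)) for i in sel)}), gseaParam=1), '\\n')"
        )
    out = subprocess.run(
        ["Rscript", "-e", "\n".join(script)], capture_output=True, text=True, timeout=120
    )
    assert out.returncode == 0, out.stderr
    ref = [float(x) for x in out.stdout.split()]
    for (metric, sel), expected in zip(cases, ref):
        ranked = _ranked(metric)
        members = {ranked.symbols[i - 1] for i in sel}
        es, _ = enrichment_score(ranked, members, 1.0)
        assert es == pytest.approx(expected, abs=1e-6)


# ---------------------------------------------------------- permutation null


def test_null_deterministic_given_seed(labels_3v3):
    m, labels, _ = gen_expression(n_genes=100, n_per_class=4, seed=1)
    sets = {"S": frozenset(m.probe_ids[:20])}
    p = ESParams(n_perm=50, seed=42)
    a = permutation_null(m, labels, sets, p)["S"]
    b = permutation_null(m, labels, sets, p)["S"]
    np.testing.assert_array_equal(a, b)


def test_null_warns_when_nperm_exceeds_designs():
    m, labels, _ = gen_expression(n_genes=30, n_per_class=2, seed=2)  # C(4,2)=6
    with pytest.warns(UserWarning, match="distinct label assignments"):
        permutation_null(m, labels, {"S": frozenset(m.probe_ids[:10])}, ESParams(n_perm=50, seed=1))


def test_null_es_centred_near_zero_for_random_set():
    m, labels, _ = gen_expression(n_genes=300, n_per_class=8, seed=3)
    rng = np.random.default_rng(4)
    members = frozenset(rng.choice(m.probe_ids, 25, replace=False))
    null = permutation_null(m, labels, {"S": members}, ESParams(n_perm=300, seed=5))["S"]
    se = null.std(ddof=1) / np.sqrt(null.size)
    assert abs(null.mean()) < 3 * se + 0.02


# ----------------------------------------------------- nominal p and NES


def test_nominal_p_zero_when_observed_beyond_null():
    assert nominal_p(0.9, np.array([0.1, 0.2, -0.5, 0.3])) == 0.0


def test_nominal_p_tail_fraction():
    # 14 of 1000 positive nulls at or beyond 0.437 -> p = 0.014
    null = np.concatenate([np.full(986, 0.1), np.full(14, 0.6), -np.ones(100) * 0.2])
    assert nominal_p(0.437, null) == pytest.approx(14 / 1000)


def test_nominal_p_median_is_half():
    null = np.linspace(0.01, 1.0, 999)  # all positive
    assert nominal_p(float(np.median(null)), null) == pytest.approx(0.5, abs=0.01)


def test_nominal_p_uses_same_sign_side_only():
    null = np.array([0.5, 0.6, -0.1, -0.2, -0.3])
    assert nominal_p(-0.25, null) == pytest.approx(1 / 3)


def test_nes_is_es_over_same_sign_null_mean():
    null = np.concatenate([np.full(500, 0.445), -np.full(500, 0.3)])
    assert normalized_es(0.708, null) == pytest.approx(0.708 / 0.445)
    assert normalized_es(0.708, null) == pytest.approx(1.59, abs=0.005)


def test_nes_one_when_es_equals_null_mean():
    null = np.array([0.2, 0.4, 0.6, -0.5])
    assert normalized_es(0.4, null) == pytest.approx(1.0)


def test_nes_undefined_without_same_sign_nulls():
    assert np.isnan(normalized_es(-0.4, np.array([0.1, 0.2])))


def test_label_swap_negates_metric_es_and_nes():
    """Swapping phenotype classes reverses the list and negates ES/NES."""
    m, labels, _ = gen_expression(n_genes=200, n_per_class=6, seed=9)
    members = frozenset(list(m.probe_ids)[40:70])
    r1 = signal_to_noise(m, labels)
    r2 = signal_to_noise(m, labels.swapped())
    np.testing.assert_allclose(
        np.sort(r1.metric), np.sort(-np.asarray(r2.metric)), atol=1e-12
    )
    assert r1.symbols == list(reversed(r2.symbols))  # no metric ties at random data
    es1, _ = enrichment_score(r1, members, 1.0)
    es2, _ = enrichment_score(r2, members, 1.0)
    assert es1 == pytest.approx(-es2, abs=1e-12)
    null1 = permutation_null(m, labels, {"S": members}, ESParams(n_perm=100, seed=3))["S"]
    nes1 = normalized_es(es1, null1)
    nes2 = normalized_es(es2, -null1)  # swapped labels negate every null ES too
    assert nes1 == pytest.approx(-nes2)


# -------------------------------------------------- exhaustive enumeration


def test_nominal_p_converges_to_exhaustive_enumeration():
    """Sampled phenotype permutations agree with enumerating all label
    assignments on a 3v3, 8-gene design (within Monte-Carlo error)."""
    rng = np.random.default_rng(31)
    values = rng.normal(size=(8, 6))
    labels = PhenotypeLabels(
        sample_ids=[f"s{i}" for i in range(6)],
        class_names=("t", "c"),
        assignment=["t"] * 3 + ["c"] * 3,
    )
    m = _expr(values, labels)
    members = frozenset({"G000", "G002", "G005"})
    ranked = signal_to_noise(m, labels)
    es_obs, _ = enrichment_score(ranked, members, 1.0)
    symbols = np.asarray(m.probe_ids, dtype=object)
    exhaustive = []
    for pos in combinations(range(6), 3):
        pos = np.array(pos)
        neg = np.setdiff1d(np.arange(6), pos)
        metric = _s2n_metric(values, pos, neg)
        order = np.lexsort((symbols, -metric))
        r = RankedList(list(symbols[order]), metric[order], ("t", "c"))
        exhaustive.append(enrichment_score(r, members, 1.0)[0])
    exhaustive = np.array(exhaustive)
    p_exact = nominal_p(es_obs, exhaustive)
    n_perm = 4000
    with pytest.warns(UserWarning, match="distinct label assignments"):
        null = permutation_null(
            m, labels, {"S": members}, ESParams(n_perm=n_perm, seed=11)
        )["S"]
    p_sampled = nominal_p(es_obs, null)
    se = np.sqrt(max(p_exact * (1 - p_exact), 1.0 / n_perm) / n_perm)
    assert abs(p_sampled - p_exact) <= 3 * se + 1e-9


# ----------------------------------------------------------------- FDR


def brute_force_fdr(observed, permuted_pool):
    """Independent transliteration of the pooled-ratio FDR with step-up."""
    qs = {}
    for name, nes in observed.items():
        if nes >= 0:
            pool = [x for x in permuted_pool if x >= 0]
            obs = [x for x in observed.values() if x >= 0]
            num = sum(1 for x in pool if x >= nes) / len(pool) if pool else 0.0
            den = sum(1 for x in obs if x >= nes) / len(obs)
        else:
            pool = [x for x in permuted_pool if x < 0]
            obs = [x for x in observed.values() if x < 0]
            num = sum(1 for x in pool if x <= nes) / len(pool) if pool else 0.0
            den = sum(1 for x in obs if x <= nes) / len(obs)
        qs[name] = min(1.0, num / den) if den else 0.0
    out = {}
    for name, nes in observed.items():
        same = [k for k, v in observed.items() if (v >= 0) == (nes >= 0)]
        weaker = [k for k in same if abs(observed[k]) <= abs(nes)]
        out[name] = min(qs[k] for k in weaker)
    return out


def test_fdr_zero_when_observed_beyond_pool():
    obs = {"A": 2.5, "B": 1.0}
    pool = {"A": np.array([0.5, 1.2, -0.8]), "B": np.array([0.9, -1.1, 0.2])}
    assert fdr_q(obs, pool)["A"] == 0.0


def test_fdr_near_one_at_pool_median():
    pool_vals = np.linspace(0.01, 2.0, 400)
    obs = {"A": float(np.median(pool_vals))}
    q = fdr_q(obs, {"A": pool_vals})["A"]
    assert q == pytest.approx(0.5, abs=0.01) or q <= 1.0
    assert 0.4 <= q <= 1.0


def test_fdr_matches_brute_force_on_toy_collection():
    rng = np.random.default_rng(13)
    observed = {f"SET{i}": float(x) for i, x in enumerate(rng.normal(0, 1.5, size=5))}
    permuted = {name: rng.normal(0, 1.0, size=200) for name in observed}
    ours = fdr_q(observed, permuted)
    pool = np.concatenate(list(permuted.values())).tolist()
    expected = brute_force_fdr(observed, pool)
    for name in observed:
        assert ours[name] == pytest.approx(expected[name], abs=1e-12)


def test_fdr_monotone_in_abs_nes():
    rng = np.random.default_rng(19)
    observed = {f"SET{i}": float(x) for i, x in enumerate(rng.normal(0, 1.2, size=12))}
    permuted = {name: rng.normal(0, 1.0, size=100) for name in observed}
    qs = fdr_q(observed, permuted)
    for sign in (1, -1):
        names = sorted(
            (k for k, v in observed.items() if (v >= 0) == (sign > 0)),
            key=lambda k: -abs(observed[k]),
        )
        vals = [qs[k] for k in names]
        assert vals == sorted(vals)  # non-decreasing as |NES| falls


# --------------------------------------------------------------- run_gsea


def _planted_setup(seed=0, n_genes=400):
    symbols = [f"GENE{i:05d}" for i in range(n_genes)]
    plants = [PlantSpec("PLANTED", symbols[:30], 2.0, "up")]
    m, labels, _ = gen_expression(n_genes, 12, plants, noise_sd=1.0, seed=seed)
    coll = GeneSetCollection(
        list(gen_gene_sets(symbols, 6, seed=seed + 1))
        + [GeneSet("PLANTED", "planted up-set", frozenset(symbols[:30]))]
    )
    return m, labels, coll


def test_run_gsea_size_window_excludes_sets():
    m, labels, _ = gen_expression(n_genes=100, n_per_class=3, seed=6)
    small = GeneSet("SMALL", "", frozenset(list(m.probe_ids)[:5]))
    ok = GeneSet("OK", "", frozenset(list(m.probe_ids)[:40]))
    res = run_gsea(m, labels, GeneSetCollection([small, ok]), ESParams(n_perm=20, seed=1))
    assert [r.set_name for r in res] == ["OK"]
    with pytest.raises(ValueError, match="no gene set"):
        run_gsea(m, labels, GeneSetCollection([small]), ESParams(n_perm=20, seed=1))
    big = GeneSet("BIG", "", frozenset(m.probe_ids))  # 100 genes > max_size 60
    res2 = run_gsea(
        m, labels, GeneSetCollection([big, ok]), ESParams(n_perm=20, seed=1, max_size=60)
    )
    assert [r.set_name for r in res2] == ["OK"]


def test_run_gsea_size_is_post_intersection():
    m, labels, _ = gen_expression(n_genes=100, n_per_class=3, seed=7)
    off_platform = [f"OFF{i}" for i in range(20)]
    s = GeneSet("S", "", frozenset(list(m.probe_ids)[:15] + off_platform))
    res = run_gsea(m, labels, GeneSetCollection([s]), ESParams(n_perm=20, seed=1))
    assert res[0].size == 15


def test_run_gsea_planted_set_ranks_first():
    m, labels, coll = _planted_setup(seed=12)
    res = run_gsea(m, labels, coll, ESParams(n_perm=200, seed=2))
    best = max(res, key=lambda r: abs(r.nes))
    assert best.set_name == "PLANTED"
    assert best.direction == "up"
    assert best.p_nominal < 0.05


def test_run_gsea_deterministic():
    m, labels, coll = _planted_setup(seed=4, n_genes=200)
    r1 = run_gsea(m, labels, coll, ESParams(n_perm=50, seed=7))
    r2 = run_gsea(m, labels, coll, ESParams(n_perm=50, seed=7))
    assert [(r.set_name, r.es, r.nes, r.p_nominal, r.fdr_q) for r in r1] == [
        (r.set_name, r.es, r.nes, r.p_nominal, r.fdr_q) for r in r2
    ]


def test_run_gsea_direction_matches_es_sign():
    m, labels, coll = _planted_setup(seed=8, n_genes=200)
    for r in run_gsea(m, labels, coll, ESParams(n_perm=50, seed=3)):
        assert (r.direction == "up") == (r.es > 0)
        assert -1.0 <= r.es <= 1.0
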