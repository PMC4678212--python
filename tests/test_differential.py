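"""Ratio statistics, Welch tests and the classifier cascade against
independent straight-loop / permutation / textbook-formula oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from azflux import (
    ExpressionMatrix,
    SampleDesign,
    ThresholdConfig,
    classify_genes,
    log2_ratio,
    reverse_contrast,
    test_contrast as contrast_pvalue,
    transcriptome_share,
)
from azflux.types import AzfluxError, ConfigurationError

TIMES = (12, 24)
TISSUES = ("AZ", "NAZ")


# --- oracles -------------------------------------------------------------


def welch_p_textbook(a, b):
    """Welch two-sample t from the textbook formulas (statistic, df, CDF)."""
    a, b = np.log2(np.asarray(a, float)), np.log2(np.asarray(b, float))
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2 * stats.t.sf(abs(t), df)


def classify_brute_force(row, thresholds):
    """Straight-loop transcription of the written classification rules."""
    ratios = [
        (tis, t, row[f"log2_{tis}_t{t}v0"]) for tis in TISSUES for t in TIMES
    ]
    mx = max(v for _, _, v in ratios)
    mn = min(v for _, _, v in ratios)
    up = mx > thresholds.fold_log2
    down = mn < -thresholds.fold_log2
    if up and down:
        if abs(mx) > abs(mn):
            down = False
        elif abs(mn) > abs(mx):
            up = False
        else:
            up = down = False
    az = max(row[f"log2_AZspec_t{t}"] for t in TIMES) > thresholds.az_specific_log2
    sig = up and any(
        v > thresholds.fold_log2 and row[f"p_{tis}_t{t}v0"] < thresholds.pvalue_max
        for tis, t, v in ratios
    )
    return up, down, az, sig


def random_diff_table(rng, n=100):
    """Random differential table drawing from a palette that includes the
    exact boundary values log2 = +-3.0 and p = 0.015."""
    ratio_palette = np.array([-5.0, -3.2, -3.0, -1.0, 0.0, 1.0, 2.9, 3.0, 3.2, 4.5])
    p_palette = np.array([0.001, 0.0149, 0.015, 0.2, 1.0])
    cols = {}
    for t in TIMES:
        cols[f"log2_AZspec_t{t}"] = rng.choice(ratio_palette, n)
    for tis in TISSUES:
        for t in TIMES:
            cols[f"log2_{tis}_t{t}v0"] = rng.choice(ratio_palette, n)
            cols[f"p_{tis}_t{t}v0"] = rng.choice(p_palette, n)
    return pd.DataFrame(cols, index=[f"g{i}" for i in range(n)])


# --- log2 ratios ---------------------------------------------------------


def test_log2_ratio_hand_values():
    means = pd.DataFrame({"a": [8.0, 3.0], "b": [1.0, 3.0]}, index=["g1", "g2"])
    r = log2_ratio(means, "a", "b")
    assert r["g1"] == pytest.approx(3.0)
    assert r["g2"] == pytest.approx(0.0)


def test_log2_ratio_antisymmetric():
    rng = np.random.default_rng(1)
    means = pd.DataFrame(
        {"a": rng.lognormal(1, 1, 10), "b": rng.lognormal(1, 1, 10)},
        index=[f"g{i}" for i in range(10)],
    )
    fwd = log2_ratio(means, "a", "b")
    rev = log2_ratio(means, "b", "a")
    assert np.allclose(fwd, -rev)


def test_log2_ratio_unknown_condition():
    means = pd.DataFrame({"a": [1.0]}, index=["g"])
    with pytest.raises(AzfluxError, match="nope"):
        log2_ratio(means, "a", "nope")


def test_reverse_contrast_involution_and_fixed_point():
    df = pd.DataFrame(
        {"log2_WTvmutant": [2.5, 0.0, -1.25], "p_WTvmutant": [0.1, 0.2, 0.3]},
        index=list("abc"),
    )
    once = reverse_contrast(df)
    assert once["log2_WTvmutant"].tolist() == [-2.5, 0.0, 1.25]
    assert once["p_WTvmutant"].tolist() == [0.1, 0.2, 0.3]  # p untouched
    pd.testing.assert_frame_equal(reverse_contrast(once), df)


# --- the two-sample test -------------------------------------------------


def test_identical_replicates_give_p_one():
    assert contrast_pvalue([5.0, 5.1, 4.9], [5.0, 5.1, 4.9]) == pytest.approx(1.0)
    assert contrast_pvalue([7.0, 7.0], [7.0, 7.0]) == 1.0


def test_separated_groups_significant():
    p = contrast_pvalue([10, 10.1, 9.9], [1000, 1010, 990])
    assert p < 0.015
    assert p == pytest.approx(welch_p_textbook([10, 10.1, 9.9], [1000, 1010, 990]), rel=1e-9)


def test_matches_textbook_welch_on_random_draws():
    rng = np.random.default_rng(5)
    for _ in range(25):
        a = rng.lognormal(3, 0.5, rng.integers(2, 6))
        b = rng.lognormal(3 + rng.uniform(-1, 1), 0.5, rng.integers(2, 6))
        assert contrast_pvalue(a, b) == pytest.approx(welch_p_textbook(a, b), rel=1e-9)


def test_single_replicate_never_significant():
    assert contrast_pvalue([10.0], [1000.0, 990.0]) == 1.0


def test_empty_condition_is_an_error():
    with pytest.raises(AzfluxError):
        contrast_pvalue([], [1.0, 2.0])


def test_permutation_oracle_agreement():
    """Welch-t accept/reject at alpha=0.015 agrees with the exact
    permutation decision on >=95% of random 4+4 draws."""
    # Exact permutation p: fraction of the C(8,4)=70 relabelings whose
    # mean difference is at least as extreme as observed, in the observed
    # direction.  The attainable floor 1/70 ~ 0.0143 sits just under the
    # alpha = 0.015 working threshold, so both tests can reject.
    rng = np.random.default_rng(99)
    alpha = 0.015
    splits = list(itertools.combinations(range(8), 4))
    agree = 0
    n_draws = 500
    for i in range(n_draws):
        delta = 0.0 if i % 2 == 0 else rng.uniform(1.0, 4.0)
        a = rng.lognormal(3 + delta * math.log(2), 0.25, 4)
        b = rng.lognormal(3, 0.25, 4)
        welch_reject = contrast_pvalue(a, b) < alpha
        pooled = np.log2(np.concatenate([a, b]))
        obs = pooled[:4].mean() - pooled[4:].mean()
        sign = 1.0 if obs >= 0 else -1.0
        count = sum(
            1
            for s in splits
            if sign
            * (pooled[list(s)].mean() - pooled[[k for k in range(8) if k not in s]].mean())
            >= abs(obs) - 1e-12
        )
        perm_reject = (count / len(splits)) < alpha
        agree += welch_reject == perm_reject
    assert agree / n_draws >= 0.95


# --- classification ------------------------------------------------------


def test_classifier_matches_brute_force_on_random_fixtures():
    thresholds = ThresholdConfig()
    rng = np.random.default_rng(2024)
    for _ in range(200):
        diff = random_diff_table(rng, n=100)
        got = classify_genes(diff, thresholds)
        for g in diff.index:
            up, down, az, sig = classify_brute_force(diff.loc[g], thresholds)
            assert got.loc[g, "changed_up"] == up, g
            assert got.loc[g, "changed_down"] == down, g
            assert got.loc[g, "az_specific"] == az, g
            assert got.loc[g, "significant_changed"] == sig, g


def test_boundary_values_excluded_under_strict_rules():
    diff = pd.DataFrame(
        {
            "log2_AZspec_t12": [3.0, 3.0 + 1e-9],
            "log2_AZ_t12v0": [3.0, 3.2],
            "p_AZ_t12v0": [0.015, 0.015],
            "log2_NAZ_t12v0": [0.0, 0.0],
            "p_NAZ_t12v0": [1.0, 1.0],
        },
        index=["boundary", "above"],
    )
    got = classify_genes(diff)
    assert not got.loc["boundary", ["changed_up", "az_specific", "significant_changed"]].any()
    assert got.loc["above", "changed_up"]
    assert got.loc["above", "az_specific"]
    # p = 0.015 exactly is not < 0.015
    assert not got.loc["above", "significant_changed"]


def test_significant_requires_p_on_a_qualifying_contrast():
    """A small p on a weak contrast does not rescue a gene whose only
    qualifying fold has a large p."""
    diff = pd.DataFrame(
        {
            "log2_AZspec_t12": [0.0],
            "log2_AZ_t12v0": [4.0],   # qualifies, but p is large
            "p_AZ_t12v0": [0.5],
            "log2_NAZ_t12v0": [1.0],  # significant p, but fold too small
            "p_NAZ_t12v0": [0.001],
        },
        index=["g"],
    )
    got = classify_genes(diff)
    assert got.loc["g", "changed_up"]
    assert not got.loc["g", "significant_changed"]


def test_up_down_conflict_resolved_by_magnitude():
    base = {
        "log2_AZspec_t12": [0.0, 0.0, 0.0],
        "log2_AZ_t12v0": [5.0, 3.5, 4.0],
        "p_AZ_t12v0": [1.0, 1.0, 1.0],
        "log2_NAZ_t12v0": [-3.5, -5.0, -4.0],
        "p_NAZ_t12v0": [1.0, 1.0, 1.0],
    }
    got = classify_genes(pd.DataFrame(base, index=["up_wins", "down_wins", "tie"]))
    assert got.loc["up_wins", "changed_up"] and not got.loc["up_wins", "changed_down"]
    assert got.loc["down_wins", "changed_down"] and not got.loc["down_wins", "changed_up"]
    assert not got.loc["tie", ["changed_up", "changed_down"]].any()


def test_null_gene_has_no_flags():
    diff = pd.DataFrame(
        {
            "log2_AZspec_t12": [0.0],
            "log2_AZ_t12v0": [0.0],
            "p_AZ_t12v0": [1.0],
            "log2_NAZ_t12v0": [0.0],
            "p_NAZ_t12v0": [1.0],
        },
        index=["g"],
    )
    got = classify_genes(diff)
    assert not got[["changed_up", "changed_down", "az_specific", "significant_changed"]].any().any()


def test_threshold_monotonicity():
    """Raising the fold cutoff never grows the changed sets; lowering the
    p cutoff never grows significant_changed."""
    rng = np.random.default_rng(8)
    diff = random_diff_table(rng, n=200)
    prev_up = prev_sig = None
    for fold in (2.0, 3.0, 4.0, 5.0):
        got = classify_genes(diff, ThresholdConfig(fold_log2=fold))
        up = set(got.index[got["changed_up"] | got["changed_down"]])
        if prev_up is not None:
            assert up <= prev_up
        prev_up = up
    for pmax in (0.2, 0.015, 0.001):
        got = classify_genes(diff, ThresholdConfig(pvalue_max=pmax))
        sig = set(got.index[got["significant_changed"]])
        if prev_sig is not None:
            assert sig <= prev_sig
        prev_sig = sig


def test_flag_consistency_invariants():
    rng = np.random.default_rng(12)
    got = classify_genes(random_diff_table(rng, n=300))
    assert not (got["changed_up"] & got["changed_down"]).any()
    assert (got["significant_changed"] <= got["changed_up"]).all()


def test_invalid_thresholds_rejected():
    with pytest.raises(ConfigurationError):
        ThresholdConfig(fold_log2=0)
    with pytest.raises(ConfigurationError):
        ThresholdConfig(pvalue_max=1.5)


# --- transcriptome share -------------------------------------------------


def _share_matrix():
    values = pd.DataFrame(
        {"s1": [50.0, 450.0, 500.0], "s2": [10.0, 10.0, 80.0]},
        index=["g1", "g2", "g3"],
    )
    return ExpressionMatrix(values, "rpkm")


def test_share_hand_arithmetic():
    m = _share_matrix()
    assert transcriptome_share(m, ["g1"], "s1") == pytest.approx(5.0)
    assert transcriptome_share(m, ["g1", "g2", "g3"], "s1") == pytest.approx(100.0)
    assert transcriptome_share(m, [], "s1") == 0.0


def test_share_matches_loop_oracle():
    rng = np.random.default_rng(3)
    values = pd.DataFrame(
        rng.lognormal(1, 1, size=(20, 12)),
        index=[f"g{i}" for i in range(20)],
        columns=[f"s{j}" for j in range(12)],
    )
    m = ExpressionMatrix(values, "rpkm")
    subset = [f"g{i}" for i in range(0, 20, 3)]
    for s in m.samples:
        num = sum(values.loc[g, s] for g in subset)
        den = sum(values.loc[g, s] for g in values.index)
        assert transcriptome_share(m, subset, s) == pytest.approx(
            100 * num / den, rel=1e-12
        )


def test_share_errors():
    m = _share_matrix()
    with pytest.raises(AzfluxError):
        transcriptome_share(m, ["gX"], "s1")
    with pytest.raises(AzfluxError):
        transcriptome_share(m, ["g1"], "sX")
    zero = ExpressionMatrix(pd.DataFrame({"s": [0.0]}, index=["g"]), "rpkm")
    with pytest.raises(AzfluxError, match="zero total"):
        transcriptome_share(zero, ["g"], "s")
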