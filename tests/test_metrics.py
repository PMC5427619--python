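"""Ranking-metric correctness: hand values, loop-based oracles, invariances."""

import numpy as np
import pytest

from gsearank import ExpressionDataset, group_summaries, rank_genes
from gsearank.metrics import (
    METRIC_NAMES,
    MwtParams,
    fit_mwt_params,
    metric_bws,
    metric_fcros,
    metric_mean_based,
    metric_msd,
    metric_mwt,
    metric_relieff,
    metric_s2n,
    metric_sor,
    metric_ttest,
    metric_wad,
)

import oracles
from conftest import swap_groups


# ----------------------------------------------------------------------
# group summaries
# ----------------------------------------------------------------------

def test_group_summaries_hand_values(toy_dataset):
    s = group_summaries(toy_dataset)
    assert s.mean1 == 2 and s.mean2 == 5
    assert s.sd1 == pytest.approx(1.0) and s.sd2 == pytest.approx(1.0)
    assert s.n1 == 3 and s.n2 == 3


def test_group_summaries_constant_gene():
    ds = ExpressionDataset(np.full((1, 6), 5.0), ["g1"], ["A"] * 3 + ["B"] * 3)
    s = group_summaries(ds)
    assert s.mean1 == s.mean2 == 5 and s.sd1 == s.sd2 == 0


def test_group_summaries_swap_symmetry(random_dataset):
    ds = random_dataset(seed=3)
    s, sw = group_summaries(ds), group_summaries(swap_groups(ds))
    np.testing.assert_allclose(s.mean1, sw.mean2)
    np.testing.assert_allclose(s.sd2, sw.sd1)
    assert (s.n1, s.n2) == (sw.n2, sw.n1)


def test_single_sample_group_sd_flagged_and_rejected():
    ds = ExpressionDataset(np.arange(4.0)[None, :], ["g1"], ["A", "B", "B", "B"])
    s = group_summaries(ds)
    assert np.isnan(s.sd1).all()
    with pytest.raises(ValueError, match="at least 2 samples"):
        metric_ttest(s)


# ----------------------------------------------------------------------
# hand-computed examples
# ----------------------------------------------------------------------

def test_hand_values_on_toy(toy_dataset):
    s = group_summaries(toy_dataset)
    assert metric_ttest(s)[0] == pytest.approx(-3 / np.sqrt(2 / 3), abs=1e-4)
    assert metric_s2n(s)[0] == pytest.approx(-1.5)
    assert metric_s2n(s, absolute=True)[0] == pytest.approx(1.5)
    assert metric_mean_based(s, "Difference")[0] == pytest.approx(-3)
    assert metric_mean_based(s, "Ratio")[0] == pytest.approx(0.4)
    assert metric_mean_based(s, "log2Ratio")[0] == pytest.approx(-1.3219, abs=1e-4)


def test_msd_hand_t_interval():
    ds = ExpressionDataset(
        np.array([[4.0, 5, 6, 1, 2, 3]]), ["g1"], ["A"] * 3 + ["B"] * 3
    )
    msd = metric_msd(group_summaries(ds))
    assert msd[0] == pytest.approx(0.733, abs=1e-3)


def test_msd_null_negative_and_swap_invariant(random_dataset):
    ds = random_dataset(seed=5, n_genes=20, n1=5, n2=5)
    identical = ExpressionDataset(
        np.tile(ds.values[:, :5], 2), ds.gene_ids, ds.labels[: ds.n_samples]
    )
    assert (metric_msd(group_summaries(identical)) < 0).all()
    np.testing.assert_allclose(
        metric_msd(group_summaries(ds)),
        metric_msd(group_summaries(swap_groups(ds))),
    )


def test_bws_hand_value():
    ds = ExpressionDataset(np.array([[1.0, 2, 3, 4]]), ["g1"], ["A", "A", "B", "B"])
    assert metric_bws(ds)[0] == pytest.approx(1.6875)


def test_sor_hand_value_and_conservation(random_dataset):
    ds = ExpressionDataset(np.array([[2.0, 7, 4]]), ["g1"], ["A", "A", "B"])
    assert metric_sor(ds)[0] == 4
    big = random_dataset(seed=1, n_genes=10, n1=4, n2=6)
    n = big.n_samples
    np.testing.assert_allclose(
        metric_sor(big) + metric_sor(swap_groups(big)), n * (n + 1) / 2
    )


def test_fcros_pairwise_example():
    ds = ExpressionDataset(np.array([[1.0, 2, 3, 4]]), ["g1"], ["A", "A", "B", "B"])
    assert metric_fcros(ds)[0] == pytest.approx(-2.0)


def test_fcros_single_pair_warns():
    ds = ExpressionDataset(np.array([[2.0, 1.0], [0.0, 0.5]]), ["g1", "g2"], ["A", "B"])
    with pytest.warns(UserWarning, match="truncation skipped"):
        out = metric_fcros(ds)
    assert out[0] == pytest.approx(1.0)


def test_wad_extremes():
    # gene B has the highest average expression -> w=1, WAD = AD
    ds = ExpressionDataset(
        np.array([[3.0, 4.0], [9.0, 11.0]]), ["gA", "gB"], ["A", "B"]
    )
    s = group_summaries(ds)
    wad = metric_wad(s)
    assert wad[0] == 0.0  # lowest average -> weight 0
    assert wad[1] == pytest.approx(s.diff[1])
    with pytest.raises(ValueError, match="average expression"):
        metric_wad(group_summaries(
            ExpressionDataset(np.array([[1.0, 3.0], [0.0, 4.0]]), ["a", "b"], ["A", "B"])
        ))


# ----------------------------------------------------------------------
# MWT moderation
# ----------------------------------------------------------------------

def test_mwt_limits(random_dataset):
    ds = random_dataset(seed=7, n_genes=40, n1=5, n2=6)
    s = group_summaries(ds)
    params = fit_mwt_params(s)
    tiny = MwtParams(params.s0_sq, 1e-12, params.dw, params.sw_sq)
    np.testing.assert_allclose(metric_mwt(s, tiny), metric_ttest(s), atol=1e-6)
    inf = MwtParams(params.s0_sq, np.inf, params.dw, params.sw_sq)
    np.testing.assert_allclose(inf.se_m**2, params.s0_sq)


def test_mwt_needs_enough_genes():
    ds = ExpressionDataset(
        np.random.default_rng(0).normal(size=(5, 8)),
        [f"g{i}" for i in range(5)],
        ["A"] * 4 + ["B"] * 4,
    )
    with pytest.raises(ValueError, match=">=10 genes"):
        fit_mwt_params(group_summaries(ds))


def test_mwt_moderation_shrinks_towards_prior(random_dataset):
    # heterogeneous variances -> finite d0 and se_m between sw and s0
    rng = np.random.default_rng(11)
    sds = rng.uniform(0.2, 3.0, 60)
    values = rng.normal(0, 1, (60, 12)) * sds[:, None] + 8
    ds = ExpressionDataset(values, [f"g{i}" for i in range(60)], ["A"] * 6 + ["B"] * 6)
    params = fit_mwt_params(group_summaries(ds))
    assert np.isfinite(params.d0) and params.d0 > 0
    lo = np.minimum(params.sw_sq, params.s0_sq)
    hi = np.maximum(params.sw_sq, params.s0_sq)
    assert ((params.se_m**2 >= lo - 1e-12) & (params.se_m**2 <= hi + 1e-12)).all()


# ----------------------------------------------------------------------
# oracle equivalence (loop-based re-implementations)
# ----------------------------------------------------------------------

def _oracle_all(ds):
    x1, x2 = ds.group_values()
    params = fit_mwt_params(group_summaries(ds))
    k = min(10, min(ds.n1, ds.n2) - 1)
    relieff = oracles.oracle_relieff(ds.values, ds.group1_mask, k)
    from scipy.stats import rankdata

    return {
        "T-test": oracles.oracle_ttest(x1, x2),
        "MWT": oracles.oracle_mwt(x1, x2, params.s0_sq, params.d0),
        "|MWT|": np.abs(oracles.oracle_mwt(x1, x2, params.s0_sq, params.d0)),
        "MSD": oracles.oracle_msd(x1, x2),
        "S2N": oracles.oracle_s2n(x1, x2),
        "|S2N|": oracles.oracle_s2n(x1, x2, absolute=True),
        "WAD": oracles.oracle_wad(x1, x2),
        "|WAD|": oracles.oracle_wad(x1, x2, absolute=True),
        "Difference": oracles.oracle_difference(x1, x2),
        "Ratio": oracles.oracle_ratio(x1, x2),
        "log2(Ratio)": oracles.oracle_ratio(x1, x2, log2=True),
        "FCROS": oracles.oracle_fcros(x1, x2),
        "SoR": oracles.oracle_sor(x1, x2),
        "BWS": oracles.oracle_bws(x1, x2),
        "ReliefF": relieff,
        "ReliefF_ranked": rankdata(np.round(relieff, 12)),
    }


@pytest.mark.parametrize("seed", range(8))
def test_all_metrics_match_loop_oracles(random_dataset, seed):
    ds = random_dataset(seed=seed, n_genes=15, n1=4, n2=5)
    expected = _oracle_all(ds)
    for name in METRIC_NAMES:
        got = rank_genes(ds, name).values
        np.testing.assert_allclose(
            got, expected[name], atol=1e-10, rtol=1e-10,
            err_msg=f"metric {name} disagrees with its loop oracle (seed {seed})",
        )


# ----------------------------------------------------------------------
# invariances
# ----------------------------------------------------------------------

@pytest.mark.parametrize("name", ["T-test", "S2N", "Difference", "WAD", "MWT"])
def test_signed_metrics_flip_under_group_swap(random_dataset, name):
    ds = random_dataset(seed=21, n_genes=20, n1=5, n2=5)
    kwargs = {}
    if name == "MWT":
        kwargs["params"] = fit_mwt_params(group_summaries(ds))
    np.testing.assert_allclose(
        rank_genes(ds, name, **kwargs).values,
        -rank_genes(swap_groups(ds), name, **kwargs).values,
        atol=1e-10,
    )


def test_ratio_inverts_and_bws_symmetric_under_swap(random_dataset):
    ds = random_dataset(seed=22, n_genes=20, n1=5, n2=6)
    r = rank_genes(ds, "Ratio").values
    r_swap = rank_genes(swap_groups(ds), "Ratio").values
    np.testing.assert_allclose(r * r_swap, 1.0)
    np.testing.assert_allclose(
        rank_genes(ds, "BWS").values, rank_genes(swap_groups(ds), "BWS").values
    )


@pytest.mark.parametrize("name", ["SoR", "BWS"])
def test_rank_metrics_invariant_to_monotone_transform(random_dataset, name):
    ds = random_dataset(seed=23, n_genes=12, n1=4, n2=5)
    transformed = ExpressionDataset(
        np.exp(ds.values / 4.0), ds.gene_ids, ds.labels
    )
    np.testing.assert_allclose(
        rank_genes(ds, name).values, rank_genes(transformed, name).values, atol=1e-8
    )


def test_relieff_ranked_is_tied_rank_of_weights(random_dataset):
    from scipy.stats import rankdata

    ds = random_dataset(seed=23, n_genes=12, n1=4, n2=5)
    np.testing.assert_allclose(
        rank_genes(ds, "ReliefF_ranked").values,
        rankdata(np.round(rank_genes(ds, "ReliefF").values, 12)),
    )


def test_location_scale_invariances(random_dataset):
    ds = random_dataset(seed=24, n_genes=15, n1=4, n2=5)
    shifted = ExpressionDataset(ds.values + 7.3, ds.gene_ids, ds.labels)
    scaled = ExpressionDataset(ds.values * 2.0, ds.gene_ids, ds.labels)
    for name in ("S2N", "T-test"):
        np.testing.assert_allclose(
            rank_genes(ds, name).values, rank_genes(shifted, name).values, atol=1e-9
        )
    np.testing.assert_allclose(
        rank_genes(ds, "S2N").values, rank_genes(scaled, "S2N").values, atol=1e-10
    )


def test_relieff_weight_range_and_k_validation(random_dataset):
    ds = random_dataset(seed=25, n_genes=30, n1=6, n2=6)
    w = metric_relieff(ds)
    assert (w >= -1).all() and (w <= 1).all()
    with pytest.raises(ValueError, match="smallest"):
        metric_relieff(ds, k=6)


def test_relieff_separating_gene_ranks_top():
    rng = np.random.default_rng(31)
    values = rng.normal(0, 1, (40, 12))
    values[0] = np.r_[rng.uniform(0, 1, 6), rng.uniform(9, 10, 6)]
    ds = ExpressionDataset(values, [f"g{i}" for i in range(40)], ["A"] * 6 + ["B"] * 6)
    w = metric_relieff(ds)
    assert np.argmax(w) == 0


# ----------------------------------------------------------------------
# dispatcher
# ----------------------------------------------------------------------

def test_dispatcher_unknown_metric_lists_names(toy_dataset):
    with pytest.raises(ValueError, match="T-test.*BWS"):
        rank_genes(toy_dataset, "nope")


def test_dispatcher_user_callable_passthrough(random_dataset):
    ds = random_dataset(seed=2)

    def my_metric(values, labels):
        return values[:, 0]

    rv = rank_genes(ds, my_metric)
    np.testing.assert_array_equal(rv.values, ds.values[:, 0])
    assert rv.metric_name == "my_metric"


def test_dispatcher_deterministic(random_dataset):
    ds = random_dataset(seed=4)
    a, b = rank_genes(ds, "BWS"), rank_genes(ds, "BWS")
    np.testing.assert_array_equal(a.values, b.values)
    np.testing.assert_array_equal(a.order, b.order)


def test_sort_order_ties_broken_by_gene_id():
    ds = ExpressionDataset(
        np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 5.0]]), ["b", "a", "c"], ["A", "B"]
    )
    rv = rank_genes(ds, "Difference")  # genes a and b tie at -1, c at -5
    assert list(rv.sorted_gene_ids()) == ["a", "b", "c"]


def test_constant_gene_gets_finite_value_everywhere(random_dataset):
    ds = random_dataset(seed=6, n_genes=15, n1=4, n2=4)
    values = ds.values.copy()
    values[3] = 5.0  # constant gene
    ds = ExpressionDataset(values, ds.gene_ids, ds.labels)
    for name in METRIC_NAMES:
        rv = rank_genes(ds, name)
        assert np.isfinite(rv.values).all(), name
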