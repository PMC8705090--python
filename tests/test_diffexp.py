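"""Normalization and NB Wald testing: exact identities and simulation checks."""

import numpy as np
import pandas as pd
import pytest

from isomirkit import DEConfig, Design, call_de, nb_wald, size_factors
from isomirkit.diffexp import DiffExpError


def _nb(rng, mean, dispersion, size):
    if dispersion <= 0:
        return np.full(size, np.round(mean))
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean), size=size)


def _design(n=6, test="B", ref="A"):
    groups = {f"{ref}{i}": ref for i in range(n)}
    groups.update({f"{test}{i}": test for i in range(n)})
    return Design(groups=groups, contrast=(test, ref))


def _matrix(rng, n_feat, n=6, mean=500.0, disp=0.1, lfc=0.0, n_null=0):
    """Balanced planted features (half up, half down) plus null features.

    Nulls and direction balance keep the median-of-ratios pseudo-reference
    anchored, as in real libraries where most features are unchanged and
    effects go both ways; an unbalanced panel would bias normalization
    itself (composition bias), which is not the estimator's property under
    test.  Planted rows come first: up-regulated, then down-regulated.
    """
    n_up = n_feat // 2 if lfc != 0 else n_feat
    n_down = n_feat - n_up
    a = _nb(rng, mean, disp, (n_feat + n_null, n)).astype(float)
    b = np.vstack(
        [
            _nb(rng, mean * 2.0**lfc, disp, (n_up, n)),
            _nb(rng, mean * 2.0**-lfc, disp, (n_down, n)),
            _nb(rng, mean, disp, (n_null, n)),
        ]
    ).astype(float)
    cols = [f"A{i}" for i in range(n)] + [f"B{i}" for i in range(n)]
    return pd.DataFrame(
        np.hstack([a, b]), columns=cols,
        index=[f"f{i}" for i in range(n_feat + n_null)],
    )


def test_size_factors_identity_and_scale():
    col = np.array([10, 200, 3000, 40, 5.0])
    matrix = pd.DataFrame({f"s{i}": col for i in range(4)})
    assert np.allclose(size_factors(matrix), 1.0)
    doubled = matrix.copy()
    doubled["s3"] *= 2
    sf = size_factors(doubled)
    assert sf["s3"] / sf["s0"] == pytest.approx(2.0)
    assert np.exp(np.log(sf).mean()) == pytest.approx(1.0)


def test_size_factors_recover_depth_gradient():
    rng = np.random.default_rng(11)
    mu = np.exp(rng.uniform(np.log(20), np.log(2000), 5000))
    depths = np.array([1.0, 2.0, 4.0])
    cols = {
        f"s{j}": _nb(rng, mu * d, 0.05, 5000) for j, d in enumerate(depths)
    }
    sf = size_factors(pd.DataFrame(cols))
    expected = depths / np.exp(np.log(depths).mean())
    assert np.allclose(sf, expected, rtol=0.05)


def test_size_factors_require_common_nonzero_feature():
    matrix = pd.DataFrame({"s1": [5, 0], "s2": [0, 5]})
    with pytest.raises(DiffExpError, match="pre-filter"):
        size_factors(matrix)


def test_identical_counts_give_zero_lfc():
    # identical columns: normalization is neutral, so a feature with the same
    # count in every sample must come out at exactly zero fold change
    col = np.array([77.0, 10.0, 400.0, 3.0, 1250.0, 60.0])
    matrix = pd.DataFrame(
        {f"{g}{i}": col for g in "AB" for i in range(6)},
        index=[f"f{i}" for i in range(6)],
    )
    records = nb_wald(matrix, _design())
    assert (records["log2fc"] == 0.0).all()
    assert records.loc["f0", "p"] == pytest.approx(1.0)


def test_scale_invariance_of_lfc():
    rng = np.random.default_rng(4)
    matrix = _matrix(rng, 200)
    design = _design()
    base = nb_wald(matrix, design)["log2fc"]
    scaled = matrix.copy()
    scaled["B2"] *= 7.0
    rescaled = nb_wald(scaled, design)["log2fc"]
    assert np.allclose(base, rescaled, atol=1e-9)


def test_contrast_symmetry_negates_lfc():
    rng = np.random.default_rng(5)
    matrix = _matrix(rng, 150, lfc=1.0)
    fwd = nb_wald(matrix, _design())
    rev = nb_wald(matrix, _design(test="A", ref="B"))
    assert np.allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-12)
    assert np.allclose(fwd["p"], rev["p"], atol=1e-12)


def test_low_count_features_flagged_not_tested():
    rng = np.random.default_rng(6)
    matrix = _matrix(rng, 20)
    matrix.iloc[0] = 0.0
    matrix.iloc[0, 0] = 3.0  # total 3 < min_total_count
    records = nb_wald(matrix, _design())
    assert bool(records["filtered"].iloc[0])
    assert np.isnan(records["p"].iloc[0])
    assert not records["filtered"].iloc[1:].any()


@pytest.mark.parametrize("lfc", [0.0, 1.0, 2.0])
@pytest.mark.parametrize("disp", [0.05, 0.2])
def test_lfc_estimates_nearly_unbiased(lfc, disp):
    rng = np.random.default_rng(int(100 * lfc + 1000 * disp))
    matrix = _matrix(rng, 400, mean=500.0, disp=disp, lfc=lfc, n_null=1200)
    records = nb_wald(matrix, _design())
    n_up = 200 if lfc != 0 else 400
    errors = np.concatenate(
        [
            records["log2fc"].iloc[:n_up] - lfc,
            records["log2fc"].iloc[n_up:400] + lfc,
        ]
    )
    assert abs(errors.mean()) < 0.1


def test_call_de_thresholds():
    records = pd.DataFrame(
        {
            "base_mean": [100.0] * 3,
            "log2fc": [1.2, 0.6, 3.0],
            "se": [0.1] * 3,
            "wald": [1.0] * 3,
            "p": [0.049, 0.049, 0.051],
            "padj": [0.1] * 3,
            "filtered": [False] * 3,
        },
        index=["kept_up", "small_lfc", "not_sig"],
    )
    de = call_de(records, DEConfig(alpha=0.05, lfc_min=1.0))
    assert list(de.index) == ["kept_up"]
    assert de.loc["kept_up", "direction"] == "up"
    # with lfc_min=0 the small-effect significant feature is kept too
    assert set(call_de(records, DEConfig(lfc_min=0.0)).index) == {"kept_up", "small_lfc"}


def test_design_validation():
    with pytest.raises(DiffExpError, match=">= 2 samples"):
        Design(groups={"a": "A", "b": "B", "c": "B"}, contrast=("B", "A"))
    with pytest.raises(DiffExpError, match="differ"):
        Design(groups={"a": "A", "b": "A"}, contrast=("A", "A"))
    design = _design()
    rng = np.random.default_rng(8)
    matrix = _matrix(rng, 10).drop(columns=["B0"])
    with pytest.raises(DiffExpError, match="missing"):
        nb_wald(matrix, design)
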