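"""Classical psychometrics: alpha, chi-square endorsement, rotated MCA."""

import numpy as np
import pandas as pd
import pytest

from epicesdif import (ResponseMatrix, chi2_endorsement, contribution_table,
                       cronbach_alpha, mca_fit, rotate_mca)


def _matrix(df, groups=None):
    g = pd.DataFrame({"g": groups if groups is not None else ["x"] * len(df)},
                     index=df.index)
    return ResponseMatrix(df.astype(np.int8), g)


class TestAlpha:
    def test_two_item_spearman_brown_identity(self):
        # equal-variance pair with Pearson r = 1/3: alpha = 2r/(1+r) = 0.5
        df = pd.DataFrame({"x": [1, 1, 1, 0, 0, 0], "y": [1, 1, 0, 0, 0, 1]})
        r = df["x"].corr(df["y"])
        assert r == pytest.approx(1 / 3)
        assert cronbach_alpha(df) == pytest.approx(2 * r / (1 + r), abs=1e-10)

    def test_duplicated_item_gives_one(self):
        df = pd.DataFrame({"x": [1, 0, 1, 0, 1], "y": [1, 0, 1, 0, 1]})
        assert cronbach_alpha(df) == pytest.approx(1.0, abs=1e-12)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(14)
        df = pd.DataFrame(rng.integers(0, 2, size=(4000, 10)))
        df.columns = [f"i{j}" for j in range(10)]
        assert abs(cronbach_alpha(df)) < 0.1

    def test_full_and_reduced_sets_differ(self, preset_full):
        m, _ = preset_full
        a11 = cronbach_alpha(m)
        a10 = cronbach_alpha(m, items=m.item_labels[:-1])
        assert a11 != pytest.approx(a10, abs=1e-6)

    def test_needs_two_items_and_variance(self):
        with pytest.raises(ValueError):
            cronbach_alpha(pd.DataFrame({"x": [0, 1]}))
        with pytest.raises(ValueError):
            cronbach_alpha(pd.DataFrame({"x": [1, 1], "y": [0, 0]}))


class TestChi2:
    def test_hand_computed_2x2(self):
        # group A: 20 yes / 80 no; group B: 40 yes / 60 no -> chi2 = 9.5238
        col = [1] * 20 + [0] * 80 + [1] * 40 + [0] * 60
        other = ([0, 1] * 50) + ([1, 0] * 50)
        df = pd.DataFrame({"q": col, "p": other})
        m = _matrix(df, ["A"] * 100 + ["B"] * 100)
        res = chi2_endorsement(m, "g")
        assert res.loc["q", "chi2"] == pytest.approx(200 * (20 * 60 - 80 * 40) ** 2
                                                     / (100 * 100 * 60 * 140), abs=1e-9)
        assert res.loc["q", "chi2"] == pytest.approx(9.5238, abs=1e-4)
        assert bool(res.loc["q", "significant"])

    def test_identical_proportions_not_flagged(self):
        col = ([1] * 30 + [0] * 70) * 2
        other = [0, 1] * 100
        m = _matrix(pd.DataFrame({"q": col, "p": other}),
                    ["A"] * 100 + ["B"] * 100)
        res = chi2_endorsement(m, "g")
        assert res.loc["q", "p"] == pytest.approx(1.0)
        assert not bool(res.loc["q", "significant"])

    def test_continuity_correction_toggle(self):
        col = [1] * 20 + [0] * 80 + [1] * 40 + [0] * 60
        other = ([0, 1] * 50) + ([1, 0] * 50)
        m = _matrix(pd.DataFrame({"q": col, "p": other}),
                    ["A"] * 100 + ["B"] * 100)
        plain = chi2_endorsement(m, "g").loc["q", "chi2"]
        yates = chi2_endorsement(m, "g", correction=True).loc["q", "chi2"]
        assert yates < plain

    def test_empty_cell_is_an_error(self):
        df = pd.DataFrame({"q": [1] * 50 + [0] * 25 + [1] * 25, "p": [0, 1] * 50})
        m = _matrix(df, ["A"] * 50 + ["B"] * 50)  # group A all-yes on q
        with pytest.raises(ValueError):
            chi2_endorsement(m, "g")


@pytest.fixture(scope="module")
def block_cohort():
    """Two independent 4-item blocks, each driven by its own latent factor."""
    rng = np.random.default_rng(23)
    n = 1200
    u, v = rng.normal(size=n), rng.normal(size=n)
    cols = {}
    for j in range(4):
        cols[f"u{j}"] = (rng.random(n) < 1 / (1 + np.exp(-(1.8 * u + 0.3 * j)))).astype(int)
    for j in range(4):
        cols[f"v{j}"] = (rng.random(n) < 1 / (1 + np.exp(-(1.8 * v - 0.3 * j)))).astype(int)
    return _matrix(pd.DataFrame(cols))


class TestMCA:
    def test_eigenvalue_sum_equals_total_inertia(self, block_cohort):
        res = mca_fit(block_cohort, n_keep=4)
        # direct computation from the indicator matrix residuals
        df = block_cohort.responses
        Z = np.column_stack([(df[c] == v).astype(float)
                             for c in df.columns for v in (0, 1)])
        N = Z.sum()
        P = Z / N
        r, c = P.sum(1), P.sum(0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        assert res.eigenvalues.sum() == pytest.approx((S ** 2).sum(), abs=1e-8)
        # all-binary items: total inertia = K/J - 1 = 1
        assert res.total_inertia == pytest.approx(1.0, abs=1e-8)

    def test_pct_variance_descending(self, block_cohort):
        res = mca_fit(block_cohort, n_keep=4)
        assert (np.diff(res.pct_variance) <= 1e-9).all()
        assert res.pct_variance.sum() == pytest.approx(100.0)

    def test_blocks_separate_on_leading_dimensions(self, block_cohort):
        res = rotate_mca(mca_fit(block_cohort, n_keep=2))
        _, full = contribution_table(res)
        for dim in full.columns:
            top = full[dim].sort_values(ascending=False).index[:3]
            prefixes = {t[0] for t in top}
            assert len(prefixes) == 1, f"{dim} mixes blocks: {list(top)}"
        # the two dimensions pick up different blocks
        lead = {full[dim].idxmax()[0] for dim in full.columns}
        assert lead == {"u", "v"}

    def test_constant_item_rejected(self):
        df = pd.DataFrame({"a": [0, 1] * 30, "b": [1] * 60})
        with pytest.raises(ValueError):
            mca_fit(_matrix(df))

    def test_needs_enough_respondents(self):
        df = pd.DataFrame({"a": [0, 1] * 3, "b": [1, 0] * 3, "c": [0, 0, 1] * 2})
        with pytest.raises(ValueError):
            mca_fit(_matrix(df))


class TestRotation:
    def test_block_variance_conserved(self, block_cohort):
        res = mca_fit(block_cohort, n_keep=4)
        rot = rotate_mca(res)
        assert rot.retained_variance.sum() == pytest.approx(
            res.retained_variance.sum(), abs=1e-10)
        assert rot.pct_variance[:4].sum() == pytest.approx(
            res.pct_variance[:4].sum(), abs=1e-8)

    def test_simple_structure_is_a_fixed_point(self):
        """Loadings already concentrated one-item-per-dimension rotate (at
        most) by sign/permutation."""
        L = np.zeros((8, 2))
        L[:4, 0] = [0.5, 0.45, 0.4, 0.35]
        L[4:, 1] = [0.5, 0.45, 0.4, 0.35]
        from epicesdif.psych import MCAResult
        cats = [f"c{i}" for i in range(8)]
        lam = (L ** 2).sum(0)
        res = MCAResult(
            eigenvalues=lam, pct_variance=100 * lam / lam.sum(),
            loadings=pd.DataFrame(L, index=cats, columns=["dim1", "dim2"]),
            category_contributions=pd.DataFrame(L ** 2 / lam, index=cats,
                                                columns=["dim1", "dim2"]),
            category_coords=pd.DataFrame(L, index=cats, columns=["dim1", "dim2"]),
            category_masses=pd.Series(np.full(8, 1 / 8), index=cats),
            item_of_category={c: c for c in cats},
            total_inertia=float(lam.sum()), n_keep=2)
        rot = rotate_mca(res)
        # rotation may permute equal-variance dimensions; each rotated
        # column must match some original column up to sign
        R = np.abs(rot.loadings.to_numpy())
        for s in range(R.shape[1]):
            assert any(np.allclose(R[:, s], np.abs(L[:, t]), atol=1e-6)
                       for t in range(L.shape[1])), s

    def test_rotation_sharpens_contributions(self, block_cohort):
        res = mca_fit(block_cohort, n_keep=4)
        rot = rotate_mca(res)
        _, before = contribution_table(res)
        _, after = contribution_table(rot)
        assert after.max().max() >= before.max().max() - 1e-9

    def test_single_dimension_rejected(self, block_cohort):
        res = mca_fit(block_cohort, n_keep=2)
        import dataclasses as dc
        res1 = dc.replace(res, n_keep=1,
                          loadings=res.loadings.iloc[:, :1],
                          category_contributions=res.category_contributions.iloc[:, :1])
        with pytest.raises(ValueError):
            rotate_mca(res1)


class TestContributionTable:
    def test_item_contributions_sum_to_one(self, block_cohort):
        res = rotate_mca(mca_fit(block_cohort, n_keep=3))
        _, full = contribution_table(res)
        assert np.allclose(full.sum(axis=0), 1.0, atol=1e-10)

    def test_display_blanks_below_threshold_but_full_kept(self, block_cohort):
        res = rotate_mca(mca_fit(block_cohort, n_keep=2))
        display, full = contribution_table(res, display_threshold=2.0)
        body = display.drop(index="% of variance")
        assert (body == "").all().all()          # nothing reaches an impossible bar
        assert (full > 0).any().any()            # machine output intact
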