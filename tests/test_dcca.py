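"""dc-CA eigen-structure against closed forms, brute force and vegan's CCA;
max-test mechanics."""

import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest

from traitshift.dcca import DCCA, max_test, prepare_relative_abundance, term_screen


def random_tables(rng, n=12, s=8, p=1, q=1):
    Y = pd.DataFrame(
        rng.integers(1, 20, (n, s)).astype(float),
        index=[f"p{i}" for i in range(n)],
        columns=[f"s{j}" for j in range(s)],
    )
    T = pd.DataFrame(rng.normal(size=(s, q)), index=Y.columns, columns=[f"t{k}" for k in range(q)])
    E = pd.DataFrame(rng.normal(size=(n, p)), index=Y.index, columns=[f"e{k}" for k in range(p)])
    return Y, T, E


def fourth_corner(Y, e, t):
    """Weighted fourth-corner correlation of two single composites, from scratch."""
    ynorm, r, c = prepare_relative_abundance(Y)
    P = ynorm.to_numpy() / ynorm.to_numpy().sum()
    e = e - r @ e
    t = t - c @ t
    e = e / np.sqrt(r @ (e * e))
    t = t / np.sqrt(c @ (t * t))
    return float((P * np.outer(e, t)).sum())


class TestPrepare:
    def test_rows_sum_to_one(self, rng):
        Y, *_ = random_tables(rng)
        ynorm, r, c = prepare_relative_abundance(Y)
        assert np.allclose(ynorm.sum(axis=1), 1.0, atol=1e-12)

    def test_plot_size_invariance(self, rng):
        Y, *_ = random_tables(rng)
        scaled = Y.copy()
        scaled.iloc[0] *= 10
        a, _, ca = prepare_relative_abundance(Y)
        b, _, cb = prepare_relative_abundance(scaled)
        pd.testing.assert_frame_equal(a, b)
        assert np.allclose(ca, cb)

    def test_weights_match_marginals(self, rng):
        Y, *_ = random_tables(rng)
        ynorm, r, c = prepare_relative_abundance(Y)
        assert np.allclose(c, ynorm.to_numpy().sum(axis=0) / len(Y))
        assert np.allclose(r, 1.0 / len(Y))

    def test_empty_plot_is_named_error(self, rng):
        Y, *_ = random_tables(rng)
        Y.iloc[2] = 0
        with pytest.raises(ValueError, match="p2"):
            prepare_relative_abundance(Y)


class TestEigenstructure:
    def test_single_pair_closed_form(self, rng):
        for _ in range(5):
            Y, T, E = random_tables(rng)
            m = DCCA(n_axes=1).fit(Y, T, E)
            r4 = fourth_corner(Y, E.iloc[:, 0].to_numpy(), T.iloc[:, 0].to_numpy())
            assert m.eigenvalues_[0] == pytest.approx(r4**2, abs=1e-8)

    def test_eigenvalues_bounded_and_sorted(self, rng):
        Y, T, E = random_tables(rng, n=20, s=12, p=3, q=3)
        m = DCCA(n_axes=3).fit(Y, T, E)
        ev = m.eigenvalues_
        assert ((ev >= -1e-12) & (ev <= 1 + 1e-12)).all()
        assert (np.diff(ev) <= 1e-12).all()

    def test_brute_force_grid_agreement(self, rng):
        Y, T, E = random_tables(rng, n=10, s=7, p=2, q=2)
        m = DCCA(n_axes=1).fit(Y, T, E)
        angles = np.linspace(0, np.pi, 721)
        best = 0.0
        for th in angles:
            e = E.to_numpy() @ np.array([np.cos(th), np.sin(th)])
            for ph in angles[::4]:
                t = T.to_numpy() @ np.array([np.cos(ph), np.sin(ph)])
                best = max(best, fourth_corner(Y, e, t) ** 2)
        assert m.eigenvalues_[0] == pytest.approx(best, abs=1e-3)

    def test_axes_orthogonal_in_weighted_metric(self, rng):
        Y, T, E = random_tables(rng, n=25, s=15, p=4, q=3)
        m = DCCA(n_axes=3).fit(Y, T, E)
        _, r, c = prepare_relative_abundance(Y)
        site = m.result_.site_scores.to_numpy()
        gram = site.T @ (r[:, None] * site)
        assert np.allclose(gram, np.eye(3), atol=1e-10)

    def test_planted_axis_recovered(self, rng):
        n, s = 40, 30
        t = rng.normal(size=s)
        e = rng.normal(size=n)
        lam = np.exp(rng.normal(0, 1, s) + 1.2 * np.outer(e, t))
        Y = pd.DataFrame(
            rng.poisson(40 * lam / lam.sum(1, keepdims=True)),
            index=[f"p{i}" for i in range(n)], columns=[f"s{j}" for j in range(s)],
        )
        Y = Y.loc[Y.sum(1) > 0, Y.sum(0) > 0]
        T = pd.DataFrame({"signal": t[:, None][[int(c[1:]) for c in Y.columns], 0],
                          "noise": rng.normal(size=Y.shape[1])}, index=Y.columns)
        E = pd.DataFrame({"signal": e[[int(p[1:]) for p in Y.index]],
                          "noise": rng.normal(size=Y.shape[0])}, index=Y.index)
        m = DCCA(n_axes=1).fit(Y, T, E)
        assert abs(m.result_.trait_correlations.loc["signal", "axis1"]) > 0.95
        assert abs(m.result_.predictor_correlations.loc["signal", "axis1"]) > 0.95

    def test_collinear_traits_named_error(self, rng):
        Y, T, E = random_tables(rng, q=2)
        T["t1"] = 2 * T["t0"]
        with pytest.raises(ValueError, match="collinear"):
            DCCA().fit(Y, T, E)

    def test_unconstrained_species_side_matches_vegan_cca(self, rng):
        """With a full-rank species indicator basis the trait constraint is not
        binding, so dc-CA reduces to plain CCA — checked against vegan."""
        Y, _, E = random_tables(rng, n=10, s=6, p=2)
        T = pd.DataFrame(np.eye(6)[:, :5], index=Y.columns)
        ours = DCCA(n_axes=2).fit(Y, T, E).eigenvalues_
        ynorm, *_ = prepare_relative_abundance(Y)
        with tempfile.TemporaryDirectory() as td:
            ynorm.to_csv(f"{td}/y.csv")
            E.to_csv(f"{td}/e.csv")
            res = subprocess.run(
                ["Rscript", "-e",
                 f'suppressMessages(library(vegan));'
                 f'y<-read.csv("{td}/y.csv",row.names=1);'
                 f'e<-read.csv("{td}/e.csv",row.names=1);'
                 f'cat(cca(y~e0+e1,data=e)$CCA$eig)'],
                capture_output=True, text=True, timeout=120,
            )
        assert res.returncode == 0, res.stderr
        vegan = np.array([float(v) for v in res.stdout.split()])
        assert np.allclose(ours, vegan[:2], atol=1e-6)


class TestMaxTest:
    def test_planted_association_saturates(self, rng):
        n, s = 30, 20
        t = rng.normal(size=s)
        e = rng.normal(size=n)
        lam = np.exp(rng.normal(0, 0.5, s) + 1.5 * np.outer(e, t))
        Y = pd.DataFrame(rng.poisson(60 * lam / lam.sum(1, keepdims=True)) + 1,
                         index=[f"p{i}" for i in range(n)], columns=[f"s{j}" for j in range(s)])
        T = pd.DataFrame({"t": t}, index=Y.columns)
        E = pd.DataFrame({"e": e}, index=Y.index)
        res = max_test(Y, T, E, n_perm=99, rng=rng)
        assert res["p_max"] == pytest.approx(1 / 100)

    def test_p_max_bounds_components(self, rng):
        Y, T, E = random_tables(rng, n=15, s=10)
        res = max_test(Y, T, E, n_perm=49, rng=rng)
        assert res["p_max"] >= res["p_community"]
        assert res["p_max"] >= res["p_species"]

    def test_stratified_permutation_controls_group_confounding(self, rng):
        """Association driven purely by a two-stratum covariate should not be
        declared significant when permutations respect the strata."""
        hits = 0
        for s in range(20):
            r = np.random.default_rng(400 + s)
            n, sp = 30, 24
            strata = np.repeat(["a", "b"], n // 2)
            t = r.normal(size=sp)
            shift = np.where(strata == "a", 1.0, -1.0)
            lam = np.exp(r.normal(0, 0.5, sp) + 1.0 * np.outer(shift, t))
            Y = pd.DataFrame(r.poisson(50 * lam / lam.sum(1, keepdims=True)) + 1,
                             index=[f"p{i}" for i in range(n)], columns=[f"s{j}" for j in range(sp)])
            T = pd.DataFrame({"t": t}, index=Y.columns)
            E = pd.DataFrame({"e": shift + 0.3 * r.normal(size=n)}, index=Y.index)
            cov = pd.DataFrame({"grp": (strata == "a").astype(float)}, index=Y.index)
            res = max_test(Y, T, E, covariates=cov, strata=pd.Series(strata, index=Y.index),
                           n_perm=99, rng=r)
            hits += res["p_max"] <= 0.05
        assert hits <= 2  # non-significant in >= 90% of runs

    def test_tiny_permutation_count_rejected(self, rng):
        Y, T, E = random_tables(rng)
        with pytest.raises(ValueError):
            max_test(Y, T, E, n_perm=5, rng=rng)


class TestTermScreen:
    def test_bonferroni_and_duplicate_terms(self, rng):
        Y, T, E = random_tables(rng, n=20, s=12)
        E2 = E.rename(columns={"e0": "dup"})
        screen = term_screen(
            Y, T, {"e": E, "e_again": E2},
            sequential={"e_again": ["e"]},
            n_perm=49, rng=rng,
        )
        assert np.allclose(screen["p_adj"], np.minimum(1.0, screen["p_max"] * 2))
        dup = screen.set_index("term").loc["e_again"]
        assert dup["eigenvalue"] == pytest.approx(0.0, abs=1e-9)
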