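import numpy as np
import pytest

from diallel.data_model import DiallelTable, from_records
from diallel.errors import DesignTooSmallError, DiallelError
from diallel.griffing import (
    ContrastKind,
    estimate_effects,
    gca_variance,
    lsd_effect_contrast,
    partition_genotype_ss,
    sca_variance,
)
from diallel.anova import rcbd_anova

from conftest import make_plot_frame, random_diallel_table


def constrained_ls_oracle(means):
    """Independent oracle: minimize sum (x_ij - u - g_i - g_j - s_ij)^2 over
    distinct entries subject to sum(g) = 0 and, for each i,
    sum_j s_ij + s_ii = 0, via the KKT system of the equality-constrained
    least-squares problem."""
    p = means.shape[0]
    entries = [(i, j) for i in range(p) for j in range(i, p)]
    n = len(entries)
    n_par = 1 + p + n  # u, g, s
    X = np.zeros((n, n_par))
    y = np.zeros(n)
    s_index = {e: 1 + p + k for k, e in enumerate(entries)}
    for row, (i, j) in enumerate(entries):
        X[row, 0] = 1.0
        X[row, 1 + i] += 1.0
        X[row, 1 + j] += 1.0
        X[row, s_index[(i, j)]] = 1.0
        y[row] = means[i, j]
    C = np.zeros((1 + p, n_par))
    C[0, 1 : 1 + p] = 1.0  # sum g = 0
    for i in range(p):
        for j in range(p):
            C[1 + i, s_index[(min(i, j), max(i, j))]] += 1.0
        C[1 + i, s_index[(i, i)]] += 1.0  # diagonal counted twice
    kkt = np.block([[X.T @ X, C.T], [C, np.zeros((C.shape[0], C.shape[0]))]])
    rhs = np.concatenate([X.T @ y, np.zeros(C.shape[0])])
    sol = np.linalg.solve(kkt, rhs)[:n_par]
    u = sol[0]
    g = sol[1 : 1 + p]
    s = np.zeros((p, p))
    for (i, j), k in s_index.items():
        s[i, j] = s[j, i] = sol[k]
    return u, g, s


class TestEstimateEffects:
    def test_additive_toy(self):
        a = np.array([1.0, 0.0, -1.0])
        means = 10.0 + a[:, None] + a[None, :]
        table = DiallelTable(p=3, trait="y", environment="e", means=means)
        eff = estimate_effects(table)
        assert eff.mu_hat == pytest.approx(10.0, abs=1e-12)
        assert eff.gca == pytest.approx(a, abs=1e-12)
        assert np.allclose(eff.sca, 0.0, atol=1e-12)

    def test_constant_table(self):
        table = DiallelTable(p=5, trait="y", environment="e", means=np.full((5, 5), 7.5))
        eff = estimate_effects(table)
        assert eff.mu_hat == pytest.approx(7.5)
        assert np.allclose(eff.gca, 0.0, atol=1e-12)
        assert np.allclose(eff.sca, 0.0, atol=1e-12)

    @pytest.mark.parametrize("p,seed", [(3, 0), (4, 1), (5, 2), (6, 3), (4, 99)])
    def test_matches_constrained_ls_oracle(self, p, seed):
        table = random_diallel_table(p, seed)
        eff = estimate_effects(table)
        u, g, s = constrained_ls_oracle(table.means)
        assert eff.mu_hat == pytest.approx(u, abs=1e-9)
        assert eff.gca == pytest.approx(g, abs=1e-9)
        assert eff.sca == pytest.approx(s, abs=1e-9)

    def test_oracle_equivalence_many_random_tables(self):
        # acceptance criterion 2: 100 random tables across p in 3..6
        for k in range(100):
            p = 3 + k % 4
            table = random_diallel_table(p, seed=1000 + k)
            eff = estimate_effects(table)
            u, g, s = constrained_ls_oracle(table.means)
            np.testing.assert_allclose(eff.mu_hat, u, atol=1e-9)
            np.testing.assert_allclose(eff.gca, g, atol=1e-9)
            np.testing.assert_allclose(eff.sca, s, atol=1e-9)

    def test_invariants(self):
        table = random_diallel_table(6, seed=5)
        eff = estimate_effects(table)
        assert abs(eff.gca.sum()) < 1e-9
        np.testing.assert_allclose(eff.reconstruct(), table.means, atol=1e-9)

    def test_permutation_equivariance(self):
        table = random_diallel_table(5, seed=8)
        perm = np.array([2, 0, 4, 1, 3])
        permuted = DiallelTable(
            p=5, trait="y", environment="e", means=table.means[np.ix_(perm, perm)]
        )
        eff = estimate_effects(table)
        eff_p = estimate_effects(permuted)
        np.testing.assert_allclose(eff_p.gca, eff.gca[perm], atol=1e-10)
        np.testing.assert_allclose(eff_p.sca, eff.sca[np.ix_(perm, perm)], atol=1e-10)

    def test_too_small(self):
        table = DiallelTable(p=2, trait="y", environment="e", means=np.zeros((2, 2)))
        with pytest.raises(DesignTooSmallError):
            estimate_effects(table)

    def test_stars_attached_with_ms_error(self):
        table = random_diallel_table(5, seed=3)
        eff = estimate_effects(table, ms_error=4.0, r=2, df_error=20)
        assert eff.se_gca == pytest.approx(np.sqrt(gca_variance(5, 2.0)))
        assert eff.se_sca_hybrid == pytest.approx(np.sqrt(sca_variance(5, 2.0)))
        assert len(eff.star_gca) == 5
        assert eff.star_sca.shape == (5, 5)
        assert set(np.unique(eff.star_sca)) <= {"ns", "*", "**"}


class TestEffectVariances:
    @pytest.mark.parametrize("p", [4, 5, 11])
    def test_single_effect_variances_match_projection(self, p):
        # independent oracle: propagate unit entry variance through the
        # closed-form linear maps of the effects
        entries = [(i, j) for i in range(p) for j in range(i, p)]
        idx = {e: k for k, e in enumerate(entries)}

        def rowsum(i):
            c = np.zeros(len(entries))
            for j in range(p):
                c[idx[(min(i, j), max(i, j))]] += 1
            return c

        tot = np.ones(len(entries))
        g0 = (rowsum(0) + _unit(idx, 0, 0, len(entries)) - tot * 2 / p) / (p + 2)
        assert (g0**2).sum() == pytest.approx(gca_variance(p, 1.0), abs=1e-12)
        s01 = (
            _unit(idx, 0, 1, len(entries))
            - (rowsum(0) + rowsum(1) + _unit(idx, 0, 0, len(entries)) + _unit(idx, 1, 1, len(entries)))
            / (p + 2)
            + tot * 2 / ((p + 1) * (p + 2))
        )
        assert (s01**2).sum() == pytest.approx(sca_variance(p, 1.0), abs=1e-12)


def _unit(idx, i, j, n):
    c = np.zeros(n)
    c[idx[(i, j)]] = 1.0
    return c


class TestPartitionGenotypeSS:
    def test_additive_data_no_sca(self):
        a = {1: 2.0, 2: 0.0, 3: -1.0, 4: -1.0}
        df = make_plot_frame(
            4, ["e1"], ["r1", "r2"], ["y"],
            lambda env, rep, i, j, t: 20.0 + a[i] + a[j],
        )
        ss_gca, ss_sca, df_gca, df_sca = partition_genotype_ss(
            from_records(df), "e1", "y"
        )
        assert ss_sca == pytest.approx(0.0, abs=1e-9)
        assert ss_gca > 0
        assert (df_gca, df_sca) == (3, 6)

    def test_constant_data(self):
        df = make_plot_frame(4, ["e1"], ["r1", "r2"], ["y"], lambda *a: 5.0)
        ss_gca, ss_sca, *_ = partition_genotype_ss(from_records(df), "e1", "y")
        assert ss_gca == pytest.approx(0.0, abs=1e-12)
        assert ss_sca == pytest.approx(0.0, abs=1e-12)

    def test_sums_to_genotype_ss(self):
        rng = np.random.default_rng(21)
        df = make_plot_frame(
            5, ["e1"], ["r1", "r2"], ["y"],
            lambda env, rep, i, j, t: float(rng.normal(30, 4)),
        )
        plots = from_records(df)
        ss_gca, ss_sca, *_ = partition_genotype_ss(plots, "e1", "y")
        # independent oracle: one-way by-entries decomposition
        sub = plots.df
        grand = sub["value"].mean()
        ent = sub.groupby(["parent_a", "parent_b"])["value"]
        ss_gen_oracle = (ent.count() * (ent.mean() - grand) ** 2).sum()
        assert ss_gca + ss_sca == pytest.approx(ss_gen_oracle, rel=1e-8)
        an = rcbd_anova(plots, "e1", "y")
        assert ss_gca + ss_sca == pytest.approx(an["genotype"].ss, rel=1e-8)
        assert ss_gca >= 0 and ss_sca >= 0


class TestLSDEffectContrast:
    # published values from the 11-parent trial: MS_error = 19.54 (yield,
    # non-saline), r = 2, df = 65
    @pytest.mark.parametrize(
        "kind,expected",
        [
            (ContrastKind.GCA_PAIR, 2.45),
            (ContrastKind.SCA_HALFSIB, 8.48),
            (ContrastKind.SCA_DISJOINT, 8.12),
        ],
    )
    def test_published_values(self, kind, expected):
        lsd = lsd_effect_contrast(kind, ms_error=19.54, r=2, p=11, df_error=65, alpha=0.05)
        assert round(lsd.value, 2) == expected

    def test_accepts_string_kind(self):
        lsd = lsd_effect_contrast("gca_pair", 19.54, 2, 11, 65)
        assert round(lsd.value, 2) == 2.45

    def test_positive_and_label_invariant(self):
        lsd = lsd_effect_contrast("sca_disjoint", 3.0, 3, 7, 40, alpha=0.10)
        assert lsd.value > 0

    def test_nonpositive_ms_error(self):
        with pytest.raises(DiallelError):
            lsd_effect_contrast("gca_pair", 0.0, 2, 11, 65)

    def test_bad_alpha(self):
        with pytest.raises(DiallelError):
            lsd_effect_contrast("gca_pair", 1.0, 2, 11, 65, alpha=1.5)
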