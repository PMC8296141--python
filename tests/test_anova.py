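"""Lattice ANOVA against a statsmodels type-I oracle; derived parameters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from strigascreen import anova
from strigascreen.simulate import TrialSimParams, simulate_trial


def projection_oracle(df, trait, model):
    """Brute-force normal-equations oracle for sequential sums of squares.

    Builds each cumulative design explicitly, forms the hat matrix through
    the pseudo-inverse and reads SS off the projection differences, so it is
    independent of the incremental least-squares path under test.
    """
    from scipy.linalg import pinv

    d = df.dropna(subset=[trait]).copy()
    y = d[trait].to_numpy(float)
    groups = [("Reps", d["replicate"].astype(str))]
    if model == "lattice":
        groups.append(
            ("Blocks(Reps)", d["replicate"].astype(str) + "/" + d["block"].astype(str))
        )
    groups.append(("Genotype", d["genotype_id"].astype(str)))
    X = np.ones((len(y), 1))
    P_prev = X @ pinv(X)
    rows = {}
    for name, fac in groups:
        X = np.column_stack([X, pd.get_dummies(fac).to_numpy(float)])
        P = X @ pinv(X)
        rows[name] = (round(np.trace(P - P_prev)), float(y @ (P - P_prev) @ y))
        P_prev = P
    resid = np.eye(len(y)) - P_prev
    rows["Residual"] = (round(np.trace(resid)), float(y @ resid @ y))
    return rows


def sm_type1_oracle(df, trait, model):
    """Independent sequential-SS oracle via statsmodels OLS + anova_lm."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    d = df.dropna(subset=[trait]).copy()
    d["blk"] = d["replicate"].astype(str) + "/" + d["block"].astype(str)
    rhs = "C(replicate)"
    if model == "lattice":
        rhs += " + C(blk)"
    rhs += " + C(genotype_id)"
    fit = ols(f"{trait} ~ {rhs}", data=d).fit()
    return sm.stats.anova_lm(fit, typ=1)


def random_design(rng, n_geno=5, n_reps=3, unbalanced=False):
    params = TrialSimParams(
        n_genotypes=n_geno,
        n_reps=n_reps,
        block_size=n_geno,
        trait_means={"Y": 5.0},
        sigma2_g={"Y": 1.0},
        sigma2_e={"Y": 0.5},
        seed=int(rng.integers(2**31)),
    )
    df = simulate_trial(params)
    if unbalanced:
        drop = rng.choice(df.index, size=rng.integers(1, 3), replace=False)
        df = df.drop(index=drop)
    return df


@pytest.mark.parametrize("unbalanced", [False, True])
def test_fit_anova_matches_statsmodels_oracle(unbalanced):
    rng = np.random.default_rng(11)
    for _ in range(20):
        df = random_design(rng, unbalanced=unbalanced)
        table = anova.fit_anova(df, "Y", model="rcbd")
        oracle = sm_type1_oracle(df, "Y", "rcbd")
        assert table.loc["Reps", "sum_sq"] == pytest.approx(
            oracle.loc["C(replicate)", "sum_sq"], abs=1e-9
        )
        assert table.loc["Genotype", "sum_sq"] == pytest.approx(
            oracle.loc["C(genotype_id)", "sum_sq"], abs=1e-9
        )
        assert table.loc["Residual", "sum_sq"] == pytest.approx(
            oracle.loc["Residual", "sum_sq"], abs=1e-9
        )
        assert table.loc["Genotype", "df"] == oracle.loc["C(genotype_id)", "df"]


def test_lattice_anova_matches_projection_oracle(balanced_trial):
    table = anova.fit_anova(balanced_trial, "Y", model="lattice")
    oracle = projection_oracle(balanced_trial, "Y", "lattice")
    for src in ("Reps", "Blocks(Reps)", "Genotype", "Residual"):
        df_o, ss_o = oracle[src]
        assert table.loc[src, "sum_sq"] == pytest.approx(ss_o, abs=1e-9)
        assert table.loc[src, "df"] == df_o
    # F and p against the residual mean square
    fg = table.loc["Genotype", "mean_sq"] / table.loc["Residual", "mean_sq"]
    assert table.loc["Genotype", "F"] == pytest.approx(fg)
    assert table.loc["Genotype", "p"] == pytest.approx(
        stats.f.sf(fg, table.loc["Genotype", "df"], table.loc["Residual", "df"])
    )


def test_all_equal_observations_give_zero_ss(balanced_trial):
    df = balanced_trial.assign(Y=3.0)
    table = anova.fit_anova(df, "Y", model="lattice")
    assert table["sum_sq"].abs().max() < 1e-18


def test_rcbd_and_lattice_agree_when_blocks_are_complete():
    rng = np.random.default_rng(5)
    df = random_design(rng)  # block_size == n_genotypes: one block per rep
    a = anova.fit_anova(df, "Y", model="rcbd")
    b = anova.fit_anova(df, "Y", model="lattice")
    assert b.loc["Blocks(Reps)", "sum_sq"] == pytest.approx(0.0, abs=1e-9)
    assert b.loc["Blocks(Reps)", "df"] == 0
    for src in ("Reps", "Genotype", "Residual"):
        assert a.loc[src, "sum_sq"] == pytest.approx(b.loc[src, "sum_sq"], abs=1e-9)


def test_partition_components_sum_to_genotype_ss(balanced_trial):
    genos = sorted(balanced_trial["genotype_id"].unique())
    parents, progenies = genos[:3], genos[3:]
    full = anova.fit_anova(balanced_trial, "Y", model="lattice")
    part = anova.partition_genotype_ss(balanced_trial, "Y", parents, progenies)
    total = part.drop(index="Residual")["sum_sq"].sum()
    assert total == pytest.approx(full.loc["Genotype", "sum_sq"], abs=1e-9)
    dfs = part.drop(index="Residual")["df"].sum()
    assert dfs == full.loc["Genotype", "df"]


def test_partition_pure_group_effect(balanced_trial):
    genos = sorted(balanced_trial["genotype_id"].unique())
    parents, progenies = genos[:3], genos[3:]
    df = balanced_trial.copy()
    df["Y"] = np.where(df["genotype_id"].isin(parents), 1.0, 5.0)
    part = anova.partition_genotype_ss(df, "Y", parents, progenies)
    assert part.loc["Parents (Par)", "sum_sq"] == pytest.approx(0.0, abs=1e-18)
    assert part.loc["Progenies (Pro)", "sum_sq"] == pytest.approx(0.0, abs=1e-18)
    assert part.loc["Par vs Pro", "sum_sq"] > 0


def test_partition_rejects_overlap_and_flags_single_parent(balanced_trial):
    genos = sorted(balanced_trial["genotype_id"].unique())
    with pytest.raises(ValueError, match="overlap"):
        anova.partition_genotype_ss(balanced_trial, "Y", genos[:3], genos[2:])
    part = anova.partition_genotype_ss(balanced_trial, "Y", genos[:1], genos[1:])
    assert part.loc["Parents (Par)", "df"] == 0
    assert "Parents (Par)" in part.attrs["zero_df_components"]


def test_combined_anova_environment_row(balanced_trial):
    pot = balanced_trial.assign(environment="pot")
    same = anova.combined_environment_anova(balanced_trial, pot, "Y")
    assert same.loc["Environment", "sum_sq"] == pytest.approx(0.0, abs=1e-18)

    delta = 2.5
    pot_off = pot.assign(Y=pot["Y"] + delta)
    table = anova.combined_environment_anova(balanced_trial, pot_off, "Y")
    n_env = len(balanced_trial)  # balanced: equal plots per environment
    assert table.loc["Environment", "sum_sq"] == pytest.approx(
        n_env * delta**2 / 2.0, rel=1e-12
    )
    # pooled residual df is the sum of per-environment residual dfs
    per_env = anova.fit_anova(balanced_trial, "Y").loc["Residual", "df"]
    assert table.loc["Residual", "df"] == 2 * per_env
    # total df bookkeeping: full decomposition spans N - 1
    assert table["df"].sum() == 2 * len(balanced_trial) - 1


def test_variance_components_from_printed_mean_squares():
    # field-trial 100-grain-weight mean squares: MSg 2.34, MSe 0.75, r 3
    s2g, s2e, s2p, clamped = anova.variance_components(2.34, 0.75, 3)
    assert s2g == pytest.approx(0.53, abs=1e-12)
    assert s2p == pytest.approx(1.28, abs=1e-12)
    assert not clamped
    h2, cls = anova.heritability(s2g, s2p)
    assert h2 == pytest.approx(41.40625, abs=1e-9)
    assert cls == "moderate"


def test_variance_components_clamping():
    s2g, _, s2p, clamped = anova.variance_components(0.5, 0.75, 3)
    assert s2g == 0.0 and clamped
    assert s2p == pytest.approx(0.75)
    assert anova.variance_components(0.75, 0.75, 3)[0] == 0.0


def test_gcv_pcv_values_and_scale_invariance(balanced_trial):
    gcv, pcv = anova.gcv_pcv(4.0, 5.0, 10.0)
    assert gcv == pytest.approx(20.0)
    assert pcv == pytest.approx(100 * np.sqrt(5) / 10)
    assert anova.gcv_pcv(0.0, 1.0, 10.0)[0] == 0.0
    with pytest.raises(ValueError):
        anova.gcv_pcv(1.0, 2.0, 0.0)
    # multiplying every observation by c leaves the coefficients unchanged
    vc1 = anova.variance_component_summary(balanced_trial, "Y", "field")
    scaled = balanced_trial.assign(Y=balanced_trial["Y"] * 3.0)
    vc2 = anova.variance_component_summary(scaled, "Y", "field")
    assert vc1.gcv_pct == pytest.approx(vc2.gcv_pct, rel=1e-9)
    assert vc1.pcv_pct == pytest.approx(vc2.pcv_pct, rel=1e-9)
    assert vc1.gcv_pct <= vc1.pcv_pct


def test_heritability_limits_and_classes():
    assert anova.heritability(2.0, 2.0) == (100.0, "high")  # sigma2_e = 0
    assert anova.heritability(0.0, 1.0) == (0.0, "low")
    assert anova.classify_heritability(30.0) == "low"
    assert anova.classify_heritability(60.0) == "moderate"
    assert anova.classify_heritability(60.1) == "high"
    with pytest.raises(ValueError):
        anova.heritability(1.0, 0.0)


def test_fisher_lsd_value_and_grouping():
    # MS_e 0.75, r 3, df 126 -> t * sqrt(0.5) ~ 1.400
    means = pd.Series({"a": 10.0, "b": 10.0, "c": 5.0})
    res = anova.fisher_lsd(means, 0.75, 126, 3, f_p_value=0.001)
    t = stats.t.ppf(0.975, 126)
    assert res.lsd == pytest.approx(t * np.sqrt(2 * 0.75 / 3), rel=1e-12)
    assert res.lsd == pytest.approx(1.400, abs=1e-3)
    assert res.groups["a"] == res.groups["b"]  # zero difference: same letter
    assert res.groups["c"] != res.groups["a"]


def test_fisher_lsd_protected_semantics():
    means = pd.Series({"a": 10.0, "b": 5.0})
    res = anova.fisher_lsd(means, 0.75, 126, 3, f_p_value=0.5)
    assert not res.protected
    assert res.groups.empty
    assert res.lsd > 0  # value still reported
    with pytest.raises(ValueError):
        anova.fisher_lsd(means, 0.75, 126, 1)


def test_singular_and_saturated_designs_rejected(balanced_trial):
    # genotype fully confounded with replicate -> singular
    df = balanced_trial.copy()
    df["genotype_id"] = "R" + df["replicate"].astype(str)
    with pytest.raises(ValueError, match="Genotype"):
        anova.fit_anova(df, "Y", model="rcbd")
    one_rep = balanced_trial[balanced_trial["replicate"] == 1]
    with pytest.raises(ValueError, match="replicates"):
        anova.fit_anova(one_rep, "Y")
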