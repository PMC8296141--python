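"""Synthetic-data generator: determinism, limits, analytic expectations."""

import numpy as np
import pandas as pd
import pytest

from strigascreen import anova, striga
from strigascreen.simulate import (
    StrigaSimParams,
    TrialSimParams,
    cross_registry_frame,
    make_study_genotypes,
    simulate_parent_panel,
    simulate_selfed_progeny,
    simulate_striga_series,
    simulate_study,
    simulate_trial,
)


def params(**kw):
    base = dict(
        n_genotypes=16,
        n_reps=3,
        block_size=4,
        trait_means={"Y": 10.0},
        sigma2_g={"Y": 1.5},
        sigma2_e={"Y": 1.0},
        seed=1,
    )
    base.update(kw)
    return TrialSimParams(**base)


def test_trial_determinism_and_layout():
    a = simulate_trial(params())
    b = simulate_trial(params())
    pd.testing.assert_frame_equal(a, b)
    # resolvable layout: each replicate holds every genotype once
    for _, rep in a.groupby("replicate"):
        assert rep["genotype_id"].nunique() == 16
        assert rep.groupby("block").size().eq(4).all()


def test_trial_rejects_nondivisible_layout():
    with pytest.raises(ValueError, match="divisible"):
        TrialSimParams(n_genotypes=10, block_size=4, trait_means={"Y": 1.0},
                       sigma2_g={"Y": 1.0}, sigma2_e={"Y": 1.0})


def test_noise_free_limit_gives_full_heritability():
    p = params(sigma2_e={"Y": 0.0}, sigma2_g={"Y": 2.0}, rep_block_var_fraction=0.0)
    df = simulate_trial(p)
    vc = anova.variance_component_summary(df, "Y", "field")
    assert vc.h2_pct == pytest.approx(100.0)
    assert vc.h2_class == "high"


def test_null_genotypic_variance_estimates_center_on_zero():
    """Under sigma2_g = 0 the unclamped genotypic-variance estimate is
    unbiased around zero, so the clamped estimate is exactly 0 in at least
    half the trials (the clamped H2 mean then carries only the positive-part
    bias of the moment estimator)."""
    h2s, s2g_raw = [], []
    for seed in range(200):
        df = simulate_trial(
            params(n_genotypes=64, block_size=8, sigma2_g={"Y": 0.0}, seed=seed)
        )
        table = anova.fit_anova(df, "Y")
        msg = table.loc["Genotype", "mean_sq"]
        mse = table.loc["Residual", "mean_sq"]
        s2g_raw.append((msg - mse) / 3.0)
        h2s.append(anova.variance_component_summary(df, "Y", "field").h2_pct)
    se = np.std(s2g_raw, ddof=1) / np.sqrt(len(s2g_raw))
    assert abs(np.mean(s2g_raw)) <= 3 * se  # unbiased before clamping
    assert np.median(h2s) == 0.0  # clamping makes the typical estimate exact 0
    assert np.mean(h2s) < 10.0  # residual positive-part bias is small


def test_genotype_effect_sample_variance_converges():
    p = params(n_genotypes=5000, block_size=8, n_reps=2,
               sigma2_g={"Y": 1.5}, sigma2_e={"Y": 0.0}, rep_block_var_fraction=0.0)
    df = simulate_trial(p)
    means = df.groupby("genotype_id")["Y"].mean()
    assert np.var(means, ddof=1) == pytest.approx(1.5, rel=0.05)


def striga_params(susc, **kw):
    base = dict(genotype_susceptibility=susc, seed=3)
    base.update(kw)
    return StrigaSimParams(**base)


def test_zero_susceptibility_gives_all_zero_series():
    trial = simulate_trial(params())
    susc = {g: 0.0 for g in trial["genotype_id"].unique()}
    series = simulate_striga_series(trial, striga_params(susc))
    assert all(striga.asnpc(s) == 0 and striga.ns_max(s) == 0 for s in series)


def test_susceptibility_orders_mean_asnpc():
    trial = pd.concat(
        [simulate_trial(params(n_genotypes=2, block_size=2, n_reps=2, seed=s))
         for s in range(100)],
        ignore_index=True,
    )  # 200 plots per genotype
    trial["plot_id"] = [f"P{i}" for i in range(len(trial))]
    susc = {"G001": 4.0, "G002": 1.0}
    series = simulate_striga_series(trial, striga_params(susc, seed=9))
    df = striga.join_with_traits(trial, series)
    means = df.groupby("genotype_id")["ASNPC"].mean()
    assert means["G001"] > means["G002"]


def test_poisson_limit_variance_to_mean_ratio():
    # dispersion -> infinity: index of dispersion ~ 1, matching a Poisson draw
    rng_oracle = np.random.default_rng(0)
    trial = simulate_trial(params(n_genotypes=4, block_size=4, n_reps=2, seed=2))
    trial = pd.concat([trial] * 250, ignore_index=True)
    trial["plot_id"] = [f"P{i}" for i in range(len(trial))]
    susc = {g: 1.0 for g in trial["genotype_id"].unique()}
    series = simulate_striga_series(trial, striga_params(susc, overdispersion=None))
    first_counts = np.array([s.counts[0] for s in series])
    ratio = first_counts.var(ddof=1) / first_counts.mean()
    oracle = rng_oracle.poisson(8.0, size=len(first_counts))
    oracle_ratio = oracle.var(ddof=1) / oracle.mean()
    assert ratio == pytest.approx(oracle_ratio, abs=0.15)
    # finite dispersion is visibly overdispersed by contrast
    series_nb = simulate_striga_series(trial, striga_params(susc, overdispersion=1.0))
    nb_counts = np.array([s.counts[0] for s in series_nb])
    assert nb_counts.var(ddof=1) / nb_counts.mean() > 2.0


def test_parent_panel_frequencies_and_missingness():
    m = simulate_parent_panel(200, 1000, maf_range=(0.1, 0.5), seed=5)
    assert not np.isnan(m.calls).any()  # missing_rate 0 -> no missing
    assert np.isin(m.calls, (0.0, 2.0)).all()  # fully homozygous inbreds
    # observed frequency of "2" calls ~ mean of the uniform(0.1, 0.5) draw
    freq2 = (m.calls == 2.0).mean()
    assert freq2 == pytest.approx(0.3, abs=0.02)
    m2 = simulate_parent_panel(50, 400, missing_rate=0.1, seed=6)
    assert np.isnan(m2.calls).mean() == pytest.approx(0.1, abs=0.02)
    assert simulate_parent_panel(5, 50, seed=8) == simulate_parent_panel(5, 50, seed=8)


def test_f1_progeny_fully_heterozygous_at_informative_loci():
    panel = simulate_parent_panel(2, 300, seed=1, sample_ids=["F", "M"])
    prog = simulate_selfed_progeny(panel, "F", "M", generation=1, n_progeny=3, seed=2)
    f, m = panel.sample("F"), panel.sample("M")
    informative = f != m
    kept = np.isin(panel.marker_ids, prog.marker_ids)
    assert (prog.calls[:, informative[kept]] == 1.0).all()


def test_f4_heterozygosity_matches_half_cubed():
    n_prog, n_loci = 500, 1000
    calls = np.vstack([np.zeros(n_loci), np.full(n_loci, 2.0)])
    panel_ids = ["F", "M"]
    from strigascreen.model import SNPMatrix

    panel = SNPMatrix(panel_ids, [f"M{i}" for i in range(n_loci)], calls)
    prog = simulate_selfed_progeny(panel, "F", "M", generation=4, n_progeny=n_prog, seed=0)
    het = (prog.calls == 1.0).mean()
    se = np.sqrt(0.125 * 0.875 / (n_prog * n_loci))
    assert abs(het - 0.125) <= 3 * se


def test_identical_parents_give_identical_progeny():
    from strigascreen.model import SNPMatrix

    calls = np.vstack([np.zeros(50), np.zeros(50)])
    panel = SNPMatrix(["F", "M"], [f"M{i}" for i in range(50)], calls)
    prog = simulate_selfed_progeny(panel, "F", "M", generation=4, n_progeny=4, seed=1)
    assert (prog.calls == 0.0).all()


def test_heterozygous_parent_markers_skipped(caplog):
    from strigascreen.model import SNPMatrix

    calls = np.array([[0.0, 1.0, 0.0], [2.0, 2.0, np.nan]])
    panel = SNPMatrix(["F", "M"], ["a", "b", "c"], calls)
    with caplog.at_level("WARNING"):
        prog = simulate_selfed_progeny(panel, "F", "M", generation=2, n_progeny=2, seed=0)
    assert prog.marker_ids == ["a"]
    assert any("skipped" in r.message for r in caplog.records)


def test_study_bundle_is_complete_and_deterministic():
    a = simulate_study(seed=4, n_markers=120)
    b = simulate_study(seed=4, n_markers=120)
    pd.testing.assert_frame_equal(a.field_traits, b.field_traits)
    assert a.snps == b.snps
    assert len(a.genotypes) == 64
    classes = pd.Series([g.material_class.value for g in a.genotypes]).value_counts()
    assert classes.to_dict() == {"F4": 26, "wild": 17, "improved": 13, "landrace": 8}
    assert len(a.field_counts) == len(a.field_traits)
    assert set(cross_registry_frame(a.genotypes)["id"]) == set(a.crosses["id"])


def test_make_study_genotypes_parent_rules():
    genos = make_study_genotypes(seed=0)
    f4 = [g for g in genos if g.material_class.value == "F4"]
    assert all(g.female_parent and g.male_parent for g in f4)
    non_f4 = {g.id for g in genos if g.material_class.value != "F4"}
    assert all(g.female_parent in non_f4 and g.male_parent in non_f4 for g in f4)
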