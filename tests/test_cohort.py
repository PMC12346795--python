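"""Synthetic-cohort generator: composition, determinism, schema round trips
and fidelity of the planted Gaussian-copula correlation structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cardioage.cohort import (CohortSpec, attenuation_factor,
                              correlation_from_pairs, default_marginal,
                              generate_cohort, load_cohort, nearest_psd,
                              save_cohort)


def test_default_composition_exact(catalog):
    t = generate_cohort(CohortSpec(seed=3), catalog)
    df = t.df
    assert len(df) == 52
    assert (df["cvd_group"] == 1.0).sum() == 30
    assert (df["cvd_group"] == 0.0).sum() == 22
    assert (df["sex"] == 1.0).sum() == 18
    assert (df["sex"] == 0.0).sum() == 34
    assert not df.isna().any().any()
    assert (df["age"] >= 60.0).all()


def test_binary_and_ordinal_codes(catalog):
    df = generate_cohort(CohortSpec(n_total=200, n_cvd=120, n_non_cvd=80,
                                    n_male=90, n_female=110, seed=1),
                         catalog).df
    for name in ("PICS", "CHD", "AH", "CVD", "S"):
        assert set(np.unique(df[name])) <= {0.0, 1.0}
    assert set(np.unique(df["E"])) <= {0.0, 1.0, 2.0}


def test_determinism_bitwise(catalog):
    spec = CohortSpec(seed=11)
    a = generate_cohort(spec, catalog).df
    b = generate_cohort(spec, catalog).df
    assert a.equals(b)
    c = generate_cohort(CohortSpec(seed=12), catalog).df
    assert not a.equals(c)


def test_empty_cohort_is_valid(catalog):
    t = generate_cohort(CohortSpec(n_total=0, n_cvd=0, n_non_cvd=0,
                                   n_male=0, n_female=0, seed=0), catalog)
    assert len(t.df) == 0
    assert list(t.df.columns) == catalog.names + ["sex", "age", "cvd_group"]


def test_inconsistent_counts_rejected(catalog):
    with pytest.raises(ValueError, match="n_total"):
        generate_cohort(CohortSpec(n_cvd=31, seed=0), catalog)
    with pytest.raises(ValueError, match="n_total"):
        generate_cohort(CohortSpec(n_male=20, seed=0), catalog)


def test_non_psd_rejected_and_repairable(catalog):
    # r(AB)=0.9, r(AC)=0.9, r(BC)=-0.9 is infeasible
    pairs = [("BMI", "ALB", 0.9), ("BMI", "SOD", 0.9), ("ALB", "SOD", -0.9)]
    spec = CohortSpec(seed=0,
                      target_correlation=correlation_from_pairs(catalog,
                                                                pairs))
    with pytest.raises(ValueError, match="positive semidefinite"):
        generate_cohort(spec, catalog)
    t = generate_cohort(spec, catalog, repair_psd=True)
    assert len(t.df) == 52


def test_nearest_psd_properties(catalog):
    pairs = [("BMI", "ALB", 0.9), ("BMI", "SOD", 0.9), ("ALB", "SOD", -0.9)]
    m = correlation_from_pairs(catalog, pairs)
    repaired = nearest_psd(m)
    w = np.linalg.eigvalsh(repaired)
    assert w.min() >= -1e-12
    assert np.allclose(np.diag(repaired), 1.0)
    assert np.allclose(repaired, repaired.T)


def test_round_trip_identity(tmp_path, catalog):
    t = generate_cohort(CohortSpec(seed=5), catalog)
    path = tmp_path / "cohort.csv"
    save_cohort(t, path)
    loaded = load_cohort(path, catalog)
    assert loaded.df.equals(t.df)


def test_missing_required_column_named(tmp_path, catalog):
    t = generate_cohort(CohortSpec(seed=5), catalog)
    df = t.df.drop(columns=["cvd_group"])
    path = tmp_path / "bad.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match="cvd_group"):
        load_cohort(path, catalog)


def test_na_cell_reported_with_coordinates(tmp_path, catalog):
    t = generate_cohort(CohortSpec(seed=5), catalog)
    df = t.df.copy().astype(object)
    df.iloc[7, df.columns.get_loc("ALB")] = "NA"
    path = tmp_path / "bad.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match=r"row 7, column 'ALB'"):
        load_cohort(path, catalog)


def test_unknown_columns_listed(tmp_path, catalog):
    t = generate_cohort(CohortSpec(seed=5), catalog)
    df = t.df.copy()
    df["mystery"] = 1.0
    path = tmp_path / "bad.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match="mystery"):
        load_cohort(path, catalog)


def test_marginal_fidelity_large_n(catalog):
    """At n = 1e5: continuous mean/sd within 2% of spec, binary prevalence
    within 0.01, ordinal frequencies near their level probabilities."""
    n = 100_000
    df = generate_cohort(CohortSpec(n_total=n, n_cvd=n // 2,
                                    n_non_cvd=n - n // 2, n_male=n // 2,
                                    n_female=n - n // 2, seed=7),
                         catalog).df
    for name in ("ALB", "SOD", "BMI"):
        m = default_marginal(catalog.get(name))
        assert df[name].mean() == pytest.approx(m.mean, rel=0.02)
        assert df[name].std() == pytest.approx(m.sd, rel=0.02)
        lo, hi = catalog.get(name).reference_range
        assert df[name].between(lo, hi).all()
    for name in ("PICS", "CHD", "S"):
        assert df[name].mean() == pytest.approx(0.5, abs=0.01)
    freqs = df["E"].value_counts(normalize=True)
    assert np.allclose(freqs.sort_index(), [1 / 3] * 3, atol=0.01)


def _mc_oracle_continuous_pair(r_latent, catalog, n=1_000_000, seed=2024):
    """Independent Monte-Carlo estimate of the observed Pearson correlation
    of the (BMI, HLA.DR) pair under the latent construction: truncated-normal
    quantile transform for BMI, affine transform for HLA.DR."""
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = r_latent * z1 + np.sqrt(1 - r_latent ** 2) * rng.standard_normal(n)
    lo, hi = 18.5, 40.0
    mean, sd = (lo + hi) / 2, (hi - lo) / 8
    bmi = stats.truncnorm.ppf(stats.norm.cdf(z1), (lo - mean) / sd,
                              (hi - mean) / sd, loc=mean, scale=sd)
    hla = 1.0 + 0.2 * z2
    return float(np.corrcoef(bmi, hla)[0, 1])


def test_planted_correlation_matches_mc_oracle(catalog):
    expected = _mc_oracle_continuous_pair(0.5, catalog)
    target = correlation_from_pairs(catalog, [("BMI", "HLA.DR", 0.5)])
    n = 100_000
    df = generate_cohort(
        CohortSpec(n_total=n, n_cvd=n // 2, n_non_cvd=n - n // 2,
                   n_male=n // 2, n_female=n - n // 2, seed=9,
                   target_correlation=target), catalog).df
    observed = float(np.corrcoef(df["BMI"], df["HLA.DR"])[0, 1])
    assert observed == pytest.approx(expected, abs=0.01)
    # and the documented looser bound at the published-scale n = 10_000
    df_small = generate_cohort(
        CohortSpec(n_total=10_000, n_cvd=5_000, n_non_cvd=5_000,
                   n_male=5_000, n_female=5_000, seed=10,
                   target_correlation=target), catalog).df
    small = float(np.corrcoef(df_small["BMI"], df_small["HLA.DR"])[0, 1])
    assert small == pytest.approx(expected, abs=0.03)


def test_threshold_attenuation_and_calibration(catalog):
    """A binary-continuous pair planted at 0.41 is attenuated by
    phi(0)/0.5 ~ 0.798 by default; calibrate=True recovers the target."""
    lam = attenuation_factor(catalog.get("PICS"),
                             default_marginal(catalog.get("PICS")))
    assert lam == pytest.approx(stats.norm.pdf(0.0) / 0.5, abs=1e-12)
    target = correlation_from_pairs(catalog, [("PICS", "CD14", 0.41)])
    n = 100_000
    kw = dict(n_total=n, n_cvd=n // 2, n_non_cvd=n - n // 2,
              n_male=n // 2, n_female=n - n // 2, seed=21,
              target_correlation=target)
    raw = generate_cohort(CohortSpec(**kw), catalog).df
    r_raw = float(np.corrcoef(raw["PICS"], raw["CD14"])[0, 1])
    assert r_raw == pytest.approx(0.41 * lam, abs=0.01)
    cal = generate_cohort(CohortSpec(**kw), catalog, calibrate=True).df
    r_cal = float(np.corrcoef(cal["PICS"], cal["CD14"])[0, 1])
    assert r_cal == pytest.approx(0.41, abs=0.01)
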