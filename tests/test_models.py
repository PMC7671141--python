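import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from noctograph.models import (
    ModelSpec,
    SpecificationError,
    fit_lmm,
    lsmeans_tukey,
    residual_diagnostics,
)
from noctograph.synthetic import DEFAULT_STAGE_EFFECTS, simulate_day_records


def small_records(rng, n_animals=8, n_days=60):
    return simulate_day_records(rng, n_animals=n_animals, n_days=n_days)


def test_stage_and_weather_cannot_cooccur():
    with pytest.raises(SpecificationError):
        ModelSpec(response="mean_daily_odba", fixed=("stage", "temp_c"))
    with pytest.raises(SpecificationError):
        ModelSpec(response="mean_daily_odba", fixed=("stage", "snow_cat"))
    # either alone is fine
    ModelSpec(response="mean_daily_odba", fixed=("stage", "sex"))
    ModelSpec(response="mean_daily_odba", fixed=("temp_c", "wind_ms", "temp_x_wind"))


def test_spec_rejects_unknown_terms():
    with pytest.raises(SpecificationError):
        ModelSpec(response="mean_daily_odba", fixed=("elevation",))
    with pytest.raises(SpecificationError):
        ModelSpec(response="body_mass", fixed=("stage",))
    with pytest.raises(SpecificationError):
        ModelSpec(response="mean_daily_odba", fixed=("stage",), random_intercepts=())


def test_fit_recovers_stage_effects(rng):
    df = small_records(rng, n_animals=12, n_days=80)
    fit = fit_lmm(df, ModelSpec(response="mean_daily_odba", fixed=("stage",)))
    assert fit.converged
    est = fit.params["estimate"]
    lact = est[[i for i in est.index if "lactation" in i][0]]
    assert lact == pytest.approx(DEFAULT_STAGE_EFFECTS["lactation"], abs=0.03)
    assert set(fit.tau00) == {"individual", "day_of_year"}
    assert fit.sigma2 > 0


def test_fit_requires_two_individuals(rng):
    df = small_records(rng, n_animals=2, n_days=40)
    df = df[df["animal_id"] == "A00"]
    with pytest.raises(Exception):
        fit_lmm(df, ModelSpec(response="mean_daily_odba", fixed=("stage",)))


def test_lsmeans_and_tukey_shape(rng):
    df = small_records(rng, n_animals=10, n_days=80)
    fit = fit_lmm(df, ModelSpec(response="mean_daily_odba", fixed=("stage",)))
    lsmeans, pairs = lsmeans_tukey(fit, "stage")
    assert len(lsmeans) == 4
    assert len(pairs) == 6  # k(k-1)/2 for k=4
    assert ((pairs["p_tukey"] >= 0) & (pairs["p_tukey"] <= 1)).all()
    # the large lactation-winter contrast must be detected
    lw = pairs[pairs["pair"].str.contains("lactation") & pairs["pair"].str.contains("winter")]
    assert bool(lw["significant"].iloc[0])


def test_lsmeans_match_raw_means_in_balanced_design(rng):
    df = small_records(rng, n_animals=10, n_days=80)
    fit = fit_lmm(df, ModelSpec(response="mean_daily_odba", fixed=("stage",)))
    lsmeans, _ = lsmeans_tukey(fit, "stage")
    raw = df.groupby("stage")["mean_daily_odba"].mean()
    for stage in raw.index:
        assert lsmeans.loc[stage, "lsmean"] == pytest.approx(raw[stage], abs=0.01)


def test_residual_diagnostics_normal_vs_heavy_tailed(rng):
    df = small_records(rng, n_animals=10, n_days=80)
    fit = fit_lmm(df, ModelSpec(response="mean_daily_odba", fixed=("stage",)))
    diag = residual_diagnostics(fit)
    assert diag["applicable"]
    assert diag["straightness"] > 0.99
    assert not diag["flag"]

    heavy = df.copy()
    heavy["mean_daily_odba"] = heavy["mean_daily_odba"] + rng.standard_t(1, len(heavy)) * 0.1
    fit_h = fit_lmm(heavy, ModelSpec(response="mean_daily_odba", fixed=("stage",)))
    diag_h = residual_diagnostics(fit_h)
    assert diag_h["straightness"] < diag["straightness"]
    assert diag_h["flag"]


def test_weather_model_fits(rng):
    df = small_records(rng, n_animals=8, n_days=60)
    w_rng = np.random.default_rng(7)
    df["temp_c"] = w_rng.normal(10, 5, len(df))
    df["wind_ms"] = w_rng.uniform(0, 6, len(df))
    df["precip_sqrt"] = np.abs(w_rng.normal(0, 1, len(df)))
    fit = fit_lmm(
        df,
        ModelSpec(
            response="mean_daily_odba",
            fixed=("temp_c", "wind_ms", "precip_sqrt", "temp_x_wind"),
        ),
    )
    assert fit.converged
    assert "temp_c:wind_ms" in fit.params.index


def test_point_estimates_match_lme4(rng, tmp_path):
    """Cross-validate MixedLM fixed effects against R lme4 on one dataset."""
    df = small_records(rng, n_animals=8, n_days=60)
    fit = fit_lmm(df, ModelSpec(response="mean_daily_odba", fixed=("stage",)))

    csv = tmp_path / "records.csv"
    df.to_csv(csv, index=False)
    out = tmp_path / "fe.csv"
    script = tmp_path / "fit.R"
    script.write_text(
        textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$stage <- relevel(factor(d$stage), ref = "winter")
            m <- lmer(mean_daily_odba ~ stage + (1 | animal_id) + (1 | day_of_year),
                      data = d, REML = TRUE)
            write.csv(data.frame(term = names(fixef(m)), estimate = fixef(m)),
                      "{out}", row.names = FALSE)
            """
        )
    )
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    r_fe = pd.read_csv(out).set_index("term")["estimate"]

    py = fit.params["estimate"]
    pairs = {
        "(Intercept)": "Intercept",
        "stagemating": [i for i in py.index if "mating" in i][0],
        "stagelactation": [i for i in py.index if "lactation" in i][0],
        "stagefattening": [i for i in py.index if "fattening" in i][0],
    }
    for r_term, py_term in pairs.items():
        assert py[py_term] == pytest.approx(r_fe[r_term], abs=1e-4)
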