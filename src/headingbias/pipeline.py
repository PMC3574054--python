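"""End-to-end orchestration of the synthetic heading-bias study.

One call simulates identification and discrimination sessions for a
cohort of synthetic subjects, reduces them to bias curves and PSE/JND
estimates, decodes an afferent-like neural population, fits the
bimodal-prior observer, and compares everything — writing each artifact
plus a machine-readable report.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import bayes, comparisons, discrimination, identification, io
from . import population_vector as pv
from . import synthetic
from .angles import wrap_deg
from .motion import make_motion_profile

__all__ = ["default_config", "run_end_to_end"]

log = logging.getLogger("headingbias")

INVESTIGATED_DIRECTIONS_DEG = (-135.0, -90.0, -45.0, 0.0, 45.0, 90.0, 135.0, 180.0)


def default_config() -> dict:
    """Baseline study configuration (all values editable)."""
    return {
        "seed": 0,
        "n_subjects": 12,
        "motion": {"duration_s": 1.0, "displacement_m": 0.13},
        "observer": {"bias_amplitude_deg": 6.0, "noise_sd_deg": 5.0,
                     "lapse_rate": 0.0},
        "staircase": {
            "step_deg": 4.0,
            "n_trials_1u1d": 35,
            "n_trials_transformed": 40,
            "start_offset_1u1d_deg": 26.0,
            "start_offset_transformed_deg": 18.0,
            "jnd_true_deg": 8.0,
        },
        "population": {"n": 313, "azimuth_peak_deg": 50.0,
                       "azimuth_spread_deg": 40.0},
        "likelihood_profile": None,  # path to YAML; None = vestibular default
        "prior_search_range_deg": [5.0, 120.0],
    }


def _observer_from_config(cfg: dict) -> synthetic.SimulatedIdentificationObserver:
    amp = float(cfg["observer"]["bias_amplitude_deg"])
    sd = float(cfg["observer"]["noise_sd_deg"])
    return synthetic.SimulatedIdentificationObserver(
        bias_fn=lambda th: amp * np.sin(2.0 * np.deg2rad(th)),
        noise_sd_fn=lambda th: np.full_like(np.asarray(th, dtype=float), sd),
        lapse_rate=float(cfg["observer"]["lapse_rate"]),
    )


def _simulate_cohort(cfg: dict, seeds) -> pd.DataFrame:
    design = synthetic.IdentificationDesign()
    observer = _observer_from_config(cfg)
    logs = []
    for i, s in enumerate(seeds, start=1):
        one = synthetic.simulate_identification(observer, design, seed=s)
        one.insert(0, "subject", f"S{i:02d}")
        logs.append(one)
    return pd.concat(logs, ignore_index=True)


def _mean_bias_curve(log: pd.DataFrame) -> pd.DataFrame:
    """Per-subject summaries averaged across subjects, heading by heading."""
    per_subject = [
        identification.summarize_identification(grp)
        for _, grp in log.groupby("subject")
    ]
    stacked = pd.concat(per_subject, ignore_index=True)
    out = (
        stacked.groupby("stimulus_deg")
        .agg(
            bias_deg=("bias_deg", "mean"),
            circ_sd_deg=("circ_sd_deg", "mean"),
            n_kept=("n_kept", "sum"),
            n_excluded=("n_excluded", "sum"),
        )
        .reset_index()
    )
    return out


def _run_discrimination(cfg: dict, seeds) -> list[dict]:
    sc = cfg["staircase"]
    amp = float(cfg["observer"]["bias_amplitude_deg"])
    results = []
    rng_seeds = iter(seeds)
    for inv in INVESTIGATED_DIRECTIONS_DEG:
        # generating model: physical pse is the stimulus perceived as `inv`
        pse_true = wrap_deg(inv - amp * np.sin(2.0 * np.deg2rad(inv)))
        obs = synthetic.Simulated2AFCObserver(
            pse_true_deg=pse_true, jnd_true_deg=float(sc["jnd_true_deg"])
        )
        step = float(sc["step_deg"])
        b1 = discrimination.run_block(
            obs, inv, discrimination.StaircaseRule(1, 1, step),
            int(sc["n_trials_1u1d"]), float(sc["start_offset_1u1d_deg"]),
            seed=next(rng_seeds),
        )
        pse_rev = discrimination.pse_from_reversals(b1)
        blocks = [b1]
        for rule in (discrimination.StaircaseRule(2, 1, step),
                     discrimination.StaircaseRule(1, 2, step)):
            blocks.append(
                discrimination.run_block(
                    obs, pse_rev, rule, int(sc["n_trials_transformed"]),
                    float(sc["start_offset_transformed_deg"]),
                    seed=next(rng_seeds),
                )
            )
        trials = pd.concat([b.trials for b in blocks], ignore_index=True)
        grouped = trials.groupby("stimulus_deg")["response_cw"].agg(["sum", "count"])
        fit = discrimination.fit_cumulative_gaussian(
            grouped.index.to_numpy(), grouped["sum"].to_numpy(),
            grouped["count"].to_numpy(),
        )
        results.append(
            {
                "investigated_deg": inv,
                "pse_reversals_deg": pse_rev,
                "pse_deg": fit.pse_deg,
                "jnd_deg": fit.jnd_deg,
                "bias_deg": discrimination.discrimination_bias(inv, fit.pse_deg),
                "n_trials": int(fit.n_trials_used),
            }
        )
    return results


def run_end_to_end(config: dict | None = None, out_dir="headingbias_out",
                   seed: int | None = None) -> dict:
    """Run the whole synthetic study; returns the report dict.

    Stages: simulate -> identification analysis -> discrimination
    analysis -> population decode -> prior fit -> comparisons.  All
    artifacts (CSV logs, summary curves, JSON report) land in
    ``out_dir``; the run is fully reproducible from the echoed config.
    """
    cfg = default_config()
    if config:
        for k, v in config.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    if seed is not None:
        cfg["seed"] = int(seed)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    ss = np.random.SeedSequence(int(cfg["seed"]))
    seeds = [int(s) for s in
             ss.generate_state(int(cfg["n_subjects"]) + 64) % (2**31)]

    log.info("stage=simulate seed=%s subjects=%s", cfg["seed"], cfg["n_subjects"])
    cohort = _simulate_cohort(cfg, seeds[: int(cfg["n_subjects"])])
    io.write_identification_log(cohort, out / "identification_log.csv")

    log.info("stage=analyze-identification")
    curve = _mean_bias_curve(cohort)
    io.write_bias_curve(curve, out / "bias_curve.csv")
    fit_curve = identification.fit_response_curve(
        identification.summarize_identification(cohort)
    )
    io.write_json(
        {
            "coefficients": fit_curve.coefficients,
            "domain_deg": fit_curve.domain_deg,
            "residual_rmse_deg": fit_curve.residual_rmse_deg,
        },
        out / "response_curve_fit.json",
    )

    log.info("stage=analyze-2afc")
    disc = _run_discrimination(cfg, seeds[int(cfg["n_subjects"]):])
    io.write_json(disc, out / "discrimination.json")

    log.info("stage=decode")
    profile = make_motion_profile(**cfg["motion"])
    pop = pv.mirror_bilateral(
        synthetic.make_afferent_population(
            n=int(cfg["population"]["n"]),
            azimuth_peak_deg=float(cfg["population"]["azimuth_peak_deg"]),
            azimuth_spread_deg=float(cfg["population"]["azimuth_spread_deg"]),
            seed=seeds[-1],
        )
    )
    decoded = pv.decode_bias_curve(pop, profile, curve["stimulus_deg"].to_numpy())
    decoded.to_csv(out / "decoded_bias_curve.csv", index=False, float_format="%.3f")

    log.info("stage=fit-prior")
    if cfg["likelihood_profile"]:
        lik = io.read_likelihood_profile(cfg["likelihood_profile"])
    else:
        lik = bayes.vestibular_likelihood_default()
    prior_fit = bayes.fit_sigma_prior(
        curve, lik, search_range_deg=tuple(cfg["prior_search_range_deg"])
    )

    log.info("stage=compare")
    mask = ~np.isin(np.abs(curve["stimulus_deg"].to_numpy()), [0.0, 180.0])
    obs_b = curve["bias_deg"].to_numpy()[mask]
    dec_b = decoded["bias_deg"].to_numpy()[mask]
    rho, p = comparisons.spearman_rho(obs_b, dec_b)
    report = {
        "config": cfg,
        "mean_abs_bias_deg": float(np.mean(np.abs(curve["bias_deg"]))),
        "peak_bias_deg": float(curve["bias_deg"].abs().max()),
        "discrimination": disc,
        "sigma_prior_hat_deg": prior_fit.sigma_prior_hat_deg,
        "prior_fit_r_squared": prior_fit.r_squared,
        "prior_fit_at_boundary": bool(prior_fit.at_boundary),
        "decode_vs_behavior": {
            "rho": rho,
            "p": p,
            "type2_slope": comparisons.type2_slope(obs_b, dec_b),
            "r_squared": comparisons.r2_vs_prediction(obs_b, dec_b),
            "n": int(mask.sum()),
        },
    }
    # timing stays out of the report file so re-runs are byte-identical
    io.write_json(report, out / "report.json")
    log.info("stage=done elapsed=%.2fs", time.perf_counter() - t0)
    return report
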