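"""File-format plumbing: CSV trial logs, population tables, configs.

All CSVs are UTF-8 with a header row and "." decimal separator; angles
are serialized in degrees with 3 decimal places.  Every writer has a
matching reader so artifacts round-trip losslessly at that precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bayes import LikelihoodProfile
from .synthetic import NeuralPopulation, Neuron

__all__ = [
    "write_identification_log",
    "read_identification_log",
    "write_2afc_log",
    "read_2afc_log",
    "write_population",
    "read_population",
    "write_bias_curve",
    "read_bias_curve",
    "read_likelihood_profile",
    "write_likelihood_profile",
    "write_json",
    "read_json",
]

_ANGLE_FMT = "%.3f"

ID_LOG_COLUMNS = ["subject", "block", "presentation", "stimulus_deg", "response_deg"]
TWOAFC_COLUMNS = [
    "subject",
    "block",
    "investigated_deg",
    "trial",
    "stimulus_deg",
    "response_cw",
    "staircase_id",
    "reversal",
]
POPULATION_COLUMNS = ["azimuth_deg", "elevation_deg", "sensitivity", "resting_discharge"]


def _write_csv(df: pd.DataFrame, path, columns) -> None:
    df.to_csv(path, index=False, columns=columns, float_format=_ANGLE_FMT)


def write_identification_log(log: pd.DataFrame, path, subject: str = "S01") -> None:
    df = log.copy()
    if "subject" not in df.columns:
        df.insert(0, "subject", subject)
    _write_csv(df, path, ID_LOG_COLUMNS)


def read_identification_log(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(ID_LOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"identification log missing columns {sorted(missing)}")
    return df


def write_2afc_log(log: pd.DataFrame, path) -> None:
    _write_csv(log, path, TWOAFC_COLUMNS)


def read_2afc_log(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TWOAFC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"2AFC log missing columns {sorted(missing)}")
    return df


def write_population(pop: NeuralPopulation, path) -> None:
    _write_csv(pop.to_frame(), path, POPULATION_COLUMNS)


def read_population(path, laterality: str = "bilateral") -> NeuralPopulation:
    df = pd.read_csv(path)
    missing = set(POPULATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"population table missing columns {sorted(missing)}")
    neurons = [
        Neuron.from_angles(
            r.azimuth_deg, r.elevation_deg, r.sensitivity, r.resting_discharge
        )
        for r in df.itertuples()
    ]
    return NeuralPopulation(neurons, laterality=laterality)


def write_bias_curve(curve: pd.DataFrame, path) -> None:
    cols = [c for c in
            ["stimulus_deg", "mean_response_deg", "bias_deg", "circ_sd_deg",
             "n_kept", "n_excluded"]
            if c in curve.columns]
    _write_csv(curve, path, cols)


def read_bias_curve(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "stimulus_deg" not in df.columns or "bias_deg" not in df.columns:
        raise ValueError("bias-curve CSV needs stimulus_deg and bias_deg columns")
    return df


def write_likelihood_profile(profile: LikelihoodProfile, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {"nodes": [[float(h), float(s)] for h, s in profile.nodes]}, fh
        )


def read_likelihood_profile(path) -> LikelihoodProfile:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"likelihood profile not found: {path}")
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return LikelihoodProfile(tuple((h, s) for h, s in data["nodes"]))


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")


def read_json(path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
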