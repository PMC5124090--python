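"""Readers and writers for the three observation-stream CSV dialects.

Counts: ``region,year,count`` with an empty count field (never a zero)
flagging a missing survey year.  Nests: ``region,year,brood,egg_days,
egg_survived,chick_days,chick_survived`` with 0/1 booleans.  Capture
histories: ``region,first_year,encounter_string`` with a 0/1 string, one
character per study year; a MARK-style ``.inp`` reader is also provided.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .model_core import NEST_COLUMNS, CaptureHistorySet, ObservedData
from .synthetic import SimulationResult

logger = logging.getLogger(__name__)

COUNTS_FILE = "counts.csv"
NESTS_FILE = "nests.csv"
HISTORIES_FILE = "histories.csv"
TRUTH_FILE = "truth.yaml"


def write_counts_csv(path, counts, years, region: str) -> None:
    df = pd.DataFrame({
        "region": region,
        "year": np.asarray(years, dtype=int),
        "count": np.asarray(counts, dtype=float),
    })
    # missing years serialise as empty fields, not zeros
    df.to_csv(path, index=False, na_rep="")


def read_counts_csv(path):
    """Returns (counts, years, region); empty count fields become NaN."""
    df = pd.read_csv(path, comment="#")
    for col in ("region", "year", "count"):
        if col not in df.columns:
            raise ValueError(f"{path}: counts CSV must have a '{col}' column")
    df = df.sort_values("year")
    years = df["year"].to_numpy(dtype=int)
    if len(np.unique(years)) != len(years):
        raise ValueError(f"{path}: duplicate years in counts CSV")
    counts = pd.to_numeric(df["count"], errors="coerce").to_numpy(dtype=float)
    region = str(df["region"].iloc[0]) if len(df) else ""
    return counts, years, region


def write_nests_csv(path, nests: pd.DataFrame) -> None:
    nests.to_csv(path, index=False, columns=NEST_COLUMNS)


def read_nests_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(NEST_COLUMNS[1:]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: nest CSV is missing columns: {sorted(missing)}")
    n0 = len(df)
    bad = df["egg_days"].isna() | df["brood"].isna()
    if bad.any():
        logger.info("%s: dropped %d incomplete nest records", path, int(bad.sum()))
        df = df[~bad]
    logger.info("%s: read %d nest records (%d rejected)", path, len(df), n0 - len(df))
    return df.reset_index(drop=True)


def write_histories_csv(path, histories: CaptureHistorySet,
                        years: Sequence[int]) -> None:
    years = np.asarray(years, dtype=int)
    strings = ["".join(map(str, row)) for row in histories.enc]
    df = pd.DataFrame({
        "region": histories.region,
        "first_year": years[histories.first],
        "encounter_string": strings,
    })
    df.to_csv(path, index=False)


def read_histories_csv(path, years: Sequence[int]) -> CaptureHistorySet:
    df = pd.read_csv(path, comment="#", dtype={"encounter_string": str})
    for col in ("region", "first_year", "encounter_string"):
        if col not in df.columns:
            raise ValueError(f"{path}: histories CSV must have a '{col}' column")
    years = np.asarray(years, dtype=int)
    T = len(years)
    enc_rows, first = [], []
    rejected = 0
    for _, row in df.iterrows():
        s = str(row["encounter_string"]).strip()
        if len(s) != T or set(s) - {"0", "1"}:
            rejected += 1
            continue
        enc = np.array([int(c) for c in s], dtype=np.int8)
        f = int(np.argmax(enc == 1))
        if enc[f] != 1 or years[f] != int(row["first_year"]):
            rejected += 1
            continue
        enc_rows.append(enc)
        first.append(f)
    if rejected:
        logger.info("%s: rejected %d malformed capture histories", path, rejected)
    region = str(df["region"].iloc[0]) if len(df) else ""
    return CaptureHistorySet(first=np.array(first, dtype=int),
                             enc=np.array(enc_rows, dtype=np.int8).reshape(len(first), T),
                             region=region)


_INP_COMMENT = re.compile(r"/\*.*?\*/", re.DOTALL)


def read_inp(path, region: str = "") -> CaptureHistorySet:
    """Read MARK-style ``.inp`` encounter histories.

    Each statement is ``<0/1 string> <frequency>;`` with ``/* */`` comments
    tolerated anywhere; the terminal semicolon is required.
    """
    text = _INP_COMMENT.sub(" ", Path(path).read_text())
    enc_rows, first = [], []
    for stmt in text.split(";")[:-1]:
        fields = stmt.split()
        if not fields:
            continue
        s = fields[0]
        if set(s) - {"0", "1"}:
            raise ValueError(f"{path}: malformed encounter string {s!r}")
        freq = int(float(fields[1])) if len(fields) > 1 else 1
        enc = np.array([int(c) for c in s], dtype=np.int8)
        if not enc.any():
            raise ValueError(f"{path}: all-zero encounter history")
        f = int(np.argmax(enc == 1))
        for _ in range(freq):
            enc_rows.append(enc)
            first.append(f)
    tail = text.split(";")[-1].strip()
    if tail:
        raise ValueError(f"{path}: statement without terminal ';': {tail!r}")
    return CaptureHistorySet(first=np.array(first, dtype=int),
                             enc=np.array(enc_rows, dtype=np.int8),
                             region=region)


def write_scenario(observed: ObservedData, directory, truth=None) -> dict:
    """Write a region's three CSV streams (plus a YAML truth file).

    ``truth`` may be a :class:`SimulationResult`, in which case the
    generating preset and yearly parameters are serialised alongside.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": d / COUNTS_FILE,
        "nests": d / NESTS_FILE,
        "histories": d / HISTORIES_FILE,
    }
    write_counts_csv(paths["counts"], observed.counts, observed.years, observed.region)
    write_nests_csv(paths["nests"], observed.nests)
    write_histories_csv(paths["histories"], observed.histories, observed.years)
    if truth is not None:
        paths["truth"] = d / TRUTH_FILE
        write_truth_yaml(paths["truth"], truth)
    return {k: str(v) for k, v in paths.items()}


def write_truth_yaml(path, truth: SimulationResult) -> None:
    preset = truth.preset
    doc = {
        "preset": {
            k: (v.tolist() if isinstance(v, np.ndarray)
                else list(v) if isinstance(v, tuple) else v)
            for k, v in vars(preset).items()
        },
        "params": {
            "phi_ad": truth.params.phi_ad.tolist(),
            "brood_size": truth.params.brood_size.tolist(),
            "phi_egg_daily": truth.params.phi_egg_daily.tolist(),
            "phi_chick_daily": truth.params.phi_chick_daily.tolist(),
            "rho": truth.params.rho.tolist(),
            "sigma_obs": float(truth.params.sigma_obs),
            "p_recapture": float(truth.params.p_recapture),
            "ep": int(truth.params.ep),
            "yp": int(truth.params.yp),
            "fpba": truth.params.fpba.tolist(),
        },
        "latent": {
            "N": truth.latent.N.tolist(),
            "N_a": truth.latent.N_a.tolist(),
            "N_r": truth.latent.N_r.tolist(),
        },
        "extinct": bool(truth.extinct),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_truth_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def read_scenario(directory, region: str | None = None) -> ObservedData:
    """Read a region directory written by :func:`write_scenario`."""
    d = Path(directory)
    counts, years, file_region = read_counts_csv(d / COUNTS_FILE)
    nests = read_nests_csv(d / NESTS_FILE)
    histories = read_histories_csv(d / HISTORIES_FILE, years)
    return ObservedData(counts=counts, nests=nests, histories=histories,
                        years=years, region=region or file_region)
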