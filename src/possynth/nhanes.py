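"""NHANES 2017-2018 ingestion: DEMO (demographics), BPX (blood pressure),
BMX (body measures) SAS transport files merged into an analysis dataset.

The user supplies the XPT files (downloadable from the NCHS website); this
module only maps and merges them. Children aged 2-17 with a positive MEC
examination weight are retained; SBP is the mean of up to three readings
and set to missing when fewer than two are available.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import AGE_MIN, AGE_MAX, AnalysisDataset, derive_sbp, from_records

logger = logging.getLogger(__name__)

DEMO_COLUMNS = {"id": "SEQN", "age": "RIDAGEYR", "gender": "RIAGENDR", "w": "WTMEC2YR"}
BPX_COLUMNS = {"id": "SEQN", "readings": ("BPXSY1", "BPXSY2", "BPXSY3")}
BMX_COLUMNS = {"id": "SEQN", "height": "BMXHT", "body_weight": "BMXWT"}


def build_nhanes_dataset(demo_path, bpx_path, bmx_path) -> AnalysisDataset:
    """Merge DEMO/BPX/BMX transport files into an :class:`AnalysisDataset`."""
    demo = pd.read_sas(demo_path, format="xport")
    bpx = pd.read_sas(bpx_path, format="xport")
    bmx = pd.read_sas(bmx_path, format="xport")

    df = demo[[DEMO_COLUMNS["id"], DEMO_COLUMNS["age"], DEMO_COLUMNS["gender"],
               DEMO_COLUMNS["w"]]].copy()
    df.columns = ["unit_id", "age", "gender", "w"]
    df = df[(df["age"] >= AGE_MIN) & (df["age"] <= AGE_MAX)]
    n_nonpos_w = int((~(df["w"] > 0)).sum())
    if n_nonpos_w:
        logger.info("dropping %d children with nonpositive MEC weight", n_nonpos_w)
        df = df[df["w"] > 0]

    readings = bpx[[BPX_COLUMNS["id"], *BPX_COLUMNS["readings"]]].copy()
    readings["sbp"] = [
        derive_sbp(row) for row in readings[list(BPX_COLUMNS["readings"])].to_numpy()
    ]
    df = df.merge(readings[[BPX_COLUMNS["id"], "sbp"]],
                  left_on="unit_id", right_on=BPX_COLUMNS["id"], how="left")
    body = bmx[[BMX_COLUMNS["id"], BMX_COLUMNS["height"], BMX_COLUMNS["body_weight"]]].copy()
    body.columns = ["seqn_bmx", "height", "body_weight"]
    df = df.merge(body, left_on="unit_id", right_on="seqn_bmx", how="left")
    df = df[["unit_id", "age", "gender", "height", "body_weight", "sbp", "w"]]
    df["age"] = df["age"].astype(int)
    df["unit_id"] = df["unit_id"].astype(np.int64)
    return from_records(df, source="nhanes-2017-2018")
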