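"""Relative expression by the comparative-Ct (2^-ddCt) method.

Each record carries the threshold cycle of the target gene and of the
reference gene (here 18S rRNA) for one replicate of one sample. Per
replicate dCt = Ct_target - Ct_reference; per sample ddCt is the mean dCt
minus the calibrator sample's mean dCt, and relative expression is
2^(-ddCt). Replicates are aggregated on the dCt scale (the standard Livak
practice) and the replicate sd is propagated to a fold-change range
2^-(ddCt -/+ sd). Amplification efficiency is fixed at 2.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["relative_expression", "knockdown_profile"]

REQUIRED_COLUMNS = ("sample", "gene", "ct_target", "ct_reference")


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if records[["ct_target", "ct_reference"]].isna().any().any():
        raise ValueError("missing reference- or target-gene Ct values")
    if (records[["ct_target", "ct_reference"]] <= 0).any().any():
        raise ValueError("Ct values must be positive")
    return records


def relative_expression(
    records: pd.DataFrame, calibrator: str
) -> pd.DataFrame:
    """Fold change per (gene, sample) relative to the calibrator sample.

    Returns a DataFrame indexed by (gene, sample) with columns ``ddct``,
    ``fold``, ``fold_lo``, ``fold_hi`` (the sd-propagated range; equal to
    ``fold`` when only one replicate exists).
    """
    records = _validate(records)
    df = records.copy()
    df["dct"] = df["ct_target"] - df["ct_reference"]

    rows = []
    for gene, sub in df.groupby("gene", sort=True):
        samples = sub.groupby("sample")["dct"].agg(["mean", "std", "count"])
        if calibrator not in samples.index:
            raise ValueError(
                f"calibrator sample {calibrator!r} absent for gene {gene!r}"
            )
        cal_mean = samples.loc[calibrator, "mean"]
        for sample, row in samples.iterrows():
            ddct = row["mean"] - cal_mean
            sd = 0.0 if np.isnan(row["std"]) else float(row["std"])
            rows.append(
                {
                    "gene": gene,
                    "sample": sample,
                    "ddct": ddct,
                    "fold": 2.0 ** (-ddct),
                    "fold_lo": 2.0 ** (-(ddct + sd)),
                    "fold_hi": 2.0 ** (-(ddct - sd)),
                    "n_replicates": int(row["count"]),
                }
            )
    return pd.DataFrame(rows).set_index(["gene", "sample"]).sort_index()


def knockdown_profile(
    records: pd.DataFrame,
    calibrator: str,
    day_of_sample: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Gene x day fold-change table vs an untreated calibrator.

    Sample labels are interpreted as post-treatment days either through
    ``day_of_sample`` or by parsing a trailing integer from labels like
    "day1"/"1d"/"d3". Adds a ``direction`` flag per cell: "up" when fold
    > 1, "down" when fold < 1, "flat" at exactly 1.
    """
    rel = relative_expression(records, calibrator).reset_index()
    rel = rel[rel["sample"] != calibrator]

    def _day(label: str) -> int:
        if day_of_sample is not None:
            return int(day_of_sample[label])
        digits = "".join(ch for ch in str(label) if ch.isdigit())
        if not digits:
            raise ValueError(f"cannot parse a day from sample label {label!r}")
        return int(digits)

    rel["day"] = rel["sample"].map(_day)
    rel["direction"] = np.select(
        [rel["fold"] > 1, rel["fold"] < 1], ["up", "down"], default="flat"
    )
    return rel.set_index(["gene", "day"]).sort_index()[
        ["sample", "fold", "fold_lo", "fold_hi", "direction"]
    ]
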