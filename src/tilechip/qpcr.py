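"""Delta-delta-Ct quantification for ChIP-qPCR and qRT-PCR.

Technical replicates are averaged first, then biological replicates; fold
is 2^(-ddCt) with
ddCt = (Ct_target - Ct_reference)_sample - (Ct_target - Ct_reference)_calibrator
and an assumed amplification efficiency of 2.  ChIP-qPCR fold enrichment
uses a reference genomic region; qRT-PCR fold change uses a housekeeping
gene (e.g. rp49) as the reference and the control genotype as calibrator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("target", "sample", "bio_rep", "ct")


class MissingCellError(KeyError):
    """A required (target, sample) combination has no Ct values."""


@dataclass
class DdctResult:
    fold: float
    ddct: float
    rep_folds: np.ndarray       # per-biological-replicate folds for the sample
    sem: float                  # SEM of the per-replicate folds
    p: float                    # two-sided unpaired t vs. calibrator rep folds


def read_ct_table(path) -> pd.DataFrame:
    """Read a delimited Ct table with columns target, sample, bio_rep[, tech_rep], ct."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if not np.all(np.isfinite(df["ct"])):
        raise ValueError("non-finite Ct values")
    return df


def _bio_rep_means(table: pd.DataFrame, target: str, sample: str) -> pd.Series:
    """Mean Ct per biological replicate (technical replicates averaged first)."""
    sel = table[(table["target"] == target) & (table["sample"] == sample)]
    if sel.empty:
        raise MissingCellError(f"no Ct values for target={target!r}, sample={sample!r}")
    return sel.groupby("bio_rep")["ct"].mean()


def _delta_ct(table: pd.DataFrame, target: str, reference: str,
              sample: str) -> pd.Series:
    """Per-biological-replicate Ct_target - Ct_reference for one sample."""
    t = _bio_rep_means(table, target, sample)
    r = _bio_rep_means(table, reference, sample)
    joined = pd.concat([t, r], axis=1, keys=["t", "r"]).dropna()
    if joined.empty:
        raise MissingCellError(
            f"no shared biological replicates for target={target!r}, "
            f"reference={reference!r}, sample={sample!r}")
    return joined["t"] - joined["r"]


def ddct_fold(table: pd.DataFrame, target: str, reference: str,
              sample: str, calibrator: str) -> DdctResult:
    """Fold change of ``target`` (vs ``reference``) in ``sample`` relative to ``calibrator``.

    Returns the point fold (2^-ddCt of the replicate-mean delta-Cts),
    per-biological-replicate folds with their SEM, and the two-sided
    unpaired t-test p-value of sample vs. calibrator replicate folds.
    """
    d_sample = _delta_ct(table, target, reference, sample)
    d_cal = _delta_ct(table, target, reference, calibrator)
    ddct = float(d_sample.mean() - d_cal.mean())
    fold = float(2.0 ** -ddct)
    rep_folds = np.asarray(2.0 ** -(d_sample - d_cal.mean()))
    cal_folds = np.asarray(2.0 ** -(d_cal - d_cal.mean()))
    sem = float(stats.sem(rep_folds)) if rep_folds.size > 1 else np.nan
    if rep_folds.size > 1 and cal_folds.size > 1:
        p = float(stats.ttest_ind(rep_folds, cal_folds, equal_var=True)[1])
    else:
        p = np.nan
    return DdctResult(fold, ddct, rep_folds, sem, p)
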