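"""Replicate-level quality control.

Pairwise Pearson correlations of log2 intensities, detection-overlap
fractions across replicates, per-sample summed intensities and spike-in
heavy/light ratio statistics.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ExperimentDesign, PeptideTable
from .preprocess import IntensityMatrix


def pairwise_pearson(m: IntensityMatrix, mode: str = "observed") -> pd.DataFrame:
    """Sample x sample Pearson r on log2 intensities.

    ``mode="observed"`` (default) uses pairwise-complete observed cells only,
    so imputation cannot inflate the correlations; cells with fewer than 3
    shared observations are reported as NaN. ``mode="imputed"`` correlates
    the full (post-imputation) matrix for Perseus-style parity.
    """
    if mode == "observed":
        data = m.observed()
        return data.corr(method="pearson", min_periods=3)
    if mode == "imputed":
        if not m.is_complete:
            raise ValidationError("matrix has missing cells; impute first or use mode='observed'")
        return m.values.corr(method="pearson")
    raise ValidationError(f"unknown mode {mode!r}")


def replicate_overlap(
    table: PeptideTable, design: ExperimentDesign
) -> dict[str, pd.Series]:
    """Per group: fraction of detected peptides seen in exactly k replicates.

    Returns {group: Series indexed by k = 1..n_replicates}; fractions sum
    to 1 over the peptides detected in at least one replicate of the group.
    """
    detected = table.intensities().notna()
    out: dict[str, pd.Series] = {}
    for group, samples in design.groups.items():
        counts = detected[samples].sum(axis=1)
        counts = counts[counts > 0]
        n = len(samples)
        fractions = pd.Series(
            {k: float((counts == k).sum()) / len(counts) if len(counts) else np.nan
             for k in range(1, n + 1)},
            name=group,
        )
        out[group] = fractions
    return out


def summed_intensities(table: PeptideTable) -> pd.Series:
    """Total raw intensity per sample (missing cells contribute 0)."""
    return table.intensities().sum(axis=0)


def spikein_stats(aucs: pd.DataFrame) -> pd.DataFrame:
    """Heavy/light spike-in ratio statistics.

    ``aucs`` columns: peptide, replicate, charge_state, heavy_auc,
    light_auc. Per (peptide, replicate) the AUCs are summed over charge
    states; the per-replicate statistic is log2(heavy_total/light_total);
    per peptide the mean, SD and CV% (of the log2 ratio) across replicates
    are reported. Replicates with a zero total are excluded with a warning;
    single-replicate peptides get a mean but undefined SD/CV.
    """
    required = {"peptide", "replicate", "heavy_auc", "light_auc"}
    missing = required - set(aucs.columns)
    if missing:
        raise ValidationError(f"spike-in table lacks column(s): {sorted(missing)}")
    totals = (
        aucs.groupby(["peptide", "replicate"], sort=True)[["heavy_auc", "light_auc"]]
        .sum()
        .reset_index()
    )
    bad = (totals["heavy_auc"] <= 0) | (totals["light_auc"] <= 0)
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} replicate(s) with zero heavy or light total",
            stacklevel=2,
        )
        totals = totals[~bad]
    totals["log2_ratio"] = np.log2(totals["heavy_auc"] / totals["light_auc"])
    rows = []
    for peptide, grp in totals.groupby("peptide", sort=True):
        ratios = grp["log2_ratio"].to_numpy()
        mean = float(ratios.mean())
        sd = float(ratios.std(ddof=1)) if len(ratios) > 1 else np.nan
        if np.isnan(sd):
            cv = np.nan
        elif sd == 0:
            cv = 0.0
        elif mean == 0:
            cv = np.nan  # CV undefined around a zero mean
        else:
            cv = 100.0 * sd / abs(mean)
        rows.append(
            {"peptide": peptide, "n_replicates": len(ratios),
             "mean_log2_ratio": mean, "sd_log2_ratio": sd, "cv_pct": cv}
        )
    return pd.DataFrame(rows)
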