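"""Log2 transform, asymmetric width normalization and Gaussian imputation.

The preprocessing chain mirrors the standard label-free workflow for
MS intensity tables:

1. ``log2_transform`` — raw intensities to log2, preserving missingness.
2. ``width_normalize`` — per sample, subtract the median and divide by the
   interquartile half-widths asymmetrically: values above the median are
   divided by ``q3 - q2``, values below by ``q2 - q1``. After the transform
   every sample's quartiles are exactly (-1, 0, 1).
3. ``impute_missing`` — fill missing cells with draws from a Gaussian whose
   SD is a fraction (default 20%) of the sample's observed SD, centred a
   configurable number of SDs below the sample mean (default 1.8, the usual
   missing-not-at-random convention for label-free data; 0 centres the
   imputation on the observed mean).

Quartiles use linear interpolation between order statistics (numpy's
default, the "type-7" rule); per-sample statistics ignore missing cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NormalizationError, ValidationError
from .io import ExperimentDesign, PeptideTable


@dataclass(frozen=True)
class NormalizationParams:
    """Observed quartiles of one sample's log2 intensities."""

    q1: float
    q2: float
    q3: float


@dataclass(frozen=True)
class ImputationParams:
    width_fraction: float = 0.2
    downshift: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_fraction <= 0:
            raise ValidationError("width_fraction must be > 0")


@dataclass
class IntensityMatrix:
    """Peptides x samples log2 intensities with explicit missing/imputed masks.

    ``missing`` marks cells that were missing in the raw data; ``imputed``
    marks the subset of those that have since been filled, so
    ``imputed <= missing`` always holds and observed cells are never
    overwritten.
    """

    values: pd.DataFrame
    missing: pd.DataFrame
    imputed: pd.DataFrame
    norm_params: dict[str, NormalizationParams] | None = None

    def __post_init__(self) -> None:
        if not (self.values.shape == self.missing.shape == self.imputed.shape):
            raise ValidationError("matrix and masks must be congruent in shape")
        if (self.imputed & ~self.missing).any().any():
            raise ValidationError("imputed mask must be a subset of the missing mask")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def peptides(self) -> pd.Index:
        return self.values.index

    @property
    def is_complete(self) -> bool:
        return not self.values.isna().any().any()

    def observed(self) -> pd.DataFrame:
        """Values with imputed cells masked out again."""
        return self.values.where(~self.missing)

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.copy(), self.missing.copy(), self.imputed.copy(),
            dict(self.norm_params) if self.norm_params else None,
        )


def log2_transform(table: PeptideTable, design: ExperimentDesign | None = None) -> IntensityMatrix:
    """Log2-transform raw intensities; missing cells stay missing.

    When a design is given, columns are restricted to (and ordered as) the
    design's samples after validating the sample ids against the table.
    """
    raw = table.intensities()
    if design is not None:
        design.validate_against(table)
        raw = raw[design.samples]
    if (raw < 0).any().any():
        raise ValidationError("raw intensities must be non-negative")
    missing = raw.isna() | (raw == 0)
    values = np.log2(raw.where(~missing))
    imputed = pd.DataFrame(False, index=raw.index, columns=raw.columns)
    return IntensityMatrix(values, missing, imputed)


def width_normalize(m: IntensityMatrix) -> IntensityMatrix:
    """Median-centre and asymmetrically scale each sample by its quartile widths.

    x -> (x - q2) / (q3 - q2) for x > q2, (x - q2) / (q2 - q1) for x < q2,
    and 0 at the median; quartiles are computed on observed values only.
    The transform is strictly monotone, so ranks are preserved.
    """
    values = m.values.copy()
    params: dict[str, NormalizationParams] = {}
    for s in values.columns:
        col = values[s]
        obs = col.dropna().to_numpy()
        if obs.size < 4:
            raise NormalizationError(f"sample {s!r}: need >= 4 observed values")
        q1, q2, q3 = np.quantile(obs, [0.25, 0.5, 0.75])
        if not (q3 > q2 and q2 > q1):
            raise NormalizationError(
                f"sample {s!r}: degenerate width (q1={q1:g}, q2={q2:g}, q3={q3:g})"
            )
        centered = col - q2
        scale = np.where(centered > 0, q3 - q2, q2 - q1)
        values[s] = centered / scale
        params[s] = NormalizationParams(q1, q2, q3)
    return IntensityMatrix(values, m.missing.copy(), m.imputed.copy(), params)


def impute_missing(m: IntensityMatrix, params: ImputationParams | None = None) -> IntensityMatrix:
    """Fill missing cells from Normal(mean_s - downshift*sd_s, (width_fraction*sd_s)^2).

    Per-sample mean and SD are computed on observed values; draws are
    deterministic given the seed (samples are processed in column order).
    A matrix with no missing cells is returned unchanged.
    """
    p = params or ImputationParams()
    holes = m.values.isna()
    if not holes.any().any():
        return m
    out = m.copy()
    rng = np.random.default_rng(p.seed)
    for s in out.values.columns:
        obs = out.values[s].dropna()
        if len(obs) < 2:
            raise ValidationError(f"sample {s!r}: need >= 2 observed values to impute")
        mu, sd = float(obs.mean()), float(obs.std(ddof=1))
        idx = holes.index[holes[s]]
        if len(idx) == 0:
            continue
        draws = rng.normal(mu - p.downshift * sd, p.width_fraction * sd, size=len(idx))
        out.values.loc[idx, s] = draws
        out.imputed.loc[idx, s] = True
    return out
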