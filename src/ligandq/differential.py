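"""S0-moderated two-sample test with permutation FDR (volcano analysis).

The test statistic is the SAM-style moderated t

    d_i = (mean_2i - mean_1i) / (se_i + s0)

where ``se_i`` is the pooled-variance standard error of the difference and
``s0`` a fold-change moderation constant that de-emphasizes tiny-variance,
tiny-effect features (s0 = 0 recovers the classical pooled t exactly).

Significance is assessed against a permutation null: group labels are
randomly reassigned (preserving group sizes) and |d| recomputed. For each
feature the q-value is the median across permutations of the null
exceedance count #{|d_null| >= |d_i|} divided by the observed exceedance
count #{|d_obs| >= |d_i|}, capped at 1 and made monotone non-increasing in
|d|. Ties count as exceedances (conservative). When the number of distinct
relabelings is at most ``n_perm`` they are enumerated exhaustively, which
also makes the procedure invariant to sample column order.

The model/results split follows the usual statsmodels pattern:
``ModeratedTTest(matrix, design, ...).fit()`` returns a
:class:`DifferentialResults` carrying the per-peptide estimates, q-values,
volcano classes and a ``summary()``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError, ZeroVarianceError
from .io import ExperimentDesign
from .preprocess import IntensityMatrix


@dataclass(frozen=True)
class TestConfig:
    """Parameters of the moderated permutation test.

    s0 = 1 is the peptidomics default; 0.2 is typical for proteome-level
    volcanoes. ``n_perm`` caps the number of relabelings (all distinct
    relabelings are enumerated when there are fewer).
    """

    s0: float = 1.0
    fdr: float = 0.01
    n_perm: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValidationError("s0 must be >= 0")
        if not 0 < self.fdr < 1:
            raise ValidationError("fdr must be in (0, 1)")
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")


def _d_statistic(x1: np.ndarray, x2: np.ndarray, s0: float) -> np.ndarray:
    """Moderated statistic per row; x1, x2 are features x samples arrays."""
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (m2 - m1) / (se + s0)
    if s0 == 0:
        d = np.where((m2 == m1) & (se == 0), 0.0, d)
    return d


def _exceedance_counts(null_abs: np.ndarray, obs_abs: np.ndarray) -> np.ndarray:
    """#{null >= obs_i} for each i, ties inclusive."""
    s = np.sort(null_abs)
    return s.size - np.searchsorted(s, obs_abs, side="left")


class ModeratedTTest:
    """Two-group moderated t-test on a complete (post-imputation) matrix.

    Parameters
    ----------
    matrix : IntensityMatrix or DataFrame
        Complete peptides x samples log2 intensities.
    design : ExperimentDesign
        Must contain exactly two groups with >= 2 samples each.
    groups : optional pair of group labels fixing the contrast direction;
        ``log2fc = mean(groups[1]) - mean(groups[0])``. Defaults to the
        order of first appearance in the design.
    """

    def __init__(
        self,
        matrix: IntensityMatrix | pd.DataFrame,
        design: ExperimentDesign,
        groups: Sequence[str] | None = None,
        s0: float = 1.0,
        fdr: float = 0.01,
        n_perm: int = 250,
        seed: int = 0,
    ) -> None:
        data = matrix.values if isinstance(matrix, IntensityMatrix) else matrix
        if data.isna().any().any():
            raise ValidationError("matrix must be complete; impute missing values first")
        design_groups = design.groups
        if groups is None:
            groups = list(design_groups)
        if len(design_groups) != 2 or set(groups) != set(design_groups):
            raise ValidationError(
                f"exactly two groups required, got {sorted(design_groups)}"
            )
        self.g1, self.g2 = groups
        self.cols1 = design_groups[self.g1]
        self.cols2 = design_groups[self.g2]
        if min(len(self.cols1), len(self.cols2)) < 2:
            raise ValidationError("each group needs >= 2 samples")
        missing = (set(self.cols1) | set(self.cols2)) - set(data.columns)
        if missing:
            raise ValidationError(f"matrix lacks sample column(s): {sorted(missing)}")
        self.data = data
        self.config = TestConfig(s0=s0, fdr=fdr, n_perm=n_perm, seed=seed)

    def _relabelings(self, n: int, n1: int) -> list[tuple[int, ...]]:
        cfg = self.config
        if comb(n, n1) <= cfg.n_perm:
            return list(itertools.combinations(range(n), n1))
        rng = np.random.default_rng(cfg.seed)
        out = []
        for _ in range(cfg.n_perm):
            perm = rng.permutation(n)
            out.append(tuple(sorted(perm[:n1])))
        return out

    def fit(self) -> "DifferentialResults":
        cfg = self.config
        x1 = self.data[self.cols1].to_numpy(float)
        x2 = self.data[self.cols2].to_numpy(float)
        d = _d_statistic(x1, x2, cfg.s0)
        mean1, mean2 = x1.mean(axis=1), x2.mean(axis=1)

        pooled = np.hstack([x1, x2])
        # canonical column order so enumeration is order-invariant
        col_order = np.argsort(list(self.cols1) + list(self.cols2), kind="stable")
        pooled = pooled[:, col_order]
        n, n1 = pooled.shape[1], len(self.cols1)

        abs_d = np.abs(d)
        obs_counts = _exceedance_counts(abs_d, abs_d)
        relabelings = self._relabelings(n, n1)
        null_counts = np.empty((len(relabelings), len(abs_d)))
        all_idx = np.arange(n)
        for k, combo in enumerate(relabelings):
            sel = np.asarray(combo)
            rest = np.setdiff1d(all_idx, sel, assume_unique=True)
            d_null = _d_statistic(pooled[:, sel], pooled[:, rest], cfg.s0)
            null_counts[k] = _exceedance_counts(np.abs(d_null), abs_d)
        med_null = np.median(null_counts, axis=0)
        q = np.minimum(1.0, med_null / obs_counts)
        # enforce monotone non-increasing q in |d|
        order = np.argsort(-abs_d, kind="stable")
        q[order] = np.maximum.accumulate(q[order])

        frame = pd.DataFrame(
            {
                "mean_g1": mean1,
                "mean_g2": mean2,
                "log2fc": mean2 - mean1,
                "d": d,
                "q": q,
            },
            index=self.data.index,
        )
        frame = volcano_classify(frame, cfg.fdr)
        return DifferentialResults(frame, cfg, (self.g1, self.g2), len(relabelings))


def volcano_classify(frame: pd.DataFrame, fdr: float) -> pd.DataFrame:
    """Assign volcano classes: up iff q <= fdr and log2fc > 0, down symmetric."""
    cls = np.where(
        (frame["q"] <= fdr) & (frame["log2fc"] > 0),
        "up",
        np.where((frame["q"] <= fdr) & (frame["log2fc"] < 0), "down", "ns"),
    )
    out = frame.copy()
    out["volcano_class"] = cls
    return out


class DifferentialResults:
    """Per-peptide differential-presentation estimates.

    ``frame`` columns: mean_g1, mean_g2, log2fc (mean_g2 - mean_g1, log2
    units), d (moderated statistic), q (permutation q-value) and
    volcano_class in {up, down, ns}.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        config: TestConfig,
        groups: tuple[str, str],
        n_relabelings: int,
    ) -> None:
        self.frame = frame
        self.config = config
        self.groups = groups
        self.n_relabelings = n_relabelings

    @property
    def counts(self) -> dict[str, int]:
        vc = self.frame["volcano_class"].value_counts()
        return {k: int(vc.get(k, 0)) for k in ("up", "down", "ns")}

    n_up = property(lambda self: self.counts["up"])
    n_down = property(lambda self: self.counts["down"])
    n_ns = property(lambda self: self.counts["ns"])

    def summary(self) -> str:
        c = self.counts
        g1, g2 = self.groups
        lines = [
            "Moderated two-sample test (permutation FDR)",
            "=" * 46,
            f"contrast:        {g2} vs {g1} (log2fc = mean_{g2} - mean_{g1})",
            f"peptides:        {len(self.frame)}",
            f"s0:              {self.config.s0:g}",
            f"target FDR:      {self.config.fdr:g}",
            f"relabelings:     {self.n_relabelings}",
            f"up / down / ns:  {c['up']} / {c['down']} / {c['ns']}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.rename_axis("sequence").to_csv(path, sep="\t", float_format="%.10g")


def one_sample_ttest(values: Sequence[float], alternative: str = "greater") -> dict:
    """One-sample t-test of mean 0; default one-sided (mean > 0).

    Returns ``{"t", "p", "n", "stars"}`` with stars at p < 0.1 / 0.05 / 0.01.
    """
    a = np.asarray(values, dtype=float)
    if a.size < 2:
        raise ValidationError("one-sample t-test needs >= 2 values")
    sd = a.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("sample standard deviation is zero; t undefined")
    t = a.mean() / (sd / np.sqrt(a.size))
    df = a.size - 1
    if alternative == "greater":
        p = float(stats.t.sf(t, df))
    elif alternative == "less":
        p = float(stats.t.cdf(t, df))
    elif alternative == "two-sided":
        p = float(2 * stats.t.sf(abs(t), df))
    else:
        raise ValidationError(f"unknown alternative {alternative!r}")
    return {"t": float(t), "p": p, "n": int(a.size), "stars": significance_stars(p)}


def significance_stars(p: float) -> str:
    """Star coding: * p < 0.1, ** p < 0.05, *** p < 0.01."""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""
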