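"""Nested peptide sets: detection, the Delta shift statistic, transition
groups and cleavage-context windows.

A *nested pair* is a (short, long) pair of peptides from the same leading
protein sharing one terminus exactly, the long one extending the short by
1-5 residues on the other side. Pairs sharing the start are *C-terminal
elongated* (side C); pairs sharing the end are *N-terminal elongated*
(side N). Containment is judged on protein coordinates, not bare strings,
so repeated subsequences elsewhere in the proteome cannot create spurious
pairs. Chains are allowed: a 9-mer may pair with both its 10-mer and
11-mer extensions.

The per-pair shift statistic is

    Delta = (mean_treated(long) - mean_ctrl(long))
          - (mean_treated(short) - mean_ctrl(short))

i.e. the long peptide's log2 fold change minus the short's, computed on
normalized/imputed log2 intensities. A literal raw-intensity-difference
reading, log2((treated_long - ctrl_long)/(treated_short - ctrl_short)) on
linear intensities, is available as ``mode="raw_diff"`` for sensitivity
analysis (undefined when either difference is non-positive).

C-side pairs are grouped by the cleavage-class transition of their
C-terminal residue (T->T, C->C, T->C, C->T; O marks the residues in
neither class) and each group is tested with a one-sided one-sample t-test
against zero change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .differential import one_sample_ttest
from .errors import ValidationError, ZeroVarianceError
from .features import classify_cterm
from .io import ExperimentDesign, PeptideTable
from .preprocess import IntensityMatrix

_CLASS_LETTER = {"tryptic": "T", "chymotryptic": "C", "other": "O"}
CANONICAL_TRANSITIONS = ("T->T", "C->C", "C->T", "T->C")


@dataclass
class NestedPair:
    """A (short, long) nested peptide pair with coordinates on one protein."""

    short: str
    long: str
    protein: str
    side: str  # "N" or "C"
    ext_len: int
    short_start: int
    short_end: int
    long_start: int
    long_end: int
    transition: str = "n/a"  # C-side only, e.g. "T->C"
    delta: float | None = None


def detect_nested_pairs(
    table: PeptideTable, max_ext: int = 5
) -> tuple[list[NestedPair], dict]:
    """All nested pairs on each leading protein, plus a detection report.

    Pairs share equal starts XOR equal ends with a length difference of
    1..max_ext. Unmapped peptides are skipped and counted in the report.
    """
    frame = table.frame
    mapped = frame[frame["mapped"].fillna(False).astype(bool) & frame["start"].notna()]
    report = {"peptides": len(frame), "skipped_unmapped": len(frame) - len(mapped)}
    pairs: list[NestedPair] = []
    for protein, grp in mapped.groupby("leading_protein", sort=True):
        rows = [
            (r.sequence, int(r.start), int(r.end))
            for r in grp.itertuples(index=False)
        ]
        by_start: dict[int, list] = {}
        by_end: dict[int, list] = {}
        for row in rows:
            by_start.setdefault(row[1], []).append(row)
            by_end.setdefault(row[2], []).append(row)
        for start, bucket in sorted(by_start.items()):
            bucket = sorted(bucket, key=lambda r: len(r[0]))
            for i in range(len(bucket)):
                for j in range(i + 1, len(bucket)):
                    short, long_ = bucket[i], bucket[j]
                    ext = len(long_[0]) - len(short[0])
                    if 1 <= ext <= max_ext:
                        pairs.append(
                            NestedPair(
                                short=short[0], long=long_[0], protein=protein,
                                side="C", ext_len=ext,
                                short_start=start, short_end=short[2],
                                long_start=start, long_end=long_[2],
                                transition=(
                                    f"{_CLASS_LETTER[classify_cterm(short[0])]}->"
                                    f"{_CLASS_LETTER[classify_cterm(long_[0])]}"
                                ),
                            )
                        )
        for end, bucket in sorted(by_end.items()):
            bucket = sorted(bucket, key=lambda r: len(r[0]))
            for i in range(len(bucket)):
                for j in range(i + 1, len(bucket)):
                    short, long_ = bucket[i], bucket[j]
                    ext = len(long_[0]) - len(short[0])
                    if 1 <= ext <= max_ext:
                        pairs.append(
                            NestedPair(
                                short=short[0], long=long_[0], protein=protein,
                                side="N", ext_len=ext,
                                short_start=short[1], short_end=end,
                                long_start=long_[1], long_end=end,
                            )
                        )
    report["pairs"] = len(pairs)
    return pairs, report


def group_means(
    matrix: IntensityMatrix | pd.DataFrame,
    design: ExperimentDesign,
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-peptide per-group mean log2 intensity (peptides x 2 groups)."""
    data = matrix.values if isinstance(matrix, IntensityMatrix) else matrix
    gmap = design.groups
    if groups is None:
        groups = list(gmap)
    if len(groups) != 2:
        raise ValidationError("exactly two groups required")
    return pd.DataFrame({g: data[gmap[g]].mean(axis=1) for g in groups})


def compute_delta(
    pair: NestedPair,
    means: pd.DataFrame,
    groups: Sequence[str] | None = None,
    mode: str = "log2fc_diff",
) -> float:
    """Delta for one pair from a peptides x groups mean table.

    groups = (control, treated); defaults to the table's column order.
    """
    ctrl, treated = groups if groups is not None else list(means.columns)
    try:
        row_l, row_s = means.loc[pair.long], means.loc[pair.short]
    except KeyError as exc:
        raise ValidationError(f"no group means for peptide {exc.args[0]!r}")
    vals = [row_l[treated], row_l[ctrl], row_s[treated], row_s[ctrl]]
    if any(pd.isna(v) for v in vals):
        raise ValidationError(f"undefined group mean for pair {pair.short}/{pair.long}")
    if mode == "log2fc_diff":
        return float((vals[0] - vals[1]) - (vals[2] - vals[3]))
    if mode == "raw_diff":
        num = 2.0 ** vals[0] - 2.0 ** vals[1]
        den = 2.0 ** vals[2] - 2.0 ** vals[3]
        if num <= 0 or den <= 0:
            return float("nan")
        return float(np.log2(num / den))
    raise ValidationError(f"unknown delta mode {mode!r}")


def compute_deltas(
    pairs: Iterable[NestedPair],
    means: pd.DataFrame,
    groups: Sequence[str] | None = None,
    mode: str = "log2fc_diff",
) -> list[NestedPair]:
    """Fill ``pair.delta`` in place for every pair; returns the list."""
    pairs = list(pairs)
    for pair in pairs:
        pair.delta = compute_delta(pair, means, groups, mode)
    return pairs


def group_and_test(pairs: Iterable[NestedPair]) -> pd.DataFrame:
    """Test each pair group's Delta values against zero (one-sided, greater).

    Rows cover each side overall (N, C) and, for the C side, each canonical
    cleavage-class transition. Groups with fewer than 2 pairs, or with zero
    variance, are reported without a p-value.
    """
    pairs = [p for p in pairs if p.delta is not None and np.isfinite(p.delta)]
    buckets: list[tuple[str, str, list[float]]] = []
    for side in ("N", "C"):
        deltas = [p.delta for p in pairs if p.side == side]
        buckets.append((side, "all", deltas))
    for trans in CANONICAL_TRANSITIONS:
        deltas = [p.delta for p in pairs if p.side == "C" and p.transition == trans]
        buckets.append(("C", trans, deltas))
    rows = []
    for side, trans, deltas in buckets:
        row = {
            "side": side,
            "transition": trans,
            "n": len(deltas),
            "mean_delta": float(np.mean(deltas)) if deltas else np.nan,
            "sd_delta": float(np.std(deltas, ddof=1)) if len(deltas) > 1 else np.nan,
            "t": np.nan,
            "p": np.nan,
            "stars": "",
        }
        if len(deltas) >= 2:
            try:
                res = one_sample_ttest(deltas, alternative="greater")
                row.update({"t": res["t"], "p": res["p"], "stars": res["stars"]})
            except ZeroVarianceError:
                pass  # all deltas identical: reported as no-shift
        rows.append(row)
    return pd.DataFrame(rows)


def cleavage_context(pair: NestedPair, proteome: Mapping[str, str]) -> dict[str, str]:
    """P5..P1 / P1'..P5' residues around the long peptide's C-terminal cut.

    P1 is the long peptide's C-terminal residue; P1'..P5' are the five
    protein residues downstream of the cleavage site. Positions beyond the
    protein boundary are emitted as '-'.
    """
    if pair.side != "C":
        raise ValidationError("cleavage context is defined for C-side pairs only")
    if pair.protein not in proteome:
        raise ValidationError(f"protein {pair.protein!r} not in proteome")
    prot = proteome[pair.protein]
    p_side = pair.long[-5:].rjust(5, "-")
    downstream = prot[pair.long_end : pair.long_end + 5]  # long_end is 1-based incl.
    p_prime = downstream.ljust(5, "-")
    return {"p_side": p_side, "p_prime": p_prime}


def context_frequency_matrix(
    pairs: Iterable[NestedPair],
    proteome: Mapping[str, str],
    transitions: Sequence[str] = ("T->C", "C->C"),
) -> pd.DataFrame:
    """Residue frequencies at P5..P1 / P1'..P5' for selected C-side groups.

    Gap characters (beyond-protein positions) are excluded per column;
    each column of the returned position x residue frame sums to 1.
    """
    windows = [
        cleavage_context(p, proteome)
        for p in pairs
        if p.side == "C" and p.transition in transitions
    ]
    if not windows:
        raise ValidationError("no C-side pairs in the requested transition groups")
    positions = ["P5", "P4", "P3", "P2", "P1", "P1'", "P2'", "P3'", "P4'", "P5'"]
    freq = {}
    for k, pos in enumerate(positions):
        residues = [
            (w["p_side"] + w["p_prime"])[k]
            for w in windows
            if (w["p_side"] + w["p_prime"])[k] != "-"
        ]
        counts = pd.Series(residues).value_counts()
        freq[pos] = counts / counts.sum()
    return pd.DataFrame(freq).fillna(0.0).sort_index()


def pairs_to_frame(pairs: Iterable[NestedPair]) -> pd.DataFrame:
    """Flatten pairs for TSV export."""
    return pd.DataFrame(
        [
            {
                "short": p.short, "long": p.long, "protein": p.protein,
                "side": p.side, "ext_len": p.ext_len,
                "short_start": p.short_start, "short_end": p.short_end,
                "long_start": p.long_start, "long_end": p.long_end,
                "transition": p.transition, "delta": p.delta,
            }
            for p in pairs
        ]
    )
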