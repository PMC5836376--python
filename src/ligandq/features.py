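"""Ligand-level features: cleavage specificity, length, hydrophobicity,
allele assignment and positional amino-acid enrichment.

Cleavage classes reflect proteasomal C-terminal preference: a peptide is
*tryptic-like* when its C-terminal residue is K or R, *chymotryptic-like*
when it is one of A, F, I, L, M, V, Y, and *other* for the remaining 11
residues (which are excluded from tryptic/chymotryptic contrasts but still
reported). The immunoproteasome induced by IFN-gamma has elevated
chymotryptic-like activity, which is why this stratification is the lens
for treatment effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from Bio.SeqUtils.ProtParamData import kd as _KYTE_DOOLITTLE

from .errors import ValidationError
from .io import AMINO_ACIDS, PeptideTable, PredictionTable

TRYPTIC_RESIDUES = frozenset("KR")
CHYMOTRYPTIC_RESIDUES = frozenset("AFILMVY")

#: Named hydrophobicity scales; Kyte-Doolittle (GRAVY) is the default.
HYDROPHOBICITY_SCALES: dict[str, Mapping[str, float]] = {
    "kyte_doolittle": dict(_KYTE_DOOLITTLE),
}


def classify_cterm(sequence: str) -> str:
    """Cleavage class from the C-terminal residue: tryptic/chymotryptic/other."""
    if not sequence:
        raise ValidationError("empty sequence")
    c = sequence[-1]
    if c in TRYPTIC_RESIDUES:
        return "tryptic"
    if c in CHYMOTRYPTIC_RESIDUES:
        return "chymotryptic"
    if c not in AMINO_ACIDS:
        raise ValidationError(f"unknown residue {c!r}")
    return "other"


def length_distribution(
    peptides_by_condition: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Length histograms per condition, overall and stratified by cleavage class.

    Returns a tidy frame (condition, cleavage_class, length, count, fraction)
    where ``cleavage_class == "all"`` is the unstratified histogram and
    fractions are within each (condition, class). Empty conditions yield no
    rows (with a warning).
    """
    import warnings

    rows = []
    for condition, peptides in peptides_by_condition.items():
        peptides = list(peptides)
        if not peptides:
            warnings.warn(f"condition {condition!r}: empty peptide set", stacklevel=2)
            continue
        df = pd.DataFrame(
            {"length": [len(p) for p in peptides],
             "cleavage_class": [classify_cterm(p) for p in peptides]}
        )
        strata = [("all", df)] + [(c, g) for c, g in df.groupby("cleavage_class")]
        for cls, sub in strata:
            counts = sub["length"].value_counts().sort_index()
            for length, count in counts.items():
                rows.append(
                    {
                        "condition": condition,
                        "cleavage_class": cls,
                        "length": int(length),
                        "count": int(count),
                        "fraction": count / len(sub),
                    }
                )
    return pd.DataFrame(rows, columns=["condition", "cleavage_class", "length", "count", "fraction"])


def hydrophobicity_score(sequence: str, scale: str | Mapping[str, float] = "kyte_doolittle") -> float:
    """Mean per-residue hydrophobicity (GRAVY for the Kyte-Doolittle scale)."""
    table = HYDROPHOBICITY_SCALES[scale] if isinstance(scale, str) else scale
    if not sequence:
        raise ValidationError("empty sequence")
    try:
        return float(np.mean([table[aa] for aa in sequence]))
    except KeyError as exc:
        raise ValidationError(f"residue {exc.args[0]!r} absent from hydrophobicity scale")


def compare_hydrophobicity(
    set1: Iterable[str], set2: Iterable[str], scale: str = "kyte_doolittle"
) -> dict:
    """Two-sided unpaired t-test of mean hydrophobicity between peptide sets."""
    a = [hydrophobicity_score(p, scale) for p in set1]
    b = [hydrophobicity_score(p, scale) for p in set2]
    t, p = stats.ttest_ind(a, b)
    return {
        "mean_1": float(np.mean(a)),
        "mean_2": float(np.mean(b)),
        "t": float(t),
        "p": float(p),
        "n_1": len(a),
        "n_2": len(b),
    }


def assign_alleles(
    table: PeptideTable | Iterable[str],
    predictions: PredictionTable,
    rank_threshold: float = 2.0,
) -> pd.DataFrame:
    """Assign each peptide to an HLA allele from a binder-prediction table.

    A peptide is ``assigned`` iff exactly one allele has %rank below the
    threshold (default 2%); with several such alleles it is ``multi_binder``,
    with none ``non_binder``; peptides absent from the prediction table are
    ``unpredicted``. Statuses partition the peptide set.
    """
    sequences = (
        list(table.sequences()) if isinstance(table, PeptideTable) else list(table)
    )
    preds = predictions.frame
    binders = preds[preds["rank_pct"] < rank_threshold]
    by_seq = {seq: grp for seq, grp in binders.groupby("sequence")}
    predicted = set(preds["sequence"])
    rows = []
    for seq in sequences:
        if seq not in predicted:
            rows.append({"sequence": seq, "allele": None, "rank_pct": np.nan,
                         "affinity_nm": np.nan, "status": "unpredicted"})
            continue
        hits = by_seq.get(seq)
        if hits is None or hits.empty:
            rows.append({"sequence": seq, "allele": None, "rank_pct": np.nan,
                         "affinity_nm": np.nan, "status": "non_binder"})
        elif len(hits) == 1:
            hit = hits.iloc[0]
            rows.append({
                "sequence": seq,
                "allele": hit["allele"],
                "rank_pct": float(hit["rank_pct"]),
                "affinity_nm": float(hit["affinity_nm"]) if "affinity_nm" in hits.columns else np.nan,
                "status": "assigned",
            })
        else:
            rows.append({"sequence": seq, "allele": None, "rank_pct": np.nan,
                         "affinity_nm": np.nan, "status": "multi_binder"})
    return pd.DataFrame(rows)


def peptides_by_allele(assignment: pd.DataFrame) -> dict[str, list[str]]:
    """Allele -> peptide sequences, restricted to uniquely assigned peptides."""
    assigned = assignment[assignment["status"] == "assigned"]
    return {a: list(g["sequence"]) for a, g in assigned.groupby("allele")}


@dataclass
class EnrichmentResult:
    """Positional residue enrichment of one peptide set against a reference.

    ``table`` has one row per (position, residue) with frequencies in both
    sets, a two-sided p-value and a direction flag; ``pfm_experiment`` /
    ``pfm_reference`` are position x residue frequency matrices whose rows
    sum to 1, suitable for logo-rendering tools.
    """

    table: pd.DataFrame
    pfm_experiment: pd.DataFrame
    pfm_reference: pd.DataFrame
    length: int
    cutoff: float


def _position_counts(peptides: list[str], length: int) -> pd.DataFrame:
    counts = pd.DataFrame(0, index=range(1, length + 1), columns=list(AMINO_ACIDS))
    for pep in peptides:
        for pos, aa in enumerate(pep, start=1):
            counts.at[pos, aa] += 1
    return counts


def position_enrichment(
    experiment: Iterable[str],
    reference: Iterable[str],
    length: int = 9,
    cutoff: float = 0.01,
) -> EnrichmentResult:
    """Per-position residue enrichment (iceLogo-style) at a fixed length.

    Both sets are restricted to peptides of the stated length. Each
    (position, residue) is tested with a two-proportion pooled-variance z
    test; when any cell of the 2x2 table is below 5 the exact
    (Fisher/hypergeometric) test is used instead, so the procedure stays
    exactly anti-symmetric under swapping experiment and reference.
    Residues with p < cutoff are flagged enriched or depleted by sign.
    """
    exp = [p for p in experiment if len(p) == length]
    ref = [p for p in reference if len(p) == length]
    if not exp or not ref:
        raise ValidationError(f"empty peptide set after restricting to length {length}")
    ce, cr = _position_counts(exp, length), _position_counts(ref, length)
    n1, n2 = len(exp), len(ref)
    rows = []
    for pos in range(1, length + 1):
        for aa in AMINO_ACIDS:
            x1, x2 = int(ce.at[pos, aa]), int(cr.at[pos, aa])
            if x1 == 0 and x2 == 0:
                continue
            p1, p2 = x1 / n1, x2 / n2
            if min(x1, n1 - x1, x2, n2 - x2) < 5:
                _, p = stats.fisher_exact([[x1, n1 - x1], [x2, n2 - x2]])
            else:
                pool = (x1 + x2) / (n1 + n2)
                se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
                z = (p1 - p2) / se if se > 0 else 0.0
                p = 2 * stats.norm.sf(abs(z))
            direction = "enriched" if p1 > p2 else "depleted" if p1 < p2 else "none"
            rows.append(
                {
                    "position": pos,
                    "residue": aa,
                    "freq_experiment": p1,
                    "freq_reference": p2,
                    "p_value": float(p),
                    "significant": bool(p < cutoff and p1 != p2),
                    "direction": direction if p < cutoff and p1 != p2 else "none",
                }
            )
    table = pd.DataFrame(rows)
    return EnrichmentResult(table, ce / n1, cr / n2, length, cutoff)
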