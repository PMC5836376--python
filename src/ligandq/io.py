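"""Tabular and sequence I/O for label-free immunopeptidomics.

Reads MaxQuant-style ``peptides`` tables (tab-separated, one row per peptide,
one raw-intensity column per sample), experiment-design tables and
binder-prediction tables, and maps peptides onto protein coordinates from a
FASTA proteome.

Conventions
-----------
* Coordinates are 1-based inclusive (``start``/``end``), matching the
  MaxQuant "Start position" column.
* A raw intensity of 0 means "not detected" and is stored as missing (NaN
  in memory, empty field on disk).
* The leading protein of a shared peptide is the first entry of its
  ``Proteins`` list, so downstream nested-set analysis is deterministic.
* Column names are resolved through a configurable *dialect* mapping so
  non-MaxQuant tables (including the synthetic generator's output) load
  through the same reader.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConsistencyError, FormatError, ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Column-name mapping for MaxQuant ``peptides.txt``.
MAXQUANT_DIALECT: dict[str, str] = {
    "sequence": "Sequence",
    "proteins": "Proteins",
    "start": "Start position",
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
    "intensity_prefix": "Intensity ",
}

_FLAG_VALUES = frozenset({"+", "1", "true", "yes"})


@dataclass
class LoadReport:
    """Row accounting for :func:`read_peptide_table`."""

    read: int = 0
    filtered_reverse: int = 0
    filtered_contaminant: int = 0
    filtered_length: int = 0
    aggregated: int = 0
    kept: int = 0

    @property
    def filtered(self) -> int:
        return self.filtered_reverse + self.filtered_contaminant + self.filtered_length


@dataclass
class PeptideTable:
    """Peptide sequences with protein mapping and per-sample raw intensities.

    ``frame`` holds one row per unique peptide sequence with the columns
    ``sequence``, ``proteins`` (';'-joined identifiers), ``leading_protein``,
    ``start``, ``end`` (1-based inclusive, nullable), ``mapped`` (bool),
    ``multiplicity`` (occurrences within the leading protein, nullable) and
    one float column per sample (NaN = missing).
    """

    frame: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        if self.frame["sequence"].duplicated().any():
            raise ValidationError("peptide sequences must be unique after aggregation")

    def __len__(self) -> int:
        return len(self.frame)

    def intensities(self) -> pd.DataFrame:
        """Raw intensities as a peptides x samples frame (NaN = missing)."""
        return self.frame.set_index("sequence")[self.samples].astype(float)

    def sequences(self) -> pd.Series:
        return self.frame["sequence"]


@dataclass
class ExperimentDesign:
    """Sample -> (group, replicate) assignment."""

    frame: pd.DataFrame  # columns: sample, group, replicate

    def __post_init__(self) -> None:
        required = {"sample", "group", "replicate"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"design table lacks column(s): {sorted(missing)}")
        if self.frame["sample"].duplicated().any():
            raise ValidationError("duplicate sample ids in design")
        if (self.frame["replicate"].astype(int) < 1).any():
            raise ValidationError("replicate numbers must be >= 1")

    @property
    def samples(self) -> list[str]:
        return list(self.frame["sample"])

    @property
    def groups(self) -> dict[str, list[str]]:
        """Group -> samples, in order of first appearance."""
        out: dict[str, list[str]] = {}
        for _, row in self.frame.iterrows():
            out.setdefault(row["group"], []).append(row["sample"])
        return out

    def validate_against(self, table: PeptideTable) -> None:
        unknown = set(self.samples) - set(table.samples)
        if unknown:
            raise ValidationError(
                f"design names sample(s) absent from the peptide table: {sorted(unknown)}"
            )
        for group, members in self.groups.items():
            if len(members) < 2:
                warnings.warn(
                    f"group {group!r} has {len(members)} sample(s); "
                    "differential testing needs >= 2",
                    stacklevel=2,
                )


@dataclass
class PredictionTable:
    """Binder predictions: one row per (sequence, allele)."""

    frame: pd.DataFrame  # columns: sequence, allele, rank_pct[, affinity_nm]

    def __post_init__(self) -> None:
        required = {"sequence", "allele", "rank_pct"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"prediction table lacks column(s): {sorted(missing)}")
        if (self.frame["rank_pct"] <= 0).any():
            raise ValidationError("rank_pct must be > 0")
        if self.frame.duplicated(subset=["sequence", "allele"]).any():
            raise ValidationError("duplicate (sequence, allele) rows in predictions")


def _flagged(col: pd.Series) -> pd.Series:
    return col.fillna("").astype(str).str.strip().str.lower().isin(_FLAG_VALUES)


def read_peptide_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    length_range: tuple[int, int] = (8, 25),
) -> tuple[PeptideTable, LoadReport]:
    """Read a peptide table, filter decoys/contaminants and aggregate duplicates.

    Rows flagged reverse or contaminant are removed, zero intensities become
    missing, sequences outside ``length_range`` are dropped, and duplicate
    sequences are merged by summing intensities per sample.
    """
    d = {**MAXQUANT_DIALECT, **(dialect or {})}
    df = pd.read_csv(path, sep="\t", dtype={d["sequence"]: str}, low_memory=False)
    report = LoadReport(read=len(df))

    if d["sequence"] not in df.columns:
        raise FormatError(f"required column {d['sequence']!r} not found in {path}")
    prefix = d["intensity_prefix"]
    intensity_cols = [c for c in df.columns if c.startswith(prefix) and c != prefix.strip()]
    if not intensity_cols:
        raise FormatError(f"no intensity columns with prefix {prefix!r} found in {path}")
    samples = [c[len(prefix):] for c in intensity_cols]

    for key, counter in (("reverse", "filtered_reverse"), ("contaminant", "filtered_contaminant")):
        col = d.get(key)
        if col and col in df.columns:
            mask = _flagged(df[col])
            setattr(report, counter, int(mask.sum()))
            df = df[~mask]

    seq = df[d["sequence"]].astype(str).str.strip().str.upper()
    bad = seq[~seq.map(lambda s: bool(s) and set(s) <= _AA_SET)]
    if len(bad):
        raise FormatError(f"invalid amino-acid sequence(s): {sorted(bad.unique())[:5]}")
    lo, hi = length_range
    in_range = seq.str.len().between(lo, hi)
    report.filtered_length = int((~in_range).sum())
    df = df[in_range]
    seq = seq[in_range]

    if df.empty:
        raise FormatError(f"no peptides left after filtering in {path}")

    inten = df[intensity_cols].apply(pd.to_numeric, errors="coerce")
    if (inten < 0).any().any():
        raise FormatError("negative intensities are not allowed")
    inten = inten.where(inten > 0)  # 0 == missing
    inten.columns = samples

    proteins = (
        df[d["proteins"]].fillna("").astype(str)
        if d.get("proteins") in df.columns
        else pd.Series("", index=df.index)
    )
    start = (
        pd.to_numeric(df[d["start"]], errors="coerce")
        if d.get("start") in df.columns
        else pd.Series(np.nan, index=df.index)
    )

    body = pd.DataFrame({"sequence": seq, "proteins": proteins, "start": start})
    body = pd.concat([body, inten], axis=1)

    n_before = len(body)
    agg = {c: "first" for c in ("proteins", "start")}
    agg.update({s: lambda x: x.sum(min_count=1) for s in samples})
    body = body.groupby("sequence", sort=False, as_index=False).agg(agg)
    report.aggregated = n_before - len(body)
    report.kept = len(body)

    body["leading_protein"] = body["proteins"].str.split(";").str[0].str.strip()
    body["start"] = body["start"].astype("Int64")
    length = body["sequence"].str.len()
    body["end"] = (body["start"] + length - 1).astype("Int64")
    body["mapped"] = body["start"].notna() & (body["leading_protein"] != "")
    body["multiplicity"] = pd.array([pd.NA] * len(body), dtype="Int64")

    order = ["sequence", "proteins", "leading_protein", "start", "end", "mapped", "multiplicity"]
    return PeptideTable(body[order + samples].reset_index(drop=True), samples), report


def write_peptide_table(table: PeptideTable, path: str | Path) -> None:
    """Write a peptide table in the MaxQuant dialect (empty field = missing)."""
    out = pd.DataFrame(
        {
            "Sequence": table.frame["sequence"],
            "Proteins": table.frame["proteins"],
            "Start position": table.frame["start"],
        }
    )
    for s in table.samples:
        out[f"Intensity {s}"] = table.frame[s]
    out.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {identifier: sequence}; the id is the first header token."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id.split()[0]] = str(rec.seq).upper()
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(proteome: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in proteome.items()]
    SeqIO.write(records, str(path), "fasta")


def _occurrences(protein: str, peptide: str) -> list[int]:
    """All 1-based start positions of ``peptide`` in ``protein`` (may overlap)."""
    hits, i = [], protein.find(peptide)
    while i != -1:
        hits.append(i + 1)
        i = protein.find(peptide, i + 1)
    return hits


def map_to_protein(
    table: PeptideTable, proteome: Mapping[str, str] | str | Path | Iterable[SeqRecord]
) -> PeptideTable:
    """Attach/verify (leading_protein, start, end) coordinates from a proteome.

    Peptides with a claimed start are verified against the claimed protein
    (a mismatch raises :class:`ConsistencyError`); peptides without one are
    located by substring search, keeping the first occurrence and recording
    the multiplicity within the chosen protein. Unmappable peptides are
    flagged ``mapped=False``, not dropped.
    """
    if isinstance(proteome, (str, Path)):
        proteome = read_fasta(proteome)
    elif not isinstance(proteome, Mapping):
        proteome = {rec.id.split()[0]: str(rec.seq).upper() for rec in proteome}

    frame = table.frame.copy()
    for i in frame.index:
        seq = frame.at[i, "sequence"]
        lead = frame.at[i, "leading_protein"]
        start = frame.at[i, "start"]
        if lead in proteome:
            prot = proteome[lead]
            if pd.notna(start):
                s = int(start)
                if prot[s - 1 : s - 1 + len(seq)] != seq:
                    raise ConsistencyError(
                        f"peptide {seq} is not at position {s} of protein {lead}"
                    )
                hits = _occurrences(prot, seq)
            else:
                hits = _occurrences(prot, seq)
                if not hits:
                    frame.at[i, "mapped"] = False
                    continue
                frame.at[i, "start"] = hits[0]
            frame.at[i, "end"] = int(frame.at[i, "start"]) + len(seq) - 1
            frame.at[i, "mapped"] = True
            frame.at[i, "multiplicity"] = len(hits)
        else:
            # exhaustive search over the proteome, FASTA order
            for name, prot in proteome.items():
                hits = _occurrences(prot, seq)
                if hits:
                    frame.at[i, "leading_protein"] = name
                    frame.at[i, "start"] = hits[0]
                    frame.at[i, "end"] = hits[0] + len(seq) - 1
                    frame.at[i, "mapped"] = True
                    frame.at[i, "multiplicity"] = len(hits)
                    break
            else:
                frame.at[i, "mapped"] = False
    return PeptideTable(frame, table.samples)


def read_design(path: str | Path) -> ExperimentDesign:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "group": str})
    return ExperimentDesign(df)


def write_design(design: ExperimentDesign, path: str | Path) -> None:
    design.frame.to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> PredictionTable:
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "allele": str})
    return PredictionTable(df)
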