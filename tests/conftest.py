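import numpy as np
import pandas as pd
import pytest

from ligandq import ExperimentDesign, PeptideTable

#: 22-residue toy protein used throughout coordinate tests.
TOY_PROTEIN = "MKTAYIAKQRQISFVKSHFSRQ"


def make_table(rows, samples):
    """Build an in-memory PeptideTable from (sequence, protein, start, {sample: val})."""
    records = []
    for seq, protein, start, intens in rows:
        rec = {
            "sequence": seq,
            "proteins": protein or "",
            "leading_protein": protein or "",
            "start": start,
            "end": (start + len(seq) - 1) if start is not None else None,
            "mapped": start is not None and bool(protein),
            "multiplicity": None,
        }
        for s in samples:
            rec[s] = intens.get(s, np.nan)
        records.append(rec)
    frame = pd.DataFrame(records)
    frame["start"] = frame["start"].astype("Int64")
    frame["end"] = frame["end"].astype("Int64")
    frame["multiplicity"] = frame["multiplicity"].astype("Int64")
    return PeptideTable(frame, list(samples))


def make_design(groups):
    """{'ctrl': ['ctrl_1', ...], ...} -> ExperimentDesign."""
    rows = [
        {"sample": s, "group": g, "replicate": i + 1}
        for g, samples in groups.items()
        for i, s in enumerate(samples)
    ]
    return ExperimentDesign(pd.DataFrame(rows))


@pytest.fixture
def toy_protein():
    return TOY_PROTEIN


@pytest.fixture
def two_group_design():
    return make_design(
        {"ctrl": [f"ctrl_{i}" for i in range(1, 5)],
         "ifng": [f"ifng_{i}" for i in range(1, 5)]}
    )
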