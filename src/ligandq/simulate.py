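"""Synthetic immunopeptidome generator with known ground truth.

Emulates the statistical structure of an HLA class I ligandome experiment
comparing an untreated and a cytokine-treated condition:

* a random proteome, with peptides cut from (and written back into)
  protein windows so every peptide is an exact substring of its source
  protein at its stated 1-based coordinates;
* allele caricatures constraining an anchor position and the C-terminal
  residue -- one tryptic-like model (C-term K/R) and one
  chymotryptic-like model (P anchor at position 2, C-term L/F/A);
* an HLA-I length distribution over 8-14 peaked at 9-mers;
* a configurable fraction of nested pairs, the long partner extending
  1-5 residues into real protein context on the N- or C-terminal side;
* log-normal intensities: a per-peptide base abundance, a treatment
  effect (an up-shift for chymotryptic-like peptides and an extra
  up-shift for long nested partners), and per-cell replicate noise;
* intensity-dependent (missing-not-at-random) dropout with logistic
  probability in log2 abundance.

Every emitted peptide carries a ground-truth row (allele, cleavage class,
nested linkage, injected effect), enabling parameter-recovery tests.
Protein windows are allocated disjointly, which keeps generation O(n) and
guarantees that the only nested relationships in the output are the
planted ones. One global seed drives a hierarchical RNG so the proteome,
intensity and missingness draws are independently reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .errors import SimulationError, ValidationError
from .features import classify_cterm
from .io import (
    AMINO_ACIDS,
    ExperimentDesign,
    PeptideTable,
    write_design,
    write_fasta,
    write_peptide_table,
)


@dataclass(frozen=True)
class AlleleModel:
    """Caricature of an HLA allele: anchor and C-terminal residue weights."""

    name: str
    cterm_weights: dict[str, float]
    anchors: dict[int, dict[str, float]] = field(default_factory=dict)

    @property
    def cterm_class(self) -> str:
        classes = {classify_cterm(aa) for aa in self.cterm_weights}
        return classes.pop() if len(classes) == 1 else "mixed"


def default_alleles() -> list[AlleleModel]:
    """One tryptic-like (A*03:01/A*68:01 flavour) and one chymotryptic-like
    (B*07:02 flavour) model -- sufficient caricatures, not binding-realistic."""
    return [
        AlleleModel("A03-like", {"K": 0.6, "R": 0.4}, {2: {"L": 0.5, "V": 0.3, "T": 0.2}}),
        AlleleModel("B07-like", {"L": 0.6, "F": 0.25, "A": 0.15}, {2: {"P": 0.9, "A": 0.1}}),
    ]


#: HLA-I length distribution over 8-14 peaked at 9-mers.
DEFAULT_LENGTH_WEIGHTS = {8: 0.10, 9: 0.45, 10: 0.20, 11: 0.12, 12: 0.07, 13: 0.04, 14: 0.02}


@dataclass(frozen=True)
class Effects:
    """Treatment effects in log2 units: chymotryptic up-shift and the extra
    up-shift of long nested partners (long-vs-short shift) on treatment."""

    delta_chym: float = 1.0
    delta_long: float = 0.5


@dataclass(frozen=True)
class Noise:
    """Log2-abundance model: base ~ N(base_mean, base_sd) per peptide plus
    N(0, replicate_sd) per cell."""

    base_mean: float = 25.0
    base_sd: float = 2.0
    replicate_sd: float = 0.25


@dataclass(frozen=True)
class Missingness:
    """Logistic MNAR dropout: P(missing) = expit((midpoint - abundance)/slope)."""

    midpoint: float = 20.0
    slope: float = 1.0


@dataclass
class SimConfig:
    n_proteins: int = 200
    protein_length: int = 400
    background: dict[str, float] | None = None  # None = uniform over 20 residues
    alleles: list[AlleleModel] = field(default_factory=default_alleles)
    length_weights: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS))
    n_peptides: int = 1000
    nested_fraction: float = 0.07
    max_ext: int = 5
    effects: Effects = field(default_factory=Effects)
    noise: Noise = field(default_factory=Noise)
    missingness: Missingness | None = field(default_factory=Missingness)
    n_replicates: int = 4
    groups: tuple[str, str] = ("ctrl", "ifng")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.nested_fraction < 1:
            raise ValidationError("nested_fraction must be in [0, 1)")
        if self.noise.base_sd <= 0 or self.noise.replicate_sd <= 0:
            raise ValidationError("all noise SDs must be > 0")
        if self.n_replicates < 2:
            raise ValidationError("need >= 2 replicates per group")
        if len(self.groups) != 2:
            raise ValidationError("exactly two groups")


@dataclass
class Ligandome:
    """Sampled proteome + peptide list with coordinates and truth attributes."""

    proteome: dict[str, str]
    peptides: pd.DataFrame  # sequence, protein, start, end, allele, cleavage_class,
    #                         role (singleton/short/long), partner, side, ext_len
    config: SimConfig


@dataclass
class SimulatedDataset:
    ligandome: Ligandome
    table: PeptideTable
    design: ExperimentDesign
    truth: pd.DataFrame


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


def _draw(rng: np.random.Generator, weights: Mapping[str, float]) -> str:
    keys = sorted(weights)
    probs = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def sample_ligandome(cfg: SimConfig) -> Ligandome:
    """Sample a proteome and an allele-constrained peptide list.

    Peptides are placed in disjoint protein windows; anchor and C-terminal
    positions are written into the protein before sequences are cut, so
    every peptide (and its nested partner, which shares the window) is an
    exact substring of the emitted FASTA.
    """
    bg = cfg.background or {aa: 1.0 for aa in AMINO_ACIDS}
    bg_keys = sorted(bg)
    bg_probs = np.array([bg[k] for k in bg_keys], dtype=float)
    bg_probs = bg_probs / bg_probs.sum()

    rng_prot = _rng(cfg.seed, 0)
    rng_pep = _rng(cfg.seed, 1)

    width = len(str(cfg.n_proteins))
    names = [f"SYN{str(i + 1).zfill(width)}" for i in range(cfg.n_proteins)]
    proteins = [
        list(rng_prot.choice(bg_keys, size=cfg.protein_length, p=bg_probs))
        for _ in range(cfg.n_proteins)
    ]

    cursors = [0] * cfg.n_proteins
    pi = 0
    lengths = sorted(cfg.length_weights)
    lweights = np.array([cfg.length_weights[k] for k in lengths], dtype=float)
    lweights = lweights / lweights.sum()

    seen: set[str] = set()
    records: list[dict] = []

    def rewrite(prot: list[str], positions: list[int]) -> None:
        for pos in positions:
            prot[pos] = bg_keys[rng_pep.choice(len(bg_keys), p=bg_probs)]

    for _ in range(cfg.n_peptides):
        L = int(lengths[rng_pep.choice(len(lengths), p=lweights)])
        nested = bool(rng_pep.random() < cfg.nested_fraction)
        side, ext = "", 0
        if nested:
            side = "C" if rng_pep.random() < 0.5 else "N"
            ext = int(rng_pep.integers(1, cfg.max_ext + 1))
        span = L + ext
        while pi < cfg.n_proteins and cursors[pi] + span > cfg.protein_length:
            pi += 1
        if pi == cfg.n_proteins:
            raise SimulationError(
                "proteome capacity exhausted; increase n_proteins or protein_length"
            )
        base = cursors[pi]
        cursors[pi] += span
        prot = proteins[pi]
        allele = cfg.alleles[int(rng_pep.integers(len(cfg.alleles)))]

        short_off = base + ext if (nested and side == "N") else base
        anchor_pos = []
        for pos, wts in sorted(allele.anchors.items()):
            if pos <= L:
                prot[short_off + pos - 1] = _draw(rng_pep, wts)
                anchor_pos.append(short_off + pos - 1)
        prot[short_off + L - 1] = _draw(rng_pep, allele.cterm_weights)
        if nested and side == "C":
            prot[base + L + ext - 1] = _draw(rng_pep, allele.cterm_weights)

        free = [
            k for k in range(short_off, short_off + L)
            if k not in anchor_pos and k != short_off + L - 1
        ]
        for _try in range(50):
            short_seq = "".join(prot[short_off : short_off + L])
            if short_seq not in seen:
                break
            rewrite(prot, free)
        else:
            raise SimulationError("could not generate a unique peptide sequence")
        seen.add(short_seq)

        if nested:
            if side == "C":
                ext_free = list(range(base + L, base + L + ext - 1))
            else:
                ext_free = list(range(base, base + ext))
            for _try in range(50):
                long_seq = "".join(prot[base : base + span])
                if long_seq not in seen:
                    break
                if not ext_free:
                    long_seq = None
                    break
                rewrite(prot, ext_free)
            else:
                raise SimulationError("could not generate a unique long partner")
            if long_seq is None:
                nested, side, ext = False, "", 0

        records.append(
            {
                "sequence": short_seq,
                "protein": names[pi],
                "start": short_off + 1,
                "end": short_off + L,
                "allele": allele.name,
                "cleavage_class": classify_cterm(short_seq),
                "role": "short" if nested else "singleton",
                "partner": long_seq if nested else "",
                "side": side,
                "ext_len": ext,
            }
        )
        if nested:
            seen.add(long_seq)
            records.append(
                {
                    "sequence": long_seq,
                    "protein": names[pi],
                    "start": base + 1,
                    "end": base + span,
                    "allele": allele.name,
                    "cleavage_class": classify_cterm(long_seq),
                    "role": "long",
                    "partner": short_seq,
                    "side": side,
                    "ext_len": ext,
                }
            )

    proteome = {name: "".join(chars) for name, chars in zip(names, proteins)}
    return Ligandome(proteome, pd.DataFrame(records), cfg)


def simulate_intensities(
    ligandome: Ligandome, cfg: SimConfig | None = None
) -> tuple[PeptideTable, ExperimentDesign, pd.DataFrame]:
    """Raw intensities + design + ground truth for a sampled ligandome.

    log2 abundance = base + treatment effect (treated samples only) +
    replicate noise; raw intensity = 2^abundance; cells drop out with
    logistic MNAR probability when missingness is configured.
    """
    cfg = cfg or ligandome.config
    peps = ligandome.peptides
    n = len(peps)
    ctrl, treated = cfg.groups
    samples = [f"{g}_{r}" for g in cfg.groups for r in range(1, cfg.n_replicates + 1)]
    treated_mask = np.array([s.startswith(f"{treated}_") for s in samples])

    rng_int = _rng(cfg.seed, 2)
    rng_mis = _rng(cfg.seed, 3)

    base = rng_int.normal(cfg.noise.base_mean, cfg.noise.base_sd, size=n)
    effect = (
        cfg.effects.delta_chym * (peps["cleavage_class"] == "chymotryptic").to_numpy(float)
        + cfg.effects.delta_long * (peps["role"] == "long").to_numpy(float)
    )
    abundance = (
        base[:, None]
        + effect[:, None] * treated_mask[None, :]
        + rng_int.normal(0.0, cfg.noise.replicate_sd, size=(n, len(samples)))
    )
    raw = 2.0 ** abundance
    if cfg.missingness is not None:
        p_miss = expit((cfg.missingness.midpoint - abundance) / cfg.missingness.slope)
        raw = np.where(rng_mis.random(size=abundance.shape) < p_miss, np.nan, raw)

    frame = pd.DataFrame(
        {
            "sequence": peps["sequence"],
            "proteins": peps["protein"],
            "leading_protein": peps["protein"],
            "start": peps["start"].astype("Int64"),
            "end": peps["end"].astype("Int64"),
            "mapped": True,
            "multiplicity": pd.array([1] * n, dtype="Int64"),
        }
    )
    for j, s in enumerate(samples):
        frame[s] = raw[:, j]
    table = PeptideTable(frame.reset_index(drop=True), samples)

    design = ExperimentDesign(
        pd.DataFrame(
            {
                "sample": samples,
                "group": [s.rsplit("_", 1)[0] for s in samples],
                "replicate": [int(s.rsplit("_", 1)[1]) for s in samples],
            }
        )
    )
    truth = peps.copy()
    truth["true_effect"] = effect
    truth["base_log2_abundance"] = base
    return table, design, truth


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Full generator run: ligandome -> intensities -> dataset bundle."""
    lig = sample_ligandome(cfg)
    table, design, truth = simulate_intensities(lig, cfg)
    return SimulatedDataset(lig, table, design, truth)


def _config_to_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["alleles"] = [asdict(a) for a in cfg.alleles]
    d["groups"] = list(cfg.groups)
    return d


def emit_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the pipeline's input formats (TSV/FASTA/YAML)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "peptides": outdir / "peptides.tsv",
        "proteome": outdir / "proteome.fasta",
        "design": outdir / "design.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "sim_config.yaml",
    }
    write_peptide_table(dataset.table, paths["peptides"])
    write_fasta(dataset.ligandome.proteome, paths["proteome"])
    write_design(dataset.design, paths["design"])
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(_config_to_dict(dataset.ligandome.config), fh, sort_keys=True)
    return paths
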