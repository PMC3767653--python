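"""Synthetic proteomes with a planted, hydrophobicity-governed cleavage rule.

Real proteasomal data show hydrophobic residues at P1 and a hydrophobic
upstream / hydrophilic downstream context around cleaved bonds.  The
generator emulates exactly that statistical structure: proteins are drawn
residue-wise from a background distribution (uniform over the 20
canonical residues by default), and each candidate bond with full +/-10
context receives a latent score

    s = beta_p1 * VHSE1(P1)
      + beta_up * mean VHSE1(P2..P10)
      - beta_down * mean VHSE1(P1'..P10')
      + Normal(0, noise_sd)

Bonds with ``s > threshold`` become planted cleavage sites; each selected
site is reported as an 8-12-mer "ligand" ending at the site, in the exact
FASTA/TSV formats the corpus module reads.  Setting every beta to zero
(with a permissive threshold) yields a label-free null corpus for
calibration controls.

All outputs are pure functions of the configuration, including its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import classifier as _classifier
from . import corpus as _corpus
from . import interpret as _interpret
from .corpus import LigandRecord
from .vhse import CANONICAL_RESIDUES, VHSE_TABLE

__all__ = [
    "SimulationConfig",
    "GroundTruthSite",
    "RecoveryReport",
    "generate_proteome",
    "latent_site_score",
    "plant_cleavages",
    "recovery_experiment",
    "write_ground_truth_tsv",
]

logger = logging.getLogger(__name__)

#: span of the planted rule on each side of the bond
RULE_HALF_WIDTH = 10

_VHSE1 = {r: VHSE_TABLE[r][0] for r in CANONICAL_RESIDUES}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic corpus.

    Defaults produce roughly 1,200 planted sites (~2,300 labeled windows
    after pretreatment) with a dominant hydrophobic-P1 effect and no
    label noise.
    """

    n_proteins: int = 40
    protein_length: int = 300
    n_ligands: int = 1200
    ligand_length_range: tuple[int, int] = (8, 12)
    beta_p1: float = 2.0
    beta_up: float = 1.0
    beta_down: float = 1.0
    noise_sd: float = 0.0
    threshold: float = 2.0
    seed: int = 0
    residue_frequencies: tuple[float, ...] | None = None  # uniform when None

    def __post_init__(self):
        if min(self.n_proteins, self.protein_length, self.n_ligands) <= 0:
            raise ValueError("counts must be positive")
        lo, hi = self.ligand_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid ligand length range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.protein_length < 2 * RULE_HALF_WIDTH + 1:
            raise ValueError(
                f"proteins must be at least {2 * RULE_HALF_WIDTH + 1} residues "
                "to hold one fully flanked candidate bond"
            )
        if self.residue_frequencies is not None:
            f = np.asarray(self.residue_frequencies, dtype=float)
            if f.shape != (20,) or (f < 0).any() or not np.isclose(f.sum(), 1.0):
                raise ValueError("residue_frequencies must be 20 probabilities summing to 1")


@dataclass(frozen=True)
class GroundTruthSite:
    source_id: str
    p1_index: int  # 0-based
    label: str  # corpus.CLEAVAGE for planted sites


@dataclass
class RecoveryReport:
    """End-to-end pipeline result on one synthetic corpus."""

    cv_table: object  # pandas DataFrame of per-setting CV metrics
    selected: dict
    max_weight_cell: tuple[str, int]
    max_weight_value: float
    contrast: _interpret.HydrophobicContrast
    n_samples: int
    n_cleavage: int
    n_noncleavage: int
    model: _classifier.TrainedModel = field(repr=False, default=None)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def generate_proteome(config: SimulationConfig) -> dict[str, str]:
    """Draw ``n_proteins`` random proteins keyed ``sim_0001`` upward."""
    rng = _rng(config, 0)
    residues = np.array(list(CANONICAL_RESIDUES))
    p = config.residue_frequencies
    out = {}
    for i in range(config.n_proteins):
        seq = rng.choice(residues, size=config.protein_length, p=p)
        out[f"sim_{i + 1:04d}"] = "".join(seq)
    return out


def latent_site_score(protein: str, p1_index: int, config: SimulationConfig) -> float:
    """Noise-free latent score of the bond after ``p1_index`` (full context required)."""
    h = RULE_HALF_WIDTH
    if p1_index - (h - 1) < 0 or p1_index + h >= len(protein):
        raise ValueError("candidate bond lacks full rule context")
    v1 = [_VHSE1[r] for r in protein[p1_index - h + 1 : p1_index + h + 1]]
    p1 = v1[h - 1]
    up = v1[: h - 1]  # P10 .. P2
    down = v1[h:]  # P1' .. P10'
    return (
        config.beta_p1 * p1
        + config.beta_up * float(np.mean(up))
        - config.beta_down * float(np.mean(down))
    )


def plant_cleavages(
    proteome: dict[str, str], config: SimulationConfig
) -> tuple[list[LigandRecord], list[GroundTruthSite]]:
    """Select bonds by the latent rule and emit ligands ending at each site.

    Ligand lengths are drawn uniformly from ``ligand_length_range``
    (shortened when the protein's N-terminus is too close).  When more
    bonds pass the threshold than ``n_ligands``, a uniform subsample is
    kept; when none pass, an empty ligand list is returned with a warning.
    """
    rng = _rng(config, 1)
    h = RULE_HALF_WIDTH
    candidates: list[tuple[str, int]] = []
    scores: list[float] = []
    for source_id in sorted(proteome):
        protein = proteome[source_id]
        for p1 in range(h - 1, len(protein) - h):
            candidates.append((source_id, p1))
            scores.append(latent_site_score(protein, p1, config))
    scores_arr = np.asarray(scores)
    if config.noise_sd > 0:
        scores_arr = scores_arr + rng.normal(0.0, config.noise_sd, size=scores_arr.shape)
    selected = np.flatnonzero(scores_arr > config.threshold)
    if selected.size == 0:
        logger.warning("no candidate bond exceeded the threshold; empty ligand set")
        return [], []
    if selected.size > config.n_ligands:
        selected = np.sort(rng.choice(selected, size=config.n_ligands, replace=False))
    lo, hi = config.ligand_length_range
    ligands: list[LigandRecord] = []
    truth: list[GroundTruthSite] = []
    for idx in selected:
        source_id, p1 = candidates[idx]
        length = int(rng.integers(lo, hi + 1))
        length = min(length, p1 + 1)  # ligand must start inside the protein
        start = p1 - length + 1
        peptide = proteome[source_id][start : p1 + 1]
        ligands.append(LigandRecord(peptide, source_id))
        truth.append(GroundTruthSite(source_id, p1, _corpus.CLEAVAGE))
    return ligands, truth


def write_ground_truth_tsv(path, truth: Sequence[GroundTruthSite]) -> None:
    with open(path, "w") as fh:
        fh.write("source_id\tp1_index_1based\tlabel\n")
        for site in truth:
            fh.write(f"{site.source_id}\t{site.p1_index + 1}\t{site.label}\n")


def recovery_experiment(
    config: SimulationConfig,
    half_width: int = 10,
    selection: Sequence[int] = (1, 3, 5),
    c_grid: Sequence[float] = (1.0,),
    folds: int = 10,
) -> RecoveryReport:
    """Generate, pretreat, cross-validate and interpret in one pass.

    Runs the full pipeline (proteome -> planted ligands -> labeled
    windows -> VHSE features -> linear SVM CV -> weight profile) and
    reports CV metrics, the grid cell carrying the maximum positive
    weight, and the upstream/downstream hydrophobicity contrast.
    """
    proteome = generate_proteome(config)
    ligands, _ = plant_cleavages(proteome, config)
    if not ligands:
        raise ValueError("simulation produced no ligands; lower the threshold")
    sample_set = _corpus.build_sample_set(proteome, ligands, half_width)
    features = _classifier.featurize(sample_set, selection)
    cv_table, selected = _classifier.cross_validate(
        features, kernel="linear", c_grid=c_grid, folds=folds, seed=config.seed
    )
    model = _classifier.train(
        features, kernel="linear", C=selected["C"], selection=selection
    )
    profile = _interpret.position_weights(model)
    max_cell = max(profile.weights, key=lambda k: profile.weights[k])
    return RecoveryReport(
        cv_table=cv_table,
        selected=selected,
        max_weight_cell=max_cell,
        max_weight_value=profile.weights[max_cell],
        contrast=_interpret.hydrophobic_contrast(profile),
        n_samples=len(sample_set),
        n_cleavage=sample_set.count(_corpus.CLEAVAGE),
        n_noncleavage=sample_set.count(_corpus.NON_CLEAVAGE),
        model=model,
    )
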