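"""Interpretation of linear-model weights as cleavage-specificity profiles.

A linear SVM trained on position-major VHSE features has one weight per
(window position, VHSE component) cell.  Reshaping the weight vector
through the model's feature map yields a profile that can be read
directly: a large positive weight for (P1, VHSE1) means hydrophobic
residues immediately upstream of the scissile bond favor cleavage.

From the profile, per-position residue preferences follow by scoring
each canonical residue a at position p:

    score(a, p) = sum_k  w(p, k) * scaled_VHSE_k(a)

where the scaling is the model's own training [0,1] scaler applied to
the descriptor constant for that feature column (pass ``scaler=None``
for raw descriptor units).  Ranking the 20 residues by score gives the
favored (top-k) and unfavored (bottom-k) sets per position, and summing
scores over the residues flanking a candidate bond gives a site-level
favorability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .classifier import ScalerParams, TrainedModel
from .corpus import position_labels
from .vhse import CANONICAL_RESIDUES, DescriptorUnavailableError, VHSE_TABLE

__all__ = [
    "PositionWeightProfile",
    "ResiduePreference",
    "HydrophobicContrast",
    "position_weights",
    "residue_scores",
    "site_score",
    "hydrophobic_contrast",
    "write_profile_tsv",
    "write_preferences_tsv",
]


@dataclass
class PositionWeightProfile:
    """Per-(position, component) weights of a linear cleavage model."""

    weights: dict[tuple[str, int], float]
    half_width: int
    selection: tuple[int, ...]
    scaler: ScalerParams | None = None
    index_map: list[tuple[str, int]] | None = None

    @property
    def positions(self) -> list[str]:
        return position_labels(self.half_width)

    def flatten(self) -> np.ndarray:
        """Weights back in feature-vector order (inverse of the reshape)."""
        order = self.index_map or [
            (pos, comp) for pos in self.positions for comp in self.selection
        ]
        return np.array([self.weights[key] for key in order])

    def scaled(self, by: float) -> "PositionWeightProfile":
        return PositionWeightProfile(
            {k: v * by for k, v in self.weights.items()},
            self.half_width,
            self.selection,
            self.scaler,
            self.index_map,
        )


@dataclass
class ResiduePreference:
    position: str
    ranking: list[tuple[str, float]]  # descending score, all 20 residues
    favored: list[str]
    unfavored: list[str]
    degenerate: bool = False  # all scores identical (e.g. all-zero profile)


@dataclass
class HydrophobicContrast:
    """Mean upstream minus mean downstream VHSE1 weight, with sign counts."""

    contrast: float
    upstream_positive: int
    upstream_negative: int
    downstream_positive: int
    downstream_negative: int


def position_weights(model: TrainedModel, raw_space: bool = False) -> PositionWeightProfile:
    """Reshape a linear model's weight vector into the (position, component) grid.

    Weights live in the scaled [0,1] feature space where the model was
    fit.  With ``raw_space=True`` each weight is divided by its feature's
    training range, converting to per-raw-descriptor-unit weights.
    """
    if model.kernel != "linear":
        raise ValueError("position weights are defined only for the linear kernel")
    w = model.weights
    if raw_space:
        rng = model.scaler.ranges
        w = np.where(rng > 0, w / np.where(rng > 0, rng, 1.0), 0.0)
    weights = {key: float(val) for key, val in zip(model.index_map, w)}
    return PositionWeightProfile(
        weights=weights,
        half_width=model.half_width,
        selection=model.selection,
        scaler=model.scaler,
        index_map=list(model.index_map),
    )


def _scaled_descriptor(
    residue: str,
    position: str,
    component: int,
    profile: PositionWeightProfile,
    scaler: ScalerParams | None,
) -> float:
    try:
        value = VHSE_TABLE[residue][component - 1]
    except KeyError:
        raise DescriptorUnavailableError(residue) from None
    if scaler is None:
        return value
    order = profile.index_map or [
        (pos, comp) for pos in profile.positions for comp in profile.selection
    ]
    j = order.index((position, component))
    lo, hi = scaler.mins[j], scaler.maxs[j]
    if hi <= lo:
        return 0.0
    return float(np.clip((value - lo) / (hi - lo), 0.0, 1.0))


def residue_scores(
    profile: PositionWeightProfile,
    position: str,
    scaler: ScalerParams | None = None,
    k: int = 4,
) -> ResiduePreference:
    """Rank the 20 residues at one position by their weighted descriptor sum."""
    if position not in profile.positions:
        raise ValueError(f"position {position!r} not in profile ({profile.positions})")
    scores = {}
    for residue in CANONICAL_RESIDUES:
        scores[residue] = sum(
            profile.weights[(position, comp)]
            * _scaled_descriptor(residue, position, comp, profile, scaler)
            for comp in profile.selection
        )
    # alphabetical tie-break keeps the ranking deterministic
    ranking = sorted(scores.items(), key=lambda it: (-it[1], it[0]))
    degenerate = len({round(v, 12) for v in scores.values()}) == 1
    return ResiduePreference(
        position=position,
        ranking=ranking,
        favored=[r for r, _ in ranking[:k]],
        unfavored=[r for r, _ in ranking[-k:]],
        degenerate=degenerate,
    )


def site_score(
    profile: PositionWeightProfile,
    upstream: Sequence[str],
    downstream: Sequence[str],
    scaler: ScalerParams | None = None,
) -> float:
    """Favorability of a candidate site given flanking residues.

    ``upstream`` and ``downstream`` are listed from the bond outward:
    ``upstream[0]`` is P1, ``upstream[1]`` is P2, ...; ``downstream[0]``
    is P1'.  Either list may be shorter than the profile's half-width.
    Larger values mean a more cleavage-favorable context.
    """
    h = profile.half_width
    if len(upstream) > h or len(downstream) > h:
        raise ValueError(f"at most {h} residues per side for this profile")
    total = 0.0
    for i, residue in enumerate(upstream):
        pos = f"P{i + 1}"
        total += sum(
            profile.weights[(pos, comp)]
            * _scaled_descriptor(residue, pos, comp, profile, scaler)
            for comp in profile.selection
        )
    for i, residue in enumerate(downstream):
        pos = f"P{i + 1}'"
        total += sum(
            profile.weights[(pos, comp)]
            * _scaled_descriptor(residue, pos, comp, profile, scaler)
            for comp in profile.selection
        )
    return total


def hydrophobic_contrast(profile: PositionWeightProfile) -> HydrophobicContrast:
    """Upstream-vs-downstream asymmetry of the hydrophobicity (VHSE1) weights.

    Positive contrast reproduces the signature of proteasomal substrates:
    hydrophobic context upstream of the bond and hydrophilic context
    downstream favor hydrolysis.
    """
    if 1 not in profile.selection:
        raise ValueError("profile does not include VHSE component 1")
    h = profile.half_width
    up = [profile.weights[(f"P{i}", 1)] for i in range(1, h + 1)]
    down = [profile.weights[(f"P{i}'", 1)] for i in range(1, h + 1)]
    return HydrophobicContrast(
        contrast=float(np.mean(up) - np.mean(down)),
        upstream_positive=sum(1 for v in up if v > 0),
        upstream_negative=sum(1 for v in up if v < 0),
        downstream_positive=sum(1 for v in down if v > 0),
        downstream_negative=sum(1 for v in down if v < 0),
    )


def write_profile_tsv(path, profile: PositionWeightProfile) -> None:
    """Rows = positions upstream->downstream, columns = selected components."""
    with open(path, "w") as fh:
        fh.write("position\t" + "\t".join(f"VHSE{c}" for c in profile.selection) + "\n")
        for pos in profile.positions:
            vals = "\t".join(f"{profile.weights[(pos, c)]:.6g}" for c in profile.selection)
            fh.write(f"{pos}\t{vals}\n")


def write_preferences_tsv(
    path,
    profile: PositionWeightProfile,
    scaler: ScalerParams | None = None,
    k: int = 4,
) -> None:
    with open(path, "w") as fh:
        fh.write("position\tfavored\tunfavored\n")
        for pos in profile.positions:
            pref = residue_scores(profile, pos, scaler=scaler, k=k)
            fh.write(f"{pos}\t{', '.join(pref.favored)}\t{', '.join(pref.unfavored)}\n")
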