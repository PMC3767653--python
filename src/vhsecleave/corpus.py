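"""Build labeled cleavage / non-cleavage windows from proteins and ligands.

An MHC-I ligand is a short peptide (typically 8-12 residues) whose
C-terminus was produced by a proteasomal cut in its source protein.  In
Schechter-Berger nomenclature the residues around the scissile bond are
written ``P_n ... P1 | P1' ... P_n'``, with P1 immediately N-terminal to
the cut.  Each located ligand therefore yields

* a *cleavage* sample: the ``2 * half_width`` window centered on the bond
  after the ligand's C-terminal residue (that residue occupies P1), and
* a *non-cleavage* sample: the same-shape window around the bond after the
  ligand's middle residue, a position assumed not to be cut (a cut there
  would have destroyed the ligand).

Windows that would run off either end of the protein are dropped
("insufficient context"), as are windows containing residues outside the
20 canonical amino acids.  Exact duplicate (window, label) pairs are
collapsed, and a window attested as both cleavage and non-cleavage keeps
only its cleavage copy: positive evidence outweighs the positional
heuristic behind the negative.

Coordinates are 0-based internally and 1-based in written reports.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .vhse import is_canonical

__all__ = [
    "LigandRecord",
    "CleavageSample",
    "SampleSet",
    "NOT_FOUND",
    "position_labels",
    "locate_peptide",
    "extract_window",
    "cleavage_site_of",
    "noncleavage_site_of",
    "build_sample_set",
    "trim_samples",
    "read_proteins_fasta",
    "read_ligands_tsv",
    "write_ligands_tsv",
    "write_samples_tsv",
    "read_samples_tsv",
    "write_drop_log",
]

logger = logging.getLogger(__name__)

CLEAVAGE = "cleavage"
NON_CLEAVAGE = "non_cleavage"

#: sentinel returned by :func:`locate_peptide` when the peptide is absent
NOT_FOUND: int = -1


@dataclass(frozen=True)
class LigandRecord:
    """A ligand/digest peptide and the identifier of its source protein."""

    peptide: str
    source_id: str


@dataclass(frozen=True)
class CleavageSample:
    """A labeled residue window centered on a putative scissile bond.

    ``site_index`` is the 0-based index, in the source protein, of the
    residue occupying P1 (the residue immediately upstream of the bond).
    """

    window: str
    label: str
    site_index: int
    source_id: str
    peptide: str
    match_offset: int


@dataclass
class SampleSet:
    samples: list[CleavageSample]
    half_width: int
    stats: Counter = field(default_factory=Counter)

    def __len__(self) -> int:
        return len(self.samples)

    def count(self, label: str) -> int:
        return sum(1 for s in self.samples if s.label == label)


def position_labels(half_width: int) -> list[str]:
    """Window position names from upstream to downstream.

    For ``half_width`` h: ``P_h ... P1, P1' ... P_h'``.  P1 sits at
    0-based window index ``h - 1``, immediately left of the scissile bond.
    """
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    return [f"P{half_width - i}" for i in range(half_width)] + [
        f"P{i + 1}'" for i in range(half_width)
    ]


def locate_peptide(protein: str, peptide: str) -> int:
    """0-based offset of the first exact occurrence of ``peptide``, or NOT_FOUND.

    Warns when the peptide occurs more than once; the first occurrence is
    used deterministically.
    """
    if not peptide:
        return NOT_FOUND
    offset = protein.find(peptide)
    if offset == NOT_FOUND:
        return NOT_FOUND
    if protein.find(peptide, offset + 1) != -1:
        logger.warning(
            "peptide %s occurs more than once in its source protein; using first match",
            peptide,
        )
    return offset


def extract_window(protein: str, p1_index: int, half_width: int) -> str | None:
    """Residue window of ``half_width`` on each side of the bond after P1.

    Returns ``protein[p1_index - half_width + 1 : p1_index + half_width + 1]``
    when the full span exists, else ``None`` (insufficient context).
    """
    if not 0 <= p1_index < len(protein):
        raise IndexError(f"p1_index {p1_index} out of bounds for protein of length {len(protein)}")
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    start = p1_index - half_width + 1
    stop = p1_index + half_width + 1
    if start < 0 or stop > len(protein):
        return None
    return protein[start:stop]


def cleavage_site_of(ligand: LigandRecord, match_offset: int) -> int:
    """P1 index of the cleavage site: the ligand's C-terminal residue."""
    return match_offset + len(ligand.peptide) - 1


def noncleavage_site_of(ligand: LigandRecord, match_offset: int) -> int:
    """P1 index of the presumed non-cleavage site: the ligand's middle residue.

    For even-length ligands the residue just upstream of center is used
    (ceil(L/2)), keeping the presumed-uncut bond strictly interior.
    """
    return match_offset + math.ceil(len(ligand.peptide) / 2) - 1


def _dedup(samples: Iterable[CleavageSample], stats: Counter) -> list[CleavageSample]:
    """Collapse duplicate (window, label) pairs; cleavage wins label conflicts."""
    by_key: dict[tuple[str, str], CleavageSample] = {}
    for s in samples:
        key = (s.window, s.label)
        if key in by_key:
            stats["duplicate_collapsed"] += 1
        else:
            by_key[key] = s
    out = []
    for (window, label), s in by_key.items():
        if label == NON_CLEAVAGE and (window, CLEAVAGE) in by_key:
            stats["label_conflict_dropped"] += 1
            continue
        out.append(s)
    return out


def build_sample_set(
    proteins: Mapping[str, str],
    ligands: Sequence[LigandRecord],
    half_width: int,
) -> SampleSet:
    """Run the full pretreatment: locate, window, label, filter, deduplicate.

    Every locatable ligand with full flanking context contributes one
    cleavage and one non-cleavage sample; drops are tallied by reason in
    ``stats``.
    """
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    stats: Counter = Counter()
    raw: list[CleavageSample] = []
    for lig in ligands:
        protein = proteins.get(lig.source_id)
        if protein is None:
            stats["source_not_found"] += 1
            continue
        offset = locate_peptide(protein, lig.peptide)
        if offset == NOT_FOUND:
            stats["peptide_not_found"] += 1
            continue
        for label, p1 in (
            (CLEAVAGE, cleavage_site_of(lig, offset)),
            (NON_CLEAVAGE, noncleavage_site_of(lig, offset)),
        ):
            window = extract_window(protein, p1, half_width)
            if window is None:
                stats[f"insufficient_context_{label}"] += 1
                continue
            if not is_canonical(window):
                stats["noncanonical_window"] += 1
                continue
            raw.append(
                CleavageSample(window, label, p1, lig.source_id, lig.peptide, offset)
            )
    samples = _dedup(raw, stats)
    for reason, n in stats.items():
        logger.info("pretreatment drop/merge: %s = %d", reason, n)
    return SampleSet(samples=samples, half_width=half_width, stats=stats)


def trim_samples(sample_set: SampleSet, new_half_width: int) -> SampleSet:
    """Symmetrically trim every window about the scissile bond, then re-dedup."""
    h = sample_set.half_width
    if new_half_width > h:
        raise ValueError(
            f"cannot trim to half_width {new_half_width} > current {h}"
        )
    if new_half_width < 1:
        raise ValueError("half_width must be >= 1")
    lo, hi = h - new_half_width, h + new_half_width
    stats: Counter = Counter(sample_set.stats)
    trimmed = [
        CleavageSample(
            s.window[lo:hi], s.label, s.site_index, s.source_id, s.peptide, s.match_offset
        )
        for s in sample_set.samples
    ]
    return SampleSet(_dedup(trimmed, stats), new_half_width, stats)


# -- file formats -----------------------------------------------------------

def read_proteins_fasta(path) -> dict[str, str]:
    """Read protein sequences keyed by FASTA record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_ligands_tsv(path) -> list[LigandRecord]:
    """Read ligand records from TSV with header ``peptide<TAB>source_id``."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["peptide", "source_id"]:
            raise ValueError(
                f"expected ligand TSV header 'peptide\\tsource_id', got {header!r}"
            )
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            peptide, source_id = line.split("\t")[:2]
            records.append(LigandRecord(peptide.upper(), source_id))
    return records


def write_ligands_tsv(path, ligands: Sequence[LigandRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("peptide\tsource_id\n")
        for lig in ligands:
            fh.write(f"{lig.peptide}\t{lig.source_id}\n")


def write_samples_tsv(path, sample_set: SampleSet) -> None:
    """Write samples as TSV; site coordinates are 1-based in files."""
    with open(path, "w") as fh:
        fh.write("window\tlabel\tsource_id\tsite_index_1based\n")
        for s in sample_set.samples:
            fh.write(f"{s.window}\t{s.label}\t{s.source_id}\t{s.site_index + 1}\n")


def read_samples_tsv(path) -> SampleSet:
    samples = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "window":
            raise ValueError(f"unexpected samples TSV header: {header!r}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            window, label, source_id, site_1based = line.split("\t")[:4]
            samples.append(
                CleavageSample(window, label, int(site_1based) - 1, source_id, "", -1)
            )
    if not samples:
        return SampleSet([], half_width=0)
    lengths = {len(s.window) for s in samples}
    if len(lengths) != 1 or next(iter(lengths)) % 2:
        raise ValueError("samples TSV windows must share one even length")
    return SampleSet(samples, half_width=next(iter(lengths)) // 2)


def write_drop_log(path, stats: Counter) -> None:
    with open(path, "w") as fh:
        fh.write("reason\tcount\n")
        for reason in sorted(stats):
            fh.write(f"{reason}\t{stats[reason]}\n")
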