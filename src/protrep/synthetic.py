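"""Synthetic protein families with known motif/label structure.

Each family is defined by a small set of conserved sequence motifs. A
member sequence is an i.i.d. random background into which the family's
motif copies are spliced at random positions, each copy independently
point-mutated at a configurable rate. Three ontologies are emitted:

``function``
    derived deterministically from motif content (one label per family,
    multi-label only where motifs are shared across families);
``domain``
    one label per motif present in the sequence;
``taxonomy``
    assigned uniformly at random, independent of the sequence.

This function-vs-taxonomy contrast is the property the benchmark modules
exercise: a sequence-based representation can recover motif-derived
labels from neighbors but has no information about the random ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import CANONICAL_AA, AnnotationTable, ProteinRecord

FUNCTION_ONTOLOGY = "function"
DOMAIN_ONTOLOGY = "domain"
TAXONOMY_ONTOLOGY = "taxonomy"

#: approximate natural amino-acid frequencies (UniProtKB composition, %),
#: in alphabetical residue order; normalize before use. A language model's
#: first learnable statistic is residue composition, so corpora meant to
#: exercise LM training should use this rather than a uniform background.
NATURAL_AA_PERCENT = (8.25, 1.37, 5.45, 6.75, 3.86, 7.07, 2.27, 5.96, 5.84, 9.66,
                      2.42, 4.06, 4.70, 3.93, 5.53, 6.56, 5.34, 6.87, 1.08, 2.92)


def natural_composition() -> tuple[float, ...]:
    """Normalized natural residue distribution for FamilySpec."""
    p = np.asarray(NATURAL_AA_PERCENT, dtype=float)
    return tuple(p / p.sum())


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of the generator.

    Defaults give 5 families x 40 members of ~116 residues with two
    10-residue motifs each, mutated at 10% per position — enough motif
    signal for k-mer representations to separate families while leaving
    most of the sequence as neutral background.
    """

    n_families: int = 5
    members_per_family: int = 40
    motif_length: int = 10
    motifs_per_family: int = 2
    background_length: int = 96
    substitution_rate: float = 0.1
    residue_distribution: tuple[float, ...] | None = None  # 20-simplex; None = uniform
    n_taxa: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_families", "members_per_family", "motif_length",
                     "motifs_per_family", "background_length", "n_taxa"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must lie in [0, 1]")
        if self.residue_distribution is not None:
            p = np.asarray(self.residue_distribution, dtype=float)
            if p.shape != (20,) or p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("residue_distribution must be a 20-simplex vector")

    @property
    def sequence_length(self) -> int:
        return self.background_length + self.motifs_per_family * self.motif_length


@dataclass
class SyntheticCorpus:
    """Generated proteins plus ground truth.

    ``truth`` maps protein id -> {"family": family label,
    "motif_positions": [(start, end, motif label), ...]}.
    """

    proteins: list[ProteinRecord]
    annotations: AnnotationTable
    truth: dict[str, dict]
    spec: FamilySpec
    family_motifs: dict[str, list[str]] = field(default_factory=dict)

    def family_of(self, protein_id: str) -> str:
        return self.truth[protein_id]["family"]


def _random_sequence(rng: np.random.Generator, length: int, p: np.ndarray | None) -> str:
    letters = rng.choice(list(CANONICAL_AA), size=length, p=p)
    return "".join(letters)


def _mutate(rng: np.random.Generator, motif: str, rate: float) -> str:
    if rate == 0.0:
        return motif
    out = list(motif)
    hits = rng.random(len(out)) < rate
    for i in np.flatnonzero(hits):
        alternatives = [a for a in CANONICAL_AA if a != out[i]]
        out[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def _splice(rng: np.random.Generator, background: str, pieces: list[tuple[str, str]]
            ) -> tuple[str, list[tuple[int, int, str]]]:
    """Insert pieces (sequence, label) at random cut points of the background."""
    cuts = sorted(rng.integers(0, len(background) + 1, size=len(pieces)))
    order = rng.permutation(len(pieces))
    out: list[str] = []
    positions: list[tuple[int, int, str]] = []
    prev = 0
    offset = 0
    for cut, j in zip(cuts, order):
        piece, label = pieces[j]
        out.append(background[prev:cut])
        start = cut + offset
        out.append(piece)
        positions.append((start, start + len(piece), label))
        offset += len(piece)
        prev = cut
    out.append(background[prev:])
    return "".join(out), positions


def generate_corpus(spec: FamilySpec) -> SyntheticCorpus:
    """Generate a fully reproducible corpus from a :class:`FamilySpec`."""
    if spec.motif_length * spec.motifs_per_family > spec.background_length:
        raise ValueError(
            "motifs exceed the total length budget: conserved content "
            f"({spec.motif_length * spec.motifs_per_family}) would outweigh the "
            f"random background ({spec.background_length})"
        )
    rng = np.random.default_rng(spec.seed)
    p = (np.asarray(spec.residue_distribution, dtype=float)
         if spec.residue_distribution is not None else None)

    family_motifs: dict[str, list[str]] = {}
    seen_motifs: set[str] = set()
    motif_labels: dict[str, str] = {}
    for f in range(spec.n_families):
        fam = f"FAM{f:03d}"
        motifs: list[str] = []
        while len(motifs) < spec.motifs_per_family:
            m = _random_sequence(rng, spec.motif_length, p)
            if m not in seen_motifs:
                seen_motifs.add(m)
                motifs.append(m)
                motif_labels[m] = f"MOT{len(motif_labels):03d}"
        family_motifs[fam] = motifs

    proteins: list[ProteinRecord] = []
    annotations = AnnotationTable()
    truth: dict[str, dict] = {}
    for f in range(spec.n_families):
        fam = f"FAM{f:03d}"
        for j in range(spec.members_per_family):
            pid = f"{fam}_P{j:03d}"
            background = _random_sequence(rng, spec.background_length, p)
            pieces = [(_mutate(rng, m, spec.substitution_rate), motif_labels[m])
                      for m in family_motifs[fam]]
            seq, positions = _splice(rng, background, pieces)
            proteins.append(ProteinRecord(pid, seq))
            truth[pid] = {"family": fam, "motif_positions": positions}
            annotations.add(pid, FUNCTION_ONTOLOGY, fam)
            for m in family_motifs[fam]:
                annotations.add(pid, DOMAIN_ONTOLOGY, motif_labels[m])
            annotations.add(pid, TAXONOMY_ONTOLOGY, f"TAX{rng.integers(spec.n_taxa):03d}")

    return SyntheticCorpus(proteins, annotations, truth, spec, family_motifs)


def inject_shared_motif(corpus: SyntheticCorpus, family_ids: Sequence[str],
                        motif: str, seed: int | None = None) -> SyntheticCorpus:
    """Return a new corpus where all members of ``family_ids`` carry ``motif``.

    The motif is inserted at a random position of each member and every
    carrier gains a shared ``domain`` label, modelling cross-family
    similarity (families whose enzymes share substrates). An empty family
    list returns an unchanged copy.
    """
    known = set(corpus.family_motifs)
    unknown = [f for f in family_ids if f not in known]
    if unknown:
        raise ValueError(f"unknown family ids: {', '.join(unknown)}")
    if len(motif) > corpus.spec.background_length:
        raise ValueError("shared motif longer than the background length budget")

    shared_label = f"MOTSHARED_{motif[:6]}"
    rng = np.random.default_rng(corpus.spec.seed + 7919 if seed is None else seed)
    targets = set(family_ids)
    proteins: list[ProteinRecord] = []
    annotations = AnnotationTable()
    truth: dict[str, dict] = {}
    for rec in corpus.proteins:
        fam = corpus.family_of(rec.id)
        positions = list(corpus.truth[rec.id]["motif_positions"])
        seq = rec.sequence
        if fam in targets:
            mutated = _mutate(rng, motif, corpus.spec.substitution_rate)
            cut = int(rng.integers(0, len(seq) + 1))
            seq = seq[:cut] + mutated + seq[cut:]
            positions = [(s + len(motif), e + len(motif), lab) if s >= cut else (s, e, lab)
                         for s, e, lab in positions]
            positions.append((cut, cut + len(motif), shared_label))
        proteins.append(ProteinRecord(rec.id, seq))
        truth[rec.id] = {"family": fam, "motif_positions": positions}
        for _, _, lab in positions:
            if lab != corpus.truth[rec.id].get("family"):
                annotations.add(rec.id, DOMAIN_ONTOLOGY, lab)
        for ont in (FUNCTION_ONTOLOGY, TAXONOMY_ONTOLOGY):
            for lab in corpus.annotations.labels(rec.id, ont):
                annotations.add(rec.id, ont, lab)
    return SyntheticCorpus(proteins, annotations, truth, corpus.spec,
                           dict(corpus.family_motifs))
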