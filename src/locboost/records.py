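"""Core domain types: protein records, label vocabularies, PSSM matrices.

A protein is an identifier, an amino-acid sequence over the 20-letter
alphabet (plus ``X`` for unknown residues), and a possibly empty set of
subcellular location labels.  A protein may reside in several compartments
at once, which is what makes localization a multi-label problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 20 proteinogenic amino acids in alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residues accepted in input sequences (``X`` = unknown).
ALPHABET = frozenset(AMINO_ACIDS + "X")

#: Canonical PSI-BLAST column order for PSSM score matrices.
PSSM_COLUMNS = "ARNDCQEGHILKMFPSTWYV"

#: The 12 subcellular locations of the Hum-mPloc 3.0 label set, used as
#: default names by the synthetic generator.
HUMAN_LOCATIONS = (
    "Centrosome",
    "Cytoplasm",
    "Cytoskeleton",
    "Endoplasmic reticulum",
    "Endosome",
    "Extracellular",
    "Golgi apparatus",
    "Lysosome",
    "Mitochondrion",
    "Nucleus",
    "Peroxisome",
    "Plasma membrane",
)


@dataclass
class ProteinRecord:
    """One protein: unique id, amino-acid sequence, set of location labels."""

    id: str
    sequence: str
    labels: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r}: sequence is empty")
        bad = [
            (i, c) for i, c in enumerate(self.sequence) if c not in ALPHABET
        ]
        if bad:
            i, c = bad[0]
            raise ValueError(
                f"protein {self.id!r}: invalid residue {c!r} at position {i}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LabelVocabulary:
    """Ordered set of location names; order is always sorted name order."""

    locations: tuple[str, ...]

    def __post_init__(self) -> None:
        if list(self.locations) != sorted(set(self.locations)):
            raise ValueError("vocabulary must be sorted and duplicate-free")

    @classmethod
    def from_labels(cls, label_sets) -> "LabelVocabulary":
        names: set[str] = set()
        for labels in label_sets:
            names.update(labels)
        return cls(tuple(sorted(names)))

    @property
    def index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.locations)}

    def __len__(self) -> int:
        return len(self.locations)

    def __contains__(self, name: str) -> bool:
        return name in self.locations

    def __iter__(self):
        return iter(self.locations)

    def encode(self, label_sets) -> np.ndarray:
        """Binary indicator matrix, one row per label set, sorted columns."""
        idx = self.index
        Y = np.zeros((len(label_sets), len(self.locations)), dtype=float)
        for i, labels in enumerate(label_sets):
            for name in labels:
                if name not in idx:
                    raise KeyError(f"label {name!r} not in vocabulary")
                Y[i, idx[name]] = 1.0
        return Y

    def decode(self, indicator: np.ndarray) -> list[set[str]]:
        """Inverse of :meth:`encode`."""
        indicator = np.asarray(indicator)
        return [
            {self.locations[j] for j in np.flatnonzero(row)}
            for row in indicator
        ]


@dataclass
class PSSMMatrix:
    """Per-residue 20-column log-odds profile in PSI-BLAST column order."""

    protein_id: str
    residues: str
    scores: np.ndarray  # (seq_len, 20) integers

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError("PSSM scores must have exactly 20 columns")
        if self.scores.shape[0] != len(self.residues):
            raise ValueError(
                f"PSSM for {self.protein_id!r}: {self.scores.shape[0]} rows "
                f"but {len(self.residues)} residues"
            )
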