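"""Readers and writers for the formats the pipeline touches.

FASTA goes through Biopython, tabular files (labels, predictions,
interaction matrices, reports) through pandas, PSSMs through a parser for
the PSI-BLAST ASCII layout, and trained pipelines through a joblib bundle
carrying a small manifest.
"""

from __future__ import annotations

import logging
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import ALPHABET, LabelVocabulary, ProteinRecord, PSSMMatrix

logger = logging.getLogger(__name__)

BUNDLE_FORMAT = "locboost-bundle"
BUNDLE_VERSION = 1


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[ProteinRecord]:
    """Read protein sequences; labels are left empty.

    The id is the header token up to the first whitespace.  Sequences are
    upper-cased and a terminal ``*`` (stop) is stripped.  Duplicate ids,
    empty sequences and out-of-alphabet residues are hard errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate protein id {entry.id!r} in {path}")
        seen.add(entry.id)
        seq = str(entry.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise ValueError(f"empty sequence for protein {entry.id!r}")
        bad = [(i, c) for i, c in enumerate(seq) if c not in ALPHABET]
        if bad:
            i, c = bad[0]
            raise ValueError(
                f"protein {entry.id!r}: invalid residue {c!r} at position {i}"
            )
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    return records


def write_fasta(records: list[ProteinRecord], path) -> None:
    entries = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(entries, str(path), "fasta")


# ---------------------------------------------------------------------------
# Label tables (TSV: columns id, labels; labels ';'-separated)

def read_labels(
    path, vocabulary: LabelVocabulary | None = None
) -> tuple[dict[str, set[str]], LabelVocabulary]:
    """Read an id → label-set table; infer the vocabulary when not given."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "id" not in df.columns or "labels" not in df.columns:
        raise ValueError(f"{path}: label TSV needs 'id' and 'labels' columns")
    dupes = df["id"][df["id"].duplicated()]
    if not dupes.empty:
        raise ValueError(f"{path}: duplicate id {dupes.iloc[0]!r}")
    mapping: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        cell = row["labels"].strip()
        labels = {tok for tok in (t.strip() for t in cell.split(";")) if tok}
        if not labels:
            logger.warning("protein %r has no labels", row["id"])
        mapping[row["id"]] = labels
    if vocabulary is None:
        vocabulary = LabelVocabulary.from_labels(mapping.values())
    else:
        for pid, labels in mapping.items():
            unknown = labels - set(vocabulary.locations)
            if unknown:
                raise ValueError(
                    f"{path}: label {sorted(unknown)[0]!r} of protein "
                    f"{pid!r} not in vocabulary"
                )
    return mapping, vocabulary


def write_labels(mapping: dict[str, set[str]], path) -> None:
    df = pd.DataFrame(
        {
            "id": list(mapping),
            "labels": [";".join(sorted(v)) for v in mapping.values()],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def attach_labels(
    records: list[ProteinRecord], mapping: dict[str, set[str]]
) -> None:
    for rec in records:
        rec.labels = set(mapping.get(rec.id, set()))


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM

def read_pssm(path, protein_id: str | None = None) -> PSSMMatrix:
    """Parse the ASCII PSSM layout produced by PSI-BLAST.

    Data rows start with a position number and a residue letter followed by
    at least 20 integers; any further columns (the weighted-percentage and
    information-content block) are ignored.  A row that starts like a data
    row but cannot supply 20 integers is a hard error naming the line.
    """
    path = Path(path)
    residues: list[str] = []
    rows: list[list[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if len(tokens) < 2:
                continue
            if not tokens[0].isdigit():
                continue
            if not (len(tokens[1]) == 1 and tokens[1].isalpha()):
                continue
            try:
                scores = [int(t) for t in tokens[2:22]]
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed PSSM row: {exc}"
                ) from None
            if len(scores) != 20:
                raise ValueError(
                    f"{path}:{lineno}: expected 20 scores, got {len(scores)}"
                )
            if int(tokens[0]) != len(rows) + 1:
                raise ValueError(
                    f"{path}:{lineno}: position {tokens[0]} out of order"
                )
            residues.append(tokens[1].upper())
            rows.append(scores)
    if not rows:
        raise ValueError(f"{path}: no PSSM data rows found")
    return PSSMMatrix(
        protein_id=protein_id or path.stem,
        residues="".join(residues),
        scores=np.array(rows, dtype=int),
    )


def write_pssm(pssm: PSSMMatrix, path) -> None:
    """Write a PSSM in the PSI-BLAST ASCII layout (score block only)."""
    from .records import PSSM_COLUMNS

    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        fh.write(" " * 11 + "".join(f"{c:>4}" for c in PSSM_COLUMNS) + "\n")
        for i, (res, row) in enumerate(zip(pssm.residues, pssm.scores), 1):
            cells = "".join(f"{int(v):>4d}" for v in row)
            fh.write(f"{i:>5d} {res} {cells}\n")


def check_pssm_against_sequence(pssm: PSSMMatrix, record: ProteinRecord):
    if len(pssm.residues) != len(record.sequence):
        raise ValueError(
            f"PSSM for {record.id!r} has {len(pssm.residues)} rows but the "
            f"sequence has {len(record.sequence)} residues"
        )


# ---------------------------------------------------------------------------
# Interaction score matrix (TSV with id header row and column)

def read_ppi_matrix(path) -> pd.DataFrame:
    """Read a symmetric protein–protein interaction score matrix.

    Values outside [0, 1] are clipped with a warning.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    vals = df.to_numpy(dtype=float)
    if (vals < 0).any() or (vals > 1).any():
        logger.warning("interaction scores outside [0, 1] clipped")
        df = df.clip(0.0, 1.0)
    return df


def write_ppi_matrix(ids: list[str], matrix: np.ndarray, path) -> None:
    pd.DataFrame(matrix, index=ids, columns=ids).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Model bundle

def save_model(bundle: dict, path) -> None:
    """Persist a trained pipeline with a manifest, as one joblib archive."""
    payload = {
        "format": BUNDLE_FORMAT,
        "version": BUNDLE_VERSION,
        **bundle,
    }
    joblib.dump(payload, path)


def load_model(path) -> dict:
    try:
        payload = joblib.load(path)
    except Exception as exc:  # truncated / corrupt archive
        raise ValueError(f"cannot load model bundle {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != BUNDLE_FORMAT:
        raise ValueError(f"{path} is not a locboost model bundle")
    if payload.get("version") != BUNDLE_VERSION:
        raise ValueError(
            f"{path}: bundle version {payload.get('version')} is not "
            f"supported (expected {BUNDLE_VERSION})"
        )
    return payload
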