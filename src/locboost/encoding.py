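"""Similarity-profile encoding of proteins.

A protein is represented as an L×1 vector of similarities to the L training
proteins, in the frozen training order.  Two sequence backends are
provided: cosine similarity of overlapping k-mer count vectors (default,
k=3) and cosine similarity of column-averaged PSSM rows when per-protein
PSSMs are available.  An optional precomputed interaction score matrix can
be folded in as a convex combination

    profile[j] = alpha * seq_sim(x, train_j) + (1 - alpha) * ppi(x, train_j)

with ``alpha = 1`` (sequence only) when no matrix is supplied.
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .records import ProteinRecord, PSSMMatrix

logger = logging.getLogger(__name__)


def kmer_profile(sequence: str, k: int) -> Counter:
    """Counts of all overlapping k-mers; total equals ``len - k + 1``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(sequence):
        raise ValueError(
            f"k={k} exceeds sequence length {len(sequence)}"
        )
    return Counter(sequence[i : i + k] for i in range(len(sequence) - k + 1))


def _cosine(a: Counter, b: Counter) -> float:
    na = np.sqrt(sum(v * v for v in a.values()))
    nb = np.sqrt(sum(v * v for v in b.values()))
    if na == 0.0 or nb == 0.0:
        return 0.0
    if len(b) < len(a):
        a, b = b, a
    dot = sum(v * b[kmer] for kmer, v in a.items())
    return float(dot / (na * nb))


def _pssm_summary(pssm: PSSMMatrix) -> np.ndarray:
    """Column-averaged PSSM rows: one 20-vector per protein."""
    return pssm.scores.mean(axis=0).astype(float)


def _pssm_cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    # rescale cosine from [-1, 1] to [0, 1]
    return float((u @ v / (nu * nv) + 1.0) / 2.0)


class SimilarityProfileEncoder(TransformerMixin, BaseEstimator):
    """Encode proteins as similarity profiles against the training set.

    Parameters
    ----------
    backend : {"kmer", "pssm"}
        Sequence-similarity backend.  ``kmer`` needs only the sequences;
        ``pssm`` needs a PSSM per protein (training and query).
    k : int
        k-mer length for the ``kmer`` backend.
    alpha : float
        Weight of sequence similarity versus interaction similarity.
        Forced to 1 when no interaction matrix is supplied.
    ppi : pandas.DataFrame, optional
        Symmetric interaction score matrix indexed by protein id.
    pssms : dict[str, PSSMMatrix], optional
        Per-protein PSSMs for the ``pssm`` backend.

    Attributes
    ----------
    training_ids_ : list[str]
        Training protein ids in frozen input order; the profile length L.
    """

    def __init__(
        self,
        backend: str = "kmer",
        k: int = 3,
        alpha: float = 1.0,
        ppi: pd.DataFrame | None = None,
        pssms: dict[str, PSSMMatrix] | None = None,
    ):
        self.backend = backend
        self.k = k
        self.alpha = alpha
        self.ppi = ppi
        self.pssms = pssms

    # -- fitting ----------------------------------------------------------

    def fit(self, records: list[ProteinRecord], y=None):
        if not records:
            raise ValueError("training set must be non-empty")
        if self.backend not in ("kmer", "pssm"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        self.alpha_ = 1.0 if self.ppi is None else float(self.alpha)
        self.training_ids_ = [r.id for r in records]
        if self.backend == "kmer":
            self._train_mat_ = self._kmer_matrix(records, fit_vocab=True)
        else:
            self._train_summaries_ = np.stack(
                [self._summary_for(r) for r in records]
            )
        return self

    def _summary_for(self, record: ProteinRecord) -> np.ndarray:
        if self.pssms is None or record.id not in self.pssms:
            raise ValueError(
                f"pssm backend: no PSSM supplied for protein {record.id!r}"
            )
        return _pssm_summary(self.pssms[record.id])

    def _kmer_matrix(self, records, fit_vocab: bool) -> sparse.csr_matrix:
        """Row-normalized sparse k-mer count matrix (shared vocabulary)."""
        if fit_vocab:
            self._vocab_: dict[str, int] = {}
        vocab = self._vocab_
        data, indices, indptr = [], [], [0]
        norms = np.empty(len(records))
        for row, rec in enumerate(records):
            prof = kmer_profile(rec.sequence, self.k)
            # norm over the full profile: k-mers outside the training
            # vocabulary contribute nothing to any dot product, but they
            # still count toward the query's length
            norms[row] = np.sqrt(sum(v * v for v in prof.values()))
            for kmer, count in prof.items():
                if kmer not in vocab:
                    if not fit_vocab:
                        continue
                    vocab[kmer] = len(vocab)
                indices.append(vocab[kmer])
                data.append(float(count))
            indptr.append(len(data))
        mat = sparse.csr_matrix(
            (data, indices, indptr),
            shape=(len(records), max(len(vocab), 1)),
        )
        zero = norms == 0.0
        if zero.any():
            logger.warning(
                "%d sequence(s) with zero-norm k-mer profile; their "
                "similarities are defined as 0",
                int(zero.sum()),
            )
        inv = np.where(zero, 0.0, 1.0 / np.where(zero, 1.0, norms))
        return sparse.diags(inv) @ mat

    # -- encoding ---------------------------------------------------------

    def transform(self, records: list[ProteinRecord]) -> np.ndarray:
        """n × L matrix of similarity profiles, entries in [0, 1]."""
        check_is_fitted(self, "training_ids_")
        if self.backend == "kmer":
            query = self._kmer_matrix(records, fit_vocab=False)
            # pad query columns if the fitted vocabulary is wider
            if query.shape[1] < self._train_mat_.shape[1]:
                query = sparse.hstack(
                    [
                        query,
                        sparse.csr_matrix(
                            (query.shape[0],
                             self._train_mat_.shape[1] - query.shape[1])
                        ),
                    ]
                ).tocsr()
            seq_sim = (query @ self._train_mat_.T).toarray()
        else:
            summaries = np.stack([self._summary_for(r) for r in records])
            seq_sim = np.array(
                [
                    [_pssm_cosine(u, v) for v in self._train_summaries_]
                    for u in summaries
                ]
            )
        seq_sim = np.clip(seq_sim, 0.0, 1.0)
        if self.alpha_ >= 1.0:
            return seq_sim
        ppi_sim = np.empty_like(seq_sim)
        for i, rec in enumerate(records):
            if rec.id not in self.ppi.index:
                raise KeyError(
                    f"protein {rec.id!r} missing from interaction matrix"
                )
            row = self.ppi.loc[rec.id]
            for j, tid in enumerate(self.training_ids_):
                if tid not in row.index:
                    raise KeyError(
                        f"training protein {tid!r} missing from "
                        "interaction matrix"
                    )
                ppi_sim[i, j] = row[tid]
        return self.alpha_ * seq_sim + (1.0 - self.alpha_) * ppi_sim


# ---------------------------------------------------------------------------
# Functional wrappers

def sequence_similarity(
    a: ProteinRecord, b: ProteinRecord, state: SimilarityProfileEncoder
) -> float:
    """Pairwise sequence similarity under the fitted encoder's backend."""
    check_is_fitted(state, "training_ids_")
    if state.backend == "kmer":
        return _cosine(
            kmer_profile(a.sequence, state.k), kmer_profile(b.sequence, state.k)
        )
    return _pssm_cosine(state._summary_for(a), state._summary_for(b))


def fit_encoder(
    train: list[ProteinRecord], **options
) -> SimilarityProfileEncoder:
    return SimilarityProfileEncoder(**options).fit(train)


def encode(
    record: ProteinRecord, state: SimilarityProfileEncoder
) -> np.ndarray:
    """L-vector similarity profile for a single protein."""
    return state.transform([record])[0]
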