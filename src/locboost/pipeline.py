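"""End-to-end predictor: similarity encoding → CNN features → boosted trees.

The pipeline fits the similarity-profile encoder on the training set,
trains the CNN on the profiles with the multi-label BCE objective, takes
the CNN's last hidden layer as the feature representation, and fits one
second-order boosted-tree ensemble per location (binary relevance).  At
prediction time, per-location probabilities ≥ threshold become the
predicted label set; a protein whose set would be empty receives its
single highest-probability location, since every protein resides
somewhere.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from . import io as lio
from .boosting import BinaryRelevanceClassifier
from .cnn import ConvNetFeatureExtractor
from .encoding import SimilarityProfileEncoder
from .metrics import EvaluationReport, PredictionSet, evaluate
from .records import LabelVocabulary, ProteinRecord
from .synthetic import SynthConfig, generate_dataset

logger = logging.getLogger(__name__)


def probabilities_to_sets(
    proba: np.ndarray, vocabulary: LabelVocabulary, threshold: float
) -> list[set[str]]:
    """Threshold per-location probabilities; argmax fallback for empty sets."""
    sets = []
    names = vocabulary.locations
    for row in np.asarray(proba):
        chosen = {names[j] for j in np.flatnonzero(row >= threshold)}
        if not chosen:
            chosen = {names[int(np.argmax(row))]}
        sets.append(chosen)
    return sets


class ProteinLocalizationPipeline(BaseEstimator):
    """The full CNN + boosted-trees localization predictor.

    All stage seeds derive deterministically from ``seed``; two fits with
    identical inputs and parameters produce identical predictions.
    """

    def __init__(
        self,
        backend: str = "kmer",
        k: int = 3,
        alpha: float = 1.0,
        conv_blocks=((16, 5, 2), (32, 5, 2)),
        fc_sizes=(64, 32),
        epochs: int = 30,
        batch_size: int = 32,
        cnn_learning_rate: float = 1e-3,
        loss: str = "bce",
        n_rounds: int = 100,
        gbt_learning_rate: float = 0.3,
        max_depth: int = 3,
        reg_lambda: float = 1.0,
        gamma: float = 0.0,
        min_child_hessian: float = 1e-3,
        threshold: float = 0.5,
        seed: int = 0,
        ppi=None,
        pssms=None,
    ):
        self.backend = backend
        self.k = k
        self.alpha = alpha
        self.conv_blocks = conv_blocks
        self.fc_sizes = fc_sizes
        self.epochs = epochs
        self.batch_size = batch_size
        self.cnn_learning_rate = cnn_learning_rate
        self.loss = loss
        self.n_rounds = n_rounds
        self.gbt_learning_rate = gbt_learning_rate
        self.max_depth = max_depth
        self.reg_lambda = reg_lambda
        self.gamma = gamma
        self.min_child_hessian = min_child_hessian
        self.threshold = threshold
        self.seed = seed
        self.ppi = ppi
        self.pssms = pssms

    def fit(self, records: list[ProteinRecord], y=None):
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        labeled = [r for r in records if r.labels]
        if not labeled:
            raise ValueError("training records carry no labels")
        self.vocabulary_ = LabelVocabulary.from_labels(
            r.labels for r in labeled
        )
        self.encoder_ = SimilarityProfileEncoder(
            backend=self.backend, k=self.k, alpha=self.alpha,
            ppi=self.ppi, pssms=self.pssms,
        ).fit(records)
        X = self.encoder_.transform(records)
        Y = self.vocabulary_.encode([r.labels for r in records])
        logger.info(
            "encoded %d training proteins -> %s profiles", len(records),
            X.shape,
        )
        self.cnn_ = ConvNetFeatureExtractor(
            conv_blocks=self.conv_blocks,
            fc_sizes=self.fc_sizes,
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.cnn_learning_rate,
            loss=self.loss,
            seed=(self.seed * 7919 + 1) % (2**31),
        ).fit(X, Y)
        logger.info(
            "CNN trained; final epoch loss %.4f",
            self.cnn_.loss_history_[-1] if self.cnn_.loss_history_ else float("nan"),
        )
        features = self.cnn_.transform(X)
        self.classifier_ = BinaryRelevanceClassifier(
            n_rounds=self.n_rounds,
            learning_rate=self.gbt_learning_rate,
            max_depth=self.max_depth,
            reg_lambda=self.reg_lambda,
            gamma=self.gamma,
            min_child_hessian=self.min_child_hessian,
            threshold=self.threshold,
            seed=(self.seed * 7919 + 2) % (2**31),
        ).fit(features, Y)
        logger.info(
            "boosted %d per-location ensembles on %d-dim features",
            len(self.classifier_.estimators_), features.shape[1],
        )
        return self

    # -- inference --------------------------------------------------------

    def predict_proba(self, records: list[ProteinRecord]) -> np.ndarray:
        X = self.encoder_.transform(records)
        return self.classifier_.predict_proba(self.cnn_.transform(X))

    def predict(
        self, records: list[ProteinRecord], threshold: float | None = None
    ) -> list[set[str]]:
        thr = self.threshold if threshold is None else threshold
        return probabilities_to_sets(
            self.predict_proba(records), self.vocabulary_, thr
        )

    def cnn_only_predict(
        self, records: list[ProteinRecord], threshold: float | None = None
    ) -> list[set[str]]:
        """Baseline: the CNN's own sigmoid head, no boosted-tree stage."""
        thr = self.threshold if threshold is None else threshold
        X = self.encoder_.transform(records)
        return probabilities_to_sets(
            self.cnn_.predict_proba(X), self.vocabulary_, thr
        )


# ---------------------------------------------------------------------------
# File-level orchestration (the CLI surface)

def _manifest(pipeline: ProteinLocalizationPipeline) -> dict:
    from . import __version__

    params = {
        k: v
        for k, v in pipeline.get_params().items()
        if k not in ("ppi", "pssms")
    }
    return {
        "locboost_version": __version__,
        "seed": pipeline.seed,
        "params": params,
    }


def run_train(
    train_fasta,
    train_labels,
    bundle_path,
    ppi_path=None,
    pssm_dir=None,
    **params,
) -> ProteinLocalizationPipeline:
    """Train from files and persist the model bundle."""
    records = lio.read_fasta(train_fasta)
    mapping, _ = lio.read_labels(train_labels)
    lio.attach_labels(records, mapping)
    ppi = lio.read_ppi_matrix(ppi_path) if ppi_path else None
    pssms = None
    if pssm_dir:
        pssms = {
            r.id: lio.read_pssm(Path(pssm_dir) / f"{r.id}.pssm", r.id)
            for r in records
        }
    pipeline = ProteinLocalizationPipeline(ppi=ppi, pssms=pssms, **params)
    pipeline.fit(records)
    lio.save_model(
        {"pipeline": pipeline, "manifest": _manifest(pipeline)}, bundle_path
    )
    import pandas as pd

    pd.DataFrame(
        {
            "epoch": range(1, len(pipeline.cnn_.loss_history_) + 1),
            "loss": pipeline.cnn_.loss_history_,
        }
    ).to_csv(str(bundle_path) + ".losses.csv", index=False)
    return pipeline


def run_predict(
    bundle_path,
    fasta_path,
    out_tsv,
    threshold: float | None = None,
    rejects_path=None,
) -> dict[str, set[str]]:
    """Predict location sets for a FASTA file; write a label TSV.

    Records violating the sequence alphabet are skipped with a warning and
    listed in a rejects file.
    """
    from Bio import SeqIO

    bundle = lio.load_model(bundle_path)
    pipeline: ProteinLocalizationPipeline = bundle["pipeline"]
    records, rejects = [], []
    for entry in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(entry.seq).upper().rstrip("*")
        try:
            records.append(ProteinRecord(id=entry.id, sequence=seq))
        except ValueError as exc:
            logger.warning("skipping %s: %s", entry.id, exc)
            rejects.append((entry.id, str(exc)))
    if rejects_path is None:
        rejects_path = str(out_tsv) + ".rejects"
    if rejects:
        with open(rejects_path, "w") as fh:
            fh.write("id\treason\n")
            for pid, reason in rejects:
                fh.write(f"{pid}\t{reason}\n")
    sets = pipeline.predict(records, threshold=threshold)
    mapping = {r.id: s for r, s in zip(records, sets)}
    lio.write_labels(mapping, out_tsv)
    return mapping


def run_eval(pred_tsv, truth_tsv, out_tsv=None) -> EvaluationReport:
    """Join predictions with truth on id and compute the report."""
    pred, pred_vocab = lio.read_labels(pred_tsv)
    truth, truth_vocab = lio.read_labels(truth_tsv)
    missing = sorted(set(pred) - set(truth))
    if missing:
        raise ValueError(
            f"predicted ids missing from truth: {', '.join(missing[:10])}"
        )
    extra = set(pred_vocab.locations) - set(truth_vocab.locations)
    if extra:
        logger.warning(
            "labels predicted but absent from truth vocabulary: %s",
            sorted(extra),
        )
    vocabulary = LabelVocabulary(
        tuple(sorted(set(pred_vocab.locations) | set(truth_vocab.locations)))
    )
    prediction_sets = [
        PredictionSet(protein_id=pid, predicted=pred[pid], truth=truth[pid])
        for pid in pred
    ]
    report = evaluate(prediction_sets, vocabulary)
    if out_tsv is not None:
        report.to_frame().to_csv(out_tsv, sep="\t", index=False)
    return report


def run_synth_benchmark(
    synth_config: SynthConfig,
    out_dir=None,
    **pipeline_params,
) -> dict:
    """Generate a synthetic dataset, train the full pipeline and a
    CNN-only baseline, and evaluate both on the held-out split.

    When ``out_dir`` is given, the dataset is written as FASTA + label TSV
    and read back through the regular readers, so the benchmark exercises
    the exact file path a user would.
    """
    train, test, motifs = generate_dataset(synth_config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for split, recs in (("train", train), ("test", test)):
            lio.write_fasta(recs, out_dir / f"{split}.fasta")
            lio.write_labels(
                {r.id: r.labels for r in recs}, out_dir / f"{split}.tsv"
            )
        train = lio.read_fasta(out_dir / "train.fasta")
        mapping, _ = lio.read_labels(out_dir / "train.tsv")
        lio.attach_labels(train, mapping)
        test = lio.read_fasta(out_dir / "test.fasta")
        mapping, _ = lio.read_labels(out_dir / "test.tsv")
        lio.attach_labels(test, mapping)

    pipeline_params.setdefault("seed", synth_config.seed)
    pipeline = ProteinLocalizationPipeline(**pipeline_params).fit(train)

    def report_for(sets):
        preds = [
            PredictionSet(protein_id=r.id, predicted=s, truth=r.labels)
            for r, s in zip(test, sets)
        ]
        return evaluate(preds, pipeline.vocabulary_)

    full = report_for(pipeline.predict(test))
    baseline = report_for(pipeline.cnn_only_predict(test))
    result = {
        "pipeline": full,
        "cnn_only": baseline,
        "motifs": motifs,
        "model": pipeline,
    }
    if out_dir is not None:
        frame = full.to_frame()
        frame.insert(0, "variant", "cnn+gbt")
        bframe = baseline.to_frame()
        bframe.insert(0, "variant", "cnn-only")
        import pandas as pd

        pd.concat([frame, bframe]).to_csv(
            out_dir / "benchmark.tsv", sep="\t", index=False
        )
    return result
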