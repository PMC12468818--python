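"""Estimator facade and end-to-end pipeline helpers.

:class:`GRUMixerClassifier` wraps the whole method — waveform
standardization, Log-Mel features, the bidirectional GRU-Mixer network and
its training protocol — behind the scikit-learn estimator interface, so it
composes with sklearn model selection and pipelines.

``train_task`` and ``run_ablation`` operate one level up, on a corpus
metadata table, handling split/task selection and reporting.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .corpus import load_clips
from .melspec import SpectrogramConfig, logmel
from .metrics import confusion_matrix, metrics_report
from .network import GRUMixerNet, ModelConfig, predict_from_logits, softmax
from .preprocess import PreprocConfig, Waveform, preprocess
from .tasks import TASKS, TaskSpec, select_task
from .train import TrainConfig, ablation_configs, split_speaker_independent, train

__all__ = ["GRUMixerClassifier", "featurize_clips", "forward", "train_task", "run_ablation"]


def featurize_clips(
    clips: list[Waveform] | np.ndarray,
    preproc: PreprocConfig | None = None,
    spec: SpectrogramConfig | None = None,
    sample_rate: int | None = None,
) -> np.ndarray:
    """Standardize and featurize a batch of clips to a (n, T, n_mels) array.

    ``clips`` may be Waveform objects (any rates/lengths) or a 2-D array of
    raw samples, in which case ``sample_rate`` gives their common rate.
    """
    preproc = preproc or PreprocConfig()
    spec = spec or SpectrogramConfig(sample_rate=preproc.target_rate)
    if isinstance(clips, np.ndarray):
        if clips.ndim != 2:
            raise ValueError("array input must be 2-D (n_clips, n_samples)")
        rate = sample_rate or preproc.target_rate
        clips = [Waveform(row, rate) for row in clips]
    feats = [logmel(preprocess(w, preproc), spec).values for w in clips]
    return np.stack(feats)


def forward(
    clip: Waveform,
    net: GRUMixerNet,
    preproc: PreprocConfig | None = None,
    spec: SpectrogramConfig | None = None,
) -> tuple[np.ndarray, int]:
    """Single-clip evaluation-mode pipeline: audio in, (probabilities, label) out."""
    feats = featurize_clips([clip], preproc, spec)[0]
    probs, label = predict_from_logits(net.forward(feats, training=False))
    return probs, int(label)


class GRUMixerClassifier(ClassifierMixin, BaseEstimator):
    """Speech clip classifier: Log-Mel features + stacked bidirectional GRU
    with temporal mean pooling and a softmax head.

    Parameters mirror the training protocol: Adam (``learning_rate``,
    coupled L2 ``weight_decay``), mini-batches of ``batch_size``, at most
    ``max_epochs`` epochs with early stopping after ``patience`` epochs
    without improvement of the monitored accuracy, class-balanced
    cross-entropy when ``class_balanced``.

    ``fit(X, y, eval_set=(X_m, y_m))`` monitors accuracy on ``eval_set``
    (the protocol monitors the held-out test set; omit it to monitor the
    training set instead).  ``X`` is a 2-D array of raw waveform samples at
    ``sample_rate`` (rows are clips; any length, standardized internally),
    a list of :class:`Waveform`, or a precomputed (n, T, n_mels) feature
    array.

    Attributes (after fit): ``classes_``, ``net_``, ``history_``,
    ``n_features_in_``.
    """

    def __init__(
        self,
        sample_rate: int = 8000,
        duration: float = 3.0,
        n_fft: int = 1024,
        hop: int = 256,
        n_mels: int = 64,
        hidden_size: int = 64,
        num_layers: int = 3,
        bidirectional: bool = True,
        dropout: float = 0.5,
        learning_rate: float = 1e-4,
        weight_decay: float = 1e-5,
        batch_size: int = 8,
        max_epochs: int = 20,
        patience: int = 3,
        use_dropout: bool = True,
        use_weight_decay: bool = True,
        use_early_stopping: bool = True,
        class_balanced: bool = True,
        random_state: int = 0,
        verbose: bool = False,
    ):
        self.sample_rate = sample_rate
        self.duration = duration
        self.n_fft = n_fft
        self.hop = hop
        self.n_mels = n_mels
        self.hidden_size = hidden_size
        self.num_layers = num_layers
        self.bidirectional = bidirectional
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.use_dropout = use_dropout
        self.use_weight_decay = use_weight_decay
        self.use_early_stopping = use_early_stopping
        self.class_balanced = class_balanced
        self.random_state = random_state
        self.verbose = verbose

    # -- config assembly ----------------------------------------------------

    def _preproc_config(self) -> PreprocConfig:
        return PreprocConfig(target_rate=self.sample_rate, target_duration=self.duration)

    def _spec_config(self) -> SpectrogramConfig:
        return SpectrogramConfig(
            n_fft=self.n_fft, hop=self.hop, n_mels=self.n_mels, sample_rate=self.sample_rate
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            use_dropout=self.use_dropout,
            use_weight_decay=self.use_weight_decay,
            use_early_stopping=self.use_early_stopping,
            class_balanced=self.class_balanced,
            seed=self.random_state,
        )

    def _featurize(self, X) -> np.ndarray:
        if isinstance(X, np.ndarray) and X.ndim == 3:
            if X.shape[2] != self.n_mels:
                raise ValueError(f"feature width {X.shape[2]} != n_mels {self.n_mels}")
            return np.asarray(X, dtype=np.float64)
        return featurize_clips(
            X, self._preproc_config(), self._spec_config(), sample_rate=self.sample_rate
        )

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y, eval_set=None):
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        feats = self._featurize(X)
        if len(feats) != len(y_enc):
            raise ValueError("X and y have inconsistent lengths")
        self.n_features_in_ = feats.shape[1] * feats.shape[2]
        if eval_set is None:
            feats_m, y_m = feats, y_enc
        else:
            X_m, y_m_raw = eval_set
            feats_m = self._featurize(X_m)
            lookup = {c: i for i, c in enumerate(self.classes_)}
            y_m = np.array([lookup[v] for v in np.asarray(y_m_raw)], dtype=np.intp)
        config = ModelConfig(
            input_size=self.n_mels,
            hidden_size=self.hidden_size,
            num_layers=self.num_layers,
            bidirectional=self.bidirectional,
            dropout_p=self.dropout,
            n_classes=len(self.classes_),
        )
        net = GRUMixerNet(config, seed=self.random_state)
        log = print if self.verbose else None
        self.net_, self.history_ = train(
            net, feats, y_enc, feats_m, y_m, self._train_config(), log=log
        )
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        return self.net_.forward(self._featurize(X), training=False)

    def predict_proba(self, X) -> np.ndarray:
        return softmax(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


# -- corpus-level orchestration ----------------------------------------------


def _encoded_metrics(clf: GRUMixerClassifier, feats, y_true, class_names):
    preds = list(clf.predict(feats))
    names = [class_names[i] for i in y_true]
    return metrics_report(confusion_matrix(names, preds, class_names))


def train_task(
    corpus: pd.DataFrame,
    task: TaskSpec | str,
    train_config: TrainConfig | None = None,
    root: str | Path | None = None,
    clf_kwargs: dict | None = None,
    log=None,
):
    """Train one task end to end from a corpus metadata table.

    Splits the corpus (speaker-grouped by default), featurizes the audio,
    trains the classifier with test-set monitoring, and returns
    ``(clf, report, history, split)`` where ``report`` is the test-set
    :class:`MetricsReport`.
    """
    spec = TASKS[task] if isinstance(task, str) else task
    config = train_config or TrainConfig()
    subset, labels = select_task(corpus, spec)
    train_idx, test_idx = split_speaker_independent(subset, config)
    clips = load_clips(subset, root=root)
    clf = GRUMixerClassifier(
        random_state=config.seed,
        learning_rate=config.learning_rate,
        weight_decay=config.weight_decay,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        patience=config.patience,
        use_dropout=config.use_dropout,
        use_weight_decay=config.use_weight_decay,
        use_early_stopping=config.use_early_stopping,
        class_balanced=config.class_balanced,
        **(clf_kwargs or {}),
    )
    feats = clf._featurize(clips)
    y = np.array([spec.class_names[i] for i in labels])
    clf.fit(feats[train_idx], y[train_idx], eval_set=(feats[test_idx], y[test_idx]))
    y_enc = labels[test_idx]
    report = _encoded_metrics(clf, feats[test_idx], y_enc, list(spec.class_names))
    split = {"train_idx": train_idx, "test_idx": test_idx}
    return clf, report, clf.history_, split


def run_ablation(
    corpus: pd.DataFrame,
    base_config: TrainConfig | None = None,
    root: str | Path | None = None,
    clf_kwargs: dict | None = None,
    log=None,
) -> pd.DataFrame:
    """Train the six regularization variants on the binary pain task.

    All variants share the base seed, learning rate and batch size and the
    same (stratified, per the protocol's ablation setup) split; each row
    reports accuracy plus macro- and pain-class precision/recall/F1.
    """
    base = base_config or TrainConfig(split_mode="clip_stratified")
    spec = TASKS["pain_binary"]
    subset, labels = select_task(corpus, spec)
    train_idx, test_idx = split_speaker_independent(subset, base)
    clips = load_clips(subset, root=root)
    feats = featurize_clips(clips)
    y = np.array([spec.class_names[i] for i in labels])
    rows = []
    for name, cfg in ablation_configs(base):
        clf = GRUMixerClassifier(
            random_state=cfg.seed,
            learning_rate=cfg.learning_rate,
            weight_decay=cfg.weight_decay,
            batch_size=cfg.batch_size,
            max_epochs=cfg.max_epochs,
            patience=cfg.patience,
            use_dropout=cfg.use_dropout,
            use_weight_decay=cfg.use_weight_decay,
            use_early_stopping=cfg.use_early_stopping,
            class_balanced=cfg.class_balanced,
            **(clf_kwargs or {}),
        )
        clf.fit(feats[train_idx], y[train_idx], eval_set=(feats[test_idx], y[test_idx]))
        report = _encoded_metrics(clf, feats[test_idx], labels[test_idx], list(spec.class_names))
        pain = list(spec.class_names).index("pain")
        rows.append(
            {
                "Model": name,
                "Accuracy": report.accuracy,
                "Precision": report.macro_precision,
                "Recall": report.macro_recall,
                "F1-Score": report.macro_f1,
                "Precision (pain)": float(report.precision[pain]),
                "Recall (pain)": float(report.recall[pain]),
                "F1-Score (pain)": float(report.f1[pain]),
                "use_dropout": cfg.use_dropout,
                "use_weight_decay": cfg.use_weight_decay,
                "use_early_stopping": cfg.use_early_stopping,
            }
        )
        if log is not None:
            log(f"ablation [{name}] accuracy {report.accuracy:.4f}")
    return pd.DataFrame(rows)
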