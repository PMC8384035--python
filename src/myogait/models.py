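"""LSTM gait-phase classifier, coupled ahead-of-time angle predictor, fine-tuning.

Both models are scikit-learn style estimators (``fit`` / ``predict`` /
``get_params``) over the numpy sequence-model toolkit in :mod:`myogait.nn`.
``X`` rows must be in time order: training internally slices X into
overlapping sequences of ``sequence_len`` windows, and prediction runs the
whole row sequence through the recurrent stack, yielding one output per
window (sequences shorter than ``sequence_len`` are fine).

The phase classifier stacks two LSTM layers (40 units each), a 20-unit
rectified-linear layer with 0.5 dropout, and a 4-way softmax. The angle
predictor couples an LSTM feature extractor (30-30-30 recurrent units plus a
5-unit rectified-linear projection) with an LSTM regressor head (30-30
recurrent, a 60-unit rectified-linear layer and a single linear output),
trained end-to-end with mean squared error against the angle one prediction
horizon (default 40 ms) ahead. Its input stream is configurable: current
angle only, sEMG features + angle, or sEMG features + gait phase + angle.

Fine-tuning continues training of an already-fitted model on a small amount
of data from a shifted condition at a reduced learning rate, the standard
remedy for the signal-distribution change induced by exoskeleton assistance.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin, clone

from . import nn
from .features import FeatureFrame
from .simulate import PHASES

INPUT_MODES = ("angle_only", "emg_based", "emg_phase_based")


def _sequence_starts(n: int, T: int, stride: int,
                     boundaries: list[tuple[int, int]] | None) -> np.ndarray:
    segs = boundaries if boundaries is not None else [(0, n)]
    starts = []
    for s0, s1 in segs:
        if s1 - s0 >= T:
            starts.append(np.arange(s0, s1 - T + 1, stride))
    if not starts:
        raise ValueError("no segment long enough for one training sequence")
    return np.concatenate(starts)


def _make_sequences(X: np.ndarray, y: np.ndarray, T: int, stride: int,
                    boundaries=None) -> tuple[np.ndarray, np.ndarray]:
    starts = _sequence_starts(len(X), T, stride, boundaries)
    idx = starts[:, None] + np.arange(T)[None, :]
    return X[idx], y[idx]


class _SequenceEstimator(BaseEstimator):
    """Shared plumbing: standardisation, sequence slicing, net training."""

    def _standardize_fit(self, X: np.ndarray) -> np.ndarray:
        self.x_mean_ = X.mean(axis=0)
        std = X.std(axis=0)
        self.x_std_ = np.where(std > 1e-12, std, 1.0)
        return (X - self.x_mean_) / self.x_std_

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean_) / self.x_std_

    def _forward_rows(self, X: np.ndarray) -> np.ndarray:
        """Run all rows as one long sequence; returns per-row outputs."""
        Xs = self._standardize(np.asarray(X, dtype=float))
        out = self.net_.forward(Xs[:, None, :], training=False)
        return out[:, 0, :]

    def _train(self, Xs, y_seq_source, loss_fn, lr, epochs,
               optimizer=None) -> dict:
        return nn.fit_network(
            self.net_, Xs, y_seq_source, loss_fn,
            lr=lr, epochs=epochs, batch_size=self.batch_size,
            seed=self.seed, val_fraction=self.val_fraction,
            patience=self.patience, optimizer=optimizer,
        )

    def copy_fitted(self):
        """Independent copy of a fitted estimator (weights included)."""
        new = clone(self)
        for attr, val in self.__dict__.items():
            if attr.endswith("_") and not attr.startswith("_"):
                if attr == "net_":
                    continue
                new.__dict__[attr] = (
                    val.copy() if isinstance(val, np.ndarray) else val
                )
        new.net_ = new._build_net(self._input_dim_)
        new.net_.set_weights(self.net_.get_weights())
        new._input_dim_ = self._input_dim_
        return new


class GaitPhaseClassifier(_SequenceEstimator, ClassifierMixin):
    """Four-phase gait classifier over windowed sEMG features.

    Parameters mirror the architecture described in the module docstring;
    ``sequence_len`` is the temporal context (in windows) used for training.
    """

    def __init__(self, lstm_sizes=(40, 40), fc_size=20, dropout=0.5,
                 sequence_len=10, stride=1, lr=1e-3, epochs=30, batch_size=64,
                 val_fraction=0.1, patience=8, seed=0):
        self.lstm_sizes = lstm_sizes
        self.fc_size = fc_size
        self.dropout = dropout
        self.sequence_len = sequence_len
        self.stride = stride
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.patience = patience
        self.seed = seed

    def _build_net(self, input_dim: int) -> nn.Sequential:
        rng = np.random.default_rng(self.seed)
        layers: list[nn.Layer] = []
        d = input_dim
        for h in self.lstm_sizes:
            layers.append(nn.LSTM(d, h, rng))
            d = h
        layers.append(nn.Dense(d, self.fc_size, rng, relu=True))
        if self.dropout:
            layers.append(nn.Dropout(self.dropout, rng))
        layers.append(nn.Dense(self.fc_size, len(self.classes_), rng))
        return nn.Sequential(layers)

    def fit(self, X, y, boundaries=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        self.classes_ = np.unique(y)
        codes = np.searchsorted(self.classes_, y)
        Xs = self._standardize_fit(X)
        self._input_dim_ = X.shape[1]
        self.net_ = self._build_net(self._input_dim_)
        Xq, Yq = _make_sequences(Xs, codes, self.sequence_len, self.stride,
                                 boundaries)
        self.history_ = self._train(Xq, Yq, nn.softmax_xent, self.lr, self.epochs)
        return self

    def continue_fit(self, X, y, lr=1e-4, epochs=10, boundaries=None):
        """Fine-tune all weights on new data at a reduced learning rate."""
        X = np.asarray(X, dtype=float)
        codes = np.searchsorted(self.classes_, np.asarray(y))
        Xs = self._standardize(X)
        Xq, Yq = _make_sequences(Xs, codes, self.sequence_len, self.stride,
                                 boundaries)
        hist = self._train(Xq, Yq, nn.softmax_xent, lr, epochs)
        self.history_ = {"fine_tune": hist}
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self._input_dim_:
            raise ValueError(
                f"feature dimension {X.shape[1]} != fitted {self._input_dim_}"
            )
        return nn.softmax(self._forward_rows(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


class AnkleAnglePredictor(_SequenceEstimator, RegressorMixin):
    """Ahead-of-time joint-angle regressor over a configurable input stream."""

    def __init__(self, extractor_sizes=(30, 30, 30, 5),
                 predictor_sizes=(30, 30, 60, 1), input_mode="emg_phase_based",
                 horizon_ms=40.0, sequence_len=10, stride=1, lr=1e-3,
                 epochs=40, batch_size=64, val_fraction=0.1, patience=10,
                 seed=0):
        self.extractor_sizes = extractor_sizes
        self.predictor_sizes = predictor_sizes
        self.input_mode = input_mode
        self.horizon_ms = horizon_ms
        self.sequence_len = sequence_len
        self.stride = stride
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.patience = patience
        self.seed = seed

    def _build_net(self, input_dim: int) -> nn.Sequential:
        rng = np.random.default_rng(self.seed)
        layers: list[nn.Layer] = []
        d = input_dim
        *ext_rec, ext_proj = self.extractor_sizes
        for h in ext_rec:
            layers.append(nn.LSTM(d, h, rng))
            d = h
        layers.append(nn.Dense(d, ext_proj, rng, relu=True))
        d = ext_proj
        *pred_rec, pred_fc, out_dim = self.predictor_sizes
        for h in pred_rec:
            layers.append(nn.LSTM(d, h, rng))
            d = h
        layers.append(nn.Dense(d, pred_fc, rng, relu=True))
        layers.append(nn.Dense(pred_fc, out_dim, rng))
        return nn.Sequential(layers)

    def fit(self, X, y, boundaries=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one target per row")
        if not np.all(np.isfinite(y)):
            raise ValueError("angle targets must be finite")
        Xs = self._standardize_fit(X)
        self.y_mean_ = float(y.mean())
        self.y_std_ = float(y.std()) or 1.0
        ys = (y - self.y_mean_) / self.y_std_
        self._input_dim_ = X.shape[1]
        self.net_ = self._build_net(self._input_dim_)
        Xq, Yq = _make_sequences(Xs, ys, self.sequence_len, self.stride,
                                 boundaries)
        self.history_ = self._train(Xq, Yq, nn.mse_loss, self.lr, self.epochs)
        return self

    def continue_fit(self, X, y, lr=1e-4, epochs=10, boundaries=None):
        """Fine-tune all weights on new data at a reduced learning rate."""
        X = np.asarray(X, dtype=float)
        ys = (np.asarray(y, dtype=float) - self.y_mean_) / self.y_std_
        Xs = self._standardize(X)
        Xq, Yq = _make_sequences(Xs, ys, self.sequence_len, self.stride,
                                 boundaries)
        hist = self._train(Xq, Yq, nn.mse_loss, lr, epochs)
        self.history_ = {"fine_tune": hist}
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self._input_dim_:
            raise ValueError(
                f"feature dimension {X.shape[1]} != fitted {self._input_dim_}"
            )
        out = self._forward_rows(X)[:, 0]
        return out * self.y_std_ + self.y_mean_


# ---------------------------------------------------------------------------
# FeatureFrame-level convenience API


def assemble_predictor_inputs(
    frame: FeatureFrame,
    input_mode: str = "emg_phase_based",
    phase: np.ndarray | None = None,
    phase_encoding: str = "onehot",
) -> np.ndarray:
    """Design matrix for the angle predictor from a feature frame.

    ``angle_only`` uses the current angle alone; ``emg_based`` prepends the
    sEMG feature block; ``emg_phase_based`` additionally inserts the gait
    phase (one-hot by default, single ordinal channel optionally). ``phase``
    overrides the frame's labels, e.g. with classifier output for a fully
    causal pipeline.
    """
    if input_mode not in INPUT_MODES:
        raise ValueError(f"input_mode must be one of {INPUT_MODES}")
    cols = []
    if input_mode in ("emg_based", "emg_phase_based"):
        cols.append(frame.X)
    if input_mode == "emg_phase_based":
        ph = np.asarray(frame.phase if phase is None else phase)
        if phase_encoding == "onehot":
            cols.append(np.eye(4)[ph])
        elif phase_encoding == "ordinal":
            cols.append(ph[:, None].astype(float))
        else:
            raise ValueError("phase_encoding must be 'onehot' or 'ordinal'")
    cols.append(frame.angle_now[:, None])
    return np.hstack(cols)


def _concat_frames(frames: list[FeatureFrame], columns) -> tuple[np.ndarray, list]:
    Xs, boundaries, pos = [], [], 0
    for fr in frames:
        x = columns(fr)
        Xs.append(x)
        boundaries.append((pos, pos + len(x)))
        pos += len(x)
    return np.concatenate(Xs), boundaries


def train_phase_classifier(
    frames: FeatureFrame | list[FeatureFrame], **params
) -> GaitPhaseClassifier:
    """Fit a :class:`GaitPhaseClassifier` on one or more feature frames.

    Raises if any of the four phases is absent from the pooled training data.
    """
    if isinstance(frames, FeatureFrame):
        frames = [frames]
    X, boundaries = _concat_frames(frames, lambda fr: fr.X)
    y = np.concatenate([fr.phase for fr in frames])
    missing = [PHASES[p] for p in range(4) if p not in set(np.unique(y))]
    if missing:
        raise ValueError(f"phases absent from training data: {missing}")
    model = GaitPhaseClassifier(**params)
    return model.fit(X, y, boundaries=boundaries)


def classify(model: GaitPhaseClassifier, frame: FeatureFrame):
    """Per-window phase labels and probabilities for a feature frame."""
    proba = model.predict_proba(frame.X)
    return model.classes_[proba.argmax(axis=1)], proba


def train_angle_predictor(
    frames: FeatureFrame | list[FeatureFrame],
    input_mode: str = "emg_phase_based",
    **params,
) -> AnkleAnglePredictor:
    """Fit an :class:`AnkleAnglePredictor` against the future-angle targets."""
    if isinstance(frames, FeatureFrame):
        frames = [frames]
    for fr in frames:
        if fr.angle_future is None or len(fr.angle_future) != len(fr):
            raise ValueError("frames must carry angle_future targets")
    X, boundaries = _concat_frames(
        frames, lambda fr: assemble_predictor_inputs(fr, input_mode)
    )
    y = np.concatenate([fr.angle_future for fr in frames])
    model = AnkleAnglePredictor(
        input_mode=input_mode, horizon_ms=frames[0].horizon_ms, **params
    )
    return model.fit(X, y, boundaries=boundaries)


def predict_ahead(
    model: AnkleAnglePredictor,
    frame: FeatureFrame,
    phase_source: str = "true_labels",
    classifier: GaitPhaseClassifier | None = None,
) -> np.ndarray:
    """Angle trace one horizon ahead, one prediction per window.

    With ``phase_source='classifier'`` the gait phase fed to the predictor
    comes from the classifier's output, making the pipeline fully causal.
    """
    if phase_source == "classifier":
        if classifier is None:
            raise ValueError("phase_source='classifier' requires a classifier")
        phase = classifier.predict(frame.X)
    elif phase_source == "true_labels":
        phase = None
    else:
        raise ValueError("phase_source must be 'true_labels' or 'classifier'")
    X = assemble_predictor_inputs(frame, model.input_mode, phase=phase)
    return model.predict(X)


def fine_tune(
    model,
    X_new: np.ndarray,
    y_new: np.ndarray,
    minutes: list[float],
    windows_per_min: float = 1500.0,
    lr: float = 1e-4,
    epochs: int = 10,
    metric_fn=None,
):
    """Adapt a fitted model to a shifted condition under growing data budgets.

    For each cumulative budget ``m`` (in minutes of windows; 1 min = 1500
    windows at a 40 ms increment), a copy of the base model continues training
    on the first ``m`` minutes of the new-condition data at reduced learning
    rate. The data after the largest budget is the fixed held-out test set.
    A zero budget returns the unadapted model. Returns
    ``(models, curve, (X_test, y_test))`` where ``curve`` holds
    ``metric_fn(model, X_test, y_test)`` per budget (None if no metric_fn).
    """
    minutes = sorted(minutes)
    max_w = int(round(max(minutes) * windows_per_min))
    if max_w >= len(X_new):
        raise ValueError(
            f"budget of {max(minutes):g} min ({max_w} windows) exceeds "
            f"available data ({len(X_new)} windows)"
        )
    X_test, y_test = X_new[max_w:], y_new[max_w:]
    models, curve = [], []
    for m in minutes:
        w = int(round(m * windows_per_min))
        if w == 0:
            adapted = model
        else:
            adapted = model.copy_fitted()
            adapted.continue_fit(X_new[:w], y_new[:w], lr=lr, epochs=epochs)
        models.append(adapted)
        curve.append(metric_fn(adapted, X_test, y_test) if metric_fn else None)
    return models, curve, (X_test, y_test)
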