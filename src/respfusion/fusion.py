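"""The four CNN fusion strategies and their training/prediction surface.

* **early** — all selected channels enter one convolutional layer jointly
  (filters span the channel axis): a single branch.
* **signal-based late** — one independent conv branch per signal; feature
  maps merge in the dense layer.
* **sensor-based late** — two independent conv branches per signal (a larger
  extracted feature set), merged likewise.
* **hybrid** — no network of its own: an elementwise majority vote over the
  binary predictions of the other three.

Every branch is conv(4 filters x 20 samples) -> ReLU -> dropout(0.5) ->
max-pool -> flatten, and the classifier head is a single sigmoid unit
thresholded at 0.5.  The chest-belt reference channel is never an input;
it exists only to produce labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import CNNModel, TrainHistory
from .snippets import SnippetSet
from .types import MODEL_CHANNEL_ORDER, PipelineConfig, RespFusionError

STRATEGIES = ("early", "signal_late", "sensor_late", "hybrid")
#: seed offsets so ensemble members are independently initialized yet
#: reproducible from one base seed
_MEMBER_SEED_OFFSET = {"early": 0, "signal_late": 1, "sensor_late": 2}


@dataclass(frozen=True)
class FusionArchitectureSpec:
    """Hyperparameters and topology selector for one fusion strategy."""

    strategy: str
    signals: tuple[str, ...] = MODEL_CHANNEL_ORDER
    n_filters: int = 4
    filter_len: int = 20
    dropout: float = 0.5
    pool_size: int = 4
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise RespFusionError(
                f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}"
            )
        signals = tuple(self.signals)
        if not signals:
            raise RespFusionError("signal set must be non-empty")
        unknown = [s for s in signals if s not in MODEL_CHANNEL_ORDER]
        if unknown:
            raise RespFusionError(
                f"unknown signals {unknown}; expected a subset of {MODEL_CHANNEL_ORDER}"
            )
        if len(set(signals)) != len(signals):
            raise RespFusionError("duplicate signals")
        object.__setattr__(self, "signals", signals)

    @property
    def branches_per_signal(self) -> int:
        return {"early": 0, "signal_late": 1, "sensor_late": 2}.get(self.strategy, 0)


@dataclass(frozen=True)
class PredictionVector:
    """Binary snippet labels with the underlying sigmoid scores."""

    y: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=np.int64)
        scores = np.asarray(self.scores, dtype=float)
        if y.shape != scores.shape:
            raise RespFusionError("labels and scores differ in length")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return int(self.y.size)


@dataclass
class FusionModel:
    """One trained (or untrained) network bound to a channel layout."""

    spec: FusionArchitectureSpec
    channel_names: tuple[str, ...]
    net: CNNModel
    history: TrainHistory | None = None

    @property
    def n_branches(self) -> int:
        return self.net.n_branches

    @property
    def n_params(self) -> int:
        return self.net.n_params


def _branch_layout(spec: FusionArchitectureSpec, channel_names: tuple[str, ...]):
    idx = []
    for s in spec.signals:
        if s not in channel_names:
            raise RespFusionError(f"signal {s!r} not among snippet channels {channel_names}")
        idx.append(channel_names.index(s))
    if spec.strategy == "early":
        return [tuple(idx)]
    if spec.strategy == "signal_late":
        return [(i,) for i in idx]
    if spec.strategy == "sensor_late":
        return [(i,) for i in idx for _ in range(2)]
    raise RespFusionError("hybrid is an ensemble; build it with train_hybrid")


def build_model(
    spec: FusionArchitectureSpec,
    snippet_len: int = 201,
    channel_names: tuple[str, ...] = MODEL_CHANNEL_ORDER,
) -> FusionModel:
    """Instantiate an untrained network for one of the three CNN strategies."""
    layout = _branch_layout(spec, tuple(channel_names))
    net = CNNModel(
        layout,
        n_channels=len(channel_names),
        snippet_len=snippet_len,
        n_filters=spec.n_filters,
        filter_len=spec.filter_len,
        pool_size=spec.pool_size,
        dropout=spec.dropout,
        seed=spec.seed,
    )
    return FusionModel(spec, tuple(channel_names), net)


def train(
    model: FusionModel, train_set: SnippetSet, config: PipelineConfig | None = None
) -> tuple[FusionModel, TrainHistory]:
    """Fit the network on a labeled snippet set; deterministic given the seed."""
    config = config or PipelineConfig()
    if train_set.labels is None:
        raise RespFusionError("training set is unlabeled")
    if tuple(train_set.channel_names) != model.channel_names:
        raise RespFusionError(
            f"channel order mismatch: model expects {model.channel_names}, "
            f"snippets provide {tuple(train_set.channel_names)}"
        )
    history = model.net.fit(
        train_set.data,
        train_set.labels,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        class_weighting=config.class_weighting,
        seed=model.spec.seed,
    )
    model.history = history
    return model, history


def predict(model: FusionModel, snips: SnippetSet) -> PredictionVector:
    """Sigmoid scores and thresholded binary labels for every snippet."""
    if tuple(snips.channel_names) != model.channel_names:
        raise RespFusionError(
            f"channel order mismatch: model expects {model.channel_names}, "
            f"snippets provide {tuple(snips.channel_names)}"
        )
    scores = model.net.predict_scores(snips.data)
    y = (scores >= model.spec.threshold).astype(np.int64)
    return PredictionVector(y, scores)


def majority_vote(
    y_early: np.ndarray, y_signal_late: np.ndarray, y_sensor_late: np.ndarray
) -> np.ndarray:
    """Elementwise 2-of-3 majority over binary vectors (no ties possible)."""
    a = np.asarray(y_early, dtype=np.int64)
    b = np.asarray(y_signal_late, dtype=np.int64)
    c = np.asarray(y_sensor_late, dtype=np.int64)
    if not (a.shape == b.shape == c.shape):
        raise RespFusionError("vote inputs differ in length")
    for v in (a, b, c):
        if v.size and not np.isin(v, [0, 1]).all():
            raise RespFusionError("vote inputs must be binary")
    return ((a + b + c) >= 2).astype(np.int64)


@dataclass
class HybridEnsemble:
    """The three trained member networks of the hybrid majority vote."""

    members: dict[str, FusionModel] = field(default_factory=dict)

    def predict(self, snips: SnippetSet) -> PredictionVector:
        votes = {name: predict(m, snips) for name, m in self.members.items()}
        y = majority_vote(
            votes["early"].y, votes["signal_late"].y, votes["sensor_late"].y
        )
        # the ensemble has no calibrated score; report the vote fraction
        score = (votes["early"].y + votes["signal_late"].y + votes["sensor_late"].y) / 3.0
        return PredictionVector(y, score)


def train_hybrid(
    train_set: SnippetSet,
    config: PipelineConfig | None = None,
    signals: tuple[str, ...] = MODEL_CHANNEL_ORDER,
    seed: int = 0,
) -> HybridEnsemble:
    """Train early, signal-late and sensor-late members on identical data and
    a deterministic per-member seed schedule; prediction majority-votes."""
    config = config or PipelineConfig()
    ensemble = HybridEnsemble()
    for strategy, offset in _MEMBER_SEED_OFFSET.items():
        spec = FusionArchitectureSpec(
            strategy=strategy,
            signals=signals,
            n_filters=config.n_filters,
            filter_len=config.filter_len,
            dropout=config.dropout,
            pool_size=config.pool_size,
            threshold=config.threshold,
            seed=seed + offset,
        )
        model = build_model(spec, config.snippet_len, tuple(train_set.channel_names))
        train(model, train_set, config)
        ensemble.members[strategy] = model
    return ensemble
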