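"""Self-supervised remaining-surgery-progress (RSP) regression.

The pretext task: from a surgical video alone, regress at every frame the
remaining progress y_t = 1 - t/tau (t = 1..tau), the fraction of the
procedure still ahead.  The labels are free — they follow from the sequence
length — yet solving the task forces the network to recognize milestone
events (for example the end of the initial diagnostic phase), which is
exactly the information the downstream activity recognizer needs.

The architecture is an encoder–decoder: a small CNN encodes each frame, a
recurrent decoder (GRU or LSTM) accumulates the trajectory history, and a
three-layer MLP head (PReLU after the first two layers, sigmoid after the
last) maps the hidden state to a progress value in (0, 1).  Training
minimizes the mean absolute error over whole sequences with Adam or
RMSProp.  Internal activations — layer outputs and recurrent gate
activations — can be extracted per frame for representation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .nn.layers import Flatten


@dataclass
class RepresentationTrace:
    """Per-frame values of one internal source for one trajectory."""

    source: str
    values: np.ndarray  # (tau, width)
    trajectory_id: int | str | None = None


def rsp_labels(tau: int) -> np.ndarray:
    """Remaining-progress labels y_t = 1 - t/tau for t = 1..tau.

    Strictly decreasing, linear in t, with y_tau = 0 exactly (the procedure
    ends at the last frame).
    """
    if tau < 1:
        raise ValueError("tau must be >= 1")
    t = np.arange(1, tau + 1, dtype=float)
    return 1.0 - t / tau


class _EncoderDecoder:
    """Assembled network; see RSPRegressor for the configuration surface."""

    def __init__(self, encoder, input_size, encoder_width, decoder, hidden_size,
                 n_layers, rng):
        if encoder != "small_cnn":
            raise ValueError(
                f"encoder {encoder!r} is a pretrained-backbone hook; provide "
                "weights via pretrained_weights or use 'small_cnn'"
            )
        chans = (1, 8, 16, 32)
        layers = []
        size = input_size
        for cin, cout in zip(chans[:-1], chans[1:]):
            layers += [nn.Conv2d(cin, cout, 3, 2, 1, rng), nn.PReLU()]
            size = (size + 2 - 3) // 2 + 1
        layers += [Flatten(), nn.Linear(chans[-1] * size * size, encoder_width, rng)]
        self.encoder = nn.Sequential(*layers)
        cell = {"gru": nn.GRU, "lstm": nn.LSTM}[decoder]
        self.decoder_layers = [
            cell(encoder_width if i == 0 else hidden_size, hidden_size, rng)
            for i in range(n_layers)
        ]
        self.head = nn.Sequential(
            nn.Linear(hidden_size, hidden_size, rng), nn.PReLU(),
            nn.Linear(hidden_size, hidden_size, rng), nn.PReLU(),
            nn.Linear(hidden_size, 1, rng), nn.Sigmoid(),
        )

    def forward(self, frames: np.ndarray) -> np.ndarray:
        x = frames[:, None, :, :]
        feats = self.encoder.forward(x)
        h = feats
        self._layer_outputs = {"encoder.out": feats}
        for i, cell in enumerate(self.decoder_layers):
            h = cell.forward(h)
            self._layer_outputs[f"decoder.l{i + 1}"] = h
        y = self.head.forward(h)[:, 0]
        self._layer_outputs["head.out"] = y[:, None]
        return y

    def backward(self, dy: np.ndarray) -> None:
        g = self.head.backward(dy[:, None])
        for cell in reversed(self.decoder_layers):
            g = cell.backward(g)
        self.encoder.backward(g)

    def zero_grad(self) -> None:
        self.encoder.zero_grad()
        for cell in self.decoder_layers:
            cell.zero_grad()
        self.head.zero_grad()

    def named_parameters(self):
        yield from self.encoder.named_parameters("encoder.")
        for i, cell in enumerate(self.decoder_layers):
            yield from cell.named_parameters(f"decoder.l{i + 1}.")
        yield from self.head.named_parameters("head.")

    def available_sources(self) -> list[str]:
        out = ["encoder.out", "head.out"]
        for i, cell in enumerate(self.decoder_layers):
            out.append(f"decoder.l{i + 1}")
            out += [f"decoder.l{i + 1}.{g}" for g in cell.GATES]
        return out

    def collect(self, source: str) -> np.ndarray:
        if source in self._layer_outputs:
            return self._layer_outputs[source].copy()
        parts = source.split(".")
        if len(parts) == 3 and parts[0] == "decoder":
            idx = int(parts[1].lstrip("l")) - 1
            if 0 <= idx < len(self.decoder_layers):
                traces = self.decoder_layers[idx].gate_traces
                if parts[2] in traces:
                    return traces[parts[2]].copy()
        raise KeyError(
            f"unknown activation source {source!r}; available: {self.available_sources()}"
        )


class RSPRegressor(BaseEstimator):
    """Sequence regressor for remaining surgery progress.

    Parameters
    ----------
    encoder : {"small_cnn", "alexnet_like", "resnet18_like"}
        Frame encoder.  The latter two are hooks for externally supplied
        pretrained backbones and require `pretrained_weights`.
    encoder_width : int
        Dimension of the per-frame spatial representation.
    decoder : {"gru", "lstm"}
    hidden_size, n_layers : int
        Recurrent decoder width and depth.
    input_size : int
        Expected frame side length in pixels.
    optimizer : {"adam", "rmsprop"}
    learning_rate : float
        Default 1e-3 suits the 16x16 toy scale; 1e-5 is the recommended
        setting at full video scale.
    epochs : int
    validation_fraction : float
        Fraction of *trajectories* held out for the per-epoch validation
        MAE (the split is by sequence, never by frame).
    seed : int
        Controls weight initialization and epoch shuffling.
    """

    def __init__(self, encoder="small_cnn", encoder_width=16, decoder="gru",
                 hidden_size=32, n_layers=1, input_size=16, frame_rate=2.0,
                 optimizer="adam", learning_rate=1e-3, epochs=60,
                 validation_fraction=0.25, seed=0, pretrained_weights=None):
        self.encoder = encoder
        self.encoder_width = encoder_width
        self.decoder = decoder
        self.hidden_size = hidden_size
        self.n_layers = n_layers
        self.input_size = input_size
        self.frame_rate = frame_rate
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.validation_fraction = validation_fraction
        self.seed = seed
        self.pretrained_weights = pretrained_weights

    def _check_video(self, video) -> np.ndarray:
        v = np.asarray(video, dtype=float)
        if v.ndim != 3 or v.shape[0] == 0:
            raise ValueError("video must be a non-empty (tau, H, W) array")
        if v.shape[1] != self.input_size or v.shape[2] != self.input_size:
            raise ValueError(
                f"frames are {v.shape[1]}x{v.shape[2]}, model expects "
                f"{self.input_size}x{self.input_size}"
            )
        return v

    def fit(self, videos, y=None):
        """Train on whole video sequences against their own RSP labels."""
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        videos = [self._check_video(v) for v in videos]
        if len(videos) < 2:
            raise ValueError("need at least two sequences (one is held out)")
        rng = np.random.default_rng(self.seed)
        if self.encoder != "small_cnn" and self.pretrained_weights is None:
            raise ValueError(
                f"encoder {self.encoder!r} requires pretrained_weights; "
                "no bundled weights exist for the backbone hooks"
            )
        self.model_ = _EncoderDecoder(
            self.encoder, self.input_size, self.encoder_width, self.decoder,
            self.hidden_size, self.n_layers, rng,
        )
        order = rng.permutation(len(videos))
        n_val = max(1, int(round(self.validation_fraction * len(videos))))
        n_val = min(n_val, len(videos) - 1)
        self.val_idx_ = np.sort(order[:n_val])
        self.train_idx_ = np.sort(order[n_val:])
        opt_cls = {"adam": nn.Adam, "rmsprop": nn.RMSProp}[self.optimizer]
        opt = opt_cls(self.model_.named_parameters(), lr=self.learning_rate)
        history = {"train_mae": [], "val_mae": []}
        for _ in range(self.epochs):
            losses = []
            for i in rng.permutation(self.train_idx_):
                v = videos[i]
                labels = rsp_labels(v.shape[0])
                self.model_.zero_grad()
                pred = self.model_.forward(v)
                resid = pred - labels
                losses.append(np.mean(np.abs(resid)))
                self.model_.backward(np.sign(resid) / resid.size)
                opt.step()
            history["train_mae"].append(float(np.mean(losses)))
            history["val_mae"].append(
                float(np.mean([self._seq_mae(videos[i]) for i in self.val_idx_]))
            )
        self.history_ = history
        return self

    def _seq_mae(self, video: np.ndarray) -> float:
        pred = self.model_.forward(video)
        return float(np.mean(np.abs(pred - rsp_labels(video.shape[0]))))

    def predict(self, video) -> np.ndarray:
        """Per-frame predicted RSP in (0, 1); deterministic."""
        v = self._check_video(video)
        return self.model_.forward(v)

    def mae(self, videos) -> float:
        """Mean absolute error against the RSP labels, averaged over sequences."""
        return float(np.mean([self._seq_mae(self._check_video(v)) for v in videos]))

    def score(self, videos, y=None) -> float:
        return -self.mae(videos)

    def extract_activations(self, video, sources, trajectory_id=None):
        """Record per-frame internal activations; never alters predictions."""
        v = self._check_video(video)
        self.model_.forward(v)
        return [
            RepresentationTrace(source=s, values=self.model_.collect(s),
                                trajectory_id=trajectory_id)
            for s in sources
        ]

    def available_sources(self) -> list[str]:
        return self.model_.available_sources()

    def save(self, path) -> None:
        """Persist configuration, weights and training history to one .npz."""
        import json

        arrays = {name.replace(".", "/"): p for name, p, _ in self.model_.named_parameters()}
        meta = json.dumps({"params": self.get_params(), "history": self.history_})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "RSPRegressor":
        import json

        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        est = cls(**meta["params"])
        rng = np.random.default_rng(est.seed)
        est.model_ = _EncoderDecoder(
            est.encoder, est.input_size, est.encoder_width, est.decoder,
            est.hidden_size, est.n_layers, rng,
        )
        for name, p, _ in est.model_.named_parameters():
            p[...] = data[name.replace(".", "/")]
        est.history_ = meta["history"]
        return est


def gate_source(layer: int = 1, gate: str = "update") -> str:
    """Source id of a decoder gate, 1-based layer indexing."""
    return f"decoder.l{layer}.{gate}"


def train_rsp(videos, **params) -> RSPRegressor:
    return RSPRegressor(**params).fit(videos)


def predict_rsp(model: RSPRegressor, video) -> np.ndarray:
    return model.predict(video)


def extract_activations(model: RSPRegressor, video, sources, trajectory_id=None):
    return model.extract_activations(video, sources, trajectory_id)
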