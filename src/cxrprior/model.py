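"""The dual-stream CNN.

Two parallel convolutional streams see the same input image; stream S1
uses 3x3 kernels throughout, stream S2 uses 5x5 kernels, so the streams
learn different families of edge/boundary features.  Each stream is
three blocks of [conv, ReLU, conv, batch-norm, ReLU, dropout, 2x2
max-pool].  The flattened stream features F_S1 and F_S2 are
concatenated into F_total, and a single dense head maps F_total to one
embedding vector nu_k per class.  Each vector is squashed to norm < 1
and the prediction score for class k is ||nu_k||, which is what the
margin loss operates on.
"""

from __future__ import annotations

import hashlib

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from cxrprior import nn


class ModelConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters.

    The three-blocks / two-convs-per-block structure and the 3x3 vs
    5x5 kernel split are fixed; filter widths, dropout and embedding
    length are free choices (defaults keep the network desk-scale).
    """

    input_size: int = 128
    n_classes: int = 2
    blocks_per_stream: int = 3
    convs_per_block: int = 2
    kernel_s1: int = 3
    kernel_s2: int = 5
    pool: int = 2
    filters_per_block: tuple[int, ...] = (16, 32, 64)
    dropout_rate: float = 0.25
    embedding_len: int = 8
    task_kind: Literal["single", "multi"] = "single"
    #: Standardize each input image to zero mean / unit variance before
    #: the streams.  Makes the network invariant to the large intensity
    #: shifts between dataset versions (raw vs CLAHE-equalized), which
    #: is what lets backbones transfer across them.
    standardize_input: bool = True
    dtype: str = "float32"

    def validate(self) -> None:
        if self.blocks_per_stream != 3 or self.convs_per_block != 2:
            raise ModelConfigError(
                "the architecture is fixed at 3 blocks of 2 convolutions per stream"
            )
        if self.kernel_s1 == self.kernel_s2:
            raise ModelConfigError("the two streams must use different kernel sizes")
        if self.pool != 2:
            raise ModelConfigError("pooling is fixed at 2x2")
        divisor = self.pool ** self.blocks_per_stream
        if self.input_size % divisor:
            raise ModelConfigError(
                f"input_size={self.input_size} must be divisible by "
                f"{divisor} (three 2x2 poolings)"
            )
        if len(self.filters_per_block) != self.blocks_per_stream:
            raise ModelConfigError(
                f"filters_per_block needs {self.blocks_per_stream} entries"
            )
        if self.n_classes < 1 or self.embedding_len < 1:
            raise ModelConfigError("n_classes and embedding_len must be >= 1")

    @property
    def feature_map_size(self) -> int:
        return self.input_size // self.pool ** self.blocks_per_stream

    @property
    def stream_feature_len(self) -> int:
        return self.feature_map_size ** 2 * self.filters_per_block[-1]


@dataclass
class StreamFeatureBank:
    """Per-stream flattened features and their concatenation F_total."""

    f_s1: np.ndarray
    f_s2: np.ndarray

    @property
    def f_total(self) -> np.ndarray:
        return np.concatenate([self.f_s1, self.f_s2], axis=-1)


@dataclass
class ClassEmbedding:
    """Per-class squashed vectors nu_k and their norms as scores."""

    vectors: np.ndarray        # (N, n_classes, embedding_len)
    scores: np.ndarray         # (N, n_classes), in [0, 1)


def _build_stream(cfg: ModelConfig, kernel: int, rng: np.random.Generator,
                  dtype) -> list[nn.Layer]:
    layers: list[nn.Layer] = []
    c_in = 1
    for width in cfg.filters_per_block:
        layers.append(nn.Conv2D(c_in, width, kernel, rng, dtype=dtype))
        layers.append(nn.ReLU())
        layers.append(nn.Conv2D(width, width, kernel, rng, dtype=dtype))
        layers.append(nn.BatchNorm2D(width, dtype=dtype))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(cfg.dropout_rate, rng))
        layers.append(nn.MaxPool2())
        c_in = width
    return layers


class DualStreamModel:
    """Build with :meth:`build`; see the module docstring for the wiring."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        cfg.validate()
        self.cfg = cfg
        self.seed = seed
        dtype = np.dtype(cfg.dtype)
        root = np.random.SeedSequence(seed)
        s1_ss, s2_ss, head_ss = root.spawn(3)
        self.stream1 = _build_stream(cfg, cfg.kernel_s1,
                                     np.random.default_rng(s1_ss), dtype)
        self.stream2 = _build_stream(cfg, cfg.kernel_s2,
                                     np.random.default_rng(s2_ss), dtype)
        self.head = nn.Dense(
            2 * cfg.stream_feature_len,
            cfg.n_classes * cfg.embedding_len,
            np.random.default_rng(head_ss),
            dtype=dtype,
        )
        # Cool head init: keeps initial embedding norms in the squash
        # map's responsive range instead of its saturated tail.
        self.head.W.value *= 0.5
        self._squash_cache = None
        self._batch_n = 0

    # -- construction ------------------------------------------------------

    @classmethod
    def build(cls, cfg: ModelConfig, seed: int = 0) -> "DualStreamModel":
        return cls(cfg, seed=seed)

    def swap_head(self, new_n_classes: int,
                  task_kind: Literal["single", "multi"] = "single",
                  seed: int = 0) -> "DualStreamModel":
        """Replace the classification head, preserving both backbones bit-exactly."""
        import dataclasses as _dc

        self.cfg = _dc.replace(self.cfg, n_classes=new_n_classes,
                               task_kind=task_kind)
        dtype = np.dtype(self.cfg.dtype)
        self.head = nn.Dense(
            2 * self.cfg.stream_feature_len,
            new_n_classes * self.cfg.embedding_len,
            np.random.default_rng(np.random.SeedSequence([seed, 0x48454144])),
            dtype=dtype,
        )
        self.head.W.value *= 0.5
        return self

    # -- parameters --------------------------------------------------------

    def backbone_params(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        for layer in [*self.stream1, *self.stream2]:
            out.extend(layer.params())
        return out

    def params(self) -> list[nn.Param]:
        return [*self.backbone_params(), *self.head.params()]

    def param_count(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def backbone_checksum(self) -> str:
        h = hashlib.sha256()
        for p in self.backbone_params():
            h.update(np.ascontiguousarray(p.value).tobytes())
        for layer in [*self.stream1, *self.stream2]:
            if isinstance(layer, nn.BatchNorm2D):
                h.update(layer.running_mean.tobytes())
                h.update(layer.running_var.tobytes())
        return h.hexdigest()

    def head_checksum(self) -> str:
        h = hashlib.sha256()
        for p in self.head.params():
            h.update(np.ascontiguousarray(p.value).tobytes())
        return h.hexdigest()

    # -- forward / backward ------------------------------------------------

    def _as_batch(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=self.cfg.dtype)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1] != self.cfg.input_size or x.shape[2] != self.cfg.input_size:
            raise ValueError(
                f"expected images of shape (N, {self.cfg.input_size}, "
                f"{self.cfg.input_size}), got {np.asarray(images).shape}"
            )
        if self.cfg.standardize_input:
            mu = x.mean(axis=(1, 2), keepdims=True)
            sd = x.std(axis=(1, 2), keepdims=True)
            x = (x - mu) / np.maximum(sd, 1e-6)
        return x[:, None]                      # (N, 1, H, W)

    def forward(self, images: np.ndarray, train: bool = False,
                capture: Sequence[nn.Layer] = ()) -> tuple[ClassEmbedding, StreamFeatureBank]:
        """Run the network; dropout is active only when ``train`` is True.

        ``capture`` names layers whose *outputs* should be recorded
        (used by Grad-CAM); they are available afterwards in
        ``self.captured``.
        """
        x = self._as_batch(images)
        n = x.shape[0]
        self._batch_n = n
        self.captured: dict[nn.Layer, np.ndarray] = {}

        feats = []
        for stream in (self.stream1, self.stream2):
            h = x
            for layer in stream:
                h = layer.forward(h, train)
                if layer in capture:
                    self.captured[layer] = h
            feats.append(h.reshape(n, -1))
        bank = StreamFeatureBank(f_s1=feats[0], f_s2=feats[1])

        raw = self.head.forward(bank.f_total, train)
        raw = raw.reshape(n, self.cfg.n_classes, self.cfg.embedding_len)
        vectors, self._squash_cache = nn.squash(raw, axis=-1)
        scores = np.linalg.norm(vectors, axis=-1)
        return ClassEmbedding(vectors=vectors, scores=scores), bank

    def backward(self, grad_vectors: np.ndarray,
                 capture_grads: Sequence[nn.Layer] = ()) -> dict[nn.Layer, np.ndarray]:
        """Backpropagate d(loss)/d(vectors) through head and both streams.

        Parameter gradients accumulate into each ``Param.grad``.
        Returns, for each layer in ``capture_grads``, the gradient of
        the loss with respect to that layer's *output*.
        """
        n = self._batch_n
        grad_raw = nn.squash_backward(grad_vectors, self._squash_cache)
        grad_flat = self.head.backward(grad_raw.reshape(n, -1))
        d = self.cfg.stream_feature_len
        fmap = self.cfg.feature_map_size
        c_last = self.cfg.filters_per_block[-1]
        grads = {}
        for stream, g in zip(
            (self.stream1, self.stream2), (grad_flat[:, :d], grad_flat[:, d:])
        ):
            h = g.reshape(n, c_last, fmap, fmap)
            for layer in reversed(stream):
                if layer in capture_grads:
                    grads[layer] = h
                h = layer.backward(h)
        return grads

    def predict(self, scores: np.ndarray) -> np.ndarray:
        """Argmax for single-label tasks, 0.5 score threshold for multi-label."""
        if self.cfg.task_kind == "single":
            return scores.argmax(axis=-1)
        return scores > 0.5

    @property
    def last_conv_s1(self) -> nn.Conv2D:
        return [l for l in self.stream1 if isinstance(l, nn.Conv2D)][-1]

    @property
    def last_conv_s2(self) -> nn.Conv2D:
        return [l for l in self.stream2 if isinstance(l, nn.Conv2D)][-1]

    # -- descriptor --------------------------------------------------------

    def describe(self) -> dict:
        size = self.cfg.input_size
        streams = []
        for name, stream, kernel in (
            ("S1", self.stream1, self.cfg.kernel_s1),
            ("S2", self.stream2, self.cfg.kernel_s2),
        ):
            s = size
            layers = []
            for layer in stream:
                d = layer.describe()
                if d["kind"] == "maxpool":
                    s //= 2
                d["output_size"] = s
                layers.append(d)
            streams.append(
                {
                    "name": name,
                    "kernel": kernel,
                    "layers": layers,
                    "n_conv": sum(1 for l in layers if l["kind"] == "conv"),
                    "n_pool": sum(1 for l in layers if l["kind"] == "maxpool"),
                    "feature_len": self.cfg.stream_feature_len,
                }
            )
        return {
            "config": asdict(self.cfg),
            "streams": streams,
            "f_total_len": 2 * self.cfg.stream_feature_len,
            "head": self.head.describe(),
            "param_count": self.param_count(),
        }

    def describe_json(self) -> str:
        return json.dumps(self.describe(), indent=2)

    # -- serialization -----------------------------------------------------

    def _state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {}
        for si, stream in enumerate((self.stream1, self.stream2), start=1):
            for li, layer in enumerate(stream):
                for pi, p in enumerate(layer.params()):
                    arrays[f"s{si}.{li}.{pi}"] = p.value
                if isinstance(layer, nn.BatchNorm2D):
                    arrays[f"s{si}.{li}.rmean"] = layer.running_mean
                    arrays[f"s{si}.{li}.rvar"] = layer.running_var
        for pi, p in enumerate(self.head.params()):
            arrays[f"head.{pi}"] = p.value
        return arrays

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {k: v for k, v in self._state_arrays().items()}
        cfg_json = json.dumps({"cfg": asdict(self.cfg), "seed": self.seed})
        np.savez_compressed(path, __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8), **arrays)
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "DualStreamModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__config__"]).decode())
            cfg = ModelConfig(**{**meta["cfg"],
                                 "filters_per_block": tuple(meta["cfg"]["filters_per_block"])})
            model = cls(cfg, seed=meta["seed"])
            for key, value in model._state_arrays().items():
                value[...] = data[key]
        return model

    def copy_state_from(self, other: "DualStreamModel") -> None:
        """Copy all weights and running stats from a same-shaped model."""
        mine, theirs = self._state_arrays(), other._state_arrays()
        for key, arr in mine.items():
            arr[...] = theirs[key]
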