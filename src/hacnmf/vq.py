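"""Vector quantisation of the three feature streams.

Three codebooks are learned by k-means from a held-out clean-speech corpus
(disjoint from all learning and test speakers): 150 centroids for the static
cepstra, 150 for the speed-of-change (delta) stream and 100 for the
acceleration (delta-delta) stream. Quantisation replaces each frame by the
index of its nearest centroid (plain Euclidean distance, ties broken by the
lowest index) independently per stream and per frame. The same clean-speech
codebooks are used for noisy input — no noise adaptation of any kind.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .frontend import FeatureMatrix

__all__ = ["DEFAULT_CODEBOOK_SIZES", "Codebook", "LabelStreams", "train_codebooks", "quantize"]

#: (static, delta, delta-delta) codebook sizes.
DEFAULT_CODEBOOK_SIZES = (150, 150, 100)

_STREAMS = ("static", "delta", "deltadelta")


@dataclass
class Codebook:
    static_centroids: np.ndarray  # (150, 13)
    delta_centroids: np.ndarray  # (150, 13)
    dd_centroids: np.ndarray  # (100, 13)
    training_fingerprint: str = ""

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (
            self.static_centroids.shape[0],
            self.delta_centroids.shape[0],
            self.dd_centroids.shape[0],
        )

    def __post_init__(self) -> None:
        for c in (self.static_centroids, self.delta_centroids, self.dd_centroids):
            if c.ndim != 2:
                raise ValueError("centroids must be 2-D arrays")
            if len(np.unique(c, axis=0)) != len(c):
                raise ValueError("duplicate centroids within a codebook")

    def save(self, path: str | Path) -> None:
        """Serialise to a versioned JSON container."""
        payload = {
            "format": "hacnmf-codebook",
            "version": 1,
            "fingerprint": self.training_fingerprint,
            "static": self.static_centroids.tolist(),
            "delta": self.delta_centroids.tolist(),
            "deltadelta": self.dd_centroids.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "Codebook":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "hacnmf-codebook":
            raise ValueError(f"{path} is not a codebook container")
        return cls(
            np.asarray(payload["static"], dtype=np.float64),
            np.asarray(payload["delta"], dtype=np.float64),
            np.asarray(payload["deltadelta"], dtype=np.float64),
            payload.get("fingerprint", ""),
        )


@dataclass
class LabelStreams:
    """Per-frame codebook labels for the three streams."""

    static_labels: np.ndarray
    delta_labels: np.ndarray
    dd_labels: np.ndarray

    def __post_init__(self) -> None:
        if not (
            len(self.static_labels) == len(self.delta_labels) == len(self.dd_labels)
        ):
            raise ValueError("label streams must have equal length")

    @property
    def n_frames(self) -> int:
        return len(self.static_labels)


def _pool(features: list[FeatureMatrix], stream: str) -> np.ndarray:
    return np.vstack([getattr(f, stream) for f in features])


def train_codebooks(
    features: list[FeatureMatrix],
    seed: int,
    sizes: tuple[int, int, int] = DEFAULT_CODEBOOK_SIZES,
) -> Codebook:
    """k-means codebooks per stream (k-means++ init, <=100 iterations).

    Requires at least 10x the largest codebook size in pooled frames.
    Deterministic for a given ``(features, seed)``.
    """
    pools = [_pool(features, s) for s in _STREAMS]
    n_frames = pools[0].shape[0]
    if n_frames < 10 * max(sizes):
        raise ValueError(
            f"insufficient training frames: {n_frames} < 10 x {max(sizes)}"
        )
    digest = hashlib.sha1()
    for p in pools:
        digest.update(np.ascontiguousarray(p).tobytes())
    centroids = []
    for p, k, sub in zip(pools, sizes, (0, 1, 2)):
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=1,
            max_iter=100,
            tol=1e-6,
            random_state=(seed * 3 + sub) % 2**31,
        ).fit(p)
        centroids.append(km.cluster_centers_.astype(np.float64))
    return Codebook(*centroids, training_fingerprint=digest.hexdigest())


def _nearest(frames: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    # argmin over squared Euclidean distance; np.argmin returns the first
    # (lowest-index) minimiser, which is the documented tie-break.
    d = (
        np.sum(frames**2, axis=1)[:, None]
        - 2.0 * frames @ centroids.T
        + np.sum(centroids**2, axis=1)[None, :]
    )
    return np.argmin(d, axis=1)


def quantize(features: FeatureMatrix, book: Codebook) -> LabelStreams:
    """Map each frame to its nearest centroid, per stream."""
    if features.static.shape[1] != book.static_centroids.shape[1]:
        raise ValueError(
            "feature dimensionality does not match the codebook"
        )
    return LabelStreams(
        _nearest(features.static, book.static_centroids),
        _nearest(features.delta, book.delta_centroids),
        _nearest(features.deltadelta, book.dd_centroids),
    )
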