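"""Histograms of Acoustic Co-occurrences (HAC) and their meaning extension.

A variable-length utterance, represented as three parallel codebook-label
streams, is converted to a fixed-length sparse count vector: for each stream
and each time lag (20 ms and 50 ms, i.e. 2 and 5 frames at the 10-ms shift),
the ordered label pair ``(a at t, b at t+lag)`` increments one counter. Only
within-stream pairs are counted, so with codebooks of sizes (150, 150, 100)
and two lags the space holds (150^2 + 150^2 + 100^2) * 2 = 110,000 counters.

Block layout (offsets within the vector)::

    [static-lag2 | static-lag5 | delta-lag2 | delta-lag5 | dd-lag2 | dd-lag5]
      22500        22500         22500        22500        10000     10000

with index a * K + b inside each block.

During learning the acoustic vector is extended by one entry per keyword
(the "meaning" block): the entry of the keyword present in the sentence is
set on, all others are zero. Test utterances carry an all-zero meaning
block. To keep the supervision from dominating reconstruction, the acoustic
block is normalised to a fixed mass (default 100) and the meaning entry is
given a smaller configurable mass (default 10).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lexicon import KEYWORDS
from .vq import DEFAULT_CODEBOOK_SIZES, LabelStreams

__all__ = [
    "DEFAULT_LAGS",
    "HACVector",
    "HACMVector",
    "HACEncoder",
    "hac_encode",
    "attach_meaning",
]

#: Time lags in frames (20 ms and 50 ms at the 10-ms frame shift).
DEFAULT_LAGS = (2, 5)

ACOUSTIC_MASS = 100.0
MEANING_MASS = 10.0


@dataclass
class HACVector:
    """Sparse non-negative co-occurrence counts."""

    dimension: int
    indices: np.ndarray  # sorted unique positions
    counts: np.ndarray  # same length, > 0

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if len(self.indices) != len(self.counts):
            raise ValueError("indices and counts must align")
        if len(self.indices) and (
            self.indices.min() < 0 or self.indices.max() >= self.dimension
        ):
            raise ValueError("index out of range")
        if np.any(self.counts < 0):
            raise ValueError("negative counts are not allowed")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def nnz(self) -> int:
        return len(self.indices)

    def to_dense(self) -> np.ndarray:
        dense = np.zeros(self.dimension)
        dense[self.indices] = self.counts
        return dense

    def to_coo_text(self, block_layout: str = "") -> str:
        """Coordinate-format text: a header naming the layout, then
        ``index,count`` lines for the non-zero entries."""
        lines = [f"# hacnmf-hac dimension={self.dimension} layout={block_layout}"]
        lines += [f"{i},{c:g}" for i, c in zip(self.indices, self.counts)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_coo_text(cls, text: str) -> "HACVector":
        lines = [l for l in text.strip().splitlines() if l]
        header = lines[0]
        if not header.startswith("# hacnmf-hac dimension="):
            raise ValueError("not a HAC coordinate-format dump")
        dim = int(header.split("dimension=")[1].split()[0])
        pairs = [l.split(",") for l in lines[1:]]
        idx = np.array([int(i) for i, _ in pairs], dtype=np.int64)
        cnt = np.array([float(c) for _, c in pairs])
        return cls(dim, idx, cnt)


@dataclass
class HACMVector(HACVector):
    """HAC vector extended with the keyword (meaning) block.

    ``acoustic_dim`` rows are acoustic; the final ``len(keywords)`` rows form
    the meaning block. For labelled learning utterances exactly one meaning
    entry is non-zero; for test utterances the meaning block is all zero.
    """

    acoustic_dim: int = 0
    keyword: str | None = None


class HACEncoder:
    """Fixed-geometry encoder from label streams to HAC(+M) vectors."""

    def __init__(
        self,
        codebook_sizes: tuple[int, int, int] = DEFAULT_CODEBOOK_SIZES,
        lags: tuple[int, ...] = DEFAULT_LAGS,
        keywords: tuple[str, ...] = KEYWORDS,
    ):
        if any(l < 1 for l in lags):
            raise ValueError("lags must be positive frame counts")
        self.codebook_sizes = tuple(codebook_sizes)
        self.lags = tuple(lags)
        self.keywords = tuple(keywords)
        # block offsets: streams outer, lags inner
        self.block_sizes = [
            k * k for k in self.codebook_sizes for _ in self.lags
        ]
        self.block_offsets = np.concatenate([[0], np.cumsum(self.block_sizes)[:-1]])

    @property
    def dimension(self) -> int:
        """Acoustic dimensionality: sum over streams of K^2 per lag."""
        return int(sum(self.block_sizes))

    @property
    def meaning_dim(self) -> int:
        return len(self.keywords)

    def expected_total(self, n_frames: int) -> int:
        """Analytic pair count: one pair per stream per valid (t, t+lag)."""
        return 3 * sum(max(n_frames - lag, 0) for lag in self.lags)

    def encode(self, labels: LabelStreams) -> HACVector:
        """Count within-stream label pairs at each lag."""
        t = labels.n_frames
        if t <= max(self.lags):
            raise ValueError(
                f"utterance of {t} frames is shorter than the largest lag "
                f"({max(self.lags)} frames)"
            )
        streams = (labels.static_labels, labels.delta_labels, labels.dd_labels)
        parts = []
        block = 0
        for stream, k in zip(streams, self.codebook_sizes):
            stream = np.asarray(stream, dtype=np.int64)
            if len(stream) and (stream.min() < 0 or stream.max() >= k):
                raise ValueError("label outside codebook range")
            for lag in self.lags:
                pair_idx = stream[:-lag] * k + stream[lag:]
                parts.append(pair_idx + self.block_offsets[block])
                block += 1
        all_idx = np.concatenate(parts)
        indices, counts = np.unique(all_idx, return_counts=True)
        return HACVector(self.dimension, indices, counts.astype(np.float64))

    def attach_meaning(
        self,
        v: HACVector,
        keyword: str | None,
        meaning_mass: float = MEANING_MASS,
        acoustic_mass: float = ACOUSTIC_MASS,
    ) -> HACMVector:
        """Normalise the acoustic block and append the meaning block.

        The acoustic counts are scaled to sum to ``acoustic_mass``; if a
        keyword is given its meaning entry is set to ``meaning_mass``
        (identical for every utterance with that keyword), otherwise the
        meaning block is all zero.
        """
        if v.dimension != self.dimension:
            raise ValueError("vector geometry does not match the encoder")
        total = v.total
        if total <= 0:
            raise ValueError("cannot normalise an all-zero HAC vector")
        scaled = v.counts * (acoustic_mass / total)
        if keyword is None:
            idx, cnt = v.indices, scaled
        else:
            if keyword not in self.keywords:
                raise KeyError(f"unknown keyword: {keyword!r}")
            kpos = self.dimension + self.keywords.index(keyword)
            idx = np.concatenate([v.indices, [kpos]])
            cnt = np.concatenate([scaled, [meaning_mass]])
        return HACMVector(
            dimension=self.dimension + self.meaning_dim,
            indices=idx,
            counts=cnt,
            acoustic_dim=self.dimension,
            keyword=keyword,
        )


def hac_encode(
    labels: LabelStreams,
    codebook_sizes: tuple[int, int, int] = DEFAULT_CODEBOOK_SIZES,
    lags: tuple[int, ...] = DEFAULT_LAGS,
) -> HACVector:
    """Convenience wrapper around :meth:`HACEncoder.encode`."""
    return HACEncoder(codebook_sizes, lags).encode(labels)


def attach_meaning(
    v: HACVector,
    keyword: str | None,
    meaning_mass: float = MEANING_MASS,
    acoustic_mass: float = ACOUSTIC_MASS,
    codebook_sizes: tuple[int, int, int] = DEFAULT_CODEBOOK_SIZES,
    lags: tuple[int, ...] = DEFAULT_LAGS,
) -> HACMVector:
    """Convenience wrapper around :meth:`HACEncoder.attach_meaning`."""
    return HACEncoder(codebook_sizes, lags).attach_meaning(
        v, keyword, meaning_mass, acoustic_mass
    )
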