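"""From scored peaks and a genome to a labeled, encoded, split dataset.

The protocol: keep the top-k peaks by score, extract the 301-nt window
centred on each peak's interval midpoint, generate dinucleotide-preserving
shuffled negatives (2 per positive by default), and split 70/20/10 into
train/validation/test with each positive and its derived negatives kept in
the same split so no shuffle-parent pair straddles a split boundary.
"""

from __future__ import annotations

import hashlib
import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .alphabet import BASES, N_INDEX, encode_indices

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 301
SPLITS = ("train", "validation", "test")

__all__ = [
    "PeakRecord",
    "SequenceExample",
    "DatasetManifest",
    "Dataset",
    "select_top_peaks",
    "extract_window",
    "extract_positive_examples",
    "dinucleotide_shuffle",
    "build_dataset",
    "one_hot_encode",
    "kmer_index_encode",
    "kmer_index_decode",
]


@dataclass
class PeakRecord:
    """A scored genomic interval (BED/narrowPeak coordinates: 0-based,
    half-open)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end}) for {self.name}")
        if not math.isfinite(self.score):
            raise ValueError(f"non-finite score for peak {self.name}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class SequenceExample:
    sequence: str
    label: int  # 1 positive, 0 negative
    provenance: str  # source peak id, or shuffle-parent id for negatives
    name: str
    split: str | None = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


@dataclass
class DatasetManifest:
    counts: dict  # {split: {label: count}}
    window_length: int
    negative_ratio: int
    split_fractions: tuple[float, float, float]
    seed: int

    @property
    def n_total(self) -> int:
        return sum(sum(by_label.values()) for by_label in self.counts.values())

    def to_dict(self) -> dict:
        return {
            "counts": {s: {str(l): c for l, c in by.items()} for s, by in self.counts.items()},
            "window_length": self.window_length,
            "negative_ratio": self.negative_ratio,
            "split_fractions": list(self.split_fractions),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DatasetManifest":
        return cls(
            counts={s: {int(l): c for l, c in by.items()} for s, by in d["counts"].items()},
            window_length=d["window_length"],
            negative_ratio=d["negative_ratio"],
            split_fractions=tuple(d["split_fractions"]),
            seed=d["seed"],
        )


class Dataset:
    """A list of labeled, split sequence examples with convenience views."""

    def __init__(self, examples: list[SequenceExample]):
        self.examples = examples

    def __len__(self) -> int:
        return len(self.examples)

    def split(self, name: str) -> list[SequenceExample]:
        if name not in SPLITS:
            raise ValueError(f"unknown split {name!r}")
        return [e for e in self.examples if e.split == name]

    def sequences(self, split: str | None = None) -> list[str]:
        exs = self.examples if split is None else self.split(split)
        return [e.sequence for e in exs]

    def labels(self, split: str | None = None) -> np.ndarray:
        exs = self.examples if split is None else self.split(split)
        return np.array([e.label for e in exs], dtype=int)

    def positives(self, split: str | None = None) -> list[SequenceExample]:
        exs = self.examples if split is None else self.split(split)
        return [e for e in exs if e.label == 1]


def select_top_peaks(peaks: list[PeakRecord], k: int) -> list[PeakRecord]:
    """The k highest-scoring peaks, sorted by descending score; ties broken by
    (chrom, start) so the selection is deterministic."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(peaks):
        raise ValueError(f"requested top {k} peaks but only {len(peaks)} available")
    return sorted(peaks, key=lambda p: (-p.score, p.chrom, p.start))[:k]


def _genome_length(genome, chrom: str) -> int:
    if hasattr(genome, "length"):
        return genome.length(chrom)
    return len(genome[chrom])


def _genome_fetch(genome, chrom: str, start: int, end: int) -> str:
    if hasattr(genome, "fetch"):
        return genome.fetch(chrom, start, end)
    return str(genome[chrom][start:end]).upper()


def extract_window(genome, peak: PeakRecord, window_length: int = DEFAULT_WINDOW) -> str | None:
    """The window_length-nt sequence centred on the peak's interval midpoint:
    genome[mid - W//2, mid - W//2 + W). Windows that overrun a chromosome end
    are skipped (None) with a logged warning, never padded."""
    mid = peak.midpoint
    start = mid - window_length // 2
    end = start + window_length
    if start < 0 or end > _genome_length(genome, peak.chrom):
        logger.warning(
            "peak %s at %s:%d-%d: window [%d, %d) overruns the chromosome; skipped",
            peak.name, peak.chrom, peak.start, peak.end, start, end,
        )
        return None
    return _genome_fetch(genome, peak.chrom, start, end)


def extract_positive_examples(
    genome,
    peaks: list[PeakRecord],
    window_length: int = DEFAULT_WINDOW,
    max_n_fraction: float = 0.10,
) -> list[SequenceExample]:
    """Extract windows for all peaks, dropping boundary overruns and
    sequences with more than ``max_n_fraction`` ambiguous (N) bases."""
    out = []
    n_dropped = 0
    for i, peak in enumerate(peaks):
        seq = extract_window(genome, peak, window_length)
        if seq is None:
            continue
        if seq.count("N") > max_n_fraction * len(seq):
            logger.warning("peak %s: >%.0f%% N bases; dropped", peak.name, 100 * max_n_fraction)
            n_dropped += 1
            continue
        name = peak.name if peak.name != "." else f"peak_{i:05d}"
        out.append(SequenceExample(sequence=seq, label=1, provenance=name, name=name))
    if n_dropped:
        logger.info("dropped %d peaks for excess N content", n_dropped)
    return out


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving all 16 dinucleotide counts.

    Altschul-Erickson scheme: the sequence is an Eulerian path on the
    base-transition multigraph; a uniformly random spanning arborescence
    toward the final base is drawn by rejection, the remaining out-edges of
    each vertex are permuted, and the path is walked from the original first
    base. First and last characters are invariant.
    """
    if len(sequence) < 2:
        raise ValueError("dinucleotide shuffling needs a sequence of length >= 2")
    codes = encode_indices(sequence)
    if (codes == N_INDEX).any():
        raise ValueError("sequence contains N; replace ambiguous bases first")
    edges: dict[int, list[int]] = defaultdict(list)
    for a, b in zip(codes[:-1], codes[1:]):
        edges[int(a)].append(int(b))
    first, last = int(codes[0]), int(codes[-1])
    vertices = [v for v in edges if v != last]
    # draw last-edges until they form an arborescence into `last`
    while True:
        last_edge = {v: edges[v][rng.integers(len(edges[v]))] for v in vertices}
        if all(_reaches(v, last, last_edge) for v in vertices):
            break
    order: dict[int, list[int]] = {}
    for v, out in edges.items():
        rest = list(out)
        if v != last:
            rest.remove(last_edge[v])
        perm = rng.permutation(len(rest))
        shuffled = [rest[i] for i in perm]
        if v != last:
            shuffled.append(last_edge[v])
        order[v] = shuffled
    ptr = {v: 0 for v in order}
    walk = [first]
    cur = first
    total = len(codes) - 1
    for _ in range(total):
        nxt = order[cur][ptr[cur]]
        ptr[cur] += 1
        walk.append(nxt)
        cur = nxt
    return "".join(BASES[c] for c in walk)


def _reaches(v: int, last: int, last_edge: dict[int, int]) -> bool:
    seen = set()
    while v != last:
        if v in seen or v not in last_edge:
            return False
        seen.add(v)
        v = last_edge[v]
    return True


def _negative_rng(seed: int, parent: str, replicate: int) -> np.random.Generator:
    digest = hashlib.sha256(f"{seed}:{parent}:{replicate}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "little"))


def _replace_ns(sequence: str, rng: np.random.Generator) -> str:
    if "N" not in sequence:
        return sequence
    chars = list(sequence)
    for i, c in enumerate(chars):
        if c == "N":
            chars[i] = BASES[rng.integers(4)]
    return "".join(chars)


def build_dataset(
    positives: list[SequenceExample],
    negative_ratio: int = 2,
    split_fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
    seed: int = 0,
) -> tuple[Dataset, DatasetManifest]:
    """Attach shuffled negatives and split.

    Negatives: exactly ``negative_ratio`` independent dinucleotide shuffles
    per positive, each from a sub-seed hashed from (seed, parent id,
    replicate) so the dataset is reproducible while shuffles stay
    independent. Splits: validation and test take floor(fraction x n)
    positive families each, the remainder trains; a family (positive plus its
    negatives) never straddles a split boundary.
    """
    if not positives:
        raise ValueError("positives must be nonempty")
    if negative_ratio < 1:
        raise ValueError("negative_ratio must be >= 1")
    if not math.isclose(sum(split_fractions), 1.0, abs_tol=1e-9):
        raise ValueError(f"split fractions {split_fractions} do not sum to 1")
    n_pos = len(positives)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_pos)
    n_val = int(split_fractions[1] * n_pos)
    n_test = int(split_fractions[2] * n_pos)
    n_train = n_pos - n_val - n_test
    split_of = {}
    for rank, idx in enumerate(perm):
        if rank < n_train:
            split_of[idx] = "train"
        elif rank < n_train + n_val:
            split_of[idx] = "validation"
        else:
            split_of[idx] = "test"
    examples: list[SequenceExample] = []
    for idx, pos in enumerate(positives):
        split = split_of[idx]
        examples.append(SequenceExample(
            sequence=pos.sequence, label=1, provenance=pos.provenance,
            name=pos.name, split=split,
        ))
        for rep in range(negative_ratio):
            sub = _negative_rng(seed, pos.name, rep)
            parent_seq = _replace_ns(pos.sequence, sub)
            neg = dinucleotide_shuffle(parent_seq, sub)
            examples.append(SequenceExample(
                sequence=neg, label=0, provenance=pos.name,
                name=f"{pos.name}_shuf{rep}", split=split,
            ))
    counts: dict[str, dict[int, int]] = {s: {0: 0, 1: 0} for s in SPLITS}
    for e in examples:
        counts[e.split][e.label] += 1
    window = len(positives[0].sequence)
    manifest = DatasetManifest(
        counts=counts, window_length=window, negative_ratio=negative_ratio,
        split_fractions=tuple(split_fractions), seed=seed,
    )
    return Dataset(examples), manifest


_ONE_HOT = np.vstack([np.eye(4, dtype=np.float32), np.full((1, 4), 0.25, dtype=np.float32)])


def one_hot_encode(sequence: str) -> np.ndarray:
    """4xL indicator matrix in base order A, C, G, T; N becomes a uniform
    0.25 column so every column sums to 1."""
    return _ONE_HOT[encode_indices(sequence)].T


def kmer_index_encode(sequence: str, k: int = 3, stride: int = 1) -> np.ndarray:
    """Overlapping k-mer indices under lexicographic A<C<G<T ordering.

    Indices lie in [0, 4**k]; 4**k is the dedicated unknown index for windows
    containing N.
    """
    if len(sequence) < k:
        raise ValueError(f"sequence length {len(sequence)} < k={k}")
    codes = encode_indices(sequence).astype(np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)[::stride]
    has_n = (windows == N_INDEX).any(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1)
    idx = (np.where(windows == N_INDEX, 0, windows) * powers).sum(axis=1)
    idx[has_n] = 4**k
    return idx


def kmer_index_decode(indices: np.ndarray, k: int = 3) -> str:
    """Inverse of kmer_index_encode at stride 1 for N-free sequences."""
    indices = np.asarray(indices, dtype=np.int64)
    if (indices >= 4**k).any():
        raise ValueError("cannot decode the unknown index")

    def kmer(i: int) -> str:
        out = []
        for _ in range(k):
            out.append(BASES[i % 4])
            i //= 4
        return "".join(reversed(out))

    first = kmer(int(indices[0]))
    return first + "".join(kmer(int(i))[-1] for i in indices[1:])
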