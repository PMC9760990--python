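"""Motif interpretation of learned convolutional filters.

A trained filter is turned into a position probability matrix (PPM) by the
alignment-and-count procedure: every sequence window whose rectified filter
activation exceeds a fraction of the filter's global maximum is stacked, base
frequencies are counted with a pseudocount, and columns are normalised. The
PPM is converted to a position weight matrix (PWM, log-odds against a
background) for sliding-window scanning, and two PWMs can be raced over a
sequence set to ask which motif a set of regulatory targets prefers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alphabet import BASES, N_INDEX, encode_indices, reverse_complement

__all__ = [
    "PositionMatrix",
    "ScanHit",
    "ComparisonTable",
    "ppm_to_pwm",
    "pwm_scan",
    "consensus_from_ppm",
    "information_content",
    "motif_match",
    "compare_filters",
    "extract_filter_ppm",
    "extract_all_filter_ppms",
    "identify_motif_filters",
]

UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


@dataclass
class PositionMatrix:
    """A 4xN matrix over bases A, C, G, T (row order fixed).

    ``form`` is ``probability`` (column-stochastic PPM) or ``log_likelihood``
    (PWM, log2 odds against ``background``).
    """

    values: np.ndarray
    form: str = "probability"
    background: tuple[float, float, float, float] = UNIFORM_BACKGROUND
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != 4:
            raise ValueError(f"expected a 4xN matrix, got shape {self.values.shape}")
        if self.values.shape[1] < 1:
            raise ValueError("matrix must have at least one column")
        if self.form not in ("probability", "log_likelihood"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.form == "probability":
            if (self.values < 0).any():
                raise ValueError("probability matrix has negative entries")
            colsums = self.values.sum(axis=0)
            if not np.allclose(colsums, 1.0, atol=1e-9):
                raise ValueError("probability matrix columns must sum to 1")

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_counts(cls, counts: np.ndarray, pseudocount: float = 0.5) -> "PositionMatrix":
        """Normalise a 4xN count matrix into a PPM, adding ``pseudocount`` per cell."""
        counts = np.asarray(counts, dtype=float) + pseudocount
        return cls(counts / counts.sum(axis=0, keepdims=True), form="probability",
                   pseudocount=pseudocount)


def ppm_to_pwm(
    ppm: PositionMatrix,
    background: tuple[float, float, float, float] = UNIFORM_BACKGROUND,
    pseudocount: float = 0.001,
) -> PositionMatrix:
    """Log-likelihood transform: entry (b, j) = log2(((p + e)/(1 + 4e)) / q_b)."""
    if ppm.form != "probability":
        raise ValueError("ppm_to_pwm expects a probability-form matrix")
    q = np.asarray(background, dtype=float)
    if (q <= 0).any():
        raise ValueError("background must be strictly positive for all four bases")
    p = (ppm.values + pseudocount) / (1.0 + 4.0 * pseudocount)
    return PositionMatrix(
        np.log2(p / q[:, None]),
        form="log_likelihood",
        background=tuple(q),
        pseudocount=pseudocount,
    )


@dataclass
class ScanHit:
    score: float
    offset: int
    sequence_id: str | None = None


def _scan_scores(pwm: PositionMatrix, sequence: str) -> np.ndarray:
    """Window sums at every forward-strand offset; N bases contribute the
    background-weighted mean column entry."""
    width = pwm.width
    if len(sequence) < width:
        raise ValueError(
            f"sequence of length {len(sequence)} shorter than motif width {width}"
        )
    q = np.asarray(pwm.background, dtype=float)
    ext = np.vstack([pwm.values, q @ pwm.values])  # row 4 scores N
    codes = encode_indices(sequence)
    windows = np.lib.stride_tricks.sliding_window_view(codes, width)
    return ext[windows, np.arange(width)].sum(axis=1)


def pwm_scan(
    pwm: PositionMatrix,
    sequence: str,
    sequence_id: str | None = None,
    both_strands: bool = False,
) -> ScanHit:
    """Best-window log-odds score over all offsets (ties -> smallest offset).

    With ``both_strands`` the reverse complement is scanned too and the better
    strand wins; the reported offset is on the forward strand either way.
    """
    if pwm.form != "log_likelihood":
        raise ValueError("pwm_scan expects a log_likelihood-form matrix")
    scores = _scan_scores(pwm, sequence)
    best = int(np.argmax(scores))
    score, offset = float(scores[best]), best
    if both_strands:
        rc_scores = _scan_scores(pwm, reverse_complement(sequence))
        rc_best = int(np.argmax(rc_scores))
        if float(rc_scores[rc_best]) > score:
            score = float(rc_scores[rc_best])
            offset = len(sequence) - pwm.width - rc_best
    return ScanHit(score=score, offset=offset, sequence_id=sequence_id)


def information_content(ppm: PositionMatrix) -> np.ndarray:
    """Per-column information content in bits: 2 - Shannon entropy."""
    if ppm.form != "probability":
        raise ValueError("information content is defined on probability matrices")
    p = ppm.values
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return 2.0 + plogp.sum(axis=0)


def consensus_from_ppm(ppm: PositionMatrix) -> tuple[str, np.ndarray]:
    """Per-column argmax base (ties alphabetical) and information content."""
    idx = np.argmax(ppm.values, axis=0)  # argmax returns the first = alphabetical
    consensus = "".join(BASES[i] for i in idx)
    return consensus, information_content(ppm)


def motif_match(consensus: str, target: str) -> tuple[int, int]:
    """Best ungapped alignment of ``target`` inside ``consensus``.

    Returns (offset, matched_positions); ties on the match count go to the
    smallest offset.
    """
    if len(target) > len(consensus):
        raise ValueError(
            f"target (length {len(target)}) longer than consensus (length {len(consensus)})"
        )
    best_off, best_n = 0, -1
    for off in range(len(consensus) - len(target) + 1):
        n = sum(1 for a, b in zip(consensus[off : off + len(target)], target) if a == b)
        if n > best_n:
            best_off, best_n = off, n
    return best_off, best_n


@dataclass
class ComparisonTable:
    """Per-sequence win counts of one PWM over another on a target set."""

    set_label: str
    n_sequences: int
    n_wins_a: int
    n_wins_b: int
    n_ties: int

    def __post_init__(self) -> None:
        if self.n_wins_a + self.n_wins_b + self.n_ties != self.n_sequences:
            raise ValueError("win/tie counts do not partition the sequence set")


def compare_filters(
    pwm_a: PositionMatrix,
    pwm_b: PositionMatrix,
    sequences,
    set_label: str = "",
    both_strands: bool = False,
) -> ComparisonTable:
    """Race two PWMs over a sequence set: strict inequality wins, exact ties
    are reported separately."""
    seqs = list(sequences)
    if not seqs:
        raise ValueError("empty sequence set")
    wins_a = wins_b = ties = 0
    for seq in seqs:
        sa = pwm_scan(pwm_a, seq, both_strands=both_strands).score
        sb = pwm_scan(pwm_b, seq, both_strands=both_strands).score
        if sa > sb:
            wins_a += 1
        elif sb > sa:
            wins_b += 1
        else:
            ties += 1
    return ComparisonTable(set_label, len(seqs), wins_a, wins_b, ties)


def _high_activation_counts(
    trained,
    positives: list[str],
    activation_fraction: float,
    pseudocount: float,
    batch: int = 256,
) -> np.ndarray:
    """Stack high-activation windows for every filter at once.

    Returns counts of shape (n_filters, 4, receptive_field); N bases spread
    0.25 over the four rows.
    """
    rf = trained.receptive_field
    # pass 1: global max activation per filter
    global_max = None
    for i in range(0, len(positives), batch):
        acts = trained.conv_activations(positives[i : i + batch])  # (B, T, F)
        m = acts.max(axis=(0, 1))
        global_max = m if global_max is None else np.maximum(global_max, m)
    n_filters = global_max.size
    counts = np.zeros((n_filters, 4, rf), dtype=float)
    # pass 2: count bases under windows activating above the threshold
    thresholds = activation_fraction * global_max
    col = np.arange(rf)
    for i in range(0, len(positives), batch):
        chunk = positives[i : i + batch]
        acts = trained.conv_activations(chunk)
        codes = np.stack([encode_indices(s) for s in chunk])
        for f in range(n_filters):
            if global_max[f] <= 0:
                continue
            rows, offs = np.nonzero(acts[:, :, f] > thresholds[f])
            if rows.size == 0:
                continue
            win = codes[rows[:, None], offs[:, None] + col]  # (n_hits, rf)
            for b in range(4):
                counts[f, b] += (win == b).sum(axis=0)
            counts[f] += 0.25 * (win == N_INDEX).sum(axis=0)
    return counts + pseudocount


def extract_filter_ppm(
    trained,
    filter_index: int,
    positives,
    activation_fraction: float = 0.5,
    pseudocount: float = 0.5,
) -> PositionMatrix:
    """PPM of one convolutional filter by alignment-and-count over positives."""
    positives = [getattr(s, "sequence", s) for s in positives]
    if not positives:
        raise ValueError("empty positive set")
    counts = _high_activation_counts(trained, positives, activation_fraction, pseudocount)
    if counts[filter_index].sum() <= pseudocount * 4 * trained.receptive_field:
        raise ValueError(
            f"no window of filter {filter_index} exceeds "
            f"{activation_fraction} x max activation; try a lower activation_fraction"
        )
    c = counts[filter_index]
    return PositionMatrix(c / c.sum(axis=0, keepdims=True), form="probability",
                          pseudocount=pseudocount)


def extract_all_filter_ppms(
    trained,
    positives,
    activation_fraction: float = 0.5,
    pseudocount: float = 0.5,
) -> list[PositionMatrix | None]:
    """PPMs for every filter in one pass; dead filters (no activation) are None."""
    positives = [getattr(s, "sequence", s) for s in positives]
    if not positives:
        raise ValueError("empty positive set")
    counts = _high_activation_counts(trained, positives, activation_fraction, pseudocount)
    floor = pseudocount * 4 * trained.receptive_field
    out: list[PositionMatrix | None] = []
    for c in counts:
        if c.sum() <= floor:
            out.append(None)
        else:
            out.append(PositionMatrix(c / c.sum(axis=0, keepdims=True),
                                      form="probability", pseudocount=pseudocount))
    return out


def top_information_filter(ppms: list[PositionMatrix | None]) -> int:
    """Index of the most informative filter.

    Filters are ranked by their most conserved column (peak per-column
    information content), with total IC as the tie-break. Peak conservation
    separates a sharp motif from a broad low-complexity preference, which can
    accumulate a larger IC total simply by spreading weak conservation over
    all columns.
    """
    best, best_key = -1, (-math.inf, -math.inf)
    for i, ppm in enumerate(ppms):
        if ppm is None:
            continue
        ic = information_content(ppm)
        key = (float(ic.max()), float(ic.sum()))
        if key > best_key:
            best, best_key = i, key
    if best < 0:
        raise ValueError("all filters are dead; nothing to rank")
    return best


def identify_motif_filters(
    ppms: list[PositionMatrix | None],
    targets: dict[str, str],
) -> dict[str, int]:
    """Assign each named consensus string to the distinct filter that best
    contains it (greedy, by descending match fraction)."""
    scores: list[tuple[float, str, int]] = []
    for name, target in targets.items():
        for i, ppm in enumerate(ppms):
            if ppm is None:
                continue
            consensus, _ = consensus_from_ppm(ppm)
            # align the shorter string inside the longer one
            if len(consensus) >= len(target):
                _, n = motif_match(consensus, target)
            else:
                _, n = motif_match(target, consensus)
            scores.append((n / min(len(target), len(consensus)), name, i))
    scores.sort(key=lambda t: (-t[0], t[1], t[2]))
    assigned: dict[str, int] = {}
    used: set[int] = set()
    for frac, name, i in scores:
        if name in assigned or i in used:
            continue
        assigned[name] = i
        used.add(i)
    missing = set(targets) - set(assigned)
    if missing:
        raise ValueError(f"could not assign filters for motifs: {sorted(missing)}")
    return assigned
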