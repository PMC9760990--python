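"""Synthetic genomes, scored peaks and regulatory target sets.

Everything downstream of the pipeline (dataset building, training,
calibration, filter interpretation) can be exercised against data with a
known ground truth: a random background genome at a chosen GC content, peaks
whose 301-nt neighbourhoods carry an instance of the canonical MYC E-box
(CACGTG) sampled from a ground-truth PPM, and separate transcription
activation / repression target sets planted with the canonical motif versus
a non-canonical G/C-box + TGGGA composite (the SP1 / MIZ-1 style repressive
signature).

All generators are pure functions of a :class:`SyntheticSpec`, including its
seed: the same spec always yields byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .alphabet import BASES, decode_indices, encode_indices
from .dataset import PeakRecord
from .interpretation import PositionMatrix, ppm_to_pwm, pwm_scan

logger = logging.getLogger(__name__)

WINDOW_LENGTH = 301
_HALF = WINDOW_LENGTH // 2  # 150
# peak widths are sampled in [150, 500]; midpoints must sit >= 250 nt from
# chromosome ends so the widest interval and the 301-nt window both fit
_MID_MARGIN = 250
_JITTER = 75
_SLOT_STRIDE = WINDOW_LENGTH + 2 * _JITTER + 1  # keeps jittered windows disjoint

__all__ = [
    "SyntheticSpec",
    "GroundTruthRecord",
    "Genome",
    "canonical_ppm",
    "noncanonical_ppm",
    "generate_genome",
    "plant_peaks",
    "generate_target_sets",
    "write_ground_truth_tsv",
    "read_ground_truth_tsv",
]


def canonical_ppm() -> PositionMatrix:
    """Ground-truth PPM of the E-box CACGTG: 0.9 on the consensus base per
    column, the remainder spread over the other three bases."""
    return _consensus_ppm("CACGTG", 0.9)


def noncanonical_ppm() -> PositionMatrix:
    """Ground-truth PPM of the non-canonical composite: a 7-column G/C-box
    ((G/T)GGGCGG style), a 1-nt uniform spacer, then TGGGA (5 columns)."""
    cols = []
    # (G/T) split column
    first = np.full(4, 0.05)
    first[BASES.index("G")] = 0.45
    first[BASES.index("T")] = 0.45
    cols.append(first)
    for b in "GGGCGG":
        cols.append(_consensus_column(b, 0.9))
    cols.append(np.full(4, 0.25))  # spacer
    for b in "TGGGA":
        cols.append(_consensus_column(b, 0.9))
    return PositionMatrix(np.column_stack(cols), form="probability")


def _consensus_column(base: str, weight: float) -> np.ndarray:
    col = np.full(4, (1.0 - weight) / 3.0)
    col[BASES.index(base)] = weight
    return col


def _consensus_ppm(consensus: str, weight: float) -> PositionMatrix:
    return PositionMatrix(
        np.column_stack([_consensus_column(b, weight) for b in consensus]),
        form="probability",
    )


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study.

    score_scale and score_noise_sd define the score model: a peak's score is
    score_scale x (log-likelihood of its motif instance under the planted
    PWM, relative to the PWM's maximum achievable value) plus Gaussian
    noise, so higher-fidelity instances rank higher regardless of which
    motif was planted, as real peak-caller scores do for stronger binding
    events.
    """

    chrom_sizes: Mapping[str, int]
    gc_content: float = 0.41  # human-genome-like background
    n_peaks: int = 3000
    motif_ppm_canonical: PositionMatrix = field(default_factory=canonical_ppm)
    motif_ppm_noncanonical: PositionMatrix = field(default_factory=noncanonical_ppm)
    plant_probability: float = 1.0
    noncanonical_fraction: float = 0.0  # fraction of planted peaks given the composite
    score_scale: float = 1.0
    score_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size < WINDOW_LENGTH:
                raise ValueError(
                    f"chromosome {chrom!r} has length {size} < window length {WINDOW_LENGTH}"
                )
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError(f"gc_content {self.gc_content} outside [0, 1]")
        if not 0.0 <= self.plant_probability <= 1.0:
            raise ValueError(f"plant_probability {self.plant_probability} outside [0, 1]")
        if not 0.0 <= self.noncanonical_fraction <= 1.0:
            raise ValueError(f"noncanonical_fraction outside [0, 1]")
        for ppm in (self.motif_ppm_canonical, self.motif_ppm_noncanonical):
            if ppm.form != "probability":
                raise ValueError("motif matrices must be probability-form PPMs")

    def _seeds(self) -> dict[str, np.random.SeedSequence]:
        children = np.random.SeedSequence(self.seed).spawn(3)
        return dict(zip(("genome", "peaks", "targets"), children))


class Genome:
    """An in-memory genome: chromosome name -> mutable base-code array."""

    def __init__(self, chroms: dict[str, np.ndarray]):
        self._chroms = chroms

    @property
    def chrom_names(self) -> list[str]:
        return list(self._chroms)

    def length(self, chrom: str) -> int:
        return self._chroms[chrom].size

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if start < 0 or end > self._chroms[chrom].size:
            raise IndexError(f"[{start}, {end}) outside chromosome {chrom}")
        return decode_indices(self._chroms[chrom][start:end])

    def write_in(self, chrom: str, start: int, sequence: str) -> None:
        codes = encode_indices(sequence)
        self._chroms[chrom][start : start + codes.size] = codes

    def write_fasta(self, path, line_width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, codes in self._chroms.items():
                fh.write(f">{chrom}\n")
                seq = decode_indices(codes)
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: encode_indices(str(fa[name][:])) for name in fa.keys()})


def generate_genome(spec: SyntheticSpec) -> Genome:
    """I.i.d. background genome: P(G) = P(C) = gc/2, P(A) = P(T) = (1-gc)/2."""
    rng = np.random.default_rng(spec._seeds()["genome"])
    gc = spec.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    chroms = {
        chrom: rng.choice(4, size=size, p=probs).astype(np.uint8)
        for chrom, size in spec.chrom_sizes.items()
    }
    return Genome(chroms)


@dataclass
class GroundTruthRecord:
    peak_id: str
    chrom: str
    motif: str  # "canonical" | "noncanonical" | "none"
    position: int | None  # 0-based offset of the planted instance on the chromosome
    instance: str | None


def _sample_instance(ppm: PositionMatrix, rng: np.random.Generator) -> str:
    cols = ppm.values.T
    return "".join(BASES[rng.choice(4, p=c / c.sum())] for c in cols)


def _slot_centers(spec: SyntheticSpec) -> list[tuple[str, int]]:
    slots = []
    for chrom, size in spec.chrom_sizes.items():
        c = _MID_MARGIN + _JITTER
        while c + _JITTER <= size - _MID_MARGIN:
            slots.append((chrom, c))
            c += _SLOT_STRIDE
    return slots


def plant_peaks(genome: Genome, spec: SyntheticSpec) -> tuple[list[PeakRecord], list[GroundTruthRecord]]:
    """Plant motif instances near peak midpoints and emit scored narrowPeak
    records plus the ground truth.

    Peaks occupy disjoint 301-nt neighbourhoods so planted instances never
    collide. Scores follow the spec's score model; unplanted peaks are scored
    by the best canonical-PWM window of their neighbourhood, so they rank low
    but not degenerately.
    """
    rng = np.random.default_rng(spec._seeds()["peaks"])
    slots = _slot_centers(spec)
    if spec.n_peaks > len(slots):
        raise ValueError(
            f"cannot place {spec.n_peaks} non-colliding peaks; "
            f"this genome supports at most {len(slots)}"
        )
    chosen = sorted(rng.choice(len(slots), size=spec.n_peaks, replace=False).tolist())
    pwm_canon = ppm_to_pwm(spec.motif_ppm_canonical)
    pwm_noncanon = ppm_to_pwm(spec.motif_ppm_noncanonical)
    peaks: list[PeakRecord] = []
    truth: list[GroundTruthRecord] = []
    for i, slot in enumerate(chosen):
        chrom, center = slots[slot]
        mid = center + int(rng.integers(-_JITTER, _JITTER + 1))
        width = int(rng.integers(150, 501))
        start = mid - width // 2
        end = start + width
        name = f"peak_{i:05d}"
        plant = rng.random() < spec.plant_probability
        if plant:
            if rng.random() < spec.noncanonical_fraction:
                kind, ppm, pwm = "noncanonical", spec.motif_ppm_noncanonical, pwm_noncanon
            else:
                kind, ppm, pwm = "canonical", spec.motif_ppm_canonical, pwm_canon
            instance = _sample_instance(ppm, rng)
            lo = mid - _HALF
            hi = mid + _HALF + 1 - len(instance)
            pos = int(rng.integers(lo, hi + 1))
            genome.write_in(chrom, pos, instance)
            codes = encode_indices(instance)
            # fidelity deficit: 0 for a consensus-perfect instance, negative
            # otherwise; comparable across motifs of different widths
            loglik = float(pwm.values[codes, np.arange(len(instance))].sum()
                           - pwm.values.max(axis=0).sum())
            truth.append(GroundTruthRecord(name, chrom, kind, pos, instance))
        else:
            window = genome.fetch(chrom, mid - _HALF, mid + _HALF + 1)
            loglik = pwm_scan(pwm_canon, window).score - float(pwm_canon.values.max(axis=0).sum())
            truth.append(GroundTruthRecord(name, chrom, "none", None, None))
        score = spec.score_scale * loglik + rng.normal(0.0, spec.score_noise_sd)
        peaks.append(PeakRecord(chrom=chrom, start=start, end=end, name=name,
                                score=float(score), summit_offset=None))
    return peaks, truth


def _random_background(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=probs).astype(np.uint8)


def generate_target_sets(
    spec: SyntheticSpec,
    n_act: int,
    n_rep: int,
    length: int = WINDOW_LENGTH,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Activation targets carry a canonical instance, repression targets a
    non-canonical one, each planted once at a random offset in a fresh
    background sequence.

    Target sets emulate curated, experimentally validated regulatory targets,
    so the planted instance is the consensus (most probable) sequence of the
    motif PPM rather than a noisy sample — validated strong sites, in
    contrast to the fidelity spread of the peak training data.
    """
    if n_act < 1 or n_rep < 1:
        raise ValueError("n_act and n_rep must both be >= 1")
    rng = np.random.default_rng(spec._seeds()["targets"])

    def make(n: int, ppm: PositionMatrix, prefix: str) -> list[tuple[str, str]]:
        instance = "".join(BASES[j] for j in np.argmax(ppm.values, axis=0))
        out = []
        for i in range(n):
            codes = _random_background(length, spec.gc_content, rng)
            pos = int(rng.integers(0, length - len(instance) + 1))
            codes[pos : pos + len(instance)] = encode_indices(instance)
            out.append((f"{prefix}_{i:04d}", decode_indices(codes)))
        return out

    activation = make(n_act, spec.motif_ppm_canonical, "act")
    repression = make(n_rep, spec.motif_ppm_noncanonical, "rep")
    return activation, repression


def write_ground_truth_tsv(truth: list[GroundTruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("peak_id\tchrom\tmotif\tposition\tinstance\n")
        for r in truth:
            pos = "" if r.position is None else str(r.position)
            inst = "" if r.instance is None else r.instance
            fh.write(f"{r.peak_id}\t{r.chrom}\t{r.motif}\t{pos}\t{inst}\n")


def read_ground_truth_tsv(path) -> list[GroundTruthRecord]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("peak_id")
        for line in fh:
            peak_id, chrom, motif, pos, inst = line.rstrip("\n").split("\t")
            out.append(GroundTruthRecord(
                peak_id, chrom, motif,
                int(pos) if pos else None, inst if inst else None,
            ))
    return out
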