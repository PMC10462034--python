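"""Synthetic nanopore signal with ground-truth labels.

The generator emits, for each k-mer traversing the pore, a dwell drawn
from a truncated Gaussian (at least one sample) and Gaussian amplitude
noise around the pore model's expected level, scaled by a multiplier of
the per-k-mer spread.  Defaults reflect a standard R9.4-style run:
10 kb mean read length, amplitude noise factor 2.0, dwell time sd 8.0
samples around ~9 samples per k-mer (450 bp/s at 4 kHz).  Stay (k-mer
re-emission) and skip (k-mer dropout) errors can be injected; both
default to zero so that segmentation errors arise only from the event
detector itself.

Signal is emitted on the pore-model pA scale (calibrated); real-world
gain/offset drift can be emulated by affine-transforming the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from squigbin.pore_model import PoreModel, kmer_indices
from squigbin.signal import write_signal_text


@dataclass(frozen=True)
class SimParams:
    """Signal-generator settings; defaults are the package's study conditions."""

    mean_read_length: int = 10_000           # bp
    amplitude_noise_factor: float = 2.0      # multiplier on per-k-mer level_sd
    dwell_mean: float = 9.0                  # samples per k-mer
    dwell_sd: float = 8.0                    # samples, truncated at 1
    stay_prob: float = 0.0                   # per-k-mer re-emission probability
    skip_prob: float = 0.0                   # per-k-mer dropout probability
    min_read_length: int = 500               # bp, truncation of the length draw

    def __post_init__(self) -> None:
        if not (0 <= self.stay_prob < 1 and 0 <= self.skip_prob < 1):
            raise ValueError("stay/skip probabilities must be in [0, 1)")
        if self.dwell_mean < 1:
            raise ValueError("dwell_mean must be >= 1 sample")
        if self.amplitude_noise_factor < 0:
            raise ValueError("amplitude_noise_factor must be >= 0")


def random_nucleotides(length: int, rng: np.random.Generator) -> str:
    """Uniform random ACGT sequence (synthetic reference material)."""
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def simulate_read(ref_seq: str, start: int, length: int, model: PoreModel,
                  params: SimParams, rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    """Simulate the raw trace of one read from a reference window.

    Each k-mer of the window is skipped with probability skip_prob,
    emitted once more with probability stay_prob, and otherwise emits
    round(max(1, Normal(dwell_mean, dwell_sd))) samples drawn around its
    expected level with sd = amplitude_noise_factor * level_sd.
    """
    if start < 0 or start + length > len(ref_seq):
        raise ValueError(
            f"window [{start}, {start + length}) outside sequence of "
            f"length {len(ref_seq)}"
        )
    window = ref_seq[start:start + length]
    idx = kmer_indices(window, model.k)
    if (idx < 0).any():
        idx = idx[idx >= 0]  # ambiguous bases emit nothing
    levels = model.means[idx]
    stdvs = model.stdvs[idx]
    k_count = levels.size

    emit = np.ones(k_count, dtype=np.int64)
    if params.skip_prob > 0:
        emit[rng.random(k_count) < params.skip_prob] = 0
    if params.stay_prob > 0:
        emit = emit + ((rng.random(k_count) < params.stay_prob) & (emit > 0))
    levels_e = np.repeat(levels, emit)
    stdvs_e = np.repeat(stdvs, emit)
    n_events = levels_e.size

    if params.dwell_sd > 0:
        dwells = np.maximum(
            1, np.round(rng.normal(params.dwell_mean, params.dwell_sd, n_events))
        ).astype(np.int64)
    else:
        dwells = np.full(n_events, int(round(params.dwell_mean)), dtype=np.int64)
    samples = np.repeat(levels_e, dwells)
    if params.amplitude_noise_factor > 0:
        sd = np.repeat(params.amplitude_noise_factor * stdvs_e, dwells)
        samples = samples + rng.standard_normal(samples.size) * sd
    truth = {"start": start, "end": start + length, "n_kmers": int(k_count)}
    return samples, truth


def simulate_dataset(refs, n_reads: int, model: PoreModel, params: SimParams,
                     seed: int | np.random.Generator = 0,
                     signal_path: str | Path | None = None,
                     truth_path: str | Path | None = None,
                     id_prefix: str = "read"):
    """Simulate a labeled dataset of reads from class-labeled references.

    ``refs`` is a list of (ref_name, sequence, class_label).  Reference,
    start position and strand are uniform per read; read lengths follow
    Normal(mean, mean/4) truncated below at ``min_read_length`` and at
    the reference length.  Returns (reads, truth) where reads is a list
    of (read_id, samples) and truth a DataFrame with one row per read;
    both are optionally written to the plain-text fixture format / TSV.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not refs:
        raise ValueError("no reference sequences supplied")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reads: list[tuple[str, np.ndarray]] = []
    rows: list[dict] = []
    for i in range(n_reads):
        ref_name, seq, class_label = refs[int(rng.integers(len(refs)))]
        max_len = len(seq)
        length = int(np.clip(
            round(rng.normal(params.mean_read_length, params.mean_read_length / 4)),
            min(params.min_read_length, max_len), max_len,
        ))
        start = int(rng.integers(0, max_len - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            samples, _ = simulate_read(seq, start, length, model, params, rng)
        else:
            rc = str(Seq(seq).reverse_complement())
            rc_start = max_len - (start + length)
            samples, _ = simulate_read(rc, rc_start, length, model, params, rng)
        read_id = f"{id_prefix}_{i:05d}"
        reads.append((read_id, samples))
        rows.append({
            "read_id": read_id, "class": class_label, "ref": ref_name,
            "start": start, "end": start + length, "strand": strand,
            "n_samples": int(samples.size),
        })
    truth = pd.DataFrame(rows)
    if signal_path is not None:
        write_signal_text(reads, signal_path)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return reads, truth
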