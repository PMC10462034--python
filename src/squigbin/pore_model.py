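"""Pore models and the picoamp-bin alphabet.

A pore model maps every DNA k-mer to the expected ionic current (mean and
spread, in pA) produced while that k-mer occupies the pore.  The model
defines the dynamic range [min_p, max_p] of expected currents, which is
divided into ``n_bins`` equal-width picoamp ranges.  Both reference
sequences (via their expected signal) and observed events are rendered as
symbols over this small alphabet, so that approximate signal matching
reduces to exact matching over bin symbols.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised for malformed pore-model tables or signal files."""


_BASES = "ACGT"
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def _kmer_to_index(kmer: str) -> int:
    idx = 0
    for ch in kmer:
        c = _CODE[ord(ch)]
        if c < 0:
            raise ValueError(f"k-mer {kmer!r} contains a non-ACGT base")
        idx = idx * 4 + int(c)
    return idx


def _index_to_kmer(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[idx % 4])
        idx //= 4
    return "".join(reversed(out))


@dataclass(frozen=True)
class PoreModel:
    """Expected-current table for all 4^k k-mers of a pore chemistry.

    ``means[i]`` / ``stdvs[i]`` are the expected level mean and spread in
    pA for the k-mer whose 2-bit encoding (A=0, C=1, G=2, T=3, most
    significant base first) is ``i``.
    """

    k: int
    means: np.ndarray
    stdvs: np.ndarray

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=np.float64)
        stdvs = np.asarray(self.stdvs, dtype=np.float64)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "stdvs", stdvs)
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if means.shape != (4 ** self.k,) or stdvs.shape != (4 ** self.k,):
            raise FormatError(
                f"pore model must cover all {4 ** self.k} {self.k}-mers "
                f"(got {means.size} levels)"
            )
        if not np.all(np.isfinite(means)) or not np.all(np.isfinite(stdvs)):
            raise FormatError("pore model levels must be finite")
        if np.any(stdvs < 0):
            raise FormatError("pore model level_stdv values must be >= 0")
        if self.min_p >= self.max_p:
            raise FormatError("pore model has degenerate level range (min_p >= max_p)")

    @property
    def min_p(self) -> float:
        return float(self.means.min())

    @property
    def max_p(self) -> float:
        return float(self.means.max())

    @property
    def level_mean(self) -> float:
        """Mean of the k-mer level means; normalization target location."""
        return float(self.means.mean())

    @property
    def level_sd(self) -> float:
        """Population sd of the k-mer level means; normalization target scale."""
        return float(self.means.std())

    @property
    def levels(self) -> dict[str, tuple[float, float]]:
        return {
            _index_to_kmer(i, self.k): (float(self.means[i]), float(self.stdvs[i]))
            for i in range(4 ** self.k)
        }

    def level(self, kmer: str) -> tuple[float, float]:
        i = _kmer_to_index(kmer)
        return float(self.means[i]), float(self.stdvs[i])


@dataclass(frozen=True)
class BinningConfig:
    """Partition of [min_p, max_p] into ``n_bins`` equal picoamp ranges."""

    n_bins: int
    min_p: float
    max_p: float

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2 (got {self.n_bins})")
        if not self.max_p > self.min_p:
            raise ValueError("max_p must exceed min_p")

    @property
    def sp(self) -> float:
        """Bin width in pA."""
        return (self.max_p - self.min_p) / self.n_bins


@dataclass
class BinSequence:
    """A read or reference rendered as symbols over the bin alphabet.

    ``symbols`` take values in [0, n_bins-1]; reference sequences may
    additionally carry a sentinel symbol (== n_bins) marking k-mers with
    ambiguous bases, which can never match a query symbol.  ``hpc`` is
    True once same-symbol runs have been collapsed.
    """

    symbols: np.ndarray
    hpc: bool = False

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int16)

    def __len__(self) -> int:
        return int(self.symbols.size)


def load_pore_model(path: str | Path) -> PoreModel:
    """Load a pore model from a tab-separated table.

    The table must have header columns ``kmer``, ``level_mean`` and
    ``level_stdv`` (extra columns are ignored) and one row for every
    k-mer of a single length.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse pore model {path}: {exc}") from exc
    required = {"kmer", "level_mean", "level_stdv"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"pore model {path} lacks columns: {sorted(missing)}")
    kmers = df["kmer"].astype(str)
    if len(df) == 0:
        raise FormatError(f"pore model {path} is empty")
    k = len(kmers.iloc[0])
    if not (kmers.str.len() == k).all():
        bad = kmers[kmers.str.len() != k].iloc[0]
        raise FormatError(f"inconsistent k-mer length at row {bad!r}")
    dup = kmers[kmers.duplicated()]
    if len(dup):
        raise FormatError(f"duplicate k-mer row {dup.iloc[0]!r}")
    for col in ("level_mean", "level_stdv"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.loc[vals.isna()].iloc[0]
            raise FormatError(f"non-numeric {col} at row {row['kmer']!r}")
    if len(df) != 4 ** k:
        raise FormatError(
            f"pore model {path} has {len(df)} rows, expected {4 ** k} for k={k}"
        )
    means = np.empty(4 ** k, dtype=np.float64)
    stdvs = np.empty(4 ** k, dtype=np.float64)
    for kmer, mean, stdv in zip(kmers, df["level_mean"], df["level_stdv"]):
        try:
            idx = _kmer_to_index(kmer)
        except ValueError as exc:
            raise FormatError(str(exc)) from exc
        means[idx] = float(mean)
        stdvs[idx] = float(stdv)
    return PoreModel(k=k, means=means, stdvs=stdvs)


def write_pore_model(model: PoreModel, path: str | Path) -> None:
    """Write a pore model as a tab-separated table (round-trips with load)."""
    with open(path, "w") as fh:
        fh.write("kmer\tlevel_mean\tlevel_stdv\n")
        for i in range(4 ** model.k):
            fh.write(
                f"{_index_to_kmer(i, model.k)}\t"
                f"{model.means[i]:.6f}\t{model.stdvs[i]:.6f}\n"
            )


def synthetic_pore_model(k: int = 6, seed: int = 7,
                         mean_range: tuple[float, float] = (65.0, 130.0),
                         stdv_range: tuple[float, float] = (1.2, 3.0)) -> PoreModel:
    """Generate a synthetic pore model for simulation and testing.

    Level means are drawn uniformly over a realistic R9.4-like dynamic
    range (~65-130 pA) and per-k-mer spreads uniformly over ~1-3 pA.
    This is a synthetic stand-in with the coarse statistics of an ONT
    model table, not a model of any real pore chemistry.
    """
    rng = np.random.default_rng(seed)
    n = 4 ** k
    means = rng.uniform(mean_range[0], mean_range[1], size=n)
    stdvs = rng.uniform(stdv_range[0], stdv_range[1], size=n)
    return PoreModel(k=k, means=means, stdvs=stdvs)


def encode_bases(seq: str) -> np.ndarray:
    """2-bit encode a nucleotide string; non-ACGT bases become -1."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def kmer_indices(seq: str, k: int) -> np.ndarray:
    """Rolling 2-bit k-mer indices; -1 where the k-mer has an ambiguous base."""
    codes = encode_bases(seq)
    if codes.size < k:
        raise ValueError(f"sequence length {codes.size} is shorter than k={k}")
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    idx = windows @ powers
    idx[(windows < 0).any(axis=1)] = -1
    return idx


def expected_signal(seq: str, model: PoreModel) -> np.ndarray:
    """Expected current trace of a nucleotide sequence, one pA value per k-mer.

    Output length is len(seq) - k + 1.  K-mers containing ambiguous
    bases yield NaN; downstream reference binning maps those to the
    sentinel symbol.
    """
    idx = kmer_indices(seq, model.k)
    out = np.where(idx >= 0, model.means[np.clip(idx, 0, None)], np.nan)
    return out


def make_bins(model: PoreModel, n_bins: int = 6) -> BinningConfig:
    """Derive the bin alphabet from a pore model's level range."""
    return BinningConfig(n_bins=n_bins, min_p=model.min_p, max_p=model.max_p)


def quantize(values: Iterable[float], cfg: BinningConfig) -> BinSequence:
    """Map pA values onto bin symbols.

    Values below min_p map to bin 0 and values above max_p to bin
    n_bins-1; in between, bins are left-closed/right-open intervals of
    width sp, with v == max_p assigned to the top bin.
    """
    v = np.asarray(values, dtype=np.float64)
    if np.isnan(v).any():
        raise ValueError("cannot quantize NaN values")
    b = np.floor((v - cfg.min_p) / cfg.sp).astype(np.int16)
    b = np.clip(b, 0, cfg.n_bins - 1)
    return BinSequence(symbols=b, hpc=False)
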