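"""Read classification from match profiles.

A read's PML vector P and document vector D are reduced to per-document
scores by summing PMLs at "peak" positions (P[i] >= P[i-1], i.e. the
start of a new match when scanning left to right), each weighted by the
document's sequence complexity C_d in [0, 1].  Multiclass calls take the
class of the argmax document; binary calls compare the top positive- and
null-class documents through the spike ratio and a threshold tau, which
can be calibrated from a burn-in sample of ratios.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from squigbin.index import NO_DOCUMENT, MatchProfile, PMLIndex, compute_pml
from squigbin.pore_model import BinningConfig, PoreModel
from squigbin.reference import ReferenceText, ShredTable
from squigbin.signal import EventDetectorParams, signal_to_binseq

UNCLASSIFIED = "unclassified"


def peak_indicator(P: np.ndarray) -> np.ndarray:
    """Boolean vector of peak PML positions.

    A position is a peak when P[i] >= P[i-1] (a jump in PML starts a new
    match); position 0 starts a match by convention.
    """
    P = np.asarray(P)
    out = np.empty(P.size, dtype=bool)
    if P.size == 0:
        return out
    out[0] = True
    out[1:] = P[1:] >= P[:-1]
    return out


def _entropy_complexity(symbols: np.ndarray, n_bins: int) -> float:
    """Order-0 empirical entropy of bin symbols, normalized to [0, 1]."""
    symbols = symbols[symbols < n_bins]  # sentinel positions carry no signal
    if symbols.size == 0:
        return 0.0
    counts = np.bincount(symbols, minlength=n_bins).astype(np.float64)
    p = counts[counts > 0] / symbols.size
    h = float(-(p * np.log2(p)).sum())
    return h / math.log2(n_bins)


def shred_complexity(ref: ReferenceText) -> dict[int, float]:
    """Per-document complexity C_d from shred bin content.

    C_d is the order-0 empirical entropy of the shred's symbols divided
    by log2(n_bins); a single-symbol shred scores 0, a shred using all
    bins equally scores 1.  Rows sharing a doc_id (the two strands of a
    locus) are pooled.
    """
    table = ref.shred_table
    if len(table) == 0:
        raise ValueError("reference has no shreds")
    # collect symbols per doc across strand rows
    parts: dict[int, list[np.ndarray]] = {}
    offsets = ref.strand_offsets()
    for i in range(len(table)):
        d = int(table.doc_id[i])
        # locate the strand containing this row
        s_idx = int(np.searchsorted(offsets, table.start[i], side="right")) - 1
        local_start = int(table.start[i]) - offsets[s_idx]
        local_end = int(table.end[i]) - offsets[s_idx]
        parts.setdefault(d, []).append(
            ref.strands[s_idx].symbols[local_start:local_end]
        )
    return {
        d: _entropy_complexity(np.concatenate(chunks), ref.n_bins)
        for d, chunks in parts.items()
    }


@dataclass
class DocumentScores:
    """Complexity-weighted peak-PML sums per document."""

    scores: dict[int, float]
    complexity: dict[int, float]
    doc_meta: dict[int, tuple[str, str]]  # doc_id -> (ref_name, class_label)

    def by_class(self) -> dict[str, float]:
        """Top document score within each class."""
        out: dict[str, float] = {}
        for d, s in self.scores.items():
            cls = self.doc_meta[d][1]
            if s > out.get(cls, -1.0):
                out[cls] = s
        return out


@dataclass
class ReadCall:
    read_id: str
    mode: str  # "multiclass" | "binary"
    predicted_class: str
    top_doc: int
    score: float
    ratio: float | None = None
    threshold: float | None = None
    n_symbols_used: int = 0
    n_chunks: int = 1


def document_scores(profile: MatchProfile, complexity: dict[int, float],
                    shred_table: ShredTable) -> DocumentScores:
    """Evaluate the weighted document vote terms.

    scores[d] = C_d * sum_i P[i] * [D[i] == d] * [peak at i]; positions
    with no document (sentinel) contribute nothing.
    """
    peaks = peak_indicator(profile.P)
    mask = peaks & (profile.D != NO_DOCUMENT)
    docs = profile.D[mask]
    pmls = profile.P[mask]
    meta = shred_table.doc_meta()
    raw: dict[int, float] = {}
    if docs.size:
        uniq, inv = np.unique(docs, return_inverse=True)
        sums = np.bincount(inv, weights=pmls.astype(np.float64))
        for d, s in zip(uniq, sums):
            d = int(d)
            if d not in meta:
                raise ValueError(f"document {d} is not in the shred table")
            raw[d] = float(s) * float(complexity.get(d, 1.0))
    # every indexed document participates in the vote (with score 0)
    scores = {int(d): raw.get(int(d), 0.0) for d in meta}
    return DocumentScores(scores=scores, complexity=dict(complexity), doc_meta=meta)


def _argmax_doc(scores: DocumentScores, restrict: set[str] | None = None) -> tuple[int, float]:
    """Best-scoring doc, ties toward lexicographically smallest ref_name
    then smallest doc_id; (-1, 0.0) if nothing scores above zero."""
    best = (NO_DOCUMENT, 0.0)
    best_key = None
    for d in sorted(scores.scores, key=lambda d: (scores.doc_meta[d][0], d)):
        if restrict is not None and scores.doc_meta[d][1] not in restrict:
            continue
        s = scores.scores[d]
        if s > 0.0 and (best_key is None or s > best[1]):
            best = (d, s)
            best_key = d
    return best


def classify_multiclass(scores: DocumentScores, class_map: dict[str, str],
                        read_id: str = "read", n_symbols: int = 0,
                        n_chunks: int = 1) -> ReadCall:
    """Assign the read to the class of the best-scoring document."""
    top_doc, top_score = _argmax_doc(scores)
    if top_doc == NO_DOCUMENT:
        cls = UNCLASSIFIED
    else:
        cls = scores.doc_meta[top_doc][1]
    return ReadCall(read_id=read_id, mode="multiclass", predicted_class=cls,
                    top_doc=top_doc, score=top_score,
                    n_symbols_used=n_symbols, n_chunks=n_chunks)


def classify_binary(scores: DocumentScores, class_map: dict[str, str],
                    tau: float = 1.0, read_id: str = "read",
                    n_symbols: int = 0, n_chunks: int = 1) -> ReadCall:
    """Spike-ratio decision between the positive and null classes.

    ratio = (top positive-document score) / (top null-document score);
    the read is positive iff ratio > tau (strict).  A zero null score
    with a positive score gives ratio +inf (positive); all-zero scores
    give an unclassified call.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    positives = {c for c, role in class_map.items() if role == "positive"}
    nulls = {c for c, role in class_map.items() if role == "null"}
    if not positives or not nulls:
        raise ValueError("binary mode requires both a positive and a null class")
    pos_doc, pos_score = _argmax_doc(scores, restrict=positives)
    null_doc, null_score = _argmax_doc(scores, restrict=nulls)
    if pos_score == 0.0 and null_score == 0.0:
        return ReadCall(read_id=read_id, mode="binary",
                        predicted_class=UNCLASSIFIED, top_doc=NO_DOCUMENT,
                        score=0.0, ratio=0.0, threshold=tau,
                        n_symbols_used=n_symbols, n_chunks=n_chunks)
    ratio = math.inf if null_score == 0.0 else pos_score / null_score
    positive = ratio > tau
    if positive:
        cls = scores.doc_meta[pos_doc][1]
        top_doc, score = pos_doc, pos_score
    else:
        cls = scores.doc_meta[null_doc][1] if null_doc != NO_DOCUMENT else UNCLASSIFIED
        top_doc, score = null_doc, null_score
    return ReadCall(read_id=read_id, mode="binary", predicted_class=cls,
                    top_doc=top_doc, score=score, ratio=ratio, threshold=tau,
                    n_symbols_used=n_symbols, n_chunks=n_chunks)


def calibrate_threshold(burnin_ratios, expected_positive_fraction: float) -> float:
    """Spike-ratio threshold from a burn-in sample.

    tau is the (1 - f) quantile (linear interpolation) of the burn-in
    ratio distribution, so the expected positive-call rate matches the
    expected positive-class abundance f.  Infinite ratios are clipped to
    a large finite value before taking the quantile.
    """
    ratios = np.asarray(list(burnin_ratios), dtype=np.float64)
    if ratios.size == 0:
        raise ValueError("burn-in ratio sample is empty")
    if not 0.0 < expected_positive_fraction < 1.0:
        raise ValueError("expected_positive_fraction must be in (0, 1)")
    if not np.isfinite(ratios).any():
        raise ValueError("burn-in sample has no finite ratios")
    ratios = np.clip(ratios, 0.0, 1e300)
    return float(np.quantile(ratios, 1.0 - expected_positive_fraction))


def classify_profile(profile: MatchProfile, ref_or_index, complexity: dict[int, float],
                     mode: str = "multiclass", tau: float = 1.0,
                     class_map: dict[str, str] | None = None,
                     read_id: str = "read", n_chunks: int = 1) -> ReadCall:
    """Score a profile and emit a call in the requested mode."""
    shred_table = (ref_or_index.shred_table
                   if not isinstance(ref_or_index, ShredTable) else ref_or_index)
    if class_map is None:
        class_map = getattr(ref_or_index, "class_map", None) or {}
    scores = document_scores(profile, complexity, shred_table)
    if mode == "binary":
        return classify_binary(scores, class_map, tau=tau, read_id=read_id,
                               n_symbols=len(profile), n_chunks=n_chunks)
    return classify_multiclass(scores, class_map, read_id=read_id,
                               n_symbols=len(profile), n_chunks=n_chunks)


DEFAULT_CHUNK_SIZE = 4_000  # samples; ~1 s of sequencing


def classify_stream(chunks, index: PMLIndex, ref: ReferenceText,
                    model: PoreModel, cfg: BinningConfig,
                    params: EventDetectorParams | None = None,
                    mode: str = "multiclass", tau: float = 1.0,
                    complexity: dict[int, float] | None = None,
                    read_id: str = "read", normalize: bool = True) -> list[ReadCall]:
    """Per-chunk streaming decisions for one read.

    After each arriving chunk the accumulated raw signal is re-run
    through the full pipeline (event state, normalization and the PML
    profile all reflect every sample seen so far), so the decision after
    the final chunk is identical to the batch decision on the complete
    signal.  Chunks must arrive in order.
    """
    if complexity is None:
        complexity = shred_complexity(ref)
    class_map = index.class_map or ref.class_map
    calls: list[ReadCall] = []
    acc: list[np.ndarray] = []
    for k, chunk in enumerate(chunks, start=1):
        chunk = np.asarray(chunk, dtype=np.float64)
        acc.append(chunk)
        samples = np.concatenate(acc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bins = signal_to_binseq(samples, model, cfg, params,
                                    normalize=normalize)
        if len(bins) == 0:
            calls.append(ReadCall(read_id=read_id, mode=mode,
                                  predicted_class=UNCLASSIFIED,
                                  top_doc=NO_DOCUMENT, score=0.0,
                                  ratio=0.0 if mode == "binary" else None,
                                  threshold=tau if mode == "binary" else None,
                                  n_symbols_used=0, n_chunks=k))
            continue
        profile = compute_pml(index, bins)
        scores = document_scores(profile, complexity, index.shred_table)
        if mode == "binary":
            call = classify_binary(scores, class_map, tau=tau, read_id=read_id,
                                   n_symbols=len(bins), n_chunks=k)
        else:
            call = classify_multiclass(scores, class_map, read_id=read_id,
                                       n_symbols=len(bins), n_chunks=k)
        calls.append(call)
    if not calls:
        raise ValueError("no chunks supplied")
    return calls


def split_into_chunks(samples: np.ndarray,
                      chunk_size: int = DEFAULT_CHUNK_SIZE) -> list[np.ndarray]:
    """Cut a raw trace into successive fixed-size signal chunks."""
    samples = np.asarray(samples)
    if chunk_size <= 0:
        raise ValueError("chunk_size must be positive")
    return [samples[i:i + chunk_size] for i in range(0, samples.size, chunk_size)] \
        or [samples]
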