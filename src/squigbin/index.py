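"""Run-length BWT index and single-pass pseudo-matching lengths.

The reference text (bin symbols plus terminators) is indexed through its
Burrows-Wheeler Transform.  The persisted structures are run-length:
maximal equal-symbol runs, per-run-boundary document labels (the sampled
document array over "shreds"), and per-run-gap thresholds that decide,
on a mismatch, whether to reposition to the preceding or the following
run of the needed symbol (the side whose suffix shares the longer common
prefix with the current one).

Pseudo-matching lengths (PMLs) are computed in one backward pass over
the query holding a small state: the current BWT row, the current match
range, the running match length and the current document label.  The
match length grows by one while the current match can be extended by the
next query symbol anywhere in the text, and resets when it cannot; it is
therefore a truncated matching statistic, bounded above by the half-MEM
matching statistics and exactly the decreasing ramp [m..1] for queries
that occur verbatim in the text.  Document labels are exact wherever the
row sits on a run boundary (in particular after every reposition) and
are propagated through LF steps in between.
"""

from __future__ import annotations

import json
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from squigbin.pore_model import BinSequence
from squigbin.reference import ReferenceText, ShredTable

NO_DOCUMENT = -1  # sentinel document label


# ---------------------------------------------------------------------------
# suffix array / LCP construction


def suffix_array(text: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n), numpy-vectorized)."""
    t = np.asarray(text, dtype=np.int64)
    n = t.size
    if n == 0:
        return np.empty(0, dtype=np.int64)
    rank = np.unique(t, return_inverse=True)[1].astype(np.int64)
    k = 1
    order = np.argsort(rank, kind="stable")
    while True:
        rank2 = np.full(n, -1, dtype=np.int64)
        if k < n:
            rank2[: n - k] = rank[k:]
        order = np.lexsort((rank2, rank))
        r_o = rank[order]
        r2_o = rank2[order]
        changed = np.empty(n, dtype=np.int64)
        changed[0] = 0
        if n > 1:
            changed[1:] = ((r_o[1:] != r_o[:-1]) | (r2_o[1:] != r2_o[:-1])).cumsum()
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = changed
        rank = new_rank
        if changed[-1] == n - 1:
            return order
        k *= 2


def lcp_array(text: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """Kasai's algorithm; lcp[i] = lcp(suffix sa[i-1], suffix sa[i]), lcp[0]=0."""
    t = np.asarray(text, dtype=np.int64)
    n = t.size
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and t[i + h] == t[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


# ---------------------------------------------------------------------------
# index structures


@dataclass
class SymbolRuns:
    """BWT runs of one symbol: head/tail offsets and inter-run thresholds.

    ``thr[j]`` is the offset where preference switches between run j and
    run j+1: a row r strictly between tail[j] and head[j+1] repositions
    to tail[j] when r < thr[j] and to head[j+1] otherwise (ties in
    common-prefix length break toward the preceding run, which is what
    the rightmost-minimum convention below realizes).
    """

    heads: list[int]
    tails: list[int]
    thr: list[int]


@dataclass
class PMLIndex:
    """BWT runs, thresholds and sampled document labels over a reference text."""

    n: int
    r: int
    bwt: np.ndarray
    sigma: int
    C: np.ndarray            # C[c] = # symbols < c in the text
    occ: np.ndarray          # occ[i, c] = # occurrences of c in bwt[:i]
    counts: np.ndarray
    run_starts: list[int]
    run_ends: np.ndarray
    doc_head: np.ndarray     # document label at the first offset of each run
    doc_tail: np.ndarray     # document label at the last offset of each run
    sym_runs: dict[int, SymbolRuns]
    first_row: int           # row whose suffix is the whole text (SA == 0)
    query_offset: int = 0    # added to external query symbols
    max_query_internal: int | None = None  # internal symbols >= this never match
    shred_table: ShredTable | None = None
    class_map: dict[str, str] | None = None
    n_bins: int | None = None
    sa: np.ndarray | None = None  # construction scaffolding, not persisted

    def lf(self, row: int) -> int:
        c = int(self.bwt[row])
        return int(self.C[c] + self.occ[row, c])

    def invert_bwt(self) -> np.ndarray:
        """Reconstruct the exact text from the BWT (invertibility check)."""
        out = np.empty(self.n, dtype=np.int64)
        row = self.first_row
        for i in range(self.n - 1, -1, -1):
            out[i] = self.bwt[row]
            row = self.lf(row)
        return out

    def _run_of(self, row: int) -> int:
        return bisect_right(self.run_starts, row) - 1

    def _doc_if_boundary(self, row: int) -> int | None:
        rid = self._run_of(row)
        if self.run_starts[rid] == row:
            return int(self.doc_head[rid])
        if self.run_ends[rid] == row:
            return int(self.doc_tail[rid])
        return None


def _build_structures(text: np.ndarray, doc_of_pos: np.ndarray | None,
                      query_offset: int, max_query_internal: int | None,
                      shred_table: ShredTable | None = None,
                      class_map: dict[str, str] | None = None,
                      n_bins: int | None = None) -> PMLIndex:
    t = np.asarray(text, dtype=np.int64)
    n = t.size
    if n == 0:
        raise ValueError("cannot index an empty text")
    if t[-1] != 0:
        raise ValueError("text must end with a terminator (symbol 0)")
    if t.min() < 0:
        raise ValueError("text symbols must be non-negative")
    sa = suffix_array(t)
    bwt = t[sa - 1]  # sa==0 wraps to t[-1], the final terminator
    sigma = int(t.max()) + 1
    first_row = int(np.nonzero(sa == 0)[0][0])

    counts = np.bincount(bwt, minlength=sigma).astype(np.int64)
    C = np.concatenate(([0], np.cumsum(counts)))[:sigma]
    occ = np.zeros((n + 1, sigma), dtype=np.int64)
    for c in range(sigma):
        occ[1:, c] = np.cumsum(bwt == c)

    is_start = np.concatenate(([True], bwt[1:] != bwt[:-1]))
    run_starts_arr = np.nonzero(is_start)[0]
    run_ends = np.concatenate((run_starts_arr[1:] - 1, [n - 1]))
    r = run_starts_arr.size

    if doc_of_pos is None:
        doc_of_pos = np.full(n, NO_DOCUMENT, dtype=np.int64)
    doc_at_row = doc_of_pos[sa]
    doc_head = doc_at_row[run_starts_arr]
    doc_tail = doc_at_row[run_ends]

    # thresholds: rightmost minimum of LCP between consecutive same-symbol runs
    lcp = lcp_array(t, sa)
    sym_runs: dict[int, SymbolRuns] = {}
    run_syms = bwt[run_starts_arr]
    for c in range(sigma):
        which = np.nonzero(run_syms == c)[0]
        heads = run_starts_arr[which]
        tails = run_ends[which]
        thr: list[int] = []
        for j in range(heads.size - 1):
            a = int(tails[j]) + 1
            b = int(heads[j + 1])
            seg = lcp[a:b + 1]
            # rightmost argmin -> ties in LCP preference break toward pred run
            kk = a + (seg.size - 1 - int(np.argmin(seg[::-1])))
            thr.append(kk)
        sym_runs[c] = SymbolRuns(heads=heads.tolist(), tails=tails.tolist(),
                                 thr=thr)

    return PMLIndex(
        n=n, r=r, bwt=bwt, sigma=sigma, C=C, occ=occ, counts=counts,
        run_starts=run_starts_arr.tolist(), run_ends=run_ends,
        doc_head=doc_head, doc_tail=doc_tail, sym_runs=sym_runs,
        first_row=first_row, query_offset=query_offset,
        max_query_internal=max_query_internal,
        shred_table=shred_table, class_map=class_map, n_bins=n_bins, sa=sa,
    )


def build_text_index(text: np.ndarray, doc_of_pos: np.ndarray | None = None,
                     query_offset: int = 0) -> PMLIndex:
    """Index an arbitrary terminator-ended symbol text (testing entry point)."""
    return _build_structures(np.asarray(text), doc_of_pos, query_offset, None)


def build_index(ref: ReferenceText) -> PMLIndex:
    """Build the PML index over a binned, shredded reference."""
    text = ref.text()
    docs = ref.doc_of_positions()
    # queries carry bin symbols only; sentinel and terminator never match
    return _build_structures(
        text, docs, query_offset=1, max_query_internal=ref.n_bins + 1,
        shred_table=ref.shred_table, class_map=dict(ref.class_map),
        n_bins=ref.n_bins,
    )


# ---------------------------------------------------------------------------
# PML computation


@dataclass
class MatchProfile:
    """Per-query-position PMLs and document labels (the vote substrate)."""

    P: np.ndarray
    D: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=np.int64)
        self.D = np.asarray(self.D, dtype=np.int64)
        if self.P.shape != self.D.shape:
            raise ValueError("P and D must have equal length")

    def __len__(self) -> int:
        return int(self.P.size)


@dataclass
class PMLState:
    """Resumable per-read matching state.

    ``lo``/``hi`` delimit the BWT range of the current match; ``row`` is
    the tracked occurrence used for document attribution.
    """

    row: int = 0
    length: int = 0
    doc: int = NO_DOCUMENT
    lo: int = 0
    hi: int | None = None
    read_id: str | None = None


def _reposition(index: PMLIndex, row: int, c: int, lo: int, hi: int) -> int:
    """Row of the nearest c-run boundary, preferring the side whose suffix
    shares the longer common prefix with the suffix at ``row`` (thresholds),
    ties toward the preceding run.  Prefers candidates inside [lo, hi)."""
    runs = index.sym_runs[c]
    jp = bisect_left(runs.tails, row) - 1       # last c-run tail < row
    js = bisect_right(runs.heads, row)          # first c-run head > row
    has_pred = jp >= 0
    has_succ = js < len(runs.heads)
    if has_pred and has_succ:
        pred = runs.tails[jp]
        succ = runs.heads[js]
        choice = pred if row < runs.thr[jp] else succ
        other = succ if choice == pred else pred
        if not (lo <= choice < hi) and (lo <= other < hi):
            choice = other
        return choice
    if has_pred:
        return runs.tails[jp]
    return runs.heads[js]


def _pml_pass(index: PMLIndex, q_int: np.ndarray, state: PMLState) -> tuple[np.ndarray, np.ndarray, PMLState]:
    """Right-to-left PML pass over internal query symbols, resumable."""
    n = index.n
    m = q_int.size
    P = np.zeros(m, dtype=np.int64)
    D = np.full(m, NO_DOCUMENT, dtype=np.int64)
    row = state.row
    length = state.length
    doc = state.doc
    lo = state.lo
    hi = state.hi if state.hi is not None else n
    occ = index.occ
    C = index.C
    bwt = index.bwt
    counts = index.counts
    max_q = index.max_query_internal

    for i in range(m - 1, -1, -1):
        c = int(q_int[i])
        absent = (
            c <= 0
            or c >= index.sigma
            or counts[c] == 0
            or (max_q is not None and c >= max_q)
        )
        if absent:
            # symbol never occurs (or never matches): full-range restart
            row, length, doc, lo, hi = 0, 0, NO_DOCUMENT, 0, n
            P[i] = 0
            D[i] = NO_DOCUMENT
            continue
        lo2 = C[c] + occ[lo, c]
        hi2 = C[c] + occ[hi, c]
        if hi2 > lo2:
            # the current match extends somewhere in the text
            if bwt[row] != c:
                row = _reposition(index, row, c, lo, hi)
                doc_b = index._doc_if_boundary(row)
                if doc_b is not None:
                    doc = doc_b
            row = C[c] + occ[row, c]
            length += 1
            lo, hi = int(lo2), int(hi2)
        else:
            # no occurrence extends the match: truncate and restart on c
            row = _reposition(index, row, c, 0, n)
            doc_b = index._doc_if_boundary(row)
            if doc_b is not None:
                doc = doc_b
            row = C[c] + occ[row, c]
            length = 1
            lo = int(C[c])
            hi = int(C[c] + counts[c])
        doc_b = index._doc_if_boundary(row)
        if doc_b is not None:
            doc = doc_b
        P[i] = length
        D[i] = doc

    return P, D, PMLState(row=int(row), length=int(length), doc=int(doc),
                          lo=int(lo), hi=int(hi), read_id=state.read_id)


def _as_internal(index: PMLIndex, query: BinSequence | np.ndarray) -> np.ndarray:
    symbols = query.symbols if isinstance(query, BinSequence) else np.asarray(query)
    return symbols.astype(np.int64) + index.query_offset


def compute_pml(index: PMLIndex, query: BinSequence | np.ndarray) -> MatchProfile:
    """PML and document vectors for a whole query, right-to-left single pass."""
    q_int = _as_internal(index, query)
    P, D, _ = _pml_pass(index, q_int, PMLState())
    return MatchProfile(P=P, D=D)


def resume_pml(index: PMLIndex, query_chunk: BinSequence | np.ndarray,
               state: PMLState | None = None,
               read_id: str | None = None) -> tuple[MatchProfile, PMLState]:
    """Process one chunk of a query, resuming from prior state.

    The backward pass runs right-to-left, so chunks of one read must be
    delivered latest-first; concatenating the fragments in reverse
    delivery order reproduces :func:`compute_pml` on the full query
    bit-for-bit.  State is small: row, match range, length, document.
    """
    if state is None:
        state = PMLState(read_id=read_id)
    elif read_id is not None:
        if state.read_id is not None and state.read_id != read_id:
            raise ValueError(
                f"state belongs to read {state.read_id!r}, not {read_id!r}"
            )
        state.read_id = read_id
    q_int = _as_internal(index, query_chunk)
    if q_int.size == 0:
        return MatchProfile(P=np.empty(0, np.int64), D=np.empty(0, np.int64)), state
    P, D, new_state = _pml_pass(index, q_int, state)
    return MatchProfile(P=P, D=D), new_state


def matching_statistics_oracle(text: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Brute-force half-MEM matching statistics (test oracle).

    MS[i] = length of the longest prefix of query[i:] occurring anywhere
    in text, by exhaustive scan.  Symbols must fit in a byte.
    """
    t = bytes(np.asarray(text, dtype=np.uint8).tolist())
    q = bytes(np.asarray(query, dtype=np.uint8).tolist())
    m = len(q)
    ms = np.zeros(m, dtype=np.int64)
    for i in range(m):
        length = 0
        while i + length < m and q[i:i + length + 1] in t:
            length += 1
        ms[i] = length
    return ms


# ---------------------------------------------------------------------------
# persistence: run-length structures plus samples


def save_index(index: PMLIndex, outdir: str | Path) -> None:
    """Persist the index as a directory of run-length structures."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_starts = np.asarray(index.run_starts, dtype=np.int64)
    run_lengths = np.asarray(index.run_ends, dtype=np.int64) - run_starts + 1
    run_symbols = index.bwt[run_starts]
    arrays: dict[str, np.ndarray] = {
        "run_symbols": run_symbols.astype(np.int64),
        "run_lengths": run_lengths,
        "doc_head": index.doc_head.astype(np.int64),
        "doc_tail": index.doc_tail.astype(np.int64),
    }
    for c, runs in index.sym_runs.items():
        arrays[f"thr_{c}"] = np.asarray(runs.thr, dtype=np.int64)
    np.savez_compressed(outdir / "rlebwt.npz", **arrays)
    meta = {
        "n": index.n,
        "r": index.r,
        "sigma": index.sigma,
        "first_row": index.first_row,
        "query_offset": index.query_offset,
        "max_query_internal": index.max_query_internal,
        "n_bins": index.n_bins,
        "class_map": index.class_map,
        "shred_size": index.shred_table.shred_size if index.shred_table else None,
    }
    (outdir / "index.json").write_text(json.dumps(meta, indent=2))
    if index.shred_table is not None:
        index.shred_table.to_tsv(outdir / "shreds.tsv")


def load_index(indir: str | Path) -> PMLIndex:
    """Load a persisted index, rebuilding rank scaffolding from the runs."""
    indir = Path(indir)
    meta = json.loads((indir / "index.json").read_text())
    data = np.load(indir / "rlebwt.npz")
    run_symbols = data["run_symbols"]
    run_lengths = data["run_lengths"]
    bwt = np.repeat(run_symbols, run_lengths)
    n = int(bwt.size)
    sigma = int(meta["sigma"])
    counts = np.bincount(bwt, minlength=sigma).astype(np.int64)
    C = np.concatenate(([0], np.cumsum(counts)))[:sigma]
    occ = np.zeros((n + 1, sigma), dtype=np.int64)
    for c in range(sigma):
        occ[1:, c] = np.cumsum(bwt == c)
    run_starts = np.concatenate(([0], np.cumsum(run_lengths)[:-1]))
    run_ends = run_starts + run_lengths - 1
    sym_runs: dict[int, SymbolRuns] = {}
    for c in range(sigma):
        which = np.nonzero(run_symbols == c)[0]
        sym_runs[c] = SymbolRuns(
            heads=run_starts[which].tolist(),
            tails=run_ends[which].tolist(),
            thr=data[f"thr_{c}"].tolist() if f"thr_{c}" in data else [],
        )
    shred_path = indir / "shreds.tsv"
    shred_table = None
    if shred_path.exists():
        shred_table = ShredTable.from_tsv(
            shred_path, shred_size=meta.get("shred_size") or 100_000
        )
    return PMLIndex(
        n=n, r=int(meta["r"]), bwt=bwt, sigma=sigma, C=C, occ=occ,
        counts=counts, run_starts=run_starts.tolist(), run_ends=run_ends,
        doc_head=data["doc_head"], doc_tail=data["doc_tail"],
        sym_runs=sym_runs, first_row=int(meta["first_row"]),
        query_offset=int(meta["query_offset"]),
        max_query_internal=meta.get("max_query_internal"),
        shred_table=shred_table, class_map=meta.get("class_map"),
        n_bins=meta.get("n_bins"), sa=None,
    )
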