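"""Canonical k-mer presence/absence matrices and shared-state statistics.

A canonical k-mer is the lexicographic minimum of a k-mer and its reverse
complement (k odd, so no self-complementary ambiguity).  The presence/absence
matrix over a panel of accessions supports pairwise shared-state rates — the
fraction of matrix columns where two accessions agree (both present or both
absent) — and per-accession distinct-k-mer outlier statistics that expose
accessions carrying novel sequence.

Internally k-mers are packed 2 bits per base into two 64-bit words (so
k <= 62), which keeps whole-panel de-duplication at numpy sort speed; the
packed order equals lexicographic order because A<C<G<T maps to 0<1<2<3.
``set[str]`` inputs are accepted everywhere for convenience and small cases.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

_RC = str.maketrans("ACGTacgt", "TGCAtgca")

# byte-level complement lookup; non-ACGT bytes map to 0 and are masked out
_COMP_LUT = np.zeros(256, dtype=np.uint8)
for _f, _r in zip(b"ACGT", b"TGCA"):
    _COMP_LUT[_f] = _r
_VALID_LUT = np.zeros(256, dtype=bool)
_CODE_LUT = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _VALID_LUT[_b] = True
    _CODE_LUT[_b] = _i
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

PACKED_DT = np.dtype([("hi", "<u8"), ("lo", "<u8")])


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _check_k(k: int) -> None:
    if k % 2 == 0:
        raise ValueError(f"k must be odd, got {k} (canonical form ambiguous)")
    if not 3 <= k <= 62:
        raise ValueError(f"k must be in [3, 62], got {k}")


def _pack_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """(N, k) base codes 0..3 -> structured (hi, lo) packed array.

    The dot products run in float64 (BLAS); values stay below 2^53 for
    k <= 62, so the packing is exact.
    """
    khi = (k + 1) // 2
    pow_hi = 4.0 ** np.arange(khi - 1, -1, -1)
    pow_lo = 4.0 ** np.arange(k - khi - 1, -1, -1)
    out = np.empty(codes.shape[0], dtype=PACKED_DT)
    c = codes.astype(np.float64)
    out["hi"] = (c[:, :khi] @ pow_hi).astype(np.uint64)
    out["lo"] = (c[:, khi:] @ pow_lo).astype(np.uint64) if k > khi else 0
    return out


def _unpack_to_bytes(packed: np.ndarray, k: int) -> np.ndarray:
    """Packed array -> fixed-width bytes array (dtype S{k})."""
    khi = (k + 1) // 2
    codes = np.empty((packed.size, k), dtype=np.uint8)
    hi = packed["hi"].copy()
    lo = packed["lo"].copy()
    for j in range(khi - 1, -1, -1):
        codes[:, j] = hi % 4
        hi //= 4
    for j in range(k - 1, khi - 1, -1):
        codes[:, j] = lo % 4
        lo //= 4
    return np.ascontiguousarray(_BASE_BYTES[codes]).view(f"S{k}").ravel()


def _strings_to_packed(kmer_strings, k: int) -> np.ndarray:
    b = np.array(sorted(kmer_strings), dtype=f"S{k}")
    win = b.view(np.uint8).reshape(-1, k)
    if not _VALID_LUT[win].all():
        raise ValueError("k-mers must contain only A/C/G/T")
    return _pack_codes(_CODE_LUT[win], k)


def _lex_unique(packed: np.ndarray) -> np.ndarray:
    """Sorted unique over packed k-mers via lexsort on the two words."""
    if packed.size == 0:
        return packed
    hi, lo = packed["hi"], packed["lo"]
    order = np.lexsort((lo, hi))
    h, l = hi[order], lo[order]
    new = np.ones(h.size, dtype=bool)
    new[1:] = (h[1:] != h[:-1]) | (l[1:] != l[:-1])
    out = np.empty(int(new.sum()), dtype=PACKED_DT)
    out["hi"] = h[new]
    out["lo"] = l[new]
    return out


def _canonical_windows(seq: str, k: int):
    """Packed canonical form of every valid window plus 0-based starts.

    Windows containing non-ACGT characters are dropped.
    """
    from numpy.lib.stride_tricks import sliding_window_view

    seq = seq.upper()
    n = len(seq)
    empty = (np.empty(0, dtype=PACKED_DT), np.empty(0, dtype=np.int64))
    if n < k:
        return empty
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    valid_base = _VALID_LUT[arr]
    cum = np.concatenate(([0], np.cumsum(~valid_base)))
    valid = (cum[k:] - cum[:-k]) == 0
    if not valid.any():
        return empty
    F = sliding_window_view(arr, k)
    # window i's reverse complement equals window (n-k-i) of the reversed
    # complement sequence
    R = sliding_window_view(_COMP_LUT[arr][::-1], k)[::-1]
    neq = F != R
    first = neq.argmax(axis=1)
    rows = np.arange(F.shape[0])
    use_r = F[rows, first] > R[rows, first]
    canon = np.where(use_r[:, None], R, F)[valid]
    return _pack_codes(_CODE_LUT[canon], k), np.flatnonzero(valid)


def kmer_array(sequences, k: int = 51) -> np.ndarray:
    """Sorted unique canonical k-mers in packed form (the bulk representation
    consumed by :func:`build_kmer_matrix`, :func:`union_kmers` and
    :func:`distinct_kmer_stats`)."""
    _check_k(k)
    if isinstance(sequences, str):
        sequences = [sequences]
    parts = [_canonical_windows(seq, k)[0] for seq in sequences]
    parts = [p for p in parts if p.size]
    if not parts:
        return np.empty(0, dtype=PACKED_DT)
    return _lex_unique(np.concatenate(parts))


def union_kmers(arrays) -> np.ndarray:
    """Union of packed k-mer arrays (e.g. pooling group members)."""
    arrays = [a for a in arrays if a.size]
    if not arrays:
        return np.empty(0, dtype=PACKED_DT)
    return _lex_unique(np.concatenate(arrays))


def extract_canonical_kmers(sequences, k: int = 51) -> set[str]:
    """All canonical k-mers over A/C/G/T windows of one or more sequences.

    Every length-k window yields the lexicographic minimum of itself and its
    reverse complement; windows containing any other character (e.g. N) are
    skipped.  ``k`` must be odd (>= 3) so that a k-mer never equals its own
    reverse complement.
    """
    packed = kmer_array(sequences, k)
    return set(_unpack_to_bytes(packed, k).astype(f"U{k}").tolist())


class KmerMatrix:
    """Binary presence/absence states of canonical k-mers across accessions.

    Columns are the canonical k-mers (lexicographic order) present in at
    least ``min_presence`` accessions; ``states[i, j]`` is True when
    accession ``i`` contains k-mer ``j``.  ``kmers`` holds the column k-mer
    strings (decoded lazily when the matrix was built from packed arrays).
    """

    def __init__(self, ids: list[str], kmers, states: np.ndarray, k: int,
                 min_presence: int, packed: np.ndarray | None = None) -> None:
        self.ids = list(ids)
        self.states = np.asarray(states, dtype=bool)
        self.k = k
        self.min_presence = min_presence
        self._kmers = list(kmers) if kmers is not None else None
        self._packed = packed
        n_cols = (len(self._kmers) if self._kmers is not None
                  else packed.size)
        if self.states.shape != (len(self.ids), n_cols):
            raise ValueError("states shape mismatch")

    @property
    def kmers(self) -> list[str]:
        if self._kmers is None:
            self._kmers = (_unpack_to_bytes(self._packed, self.k)
                           .astype(f"U{self.k}").tolist())
        return self._kmers

    @property
    def n_accessions(self) -> int:
        return len(self.ids)

    @property
    def n_kmers(self) -> int:
        return self.states.shape[1]

    def row(self, accession: str) -> np.ndarray:
        try:
            return self.states[self.ids.index(accession)]
        except ValueError:
            raise KeyError(f"accession {accession!r} not in k-mer matrix") from None


def build_kmer_matrix(kmer_sets: dict, min_presence: int = 2,
                      k: int | None = None) -> KmerMatrix:
    """Assemble the panel presence/absence matrix from per-accession k-mers.

    ``kmer_sets`` maps accession -> k-mers, either packed arrays from
    :func:`kmer_array` (fast path) or plain ``set[str]`` of equal-length
    strings.  Columns are the union of k-mers occurring in >=
    ``min_presence`` accessions, in lexicographic order.
    """
    if len(kmer_sets) < 2:
        raise ValueError("k-mer matrix requires >= 2 accessions")
    ids = list(kmer_sets)
    first = kmer_sets[ids[0]]
    if isinstance(first, np.ndarray):
        if k is None:
            raise ValueError("k required with packed k-mer arrays")
        return _build_matrix_packed(kmer_sets, ids, min_presence, k)
    # generic path: arbitrary equal-length strings (handy for small cases)
    lengths = {len(km) for s in kmer_sets.values() for km in s}
    if len(lengths) > 1:
        raise ValueError("k-mers of mixed lengths")
    width = lengths.pop() if lengths else 1
    counts: dict[str, int] = {}
    for s in kmer_sets.values():
        for km in s:
            counts[km] = counts.get(km, 0) + 1
    cols = sorted(km for km, c in counts.items() if c >= min_presence)
    if not cols:
        raise ValueError("no k-mer present in >= min_presence accessions")
    states = np.zeros((len(ids), len(cols)), dtype=bool)
    colindex = {km: j for j, km in enumerate(cols)}
    for i, acc in enumerate(ids):
        for km in kmer_sets[acc]:
            j = colindex.get(km)
            if j is not None:
                states[i, j] = True
    return KmerMatrix(ids, cols, states, k if k is not None else width,
                      min_presence)


def _build_matrix_packed(kmer_sets: dict, ids: list[str], min_presence: int,
                         k: int) -> KmerMatrix:
    sizes = [kmer_sets[acc].size for acc in ids]
    all_hi = np.concatenate([kmer_sets[acc]["hi"] for acc in ids])
    all_lo = np.concatenate([kmer_sets[acc]["lo"] for acc in ids])
    owner = np.repeat(np.arange(len(ids)), sizes)
    order = np.lexsort((all_lo, all_hi))
    h, l, owner = all_hi[order], all_lo[order], owner[order]
    new = np.ones(h.size, dtype=bool)
    if h.size:
        new[1:] = (h[1:] != h[:-1]) | (l[1:] != l[:-1])
    col_of = np.cumsum(new) - 1
    counts = np.bincount(col_of, minlength=int(col_of[-1]) + 1 if h.size else 0)
    keep = counts >= min_presence
    if not keep.any():
        raise ValueError("no k-mer present in >= min_presence accessions")
    newcol = np.cumsum(keep) - 1
    states = np.zeros((len(ids), int(keep.sum())), dtype=bool)
    sel = keep[col_of]
    states[owner[sel], newcol[col_of[sel]]] = True
    uniq = np.empty(int(keep.sum()), dtype=PACKED_DT)
    uniq["hi"] = h[new][keep]
    uniq["lo"] = l[new][keep]
    return KmerMatrix(ids, None, states, k, min_presence, packed=uniq)


def shared_state_rate(m: KmerMatrix, a: str, b: str) -> float:
    """Fraction of matrix columns where two accessions have equal state."""
    return float((m.row(a) == m.row(b)).mean())


def shared_rate_matrix(m: KmerMatrix) -> pd.DataFrame:
    """All pairwise shared-state rates (symmetric, unit diagonal)."""
    s = m.states.astype(np.float32)
    ncol = s.shape[1]
    both = s @ s.T
    neither = (1 - s) @ (1 - s).T
    return pd.DataFrame((both + neither) / ncol, index=m.ids, columns=m.ids,
                        dtype=float)


def distinct_kmer_stats(kmer_sets: dict, outlier_sd: float = 3.0) -> pd.DataFrame:
    """Per-accession distinct-k-mer counts with leave-one-out outlier flags.

    An accession is flagged when its count exceeds mean + ``outlier_sd`` x SD
    of all *other* accessions' counts; this detects novel-sequence carriers
    without the outlier inflating its own baseline.
    """
    if len(kmer_sets) < 3:
        raise ValueError("outlier statistics require >= 3 accessions")
    ids = list(kmer_sets)
    counts = np.array([len(kmer_sets[a]) for a in ids], dtype=float)
    flags = np.zeros(len(ids), dtype=bool)
    for i in range(len(ids)):
        others = np.delete(counts, i)
        flags[i] = counts[i] > others.mean() + outlier_sd * others.std()
    return pd.DataFrame({"accession": ids, "distinct_kmers": counts.astype(int),
                         "outlier": flags})


def pair_count(n_accessions: int) -> int:
    """Number of unordered accession pairs, n(n-1)/2."""
    if n_accessions < 2:
        raise ValueError("pair count needs >= 2 accessions")
    return n_accessions * (n_accessions - 1) // 2


# ---------------------------------------------------------------------------
# Persistence: k-mer list + per-accession bitstrings (plain text)
# ---------------------------------------------------------------------------

def save_kmer_matrix(m: KmerMatrix, directory: str) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    (d / "kmers.txt").write_text("\n".join(m.kmers) + "\n")
    with open(d / "states.txt", "w") as fh:
        fh.write(f"#k={m.k}\tmin_presence={m.min_presence}\n")
        for i, acc in enumerate(m.ids):
            bits = np.where(m.states[i], "1", "0")
            fh.write(f"{acc}\t{''.join(bits)}\n")


def load_kmer_matrix(directory: str) -> KmerMatrix:
    d = Path(directory)
    kmers = (d / "kmers.txt").read_text().split()
    ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(d / "states.txt") as fh:
        header = fh.readline().lstrip("#").split()
        meta = dict(kv.split("=") for kv in header)
        for line in fh:
            acc, bits = line.rstrip("\n").split("\t")
            ids.append(acc)
            rows.append(np.frombuffer(bits.encode(), dtype=np.uint8) == ord("1"))
    return KmerMatrix(ids, kmers, np.vstack(rows), int(meta["k"]),
                      int(meta["min_presence"]))
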