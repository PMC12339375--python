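"""FracMinHash sketching of genomes and read sets.

A genome is reduced to a subsampled set of canonical k-mer hashes (roughly a
fraction 1/c of all k-mers), with multicopy k-mers and k-mers closer than a
spacing bound masked out so that the retained k-mers behave independently.
A read set is reduced to a multiset of the same hashes; paired-end overlap
and PCR duplicates are corrected at ingestion time so that downstream
multiplicity statistics stay Poisson-like.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from itertools import zip_longest
from typing import ClassVar, Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Size of the 64-bit hash space (the M in h(x) < M/c).
HASH_SPACE = 1 << 64

_U64 = np.uint64
_MASK64 = HASH_SPACE - 1

# 2-bit nucleotide encoding; anything that is not ACGT/acgt maps to 255.
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i
del _i, _b

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


class ParameterMismatchError(ValueError):
    """Raised when sketches built with different (k, c, hash_seed) are mixed."""


def _splitmix64(x: int) -> int:
    """Scalar splitmix64 step, used to expand hash_seed into a 64-bit salt."""
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK64
    return x ^ (x >> 31)


@dataclass(frozen=True)
class SketchParams:
    """Parameters governing k-mer sketching.

    Sketches are only comparable when ``(k, c, hash_seed)`` agree. ``k``
    must be odd so that no k-mer equals its own reverse complement.
    """

    k: int = 31
    c: int = 200
    hash_seed: int = 0
    dedup_fp_rate: float = 1e-4

    M: ClassVar[int] = HASH_SPACE

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 32:
            raise ValueError(f"k must be in [1, 32], got {self.k}")
        if self.k % 2 == 0:
            raise ValueError("k must be odd (palindromic k-mers break canonicalization)")
        if self.c < 1:
            raise ValueError(f"c must be >= 1, got {self.c}")
        if not 0 <= self.hash_seed < HASH_SPACE:
            raise ValueError("hash_seed must fit in an unsigned 64-bit integer")
        if not 0.0 < self.dedup_fp_rate <= 1.0:
            raise ValueError("dedup_fp_rate must be in (0, 1]")

    @property
    def keep_threshold(self) -> int:
        """A k-mer is retained iff its hash is strictly below floor(M/c)."""
        return HASH_SPACE // self.c

    def require_compatible(self, other: "SketchParams", context: str = "") -> None:
        for name in ("k", "c", "hash_seed"):
            a, b = getattr(self, name), getattr(other, name)
            if a != b:
                where = f" ({context})" if context else ""
                raise ParameterMismatchError(
                    f"sketch parameter mismatch{where}: {name}={a} vs {name}={b}"
                )


@dataclass(eq=False)
class GenomeSketch:
    """Masked FracMinHash k-mer set of one reference genome."""

    genome_id: str
    genome_length: int
    params: SketchParams
    kmers: np.ndarray  # sorted uint64 hashes

    @property
    def n_kmers(self) -> int:
        return int(self.kmers.size)


@dataclass(eq=False)
class SampleSketch:
    """Deduplicated multiset of FracMinHash k-mers from a read set."""

    sample_id: str
    params: SketchParams
    counts: dict  # hash (int) -> multiplicity (int >= 1)
    total_bases: int
    mean_read_length: float
    paired: bool
    dedup_applied: bool

    def count_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Sorted (hashes, multiplicities) arrays; cached after first call."""
        cached = getattr(self, "_arrays", None)
        if cached is None:
            if self.counts:
                h = np.fromiter(self.counts.keys(), dtype=_U64, count=len(self.counts))
                m = np.fromiter(self.counts.values(), dtype=np.int64, count=len(self.counts))
                order = np.argsort(h)
                cached = (h[order], m[order])
            else:
                cached = (np.empty(0, dtype=_U64), np.empty(0, dtype=np.int64))
            self._arrays = cached
        return cached

    def multiplicity_histogram(self) -> Counter:
        """Sample-wide histogram n_a: number of distinct k-mers seen a times."""
        return Counter(self.counts.values())


# ---------------------------------------------------------------------------
# k-mer enumeration and hashing
# ---------------------------------------------------------------------------

def encode_sequence(sequence) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A,C,G,T -> 0..3, else 255)."""
    if isinstance(sequence, str):
        data = sequence.encode("ascii", "replace")
    elif isinstance(sequence, (bytes, bytearray)):
        data = bytes(sequence)
    else:
        arr = np.asarray(sequence, dtype=np.uint8)
        return _ENCODE[arr]
    return _ENCODE[np.frombuffer(data, dtype=np.uint8)]


def decode_sequence(codes: np.ndarray) -> str:
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def _canonical_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical 2-bit k-mer codes for every valid window.

    Returns (positions, canonical codes). Windows containing any non-ACGT
    base are skipped. The canonical code is min(forward, reverse-complement)
    on the 2-bit encoding, which is the lexicographic minimum.
    """
    n = codes.size
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=_U64)
    bad = codes > 3
    if bad.any():
        cum = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(bad, out=cum[1:])
        valid = (cum[k:] - cum[:-k]) == 0
    else:
        valid = None
    b = (codes & np.uint8(3)).astype(_U64)
    fwd = np.zeros(m, dtype=_U64)
    rev = np.zeros(m, dtype=_U64)
    two = _U64(2)
    three = _U64(3)
    for j in range(k):
        col = b[j : j + m]
        fwd = (fwd << two) | col
        rev = rev | ((col ^ three) << _U64(2 * j))
    canon = np.minimum(fwd, rev)
    if valid is None:
        return np.arange(m, dtype=np.int64), canon
    pos = np.nonzero(valid)[0]
    return pos, canon[pos]


def _mix64(values: np.ndarray, hash_seed: int) -> np.ndarray:
    """Invertible 64-bit finalizer (splitmix64 constants), salted by seed."""
    z = values ^ _U64(_splitmix64(hash_seed))
    z = z ^ (z >> _U64(30))
    z = z * _U64(0xBF58476D1CE4E5B9)
    z = z ^ (z >> _U64(27))
    z = z * _U64(0x94D049BB133111EB)
    return z ^ (z >> _U64(31))


def canonical_kmer_hashes(sequence, params: SketchParams) -> tuple[np.ndarray, np.ndarray]:
    """Hashes of canonical k-mers for every valid window of ``sequence``.

    Returns (positions, hashes), both aligned arrays; a sequence shorter
    than k yields empty arrays. Deterministic given ``params.hash_seed``.
    """
    codes = encode_sequence(sequence)
    pos, canon = _canonical_codes(codes, params.k)
    return pos, _mix64(canon, params.hash_seed)


def fracminhash_keep(hashes, params: SketchParams):
    """True where a hash passes the FracMinHash filter h(x) < floor(M/c)."""
    if np.isscalar(hashes) or isinstance(hashes, (int, np.integer)):
        if params.c == 1:
            return True
        return int(hashes) < params.keep_threshold
    hashes = np.asarray(hashes, dtype=_U64)
    if params.c == 1:
        return np.ones(hashes.shape, dtype=bool)
    return hashes < _U64(params.keep_threshold)


def _in_sorted(values: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Membership of ``values`` in a sorted array ``table``."""
    if table.size == 0:
        return np.zeros(values.shape, dtype=bool)
    idx = np.searchsorted(table, values)
    out = np.zeros(values.shape, dtype=bool)
    inside = idx < table.size
    out[inside] = table[idx[inside]] == values[inside]
    return out


# ---------------------------------------------------------------------------
# Genome sketching
# ---------------------------------------------------------------------------

def _named_contigs(records) -> list[tuple[str, str]]:
    if isinstance(records, str):
        records = [records]
    out = []
    for i, rec in enumerate(records):
        if isinstance(rec, str):
            out.append((f"contig_{i}", rec))
        else:
            name, seq = rec
            out.append((str(name), str(seq)))
    return out


def sketch_genome(
    records,
    params: SketchParams,
    spacing: int = 30,
    genome_id: str = "genome",
) -> GenomeSketch:
    """Sketch one reference genome from its contig sequences.

    Applies, in order: FracMinHash selection, removal of every k-mer whose
    canonical form occurs more than once anywhere in the genome (all copies
    dropped), and a greedy left-to-right per-contig spacing filter dropping
    retained k-mers that start fewer than ``spacing`` bases after the
    previously kept k-mer.
    """
    contigs = _named_contigs(records)
    if not contigs:
        raise ValueError("at least one record is required to sketch a genome")
    genome_length = sum(len(seq) for _, seq in contigs)

    per_contig: list[tuple[np.ndarray, np.ndarray]] = []
    all_codes: list[np.ndarray] = []
    for _, seq in contigs:
        pos, canon = _canonical_codes(encode_sequence(seq), params.k)
        per_contig.append((pos, canon))
        all_codes.append(canon)

    concat = np.concatenate(all_codes) if all_codes else np.empty(0, dtype=_U64)
    uniq, cnt = np.unique(concat, return_counts=True)
    multicopy = uniq[cnt > 1]

    kept: list[np.ndarray] = []
    for pos, canon in per_contig:
        if canon.size == 0:
            continue
        hashes = _mix64(canon, params.hash_seed)
        mask = np.asarray(fracminhash_keep(hashes, params))
        if multicopy.size:
            mask &= ~_in_sorted(canon, multicopy)
        p = pos[mask]
        h = hashes[mask]
        if spacing > 0 and p.size:
            sel = np.zeros(p.size, dtype=bool)
            prev = None
            for i, start in enumerate(p.tolist()):
                if prev is None or start - prev >= spacing:
                    sel[i] = True
                    prev = start
            h = h[sel]
        kept.append(h)

    if kept:
        kmers = np.unique(np.concatenate(kept))
    else:
        kmers = np.empty(0, dtype=_U64)
    if kmers.size == 0:
        logger.warning("genome %s produced an empty sketch", genome_id)
    return GenomeSketch(genome_id=genome_id, genome_length=genome_length,
                        params=params, kmers=kmers)


# ---------------------------------------------------------------------------
# PCR-duplicate detection
# ---------------------------------------------------------------------------

class DuplicateStore:
    """Membership structure for duplicate read detection.

    The contract is an *approximate* set with false-positive probability at
    most ``fp_rate`` per query; this implementation stores exact tuples
    (false-positive probability 0), trading a little memory for simplicity.
    """

    def __init__(self, fp_rate: float = 1e-4):
        self.fp_rate = fp_rate
        self._seen: set = set()
        self.n_queries = 0

    def __len__(self) -> int:
        return len(self._seen)

    def check_and_insert(self, *tuples) -> bool:
        """Return True (duplicate) if any tuple is present; else insert all."""
        self.n_queries += len(tuples)
        for t in tuples:
            if t in self._seen:
                return True
        self._seen.update(tuples)
        return False


#: Single-end reads longer than this are assumed to be long reads and are
#: never treated as PCR duplicates.
SINGLE_END_DEDUP_MAX_LEN = 400
#: Single-end dedup applies only while the k-mer's running multiplicity is
#: below this bound (duplicates are indistinguishable at high coverage).
SINGLE_END_DEDUP_MAX_MULT = 4
_FLANK = 32  # length of the masked flanking window


def _masked_fingerprints(window: str) -> tuple[int, int]:
    """Two 16-mer fingerprints of a 32-bp window (odd/even base masks).

    A single substitution in the window changes exactly one of the two
    fingerprints. Ambiguous bases are read as A.
    """
    codes = _ENCODE[np.frombuffer(window[:_FLANK].encode("ascii", "replace"), dtype=np.uint8)]
    codes = np.where(codes > 3, 0, codes)
    odd = 0
    for b in codes[1::2].tolist():
        odd = (odd << 2) | b
    even = 0
    for b in codes[0::2].tolist():
        even = (even << 2) | b
    return odd, even


def pcr_duplicate_check(kmer_hash, read_or_pair, store: DuplicateStore,
                        multiplicity: int = 0) -> bool:
    """Check/update the duplicate store for one FracMinHash k-mer.

    ``read_or_pair`` is either a single read sequence or a (mate1, mate2)
    tuple. Returns True when the observation should be discarded as a PCR
    duplicate; otherwise the fingerprint tuples are inserted and False is
    returned. Reads too short for a 32-bp window skip dedup entirely.
    """
    if isinstance(read_or_pair, tuple):
        s1, s2 = read_or_pair
        if len(s1) < _FLANK or len(s2) < _FLANK:
            return False
        y1, y2 = _masked_fingerprints(s1[:_FLANK])
        z1, z2 = _masked_fingerprints(s2[:_FLANK])
    else:
        s = read_or_pair
        if len(s) < _FLANK or len(s) > SINGLE_END_DEDUP_MAX_LEN:
            return False
        if multiplicity >= SINGLE_END_DEDUP_MAX_MULT:
            return False
        y1, y2 = _masked_fingerprints(s[:_FLANK])
        mid = min(len(s) // 2, len(s) - _FLANK)
        z1, z2 = _masked_fingerprints(s[mid : mid + _FLANK])
    x = int(kmer_hash)
    return store.check_and_insert((x, y1, z1), (x, y2, z2))


# ---------------------------------------------------------------------------
# Read sketching
# ---------------------------------------------------------------------------

def _seq_of(record) -> str:
    if isinstance(record, str):
        return record
    return str(record[1])


def _batch_kept_hashes(seqs: Sequence[str], params: SketchParams) -> list[np.ndarray]:
    """Kept FracMinHash hashes per read, computed in one vectorized pass.

    Reads are joined with an N separator so no window crosses a boundary.
    """
    if not seqs:
        return []
    joined = "N".join(seqs)
    pos, hashes = canonical_kmer_hashes(joined, params)
    if params.c > 1:
        mask = hashes < _U64(params.keep_threshold)
        pos = pos[mask]
        hashes = hashes[mask]
    starts = np.zeros(len(seqs) + 1, dtype=np.int64)
    np.cumsum([len(s) + 1 for s in seqs], out=starts[1:])
    cuts = np.searchsorted(pos, starts)
    return [hashes[cuts[i] : cuts[i + 1]] for i in range(len(seqs))]


def sketch_reads(
    reads: Iterable,
    params: SketchParams,
    reads2: Iterable | None = None,
    dedup: bool = True,
    sample_id: str = "sample",
    batch_size: int = 4096,
) -> SampleSketch:
    """Sketch a read set (single-end, or paired when ``reads2`` is given).

    Records may be plain sequence strings or (name, sequence) tuples.
    Multiplicities obey the pair-overlap rule (a k-mer seen in both mates of
    one pair is counted once) and, when ``dedup`` is on, the PCR-duplicate
    rule. Reads shorter than k still contribute to total_bases.
    """
    counts: Counter = Counter()
    store = DuplicateStore(params.dedup_fp_rate) if dedup else None
    total_bases = 0
    total_len = 0
    n_reads = 0
    paired = reads2 is not None

    def ingest_meta(seq: str) -> None:
        nonlocal total_bases, total_len, n_reads
        total_bases += len(seq)
        total_len += len(seq)
        n_reads += 1

    if paired:
        buf1: list[str] = []
        buf2: list[str] = []

        def flush_pairs() -> None:
            n = len(buf1)
            if n == 0:
                return
            kept = _batch_kept_hashes(buf1 + buf2, params)
            for i in range(n):
                h1, h2 = kept[i], kept[n + i]
                if h1.size == 0 and h2.size == 0:
                    continue
                c1 = Counter(h1.tolist())
                c2 = Counter(h2.tolist())
                s1, s2 = buf1[i], buf2[i]
                for x in sorted(set(c1) | set(c2)):
                    a, b = c1.get(x, 0), c2.get(x, 0)
                    mult = max(a, b) if (a and b) else (a + b)
                    if store is not None and pcr_duplicate_check(x, (s1, s2), store):
                        continue
                    counts[x] += mult
            buf1.clear()
            buf2.clear()

        index = 0
        for r1, r2 in zip_longest(reads, reads2):
            if r1 is None or r2 is None:
                which = "first" if r1 is None else "second"
                raise ValueError(
                    f"paired read streams have unequal record counts: the {which} "
                    f"stream is exhausted at record index {index}"
                )
            s1, s2 = _seq_of(r1), _seq_of(r2)
            ingest_meta(s1)
            ingest_meta(s2)
            buf1.append(s1)
            buf2.append(s2)
            if len(buf1) >= batch_size:
                flush_pairs()
            index += 1
        flush_pairs()
    else:
        buf: list[str] = []

        def flush_single() -> None:
            if not buf:
                return
            kept = _batch_kept_hashes(buf, params)
            for i, h in enumerate(kept):
                if h.size == 0:
                    continue
                s = buf[i]
                for x, mult in sorted(Counter(h.tolist()).items()):
                    if store is not None and pcr_duplicate_check(
                        x, s, store, multiplicity=counts[x]
                    ):
                        continue
                    counts[x] += mult
            buf.clear()

        for rec in reads:
            s = _seq_of(rec)
            ingest_meta(s)
            buf.append(s)
            if len(buf) >= batch_size:
                flush_single()
        flush_single()

    mean_len = (total_len / n_reads) if n_reads else 0.0
    return SampleSketch(
        sample_id=sample_id,
        params=params,
        counts=dict(counts),
        total_bases=total_bases,
        mean_read_length=mean_len,
        paired=paired,
        dedup_applied=dedup,
    )
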