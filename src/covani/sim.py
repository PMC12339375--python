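"""Synthetic genomes, mutated relatives and read sets for testing.

The generators realize exactly the statistical structure the inference
assumes: i.i.d. substitutions at rate theta between genomes, uniform read
start positions at a target coverage, i.i.d. per-base read errors at rate
epsilon, paired-end fragments with the second mate reverse-complemented,
and optional verbatim PCR duplication.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from .sketch import _canonical_codes, decode_sequence, encode_sequence


@dataclass
class SimulationTruth:
    """Ground-truth parameters of one simulated read set."""

    theta: float
    tau: float
    delta: float
    epsilon: float
    read_length: int
    paired: bool
    fragment_mean: Optional[float] = None
    fragment_sd: Optional[float] = None
    pcr_duplicate_rate: float = 0.0
    seed: int = 0
    n_substitutions: Optional[int] = None

    def expected_effective_coverage(self, k: int) -> float:
        L = self.read_length
        return self.delta * (1.0 - self.epsilon) ** k * (L - k + 1) / L

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def random_genome(length: int, seed: int = 0) -> str:
    """Uniform i.i.d. ACGT sequence of the given length."""
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    return decode_sequence(rng.integers(0, 4, length, dtype=np.uint8))


def mutate_genome(sequence: str, theta: float, seed: int = 0) -> tuple[str, int]:
    """Substitute each base independently with probability theta.

    A substituted base becomes one of the three other bases uniformly.
    Returns the mutated sequence and the realized substitution count.
    """
    if not 0.0 <= theta < 1.0:
        raise ValueError("theta must be in [0, 1)")
    codes = encode_sequence(sequence).copy()
    rng = np.random.default_rng(seed)
    hits = rng.random(codes.size) < theta
    n = int(hits.sum())
    if n:
        codes[hits] = (codes[hits] + rng.integers(1, 4, n, dtype=np.uint8)) % 4
    return decode_sequence(codes), n


def _extract_rows(codes: np.ndarray, starts: np.ndarray, L: int) -> np.ndarray:
    return codes[starts[:, None] + np.arange(L)]


def _apply_errors(rows: np.ndarray, epsilon: float, rng) -> np.ndarray:
    if epsilon <= 0:
        return rows
    mask = rng.random(rows.shape) < epsilon
    n = int(mask.sum())
    if n:
        rows = rows.copy()
        rows[mask] = (rows[mask] + rng.integers(1, 4, n, dtype=np.uint8)) % 4
    return rows


def near_duplicate(sequence: str, rng) -> str:
    """Copy of a read with exactly one random substitution."""
    codes = encode_sequence(sequence).copy()
    p = int(rng.integers(0, codes.size))
    codes[p] = (codes[p] + int(rng.integers(1, 4))) % 4
    return decode_sequence(codes)


def sample_reads(
    sequence: str,
    target_delta: float,
    read_length: int = 150,
    epsilon: float = 0.0,
    paired: bool = False,
    fragment_mean: float = 300.0,
    fragment_sd: float = 50.0,
    pcr_duplicate_rate: float = 0.0,
    seed: int = 0,
    theta: float = 0.0,
):
    """Sample reads uniformly at random from a (linear) genome.

    Returns ``(reads, truth)`` for single-end input, where ``reads`` is a
    list of (name, sequence) tuples, or ``((reads1, reads2), truth)`` for
    paired-end input with mate 2 reverse-complemented. With probability
    ``pcr_duplicate_rate`` a read (pair) is emitted a second time verbatim.
    ``theta`` is recorded in the truth object only; mutate first with
    :func:`mutate_genome` when a diverged source genome is wanted.
    """
    if target_delta <= 0:
        raise ValueError("target_delta must be positive")
    rng = np.random.default_rng(seed)
    codes = encode_sequence(sequence)
    G = codes.size
    L = int(read_length)
    if G < L:
        raise ValueError(f"genome length {G} is shorter than the read length {L}")

    truth = SimulationTruth(
        theta=theta, tau=1.0 - theta, delta=target_delta, epsilon=epsilon,
        read_length=L, paired=paired,
        fragment_mean=fragment_mean if paired else None,
        fragment_sd=fragment_sd if paired else None,
        pcr_duplicate_rate=pcr_duplicate_rate, seed=seed,
    )

    if paired:
        n = max(1, int(round(target_delta * G / (2 * L))))
        frags = np.clip(
            np.rint(rng.normal(fragment_mean, fragment_sd, n)).astype(np.int64), L, G
        )
        starts = (rng.random(n) * (G - frags + 1)).astype(np.int64)
        m1 = _apply_errors(_extract_rows(codes, starts, L), epsilon, rng)
        m2 = _extract_rows(codes, starts + frags - L, L)
        m2 = (3 - m2)[:, ::-1]  # reverse complement
        m2 = _apply_errors(m2, epsilon, rng)
        reads1 = [(f"r{i}/1", decode_sequence(m1[i])) for i in range(n)]
        reads2 = [(f"r{i}/2", decode_sequence(m2[i])) for i in range(n)]
        if pcr_duplicate_rate > 0:
            dup = np.nonzero(rng.random(n) < pcr_duplicate_rate)[0]
            for i in dup.tolist():
                reads1.append((f"r{i}_dup/1", reads1[i][1]))
                reads2.append((f"r{i}_dup/2", reads2[i][1]))
        return (reads1, reads2), truth

    n = max(1, int(round(target_delta * G / L)))
    starts = rng.integers(0, G - L + 1, n)
    rows = _apply_errors(_extract_rows(codes, starts, L), epsilon, rng)
    reads = [(f"r{i}", decode_sequence(rows[i])) for i in range(n)]
    if pcr_duplicate_rate > 0:
        dup = np.nonzero(rng.random(n) < pcr_duplicate_rate)[0]
        for i in dup.tolist():
            reads.append((f"r{i}_dup", reads[i][1]))
    return reads, truth


def kmer_set(sequence: str, k: int) -> set:
    """Full (unsubsampled) set of canonical k-mer codes of a sequence."""
    _, canon = _canonical_codes(encode_sequence(sequence), k)
    return set(canon.tolist())


def brute_containment_ani(kmer_set_a: set, kmer_set_b: set, k: int) -> float:
    """(|A ∩ B| / |A|)^(1/k) over complete k-mer sets — the test oracle."""
    if not kmer_set_a:
        raise ValueError("containment is undefined for an empty k-mer set A")
    frac = len(kmer_set_a & kmer_set_b) / len(kmer_set_a)
    return frac ** (1.0 / k)
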