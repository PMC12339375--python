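"""Per-genome querying and winner-take-all metagenome profiling.

``query`` estimates containment ANI for each genome independently.
``profile`` additionally reassigns k-mers shared between candidate genomes
to the genome with the highest putative ANI, re-estimates, keeps genomes
above an ANI detection threshold and reports abundances.
"""

from __future__ import annotations

import logging
import zlib
from collections import Counter
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .inference import (
    AniEstimate,
    CoveragePolicy,
    MultiplicityHistogram,
    SampleErrorModel,
    TooFewKmersError,
    build_histogram,
    estimate_from_histogram,
)
from .sketch import GenomeSketch, SampleSketch

logger = logging.getLogger(__name__)

DEFAULT_MIN_ANI = 0.95
DEFAULT_CANDIDATE_FLOOR = 0.90


@dataclass
class ProfileRecord:
    genome_id: str
    adjusted_ani: float
    effective_coverage: float
    true_coverage: Optional[float]
    genome_length: int
    taxonomic_abundance: float  # percent
    sequence_abundance: float  # percent
    n_kmers_reassigned: int


@dataclass
class ProfileReport:
    sample_id: str
    records: list
    percent_reads_detected: float
    unknown_scaled: bool


def _genome_seed(seed: int, genome_id: str) -> np.random.SeedSequence:
    """Per-genome bootstrap seed, independent of genome ordering."""
    return np.random.SeedSequence([int(seed), zlib.crc32(genome_id.encode())])


def query(
    genomes: Sequence[GenomeSketch],
    sample: SampleSketch,
    policy: Optional[CoveragePolicy] = None,
    error_model: Optional[SampleErrorModel] = None,
    seed: int = 0,
    read_length: Optional[float] = None,
) -> list[AniEstimate]:
    """Independent ANI estimate per genome, best ANI first.

    Genomes whose sketches are too small are skipped with a logged reason.
    No k-mer reassignment is performed.
    """
    policy = policy or CoveragePolicy()
    L = read_length if read_length is not None else sample.mean_read_length
    out: list[AniEstimate] = []
    for g in genomes:
        hist = build_histogram(g, sample)
        try:
            est = estimate_from_histogram(
                hist, genome_id=g.genome_id, k=g.params.k, policy=policy,
                error_model=error_model, mean_read_length=L,
                seed=_genome_seed(seed, g.genome_id),
            )
        except TooFewKmersError as exc:
            logger.info("skipping genome: %s", exc)
            continue
        out.append(est)
    out.sort(key=lambda e: (-e.adjusted_ani, e.genome_id))
    return out


def reassign_kmers(
    genomes: Sequence[GenomeSketch],
    sample: SampleSketch,
    putative: Sequence[AniEstimate],
) -> dict:
    """Winner-take-all reassignment of shared sample k-mers.

    Every sample k-mer contained in at least one candidate genome is
    credited, with its full multiplicity, to the candidate with the highest
    putative ANI (ties broken by lexicographic genome_id). Losing genomes
    treat the k-mer as absent but keep it in their sketch size N. Returns a
    genome_id -> MultiplicityHistogram map.
    """
    ani = {e.genome_id: e.adjusted_ani for e in putative}
    by_id = {g.genome_id: g for g in genomes}
    order = sorted(ani, key=lambda gid: (-ani[gid], gid))
    hashes, mults = sample.count_arrays()

    contained: dict = {}
    for gid in order:
        g = by_id[gid]
        if g.kmers.size and hashes.size:
            idx = np.searchsorted(hashes, g.kmers)
            inside = idx < hashes.size
            hit = np.zeros(g.kmers.shape, dtype=bool)
            hit[inside] = hashes[idx[inside]] == g.kmers[inside]
            contained[gid] = (g.kmers[hit], mults[idx[hit]])
        else:
            contained[gid] = (np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64))

    owner: dict = {}
    for gid in order:  # highest putative ANI claims first
        for h in contained[gid][0].tolist():
            if h not in owner:
                owner[h] = gid

    hists: dict = {}
    for gid in order:
        ks, ms = contained[gid]
        counts: Counter = Counter()
        for h, m in zip(ks.tolist(), ms.tolist()):
            if owner[h] == gid:
                counts[int(m)] += 1
        hists[gid] = MultiplicityHistogram(
            n_sketch_kmers=by_id[gid].n_kmers, counts=dict(counts)
        )
    return hists


def percent_reads_detected(records: Sequence[ProfileRecord], total_bases: int) -> float:
    """100 * sum(delta_i * GL_i) / total_bases, capped at 100."""
    if total_bases <= 0:
        raise ValueError("total_bases must be positive")
    covered = 0.0
    for r in records:
        delta = r.true_coverage if r.true_coverage is not None else r.effective_coverage
        covered += delta * r.genome_length
    return min(100.0, 100.0 * covered / total_bases)


def profile(
    genomes: Sequence[GenomeSketch],
    sample: SampleSketch,
    policy: Optional[CoveragePolicy] = None,
    error_model: Optional[SampleErrorModel] = None,
    min_ani: float = DEFAULT_MIN_ANI,
    unknown_scaling: bool = False,
    seed: int = 0,
    read_length: Optional[float] = None,
    candidate_floor: float = DEFAULT_CANDIDATE_FLOOR,
) -> ProfileReport:
    """Species-level profile of a sample against a genome database.

    Pipeline: putative ANIs as in ``query``, winner-take-all k-mer
    reassignment among candidates whose naive ANI reaches
    ``candidate_floor``, re-estimation on the reassigned histograms,
    detection at ``adjusted_ani >= min_ani``, then abundances and the
    percentage of reads detected. With ``unknown_scaling`` both abundance
    columns are multiplied by percent_reads_detected / 100.
    """
    policy = policy or CoveragePolicy()
    L = read_length if read_length is not None else sample.mean_read_length
    putative = query(genomes, sample, policy=policy, error_model=error_model,
                     seed=seed, read_length=read_length)
    candidates = [e for e in putative if e.naive_ani >= candidate_floor]
    by_id = {g.genome_id: g for g in genomes}

    hists = reassign_kmers([by_id[e.genome_id] for e in candidates], sample, candidates)

    kept: list[tuple[AniEstimate, GenomeSketch]] = []
    for e in candidates:
        g = by_id[e.genome_id]
        est = estimate_from_histogram(
            hists[e.genome_id], genome_id=e.genome_id, k=g.params.k,
            policy=policy, error_model=error_model, mean_read_length=L,
            seed=_genome_seed(seed, e.genome_id),
        )
        if est.adjusted_ani >= min_ani and est.n_contained > 0:
            kept.append((est, g))

    if not kept:
        return ProfileReport(sample_id=sample.sample_id, records=[],
                             percent_reads_detected=0.0,
                             unknown_scaled=unknown_scaling)

    lams = np.array([e.effective_coverage for e, _ in kept], dtype=float)
    lengths = np.array([g.genome_length for _, g in kept], dtype=float)
    tax = 100.0 * lams / lams.sum()
    seq = 100.0 * (lams * lengths) / (lams * lengths).sum()

    records = [
        ProfileRecord(
            genome_id=e.genome_id,
            adjusted_ani=e.adjusted_ani,
            effective_coverage=e.effective_coverage,
            true_coverage=e.true_coverage,
            genome_length=g.genome_length,
            taxonomic_abundance=float(t),
            sequence_abundance=float(s),
            n_kmers_reassigned=e.n_contained,
        )
        for (e, g), t, s in zip(kept, tax, seq)
    ]
    prd = percent_reads_detected(records, sample.total_bases)
    if unknown_scaling:
        factor = prd / 100.0
        records = [
            replace(r, taxonomic_abundance=r.taxonomic_abundance * factor,
                    sequence_abundance=r.sequence_abundance * factor)
            for r in records
        ]
    records.sort(key=lambda r: (-r.taxonomic_abundance, r.genome_id))
    return ProfileReport(sample_id=sample.sample_id, records=records,
                         percent_reads_detected=prd,
                         unknown_scaled=unknown_scaling)
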