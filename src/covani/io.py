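"""File formats: sketches, FASTA/FASTQ readers, TSV reports.

Sketch files are versioned. The binary dialect starts with the magic
``NYSK`` and stores little-endian integers; a plain-text JSON dialect
(chosen by a ``.json`` suffix or ``format="json"``) holds the same fields
for debugging and text-only pipelines. Reading is transparent to gzip.
"""

from __future__ import annotations

import gzip
import json
import struct
from typing import Iterator, Union

import numpy as np
from Bio import SeqIO
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .sketch import GenomeSketch, SampleSketch, SketchParams

MAGIC = b"NYSK"
FORMAT_VERSION = 1
_TYPE_GENOME = 0
_TYPE_SAMPLE = 1

Sketch = Union[GenomeSketch, SampleSketch]


# ---------------------------------------------------------------------------
# Sequence input
# ---------------------------------------------------------------------------

def open_text(path):
    """Open a possibly gzip-compressed file for text reading."""
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from a FASTA file (gzip transparent)."""
    with open_text(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            yield title.split()[0], seq


def sniff_format(path) -> str:
    with open_text(path) as fh:
        first = fh.read(1)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError(f"{path}: not recognizably FASTA or FASTQ")


def read_reads(path) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) reads from FASTA or FASTQ (gzip transparent)."""
    fmt = sniff_format(path)
    with open_text(path) as fh:
        if fmt == "fasta":
            for title, seq in SimpleFastaParser(fh):
                yield title.split()[0], seq
        else:
            for title, seq, _qual in FastqGeneralIterator(fh):
                yield title.split()[0], seq


def write_fasta(path, records) -> None:
    """Write (id, sequence) records as FASTA, 80 columns."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_fastq(path, records, quality_char: str = "I") -> None:
    """Write (name, sequence) records as FASTQ with a fixed quality symbol."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


# ---------------------------------------------------------------------------
# Sketch files
# ---------------------------------------------------------------------------

def _params_dict(params: SketchParams) -> dict:
    return {"k": params.k, "c": params.c, "hash_seed": params.hash_seed,
            "dedup_fp_rate": params.dedup_fp_rate}


def _sketch_format(path, format: str) -> str:
    if format == "auto":
        return "json" if str(path).endswith(".json") else "binary"
    if format not in ("json", "binary"):
        raise ValueError(f"unknown sketch format {format!r}")
    return format


def write_sketch(sketch: Sketch, path, format: str = "auto") -> None:
    fmt = _sketch_format(path, format)
    if fmt == "json":
        _write_sketch_json(sketch, path)
    else:
        _write_sketch_binary(sketch, path)


def read_sketch(path) -> Sketch:
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic == MAGIC:
        return _read_sketch_binary(path)
    return _read_sketch_json(path)


def _write_sketch_json(sketch: Sketch, path) -> None:
    doc = {"magic": MAGIC.decode(), "version": FORMAT_VERSION,
           "params": _params_dict(sketch.params)}
    if isinstance(sketch, GenomeSketch):
        doc["type"] = "genome"
        doc["genome_id"] = sketch.genome_id
        doc["genome_length"] = sketch.genome_length
        doc["kmers"] = sketch.kmers.tolist()
    else:
        doc["type"] = "sample"
        doc["sample_id"] = sketch.sample_id
        doc["total_bases"] = sketch.total_bases
        doc["mean_read_length"] = sketch.mean_read_length
        doc["paired"] = sketch.paired
        doc["dedup_applied"] = sketch.dedup_applied
        hashes, mults = sketch.count_arrays()
        doc["kmers"] = hashes.tolist()
        doc["multiplicities"] = mults.tolist()
    with open(path, "w") as fh:
        json.dump(doc, fh)


def _read_sketch_json(path) -> Sketch:
    with open_text(path) as fh:
        doc = json.load(fh)
    if doc.get("magic") != MAGIC.decode():
        raise ValueError(f"{path}: not a sketch file")
    if doc.get("version") != FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported sketch version {doc.get('version')}")
    params = SketchParams(**doc["params"])
    kmers = np.asarray(doc["kmers"], dtype=np.uint64)
    if doc["type"] == "genome":
        return GenomeSketch(genome_id=doc["genome_id"],
                            genome_length=doc["genome_length"],
                            params=params, kmers=kmers)
    mults = doc["multiplicities"]
    counts = {int(h): int(m) for h, m in zip(doc["kmers"], mults)}
    return SampleSketch(sample_id=doc["sample_id"], params=params, counts=counts,
                        total_bases=doc["total_bases"],
                        mean_read_length=doc["mean_read_length"],
                        paired=doc["paired"], dedup_applied=doc["dedup_applied"])


def _write_str(fh, s: str) -> None:
    data = s.encode("utf-8")
    fh.write(struct.pack("<I", len(data)))
    fh.write(data)


def _read_str(fh) -> str:
    (n,) = struct.unpack("<I", fh.read(4))
    return fh.read(n).decode("utf-8")


def _write_sketch_binary(sketch: Sketch, path) -> None:
    p = sketch.params
    with open(path, "wb") as fh:
        kind = _TYPE_GENOME if isinstance(sketch, GenomeSketch) else _TYPE_SAMPLE
        fh.write(MAGIC)
        fh.write(struct.pack("<HBHIQd", FORMAT_VERSION, kind, p.k, p.c,
                             p.hash_seed, p.dedup_fp_rate))
        if isinstance(sketch, GenomeSketch):
            _write_str(fh, sketch.genome_id)
            fh.write(struct.pack("<QQ", sketch.genome_length, sketch.n_kmers))
            fh.write(np.ascontiguousarray(sketch.kmers, dtype="<u8").tobytes())
        else:
            _write_str(fh, sketch.sample_id)
            hashes, mults = sketch.count_arrays()
            fh.write(struct.pack("<QdBBQ", sketch.total_bases,
                                 sketch.mean_read_length, int(sketch.paired),
                                 int(sketch.dedup_applied), hashes.size))
            fh.write(np.ascontiguousarray(hashes, dtype="<u8").tobytes())
            fh.write(np.ascontiguousarray(mults, dtype="<u4").tobytes())


def _read_sketch_binary(path) -> Sketch:
    with open(path, "rb") as fh:
        if fh.read(4) != MAGIC:
            raise ValueError(f"{path}: not a sketch file")
        version, kind, k, c, seed, fp = struct.unpack("<HBHIQd", fh.read(25))
        if version != FORMAT_VERSION:
            raise ValueError(f"{path}: unsupported sketch version {version}")
        params = SketchParams(k=k, c=c, hash_seed=seed, dedup_fp_rate=fp)
        if kind == _TYPE_GENOME:
            genome_id = _read_str(fh)
            length, n = struct.unpack("<QQ", fh.read(16))
            kmers = np.frombuffer(fh.read(8 * n), dtype="<u8").astype(np.uint64)
            return GenomeSketch(genome_id=genome_id, genome_length=length,
                                params=params, kmers=kmers)
        if kind != _TYPE_SAMPLE:
            raise ValueError(f"{path}: unknown sketch type {kind}")
        sample_id = _read_str(fh)
        total_bases, mean_len, paired, dedup, n = struct.unpack("<QdBBQ", fh.read(26))
        hashes = np.frombuffer(fh.read(8 * n), dtype="<u8")
        mults = np.frombuffer(fh.read(4 * n), dtype="<u4")
        counts = {int(h): int(m) for h, m in zip(hashes.tolist(), mults.tolist())}
        return SampleSketch(sample_id=sample_id, params=params, counts=counts,
                            total_bases=total_bases, mean_read_length=mean_len,
                            paired=bool(paired), dedup_applied=bool(dedup))


# ---------------------------------------------------------------------------
# TSV reports
# ---------------------------------------------------------------------------

QUERY_COLUMNS = [
    "sample", "genome", "adjusted_ANI", "naive_ANI", "ANI_CI_5", "ANI_CI_95",
    "eff_cov", "true_cov", "n_sketch_kmers", "n_contained", "adjustment_applied",
]

PROFILE_COLUMNS = [
    "sample", "genome", "taxonomic_abundance", "sequence_abundance",
    "adjusted_ANI", "eff_cov", "true_cov", "genome_length", "n_kmers_reassigned",
]


def _fmt_pct(x) -> str:
    return "NA" if x is None else f"{100.0 * x:.4f}"


def _fmt_raw_pct(x) -> str:
    return "NA" if x is None else f"{x:.4f}"


def _fmt(x) -> str:
    return "NA" if x is None else f"{x:.4f}"


def write_query_tsv(fh, sample_id: str, estimates) -> None:
    fh.write("\t".join(QUERY_COLUMNS) + "\n")
    for e in estimates:
        fh.write("\t".join([
            sample_id, e.genome_id, _fmt_pct(e.adjusted_ani),
            _fmt_pct(e.naive_ani), _fmt_pct(e.ci_low), _fmt_pct(e.ci_high),
            _fmt(e.effective_coverage), _fmt(e.true_coverage),
            str(e.n_sketch_kmers), str(e.n_contained),
            "true" if e.adjustment_applied else "false",
        ]) + "\n")


def write_profile_tsv(fh, report, params: SketchParams) -> None:
    fh.write(
        f"# percent_reads_detected={report.percent_reads_detected:.4f}\t"
        f"k={params.k}\tc={params.c}\thash_seed={params.hash_seed}\t"
        f"unknown_scaled={str(report.unknown_scaled).lower()}\n"
    )
    fh.write("\t".join(PROFILE_COLUMNS) + "\n")
    for r in report.records:
        fh.write("\t".join([
            report.sample_id, r.genome_id,
            _fmt_raw_pct(r.taxonomic_abundance),
            _fmt_raw_pct(r.sequence_abundance),
            _fmt_pct(r.adjusted_ani), _fmt(r.effective_coverage),
            _fmt(r.true_coverage), str(r.genome_length),
            str(r.n_kmers_reassigned),
        ]) + "\n")


def write_manifest(path, config: dict) -> None:
    """Machine-readable run manifest written next to an output file."""
    with open(path, "w") as fh:
        json.dump(config, fh, indent=1, sort_keys=True, default=str)
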