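"""Per-chromosome strand-separated pileup ("dynamic matrix").

For each position of the chromosome currently being processed, the number
of supporting reads and the summed Phred quality are recorded for all four
bases on the Watson and Crick strands separately. The whole structure is
allocated when a chromosome's reads start arriving and released when its
calls have been emitted, so peak memory is bounded by the largest single
chromosome rather than the genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bisulfite import BASES, BASE_INDEX, WATSON, CRICK, effective_counts
from .filters import FilterParams, classify_candidate, _CONSUMES_QUERY, _CONSUMES_REF


@dataclass
class StrandBaseProfile:
    """Counts and Phred-quality sums for A/C/G/T on each strand at one position.

    All bases are in SAM forward orientation; "Crick" means the read
    originated from the Crick bisulfite strand, not that its bases are
    complemented.
    """

    watson_count: np.ndarray
    crick_count: np.ndarray
    watson_qual_sum: np.ndarray
    crick_qual_sum: np.ndarray

    @classmethod
    def from_counts(cls, watson=None, crick=None, qual: int = 30) -> "StrandBaseProfile":
        """Build a profile from ``{base: count}`` or ``{base: (count, qual)}`` dicts.

        Convenience constructor for tests and examples; ``qual`` is the
        per-base Phred quality used when only a count is given.
        """
        wc = np.zeros(4, dtype=np.int64)
        cc = np.zeros(4, dtype=np.int64)
        wq = np.zeros(4, dtype=np.int64)
        cq = np.zeros(4, dtype=np.int64)
        for spec, counts, quals in ((watson, wc, wq), (crick, cc, cq)):
            for base, value in (spec or {}).items():
                n, q = value if isinstance(value, tuple) else (value, qual)
                i = BASE_INDEX[base]
                counts[i] = n
                quals[i] = n * q
        return cls(wc, cc, wq, cq)

    @property
    def total(self) -> int:
        return int(self.watson_count.sum() + self.crick_count.sum())


class ChromMatrix:
    """Strand-separated pileup over one chromosome.

    ``counts`` and ``qual_sums`` are indexed ``[position, strand, base]``
    with strand 0 = Watson, 1 = Crick and bases in A,C,G,T order.
    """

    def __init__(self, chrom_name: str, length: int):
        if length <= 0:
            raise ValueError(f"chromosome length must be positive, got {length}")
        self.chrom_name = chrom_name
        self.length = length
        self.counts = np.zeros((length, 2, 4), dtype=np.int32)
        self.qual_sums = np.zeros((length, 2, 4), dtype=np.int64)

    def profile(self, position: int) -> StrandBaseProfile:
        if not (0 <= position < self.length):
            raise IndexError(f"position {position} outside [0, {self.length})")
        return StrandBaseProfile(
            watson_count=self.counts[position, WATSON],
            crick_count=self.counts[position, CRICK],
            watson_qual_sum=self.qual_sums[position, WATSON],
            crick_qual_sum=self.qual_sums[position, CRICK],
        )

    def release(self) -> None:
        """Drop the position arrays (per-chromosome allocate/fill/call/release cycle)."""
        self.counts = np.zeros((0, 2, 4), dtype=np.int32)
        self.qual_sums = np.zeros((0, 2, 4), dtype=np.int64)
        self.length = 0


def infer_bisulfite_strand(read) -> tuple[int, bool]:
    """Bisulfite strand of origin of an aligned read.

    Recognizes the BSMAP ``ZS`` tag ('+…' Watson, '-…' Crick) and the
    Bismark ``XG`` tag (CT Watson, GA Crick). Without either tag, falls
    back to the FLAG: for single-end reads reverse ⇒ Crick; for paired
    reads the mate mirrors read1's orientation. Returns
    ``(strand, used_fallback)`` so callers can count untagged reads.
    """
    for tag in ("ZS", "XG"):
        if read.has_tag(tag):
            value = str(read.get_tag(tag))
            if tag == "ZS":
                return (WATSON if value.startswith("+") else CRICK), False
            return (WATSON if value.upper().startswith("CT") else CRICK), False
    if read.is_paired and read.is_read2:
        return (WATSON if read.is_reverse else CRICK), True
    return (CRICK if read.is_reverse else WATSON), True


def aligned_bases(read, min_base_quality: int):
    """Yield ``(ref_position, base_index, quality)`` for aligned M/=/X bases.

    Insertions and clips consume query only; deletions and reference skips
    advance the reference coordinate without contributing observations.
    Bases below the quality floor and N bases are dropped.
    """
    seq = read.query_sequence
    quals = read.query_qualities
    if seq is None or quals is None:
        return
    qpos = 0
    rpos = read.reference_start
    for op, length in read.cigartuples or ():
        if op in (0, 7, 8):
            for i in range(length):
                q = quals[qpos + i]
                if q < min_base_quality:
                    continue
                idx = BASE_INDEX.get(seq[qpos + i].upper())
                if idx is None:
                    continue
                yield rpos + i, idx, q
            qpos += length
            rpos += length
        elif op in _CONSUMES_QUERY or op in _CONSUMES_REF:
            if op in _CONSUMES_QUERY:
                qpos += length
            if op in _CONSUMES_REF:
                rpos += length
        else:
            raise ValueError(f"unsupported CIGAR operation code {op} in read {read.query_name}")


def accumulate_read(matrix: ChromMatrix, read, strand: int, min_base_quality: int) -> None:
    """Add one admitted read's aligned bases to the matrix."""
    if read.reference_name != matrix.chrom_name:
        raise ValueError(
            f"read {read.query_name} maps to {read.reference_name}, "
            f"matrix holds {matrix.chrom_name}")
    if read.reference_end is not None and read.reference_end > matrix.length:
        raise IndexError(
            f"read {read.query_name} extends to {read.reference_end}, "
            f"beyond chromosome length {matrix.length}")
    for rpos, idx, q in aligned_bases(read, min_base_quality):
        matrix.counts[rpos, strand, idx] += 1
        matrix.qual_sums[rpos, strand, idx] += q


def accumulate_pair(matrix: ChromMatrix, read1, read2, strand: int,
                    min_base_quality: int) -> None:
    """Add an overlapping mate pair, counting overlapped positions once.

    Where the mates overlap, the base from the mate with the higher base
    quality is kept (ties favour read1), so a single sequenced molecule
    contributes at most one observation per position.
    """
    for read in (read1, read2):
        if read.reference_name != matrix.chrom_name:
            raise ValueError(f"read {read.query_name} maps off-chromosome")
        if read.reference_end is not None and read.reference_end > matrix.length:
            raise IndexError(f"read {read.query_name} beyond chromosome bounds")
    chosen: dict[int, tuple[int, int]] = {}
    for rpos, idx, q in aligned_bases(read1, min_base_quality):
        chosen[rpos] = (idx, q)
    for rpos, idx, q in aligned_bases(read2, min_base_quality):
        prev = chosen.get(rpos)
        if prev is None or q > prev[1]:
            chosen[rpos] = (idx, q)
    for rpos, (idx, q) in chosen.items():
        matrix.counts[rpos, strand, idx] += 1
        matrix.qual_sums[rpos, strand, idx] += q


def emit_candidates(matrix: ChromMatrix, reference: str, params: FilterParams):
    """Yield candidate variant positions in ascending coordinate order.

    A position qualifies when its retained depth lies within
    ``[min_cover, max_cover]`` and at least one non-reference allele
    passes the frequency and minimum-support gates on
    bisulfite-effective counts. Yields ``(position, profile, ref_base)``.
    """
    if len(reference) < matrix.length:
        raise IndexError(
            f"reference for {matrix.chrom_name} has {len(reference)} bp, "
            f"matrix expects {matrix.length}")
    depth = matrix.counts.sum(axis=(1, 2))
    eligible = np.nonzero((depth >= params.min_cover) & (depth <= params.max_cover))[0]
    for pos in eligible:
        ref_base = reference[pos].upper()
        if ref_base not in BASES:
            continue
        profile = matrix.profile(int(pos))
        eff = effective_counts(profile)
        d = eff.eff_depth
        if d == 0:
            continue
        freqs = {b: float(eff.eff[i]) / d for i, b in enumerate(BASES)}
        counts = {b: float(eff.eff[i]) for i, b in enumerate(BASES)}
        keep, _ = classify_candidate(freqs, counts, ref_base, params)
        if keep:
            yield int(pos), profile, ref_base
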