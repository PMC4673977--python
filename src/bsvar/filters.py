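"""Read admission filters and allele-frequency computation for candidate discovery."""

from __future__ import annotations

from dataclasses import dataclass

from .bisulfite import BASES, BASE_INDEX, WATSON, CRICK, effective_counts

#: CIGAR ops that consume the query / the reference
_CONSUMES_QUERY = frozenset((0, 1, 4, 7, 8))
_CONSUMES_REF = frozenset((0, 2, 3, 7, 8))


@dataclass
class FilterParams:
    """Thresholds for read admission and candidate-site discovery.

    ``min_het_freq`` is the minimum non-reference allele frequency for a
    position to enter the candidate set (the method's single published
    default, 0.1). ``min_hom_freq`` governs the LowFreq VCF filter on
    homozygous-alt calls, not discovery. Base qualities are raw Phred
    values (already decoded from Phred+33 by the SAM layer).
    """

    min_map_quality: int = 20
    min_base_quality: int = 15
    max_mismatch_rate: float = 0.05
    min_het_freq: float = 0.1
    min_hom_freq: float = 0.85
    min_cover: int = 10
    max_cover: int = 1000
    min_alt_reads: int = 2

    def __post_init__(self):
        if not (0.0 <= self.min_het_freq <= self.min_hom_freq <= 1.0):
            raise ValueError(
                "require 0 <= min_het_freq <= min_hom_freq <= 1, got "
                f"{self.min_het_freq} / {self.min_hom_freq}")
        if self.min_cover > self.max_cover:
            raise ValueError("min_cover must not exceed max_cover")
        if self.max_mismatch_rate < 0:
            raise ValueError("max_mismatch_rate must be >= 0")


def bisulfite_mismatch_rate(read, chrom_sequence: str, strand: int) -> float:
    """Mismatch rate of an aligned read, ignoring expected conversions.

    C→T differences on Watson-strand reads and G→A differences on
    Crick-strand reads are bisulfite conversions, not errors, and are
    excluded. The denominator is the number of aligned (M/=/X) bases with
    a determined base on both read and reference.
    """
    seq = read.query_sequence
    qpos = 0
    rpos = read.reference_start
    aligned = 0
    mismatches = 0
    for op, length in read.cigartuples or ():
        if op in (0, 7, 8):         # M, =, X
            for i in range(length):
                qb = seq[qpos + i].upper()
                rb = chrom_sequence[rpos + i].upper()
                if qb == "N" or rb == "N":
                    continue
                aligned += 1
                if qb != rb:
                    if strand == WATSON and rb == "C" and qb == "T":
                        continue
                    if strand == CRICK and rb == "G" and qb == "A":
                        continue
                    mismatches += 1
            qpos += length
            rpos += length
        else:
            if op in _CONSUMES_QUERY:
                qpos += length
            if op in _CONSUMES_REF:
                rpos += length
    return mismatches / aligned if aligned else 0.0


def admit_read(read, params: FilterParams, chrom_sequence: str | None = None,
               strand: int | None = None) -> tuple[bool, str | None]:
    """Decide whether an alignment enters the pileup.

    Returns ``(True, None)`` or ``(False, reason)`` where ``reason`` names
    the first failed test. When ``chrom_sequence`` is given the
    bisulfite-adjusted mismatch rate is checked as well (``strand``
    required in that case).
    """
    if read.is_unmapped:
        raise ValueError("admit_read requires a mapped read; caller must skip unmapped reads")
    if read.is_secondary or read.is_supplementary:
        return False, "not_primary"
    if read.is_duplicate:
        return False, "duplicate"
    if read.is_qcfail:
        return False, "qc_fail"
    if read.mapping_quality < params.min_map_quality:
        return False, "map_quality"
    if chrom_sequence is not None:
        if strand is None:
            raise ValueError("strand is required for the mismatch-rate check")
        if bisulfite_mismatch_rate(read, chrom_sequence, strand) > params.max_mismatch_rate:
            return False, "mismatch_rate"
    return True, None


def allele_frequency(profile, allele: str, ref_base: str | None = None) -> float:
    """Frequency of ``allele`` among bisulfite-unambiguous observations.

    freq(X) = effCount(X) / Σ_b effCount(b); ambiguous Watson-T and
    Crick-A observations appear in neither numerator nor denominator, so
    the four frequencies sum to 1.
    """
    eff = effective_counts(profile)
    depth = eff.eff_depth
    if depth == 0:
        raise ValueError("allele frequency undefined at zero effective depth")
    return float(eff.eff[BASE_INDEX[allele]]) / depth


def classify_candidate(freqs, eff_counts, ref_base: str,
                       params: FilterParams) -> tuple[bool, list[str]]:
    """Frequency gate for candidate SNP sites.

    Keeps every non-reference allele with frequency >= ``min_het_freq``
    and unambiguous support >= ``min_alt_reads``; the site is dropped when
    no allele survives. ``freqs`` and ``eff_counts`` map base -> value.
    Candidate alleles are returned ordered by descending frequency
    (ties broken alphabetically).
    """
    kept = [
        b for b in BASES
        if b != ref_base
        and freqs.get(b, 0.0) >= params.min_het_freq
        and eff_counts.get(b, 0.0) >= params.min_alt_reads
    ]
    kept.sort(key=lambda b: (-freqs[b], b))
    return bool(kept), kept
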