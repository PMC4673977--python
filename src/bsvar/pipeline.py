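"""End-to-end calling pipeline: pileup per chromosome, genotype, emit outputs.

Runs the two calling stages chromosome by chromosome: (1) build the
strand-separated pileup matrix and extract frequency-passing candidate
sites, (2) genotype each candidate with the Bayesian model. Variant
genotypes go to the VCF; methylation levels are extracted from the
genotype-corrected sequence so that, e.g., a site called as a C→T
homozygote no longer produces a (spurious, fully "unmethylated")
methylation record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .bisulfite import context_of, methylation_call
from .filters import FilterParams, admit_read
from .genotyper import DepthOutOfRange, GenotypeCall, GenotypePrior, call_site
from .io import (DataError, MethylationWriter, Reference, ReferenceMismatchError,
                 stream_alignments, write_vcf)
from .pileup import (ChromMatrix, accumulate_pair, accumulate_read,
                     emit_candidates, infer_bisulfite_strand)

log = logging.getLogger("bsvar")


@dataclass
class CallSummary:
    """Counters and outputs of one calling run."""

    reads_total: int = 0
    reads_admitted: int = 0
    rejected: dict = field(default_factory=dict)
    strand_fallback: int = 0
    candidates: int = 0
    variants_written: int = 0
    context_undetermined: int = 0
    depth_skipped: int = 0
    calls: list = field(default_factory=list)  # (chrom, GenotypeCall) at candidates


def _mate_may_overlap(read) -> bool:
    return (read.is_paired and not read.mate_is_unmapped
            and read.next_reference_id == read.reference_id
            and read.reference_start <= read.next_reference_start < read.reference_end)


def build_matrix(chrom: str, sequence: str, reads, params: FilterParams,
                 summary: CallSummary) -> ChromMatrix:
    """Accumulate admitted reads of one chromosome into a fresh matrix.

    Overlapping mate pairs are buffered and accumulated together so the
    overlapped bases are counted once (higher-quality mate wins).
    """
    matrix = ChromMatrix(chrom, len(sequence))
    pending: dict[str, tuple] = {}
    for read in reads:
        summary.reads_total += 1
        strand, fallback = infer_bisulfite_strand(read)
        if fallback:
            summary.strand_fallback += 1
        ok, reason = admit_read(read, params, chrom_sequence=sequence, strand=strand)
        if not ok:
            summary.rejected[reason] = summary.rejected.get(reason, 0) + 1
            continue
        summary.reads_admitted += 1
        mate = pending.pop(read.query_name, None)
        if mate is not None:
            accumulate_pair(matrix, mate[0], read, mate[1], params.min_base_quality)
        elif _mate_may_overlap(read):
            pending[read.query_name] = (read, strand)
        else:
            accumulate_read(matrix, read, strand, params.min_base_quality)
    for read, strand in pending.values():  # mates never arrived
        accumulate_read(matrix, read, strand, params.min_base_quality)
    return matrix


def call_chromosome(matrix: ChromMatrix, sequence: str, params: FilterParams,
                    prior: GenotypePrior, summary: CallSummary | None = None
                    ) -> list[GenotypeCall]:
    """Genotype every candidate site of one accumulated chromosome."""
    summary = summary if summary is not None else CallSummary()
    calls = []
    for pos, profile, ref_base in emit_candidates(matrix, sequence, params):
        summary.candidates += 1
        try:
            call = call_site(profile, ref_base, prior, params, position=pos)
        except DepthOutOfRange:
            summary.depth_skipped += 1
            continue
        calls.append(call)
    return calls


def corrected_sequence(sequence: str, calls) -> str:
    """Reference sequence with called genotypes substituted in.

    Homozygous-alt calls replace the base; heterozygotes keep the
    reference base when the reference allele is present, else the
    alphabetically first allele.
    """
    seq = list(sequence)
    for call in calls:
        a1, a2 = call.genotype
        if a1 == a2:
            seq[call.position] = a1
        elif seq[call.position].upper() not in call.genotype:
            seq[call.position] = a1
    return "".join(seq)


def extract_methylation(matrix: ChromMatrix, corrected: str, calls,
                        summary: CallSummary | None = None):
    """Yield methylation records for every covered cytosine of the corrected sequence.

    Each strand of a CpG is reported as its own record, from its own
    conversion-informative strand (Watson C/(C+T), Crick G/(G+A)).
    Cytosines with an undetermined context (chromosome edge) are counted
    and skipped.
    """
    by_pos = {c.position: c for c in calls}
    watson = matrix.counts[:, 0, :]
    crick = matrix.counts[:, 1, :]
    for pos in range(matrix.length):
        base = corrected[pos].upper()
        if base == "C":
            strand = "+"
            if watson[pos, 1] + watson[pos, 3] == 0:  # C + T counts
                continue
        elif base == "G":
            strand = "-"
            if crick[pos, 2] + crick[pos, 0] == 0:    # G + A counts
                continue
        else:
            continue
        call = by_pos.get(pos)
        genotype = call.genotype if call is not None else (base, base)
        context = context_of(corrected, pos, strand)
        if context is None:
            if summary is not None:
                summary.context_undetermined += 1
            continue
        rec = methylation_call(matrix.profile(pos), genotype, strand, context,
                               position=pos,
                               genotype_corrected=call is not None)
        if rec is not None:
            yield rec


def run_call(alignments, fasta, vcf_out, meth_paths: dict[str, str] | None = None,
             params: FilterParams | None = None,
             prior: GenotypePrior | None = None,
             sample: str = "SAMPLE") -> CallSummary:
    """Run the full caller over a sorted SAM/BAM and an indexed FASTA.

    ``meth_paths`` maps context name to output TSV path. Returns the run
    summary; the VCF holds variant genotypes only.
    """
    params = params or FilterParams()
    prior = prior or GenotypePrior()
    summary = CallSummary()
    variant_records = []
    meth_writer = MethylationWriter(meth_paths or {})
    with Reference(fasta) as reference:
        try:
            for chrom, header_len, reads in stream_alignments(alignments):
                missing = reference.check_names([chrom])
                if missing:
                    raise ReferenceMismatchError(
                        f"alignment sequence {missing[0]!r} absent from reference "
                        f"(reference has: {', '.join(reference.names)})")
                sequence = reference.get(chrom)
                if header_len and header_len != len(sequence):
                    raise DataError(
                        f"{chrom}: header length {header_len} != reference "
                        f"length {len(sequence)}")
                matrix = build_matrix(chrom, sequence, reads, params, summary)
                calls = call_chromosome(matrix, sequence, params, prior, summary)
                summary.calls.extend((chrom, c) for c in calls)
                variant_records.extend(
                    (chrom, c) for c in calls if c.is_variant)
                corrected = corrected_sequence(sequence, calls)
                for rec in extract_methylation(matrix, corrected, calls, summary):
                    meth_writer.write(chrom, rec)
                matrix.release()
                log.info("%s: %d candidates, %d variant calls", chrom,
                         summary.candidates,
                         sum(1 for _, c in variant_records if _ == chrom))
            contigs = {name: reference.length(name) for name in reference.names}
            summary.variants_written = write_vcf(
                vcf_out, variant_records, contigs, sample=sample)
        finally:
            meth_writer.close()
    log.info("reads: %d total, %d admitted (rejected: %s); %d candidates; "
             "%d variants written", summary.reads_total, summary.reads_admitted,
             summary.rejected or "none", summary.candidates,
             summary.variants_written)
    return summary
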