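"""Alignment streaming, reference access, and VCF / methylation-table output."""

from __future__ import annotations

import os

import pysam


class DataError(Exception):
    """Malformed or inconsistent input data (exit code 2 at the CLI)."""


class SortOrderError(DataError):
    """Alignments are not coordinate-sorted."""


class FormatError(DataError):
    """Unreadable or truncated input file."""


class ReferenceMismatchError(DataError):
    """Alignment header and reference FASTA disagree on sequence names."""


def stream_alignments(path):
    """Yield ``(chrom, length, reads)`` per chromosome from a sorted SAM/BAM.

    Reads are delivered chromosome-by-chromosome so the pileup matrix can
    be allocated and released per chromosome. Unmapped reads are skipped.
    Out-of-order positions, or a chromosome appearing twice, raise
    :class:`SortOrderError` naming the offending position.
    """
    try:
        af = pysam.AlignmentFile(str(path), "r", check_sq=False)
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot open alignments {path}: {exc}") from exc
    try:
        lengths = dict(zip(af.references, af.lengths))
        current = None
        batch: list = []
        seen: set[str] = set()
        last_pos = -1
        for read in af:
            if read.is_unmapped:
                continue
            chrom = read.reference_name
            if chrom != current:
                if current is not None:
                    yield current, lengths.get(current, 0), batch
                if chrom in seen:
                    raise SortOrderError(
                        f"unsorted input: {chrom} reappears at position "
                        f"{read.reference_start + 1} after other chromosomes")
                seen.add(chrom)
                current = chrom
                batch = []
                last_pos = -1
            if read.reference_start < last_pos:
                raise SortOrderError(
                    f"unsorted input: {chrom}:{read.reference_start + 1} "
                    f"follows {chrom}:{last_pos + 1}")
            last_pos = read.reference_start
            batch.append(read)
        if current is not None:
            yield current, lengths.get(current, 0), batch
    finally:
        af.close()


class Reference:
    """Random access to an indexed FASTA, uppercased, cached per chromosome."""

    def __init__(self, path):
        path = str(path)
        if not os.path.exists(path):
            raise FormatError(f"reference FASTA not found: {path}")
        if not os.path.exists(path + ".fai"):
            pysam.faidx(path)
        self._fasta = pysam.FastaFile(path)
        self._cache: dict[str, str] = {}

    @property
    def names(self) -> list[str]:
        return list(self._fasta.references)

    def length(self, chrom: str) -> int:
        self._require(chrom)
        return self._fasta.get_reference_length(chrom)

    def get(self, chrom: str) -> str:
        """Full chromosome sequence, uppercase (soft-masking removed)."""
        self._require(chrom)
        if chrom not in self._cache:
            self._cache[chrom] = self._fasta.fetch(chrom).upper()
        return self._cache[chrom]

    def _require(self, chrom: str) -> None:
        if chrom not in self._fasta.references:
            raise ReferenceMismatchError(
                f"chromosome {chrom!r} absent from reference; "
                f"reference has: {', '.join(self._fasta.references)}")

    def check_names(self, alignment_names) -> list[str]:
        """Alignment sequence names missing from the reference."""
        return [n for n in alignment_names if n not in self._fasta.references]

    def close(self) -> None:
        self._fasta.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def _vcf_header(contigs: dict[str, int], sample: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line("##source=bsvar")
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("DP", 1, "Integer", "Retained read depth")
    header.info.add("ADF", "R", "Integer", "Watson-strand (forward) read count per allele")
    header.info.add("ADR", "R", "Integer", "Crick-strand (reverse) read count per allele")
    header.info.add("AF", "A", "Float", "Bisulfite-effective alt allele frequency")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Retained read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality (phred)")
    header.filters.add("LowQual", None, None, "Genotype quality below cutoff")
    header.filters.add("LowFreq", None, None,
                       "Homozygous-alt call with alt frequency below the homozygous threshold")
    header.add_sample(sample)
    return header


def write_vcf(path, calls, contigs: dict[str, int], sample: str = "SAMPLE") -> int:
    """Write variant genotype calls as VCF 4.2.

    ``calls`` is an iterable of ``(chrom, GenotypeCall)`` sorted by
    (chrom, position); homozygous-reference calls are skipped. Returns the
    number of records written. Per-strand allele depths go to ADF/ADR so
    standard tooling can read depth by strand.
    """
    n = 0
    with pysam.VariantFile(str(path), "w", header=_vcf_header(contigs, sample)) as vf:
        for chrom, call in calls:
            alts = [a for a in dict.fromkeys(call.genotype) if a != call.ref_base]
            if not alts:
                continue
            alleles = (call.ref_base, *alts)
            rec = vf.new_record(
                contig=chrom, start=call.position, alleles=alleles,
                qual=float(call.phred_quality))
            rec.filter.add(call.filter)
            profile = call.profile
            eff = call.effective
            rec.info["DP"] = call.depth
            if profile is not None:
                from .bisulfite import BASE_INDEX
                rec.info["ADF"] = tuple(int(profile.watson_count[BASE_INDEX[a]])
                                        for a in alleles)
                rec.info["ADR"] = tuple(int(profile.crick_count[BASE_INDEX[a]])
                                        for a in alleles)
            if eff is not None and eff.eff_depth > 0:
                rec.info["AF"] = tuple(eff.count(a) / eff.eff_depth for a in alts)
            gt = tuple(sorted(alleles.index(a) for a in call.genotype))
            rec.samples[sample]["GT"] = gt
            rec.samples[sample]["DP"] = call.depth
            rec.samples[sample]["GQ"] = call.phred_quality
            vf.write(rec)
            n += 1
    return n


def read_vcf_genotypes(path) -> list[tuple[str, int, str, tuple[str, ...], tuple[str, str], str]]:
    """Parse a VCF into ``(chrom, pos0, ref, alts, genotype, filter)`` tuples."""
    out = []
    with pysam.VariantFile(str(path)) as vf:
        sample = list(vf.header.samples)[0] if list(vf.header.samples) else None
        for rec in vf:
            alleles = (rec.ref, *(rec.alts or ()))
            if sample is not None:
                gt_idx = rec.samples[sample]["GT"]
                genotype = tuple(sorted(alleles[i] for i in gt_idx))
            else:
                genotype = tuple(sorted((rec.ref, (rec.alts or (rec.ref,))[0])))
            flt = ";".join(rec.filter.keys()) or "PASS"
            out.append((rec.chrom, rec.start, rec.ref, tuple(rec.alts or ()),
                        genotype, flt))
    return out


METH_COLUMNS = ("chrom", "pos", "strand", "context", "methylated", "total", "level")


class MethylationWriter:
    """Per-context methylation tables (TSV, 1-based positions).

    ``paths`` maps context ("CpG"/"CHG"/"CHH") to an output file; contexts
    without a path are silently dropped.
    """

    def __init__(self, paths: dict[str, str]):
        self._handles = {}
        self.counts = {ctx: 0 for ctx in paths}
        for ctx, path in paths.items():
            self._handles[ctx] = open(path, "w")
            self._handles[ctx].write("#" + "\t".join(METH_COLUMNS) + "\n")

    def write(self, chrom: str, rec) -> None:
        handle = self._handles.get(rec.context)
        if handle is None or rec.level is None:
            return
        handle.write(
            f"{chrom}\t{rec.position + 1}\t{rec.strand}\t{rec.context}\t"
            f"{rec.methylated}\t{rec.total}\t{rec.level:.4f}\n")
        self.counts[rec.context] += 1

    def close(self) -> None:
        for h in self._handles.values():
            h.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def read_methylation(path) -> list[tuple[str, int, str, str, int, int, float]]:
    """Parse a methylation TSV back into tuples (positions back to 0-based)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, strand, ctx, meth, total, level = line.rstrip("\n").split("\t")
            out.append((chrom, int(pos) - 1, strand, ctx, int(meth), int(total),
                        float(level)))
    return out
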