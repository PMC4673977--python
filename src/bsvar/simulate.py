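"""Bisulfite read simulator with known genotypes and methylation levels.

Generates a random diploid sample on a random reference, draws single-end
reads from both haplotypes and both bisulfite strands, applies per-cytosine
bisulfite conversion (a sample C on the read's strand of origin survives
with probability equal to its methylation level, otherwise converts to T
with the conversion rate) and uniform sequencing error, and writes a
coordinate-sorted SAM carrying the bisulfite strand tag together with the
ground-truth SNPs and methylation levels. Everything is driven by one
seeded generator, so a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pysam

from .bisulfite import BASES, BASE_INDEX, context_of
from .io import DataError, read_vcf_genotypes

CHROM = "sim1"

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}


@dataclass
class SimParams:
    """Study conditions for the synthetic bisulfite experiment.

    Defaults emulate a desk-scale RRBS-like evaluation: a 10 kb genome at
    20× mean coverage, SNPs at 1 per kb (half heterozygous, transitions
    twice as likely as transversions), CpG methylation high and non-CpG
    methylation low as in mammalian somatic tissue, 99% bisulfite
    conversion, and a 1% uniform sequencing error rate with matching
    constant Phred qualities.
    """

    genome_length: int = 10_000
    snp_rate: float = 0.001
    het_fraction: float = 0.5
    methylation_by_context: dict = field(
        default_factory=lambda: {"CpG": 0.8, "CHG": 0.05, "CHH": 0.02})
    conversion_rate: float = 0.99
    depth: float = 20.0
    read_length: int = 100
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        for name in ("snp_rate", "het_fraction", "conversion_rate", "error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.genome_length < self.read_length:
            raise ValueError("genome_length must be >= read_length")

    @property
    def phred_quality(self) -> int:
        if self.error_rate <= 0:
            return 60
        return int(round(-10.0 * math.log10(self.error_rate)))


@dataclass
class TruthSet:
    """Planted ground truth: SNPs and per-cytosine methylation levels."""

    snps: list  # (position, ref_base, genotype tuple)
    methylation: list  # (position, strand, context, level)

    def snp_dict(self) -> dict[int, tuple[str, str]]:
        return {pos: gt for pos, _ref, gt in self.snps}

    def write_vcf(self, path, genome_length: int) -> None:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={CHROM},length={genome_length}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTRUTH\n")
            for pos, ref, gt in self.snps:
                alts = [a for a in dict.fromkeys(gt) if a != ref]
                alleles = [ref, *alts]
                gt_str = "/".join(str(alleles.index(a)) for a in gt)
                fh.write(f"{CHROM}\t{pos + 1}\t.\t{ref}\t{','.join(alts)}\t.\t"
                         f"PASS\t.\tGT\t{gt_str}\n")

    def write_methylation(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tpos\tstrand\tcontext\tlevel\n")
            for pos, strand, ctx, level in self.methylation:
                fh.write(f"{CHROM}\t{pos + 1}\t{strand}\t{ctx}\t{level:.4f}\n")


def _nearest_base(reference: str, base: str, near: int, exclude=()) -> int:
    """Position of the reference ``base`` closest to ``near`` (ties toward lower)."""
    excluded = set(exclude)
    best = None
    for pos, b in enumerate(reference):
        if b == base and pos not in excluded:
            if best is None or abs(pos - near) < abs(best - near):
                best = pos
    if best is None:
        raise ValueError(f"no {base} available in reference")
    return best


def _plant_snp(rng: np.random.Generator, ref_base: str, het_fraction: float):
    """Pick alt allele (ts:tv = 2) and zygosity for one SNP."""
    if rng.random() < 2.0 / 3.0:
        alt = _TRANSITION[ref_base]
    else:
        alt = _TRANSVERSIONS[ref_base][rng.integers(2)]
    het = rng.random() < het_fraction
    return alt, het


def simulate_genome(params: SimParams, rng: np.random.Generator | None = None,
                    extra_snps=None):
    """Random reference + diploid haplotypes + truth.

    ``extra_snps`` optionally forces specific variants, either as
    ``(position, alt_base, "hom"|"het")`` or as a mapping
    ``{"ref": "C", "alt": "T", "zygosity": "hom", "near": 5000}`` which is
    resolved to the reference base of that kind closest to ``near`` (not
    already a SNP). Positions there override any randomly planted SNP.
    Returns ``(reference, hap1, hap2, truth)``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    L = params.genome_length
    ref_idx = rng.integers(0, 4, size=L)
    reference = "".join(BASES[i] for i in ref_idx)
    hap1 = list(reference)
    hap2 = list(reference)

    planned: dict[int, tuple[str, bool]] = {}
    snp_mask = rng.random(L) < params.snp_rate
    for pos in np.nonzero(snp_mask)[0]:
        alt, het = _plant_snp(rng, reference[pos], params.het_fraction)
        planned[int(pos)] = (alt, het)
    for entry in (extra_snps or ()):
        if isinstance(entry, dict):
            pos = _nearest_base(reference, entry["ref"], entry["near"],
                                exclude=planned.keys())
            alt, zygosity = entry["alt"], entry["zygosity"]
        else:
            pos, alt, zygosity = entry
        if reference[pos] == alt:
            raise ValueError(f"planted allele equals reference at {pos}")
        planned[int(pos)] = (alt, zygosity == "het")

    snps = []
    for pos in sorted(planned):
        alt, het = planned[pos]
        ref_base = reference[pos]
        if het:
            which = rng.integers(2)
            (hap1 if which == 0 else hap2)[pos] = alt
            genotype = tuple(sorted((ref_base, alt)))
        else:
            hap1[pos] = alt
            hap2[pos] = alt
            genotype = (alt, alt)
        snps.append((pos, ref_base, genotype))

    hap1 = "".join(hap1)
    hap2 = "".join(hap2)
    truth_meth = _methylation_truth(hap1, hap2, params)
    return reference, hap1, hap2, TruthSet(snps=snps, methylation=truth_meth)


def _context_or_chh(seq: str, pos: int, strand: str) -> str:
    # cytosines within 2 bp of the chromosome end default to CHH
    return context_of(seq, pos, strand) or "CHH"


def _methylation_truth(hap1: str, hap2: str, params: SimParams) -> list:
    """One level per (position, strand) over the union of sample cytosines.

    Levels are deterministic per context; where the haplotypes disagree on
    context (only possible next to a SNP) haplotype 1 takes precedence.
    """
    levels = params.methylation_by_context
    out = []
    L = len(hap1)
    for pos in range(L):
        for strand, base in (("+", "C"), ("-", "G")):
            if hap1[pos] == base:
                ctx = _context_or_chh(hap1, pos, strand)
            elif hap2[pos] == base:
                ctx = _context_or_chh(hap2, pos, strand)
            else:
                continue
            out.append((pos, strand, ctx, levels[ctx]))
    return out


def _level_arrays(hap: str, params: SimParams):
    """Per-position methylation level for this haplotype's C (+) and G (−) sites."""
    levels = params.methylation_by_context
    L = len(hap)
    plus = np.zeros(L)
    minus = np.zeros(L)
    for pos in range(L):
        if hap[pos] == "C":
            plus[pos] = levels[_context_or_chh(hap, pos, "+")]
        elif hap[pos] == "G":
            minus[pos] = levels[_context_or_chh(hap, pos, "-")]
    return plus, minus


def simulate_reads(hap1: str, hap2: str, params: SimParams, sam_path,
                   rng: np.random.Generator | None = None) -> int:
    """Draw reads, apply conversion and error, write a sorted tagged SAM.

    Returns the number of reads written. Reads are single-end, full-match
    CIGAR, MAPQ 60, constant base quality matching ``error_rate``, with a
    BSMAP-style ``ZS`` strand tag ("++" Watson, "--" Crick).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    L = params.genome_length
    rl = params.read_length
    # fragment starts range over [-rl+1, L-1] and reads are clipped to the
    # chromosome, so mean coverage is uniform (no ramp at the ends)
    n_starts = L + rl - 1
    n_reads = int(round(params.depth * n_starts / rl))
    haps = [np.frombuffer(h.encode(), dtype=np.uint8) for h in (hap1, hap2)]
    code = np.full(256, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        code[ord(b)] = i
    hap_codes = [code[h].astype(np.int64) for h in haps]
    level_plus, level_minus = zip(*(_level_arrays(h, params) for h in (hap1, hap2)))

    frag_starts = rng.integers(-rl + 1, L, size=n_reads)
    which_hap = rng.integers(0, 2, size=n_reads)
    which_strand = rng.integers(0, 2, size=n_reads)  # 0 Watson, 1 Crick

    c_idx, g_idx, t_idx, a_idx = (BASE_INDEX[b] for b in "CGTA")
    reads = []
    for i in range(n_reads):
        start = max(0, int(frag_starts[i]))
        end = min(L, int(frag_starts[i]) + rl)
        if end - start < 20:    # too short to map credibly
            continue
        h = int(which_hap[i])
        crick = bool(which_strand[i])
        window = hap_codes[h][start:end].copy()
        if crick:
            sites = np.nonzero(window == g_idx)[0]
            lev = level_minus[h][start + sites]
            converted_base = a_idx
        else:
            sites = np.nonzero(window == c_idx)[0]
            lev = level_plus[h][start + sites]
            converted_base = t_idx
        if sites.size:
            methylated = rng.random(sites.size) < lev
            unmeth = sites[~methylated]
            if unmeth.size:
                converts = rng.random(unmeth.size) < params.conversion_rate
                window[unmeth[converts]] = converted_base
        if params.error_rate > 0:
            err_mask = rng.random(window.size) < params.error_rate
            k = int(err_mask.sum())
            if k:
                shift = rng.integers(1, 4, size=k)
                window[err_mask] = (window[err_mask] + shift) % 4
        seq = "".join(BASES[b] for b in window)
        reads.append((start, crick, i, seq))

    reads.sort(key=lambda r: (r[0], r[2]))
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": CHROM, "LN": L}]}
    qual = params.phred_quality
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        for start, crick, idx, seq in reads:
            a = pysam.AlignedSegment(header=out.header)
            a.query_name = f"sim_read_{idx}"
            a.flag = 16 if crick else 0
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = 60
            a.cigartuples = [(0, len(seq))]
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array(chr(qual + 33) * len(seq))
            a.set_tag("ZS", "--" if crick else "++")
            out.write(a)
    return len(reads)


def write_fasta(path, name: str, sequence: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i:i + width] + "\n")


def simulate(params: SimParams, out_prefix: str, extra_snps=None):
    """Full fixture: ref FASTA, sorted tagged SAM, truth VCF and truth methylation.

    Returns ``(reference, hap1, hap2, truth, paths)``.
    """
    rng = np.random.default_rng(params.seed)
    reference, hap1, hap2, truth = simulate_genome(params, rng=rng,
                                                   extra_snps=extra_snps)
    paths = {
        "fasta": f"{out_prefix}.ref.fa",
        "sam": f"{out_prefix}.reads.sam",
        "truth_vcf": f"{out_prefix}.truth.vcf",
        "truth_meth": f"{out_prefix}.truth.meth.tsv",
    }
    write_fasta(paths["fasta"], CHROM, reference)
    simulate_reads(hap1, hap2, params, paths["sam"], rng=rng)
    truth.write_vcf(paths["truth_vcf"], params.genome_length)
    truth.write_methylation(paths["truth_meth"])
    return reference, hap1, hap2, truth, paths


@dataclass
class EvalSummary:
    """Confusion summary of called SNPs against planted truth."""

    tp: int
    fp: int
    fn: int
    concordant: int
    n_called: int
    n_truth: int

    @property
    def fpr(self) -> float:
        """Fraction of called SNPs absent from truth (validation-style FPR)."""
        return self.fp / self.n_called if self.n_called else 0.0

    @property
    def fnr(self) -> float:
        return self.fn / self.n_truth if self.n_truth else 0.0

    @property
    def concordance(self) -> float:
        """Genotype agreement over positions present in both call set and truth."""
        return self.concordant / self.tp if self.tp else 1.0


def evaluate_calls(vcf_path, truth: TruthSet, genome_name: str = CHROM,
                   pass_only: bool = True) -> EvalSummary:
    """Compare a called VCF against the planted truth set.

    The final SNP set is the PASS records; set ``pass_only=False`` to
    include filtered (LowQual/LowFreq) records as calls.
    """
    truth_gt = truth.snp_dict()
    called: dict[int, tuple[str, str]] = {}
    for chrom, pos0, _ref, _alts, genotype, flt in read_vcf_genotypes(vcf_path):
        if chrom != genome_name:
            raise DataError(
                f"VCF chromosome {chrom!r} does not match truth genome {genome_name!r}")
        if pass_only and flt != "PASS":
            continue
        called[pos0] = genotype
    tp = sum(1 for p in called if p in truth_gt)
    fp = len(called) - tp
    fn = sum(1 for p in truth_gt if p not in called)
    concordant = sum(1 for p, gt in called.items() if truth_gt.get(p) == gt)
    return EvalSummary(tp=tp, fp=fp, fn=fn, concordant=concordant,
                       n_called=len(called), n_truth=len(truth_gt))
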