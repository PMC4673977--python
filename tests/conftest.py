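"""Shared fixtures: hand-built SAM files and session-scoped simulations."""

import pysam
import pytest

from bsvar.filters import FilterParams
from bsvar.genotyper import GenotypePrior
from bsvar.pipeline import run_call
from bsvar.simulate import SimParams, simulate

#: seed used for the simulation-based acceptance checks
ACCEPTANCE_SEED = 11


def make_sam(path, reads, chrom="chr1", length=1000, extra_sq=None):
    """Write a SAM file from simple read tuples.

    Each read is ``(qname, flag, pos0, mapq, cigar, seq, qual_string, tags)``
    where ``tags`` is a dict; ``None`` entries for qual default to Q30.
    ``extra_sq`` adds more reference sequences as ``{name: length}``.
    """
    sq = [{"SN": chrom, "LN": length}]
    for name, ln in (extra_sq or {}).items():
        sq.append({"SN": name, "LN": ln})
    header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": sq}
    refs = [d["SN"] for d in sq]
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for qname, flag, pos, mapq, cigar, seq, qual, tags in reads:
            tags = dict(tags or {})
            a = pysam.AlignedSegment(header=out.header)
            a.query_name = qname
            a.flag = flag
            a.reference_id = refs.index(tags.pop("_chrom", chrom))
            a.reference_start = pos
            a.mapping_quality = mapq
            a.cigarstring = cigar
            a.query_sequence = seq
            qual = qual if qual is not None else "?" * len(seq)  # '?' = Q30
            a.query_qualities = pysam.qualitystring_to_array(qual)
            for key, value in (tags or {}).items():
                a.set_tag(key, value)
            out.write(a)
    return str(path)


def write_fasta(path, sequences: dict):
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")
    return str(path)


@pytest.fixture()
def default_params():
    return FilterParams()


@pytest.fixture()
def default_prior():
    return GenotypePrior()


class SimRun:
    """A simulation plus a full calling run over it."""

    def __init__(self, tmp_path, params, extra_snps=None):
        self.params = params
        (self.reference, self.hap1, self.hap2, self.truth,
         self.paths) = simulate(params, str(tmp_path / "sim"), extra_snps=extra_snps)
        self.vcf = str(tmp_path / "calls.vcf")
        self.meth = {ctx: str(tmp_path / f"meth_{ctx}.tsv")
                     for ctx in ("CpG", "CHG", "CHH")}
        self.summary = run_call(self.paths["sam"], self.paths["fasta"],
                                self.vcf, self.meth)


@pytest.fixture(scope="session")
def sim_with_snps(tmp_path_factory):
    """Default study conditions (10 kb, 20x, 1% error, 99% conversion,
    snp_rate 0.001) plus one guaranteed homozygous C→T SNP mid-genome."""
    tmp = tmp_path_factory.mktemp("sim_snps")
    params = SimParams(seed=ACCEPTANCE_SEED)
    planted = [{"ref": "C", "alt": "T", "zygosity": "hom", "near": 5000}]
    return SimRun(tmp, params, extra_snps=planted)


@pytest.fixture(scope="session")
def sim_no_snps(tmp_path_factory):
    """Same conditions without SNPs: every variant-like signal is
    conversion or sequencing error."""
    tmp = tmp_path_factory.mktemp("sim_nosnp")
    params = SimParams(seed=ACCEPTANCE_SEED, snp_rate=0.0)
    return SimRun(tmp, params)
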