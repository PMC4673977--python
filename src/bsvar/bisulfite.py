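"""Strand-aware interpretation of bisulfite base observations.

Bisulfite treatment converts unmethylated cytosines to uracil, read as T.
In SAM forward coordinates this means a Watson-strand read may legitimately
show T at a C position (converted, unmethylated C), and a Crick-strand read
may show A at a G position. Treating such observations as ordinary mismatch
evidence would flood a variant caller with spurious C→T and G→A calls, so
the two strands have to be interpreted independently:

* a Watson-strand T is ambiguous between genomic T and converted C and is
  excluded from the unambiguous ("effective") support of both alleles;
* a Crick-strand A is symmetrically ambiguous between genomic A and the
  converted complement of G.

Consequently C-versus-T discrimination rests on Crick reads (which are
unaffected by Watson-strand conversion) and A-versus-G discrimination rests
on Watson reads. Methylation level at a cytosine is the conversion-protected
fraction on the informative strand: ``C/(C+T)`` over Watson reads for a
Watson-strand cytosine, ``G/(G+A)`` over Crick reads for a Crick-strand
cytosine (forward coordinates throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: strand codes used for the pileup axis
WATSON = 0
CRICK = 1

_A, _C, _G, _T = 0, 1, 2, 3

#: methylation context labels
CONTEXTS = ("CpG", "CHG", "CHH")


@dataclass
class EffectiveCounts:
    """Bisulfite-disambiguated support at one position.

    ``eff`` holds, per base A/C/G/T (forward orientation), the number of
    observations that unambiguously support that base. Watson-strand T and
    Crick-strand A observations are counted separately as ambiguous.
    """

    eff: np.ndarray = field(default_factory=lambda: np.zeros(4))
    ambiguous_watson_t: int = 0
    ambiguous_crick_a: int = 0

    @property
    def eff_depth(self) -> float:
        return float(self.eff.sum())

    @property
    def total(self) -> float:
        return self.eff_depth + self.ambiguous_watson_t + self.ambiguous_crick_a

    def count(self, base: str) -> float:
        return float(self.eff[BASE_INDEX[base]])


def effective_counts(profile) -> EffectiveCounts:
    """Split a strand-separated base profile into unambiguous and ambiguous support.

    Parameters
    ----------
    profile : StrandBaseProfile
        Per-strand counts at one reference position (forward orientation).
    """
    w = profile.watson_count
    c = profile.crick_count
    eff = np.zeros(4)
    eff[_A] = w[_A]                 # Crick A is ambiguous (G vs A)
    eff[_C] = w[_C] + c[_C]
    eff[_G] = w[_G] + c[_G]
    eff[_T] = c[_T]                 # Watson T is ambiguous (C vs T)
    return EffectiveCounts(
        eff=eff,
        ambiguous_watson_t=int(w[_T]),
        ambiguous_crick_a=int(c[_A]),
    )


def context_of(sequence: str, position: int, strand: str = "+") -> str | None:
    """Methylation context (CpG/CHG/CHH) of a cytosine in ``sequence``.

    ``sequence`` should be the genotype-corrected chromosome sequence in
    forward orientation. For ``strand == "-"`` the cytosine lives on the
    Crick strand at a forward-G position and the context is read 5'→3' on
    the Crick strand, i.e. from forward positions ``position-1`` and
    ``position-2`` complemented.

    Returns ``None`` when the context is undetermined (within 2 bp of the
    chromosome end, or an N in the window).
    """
    if strand == "+":
        n1 = sequence[position + 1] if position + 1 < len(sequence) else None
        n2 = sequence[position + 2] if position + 2 < len(sequence) else None
    elif strand == "-":
        n1 = (COMPLEMENT.get(sequence[position - 1], "N")
              if position - 1 >= 0 else None)
        n2 = (COMPLEMENT.get(sequence[position - 2], "N")
              if position - 2 >= 0 else None)
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if n1 is None or n1 == "N":
        return None
    if n1 == "G":
        return "CpG"          # determined by the first neighbour alone
    if n2 is None or n2 == "N":
        return None
    if n2 == "G":
        return "CHG"
    return "CHH"


@dataclass
class MethylationCall:
    """Methylation level at one cytosine, on one strand."""

    position: int               # 0-based forward coordinate
    strand: str                 # '+' Watson cytosine, '-' Crick cytosine
    context: str | None         # CpG/CHG/CHH, None if undetermined
    methylated: int
    total: int
    level: float | None         # None when total == 0
    genotype_corrected: bool = False


def methylation_call(profile, genotype: tuple[str, str], strand: str,
                     context: str | None,
                     position: int = 0,
                     genotype_corrected: bool = False) -> MethylationCall | None:
    """Genotype-aware methylation level at one position.

    Returns ``None`` when the called genotype removes the cytosine from the
    strand under consideration (e.g. a C→T homozygote has no cytosine left
    to be methylated). With zero informative depth a no-call record
    (``level is None``) is returned.
    """
    if strand == "+":
        if "C" not in genotype:
            return None
        meth = int(profile.watson_count[_C])
        unmeth = int(profile.watson_count[_T])
    elif strand == "-":
        if "G" not in genotype:
            return None
        meth = int(profile.crick_count[_G])
        unmeth = int(profile.crick_count[_A])
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    total = meth + unmeth
    level = meth / total if total > 0 else None
    return MethylationCall(
        position=position, strand=strand, context=context,
        methylated=meth, total=total, level=level,
        genotype_corrected=genotype_corrected,
    )
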