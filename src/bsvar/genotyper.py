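"""Approximate Bayesian diploid genotyping at candidate sites.

For each candidate position the posterior P(G|D) over the ten unordered
diploid genotypes is computed as prior × product likelihood, normalized.
The likelihood uses a single per-site average sequencing error rate (the
mean Phred-implied error over the retained observations) instead of a full
per-read error model, and treats bisulfite-ambiguous observations
(Watson-strand T, Crick-strand A) with an equal-split emission over the
two bases they could represent. The genotype with the largest posterior is
the call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bisulfite import BASES, EffectiveCounts, effective_counts
from .filters import FilterParams

#: the ten unordered diploid genotypes, alphabetical
GENOTYPES: tuple[tuple[str, str], ...] = tuple(
    (BASES[i], BASES[j]) for i in range(4) for j in range(i, 4)
)

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: clamp bounds for the average error rate
MIN_ERROR = 1e-4
MAX_ERROR = 0.5

#: Phred quality cap on emitted calls
QUAL_CAP = 1000
LOWQUAL_CUTOFF = 10


class DepthOutOfRange(ValueError):
    """Raised when a site's retained depth falls outside [min_cover, max_cover]."""


@dataclass
class GenotypePrior:
    """SOAPsnp-style prior over diploid genotypes.

    ``ref_hom``/``het_with_ref``/``non_ref_hom`` are unnormalized weights
    for the homozygous-reference genotype, each heterozygote containing
    the reference allele, and each non-reference homozygote; genotypes
    containing no reference allele get ``het_with_ref × non_ref_hom``.
    Genotypes containing the transition partner of the reference are
    additionally weighted by ``ts_tv_weight`` before normalization, since
    transitions outnumber transversions in real genomes.
    """

    ref_hom: float = 0.9985
    het_with_ref: float = 0.001
    non_ref_hom: float = 0.0005
    ts_tv_weight: float = 4.0

    def probabilities(self, ref_base: str) -> np.ndarray:
        """Normalized prior over ``GENOTYPES`` for the given reference base."""
        ts = _TRANSITION[ref_base]
        weights = np.empty(len(GENOTYPES))
        for k, (a1, a2) in enumerate(GENOTYPES):
            if a1 == ref_base and a2 == ref_base:
                w = self.ref_hom
            elif ref_base in (a1, a2):
                w = self.het_with_ref
            elif a1 == a2:
                w = self.non_ref_hom
            else:
                w = self.het_with_ref * self.non_ref_hom
            if ts in (a1, a2):
                w *= self.ts_tv_weight
            weights[k] = w
        return weights / weights.sum()


@dataclass
class GenotypeCall:
    """A called diploid genotype at one position."""

    position: int                    # 0-based
    ref_base: str
    genotype: tuple[str, str]        # unordered, alphabetical
    posterior: float
    phred_quality: int
    depth: int                       # retained reads at the site
    filter: str                      # PASS | LowQual | LowFreq
    effective: EffectiveCounts | None = None
    profile: object | None = None    # StrandBaseProfile backing the call

    @property
    def is_variant(self) -> bool:
        return self.genotype != (self.ref_base, self.ref_base)


def average_error_rate(profile) -> float:
    """Mean Phred-implied error probability over the retained observations.

    Computed per (strand, base) class from the stored quality sums:
    each class contributes ``count × 10^(−(qual_sum/count)/10)``. The
    result is clamped to [1e-4, 0.5].
    """
    counts = np.stack([profile.watson_count, profile.crick_count]).ravel()
    quals = np.stack([profile.watson_qual_sum, profile.crick_qual_sum]).ravel()
    total = counts.sum()
    if total == 0:
        raise ValueError("average error rate undefined at zero depth")
    nz = counts > 0
    mean_q = quals[nz] / counts[nz]
    err = float((counts[nz] * np.power(10.0, -mean_q / 10.0)).sum() / total)
    return min(max(err, MIN_ERROR), MAX_ERROR)


def _emission(base: str, allele: str, err: float) -> float:
    return 1.0 - err if base == allele else err / 3.0


def log_likelihood(effective: EffectiveCounts, genotype: tuple[str, str],
                   err: float) -> float:
    """log P(D|G) under the average-error product model.

    Each unambiguous observation of base b contributes
    ½·p(b|a1) + ½·p(b|a2) with p(b|a) = 1−err if b=a else err/3. A
    bisulfite-ambiguous observation splits its emission equally over the
    two bases it could represent (Watson T over C/T, Crick A over A/G).
    """
    a1, a2 = genotype
    ll = 0.0
    for i, b in enumerate(BASES):
        n = effective.eff[i]
        if n > 0:
            p = 0.5 * (_emission(b, a1, err) + _emission(b, a2, err))
            ll += n * math.log(p)
    if effective.ambiguous_watson_t:
        p = 0.5 * sum(0.5 * (_emission("T", a, err) + _emission("C", a, err))
                      for a in (a1, a2))
        ll += effective.ambiguous_watson_t * math.log(p)
    if effective.ambiguous_crick_a:
        p = 0.5 * sum(0.5 * (_emission("A", a, err) + _emission("G", a, err))
                      for a in (a1, a2))
        ll += effective.ambiguous_crick_a * math.log(p)
    return ll


def likelihood(effective: EffectiveCounts, genotype: tuple[str, str],
               err: float) -> float:
    """P(D|G); the empty product is 1."""
    return math.exp(log_likelihood(effective, genotype, err))


def posterior(effective: EffectiveCounts, ref_base: str, prior: GenotypePrior,
              err: float) -> np.ndarray:
    """Posterior P(G|D) over ``GENOTYPES``, normalized in log space."""
    log_p = np.log(prior.probabilities(ref_base))
    for k, g in enumerate(GENOTYPES):
        log_p[k] += log_likelihood(effective, g, err)
    log_p -= log_p.max()
    p = np.exp(log_p)
    return p / p.sum()


def _select_genotype(post: np.ndarray, ref_base: str) -> tuple[int, float]:
    """Argmax with ties broken toward the reference allele, then alphabetically."""
    best = float(post.max())
    tied = [k for k in range(len(GENOTYPES))
            if post[k] >= best - 1e-12 * max(best, 1.0)]
    tied.sort(key=lambda k: (ref_base not in GENOTYPES[k], GENOTYPES[k]))
    k = tied[0]
    return k, float(post[k])


def call_site(profile, ref_base: str, prior: GenotypePrior,
              params: FilterParams, position: int = 0) -> GenotypeCall:
    """Call the maximum-posterior genotype at one candidate site."""
    depth = profile.total
    if depth < params.min_cover or depth > params.max_cover:
        raise DepthOutOfRange(
            f"depth {depth} outside [{params.min_cover}, {params.max_cover}] "
            f"at position {position}")
    err = average_error_rate(profile)
    eff = effective_counts(profile)
    post = posterior(eff, ref_base, prior, err)
    k, p = _select_genotype(post, ref_base)
    genotype = GENOTYPES[k]
    if p >= 1.0:
        phred = QUAL_CAP
    else:
        phred = min(QUAL_CAP, int(round(-10.0 * math.log10(1.0 - p))))
    flt = "PASS"
    if phred < LOWQUAL_CUTOFF or eff.eff_depth == 0:
        flt = "LowQual"
    else:
        a1, a2 = genotype
        if a1 == a2 and a1 != ref_base and eff.eff_depth > 0:
            alt_freq = eff.count(a1) / eff.eff_depth
            if params.min_het_freq <= alt_freq < params.min_hom_freq:
                flt = "LowFreq"
    return GenotypeCall(
        position=position, ref_base=ref_base, genotype=genotype,
        posterior=p, phred_quality=phred, depth=depth, filter=flt,
        effective=eff, profile=profile,
    )
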