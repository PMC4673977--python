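"""Independent brute-force genotyping oracle.

Recomputes prior × product-likelihood over all ten diploid genotypes with
plain per-observation arithmetic (no log space, no vectorization, no reuse
of the package's likelihood code), for cross-checking the production
genotyper. Input is the raw strand-separated counts with one quality per
(strand, base) class.
"""

import math

BASES = "ACGT"
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
GENOTYPES = [a + b for i, a in enumerate(BASES) for b in BASES[i:]]


def oracle_error_rate(watson, crick):
    """Mean of per-observation Phred-implied error rates, clamped to [1e-4, 0.5]."""
    total = 0
    acc = 0.0
    for counts in (watson, crick):
        for base, (n, q) in counts.items():
            total += n
            acc += n * 10.0 ** (-q / 10.0)
    if total == 0:
        raise ValueError("no observations")
    return min(max(acc / total, 1e-4), 0.5)


def oracle_posteriors(watson, crick, ref_base, err=None,
                      ref_hom=0.9985, het_with_ref=0.001, non_ref_hom=0.0005,
                      ts_tv_weight=4.0):
    """Posterior over the 10 genotypes by direct enumeration.

    ``watson``/``crick`` map base -> (count, phred_quality) in SAM forward
    orientation. Watson T observations emit as "C or T" (half-half),
    Crick A observations as "A or G"; every other observation emits its
    own base. Returns ``{genotype_string: posterior}``.
    """
    if err is None:
        err = oracle_error_rate(watson, crick)

    def p_base(obs, allele):
        return 1.0 - err if obs == allele else err / 3.0

    def p_obs(kind, allele):
        # kind: a concrete base, or ("split", b1, b2) for ambiguous reads
        if isinstance(kind, tuple):
            return 0.5 * p_base(kind[1], allele) + 0.5 * p_base(kind[2], allele)
        return p_base(kind, allele)

    observations = []
    for base, (n, _q) in watson.items():
        kind = ("split", "C", "T") if base == "T" else base
        observations.extend([kind] * n)
    for base, (n, _q) in crick.items():
        kind = ("split", "A", "G") if base == "A" else base
        observations.extend([kind] * n)

    ts = TRANSITION[ref_base]
    unnorm = {}
    for g in GENOTYPES:
        a1, a2 = g[0], g[1]
        if g == ref_base + ref_base:
            prior = ref_hom
        elif ref_base in g:
            prior = het_with_ref
        elif a1 == a2:
            prior = non_ref_hom
        else:
            prior = het_with_ref * non_ref_hom
        if ts in g:
            prior *= ts_tv_weight
        log_value = math.log(prior)
        for obs in observations:
            log_value += math.log(0.5 * p_obs(obs, a1) + 0.5 * p_obs(obs, a2))
        unnorm[g] = log_value
    peak = max(unnorm.values())
    expd = {g: math.exp(v - peak) for g, v in unnorm.items()}
    z = sum(expd.values())
    return {g: v / z for g, v in expd.items()}


def oracle_best_genotype(posteriors, ref_base):
    """Argmax with ties toward genotypes containing the reference, then alphabetical."""
    best = max(posteriors.values())
    tied = [g for g, p in posteriors.items() if p >= best - 1e-12 * max(best, 1.0)]
    tied.sort(key=lambda g: (ref_base not in g, g))
    return tied[0]
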