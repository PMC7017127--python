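"""Independent reference implementations used only to check the package.

These deliberately avoid the package's own code paths: the somatic-label
oracle enumerates posteriors with 60-digit `decimal` arithmetic, and the
change-point oracle is an exhaustive two-segment scan.
"""

from decimal import Decimal, getcontext

import numpy as np

getcontext().prec = 60

_TEN = Decimal(10)


def decimal_posteriors(gl):
    ws = [_TEN ** Decimal(repr(g)) for g in gl]
    total = sum(ws)
    return [w / total for w in ws]


def _phred(p_error: Decimal) -> Decimal:
    cap = Decimal(200)
    if p_error <= 0:
        return cap
    val = Decimal(-10) * (p_error.ln() / _TEN.ln())
    return min(val, cap)


def label_site_oracle(site, thresholds):
    """Arbitrary-precision re-derivation of the full labelling decision
    (site filter + shared-low-frequency rule + evidence rule)."""
    t, n = site.tumor, site.normal
    if t.dp == 0 and n.dp == 0:
        return "failed_site_filter"
    if max(t.ad[1], n.ad[1]) < thresholds.min_alt_reads:
        return "failed_site_filter"
    af_t = Decimal(t.ad[1]) / Decimal(t.dp) if t.dp else Decimal(0)
    af_n = Decimal(n.ad[1]) / Decimal(n.dp) if n.dp else Decimal(0)
    if max(af_t, af_n) < Decimal(repr(thresholds.min_af)):
        return "failed_site_filter"
    if not Decimal(repr(site.qual)) > Decimal(repr(thresholds.min_site_qual)):
        return "failed_site_filter"
    if t.gl is None or n.gl is None:
        return "failed_site_filter"
    post_t = decimal_posteriors(t.gl)
    post_n = decimal_posteriors(n.gl)
    tumor_nonref = _phred(Decimal(1) - max(post_t[1], post_t[2]))
    normal_ref = _phred(Decimal(1) - post_n[0])
    normal_nonref = _phred(Decimal(1) - max(post_n[1], post_n[2]))
    low = Decimal(repr(thresholds.low_af_cutoff))
    min_ev = Decimal(repr(thresholds.min_evidence_phred))
    if af_t < low and n.ad[1] >= 1 and af_n < low:
        return "shared_low_frequency"
    if tumor_nonref >= min_ev and normal_ref >= min_ev:
        return "somatic"
    if normal_nonref >= min_ev:
        return "germline"
    return "reference"


def best_two_segment_boundary(x, min_width=2):
    """Exhaustive scan for the single boundary maximizing the two-sample
    t-statistic between prefix and suffix; None when no candidate."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    best_t, best_k = -1.0, None
    for k in range(min_width, n - min_width + 1):
        a, b = x[:k], x[k:]
        m1, m2 = a.mean(), b.mean()
        sp2 = (((a - m1) ** 2).sum() + ((b - m2) ** 2).sum()) / max(n - 2, 1)
        diff = abs(m1 - m2)
        if sp2 > 0:
            t = diff / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        else:
            t = 0.0 if diff < 1e-12 else 1e12
        if t > best_t:
            best_t, best_k = t, k
    return best_k


def diploid_gl_oracle(ref_reads, alt_reads, eps):
    """Closed-form log10 genotype likelihoods for the diploid read model."""
    import math

    dp = ref_reads + alt_reads
    return (
        ref_reads * math.log10(1 - eps) + alt_reads * math.log10(eps),
        dp * math.log10(0.5),
        alt_reads * math.log10(1 - eps) + ref_reads * math.log10(eps),
    )
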