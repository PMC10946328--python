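"""Ordering genes by inflection times and inferring regulatory interactions.

Two genes switch "simultaneously" when the posterior clouds of their
inflection-time estimates overlap: the estimates of both genes are binned
into 100 equally spaced bins spanning the pooled range, and the overlap is
P(A=B) = sum_i min(p_A(x_i), p_B(x_i)) — also reported as the p-value for a
difference in switch timing.  With overlap >= 1% the switch is simultaneous
and the interaction is mutual (positive when the inflection signs agree,
negative when they differ).  Without overlap, interactions follow the
timing/sign rules: (+ then +) and (- then -) mean the earlier gene
positively regulates the later; (+ then -) means the earlier gene represses
the later while the later activates the earlier; (- then +) yields no call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OverlapEstimate",
    "RegulatoryEdge",
    "CascadeOrdering",
    "inflection_overlap",
    "infer_interaction",
    "order_cascade",
    "screen_upstream_regulators",
]

N_OVERLAP_BINS = 100
DEFAULT_OVERLAP_THRESHOLD = 0.01


@dataclass
class OverlapEstimate:
    """Histogram-intersection overlap of two inflection-time sample sets."""

    bin_edges: np.ndarray
    p_a: np.ndarray
    p_b: np.ndarray
    overlap: float

    @property
    def p_value(self) -> float:
        """Percentage-overlap p-value for a difference in switch timing."""
        return self.overlap


@dataclass
class RegulatoryEdge:
    source: str
    target: str
    relation: str  # positive | negative | mutual_positive | mutual_negative | none
    overlap: float
    source_median: float
    target_median: float


@dataclass
class CascadeOrdering:
    """Genes sorted by posterior median first-inflection time."""

    genes: list
    first_inflection_medians: np.ndarray
    dynamic_classes: list
    table: object = field(default=None, repr=False)  # pandas DataFrame


def inflection_overlap(samples_a, samples_b) -> OverlapEstimate:
    """Overlap P(A=B) of two inflection-time sample sets (Eq.-style histogram
    intersection over 100 equal bins spanning the pooled min..max)."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both sample sets must be nonempty")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        # all estimates identical across both genes
        edges = np.linspace(lo - 0.5, lo + 0.5, N_OVERLAP_BINS + 1)
        p = np.zeros(N_OVERLAP_BINS)
        p[N_OVERLAP_BINS // 2] = 1.0
        return OverlapEstimate(edges, p, p.copy(), 1.0)
    edges = np.linspace(lo, hi, N_OVERLAP_BINS + 1)
    p_a = np.histogram(a, bins=edges)[0] / a.size
    p_b = np.histogram(b, bins=edges)[0] / b.size
    overlap = float(np.minimum(p_a, p_b).sum())
    return OverlapEstimate(edges, p_a, p_b, overlap)


def _locus_of(result, locus):
    """Time samples, majority sign and median of one inflection locus."""
    infl = result.inflections
    if infl.n_loci == 0:
        raise ValueError(f"gene {result.gene!r} has a uniform fit; "
                         "no inflection point to compare")
    if locus == "first":
        idx = int(np.argmin(np.median(infl.times, axis=0)))
    elif locus == "second":
        idx = infl.n_loci - 1
    else:
        idx = int(locus)
    times = infl.times[:, idx]
    sign = 1 if infl.signs[:, idx].mean() >= 0 else -1
    return times, sign, float(np.median(times))


def infer_interaction(result_a, result_b, overlap_threshold=DEFAULT_OVERLAP_THRESHOLD,
                      locus_a="first", locus_b="first"):
    """Directed interaction calls between two genes from the timing and sign
    of one inflection locus of each.  Returns (edge A->B, edge B->A)."""
    times_a, sign_a, med_a = _locus_of(result_a, locus_a)
    times_b, sign_b, med_b = _locus_of(result_b, locus_b)
    ov = inflection_overlap(times_a, times_b).overlap

    def edge(src, tgt, relation, med_s, med_t):
        return RegulatoryEdge(src.gene, tgt.gene, relation, ov, med_s, med_t)

    if ov >= overlap_threshold:
        relation = "mutual_positive" if sign_a == sign_b else "mutual_negative"
        return (edge(result_a, result_b, relation, med_a, med_b),
                edge(result_b, result_a, relation, med_b, med_a))

    # order by median time: "first" = earlier inflection
    if med_a <= med_b:
        first, second = (result_a, med_a, sign_a), (result_b, med_b, sign_b)
        flipped = False
    else:
        first, second = (result_b, med_b, sign_b), (result_a, med_a, sign_a)
        flipped = True
    (res_1, med_1, sign_1), (res_2, med_2, sign_2) = first, second
    fwd = rev = "none"
    if sign_1 > 0 and sign_2 > 0:
        fwd = "positive"
    elif sign_1 > 0 and sign_2 < 0:
        fwd, rev = "negative", "positive"
    elif sign_1 < 0 and sign_2 < 0:
        fwd = "positive"
    # (- then +): no relationship
    e_fwd = edge(res_1, res_2, fwd, med_1, med_2)
    e_rev = edge(res_2, res_1, rev, med_2, med_1)
    return (e_rev, e_fwd) if flipped else (e_fwd, e_rev)


def order_cascade(results) -> CascadeOrdering:
    """Stable sort of non-uniform genes by posterior median first-inflection
    time, ties broken by gene id."""
    import pandas as pd

    entries = []
    for res in results:
        if res.inflections.n_loci == 0:
            continue
        med = float(np.median(res.inflections.first_times()))
        entries.append((med, res.gene, res))
    entries.sort(key=lambda e: (e[0], e[1]))
    genes = [e[1] for e in entries]
    medians = np.array([e[0] for e in entries])
    classes = [e[2].dynamic_class for e in entries]
    table = pd.DataFrame({
        "gene": genes,
        "first_inflection_median": medians,
        "dynamic_class": classes,
        "family": [e[2].family.name for e in entries],
    })
    return CascadeOrdering(genes, medians, classes, table)


def screen_upstream_regulators(target, candidates, coregulator_ids=None,
                               overlap_threshold=DEFAULT_OVERLAP_THRESHOLD):
    """Candidate positive upstream regulators of ``target``.

    A candidate transcription factor qualifies when its first inflection is
    positive and occurs simultaneously with (overlap >= threshold) or before
    the target's first inflection, or when it has a negative inflection after
    the target's first inflection.  Candidates listed in ``coregulator_ids``
    are screened as transcriptional co-activators/co-repressors instead: they
    must show a transient up-regulation with the first inflection
    simultaneous with or before the target's.
    """
    if target.inflections.n_loci == 0:
        raise ValueError(f"target {target.gene!r} has a uniform fit")
    t_times, _, t_med = _locus_of(target, "first")
    coregs = set(coregulator_ids or ())
    hits = []
    for cand in candidates:
        if cand.gene == target.gene or cand.inflections.n_loci == 0:
            continue
        times, sign, med = _locus_of(cand, "first")
        simultaneous = inflection_overlap(times, t_times).overlap >= overlap_threshold
        if cand.gene in coregs:
            if cand.dynamic_class == "transient_up" and (simultaneous or med <= t_med):
                hits.append(cand.gene)
            continue
        if sign > 0 and (simultaneous or med <= t_med):
            hits.append(cand.gene)
        elif sign < 0 and med > t_med:
            hits.append(cand.gene)
    return hits
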