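"""Per-gene and per-set SNP burden statistics.

Burden is expressed per kilobase of CDS: ``rate = 1000 * count /
gene_length``. Set-level rates are pooled and length-weighted (total count
over total length), which is the convention that matches per-kb footers of
published per-gene inventories; the unweighted mean of per-gene rates is
carried alongside for reference. The candidate-versus-housekeeping contrast
reports rate ratios with a gene-level bootstrap interval — an uncertainty
add-on beyond the raw rates, labelled as such in the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import (
    BurdenSummary,
    CDS,
    EffectCall,
    GeneModel,
    HighNsRule,
    NONSYNONYMOUS,
    SYNONYMOUS,
    SetBurden,
    SnpBurdenError,
)


def gene_burden(
    calls: list[EffectCall],
    model_or_length: GeneModel | int,
    gene_id: str | None = None,
    collapse_stops: bool = True,
) -> BurdenSummary:
    """Tally one gene's CDS SNP calls into counts and per-kb rates.

    ``collapse_stops`` folds stop_gain/stop_loss into nonsynonymous and
    stop_retained into synonymous (the two-way sSNP/nsSNP convention);
    without it those calls count under ``n_other``.
    """
    if isinstance(model_or_length, GeneModel):
        length = model_or_length.cds_length
        gene_id = gene_id or model_or_length.gene_id
    else:
        length = int(model_or_length)
        if gene_id is None:
            raise SnpBurdenError("gene_id required when passing a bare length")
    if length <= 0:
        raise SnpBurdenError(f"gene {gene_id!r}: zero or negative CDS length")
    n_snp = n_s = n_ns = n_other = 0
    for call in calls:
        if call.region != CDS:
            continue
        n_snp += 1
        k = call.collapsed_klass() if collapse_stops else call.klass
        if k == SYNONYMOUS:
            n_s += 1
        elif k == NONSYNONYMOUS:
            n_ns += 1
        else:
            n_other += 1
    return BurdenSummary(
        gene_id=gene_id, gene_length=length,
        n_snp=n_snp, n_s=n_s, n_ns=n_ns, n_other=n_other,
    )


def set_burden(summaries: list[BurdenSummary], set_name: str) -> SetBurden:
    """Pool per-gene summaries into length-weighted set rates."""
    if not summaries:
        raise SnpBurdenError(f"set {set_name!r}: no gene summaries")
    return SetBurden(
        set_name=set_name,
        total_length=sum(s.gene_length for s in summaries),
        n_snp=sum(s.n_snp for s in summaries),
        n_s=sum(s.n_s for s in summaries),
        n_ns=sum(s.n_ns for s in summaries),
        genes=tuple(summaries),
    )


def flag_high_ns(
    summaries: list[BurdenSummary], rule: HighNsRule = HighNsRule()
) -> list[BurdenSummary]:
    """Genes passing the high-nsSNP rule, highest ns rate first."""
    hits = [s for s in summaries if rule.matches(s)]
    hits.sort(key=lambda s: (-s.rate_ns, s.gene_id))
    return hits


@dataclass(frozen=True)
class RateRatio:
    """One class's rate ratio between two sets, with bootstrap interval."""

    klass: str
    rate_a: float
    rate_b: float
    ratio: float | None  # None when the denominator rate is 0
    ci_low: float | None = None
    ci_high: float | None = None


@dataclass(frozen=True)
class SetComparison:
    label: str
    set_a: str
    set_b: str
    ratios: tuple[RateRatio, ...]
    bootstrap_reps: int
    note: str = (
        "rate ratios are pooled per-kb rates of set A over set B; the "
        "bootstrap interval (gene-level resampling) is an uncertainty "
        "add-on beyond the raw rates"
    )

    def ratio_for(self, klass: str) -> RateRatio:
        for r in self.ratios:
            if r.klass == klass:
                return r
        raise KeyError(klass)


def _pooled_rates(lengths: np.ndarray, counts: np.ndarray) -> np.ndarray:
    return 1000.0 * counts.sum(axis=-2) / lengths.sum(axis=-1, keepdims=False)


def compare_sets(
    a: SetBurden,
    b: SetBurden,
    bootstrap_reps: int = 1000,
    seed: int = 0,
) -> SetComparison:
    """Contrast two gene sets: per-class pooled-rate ratios A/B.

    Ratios with a zero denominator are reported as undefined (None), never
    infinite. The percentile bootstrap resamples genes with replacement
    within each set independently; replicates with a zero denominator are
    dropped from the interval.
    """
    rng = np.random.default_rng(seed)
    classes = ("snp", "s", "ns")
    point = {
        "snp": (a.rate_snp, b.rate_snp),
        "s": (a.rate_s, b.rate_s),
        "ns": (a.rate_ns, b.rate_ns),
    }

    def _arrays(s: SetBurden):
        lengths = np.array([g.gene_length for g in s.genes], dtype=float)
        counts = np.array(
            [[g.n_snp, g.n_s, g.n_ns] for g in s.genes], dtype=float
        )
        return lengths, counts

    la, ca = _arrays(a)
    lb, cb = _arrays(b)
    boots: dict[str, list[float]] = {k: [] for k in classes}
    for _ in range(bootstrap_reps):
        ia = rng.integers(0, len(la), len(la))
        ib = rng.integers(0, len(lb), len(lb))
        ra = 1000.0 * ca[ia].sum(axis=0) / la[ia].sum()
        rb = 1000.0 * cb[ib].sum(axis=0) / lb[ib].sum()
        for j, k in enumerate(classes):
            if rb[j] > 0:
                boots[k].append(ra[j] / rb[j])
    ratios = []
    for k in classes:
        ra, rb = point[k]
        ratio = ra / rb if rb > 0 else None
        lo = hi = None
        if boots[k]:
            lo, hi = np.percentile(boots[k], [2.5, 97.5]).tolist()
        ratios.append(RateRatio(k, ra, rb, ratio, lo, hi))
    return SetComparison(
        label=f"{a.set_name} vs {b.set_name}",
        set_a=a.set_name,
        set_b=b.set_name,
        ratios=tuple(ratios),
        bootstrap_reps=bootstrap_reps,
    )
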