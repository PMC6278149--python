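"""Variant retention rules: minimum read depth and INDEL vicinity.

A variant passes the depth rule when its read depth is at least
``FilterConfig.depth_min`` (inclusive; the default of 5 keeps a depth-5
record). A SNP passes the vicinity rule when its distance to the nearest
INDEL on the same contig exceeds ``indel_window`` nt, where an INDEL occupies
its reference span ``[pos, pos + len(ref) - 1]`` and distance is the gap
between the SNP position and that span (0 if inside). INDEL records
themselves never survive filtering — the pipeline analyses SNPs only.

:func:`apply_variant_filters` evaluates both rules against the *full* input
list: a SNP is removed if it is near any called INDEL, whatever that INDEL's
own depth. This makes the retained set independent of rule order; the report
attributes each removal to the first failing rule in the fixed order
(depth, then vicinity).
"""

from __future__ import annotations

from .models import FilterConfig, FilterReport, SnpBurdenError, VariantRecord

REASON_DEPTH = "low_depth"
REASON_UNKNOWN_DEPTH = "unknown_depth"
REASON_NEAR_INDEL = "near_indel"
REASON_IS_INDEL = "is_indel"


def _depth_ok(v: VariantRecord, cfg: FilterConfig) -> bool | None:
    """True/False for known depth; None for unknown depth."""
    if v.depth is None:
        return None
    return v.depth >= cfg.depth_min


def filter_by_depth(
    variants: list[VariantRecord], cfg: FilterConfig = FilterConfig()
) -> tuple[list[VariantRecord], FilterReport]:
    """Keep variants with depth >= the threshold.

    Unknown depth is a removal under ``strict_depth`` and a retained-but-
    flagged record otherwise.
    """
    report = FilterReport(n_input=len(variants))
    retained = []
    for v in variants:
        ok = _depth_ok(v, cfg)
        if ok is None:
            if cfg.strict_depth:
                report.removed.append((v, REASON_UNKNOWN_DEPTH))
            else:
                report.flagged_unknown_depth.append(v)
                retained.append(v)
        elif ok:
            retained.append(v)
        else:
            report.removed.append((v, REASON_DEPTH))
    report.n_retained = len(retained)
    return retained, report


def indel_distance(snp: VariantRecord, indel: VariantRecord) -> int | None:
    """Gap in nt between a SNP position and an INDEL's reference span.

    0 when the SNP lies inside the span; None when on different contigs.
    """
    if snp.contig_id != indel.contig_id:
        return None
    lo, hi = indel.ref_span
    if snp.pos < lo:
        return lo - snp.pos
    if snp.pos > hi:
        return snp.pos - hi
    return 0


def filter_indel_proximity(
    variants: list[VariantRecord], cfg: FilterConfig = FilterConfig()
) -> tuple[list[VariantRecord], FilterReport]:
    """Keep SNPs farther than ``indel_window`` nt from every INDEL.

    The INDELs considered are those present in ``variants``; they are
    removed from the output themselves (reason ``is_indel``).
    """
    report = FilterReport(n_input=len(variants))
    indels_by_contig: dict[str, list[VariantRecord]] = {}
    for v in variants:
        if v.vclass == "INDEL":
            indels_by_contig.setdefault(v.contig_id, []).append(v)
    retained = []
    for v in variants:
        if v.vclass == "INDEL":
            report.removed.append((v, REASON_IS_INDEL))
            continue
        near = any(
            d is not None and d <= cfg.indel_window
            for d in (
                indel_distance(v, ind)
                for ind in indels_by_contig.get(v.contig_id, [])
            )
        )
        if near:
            report.removed.append((v, REASON_NEAR_INDEL))
        else:
            retained.append(v)
    report.n_retained = len(retained)
    return retained, report


def apply_variant_filters(
    variants: list[VariantRecord], cfg: FilterConfig = FilterConfig()
) -> tuple[list[VariantRecord], FilterReport]:
    """Apply both retention rules; returns (retained SNPs, report).

    Idempotent: re-applying to its own output changes nothing (the output
    contains no INDELs and only depth-passing SNPs).
    """
    report = FilterReport(n_input=len(variants))
    indels_by_contig: dict[str, list[VariantRecord]] = {}
    for v in variants:
        if v.vclass == "INDEL":
            indels_by_contig.setdefault(v.contig_id, []).append(v)
    retained = []
    for v in variants:
        depth_ok = _depth_ok(v, cfg)
        if depth_ok is None and cfg.strict_depth:
            report.removed.append((v, REASON_UNKNOWN_DEPTH))
            continue
        if depth_ok is False:
            report.removed.append((v, REASON_DEPTH))
            continue
        if v.vclass == "INDEL":
            report.removed.append((v, REASON_IS_INDEL))
            continue
        near = any(
            d is not None and d <= cfg.indel_window
            for d in (
                indel_distance(v, ind)
                for ind in indels_by_contig.get(v.contig_id, [])
            )
        )
        if near:
            report.removed.append((v, REASON_NEAR_INDEL))
            continue
        if depth_ok is None:
            report.flagged_unknown_depth.append(v)
        retained.append(v)
    report.n_retained = len(retained)
    return retained, report
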