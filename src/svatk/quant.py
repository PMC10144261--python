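"""Relative quantitation of variant peptides against their wildtype pairs.

A sequence variant at the 0.1–1% level is quantified as the fraction of the
peptide pool carrying the substitution: 100 · A_v / (A_v + A_wt), where the
areas are extracted-ion-chromatogram areas summed over charge states and
enzymes before ratioing.  Summing first (ratio of sums, not mean of ratios)
keeps the estimate dominated by the best-measured charge states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .digestion import PeptideMatch
from .psm_io import PSMRecord
from .triage import TriageAnnotation


class UnpairedVariantError(ValueError):
    """No wildtype peptide covers the variant position."""


@dataclass(frozen=True)
class QuantResult:
    """Per-variant relative quantitation summary."""

    variant_name: str
    rel_quant_pct: float
    n_psms: int
    best_score: float
    area_variant: float
    area_wildtype: float
    missing_wildtype: bool = False


def pair_wildtype(
    variant_peptide: PeptideMatch | PSMRecord,
    variant_position: int,
    peptide_index: Sequence[PeptideMatch],
) -> PeptideMatch:
    """Wildtype counterpart of a variant peptide.

    Prefers the unmodified peptide with the identical protein span and
    enzyme; failing that, the shortest fully specific peptide covering the
    variant position (a substitution that creates or destroys a cleavage
    site changes the variant peptide's span, so an exact-span wildtype may
    not exist).
    """
    exact = [
        p for p in peptide_index
        if (p.protein_id, p.start, p.end, p.enzyme) ==
           (variant_peptide.protein_id, variant_peptide.start,
            variant_peptide.end, variant_peptide.enzyme)
    ]
    if exact:
        return exact[0]
    covering = [
        p for p in peptide_index
        if p.protein_id == variant_peptide.protein_id
        and p.enzyme == variant_peptide.enzyme
        and p.specificity == "full"
        and p.start <= variant_position <= p.end
    ]
    if not covering:
        raise UnpairedVariantError(
            f"no wildtype peptide covers position {variant_position} of "
            f"{variant_peptide.protein_id} ({variant_peptide.enzyme})")
    covering.sort(key=lambda p: (p.end - p.start, p.start))
    return covering[0]


def relative_quant(area_variant: float, area_wildtype: float) -> float:
    """Percent of the pool carried by the variant: 100·v/(v+w)."""
    if area_variant < 0 or area_wildtype < 0:
        raise ValueError("XIC areas must be >= 0")
    if area_variant == 0 and area_wildtype == 0:
        raise ValueError("variant and wildtype areas are both zero")
    if area_wildtype == 0:
        warnings.warn("wildtype area is zero; relative quant saturates at 100%",
                      stacklevel=2)
    return 100.0 * area_variant / (area_variant + area_wildtype)


def summarize_variant(
    variant_psms: Sequence[PSMRecord],
    area_wildtype: float,
) -> QuantResult:
    """Aggregate one variant: sum areas across charge states, then ratio."""
    if not variant_psms:
        raise ValueError("summarize_variant requires at least one PSM")
    name = variant_psms[0].variant.name
    area_v = sum(p.xic_area for p in variant_psms)
    missing = area_wildtype == 0 and area_v > 0
    with warnings.catch_warnings():
        if missing:
            warnings.simplefilter("ignore")
        pct = relative_quant(area_v, area_wildtype)
    return QuantResult(
        variant_name=name,
        rel_quant_pct=pct,
        n_psms=len(variant_psms),
        best_score=max(p.score for p in variant_psms),
        area_variant=area_v,
        area_wildtype=area_wildtype,
        missing_wildtype=missing,
    )


def _wildtype_area_for(
    variant_psms: Sequence[PSMRecord],
    wildtype_by_span: Mapping[tuple[str, int, int, str], list[PSMRecord]],
    wildtype_covering: Sequence[PSMRecord],
    position: int,
) -> float:
    """Sum wildtype areas matched span-for-span to the variant's evidence."""
    area = 0.0
    for span in sorted({(p.protein_id, p.start, p.end, p.enzyme)
                        for p in variant_psms}):
        matched = wildtype_by_span.get(span)
        if matched is None:
            protein_id, _, _, enzyme = span
            covering = [
                w for w in wildtype_covering
                if w.protein_id == protein_id and w.enzyme == enzyme
                and w.start <= position <= w.end
            ]
            if covering:
                covering.sort(key=lambda w: (w.end - w.start, w.start))
                best = (covering[0].start, covering[0].end)
                matched = [w for w in covering
                           if (w.start, w.end) == best]
            else:
                matched = []
        area += sum(w.xic_area for w in matched)
    return area


def quantify_variants(
    psms: Sequence[PSMRecord],
    annotations: Iterable[TriageAnnotation] | None = None,
) -> dict[str, QuantResult]:
    """Per-variant quantitation over a PSM table.

    Wildtype areas come from the unmodified PSMs: the exact-span counterpart
    when present, else the shortest covering wildtype peptide of the same
    enzyme.  When ``annotations`` are given, only retained variant PSMs are
    counted (wildtype PSMs are always usable).  Variants whose every PSM was
    annotated away are omitted.
    """
    retained: set[str] | None = None
    if annotations is not None:
        retained = {a.psm_id for a in annotations if a.status == "retained"}
    wildtype = [p for p in psms if p.variant is None]
    wildtype_by_span: dict[tuple[str, int, int, str], list[PSMRecord]] = {}
    for w in wildtype:
        wildtype_by_span.setdefault(
            (w.protein_id, w.start, w.end, w.enzyme), []).append(w)
    by_variant: dict[str, list[PSMRecord]] = {}
    for p in psms:
        if p.variant is None:
            continue
        if retained is not None and p.psm_id not in retained:
            continue
        by_variant.setdefault(p.variant.name, []).append(p)
    results = {}
    for name, group in sorted(by_variant.items()):
        area_w = _wildtype_area_for(
            group, wildtype_by_span, wildtype, group[0].variant.position)
        results[name] = summarize_variant(group, area_w)
    return results
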