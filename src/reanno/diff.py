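"""Annotation comparison: added/removed/retained ledgers and summaries.

Same-genome mode matches features by contig, strand, feature type and
reciprocal coordinate overlap; cross-genome mode (for comparing strains,
where coordinates are incommensurable) matches by case-insensitive gene
name.  ``proportion`` is the single rounding rule for every printed
ratio: half-up, to a stated number of decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .core import AnnotationSet, Feature, ThresholdConfig

__all__ = ["DiffReport", "diff", "proportion"]

logger = logging.getLogger(__name__)


def proportion(numerator: int, denominator: int, decimals: int = 0) -> float:
    """numerator / denominator as a percent, half-up rounded.

    Half-up (not banker's) rounding matches how ratios are conventionally
    printed in annotation reports: proportion(123, 194, 0) == 63.0.
    """
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if numerator < 0:
        raise ValueError("numerator must be >= 0")
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class DiffReport:
    added: list[Feature] = field(default_factory=list)
    removed: list[Feature] = field(default_factory=list)
    retained: list[tuple[Feature, Feature]] = field(default_factory=list)
    category_summary_old: dict = field(default_factory=dict)
    category_summary_new: dict = field(default_factory=dict)
    shared_fraction: float = 0.0  # percent of old features retained


def _same_genome_matches(
    old: list[Feature], new: list[Feature], min_frac: float
) -> list[tuple[Feature, Feature, int]]:
    """Candidate (old, new, overlap) pairs passing the reciprocal-overlap rule."""
    by_key: dict[tuple, list[Feature]] = {}
    for f in new:
        by_key.setdefault((f.location.contig_id, f.location.strand, f.ftype), []).append(f)
    pairs = []
    for fo in old:
        key = (fo.location.contig_id, fo.location.strand, fo.ftype)
        for fn in by_key.get(key, []):
            ov = fo.location.overlap(fn.location)
            if ov >= min_frac * fo.length and ov >= min_frac * fn.length:
                pairs.append((fo, fn, ov))
    return pairs


def diff(
    old: AnnotationSet,
    new: AnnotationSet,
    cfg: ThresholdConfig | None = None,
    cross_genome: bool = False,
) -> DiffReport:
    """Compare two annotations.

    Same-genome mode requires matching genome ids and pairs features by
    reciprocal overlap >= ``cfg.match_overlap_min``; many-to-many
    candidates are resolved greedily by largest overlap (logged).
    Cross-genome mode pairs by case-insensitive gene name and ignores
    coordinates.  ``shared_fraction`` is the percent of old features
    retained, at one decimal.
    """
    cfg = cfg or ThresholdConfig()
    if not cross_genome and old.genome_id != new.genome_id:
        raise ValueError(
            f"genome ids differ ({old.genome_id!r} vs {new.genome_id!r}); "
            "use cross_genome=True to match by gene name"
        )
    from .pipeline import summarize  # local import: pipeline imports this module

    retained: list[tuple[Feature, Feature]] = []
    if cross_genome:
        def names(feats: list[Feature]) -> dict[str, Feature]:
            out: dict[str, Feature] = {}
            for f in feats:
                if f.gene_name:
                    out.setdefault(f.gene_name.lower(), f)
            return out

        old_names = names(old.features)
        new_names = names(new.features)
        matched = set(old_names) & set(new_names)
        retained = [(old_names[n], new_names[n]) for n in sorted(matched)]
        matched_old = {f.feature_id for f, _ in retained}
        matched_new = {f.feature_id for _, f in retained}
    else:
        pairs = _same_genome_matches(old.features, new.features, cfg.match_overlap_min)
        pairs.sort(key=lambda t: (-t[2], t[0].feature_id, t[1].feature_id))
        matched_old: set[str] = set()
        matched_new: set[str] = set()
        for fo, fn, ov in pairs:
            if fo.feature_id in matched_old or fn.feature_id in matched_new:
                logger.debug(
                    "ambiguous match %s/%s resolved by larger overlap", fo.feature_id, fn.feature_id
                )
                continue
            matched_old.add(fo.feature_id)
            matched_new.add(fn.feature_id)
            retained.append((fo, fn))

    removed = [f for f in old.features if f.feature_id not in matched_old]
    added = [f for f in new.features if f.feature_id not in matched_new]
    shared = proportion(len(retained), len(old.features), 1) if old.features else 0.0
    return DiffReport(
        added=added,
        removed=removed,
        retained=retained,
        category_summary_old=summarize(old),
        category_summary_new=summarize(new),
        shared_fraction=shared,
    )
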