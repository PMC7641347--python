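"""Diversity summaries: depth categories, per-sample richness, rank
resolution by marker, taxon-by-depth detection tables and method overlap.

Depth categories follow the survey's stratification of the water column:
shallow (< 500 m), mid-depth (500-1400 m, both boundaries inclusive) and
deep (> 1400 m).  "Fish" means ray-finned or cartilaginous fishes
(class Actinopteri or Chondrichthyes); group membership additionally
requires a selection score of at least 90 so that marginal matches do not
inflate the group counts.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import ESVTable, SampleMeta
from .taxonomy import Assignment

DEPTH_CATEGORIES = ("shallow", "mid", "deep")

FISH_CLASSES = frozenset({"Actinopteri", "Chondrichthyes"})

#: Minimum selection score for counting an ESV in a taxonomic group.
GROUP_SCORE_MIN = 90.0


def depth_category(depth_m: float) -> str:
    """Stratify a sampling depth: shallow < 500 m, mid 500-1400 m, deep > 1400 m."""
    if depth_m < 0 or depth_m != depth_m:
        raise ValueError(f"depth must be finite and >= 0, got {depth_m}")
    if depth_m < 500.0:
        return "shallow"
    if depth_m <= 1400.0:
        return "mid"
    return "deep"


def esv_counts_per_sample(table: ESVTable) -> pd.Series:
    """Number of ESVs with at least one read, per sample."""
    df = table.counts
    present = df[df["read_count"] > 0]
    counts = present.groupby("sample_id")["esv_id"].nunique()
    # keep samples whose rows are all zero, reported as 0
    all_samples = pd.Index(table.sample_ids, name="sample_id")
    return counts.reindex(all_samples, fill_value=0).rename("n_esv").astype(int)


def _in_group(a: Assignment, group: str) -> bool:
    if a.best_score < GROUP_SCORE_MIN:
        return False
    if group == "metazoa":
        return a.assigned.kingdom == "Metazoa"
    if group == "fish":
        return a.assigned.class_ in FISH_CLASSES
    raise ValueError(f"unknown group filter {group!r}; expected 'metazoa' or 'fish'")


def rank_resolution_summary(
    assignments: Sequence[Assignment], group: str = "fish"
) -> pd.DataFrame:
    """Per-marker counts and percentages of group ESVs named at each rank.

    A species-level assignment also counts at genus and family, so the
    counts are nested (species <= genus <= family <= group).  Percentages
    are relative to the number of group ESVs, rounded to one decimal.
    """
    if group not in ("metazoa", "fish"):
        raise ValueError(f"unknown group filter {group!r}; expected 'metazoa' or 'fish'")
    by_marker: dict[str, list[Assignment]] = {}
    for a in assignments:
        by_marker.setdefault(a.marker or "", []).append(a)
    rows = []
    for marker, sub in by_marker.items():
        n_total = len(sub)
        with_tax = [a for a in sub if a.assigned_rank != "none"]
        in_group = [a for a in with_tax if _in_group(a, group)]
        n_group = len(in_group)
        n_family = sum(a.assigned.family is not None for a in in_group)
        n_genus = sum(a.assigned.genus is not None for a in in_group)
        n_species = sum(a.assigned.species is not None for a in in_group)

        def pct(n: int) -> float:
            return round(100.0 * n / n_group, 1) if n_group else 0.0

        rows.append(
            {
                "marker": marker,
                "n_esv_total": n_total,
                "n_esv_with_tax": len(with_tax),
                "n_group_esv": n_group,
                "n_family": n_family,
                "pct_family": pct(n_family),
                "n_genus": n_genus,
                "pct_genus": pct(n_genus),
                "n_species": n_species,
                "pct_species": pct(n_species),
            }
        )
    return pd.DataFrame(rows)


def _taxon_key(a: Assignment) -> tuple[str, str, str, str]:
    """Identity of a taxon at its assigned rank (order..species columns)."""
    lin = a.assigned
    return (
        lin.order or "",
        lin.family or "",
        lin.genus or "",
        lin.species or "",
    )


def taxon_detection_table(
    assignments: Sequence[Assignment],
    tables: Sequence[ESVTable],
    metadata: Sequence[SampleMeta],
    min_reads: int = 1,
) -> pd.DataFrame:
    """One row per distinct taxon at its assigned rank, with depth-category
    detection flags and the number of distinct samples with detections.

    Only assignments resolved to family rank or deeper enter the table (it
    is a family-and-below summary).  A taxon counts as detected in a depth
    category when at least ``min_reads`` reads of one of its ESVs occur in
    at least one non-control sample of that category; sample counts pool
    across markers.  Control samples never contribute.
    """
    meta_by_id = {m.sample_id: m for m in metadata}
    # assigned taxon per (marker, esv)
    tax_by_esv: dict[tuple[str, str], tuple] = {}
    for a in assignments:
        if a.assigned_rank in ("family", "genus", "species"):
            tax_by_esv[(a.marker or "", a.esv_id)] = _taxon_key(a)

    detections: dict[tuple, set[str]] = {}
    cat_flags: dict[tuple, set[str]] = {}
    for table in tables:
        df = table.counts
        hit = df[df["read_count"] >= min_reads]
        for esv_id, sample_id in zip(hit["esv_id"], hit["sample_id"]):
            key = tax_by_esv.get((table.marker, str(esv_id)))
            if key is None:
                continue
            meta = meta_by_id.get(str(sample_id))
            if meta is None or meta.is_control:
                continue
            detections.setdefault(key, set()).add(str(sample_id))
            cat_flags.setdefault(key, set()).add(depth_category(meta.depth_m))

    rows = []
    for key in sorted(detections):
        order, family, genus, species = key
        cats = cat_flags[key]
        rows.append(
            {
                "order": order,
                "family": family,
                "genus": genus,
                "species": species,
                "deep": "deep" in cats,
                "mid": "mid" in cats,
                "shallow": "shallow" in cats,
                "n_samples": len(detections[key]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["order", "family", "genus", "species", "deep", "mid", "shallow", "n_samples"],
    )


def count_distinct_taxa(
    detection_table: pd.DataFrame, rank: str, category: Optional[str] = None
) -> int:
    """Distinct named taxa at a rank, optionally restricted to rows flagged
    in one depth category.  A name is counted once across rows."""
    if rank not in ("family", "genus", "species"):
        raise ValueError(f"rank must be family, genus or species, got {rank!r}")
    df = detection_table
    if df.empty:
        return 0
    if category is not None:
        if category not in DEPTH_CATEGORIES:
            raise ValueError(f"unknown depth category {category!r}")
        df = df[df[category].astype(bool)]
    names = {n for n in df[rank] if isinstance(n, str) and n}
    return len(names)


def method_overlap(
    edna_taxa: Iterable[str], conventional_taxa: Iterable[str]
) -> tuple[int, int, int]:
    """Partition two taxon-name sets: (eDNA-only, shared, conventional-only)."""
    e, c = set(edna_taxa), set(conventional_taxa)
    return (len(e - c), len(e & c), len(c - e))
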