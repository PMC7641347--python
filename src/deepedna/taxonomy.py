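"""Selection-criterion + LCA taxonomy assignment for ESVs.

Each similarity hit is scored by a *selection criterion*: percent identity
multiplied by percent query-reference overlap (both on a 0-100 scale, so a
perfect full-length match scores 100).  The top-scoring hits (ties within a
tolerance) are collapsed to their lowest common ancestor, and the resulting
lineage is truncated to the deepest rank whose threshold the best score
meets: species requires a perfect 100, genus at least 98, family at least
95.  Below 95 the lineage is reported above the family level only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .io import RANKS, HitRecord, Lineage

logger = logging.getLogger("deepedna")

#: Ranks at which thresholded assignment operates, shallow to deep.
ASSIGNABLE_RANKS = ("family", "genus", "species")


@dataclass(frozen=True)
class Thresholds:
    """Minimum selection scores for reporting at each rank (inclusive)."""

    family_min: float = 95.0
    genus_min: float = 98.0
    species_min: float = 100.0
    tie_tol: float = 1e-9

    def __post_init__(self) -> None:
        if not (self.family_min <= self.genus_min <= self.species_min <= 100.0):
            raise ValueError(
                "thresholds must satisfy family_min <= genus_min <= species_min <= 100"
            )
        if self.tie_tol < 0:
            raise ValueError("tie_tol must be >= 0")


DEFAULT_THRESHOLDS = Thresholds()


@dataclass(frozen=True)
class Assignment:
    """An ESV's rank-resolved taxonomic call."""

    esv_id: str
    assigned: Lineage
    best_score: float
    assigned_rank: str  # none | above_family | family | genus | species
    n_tied_hits: int
    marker: Optional[str] = None


def selection_score(identity_pct: float, overlap_pct: float) -> float:
    """Percent identity times percent overlap, on a 0-100 scale."""
    if not 0.0 <= identity_pct <= 100.0:
        raise ValueError(f"identity_pct {identity_pct} outside [0, 100]")
    if not 0.0 <= overlap_pct <= 100.0:
        raise ValueError(f"overlap_pct {overlap_pct} outside [0, 100]")
    return identity_pct * overlap_pct / 100.0


def hit_score(hit: HitRecord) -> float:
    """Selection score of a hit (overlap = query coverage capped at 100)."""
    return selection_score(hit.identity_pct, hit.overlap_pct)


def lca(lineages: Sequence[Lineage]) -> Lineage:
    """Lowest common ancestor: the deepest rank prefix shared by all inputs.

    Returns an empty lineage when not even the kingdom is shared.
    """
    if len(lineages) == 0:
        raise ValueError("lca of an empty set of lineages is undefined")
    shared: list[Optional[str]] = []
    tuples = [lin.as_tuple() for lin in lineages]
    for level in range(len(RANKS)):
        names = {t[level] for t in tuples}
        if len(names) == 1 and None not in names:
            shared.append(names.pop())
        else:
            break
    shared += [None] * (len(RANKS) - len(shared))
    return Lineage(*shared)


def _rank_permitted(best_score: float, thresholds: Thresholds) -> Optional[str]:
    """Deepest rank whose (inclusive) threshold the score meets."""
    tol = thresholds.tie_tol
    if best_score >= thresholds.species_min - tol:
        return "species"
    if best_score >= thresholds.genus_min - tol:
        return "genus"
    if best_score >= thresholds.family_min - tol:
        return "family"
    return None


def assign_esv(
    hits: Sequence[HitRecord],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    marker: Optional[str] = None,
) -> Assignment:
    """Assign taxonomy to one ESV from its hits.

    Procedure: score every hit; keep only the best hit per subject taxon so
    duplicated references cannot dominate; take the maximum score; collapse
    all hits tying that maximum (within ``tie_tol``) to their lowest common
    ancestor; truncate the result to the deepest rank permitted by the
    score thresholds.  If even the family threshold is unmet the lineage is
    reported truncated above family rank (``above_family``).
    """
    if not hits:
        return Assignment(
            esv_id="", assigned=Lineage(), best_score=0.0,
            assigned_rank="none", n_tied_hits=0, marker=marker,
        )
    query_ids = {h.query_id for h in hits}
    if len(query_ids) != 1:
        raise ValueError(f"hits must share one query_id, got {sorted(query_ids)}")
    esv_id = hits[0].query_id

    # best hit per subject taxon
    best_per_taxon: dict[tuple, HitRecord] = {}
    score_per_taxon: dict[tuple, float] = {}
    for h in hits:
        key = h.subject_taxon.as_tuple()
        s = hit_score(h)
        if key not in best_per_taxon or s > score_per_taxon[key]:
            best_per_taxon[key] = h
            score_per_taxon[key] = s

    best_score = max(score_per_taxon.values())
    tied = [
        best_per_taxon[key]
        for key, s in score_per_taxon.items()
        if s >= best_score - thresholds.tie_tol
    ]
    candidate = lca([h.subject_taxon for h in tied])
    permitted = _rank_permitted(best_score, thresholds)

    if permitted is None:
        # below the family threshold: never report at family or deeper
        truncated = candidate.truncate("order")
        rank = "above_family"
    else:
        truncated = candidate.truncate(permitted)
        deepest = truncated.deepest_rank()
        if deepest in ASSIGNABLE_RANKS:
            rank = deepest
        else:
            rank = "above_family"
    return Assignment(
        esv_id=esv_id,
        assigned=truncated,
        best_score=best_score,
        assigned_rank=rank,
        n_tied_hits=len(tied),
        marker=marker,
    )


def assign_all(
    hits: Iterable[HitRecord],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    marker: Optional[str] = None,
) -> list[Assignment]:
    """Group hits by query and assign each ESV; order follows first appearance."""
    grouped: dict[str, list[HitRecord]] = {}
    for h in hits:
        grouped.setdefault(h.query_id, []).append(h)
    return [assign_esv(hs, thresholds, marker=marker) for hs in grouped.values()]


def filter_spurious(
    assignments: Sequence[Assignment], blocklist: Iterable[str]
) -> list[Assignment]:
    """Drop assignments whose lineage contains any blocklisted name.

    The survey context makes some database matches implausible (terrestrial
    or domestic taxa in deep-sea water samples); the blocklist names them
    at any rank.  An empty blocklist is the identity.
    """
    block = set(blocklist)
    if not block:
        return list(assignments)
    kept = [
        a for a in assignments
        if not any(a.assigned.contains_name(name) for name in block)
    ]
    n_removed = len(assignments) - len(kept)
    if n_removed:
        logger.info("filter_spurious removed %d assignment(s)", n_removed)
    return kept


# ---------------------------------------------------------------------------
# tabular round trip

import pandas as pd  # noqa: E402


def assignments_to_frame(assignments: Sequence[Assignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        row = {
            "esv_id": a.esv_id,
            "marker": a.marker or "",
            "best_score": a.best_score,
            "assigned_rank": a.assigned_rank,
            "n_tied_hits": a.n_tied_hits,
        }
        row.update(
            {rank: name or "" for rank, name in zip(RANKS, a.assigned.as_tuple())}
        )
        rows.append(row)
    cols = ["esv_id", "marker", "best_score", "assigned_rank", "n_tied_hits", *RANKS]
    return pd.DataFrame(rows, columns=cols)


def frame_to_assignments(df: pd.DataFrame) -> list[Assignment]:
    out = []
    for _, row in df.iterrows():
        lin = Lineage.from_mapping({rank: row.get(rank, "") for rank in RANKS})
        out.append(
            Assignment(
                esv_id=str(row["esv_id"]),
                assigned=lin,
                best_score=float(row["best_score"]),
                assigned_rank=str(row["assigned_rank"]),
                n_tied_hits=int(row["n_tied_hits"]),
                marker=str(row["marker"]) or None,
            )
        )
    return out


def write_assignments(assignments: Sequence[Assignment], path, sep: str = "\t") -> None:
    assignments_to_frame(assignments).to_csv(path, sep=sep, index=False)


def read_assignments(path, sep: str = "\t") -> list[Assignment]:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df["best_score"] = df["best_score"].astype(float)
    df["n_tied_hits"] = df["n_tied_hits"].astype(int)
    return frame_to_assignments(df)
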