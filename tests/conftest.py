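"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive results by brute force (explicit
enumeration, or a different optimization algorithm) so that agreement
with the package is a genuine dual-route check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from deepedna.io import RANKS, HitRecord, Lineage
from deepedna.taxonomy import Thresholds

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def fish_lineage():
    def make(order="Gadiformes", family="Moridae", genus="Antimora", species="Antimora rostrata"):
        return Lineage(
            kingdom="Metazoa",
            phylum="Chordata",
            class_="Actinopteri",
            order=order,
            family=family,
            genus=genus,
            species=species,
        )

    return make


@pytest.fixture
def make_hit(fish_lineage):
    def make(
        query_id="esv1",
        lineage=None,
        identity=100.0,
        align_len=150,
        query_len=150,
        evalue=1e-30,
        bitscore=300.0,
    ):
        return HitRecord(
            query_id=query_id,
            subject_taxon=lineage if lineage is not None else fish_lineage(),
            identity_pct=identity,
            align_len=align_len,
            query_len=query_len,
            evalue=evalue,
            bitscore=bitscore,
        )

    return make


# ---------------------------------------------------------------------------
# oracle: brute-force taxonomy assignment


def brute_force_assign(hits, thresholds=Thresholds()):
    """Assignment by explicit enumeration, independent of assign_esv.

    Scores every hit from scratch, takes the best score per subject taxon,
    enumerates the tied set, walks the rank ladder top-down to find the
    shared prefix, and decides the reporting rank by an explicit
    if-ladder over the thresholds.  Returns (rank, lineage_tuple).
    """
    per_taxon: dict[tuple, float] = {}
    for h in hits:
        overlap = 100.0 * h.align_len / h.query_len
        if overlap > 100.0:
            overlap = 100.0
        score = h.identity_pct * overlap / 100.0
        key = h.subject_taxon.as_tuple()
        if key not in per_taxon or score > per_taxon[key]:
            per_taxon[key] = score
    best = max(per_taxon.values())
    tied = [k for k, s in per_taxon.items() if s >= best - thresholds.tie_tol]

    shared: list = []
    for level in range(len(RANKS)):
        vals = {k[level] for k in tied}
        if len(vals) == 1 and None not in vals:
            shared.append(next(iter(vals)))
        else:
            break

    tol = thresholds.tie_tol
    if best >= thresholds.species_min - tol:
        cut = RANKS.index("species")
    elif best >= thresholds.genus_min - tol:
        cut = RANKS.index("genus")
    elif best >= thresholds.family_min - tol:
        cut = RANKS.index("family")
    else:
        cut = RANKS.index("order")
    kept = shared[: cut + 1]
    lineage = tuple(kept) + (None,) * (len(RANKS) - len(kept))

    depth = len(kept) - 1
    if cut == RANKS.index("order"):
        rank = "above_family"
    elif depth >= RANKS.index("species") and cut >= RANKS.index("species"):
        rank = "species"
    elif depth >= RANKS.index("genus") and cut >= RANKS.index("genus"):
        rank = "genus"
    elif depth >= RANKS.index("family"):
        rank = "family"
    else:
        rank = "above_family"
    return rank, lineage


# ---------------------------------------------------------------------------
# oracle: ADMM minimizer of the tie-broken rank dispersion


def admm_rank_oracle(y, X, max_iters=200_000, tol=1e-13):
    """Minimize the same tie-broken dispersion as rank_fit, but by ADMM
    on the pairwise-difference L1 form (an entirely different algorithm:
    alternating ridge solves and soft-thresholding with adaptive rho)."""
    from deepedna.robust import TIE_BREAK_LAMBDA, pairwise_differences, rank_dispersion

    y = np.asarray(y, dtype=float)
    n = len(y)
    dy, dX = pairwise_differences(y, X)
    w = np.sqrt(12.0) / (2.0 * (n + 1.0))
    anchor = np.linalg.lstsq(X - X.mean(0), y - y.mean(), rcond=None)[0]
    lam = TIE_BREAK_LAMBDA * (1.0 + abs(rank_dispersion(y - X @ anchor)))
    rho = w * 10.0
    p = X.shape[1]
    G = dX.T @ dX
    beta = anchor.copy()
    r = dy - dX @ beta
    u = np.zeros_like(dy)
    A = 2 * lam * np.eye(p) + rho * G
    for it in range(max_iters):
        beta_new = np.linalg.solve(A, 2 * lam * anchor + rho * dX.T @ (dy - r + u))
        v = dy - dX @ beta_new + u
        r_new = np.sign(v) * np.maximum(np.abs(v) - w / rho, 0.0)
        u = v - r_new
        pri = np.linalg.norm(dy - dX @ beta_new - r_new)
        dua = rho * np.linalg.norm(dX.T @ (r_new - r))
        step = np.linalg.norm(beta_new - beta)
        beta, r = beta_new, r_new
        if it % 200 == 199:
            if pri > 10 * dua:
                rho *= 2
                u /= 2
                A = 2 * lam * np.eye(p) + rho * G
            elif dua > 10 * pri:
                rho /= 2
                u *= 2
                A = 2 * lam * np.eye(p) + rho * G
        if step < tol and pri < 1e-11:
            break
    return beta
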