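"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the survey design the pipeline expects: a ranked
fish taxonomy with deliberate congeneric species pairs (so LCA collapses
are exercised), similarity-hit tables whose best selection scores are
placed in chosen strata around the 95/98/100 thresholds, sample metadata
with the two-volume (0.25 L vs 1.5 L) and three-depth-stratum structure
and a volume- and depth-dependent DNA concentration, and binary detection
histories drawn forward from the occupancy model.  Every generator is a
pure function of its arguments and a seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import Lineage, SampleMeta
from .occupancy import DetectionArray

#: Hit-score strata and the assignment rank each must produce.
STRATA = ("species", "genus", "family", "above_family", "tie_congener")


@dataclass(frozen=True)
class OccupancyTruth:
    """Community hyperparameters a detection history is drawn from."""

    mu_beta0: float = 0.5
    sigma_beta0: float = 1.0
    mu_beta1: float = -1.0
    sigma_beta1: float = 0.5
    mu_theta: float = 1.5  # logit scale: mean availability ~0.82
    sigma_theta: float = 0.5
    mu_alpha: tuple[float, ...] = (0.5, 0.0, -0.5)
    sigma_alpha: float = 0.75


@dataclass(frozen=True)
class SimConfig:
    """Study-design defaults for the synthetic survey.

    The sampling layout mirrors the field design: small-volume (0.25 L)
    stations in the first year and large-volume (1.5 L) stations in the
    second, each sampled at the surface, the deep scattering layer and
    just above the bottom, in triplicate, with one field blank per
    station.  DNA concentrations are in pg/uL.
    """

    # taxonomy shape
    n_families: int = 6
    genera_per_family: int = 2
    species_per_genus: int = 2
    # sampling design
    n_stations_small: int = 7
    n_stations_large: int = 10
    replicates: int = 3
    volume_small_l: float = 0.25
    volume_large_l: float = 1.5
    # DNA concentration model (pg/uL)
    conc_baseline: float = 30.0
    conc_volume_effect: float = 60.0  # added for 1.5 L samples
    conc_depth_effect: float = 15.0  # subtracted for deep (>1400 m) samples
    conc_sd: float = 15.0
    # hit-table noise
    query_len: int = 150
    decoy_hits: int = 2
    # occupancy community truth
    occupancy: OccupancyTruth = field(default_factory=OccupancyTruth)


DEFAULT_CONFIG = SimConfig()


# ---------------------------------------------------------------------------
# taxonomy


def make_taxonomy(
    n_families: int = 6,
    genera_per_family: int = 2,
    species_per_genus: int = 2,
    class_name: str = "Actinopteri",
) -> dict[str, Lineage]:
    """A consistent 7-rank fish taxonomy keyed by species-level taxon keys.

    Families are paired into orders; every genus with >= 2 species yields
    congeneric pairs (see :func:`congeneric_pair_count`).
    """
    if min(n_families, genera_per_family, species_per_genus) < 1:
        raise ValueError("taxonomy sizes must be >= 1")
    out: dict[str, Lineage] = {}
    counter = itertools.count(1)
    for f in range(n_families):
        order = f"Simorder{f // 2 + 1:02d}"
        family = f"Simfamily{f + 1:02d}"
        for g in range(genera_per_family):
            genus = f"Simgenus{f + 1:02d}x{g + 1:02d}"
            for s in range(species_per_genus):
                key = f"tx{next(counter):04d}"
                out[key] = Lineage(
                    kingdom="Metazoa",
                    phylum="Chordata",
                    class_=class_name,
                    order=order,
                    family=family,
                    genus=genus,
                    species=f"{genus} sp{s + 1:02d}",
                )
    return out


def congeneric_pair_count(taxonomy: Mapping[str, Lineage]) -> int:
    """Number of unordered species pairs sharing a genus."""
    per_genus: dict[str, int] = {}
    for lin in taxonomy.values():
        if lin.species is not None and lin.genus is not None:
            per_genus[lin.genus] = per_genus.get(lin.genus, 0) + 1
    return sum(n * (n - 1) // 2 for n in per_genus.values())


# ---------------------------------------------------------------------------
# hit tables


def _score_to_hit(rng, score: float, qlen: int) -> tuple[float, int]:
    """Split a target selection score into (identity, align_len).

    Either full overlap with identity = score, or full identity with
    partial overlap, chosen at random — both give the same score.
    """
    if rng.uniform() < 0.5 or score > 99.5:
        return score, qlen
    align = int(round(qlen * score / 100.0))
    # rounding align_len changes the overlap; rescale identity to hold score
    overlap = 100.0 * align / qlen
    return min(100.0, score / overlap * 100.0), align


def make_hit_table(
    truth: Mapping[str, str],
    taxonomy: Mapping[str, Lineage],
    seed: int,
    strata: Optional[Mapping[str, str]] = None,
    query_len: int = 150,
    decoy_hits: int = 2,
) -> tuple[pd.DataFrame, dict[str, tuple[str, Lineage]]]:
    """Simulate a hit table whose assignments are known in advance.

    ``truth`` maps each ESV id to its true (species-level) taxon key;
    ``strata`` places each ESV's best score in a threshold stratum
    (cycled through all strata when omitted).  Hits are simulated at the
    score level, not by aligning sequences.  Returns the hit table (the
    default reader column order) and the expected assignment per ESV:
    (expected rank, expected truncated lineage).
    """
    if not truth:
        raise ValueError("truth map must be non-empty")
    rng = np.random.default_rng(seed)
    keys = list(taxonomy)
    if strata is None:
        cycle = itertools.cycle(STRATA)
        strata = {esv: next(cycle) for esv in truth}
    rows = []
    expected: dict[str, tuple[str, Lineage]] = {}

    def add_row(esv, key, score):
        identity, align = _score_to_hit(rng, score, query_len)
        rows.append(
            {
                "query_id": esv,
                "taxon_key": key,
                "identity_pct": round(identity, 3),
                "align_len": align,
                "query_len": query_len,
                "evalue": 1e-30,
                "bitscore": round(2.0 * align, 1),
            }
        )
        # recompute the realized score after rounding
        h_over = min(100.0, 100.0 * align / query_len)
        return round(identity, 3) * h_over / 100.0

    for esv, key in truth.items():
        stratum = strata[esv]
        lin = taxonomy[key]
        if stratum == "species":
            best = add_row(esv, key, 100.0)
            expected[esv] = ("species", lin)
        elif stratum == "tie_congener":
            congeners = [
                k for k in keys
                if k != key and taxonomy[k].genus == lin.genus
            ]
            if not congeners:
                raise ValueError(f"no congener available for {key}")
            add_row(esv, key, 100.0)
            add_row(esv, rng.choice(congeners), 100.0)
            best = 100.0
            expected[esv] = ("genus", lin.truncate("genus"))
        elif stratum == "genus":
            best = add_row(esv, key, rng.uniform(98.3, 99.5))
            expected[esv] = ("genus", lin.truncate("genus"))
        elif stratum == "family":
            best = add_row(esv, key, rng.uniform(95.3, 97.5))
            expected[esv] = ("family", lin.truncate("family"))
        elif stratum == "above_family":
            best = add_row(esv, key, rng.uniform(85.0, 94.5))
            expected[esv] = ("above_family", lin.truncate("order"))
        else:
            raise ValueError(f"unknown stratum {stratum!r}")
        # decoys: clearly lower-scoring hits to random other taxa
        others = [k for k in keys if taxonomy[k].genus != lin.genus]
        for _ in range(decoy_hits):
            if not others:
                break
            add_row(esv, rng.choice(others), max(60.0, best - rng.uniform(4.0, 15.0)))
    df = pd.DataFrame(rows)
    return df, expected


# ---------------------------------------------------------------------------
# metadata + DNA concentration


def make_metadata_and_concentration(
    config: SimConfig = DEFAULT_CONFIG, seed: int = 0
) -> list[SampleMeta]:
    """Sample metadata with the two-volume, three-stratum design and a
    volume- and depth-dependent DNA concentration signal.

    conc = baseline + b_vol * 1[volume = large] - b_depth * 1[deep]
           + Normal(0, sd), truncated at 0 (concentrations are
    non-negative).  One field blank per station is flagged as a control.
    """
    rng = np.random.default_rng(seed)
    out: list[SampleMeta] = []
    station_no = itertools.count(1)
    plans = [(2018, config.n_stations_small, config.volume_small_l),
             (2019, config.n_stations_large, config.volume_large_l)]
    for year, n_stations, volume in plans:
        for _ in range(n_stations):
            sn = next(station_no)
            station = f"ST{sn:02d}"
            transect = f"T{(sn - 1) % 3 + 1}"
            bottom = float(rng.uniform(500.0, 3000.0))
            dsl = float(rng.uniform(360.0, 536.0))
            depths = [
                (5.0, "surface"),
                (dsl, "deep_scattering_layer"),
                (bottom, "bottom"),
            ]
            for depth, location in depths:
                for r in range(config.replicates):
                    conc = (
                        config.conc_baseline
                        + config.conc_volume_effect * (volume == config.volume_large_l)
                        - config.conc_depth_effect * (depth > 1400.0)
                        + rng.normal(0.0, config.conc_sd)
                    )
                    out.append(
                        SampleMeta(
                            sample_id=f"{station}-{location[:3]}-{r + 1}",
                            station=station,
                            transect=transect,
                            year=year,
                            depth_m=round(depth, 1),
                            location=location,
                            volume_l=volume,
                            dna_conc=round(max(conc, 0.0), 3),
                            is_control=False,
                        )
                    )
            out.append(
                SampleMeta(
                    sample_id=f"{station}-blank",
                    station=station,
                    transect=transect,
                    year=year,
                    depth_m=0.0,
                    location="surface",
                    volume_l=volume,
                    dna_conc=round(float(abs(rng.normal(0.0, 0.05))), 3),
                    is_control=True,
                )
            )
    return out


# ---------------------------------------------------------------------------
# detection histories


def make_detection_history(
    n_taxa: int = 20,
    n_sites: int = 30,
    n_replicates: int = 3,
    n_markers: int = 3,
    hyper: OccupancyTruth = OccupancyTruth(),
    seed: int = 0,
    depth_m: Optional[np.ndarray] = None,
) -> tuple[DetectionArray, dict[str, np.ndarray]]:
    """Draw a detection history forward from the occupancy hierarchy.

    Taxon-level parameters are drawn from the community hyperpriors, then
    latent occupancy z and availability a, then detections y.  Returns the
    array and the full ground truth (hyperparameters, taxon parameters and
    latent states) for recovery tests.
    """
    if min(n_taxa, n_sites, n_replicates, n_markers) < 1:
        raise ValueError("all dimensions must be >= 1")
    if len(hyper.mu_alpha) != n_markers:
        raise ValueError("hyper.mu_alpha must have one entry per marker")
    rng = np.random.default_rng(seed)
    K, I, J, M = n_taxa, n_sites, n_replicates, n_markers
    if depth_m is None:
        depth_m = np.linspace(100.0, 2600.0, I)
    depth_m = np.asarray(depth_m, dtype=float)
    d = (depth_m - depth_m.mean()) / depth_m.std() if depth_m.std() > 0 else np.zeros(I)

    beta0 = rng.normal(hyper.mu_beta0, hyper.sigma_beta0, K)
    beta1 = rng.normal(hyper.mu_beta1, hyper.sigma_beta1, K)
    lth = rng.normal(hyper.mu_theta, hyper.sigma_theta, K)
    alpha = rng.normal(np.asarray(hyper.mu_alpha)[:, None], hyper.sigma_alpha, (M, K))

    psi = expit(beta0[None, :] + beta1[None, :] * d[:, None])  # (I, K)
    theta = expit(lth)
    p = expit(alpha)

    z = (rng.uniform(size=(I, K)) < psi).astype(float)
    a = (rng.uniform(size=(I, J, K)) < z[:, None, :] * theta[None, None, :]).astype(float)
    y = (
        rng.uniform(size=(K, I, J, M))
        < a.transpose(2, 0, 1)[:, :, :, None] * p.T[:, None, None, :]
    ).astype(float)

    data = DetectionArray(
        y=y,
        depth_m=depth_m,
        taxa=[f"taxon{k + 1:02d}" for k in range(K)],
        sites=[f"site{i + 1:02d}" for i in range(I)],
        markers=[f"marker{m + 1}" for m in range(M)],
    )
    truth = {
        "beta0": beta0,
        "beta1": beta1,
        "theta": theta,
        "alpha": alpha,
        "psi": psi,
        "z": z,
        "a": a,
        "mu_alpha": np.asarray(hyper.mu_alpha, dtype=float),
        "sigma_alpha": np.float64(hyper.sigma_alpha),
        "mu_theta": np.float64(hyper.mu_theta),
        "mu_beta0": np.float64(hyper.mu_beta0),
        "mu_beta1": np.float64(hyper.mu_beta1),
    }
    return data, truth
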