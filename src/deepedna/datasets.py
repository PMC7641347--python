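"""Bundled example data: published summary tables from a deep-sea eDNA
metabarcoding survey of fish communities in the Labrador Sea.

Two small tables ship with the package so that the summary operations can
be exercised on real survey output without any sequence data:

* a fish taxon-by-depth detection table (one row per taxon at its assigned
  rank, with detection flags for the shallow / mid / deep strata and the
  number of water samples the taxon appeared in), and
* per-marker ESV counts for seven primer sets: total ESVs, ESVs with any
  taxonomic match, fish ESVs (class Actinopteri or Chondrichthyes), and of
  those how many were named at family, genus and species rank.

Both are hand-transcribed survey summaries, not outputs of this package.
"""

from __future__ import annotations

import io as _io

import pandas as pd

_FISH_DETECTIONS_TSV = """\
order\tfamily\tgenus\tspecies\tdeep\tmid\tshallow\tn_samples
Alepocephaliformes\tAlepocephalidae\tAlepocephalus\tAlepocephalus agassizii\tY\t\t\t1
Alepocephaliformes\tAlepocephalidae\tAlepocephalus\t\tY\t\tY\t4
Alepocephaliformes\tAlepocephalidae\t\t\tY\t\tY\t2
Anguilliformes\tSynaphobranchidae\tSynaphobranchus\t\tY\tY\t\t2
Argentiniformes\tBathylagidae\tBathylagus\tBathylagus euryops\tY\tY\t\t2
Argentiniformes\tBathylagidae\tBathylagus\t\tY\tY\t\t3
Argentiniformes\tBathylagidae\t\t\tY\t\t\t1
Aulopiformes\tParalepididae\tParalepis\tParalepis coregonoides\t\tY\t\t1
Beryciformes\tMelamphaidae\tPoromitra\t\tY\tY\t\t2
Beryciformes\tMelamphaidae\t\t\t\tY\t\t1
Clupeiformes\tClupeidae\t\t\tY\t\tY\t3
Gadiformes\tMacrouridae\tCoryphaenoides\tCoryphaenoides rupestris\t\tY\t\t1
Gadiformes\tMacrouridae\tMacrourus\t\t\tY\t\t2
Gadiformes\tMacrouridae\t\t\tY\tY\tY\t12
Gadiformes\tMoridae\tAntimora\tAntimora rostrata\tY\t\tY\t4
Gadiformes\tMoridae\tAntimora\t\tY\t\tY\t4
Myctophiformes\tMyctophidae\tBenthosema\tBenthosema glaciale\tY\tY\tY\t11
Myctophiformes\tMyctophidae\tLampanyctus\tLampanyctus macdonaldi\tY\tY\tY\t6
Myctophiformes\tMyctophidae\tLampanyctus\t\tY\tY\tY\t7
Myctophiformes\tMyctophidae\tNotoscopelus\t\t\t\tY\t1
Myctophiformes\tMyctophidae\tProtomyctophum\t\t\tY\tY\t5
Myctophiformes\tMyctophidae\t\t\tY\tY\tY\t41
Perciformes\tAnarhichadidae\tAnarhichas\tAnarhichas denticulatus\t\tY\t\t1
Perciformes\tAnarhichadidae\tAnarhichas\t\t\tY\tY\t4
Perciformes\tAnarhichadidae\t\t\t\tY\tY\t2
Perciformes\tCottidae\tIcelus\t\t\tY\tY\t2
Perciformes\tLiparidae\tPsednos\tPsednos groenlandicus\tY\t\tY\t2
Perciformes\tLiparidae\tPsednos\t\t\t\tY\t1
Perciformes\tPholidae\tPholis\t\t\t\tY\t1
Perciformes\tPholidae\t\t\t\t\tY\t2
Perciformes\tSebastidae\tSebastes\tSebastes mentella\t\tY\t\t2
Perciformes\tSebastidae\tSebastes\t\t\tY\t\t2
Perciformes\tZoarcidae\t\t\t\t\tY\t2
Pleuronectiformes\tPleuronectidae\tReinhardtius\tReinhardtius hippoglossoides\t\tY\t\t1
Pleuronectiformes\tPleuronectidae\t\t\t\tY\t\t1
Rajiformes\tRajidae\tAmblyraja\t\tY\t\t\t2
Rajiformes\tRajidae\tRajella\tRajella bigelowi\tY\t\t\t2
Rajiformes\tRajidae\tRajella\t\tY\t\t\t2
Rajiformes\tRajidae\t\t\tY\t\t\t2
Salmoniformes\tSalmonidae\t\t\t\tY\tY\t2
Stomiiformes\tGonostomatidae\tCyclothone\tCyclothone microdon\tY\tY\tY\t6
Stomiiformes\tGonostomatidae\tCyclothone\t\t\tY\tY\t9
Stomiiformes\tGonostomatidae\t\t\t\tY\tY\t4
Stomiiformes\tStomiidae\tStomias\tStomias boa\t\tY\tY\t2
Stomiiformes\tStomiidae\tStomias\t\t\tY\tY\t2
Uranoscopiformes\tAmmodytidae\tAmmodytes\tAmmodytes hexapterus\t\t\tY\t1
"""

# marker, total ESVs, ESVs with any match, fish ESVs, family-named,
# genus-named, species-named (fish = Actinopteri or Chondrichthyes)
_MARKER_FISH_COUNTS_TSV = """\
marker\tn_esv_total\tn_esv_with_tax\tn_group_esv\tn_family\tn_genus\tn_species
12SV5\t890\t245\t2\t2\t2\t1
12Steleo\t1192\t1106\t110\t107\t49\t7
12S MiFishU\t13228\t12935\t29\t27\t21\t4
18SV9M\t7081\t6878\t9\t2\t0\t0
COI F230\t16252\t15952\t2\t0\t0\t0
COI FishE\t89506\t61647\t19\t16\t12\t9
COI Leray\t20190\t16628\t0\t0\t0\t0
"""

# the published percentages alongside the counts (one decimal)
_MARKER_FISH_PCT = {
    "12SV5": (100.0, 100.0, 50.0),
    "12Steleo": (97.3, 44.5, 6.4),
    "12S MiFishU": (93.1, 72.4, 13.8),
    "18SV9M": (22.2, 0.0, 0.0),
    "COI F230": (0.0, 0.0, 0.0),
    "COI FishE": (84.2, 63.2, 47.4),
    "COI Leray": (0.0, 0.0, 0.0),
}


def load_fish_detections() -> pd.DataFrame:
    """Fish taxon-by-depth detection table (46 taxa, boolean strata flags).

    Same schema as :func:`deepedna.diversity.taxon_detection_table` output.
    """
    df = pd.read_csv(_io.StringIO(_FISH_DETECTIONS_TSV), sep="\t", keep_default_na=False)
    for col in ("deep", "mid", "shallow"):
        df[col] = df[col] == "Y"
    return df


def load_marker_fish_counts() -> pd.DataFrame:
    """Per-marker fish ESV counts for the seven primer sets surveyed."""
    return pd.read_csv(_io.StringIO(_MARKER_FISH_COUNTS_TSV), sep="\t")


def marker_fish_percentages() -> dict[str, tuple[float, float, float]]:
    """Published (family, genus, species) percentages per marker."""
    return dict(_MARKER_FISH_PCT)


def assignments_from_marker_counts(counts=None):
    """Expand the per-marker count table into a minimal assignment list.

    Builds, for each marker, exactly ``n_species`` species-level fish
    assignments, ``n_genus - n_species`` genus-level, ``n_family -
    n_genus`` family-level, ``n_group_esv - n_family`` fish assignments
    above family rank, plus non-fish and unmatched placeholders so the
    totals agree — letting the rank-resolution summary be recomputed from
    counts alone.
    """
    from .io import Lineage
    from .taxonomy import Assignment

    if counts is None:
        counts = load_marker_fish_counts()
    full = Lineage("Metazoa", "Chordata", "Actinopteri", "Clupeiformes",
                   "Clupeidae", "Clupea", "Clupea harengus")
    protist = Lineage("Chromista")
    out = []
    for row in counts.itertuples():
        n_above = row.n_group_esv - row.n_family
        n_nonfish = row.n_esv_with_tax - row.n_group_esv
        n_none = row.n_esv_total - row.n_esv_with_tax
        specs = (
            [("species", full, 100.0)] * row.n_species
            + [("genus", full.truncate("genus"), 98.5)] * (row.n_genus - row.n_species)
            + [("family", full.truncate("family"), 96.0)] * (row.n_family - row.n_genus)
            + [("above_family", full.truncate("order"), 92.0)] * n_above
            + [("above_family", protist, 93.0)] * n_nonfish
            + [("none", Lineage(), 0.0)] * n_none
        )
        for i, (rank, lin, score) in enumerate(specs):
            out.append(
                Assignment(
                    esv_id=f"{row.marker}-{i:06d}", assigned=lin, best_score=score,
                    assigned_rank=rank, n_tied_hits=1 if rank != "none" else 0,
                    marker=row.marker,
                )
            )
    return out
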