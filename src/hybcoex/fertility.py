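"""Fertility classification of hybrid males and the PC1-based split of
subfertile samples into normal- versus aberrant-expression groups.

Two fertility proxies are used: relative testis weight (testis weight / body
weight) and sperm count.  Pure-subspecies samples define the reference mean,
SD and min-max range (both subspecies pooled by default).  Hybrids are:

* ``subfertile``  -- either phenotype outside the pure range,
* ``fertile``     -- both phenotypes within 1 SD of the pure mean,
* ``intermediate``-- otherwise (inside the range, but >1 SD on >=1 trait).

Boundary values count as "within".  Subfertile samples whose genome-wide
expression PC1 score falls strictly outside the range spanned by fertile
hybrids and pure samples are labelled SFAE (subfertile aberrant expression),
the rest SFNE (subfertile normal expression).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_core import PURE_POPULATIONS, relative_testis_weight

PHENOTYPES = ("relative_testis_weight", "sperm_count")

CLASS_COLUMNS = [
    "sample_id", "population", "fertility_class", "expression_class",
    "relative_testis_weight", "sperm_count", "pc1_score",
]


class ClassificationError(ValueError):
    pass


def _phenotype_frame(sample_table: pd.DataFrame) -> pd.DataFrame:
    pheno = pd.DataFrame(
        {
            "relative_testis_weight": relative_testis_weight(sample_table).to_numpy(),
            "sperm_count": sample_table["sperm_count"].to_numpy(),
        },
        index=sample_table["sample_id"],
    )
    missing = pheno.isna().any(axis=1)
    if missing.any():
        raise ClassificationError(
            f"missing fertility phenotype for sample(s) {list(pheno.index[missing][:5])}"
        )
    return pheno


def classify_fertility(
    sample_table: pd.DataFrame, pool_subspecies: bool = True
) -> pd.DataFrame:
    """Label every sample pure / fertile / intermediate / subfertile.

    ``pool_subspecies=False`` computes reference statistics per subspecies and
    takes the union of the per-subspecies 1-SD bands and ranges.
    """
    pheno = _phenotype_frame(sample_table)
    pops = pd.Series(
        sample_table["population"].to_numpy(), index=sample_table["sample_id"]
    )
    is_pure = pops.isin(PURE_POPULATIONS)
    if is_pure.sum() < 2:
        raise ClassificationError("need >= 2 pure-subspecies samples")

    groups = (
        [pheno[is_pure]]
        if pool_subspecies
        else [pheno[pops == p] for p in PURE_POPULATIONS if (pops == p).any()]
    )
    lo_band = pd.DataFrame([g.mean() - g.std(ddof=1) for g in groups]).min()
    hi_band = pd.DataFrame([g.mean() + g.std(ddof=1) for g in groups]).max()
    lo_range = pd.DataFrame([g.min() for g in groups]).min()
    hi_range = pd.DataFrame([g.max() for g in groups]).max()

    records = []
    for sid, pop in pops.items():
        p = pheno.loc[sid]
        if pop in PURE_POPULATIONS:
            cls = "pure"
        elif ((p < lo_range) | (p > hi_range)).any():
            cls = "subfertile"
        elif ((p >= lo_band) & (p <= hi_band)).all():
            cls = "fertile"
        else:
            cls = "intermediate"
        records.append(
            {
                "sample_id": sid,
                "population": pop,
                "fertility_class": cls,
                "expression_class": "not_applicable",
                "relative_testis_weight": p["relative_testis_weight"],
                "sperm_count": p["sperm_count"],
                "pc1_score": np.nan,
            }
        )
    return pd.DataFrame.from_records(records, columns=CLASS_COLUMNS)


def split_expression_class(
    classification: pd.DataFrame, pc1_scores: pd.Series
) -> pd.DataFrame:
    """Split subfertile samples into SFNE / SFAE by genome-wide PC1.

    The reference interval is the [min, max] of PC1 over fertile hybrids and
    pure samples; a subfertile sample is SFAE iff its PC1 score lies strictly
    outside that interval.
    """
    out = classification.copy()
    pc1 = pc1_scores.reindex(out["sample_id"])
    if pc1.isna().any():
        missing = list(out.loc[pc1.isna().to_numpy(), "sample_id"][:5])
        raise ClassificationError(f"PC1 score missing for sample(s) {missing}")
    out["pc1_score"] = pc1.to_numpy()

    ref_mask = out["fertility_class"].isin(["fertile", "pure"])
    if not ref_mask.any():
        raise ClassificationError(
            "no fertile hybrids or pure samples to define the PC1 reference range"
        )
    lo = out.loc[ref_mask, "pc1_score"].min()
    hi = out.loc[ref_mask, "pc1_score"].max()

    subf = out["fertility_class"] == "subfertile"
    outside = (out["pc1_score"] < lo) | (out["pc1_score"] > hi)
    out.loc[subf & outside, "expression_class"] = "SFAE"
    out.loc[subf & ~outside, "expression_class"] = "SFNE"
    return out


def reference_pc1_interval(classification: pd.DataFrame) -> tuple[float, float]:
    """The fertile+pure PC1 [min, max] interval used for the SFNE/SFAE split."""
    ref = classification[classification["fertility_class"].isin(["fertile", "pure"])]
    return float(ref["pc1_score"].min()), float(ref["pc1_score"].max())
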