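"""Embryo-to-yolk-sac comparisons within conceptuses.

Three congruence views: (1) do genes strongly stage-correlated in both
tissues agree in correlation sign; (2) do genes differentially expressed in
both tissues agree in fold-change direction; (3) does a conceptus's overall
response magnitude, summarized as its coordinate on the first principal
component of the condition-discriminating genes, coordinate between its two
tissues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ValidationError
from .multivariate import PCAResult, orient_dimension
from .stagecorr import select_strong

GENE_UNIVERSES = ("pearson_all_strong", "diabetic_unique_strong")


def match_pairs(meta: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Complete (embryo, yolk-sac) sample pairs keyed by conceptus.

    Returns the pair table (conceptus_id, embryo_sample, yolk_sac_sample)
    and the ids of incomplete conceptuses.
    """
    rows, incomplete = [], []
    for cid, grp in meta.groupby("conceptus_id", sort=True):
        by_tissue = dict(zip(grp["tissue"], grp["sample_id"]))
        if "embryo" in by_tissue and "yolk_sac" in by_tissue:
            rows.append({"conceptus_id": cid,
                         "embryo_sample": by_tissue["embryo"],
                         "yolk_sac_sample": by_tissue["yolk_sac"]})
        else:
            incomplete.append(cid)
    cols = ["conceptus_id", "embryo_sample", "yolk_sac_sample"]
    return pd.DataFrame(rows, columns=cols), incomplete


@dataclass
class CongruenceReport:
    """Concordance of a per-gene sign between the two tissues."""

    universe: str
    n_shared: int
    n_concordant: int
    discordant_genes: list[str]

    @property
    def n_discordant(self) -> int:
        return len(self.discordant_genes)

    @property
    def concordance(self) -> float:
        return self.n_concordant / self.n_shared if self.n_shared else float("nan")

    def to_dict(self) -> dict:
        return {"universe": self.universe, "n_shared": self.n_shared,
                "n_concordant": self.n_concordant,
                "n_discordant": self.n_discordant,
                "discordant_genes": sorted(self.discordant_genes),
                "concordance": self.concordance}


def correlation_congruence(records_embryo: pd.DataFrame,
                           records_yolk: pd.DataFrame,
                           gene_universe: str = "pearson_all_strong",
                           cutoff: float = 0.5) -> CongruenceReport:
    """Sign agreement of stage correlations across tissues.

    ``pearson_all_strong`` compares genes strong by the pooled coefficient
    (r over all samples) in both tissues, on the sign of that coefficient.
    ``diabetic_unique_strong`` builds, per tissue, the genes strong only
    under the diabetic condition (strong in the diabetic stratum minus any
    gene strong in the normal stratum), intersects across tissues, and
    compares the diabetic-stratum signs.
    """
    if gene_universe not in GENE_UNIVERSES:
        raise ValueError(f"unknown gene universe {gene_universe!r}")
    stratum = "all" if gene_universe == "pearson_all_strong" else "diabetic"
    sets = {}
    for name, rec in (("embryo", records_embryo), ("yolk_sac", records_yolk)):
        corr, anti = select_strong(rec, cutoff=cutoff, stratum=stratum)
        strong = corr | anti
        if gene_universe == "diabetic_unique_strong":
            corr_n, anti_n = select_strong(rec, cutoff=cutoff, stratum="normal")
            strong = strong - (corr_n | anti_n)
        sets[name] = strong
    shared = sorted(sets["embryo"] & sets["yolk_sac"])
    re = records_embryo.set_index("gene_id")[f"r_{stratum}"]
    ry = records_yolk.set_index("gene_id")[f"r_{stratum}"]
    discordant = [g for g in shared if np.sign(re[g]) != np.sign(ry[g])]
    return CongruenceReport(universe=gene_universe, n_shared=len(shared),
                            n_concordant=len(shared) - len(discordant),
                            discordant_genes=discordant)


def de_direction_congruence(de_embryo: pd.DataFrame, de_yolk: pd.DataFrame,
                            ) -> CongruenceReport:
    """Fold-change direction agreement for genes significant in both tissues."""
    sig_e = de_embryo[de_embryo["significant"]].set_index("gene_id")["log2fc"]
    sig_y = de_yolk[de_yolk["significant"]].set_index("gene_id")["log2fc"]
    shared = sorted(set(sig_e.index) & set(sig_y.index))
    discordant = [g for g in shared if np.sign(sig_e[g]) != np.sign(sig_y[g])]
    return CongruenceReport(universe="de_significant_both", n_shared=len(shared),
                            n_concordant=len(shared) - len(discordant),
                            discordant_genes=discordant)


@dataclass
class CoordinationResult:
    """Per-conceptus composite coordinates and their OLS relationship."""

    points: pd.DataFrame  # conceptus_id, embryo_dim1, yolk_sac_dim1, condition
    slope: float
    intercept: float
    r_squared: float
    spread: dict[str, dict[str, float]]  # condition -> axis -> range

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept,
                "r_squared": self.r_squared, "spread": self.spread,
                "n_pairs": int(len(self.points))}


def composite_coordination(pca_embryo: PCAResult, pca_yolk: PCAResult,
                           meta: pd.DataFrame) -> CoordinationResult:
    """Relate each conceptus's embryo and yolk-sac Dimension-1 coordinates.

    Both PCAs are expected on the tissue-specific condition-discriminating
    (differentially expressed) gene subsets; each Dimension 1 is re-oriented
    so the normal condition's mean is positive, making the quadrant language
    well defined. Fits ordinary least squares of the yolk-sac coordinate on
    the embryo coordinate and reports the per-condition coordinate ranges.
    """
    pairs, _ = match_pairs(meta)
    pca_embryo = orient_dimension(pca_embryo, meta, dim=1)
    pca_yolk = orient_dimension(pca_yolk, meta, dim=1)
    ce = pca_embryo.coordinates["Dim1"]
    cy = pca_yolk.coordinates["Dim1"]
    pairs = pairs[pairs["embryo_sample"].isin(ce.index)
                  & pairs["yolk_sac_sample"].isin(cy.index)]
    if len(pairs) < 3:
        raise ValidationError("composite coordination needs >= 3 complete pairs")
    cond = meta.drop_duplicates("conceptus_id").set_index("conceptus_id")["condition"]
    points = pd.DataFrame({
        "conceptus_id": pairs["conceptus_id"].to_numpy(),
        "embryo_dim1": ce.loc[pairs["embryo_sample"]].to_numpy(),
        "yolk_sac_dim1": cy.loc[pairs["yolk_sac_sample"]].to_numpy(),
        "condition": cond.loc[pairs["conceptus_id"]].to_numpy(),
    })
    fit = stats.linregress(points["embryo_dim1"], points["yolk_sac_dim1"])
    spread = {}
    for c, grp in points.groupby("condition"):
        spread[c] = {
            "embryo_range": float(grp["embryo_dim1"].max() - grp["embryo_dim1"].min()),
            "yolk_sac_range": float(grp["yolk_sac_dim1"].max()
                                    - grp["yolk_sac_dim1"].min()),
        }
    return CoordinationResult(points=points, slope=float(fit.slope),
                              intercept=float(fit.intercept),
                              r_squared=float(fit.rvalue ** 2), spread=spread)
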