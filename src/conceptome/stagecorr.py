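"""Per-gene Pearson correlation of expression to somite stage.

The centerpiece of the pipeline: for every gene, the product-moment
correlation between its log-normalized expression and the embryo's
somite-pair count is computed over all samples of a tissue and separately
within each metabolic condition. Genes whose coefficient exceeds the strong
cutoff (|r| > 0.5, strict) form the correlated / anti-correlated sets; the
normal-vs-diabetic set algebra quantifies how the exposure redraws the
stage-coupled transcriptome, and per-gene shift classes (stable, weakened,
strengthened, reversed) describe how individual genes move.

Correlations use log-normalized values, not per-gene z-scores: scaling a
gene is an affine map and leaves Pearson r unchanged, but the normalization
choice does matter and is therefore fixed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ValidationError

STRATA = ("all", "normal", "diabetic")
SHIFT_CLASSES = ("stable", "weakened", "strengthened", "reversed", "NA")


def pearson_r(x, y) -> float:
    """Product-moment correlation; NaN when either vector is constant."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValidationError("pearson_r needs at least 3 observations")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd * xd).sum() * (yd * yd).sum())
    if denom == 0:
        return float("nan")
    return float(np.clip((xd * yd).sum() / denom, -1.0, 1.0))


def _rowwise_pearson(values: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Pearson r of every row of ``values`` against the vector ``s``."""
    sd = s - s.mean()
    s_ss = (sd * sd).sum()
    vd = values - values.mean(axis=1, keepdims=True)
    v_ss = (vd * vd).sum(axis=1)
    denom = np.sqrt(v_ss * s_ss)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vd @ sd) / denom
    r = np.where(denom > 0, r, np.nan)
    return np.clip(r, -1.0, 1.0)


def stage_correlations(norm: pd.DataFrame, meta: pd.DataFrame,
                       cutoff: float = 0.5, delta: float = 0.2,
                       ) -> pd.DataFrame:
    """Per-gene stage correlations overall and per condition, with classes.

    ``norm`` is a genes x samples log-normalized matrix for a single tissue.
    Returns one row per gene: ``r_all``, ``r_normal``, ``r_diabetic``, the
    strong classification per stratum, and the normal-to-diabetic shift
    class. A coefficient is NaN when the gene is constant in the stratum,
    the stratum has fewer than 3 samples, or it covers fewer than 3 distinct
    stage values.
    """
    meta_by_id = meta.set_index("sample_id")
    cond = meta_by_id.loc[norm.columns, "condition"].to_numpy()
    stage = meta_by_id.loc[norm.columns, "somite_pairs"].to_numpy(float)
    values = norm.to_numpy(float)
    out = {"gene_id": list(norm.index)}
    for stratum in STRATA:
        mask = np.ones(len(cond), bool) if stratum == "all" else cond == stratum
        if mask.sum() < 3 or len(np.unique(stage[mask])) < 3:
            import warnings
            warnings.warn(f"stratum {stratum!r} has too few samples or stage "
                          "values; coefficients set to NaN", stacklevel=2)
            out[f"r_{stratum}"] = np.full(values.shape[0], np.nan)
            continue
        out[f"r_{stratum}"] = _rowwise_pearson(values[:, mask], stage[mask])
    records = pd.DataFrame(out)
    for stratum in STRATA:
        records[f"class_{stratum}"] = [
            _strong_class(r, cutoff) for r in records[f"r_{stratum}"]]
    records["shift_class"] = [
        classify_shift(rn, rd, cutoff=cutoff, delta=delta)
        for rn, rd in zip(records["r_normal"], records["r_diabetic"])]
    return records


def _strong_class(r: float, cutoff: float) -> str:
    if np.isnan(r):
        return "NA"
    if r > cutoff:
        return "correlated"
    if r < -cutoff:
        return "anti_correlated"
    return "none"


def select_strong(records: pd.DataFrame, cutoff: float = 0.5,
                  stratum: str = "all") -> tuple[set[str], set[str]]:
    """Strongly correlated and anti-correlated gene sets for one stratum.

    The boundary is strict: |r| must exceed the cutoff; NaN coefficients are
    excluded from both sets.
    """
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}")
    r = records[f"r_{stratum}"]
    correlated = set(records.loc[r > cutoff, "gene_id"])
    anti = set(records.loc[r < -cutoff, "gene_id"])
    return correlated, anti


@dataclass
class CorrSetSummary:
    """Strong-set sizes per stratum and the normal/diabetic set algebra."""

    cutoff: float
    n_correlated: dict[str, int]
    n_anti_correlated: dict[str, int]
    tail_mass: dict[str, float]
    unique_to_normal: int
    unique_to_diabetic: int
    shared: int

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "n_correlated": self.n_correlated,
            "n_anti_correlated": self.n_anti_correlated,
            "tail_mass": self.tail_mass,
            "unique_to_normal": self.unique_to_normal,
            "unique_to_diabetic": self.unique_to_diabetic,
            "shared": self.shared,
        }


def correlation_set_algebra(records: pd.DataFrame, cutoff: float = 0.5,
                            ) -> CorrSetSummary:
    """Overlap algebra between the normal and diabetic strong sets.

    Sign-aware: a gene correlated in one condition but anti-correlated in the
    other is counted in both unique sets, never as shared. Tail mass is the
    fraction of genes with |r| > cutoff among non-NaN genes of each stratum.
    """
    n_corr, n_anti, tail = {}, {}, {}
    sets = {}
    for stratum in STRATA:
        c, a = select_strong(records, cutoff=cutoff, stratum=stratum)
        n_corr[stratum] = len(c)
        n_anti[stratum] = len(a)
        n_defined = int(records[f"r_{stratum}"].notna().sum())
        tail[stratum] = (len(c) + len(a)) / n_defined if n_defined else float("nan")
        sets[stratum] = (c, a)
    cn, an = sets["normal"]
    cd, ad = sets["diabetic"]
    shared = len(cn & cd) + len(an & ad)
    unique_normal = len((cn | an)) - len(cn & cd) - len(an & ad)
    unique_diabetic = len((cd | ad)) - len(cn & cd) - len(an & ad)
    return CorrSetSummary(cutoff=cutoff, n_correlated=n_corr,
                          n_anti_correlated=n_anti, tail_mass=tail,
                          unique_to_normal=unique_normal,
                          unique_to_diabetic=unique_diabetic, shared=shared)


def classify_shift(r_normal: float, r_diabetic: float, cutoff: float = 0.5,
                   delta: float = 0.2) -> str:
    """How a gene's stage correlation moves from normal to diabetic.

    ``reversed`` — the sign flips and at least one coefficient is strong;
    ``weakened`` / ``strengthened`` — |r| moves by at least ``delta`` down or
    up; ``stable`` otherwise; ``NA`` when either coefficient is undefined.
    """
    if np.isnan(r_normal) or np.isnan(r_diabetic):
        return "NA"
    if (np.sign(r_normal) != np.sign(r_diabetic)
            and max(abs(r_normal), abs(r_diabetic)) > cutoff):
        return "reversed"
    if abs(r_diabetic) <= abs(r_normal) - delta:
        return "weakened"
    if abs(r_diabetic) >= abs(r_normal) + delta:
        return "strengthened"
    return "stable"


def coefficient_histogram(records: pd.DataFrame, bins: int = 40,
                          ) -> pd.DataFrame:
    """Binned coefficient counts over [-1, 1] per stratum.

    Bins are half-open [lo, hi) with the last bin closed; NaN coefficients
    are excluded and reported in the ``n_na`` attribute column.
    """
    edges = np.linspace(-1.0, 1.0, bins + 1)
    rows = []
    for stratum in STRATA:
        r = records[f"r_{stratum}"].to_numpy(float)
        n_na = int(np.isnan(r).sum())
        counts, _ = np.histogram(r[~np.isnan(r)], bins=edges)
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            rows.append({"stratum": stratum, "bin_lo": lo, "bin_hi": hi,
                         "count": int(c), "n_na": n_na})
    return pd.DataFrame(rows)
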