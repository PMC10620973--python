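"""Gene filtering, library-size normalization, per-gene scaling, sex calls.

Normalization is log1p of counts-per-10k: ``log(1 + count / total * 1e4)``
with the natural logarithm. Scaling standardizes each gene across samples
(mean 0, unit variance, sample sd with ``ddof=1``); constant genes become
all-zero rows and are flagged rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import CountMatrix, ValidationError

FILTER_POLICIES = ("mean", "all", "any")

DEFAULT_X_MARKER = "Xist"
DEFAULT_Y_MARKERS = ("Ddx3y", "Uty", "Kdm5d")


@dataclass
class FilterReport:
    """Outcome of low-count filtering: what survived and what was removed."""

    n_input: int
    n_retained: int
    removed: list[str]

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def filter_low_counts(counts: CountMatrix, min_per_sample: float = 3,
                      policy: str = "mean",
                      ) -> tuple[CountMatrix, FilterReport]:
    """Drop weakly expressed genes before any downstream testing.

    Policies interpret "at least ``min_per_sample`` counts per sample" as:
    ``mean`` — mean count across samples >= threshold (default);
    ``all`` — every sample >= threshold; ``any`` — at least one sample >=
    threshold. All comparisons are inclusive at the boundary. The policies
    are nested: all => mean => any.
    """
    if policy not in FILTER_POLICIES:
        raise ValueError(f"unknown filter policy {policy!r}")
    values = counts.counts.to_numpy()
    if policy == "mean":
        keep = values.mean(axis=1) >= min_per_sample
    elif policy == "all":
        keep = (values >= min_per_sample).all(axis=1)
    else:
        keep = (values >= min_per_sample).any(axis=1)
    if not keep.any():
        raise ValidationError(
            f"no gene passes the {policy!r} filter at threshold "
            f"{min_per_sample}; review the threshold")
    removed = [g for g, k in zip(counts.gene_ids, keep) if not k]
    filtered = CountMatrix(counts.counts.loc[keep])
    return filtered, FilterReport(n_input=len(keep), n_retained=int(keep.sum()),
                                  removed=removed)


def lognormalize(counts: CountMatrix, scalefactor: float = 1e4) -> pd.DataFrame:
    """log1p counts-per-``scalefactor`` normalization (genes x samples).

    Invariant to multiplying a sample's counts and total by the same factor;
    zero counts map to exactly zero.
    """
    totals = counts.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(
            f"sample(s) with zero total counts: {zero.index.tolist()}")
    return np.log1p(counts.counts / totals * scalefactor)


@dataclass
class ScaledMatrix:
    """Per-gene standardized expression plus the list of constant genes."""

    values: pd.DataFrame
    constant_genes: list[str] = field(default_factory=list)


def scale_genes(norm: pd.DataFrame) -> ScaledMatrix:
    """Z-score each gene across samples (ddof=1); constant genes -> zeros."""
    if norm.shape[1] < 2:
        raise ValidationError("scaling requires at least 2 samples")
    values = norm.to_numpy(float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    scaled = (values - mean) / sd
    scaled[constant] = 0.0
    return ScaledMatrix(
        values=pd.DataFrame(scaled, index=norm.index, columns=norm.columns),
        constant_genes=[g for g, c in zip(norm.index, constant) if c])


def _call_one(x: float, y: float, tau_x: float, tau_y: float) -> str:
    if x > tau_x and y <= tau_y:
        return "female"
    if x <= tau_x and y > tau_y:
        return "male"
    return "unknown"


def infer_sex(norm_by_tissue: dict[str, pd.DataFrame], meta: pd.DataFrame,
              x_marker: str = DEFAULT_X_MARKER,
              y_markers: tuple[str, ...] = DEFAULT_Y_MARKERS,
              tau_x: float = 0.5, tau_y: float = 0.5,
              annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Call conceptus sex from X-inactivation and Y-chromosome markers.

    A sample is called female when the X marker (Xist by default) is expressed
    above ``tau_x`` while the summed Y markers (Ddx3y, Uty, Kdm5d) stay at or
    below ``tau_y``; male in the mirrored case; unknown when the two clauses
    conflict. Calls from the embryo and yolk-sac sample of a conceptus must
    agree, otherwise the conceptus is left unknown and flagged.

    Marker names are matched against the matrix index directly, or resolved
    through ``annotation`` symbols when provided. Returns one row per
    conceptus: call, mean marker levels, and the cross-tissue agreement flag.
    """
    meta_by_id = meta.set_index("sample_id")
    records: dict[str, dict] = {}
    for tissue, norm in norm_by_tissue.items():
        ids = _resolve_markers(norm.index, [x_marker, *y_markers], annotation)
        x_id, y_ids = ids[0], [i for i in ids[1:] if i is not None]
        for sid in norm.columns:
            cid = meta_by_id.loc[sid, "conceptus_id"]
            rec = records.setdefault(cid, {"calls": [], "x": [], "y": []})
            if x_id is None or not y_ids:
                rec["calls"].append("unknown")
                continue
            x = float(norm.loc[x_id, sid])
            y = float(norm.loc[y_ids, sid].sum())
            rec["x"].append(x)
            rec["y"].append(y)
            rec["calls"].append(_call_one(x, y, tau_x, tau_y))
    rows = []
    for cid, rec in records.items():
        calls = set(rec["calls"])
        agree = len(calls) == 1
        call = rec["calls"][0] if agree else "unknown"
        rows.append({"conceptus_id": cid, "call": call,
                     "x_level": float(np.mean(rec["x"])) if rec["x"] else np.nan,
                     "y_level": float(np.mean(rec["y"])) if rec["y"] else np.nan,
                     "tissues_agree": agree})
    return pd.DataFrame(rows)


def _resolve_markers(index, names, annotation) -> list:
    """Map marker names to row ids of the matrix (None when absent)."""
    symbol_map = {}
    if annotation is not None and "symbol" in annotation.columns:
        symbol_map = dict(zip(annotation["symbol"], annotation["gene_id"]))
    resolved = []
    for name in names:
        if name in index:
            resolved.append(name)
        elif symbol_map.get(name) in index:
            resolved.append(symbol_map[name])
        else:
            import warnings
            warnings.warn(f"marker gene {name!r} not found in matrix",
                          stacklevel=3)
            resolved.append(None)
    return resolved
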