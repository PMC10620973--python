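"""Synthetic paired embryo / yolk-sac UMI-count datasets with ground truth.

The generator emulates a two-condition developmental study: for each metabolic
condition (normal, diabetic) it creates ``n_per_condition`` conceptuses, each
contributing one embryo and one yolk-sac sample that share somite stage, sex,
dam and condition. Counts are negative-binomial with per-gene dispersion and
log-normal library-size variation, and the log mean follows

    log mu_gj = log(w_g * L_j)                       baseline x library size
              + ln2 * lfc_g * e_c * I[diabetic_j]    condition effect
              + beta_g(cond_j) * (s_j - s_bar)       somite-stage coupling
              + sex-marker gating                    X / Y marker genes

where ``w_g`` is the gene's relative abundance, ``L_j`` the sample's library
size, ``s_j`` the somite-pair count (centered so the baseline is
stage-independent), and ``e_c`` a per-conceptus exposure-severity factor
(shared by both tissues of a conceptus) that makes the diabetic response
heterogeneous across individuals, as bulk exposures are.

Planted gene classes are disjoint:

* ``de_embryo`` / ``de_yolk`` / ``de_shared`` — condition effects in one or
  both tissues (shared genes keep the same signed log2 fold change in both);
* ``stage_shared`` — somite-stage slope of equal sign in both tissues and
  both conditions;
* ``stage_diabetic_only`` — slope only under the diabetic condition;
* ``stage_reversed`` — slope of opposite sign in the two conditions;
* ``x_marker`` / ``y_marker`` — female-only / male-only expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import CountMatrix, Dataset, validate_dataset

GENE_CLASSES = ("null", "de_embryo", "de_yolk", "de_shared", "stage_shared",
                "stage_diabetic_only", "stage_reversed", "x_marker", "y_marker")

MARKER_SYMBOLS = ("Xist", "Ddx3y", "Uty", "Kdm5d")


@dataclass
class SimConfig:
    """Study-design and generative-model parameters.

    Defaults reproduce the reference design: 33 conceptuses per condition,
    somite stages 5-9 with frequency profile 24:10:11:13:8 over 66, sex split
    29 female : 37 male, and a mean library of 2e5 UMI counts (a scaled-down
    library at a desk-scale gene count of 4,000).
    """

    n_per_condition: int = 33
    somite_levels: tuple[int, ...] = (5, 6, 7, 8, 9)
    somite_props: tuple[float, ...] = (24, 10, 11, 13, 8)
    female_fraction: float = 29 / 66
    n_dams: tuple[int, int] = (10, 12)  # (normal, diabetic) litters

    n_genes: int = 4000
    mean_library_size: float = 2.0e5
    library_sigma: float = 0.25          # sd of log library size
    dispersion_median: float = 0.05      # NB dispersion, log-normal across genes
    dispersion_sigma: float = 0.5
    abundance_sigma: float = 1.2         # sd of log relative abundance

    n_de_embryo: int = 150
    n_de_yolk: int = 40
    n_de_shared: int = 30
    n_stage_shared: int = 150
    n_stage_diabetic_only: int = 150
    n_stage_reversed: int = 20
    n_x_markers: int = 1
    n_y_markers: int = 3

    de_log2fc_range: tuple[float, float] = (0.3, 1.5)
    stage_slope: float = 0.25            # natural-log units per somite pair
    exposure_sd: float = 0.35            # conceptus-level severity spread
    marker_mean_count: float = 200.0     # expected marker counts in the on-sex
    marker_off_factor: float = 1e-4      # leak of markers in the off-sex
    min_planted_mean: float = 20.0       # floor on planted genes' baseline count
    x_chrom_fraction: float = 0.04       # background genes annotated to X

    def __post_init__(self) -> None:
        if len(self.somite_levels) != len(self.somite_props):
            raise ValueError("somite_levels and somite_props lengths differ")
        if any(p < 0 for p in self.somite_props) or sum(self.somite_props) <= 0:
            raise ValueError("somite_props must be nonnegative with positive sum")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must be in [0, 1]")
        if self.n_planted > self.n_genes:
            raise ValueError(
                f"planted gene classes ({self.n_planted}) exceed n_genes "
                f"({self.n_genes})")
        for name in ("mean_library_size", "dispersion_median", "library_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_planted(self) -> int:
        return (self.n_de_embryo + self.n_de_yolk + self.n_de_shared
                + self.n_stage_shared + self.n_stage_diabetic_only
                + self.n_stage_reversed + self.n_x_markers + self.n_y_markers)


def null_config(**overrides) -> SimConfig:
    """A configuration with every planted effect removed (pure noise)."""
    cfg = SimConfig(n_de_embryo=0, n_de_yolk=0, n_de_shared=0,
                    n_stage_shared=0, n_stage_diabetic_only=0,
                    n_stage_reversed=0, n_x_markers=0, n_y_markers=0)
    return replace(cfg, **overrides)


@dataclass
class SyntheticTruth:
    """Ground-truth labels for a simulated dataset.

    ``genes`` has one row per gene: class, chromosome, signed log2 fold
    change per tissue, somite slope per (tissue, condition), baseline
    relative abundance, NB dispersion, and sex-marker role. ``samples`` has
    one row per sample: the design columns plus the true library size and the
    conceptus exposure-severity factor.
    """

    genes: pd.DataFrame
    samples: pd.DataFrame
    config: SimConfig = field(repr=False, default=None)

    def genes_in_class(self, cls: str) -> list[str]:
        return self.genes.loc[self.genes["gene_class"] == cls, "gene_id"].tolist()


def _largest_remainder(props, total: int) -> np.ndarray:
    """Integer allocation of `total` across categories proportional to props."""
    props = np.asarray(props, dtype=float)
    quota = props / props.sum() * total
    alloc = np.floor(quota).astype(int)
    rem = total - alloc.sum()
    order = np.argsort(-(quota - alloc), kind="stable")
    alloc[order[:rem]] += 1
    return alloc


def generate_design(config: SimConfig, seed: int) -> pd.DataFrame:
    """Draw the sample design: paired conceptuses with stage, sex and dam.

    Somite-stage counts match the configured frequency profile as closely as
    integer rounding allows, split across conditions as evenly as possible;
    sexes follow the configured ratio. Deterministic given (config, seed).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    n = config.n_per_condition
    total_counts = _largest_remainder(config.somite_props, 2 * n)
    half = total_counts // 2
    odd_idx = np.flatnonzero(total_counts % 2 == 1)
    per_cond = {c: half.copy() for c in ("normal", "diabetic")}
    if len(odd_idx):
        order = rng.permutation(odd_idx)
        for k, i in enumerate(order):
            per_cond["normal" if k % 2 == 0 else "diabetic"][i] += 1
    # even out totals if the alternation left the conditions unbalanced
    diff = per_cond["normal"].sum() - n
    if diff != 0:  # pragma: no cover - only for pathological profiles
        donor, recv = (("normal", "diabetic") if diff > 0 else ("diabetic", "normal"))
        for _ in range(abs(diff)):
            i = int(np.argmax(per_cond[donor]))
            per_cond[donor][i] -= 1
            per_cond[recv][i] += 1

    n_female = int(round(config.female_fraction * 2 * n))
    sexes = np.array(["female"] * n_female + ["male"] * (2 * n - n_female))
    rng.shuffle(sexes)

    rows = []
    k = 0
    for cond, prefix, n_dams in (("normal", "N", config.n_dams[0]),
                                 ("diabetic", "D", config.n_dams[1])):
        stages = np.repeat(config.somite_levels, per_cond[cond])
        rng.shuffle(stages)
        for i in range(n):
            cid = f"{prefix}{i + 1:02d}"
            dam = f"{prefix}dam{(i % n_dams) + 1:02d}"
            for tissue in ("embryo", "yolk_sac"):
                rows.append({"sample_id": f"{cid}_{tissue}", "tissue": tissue,
                             "condition": cond, "somite_pairs": int(stages[i]),
                             "conceptus_id": cid, "dam_id": dam,
                             "sex": sexes[k]})
            k += 1
    return pd.DataFrame(rows)


def generate_truth(config: SimConfig, design: pd.DataFrame, seed: int,
                   ) -> SyntheticTruth:
    """Assign disjoint gene classes, effect sizes, baselines and library sizes.

    Planted genes are drawn from the better-expressed part of the baseline
    abundance distribution (expected count >= ``min_planted_mean`` at the mean
    library size) so that the planted slopes translate into their intended
    population correlations rather than being drowned by shot noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    G = config.n_genes
    gene_ids = np.array([f"g{i + 1:05d}" for i in range(G)])

    log_w = rng.normal(0.0, config.abundance_sigma, size=G)
    w = np.exp(log_w)
    w /= w.sum()
    dispersion = np.exp(rng.normal(np.log(config.dispersion_median),
                                   config.dispersion_sigma, size=G))

    expected = w * config.mean_library_size
    eligible = np.flatnonzero(expected >= config.min_planted_mean)
    if len(eligible) < config.n_planted:
        raise ValueError(
            f"only {len(eligible)} genes exceed the planted-gene baseline "
            f"floor, but {config.n_planted} planted genes requested")
    chosen = rng.choice(eligible, size=config.n_planted, replace=False)

    gene_class = np.full(G, "null", dtype=object)
    lfc = {"embryo": np.zeros(G), "yolk_sac": np.zeros(G)}
    slope = {("embryo", "normal"): np.zeros(G),
             ("embryo", "diabetic"): np.zeros(G),
             ("yolk_sac", "normal"): np.zeros(G),
             ("yolk_sac", "diabetic"): np.zeros(G)}
    sex_role = np.full(G, "none", dtype=object)

    pos = 0

    def take(k: int) -> np.ndarray:
        nonlocal pos
        idx = chosen[pos:pos + k]
        pos += k
        return idx

    lo, hi = config.de_log2fc_range
    for cls, k in (("de_embryo", config.n_de_embryo),
                   ("de_yolk", config.n_de_yolk),
                   ("de_shared", config.n_de_shared)):
        idx = take(k)
        gene_class[idx] = cls
        mag = rng.uniform(lo, hi, size=k) * rng.choice([-1.0, 1.0], size=k)
        if cls in ("de_embryo", "de_shared"):
            lfc["embryo"][idx] = mag
        if cls in ("de_yolk", "de_shared"):
            lfc["yolk_sac"][idx] = mag

    beta = config.stage_slope
    idx = take(config.n_stage_shared)
    gene_class[idx] = "stage_shared"
    sign = rng.choice([-1.0, 1.0], size=len(idx))
    for key in slope:
        slope[key][idx] = sign * beta

    idx = take(config.n_stage_diabetic_only)
    gene_class[idx] = "stage_diabetic_only"
    sign = rng.choice([-1.0, 1.0], size=len(idx))
    for tissue in ("embryo", "yolk_sac"):
        slope[(tissue, "diabetic")][idx] = sign * beta

    idx = take(config.n_stage_reversed)
    gene_class[idx] = "stage_reversed"
    sign = rng.choice([-1.0, 1.0], size=len(idx))
    for tissue in ("embryo", "yolk_sac"):
        slope[(tissue, "normal")][idx] = sign * beta
        slope[(tissue, "diabetic")][idx] = -sign * beta

    marker_w = config.marker_mean_count / config.mean_library_size
    x_idx = take(config.n_x_markers)
    gene_class[x_idx] = "x_marker"
    sex_role[x_idx] = "x_marker"
    w[x_idx] = marker_w
    y_idx = take(config.n_y_markers)
    gene_class[y_idx] = "y_marker"
    sex_role[y_idx] = "y_marker"
    w[y_idx] = marker_w / 2  # individual Y markers sit lower than Xist

    chromosome = rng.choice([str(i) for i in range(1, 20)], size=G)
    n_x_bg = int(config.x_chrom_fraction * G)
    bg = np.flatnonzero(gene_class == "null")
    chromosome[rng.choice(bg, size=min(n_x_bg, len(bg)), replace=False)] = "X"
    chromosome[x_idx] = "X"
    chromosome[y_idx] = "Y"

    symbol = gene_ids.astype(object).copy()
    for j, gi in enumerate(np.concatenate([x_idx, y_idx])):
        symbol[gi] = MARKER_SYMBOLS[j]

    genes = pd.DataFrame({
        "gene_id": gene_ids, "symbol": symbol, "chromosome": chromosome,
        "gene_class": gene_class,
        "baseline_weight": w / w.sum(),
        "dispersion": dispersion,
        "lfc_embryo": lfc["embryo"], "lfc_yolk_sac": lfc["yolk_sac"],
        "slope_normal_embryo": slope[("embryo", "normal")],
        "slope_diabetic_embryo": slope[("embryo", "diabetic")],
        "slope_normal_yolk_sac": slope[("yolk_sac", "normal")],
        "slope_diabetic_yolk_sac": slope[("yolk_sac", "diabetic")],
        "sex_role": sex_role,
    })

    samples = design.copy()
    mu_log = np.log(config.mean_library_size) - config.library_sigma ** 2 / 2
    samples["library_size"] = np.exp(
        rng.normal(mu_log, config.library_sigma, size=len(samples)))
    severity = {}
    for cid, cond in design.drop_duplicates("conceptus_id")[
            ["conceptus_id", "condition"]].itertuples(index=False):
        if cond == "diabetic" and config.exposure_sd > 0:
            shape = 1.0 / config.exposure_sd ** 2
            severity[cid] = rng.gamma(shape, 1.0 / shape)
        else:
            severity[cid] = 1.0 if cond == "diabetic" else 0.0
    samples["exposure_severity"] = samples["conceptus_id"].map(severity)
    return SyntheticTruth(genes=genes, samples=samples, config=config)


def simulate_counts(design: pd.DataFrame, truth: SyntheticTruth,
                    config: SimConfig, seed: int) -> Dataset:
    """Sample NB counts per tissue from the generative model.

    Returns a validated :class:`Dataset` whose annotation carries the marker
    genes on the X / Y chromosomes. Deterministic given (truth, seed).
    """
    g = truth.genes
    samples = truth.samples
    s_bar = samples.drop_duplicates("conceptus_id")["somite_pairs"].mean()
    counts: dict[str, CountMatrix] = {}
    for t_i, tissue in enumerate(("embryo", "yolk_sac")):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 303, t_i]))
        sub = samples[samples["tissue"] == tissue].reset_index(drop=True)
        diab = (sub["condition"] == "diabetic").to_numpy(float)
        stage = sub["somite_pairs"].to_numpy(float) - s_bar
        sev = sub["exposure_severity"].to_numpy(float)
        lib = sub["library_size"].to_numpy(float)
        female = (sub["sex"] == "female").to_numpy(float)

        w = g["baseline_weight"].to_numpy()
        lfc = g[f"lfc_{tissue}"].to_numpy()
        b_n = g[f"slope_normal_{tissue}"].to_numpy()
        b_d = g[f"slope_diabetic_{tissue}"].to_numpy()
        log_mu = (np.log(np.outer(w, lib))
                  + np.log(2.0) * np.outer(lfc, diab * sev)
                  + np.outer(b_n, stage * (1 - diab))
                  + np.outer(b_d, stage * diab))
        x_mask = (g["sex_role"] == "x_marker").to_numpy()
        y_mask = (g["sex_role"] == "y_marker").to_numpy()
        off = np.log(config.marker_off_factor)
        log_mu[x_mask] += off * (1 - female)[None, :]
        log_mu[y_mask] += off * female[None, :]

        mu = np.exp(np.clip(log_mu, -50, 50))
        alpha = g["dispersion"].to_numpy()[:, None]
        size = 1.0 / alpha
        p = size / (size + mu)
        y = rng.negative_binomial(size, p)
        counts[tissue] = CountMatrix(
            pd.DataFrame(y.astype(np.int64), index=g["gene_id"].to_numpy(),
                         columns=sub["sample_id"].to_numpy()))
    annotation = g[["gene_id", "chromosome", "symbol"]].copy()
    lo, hi = min(config.somite_levels), max(config.somite_levels)
    return validate_dataset(counts, design, annotation, somite_window=(lo, hi))


def simulate_dataset(config: SimConfig, seed: int,
                     ) -> tuple[Dataset, SyntheticTruth]:
    """Design, truth and counts in one call (the usual entry point)."""
    design = generate_design(config, seed)
    truth = generate_truth(config, design, seed)
    dataset = simulate_counts(design, truth, config, seed)
    return dataset, truth
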