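"""Detection of isotope-labelled OTUs from SIP density-gradient count tables.

A stable-isotope-probing (SIP) experiment separates nucleic acids along an
isopycnic density gradient and sequences every fraction.  Because fully
15N-labelled RNA is only ~0.015 g/ml denser than unlabelled RNA, labelled
templates never form a separated peak; instead, an actively 15N-incorporating
taxon shows a higher-than-average share of its reads in the fractions where
labelled template is expected ("heavy" fractions in RNA-SIP, "light"
fractions in a bis-benzimide secondary DNA gradient).

The caller implemented here treats the fractions of a single gradient as two
groups of replicate count samples (labelled-window vs unlabelled-window
fractions), normalizes them with median-of-ratios size factors, estimates a
per-OTU negative-binomial dispersion with shrinkage toward a mean-dispersion
trend, fits a two-group NB log-linear model per OTU, and calls enrichment
with a one-sided Wald test, Benjamini-Hochberg corrected within the
gradient.  Model calls are then confirmed by an abundance floor on the mean
normalized count and a "hump-shape" diagnostic that requires the OTU's
density profile to peak inside the labelled window.

An alternative mode compares the labelled-window fractions of a 15N gradient
against the same window of an unlabelled control gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DensityWindows",
    "GradientFractionTable",
    "HumpResult",
    "assign_fraction_classes",
    "normalize_copy_profile",
    "filter_sparse_otus",
    "estimate_size_factors",
    "estimate_dispersions",
    "fit_nb_two_group",
    "test_enrichment",
    "call_gradient",
    "compare_to_control_mode",
    "hump_shape_diagnostic",
    "consolidate_calls",
]

DISPERSION_FLOOR = 1e-8

LABELLED = "labelled"
UNLABELLED = "unlabelled"
EXCLUDED = "excluded"


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class DensityWindows:
    """Buoyant-density windows delimiting where labelled template concentrates.

    ``orientation`` records whether labelled template runs heavy (RNA in
    CsTFA) or light (DNA in a bis-benzimide secondary CsCl gradient); it
    determines which outermost window boundary is treated as closed.
    """

    labelled: tuple[float, float]
    unlabelled: tuple[float, float]
    orientation: str = "labelled-is-heavy"

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("labelled", self.labelled), ("unlabelled", self.unlabelled)):
            if not lo < hi:
                raise ValueError(f"{name} window must have lo < hi, got ({lo}, {hi})")
        lo1, hi1 = sorted([self.labelled, self.unlabelled])[0]
        lo2, hi2 = sorted([self.labelled, self.unlabelled])[1]
        if hi1 > lo2:
            raise ValueError("density windows may only touch at a shared boundary")
        if self.orientation not in ("labelled-is-heavy", "labelled-is-light"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @classmethod
    def rna_default(cls) -> "DensityWindows":
        """RNA-CsTFA windows: heavy 1.785-1.820, light 1.740-1.785 g/ml."""
        return cls(labelled=(1.785, 1.820), unlabelled=(1.740, 1.785), orientation="labelled-is-heavy")

    @classmethod
    def dna_default(cls) -> "DensityWindows":
        """Secondary DNA gradient: labelled template light, 1.665-1.695 g/ml."""
        return cls(labelled=(1.665, 1.695), unlabelled=(1.695, 1.750), orientation="labelled-is-light")

    def classify(self, density: float) -> str:
        """Class of a single fraction density.

        Windows are half-open [lo, hi); the outermost boundary of the pair
        (the highest hi) is additionally closed so the extreme fraction is
        not dropped.
        """
        outer_hi = max(self.labelled[1], self.unlabelled[1])
        for cls_name, (lo, hi) in ((LABELLED, self.labelled), (UNLABELLED, self.unlabelled)):
            if lo <= density < hi or (hi == outer_hi and density == hi):
                return cls_name
        return EXCLUDED


@dataclass
class GradientFractionTable:
    """Counts and metadata of the sequenced fractions of one SIP gradient.

    ``counts`` is fractions x OTUs; ``densities`` and ``copy_quant`` are
    indexed like its rows.  ``classes`` is filled by
    :func:`assign_fraction_classes`.
    """

    gradient_id: str
    label_status: str  # "15N" or "14N-control"
    medium: str  # "RNA-CsTFA" or "DNA-CsCl-secondary"
    timepoint: float
    densities: pd.Series
    counts: pd.DataFrame
    copy_quant: pd.Series | None = None
    classes: pd.Series | None = None

    def __post_init__(self) -> None:
        self.densities = pd.Series(self.densities, dtype=float)
        if not self.densities.index.equals(self.counts.index):
            raise ValueError(f"gradient {self.gradient_id}: density index does not match count rows")
        diffs = np.diff(self.densities.to_numpy())
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError(f"gradient {self.gradient_id}: densities must be strictly monotone")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError(f"gradient {self.gradient_id}: negative counts")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError(f"gradient {self.gradient_id}: counts must be integers")

    @property
    def otu_ids(self) -> pd.Index:
        return self.counts.columns

    def with_otus(self, otus: Sequence[str]) -> "GradientFractionTable":
        """Copy of the table restricted to the given OTU columns."""
        return replace(self, counts=self.counts[list(otus)].copy())


# ---------------------------------------------------------------------------
# fraction bookkeeping


def assign_fraction_classes(table: GradientFractionTable, windows: DensityWindows) -> GradientFractionTable:
    """Label each fraction of a gradient as labelled / unlabelled / excluded.

    Raises if either analysis class ends up with fewer than two fractions,
    since the downstream two-group model needs replication on both sides.
    """
    classes = table.densities.map(windows.classify)
    for cls_name in (LABELLED, UNLABELLED):
        n = int((classes == cls_name).sum())
        if n < 2:
            raise ValueError(
                f"gradient {table.gradient_id}: only {n} fraction(s) classified {cls_name}; "
                "need at least 2 per class"
            )
    out = replace(table)
    out.classes = classes.rename("class")
    return out


def normalize_copy_profile(table: GradientFractionTable) -> pd.Series:
    """Per-fraction share of the gradient's total template (qPCR profile).

    Mirrors the standard gradient QC plot: the proportion of rRNA copies
    recovered from each fraction out of the whole gradient, summing to 1.
    """
    if table.copy_quant is None:
        raise ValueError(f"gradient {table.gradient_id}: no copy quantification available")
    q = pd.Series(table.copy_quant, dtype=float)
    if (q < 0).any():
        raise ValueError("copy quantities must be non-negative")
    total = q.sum()
    if total <= 0:
        raise ValueError(f"gradient {table.gradient_id}: all-zero copy quantification")
    return q / total


def filter_sparse_otus(
    tables: Sequence[GradientFractionTable],
    min_total: int = 10,
    min_prevalence: float = 0.20,
) -> tuple[list[GradientFractionTable], pd.DataFrame]:
    """Remove sparse OTUs jointly across every fraction of every gradient.

    An OTU is removed if its total count over all samples is below
    ``min_total`` OR it appears (count > 0) in less than ``min_prevalence``
    of the samples; OTUs sitting exactly on either boundary are kept.
    Returns the filtered tables and a per-OTU removal report.
    """
    if not tables:
        raise ValueError("need at least one gradient table")
    combined = pd.concat([t.counts for t in tables], axis=0)
    total = combined.sum(axis=0)
    prevalence = (combined > 0).mean(axis=0)
    kept = (total >= min_total) & (prevalence >= min_prevalence)
    reason = np.where(
        kept, "",
        np.where(total < min_total,
                 np.where(prevalence < min_prevalence, "total+prevalence", "total"),
                 "prevalence"),
    )
    report = pd.DataFrame(
        {"total_count": total, "prevalence": prevalence, "kept": kept, "removal_reason": reason}
    )
    keep_ids = list(combined.columns[kept])
    return [t.with_otus(keep_ids) for t in tables], report


# ---------------------------------------------------------------------------
# normalization and dispersion


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (samples are rows, OTUs columns).

    Each sample's factor is the median, over reference OTUs, of its counts
    divided by the OTU's geometric mean across samples; reference OTUs are
    those detected in every sample.  Factors are rescaled to geometric
    mean 1.  If no OTU is detected everywhere, geometric means are computed
    over positive counts only (with a warning).
    """
    if counts.shape[0] < 2:
        raise ValueError("need at least two samples to estimate size factors")
    arr = counts.to_numpy(dtype=float)
    all_positive = (arr > 0).all(axis=0)
    with np.errstate(divide="ignore"):
        log_arr = np.log(arr)
    if all_positive.any():
        ref = all_positive
        log_gm = log_arr[:, ref].mean(axis=0)
        ratios = log_arr[:, ref] - log_gm[None, :]
        log_factors = np.median(ratios, axis=1)
    else:
        warnings.warn(
            "no OTU detected in every sample; falling back to positive-count geometric means",
            stacklevel=2,
        )
        pos = arr > 0
        with np.errstate(invalid="ignore"):
            log_gm = np.where(pos, log_arr, np.nan)
        log_gm = np.nanmean(log_gm, axis=0)
        log_factors = np.empty(arr.shape[0])
        for j in range(arr.shape[0]):
            r = log_arr[j, pos[j, :]] - log_gm[pos[j, :]]
            if r.size == 0:
                raise ValueError(f"sample {counts.index[j]!r} has no positive counts")
            log_factors[j] = np.median(r)
    log_factors = log_factors - log_factors.mean()  # geometric mean 1
    return pd.Series(np.exp(log_factors), index=counts.index, name="size_factor")


def estimate_dispersions(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    shrinkage_weight: float = 0.5,
    floor: float = DISPERSION_FLOOR,
) -> pd.DataFrame:
    """Per-OTU NB dispersion: method of moments shrunk toward a fitted trend.

    Raw per-OTU estimates on normalized counts, alpha = max(0, (s^2-m)/m^2),
    are shrunk in log space toward the trend alpha(mu) = a/mu + b fitted by
    least squares over OTUs with a positive raw estimate.  OTUs whose raw
    estimate is zero (at or below Poisson variability) keep the floor;
    zero-mean OTUs are flagged untestable.
    """
    if counts.shape[0] < 3:
        raise ValueError("need at least three samples for moment dispersion estimation")
    q = counts.to_numpy(dtype=float) / size_factors.to_numpy(dtype=float)[:, None]
    m = q.mean(axis=0)
    v = q.var(axis=0, ddof=1)
    testable = m > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(testable, np.maximum(0.0, (v - m) / m**2), np.nan)

    fit_mask = testable & (raw > 0)
    if fit_mask.sum() >= 2:
        X = np.column_stack([1.0 / m[fit_mask], np.ones(fit_mask.sum())])
        coef, *_ = np.linalg.lstsq(X, raw[fit_mask], rcond=None)
        a, b = np.maximum(coef, 0.0)
    else:  # nearly everything at the Poisson floor: flat trend at the floor
        a, b = 0.0, floor
    with np.errstate(divide="ignore", invalid="ignore"):
        trend = np.where(testable, a / m + b, np.nan)
    trend = np.maximum(trend, floor)

    final = np.full_like(raw, np.nan)
    pos = fit_mask
    final[pos] = np.exp(
        shrinkage_weight * np.log(raw[pos]) + (1.0 - shrinkage_weight) * np.log(trend[pos])
    )
    final[testable & ~pos] = floor
    final = np.where(testable, np.maximum(final, floor), np.nan)

    return pd.DataFrame(
        {
            "mean_norm_count": m,
            "raw_dispersion": raw,
            "trend_dispersion": trend,
            "final_dispersion": final,
            "testable": testable,
        },
        index=counts.columns,
    )


# ---------------------------------------------------------------------------
# negative-binomial two-group model


def fit_nb_two_group(
    counts: np.ndarray,
    size_factors: np.ndarray,
    group: np.ndarray,
    dispersions: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
    eta_bound: float = 30.0,
) -> dict[str, np.ndarray]:
    """Fit K_ij ~ NB(mu_ij, alpha_i) with log mu_ij = log s_j + b0_i + b1_i x_j.

    Vectorized Fisher scoring over OTUs (rows of ``counts``); ``group`` is
    the 0/1 indicator of the labelled class over samples (columns).  Returns
    per-OTU arrays: coefficients, standard error of b1, one-sided Wald
    p-value for b1 > 0, and the Wald z statistic.  Linear predictors are
    clamped to +-``eta_bound`` so groups with all-zero counts degenerate
    gracefully instead of diverging.
    """
    K = np.asarray(counts, dtype=float)
    s = np.asarray(size_factors, dtype=float)
    x = np.asarray(group, dtype=float)
    alpha = np.asarray(dispersions, dtype=float)[:, None]
    if K.ndim != 2:
        raise ValueError("counts must be 2-D (OTUs x samples)")
    n_otus, n_samples = K.shape
    if not ((x == 0) | (x == 1)).all() or x.sum() == 0 or x.sum() == n_samples:
        raise ValueError("group must be a 0/1 indicator with both groups present")

    # moment-based initialization from group means of normalized counts
    q = K / s[None, :]
    m0 = q[:, x == 0].mean(axis=1)
    m1 = q[:, x == 1].mean(axis=1)
    eps = 1e-4
    b0 = np.log(np.maximum(m0, eps))
    b1 = np.log(np.maximum(m1, eps)) - b0

    logs = np.log(s)[None, :]
    for _ in range(max_iter):
        eta = np.clip(b0[:, None] + b1[:, None] * x[None, :], -eta_bound, eta_bound)
        mu = np.exp(eta + logs)
        denom = 1.0 + alpha * mu
        r = (K - mu) / denom  # score contributions per sample
        W = mu / denom  # Fisher weights
        U0 = r.sum(axis=1)
        U1 = (r * x[None, :]).sum(axis=1)
        I00 = W.sum(axis=1)
        I01 = (W * x[None, :]).sum(axis=1)
        I11 = I01  # x is binary, x^2 == x
        det = np.maximum(I00 * I11 - I01**2, 1e-300)
        step0 = (I11 * U0 - I01 * U1) / det
        step1 = (I00 * U1 - I01 * U0) / det
        step0 = np.clip(step0, -5.0, 5.0)
        step1 = np.clip(step1, -5.0, 5.0)
        b0 = np.clip(b0 + step0, -eta_bound, eta_bound)
        b1 = np.clip(b1 + step1, -2 * eta_bound, 2 * eta_bound)
        if max(np.abs(step0).max(initial=0.0), np.abs(step1).max(initial=0.0)) < tol:
            break

    eta = np.clip(b0[:, None] + b1[:, None] * x[None, :], -eta_bound, eta_bound)
    mu = np.exp(eta + logs)
    denom = 1.0 + alpha * mu
    W = mu / denom
    I00 = W.sum(axis=1)
    I01 = (W * x[None, :]).sum(axis=1)
    det = np.maximum(I00 * I01 - I01**2, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        se_b1 = np.sqrt(I00 / det)
    z = b1 / se_b1
    p_one_sided = stats.norm.sf(z)
    return {
        "b0": b0,
        "b1": b1,
        "se_b1": se_b1,
        "wald_z": z,
        "wald_p": p_one_sided,
        "mean_unlabelled": m0,
        "mean_labelled": m1,
    }


def _check_groups(counts: pd.DataFrame, group: np.ndarray, gradient_id: str) -> None:
    for g, name in ((0, UNLABELLED), (1, LABELLED)):
        sub = counts.to_numpy()[group == g, :]
        if sub.shape[0] < 2:
            raise ValueError(f"gradient {gradient_id}: {name} class has fewer than 2 fractions")
        if sub.sum() == 0:
            raise ValueError(f"gradient {gradient_id}: {name} class is all zero")


def _enrichment_frame(
    counts: pd.DataFrame,
    group: np.ndarray,
    size_factors: pd.Series,
    dispersions: pd.DataFrame,
    gradient_id: str,
    lfc_threshold: float,
    alpha: float,
    mode: str,
) -> pd.DataFrame:
    """Shared NB/Wald/BH machinery behind both comparison modes."""
    testable = dispersions["testable"].to_numpy()
    if not testable.any():
        raise ValueError(f"gradient {gradient_id}: no testable OTU (all zero)")
    _check_groups(counts, group, gradient_id)

    otus = counts.columns
    K = counts.to_numpy(dtype=float).T[testable, :]
    disp = dispersions.loc[testable, "final_dispersion"].to_numpy()
    fit = fit_nb_two_group(K, size_factors.to_numpy(), group, disp)

    ln2 = np.log(2.0)
    lfc = fit["b1"] / ln2
    # groups with no reads at all: report the pseudo-mean ratio instead of a clamp
    degenerate = (fit["mean_labelled"] == 0) | (fit["mean_unlabelled"] == 0)
    pseudo = np.log2((fit["mean_labelled"] + 0.5) / (fit["mean_unlabelled"] + 0.5))
    lfc = np.where(degenerate, pseudo, lfc)

    padj = multipletests(fit["wald_p"], method="fdr_bh")[1]
    base_mean = (
        counts.to_numpy(dtype=float) / size_factors.to_numpy()[:, None]
    ).mean(axis=0)[testable]

    res = pd.DataFrame(
        {
            "otu_id": otus[testable],
            "gradient_id": gradient_id,
            "base_mean": base_mean,
            "log2_fold_change": lfc,
            "wald_se": fit["se_b1"],
            "wald_p": fit["wald_p"],
            "padj": padj,
            "mode": mode,
        }
    )
    res["model_enriched"] = (res["padj"] < alpha) & (res["log2_fold_change"] > lfc_threshold)
    return res.set_index("otu_id")


def test_enrichment(
    table: GradientFractionTable,
    size_factors: pd.Series | None = None,
    dispersions: pd.DataFrame | None = None,
    lfc_threshold: float = 0.25,
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Call 15N-enriched OTUs within one gradient (labelled vs unlabelled fractions).

    Requires fraction classes (see :func:`assign_fraction_classes`).  Size
    factors and dispersions default to estimates on this gradient's analysed
    fractions.  Returns one row per testable OTU with the NB log2
    fold-change (labelled over unlabelled), one-sided Wald p, BH-adjusted p
    within the gradient, mean normalized count, and the model-enrichment
    flag padj < alpha AND log2FC > lfc_threshold.
    """
    if table.classes is None:
        raise ValueError("fraction classes not assigned; call assign_fraction_classes first")
    keep = table.classes.isin([LABELLED, UNLABELLED])
    counts = table.counts.loc[keep]
    group = (table.classes[keep] == LABELLED).to_numpy().astype(int)
    _check_groups(counts, group, table.gradient_id)
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    else:
        size_factors = size_factors.loc[counts.index]
    if dispersions is None:
        dispersions = estimate_dispersions(counts, size_factors)
    return _enrichment_frame(
        counts, group, size_factors, dispersions,
        table.gradient_id, lfc_threshold, alpha, mode="within-gradient",
    )


def compare_to_control_mode(
    labelled_gradient: GradientFractionTable,
    control_gradient: GradientFractionTable,
    windows: DensityWindows,
    lfc_threshold: float = 0.25,
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Alternative calling mode: labelled-window fractions, 15N vs control gradient.

    Compares only the fractions where labelled template is expected to
    concentrate, between the labelled gradient and an unlabelled control
    gradient, using the same NB/Wald machinery.  More exposed to
    between-vial ("bottle") effects than the within-gradient mode.
    """
    if not labelled_gradient.otu_ids.equals(control_gradient.otu_ids):
        raise ValueError("gradients must share the same OTU universe")
    parts = []
    for tab, grp in ((control_gradient, 0), (labelled_gradient, 1)):
        mask = tab.densities.map(windows.classify) == LABELLED
        if int(mask.sum()) < 2:
            raise ValueError(
                f"gradient {tab.gradient_id}: fewer than 2 fractions in the labelled window"
            )
        sub = tab.counts.loc[mask].copy()
        sub.index = [f"{tab.gradient_id}:{i}" for i in sub.index]
        parts.append((sub, np.full(sub.shape[0], grp)))
    counts = pd.concat([p[0] for p in parts], axis=0)
    group = np.concatenate([p[1] for p in parts])
    _check_groups(counts, group, labelled_gradient.gradient_id)
    size_factors = estimate_size_factors(counts)
    dispersions = estimate_dispersions(counts, size_factors)
    return _enrichment_frame(
        counts, group, size_factors, dispersions,
        labelled_gradient.gradient_id, lfc_threshold, alpha, mode="vs-control",
    )


# ---------------------------------------------------------------------------
# confirmation diagnostics


@dataclass(frozen=True)
class HumpResult:
    """Outcome of the hump-shape confirmation of one OTU's density profile."""

    passed: bool
    peak_density: float
    reason: str = ""


def hump_shape_diagnostic(
    profile: pd.Series,
    densities: pd.Series,
    windows: DensityWindows,
    smooth_width: int = 3,
    prominence_factor: float = 2.0,
) -> HumpResult:
    """Formalized hump-shape check of an OTU's normalized density profile.

    The profile (normalized abundance per fraction, ordered by density) is
    smoothed with a ``smooth_width``-fraction moving average; the diagnostic
    passes when the smoothed maximum falls inside the labelled window and
    exceeds ``prominence_factor`` times the median of the raw profile.  This
    is a conservative, reproducible stand-in for the visual inspection of
    per-OTU gradient profiles.
    """
    values = pd.Series(profile, dtype=float)
    if len(values) < 5:
        raise ValueError("need at least 5 fractions for the hump diagnostic")
    if not np.isfinite(values).all():
        raise ValueError("profile contains non-finite values")
    if (values <= 0).all():
        return HumpResult(False, float("nan"), "all-zero profile")
    smoothed = values.rolling(smooth_width, center=True, min_periods=1).mean()
    peak_pos = int(np.argmax(smoothed.to_numpy()))
    peak_density = float(np.asarray(densities, dtype=float)[peak_pos])
    if not smoothed.iloc[peak_pos] > prominence_factor * values.median():
        return HumpResult(False, peak_density, "peak not prominent over gradient median")
    if windows.classify(peak_density) != LABELLED:
        return HumpResult(False, peak_density, "peak outside labelled window")
    return HumpResult(True, peak_density)


def call_gradient(
    table: GradientFractionTable,
    windows: DensityWindows,
    lfc_threshold: float = 0.25,
    alpha: float = 0.1,
    min_base_mean: float = 1.25,
    smooth_width: int = 3,
    prominence_factor: float = 2.0,
) -> pd.DataFrame:
    """Full per-gradient pipeline: classes, NB/Wald calls, and confirmation flags.

    Adds to :func:`test_enrichment` output: ``abundance_pass`` (mean
    normalized count at or above ``min_base_mean``), ``hump_pass`` and
    ``peak_density`` from the hump diagnostic, and ``confirmed`` =
    model_enriched AND abundance_pass AND hump_pass.
    """
    classified = assign_fraction_classes(table, windows)
    res = test_enrichment(classified, lfc_threshold=lfc_threshold, alpha=alpha)

    keep = classified.classes.isin([LABELLED, UNLABELLED])
    counts = classified.counts.loc[keep]
    size_factors = estimate_size_factors(counts)
    norm = counts.div(size_factors, axis=0)
    densities = classified.densities.loc[keep]

    hump_pass = {}
    peak_density = {}
    for otu in res.index:
        prof = norm[otu]
        total = prof.sum()
        prof = prof / total if total > 0 else prof
        h = hump_shape_diagnostic(prof, densities, windows, smooth_width, prominence_factor)
        hump_pass[otu] = h.passed
        peak_density[otu] = h.peak_density
    res["abundance_pass"] = res["base_mean"] >= min_base_mean
    res["hump_pass"] = pd.Series(hump_pass)
    res["peak_density"] = pd.Series(peak_density)
    res["confirmed"] = res["model_enriched"] & res["abundance_pass"] & res["hump_pass"]
    return res


def consolidate_calls(
    results: Iterable[pd.DataFrame],
    min_base_mean: float = 1.25,
    taxonomy: pd.Series | None = None,
) -> dict:
    """Merge per-gradient enrichment results into a confirmed-OTU call set.

    An OTU is confirmed when, in at least one gradient, it is model-enriched
    with mean normalized count >= ``min_base_mean`` and a passing hump
    diagnostic.  The summary carries the mean log2 fold-change of each OTU
    across gradients; with a taxonomy (OTU -> phylum) a per-phylum mean
    log2FC table is added.
    """
    frames = list(results)
    if not frames:
        raise ValueError("need results from at least one gradient")
    allres = pd.concat([f.reset_index() for f in frames], axis=0, ignore_index=True)
    if "hump_pass" not in allres:
        allres["hump_pass"] = True
    if "abundance_pass" not in allres:
        allres["abundance_pass"] = allres["base_mean"] >= min_base_mean
    allres["confirmed_row"] = (
        allres["model_enriched"] & allres["abundance_pass"] & allres["hump_pass"]
    )
    summary = allres.groupby("otu_id").agg(
        mean_log2_fold_change=("log2_fold_change", "mean"),
        mean_base_mean=("base_mean", "mean"),
        n_gradients=("gradient_id", "nunique"),
        n_gradients_enriched=("model_enriched", "sum"),
        confirmed=("confirmed_row", "any"),
    )
    confirmed = set(summary.index[summary["confirmed"]])
    out = {"confirmed_otus": confirmed, "summary": summary}
    if taxonomy is not None:
        tax = taxonomy.reindex(summary.index).fillna("Unclassified")
        out["phylum_summary"] = (
            summary.assign(phylum=tax)
            .groupby("phylum")["mean_log2_fold_change"]
            .agg(["mean", "count"])
            .rename(columns={"mean": "mean_log2_fold_change", "count": "n_otus"})
        )
    return out
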