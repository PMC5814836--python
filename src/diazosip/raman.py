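"""Single-cell Raman preprocessing and the 15N labelling classification harness.

Raman microspectroscopy detects 15N incorporation in single cells through
small red-shifts of peaks arising from N-containing molecules (adenine ring
breathing at 728 cm-1, O-P-O/cytosine/uracil at 783, amide III at 1247, ...).
The phenylalanine peak at 1003 cm-1 does not shift and serves as the
wavenumber-calibration reference.

The harness mirrors a standard workflow: alignment check against the
1003 cm-1 reference, iterative polynomial baseline (background) correction,
normalization to the sum of absolute intensities, then random-forest
classification — a binary labelled/unlabelled model (unlabelled = 0 and
5 at% 15N, labelled = 10-100 at%), a six-level model over enrichment
levels, and a leave-one-strain-out evaluation that tests whether labelling
of a strain absent from the training set can be predicted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "Spectrum",
    "ConfusionMatrix",
    "ClassMetrics",
    "PHENYLALANINE_CM",
    "UNLABELLED_LEVELS",
    "check_alignment",
    "baseline_correct",
    "normalize_spectrum",
    "preprocess",
    "spectra_to_matrix",
    "train_two_class_model",
    "train_multilevel_model",
    "loso_evaluate",
    "loso_all",
    "confusion_metrics",
]

#: Wavenumber of the phenylalanine ring-breathing reference peak (cm-1).
PHENYLALANINE_CM = 1003.0

#: at% 15N levels counted as "unlabelled" in the two-class model.
UNLABELLED_LEVELS = frozenset({0, 5})


@dataclass
class Spectrum:
    """One single-cell Raman spectrum with its ground-truth metadata."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    strain: str = ""
    at_percent: float | None = None
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.shape != self.intensities.shape:
            raise ValueError("wavenumber and intensity vectors must have equal length")
        if self.wavenumbers.ndim != 1 or self.wavenumbers.size < 2:
            raise ValueError("spectrum needs at least two points")
        if not (np.diff(self.wavenumbers) > 0).all():
            raise ValueError("wavenumbers must be strictly increasing")

    def resample(self, grid: np.ndarray) -> "Spectrum":
        """Linear interpolation onto a common wavenumber grid."""
        grid = np.asarray(grid, dtype=float)
        intens = np.interp(grid, self.wavenumbers, self.intensities)
        return replace(self, wavenumbers=grid, intensities=intens)


# ---------------------------------------------------------------------------
# preprocessing


@dataclass(frozen=True)
class AlignmentResult:
    passed: bool
    peak_position: float
    reason: str = ""


def check_alignment(
    spectrum: Spectrum,
    tolerance_cm: float = 3.0,
    search_halfwidth: float = 13.0,
) -> AlignmentResult:
    """Verify wavenumber calibration against the phenylalanine peak.

    Finds the local maximum nearest 1003 cm-1 inside the search window;
    passes when it lies within ``tolerance_cm`` of the reference position.
    """
    lo, hi = PHENYLALANINE_CM - search_halfwidth, PHENYLALANINE_CM + search_halfwidth
    w, y = spectrum.wavenumbers, spectrum.intensities
    if w[0] > lo or w[-1] < hi:
        raise ValueError(f"grid must cover {lo:g}-{hi:g} cm-1 for the alignment check")
    window = (w >= lo) & (w <= hi)
    idx = np.flatnonzero(window)
    yw = y[idx]
    # local maxima within the window (plateau-tolerant at window edges)
    interior = (yw[1:-1] >= yw[:-2]) & (yw[1:-1] >= yw[2:]) if yw.size > 2 else np.array([], bool)
    local = np.flatnonzero(interior) + 1
    if local.size == 0:
        return AlignmentResult(False, float("nan"), "no local maximum near the reference peak")
    best = local[np.argmax(yw[local])]
    pos = float(w[idx[best]])
    if abs(pos - PHENYLALANINE_CM) <= tolerance_cm:
        return AlignmentResult(True, pos)
    return AlignmentResult(False, pos, f"peak at {pos:g} cm-1 off by more than {tolerance_cm:g}")


def baseline_correct(
    spectrum: Spectrum,
    degree: int = 6,
    tol: float = 0.01,
    max_iter: int = 100,
) -> tuple[Spectrum, np.ndarray]:
    """Iterative modified-polyfit background (fluorescence) removal.

    Fits a polynomial of the given degree, replaces every intensity lying
    above the fit by the fit itself, and repeats until the relative RMS
    change of the fitted baseline drops below ``tol`` or ``max_iter`` is
    reached.  Peaks, which sit above the slowly varying background, are
    progressively excluded from the fit; the corrected spectrum is the input
    minus the final baseline.
    """
    y = spectrum.intensities
    if not np.isfinite(y).all():
        raise ValueError("non-finite intensities")
    if y.size < degree + 2:
        raise ValueError(f"need at least degree+2 = {degree + 2} points")
    # scale x to [-1, 1] for numerical conditioning of the Vandermonde fit
    w = spectrum.wavenumbers
    x = 2.0 * (w - w[0]) / (w[-1] - w[0]) - 1.0
    work = y.copy()
    baseline = np.zeros_like(y)
    for _ in range(max_iter):
        coeffs = np.polynomial.polynomial.polyfit(x, work, degree)
        new_baseline = np.polynomial.polynomial.polyval(x, coeffs)
        work = np.minimum(work, new_baseline)
        change = np.sqrt(np.mean((new_baseline - baseline) ** 2))
        scale = np.sqrt(np.mean(new_baseline**2))
        baseline = new_baseline
        if change <= tol * max(scale, 1e-30):
            break
    corrected = replace(spectrum, intensities=y - baseline)
    return corrected, baseline


def normalize_spectrum(spectrum: Spectrum) -> Spectrum:
    """Scale a spectrum to unit sum of absolute intensities (scale-invariant)."""
    total = np.abs(spectrum.intensities).sum()
    if total == 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return replace(spectrum, intensities=spectrum.intensities / total)


def preprocess(
    spectra: list[Spectrum],
    degree: int = 6,
    tol: float = 0.01,
    max_iter: int = 100,
    alignment_tolerance_cm: float = 3.0,
    grid: np.ndarray | None = None,
) -> list[Spectrum]:
    """Alignment check, baseline correction and normalization, in that order.

    Spectra failing the alignment check are dropped with a warning.  When a
    common ``grid`` is given (or the grids differ), spectra are linearly
    resampled onto it before correction.
    """
    if grid is None:
        grid = spectra[0].wavenumbers
    out = []
    for spec in spectra:
        if spec.wavenumbers.shape != grid.shape or not np.array_equal(spec.wavenumbers, grid):
            spec = spec.resample(grid)
        ali = check_alignment(spec, tolerance_cm=alignment_tolerance_cm)
        if not ali.passed:
            warnings.warn(
                f"spectrum {spec.cell_id or '<unnamed>'} failed alignment: {ali.reason}",
                stacklevel=2,
            )
            continue
        corrected, _ = baseline_correct(spec, degree=degree, tol=tol, max_iter=max_iter)
        out.append(normalize_spectrum(corrected))
    if not out:
        raise ValueError("no spectrum survived preprocessing")
    return out


def spectra_to_matrix(spectra: list[Spectrum]) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack spectra into a feature matrix plus a metadata frame (strain, at%)."""
    grid = spectra[0].wavenumbers
    for spec in spectra:
        if not np.array_equal(spec.wavenumbers, grid):
            raise ValueError("spectra must share a common grid; run preprocess() first")
    X = np.vstack([s.intensities for s in spectra])
    meta = pd.DataFrame(
        {
            "cell_id": [s.cell_id for s in spectra],
            "strain": [s.strain for s in spectra],
            "at_percent": [s.at_percent for s in spectra],
        }
    )
    return X, meta


# ---------------------------------------------------------------------------
# confusion matrices and metrics


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 actual x predicted counts for the labelled/unlabelled decision."""

    tp: int  # actual labelled, predicted labelled
    fn: int  # actual labelled, predicted unlabelled
    fp: int  # actual unlabelled, predicted labelled
    tn: int  # actual unlabelled, predicted unlabelled

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_labels(cls, actual_labelled: np.ndarray, predicted_labelled: np.ndarray) -> "ConfusionMatrix":
        a = np.asarray(actual_labelled, dtype=bool)
        p = np.asarray(predicted_labelled, dtype=bool)
        return cls(
            tp=int((a & p).sum()),
            fn=int((a & ~p).sum()),
            fp=int((~a & p).sum()),
            tn=int((~a & ~p).sum()),
        )


@dataclass(frozen=True)
class ClassMetrics:
    """Derived rates of a 2x2 confusion matrix.

    ``false_pos_rate`` and ``false_neg_rate`` follow the predicted-class
    denominators used in the SIP-Raman literature (false discovery and false
    omission rates): falsely-labelled over all predicted labelled, and
    falsely-unlabelled over all predicted unlabelled.  ``miss_rate`` is the
    conventional complement of sensitivity, reported separately to avoid
    ambiguity.  Undefined ratios (zero denominator) are NaN.
    """

    false_pos_rate: float
    false_neg_rate: float
    sensitivity: float
    specificity: float
    per_class_error: dict = field(default_factory=dict)
    overall_error: float = float("nan")
    miss_rate: float = float("nan")


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def confusion_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """All performance rates of a labelled/unlabelled confusion matrix."""
    return ClassMetrics(
        false_pos_rate=_ratio(cm.fp, cm.tp + cm.fp),
        false_neg_rate=_ratio(cm.fn, cm.fn + cm.tn),
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        per_class_error={
            "labelled": _ratio(cm.fn, cm.tp + cm.fn),
            "unlabelled": _ratio(cm.fp, cm.fp + cm.tn),
        },
        overall_error=_ratio(cm.fn + cm.fp, cm.total),
        miss_rate=_ratio(cm.fn, cm.tp + cm.fn),
    )


# ---------------------------------------------------------------------------
# random-forest models


def _rf(n_trees: int, seed: int | None) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )


def _two_class_labels(meta: pd.DataFrame) -> np.ndarray:
    levels = meta["at_percent"].to_numpy()
    if np.any(pd.isna(levels)):
        raise ValueError("every spectrum needs a known at% label for training")
    return ~np.isin(levels, list(UNLABELLED_LEVELS))  # True == labelled


def train_two_class_model(
    spectra: list[Spectrum],
    n_trees: int = 500,
    seed: int | None = None,
) -> tuple[RandomForestClassifier, ConfusionMatrix]:
    """Random forest separating labelled (10-100 at%) from unlabelled (0, 5 at%) cells.

    Returns the fitted model and the out-of-bag confusion matrix, the
    internal cross-validation estimate of its error.
    """
    X, meta = spectra_to_matrix(spectra)
    y = _two_class_labels(meta)
    if y.all() or not y.any():
        raise ValueError("both labelled and unlabelled cells are required for training")
    model = _rf(n_trees, seed).fit(X, y)
    oob_pred = _oob_predictions(model, y)
    return model, ConfusionMatrix.from_labels(y, oob_pred)


def _oob_predictions(model: RandomForestClassifier, y: np.ndarray) -> np.ndarray:
    proba = model.oob_decision_function_
    missing = ~np.isfinite(proba).all(axis=1)
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} sample(s) never out-of-bag; counted as errors",
            stacklevel=3,
        )
        proba = proba.copy()
        proba[missing] = 0.0
        # force a wrong class for never-oob samples
        wrong = np.array([np.argmax(model.classes_ != yi) for yi in y[missing]])
        proba[missing, wrong] = 1.0
    return model.classes_[np.argmax(proba, axis=1)]


def train_multilevel_model(
    spectra: list[Spectrum],
    n_trees: int = 500,
    seed: int | None = None,
) -> tuple[RandomForestClassifier, pd.DataFrame]:
    """Random forest over the at% enrichment levels (0/5/10/25/50/100).

    Returns the model and the out-of-bag confusion table over levels
    (rows actual, columns predicted).
    """
    X, meta = spectra_to_matrix(spectra)
    y = meta["at_percent"].to_numpy(dtype=float)
    levels = np.unique(y)
    if levels.size < 2:
        raise ValueError("need at least two enrichment levels")
    model = _rf(n_trees, seed).fit(X, y)
    oob_pred = _oob_predictions(model, y)
    table = pd.crosstab(
        pd.Series(y, name="actual"), pd.Series(oob_pred, name="predicted"), dropna=False
    ).reindex(index=levels, columns=levels, fill_value=0)
    return model, table


def loso_evaluate(
    spectra: list[Spectrum],
    held_out_strain: str,
    n_trees: int = 500,
    seed: int | None = None,
) -> tuple[ConfusionMatrix, ClassMetrics]:
    """Leave-one-strain-out: train the two-class model without one strain, predict it.

    Measures whether labelling of a strain never seen in training — the
    realistic situation for environmental cells — can still be predicted.
    """
    strains = {s.strain for s in spectra}
    if held_out_strain not in strains:
        raise ValueError(f"unknown strain {held_out_strain!r}")
    if len(strains) < 3:
        raise ValueError("need the held-out strain plus at least two training strains")
    train = [s for s in spectra if s.strain != held_out_strain]
    test = [s for s in spectra if s.strain == held_out_strain]
    model, _ = train_two_class_model(train, n_trees=n_trees, seed=seed)
    X_test, meta_test = spectra_to_matrix(test)
    y_test = _two_class_labels(meta_test)
    pred = model.predict(X_test)
    cm = ConfusionMatrix.from_labels(y_test, pred)
    return cm, confusion_metrics(cm)


def loso_all(
    spectra: list[Spectrum],
    n_trees: int = 500,
    seed: int | None = None,
) -> dict[str, tuple[ConfusionMatrix, ClassMetrics]]:
    """Run the leave-one-strain-out evaluation once per strain."""
    strains = sorted({s.strain for s in spectra})
    return {
        strain: loso_evaluate(spectra, strain, n_trees=n_trees, seed=seed)
        for strain in strains
    }
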