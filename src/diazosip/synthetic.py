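"""Seeded generators of SIP experiments, Raman spectra and tracer timecourses.

Every downstream stage of the package is testable without sequencing data:
these generators emulate the statistical structure of a 15N-SIP study —
density-gradient fraction count tables with known labelled OTUs, per-cell
Raman spectra with known strain identity and labelling level, and replicated
EA-IRMS delta-15N measurements of different biomolecule pools.

Gradient model
--------------
Each OTU's template mass along the gradient is a Gaussian in buoyant density
(isopycnic equilibrium band) centred at the unlabelled density plus, in RNA
mode, ``full_label_shift`` times its label fraction (fully 15N-labelled RNA
bands ~0.015 g/ml denser than unlabelled RNA); a uniform background
component spreads part of each OTU's mass across the whole gradient, as some
template is always recovered everywhere.  In DNA mode the unlabelled centre
depends linearly on G+C content (the "G+C effect") and labelling moves the
band toward the light recovery window of the bis-benzimide secondary
gradient.  Fraction densities are the midpoints of equal-width bins spanning
the gradient's density range; read counts per fraction are multinomial draws
over OTUs from the (optionally Gamma-overdispersed) expected mass shares, so
the negative-binomial count model downstream is well specified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .raman import PHENYLALANINE_CM, Spectrum
from .sip import GradientFractionTable

__all__ = [
    "GradientSimParams",
    "RamanPeak",
    "SpectraSimParams",
    "default_strain_peak_table",
    "FIG2_DAY3_POOLS",
    "simulate_gradient_experiment",
    "expected_fraction_profiles",
    "fraction_densities",
    "simulate_spectra",
    "simulate_isotope_timecourse",
]


# ---------------------------------------------------------------------------
# gradient experiments


@dataclass(frozen=True)
class GradientSimParams:
    """Parameters of a simulated SIP gradient experiment.

    Defaults emulate an RNA-CsTFA gradient: 20 equal-volume fractions over
    1.740-1.835 g/ml, unlabelled RNA banding at 1.773 g/ml (within the
    1.760-1.786 g/ml range where most unlabelled RNA concentrates) with a
    0.008 g/ml band width, a +0.015 g/ml shift at full 15N labelling, and
    ~3000 reads per fraction (the post-filter per-sample depth scale of a
    MiSeq SIP run).
    """

    n_fractions: int = 20
    density_range: tuple[float, float] = (1.740, 1.835)
    n_otus: int = 300
    community_lognormal: tuple[float, float] = (0.0, 1.5)
    reads_per_fraction: int | Sequence[int] = 3000
    unlabelled_density_mean: float = 1.773
    density_sd: float = 0.008
    full_label_shift: float = 0.015
    labelled_otu_ids: frozenset = frozenset()
    label_fraction: float | Mapping[str, float] = 1.0
    mode: str = "RNA"  # "RNA" or "DNA"
    gc_content: tuple[float, ...] | None = None  # % per OTU, DNA mode only
    background_spread_fraction: float = 0.05
    dispersion: float = 0.1  # Gamma overdispersion of per-(OTU, fraction) mass
    fixed_abundances: Mapping[str, float] | None = None  # pin specific OTUs' relative abundance
    timepoint: float = 7.0
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.density_range
        if not lo < hi:
            raise ValueError("density_range must satisfy min < max")
        if self.n_fractions < 2 or self.n_otus < 1:
            raise ValueError("need at least 2 fractions and 1 OTU")
        if not 0.0 <= self.background_spread_fraction <= 1.0:
            raise ValueError("background_spread_fraction must be in [0, 1]")
        if self.mode not in ("RNA", "DNA"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "DNA" and self.gc_content is not None and len(self.gc_content) != self.n_otus:
            raise ValueError("gc_content must have one value per OTU")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        reads = self.reads_per_fraction
        if np.ndim(reads) == 0:
            if reads <= 0:
                raise ValueError("reads_per_fraction must be positive")
        else:
            if len(reads) != self.n_fractions:
                raise ValueError(
                    f"reads_per_fraction vector has length {len(reads)}, expected {self.n_fractions}"
                )
            if any(r <= 0 for r in reads):
                raise ValueError("reads_per_fraction must be positive")

    @property
    def otu_ids(self) -> list[str]:
        return [f"OTU_{i + 1:04d}" for i in range(self.n_otus)]

    def label_fractions(self) -> pd.Series:
        """Per-OTU label fraction (0 outside ``labelled_otu_ids``)."""
        ids = self.otu_ids
        bad = set(self.labelled_otu_ids) - set(ids)
        if bad:
            raise ValueError(f"labelled_otu_ids not in the OTU universe: {sorted(bad)}")
        lf = pd.Series(0.0, index=ids)
        for otu in self.labelled_otu_ids:
            v = self.label_fraction[otu] if isinstance(self.label_fraction, Mapping) else self.label_fraction
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"label fraction for {otu} must be in [0, 1], got {v}")
            lf[otu] = v
        return lf

    def reads_vector(self) -> np.ndarray:
        if np.ndim(self.reads_per_fraction) == 0:
            return np.full(self.n_fractions, int(self.reads_per_fraction))
        return np.asarray(self.reads_per_fraction, dtype=int)


def fraction_densities(params: GradientSimParams) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width bin edges and midpoints spanning the gradient's density range."""
    lo, hi = params.density_range
    edges = np.linspace(lo, hi, params.n_fractions + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    return edges, mids


# anchors of the linear G+C / buoyant-density relation, compressed into the
# secondary-gradient recovery range (unlabelled DNA above the light window)
_GC_ANCHORS = (30.0, 70.0)
_DNA_UNLABELLED_RANGE = (1.700, 1.745)
_DNA_LABELLED_CENTER = 1.680  # middle of the 1.665-1.695 g/ml light window


def _band_centers(params: GradientSimParams, label_fractions: pd.Series) -> np.ndarray:
    lf = label_fractions.to_numpy()
    if params.mode == "RNA":
        return params.unlabelled_density_mean + params.full_label_shift * lf
    gc = np.asarray(
        params.gc_content if params.gc_content is not None else np.full(params.n_otus, 50.0),
        dtype=float,
    )
    raw = 1.660 + 0.00098 * gc  # classic linear buoyant-density relation
    lo_gc, hi_gc = _GC_ANCHORS
    raw_lo, raw_hi = 1.660 + 0.00098 * lo_gc, 1.660 + 0.00098 * hi_gc
    t = np.clip((raw - raw_lo) / (raw_hi - raw_lo), 0.0, 1.0)
    c_unlab = _DNA_UNLABELLED_RANGE[0] + t * (_DNA_UNLABELLED_RANGE[1] - _DNA_UNLABELLED_RANGE[0])
    # labelling re-centers the band into the light window, keeping a
    # compressed trace of the G+C spread
    c_lab = _DNA_LABELLED_CENTER + 0.1 * (c_unlab - np.mean(_DNA_UNLABELLED_RANGE))
    return (1.0 - lf) * c_unlab + lf * c_lab


def expected_fraction_profiles(
    params: GradientSimParams, labelled: bool = True
) -> pd.DataFrame:
    """Expected share of each OTU's template mass per fraction (rows sum to 1).

    Gaussian band mass integrated over each fraction's density bin,
    renormalized over the gradient, mixed with the uniform background
    component.  ``labelled=False`` gives the profiles of a control gradient
    (every label fraction treated as zero).
    """
    edges, mids = fraction_densities(params)
    lf = params.label_fractions()
    if not labelled:
        lf = lf * 0.0
    centers = _band_centers(params, lf)
    cdf = stats.norm.cdf(edges[None, :], loc=centers[:, None], scale=params.density_sd)
    gauss = np.diff(cdf, axis=1)
    rows = gauss.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1.0  # a band entirely outside the range: pure background
    gauss = gauss / rows
    bg = params.background_spread_fraction
    profile = (1.0 - bg) * gauss + bg / params.n_fractions
    return pd.DataFrame(profile, index=params.otu_ids, columns=[f"F{i + 1:02d}" for i in range(params.n_fractions)])


def _relative_abundances(params: GradientSimParams, rng: np.random.Generator) -> np.ndarray:
    mu, sigma = params.community_lognormal
    a = rng.lognormal(mu, sigma, params.n_otus)
    a = a / a.sum()
    if params.fixed_abundances:
        ids = params.otu_ids
        bad = set(params.fixed_abundances) - set(ids)
        if bad:
            raise ValueError(f"fixed_abundances not in the OTU universe: {sorted(bad)}")
        fixed_total = float(sum(params.fixed_abundances.values()))
        if not 0.0 < fixed_total < 1.0:
            raise ValueError("fixed abundances must sum into (0, 1)")
        fixed_idx = {ids.index(k): v for k, v in params.fixed_abundances.items()}
        free = np.ones(params.n_otus, dtype=bool)
        for i in fixed_idx:
            free[i] = False
        a[free] *= (1.0 - fixed_total) / a[free].sum()
        for i, v in fixed_idx.items():
            a[i] = v
    return a


def simulate_gradient_experiment(
    params: GradientSimParams,
    include_control: bool = True,
) -> tuple[list[GradientFractionTable], frozenset, dict[str, pd.Series]]:
    """Simulate one labelled SIP gradient (plus, optionally, a control gradient).

    Both gradients share the community's relative abundances (the template
    comes from the same soil incubation); the control gradient has every
    label fraction at zero.  Returns the gradient tables, the ground-truth
    labelled OTU set, and the expected per-fraction template share (the
    qPCR-style profile, summing to 1) per gradient.
    """
    rng = np.random.default_rng(params.seed)
    _, mids = fraction_densities(params)
    abundances = _relative_abundances(params, rng)
    reads = params.reads_vector()
    medium = "RNA-CsTFA" if params.mode == "RNA" else "DNA-CsCl-secondary"

    tables: list[GradientFractionTable] = []
    qpcr: dict[str, pd.Series] = {}
    runs = [("15N", True)] + ([("14N-control", False)] if include_control else [])
    for status, labelled in runs:
        profile = expected_fraction_profiles(params, labelled=labelled).to_numpy()
        mass = abundances[:, None] * profile
        frac_ids = [f"F{i + 1:02d}" for i in range(params.n_fractions)]
        gradient_id = f"{params.mode}_{status}_d{params.timepoint:g}"
        share = mass.sum(axis=0) / mass.sum()
        qpcr[gradient_id] = pd.Series(share, index=frac_ids, name="copy_share")

        noisy = mass.copy()
        if params.dispersion > 0:
            shape = 1.0 / params.dispersion
            noisy = noisy * rng.gamma(shape, 1.0 / shape, size=mass.shape)
        counts = np.empty((params.n_fractions, params.n_otus), dtype=int)
        for f in range(params.n_fractions):
            p = noisy[:, f]
            p = p / p.sum()
            counts[f, :] = rng.multinomial(reads[f], p)
        table = GradientFractionTable(
            gradient_id=gradient_id,
            label_status=status,
            medium=medium,
            timepoint=params.timepoint,
            densities=pd.Series(mids, index=frac_ids, name="density_g_ml"),
            counts=pd.DataFrame(counts, index=frac_ids, columns=params.otu_ids),
            copy_quant=qpcr[gradient_id],
        )
        tables.append(table)
    return tables, frozenset(params.labelled_otu_ids), qpcr


# ---------------------------------------------------------------------------
# Raman spectra


@dataclass(frozen=True)
class RamanPeak:
    """One indicative Raman peak: Gaussian profile plus its full-label shift."""

    center: float
    width: float = 8.0
    height: float = 1.0
    shift_at_full_label: float = -6.0


#: Indicative peak positions (cm-1) that red-shift with 15N incorporation;
#: 1003 (phenylalanine) is the unshifted calibration reference.
INDICATIVE_PEAKS = (728.0, 783.0, 1174.0, 1247.0, 1340.0, 1480.0, 1577.0)

_PEAK_HEIGHTS = {728.0: 1.0, 783.0: 0.9, 1003.0: 1.2, 1174.0: 0.5,
                 1247.0: 0.8, 1340.0: 0.9, 1480.0: 0.7, 1577.0: 0.6}


def _peaks(
    centers: Sequence[float],
    shift: float = -6.0,
    center_offset: float = 0.0,
    width: float = 8.0,
) -> tuple[RamanPeak, ...]:
    out = [RamanPeak(PHENYLALANINE_CM, width=width,
                     height=_PEAK_HEIGHTS[PHENYLALANINE_CM], shift_at_full_label=0.0)]
    out += [
        RamanPeak(c + center_offset, width=width, height=_PEAK_HEIGHTS[c], shift_at_full_label=shift)
        for c in centers
    ]
    return tuple(sorted(out, key=lambda p: p.center))


def default_strain_peak_table(shift: float = -6.0) -> dict[str, tuple[RamanPeak, ...]]:
    """Eight synthetic strains emulating the peak repertoires of a diverse panel.

    Four strains carry the full indicative-peak set; one lacks 728 cm-1, one
    lacks 1174 and 1480 cm-1, and two cyanobacteria-like strains retain only
    1247, 1340 and 1480 cm-1, with broader peaks whose centres sit a few
    cm-1 off the other strains' positions (a different molecular environment
    after pigment bleaching).  Every strain carries the unshifted 1003 cm-1
    phenylalanine reference.
    """
    full = INDICATIVE_PEAKS
    cyano = (1247.0, 1340.0, 1480.0)
    return {
        "full_peaks_A": _peaks(full, shift),
        "full_peaks_B": _peaks(full, shift),
        "full_peaks_C": _peaks(full, shift),
        "full_peaks_D": _peaks(full, shift),
        "no_728": _peaks(tuple(c for c in full if c != 728.0), shift),
        "no_1174_1480": _peaks(tuple(c for c in full if c not in (1174.0, 1480.0)), shift),
        "cyano_like_A": _peaks(cyano, shift, center_offset=3.0, width=12.0),
        "cyano_like_B": _peaks(cyano, shift, center_offset=4.0, width=12.0),
    }


@dataclass(frozen=True)
class SpectraSimParams:
    """Parameters of the single-cell spectra generator.

    The wavenumber grid is 400-1914 cm-1 in 2 cm-1 steps; peak positions
    shift by ``shift_at_full_label`` times at%/100; a polynomial baseline
    (coefficients over x scaled to [0, 1], degree at most 6) emulates the
    fluorescence background and Gaussian noise the detector.
    """

    wavenumber_start: float = 400.0
    wavenumber_stop: float = 1914.0
    wavenumber_step: float = 2.0
    strain_peak_table: Mapping[str, tuple[RamanPeak, ...]] = field(
        default_factory=default_strain_peak_table
    )
    baseline_poly_coeffs: tuple[float, ...] = (0.1, 0.3, -0.2, 0.2)  # a0 + a1 x + ...
    noise_sd: float = 0.01
    at_levels: tuple[float, ...] = (0, 5, 10, 25, 50, 100)
    cells_per_level: int = 30
    intensity_scale_jitter: float = 0.2  # per-cell uniform scale +-20%
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.strain_peak_table:
            raise ValueError("strain_peak_table must not be empty")
        if len(self.baseline_poly_coeffs) > 7:
            raise ValueError("baseline polynomial degree must be at most 6")
        if self.noise_sd < 0 or self.cells_per_level < 1:
            raise ValueError("invalid noise_sd or cells_per_level")
        for level in self.at_levels:
            if not 0 <= level <= 100:
                raise ValueError(f"at% level out of range: {level}")
        grid = self.grid()
        for strain, peaks in self.strain_peak_table.items():
            centers = [p.center for p in peaks]
            if not all(grid[0] <= c <= grid[-1] for c in centers):
                raise ValueError(f"strain {strain!r} has peaks outside the wavenumber grid")
            ref = [p for p in peaks if p.center == PHENYLALANINE_CM]
            if not ref or any(p.shift_at_full_label != 0.0 for p in ref):
                raise ValueError(
                    f"strain {strain!r} must carry an unshifted {PHENYLALANINE_CM:g} cm-1 reference peak"
                )

    def grid(self) -> np.ndarray:
        return np.arange(self.wavenumber_start, self.wavenumber_stop + self.wavenumber_step / 2,
                         self.wavenumber_step)


def simulate_spectra(params: SpectraSimParams) -> list[Spectrum]:
    """Generate ``cells_per_level`` spectra per strain and at% level.

    Each spectrum is the sum of the strain's Gaussian peaks (centres shifted
    proportionally to the labelling level), a per-cell intensity scale, the
    polynomial baseline and additive Gaussian noise.
    """
    rng = np.random.default_rng(params.seed)
    grid = params.grid()
    x01 = (grid - grid[0]) / (grid[-1] - grid[0])
    baseline = np.polynomial.polynomial.polyval(x01, np.asarray(params.baseline_poly_coeffs, dtype=float))
    spectra: list[Spectrum] = []
    for strain, peaks in params.strain_peak_table.items():
        for level in params.at_levels:
            for cell in range(params.cells_per_level):
                signal = np.zeros_like(grid)
                for peak in peaks:
                    center = peak.center + peak.shift_at_full_label * level / 100.0
                    signal += peak.height * np.exp(-0.5 * ((grid - center) / peak.width) ** 2)
                scale = 1.0 + params.intensity_scale_jitter * (2.0 * rng.random() - 1.0)
                intensities = scale * signal + baseline + rng.normal(0.0, params.noise_sd, grid.size)
                spectra.append(
                    Spectrum(
                        wavenumbers=grid,
                        intensities=intensities,
                        strain=strain,
                        at_percent=float(level),
                        cell_id=f"{strain}_at{level:g}_c{cell + 1:02d}",
                    )
                )
    return spectra


# ---------------------------------------------------------------------------
# EA-IRMS tracer timecourse


#: Day-3 delta-15N (permil) mean +- SEM of the different pools after a 15N2
#: soil incubation: RNA is by far the most sensitive target, DNA the least.
FIG2_DAY3_POOLS: dict[str, tuple[float, float]] = {
    "RNA": (1264.0, 370.0),
    "nucleic_acids": (224.0, 96.0),
    "protein": (194.0, 9.0),
    "bulk_soil": (118.0, 6.0),
    "DNA": (5.0, 3.0),
}


def simulate_isotope_timecourse(
    pool_means: Mapping[str, tuple[float, float]] | Mapping[str, Mapping[float, tuple[float, float]]],
    n_replicates: int = 3,
    seed: int | None = None,
) -> pd.DataFrame:
    """Replicated delta-15N draws from printed mean +- SEM summaries.

    ``pool_means`` maps pool name to (mean, sem) or to {day: (mean, sem)}.
    Per-replicate values are drawn normal with sd = sem * sqrt(n_replicates),
    so the sample mean of the simulated replicates has the printed SEM in
    expectation.  SEM = 0 reproduces the mean exactly.
    """
    rng = np.random.default_rng(seed)
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rows = []
    for pool, value in pool_means.items():
        per_day = value if isinstance(value, Mapping) else {float("nan"): value}
        for day, (mean, sem) in per_day.items():
            if sem < 0:
                raise ValueError(f"negative SEM for pool {pool!r}")
            sd = sem * np.sqrt(n_replicates)
            draws = mean + sd * rng.standard_normal(n_replicates)
            for rep, v in enumerate(draws, start=1):
                rows.append({"pool": pool, "day": day, "replicate": rep, "delta_permil": v})
    return pd.DataFrame(rows)
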