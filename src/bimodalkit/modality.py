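"""Unimodal/bimodal classification and shape statistics of expression distributions.

Two criteria are combined, mirroring common flow-cytometry practice:

* **BIC criterion** — 1- and 2-component Gaussian mixtures are fitted by EM
  on the analysis scale (log10 for fluorescence intensities, raw for
  simulated protein counts).  Bimodality requires strong evidence
  (ΔBIC ≥ 10), a minor-component weight ≥ 0.05, component means at least
  2·min(σ) apart with Ashman's D ≥ 2, and a fitted mixture whose density
  is itself two-moded (without the last two guards a two-Gaussian fit
  "wins" on any right-skewed bursty sample whose density has one mode).
* **Peak criterion** — a kernel density estimate (Silverman bandwidth) has
  at least two local maxima with prominence ≥ 5% of the peak density and
  separation ≥ 5% of the data range.

A distribution is called bimodal if *either* criterion fires.  For bimodal
calls three dimensionless shape parameters are defined on the analysis
scale, with pk1 < pk2 the two dominant peak positions and PDF1, PDF2 the
density heights there:

    d = (pk2 - pk1) / (max - min)            relative distance between peaks
    h = (PDF1 - PDF2) / max(density)         relative peak-height difference
    o = n_overlap / n_total                  fraction of cells strictly
                                             between the peaks

All three are invariant under positive affine rescaling of the data (the
bandwidth rule is scale-covariant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde
from sklearn.mixture import GaussianMixture

__all__ = [
    "ModalityConfig",
    "DensityCurve",
    "MixtureFit",
    "ModalityCall",
    "ShapeParams",
    "estimate_density",
    "detect_peaks",
    "classify_bic",
    "classify_modality",
    "shape_params",
]

MIN_VALUES = 50


@dataclass(frozen=True)
class ModalityConfig:
    """Thresholds of the two bimodality criteria (module-wide defaults)."""

    delta_bic: float = 10.0          # required BIC1 - BIC2 margin
    min_weight: float = 0.05         # minor mixture-component weight floor
    separation_sigmas: float = 2.0   # |mu2-mu1| >= this * min(sigma)
    ashman_d_min: float = 2.0        # |mu2-mu1|/sqrt((s1^2+s2^2)/2) >= this
    require_mixture_bimodal: bool = True  # fitted 2-GMM density must have 2 modes
    min_prominence_frac: float = 0.05
    min_separation_frac: float = 0.05
    n_grid: int = 512
    n_init: int = 10                 # EM restarts
    random_state: int = 0
    #: bandwidth / component-SD floors, in units of the sample's lattice gap
    #: (the smallest positive spacing between distinct values); keeps KDE and
    #: EM from resolving the integer lattice of low-count data as structure,
    #: while scaling covariantly under affine rescaling
    bandwidth_floor_gaps: float = 0.6
    sd_floor_gaps: float = 0.5


DEFAULT_CONFIG = ModalityConfig()


@dataclass
class DensityCurve:
    """Kernel density estimate on a regular grid spanning the data range."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    scale: str = "raw"   # "raw" or "log10"

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass
class MixtureFit:
    """Gaussian mixture parameters on the analysis scale, sorted by mean."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    bic: float
    converged: bool = True


@dataclass
class ShapeParams:
    """Shape statistics of a bimodal distribution (analysis scale)."""

    d: float
    h: float
    o: float
    pk1: float
    pk2: float
    pdf1: float
    pdf2: float
    n_overlap: int
    n_total: int


@dataclass
class ModalityCall:
    """Classification verdict with the evidence behind it."""

    verdict: str                     # "unimodal" | "bimodal"
    bic_criterion: bool
    peaks_criterion: bool
    fit1: MixtureFit | None
    fit2: MixtureFit | None
    density: DensityCurve
    peaks: list = field(default_factory=list)   # (position, height), by position
    pk1: float | None = None
    pk2: float | None = None
    pdf1: float | None = None
    pdf2: float | None = None
    scale: str = "raw"
    h_convention: str = "PDF1-PDF2"  # lower-position peak height first

    @property
    def is_bimodal(self) -> bool:
        return self.verdict == "bimodal"


def _analysis_values(values: np.ndarray, kind: str) -> tuple[np.ndarray, str]:
    values = np.asarray(values, dtype=float)
    if kind == "intensity":
        if np.any(values <= 0):
            raise ValueError("intensity values must be > 0 for log10 analysis")
        return np.log10(values), "log10"
    return values, "raw"


def _lattice_gap(x: np.ndarray) -> float:
    """Smallest positive spacing between distinct sample values."""
    u = np.unique(x)
    return float(np.diff(u).min()) if u.size > 1 else 0.0


def estimate_density(
    values, bandwidth: float | None = None, kind: str = "count",
    config: ModalityConfig = DEFAULT_CONFIG,
) -> DensityCurve:
    """KDE on a 512-point grid spanning [min, max] of the data.

    Intensities are estimated on log10 scale; counts on the raw scale.  The
    default bandwidth is Silverman's rule with a floor of
    ``bandwidth_floor_gaps`` lattice gaps (so integer-valued low-count data
    are smoothed over, not resolved into one spike per count).  Both rules
    are scale-covariant, so the resulting shape statistics are invariant to
    positive rescaling.  An explicit ``bandwidth`` is interpreted as
    ``scipy.stats.gaussian_kde``'s ``bw_method`` factor (a multiple of the
    sample SD).
    """
    x, scale = _analysis_values(values, kind)
    if x.size < MIN_VALUES:
        raise ValueError(f"need at least {MIN_VALUES} values, got {x.size}")
    if np.ptp(x) == 0 or x.std() == 0:
        raise ValueError("degenerate (constant) sample: density undefined")
    if bandwidth is None:
        sd = x.std(ddof=1)
        bw = 1.06 * sd * x.size ** (-0.2)  # Silverman, 1-D
        bw = max(bw, config.bandwidth_floor_gaps * _lattice_gap(x))
        kde = gaussian_kde(x, bw_method=bw / sd)
    else:
        kde = gaussian_kde(x, bw_method=bandwidth)
    grid = np.linspace(x.min(), x.max(), config.n_grid)
    dens = kde(grid)
    return DensityCurve(
        grid=grid, density=dens,
        bandwidth=float(kde.factor * x.std(ddof=1)), scale=scale,
    )


def detect_peaks(
    density: DensityCurve,
    min_prominence_frac: float | None = None,
    min_separation_frac: float | None = None,
    config: ModalityConfig = DEFAULT_CONFIG,
) -> list[tuple[float, float]]:
    """Local maxima of the density curve, ordered by position.

    A maximum must have prominence ≥ ``min_prominence_frac`` × max density
    and be ≥ ``min_separation_frac`` × data range away from its neighbours.
    Grid endpoints can qualify (a mode pressed against the data boundary is
    still a mode).
    """
    pf = config.min_prominence_frac if min_prominence_frac is None else min_prominence_frac
    sf = config.min_separation_frac if min_separation_frac is None else min_separation_frac
    y = density.density
    # pad so boundary maxima are detectable with a prominence
    ypad = np.concatenate(([0.0], y, [0.0]))
    distance = max(1, int(round(sf * (len(y) - 1))))
    idx, _ = find_peaks(ypad, prominence=pf * y.max(), distance=distance)
    idx = idx - 1
    return [(float(density.grid[i]), float(y[i])) for i in idx]


def top_two_peaks(peaks: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """The two tallest peaks, returned in position order."""
    best = sorted(peaks, key=lambda p: p[1], reverse=True)[:2]
    return sorted(best, key=lambda p: p[0])


def _fit_gmm(x: np.ndarray, k: int, config: ModalityConfig) -> MixtureFit:
    # variance floor tied to the lattice gap: EM must not shrink a component
    # onto a single discrete count value
    reg = max(1e-6, (config.sd_floor_gaps * _lattice_gap(x)) ** 2)
    gm = GaussianMixture(
        n_components=k,
        n_init=config.n_init,
        random_state=config.random_state,
        covariance_type="full",
        reg_covar=reg,
        max_iter=500,
    )
    X = x.reshape(-1, 1)
    gm.fit(X)
    order = np.argsort(gm.means_.ravel())
    return MixtureFit(
        weights=gm.weights_[order],
        means=gm.means_.ravel()[order],
        sds=np.sqrt(gm.covariances_.reshape(-1)[order]),
        bic=float(gm.bic(X)),
        converged=bool(gm.converged_),
    )


def mixture_is_bimodal(fit: MixtureFit, n_grid: int = 1024) -> bool:
    """Whether the fitted 2-component mixture density itself has two modes.

    A 2-component fit preferred by BIC on a skewed but single-moded sample
    typically has heavily overlapping components whose summed density has a
    single maximum; such fits must not count as bimodality.
    """
    lo = float((fit.means - 5 * fit.sds).min())
    hi = float((fit.means + 5 * fit.sds).max())
    x = np.linspace(lo, hi, n_grid)
    dens = np.zeros_like(x)
    for w, m, s in zip(fit.weights, fit.means, fit.sds):
        dens += w * np.exp(-0.5 * ((x - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    return int(interior.sum()) >= 2


def classify_bic(
    values, kind: str = "count", config: ModalityConfig = DEFAULT_CONFIG,
) -> tuple[bool, MixtureFit, MixtureFit, float, float]:
    """BIC comparison of 1- vs 2-component Gaussian mixtures.

    Returns (is_bimodal, fit1, fit2, BIC1, BIC2).  Non-convergence of EM
    makes the criterion false.  Besides the BIC margin, the minor-weight
    floor and the mean-separation guard, the winning 2-component fit must
    describe an actually two-moded density (see :func:`mixture_is_bimodal`).
    """
    x, _ = _analysis_values(values, kind)
    if x.size < MIN_VALUES:
        raise ValueError(f"need at least {MIN_VALUES} values, got {x.size}")
    fit1 = _fit_gmm(x, 1, config)
    fit2 = _fit_gmm(x, 2, config)
    ok = fit2.converged and fit1.converged
    evidence = fit2.bic <= fit1.bic - config.delta_bic
    weight_ok = fit2.weights.min() >= config.min_weight
    delta = abs(fit2.means[1] - fit2.means[0])
    sep_ok = delta >= config.separation_sigmas * fit2.sds.min()
    # Ashman's D: separation relative to the pooled component width; a
    # mixture needs D >~ 2 before its density can show two modes
    ashman_d = delta / np.sqrt(0.5 * float(fit2.sds[0] ** 2 + fit2.sds[1] ** 2))
    sep_ok = sep_ok and ashman_d >= config.ashman_d_min
    shape_ok = (not config.require_mixture_bimodal) or mixture_is_bimodal(fit2)
    return (
        bool(ok and evidence and weight_ok and sep_ok and shape_ok),
        fit1, fit2, fit1.bic, fit2.bic,
    )


def classify_modality(
    values, kind: str = "count", config: ModalityConfig = DEFAULT_CONFIG,
) -> ModalityCall:
    """Combined verdict: bimodal iff the BIC or the peak criterion fires.

    For bimodal calls, pk1 < pk2 and their density heights are populated
    from the KDE; if the KDE itself shows fewer than two qualifying peaks
    (BIC-only bimodality), the mixture component means are used as peak
    positions, with heights read off the density curve.
    """
    density = estimate_density(values, kind=kind, config=config)
    peaks = detect_peaks(density, config=config)
    peaks_crit = len(peaks) >= 2
    bic_crit, fit1, fit2, _, _ = classify_bic(values, kind=kind, config=config)
    verdict = "bimodal" if (bic_crit or peaks_crit) else "unimodal"
    call = ModalityCall(
        verdict=verdict,
        bic_criterion=bic_crit,
        peaks_criterion=peaks_crit,
        fit1=fit1,
        fit2=fit2,
        density=density,
        peaks=peaks,
        scale=density.scale,
    )
    if verdict == "bimodal":
        if peaks_crit:
            (p1, h1), (p2, h2) = top_two_peaks(peaks)
        else:
            p1, p2 = fit2.means
            h1 = float(np.interp(p1, density.grid, density.density))
            h2 = float(np.interp(p2, density.grid, density.density))
        if p1 == p2:
            raise ValueError("degenerate bimodal call: coincident peaks")
        call.pk1, call.pdf1 = float(p1), float(h1)
        call.pk2, call.pdf2 = float(p2), float(h2)
    return call


def shape_params(call: ModalityCall, values, kind: str = "count") -> ShapeParams:
    """Shape parameters d, h, o of a bimodal distribution.

    Only defined for bimodal calls.  The distribution range in d is the
    empirical max - min of the (analysis-scale) sample, not the density
    grid span; n_overlap counts observations strictly between the peaks.
    """
    if not call.is_bimodal:
        raise ValueError("shape parameters are only defined for bimodal distributions")
    x, scale = _analysis_values(values, kind)
    if scale != call.scale:
        raise ValueError(f"value kind {kind!r} does not match call scale {call.scale!r}")
    pk1, pk2 = call.pk1, call.pk2
    rng = x.max() - x.min()
    if rng <= 0:
        raise ValueError("degenerate sample range")
    d = (pk2 - pk1) / rng
    h = (call.pdf1 - call.pdf2) / call.density.density.max()
    n_overlap = int(np.sum((x > pk1) & (x < pk2)))
    n_total = int(x.size)
    return ShapeParams(
        d=float(d), h=float(h), o=n_overlap / n_total,
        pk1=pk1, pk2=pk2, pdf1=call.pdf1, pdf2=call.pdf2,
        n_overlap=n_overlap, n_total=n_total,
    )
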