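"""Synthetic flow-cytometry-like single-cell datasets.

Generates tables with the statistical structure of bacterial reporter
cytometry: a right-skewed (log-normal mixture) fluorescence channel FITC-H
on top of an autofluorescence floor, multiplicative log-normal extrinsic
noise, small replicate-to-replicate mean shifts with three biological
replicates per condition, and unimodal size-proxy channels (SSC-H, FSC-H,
pulse Width) correlated with intensity through a Gaussian copula but never
themselves bimodal.

All fixtures shipped here are synthetic: they imitate qualitative features
(distant vs close modes, asymmetric vs even mode weights) and make no claim
of matching any measured gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ssa import SnapshotDistribution

__all__ = [
    "PopulationSpec",
    "CytometryTable",
    "SYNTHETIC_FIXTURES",
    "generate_population",
    "generate_wt_background",
    "merge_replicates",
    "model_to_intensity",
]

CHANNELS = ("FITC-H", "SSC-H", "FSC-H", "Width")
#: log10 mean and sd of the unimodal size-proxy channels
SIZE_CHANNELS = {"SSC-H": (3.5, 0.20), "FSC-H": (4.0, 0.15), "Width": (2.0, 0.05)}


@dataclass(frozen=True)
class PopulationSpec:
    """Recipe for one synthetic condition.

    ``components`` lists (weight, log10-mean, log10-SD) of the expressing
    mixture on the intensity channel; ``extrinsic_sd`` is the log10-SD of a
    multiplicative cell-wide noise factor; every cell additionally carries a
    log-normal autofluorescence floor; ``replicate_shift_sd`` jitters the
    per-replicate component means (log10).  ``size_corr`` is the Pearson
    correlation between log-intensity and the log size channels.
    """

    components: tuple[tuple[float, float, float], ...]
    extrinsic_sd: float = 0.0
    autofluor_mean: float = 1.7     # log10 a.u.
    autofluor_sd: float = 0.10
    replicate_shift_sd: float = 0.02
    n_cells: int = 10000
    n_replicates: int = 3
    size_corr: float = 0.4
    condition: str = "synthetic"

    def __post_init__(self) -> None:
        w = np.array([c[0] for c in self.components], dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("component weights must be >= 0 and sum to 1")
        for _, _, sd in self.components:
            if sd < 0:
                raise ValueError("component SDs must be >= 0")
        if self.extrinsic_sd < 0 or self.autofluor_sd < 0 or self.replicate_shift_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if not abs(self.size_corr) < 1:
            raise ValueError("|size_corr| must be < 1")
        if self.n_cells < 1 or self.n_replicates < 1:
            raise ValueError("n_cells and n_replicates must be >= 1")


@dataclass
class CytometryTable:
    """Per-cell channel table with replicate ids and a condition label."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS + ("replicate", "condition") if c not in self.frame]
        if missing:
            raise ValueError(f"cytometry table missing columns: {missing}")
        for c in CHANNELS:
            if (self.frame[c] <= 0).any():
                raise ValueError(f"channel {c} has non-positive values")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def condition(self) -> str:
        labels = self.frame["condition"].unique()
        return labels[0] if len(labels) == 1 else "mixed"

    def intensities(self) -> SnapshotDistribution:
        """FITC-H channel as an intensity-kind snapshot distribution."""
        return SnapshotDistribution(
            values=self.frame["FITC-H"].to_numpy(),
            replicate=self.frame["replicate"].to_numpy(),
            condition=self.condition,
            kind="intensity",
        )

    def channel(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy()


def _size_channels(rng: np.random.Generator, z_intensity: np.ndarray,
                   corr: float) -> dict:
    """Unimodal log-normal size proxies, copula-correlated with intensity."""
    n = z_intensity.size
    sd_z = z_intensity.std()
    z = (z_intensity - z_intensity.mean()) / (sd_z if sd_z > 0 else 1.0)
    out = {}
    for name, (mu, sd) in SIZE_CHANNELS.items():
        eps = rng.standard_normal(n)
        out[name] = 10.0 ** (mu + sd * (corr * z + np.sqrt(1 - corr**2) * eps))
    return out


def generate_population(spec: PopulationSpec, seed: int) -> CytometryTable:
    """Draw a full synthetic condition (all replicates) reproducibly.

    Per cell: intensity = autofluorescence + mixture draw × extrinsic
    factor, all log-normal on log10 scale; replicate-level mean shifts are
    applied to the expressing components only.
    """
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    weights = np.array([c[0] for c in spec.components])
    mus = np.array([c[1] for c in spec.components])
    sds = np.array([c[2] for c in spec.components])
    frames = []
    for rep in range(spec.n_replicates):
        n = spec.n_cells
        shift = rng.normal(0.0, spec.replicate_shift_sd)
        comp = rng.choice(len(weights), size=n, p=weights)
        log_sig = rng.normal(mus[comp] + shift, sds[comp])
        log_ext = rng.normal(0.0, spec.extrinsic_sd, size=n)
        signal = 10.0 ** (log_sig + log_ext)
        auto = 10.0 ** rng.normal(spec.autofluor_mean, spec.autofluor_sd, size=n)
        fitc = auto + signal
        cols = {"FITC-H": fitc}
        cols.update(_size_channels(rng, np.log10(fitc), spec.size_corr))
        df = pd.DataFrame(cols)
        df["replicate"] = rep
        df["condition"] = spec.condition
        frames.append(df)
    return CytometryTable(pd.concat(frames, ignore_index=True))


def generate_wt_background(n: int, seed: int, *, autofluor_mean: float = 1.7,
                           autofluor_sd: float = 0.10,
                           size_corr: float = 0.4) -> CytometryTable:
    """Wild-type (non-fluorescent strain) background: autofluorescence only."""
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    fitc = 10.0 ** rng.normal(autofluor_mean, autofluor_sd, size=n)
    cols = {"FITC-H": fitc}
    cols.update(_size_channels(rng, np.log10(fitc), size_corr))
    df = pd.DataFrame(cols)
    df["replicate"] = 0
    df["condition"] = "WT"
    return CytometryTable(df)


def merge_replicates(tables: list[CytometryTable]) -> CytometryTable:
    """Concatenate biological replicates of one condition before fitting."""
    if not tables:
        raise ValueError("no tables to merge")
    conditions = {t.condition for t in tables}
    if len(conditions) != 1:
        raise ValueError(f"cannot merge different conditions: {sorted(conditions)}")
    return CytometryTable(
        pd.concat([t.frame for t in tables], ignore_index=True)
    )


def model_to_intensity(
    snapshot: SnapshotDistribution,
    gain: float = 3.0,
    extrinsic_sd: float = 0.25,
    autofluor: tuple[float, float] = (1.7, 0.10),
    seed: int = 0,
    *,
    size_corr: float = 0.4,
) -> CytometryTable:
    """Overlay measurement structure on simulated protein counts.

    intensity = autofluorescence + gain × count × (log-normal extrinsic
    factor).  The intrinsic reaction noise of the simulator underestimates
    the spread of real cytometry data; the extrinsic factor stands in for
    cell-to-cell differences in shared components and measurement error.
    """
    if gain <= 0:
        raise ValueError("gain must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    counts = np.asarray(snapshot.values, dtype=float)
    n = counts.size
    ext = 10.0 ** rng.normal(0.0, extrinsic_sd, size=n)
    auto = 10.0 ** rng.normal(autofluor[0], autofluor[1], size=n)
    fitc = auto + gain * counts * ext
    cols = {"FITC-H": fitc}
    cols.update(_size_channels(rng, np.log10(fitc), size_corr))
    df = pd.DataFrame(cols)
    df["replicate"] = snapshot.replicate
    df["condition"] = snapshot.condition or "model"
    return CytometryTable(df)


def _fixture(name, comps, **kw) -> PopulationSpec:
    return PopulationSpec(components=comps, extrinsic_sd=0.08,
                          condition=name, **kw)


#: Seven named synthetic condition recipes (labelled synthetic; qualitative
#: styles only: distant vs close modes, asymmetric vs even mode weights).
SYNTHETIC_FIXTURES: dict[str, PopulationSpec] = {
    "synthetic_distant_asym_low": _fixture(
        "synthetic_distant_asym_low", ((0.30, 2.2, 0.12), (0.70, 3.6, 0.20))),
    "synthetic_distant_asym_high": _fixture(
        "synthetic_distant_asym_high", ((0.20, 2.3, 0.15), (0.80, 3.8, 0.18))),
    "synthetic_distant_even": _fixture(
        "synthetic_distant_even", ((0.50, 2.3, 0.15), (0.50, 3.7, 0.20))),
    "synthetic_close_even": _fixture(
        "synthetic_close_even", ((0.50, 2.8, 0.15), (0.50, 3.4, 0.18))),
    "synthetic_close_asym": _fixture(
        "synthetic_close_asym", ((0.35, 2.9, 0.15), (0.65, 3.5, 0.18))),
    "synthetic_low_expressing": _fixture(
        "synthetic_low_expressing", ((0.45, 2.1, 0.12), (0.55, 3.0, 0.20))),
    "synthetic_broad_right": _fixture(
        "synthetic_broad_right", ((0.40, 2.5, 0.18), (0.60, 3.9, 0.25))),
}
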