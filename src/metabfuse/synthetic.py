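"""Synthetic two-platform plasma metabolomics generator.

Emulates the study conditions the downstream pipeline is built for: a
2-diet x 2-time mouse design (default n=8/arm) and a binary 23-vs-23 human
design; group effects concentrated in a known metabolite subset that can be
split across the NMR and MS blocks; a fumarate reference singlet at 6.5 ppm;
residual water/methanol nuisance signals inside the exclusion windows;
per-sample global chemical-shift jitter; baseline Gaussian noise on spectra;
and multiplicative injection-order drift on MS intensities with pooled-QC
injections every five analytical samples.

Every operation is deterministic given its seed, so each downstream stage is
testable against known ground truth without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .nmr import Spectrum

__all__ = [
    "SpectralSignature",
    "StudyDesign",
    "EffectSpec",
    "SyntheticTruth",
    "make_library",
    "simulate_concentrations",
    "render_spectra",
    "render_ms_table",
    "make_clinical_table",
    "annotate_peaks",
    "mouse_design",
    "human_design",
]

REFERENCE_PPM = 6.5
REFERENCE_WINDOW = (6.45, 6.58)  # the fumarate exclusion window
PPM_RANGE = (0.2, 10.0)  # metabolite peaks live here


@dataclass
class SpectralSignature:
    """Lorentzian mixture for one metabolite: (center_ppm, height, linewidth)."""

    metabolite_id: str
    peaks: list[tuple[float, float, float]]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("a signature needs at least one peak")
        for c, h, w in self.peaks:
            if not (PPM_RANGE[0] < c < PPM_RANGE[1]):
                raise ValueError(f"peak center {c} outside {PPM_RANGE}")
            if REFERENCE_WINDOW[0] <= c <= REFERENCE_WINDOW[1]:
                raise ValueError("peak center inside the reference window")
            if h <= 0 or not (0.0005 < w < 0.02):
                raise ValueError("height must be > 0, linewidth in (0.0005, 0.02)")


@dataclass
class StudyDesign:
    """Arms with sizes, and per-arm numeric factor levels.

    ``factors`` maps factor name -> {arm label: numeric level}; the coding is
    what enters the response matrix (e.g. CD=0/HFD=1, week1=0/week8=1).
    """

    arms: list[tuple[str, int]]
    factors: Mapping[str, Mapping[str, float]]
    seed: int = 0

    def __post_init__(self) -> None:
        for label, n in self.arms:
            if n < 3:
                raise ValueError(f"arm {label!r} has n={n}; need n >= 3")
        for name, levels in self.factors.items():
            missing = [a for a, _ in self.arms if a not in levels]
            if missing:
                raise ValueError(f"factor {name!r} missing levels for arms {missing}")

    def sample_ids(self) -> list[str]:
        return [f"{label}_{i + 1:02d}" for label, n in self.arms for i in range(n)]

    def metadata(self) -> pd.DataFrame:
        rows = []
        for label, n in self.arms:
            for _ in range(n):
                rows.append({"arm": label, **{f: lv[label] for f, lv in self.factors.items()}})
        return pd.DataFrame(rows, index=self.sample_ids())


def mouse_design(n_per_arm: int = 8, seed: int = 0) -> StudyDesign:
    """2 diets x 2 times-on-diet; diet CD=0/HFD=1, week 1=0/week 8=1."""
    arms = [(a, n_per_arm) for a in ("CD_wk1", "HFD_wk1", "CD_wk8", "HFD_wk8")]
    factors = {
        "diet": {"CD_wk1": 0.0, "HFD_wk1": 1.0, "CD_wk8": 0.0, "HFD_wk8": 1.0},
        "week": {"CD_wk1": 0.0, "HFD_wk1": 0.0, "CD_wk8": 1.0, "HFD_wk8": 1.0},
    }
    return StudyDesign(arms, factors, seed=seed)


def human_design(n_per_arm: int = 23, seed: int = 0) -> StudyDesign:
    """Binary case-control design: diabetes 0/1."""
    arms = [("ctrl", n_per_arm), ("diab", n_per_arm)]
    return StudyDesign(arms, {"diabetes": {"ctrl": 0.0, "diab": 1.0}}, seed=seed)


@dataclass
class EffectSpec:
    """Which metabolites respond to which factor, and in which block(s).

    ``affected`` maps metabolite_id -> (factor name, log-fold effect per unit
    level). ``block_assignment`` maps metabolite_id -> one of
    ``nmr_only | ms_only | both`` (default ``both`` for unlisted ids),
    encoding the assumption that the two platforms carry complementary
    signal.
    """

    affected: Mapping[str, tuple[str, float]] = field(default_factory=dict)
    block_assignment: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m, (f, e) in self.affected.items():
            if not np.isfinite(e):
                raise ValueError(f"effect for {m!r} is not finite")
        for m, b in self.block_assignment.items():
            if b not in ("nmr_only", "ms_only", "both"):
                raise ValueError(f"unknown block assignment {b!r} for {m!r}")

    def block_of(self, metabolite_id: str) -> str:
        return self.block_assignment.get(metabolite_id, "both")


@dataclass
class SyntheticTruth:
    """Ground truth: per-sample concentrations plus the planted effect list."""

    concentrations: pd.DataFrame  # samples x metabolites, a.u., > 0
    metadata: pd.DataFrame
    affected: dict[str, tuple[str, float]]
    effects: EffectSpec
    seed: int

    def nmr_metabolites(self) -> list[str]:
        return [m for m in self.concentrations.columns if self.effects.block_of(m) != "ms_only"]

    def ms_metabolites(self) -> list[str]:
        return [m for m in self.concentrations.columns if self.effects.block_of(m) != "nmr_only"]


def make_library(n_metabolites: int, seed: int) -> list[SpectralSignature]:
    """Random but reproducible Lorentzian signatures, 1-4 peaks each.

    All centers lie in (0.2, 10.0) ppm and outside the reference window.
    """
    if n_metabolites < 1:
        raise ValueError("n_metabolites must be >= 1")
    rng = np.random.default_rng(seed)
    library = []
    for i in range(n_metabolites):
        n_peaks = int(rng.integers(1, 5))
        peaks = []
        while len(peaks) < n_peaks:
            c = float(rng.uniform(*PPM_RANGE))
            if REFERENCE_WINDOW[0] - 0.01 <= c <= REFERENCE_WINDOW[1] + 0.01:
                continue  # resample away from the reference region
            h = float(rng.uniform(0.3, 1.0))
            w = float(rng.uniform(0.001, 0.006))
            peaks.append((c, h, w))
        library.append(SpectralSignature(f"M{i + 1:02d}", peaks))
    return library


def simulate_concentrations(
    design: StudyDesign,
    library: Sequence[SpectralSignature],
    effects: EffectSpec,
    sigma: float = 0.3,
    baseline_spread: float = 0.5,
) -> SyntheticTruth:
    """Draw log-normal concentrations with planted group effects.

    log-concentration = metabolite baseline + factor-level x log-fold effect
    + N(0, sigma). Unaffected metabolites have equal arm means in
    expectation; concentrations are strictly positive by construction.
    """
    ids = [s.metabolite_id for s in library]
    unknown = [m for m in effects.affected if m not in ids]
    if unknown:
        raise KeyError(f"affected metabolites not in library: {unknown}")
    rng = np.random.default_rng(design.seed)
    meta = design.metadata()
    n, p = len(meta), len(ids)
    baseline = rng.uniform(-baseline_spread, baseline_spread, size=p)
    logc = np.tile(baseline, (n, 1))
    for j, m in enumerate(ids):
        if m in effects.affected:
            factor, eff = effects.affected[m]
            logc[:, j] += eff * meta[factor].to_numpy(dtype=float)
    logc += rng.normal(0.0, sigma, size=(n, p))
    conc = pd.DataFrame(np.exp(logc), index=meta.index, columns=ids)
    return SyntheticTruth(conc, meta, dict(effects.affected), effects, design.seed)


def _lorentz(ppm: np.ndarray, center: float, height: float, width: float) -> np.ndarray:
    return height / (1.0 + ((ppm - center) / width) ** 2)


def render_spectra(
    truth: SyntheticTruth,
    library: Sequence[SpectralSignature],
    grid_step_ppm: float = 0.0005,
    jitter_ppm: float = 0.005,
    noise_sd: float = 0.01,
    seed: int = 0,
    reference_height: float = 5.0,
    nuisance: bool = True,
) -> list[Spectrum]:
    """Render one phased 0-12 ppm spectrum per sample.

    spectrum = sum over metabolites of concentration x Lorentzian mixture,
    globally shifted per sample by U(-jitter, +jitter), plus the fumarate
    reference singlet at 6.5 ppm, nuisance water (~4.9 ppm, broad) and
    methanol (3.335 ppm) signals inside the exclusion windows, and baseline
    Gaussian noise.
    """
    if grid_step_ppm <= 0:
        raise ValueError("grid step must be positive")
    rng = np.random.default_rng(seed)
    grid = np.arange(0.0, 12.0 + grid_step_ppm / 2, grid_step_ppm)
    sigs = {s.metabolite_id: s for s in library}
    nmr_ids = truth.nmr_metabolites()
    spectra = []
    for sid in truth.concentrations.index:
        delta = float(rng.uniform(-jitter_ppm, jitter_ppm)) if jitter_ppm > 0 else 0.0
        y = np.zeros_like(grid)
        for m in nmr_ids:
            conc = truth.concentrations.at[sid, m]
            for c, h, w in sigs[m].peaks:
                y += conc * _lorentz(grid, c + delta, h, w)
        # internal standard: same amount in every tube
        y += _lorentz(grid, REFERENCE_PPM + delta, reference_height, 0.002)
        if nuisance:
            y += _lorentz(grid, 4.90 + delta, float(rng.uniform(2.0, 5.0)), 0.05)
            y += _lorentz(grid, 3.335 + delta, float(rng.uniform(0.5, 2.0)), 0.004)
        if noise_sd > 0:
            y += rng.normal(0.0, noise_sd, size=grid.shape)
        spectra.append(Spectrum(grid, y, sid))
    return spectra


DRIFT_SHAPES = ("none", "linear", "exponential")


def _drift_curve(shape: str, magnitude: float, orders: np.ndarray) -> np.ndarray:
    """Multiplicative drift factor over the run; 1.0 at the first injection,
    1 + magnitude at the last."""
    if shape not in DRIFT_SHAPES:
        raise ValueError(f"unknown drift shape {shape!r}; expected one of {DRIFT_SHAPES}")
    if shape == "none" or magnitude == 0:
        return np.ones_like(orders, dtype=float)
    frac = (orders - orders.min()) / max(orders.max() - orders.min(), 1)
    if shape == "linear":
        return 1.0 + magnitude * frac
    return (1.0 + magnitude) ** frac  # exponential decay/growth to 1+magnitude


def render_ms_table(
    truth: SyntheticTruth,
    drift: tuple[str, float] = ("linear", -0.3),
    qc_every: int = 5,
    seed: int = 0,
    technical_cv: float = 0.10,
    scale: float = 1e4,
    randomize_order: bool = True,
) -> pd.DataFrame:
    """Simulate the LC-MS run: drift x lognormal technical noise, QC rows.

    Study samples are injected in randomized order (standard practice, so
    drift is not confounded with group; disable for a worst-case run). The
    run opens with one pooled-QC injection and inserts another after every
    ``qc_every`` analytical samples (40 samples at qc_every=5 gives 9 QC
    injections). QC composition is the mean of all study-sample
    concentrations. Returns a tidy table: rows = injections in order,
    columns = MS-block metabolites plus ``sample_id, injection_order, is_qc``.
    """
    if qc_every < 2:
        raise ValueError("qc_every must be >= 2")
    rng = np.random.default_rng(seed)
    ms_ids = truth.ms_metabolites()
    conc = truth.concentrations[ms_ids]
    qc_conc = conc.mean(axis=0)
    sample_order = list(conc.index)
    if randomize_order:
        sample_order = [sample_order[i] for i in rng.permutation(len(sample_order))]

    rows: list[tuple[str, bool, np.ndarray]] = [("QC_01", True, qc_conc.to_numpy())]
    n_qc = 1
    for i, sid in enumerate(sample_order, start=1):
        rows.append((sid, False, conc.loc[sid].to_numpy()))
        if i % qc_every == 0:
            n_qc += 1
            rows.append((f"QC_{n_qc:02d}", True, qc_conc.to_numpy()))

    orders = np.arange(1, len(rows) + 1)
    shape, magnitude = drift
    dcurve = _drift_curve(shape, magnitude, orders)
    sigma = np.sqrt(np.log1p(technical_cv**2))  # lognormal CV -> log-sd
    out = np.empty((len(rows), len(ms_ids)))
    for i, (sid, is_qc, c) in enumerate(rows):
        noise = np.exp(rng.normal(0.0, sigma, size=len(ms_ids))) if sigma > 0 else 1.0
        out[i] = scale * c * dcurve[i] * noise
    df = pd.DataFrame(out, columns=ms_ids)
    df.insert(0, "sample_id", [r[0] for r in rows])
    df.insert(1, "injection_order", orders)
    df.insert(2, "is_qc", [r[1] for r in rows])
    return df


def make_clinical_table(
    truth: SyntheticTruth,
    seed: int = 0,
    outcome_factor: str = "diabetes",
    linked_metabolites: Sequence[str] = (),
) -> pd.DataFrame:
    """Clinical covariates for the cross-sectional correlation screen.

    Covariates follow the metabolic-syndrome roster (BMI, waist, blood
    pressure, glucose/insulin/HOMA-IR/HbA1c, lipids, CRP). Glucose-axis
    covariates load on the outcome factor; covariates can additionally be
    linked to specific metabolite log-concentrations so planted
    metabolite-clinical correlations exist by construction.
    """
    rng = np.random.default_rng(seed)
    meta = truth.metadata
    n = len(meta)
    y = meta[outcome_factor].to_numpy(dtype=float) if outcome_factor in meta else np.zeros(n)
    link = np.zeros(n)
    for m in linked_metabolites:
        z = np.log(truth.concentrations[m].to_numpy())
        link += (z - z.mean()) / max(z.std(), 1e-12)

    def cov(base, spread, load_y=0.0, load_link=0.0):
        return base + load_y * y + load_link * link + rng.normal(0, spread, n)

    df = pd.DataFrame(
        {
            "BMI": cov(25.0, 3.0, load_y=4.0, load_link=0.5),
            "waist": cov(82.0, 9.0, load_y=12.0, load_link=1.0),
            "SBP": cov(150.0, 18.0, load_y=4.0),
            "DBP": cov(90.0, 8.0),
            "glucose": cov(5.2, 0.6, load_y=4.0, load_link=0.2),
            "insulin": cov(6.5, 2.5, load_y=6.5, load_link=0.4),
            "HOMA_IR": cov(1.6, 0.8, load_y=3.3, load_link=0.2),
            "HbA1c": cov(4.9, 0.4, load_y=2.3, load_link=0.1),
            "cholesterol": cov(6.2, 1.0, load_link=0.2),
            "TAG": cov(1.4, 0.7, load_y=0.5, load_link=0.2),
            "HDL": cov(1.3, 0.3, load_y=-0.1),
            "LDL": cov(4.2, 0.9, load_link=0.2),
            "CRP": cov(0.35, 0.3, load_y=0.15),
        },
        index=meta.index,
    )
    return df


def annotate_peaks(
    peak_positions: Sequence[float],
    library: Sequence[SpectralSignature],
    tol_ppm: float = 0.01,
    truth: SyntheticTruth | None = None,
) -> dict[str, list[str]]:
    """Map NMR peak variables to candidate metabolites by proximity.

    A variable named ``nmr_<ppm:.4f>`` gets every metabolite with a signature
    peak within ``tol_ppm``; several candidates mark an overlapped signal
    (which the pathway stage will drop). If ``truth`` is given, only
    NMR-block metabolites are considered.
    """
    allowed = set(truth.nmr_metabolites()) if truth is not None else None
    out: dict[str, list[str]] = {}
    for pos in peak_positions:
        cands = []
        for sig in library:
            if allowed is not None and sig.metabolite_id not in allowed:
                continue
            if any(abs(pos - c) <= tol_ppm for c, _, _ in sig.peaks):
                cands.append(sig.metabolite_id)
        if cands:
            out[f"nmr_{pos:.4f}"] = sorted(set(cands))
    return out
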