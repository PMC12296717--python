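"""Synthetic multi-platform study generator.

The study emulated here: 84 samples of one herbal material from six
origins, measured on four platforms — two feature tables (LC-MS,
GC-MS) and two raw 1-D spectra (¹H NMR on a ppm axis, MIR on a
wavenumber axis).  70 samples from two origins (YN, GX) form the model
set; 14 samples from four further origins (GD, FJ, MD, LQS) are held
out for external validation.  Discriminative structure is *planted*:
a known subset of features (tabular columns or spectral peaks) carries
group-dependent signal, and the ground truth is persisted next to the
data so recovery metrics are computable without re-simulation.

Group effects are mean shifts on the (log-intensity-like) tabular scale
and log-amplitude shifts (multiplicative) on spectral peaks.  The two
model groups are separated by exactly ``effect_size × noise_sd`` on
each informative tabular feature; external groups receive independent
Gaussian shift coefficients on the same informative features, so the
variables that discriminate the model groups also spread the external
groups — the premise behind validating screened variables on unseen
origins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import FeatureBlock, SampleManifest, child_seed
from .preprocess import Spectrum

# log-amplitude change per unit effect_size on informative spectral peaks
SPECTRAL_LOG_EFFECT = 0.25
# fixed nuisance features of a ¹H spectrum
NMR_REFERENCE_AMPLITUDE = 10.0
NMR_WATER_CENTER = 4.9
NMR_WATER_WIDTH = 0.06


@dataclass
class BlockSpec:
    """Recipe for one platform's synthetic block.

    Tabular blocks set ``n_features``; spectral blocks set ``axis``
    (start, stop, step — ppm or cm⁻¹) plus peak parameters.
    """

    platform: str
    n_features: int | None = None
    axis: tuple[float, float, float] | None = None
    n_informative: int = 0
    effect_size: float = 0.0
    noise_sd: float = 1.0
    baseline_amplitude: float = 0.0
    peak_width: float = 0.01
    n_peaks: int = 40
    amplitude_scale: float = 1.0
    shift_jitter: float = 0.0
    sample_effect_sd: float = 0.0

    def __post_init__(self) -> None:
        if (self.n_features is None) == (self.axis is None):
            raise ValueError("set exactly one of n_features (tabular) or axis (spectral)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be ≥ 0")
        # tabular group shifts are expressed in noise-sd units, so zero noise
        # is meaningless there; a noiseless spectrum is a legitimate limit
        if self.noise_sd < 0 or (self.kind == "tabular" and self.noise_sd == 0):
            raise ValueError("noise_sd must be > 0 (≥ 0 for spectral blocks)")
        if self.kind == "tabular":
            if self.n_features < 1 or self.n_informative > self.n_features:
                raise ValueError("need 0 ≤ n_informative ≤ n_features ≥ 1")
        else:
            start, stop, step = self.axis
            if step <= 0:
                raise ValueError("axis step must be > 0")
            if stop <= start:
                raise ValueError("axis stop must exceed start")
            if self.n_informative > self.n_peaks:
                raise ValueError("n_informative must be ≤ n_peaks")

    @property
    def kind(self) -> str:
        return "tabular" if self.n_features is not None else "spectral"

    def grid(self) -> np.ndarray:
        start, stop, step = self.axis
        n = int(np.floor((stop - start) / step + 1e-9)) + 1
        return start + step * np.arange(n)


@dataclass
class SyntheticSpec:
    """Whole-study recipe: groups, external groups and per-platform blocks."""

    seed: int
    groups: list[tuple[str, int]]
    blocks: list[BlockSpec]
    external_groups: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [g for g, _ in self.groups] + [g for g, _ in self.external_groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")
        if any(n < 2 for _, n in list(self.groups) + list(self.external_groups)):
            raise ValueError("every group needs n_samples ≥ 2")
        plats = [b.platform for b in self.blocks]
        if len(set(plats)) != len(plats):
            raise ValueError("one block per platform")

    def manifest(self) -> SampleManifest:
        return SampleManifest.from_counts(self.groups, self.external_groups)


def _group_coefficients(
    manifest: SampleManifest, n_signals: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-(group, signal) shift coefficients.

    Model groups get fixed, evenly spaced coefficients (two groups:
    −0.5 and +0.5, i.e. unit separation).  External groups get
    independent N(0, 1) coefficients per signal.
    """
    model = manifest.model_groups
    ext = manifest.external_groups
    rows = {}
    g = len(model)
    for i, lab in enumerate(model):
        rows[lab] = np.full(n_signals, i - (g - 1) / 2.0)
    for lab in ext:
        rows[lab] = rng.normal(0.0, 1.0, n_signals)
    return pd.DataFrame(rows).T  # groups × signals


def generate_feature_block(
    spec: BlockSpec, manifest: SampleManifest, rng: np.random.Generator
) -> tuple[FeatureBlock, dict]:
    """Simulate a tabular block: baseline per feature + group shift + noise.

    Exactly ``n_informative`` columns carry group-dependent means; the
    shift between the two model groups equals ``effect_size × noise_sd``.
    A per-sample offset of sd ``sample_effect_sd`` added to every column
    emulates batch/dilution nuisance variation (the reason blocks are
    Z-scored downstream).  Returns the block and a provenance dict
    naming the planted columns.
    """
    if spec.kind != "tabular":
        raise ValueError("generate_feature_block needs a tabular BlockSpec")
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    n, p = len(manifest), spec.n_features
    cols = [f"{spec.platform.lower()}_f{j:04d}" for j in range(p)]

    base = rng.normal(0.0, 1.0, p)
    informative = np.sort(rng.choice(p, size=spec.n_informative, replace=False))
    coeff = _group_coefficients(manifest, spec.n_informative, rng)
    noise = rng.normal(0.0, spec.noise_sd, size=(n, p))

    X = np.tile(base, (n, 1)) + noise
    if spec.sample_effect_sd > 0:
        X += rng.normal(0.0, spec.sample_effect_sd, size=(n, 1))
    shift = spec.effect_size * spec.noise_sd
    groups = manifest.frame["group"].to_numpy()
    for i, g in enumerate(groups):
        X[i, informative] += shift * coeff.loc[g].to_numpy()

    data = pd.DataFrame(X, index=manifest.sample_ids, columns=cols)
    info = {
        "kind": "tabular",
        "platform": spec.platform,
        "informative": [cols[j] for j in informative],
    }
    return FeatureBlock(spec.platform, data), info


def _gaussian(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / width) ** 2)


def generate_spectrum_block(
    spec: BlockSpec, manifest: SampleManifest, rng: np.random.Generator
) -> tuple[dict[str, Spectrum], dict]:
    """Simulate per-sample 1-D spectra: baseline + Gaussian peaks + noise.

    Peaks sit at fixed positions shared by all samples; ``n_informative``
    of them have group-dependent log-amplitudes.  NMR spectra always get
    a reference singlet at 0.00 ppm and a nuisance "water" band inside
    4.8–5.0 ppm whose amplitude varies arbitrarily across samples.
    """
    if spec.kind != "spectral":
        raise ValueError("generate_spectrum_block needs a spectral BlockSpec")
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    x = spec.grid()
    start, stop, _ = spec.axis
    is_nmr = spec.platform.upper() == "NMR"

    margin = 5.0 * spec.peak_width
    forbidden = []
    if is_nmr:
        forbidden = [(4.8 - margin, 5.0 + margin), (-0.1 - margin, 0.1 + margin)]
    candidates = rng.uniform(start + margin, stop - margin, size=max(20 * spec.n_peaks, 100))
    ok = np.ones(candidates.size, dtype=bool)
    for lo, hi in forbidden:
        ok &= ~((candidates >= lo) & (candidates <= hi))
    positions = np.sort(candidates[ok][: spec.n_peaks])
    if positions.size < spec.n_peaks:
        raise ValueError("axis too narrow for the requested number of peaks")

    amps = spec.amplitude_scale * rng.lognormal(mean=0.0, sigma=0.4, size=spec.n_peaks)
    informative = np.sort(rng.choice(spec.n_peaks, size=spec.n_informative, replace=False))
    coeff = _group_coefficients(manifest, spec.n_informative, rng)

    span = stop - start
    baseline = spec.baseline_amplitude * (0.6 + 0.4 * np.sin(2 * np.pi * (x - start) / span))

    spectra: dict[str, Spectrum] = {}
    for sid, g in zip(manifest.sample_ids, manifest.frame["group"]):
        log_amps = np.log(amps).copy()
        log_amps[informative] += SPECTRAL_LOG_EFFECT * spec.effect_size * coeff.loc[g].to_numpy()
        if spec.sample_effect_sd > 0:
            # per-sample global amplitude factor: dilution / scattering nuisance
            log_amps += rng.normal(0.0, spec.sample_effect_sd)
        a = np.exp(log_amps)
        y = baseline.copy()
        for pos, amp in zip(positions, a):
            y += amp * _gaussian(x, pos, spec.peak_width)
        axis = x
        if is_nmr:
            y = y + NMR_REFERENCE_AMPLITUDE * spec.amplitude_scale * _gaussian(
                x, 0.0, spec.peak_width
            )
            water_amp = rng.uniform(0.0, 20.0) * spec.amplitude_scale
            y = y + water_amp * _gaussian(x, NMR_WATER_CENTER, NMR_WATER_WIDTH)
        if spec.shift_jitter > 0:
            axis = x + rng.uniform(-spec.shift_jitter, spec.shift_jitter)
        y = y + rng.normal(0.0, spec.noise_sd, size=x.size)
        spectra[sid] = Spectrum(axis, y)

    info = {
        "kind": "spectral",
        "platform": spec.platform,
        "peak_positions": positions.tolist(),
        "informative_peaks": informative.tolist(),
        "informative_positions": positions[informative].tolist(),
        "peak_width": spec.peak_width,
    }
    return spectra, info


@dataclass
class StudyData:
    """One simulated study: manifest, raw blocks, and planted-feature truth."""

    manifest: SampleManifest
    tabular: dict[str, FeatureBlock]
    spectra: dict[str, dict[str, Spectrum]]
    truth: dict

    def write(self, outdir: str | Path) -> None:
        """Persist as plain text: CSV tables, two-column spectra, truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.manifest.to_csv(outdir / "manifest.csv")
        for plat, block in self.tabular.items():
            block.to_csv(outdir / f"{plat.lower()}.csv")
        for plat, spectra in self.spectra.items():
            d = outdir / plat.lower()
            d.mkdir(exist_ok=True)
            for sid, sp in spectra.items():
                np.savetxt(
                    d / f"{sid}.txt",
                    np.column_stack([sp.axis, sp.intensity]),
                    fmt="%.8g",
                )
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2))

    @classmethod
    def load(cls, indir: str | Path) -> "StudyData":
        indir = Path(indir)
        manifest = SampleManifest.from_csv(indir / "manifest.csv")
        truth = json.loads((indir / "truth.json").read_text())
        tabular, spectra = {}, {}
        for plat, entry in truth["blocks"].items():
            if entry["kind"] == "tabular":
                tabular[plat] = FeatureBlock.from_csv(plat, indir / f"{plat.lower()}.csv")
            else:
                d = indir / plat.lower()
                spectra[plat] = {
                    sid: Spectrum(*np.loadtxt(d / f"{sid}.txt", unpack=True))
                    for sid in manifest.sample_ids
                }
        return cls(manifest, tabular, spectra, truth)


def generate_study(spec: SyntheticSpec) -> StudyData:
    """Simulate every block of the study from one global seed.

    Each block draws from its own child generator keyed by platform
    name, so adding a block never perturbs previously generated ones;
    identical specs yield identical output.
    """
    manifest = spec.manifest()
    tabular: dict[str, FeatureBlock] = {}
    spectra: dict[str, dict[str, Spectrum]] = {}
    blocks_truth: dict[str, dict] = {}
    for bs in spec.blocks:
        rng = np.random.default_rng(child_seed(spec.seed, bs.platform))
        if bs.kind == "tabular":
            block, info = generate_feature_block(bs, manifest, rng)
            tabular[bs.platform] = block
        else:
            sps, info = generate_spectrum_block(bs, manifest, rng)
            spectra[bs.platform] = sps
        blocks_truth[bs.platform] = info
    n_planted = sum(b.n_informative for b in spec.blocks)
    truth = {
        "seed": spec.seed,
        "blocks": blocks_truth,
        "n_informative_total": n_planted,
    }
    return StudyData(manifest, tabular, spectra, truth)


def default_study_spec(seed: int = 0) -> SyntheticSpec:
    """The default simulated study, shaped like the motivating one.

    Two model origins of 35 samples each (70 modelled) and four external
    origins (4+4+3+3 = 14 held out).  Four blocks: LC-MS and GC-MS
    feature tables, an NMR ppm-axis spectrum and an MIR wavenumber-axis
    spectrum, each with a handful of planted discriminative features at
    a standardized between-group shift of 2.
    """
    return SyntheticSpec(
        seed=seed,
        groups=[("YN", 35), ("GX", 35)],
        external_groups=[("GD", 4), ("FJ", 4), ("MD", 3), ("LQS", 3)],
        blocks=[
            BlockSpec(
                "LCMS", n_features=300, n_informative=10, effect_size=2.0,
                noise_sd=1.0, sample_effect_sd=1.0,
            ),
            BlockSpec(
                "GCMS", n_features=120, n_informative=8, effect_size=2.0,
                noise_sd=1.0, sample_effect_sd=1.0,
            ),
            BlockSpec(
                "NMR",
                axis=(-0.2, 12.4, 0.001),
                n_peaks=60,
                n_informative=8,
                effect_size=2.0,
                noise_sd=0.05,
                peak_width=0.004,
                amplitude_scale=1.0,
                shift_jitter=0.01,
                sample_effect_sd=0.2,
            ),
            BlockSpec(
                "MIR",
                axis=(400.0, 4000.0, 4.0),
                n_peaks=25,
                n_informative=6,
                effect_size=2.0,
                noise_sd=0.01,
                peak_width=25.0,
                baseline_amplitude=0.3,
                amplitude_scale=1.0,
                sample_effect_sd=0.3,
            ),
        ],
    )


def spec_from_yaml(path: str | Path, seed: int | None = None) -> SyntheticSpec:
    """Read a SyntheticSpec from YAML (CLI front door)."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    blocks = [BlockSpec(**b) for b in raw["blocks"]]
    for b in blocks:
        if b.axis is not None:
            b.axis = tuple(b.axis)
    return SyntheticSpec(
        seed=int(raw["seed"] if seed is None else seed),
        groups=[tuple(g) for g in raw["groups"]],
        blocks=blocks,
        external_groups=[tuple(g) for g in raw.get("external_groups", [])],
    )
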