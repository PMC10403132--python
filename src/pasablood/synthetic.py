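"""Synthetic blood-signal cohorts with known ground truth.

No signal data are deposited with the study this pipeline mirrors, so every
downstream stage is exercised on generated cohorts instead.  Each subject's
trace is a deterministic pulse template — a smooth rise–decay envelope
carrying a damped oscillation, sitting on a negative baseline offset — whose
amplitude, time constants and oscillation frequency vary between subjects.
Replicates add iid Gaussian noise and a uniform trigger-jitter onset shift
(<= 0.5 ms).  Raw photoacoustic traces live in roughly −1…0.5 V, raw
absorption-spectroscopy traces in −100…20 V; values are clipped to the
configured range so containment holds even in the noise tails.

Biochemical panels are built from the *true* (noiseless, jitter-free)
feature values of each subject: parameters named in the effect map equal a
stated degree-1..3 polynomial of one true feature plus Gaussian noise;
all other parameters are pure standard-normal noise.  The ground-truth
record keeps every coefficient and true feature value so recovery can be
scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .freq_features import FEATURE_NAMES, FeatureConfig, extract_all_features
from .prep import (
    MODALITIES,
    AveragedSignal,
    ReplicateSet,
    SignalTrace,
    preprocess_replicates,
    write_replicates,
)

__all__ = [
    "GeneratorConfig",
    "EffectSpec",
    "CohortSpec",
    "CohortData",
    "PARAMETER_NAMES",
    "DEFAULT_EFFECTS",
    "generate_replicates",
    "template_trace",
    "true_features",
    "generate_cohort",
    "write_cohort",
]

PARAMETER_NAMES = (
    "ALT", "TP", "ALB.BCG", "GLO", "BUN", "UA", "CRE", "TCH", "TG", "GLU.AC",
    "eGFR", "Na", "K", "Cl", "Ca", "Fe", "TIBC", "HDL.C", "LDL.C",
)

_MODALITY_CODE = {"PA": 0, "AS": 1}


def _modality_code(modality: str) -> int:
    try:
        return _MODALITY_CODE[modality]
    except KeyError:
        raise ValueError(
            f"unknown modality {modality!r}; expected one of {MODALITIES}"
        ) from None


@dataclass(frozen=True)
class GeneratorConfig:
    """Acquisition-level settings of the emulated recording systems.

    Defaults follow the study protocol: 2500 samples over 5 ms
    (dt = 0.002 ms), 10 photoacoustic and 5 absorption-spectroscopy
    replicates per subject, trigger jitter up to 0.5 ms.  ``noise_sd`` is
    the per-sample Gaussian noise s.d. for photoacoustic traces (volts);
    ``noise_sd_as`` the same for absorption spectroscopy, larger because
    that modality's raw span is ~80x wider.
    """

    n_samples: int = 2500
    duration: float = 5.0
    dt: float = 0.002
    n_replicates_pa: int = 10
    n_replicates_as: int = 5
    trigger_jitter_max: float = 0.5
    noise_sd: float = 0.01
    noise_sd_as: float = 0.8
    pa_raw_range: tuple = (-1.0, 0.5)
    as_raw_range: tuple = (-100.0, 20.0)
    sampling_rate_mode: str = "paper_dims"
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(self.n_samples * self.dt, self.duration):
            raise ValueError(
                f"n_samples*dt = {self.n_samples * self.dt:g} must equal "
                f"duration = {self.duration:g} ms"
            )
        if not self.trigger_jitter_max < self.duration:
            raise ValueError("trigger_jitter_max must be smaller than the duration")
        if self.noise_sd < 0 or self.noise_sd_as < 0:
            raise ValueError("noise s.d. must be nonnegative")
        if self.sampling_rate_mode not in ("paper_dims", "wideband"):
            raise ValueError(
                f"unknown sampling_rate_mode {self.sampling_rate_mode!r}"
            )

    @property
    def nyquist_mhz(self) -> float:
        return 0.5e-3 / self.dt

    def raw_range(self, modality: str):
        return self.pa_raw_range if _modality_code(modality) == 0 else self.as_raw_range

    def replicate_count(self, modality: str) -> int:
        return self.n_replicates_pa if _modality_code(modality) == 0 else self.n_replicates_as

    def replicate_noise_sd(self, modality: str) -> float:
        return self.noise_sd if _modality_code(modality) == 0 else self.noise_sd_as


def _subject_template_params(config: GeneratorConfig, subject_seed: int) -> dict:
    """Per-subject pulse-shape parameters, reproducible from the seeds."""
    rng = np.random.default_rng([int(config.seed), int(subject_seed), 11])
    dur = config.duration  # time constants scale with the record length
    return {
        "amp": rng.uniform(0.4, 1.0),
        "tau_rise": rng.uniform(0.010, 0.024) * dur,   # ms
        "tau_decay": rng.uniform(0.10, 0.18) * dur,    # ms
        "ring_rel": rng.uniform(0.10, 0.18),           # rel. oscillation amplitude
        "ring_freq": rng.uniform(0.15, 0.22) * config.nyquist_mhz,  # MHz
        "onset": 0.14 * dur,                           # ms, before jitter
    }


def _template(t: np.ndarray, params: dict, modality: str,
              config: GeneratorConfig, onset: float) -> np.ndarray:
    s = t - onset
    pos = s > 0
    env = np.zeros_like(t)
    env[pos] = (1.0 - np.exp(-s[pos] / params["tau_rise"])) * np.exp(
        -s[pos] / params["tau_decay"]
    )
    ring = np.zeros_like(t)
    # f in MHz, t in ms -> 1e3 cycles per (MHz*ms)
    ring[pos] = params["ring_rel"] * np.sin(2e3 * np.pi * params["ring_freq"] * s[pos])
    shape = env * (1.0 + ring)
    lo, hi = config.raw_range(modality)
    span = hi - lo
    base = lo + 0.15 * span
    return base + 0.85 * span * params["amp"] * shape


def template_trace(config: GeneratorConfig, modality: str, subject_seed: int) -> SignalTrace:
    """The subject's noiseless, jitter-free pulse template."""
    _modality_code(modality)
    params = _subject_template_params(config, subject_seed)
    t = np.arange(config.n_samples) * config.dt
    y = _template(t, params, modality, config, onset=params["onset"])
    return SignalTrace(t=t, y=y, dt=config.dt, modality=modality)


def generate_replicates(
    config: GeneratorConfig, modality: str, subject_seed: int
) -> ReplicateSet:
    """Replicate traces for one subject: template + jitter + Gaussian noise.

    Identical (config, modality, subject_seed) reproduce bit-identical
    output.  Each replicate's onset shift is uniform on
    [0, trigger_jitter_max]; values are clipped to the modality's raw range.
    """
    code = _modality_code(modality)
    params = _subject_template_params(config, subject_seed)
    n_rep = config.replicate_count(modality)
    noise_sd = config.replicate_noise_sd(modality)
    lo, hi = config.raw_range(modality)
    rng = np.random.default_rng([int(config.seed), int(subject_seed), 13, code])
    t = np.arange(config.n_samples) * config.dt
    traces = []
    for _ in range(n_rep):
        jitter = rng.uniform(0.0, config.trigger_jitter_max)
        y = _template(t, params, modality, config, onset=params["onset"] + jitter)
        y = y + rng.normal(0.0, noise_sd, size=config.n_samples)
        np.clip(y, lo, hi, out=y)
        traces.append(SignalTrace(t=t, y=y, dt=config.dt, modality=modality))
    return ReplicateSet(
        subject_id=f"subject{subject_seed}", modality=modality, traces=tuple(traces)
    )


def true_features(
    config: GeneratorConfig,
    modality: str,
    subject_seed: int,
    feature_config: FeatureConfig | None = None,
    discard_ms: float = 0.5,
) -> pd.Series:
    """The 31 features of the noiseless template, via the real pipeline."""
    cfg = feature_config or FeatureConfig(sampling_rate_mode=config.sampling_rate_mode)
    tmpl = template_trace(config, modality, subject_seed)
    single = ReplicateSet(
        subject_id=f"subject{subject_seed}", modality=modality, traces=(tmpl,)
    )
    return extract_all_features(preprocess_replicates(single, discard_ms), cfg)


@dataclass(frozen=True)
class EffectSpec:
    """One planted parameter<-feature effect: a polynomial plus noise.

    ``coefficients`` are ascending powers (c0, c1, ..., c_degree):
    parameter = sum_d c_d * feature**d + N(0, noise_sd).
    """

    parameter: str
    feature: str
    degree: int
    coefficients: tuple
    noise_sd: float
    modality: str = "PA"

    def __post_init__(self) -> None:
        if self.degree not in (1, 2, 3):
            raise ValueError(f"degree must be 1, 2 or 3, got {self.degree}")
        if len(self.coefficients) != self.degree + 1:
            raise ValueError(
                f"degree {self.degree} needs {self.degree + 1} coefficients, "
                f"got {len(self.coefficients)}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        _modality_code(self.modality)

    def mean_response(self, x: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(x, np.asarray(self.coefficients, float))


# Planted study conditions: three strongly explained parameters (two linear,
# one curved) and BUN deliberately left as pure noise.  Coefficients are in
# raw feature units of the default photoacoustic template population; noise
# s.d. values set the generating in-sample R^2 near 0.97 (ALB.BCG), 0.80
# (CRE) and 0.90 (UA) for the default cohort's feature spread.  The carrier
# features are ones the stepwise VIF pruning characteristically retains, so
# recovery of the planted structure is identifiable by construction.
DEFAULT_EFFECTS = (
    EffectSpec("ALB.BCG", "time_area", 1, (3.5, 2.0), 0.062, "PA"),
    EffectSpec("CRE", "time_area", 1, (0.9, 1.2), 0.106, "PA"),
    EffectSpec("UA", "time_area", 2, (2.0, 0.0, 6.0), 0.402, "PA"),
)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition and the planted parameter<-feature effect map."""

    n_subjects: int = 14
    n_both: int = 12
    n_pa_only: int = 1
    n_as_only: int = 1
    effect_map: tuple = DEFAULT_EFFECTS
    parameter_names: tuple = PARAMETER_NAMES

    def __post_init__(self) -> None:
        if self.n_both + self.n_pa_only + self.n_as_only != self.n_subjects:
            raise ValueError(
                "n_both + n_pa_only + n_as_only must equal n_subjects "
                f"({self.n_both}+{self.n_pa_only}+{self.n_as_only} != {self.n_subjects})"
            )
        if len(set(self.parameter_names)) != len(self.parameter_names):
            raise ValueError("parameter names must be distinct")
        object.__setattr__(self, "effect_map", tuple(self.effect_map))
        seen = set()
        for eff in self.effect_map:
            if eff.parameter not in self.parameter_names:
                raise ValueError(f"effect map names unknown parameter {eff.parameter!r}")
            if eff.feature not in FEATURE_NAMES:
                raise ValueError(f"effect map names unknown feature {eff.feature!r}")
            if eff.parameter in seen:
                raise ValueError(f"parameter {eff.parameter!r} appears twice in effect map")
            seen.add(eff.parameter)


@dataclass(frozen=True)
class CohortData:
    """Everything generated for one cohort, including the ground truth."""

    config: GeneratorConfig
    spec: CohortSpec
    subjects: tuple                 # subject ids in order
    modalities: dict                # subject id -> tuple of performed modalities
    replicates: dict                # modality -> {subject id: ReplicateSet}
    panel: pd.DataFrame             # one row per subject, 19 parameter columns
    truth: dict                     # coefficients, seeds, true features, generating R^2


def generate_cohort(
    config: GeneratorConfig,
    spec: CohortSpec,
    feature_config: FeatureConfig | None = None,
    discard_ms: float = 0.5,
) -> CohortData:
    """Generate replicate sets, the biochemical panel and the truth record.

    The default cohort is 14 subjects: 12 measured with both modalities, one
    photoacoustic-only and one absorption-spectroscopy-only.  True features
    are computed for every subject under *both* modalities (the planted
    effects are functions of the subject's physiology, not of which
    instruments happened to run), while replicate traces exist only for the
    performed modalities.
    """
    width = max(2, len(str(spec.n_subjects)))
    subjects = tuple(f"S{i + 1:0{width}d}" for i in range(spec.n_subjects))
    seeds = {sid: i + 1 for i, sid in enumerate(subjects)}
    assignment = {}
    for i, sid in enumerate(subjects):
        if i < spec.n_both:
            assignment[sid] = ("PA", "AS")
        elif i < spec.n_both + spec.n_pa_only:
            assignment[sid] = ("PA",)
        else:
            assignment[sid] = ("AS",)

    replicates: dict = {m: {} for m in MODALITIES}
    for sid in subjects:
        for m in assignment[sid]:
            rs = generate_replicates(config, m, seeds[sid])
            replicates[m][sid] = ReplicateSet(
                subject_id=sid, modality=m, traces=rs.traces
            )

    truth_features = {}
    for m in MODALITIES:
        rows = [true_features(config, m, seeds[sid], feature_config, discard_ms)
                for sid in subjects]
        truth_features[m] = pd.DataFrame(rows, index=list(subjects))

    effects_by_param = {e.parameter: e for e in spec.effect_map}
    rng = np.random.default_rng([int(config.seed), 97])
    panel = {}
    generating_r2 = {}
    for p_idx, pname in enumerate(spec.parameter_names):
        eff = effects_by_param.get(pname)
        if eff is None:
            panel[pname] = rng.normal(0.0, 1.0, size=spec.n_subjects)
            continue
        x = truth_features[eff.modality][eff.feature].to_numpy()
        if not np.all(np.isfinite(x)):
            raise ValueError(
                f"true feature {eff.feature!r} ({eff.modality}) is missing for "
                "some subjects and cannot carry a planted effect"
            )
        mu = eff.mean_response(x)
        panel[pname] = mu + rng.normal(0.0, eff.noise_sd, size=spec.n_subjects)
        var_mu = float(np.var(mu, ddof=1)) if spec.n_subjects > 1 else 0.0
        generating_r2[pname] = var_mu / (var_mu + eff.noise_sd**2) if var_mu > 0 else 0.0

    panel_df = pd.DataFrame(panel, index=list(subjects)).rename_axis("subject_id")

    truth = {
        "seed": int(config.seed),
        "subject_seeds": seeds,
        "modalities": {sid: list(assignment[sid]) for sid in subjects},
        "effects": [asdict(e) for e in spec.effect_map],
        "generating_r2": generating_r2,
        "true_features": {m: truth_features[m] for m in MODALITIES},
    }
    return CohortData(
        config=config,
        spec=spec,
        subjects=subjects,
        modalities=assignment,
        replicates=replicates,
        panel=panel_df,
        truth=truth,
    )


def write_cohort(cohort: CohortData, outdir, header_comment: str | None = None) -> None:
    """Write traces (CSV per subject), panel TSV and ground-truth JSON."""
    outdir = Path(outdir)
    for m, sets in cohort.replicates.items():
        for sid, rs in sets.items():
            write_replicates(outdir / "traces" / m / f"{sid}.csv", rs, header_comment)
    with open(outdir / "panel.tsv", "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        cohort.panel.to_csv(fh, sep="\t", float_format="%.10g")
    truth = dict(cohort.truth)
    truth["true_features"] = {
        m: {c: df[c].round(12).where(df[c].notna(), None).tolist()
            for c in df.columns}
        for m, df in cohort.truth["true_features"].items()
    }
    truth["subjects"] = list(cohort.subjects)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
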