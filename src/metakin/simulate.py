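"""Synthetic incremental-ergometry cohorts with known kinetic ground truth.

The generator reproduces the structure of a graded cycle-ergometry
biomarker study: workload starts at 50 W and rises by 25 W every 3 min up
to an individual maximum between 150 W and 425 W; dried-blood-spot samples
are drawn at rest, 2:30 min into every workload level, and 5 min after the
end of exercise.  Each metabolite's true trajectory follows one of seven
kinetic basis shapes (constant, logarithmic, sigmoid, linear, quadratic,
exponential, hockey-stick) expressed directly on the common relative
workload axis [0, 117], so ground truth is exactly comparable to pipeline
output after rescaling.  Concentrations carry multiplicative log-normal
noise and the maximum-load sample may be missing, as in the study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .io import Cohort, RECOVERY, REST

#: Protocol constants (watts / minutes).
START_WORKLOAD_W = 50.0
WORKLOAD_STEP_W = 25.0
LEVEL_DURATION_MIN = 3.0
METABOLITE_SAMPLE_OFFSET_MIN = 2.5  # metabolite profiling at 2:30 into a level
LACTATE_SAMPLE_OFFSET_MIN = 1.5  # lactate reference at 1:30 into a level
RECOVERY_DELAY_MIN = 5.0
MIN_MAX_WORKLOAD_W = 150.0
MAX_MAX_WORKLOAD_W = 425.0

#: Relative workload position of the recovery sample on the common axis.
RECOVERY_POSITION = 117.0

TEMPLATE_KINDS = (
    "sustained_const",
    "early_log",
    "halving_sigmoid",
    "late_linear",
    "late_quadratic",
    "late_exponential",
    "delayed_hockey",
)

#: Kinetic response pattern each basis shape realises.
KIND_TO_PATTERN: Mapping[str, str] = {
    "sustained_const": "sustained",
    "early_log": "early",
    "halving_sigmoid": "halving",
    "late_linear": "late",
    "late_quadratic": "late",
    "late_exponential": "late",
    "delayed_hockey": "delayed",
}


@dataclass(frozen=True)
class TemplateSpec:
    """Ground-truth kinetic shape of one simulated metabolite.

    ``amplitude`` is the relative change (fraction of baseline) the shape
    reaches at the end of exercise (position 100), negative for decreasing
    metabolites.  ``log_beta``/``sigmoid_tau``/``exp_rate`` tune the
    logarithmic, sigmoid and exponential shapes; ``breakpoint`` sets where
    the hockey stick turns (flat before, linear after).
    ``dip`` optionally overlays an early transient trough on [0, 25], as
    seen for short-chain acylcarnitines that are consumed before rising.
    """

    kind: str
    baseline: float
    amplitude: float = 0.0
    log_beta: float = 0.2
    sigmoid_tau: float = 8.0
    exp_rate: float = 3.0
    breakpoint: float = 100.0
    dip: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in TEMPLATE_KINDS:
            raise ValueError(f"unknown template kind {self.kind!r}")
        if not self.baseline > 0:
            raise ValueError("baseline must be positive")
        if abs(self.amplitude) > 5:
            raise ValueError("|amplitude| must be <= 5")

    @property
    def pattern(self) -> str:
        return KIND_TO_PATTERN[self.kind]


def template_value(spec: TemplateSpec, s) -> np.ndarray | float:
    """Ground-truth relative deviation from baseline at relative position ``s``.

    All shapes are anchored at 0 at rest (s = 0) and scaled to reach
    ``amplitude`` at the end of exercise (s = 100).  Exercise-driven
    shapes hold their end-of-exercise value through recovery (a late
    response is a change *up to the end* of physical activity); only the
    hockey stick moves after position 100, flat before its breakpoint
    and reaching ``amplitude`` at the recovery position.  ``s`` must lie
    in [0, 117].
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any((s_arr < 0.0) | (s_arr > RECOVERY_POSITION)):
        raise ValueError(f"relative position outside [0, {RECOVERY_POSITION:g}]")
    a = spec.amplitude
    s_ex = np.minimum(s_arr, 100.0)  # exercise window; plateau during recovery
    if spec.kind == "sustained_const":
        out = np.zeros_like(s_arr)
    elif spec.kind == "early_log":
        b = spec.log_beta
        out = a * np.log1p(b * s_ex) / math.log1p(100.0 * b)
    elif spec.kind == "halving_sigmoid":
        tau = spec.sigmoid_tau
        g = 1.0 / (1.0 + np.exp(-(s_ex - 50.0) / tau))
        g0 = 1.0 / (1.0 + math.exp(50.0 / tau))
        g100 = 1.0 / (1.0 + math.exp(-50.0 / tau))
        out = a * (g - g0) / (g100 - g0)
    elif spec.kind == "late_linear":
        out = a * s_ex / 100.0
    elif spec.kind == "late_quadratic":
        out = a * (s_ex / 100.0) ** 2
    elif spec.kind == "late_exponential":
        r = spec.exp_rate
        out = a * np.expm1(r * s_ex / 100.0) / math.expm1(r)
    else:  # delayed_hockey
        k = spec.breakpoint
        out = np.where(s_arr < k, 0.0, a * (s_arr - k) / (RECOVERY_POSITION - k))
    if spec.dip:
        bump = np.where(s_arr < 25.0, np.sin(np.pi * s_arr / 25.0), 0.0)
        out = out - spec.dip * bump
    return out if out.ndim else float(out)


def true_mfc(spec: TemplateSpec, grid_step: float = 1.0) -> float:
    """Directional maximum fold change implied by a template's true curve.

    Evaluated on a dense grid over [0, 117]; >= 1 when the minimum occurs
    before the maximum, <= 1 otherwise (the MFC orientation rule).
    """
    s = np.arange(0.0, RECOVERY_POSITION + grid_step / 2, grid_step)
    rel = np.asarray(template_value(spec, s))
    conc = 1.0 + rel
    i_min, i_max = int(np.argmin(conc)), int(np.argmax(conc))
    if i_min == i_max:
        return 1.0
    if i_min < i_max:
        return float(conc[i_max] / conc[i_min])
    return float(conc[i_min] / conc[i_max])


def demo_panel() -> dict[str, TemplateSpec]:
    """One metabolite per basis shape, amplitudes large enough to classify.

    Baselines are plausible blood concentrations in uM; amplitudes mirror
    the magnitudes reported for the study's marker metabolites (a late
    exponential rise of ~97% for acetylcarnitine-like behaviour, ~32%
    linear for alanine-like, a delayed post-exercise surge for glucose).
    """
    return {
        "sustained_like": TemplateSpec("sustained_const", baseline=120.0),
        "early_like": TemplateSpec("early_log", baseline=0.30, amplitude=0.30),
        "halving_like": TemplateSpec("halving_sigmoid", baseline=25.0, amplitude=0.30),
        "late_linear_like": TemplateSpec("late_linear", baseline=350.0, amplitude=0.32),
        "late_quadratic_like": TemplateSpec("late_quadratic", baseline=1.5, amplitude=0.40),
        "late_exponential_like": TemplateSpec("late_exponential", baseline=8.0, amplitude=0.97),
        "delayed_like": TemplateSpec("delayed_hockey", baseline=4500.0, amplitude=0.32),
    }


def study_panel() -> dict[str, TemplateSpec]:
    """A 30-metabolite panel emulating the reference exercise cohort.

    Shapes and amplitudes follow the published kinetic characterisation:
    a strong late-exponential rise for acetylcarnitine, late rises for the
    other short-chain acylcarnitines and the glucogenic amino acids, an
    early trough-then-rise for valerylcarnitine, a sigmoid for methionine,
    delayed post-exercise surges for glucose and octadecadienylcarnitine,
    and sustained behaviour for the remainder.  Amplitudes are set so the
    implied true MFCs match the published ranking (MFC = 1 + amplitude
    for monotone increasing shapes).
    """
    aa = 200.0  # generic amino-acid baseline, uM
    ac = 0.5  # generic acylcarnitine baseline, uM
    panel: dict[str, TemplateSpec] = {
        "Acetylcarnitine (C2)": TemplateSpec("late_exponential", baseline=8.0, amplitude=0.97),
        "Propionylcarnitine (C3)": TemplateSpec("late_linear", baseline=1.2, amplitude=0.52),
        "Alanine": TemplateSpec("late_linear", baseline=350.0, amplitude=0.42),
        "Valerylcarnitine (C5)": TemplateSpec(
            "early_log", baseline=0.15, amplitude=0.13, dip=0.16
        ),
        "Arginine": TemplateSpec("late_linear", baseline=90.0, amplitude=0.36),
        "Glucose": TemplateSpec("delayed_hockey", baseline=4500.0, amplitude=0.32),
        "Butyrylcarnitine (C4)": TemplateSpec("late_quadratic", baseline=0.25, amplitude=0.27),
        "Methylmalonylcarnitine (C3-DC-M)": TemplateSpec(
            "late_linear", baseline=0.06, amplitude=0.26
        ),
        "Hydroxyvalerylcarnitine (C5-OH)": TemplateSpec(
            "late_linear", baseline=0.05, amplitude=0.26
        ),
        "Octadecadienylcarnitine (C18:2)": TemplateSpec(
            "delayed_hockey", baseline=0.30, amplitude=0.21
        ),
        "Methionine": TemplateSpec("halving_sigmoid", baseline=25.0, amplitude=0.16),
        "Carnitine (C0)": TemplateSpec("late_linear", baseline=35.0, amplitude=-0.08),
        "Aspartic_Acid": TemplateSpec("late_linear", baseline=15.0, amplitude=-0.12),
    }
    sustained = (
        "Ornithine",
        "Tryptophan",
        "Octadecanoylcarnitine (C18)",
        "Histidine",
        "Phenylalanine",
        "Hexadecanoylcarnitine (C16)",
        "Citrulline",
        "Glutamic_Acid",
        "Tyrosine",
        "Glycine",
        "Lysine",
        "Proline",
        "Serine",
        "Octadecenoylcarnitine (C18:1)",
        "Threonine",
        "Valine",
        "xLeucine (Leucine + Isoleucine)",
    )
    for i, name in enumerate(sustained):
        base = ac * (1 + i % 3) if "carnitine" in name.lower() else aa * (0.5 + 0.25 * (i % 4))
        panel[name] = TemplateSpec("sustained_const", baseline=base)
    return panel


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of a synthetic cohort run.

    Defaults reproduce the study conditions: 47 subjects, individual
    maximum workloads uniform over the 25 W steps from 150 W to 425 W,
    ~10% multiplicative noise (the study does not quantify measurement
    noise; 10% CV is a typical targeted-MS figure) and a 12/47 chance of
    a missing maximum-load sample.
    """

    n_subjects: int = 47
    panel: Mapping[str, TemplateSpec] = field(default_factory=study_panel)
    noise_cv: float = 0.1
    p_missing_max: float = 12.0 / 47.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.noise_cv <= 1:
            raise ValueError("noise_cv must be in [0, 1]")
        if not 0 <= self.p_missing_max <= 1:
            raise ValueError("p_missing_max must be in [0, 1]")
        if len(self.panel) == 0:
            raise ValueError("panel must contain at least one metabolite")


def _workload_choices() -> np.ndarray:
    return np.arange(MIN_MAX_WORKLOAD_W, MAX_MAX_WORKLOAD_W + 1, WORKLOAD_STEP_W)


def _subject_protocol(max_workload: float) -> pd.DataFrame:
    """Stage table for one subject: rest, each level, recovery.

    Level k (workload 50 + 25(k-1) W) starts at 3(k-1) min; the metabolite
    sample is drawn 2:30 min in.  Exercise ends when the last level
    completes; recovery is sampled 5 min later.  Relative positions put
    rest at 0, level k at 100*W_k/W_max and recovery at 117.
    """
    workloads = np.arange(START_WORKLOAD_W, max_workload + 1, WORKLOAD_STEP_W)
    n_levels = len(workloads)
    rows = [
        {
            "stage": REST,
            "workload_w": np.nan,
            "time_min": 0.0,
            "position": 0.0,
        }
    ]
    for k, w in enumerate(workloads, start=1):
        rows.append(
            {
                "stage": f"{w:.0f}W",
                "workload_w": float(w),
                "time_min": LEVEL_DURATION_MIN * (k - 1) + METABOLITE_SAMPLE_OFFSET_MIN,
                "position": 100.0 * w / max_workload,
            }
        )
    rows.append(
        {
            "stage": RECOVERY,
            "workload_w": np.nan,
            "time_min": LEVEL_DURATION_MIN * n_levels + RECOVERY_DELAY_MIN,
            "position": RECOVERY_POSITION,
        }
    )
    return pd.DataFrame(rows)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal noise with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2, sigma=math.sqrt(sigma2), size=size)


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, pd.DataFrame]:
    """Simulate a cohort plus its ground truth.

    Returns the :class:`~metakin.io.Cohort` and a truth table with one row
    per metabolite: the template kind, its expected kinetic pattern label
    and the true directional MFC of the noiseless curve.

    Subjects are assigned to the four study groups (male/female x
    average/athletic) cyclically; group labels are carried but unused by
    the pipeline.  With probability ``p_missing_max`` a subject's
    maximum-load concentration is blanked for all metabolites — the row
    stays, as an explicit gap; rest and recovery are never blanked —
    mirroring the study's missingness at individual maximum load.
    """
    rng = np.random.default_rng(config.seed)
    choices = _workload_choices()
    groups = ("male_average", "female_average", "male_athletic", "female_athletic")
    records: list[pd.DataFrame] = []
    for i in range(config.n_subjects):
        sid = str(i + 1)
        max_w = float(rng.choice(choices))
        proto = _subject_protocol(max_w)
        drop_max = rng.random() < config.p_missing_max
        for name, spec in config.panel.items():
            rel = np.asarray(template_value(spec, proto["position"].to_numpy()))
            conc = spec.baseline * (1.0 + rel)
            conc = conc * _lognormal_factors(rng, config.noise_cv, len(conc))
            if drop_max:
                conc = np.where(proto["workload_w"].to_numpy() == max_w, np.nan, conc)
            block = proto.assign(
                subject_id=sid,
                group=groups[i % len(groups)],
                metabolite=name,
                concentration_um=conc,
            )
            records.append(block.drop(columns="position"))
    data = pd.concat(records, ignore_index=True)
    truth = pd.DataFrame(
        {
            "metabolite": list(config.panel),
            "kind": [s.kind for s in config.panel.values()],
            "pattern": [s.pattern for s in config.panel.values()],
            "baseline_um": [s.baseline for s in config.panel.values()],
            "true_mfc": [true_mfc(s) for s in config.panel.values()],
        }
    )
    return Cohort(data), truth


#: Calibration of the lactate gold-standard channel (mM): cohort medians of
#: roughly 1.2 at rest, 8.5 at maximum workload and 7.2 after recovery.
LACTATE_REST_MM = 1.2
LACTATE_MAX_MM = 8.5
LACTATE_RECOVERY_MM = 7.2


def lactate_reference(config: SimulationConfig) -> Cohort:
    """Simulate the lactate gold-standard channel (concentrations in mM).

    Lactate rises monotonically from rest to maximum load following a
    late-exponential profile — near-sustained early, then a steep climb,
    the classic lactate response to graded exercise — and partially
    recovers.  Samples are drawn 1:30 min into each level (one minute
    before the metabolite samples).  With ``noise_cv = 0`` every subject
    hits the calibration medians exactly.
    """
    rng = np.random.default_rng(None if config.seed is None else config.seed + 1)
    rate = 3.0  # late-exponential shape constant of the lactate rise

    def _lactate_mm(pos: np.ndarray) -> np.ndarray:
        rise = (LACTATE_MAX_MM - LACTATE_REST_MM) * np.expm1(
            rate * np.minimum(pos, 100.0) / 100.0
        ) / math.expm1(rate)
        return LACTATE_REST_MM + rise

    choices = _workload_choices()
    records: list[pd.DataFrame] = []
    for i in range(config.n_subjects):
        sid = str(i + 1)
        max_w = float(rng.choice(choices))
        proto = _subject_protocol(max_w)
        is_level = proto["stage"].isin([REST, RECOVERY]) == False  # noqa: E712
        proto.loc[is_level, "time_min"] += LACTATE_SAMPLE_OFFSET_MIN - METABOLITE_SAMPLE_OFFSET_MIN
        pos = proto["position"].to_numpy()
        conc = _lactate_mm(pos)
        conc[proto["stage"] == RECOVERY] = LACTATE_RECOVERY_MM
        conc = conc * _lognormal_factors(rng, config.noise_cv, len(conc))
        records.append(
            proto.assign(
                subject_id=sid,
                group="all",
                metabolite="Lactate",
                concentration_um=conc,  # mM for this channel
            ).drop(columns="position")
        )
    return Cohort(pd.concat(records, ignore_index=True))


def noiseless(config: SimulationConfig) -> SimulationConfig:
    """The same configuration with noise and missingness switched off."""
    return replace(config, noise_cv=0.0, p_missing_max=0.0)
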