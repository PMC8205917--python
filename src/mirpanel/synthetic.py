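"""Synthetic case-control serum miRNA cohorts.

Generates cohorts with the statistical structure the panel-discovery
pipeline assumes, so every downstream stage is testable without microarray
data: log-normal fluorescence signals with a detection floor, three stable
internal-control miRNAs, a per-sample multiplicative technical factor that
normalization must cancel, per-control-source offsets, and planted
discriminative markers.

One planted marker is a *suppressor*: its case/control means are equal
(marginal AUC ~ 0.5) but it shares a latent nuisance factor with a true
up-marker, so a linear discriminant that includes it can subtract the
shared noise and beat the up-marker alone. This reproduces the phenomenon
of a near-chance miRNA that nevertheless raises a panel's AUC.

The signal model, per miRNA m and sample s::

    log2 x[m,s] = baseline_m + effect_m * 1[s is case]
                  + loading_m * Z_s + batch(source_s) + tech_s
                  + Normal(0, sd_m)
    raw x[m,s]  = max(2 ** log2 x[m,s], detection_floor)

Z_s ~ N(0,1) is the shared latent nuisance; tech_s is the sample-wide
technical factor (normal in log2, i.e. log-normal multiplicative); batch is
an additive log2 offset per control serum source. Both batch and tech act
uniformly on all miRNAs of a sample, so internal-control normalization
removes them exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, SampleTable, SAMPLE_COLUMNS

__all__ = [
    "MarkerSpec",
    "SimulationConfig",
    "default_markers",
    "recovery_markers",
    "generate_cohort",
    "split_discovery_validation",
    "marginal_auc_normal",
]

MARKER_ROLES = ("up", "down", "moderate", "suppressor")


@dataclass(frozen=True)
class MarkerSpec:
    """A planted discriminative miRNA.

    ``effect`` is the case-minus-control shift in log2 units;
    ``latent_loading`` couples the miRNA to the shared nuisance factor
    (nonzero only for suppressor pairs).
    """

    mirna_id: str
    effect: float
    role: str
    latent_loading: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in MARKER_ROLES:
            raise ValueError(f"unknown marker role {self.role!r}")
        if self.role == "up" and not self.effect > 0:
            raise ValueError("up marker requires effect > 0")
        if self.role == "down" and not self.effect < 0:
            raise ValueError("down marker requires effect < 0")
        if self.role == "suppressor":
            if abs(self.effect) > 0.2:
                raise ValueError("suppressor requires near-zero effect")
            if self.latent_loading == 0:
                raise ValueError("suppressor requires nonzero latent_loading")


def default_markers() -> tuple[MarkerSpec, ...]:
    """Default planted panel: marginal AUCs spanning ~0.46-0.93.

    The up-marker and the suppressor share the latent nuisance (loading 1),
    so the suppressor's marginal AUC sits near chance while its inclusion
    raises the panel AUC.
    """
    return (
        MarkerSpec("miR-sim-up", effect=3.0, role="up", latent_loading=1.0),
        MarkerSpec("miR-sim-down", effect=-1.5, role="down"),
        MarkerSpec("miR-sim-mod", effect=1.0, role="moderate"),
        MarkerSpec("miR-sim-sup", effect=0.0, role="suppressor", latent_loading=1.0),
    )


def recovery_markers() -> tuple[MarkerSpec, ...]:
    """Harder recovery setting: weaker effects (1.6 / -1.2 / 0.8 log2 units
    plus a suppressor), used for the parameter-recovery suites."""
    return (
        MarkerSpec("miR-sim-up", effect=1.6, role="up", latent_loading=1.0),
        MarkerSpec("miR-sim-down", effect=-1.2, role="down"),
        MarkerSpec("miR-sim-mod", effect=0.8, role="moderate"),
        MarkerSpec("miR-sim-sup", effect=0.0, role="suppressor", latent_loading=1.0),
    )


def _check_fractions(name: str, fr: Sequence[float]) -> tuple[float, ...]:
    fr = tuple(float(f) for f in fr)
    if any(f < 0 or f > 1 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
        raise ValueError(f"{name} must lie in [0,1] and sum to 1, got {fr}")
    return fr


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the discovery arm of the motivating case-control study:
    control sources split 0.351/0.327/0.322, case stages 0.952/0.041/0.007
    (IA/IB/II), histology 0.564/0.422/0.014, age ~65 (20-90), 72% male.
    300 miRNAs keep test cohorts small; pass 2565 to mimic the chip.
    """

    n_case: int = 200
    n_control: int = 200
    n_mirna: int = 300
    control_mirna_ids: tuple[str, str, str] = ("miR-ctl-1", "miR-ctl-2", "miR-ctl-3")
    control_source_fractions: tuple[float, float, float] = (0.351, 0.327, 0.322)
    expressed_fraction: float = 0.18
    baseline_log2_range: tuple[float, float] = (7.0, 13.0)
    background_log2_range: tuple[float, float] = (3.0, 6.0)
    marker_baseline_log2: float = 9.0
    control_baseline_log2: tuple[float, float, float] = (10.0, 10.5, 11.0)
    noise_sd: float = 1.0
    control_sd: float = 0.05
    detection_floor: float = 8.0
    planted_markers: tuple[MarkerSpec, ...] = field(default_factory=default_markers)
    batch_shifts: tuple[float, float, float] = (0.0, 0.15, -0.15)
    technical_sd: float = 0.3
    stage_fractions: tuple[float, float, float] = (0.952, 0.041, 0.007)
    histology_fractions: tuple[float, float, float] = (0.564, 0.422, 0.014)
    age_mean: float = 65.0
    age_sd: float = 11.0
    age_range: tuple[float, float] = (20.0, 90.0)
    male_fraction: float = 0.72
    seed: int = 0

    def __post_init__(self) -> None:
        self.control_source_fractions = _check_fractions(
            "control_source_fractions", self.control_source_fractions
        )
        self.stage_fractions = _check_fractions("stage_fractions", self.stage_fractions)
        self.histology_fractions = _check_fractions(
            "histology_fractions", self.histology_fractions
        )
        if len(set(self.control_mirna_ids)) != 3:
            raise ValueError("exactly 3 distinct control miRNAs required")
        if self.n_mirna <= len(self.planted_markers) + 3:
            raise ValueError("n_mirna must exceed planted markers + 3 controls")
        if not 0 <= self.male_fraction <= 1:
            raise ValueError("male_fraction must lie in [0,1]")
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("need at least one sample per group")


def marginal_auc_normal(effect: float, sd: float, latent_loading: float = 0.0) -> float:
    """Closed-form single-feature AUC for the generator's normal model:
    Phi(effect / (sd_total * sqrt(2))) with sd_total^2 = sd^2 + loading^2."""
    from scipy.stats import norm

    total = math.hypot(sd, latent_loading)
    return float(norm.cdf(effect / (total * math.sqrt(2.0))))


def _counts_largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer composition of n following the fractions (deterministic)."""
    quotas = [n * f for f in fractions]
    counts = [int(math.floor(q)) for q in quotas]
    short = n - sum(counts)
    order = np.argsort([-(q - math.floor(q)) for q in quotas], kind="stable")
    for i in range(short):
        counts[order[i]] += 1
    return counts


def _categorical(rng: np.random.Generator, n: int, levels, fractions) -> np.ndarray:
    counts = _counts_largest_remainder(n, fractions)
    vals = np.repeat(list(levels), counts)
    return rng.permutation(vals)


def generate_cohort(config: SimulationConfig) -> tuple[ExpressionMatrix, SampleTable]:
    """Draw one cohort: raw signal matrix plus metadata.

    Deterministic given ``config.seed``. Covariate compositions follow the
    configured proportions exactly (largest-remainder rounding, then
    shuffled), emulating age/gender matching by drawing cases and controls
    from identical covariate distributions.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_case + config.n_control
    marker_ids = [m.mirna_id for m in config.planted_markers]
    if set(marker_ids) & set(config.control_mirna_ids):
        raise ValueError("planted markers cannot be control miRNAs")

    n_null = config.n_mirna - len(marker_ids) - 3
    null_ids = [f"miR-sim-{i:04d}" for i in range(n_null)]
    mirna_ids = marker_ids + list(config.control_mirna_ids) + null_ids

    # serum is miRNA-poor: a minority of species is robustly expressed,
    # the rest sit near the detection floor and fail the robust filter
    expressed = rng.random(n_null) < config.expressed_fraction
    null_baseline = np.where(
        expressed,
        rng.uniform(*config.baseline_log2_range, size=n_null),
        rng.uniform(*config.background_log2_range, size=n_null),
    )
    baseline = np.concatenate(
        [
            np.full(len(marker_ids), config.marker_baseline_log2),
            np.asarray(config.control_baseline_log2, dtype=float),
            null_baseline,
        ]
    )
    sd = np.full(config.n_mirna, config.noise_sd)
    sd[len(marker_ids):len(marker_ids) + 3] = config.control_sd
    effect = np.zeros(config.n_mirna)
    loading = np.zeros(config.n_mirna)
    for j, m in enumerate(config.planted_markers):
        effect[j] = m.effect
        loading[j] = m.latent_loading

    is_case = np.concatenate(
        [np.ones(config.n_case, bool), np.zeros(config.n_control, bool)]
    )
    source = np.concatenate(
        [
            np.full(config.n_case, "none"),
            _categorical(
                rng, config.n_control, ("A", "B", "C"), config.control_source_fractions
            ),
        ]
    )
    batch = dict(zip(("A", "B", "C"), config.batch_shifts), none=0.0)
    batch_s = np.array([batch[s] for s in source])

    z = rng.normal(size=n)  # shared latent nuisance
    tech = rng.normal(0.0, config.technical_sd, size=n)

    log2sig = (
        baseline[:, None]
        + effect[:, None] * is_case[None, :]
        + loading[:, None] * z[None, :]
        + (batch_s + tech)[None, :]
        + rng.normal(size=(config.n_mirna, n)) * sd[:, None]
    )
    raw = np.maximum(np.exp2(log2sig), config.detection_floor)

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    matrix = ExpressionMatrix(
        pd.DataFrame(raw, index=pd.Index(mirna_ids, name="mirna_id"), columns=sample_ids),
        scale="raw",
    )

    age = np.clip(
        rng.normal(config.age_mean, config.age_sd, size=n), *config.age_range
    ).round(0)
    n_male_case = _counts_largest_remainder(
        config.n_case, (config.male_fraction, 1 - config.male_fraction)
    )[0]
    n_male_ctl = _counts_largest_remainder(
        config.n_control, (config.male_fraction, 1 - config.male_fraction)
    )[0]
    gender = np.concatenate(
        [
            rng.permutation(
                ["male"] * n_male_case + ["female"] * (config.n_case - n_male_case)
            ),
            rng.permutation(
                ["male"] * n_male_ctl + ["female"] * (config.n_control - n_male_ctl)
            ),
        ]
    )
    stage = np.concatenate(
        [
            _categorical(rng, config.n_case, ("IA", "IB", "II"), config.stage_fractions),
            np.full(config.n_control, "none"),
        ]
    )
    histology = np.concatenate(
        [
            _categorical(
                rng,
                config.n_case,
                ("differentiated", "undifferentiated", "special"),
                config.histology_fractions,
            ),
            np.full(config.n_control, "none"),
        ]
    )
    samples = SampleTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": np.where(is_case, "case", "control"),
                "control_source": source,
                "age": age,
                "gender": gender,
                "stage": stage,
                "histology": histology,
                "split": "unassigned",
            },
            columns=list(SAMPLE_COLUMNS),
        )
    )
    return matrix, samples


def null_config(seed: int = 0, n_case: int = 200, n_control: int = 200,
                n_mirna: int = 300) -> SimulationConfig:
    """A cohort with no planted signal, batch shifts, or technical noise."""
    return SimulationConfig(
        n_case=n_case,
        n_control=n_control,
        n_mirna=n_mirna,
        planted_markers=(),
        batch_shifts=(0.0, 0.0, 0.0),
        technical_sd=0.0,
        seed=seed,
    )


def split_discovery_validation(
    samples: SampleTable, ratio: float = 0.5, seed: int = 0
) -> SampleTable:
    """Assign discovery/validation membership, stratified by group and, within
    controls, by control source.

    Each stratum's discovery count is within one sample of ``ratio`` times
    its size. When a group's total quota is fractional, the case group
    rounds down and the control group rounds up, so odd equal-sized groups
    split complementarily (e.g. 1417+1417 at 1:1 gives one arm 708 cases
    and 709 controls, the other 709 and 708). Deterministic given ``seed``.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    df = samples.df.copy()
    split = pd.Series("validation", index=df.index)

    def assign(stratum_idx: np.ndarray, n_disc: int) -> None:
        chosen = rng.permutation(stratum_idx)[:n_disc]
        split.loc[chosen] = "discovery"

    case_idx = df.index[df["group"] == "case"].to_numpy()
    if len(case_idx) == 0:
        warnings.warn("empty case stratum", stacklevel=2)
    assign(case_idx, int(math.floor(len(case_idx) * ratio)))

    ctl = df["group"] == "control"
    n_ctl = int(ctl.sum())
    if n_ctl == 0:
        warnings.warn("empty control stratum", stacklevel=2)
    n_disc_ctl = int(math.ceil(n_ctl * ratio))
    sources = [s for s in ("A", "B", "C", "none")
               if (ctl & (df["control_source"] == s)).any()]
    if n_ctl > 0 and not sources:
        sources = ["none"]
    strata = [df.index[ctl & (df["control_source"] == s)].to_numpy()
              for s in sources]
    sizes = [len(s) for s in strata]
    # per-stratum quotas, largest-remainder rounded to hit the group total
    counts = [int(math.floor(size * ratio)) for size in sizes]
    short = n_disc_ctl - sum(counts)
    order = np.argsort([-(size * ratio - math.floor(size * ratio)) for size in sizes],
                       kind="stable")
    for i in range(short):
        counts[order[i % len(sources)]] += 1
    for stratum_idx, n_disc in zip(strata, counts):
        assign(stratum_idx, n_disc)

    df["split"] = split
    return SampleTable(df)
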