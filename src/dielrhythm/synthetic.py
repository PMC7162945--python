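"""Synthetic multi-organ diel expression datasets with known ground truth.

The generator emulates the structure of a two-color oligoarray diel time
course: per-organ tables of LOWESS-normalized log-ratios at 14 time
points (2-h steps starting 2 h before dawn), two replicate
hybridizations per time point, a per-cell detection mask with dropout,
a rhythmic subset whose peak times concentrate at dawn and dusk, and
cross-organ sharing of expressed/rhythmic transcripts with optional
planted phase shifts.  Every stage of the analysis pipeline can thus be
checked against planted truth.

Rhythmic series follow ``baseline + amplitude*cos(2*pi*(t-phase)/period)``
plus i.i.d. Gaussian noise (additive noise is appropriate on the
normalized log scale); a sawtooth waveform is available for robustness
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import DielDesign, generate_design
from .preprocessing import ExpressionMatrix, collapse_replicates

__all__ = [
    "DEFAULT_PHASE_LAW",
    "OrganSpec",
    "SharingSpec",
    "OrganDataset",
    "simulate_series",
    "draw_phases",
    "generate_organ_dataset",
    "generate_multi_organ",
    "generate_annotation",
]


class SyntheticDataError(ValueError):
    pass


#: Dawn/dusk-concentrated mixture of wrapped normals: (weight, mean ZT, SD h).
#: Weights and spread chosen to mirror phase histograms in which roughly
#: 35-45% of rhythmic transcripts fall in the modal 2-h bin near dawn and a
#: secondary group peaks near dusk.
DEFAULT_PHASE_LAW: tuple[tuple[float, float, float], ...] = (
    (0.6, 0.5, 0.6),
    (0.4, 12.0, 0.6),
)


def simulate_series(
    design: DielDesign,
    baseline: float,
    amplitude: float,
    phase_zt: float,
    noise_sd: float,
    rng: np.random.Generator | int,
    waveform: str = "cosine",
) -> np.ndarray:
    """One rhythmic series sampled at the design's time points."""
    if amplitude < 0:
        raise SyntheticDataError("amplitude must be non-negative")
    if noise_sd < 0:
        raise SyntheticDataError("noise_sd must be non-negative")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    t = np.asarray(design.sample_times_zt, dtype=float)
    theta = 2.0 * np.pi * (t - phase_zt) / design.period_h
    if waveform == "cosine":
        shape = np.cos(theta)
    elif waveform == "sawtooth":
        # peak at the phase, linear fall across the cycle
        shape = 1.0 - 2.0 * ((t - phase_zt) % design.period_h) / design.period_h
    else:
        raise SyntheticDataError(f"unknown waveform {waveform!r}")
    return baseline + amplitude * shape + rng.normal(0.0, noise_sd, size=t.size)


def draw_phases(
    n: int,
    phase_law,
    rng: np.random.Generator,
    period_h: float = 24.0,
) -> np.ndarray:
    """Draw peak times from a phase law.

    ``phase_law`` is either the string ``"uniform"`` or a sequence of
    ``(weight, mean_zt, sd_h)`` wrapped-normal mixture components
    (``sd_h`` 0 plants exact phases).
    """
    if isinstance(phase_law, str):
        if phase_law != "uniform":
            raise SyntheticDataError(f"unknown phase law {phase_law!r}")
        return rng.uniform(0.0, period_h, size=n)
    comps = [tuple(map(float, c)) for c in phase_law]
    if not comps:
        raise SyntheticDataError("empty phase law")
    weights = np.array([c[0] for c in comps])
    if np.any(weights < 0) or weights.sum() <= 0:
        raise SyntheticDataError("phase-law weights must be non-negative")
    weights = weights / weights.sum()
    which = rng.choice(len(comps), size=n, p=weights)
    means = np.array([c[1] for c in comps])[which]
    sds = np.array([c[2] for c in comps])[which]
    return (means + rng.normal(0.0, 1.0, size=n) * sds) % period_h


@dataclass(frozen=True)
class OrganSpec:
    """Per-organ generator parameters (defaults are the study conditions)."""

    n_transcripts: int = 1000
    rhythmic_fraction: float = 0.3
    phase_law: object = DEFAULT_PHASE_LAW
    amplitude_range: tuple[float, float] = (1.0, 1.0)
    noise_sd: float = 0.25
    dropout_rate: float = 0.1
    n_replicates: int = 2
    baseline_sd: float = 0.5
    waveform: str = "cosine"

    def __post_init__(self) -> None:
        if self.n_transcripts <= 0:
            raise SyntheticDataError("n_transcripts must be positive")
        for name in ("rhythmic_fraction", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SyntheticDataError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise SyntheticDataError("noise_sd must be non-negative")
        if self.amplitude_range[0] < 0 or self.amplitude_range[1] < self.amplitude_range[0]:
            raise SyntheticDataError("invalid amplitude range")
        if self.n_replicates < 1:
            raise SyntheticDataError("need at least one replicate")


@dataclass(frozen=True)
class SharingSpec:
    """Cross-organ overlap structure.

    shared_expressed_fraction : fraction of the smallest organ's
        transcripts expressed in *all* organs.
    shared_rhythmic_fraction : fraction of the smallest organ's rhythmic
        quota that is rhythmic in all organs (with a common base phase).
    phase_shift_h : per-organ phase shift added to shared rhythmic
        transcripts (absent organs shift 0).
    background_detection_rate : detection probability for transcripts
        not expressed in an organ (background-level signals).
    """

    shared_expressed_fraction: float = 0.75
    shared_rhythmic_fraction: float = 0.5
    phase_shift_h: Mapping[str, float] = field(default_factory=dict)
    background_detection_rate: float = 0.15

    def __post_init__(self) -> None:
        for name in (
            "shared_expressed_fraction",
            "shared_rhythmic_fraction",
            "background_detection_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SyntheticDataError(f"{name} must be in [0, 1]")


@dataclass
class OrganDataset:
    """Replicate expression matrices plus per-transcript ground truth.

    ``truth`` columns: expressed, rhythmic (flags), true_phase_zt (NaN
    when not rhythmic), amplitude, noise_sd, baseline, and
    shared_rhythmic (planted as rhythmic in every organ with a common
    base phase).
    """

    organ: str
    replicates: list[ExpressionMatrix]
    truth: pd.DataFrame

    @property
    def matrix(self) -> ExpressionMatrix:
        """Replicate-averaged matrix (detected = detected in any replicate)."""
        return collapse_replicates(self.replicates)


def _materialize_organ(
    design: DielDesign,
    organ: str,
    ids: Sequence[str],
    expressed: np.ndarray,
    phases: np.ndarray,
    spec: OrganSpec,
    rng: np.random.Generator,
    background_detection_rate: float = 0.15,
    shared_rhythmic: np.ndarray | None = None,
) -> OrganDataset:
    """Build replicate matrices for one organ from planted truth arrays."""
    n = len(ids)
    t = np.asarray(design.sample_times_zt, dtype=float)
    rhythmic = np.isfinite(phases)
    baseline = rng.normal(0.0, spec.baseline_sd, size=n)
    amplitude = np.where(
        rhythmic, rng.uniform(*spec.amplitude_range, size=n), 0.0
    )
    theta = 2.0 * np.pi * (t[None, :] - phases[:, None]) / design.period_h
    if spec.waveform == "cosine":
        shape = np.where(rhythmic[:, None], np.cos(np.nan_to_num(theta)), 0.0)
    elif spec.waveform == "sawtooth":
        frac = ((t[None, :] - np.nan_to_num(phases[:, None])) % design.period_h)
        shape = np.where(rhythmic[:, None], 1.0 - 2.0 * frac / design.period_h, 0.0)
    else:
        raise SyntheticDataError(f"unknown waveform {spec.waveform!r}")
    signal = baseline[:, None] + amplitude[:, None] * shape
    columns = design.time_labels()
    replicates = []
    for _ in range(spec.n_replicates):
        values = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape)
        detect_p = np.where(expressed, 1.0 - spec.dropout_rate, background_detection_rate)
        mask = (rng.random(signal.shape) < detect_p[:, None]).astype(int)
        replicates.append(
            ExpressionMatrix(
                organ=organ,
                values=pd.DataFrame(values, index=list(ids), columns=columns),
                detected=pd.DataFrame(mask, index=list(ids), columns=columns),
                design=design,
            )
        )
    truth = pd.DataFrame(
        {
            "expressed": expressed.astype(bool),
            "rhythmic": rhythmic,
            "true_phase_zt": phases,
            "amplitude": amplitude,
            "noise_sd": spec.noise_sd,
            "baseline": baseline,
            "shared_rhythmic": (
                shared_rhythmic
                if shared_rhythmic is not None
                else np.zeros(n, dtype=bool)
            ),
        },
        index=pd.Index(list(ids), name="transcript_id"),
    )
    return OrganDataset(organ=organ, replicates=replicates, truth=truth)


def generate_organ_dataset(
    design: DielDesign | None = None,
    spec: OrganSpec | None = None,
    rng_seed: int = 0,
    organ: str = "L1",
    transcript_ids: Sequence[str] | None = None,
) -> OrganDataset:
    """Single-organ dataset: all transcripts expressed, an exact
    ``round(n * rhythmic_fraction)`` of them rhythmic."""
    design = design or generate_design()
    spec = spec or OrganSpec()
    rng = np.random.default_rng(rng_seed)
    n = spec.n_transcripts
    ids = (
        list(transcript_ids)
        if transcript_ids is not None
        else [f"T{i:06d}" for i in range(n)]
    )
    if len(ids) != n:
        raise SyntheticDataError("transcript_ids length does not match n_transcripts")
    n_rhythmic = int(round(n * spec.rhythmic_fraction))
    rhythmic_idx = rng.choice(n, size=n_rhythmic, replace=False)
    phases = np.full(n, np.nan)
    phases[rhythmic_idx] = draw_phases(n_rhythmic, spec.phase_law, rng, design.period_h)
    expressed = np.ones(n, dtype=bool)
    return _materialize_organ(design, organ, ids, expressed, phases, spec, rng)


def generate_multi_organ(
    design: DielDesign | None = None,
    organ_specs: Mapping[str, OrganSpec] | None = None,
    sharing: SharingSpec | None = None,
    rng_seed: int = 0,
) -> dict[str, OrganDataset]:
    """Multi-organ dataset over a common transcript universe.

    A shared pool is expressed in every organ; the remainder of each
    organ's expressed quota is organ-specific.  A shared-rhythmic subset
    of the pool is rhythmic in all organs with a common base phase (plus
    any per-organ planted shift); each organ tops up its rhythmic quota
    from its remaining expressed transcripts.  Matrices cover the whole
    universe, so transcripts absent from an organ appear as
    background-level, rarely detected rows.
    """
    design = design or generate_design()
    if organ_specs is None:
        organ_specs = {o: OrganSpec() for o in ("L1", "I1", "I5")}
    if len(organ_specs) < 2:
        raise SyntheticDataError("need at least two organs")
    sharing = sharing or SharingSpec()
    organs = list(organ_specs)
    n_min = min(s.n_transcripts for s in organ_specs.values())
    n_shared = int(round(sharing.shared_expressed_fraction * n_min))
    for organ, spec in organ_specs.items():
        if n_shared > spec.n_transcripts:
            raise SyntheticDataError(
                f"shared pool ({n_shared}) exceeds {organ} total ({spec.n_transcripts})"
            )
    r_quota = {
        o: int(round(s.n_transcripts * s.rhythmic_fraction))
        for o, s in organ_specs.items()
    }
    n_shared_rhythmic = int(round(sharing.shared_rhythmic_fraction * min(r_quota.values())))
    if n_shared_rhythmic > n_shared:
        raise SyntheticDataError("shared rhythmic pool exceeds shared expressed pool")

    shared_ids = [f"S{i:06d}" for i in range(n_shared)]
    specific_ids = {
        o: [f"{o}.X{i:06d}" for i in range(s.n_transcripts - n_shared)]
        for o, s in organ_specs.items()
    }
    universe = shared_ids + [tid for o in organs for tid in specific_ids[o]]
    index = {tid: k for k, tid in enumerate(universe)}

    parent = np.random.default_rng(rng_seed)
    shared_rhythmic_ids = list(
        parent.choice(shared_ids, size=n_shared_rhythmic, replace=False)
    )
    first_spec = organ_specs[organs[0]]
    base_phases = draw_phases(
        n_shared_rhythmic, first_spec.phase_law, parent, design.period_h
    )

    out: dict[str, OrganDataset] = {}
    for oi, organ in enumerate(organs):
        spec = organ_specs[organ]
        rng = np.random.default_rng([rng_seed, oi])
        expressed_ids = set(shared_ids) | set(specific_ids[organ])
        expressed = np.zeros(len(universe), dtype=bool)
        expressed[[index[tid] for tid in expressed_ids]] = True
        phases = np.full(len(universe), np.nan)
        shift = float(sharing.phase_shift_h.get(organ, 0.0))
        for tid, ph in zip(shared_rhythmic_ids, base_phases):
            phases[index[tid]] = (ph + shift) % design.period_h
        n_extra = r_quota[organ] - n_shared_rhythmic
        if n_extra < 0:
            raise SyntheticDataError(
                f"shared rhythmic pool exceeds {organ}'s rhythmic quota"
            )
        candidates = sorted(expressed_ids - set(shared_rhythmic_ids))
        extra_ids = rng.choice(candidates, size=n_extra, replace=False)
        extra_phases = draw_phases(n_extra, spec.phase_law, rng, design.period_h)
        for tid, ph in zip(extra_ids, extra_phases):
            phases[index[tid]] = ph
        shared_flag = np.zeros(len(universe), dtype=bool)
        shared_flag[[index[tid] for tid in shared_rhythmic_ids]] = True
        out[organ] = _materialize_organ(
            design,
            organ,
            universe,
            expressed,
            phases,
            spec,
            rng,
            background_detection_rate=sharing.background_detection_rate,
            shared_rhythmic=shared_flag,
        )
    return out


def generate_annotation(
    transcript_ids: Sequence[str],
    categories: Sequence[str],
    enrichment_spec: Mapping[str, float] | None = None,
    rhythmic_ids: Sequence[str] = (),
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Assign one functional category per transcript.

    ``enrichment_spec`` maps a category to the odds multiplier applied
    to rhythmic transcripts: odds 1 everywhere means no planted
    association; odds >> 1 for a category makes it overrepresented among
    the rhythmic set.  Returns a two-column table
    (transcript_id, category).
    """
    categories = list(categories)
    if not categories:
        raise SyntheticDataError("category list must not be empty")
    if len(set(categories)) != len(categories):
        raise SyntheticDataError("duplicate category labels")
    ids = list(transcript_ids)
    unknown = set(rhythmic_ids) - set(ids)
    if unknown:
        raise SyntheticDataError(f"unknown transcript ids: {sorted(unknown)[:3]}")
    spec = dict(enrichment_spec or {})
    bad = set(spec) - set(categories)
    if bad:
        raise SyntheticDataError(f"enrichment odds for unknown categories: {sorted(bad)}")
    rng = np.random.default_rng(rng_seed)
    rhythmic = set(rhythmic_ids)
    base = np.ones(len(categories))
    odds = np.array([spec.get(c, 1.0) for c in categories])
    if np.any(odds < 0):
        raise SyntheticDataError("odds must be non-negative")
    labels = []
    p_base = base / base.sum()
    p_rhyt = base * odds
    p_rhyt = p_rhyt / p_rhyt.sum()
    for tid in ids:
        p = p_rhyt if tid in rhythmic else p_base
        labels.append(categories[rng.choice(len(categories), p=p)])
    return pd.DataFrame({"transcript_id": ids, "category": labels})
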