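"""End-to-end inference of rhythmic transcripts and their phases.

Stage order: expression call -> Z-score -> weighted network -> modules
-> sign split -> median representatives -> merge -> adjacency membership
filter -> rhythmicity test of each representative -> module rhythm call
(adjusted P < 0.75) -> member noise filter (Spearman >= 0.3 against the
representative) -> cross-organ dendrogram phase correction -> final
per-transcript rhythm/phase calls.

A transcript is rhythmic iff it is a retained member of a rhythmic
module; its phase is the module's dendrogram-corrected phase (hours
after dawn, in [0, period)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .design import DielDesign
from .jtk import JtkConfig, JtkResult, jtk_test
from .network import (
    CoexpressionModule,
    NetworkConfig,
    apply_adjacency_threshold,
    build_modules,
    merge_close_modules,
)
from .preprocessing import (
    ExpressionCallConfig,
    ExpressionMatrix,
    call_expressed,
    collapse_replicates,
    zscore_rows,
)
from .setstats import day_night_fraction, percent

log = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds of the inference, at the study's defaults."""

    p_adjusted_max: float = 0.75
    member_min_spearman: float = 0.3
    phase_tolerance_h: float = 2.0
    dendrogram_cut: float = 0.25
    expression: ExpressionCallConfig = field(default_factory=ExpressionCallConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    jtk: JtkConfig = field(default_factory=JtkConfig)

    def __post_init__(self) -> None:
        if not 0.0 < self.p_adjusted_max <= 1.0:
            raise PipelineError("p_adjusted_max must be in (0, 1]")
        if not -1.0 <= self.member_min_spearman <= 1.0:
            raise PipelineError("member_min_spearman must be in [-1, 1]")
        if self.phase_tolerance_h < 0:
            raise PipelineError("phase_tolerance_h must be non-negative")
        if self.dendrogram_cut < 0:
            raise PipelineError("dendrogram_cut must be non-negative")


def call_rhythmic_modules(
    jtk_results: dict[str, JtkResult], p_adjusted_max: float = 0.75
) -> dict[str, bool]:
    """Module rhythm flags: adjusted P strictly below the threshold."""
    return {mid: res.p_adjusted < p_adjusted_max for mid, res in jtk_results.items()}


def filter_noisy_members(
    module: CoexpressionModule,
    zscored: pd.DataFrame,
    min_spearman: float = 0.3,
) -> tuple[str, ...]:
    """Drop members whose Spearman correlation with the representative
    falls below the threshold (kept at the boundary); constant members,
    whose rank correlation is undefined, are dropped and logged."""
    import warnings

    from scipy.stats import ConstantInputWarning

    rep = module.representative
    retained = []
    for tid in module.member_ids:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConstantInputWarning)
            rho = spearmanr(zscored.loc[tid].to_numpy(dtype=float), rep).statistic
        if not np.isfinite(rho):
            log.warning("member %s has undefined Spearman rho; dropped", tid)
            continue
        if rho >= min_spearman:
            retained.append(tid)
    return tuple(retained)


def circular_median(phases: list[float], period_h: float = 24.0) -> float:
    """Circular median: the given phase minimizing total circular
    distance to the others; ties resolved toward the earliest phase."""
    if not phases:
        raise PipelineError("no phases to take a median of")
    best = None
    for cand in sorted(phases):
        cost = sum(_circ_dist(cand, p, period_h) for p in phases)
        if best is None or cost < best[0] - 1e-12:
            best = (cost, cand)
    return best[1]


def _circ_dist(a: float, b: float, period_h: float) -> float:
    d = abs(a - b) % period_h
    return min(d, period_h - d)


def correct_phases_by_dendrogram(
    modules: list[CoexpressionModule],
    jtk_phases: dict[str, float],
    cut_height: float = 0.25,
    period_h: float = 24.0,
) -> dict[str, float]:
    """Consensus phases from a dendrogram of all representatives.

    All modules of all organs are clustered (average linkage on
    1 - Pearson of representatives) and the tree is cut at
    ``cut_height``; every module in a cluster receives the cluster's
    consensus phase, the circular median of the members' test phases.
    Modules with a constant representative keep their phase untouched.
    """
    if not modules:
        raise PipelineError("no modules to phase-correct")
    usable = [m for m in modules if np.ptp(m.representative) > 0]
    corrected = {m.module_id: jtk_phases[m.module_id] for m in modules}
    if len(usable) < 2:
        return corrected
    usable = sorted(usable, key=lambda m: m.module_id)
    reps = np.vstack([m.representative for m in usable])
    dissim = 1.0 - np.corrcoef(reps)
    np.fill_diagonal(dissim, 0.0)
    dissim = np.maximum(dissim, 0.0)
    tree = linkage(squareform(dissim, checks=False), method="average")
    labels = fcluster(tree, t=cut_height, criterion="distance")
    clusters: dict[int, list[CoexpressionModule]] = {}
    for lab, mod in zip(labels, usable):
        clusters.setdefault(int(lab), []).append(mod)
    for members in clusters.values():
        if len(members) < 2:
            continue
        consensus = circular_median(
            [jtk_phases[m.module_id] for m in members], period_h
        )
        for m in members:
            corrected[m.module_id] = consensus
    return corrected


def classify_phase_relation(
    phase_a: float,
    phase_b: float,
    tolerance_h: float = 2.0,
    period_h: float = 24.0,
) -> str:
    """Same / delayed / advanced call for organ B's peak relative to A's.

    The signed circular difference ``phase_b - phase_a`` is wrapped into
    (-period/2, period/2]; within +/- tolerance the phases are the same,
    a positive excess is a delay, a negative one an advance.
    """
    d = (phase_b - phase_a) % period_h
    if d > period_h / 2:
        d -= period_h
    if abs(d) <= tolerance_h + 1e-12:
        return "same"
    return "delayed" if d > 0 else "advanced"


@dataclass
class OrganResult:
    """Per-organ intermediate state retained for reporting and tests."""

    organ: str
    matrix: ExpressionMatrix
    expressed: set[str]
    degenerate: list[str]
    modules: list[CoexpressionModule]
    unassigned: list[str]
    jtk_results: dict[str, JtkResult]
    rhythmic_modules: dict[str, bool]
    retained_members: dict[str, tuple[str, ...]]


@dataclass
class PipelineResult:
    calls: dict[str, pd.DataFrame]
    module_table: pd.DataFrame
    summary: dict
    organ_results: dict[str, OrganResult]
    corrected_phases: dict[str, float]


def _phase_bin_label(phase: float, bin_h: float = 2.0) -> str:
    start = int(np.floor(phase / bin_h) * bin_h)
    return f"ZT{start:02d}"


def assign_transcript_calls(
    organ_result: OrganResult,
    corrected_phases: dict[str, float],
    design: DielDesign,
) -> pd.DataFrame:
    """Per-transcript rhythm/phase table for one organ."""
    membership: dict[str, tuple[str, float]] = {}
    for mod in organ_result.modules:
        if not organ_result.rhythmic_modules.get(mod.module_id, False):
            continue
        phase = corrected_phases[mod.module_id] % design.period_h
        for tid in organ_result.retained_members.get(mod.module_id, ()):
            if tid in membership:
                raise PipelineError(
                    f"transcript {tid!r} retained in two modules"
                )
            membership[tid] = (mod.module_id, phase)
    rows = []
    for tid in organ_result.matrix.transcript_ids:
        expressed = tid in organ_result.expressed
        mod_id, phase = membership.get(tid, (None, np.nan))
        rhythmic = mod_id is not None
        rows.append(
            {
                "transcript_id": tid,
                "organ": organ_result.organ,
                "expressed": expressed,
                "rhythmic": rhythmic,
                "module_id": mod_id if rhythmic else "",
                "phase_zt": phase,
                "phase_bin": _phase_bin_label(phase) if rhythmic else "",
                "day_peak": bool(rhythmic and phase < design.photoperiod_h),
            }
        )
    return pd.DataFrame(rows)


def run_full_pipeline(
    matrices: dict[str, ExpressionMatrix | list[ExpressionMatrix]],
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Run the whole inference on one or more organs.

    ``matrices`` maps organ label to either a replicate-collapsed
    matrix or a list of replicate matrices (which are averaged first).
    Deterministic given inputs and config.
    """
    if not matrices:
        raise PipelineError("no input matrices")
    organ_results: dict[str, OrganResult] = {}
    design = None
    for organ in sorted(matrices):
        entry = matrices[organ]
        mat = collapse_replicates(entry) if isinstance(entry, list) else entry
        design = mat.design
        log.info("[%s] expression call", organ)
        expressed = call_expressed(mat, config.expression)
        if len(expressed) < 2:
            raise PipelineError(f"stage expression-call [{organ}]: "
                                f"fewer than 2 expressed transcripts")
        sub = mat.values.loc[sorted(expressed)]
        z, degenerate = zscore_rows(sub)
        log.info("[%s] network and modules on %d series", organ, z.shape[0])
        try:
            modules, adjacency, unassigned = build_modules(z, config.network, organ)
            modules = merge_close_modules(modules, config.network.merge_dissim_max, z)
            modules = apply_adjacency_threshold(
                modules, adjacency, config.network.adjacency_min
            )
        except Exception as exc:
            raise PipelineError(f"stage modules [{organ}]: {exc}") from exc
        times = np.asarray(design.sample_times_zt)
        jtk_results = {
            m.module_id: jtk_test(m.representative, times, config.jtk, m.module_id)
            for m in modules
        }
        rhythmic = call_rhythmic_modules(jtk_results, config.p_adjusted_max)
        retained = {
            m.module_id: filter_noisy_members(m, z, config.member_min_spearman)
            for m in modules
        }
        organ_results[organ] = OrganResult(
            organ=organ,
            matrix=mat,
            expressed=expressed,
            degenerate=degenerate,
            modules=modules,
            unassigned=unassigned,
            jtk_results=jtk_results,
            rhythmic_modules=rhythmic,
            retained_members=retained,
        )
    all_modules = [m for r in organ_results.values() for m in r.modules]
    all_phases = {
        m.module_id: organ_results[m.organ].jtk_results[m.module_id].phase_zt
        for m in all_modules
    }
    corrected = (
        correct_phases_by_dendrogram(
            all_modules, all_phases, config.dendrogram_cut, design.period_h
        )
        if all_modules
        else {}
    )
    calls = {
        organ: assign_transcript_calls(res, corrected, design)
        for organ, res in organ_results.items()
    }
    module_rows = []
    for res in organ_results.values():
        for m in res.modules:
            jr = res.jtk_results[m.module_id]
            module_rows.append(
                {
                    "module_id": m.module_id,
                    "organ": m.organ,
                    "sign": m.sign,
                    "n_members": len(m.member_ids),
                    "n_retained": len(res.retained_members[m.module_id]),
                    "p_exact": jr.p_exact,
                    "p_adjusted": jr.p_adjusted,
                    "tau": jr.tau,
                    "phase_jtk": jr.phase_zt,
                    "phase_corrected": corrected[m.module_id],
                    "rhythmic": res.rhythmic_modules[m.module_id],
                }
            )
    module_table = pd.DataFrame(module_rows)
    summary: dict = {"organs": {}}
    for organ, res in organ_results.items():
        df = calls[organ]
        n_exp = int(df["expressed"].sum())
        n_rhy = int(df["rhythmic"].sum())
        phases = df.loc[df["rhythmic"], "phase_zt"]
        summary["organs"][organ] = {
            "n_transcripts": int(len(df)),
            "n_expressed": n_exp,
            "n_rhythmic": n_rhy,
            "pct_rhythmic_of_expressed": percent(n_rhy, n_exp) if n_exp else 0.0,
            "n_modules": len(res.modules),
            "n_rhythmic_modules": int(sum(res.rhythmic_modules.values())),
            "day_peak_fraction": (
                day_night_fraction(phases, design.photoperiod_h)
                if len(phases)
                else float("nan")
            ),
        }
    return PipelineResult(
        calls=calls,
        module_table=module_table,
        summary=summary,
        organ_results=organ_results,
        corrected_phases=corrected,
    )
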