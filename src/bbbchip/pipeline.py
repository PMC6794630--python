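"""End-to-end experiments: amyloid-beta accumulation, permeability recovery,
and two-group comparison.

Three orchestrated studies mirror how the device is actually used:

* :func:`run_abeta_profile_experiment` - the 7-day accumulation scenario
  (distributed secretion in the 3D culture channel, tight endothelial
  barrier, daily medium replacement of the luminal channel) with daily
  cross-channel profiles and the barrier-adjacent concentration time course;
* :func:`run_recovery_experiment` - the estimator-validation harness:
  generate a synthetic cohort with known truths, render, estimate, and
  summarise recovery (bias, RMSE) and the group comparison;
* :func:`compare_groups_ttest` - the two-sample Student's t test used for
  group comparisons (pooled variance by default, Welch behind a flag).

Every report is reproducible from (config, master seed, package version).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .geometry import DeviceLayout, build_default_layout
from .imaging import (
    ImagingModel,
    draw_cohort_permeabilities,
    generate_cohort,
)
from .permeability import (
    PermeabilityAssayModel,
    default_control_volume,
    recommended_cv_depth_um,
)
from .transport import (
    ReplacementSchedule,
    SimulationConfig,
    SimulationHistory,
    SourceSpec,
    profile_along_axis,
    run,
)
from .units import S_PER_DAY

__all__ = [
    "TTestResult",
    "AbetaProfileReport",
    "RunReport",
    "compare_groups_ttest",
    "run_abeta_profile_experiment",
    "run_recovery_experiment",
    "cohort_separation_rate",
    "ABETA_SOURCE_RATE_MOL_M3_S",
    "ABETA_INITIAL_MOL_M3",
]

logger = logging.getLogger("bbbchip")

#: Distributed amyloid-beta secretion rate in the 3D culture channel.
ABETA_SOURCE_RATE_MOL_M3_S = 1.4e-12
#: Amyloid-beta already present in the 3D culture channel when the chambers
#: are connected.
ABETA_INITIAL_MOL_M3 = 1.65e-7


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    dof: float
    pvalue: float
    kind: str = "student"

    def to_dict(self) -> dict:
        return {
            "t": self.statistic,
            "dof": self.dof,
            "p": self.pvalue,
            "kind": self.kind,
        }


def compare_groups_ttest(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> TTestResult:
    """Two-sided two-sample t test on raw values.

    Student's pooled-variance test by default (the group comparison the
    barrier study reports); ``welch=True`` drops the equal-variance
    assumption.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("groups must be finite")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and a.mean() == b.mean():
        # zero pooled variance and equal means: t is 0/0; define as no effect
        return TTestResult(0.0, len(a) + len(b) - 2, 1.0)
    res = stats.ttest_ind(a, b, equal_var=not welch)
    if welch:
        va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
        dof = (va + vb) ** 2 / (
            va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
        )
        kind = "welch"
    else:
        dof = len(a) + len(b) - 2
        kind = "student"
    return TTestResult(float(res.statistic), float(dof), float(res.pvalue), kind)


# ---------------------------------------------------------------------------
# amyloid-beta accumulation
# ---------------------------------------------------------------------------


@dataclass
class AbetaProfileReport:
    """Daily cross-channel profiles and the barrier-adjacent time course."""

    history: SimulationHistory
    daily_profiles: pd.DataFrame  # columns: day, position_um, concentration
    barrier_adjacent: pd.DataFrame  # columns: time_s, concentration
    config_echo: dict

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.daily_profiles.to_csv(out / "abeta_daily_profiles.csv", index=False)
        self.barrier_adjacent.to_csv(
            out / "abeta_barrier_adjacent.csv", index=False
        )
        (out / "abeta_config.json").write_text(json.dumps(self.config_echo, indent=2))
        self._plot(out / "abeta_profiles.png")

    def _plot(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
        for day, g in self.daily_profiles.groupby("day"):
            ax1.plot(g.position_um, g.concentration_mol_m3, label=f"day {day:g}")
        for role, x in self.history.grid.layout.region_boundaries_um():
            ax1.axvline(x, color="0.8", lw=0.8)
        ax1.set_xlabel("position across channels (um)")
        ax1.set_ylabel("concentration (mol m$^{-3}$)")
        ax1.legend(fontsize=7)
        ax2.plot(self.barrier_adjacent.time_s / S_PER_DAY,
                 self.barrier_adjacent.concentration_mol_m3)
        ax2.set_xlabel("time (days)")
        ax2.set_ylabel("barrier-adjacent gel conc. (mol m$^{-3}$)")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def run_abeta_profile_experiment(
    layout: DeviceLayout | None = None,
    days: float = 7.0,
    source_rate_mol_m3_s: float = ABETA_SOURCE_RATE_MOL_M3_S,
    initial_mol_m3: float = ABETA_INITIAL_MOL_M3,
    replacement_period_s: float = S_PER_DAY,
    dx_um: float = 25.0,
    dt_s: float = 600.0,
    snapshot_interval_s: float = 21600.0,
    scheme: str = "implicit",
    out_dir=None,
) -> AbetaProfileReport:
    """Simulate the amyloid-beta accumulation scenario and report profiles.

    Defaults: constant distributed secretion of 1.4e-12 mol m^-3 s^-1 in the
    3D culture channel (which also starts at 1.65e-7 mol m^-3), barrier
    conductance from the layout (D_b/h_b), daily replacement of the luminal
    channel with fresh medium (reset to 0), 7 days.
    """
    layout = layout if layout is not None else build_default_layout()
    sources = ()
    if source_rate_mol_m3_s > 0:
        sources = (SourceSpec("ren_3d_mc", source_rate_mol_m3_s),)
    config = SimulationConfig(
        layout=layout,
        solute="abeta",
        dx_um=dx_um,
        dt_s=dt_s,
        t_end_s=days * S_PER_DAY,
        initial_values={"ren_3d_mc": initial_mol_m3} if initial_mol_m3 > 0 else {},
        sources=sources,
        schedule=(ReplacementSchedule("bec_barrier_mc", replacement_period_s, 0.0),),
        snapshot_interval_s=snapshot_interval_s,
        scheme=scheme,
    )
    logger.info(
        "abeta-profile: S=%.3g mol/m3/s, C0=%.3g mol/m3, K=%.3g m/s, %.1f days",
        source_rate_mol_m3_s, initial_mol_m3,
        config.resolved_conductance(), days,
    )
    history = run(config)

    rows = []
    for day in range(1, int(days) + 1):
        prof = profile_along_axis(history, day * S_PER_DAY)
        rows.append(
            pd.DataFrame(
                {
                    "day": day,
                    "position_um": prof.position_um,
                    "concentration_mol_m3": prof.concentration_mol_m3,
                }
            )
        )
    daily = pd.concat(rows, ignore_index=True)

    face = history.grid.membrane_cols[0]
    adjacent = history.snapshots[:, :, face - 1].mean(axis=1)
    barrier_adjacent = pd.DataFrame(
        {"time_s": history.times_s, "concentration_mol_m3": adjacent}
    )
    report = AbetaProfileReport(
        history=history,
        daily_profiles=daily,
        barrier_adjacent=barrier_adjacent,
        config_echo={
            "source_rate_mol_m3_s": source_rate_mol_m3_s,
            "initial_mol_m3": initial_mol_m3,
            "membrane_conductance_m_s": config.resolved_conductance(),
            "days": days,
            "dx_um": dx_um,
            "dt_s": dt_s,
            "scheme": scheme,
            "version": __version__,
        },
    )
    if out_dir is not None:
        report.save(out_dir)
    return report


# ---------------------------------------------------------------------------
# recovery experiment
# ---------------------------------------------------------------------------


@dataclass
class RunReport:
    """Per-device estimates, group summaries, and the group comparison."""

    table: pd.DataFrame
    group_summary: pd.DataFrame
    ttest: TTestResult | None
    config_echo: dict
    master_seed: int
    version: str = __version__

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "devices.csv", index=False)
        self.group_summary.to_csv(out / "group_summary.csv", index=False)
        summary = {
            "config": self.config_echo,
            "master_seed": self.master_seed,
            "version": self.version,
            "ttest": self.ttest.to_dict() if self.ttest else None,
            "groups": self.group_summary.to_dict(orient="records"),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))


def _summarise_groups(table: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for group, g in table.groupby("group", sort=False):
        est = g.loc[g.status == "ok", "p_hat_cm_s"]
        n = len(est)
        sd = est.std(ddof=1) if n > 1 else np.nan
        rel_err = (g.p_hat_cm_s - g.p_true_cm_s) / g.p_true_cm_s
        rows.append(
            {
                "group": group,
                "n": n,
                "mean_cm_s": est.mean(),
                "sem_cm_s": sd / np.sqrt(n) if n > 1 else np.nan,
                "sd_cm_s": sd,
                "mean_true_cm_s": g.p_true_cm_s.mean(),
                "bias_frac": rel_err.mean(),
                "rmse_frac": float(np.sqrt(np.mean(rel_err.dropna() ** 2))),
            }
        )
    return pd.DataFrame(rows)


def run_recovery_experiment(
    n_wt: int = 13,
    n_ad: int = 25,
    p_means_cm_s: Mapping[str, float] | None = None,
    dispersion: float = 0.25,
    model: ImagingModel | None = None,
    seed: int = 0,
    layout: DeviceLayout | None = None,
    solute: str = "dextran_40kda",
    fit_mode: str = "two_point",
    window_s: float = 600.0,
    cv_depth_um: float | None = None,
    dx_um: float = 25.0,
    n_frames: int = 3,
    frame_interval_s: float = 300.0,
    out_dir=None,
) -> RunReport:
    """Generate -> render -> estimate for a full synthetic cohort.

    The per-device table joins ground truth and estimate; group summaries
    report mean +/- SEM, bias, and RMSE; the group comparison is Student's t
    on the estimates. A failed device is recorded with its error and the run
    continues. ``cv_depth_um=None`` applies the capture rule
    3*sqrt(2*D_gel*window).
    """
    layout = layout if layout is not None else build_default_layout()
    model = model if model is not None else ImagingModel()
    if cv_depth_um is None:
        d_gel = layout.materials["collagen_scaffold"].diffusivity[solute]
        cv_depth_um = recommended_cv_depth_um(d_gel, window_s)

    cohort = generate_cohort(
        n_wt=n_wt,
        n_ad=n_ad,
        p_means_cm_s=dict(p_means_cm_s) if p_means_cm_s else None,
        dispersion=dispersion,
        model=model,
        seed=seed,
        layout=layout,
        solute=solute,
        frame_interval_s=frame_interval_s,
        n_frames=n_frames,
        dx_um=dx_um,
    )

    rows = []
    for stack, truth in cohort:
        row = {
            "device_id": truth.device_id,
            "group": truth.group,
            "p_true_cm_s": truth.p_true_cm_s,
            "seed": truth.seed,
        }
        try:
            cvspec = default_control_volume(
                layout, stack.pixel_size_um, depth_um=cv_depth_um
            )
            res = PermeabilityAssayModel.from_timelapse(stack, cvspec).fit(
                mode=fit_mode, window_s=window_s
            )
            row.update(
                p_hat_cm_s=res.p_cm_s,
                slope=res.slope,
                delta_im=res.delta_im,
                fit_mode=res.fit_mode,
                window_s=res.window_s,
                flags=";".join(res.flags),
                status="ok",
            )
        except Exception as exc:  # record and continue
            logger.warning("device %s failed: %s", truth.device_id, exc)
            row.update(
                p_hat_cm_s=np.nan, slope=np.nan, delta_im=np.nan,
                fit_mode=fit_mode, window_s=window_s,
                flags=type(exc).__name__, status="failed",
            )
        rows.append(row)
    table = pd.DataFrame(rows)

    ttest = None
    ok = table[table.status == "ok"]
    groups = list(dict.fromkeys(table.group))
    if len(groups) == 2:
        a = ok.loc[ok.group == groups[0], "p_hat_cm_s"]
        b = ok.loc[ok.group == groups[1], "p_hat_cm_s"]
        if len(a) >= 2 and len(b) >= 2:
            ttest = compare_groups_ttest(a, b)

    report = RunReport(
        table=table,
        group_summary=_summarise_groups(table),
        ttest=ttest,
        config_echo={
            "n_wt": n_wt,
            "n_ad": n_ad,
            "p_means_cm_s": dict(p_means_cm_s) if p_means_cm_s
            else {"wt": 1.96e-6, "ad": 6.45e-6},
            "dispersion": dispersion,
            "solute": solute,
            "fit_mode": fit_mode,
            "window_s": window_s,
            "cv_depth_um": cv_depth_um,
            "dx_um": dx_um,
            "n_frames": n_frames,
            "frame_interval_s": frame_interval_s,
        },
        master_seed=seed,
    )
    if out_dir is not None:
        report.save(out_dir)
    return report


def cohort_separation_rate(
    n_seeds: int = 200,
    n_wt: int = 13,
    n_ad: int = 25,
    p_means_cm_s: Mapping[str, float] | None = None,
    dispersion: float = 0.25,
    alpha: float = 1e-4,
    master_seed: int = 0,
) -> float:
    """Fraction of cohort draws whose pooled t test rejects at ``alpha``.

    Operates on the drawn per-device permeabilities (the sampling layer of
    the cohort model); estimator noise on top of these is characterised
    separately by the recovery experiment.
    """
    if p_means_cm_s is None:
        p_means_cm_s = {"wt": 1.96e-6, "ad": 6.45e-6}
    seeds = np.random.SeedSequence(master_seed).generate_state(n_seeds)
    hits = 0
    for s in seeds:
        rng = np.random.default_rng(int(s) % (2**31))
        a = draw_cohort_permeabilities(n_wt, p_means_cm_s["wt"], dispersion, rng)
        b = draw_cohort_permeabilities(n_ad, p_means_cm_s["ad"], dispersion, rng)
        if compare_groups_ttest(a, b).pvalue < alpha:
            hits += 1
    return hits / n_seeds
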