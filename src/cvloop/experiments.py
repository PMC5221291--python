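"""Baseline calibration, the 3x3 condition/group grid, and trend checks.

The study design crosses three ventricular conditions — ``normal`` (heart
failure without regurgitation), ``ar`` (5% aortic regurgitation) and ``mr``
(5% mitral regurgitation) — with three groups defined by LVAD cannulation:
``control`` (no pump), ``laao`` (LA -> aorta) and ``lvao`` (LV -> aorta).
Before running the grid, the failing baseline is calibrated so the
control/normal cell reproduces the reference phenotype: stroke volume 20 mL
at end-diastolic volume 100 mL, i.e. a 20% ejection fraction.

The calibrated model's predictions are summarized by direction-of-effect
trend checks (T1--T9) encoding the expected hemodynamic findings, e.g. that
LA cannulation in the non-regurgitant failing heart traps blood in the LV
(isovolumic contraction, zero EF and stroke work).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .circulation import CircParams, LvadConfig, ModelConfig, simulate
from .metrics import CycleMetrics, cycle_metrics, extract_cycle

__all__ = [
    "Condition",
    "Group",
    "TrendCheck",
    "CONDITIONS",
    "GROUPS",
    "apply_cell",
    "run_cell",
    "CalibrationResult",
    "calibrate_baseline",
    "GridResult",
    "run_grid",
    "trend_report",
]

logger = logging.getLogger(__name__)

DEFAULT_LVAD_FLOW = 40.0   # mL/s, constant continuous-flow pump flux
DEFAULT_SF = 5.0           # percent leak defining the AR / MR conditions


@dataclass(frozen=True)
class Condition:
    """Ventricular condition: valve leak scale factors in percent."""

    label: str
    sf_mi: float
    sf_ao: float

    _ALLOWED = {"normal": (0.0, 0.0), "ar": (0.0, DEFAULT_SF), "mr": (DEFAULT_SF, 0.0)}

    def __post_init__(self) -> None:
        expected = self._ALLOWED.get(self.label)
        if expected is None:
            raise ValueError(f"unknown condition {self.label!r}")
        if (self.sf_mi, self.sf_ao) != expected:
            raise ValueError(
                f"condition {self.label!r} requires (sf_mi, sf_ao)={expected}, "
                f"got ({self.sf_mi}, {self.sf_ao})")

    @classmethod
    def named(cls, label: str) -> "Condition":
        if label not in cls._ALLOWED:
            raise ValueError(f"unknown condition {label!r}")
        sf_mi, sf_ao = cls._ALLOWED[label]
        return cls(label, sf_mi, sf_ao)


@dataclass(frozen=True)
class Group:
    """LVAD group: cannulation topology and pump flux."""

    label: str
    lvad: LvadConfig

    def __post_init__(self) -> None:
        if self.label == "control":
            if self.lvad.mode != "none":
                raise ValueError("control group must have LVAD mode 'none'")
        elif self.label in ("laao", "lvao"):
            if self.lvad.mode != self.label:
                raise ValueError(f"group {self.label!r} must use LVAD mode {self.label!r}")
        else:
            raise ValueError(f"unknown group {self.label!r}")

    @classmethod
    def named(cls, label: str, flow: float = DEFAULT_LVAD_FLOW) -> "Group":
        if label == "control":
            return cls(label, LvadConfig("none", 0.0))
        return cls(label, LvadConfig(label, flow))


CONDITIONS = ("normal", "ar", "mr")
GROUPS = ("control", "laao", "lvao")


def apply_cell(cfg: ModelConfig, condition: Condition, group: Group) -> ModelConfig:
    """Return the configuration for one grid cell (leaks + pump applied)."""
    circ = replace(cfg.circ, sf_mi=condition.sf_mi, sf_ao=condition.sf_ao)
    return cfg.with_(circ=circ, lvad=group.lvad)


@dataclass
class CellResult:
    """One grid cell: its metrics plus the extracted steady-state cycle.

    ``volume_drift`` is the maximum relative deviation of total blood volume
    over the whole run (a closed-loop conservation diagnostic);
    ``lvpp_defect`` is the relative change of peak LV pressure between the
    last two complete cycles (steady-state diagnostic).
    """

    condition: str
    group: str
    metrics: CycleMetrics
    cycle: pd.DataFrame
    periodicity_defect: float
    suction_active: bool
    volume_drift: float
    lvpp_defect: float


def run_cell(
    cfg: ModelConfig,
    condition: Condition,
    group: Group,
    duration: float = 20.0,
    window_start: float = 18.6,
) -> CellResult:
    """Simulate one cell and measure the steady-state cycle."""
    cell_cfg = apply_cell(cfg, condition, group)
    try:
        res = simulate(cell_cfg, duration=duration)
    except RuntimeError as exc:
        raise RuntimeError(
            f"grid cell ({condition.label}, {group.label}) failed: {exc}") from exc
    cyc = extract_cycle(res.data, window_start, cell_cfg.calcium.bcl)

    vol = res.data[[f"v_{x}" for x in
                    ("lv", "la", "rv", "ra", "sa", "sv", "pa", "pv")]].sum(axis=1)
    drift = float(np.max(np.abs(vol - vol.iloc[0])) / vol.iloc[0])

    t = res.data["time_s"].to_numpy()
    p_lv = res.data["p_lv"].to_numpy()
    bcl_s = cell_cfg.calcium.bcl / 1000.0
    n_cyc = int(np.floor((t[-1] + 1e-9) / bcl_s))
    last = p_lv[(t >= (n_cyc - 1) * bcl_s) & (t < n_cyc * bcl_s)].max()
    prev = p_lv[(t >= (n_cyc - 2) * bcl_s) & (t < (n_cyc - 1) * bcl_s)].max()
    lvpp_defect = float(abs(last - prev) / prev)

    return CellResult(condition.label, group.label, cycle_metrics(cyc), cyc,
                      res.periodicity_defect, res.suction_active,
                      drift, lvpp_defect)


@dataclass
class CalibrationResult:
    """Calibrated configuration plus convergence diagnostics."""

    config: ModelConfig
    sv: float
    edv: float
    residual_sv: float
    residual_edv: float
    n_simulations: int
    converged: bool

    def summary(self) -> dict:
        return {
            "p_act_gain": self.config.lv.p_act_gain,
            "total_blood_volume": self.config.total_blood_volume,
            "sv": self.sv, "edv": self.edv,
            "residual_sv": self.residual_sv, "residual_edv": self.residual_edv,
            "n_simulations": self.n_simulations, "converged": self.converged,
        }


def _phenotype(cfg: ModelConfig, duration: float, window_start: float) -> tuple[float, float]:
    cell = run_cell(cfg, Condition.named("normal"), Group.named("control"),
                    duration=duration, window_start=window_start)
    return cell.metrics.sv, cell.metrics.edv


def calibrate_baseline(
    cfg: ModelConfig,
    sv_target: float = 20.0,
    edv_target: float = 100.0,
    tol_sv: float = 0.1,
    tol_edv: float = 0.5,
    max_iter: int = 12,
    duration: float = 20.0,
    window_start: float = 18.6,
) -> CalibrationResult:
    """Anchor the failing baseline to the reference phenotype.

    Adjusts the LV contractile gain (which controls stroke volume) and the
    total blood volume (which controls preload and hence end-diastolic
    volume) with a damped Newton iteration on the two residuals
    ``(SV - sv_target, EDV - edv_target)``, each evaluated from a full run's
    steady-state cycle.  The Jacobian is re-estimated by forward differences
    at every step; the iteration is deterministic, starting from the fixture
    values.  Raises ``RuntimeError`` with the residuals if it fails to
    converge within ``max_iter`` Newton steps.
    """
    x = np.array([cfg.lv.p_act_gain, cfg.total_blood_volume], dtype=float)
    n_sim = 0

    def set_x(base: ModelConfig, x: np.ndarray) -> ModelConfig:
        lv = replace(base.lv, p_act_gain=float(x[0]))
        return base.with_(lv=lv, total_blood_volume=float(x[1]))

    def residual(x: np.ndarray) -> np.ndarray:
        nonlocal n_sim
        n_sim += 1
        sv, edv = _phenotype(set_x(cfg, x), duration, window_start)
        return np.array([sv - sv_target, edv - edv_target])

    f = residual(x)
    for _ in range(max_iter):
        if abs(f[0]) <= tol_sv and abs(f[1]) <= tol_edv:
            break
        # forward-difference Jacobian (relative steps)
        J = np.empty((2, 2))
        h = np.array([max(1e-3, 0.02 * abs(x[0])), max(1.0, 0.01 * abs(x[1]))])
        for j in range(2):
            xp = x.copy()
            xp[j] += h[j]
            J[:, j] = (residual(xp) - f) / h[j]
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"calibration Jacobian singular; residuals={f}") from exc
        # damp overly aggressive steps
        step[0] = float(np.clip(step[0], -0.5 * x[0], 0.5 * x[0]))
        step[1] = float(np.clip(step[1], -0.2 * x[1], 0.2 * x[1]))
        x = x + step
        f = residual(x)
        logger.info("calibration step: gain=%.4f volume=%.1f residuals=(%.3f, %.3f)",
                    x[0], x[1], f[0], f[1])

    converged = bool(abs(f[0]) <= tol_sv and abs(f[1]) <= tol_edv)
    if not converged:
        raise RuntimeError(
            f"calibration did not converge after {max_iter} Newton steps: "
            f"residual SV={f[0]:+.3f} mL, EDV={f[1]:+.3f} mL")
    return CalibrationResult(
        config=set_x(cfg, x), sv=sv_target + f[0], edv=edv_target + f[1],
        residual_sv=float(f[0]), residual_edv=float(f[1]),
        n_simulations=n_sim, converged=converged)


@dataclass
class GridResult:
    """Results of the full 3 conditions x 3 groups experiment."""

    cells: dict

    def cell(self, condition: str, group: str) -> CellResult:
        return self.cells[(condition, group)]

    def metrics_table(self) -> pd.DataFrame:
        rows = []
        for (cond, grp), cell in self.cells.items():
            row = {"condition": cond, "group": grp}
            row.update(cell.metrics.as_dict())
            row["periodicity_defect"] = cell.periodicity_defect
            row["suction_active"] = cell.suction_active
            row["volume_drift"] = cell.volume_drift
            row["lvpp_defect"] = cell.lvpp_defect
            rows.append(row)
        return pd.DataFrame(rows)


def run_grid(cfg: ModelConfig, duration: float = 20.0,
             window_start: float = 18.6) -> GridResult:
    """Run all nine condition x group cells with the calibrated parameters.

    Cells are independent (no shared mutable state), so the table is
    identical whatever order they are run in.
    """
    cells = {}
    for cond in CONDITIONS:
        for grp in GROUPS:
            cells[(cond, grp)] = run_cell(
                cfg, Condition.named(cond), Group.named(grp),
                duration=duration, window_start=window_start)
    return GridResult(cells)


@dataclass
class TrendCheck:
    """One direction-of-effect check between named grid cells.

    ``comparisons`` lists (label, lhs, op, rhs) tuples of the numbers
    actually compared; the check passes only if every comparison holds.
    """

    id: str
    description: str
    comparisons: list = field(default_factory=list)

    def compare(self, label: str, lhs: float, op: str, rhs: float) -> None:
        ok = {"<": lhs < rhs, "<=": lhs <= rhs, ">": lhs > rhs, ">=": lhs >= rhs}[op]
        self.comparisons.append(
            {"label": label, "lhs": float(lhs), "op": op, "rhs": float(rhs), "pass": bool(ok)})

    @property
    def passed(self) -> bool:
        return all(c["pass"] for c in self.comparisons)

    def as_dict(self) -> dict:
        return {"id": self.id, "description": self.description,
                "pass": self.passed, "comparisons": self.comparisons}


def trend_report(grid: GridResult) -> list[TrendCheck]:
    """Evaluate the qualitative hemodynamic findings on the calibrated grid.

    T1  normal+LAAO: no ejection — EF ~ 0 and stroke work ~ 0.
    T2  normal+LAAO: LV pressure never exceeds aortic pressure (isovolumic
        contraction), cross-checked by a vanishing forward aortic volume.
    T3  AR lowers LVPP and raises LAPP in the control group.
    T4  MR raises LAPP in the control group.
    T5  LAAO under AR is harmful: LVPP and stroke work rise vs AR control.
    T6  LVAO under AR does not increase ATP consumption vs AR control.
    T7  Under MR, both cannulations cut ATP consumption and raise mean
        aortic pressure (better coronary perfusion).
    T8  Under the normal condition both cannulations raise peak aortic
        pressure (continuous pump flux into the aorta).
    T9  The pump unloads its inlet chamber: LAPP falls under LAAO, LVPP
        falls under LVAO (normal condition).
    """
    def m(cond: str, grp: str) -> CycleMetrics:
        try:
            return grid.cell(cond, grp).metrics
        except KeyError as exc:
            raise ValueError(f"grid is missing cell ({cond}, {grp})") from exc

    checks: list[TrendCheck] = []

    t1 = TrendCheck("T1", "normal+LAAO: zero ejection fraction and stroke work")
    t1.compare("ef (fraction)", m("normal", "laao").ef, "<", 0.005)
    t1.compare("|stroke_work| (mmHg mL)", abs(m("normal", "laao").stroke_work), "<", 1.0)
    checks.append(t1)

    t2 = TrendCheck("T2", "normal+LAAO: isovolumic contraction, LV pressure below aortic")
    t2.compare("max(P_LV - P_AO) (mmHg)", m("normal", "laao").lv_minus_ao_max, "<", 0.0)
    t2.compare("aortic forward volume (mL)", m("normal", "laao").ao_forward_volume, "<", 0.05)
    checks.append(t2)

    t3 = TrendCheck("T3", "AR control vs normal control: lower LVPP, higher LAPP")
    t3.compare("LVPP", m("ar", "control").lvpp, "<", m("normal", "control").lvpp)
    t3.compare("LAPP", m("ar", "control").lapp, ">", m("normal", "control").lapp)
    checks.append(t3)

    t4 = TrendCheck("T4", "MR control vs normal control: higher LAPP")
    t4.compare("LAPP", m("mr", "control").lapp, ">", m("normal", "control").lapp)
    checks.append(t4)

    t5 = TrendCheck("T5", "AR+LAAO vs AR control: higher LVPP and stroke work")
    t5.compare("LVPP", m("ar", "laao").lvpp, ">", m("ar", "control").lvpp)
    t5.compare("stroke_work", m("ar", "laao").stroke_work, ">", m("ar", "control").stroke_work)
    checks.append(t5)

    t6 = TrendCheck("T6", "AR+LVAO vs AR control: ATP rate not higher")
    t6.compare("atp_mean", m("ar", "lvao").atp_mean, "<=", m("ar", "control").atp_mean)
    checks.append(t6)

    t7 = TrendCheck("T7", "MR + either cannulation: lower ATP rate, higher mean aortic pressure")
    t7.compare("atp_mean (LAAO)", m("mr", "laao").atp_mean, "<", m("mr", "control").atp_mean)
    t7.compare("atp_mean (LVAO)", m("mr", "lvao").atp_mean, "<", m("mr", "control").atp_mean)
    t7.compare("ao_mean (LAAO)", m("mr", "laao").ao_mean, ">", m("mr", "control").ao_mean)
    t7.compare("ao_mean (LVAO)", m("mr", "lvao").ao_mean, ">", m("mr", "control").ao_mean)
    checks.append(t7)

    t8 = TrendCheck("T8", "normal + either cannulation: higher peak aortic pressure")
    t8.compare("ao_peak (LAAO)", m("normal", "laao").ao_peak, ">", m("normal", "control").ao_peak)
    t8.compare("ao_peak (LVAO)", m("normal", "lvao").ao_peak, ">", m("normal", "control").ao_peak)
    checks.append(t8)

    t9 = TrendCheck("T9", "normal condition: the pump unloads its inlet chamber")
    t9.compare("LAPP (LAAO < control)", m("normal", "laao").lapp, "<", m("normal", "control").lapp)
    t9.compare("LVPP (LVAO < control)", m("normal", "lvao").lvpp, "<", m("normal", "control").lvpp)
    checks.append(t9)

    return checks


def report_to_json(checks: list[TrendCheck], path) -> None:
    with open(path, "w") as fh:
        json.dump([c.as_dict() for c in checks], fh, indent=2)
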