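"""Quadratic ligand-depletion anisotropy model and Kd fitting.

Fluorescence anisotropy titrations measure the bound fraction of a
fluorescently labelled RNA probe as protein is titrated in.  When the probe
concentration [P] is comparable to Kd the free-ligand approximation fails,
so the bound fraction is obtained from the exact (quadratic) solution of
the 1:1 binding equilibrium with ligand depletion:

    r = r0 + (r1 - r0) * [ (Kd + [Rec] + [P])
                           - sqrt((Kd + [Rec] + [P])^2 - 4 [Rec] [P]) ] / (2 [P])

where r0 / r1 are the anisotropies of the free and fully bound probe and
[Rec] is the total protein concentration.  Fitting uses multi-start
weighted nonlinear least squares (weights 1/sd when per-point standard
deviations are available), with the Kd starts log-spaced across and beyond
the titrated concentration range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BindingModel:
    """Parameters of the quadratic anisotropy isotherm (concentrations in nM)."""

    kd: float
    r0: float
    r1: float
    probe_conc: float

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("Kd must be positive")
        if self.probe_conc <= 0:
            raise ValueError("probe concentration must be positive")

    def __call__(self, rec_conc) -> np.ndarray:
        return model_anisotropy(self, rec_conc)


@dataclass(frozen=True)
class TitrationPoint:
    rec_conc: float
    r: float
    sd: float | None = None


@dataclass
class FitResult:
    """Fitted model, standard errors and a convergence report."""

    model: BindingModel | None
    se: dict[str, float] = field(default_factory=dict)
    converged: bool = False
    unidentifiable: bool = False
    message: str = ""
    residual_norm: float = float("nan")


def model_anisotropy(m: BindingModel, rec_conc) -> np.ndarray:
    """Anisotropy at total protein concentration(s) ``rec_conc``.

    The discriminant is clamped at zero against round-off so the square
    root never goes negative for valid concentrations.
    """
    rec = np.asarray(rec_conc, dtype=float)
    if np.any(rec < 0):
        raise ValueError("protein concentration must be >= 0")
    p = m.probe_conc
    s = m.kd + rec + p
    disc = np.maximum(s * s - 4.0 * rec * p, 0.0)
    bound_frac = (s - np.sqrt(disc)) / (2.0 * p)
    return m.r0 + (m.r1 - m.r0) * bound_frac


def delta_anisotropy(points: Sequence[TitrationPoint]) -> list[TitrationPoint]:
    """Subtract the basal probe anisotropy from every point.

    The baseline is the point at [Rec] = 0; when absent, the minimum-[Rec]
    point is used instead (logged).  The baseline point is retained at 0.
    """
    if not points:
        return []
    zero = [p for p in points if p.rec_conc == 0]
    if zero:
        baseline = zero[0].r
    else:
        pmin = min(points, key=lambda p: p.rec_conc)
        baseline = pmin.r
        logger.info("delta_anisotropy: no [Rec]=0 point; using minimum "
                    "[Rec]=%g as baseline", pmin.rec_conc)
    return [TitrationPoint(p.rec_conc, p.r - baseline, p.sd) for p in points]


def _kd_starts(rec: np.ndarray, n: int = 7) -> np.ndarray:
    pos = rec[rec > 0]
    lo, hi = pos.min() / 10.0, pos.max() * 10.0
    return np.geomspace(lo, hi, n)


def fit_anisotropy(
    points: Sequence[TitrationPoint],
    probe_conc: float,
    weighted: bool = False,
    fix_r1: float | None = None,
    seed: int | None = None,
) -> FitResult:
    """Fit (Kd, r0, r1) by multi-start weighted nonlinear least squares.

    Requires >= 4 points spanning at least a 10-fold [Rec] range.  Weights
    are 1/sd when ``weighted`` and per-point sds are present.  Kd starts on
    a log grid spanning [min [Rec]/10, max [Rec]*10]; the best-objective
    fit is returned.  Flat data or a Kd pinned at the grid boundary yields
    an ``unidentifiable`` flag with no Kd reported.  Deterministic: the fit
    itself is deterministic, ``seed`` is accepted for interface symmetry.
    """
    rec = np.array([p.rec_conc for p in points], dtype=float)
    robs = np.array([p.r for p in points], dtype=float)
    if rec.size < 4:
        return FitResult(None, message="need at least 4 titration points")
    pos = rec[rec > 0]
    if pos.size == 0 or pos.max() / pos.min() < 10:
        return FitResult(None, message="titration must span a 10-fold range")

    sds = np.array([p.sd if p.sd else np.nan for p in points], dtype=float)
    use_w = weighted and np.all(np.isfinite(sds)) and np.all(sds > 0)
    w = 1.0 / sds if use_w else np.ones_like(robs)

    rng = robs.max() - robs.min()
    if rng <= 0 or rng < 1e-12:
        return FitResult(None, unidentifiable=True, message="flat data")

    r0_init = float(robs[np.argmin(rec)])
    r1_init = float(robs[np.argmax(rec)])

    if fix_r1 is None:
        def resid(theta):
            kd, r0, r1 = theta
            m = BindingModel(kd=kd, r0=r0, r1=r1, probe_conc=probe_conc)
            return w * (model_anisotropy(m, rec) - robs)
        lower = [1e-9, -np.inf, -np.inf]
        upper = [np.inf, np.inf, np.inf]
        make_theta = lambda kd: [kd, r0_init, r1_init]
        names = ["kd", "r0", "r1"]
    else:
        def resid(theta):
            kd, r0 = theta
            m = BindingModel(kd=kd, r0=r0, r1=fix_r1, probe_conc=probe_conc)
            return w * (model_anisotropy(m, rec) - robs)
        lower = [1e-9, -np.inf]
        upper = [np.inf, np.inf]
        make_theta = lambda kd: [kd, r0_init]
        names = ["kd", "r0"]

    kd_grid = _kd_starts(rec)
    best = None
    for kd0 in kd_grid:
        try:
            sol = least_squares(resid, make_theta(kd0), bounds=(lower, upper))
        except Exception:  # singular steps on extreme starts
            continue
        if not sol.success:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return FitResult(None, message="no start converged")

    kd_fit = float(best.x[0])
    if kd_fit <= kd_grid[0] * 1.001 or kd_fit >= kd_grid[-1] * 0.999:
        return FitResult(None, unidentifiable=True,
                         message="fitted Kd at grid boundary",
                         residual_norm=float(np.linalg.norm(best.fun)))

    # standard errors from the Jacobian at the optimum
    dof = max(rec.size - best.x.size, 1)
    s2 = 2.0 * best.cost / dof
    try:
        cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
        se = {n: float(np.sqrt(max(cov[i, i], 0.0))) for i, n in enumerate(names)}
    except np.linalg.LinAlgError:
        se = {}
    if fix_r1 is None:
        model = BindingModel(kd_fit, float(best.x[1]), float(best.x[2]), probe_conc)
    else:
        model = BindingModel(kd_fit, float(best.x[1]), fix_r1, probe_conc)
    return FitResult(model=model, se=se, converged=True,
                     residual_norm=float(np.linalg.norm(best.fun)))


def read_titration_tsv(path_or_buf) -> list[TitrationPoint]:
    """Read a titration TSV with columns rec_conc_nM, anisotropy[, sd]."""
    df = pd.read_csv(path_or_buf, sep="\t")
    has_sd = "sd" in df.columns
    return [
        TitrationPoint(
            rec_conc=float(row.rec_conc_nM),
            r=float(row.anisotropy),
            sd=float(row.sd) if has_sd and np.isfinite(row.sd) else None,
        )
        for row in df.itertuples(index=False)
    ]


def write_fit_tsv(results: dict[str, FitResult], path_or_buf) -> None:
    rows = []
    for name, res in results.items():
        row = {"curve": name, "converged": res.converged,
               "unidentifiable": res.unidentifiable}
        if res.model is not None:
            row.update(kd_nM=res.model.kd, r0=res.model.r0, r1=res.model.r1,
                       kd_se=res.se.get("kd", float("nan")))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path_or_buf, sep="\t", index=False)
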