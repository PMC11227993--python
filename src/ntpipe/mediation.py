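"""Non-parametric bootstrap mediation analysis and the model suite over
(local GMV, local INT, DMN INT, MMSE).

The three-variable mediation model is estimated by ordinary least squares:

    a   slope of M ~ X                 (path into the mediator)
    b   slope of M in Y ~ X + M        (mediator effect, adjusted for X)
    c   slope of Y ~ X                 (total effect)
    c'  slope of X in Y ~ X + M        (direct effect)
    ab  = a * b                        (indirect effect)

For OLS on a common sample the decomposition c = c' + ab holds exactly.
Inference on ab is by subject-level resampling with replacement: the
percentile 2.5/97.5 interval and a two-tailed sign-crossing p-value floored
at 1/n_boot.  Mediation is only interpreted when the three pairwise
correlations are individually significant (the precondition screen); the
caller decides whether to gate on it.

Variables enter on their native scales and, by default, without covariates.
Complete-case analysis is used throughout: rows with a missing value in any
of the three variables are dropped per model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .stats import CorrelationResult, bonferroni_correct, pearson_bootstrap

DEFAULT_CONTROL_NETWORKS = ("frontoparietal", "DAN", "VAN", "limbic", "somatomotor", "visual")


@dataclass(frozen=True)
class MediationModelSpec:
    x_name: str
    m_name: str
    y_name: str
    n_boot: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if len({self.x_name, self.m_name, self.y_name}) != 3:
            raise ValueError("x, m and y must be three distinct variables")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")


@dataclass(frozen=True)
class MediationResult:
    a: float
    b: float
    c: float
    c_prime: float
    ab: float
    ci_low: float
    ci_high: float
    p: float
    n_boot: int
    seed: int
    n: int
    cprime_ci_low: float = np.nan
    cprime_ci_high: float = np.nan

    def __post_init__(self) -> None:
        if abs(self.c - (self.c_prime + self.ab)) > 1e-8 * max(1.0, abs(self.c)):
            raise ValueError("OLS decomposition c = c' + ab violated")


@dataclass(frozen=True)
class ModelOutcome:
    """One entry of the model suite: a fitted mediation, or the named
    reason it was not evaluated."""

    model_id: str
    spec: Optional[MediationModelSpec]
    status: str  # "ok" | "not_evaluated"
    reason: str = ""
    preconditions: dict = field(default_factory=dict)
    result: Optional[MediationResult] = None
    p_bonferroni: float = np.nan


def _complete_cases(data: pd.DataFrame, cols: Sequence[str]) -> np.ndarray:
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"missing columns: {missing}")
    sub = data[list(cols)].astype(float)
    return sub.dropna().to_numpy()


def _paths(x, m, y):
    """Closed-form OLS paths from centred cross-moments (vectorized over a
    leading bootstrap axis when present)."""
    xc = x - x.mean(axis=-1, keepdims=True)
    mc = m - m.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    sxx = (xc * xc).mean(axis=-1)
    smm = (mc * mc).mean(axis=-1)
    sxm = (xc * mc).mean(axis=-1)
    sxy = (xc * yc).mean(axis=-1)
    smy = (mc * yc).mean(axis=-1)
    det = sxx * smm - sxm**2
    with np.errstate(invalid="ignore", divide="ignore"):
        a = sxm / sxx
        b = (sxx * smy - sxm * sxy) / det
        c_prime = (smm * sxy - sxm * smy) / det
        c = sxy / sxx
    return a, b, c, c_prime


def precondition_correlations(
    data: pd.DataFrame, spec: MediationModelSpec,
) -> tuple[dict[tuple[str, str], CorrelationResult], bool]:
    """Pairwise Pearson correlations (with bootstrap p) for (x,m), (m,y),
    (x,y), and a flag that all three are significant at 0.05."""
    cols = (spec.x_name, spec.m_name, spec.y_name)
    arr = _complete_cases(data, cols)
    if arr.shape[0] < 4:
        raise ValueError(f"need >= 4 complete cases, got {arr.shape[0]}")
    for j, c in enumerate(cols):
        if np.ptp(arr[:, j]) == 0:
            raise ValueError(f"column {c!r} is constant")
    pairs = [(0, 1), (1, 2), (0, 2)]
    out: dict[tuple[str, str], CorrelationResult] = {}
    rng = np.random.default_rng(spec.seed)
    for i, j in pairs:
        out[(cols[i], cols[j])] = pearson_bootstrap(
            arr[:, i], arr[:, j], n_boot=spec.n_boot, seed=rng
        )
    passed = all(res.p_boot < 0.05 for res in out.values())
    return out, passed


def fit_mediation(data: pd.DataFrame, spec: MediationModelSpec) -> MediationResult:
    """Point estimates by OLS plus subject-resampling bootstrap of the
    indirect effect ab (and of c' for its interval)."""
    arr = _complete_cases(data, (spec.x_name, spec.m_name, spec.y_name))
    n = arr.shape[0]
    if n < 5:
        raise ValueError(f"need >= 5 complete cases, got {n}")
    x, m, y = arr[:, 0], arr[:, 1], arr[:, 2]
    r_xm = np.corrcoef(x, m)[0, 1]
    if abs(r_xm) > 1 - 1e-12:
        raise ValueError("X and M are collinear; mediation paths are unidentified")
    a, b, c, c_prime = _paths(x, m, y)
    ab = a * b

    rng = np.random.default_rng(spec.seed)
    idx = rng.integers(0, n, size=(spec.n_boot, n))
    ab_b_a, ab_b_b, _, cp_b = _paths(x[idx], m[idx], y[idx])
    ab_b = ab_b_a * ab_b_b
    ok = np.isfinite(ab_b)
    ab_b = ab_b[ok]
    cp_b = cp_b[np.isfinite(cp_b)]
    ci_low, ci_high = np.percentile(ab_b, [2.5, 97.5])
    cp_lo, cp_hi = np.percentile(cp_b, [2.5, 97.5]) if cp_b.size else (np.nan, np.nan)
    p = 2 * min(np.mean(ab_b <= 0), np.mean(ab_b >= 0))
    p = float(min(1.0, max(p, 1.0 / spec.n_boot)))
    return MediationResult(
        a=float(a), b=float(b), c=float(c), c_prime=float(c_prime), ab=float(ab),
        ci_low=float(ci_low), ci_high=float(ci_high), p=p,
        n_boot=spec.n_boot, seed=spec.seed, n=n,
        cprime_ci_low=float(cp_lo), cprime_ci_high=float(cp_hi),
    )


def _suite_models(roi: str, dmn_col: str, networks: Sequence[str]) -> list[tuple[str, tuple[str, str, str]]]:
    models = [
        (f"{roi}:int->dmn->mmse", (f"{roi}_int", dmn_col, "mmse")),
        (f"{roi}:dmn->int->mmse", (dmn_col, f"{roi}_int", "mmse")),
        (f"{roi}:gmv->int->dmn", (f"gmv_{roi}", f"{roi}_int", dmn_col)),
        (f"{roi}:gmv->int->mmse", (f"gmv_{roi}", f"{roi}_int", "mmse")),
        (f"{roi}:int->gmv->dmn", (f"{roi}_int", f"gmv_{roi}", dmn_col)),  # reversed sensitivity
    ]
    for net in networks:
        models.append((f"{roi}:int->{net}->mmse", (f"{roi}_int", f"{net}_int", "mmse")))
    return models


def run_model_suite(
    data: pd.DataFrame,
    roi_names: Sequence[str] = ("AG", "SMG"),
    network_names: Sequence[str] = DEFAULT_CONTROL_NETWORKS,
    dmn_col: str = "DMN_int",
    n_boot: int = 10_000,
    seed: int = 0,
    gate_on_preconditions: bool = True,
) -> dict[str, ModelOutcome]:
    """The full mediation-model suite for each focal ROI.

    Per ROI: (1) ROI INT -> DMN INT -> MMSE, (2) DMN INT -> ROI INT ->
    MMSE, (3) ROI GMV -> ROI INT -> DMN INT, (4) ROI GMV -> ROI INT ->
    MMSE, the reversed sensitivity model ROI INT -> ROI GMV -> DMN INT,
    and the six network-control variants of (1).  Bonferroni correction
    over the focal ROIs is applied to every mediation p.  Models whose
    variables are missing or whose precondition screen fails are reported
    as not evaluated with the reason named.
    """
    m_corr = max(1, len(roi_names))
    out: dict[str, ModelOutcome] = {}
    base_rng = np.random.default_rng(seed)
    for roi in roi_names:
        for model_id, (xc, mc, yc) in _suite_models(roi, dmn_col, network_names):
            sub_seed = int(base_rng.integers(0, 2**31 - 1))
            spec = MediationModelSpec(x_name=xc, m_name=mc, y_name=yc,
                                      n_boot=n_boot, seed=sub_seed)
            missing = [c for c in (xc, mc, yc) if c not in data.columns]
            if missing:
                out[model_id] = ModelOutcome(
                    model_id=model_id, spec=spec, status="not_evaluated",
                    reason=f"missing columns: {missing}")
                continue
            try:
                pre, passed = precondition_correlations(data, spec)
            except (ValueError, KeyError) as err:
                out[model_id] = ModelOutcome(
                    model_id=model_id, spec=spec, status="not_evaluated",
                    reason=str(err))
                continue
            pre_report = {f"{p[0]}~{p[1]}": {"r": res.r, "p": res.p_boot, "n": res.n}
                          for p, res in pre.items()}
            if gate_on_preconditions and not passed:
                failing = [f"{p[0]}~{p[1]}" for p, res in pre.items() if res.p_boot >= 0.05]
                out[model_id] = ModelOutcome(
                    model_id=model_id, spec=spec, status="not_evaluated",
                    reason=f"precondition correlations not significant: {failing}",
                    preconditions=pre_report)
                continue
            result = fit_mediation(data, spec)
            out[model_id] = ModelOutcome(
                model_id=model_id, spec=spec, status="ok",
                preconditions=pre_report, result=result,
                p_bonferroni=bonferroni_correct(result.p, m_corr))
    return out


def suite_to_frame(suite: dict[str, ModelOutcome]) -> pd.DataFrame:
    """Flatten a model suite into a tidy table (one row per model)."""
    rows = []
    for model_id, oc in suite.items():
        row = {"model": model_id, "status": oc.status, "reason": oc.reason}
        if oc.result is not None:
            r = oc.result
            row.update(a=r.a, b=r.b, c=r.c, c_prime=r.c_prime, ab=r.ab,
                       ci_low=r.ci_low, ci_high=r.ci_high, p=r.p,
                       p_bonferroni=oc.p_bonferroni, n=r.n)
        rows.append(row)
    return pd.DataFrame(rows)
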