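"""Cognitive-component analysis: z-scored neuropsychological composites
correlated with DMN INT under Bonferroni correction over five components.

Component membership:

    attention         digit span
    processing_speed  trail making A (inverted) + digit symbol
    executive         trail making B (inverted)
    memory            logical memory
    language          Boston naming + category fluency

Raw scores are z-scored against a reference population (the CN group by
default); trail-making z-scores are negated so that higher always means
better.  Multi-test components are unweighted means of the member z-scores
that are available for the subject.  Pearson correlation is invariant to
the affine z-scoring, so the reference-population choice affects the z
values but not the r's.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .stats import bonferroni_correct, pearson_bootstrap

COMPONENTS: dict[str, tuple[str, ...]] = {
    "attention": ("digit_span",),
    "processing_speed": ("tmt_a", "digit_symbol"),
    "executive": ("tmt_b",),
    "memory": ("logical_memory",),
    "language": ("boston_naming", "category_fluency"),
}
INVERTED_TESTS = frozenset({"tmt_a", "tmt_b"})  # completion times: larger is worse
ALL_TESTS = tuple(t for tests in COMPONENTS.values() for t in tests)


def reference_stats(battery: pd.DataFrame, tests: Sequence[str] = ALL_TESTS) -> pd.DataFrame:
    """Reference means and SDs (rows indexed by test name)."""
    rows = {}
    for t in tests:
        if t not in battery.columns:
            continue
        vals = battery[t].dropna().to_numpy(dtype=float)
        if vals.size >= 2:
            rows[t] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))}
    return pd.DataFrame(rows).T


def componentize(battery: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Per-subject component z-scores from raw test scores.

    ``reference`` is the output of :func:`reference_stats`.  A component is
    NaN for a subject only when every member test is missing.
    """
    for t in reference.index:
        if not (reference.loc[t, "sd"] > 0):
            raise ValueError(f"reference SD for {t!r} is not positive")
    zcols = {}
    for t in ALL_TESTS:
        if t not in battery.columns or t not in reference.index:
            continue
        z = (battery[t].astype(float) - reference.loc[t, "mean"]) / reference.loc[t, "sd"]
        if t in INVERTED_TESTS:
            z = -z
        zcols[t] = z
    out = pd.DataFrame(index=battery.index)
    for comp, tests in COMPONENTS.items():
        members = [zcols[t] for t in tests if t in zcols]
        if members:
            out[comp] = pd.concat(members, axis=1).mean(axis=1, skipna=True)
        else:
            out[comp] = np.nan
    return out


def component_correlations(
    components: pd.DataFrame,
    dmn_int: Sequence[float],
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Bootstrap Pearson correlation of each component with DMN INT.

    Bonferroni correction uses m = 5 (the number of components) regardless
    of how many could be evaluated.  Components with fewer than 4 complete
    cases are reported as not evaluated; the others are unaffected.
    """
    dmn = np.asarray(dmn_int, dtype=float)
    if len(dmn) != len(components):
        raise ValueError("dmn_int length must match the component table")
    m = len(COMPONENTS)
    rng = np.random.default_rng(seed)
    rows = []
    for comp in COMPONENTS:
        col = components[comp].to_numpy(dtype=float) if comp in components else np.full(len(dmn), np.nan)
        ok = np.isfinite(col) & np.isfinite(dmn)
        if ok.sum() < 4 or np.ptp(col[ok]) == 0:
            rows.append({"component": comp, "n": int(ok.sum()), "r": np.nan,
                         "p": np.nan, "p_bonferroni": np.nan,
                         "status": "not_evaluated", "significant": False})
            continue
        res = pearson_bootstrap(col[ok], dmn[ok], n_boot=n_boot, seed=rng)
        p_bonf = bonferroni_correct(res.p_boot, m)
        rows.append({"component": comp, "n": res.n, "r": res.r, "p": res.p_boot,
                     "p_bonferroni": p_bonf, "status": "ok",
                     "significant": bool(p_bonf < alpha)})
    return pd.DataFrame(rows)
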