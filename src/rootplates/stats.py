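"""Condition summaries and WS-vs-WW treatment contrasts per structure and day.

The treatment test is a linear mixed-effects ANOVA on length:

    length_mm ~ condition * day   (day categorical, 3 levels)

with random intercepts for plate and for seedling-within-plate — seedlings
are photographed repeatedly, plates share soil batches.  For every
structure, the per-timepoint WS − WW contrast, its standard error and a
p-value are reported; points with p below alpha (default 0.05) are flagged
significant.  No multiplicity correction is applied by default (a Holm
option exists but is off), matching the flat per-timepoint cutoff the
difference plots use.

Degrees of freedom use a between-within (containment) approximation:
df = (#seedlings entering the fit) − 2, which on balanced designs equals
the two-sample-t df and is what a Satterthwaite approximation converges to
there.  Singular fits fall back deterministically: drop the seedling term,
then the plate term (ordinary least squares).

The model is exposed statsmodels-style: :class:`WaterStressModel` built
from two compiled conditions, whose :meth:`~WaterStressModel.fit` returns a
:class:`WaterStressResults` with estimates, contrasts and ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

from .compile import (
    STATUS_ABSENT,
    STATUS_MEASURED,
    CompiledCondition,
    root6_included,
)
from .errors import ModelFitError
from .smartroot_io import STRUCTURE_ORDER

_FORMULA = "length_mm ~ C(condition, Treatment('WW')) * C(day)"
_COND_TERM = "C(condition, Treatment('WW'))[T.WS]"


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of the mixed-model treatment contrast.

    alpha
        per-timepoint significance cutoff.
    include_plate, include_seedling
        random-intercept terms; the fallback ladder clears them in order
        (seedling first) when a fit is singular.
    singular_tol
        a variance component below ``singular_tol`` × residual variance is
        treated as zero (singular fit → fallback).
    holm
        apply a Holm correction across the three per-day p-values of one
        structure (off by default).
    """

    alpha: float = 0.05
    include_plate: bool = True
    include_seedling: bool = True
    singular_tol: float = 1e-6
    holm: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ModelFitError(f"alpha must be in (0, 1), got {self.alpha}")


def _usable_rows(compiled: CompiledCondition) -> pd.DataFrame:
    d = compiled.data
    sel = d[d["status"].isin([STATUS_MEASURED, STATUS_ABSENT])].copy()
    sel["condition"] = compiled.condition
    return sel


def summarize(compiled: CompiledCondition) -> pd.DataFrame:
    """Per structure × day summary: mean, SEM and n under the status rules.

    Occluded rows are excluded from both the mean and n; absent late roots
    enter as zeros.  SEM (sample sd / √n) is reported only for n ≥ 2; empty
    cells give NaN means with n = 0.
    """
    usable = _usable_rows(compiled)
    rows = []
    for struct in compiled.structures:
        for day in (0, 1, 2):
            cell = usable[(usable["structure"] == struct) & (usable["day"] == day)]
            n = int(len(cell))
            mean = float(cell["length_mm"].mean()) if n else np.nan
            sem = float(cell["length_mm"].std(ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
            rows.append(
                {
                    "structure": struct,
                    "day": day,
                    "condition": compiled.condition,
                    "mean_mm": mean,
                    "sem_mm": sem,
                    "n": n,
                }
            )
    return pd.DataFrame(rows, columns=["structure", "day", "condition", "mean_mm", "sem_mm", "n"])


class WaterStressModel:
    """Mixed-effects model of one structure's length across condition × day.

    Build with :meth:`from_compiled` (the usual route) or directly from a
    long DataFrame with columns ``length_mm, condition, day, plate_uid,
    seedling_uid``.
    """

    def __init__(self, data: pd.DataFrame, structure: str, spec: Optional[ModelSpec] = None):
        self.spec = spec or ModelSpec()
        self.structure = structure
        required = {"length_mm", "condition", "day", "plate_uid", "seedling_uid"}
        missing = required - set(data.columns)
        if missing:
            raise ModelFitError(f"model data missing columns {sorted(missing)}")
        if data.empty:
            raise ModelFitError(
                f"no usable (non-occluded) observations for {structure}"
            )
        for cond in ("WW", "WS"):
            if not (data["condition"] == cond).any():
                raise ModelFitError(f"{structure}: no usable observations for {cond}")
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_compiled(
        cls,
        ww: CompiledCondition,
        ws: CompiledCondition,
        structure: str,
        spec: Optional[ModelSpec] = None,
    ) -> "WaterStressModel":
        """Assemble the model frame from two compiled conditions.

        Occluded rows are dropped; absent late roots enter as true zeros
        (they count toward n and means).  Plate and seedling identifiers are
        namespaced by condition — WW plate 1 and WS plate 1 are different
        plates.
        """
        if {ww.condition, ws.condition} != {"WW", "WS"}:
            raise ModelFitError(
                f"expected one WW and one WS condition, got {ww.condition}/{ws.condition}"
            )
        frames = []
        for compiled in (ww, ws):
            sel = _usable_rows(compiled)
            sel = sel[sel["structure"] == structure]
            frames.append(sel)
        df = pd.concat(frames, ignore_index=True)
        if df.empty:
            raise ModelFitError(
                f"all rows occluded or missing for structure {structure!r}"
            )
        df["plate_uid"] = df["condition"] + "-p" + df["plate_index"].astype(str)
        df["seedling_uid"] = df["condition"] + "-s" + df["seedling_index"].astype(str)
        df = df[["length_mm", "condition", "day", "plate_uid", "seedling_uid"]]
        return cls(df, structure, spec)

    # -- fitting -------------------------------------------------------------

    def _fit_once(self, include_plate: bool, include_seedling: bool):
        """One rung of the fallback ladder. Returns (results, singular, kind)."""
        df = self.data
        if not include_plate and not include_seedling:
            res = smf.ols(_FORMULA, data=df).fit()
            return res, False, "ols"
        groups = "plate_uid" if include_plate else "seedling_uid"
        vc = (
            {"seedling": "0 + C(seedling_uid)"}
            if (include_plate and include_seedling)
            else None
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm(_FORMULA, data=df, groups=df[groups], re_formula="1", vc_formula=vc)
            try:
                res = md.fit(reml=True, method="lbfgs", maxiter=200)
            except (np.linalg.LinAlgError, ValueError) as exc:
                return None, True, f"failed:{exc}"
        scale = max(float(res.scale), 1e-12)
        variances = [float(res.cov_re.iloc[0, 0])]
        if vc is not None and len(res.vcomp):
            variances.append(float(res.vcomp[0]))
        singular = (not res.converged) or any(
            v < self.spec.singular_tol * scale for v in variances
        )
        kind = "plate+seedling" if vc is not None else ("plate" if include_plate else "seedling")
        return res, singular, kind

    def fit(self) -> "WaterStressResults":
        """Fit with the deterministic fallback ladder and build results.

        Ladder: plate + seedling-within-plate random intercepts → plate
        only → fixed effects only (OLS).  A rung is abandoned when the fit
        fails to converge or a variance component collapses to zero.
        """
        ladder = []
        if self.spec.include_plate and self.spec.include_seedling:
            ladder.append((True, True))
        if self.spec.include_plate:
            ladder.append((True, False))
        ladder.append((False, False))

        res = None
        fallback = "ols"
        for include_plate, include_seedling in ladder:
            res, singular, kind = self._fit_once(include_plate, include_seedling)
            if res is not None and not singular:
                fallback = kind
                break
        else:
            # every mixed rung singular: the OLS rung always succeeds
            res, _, fallback = self._fit_once(False, False)
        if res is None:  # pragma: no cover - OLS cannot fail on validated data
            raise ModelFitError(f"could not fit any model for {self.structure}")
        return WaterStressResults(self, res, fallback)


class WaterStressResults:
    """Fitted treatment-contrast model for one structure.

    Carries the per-day WS − WW contrasts (estimate, SE, p), which random
    structure survived the fallback ladder, and a ``summary()`` table.
    """

    def __init__(self, model: WaterStressModel, fitted, fallback: str):
        self.model = model
        self.structure = model.structure
        self.fitted = fitted
        self.fallback = fallback
        #: between-within df: seedlings minus the two condition groups
        self.df_resid_contrast = max(
            int(model.data["seedling_uid"].nunique()) - 2, 1
        )
        self.contrasts_ = self._compute_contrasts()

    def _compute_contrasts(self) -> pd.DataFrame:
        names = list(self.fitted.model.exog_names)
        days = sorted(self.model.data["day"].unique())
        rows = []
        for day in days:
            L = np.zeros(len(names))
            L[names.index(_COND_TERM)] = 1.0
            inter = f"{_COND_TERM}:C(day)[T.{day}]"
            if inter in names:
                L[names.index(inter)] = 1.0
            tt = self.fitted.t_test(L.reshape(1, -1))
            est = float(np.atleast_1d(tt.effect)[0])
            se = float(np.atleast_1d(tt.sd.ravel())[0])
            if se > 0 and np.isfinite(se):
                tstat = est / se
                p = float(2.0 * scipy.stats.t.sf(abs(tstat), self.df_resid_contrast))
            else:
                tstat, p = np.nan, np.nan
            rows.append(
                {
                    "structure": self.structure,
                    "day": int(day),
                    "estimate_mm": est,
                    "se_mm": se,
                    "t": tstat,
                    "p_value": p,
                }
            )
        return pd.DataFrame(rows)

    def differences(self, alpha: Optional[float] = None) -> pd.DataFrame:
        """Difference-table rows for this structure: estimate, SE, p, significance."""
        alpha = self.model.spec.alpha if alpha is None else alpha
        out = self.contrasts_.drop(columns=["t"]).copy()
        pvals = out["p_value"].to_numpy(copy=True)
        if self.model.spec.holm:
            order = np.argsort(pvals)
            m = np.sum(np.isfinite(pvals))
            adj = pvals.copy()
            running = 0.0
            for rank, idx in enumerate(order):
                if not np.isfinite(pvals[idx]):
                    continue
                running = max(running, min(1.0, (m - rank) * pvals[idx]))
                adj[idx] = running
            pvals = adj
            out["p_value"] = pvals
        out["significant"] = np.isfinite(pvals) & (pvals < alpha)
        out["fallback"] = self.fallback
        return out

    def summary(self) -> str:
        """Human-readable report: model structure and per-day contrasts."""
        spec = self.model.spec
        lines = [
            f"Water-stress contrast model — structure: {self.structure}",
            f"  formula: {_FORMULA}",
            f"  random terms kept: {self.fallback}"
            + ("" if self.fallback != "ols" else " (fixed effects only)"),
            f"  contrast df (between-within): {self.df_resid_contrast}",
            f"  n obs: {len(self.model.data)}, alpha: {spec.alpha}",
            "",
            f"  {'day':>3} {'WS-WW (mm)':>12} {'SE':>8} {'p':>10}",
        ]
        for _, r in self.contrasts_.iterrows():
            lines.append(
                f"  {int(r['day']):>3} {r['estimate_mm']:>12.4f} "
                f"{r['se_mm']:>8.4f} {r['p_value']:>10.4g}"
            )
        return "\n".join(lines)


def fit_structure_model(
    ww: CompiledCondition,
    ws: CompiledCondition,
    structure: str,
    spec: Optional[ModelSpec] = None,
) -> WaterStressResults:
    """Fit the per-structure mixed model; functional facade over the classes."""
    return WaterStressModel.from_compiled(ww, ws, structure, spec).fit()


def posthoc_differences(
    results: WaterStressResults, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-timepoint WS − WW contrasts of a fitted model at cutoff ``alpha``."""
    return results.differences(alpha=alpha)


def summary_ws_vs_ww(
    ww: CompiledCondition,
    ws: CompiledCondition,
    alpha: float = 0.05,
    root6_threshold: int = 3,
    spec: Optional[ModelSpec] = None,
) -> pd.DataFrame:
    """Difference table over all structures: shoot, roots 1–5, root 6 if included.

    Root 6 enters when either condition passes the inclusion rule (> threshold
    seedlings ever showing a sixth root); the model then uses the other
    condition's absent-zero rows as data.  Structure order is stable.
    """
    if ws.data.empty:
        raise ModelFitError("empty WS input")
    if ww.data.empty:
        raise ModelFitError("empty WW input")
    structures = [s for s in STRUCTURE_ORDER if s != "root6"]
    if root6_included(ww, root6_threshold) or root6_included(ws, root6_threshold):
        structures.append("root6")
    spec = spec or ModelSpec(alpha=alpha)
    if spec.alpha != alpha:
        spec = replace(spec, alpha=alpha)
    frames = []
    for struct in structures:
        res = fit_structure_model(ww, ws, struct, spec)
        frames.append(res.differences(alpha=alpha))
    return pd.concat(frames, ignore_index=True)
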