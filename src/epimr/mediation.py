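"""Natural direct/indirect effects under the nested case-control design.

Decomposes the effect of a continuous exposure (e.g. waist circumference)
on a binary outcome into the natural direct effect (NDE) and the natural
indirect effect (NIE) through a continuous mediator (e.g. a circulating
biomarker), assuming no exposure-mediator interaction and a rare outcome:

- mediator model: least squares of mediator on exposure + adjustment,
  fitted among controls (representative of the risk-set population under
  incidence-density sampling); slope alpha1;
- outcome model: conditional logistic regression on exposure + mediator
  + adjustment; coefficients beta_exp and beta_med;
- log NDE = beta_exp * delta, log NIE = alpha1 * beta_med * delta,
  log total = log NDE + log NIE; proportion mediated =
  log NIE / log total on the log-OR scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nested_case_control import _as_frame, clogit_fit


@dataclass(frozen=True)
class MediationResult:
    """Product-method natural-effect decomposition (rare-outcome ORs)."""

    nde_or: float
    nie_or: float
    total_or: float
    proportion_mediated: float | None
    alpha1: float
    beta_exposure: float
    beta_mediator: float
    delta: float
    converged: bool
    ci: dict | None = None


def natural_effects(
    alpha1: float, beta_exposure: float, beta_mediator: float, delta: float = 1.0,
    converged: bool = True, ci: dict | None = None,
) -> MediationResult:
    """Closed-form product-method decomposition from fitted coefficients."""
    log_nde = beta_exposure * delta
    log_nie = alpha1 * beta_mediator * delta
    log_total = log_nde + log_nie
    proportion = None if abs(log_total) < 1e-10 else log_nie / log_total
    return MediationResult(
        nde_or=float(np.exp(log_nde)),
        nie_or=float(np.exp(log_nie)),
        total_or=float(np.exp(log_total)),
        proportion_mediated=proportion,
        alpha1=float(alpha1),
        beta_exposure=float(beta_exposure),
        beta_mediator=float(beta_mediator),
        delta=float(delta),
        converged=converged,
        ci=ci,
    )


def _mediator_slope(df: pd.DataFrame, exposure: str, mediator: str, adjustment,
                    case_col: str, sample: str) -> float:
    if sample == "controls":
        sub = df[df[case_col] == 0]
    elif sample == "all":
        sub = df
    else:
        raise ValueError("mediator_sample must be 'controls' or 'all'")
    cols = [exposure] + list(adjustment)
    X = np.column_stack([np.ones(len(sub))] + [sub[c].to_numpy(dtype=float) for c in cols])
    y = sub[mediator].to_numpy(dtype=float)
    ok = ~np.isnan(X).any(axis=1) & ~np.isnan(y)
    coef, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
    return float(coef[1])


def mediate_ncc(
    data,
    exposure: str,
    mediator: str,
    adjustment=(),
    delta: float = 1.0,
    set_col: str = "set_id",
    case_col: str = "is_case",
    mediator_sample: str = "controls",
    n_bootstrap: int = 0,
    seed: int | None = None,
) -> MediationResult:
    """Causal mediation analysis on matched nested case-control data.

    ``delta`` is the exposure increment the ORs refer to (e.g. 1 cm of
    waist circumference). ``mediator_sample`` selects whether the
    mediator model uses controls only (default) or the whole sample.
    ``n_bootstrap > 0`` adds percentile intervals from resampling matched
    sets.
    """
    df = _as_frame(data)
    adjustment = list(adjustment)

    def fit_once(frame: pd.DataFrame) -> tuple[float, float, float, bool]:
        a1 = _mediator_slope(frame, exposure, mediator, adjustment, case_col, mediator_sample)
        out = clogit_fit(frame, [exposure, mediator] + adjustment,
                         set_col=set_col, case_col=case_col)
        return a1, out.coefficients[exposure], out.coefficients[mediator], out.converged

    alpha1, b_exp, b_med, converged = fit_once(df)
    ci = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        set_ids = df[set_col].unique()
        groups = {sid: grp for sid, grp in df.groupby(set_col)}
        draws = {"nde_or": [], "nie_or": [], "proportion_mediated": []}
        for b in range(n_bootstrap):
            chosen = rng.choice(set_ids, size=len(set_ids), replace=True)
            frames = []
            for j, sid in enumerate(chosen):
                g = groups[sid].copy()
                g[set_col] = f"b{j}"
                frames.append(g)
            boot = pd.concat(frames, ignore_index=True)
            try:
                a1, be, bm, _ = fit_once(boot)
            except (ValueError, np.linalg.LinAlgError):
                continue
            res = natural_effects(a1, be, bm, delta)
            draws["nde_or"].append(res.nde_or)
            draws["nie_or"].append(res.nie_or)
            if res.proportion_mediated is not None:
                draws["proportion_mediated"].append(res.proportion_mediated)
        ci = {
            key: tuple(np.percentile(vals, [2.5, 97.5])) if vals else (np.nan, np.nan)
            for key, vals in draws.items()
        }
    return natural_effects(alpha1, b_exp, b_med, delta, converged=converged, ci=ci)
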