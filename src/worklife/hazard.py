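"""Discrete-time marginal hazard models for state occupancy.

For each outcome state a person-year panel is built: one row per person per
observed whole year of age, with a binary indicator of occupying the
outcome state at any point during that year.  The marginal occupancy
probability is modelled with a complementary log-log link,

    log(-log(1 - Q_ji)) = alpha_j + beta' Z_i,   j = 20, ..., 58,

one intercept per year of age, via generalized estimating equations with an
AR(1) working correlation (the yearly indicators are balanced in time) and
a robust sandwich covariance.  Exponentiated coefficients are reported as
hazard rate ratios (HRR) against the reference group (average IQ, no
mental-health problems), split into effects before and after age 35 through
a group x period interaction within a single model per outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import covariates as cov
from .states import StateSpace, merged_state_space

REFERENCE = "average/none"
SPLIT_AGE = 35
PHYSICAL_COLS = ["phys_health", "arm", "hand", "walking", "back", "skin"]


def build_panel(intervals: pd.DataFrame, events: pd.DataFrame,
                covariates: pd.DataFrame, outcome_state: int,
                space: StateSpace | None = None,
                windows: pd.DataFrame | None = None) -> pd.DataFrame:
    """Person-year panel of occupancy indicators for one outcome state.

    Rows cover each whole year of age inside the person's observation
    window (given explicitly via ``windows`` with columns person_id,
    entry_age, exit_age, or derived from the at-risk intervals).  The
    indicator is 1 when the person occupies the outcome state at any point
    during that year.  Death is absorbing: for the death outcome the
    indicator stays 1 through the end of the window; for any other outcome
    the panel stops after the year containing the death.  Years spent
    entirely emigrated are excluded from other outcomes' rows.  Only
    persons with complete IQ and mental-health classification enter (they
    are the regression population); persons with no whole observed year
    are rejected.
    """
    space = space or merged_state_space()
    if outcome_state not in space.codes:
        raise ValueError(f"outcome state {outcome_state} not in space")
    absorbing = space.absorbing_code
    emigrated = next((s.code for s in space.states if s.label == "emigrated"),
                     None)

    cls = cov.classify_cohort(covariates).set_index("person_id")
    cls = cls[cls["group"].notna()]
    phys = cov.dichotomize_physical(cls) if set(PHYSICAL_COLS) <= \
        set(cls.columns) else None

    death_age: dict = {}
    if not events.empty:
        deaths = events[events["to_state"] == absorbing]
        death_age = dict(zip(deaths["person_id"], deaths["time"]))

    win = windows.set_index("person_id") if windows is not None else None

    rows: list[dict] = []
    for pid, ivs in intervals.groupby("person_id", sort=False):
        if pid not in cls.index:
            continue
        died = death_age.get(pid)
        if win is not None and pid in win.index:
            entry = float(win.at[pid, "entry_age"])
            window_exit = float(win.at[pid, "exit_age"])
        else:
            entry = float(ivs["entry_age"].min())
            window_exit = float(ivs["exit_age"].max())
            if died is not None:
                # intervals stop at death; run the absorbing indicator into
                # at least the year after the death
                window_exit = max(window_exit, float(np.ceil(died + 1e-9)))
        first_year = int(np.ceil(entry - 1e-9))
        last_year = int(np.floor(window_exit + 1e-9))
        if outcome_state != absorbing and died is not None:
            last_year = min(last_year, int(np.floor(died)) + 1)
        years = range(first_year, last_year)
        if not len(ivs) or first_year >= last_year:
            raise ValueError(f"person {pid} has no whole observed year")
        occ = ivs[ivs["state"] == outcome_state]
        emi = ivs[ivs["state"] == emigrated] if emigrated is not None and \
            outcome_state not in (emigrated, absorbing) else None
        for j in years:
            y0, y1 = float(j), float(j + 1)
            if died is not None and outcome_state != absorbing and \
                    y0 >= died:
                break
            if emi is not None and len(emi):
                covered = ((emi["entry_age"] <= y0 + 1e-9)
                           & (emi["exit_age"] >= y1 - 1e-9)).any()
                if covered:
                    continue
            if outcome_state == absorbing:
                ind = int(died is not None and died < y1)
            else:
                ind = int(bool(len(occ)) and
                          ((occ["entry_age"] < y1)
                           & (occ["exit_age"] > y0)).any())
            rows.append({"person_id": pid, "age_year": j, "y": ind})
    panel = pd.DataFrame(rows)
    if panel.empty:
        raise ValueError("empty person-year panel")
    panel = panel.merge(cls[["iq_cat", "mental_cat", "group", "bmi"]],
                        left_on="person_id", right_index=True, how="left")
    if phys is not None:
        panel = panel.merge(phys, left_on="person_id", right_index=True,
                            how="left")
    panel["period"] = np.where(panel["age_year"] < SPLIT_AGE, "before35",
                               "after35")
    return panel


@dataclass
class GEEFit:
    """A fitted marginal cloglog model for one outcome state."""

    outcome_state: int
    params: pd.Series
    cov_robust: pd.DataFrame
    rho: float
    converged: bool
    adjusted: bool
    n_obs: int
    n_persons: int
    #: group x period cells with no events (separation); their contrast
    #: columns were dropped and their HRRs are not estimable
    separated_terms: tuple[str, ...] = ()
    result: object = None

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_robust)),
                         index=self.params.index)


def _design(panel: pd.DataFrame, adjusted: bool,
            split_age: int | None = SPLIT_AGE
            ) -> tuple[pd.DataFrame, list[str]]:
    """Year intercepts + (non-reference group x period) contrast columns."""
    X = pd.get_dummies(panel["age_year"].astype(int), prefix="age",
                       dtype=float)
    terms: list[str] = []
    for group in sorted(panel["group"].dropna().unique()):
        if group == REFERENCE:
            continue
        in_group = (panel["group"] == group).to_numpy(dtype=float)
        if split_age is None:
            name = f"g[{group}]"
            X[name] = in_group
            terms.append(name)
        else:
            for period in ("before35", "after35"):
                mask = in_group * (panel["period"] == period
                                   ).to_numpy(dtype=float)
                if mask.any():
                    name = f"g[{group}]:{period}"
                    X[name] = mask
                    terms.append(name)
    if adjusted:
        for col in PHYSICAL_COLS:
            icol = col + "_impaired"
            if icol in panel.columns:
                X[icol] = panel[icol].to_numpy(dtype=float)
        X["bmi"] = panel["bmi"].to_numpy(dtype=float)
    return X, terms


def fit_cloglog_gee(panel: pd.DataFrame, adjusted: bool = False,
                    correlation: str = "ar1", outcome_state: int = 0,
                    split_age: int | None = SPLIT_AGE,
                    on_separation: str = "drop",
                    maxiter: int = 60) -> GEEFit:
    """Fit the discrete-time cloglog GEE for one outcome.

    ``correlation`` is "ar1" (default) or "independence"; under
    independence the estimating equations coincide with a pooled
    single-observation cloglog regression.  Adjusted fits add the six
    dichotomized physical scores (any impairment vs none) and continuous
    BMI; rows with missing adjustment covariates are dropped.  Group x
    period cells with no events cannot carry a finite estimate (complete
    separation); they are dropped from the design and reported on the fit
    (``on_separation="raise"`` turns them into an error instead).
    """
    panel = panel.sort_values(["person_id", "age_year"], kind="stable")
    X, _ = _design(panel, adjusted, split_age)
    y = panel["y"].to_numpy(dtype=float)
    keep = np.isfinite(X.to_numpy(dtype=float)).all(axis=1)
    if not keep.all():
        X, y = X.loc[keep], y[keep]
        panel = panel.loc[keep]
    if panel["group"].nunique() < 2:
        raise ValueError("panel needs at least two covariate groups")
    zero_cells = [c for c in X.columns if c.startswith("g[")
                  and y[X[c].to_numpy() > 0].sum() == 0]
    if zero_cells:
        if on_separation == "raise":
            raise ValueError(f"complete separation: no events in "
                             f"{zero_cells}")
        X = X.drop(columns=zero_cells)

    if correlation == "ar1":
        cov_struct = sm.cov_struct.Autoregressive(grid=True)
    elif correlation == "independence":
        cov_struct = sm.cov_struct.Independence()
    else:
        raise ValueError(f"unknown working correlation {correlation!r}")
    family = sm.families.Binomial(link=sm.families.links.CLogLog())
    model = sm.GEE(y, X.to_numpy(dtype=float),
                   groups=panel["person_id"].to_numpy(),
                   time=panel["age_year"].to_numpy(dtype=float),
                   family=family, cov_struct=cov_struct)
    result = model.fit(maxiter=maxiter)
    params = pd.Series(result.params, index=X.columns)
    vcov = pd.DataFrame(result.cov_params(), index=X.columns,
                        columns=X.columns)
    rho = float(np.atleast_1d(cov_struct.dep_params)[0]) \
        if correlation == "ar1" else 0.0
    converged = bool(np.isfinite(result.params).all()
                     and np.isfinite(result.bse).all())
    return GEEFit(outcome_state=outcome_state, params=params,
                  cov_robust=vcov, rho=rho, converged=converged,
                  adjusted=adjusted, n_obs=len(y),
                  n_persons=panel["person_id"].nunique(),
                  separated_terms=tuple(zero_cells), result=result)


def hrr_table(fits: list[GEEFit] | GEEFit, level: float = 0.95,
              space: StateSpace | None = None) -> pd.DataFrame:
    """Hazard-rate-ratio table (outcome, mental, iq, period, hrr, lo, hi, p).

    Reference rows (average IQ, no problems) carry HRR = 1 exactly.
    """
    from scipy.stats import norm
    space = space or merged_state_space()
    if isinstance(fits, GEEFit):
        fits = [fits]
    z = norm.ppf(0.5 + level / 2)
    rows = []
    for fit in fits:
        label = space.labels.get(fit.outcome_state, str(fit.outcome_state))
        se = fit.se()
        term_names = [n for n in fit.params.index if n.startswith("g[")] \
            + list(fit.separated_terms)
        groups = sorted({n.split("]")[0][2:] for n in term_names}
                        | {REFERENCE})
        periods = sorted({n.rsplit(":", 1)[1] for n in term_names
                          if ":" in n}) or [None]
        for group in groups:
            iq_cat, mental_cat = group.split("/")
            for period in periods:
                if group == REFERENCE:
                    rows.append(dict(outcome=label, iq=iq_cat,
                                     mental=mental_cat, period=period,
                                     hrr=1.0, lo=np.nan, hi=np.nan,
                                     p=np.nan, adjusted=fit.adjusted))
                    continue
                name = f"g[{group}]" if period is None \
                    else f"g[{group}]:{period}"
                if name in fit.separated_terms or \
                        name not in fit.params.index:
                    # no events (separation) or no exposure in this cell:
                    # the contrast is not estimable
                    rows.append(dict(outcome=label, iq=iq_cat,
                                     mental=mental_cat, period=period,
                                     hrr=np.nan, lo=np.nan, hi=np.nan,
                                     p=np.nan, adjusted=fit.adjusted))
                    continue
                b, s = float(fit.params[name]), float(se[name])
                p = 2 * norm.sf(abs(b / s)) if s > 0 else np.nan
                rows.append(dict(outcome=label, iq=iq_cat, mental=mental_cat,
                                 period=period, hrr=float(np.exp(b)),
                                 lo=float(np.exp(b - z * s)),
                                 hi=float(np.exp(b + z * s)), p=p,
                                 adjusted=fit.adjusted))
    return pd.DataFrame(rows)
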