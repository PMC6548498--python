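"""Per-bird biomechanics table and linear mixed-effects models.

Each bird contributes one row aggregating its kinematics (median over
its sampled frames), wingbeat frequency, nearest-neighbor geometry and
flock-level position descriptors:

* ``flock_position`` — rank of the bird's mean along-track coordinate,
  scaled to [0, 1] with 0 the frontmost bird;
* ``edge_distance`` — horizontal distance to the flock boundary, in
  wingspans;
* ``nn_species_code`` — -1 / 0 / +1 for a smaller / same-species /
  larger nearest neighbor;
* ``aero_neighbor`` — 1 when the nearest *leading* neighbor sits in the
  zone where wake interaction is plausible (0.7-1.5 wingspans lateral
  and within two wingspans 3D distance), else 0.

Wingbeat frequency and airspeed are modelled with random-intercept
linear mixed-effects models grouped by flock, fit by maximum likelihood
so that fixed-effect structures can be compared with the Bayesian
information criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

AERO_LATERAL_WS = (0.7, 1.5)
AERO_DISTANCE_WS = 2.0

__all__ = ["build_biomech_table", "aero_neighbor_flag", "ModelFit", "fit_lme",
           "select_model"]


def aero_neighbor_flag(lateral_abs_ws, distance3d_ws, leading) -> np.ndarray:
    """1 when a leading nearest neighbor lies in the aerodynamic zone."""
    lat = np.asarray(lateral_abs_ws, dtype=float)
    d3 = np.asarray(distance3d_ws, dtype=float)
    lead = np.asarray(leading, dtype=bool)
    return (
        lead & (lat >= AERO_LATERAL_WS[0]) & (lat <= AERO_LATERAL_WS[1])
        & (d3 <= AERO_DISTANCE_WS)
    ).astype(int)


def _flock_position(kinematics: pd.DataFrame) -> pd.Series:
    """Rank of each bird's mean along-track coordinate, scaled to [0, 1]
    (0 = front).  The travel direction is the flock's mean velocity."""
    v = kinematics[["vx", "vy"]].mean().to_numpy()
    v = v / np.hypot(*v)
    per_bird = kinematics.groupby("bird_id").apply(
        lambda s: s["x"].mean() * v[0] + s["y"].mean() * v[1],
        include_groups=False,
    )
    rank = per_bird.rank(method="average", ascending=False) - 1  # 0 = frontmost
    n = len(rank)
    return (rank / max(n - 1, 1)).rename("flock_position")


def build_biomech_table(
    flock,
    offsets: pd.DataFrame,
    kinematics: pd.DataFrame,
    wingbeat_hz: dict | pd.Series,
    edge_distance_ws: pd.Series,
) -> pd.DataFrame:
    """One biomechanics row per bird with wingbeat data.

    ``kinematics`` must already carry an ``airspeed`` column; offsets
    are the nearest-neighbor records of this flock.  Birds without a
    wingbeat frequency are excluded (mirroring the exclusion of birds
    whose flapping could not be measured).  Raises on bird ids present
    in ``offsets`` but missing from ``kinematics``.
    """
    wingbeat_hz = pd.Series(dict(wingbeat_hz), name="wingbeat_hz", dtype=float)

    orphans = set(offsets["focal_id"]) - set(kinematics["bird_id"])
    if orphans:
        raise ValueError(f"offsets reference unknown birds: {sorted(orphans)[:5]} ...")

    kin_agg = kinematics.groupby("bird_id").agg(
        airspeed=("airspeed", "median"), z_speed=("z_speed", "median")
    )
    off_agg = offsets.groupby("focal_id").agg(
        nn_distance=("distance3d_ws", "median"),
        lateral_abs_ws=("lateral_abs_ws", "median"),
        distance3d_ws=("distance3d_ws", "median"),
        leading_frac=("leading", "mean"),
        nn_species_code=("nn_species_code", lambda s: int(np.sign(s.mean()))),
    )
    off_agg["aero_neighbor"] = aero_neighbor_flag(
        off_agg["lateral_abs_ws"], off_agg["distance3d_ws"], off_agg["leading_frac"] > 0.5
    )
    pos = _flock_position(kinematics)
    species = kinematics.groupby("bird_id")["species"].first()

    table = (
        kin_agg.join(off_agg, how="inner")
        .join(pos, how="inner")
        .join(wingbeat_hz, how="inner")
        .join(edge_distance_ws.rename("edge_distance"), how="left")
        .join(species, how="left")
        .dropna(subset=["wingbeat_hz", "airspeed"])
        .reset_index(names="bird_id")
    )
    table["flock_id"] = flock.flock_id
    table["is_godwit"] = (table["species"] == "godwit").astype(int)
    table["is_avocet"] = (table["species"] == "avocet").astype(int)
    return table


@dataclass
class ModelFit:
    response: str
    terms: list
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df_resid: float
    bic: float
    grouping: str
    singular: bool = False

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params, "se": self.bse, "t": self.tvalues,
             "p": self.pvalues}
        )


def _bic(llf: float, n_params: int, nobs: int) -> float:
    return float(-2.0 * llf + n_params * np.log(nobs))


def fit_lme(table: pd.DataFrame, response: str, fixed_terms,
            grouping: str = "flock_id", reml: bool = True) -> ModelFit:
    """Random-intercept mixed model, grouped by flock.

    REML (the default, standard for coefficient estimation) is switched
    to maximum likelihood inside :func:`select_model`, where fixed-effect
    structures are compared and REML likelihoods are not comparable.
    BIC is computed from the log-likelihood with the fixed effects, the
    random-intercept variance and the residual variance all counted as
    parameters.  A singular random-effect fit (zero between-group
    variance or convergence failure) falls back to OLS with a flag.
    """
    fixed_terms = list(fixed_terms)
    rhs = " + ".join(fixed_terms) if fixed_terms else "1"
    formula = f"{response} ~ {rhs}"
    n_groups = table[grouping].nunique()
    if n_groups < 2:
        raise ValueError("need >= 2 groups for a mixed model")

    singular = False
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm(formula, table, groups=table[grouping])
            fit = md.fit(reml=reml)
        re_var = float(fit.cov_re.iloc[0, 0])
        if not np.isfinite(re_var) or re_var <= 1e-10 or not fit.converged:
            raise RuntimeError("singular random-intercept fit")
        params = fit.fe_params
        k = len(params) + 2  # + random-intercept variance + residual variance
        return ModelFit(response, fixed_terms, params, fit.bse_fe[params.index],
                        fit.tvalues[params.index], fit.pvalues[params.index],
                        float(fit.df_resid), _bic(fit.llf, k, len(table)),
                        grouping)
    except Exception as exc:
        logger.warning("mixed fit failed (%s); refitting OLS without random effect", exc)
        singular = True
    ols = smf.ols(formula, table).fit()
    k = len(ols.params) + 1
    return ModelFit(response, fixed_terms, ols.params, ols.bse, ols.tvalues,
                    ols.pvalues, float(ols.df_resid),
                    _bic(ols.llf, k, len(table)), grouping, singular=singular)


def select_model(table: pd.DataFrame, response: str, candidate_terms,
                 grouping: str = "flock_id", mode: str = "greedy",
                 forced_terms=()) -> tuple:
    """BIC model selection over fixed-effect terms.

    ``mode='exhaustive'`` scores every subset (capped at 2^10
    candidates); ``'greedy'`` does forward selection.  Returns
    ``(best_fit, history)`` where history is a DataFrame of (terms, bic)
    evaluated.  ``forced_terms`` are always included.
    """
    candidates = [t for t in candidate_terms if t not in forced_terms]
    history = []

    def score(terms):
        fit = fit_lme(table, response, list(forced_terms) + list(terms), grouping,
                      reml=False)
        history.append({"terms": tuple(sorted(fit.terms)), "bic": fit.bic})
        return fit

    if mode == "exhaustive":
        if len(candidates) > 10:
            raise ValueError("exhaustive selection capped at 10 candidate terms")
        from itertools import combinations

        best = None
        for r in range(len(candidates) + 1):
            for combo in combinations(candidates, r):
                fit = score(combo)
                if best is None or fit.bic < best.bic:
                    best = fit
    else:
        current: list = []
        best = score(current)
        improved = True
        while improved and len(current) < len(candidates):
            improved = False
            trial_fits = []
            for t in candidates:
                if t in current:
                    continue
                trial_fits.append(score(current + [t]))
            if trial_fits:
                cand = min(trial_fits, key=lambda f: f.bic)
                if cand.bic < best.bic:
                    best = cand
                    current = [t for t in cand.terms if t not in forced_terms]
                    improved = True
    return best, pd.DataFrame(history)


def bic_penalty_of_term(table: pd.DataFrame, base_fit: ModelFit, term: str,
                        grouping: str = "flock_id") -> float:
    """BIC change when ``term`` is added to an already selected model
    (positive = the added term worsens the criterion)."""
    with_term = fit_lme(table, base_fit.response, base_fit.terms + [term], grouping,
                        reml=False)
    return float(with_term.bic - base_fit.bic)
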