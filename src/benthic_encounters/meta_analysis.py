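"""Mixed-effects meta-analysis of fitted feeding parameters.

Fitted per-pair capture rates (at half-saturation, in biomass units) and
maximum feeding rates are log-transformed, standardised, and modelled as
linear mixed effects of log consumer mass (C), log resource mass (R) and
log temperature (T), with encounter strategy as a non-interacting
categorical fixed effect and taxonomic grouping as a random intercept.
The candidate fixed-effect structures are every marginality-respecting
combination of the three metabolic predictors and their two-way
interactions, each with and without strategy — 36 structures including
the null — ranked by small-sample AICc from maximum-likelihood fits
(ML, not REML, so likelihoods are comparable across fixed structures).
Uncertainty in the selected model's mass scaling is summarised by
nonparametric case-resampling bootstrap prediction bands per strategy.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .functional_response import FittedResponse, aicc
from .trials import TrialSet

__all__ = [
    "ModelStructure", "FittedStructure", "enumerate_structures",
    "build_meta_table", "fit_structure", "select_structure",
    "bootstrap_predictions", "RESPONSES",
]

RESPONSES = {"capture": "log_capture", "max_feed": "log_max_feed"}

_PREDICTORS = {"C": "log_consumer_mass", "R": "log_resource_mass",
               "T": "log_temperature"}

#: Boltzmann constant in eV/K, for the optional Arrhenius axis.
_K_B = 8.617333e-5


@dataclass(frozen=True)
class ModelStructure:
    """One candidate fixed-effects structure.

    `mains` is a subset of {"C", "R", "T"}; `interactions` holds two-way
    products, each only permitted when both parents are present
    (marginality); `strategy` toggles the categorical encounter-strategy
    term.
    """

    mains: frozenset = frozenset()
    interactions: frozenset = frozenset()
    strategy: bool = False

    def __post_init__(self) -> None:
        if not self.mains <= {"C", "R", "T"}:
            raise ValueError("mains must be a subset of {C, R, T}")
        for pair in self.interactions:
            if not (len(pair) == 2 and pair <= self.mains):
                raise ValueError("interactions require both main effects")

    def formula_rhs(self) -> str:
        terms = [_PREDICTORS[m] for m in sorted(self.mains)]
        terms += [":".join(_PREDICTORS[m] for m in sorted(pair))
                  for pair in sorted(self.interactions, key=sorted)]
        if self.strategy:
            terms.append("C(strategy)")
        return " + ".join(terms) if terms else "1"

    def label(self) -> str:
        ints = ["*".join(sorted(p)) for p in sorted(self.interactions, key=sorted)]
        parts = sorted(self.mains) + ints + (["strategy"] if self.strategy else [])
        return " + ".join(parts) if parts else "null"


def enumerate_structures() -> list[ModelStructure]:
    """All 36 marginality-closed fixed-effect structures (incl. the null).

    Hierarchy: the empty model, the three singletons, each of the three
    pairs with or without its interaction, and the full triple with any
    of the 2^3 interaction subsets — 18 structures, each duplicated with
    and without the strategy term.
    """
    structures = []
    for k in range(4):
        for mains in itertools.combinations("CRT", k):
            mains_set = frozenset(mains)
            pairs = [frozenset(p) for p in itertools.combinations(sorted(mains), 2)]
            for n_int in range(len(pairs) + 1):
                for ints in itertools.combinations(pairs, n_int):
                    for strat in (False, True):
                        structures.append(ModelStructure(
                            mains=mains_set, interactions=frozenset(ints),
                            strategy=strat))
    return structures


# ---------------------------------------------------------------------------
# Meta-table assembly
# ---------------------------------------------------------------------------

def build_meta_table(fits: list[FittedResponse], trials: list[TrialSet],
                     temp_transform: str = "log",
                     standardise: bool = True) -> tuple[pd.DataFrame, int]:
    """Join selected fits to trial covariates and transform for modelling.

    Masses, temperature and the two rate responses are natural-log
    transformed; responses are then z-scored across the table.  By
    default temperature enters as log(deg C) — Celsius values <= 0 are
    rejected with an explicit message — with ``temp_transform=
    "arrhenius"`` substituting the inverse thermal energy 1/(k_B T_K).
    Records whose fit failed or whose transformed values are non-finite
    (e.g. zero capture or unsaturated h = 0 responses) are excluded;
    the count of exclusions is returned alongside the table.
    """
    by_pair = {t.pair_id: t for t in trials}
    rows, excluded = [], 0
    for fit in fits:
        t = by_pair.get(fit.pair_id)
        if t is None or not fit.converged or fit.flag == "all_zero_null_fit":
            excluded += 1
            continue
        if temp_transform == "log":
            if t.temperature <= 0:
                raise ValueError(
                    f"pair {t.pair_id}: temperature {t.temperature} deg C <= 0 "
                    "cannot be log-transformed; use temp_transform='arrhenius'")
            temp_val = math.log(t.temperature)
        elif temp_transform == "arrhenius":
            temp_val = 1.0 / (_K_B * (t.temperature + 273.15))
        else:
            raise ValueError("temp_transform must be 'log' or 'arrhenius'")
        cap = fit.capture_biomass_g_per_day
        mf = fit.max_feed_biomass_g_per_day
        rows.append({
            "pair_id": fit.pair_id,
            "log_capture": math.log(cap) if cap and cap > 0 and
            math.isfinite(cap) else np.nan,
            "log_max_feed": math.log(mf) if mf and mf > 0 and
            math.isfinite(mf) else np.nan,
            "log_consumer_mass": math.log(t.consumer_mass),
            "log_resource_mass": math.log(t.resource_mass),
            "log_temperature": temp_val,
            "strategy": t.strategy, "taxon_group": t.taxon_group,
            "q": fit.params.q,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df, excluded
    dropped = int(df["log_capture"].isna().sum())
    if standardise:
        for col in ("log_capture", "log_max_feed"):
            vals = df[col]
            sd = vals.std(ddof=1)
            if sd and np.isfinite(sd) and sd > 0:
                df[col] = (vals - vals.mean()) / sd
    df.attrs["n_excluded_fits"] = excluded
    df.attrs["n_nonfinite_capture"] = dropped
    return df, excluded


# ---------------------------------------------------------------------------
# Mixed-model fitting and selection
# ---------------------------------------------------------------------------

@dataclass
class FittedStructure:
    """One mixed-model fit of a candidate structure."""

    structure: ModelStructure
    response: str
    loglik: float
    k: int
    n: int
    AICc: float
    fe_params: pd.Series
    group_sd: float
    result: object = field(repr=False, default=None)
    flag: str = ""


def fit_structure(records: pd.DataFrame, structure: ModelStructure,
                  response: str = "capture",
                  reml: bool = False) -> FittedStructure:
    """Fit one random-intercept mixed model by (restricted) ML.

    The random intercept is per taxonomic group; `k` counts the fixed
    effects (including the intercept) plus the two variance components
    (group and residual).  A group variance estimated at the boundary
    (effectively zero) is retained but flagged.
    """
    col = RESPONSES[response]
    data = records.dropna(subset=[col]).copy()
    if data["taxon_group"].nunique() < 2:
        raise ValueError("need at least 2 taxonomic groups for a random intercept")
    formula = f"{col} ~ {structure.formula_rhs()}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data["taxon_group"])
        result = model.fit(reml=reml)
        if not math.isfinite(float(result.llf)):
            # a variance driven exactly to the boundary can defeat the
            # default optimiser; Powell is slower but robust there
            result = model.fit(reml=reml, method="powell")
    if not math.isfinite(float(result.llf)):
        raise RuntimeError(f"mixed-model likelihood not finite for "
                           f"{structure.label()!r}")
    k = len(result.fe_params) + 2
    n = len(data)
    if n <= k + 2:
        raise ValueError(f"too few records (n={n}) for k={k} parameters")
    group_var = float(np.asarray(result.cov_re)[0, 0])
    flag = "variance_boundary" if group_var < 1e-8 else ""
    ll = float(result.llf)
    return FittedStructure(
        structure=structure, response=response, loglik=ll, k=k, n=n,
        AICc=aicc(ll, k, n), fe_params=result.fe_params,
        group_sd=math.sqrt(max(group_var, 0.0)), result=result, flag=flag)


def select_structure(records: pd.DataFrame, response: str = "capture",
                     structures: list[ModelStructure] | None = None,
                     ) -> tuple[FittedStructure, pd.DataFrame]:
    """Fit every candidate structure and rank by AICc.

    Returns the lowest-AICc fit together with the full ranked table
    (label, k, loglik, AICc, delta AICc, flags); fit failures are
    recorded in the table and excluded from the ranking.
    """
    structures = structures if structures is not None else enumerate_structures()
    fits, rows = [], []
    for s in structures:
        try:
            f = fit_structure(records, s, response)
            fits.append(f)
            rows.append({"structure": s.label(), "k": f.k, "loglik": f.loglik,
                         "AICc": f.AICc, "flag": f.flag, "failed": False})
        except Exception as exc:  # noqa: BLE001 - failures belong in the table
            rows.append({"structure": s.label(), "k": np.nan, "loglik": np.nan,
                         "AICc": np.nan, "flag": str(exc), "failed": True})
    if not fits:
        raise RuntimeError("every candidate structure failed to fit")
    table = pd.DataFrame(rows)
    best_aicc = np.nanmin(table["AICc"].to_numpy())
    table["delta_AICc"] = table["AICc"] - best_aicc
    table = table.sort_values("AICc").reset_index(drop=True)
    best = min(fits, key=lambda f: f.AICc)
    return best, table


def bootstrap_predictions(best: FittedStructure, records: pd.DataFrame,
                          n_boot: int = 200, seed: int | None = None,
                          mass_grid: np.ndarray | None = None,
                          n_grid: int = 25, max_retries: int = 3,
                          ) -> pd.DataFrame:
    """Bootstrap prediction bands over log consumer mass per strategy.

    Records are case-resampled with replacement, stratified by encounter
    strategy so group sizes are preserved; each resample is refitted
    with the selected structure and its fixed-effect prediction is
    evaluated over a log-consumer-mass grid with other covariates held
    at their overall medians.  Returns tidy rows (strategy, log_mass,
    fit, lo, hi) where `fit` is the point prediction from the original
    model and lo/hi the 2.5/97.5 bootstrap percentiles (equal to `fit`
    when n_boot = 0).
    """
    col = RESPONSES[best.response]
    data = records.dropna(subset=[col]).reset_index(drop=True)
    if mass_grid is None:
        mass_grid = np.linspace(data["log_consumer_mass"].min(),
                                data["log_consumer_mass"].max(), n_grid)
    strategies = sorted(data["strategy"].unique())
    med_R = float(data["log_resource_mass"].median())
    med_T = float(data["log_temperature"].median())

    def grid_frame() -> pd.DataFrame:
        frames = []
        for s in strategies:
            frames.append(pd.DataFrame({
                "log_consumer_mass": mass_grid,
                "log_resource_mass": med_R,
                "log_temperature": med_T,
                "strategy": s,
            }))
        return pd.concat(frames, ignore_index=True)

    grid = grid_frame()
    point = np.asarray(best.result.predict(exog=grid))

    rng = np.random.default_rng(seed)
    idx_by_strategy = {s: np.flatnonzero(data["strategy"] == s)
                       for s in strategies}
    preds = []
    attempts = 0
    while len(preds) < n_boot and attempts < max_retries * max(n_boot, 1):
        attempts += 1
        take = np.concatenate([
            rng.choice(idx, size=idx.size, replace=True)
            for idx in idx_by_strategy.values()])
        sample = data.iloc[take].reset_index(drop=True)
        try:
            refit = fit_structure(sample, best.structure, best.response)
            preds.append(np.asarray(refit.result.predict(exog=grid)))
        except Exception:  # singular resample: redraw
            continue
    if n_boot > 0 and len(preds) < n_boot:
        warnings.warn(f"only {len(preds)}/{n_boot} bootstrap refits succeeded",
                      stacklevel=2)
    if preds:
        arr = np.vstack(preds)
        lo = np.percentile(arr, 2.5, axis=0)
        hi = np.percentile(arr, 97.5, axis=0)
    else:
        lo = hi = point
    out = grid[["strategy", "log_consumer_mass"]].copy()
    out = out.rename(columns={"log_consumer_mass": "log_mass"})
    out["fit"] = point
    out["lo"] = np.minimum(lo, point)
    out["hi"] = np.maximum(hi, point)
    return out
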