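"""Response models for the behavioral analysis.

Five responses are modeled (one per aspect of the bird-vessel
interaction), plus the mass-gain model:

==================  =================  ==========================  ===============
name                family             response                    offset
==================  =================  ==========================  ===============
encounter_rate      negative binomial  encounters per trip         log trip days
attend_prob         binomial           any attendance at encounter --
attend_duration     negative binomial  attendance fixes            --
attend_prop         negative binomial  attendance fixes            log event fixes
attend_distance     gaussian           mean boat distance (m)      --
mass_gain           gaussian (LM)      mass gained at sea (g)      --
==================  =================  ==========================  ===============

Fixed effects follow the study design: age, sex and their interaction in
every model; the concurrent average boat density for encounter rate; year
group (pooled high-boat years vs the low-boat year) with its sex and age
interactions, the average number of vessels within attraction range, and
a vessel-activity covariate for the encounter-level models.

Estimation: Gaussian mixed models use ``statsmodels`` MixedLM (random
bird intercept plus trip-within-bird variance component, fitted by ML so
likelihood-ratio tests on fixed terms are valid); binomial mixed models
are fitted by ``lme4::glmer`` through Rscript (with a variational-Bayes
fallback in pure Python); negative-binomial responses are fitted without
random terms and inference uses cluster-robust standard errors clustered
on bird, since the grouping factors are nested in bird.  First-order interactions are pruned
sequentially worst-first at the configured significance level; main
effects (and random terms) are never removed.
"""

from __future__ import annotations

import re
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .params import AnalysisParams

MODEL_NAMES = ("encounter_rate", "attend_prob", "attend_duration",
               "attend_prop", "attend_distance", "mass_gain")


@dataclass
class ModelSpec:
    name: str
    family: str              # "negative-binomial" | "binomial" | "gaussian"
    response: str
    fixed: list              # patsy-style terms; interactions contain ":"
    offset: str | None = None
    random: tuple = ()       # grouping factors, outermost first
    alpha: float = 0.05

    @property
    def interactions(self) -> list:
        return [t for t in self.fixed if ":" in t]


@dataclass
class ModelResult:
    spec: ModelSpec
    terms: pd.DataFrame      # term, estimate, se, statistic, p
    dropped: list
    formula: str
    n_obs: int
    n_groups: dict
    converged: bool
    mixed: bool              # False when cluster-robust fallback engine used
    notes: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return self.terms.copy()

    def manifest(self) -> dict:
        return {
            "model": self.spec.name, "family": self.spec.family,
            "formula": self.formula, "pruned_interactions": list(self.dropped),
            "n_obs": self.n_obs, "n_groups": self.n_groups,
            "converged": self.converged, "mixed_random_effects": self.mixed,
            "notes": list(self.notes),
        }


def model_spec(name: str, alpha: float = 0.05) -> ModelSpec:
    base = ["age", "sex", "age:sex"]
    year_terms = ["year_group", "year_group:age", "year_group:sex"]
    if name == "encounter_rate":
        return ModelSpec(name, "negative-binomial", "n_encounters",
                         base + ["avg_boats_present"],
                         offset="np.log(duration_days)",
                         random=("bird_id",), alpha=alpha)
    if name == "attend_prob":
        return ModelSpec(name, "binomial", "has_attendance",
                         base + year_terms
                         + ["avg_boats_in_range", "time_to_fishing_hr"],
                         random=("bird_id", "trip_id"), alpha=alpha)
    if name == "attend_duration":
        return ModelSpec(name, "negative-binomial", "n_attendance",
                         base + year_terms
                         + ["avg_boats_in_range", "prop_fishing"],
                         random=("bird_id", "trip_id"), alpha=alpha)
    if name == "attend_prop":
        return ModelSpec(name, "negative-binomial", "n_attendance",
                         base + year_terms
                         + ["avg_boats_in_range", "prop_fishing"],
                         offset="np.log(n_locations)",
                         random=("bird_id", "trip_id"), alpha=alpha)
    if name == "attend_distance":
        return ModelSpec(name, "gaussian", "mean_distance_m",
                         base + year_terms
                         + ["avg_boats_in_range", "prop_fishing"],
                         random=("bird_id", "trip_id"), alpha=alpha)
    raise ValueError(f"unknown model {name!r}")


def build_design(name: str, trips: pd.DataFrame | None = None,
                 events: pd.DataFrame | None = None) -> pd.DataFrame:
    """Model frame for one response; rows with missing covariates dropped.

    ``trips`` is the trip-summary frame; ``events`` the event frame of
    retained events with covariates and bird metadata attached.
    """
    spec = model_spec(name)
    if name == "encounter_rate":
        if trips is None:
            raise ValueError("encounter_rate needs trip summaries")
        cols = ["n_encounters", "duration_days", "age", "sex",
                "avg_boats_present", "bird_id", "trip_id"]
        frame = trips[cols].copy()
    else:
        if events is None:
            raise ValueError(f"{name} needs the events frame")
        ev = events[events["retained_daylight"]].copy()
        if name in ("attend_duration", "attend_prop", "attend_distance"):
            ev = ev[ev["has_attendance"]]
        if "year_group" not in ev.columns:
            raise ValueError("events frame lacks year_group")
        cols = list(dict.fromkeys(
            [spec.response] + _vars_of(spec) + ["bird_id", "trip_id"]))
        frame = ev[cols].copy()
    frame[spec.response] = frame[spec.response].astype(
        int if spec.family != "gaussian" else float)
    n0 = len(frame)
    frame = frame.dropna().reset_index(drop=True)
    if len(frame) < n0:
        frame.attrs["n_dropped_missing"] = n0 - len(frame)
    return frame


def _vars_of(spec: ModelSpec) -> list:
    out = []
    for t in spec.fixed:
        out.extend(t.split(":"))
    if spec.offset:
        m = re.search(r"np\.log\((\w+)\)", spec.offset)
        if m:
            out.append(m.group(1))
    return list(dict.fromkeys(out))


def _formula(spec: ModelSpec, fixed: list) -> str:
    return f"{spec.response} ~ " + " + ".join(fixed) if fixed else f"{spec.response} ~ 1"


def _term_pvalues(params, bse, names) -> pd.DataFrame:
    z = np.asarray(params) / np.asarray(bse)
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"term": names, "estimate": np.asarray(params),
                         "se": np.asarray(bse), "statistic": z, "p": p})


def _interaction_columns(term: str, names) -> list:
    """Design-matrix columns belonging to a ``a:b`` interaction term."""
    a, b = term.split(":")
    pat_parts = [re.escape(a), re.escape(b)]
    cols = []
    for nm in names:
        if ":" not in nm:
            continue
        left, right = nm.split(":", 1)
        def match(part, var):
            return part == var or part.startswith(f"{var}[")
        if ((match(left, a) and match(right, b))
                or (match(left, b) and match(right, a))):
            cols.append(nm)
    return cols


def _fit_nb(spec, frame, fixed):
    """Negative-binomial fit with cluster-robust SEs on bird_id.

    Primary engine is full ML (statsmodels discrete NegativeBinomial,
    jointly estimating the dispersion).  Count frames from small studies
    can put the dispersion on the boundary and make that Hessian
    singular; the fallback then fits a Poisson GLM by IRLS, estimates
    the NB dispersion by the Cameron-Trivedi auxiliary regression, and
    refits a fixed-dispersion NB GLM.
    """
    formula = _formula(spec, fixed)
    offset = None
    if spec.offset:
        var = re.search(r"np\.log\((\w+)\)", spec.offset).group(1)
        offset = np.log(frame[var].astype(float))
    cov_kw = dict(cov_type="cluster", cov_kwds={"groups": frame["bird_id"]}) \
        if "bird_id" in frame else {}
    try:
        model = smf.negativebinomial(formula, data=frame, offset=offset)
        with np.errstate(all="ignore"):
            res = model.fit(method="bfgs", maxiter=500, disp=0, **cov_kw)
        conv = bool(res.mle_retvals.get("converged", True))
        if conv and np.all(np.isfinite(res.bse)):
            terms = _term_pvalues(res.params.values, res.bse.values,
                                  list(res.params.index))
            return res, terms, True
    except (np.linalg.LinAlgError, ValueError):
        pass

    with np.errstate(all="ignore"):
        try:
            pois = smf.glm(formula, data=frame, offset=offset,
                           family=sm.families.Poisson()).fit(**cov_kw)
        except np.linalg.LinAlgError as err:
            raise ValueError(
                f"design matrix for {spec.name!r} is singular (collinear or "
                "constant covariates); inspect the model frame") from err
        mu = pois.fittedvalues.to_numpy()
        y = np.asarray(pois.model.endog, dtype=float)
        # auxiliary OLS through the origin: ((y-mu)^2 - y)/mu ~ alpha * mu
        aux = ((y - mu) ** 2 - y) / mu
        alpha = float(max(0.0, np.sum(aux * mu) / np.sum(mu ** 2)))
        if alpha > 1e-8:
            res = smf.glm(formula, data=frame, offset=offset,
                          family=sm.families.NegativeBinomial(alpha=alpha)
                          ).fit(**cov_kw)
        else:
            res = pois
    terms = _term_pvalues(res.params.values, res.bse.values,
                          list(res.params.index))
    terms = pd.concat([terms, pd.DataFrame(
        [{"term": "alpha", "estimate": alpha, "se": np.nan,
          "statistic": np.nan, "p": np.nan}])], ignore_index=True)
    terms.attrs["note"] = ("dispersion estimated by auxiliary regression "
                           f"(alpha={alpha:.4g}); ML dispersion fit was "
                           "singular")
    return res, terms, True


def _r_to_patsy_names(names, frame) -> list:
    """Rewrite R coefficient names (sexM) to patsy style (sex[T.M])."""
    cat_levels = {c: sorted(map(str, frame[c].dropna().unique()))
                  for c in frame.columns if frame[c].dtype == object}

    def fix_part(part):
        for var, levels in cat_levels.items():
            if part.startswith(var) and part != var:
                lev = part[len(var):]
                if lev in levels:
                    return f"{var}[T.{lev}]"
        return part

    out = []
    for nm in names:
        if nm == "(Intercept)":
            out.append("Intercept")
        else:
            out.append(":".join(fix_part(p) for p in nm.split(":")))
    return out


def _glmer(spec, frame, fixed):
    """Binomial GLMM with random intercepts via lme4::glmer (Rscript)."""
    rhs = " + ".join(fixed) if fixed else "1"
    re_part = " + ".join(f"(1 | {g})" for g in spec.random)
    r_formula = f"{spec.response} ~ {rhs} + {re_part}"
    with tempfile.TemporaryDirectory() as td:
        data_csv = Path(td) / "frame.csv"
        coef_csv = Path(td) / "coef.csv"
        df = frame.copy()
        df[spec.response] = df[spec.response].astype(int)
        df.to_csv(data_csv, index=False)
        script = f"""
suppressMessages(library(lme4))
d <- read.csv("{data_csv}", stringsAsFactors = TRUE)
m <- glmer({r_formula}, data = d, family = binomial,
           control = glmerControl(check.conv.singular = "ignore"))
co <- summary(m)$coefficients
write.csv(data.frame(term = rownames(co), estimate = co[, 1], se = co[, 2]),
          "{coef_csv}", row.names = FALSE)
"""
        proc = subprocess.run(["Rscript", "--vanilla", "-e", script],
                              capture_output=True, text=True, timeout=600)
        if proc.returncode != 0:
            raise RuntimeError(f"glmer failed: {proc.stderr[-400:]}")
        co = pd.read_csv(coef_csv)
    terms = _term_pvalues(co["estimate"].to_numpy(), co["se"].to_numpy(),
                          _r_to_patsy_names(co["term"], frame))
    return terms


def _fit_binomial_mixed(spec, frame, fixed):
    """Binomial mixed model: lme4::glmer, with a variational fallback.

    glmer gives maximum-likelihood estimates with trustworthy standard
    errors; if the R engine is unavailable the variational-Bayes fit in
    statsmodels supplies the same point estimates but optimistic SEs
    (flagged in the result notes).
    """
    try:
        terms = _glmer(spec, frame, fixed)
        return None, terms, True
    except (OSError, RuntimeError, subprocess.TimeoutExpired) as err:
        formula = _formula(spec, fixed)
        vc = {}
        if "bird_id" in spec.random:
            vc["bird"] = "0 + C(bird_id)"
        if "trip_id" in spec.random and \
                frame["trip_id"].nunique() < len(frame):
            vc["trip"] = "0 + C(trip_id)"
        model = sm.BinomialBayesMixedGLM.from_formula(formula, vc, frame)
        import warnings
        with warnings.catch_warnings(), np.errstate(all="ignore"):
            warnings.simplefilter("ignore", RuntimeWarning)
            res = model.fit_vb()
        k = len(res.fe_mean)
        names = list(model.exog_names)
        terms = _term_pvalues(res.fe_mean, res.fe_sd, names[:k])
        terms.attrs["note"] = (
            "variational-Bayes fallback (glmer unavailable: "
            f"{str(err)[:120]}); standard errors are optimistic")
        return res, terms, True


def _fit_gaussian_mixed(spec, frame, fixed):
    formula = _formula(spec, fixed)
    if spec.random:
        try:
            vc = ({"trip": "0 + C(trip_id)"}
                  if "trip_id" in spec.random else None)
            model = smf.mixedlm(formula, data=frame,
                                groups=frame["bird_id"],
                                re_formula="1", vc_formula=vc)
            import warnings
            with warnings.catch_warnings(), np.errstate(all="ignore"):
                warnings.simplefilter("ignore")
                res = model.fit(reml=False, maxiter=500)
            ok = bool(res.converged) and np.all(np.isfinite(
                res.bse[model.exog_names]))
        except (np.linalg.LinAlgError, ValueError):
            ok = False
        if ok:
            names = [n for n in res.params.index if n in model.exog_names]
            terms = _term_pvalues(res.params[names].values,
                                  res.bse[names].values, names)
            return res, terms, True
        # mixed fit failed: OLS with cluster-robust SEs on bird_id
        res = smf.ols(formula, data=frame).fit(
            cov_type="cluster", cov_kwds={"groups": frame["bird_id"]})
        terms = _term_pvalues(res.params.values, res.bse.values,
                              list(res.params.index))
        terms.attrs["note"] = ("gaussian mixed fit did not converge; OLS "
                               "with cluster-robust SEs on bird_id")
        return res, terms, True
    res = smf.ols(formula, data=frame).fit()
    terms = pd.DataFrame({"term": res.params.index, "estimate": res.params.values,
                          "se": res.bse.values, "statistic": res.tvalues.values,
                          "p": res.pvalues.values})
    return res, terms, True


_ENGINES = {"negative-binomial": _fit_nb, "binomial": _fit_binomial_mixed,
            "gaussian": _fit_gaussian_mixed}


def _lrt_pvalue(spec, frame, fixed, term):
    """Likelihood-ratio p for one interaction term (gaussian mixed models).

    Returns None when either fit fell back to OLS, in which case the
    caller uses the Wald p-value instead (an LRT across different
    engines is meaningless).
    """
    full, terms_full, _ = _fit_gaussian_mixed(spec, frame, fixed)
    reduced, terms_red, _ = _fit_gaussian_mixed(
        spec, frame, [t for t in fixed if t != term])
    if terms_full.attrs.get("note") or terms_red.attrs.get("note"):
        return None
    ncols = max(1, len(_interaction_columns(term, terms_full["term"])))
    lr = 2.0 * (full.llf - reduced.llf)
    return float(stats.chi2.sf(max(lr, 0.0), df=ncols))


def fit_with_pruning(spec: ModelSpec, frame: pd.DataFrame) -> ModelResult:
    """Fit, then sequentially drop the worst nonsignificant interaction.

    Only first-order interaction terms are candidates; the least
    significant one with p > alpha is removed and the model refitted,
    until every remaining interaction is significant or none remain.
    """
    if len(frame) == 0:
        raise ValueError("empty model frame")
    engine = _ENGINES[spec.family]
    fixed = list(spec.fixed)
    dropped = []
    while True:
        res, terms, conv = engine(spec, frame, fixed)
        inter = [t for t in fixed if ":" in t]
        if not inter:
            break
        pvals = {}
        for t in inter:
            p = None
            if spec.family == "gaussian" and spec.random:
                p = _lrt_pvalue(spec, frame, fixed, t)
            if p is None:
                cols = _interaction_columns(t, terms["term"])
                p = (float(terms.set_index("term").loc[cols, "p"].min())
                     if cols else 1.0)
            pvals[t] = p
        worst = max(pvals, key=lambda t: pvals[t])
        if pvals[worst] <= spec.alpha:
            break
        fixed.remove(worst)
        dropped.append(worst)

    n_groups = {g: int(frame[g].nunique()) for g in spec.random}
    notes = []
    if spec.family == "negative-binomial" and spec.random:
        notes.append("negative-binomial fitted without random terms; "
                     "cluster-robust SEs on bird_id")
    if terms.attrs.get("note"):
        notes.append(terms.attrs["note"])
    mixed = (spec.family != "negative-binomial" and bool(spec.random)
             and not any("did not converge" in n for n in notes))
    return ModelResult(
        spec=spec, terms=terms, dropped=dropped,
        formula=_formula(spec, fixed), n_obs=len(frame), n_groups=n_groups,
        converged=conv, mixed=mixed, notes=notes,
    )


def fit_model(name: str, trips: pd.DataFrame | None = None,
              events: pd.DataFrame | None = None,
              alpha: float = 0.05) -> ModelResult:
    spec = model_spec(name, alpha)
    frame = build_design(name, trips, events)
    return fit_with_pruning(spec, frame)


# ----------------------------------------------------------- mass gain

def corrected_mass_gain(meta: pd.DataFrame, params: AnalysisParams) -> pd.Series:
    """Mass gained at sea, correcting weighings for mass loss on the nest.

    Optional columns ``days_nest_before`` / ``days_nest_after`` give the
    days spent on the nest between weighing and departure / between
    return and weighing; the configured loss rate (g/day) projects both
    weighings to the moments of departure and return.
    """
    rate = params.nest_mass_loss_rate
    before = meta.get("days_nest_before", pd.Series(0.0, index=meta.index))
    after = meta.get("days_nest_after", pd.Series(0.0, index=meta.index))
    dep = meta["mass_departure"] - rate * before.fillna(0.0)
    ret = meta["mass_return"] + rate * after.fillna(0.0)
    return ret - dep


def fit_mass_gain(meta: pd.DataFrame, trips: pd.DataFrame,
                  params: AnalysisParams | None = None) -> ModelResult:
    """Linear model of mass gained at sea; no random effects.

    ``meta`` needs one row per weighed bird (bird_id, sex, year,
    mass_departure, mass_return); the trip summaries supply each bird's
    proportion of trip time spent attending vessels.  Departure mass
    enters as the within-sex anomaly, so the strong sexual size
    dimorphism does not masquerade as a departure-mass effect.
    """
    params = params or AnalysisParams()
    meta = meta.dropna(subset=["mass_departure", "mass_return"]).copy()
    if meta["bird_id"].duplicated().any():
        raise ValueError("mass-gain model expects one record per bird")
    counts = meta["sex"].value_counts()
    if counts.reindex(["M", "F"]).fillna(0).min() < 2:
        raise ValueError("need at least 2 weighed birds of each sex")

    per_bird = (trips.groupby("bird_id")["attendance_prop_of_trip"]
                .mean().rename("attendance_prop"))
    frame = meta.merge(per_bird, on="bird_id", how="left")
    frame["attendance_prop"] = frame["attendance_prop"].fillna(0.0)
    frame["mass_gain"] = corrected_mass_gain(frame, params).values
    frame["dep_mass_anomaly"] = (
        frame["mass_departure"]
        - frame.groupby("sex")["mass_departure"].transform("mean"))

    spec = ModelSpec("mass_gain", "gaussian", "mass_gain",
                     ["C(year)", "sex", "attendance_prop",
                      "sex:attendance_prop", "dep_mass_anomaly"],
                     random=(), alpha=params.alpha)
    return fit_with_pruning(spec, frame)


def fit_all(trips: pd.DataFrame, events: pd.DataFrame,
            alpha: float = 0.05) -> dict:
    """Fit the five behavioral response models."""
    return {name: fit_model(name, trips, events, alpha)
            for name in MODEL_NAMES if name != "mass_gain"}
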