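"""Matched case-control selection inference with Monte Carlo variance
correction.

One logistic regression is fitted per control replicate (observed rows are
the cases in every fit, that replicate's simulated rows the controls, all
observations weighted equally, no random effects). Across the replicate
fits, the mean coefficient is the point estimate and the *standard
deviation* of the coefficients — not the standard error of the mean — is the
reported standard error; autocorrelated tracks make model-based standard
errors overconfident and the replicate spread absorbs that. p-values come
from a two-sided normal tail on mean/SD.

Backward elimination removes, at each pass, the least-significant removable
term with p above alpha and refits everything. A main effect is never
removable while any remaining term contains it (for the quadratic
concentration term, the linear term counts as contained); interaction terms
are always removable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import (
    IncompleteProfileError,
    InsufficientReplicatesError,
    SeparationError,
)

__all__ = [
    "SINGLE_EFFECTS",
    "INTERACTIONS",
    "ModelFormula",
    "ReplicateFit",
    "RSFResult",
    "SelectionCurve",
    "design_matrix",
    "fit_single_rsf",
    "mc_inference",
    "stepwise_eliminate",
    "odds_of_selection",
    "peak_ice_concentration",
    "peak_from_coefficients",
]

SINGLE_EFFECTS = [
    "sex",
    "sqrt_d2coast",
    "sqrt_depth_m",
    "sqrt_d21kiso",
    "sqrt_d2ice",
    "ice_conc",
    "ice_conc2",
    "sea_ice",
]

INTERACTIONS = [
    "sea_ice:sqrt_d2ice",
    "sex:sqrt_d2coast",
    "sex:sqrt_depth_m",
    "sex:sqrt_d21kiso",
    "sex:sqrt_d2ice",
    "sex:ice_conc",
    "sex:ice_conc2",
    "sex:sea_ice",
    "sex:sea_ice:sqrt_d2ice",
]

#: Base (untransformed) covariate feeding each single-effect term.
_BASE_OF = {
    "sex": "sex",
    "sqrt_d2coast": "d2coast",
    "sqrt_depth_m": "depth_m",
    "sqrt_d21kiso": "d21kiso",
    "sqrt_d2ice": "d2ice",
    "ice_conc": "ice_conc",
    "ice_conc2": "ice_conc",
    "sea_ice": "sea_ice",
}


def _parts(term: str) -> list[str]:
    return term.split(":")


def _constituents(term: str) -> set[str]:
    """Single effects implied by a term (quadratic implies linear)."""
    out = set(_parts(term))
    if "ice_conc2" in out:
        out.add("ice_conc")
    return out


@dataclass
class ModelFormula:
    """Ordered term list over the model vocabulary; intercept implicit.

    Hierarchy invariants are enforced at construction: every part of an
    interaction must be present as a single effect, and the quadratic
    concentration term requires the linear one.
    """

    terms: list[str]

    def __post_init__(self):
        vocab = set(SINGLE_EFFECTS) | set(INTERACTIONS)
        unknown = [t for t in self.terms if t not in vocab]
        if unknown:
            raise ValueError(f"unknown model terms: {unknown}")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms in formula")
        present = set(self.terms)
        for t in self.terms:
            for p in _parts(t):
                if p not in present:
                    raise ValueError(f"hierarchy violation: {t!r} requires single effect {p!r}")
        if "ice_conc2" in present and "ice_conc" not in present:
            raise ValueError("hierarchy violation: ice_conc2 requires ice_conc")

    @classmethod
    def initial(cls) -> "ModelFormula":
        return cls(terms=SINGLE_EFFECTS + INTERACTIONS)

    def drop(self, term: str) -> "ModelFormula":
        return ModelFormula(terms=[t for t in self.terms if t != term])

    def removable(self) -> list[str]:
        """Terms eligible for elimination under the marginality rule."""
        out = []
        for t in self.terms:
            if ":" in t:
                out.append(t)
                continue
            protected = any(
                t in _constituents(u) for u in self.terms if u != t and (":" in u or u == "ice_conc2")
            )
            if not protected:
                out.append(t)
        return out

    def required_bases(self) -> set[str]:
        return {_BASE_OF[p] for t in self.terms for p in _parts(t)}


def _single_column(df: pd.DataFrame, effect: str) -> np.ndarray:
    if effect == "sex":
        return (df["sex"].astype(str) == "M").astype(float).values
    if effect == "sea_ice":
        return (df["sea_ice"].astype(str) == "no").astype(float).values
    return df[effect].astype(float).values


def design_matrix(df: pd.DataFrame, formula: ModelFormula) -> pd.DataFrame:
    """Numeric design matrix with an intercept column first.

    ``sex`` is coded as an indicator for M, ``sea_ice`` as an indicator for
    open water (sea_ice = no); interactions are elementwise products.
    """
    X = {"intercept": np.ones(len(df))}
    for t in formula.terms:
        col = np.ones(len(df))
        for p in _parts(t):
            col = col * _single_column(df, p)
        X[t] = col
    return pd.DataFrame(X, index=df.index)


def _non_identifiable(X: pd.DataFrame, rtol: float = 1e-8) -> list[str]:
    """Columns that add no rank to the design (constant or collinear).

    Greedy Gram-Schmidt in column order, so earlier (lower-order) terms are
    kept preferentially over the later terms they absorb.
    """
    n = len(X)
    basis = np.empty((n, 0))
    dropped = []
    for c in X.columns:
        v = X[c].values.astype(float)
        r = v - basis @ (basis.T @ v)
        nr = np.linalg.norm(r)
        if nr > rtol * max(1.0, np.linalg.norm(v)):
            basis = np.column_stack((basis, r / nr))
        else:
            dropped.append(c)
    return dropped


@dataclass
class ReplicateFit:
    replicate: int
    coef: dict
    converged: bool
    llf: float
    dropped: list = field(default_factory=list)


def fit_single_rsf(
    rows: pd.DataFrame,
    formula: ModelFormula,
    replicate: int = 0,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> ReplicateFit:
    """Maximum-likelihood logistic fit of case (1) versus control (0) rows.

    IRLS with tolerance 1e-8 and at most 100 iterations; every observation
    weighted equally. Constant (non-identifiable) columns are dropped and
    recorded; perfect separation raises :class:`SeparationError` naming the
    worst term; non-convergence is flagged, not raised.
    """
    y = rows["case"].astype(float).values
    if y.min() == y.max():
        raise ValueError("both case and control rows are required")
    X = design_matrix(rows, formula)
    dropped = _non_identifiable(X)
    X = X.drop(columns=dropped)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = model.fit(tol=tol, maxiter=maxiter)
        llf = float(res.llf)
    params = res.params
    # perfect separation: the likelihood is (numerically) maximized at 1
    if llf > -1e-6 and np.abs(params.values).max() > 30.0:
        worst = params.abs().idxmax()
        raise SeparationError(f"perfect separation suspected for term {worst!r}")
    coef = {t: float(params[t]) if t in params.index else float("nan") for t in ["intercept", *formula.terms]}
    return ReplicateFit(
        replicate=replicate,
        coef=coef,
        converged=bool(res.converged),
        llf=llf,
        dropped=dropped,
    )


_TINY_P = np.nextafter(0.0, 1.0)


def mc_inference(fits: list[ReplicateFit]) -> pd.DataFrame:
    """Replicate-spread inference table: mean, SD-as-SE, z, two-sided p.

    Only converged fits enter. A zero replicate spread is flagged
    ``degenerate_se`` and its p reported below machine minimum rather
    than as an exact zero.
    """
    good = [f for f in fits if f.converged]
    if len(good) < 2:
        raise InsufficientReplicatesError(f"need >= 2 converged replicate fits, have {len(good)}")
    terms = list(good[0].coef.keys())
    mat = np.array([[f.coef[t] for t in terms] for f in good])
    rows = []
    for j, t in enumerate(terms):
        vals = mat[:, j]
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            rows.append({"term": t, "mean": np.nan, "se": np.nan, "z": np.nan, "p": np.nan,
                         "n_reps": int(vals.size), "degenerate_se": False})
            continue
        mean = float(vals.mean())
        se = float(vals.std(ddof=1))
        # treat numerically-zero spread (constant coefficients) as degenerate
        if se <= abs(mean) * 1e-12 + 1e-300:
            se = 0.0
            z = np.inf * np.sign(mean) if mean != 0 else 0.0
            p = _TINY_P if mean != 0 else 1.0
            degenerate = True
        else:
            z = mean / se
            p = float(2.0 * sps.norm.sf(abs(z)))
            degenerate = False
        rows.append({"term": t, "mean": mean, "se": se, "z": float(z), "p": p,
                     "n_reps": int(vals.size), "degenerate_se": degenerate})
    return pd.DataFrame(rows).set_index("term")


@dataclass
class RSFResult:
    """Final inference table, elimination trace, and final formula."""

    stats: pd.DataFrame
    trace: pd.DataFrame
    formula: ModelFormula
    n_replicates: int

    def coefficient(self, term: str) -> float:
        return float(self.stats.loc[term, "mean"])


def _fit_all_replicates(rows: pd.DataFrame, formula: ModelFormula) -> list[ReplicateFit]:
    case_rows = rows.loc[rows["case"] == 1]
    reps = sorted(r for r in rows["replicate"].unique() if r != 0)
    fits = []
    for r in reps:
        sub = pd.concat([case_rows, rows.loc[rows["replicate"] == r]], ignore_index=True)
        fits.append(fit_single_rsf(sub, formula, replicate=int(r)))
    return fits


def stepwise_eliminate(
    rows: pd.DataFrame,
    initial: ModelFormula | None = None,
    alpha: float = 0.05,
    refit: bool = True,
) -> RSFResult:
    """Backward elimination at ``alpha`` over Monte Carlo p-values.

    Each pass refits all replicates (``refit=False`` reuses the first pass's
    coefficients, recomputing p-values only), removes the single least
    significant removable term with p > alpha, and stops when every
    removable term is significant. Ties prefer the higher-order term, then
    alphabetical order.
    """
    formula = initial or ModelFormula.initial()
    trace_rows = []
    step = 1
    fits = _fit_all_replicates(rows, formula)
    while True:
        if refit or not trace_rows:
            stats_tbl = mc_inference(fits)
        removable = formula.removable()
        cand = []
        for t in removable:
            p = stats_tbl.loc[t, "p"] if t in stats_tbl.index else np.nan
            p = 1.0 if np.isnan(p) else float(p)
            if p > alpha:
                cand.append((p, len(_parts(t)), t))
        if not cand:
            break
        # worst p first; ties -> higher interaction order, then name
        cand.sort(key=lambda c: (-c[0], -c[1], c[2]))
        p_rm, _, term = cand[0]
        trace_rows.append({"step": step, "term": term, "p_at_removal": p_rm})
        formula = formula.drop(term)
        step += 1
        if refit:
            fits = _fit_all_replicates(rows, formula)
        else:
            for f in fits:
                f.coef.pop(term, None)
            stats_tbl = mc_inference(fits)
    final_stats = mc_inference(fits)
    trace = pd.DataFrame(trace_rows, columns=["step", "term", "p_at_removal"])
    return RSFResult(stats=final_stats, trace=trace, formula=formula, n_replicates=len(fits))


@dataclass
class SelectionCurve:
    vary: str
    grid: np.ndarray
    odds: np.ndarray
    availability: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {"value": self.grid, "odds": self.odds}
        if self.availability is not None:
            d["availability"] = self.availability
        return pd.DataFrame(d)


def odds_of_selection(
    result: RSFResult,
    profile: dict,
    vary: str,
    grid: np.ndarray,
    control_rows: pd.DataFrame | None = None,
) -> SelectionCurve:
    """Odds-of-selection curve: exp(linear predictor) along one covariate.

    ``profile`` fixes every base covariate the final model needs (natural
    scale: distances in km, depth in m, concentration in %, ``sex`` in
    {F, M}, ``sea_ice`` in {yes, no}); ``vary`` names the base covariate
    swept over ``grid``. Odds > 1 flag selected habitat. When
    ``control_rows`` are given, the empirical density of the varied
    covariate among them is attached as availability shading weights.
    """
    grid = np.asarray(grid, dtype=float)
    needed = result.formula.required_bases()
    missing = sorted(needed - set(profile) - {vary})
    if missing:
        raise IncompleteProfileError(f"profile missing covariates: {missing}")
    base = {k: [v] * len(grid) for k, v in profile.items()}
    base[vary] = grid
    df = pd.DataFrame(base)
    for col in ("d2coast", "depth_m", "d21kiso", "d2ice"):
        if col in df:
            df["sqrt_" + col] = np.sqrt(df[col].astype(float))
    if "ice_conc" in df:
        df["ice_conc2"] = df["ice_conc"].astype(float) ** 2
    if "sex" not in df:
        df["sex"] = "F"
    if "sea_ice" not in df:
        df["sea_ice"] = "yes"
    X = design_matrix(df, result.formula)
    beta = result.stats.loc[X.columns, "mean"].values
    odds = np.exp(X.values @ beta)
    availability = None
    if control_rows is not None and vary in control_rows.columns:
        vals = control_rows[vary].astype(float).dropna().values
        hist, edges = np.histogram(vals, bins=min(30, max(5, int(np.sqrt(vals.size)))), density=True)
        idx = np.clip(np.digitize(grid, edges) - 1, 0, len(hist) - 1)
        availability = hist[idx] / hist.max() if hist.max() > 0 else np.zeros_like(grid)
    return SelectionCurve(vary=vary, grid=grid, odds=odds, availability=availability)


def peak_from_coefficients(beta_linear: float, beta_quadratic: float) -> float | None:
    """Stationary point of ``b1*c + b2*c^2`` on [0, 100]; None unless concave."""
    if not np.isfinite(beta_quadratic) or beta_quadratic >= 0:
        return None
    return float(np.clip(-beta_linear / (2.0 * beta_quadratic), 0.0, 100.0))


def peak_ice_concentration(result: RSFResult) -> float | None:
    """Concentration (%) maximizing the fitted quadratic concentration effect."""
    if "ice_conc" not in result.formula.terms or "ice_conc2" not in result.formula.terms:
        return None
    return peak_from_coefficients(result.coefficient("ice_conc"), result.coefficient("ice_conc2"))
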