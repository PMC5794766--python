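"""Bioassay statistics: growth inhibition, log-logistic LC50/GI50,
root-protection pass/fail proportions, and efficiency-corrected qPCR ratios.

Conventions
-----------
Mortality dose-response is modelled as a binomial log-logistic curve on
log10(dose),

    p(d) = c + (1 - c) / (1 + (d / LC50)^(-slope)),

where ``c`` is the background (control) mortality floor, an Abbott-style
correction estimated from pooled dose-0 wells. LC50 is the dose at which the
*corrected* mortality reaches 50%. Confidence intervals come from the profile
likelihood of log10(LC50).

Growth inhibition follows the diet-overlay bioassay bookkeeping:

    GI = 1 - (TWIT / TNIT) / (TWIBC / TNIBC)

with TWIT/TWIBC the total weight of live insects and TNIT/TNIBC the total
number of insects in treatment and background check (negative control).

Root damage uses the 0-1 node-injury scale (NIS); NIS <= 0.5 is a "pass".

Relative expression uses the Pfaffl efficiency-corrected ratio
E_target^dCt_target / E_ref^dCt_ref with dCt = mean Ct(control) - mean
Ct(treated); knockdown % = 100 * (1 - ratio).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

CHI2_95_1DF = 3.841458820694124  # profile-likelihood cutoff, 1 df


@dataclass(frozen=True)
class BioassayWell:
    """One treatment replicate well: dose, insects at start, dead, total
    live weight (mg). Controls carry dose 0."""

    treatment: str
    dose: float
    n_start: int
    n_dead: int
    total_live_weight: float
    replicate: str = "r1"

    def __post_init__(self) -> None:
        if not (0 <= self.n_dead <= self.n_start):
            raise ValueError(f"{self.treatment}: n_dead outside [0, n_start]")
        if self.total_live_weight < 0:
            raise ValueError("total_live_weight must be >= 0")
        if self.n_dead == self.n_start and self.total_live_weight != 0:
            raise ValueError("all-dead well cannot carry live weight")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")


@dataclass
class DoseResponseFit:
    kind: Literal["LC50", "GI50"]
    point: float | None
    ci_low: float | None
    ci_high: float | None
    slope: float | None
    control_rate: float
    n_doses: int
    converged: bool
    notes: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class RootEvent:
    """One transgenic event's root bioassay outcome on the 0-1 NIS scale."""

    construct: str
    event_id: str
    test_date: str
    nis: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.nis <= 1.0):
            raise ValueError(f"NIS {self.nis} outside [0, 1]")


@dataclass(frozen=True)
class QpcrMeasurement:
    """Replicate Ct sets for one gene under treated and control conditions."""

    gene: str
    efficiency: float
    ct_treated: tuple[float, ...]
    ct_control: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.efficiency <= 1.0:
            raise ValueError("amplification efficiency must exceed 1 fold/cycle")
        if not self.ct_treated or not self.ct_control:
            raise ValueError("replicate Ct sets must be non-empty")
        if min(self.ct_treated + self.ct_control) <= 0:
            raise ValueError("Ct values must be positive")


# --- growth inhibition ------------------------------------------------------

def growth_inhibition(twit: float, tnit: int, twibc: float, tnibc: int) -> float:
    """GI = 1 - (TWIT/TNIT)/(TWIBC/TNIBC); negative values allowed."""
    if tnit <= 0 or tnibc <= 0:
        raise ValueError("insect counts must be positive")
    if twibc <= 0:
        raise ValueError("control collapse: total control live weight is zero")
    return 1.0 - (twit / tnit) / (twibc / tnibc)


def gi_from_wells(treated: Sequence[BioassayWell], controls: Sequence[BioassayWell]) -> float:
    """Pooled GI of a treatment group against pooled negative controls."""
    twit = sum(w.total_live_weight for w in treated)
    tnit = sum(w.n_start for w in treated)
    twibc = sum(w.total_live_weight for w in controls)
    tnibc = sum(w.n_start for w in controls)
    return growth_inhibition(twit, tnit, twibc, tnibc)


# --- dose-response ----------------------------------------------------------

def _pooled_by_dose(wells: Sequence[BioassayWell]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "dose": [w.dose for w in wells],
            "n": [w.n_start for w in wells],
            "dead": [w.n_dead for w in wells],
            "weight": [w.total_live_weight for w in wells],
        }
    )
    return df.groupby("dose", as_index=False).sum()


def _binom_nll(dead: np.ndarray, n: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -float(np.sum(dead * np.log(p) + (n - dead) * np.log1p(-p)))


def _fit_mortality(
    x: np.ndarray, dead: np.ndarray, n: np.ndarray, c: float
) -> tuple[float, float, float]:
    """Maximize the binomial likelihood of p = c + (1-c)*expit(b0 + b1*x);
    returns (b0, b1, nll)."""

    def nll(theta: np.ndarray) -> float:
        b0, b1 = theta
        return _binom_nll(dead, n, c + (1 - c) * expit(b0 + b1 * x))

    # moment-style start: linear fit of empirical logits
    with np.errstate(divide="ignore"):
        p_emp = np.clip((dead / n - c) / (1 - c), 0.02, 0.98)
        z = np.log(p_emp / (1 - p_emp))
    b1_0, b0_0 = np.polyfit(x, z, 1)
    best = None
    for start in ([b0_0, b1_0], [0.0, 1.0], [0.0, 3.0]):
        res = optimize.minimize(nll, start, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    return float(best.x[0]), float(best.x[1]), float(best.fun)


def _profile_nll_mu(x: np.ndarray, dead: np.ndarray, n: np.ndarray, c: float, mu: float) -> float:
    """NLL profiled over slope with log10(LC50) fixed at mu."""

    def nll(b1: float) -> float:
        return _binom_nll(dead, n, c + (1 - c) * expit(b1 * (x - mu)))

    res = optimize.minimize_scalar(nll, bounds=(1e-6, 100.0), method="bounded")
    return float(res.fun)


def _profile_ci(
    x: np.ndarray, dead: np.ndarray, n: np.ndarray, c: float, mu_hat: float, nll_hat: float
) -> tuple[float | None, float | None]:
    def dev(mu: float) -> float:
        return 2.0 * (_profile_nll_mu(x, dead, n, c, mu) - nll_hat) - CHI2_95_1DF

    span = max(x.max() - x.min(), 1.0)
    lo = hi = None
    for sign, out in ((-1, "lo"), (+1, "hi")):
        a, b = mu_hat, mu_hat
        step = 0.1
        for _ in range(200):
            b = a + sign * step
            if dev(b) > 0:
                break
            a = b
            step *= 1.5
            if abs(b - mu_hat) > 6 * span:
                break
        else:
            continue
        if dev(b) > 0:
            try:
                root = optimize.brentq(dev, min(a, b), max(a, b), xtol=1e-6)
            except ValueError:
                continue
            if out == "lo":
                lo = root
            else:
                hi = root
    return lo, hi


def fit_dose_response(
    wells: Sequence[BioassayWell],
    response: Literal["mortality", "GI"] = "mortality",
    abbott: bool | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    profile_ci: bool = True,
) -> DoseResponseFit:
    """Fit a log-logistic dose-response curve and locate the 50% dose.

    Parameters
    ----------
    wells:
        Treatment wells at positive doses plus (for GI, and for the Abbott
        floor) dose-0 negative-control wells.
    response:
        ``"mortality"`` fits a binomial logit on log10(dose) with optional
        control-mortality floor; ``"GI"`` fits a 2-parameter log-logistic
        curve to per-dose growth inhibition, with a seeded well-resampling
        bootstrap CI.
    abbott:
        Force the control-mortality floor on/off; default (None) enables it
        only when pooled control mortality >= 5%.
    """
    pooled = _pooled_by_dose(wells)
    treated = pooled[pooled.dose > 0]
    controls = pooled[pooled.dose == 0]
    doses = treated.dose.to_numpy(float)
    if len(doses) < 4:
        raise ValueError("fit_dose_response requires >= 4 distinct positive doses")
    notes: list[str] = []

    control_rate = 0.0
    if len(controls):
        control_rate = float(controls.dead.sum() / controls.n.sum())

    if response == "mortality":
        if abbott is None:
            abbott = control_rate >= 0.05
        c = control_rate if abbott else 0.0
        x = np.log10(doses)
        dead = treated.dead.to_numpy(float)
        n = treated.n.to_numpy(float)
        if dead.sum() == 0 or dead.sum() == n.sum():
            return DoseResponseFit("LC50", None, None, None, None, control_rate,
                                   len(doses), False, ["no mortality gradient across doses"])
        p_emp = dead / n
        order = np.argsort(x)
        if not np.all(np.diff(p_emp[order]) >= -0.25):
            notes.append("non-monotone dose-mortality pattern")
        b0, b1, nll_hat = _fit_mortality(x, dead, n, c)
        if b1 <= 0:
            return DoseResponseFit("LC50", None, None, None, b1, control_rate,
                                   len(doses), False, notes + ["negative fitted slope"])
        mu_hat = -b0 / b1
        lc50 = 10.0 ** mu_hat
        lo = hi = None
        if profile_ci:
            lo_mu, hi_mu = _profile_ci(x, dead, n, c, mu_hat, nll_hat)
            lo = 10.0 ** lo_mu if lo_mu is not None else None
            hi = 10.0 ** hi_mu if hi_mu is not None else None
        return DoseResponseFit("LC50", lc50, lo, hi, b1, control_rate,
                               len(doses), True, notes)

    # GI mode
    if not len(controls):
        raise ValueError("GI dose-response requires dose-0 control wells")
    ctrl_wells = [w for w in wells if w.dose == 0]
    by_dose: dict[float, list[BioassayWell]] = {}
    for w in wells:
        if w.dose > 0:
            by_dose.setdefault(w.dose, []).append(w)

    def gi_curve_fit(ws_by_dose: dict[float, list[BioassayWell]],
                     ctrls: Sequence[BioassayWell]) -> tuple[float, float] | None:
        ds = sorted(ws_by_dose)
        gi = np.array([gi_from_wells(ws_by_dose[d], ctrls) for d in ds])
        xx = np.log10(np.array(ds))

        def model(xv: np.ndarray, mu: float, b: float) -> np.ndarray:
            return expit(b * (xv - mu))

        try:
            popt, _ = optimize.curve_fit(
                model, xx, gi, p0=[float(np.median(xx)), 1.0],
                bounds=([xx.min() - 6, 0.01], [xx.max() + 6, 50.0]), maxfev=10000
            )
        except RuntimeError:
            return None
        return float(popt[0]), float(popt[1])

    fit = gi_curve_fit(by_dose, ctrl_wells)
    if fit is None:
        return DoseResponseFit("GI50", None, None, None, None, control_rate,
                               len(doses), False, ["GI curve fit failed"])
    mu_hat, b_hat = fit
    gi50 = 10.0 ** mu_hat
    lo = hi = None
    if n_boot > 0:
        if seed is None:
            raise ValueError("GI bootstrap requires an explicit seed")
        rng = np.random.default_rng(seed)
        mus = []
        for _ in range(n_boot):
            rs_by_dose = {
                d: [ws[i] for i in rng.integers(0, len(ws), len(ws))]
                for d, ws in by_dose.items()
            }
            rs_ctrl = [ctrl_wells[i] for i in rng.integers(0, len(ctrl_wells), len(ctrl_wells))]
            if sum(w.total_live_weight for w in rs_ctrl) <= 0:
                continue
            f = gi_curve_fit(rs_by_dose, rs_ctrl)
            if f is not None:
                mus.append(f[0])
        if len(mus) >= max(20, n_boot // 2):
            lo, hi = (10.0 ** q for q in np.quantile(mus, [0.025, 0.975]))
        else:
            notes.append("bootstrap unstable; CI omitted")
    return DoseResponseFit("GI50", gi50, lo, hi, b_hat, control_rate,
                           len(doses), True, notes)


# --- root protection --------------------------------------------------------

def pass_fail(event: RootEvent) -> Literal["pass", "fail"]:
    """NIS <= 0.5 is a pass; the 0.5 boundary itself passes."""
    return "pass" if event.nis <= 0.5 else "fail"


@dataclass
class ProportionModelResult:
    proportions: pd.DataFrame  # construct, n, passed, proportion, sem
    model_params: pd.Series | None
    model_proportions: pd.Series | None  # date-averaged model-adjusted proportions
    warnings: list[str]


def construct_proportions(events: Sequence[RootEvent]) -> ProportionModelResult:
    """Per-construct pass proportions with binomial SEM, plus a fixed-effects
    logit model (construct + test date) when several test dates are present.

    Raw proportions are always reported; the model supplements them. Complete
    separation (a construct passing or failing every event) is reported as a
    warning and the model is skipped for safety.
    """
    if not events:
        raise ValueError("no root events supplied")
    df = pd.DataFrame(
        {
            "construct": [e.construct for e in events],
            "test_date": [e.test_date for e in events],
            "passed": [1 if pass_fail(e) == "pass" else 0 for e in events],
        }
    )
    notes: list[str] = []
    grp = df.groupby("construct")["passed"].agg(n="count", passed="sum").reset_index()
    grp["proportion"] = grp.passed / grp.n
    grp["sem"] = np.sqrt(grp.proportion * (1 - grp.proportion) / grp.n)
    params = None
    model_props = None
    n_dates = df.test_date.nunique()
    separated = bool(((grp.proportion == 0) | (grp.proportion == 1)).any())
    if separated:
        notes.append("complete separation: some constructs pass or fail uniformly; "
                     "model effects for them are inestimable")
    if n_dates >= 2 and not separated:
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.glm("passed ~ C(construct) + C(test_date)", data=df,
                            family=sm.families.Binomial())
            res = model.fit()
        params = res.params
        # average model proportions over observed dates for each construct
        preds = []
        dates = df.test_date.unique()
        for con in grp.construct:
            newdata = pd.DataFrame({"construct": con, "test_date": dates})
            preds.append(float(res.predict(newdata).mean()))
        model_props = pd.Series(preds, index=grp.construct.to_list())
    elif n_dates < 2:
        notes.append("single test date: date effects not estimable; raw proportions only")
    return ProportionModelResult(grp, params, model_props, notes)


# --- qPCR -------------------------------------------------------------------

@dataclass
class PfafflResult:
    ratio: float
    knockdown_pct: float
    dct_target: float
    dct_reference: float
    replicate_ratios: tuple[float, ...] | None


def pfaffl_ratio(target: QpcrMeasurement, reference: QpcrMeasurement) -> PfafflResult:
    """Efficiency-corrected relative expression of the target gene.

    ratio = E_t^dCt_t / E_r^dCt_r, dCt = mean Ct(control) - mean Ct(treated).
    With both efficiencies exactly 2 this reduces to the textbook 2^-ddCt.
    """
    dct_t = float(np.mean(target.ct_control) - np.mean(target.ct_treated))
    dct_r = float(np.mean(reference.ct_control) - np.mean(reference.ct_treated))
    ratio = target.efficiency ** dct_t / reference.efficiency ** dct_r
    reps = None
    if (len(target.ct_treated) == len(reference.ct_treated)
            and len(target.ct_control) == len(reference.ct_control)):
        ct_t = float(np.mean(target.ct_control))
        ct_r = float(np.mean(reference.ct_control))
        reps = tuple(
            target.efficiency ** (ct_t - t) / reference.efficiency ** (ct_r - r)
            for t, r in zip(target.ct_treated, reference.ct_treated)
        )
    return PfafflResult(ratio, 100.0 * (1.0 - ratio), dct_t, dct_r, reps)


# --- mortality summaries ----------------------------------------------------

def mortality_summary(wells: Iterable[BioassayWell]) -> pd.DataFrame:
    """Mean % mortality and SEM across replicates, per treatment.

    SEM is the standard deviation of per-replicate percentages over sqrt(r);
    with a single replicate it is reported as NaN, not 0.
    """
    rows = [
        {"treatment": w.treatment, "replicate": w.replicate,
         "pct": 100.0 * w.n_dead / w.n_start}
        for w in wells
    ]
    df = pd.DataFrame(rows)
    out = (
        df.groupby("treatment")["pct"]
        .agg(mean_pct="mean", sd="std", r="count")
        .reset_index()
    )
    out["sem"] = out.sd / np.sqrt(out.r)
    out.loc[out.r == 1, "sem"] = np.nan
    return out[["treatment", "mean_pct", "sem", "r"]]
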