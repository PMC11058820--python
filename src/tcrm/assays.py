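"""SPR 1:1 Langmuir kinetics, equilibrium analysis, and ELISA quantification.

Sensorgrams follow the closed-form 1:1 (Langmuir) binding model.  During
analyte injection at concentration C,

    R(t) = C ka Rmax / (C ka + kd) * (1 - exp(-(C ka + kd) t)),

and after the injection stops at t_assoc,

    R(t) = R(t_assoc) * exp(-kd (t - t_assoc)).

Kinetic fitting is a global least-squares over the full concentration
series with shared ka, kd and Rmax, run in log-parameter space from
multiple starts.  KD = kd/ka holds exactly in every fit.  ELISA peptide-
exchange efficiency is reported as percent positive signal relative to the
positive/negative control wells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "Sensorgram", "KineticFit", "AffinityRecord", "ElisaPlate",
    "PercentPositive", "simulate_sensorgram", "fit_1to1", "fit_equilibrium",
    "fold_change", "percent_positive", "classify_binders", "analyze_plate",
    "read_sensorgrams", "write_sensorgrams", "read_plate", "write_plate",
    "FitError",
]


class FitError(RuntimeError):
    def __init__(self, message, best_params=None):
        super().__init__(message)
        self.best_params = best_params


@dataclass
class Sensorgram:
    time: np.ndarray          # s, strictly increasing
    response: np.ndarray      # RU
    concentration: float      # M
    t_assoc: float            # s, end of injection
    t_end: float              # s, end of dissociation read

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.response = np.asarray(self.response, float)
        if len(self.time) != len(self.response):
            raise ValueError("time and response lengths differ")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.t_assoc >= self.t_end:
            raise ValueError("association must precede dissociation")


def langmuir_curve(t, conc, ka, kd, rmax, t_assoc):
    """Noise-free 1:1 response at times ``t`` (vectorized)."""
    t = np.asarray(t, float)
    kobs = conc * ka + kd
    req = conc * ka * rmax / kobs
    r_assoc = req * (1.0 - np.exp(-kobs * np.minimum(t, t_assoc)))
    r_end = req * (1.0 - np.exp(-kobs * t_assoc))
    return np.where(t <= t_assoc, r_assoc,
                    r_end * np.exp(-kd * np.maximum(t - t_assoc, 0.0)))


def simulate_sensorgram(ka: float, kd: float, rmax: float, conc_series,
                        t_assoc: float = 60.0, t_dissoc: float = 120.0,
                        dt: float = 0.5, noise_sd: float = 0.0,
                        seed: int | None = None) -> list[Sensorgram]:
    """One noisy 1:1 sensorgram per analyte concentration (M)."""
    if min(ka, kd, rmax, t_assoc, t_dissoc, dt) <= 0:
        raise ValueError("rates, Rmax and times must be positive")
    if len(list(conc_series)) == 0:
        raise ValueError("empty concentration series")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    out = []
    for conc in conc_series:
        if conc <= 0:
            raise ValueError("concentrations must be positive")
        r = langmuir_curve(t, conc, ka, kd, rmax, t_assoc)
        if noise_sd > 0:
            r = r + rng.normal(0.0, noise_sd, size=len(t))
        out.append(Sensorgram(time=t.copy(), response=r,
                              concentration=float(conc), t_assoc=t_assoc,
                              t_end=t_assoc + t_dissoc))
    return out


@dataclass
class KineticFit:
    ka: float                 # 1/(M s)
    kd: float                 # 1/s
    rmax: float               # RU (global)
    residual_sse: float       # RU^2
    stderr: dict = field(default_factory=dict)
    n_points: int = 0
    warnings: list = field(default_factory=list)

    @property
    def KD(self) -> float:
        return self.kd / self.ka


def _kinetic_residuals(theta, sensorgrams):
    ka, kd, rmax = np.exp(theta)
    res = []
    for sg in sensorgrams:
        pred = langmuir_curve(sg.time, sg.concentration, ka, kd, rmax,
                              sg.t_assoc)
        res.append(sg.response - pred)
    return np.concatenate(res)


def _initial_guess(sensorgrams):
    rmax0 = max(float(sg.response.max()) for sg in sensorgrams) * 1.2
    rmax0 = max(rmax0, 1e-6)
    top = max(sensorgrams, key=lambda s: s.concentration)
    mask = top.time > top.t_assoc
    kd0 = 0.05
    if mask.sum() >= 3:
        td = top.time[mask] - top.t_assoc
        rd = top.response[mask]
        r0 = rd[0]
        if r0 > 0:
            half = np.nonzero(rd < r0 / 2)[0]
            if len(half):
                kd0 = max(np.log(2.0) / max(td[half[0]], 1e-9), 1e-5)
    concs = sorted(sg.concentration for sg in sensorgrams)
    kd_guess_conc = concs[len(concs) // 2]
    ka0 = kd0 / kd_guess_conc
    return ka0, kd0, rmax0


def fit_1to1(sensorgrams: list[Sensorgram]) -> KineticFit:
    """Global 1:1 kinetic fit with shared ka, kd, Rmax across the series.

    Runs from three starting points spanning two decades around a
    data-derived guess to avoid local minima; parameters are optimized in
    log space so positivity is structural.
    """
    if not sensorgrams:
        raise ValueError("no sensorgrams given")
    warns = []
    concs = {sg.concentration for sg in sensorgrams}
    if len(concs) < 2:
        msg = ("single analyte concentration: ka and Rmax are nearly "
               "degenerate; the fit is attempted but poorly constrained")
        warnings.warn(msg)
        warns.append(msg)

    ka0, kd0, rmax0 = _initial_guess(sensorgrams)
    best = None
    for factor in (1e-2, 1.0, 1e2):
        theta0 = np.log([ka0 * factor, kd0, rmax0])
        try:
            sol = least_squares(_kinetic_residuals, theta0,
                                args=(sensorgrams,), method="lm",
                                xtol=1e-15, ftol=1e-15, gtol=1e-15,
                                max_nfev=20000)
        except Exception:
            continue
        sse = float(np.sum(sol.fun ** 2))
        if best is None or sse < best[0]:
            best = (sse, sol)
    if best is None:
        raise FitError("1:1 kinetic fit failed from every start",
                       best_params={"ka": ka0, "kd": kd0, "rmax": rmax0})
    sse, sol = best
    ka, kd, rmax = np.exp(sol.x)

    n = sum(len(sg.time) for sg in sensorgrams)
    dof = max(n - 3, 1)
    stderr = {}
    try:
        J = sol.jac
        cov = np.linalg.inv(J.T @ J) * (sse / dof)
        se_log = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        stderr = {"ka": ka * se_log[0], "kd": kd * se_log[1],
                  "rmax": rmax * se_log[2],
                  "KD": (kd / ka) * float(np.hypot(se_log[0], se_log[1]))}
    except np.linalg.LinAlgError:
        warns.append("singular Jacobian: standard errors unavailable")
    if not all(np.isfinite([ka, kd, rmax])):
        raise FitError("non-finite fitted parameters",
                       best_params={"ka": ka, "kd": kd, "rmax": rmax})
    kd_over_ka = kd / ka
    cmax = max(concs)
    if kd_over_ka > cmax:
        msg = (f"fitted KD ({kd_over_ka:.3g} M) exceeds the highest analyte "
               f"concentration ({cmax:.3g} M); series does not span "
               "half-saturation")
        warnings.warn(msg)
        warns.append(msg)
    return KineticFit(ka=float(ka), kd=float(kd), rmax=float(rmax),
                      residual_sse=sse, stderr=stderr, n_points=n,
                      warnings=warns)


def fit_equilibrium(plateaus) -> tuple[float, float]:
    """(KD, Rmax) from steady-state responses Req = Rmax C / (C + KD).

    ``plateaus`` is a sequence of (concentration M, Req RU) pairs; at least
    three distinct concentrations are required.
    """
    pts = [(float(c), float(r)) for c, r in plateaus]
    if len({c for c, _ in pts}) < 3:
        raise ValueError("need plateaus at >= 3 concentrations")
    c = np.array([p[0] for p in pts])
    r = np.array([p[1] for p in pts])
    if np.allclose(r, r[0]):
        raise FitError("all plateau responses equal: KD is unidentifiable")

    def resid(theta):
        kd_, rmax_ = np.exp(theta)
        return r - rmax_ * c / (c + kd_)

    theta0 = np.log([np.median(c), max(r.max() * 1.2, 1e-9)])
    sol = least_squares(resid, theta0, method="lm",
                        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20000)
    kd_, rmax_ = np.exp(sol.x)
    return float(kd_), float(rmax_)


# ---------------------------------------------------------------------------
# affinity tables

@dataclass
class AffinityRecord:
    label: str
    KD: float                 # uM
    fold_change: float = 1.0  # KD_reference / KD_variant


def _round_sig(x: float, sig: int = 3) -> float:
    return float(f"{x:.{sig}g}")


def fold_change(reference: AffinityRecord, variant: AffinityRecord,
                sig: int = 3) -> float:
    """KD_reference / KD_variant to 3 significant figures (>1 = variant
    binds tighter)."""
    if reference.KD <= 0 or variant.KD <= 0:
        raise ValueError("dissociation constants must be positive")
    return _round_sig(reference.KD / variant.KD, sig)


# ---------------------------------------------------------------------------
# ELISA

@dataclass
class PercentPositive:
    value: float              # %
    sem: float | None = None  # % (replicates only)
    n: int = 1


def percent_positive(od_sample, od_negative, od_positive) -> PercentPositive:
    """Percent positive signal:
    100 * (OD_sample - OD_neg) / (OD_pos - OD_neg).

    Control inputs may be replicate arrays (averaged); a replicate sample
    array yields mean +/- SEM.  Values are not clamped: exchange can exceed
    the positive control or fall below the negative one.
    """
    neg = float(np.mean(od_negative))
    pos = float(np.mean(od_positive))
    if pos == neg:
        raise ValueError("positive and negative control ODs are equal; "
                         "percent positive is undefined")
    samples = np.atleast_1d(np.asarray(od_sample, float))
    vals = 100.0 * (samples - neg) / (pos - neg)
    if len(vals) > 1:
        sem = float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
    else:
        sem = None
    return PercentPositive(value=float(np.mean(vals)), sem=sem,
                           n=len(vals))


DEFAULT_BINDER_THRESHOLDS = {"strong": 40.0, "intermediate": 10.0}


def classify_binders(percentages: dict,
                     thresholds: dict | None = None) -> dict:
    """Category per peptide: strong / intermediate / weak stability.

    Thresholds are configurable; the defaults (strong >= 40%, intermediate
    >= 10%) reproduce the verbal categories used for the KRAS peptide panel.
    """
    th = thresholds or DEFAULT_BINDER_THRESHOLDS
    out = {}
    for label, p in percentages.items():
        v = p.value if isinstance(p, PercentPositive) else float(p)
        if v >= th["strong"]:
            out[label] = "strong"
        elif v >= th["intermediate"]:
            out[label] = "intermediate"
        else:
            out[label] = "weak"
    return out


@dataclass
class ElisaPlate:
    od: dict                  # well -> OD405
    roles: dict               # well -> "positive" | "negative" | peptide id

    def __post_init__(self):
        roles = set(self.roles.values())
        if "positive" not in roles or "negative" not in roles:
            raise ValueError(
                "plate needs at least one positive and one negative "
                "control well")

    def wells_for(self, role: str) -> list[str]:
        return sorted(w for w, r in self.roles.items() if r == role)

    def ods_for(self, role: str) -> np.ndarray:
        return np.array([self.od[w] for w in self.wells_for(role)])


def analyze_plate(plate: ElisaPlate, thresholds: dict | None = None
                  ) -> pd.DataFrame:
    """Per-peptide percent positive (mean +/- SEM over replicates) and
    binder category."""
    neg = plate.ods_for("negative")
    pos = plate.ods_for("positive")
    peptides = sorted({r for r in plate.roles.values()
                       if r not in ("positive", "negative")})
    rows = []
    for pep in peptides:
        pp = percent_positive(plate.ods_for(pep), neg, pos)
        rows.append({"peptide": pep, "percent_positive": pp.value,
                     "sem": pp.sem, "n": pp.n})
    df = pd.DataFrame(rows)
    if len(df):
        cats = classify_binders(
            dict(zip(df["peptide"], df["percent_positive"])), thresholds)
        df["category"] = df["peptide"].map(cats)
    return df


# ---------------------------------------------------------------------------
# CSV formats

def write_sensorgrams(sensorgrams: list[Sensorgram], path) -> None:
    frames = []
    for sg in sensorgrams:
        frames.append(pd.DataFrame({
            "time_s": sg.time, "response_RU": sg.response,
            "conc_M": sg.concentration,
            "phase": np.where(sg.time <= sg.t_assoc,
                              "association", "dissociation")}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_sensorgrams(path) -> list[Sensorgram]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such sensorgram file: {path}")
    df = pd.read_csv(path)
    required = {"time_s", "response_RU", "conc_M", "phase"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing columns {sorted(missing)}")
    out = []
    for conc, grp in df.groupby("conc_M", sort=True):
        grp = grp.sort_values("time_s")
        assoc = grp[grp["phase"] == "association"]
        t_assoc = float(assoc["time_s"].max()) if len(assoc) else 0.0
        out.append(Sensorgram(
            time=grp["time_s"].to_numpy(),
            response=grp["response_RU"].to_numpy(),
            concentration=float(conc), t_assoc=t_assoc,
            t_end=float(grp["time_s"].max()) + 1e-9))
    return out


def write_plate(plate: ElisaPlate, path) -> None:
    rows = [{"well": w, "role": ("sample" if plate.roles[w] not in
                                 ("positive", "negative")
                                 else plate.roles[w]),
             "peptide": (plate.roles[w] if plate.roles[w] not in
                         ("positive", "negative") else ""),
             "od405": plate.od[w]}
            for w in sorted(plate.od)]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_plate(path) -> ElisaPlate:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such plate file: {path}")
    df = pd.read_csv(path, keep_default_na=False)
    od, roles = {}, {}
    for _, row in df.iterrows():
        well = str(row["well"])
        od[well] = float(row["od405"])
        roles[well] = (str(row["peptide"]) if row["role"] == "sample"
                       else str(row["role"]))
    return ElisaPlate(od=od, roles=roles)
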