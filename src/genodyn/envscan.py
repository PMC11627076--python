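"""Scan potentials against environmental parameters for smooth dependencies.

For each SNP and environmental parameter, per-population potentials (the
distributed potential where the SNP sits in a haploblock, the marginal
potential otherwise) are fitted with a small library of simple functional
forms.  A dependency is flagged when the RMS residual of the best fit,
divided by the max-minus-min of the observed potentials, is at most the
threshold (default 10%).  The adaptive force is the negated slope of the
fitted curve; for nonlinear forms the headline value is the mean derivative
over the observed parameter range.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateForm",
    "ScanPoint",
    "ScanResult",
    "FORM_N_PARAMS",
    "DEFAULT_FORMS",
    "assemble_scan_points",
    "fit_form",
    "select_and_flag",
    "adaptive_force",
    "scan_all",
    "results_to_frame",
]

FORM_N_PARAMS = {"constant": 1, "linear": 2, "quadratic": 3, "expsat": 3}
DEFAULT_FORMS = ("constant", "linear", "quadratic", "expsat")
DEFAULT_RMS_THRESHOLD = 0.10


@dataclass
class CandidateForm:
    """A fitted functional form mu(lambda)."""

    form_id: str
    parameters: np.ndarray
    monotone_required: bool = False

    def __post_init__(self) -> None:
        if self.form_id not in FORM_N_PARAMS:
            raise ValueError(f"unknown form {self.form_id!r}")
        self.parameters = np.asarray(self.parameters, dtype=float)
        if self.parameters.size != FORM_N_PARAMS[self.form_id]:
            raise ValueError(
                f"{self.form_id} takes {FORM_N_PARAMS[self.form_id]} parameters"
            )

    @property
    def n_parameters(self) -> int:
        return FORM_N_PARAMS[self.form_id]

    def __call__(self, lam):
        lam = np.asarray(lam, dtype=float)
        p = self.parameters
        if self.form_id == "constant":
            return np.full_like(lam, p[0])
        if self.form_id == "linear":
            return p[0] + p[1] * lam
        if self.form_id == "quadratic":
            return p[0] + p[1] * lam + p[2] * lam * lam
        return p[0] + p[1] * np.exp(-p[2] * lam)

    def derivative(self, lam):
        lam = np.asarray(lam, dtype=float)
        p = self.parameters
        if self.form_id == "constant":
            return np.zeros_like(lam)
        if self.form_id == "linear":
            return np.full_like(lam, p[1])
        if self.form_id == "quadratic":
            return p[1] + 2.0 * p[2] * lam
        return -p[1] * p[2] * np.exp(-p[2] * lam)

    def is_monotone(self, lam_lo: float, lam_hi: float) -> bool:
        """True when the derivative does not change sign on [lo, hi]."""
        if self.form_id in ("constant", "linear", "expsat"):
            return True
        b, c = self.parameters[1], self.parameters[2]
        if c == 0:
            return True
        vertex = -b / (2.0 * c)
        return not (lam_lo < vertex < lam_hi)

    def describe(self) -> str:
        p = self.parameters
        if self.form_id == "constant":
            return f"mu = {p[0]:.6g}"
        if self.form_id == "linear":
            return f"mu = {p[0]:.6g} + {p[1]:.6g}*lam"
        if self.form_id == "quadratic":
            return f"mu = {p[0]:.6g} + {p[1]:.6g}*lam + {p[2]:.6g}*lam^2"
        return f"mu = {p[0]:.6g} + {p[1]:.6g}*exp(-{p[2]:.6g}*lam)"


@dataclass(frozen=True)
class ScanPoint:
    population: str
    lam: float
    mu: float
    linked: bool


@dataclass
class ScanResult:
    snp_id: str
    target: str  # allele_major | allele_minor | snp
    parameter_name: str
    best_form: CandidateForm | None
    rms_deviation: float
    potential_range: float
    relative_rms: float
    flagged: bool
    adaptive_force_linear: float
    adaptive_force: float
    adaptive_force_curve: str
    per_population_points: list = field(default_factory=list)
    reason: str = ""


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _as_arrays(points) -> tuple:
    pts = list(points)
    lam = np.array([p.lam if isinstance(p, ScanPoint) else p[0] for p in pts])
    mu = np.array([p.mu if isinstance(p, ScanPoint) else p[1] for p in pts])
    return lam.astype(float), mu.astype(float)


def _fit_poly(lam: np.ndarray, mu: np.ndarray, degree: int) -> np.ndarray:
    X = np.vander(lam, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(X, mu, rcond=None)
    return coef


def _expsat_profile(lam: np.ndarray, mu: np.ndarray, c: np.ndarray):
    """SSE and (a, b) of the linear subproblem for each decay rate c.

    For fixed c, ``a + b*exp(-c*lam)`` is linear in (a, b); the 2x2 normal
    equations are solved in closed form, vectorized over c.
    """
    c = np.atleast_1d(np.asarray(c, dtype=float))
    E = np.exp(-np.outer(c, lam))  # (n_c, n_points)
    n = lam.size
    se = E.sum(axis=1)
    see = (E * E).sum(axis=1)
    sy = mu.sum()
    sey = E @ mu
    det = n * see - se * se
    safe = np.abs(det) > 1e-12 * n * np.maximum(see, 1.0)
    a = np.where(safe, (sy * see - se * sey) / np.where(safe, det, 1.0), sy / n)
    b = np.where(safe, (n * sey - se * sy) / np.where(safe, det, 1.0), 0.0)
    resid = a[:, None] + b[:, None] * E - mu
    return (resid * resid).sum(axis=1), a, b


def _fit_expsat(lam: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Fit a + b*exp(-c*lam), c >= 0, by a deterministic grid + refinement.

    The decay rate is scanned on a log grid scaled to the observed lambda
    span and the best bracket refined with a bounded scalar minimization
    of the c-profiled SSE.  No randomness is involved.
    """
    span = float(np.ptp(lam))
    scale = span if span > 0 else 1.0
    grid = np.concatenate([[1e-8], np.geomspace(1e-3, 30.0, 40) / scale])
    sses, _, _ = _expsat_profile(lam, mu, grid)
    i = int(np.argmin(sses))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    c_best = float(grid[i])
    if hi > lo:
        res = minimize_scalar(
            lambda c: float(_expsat_profile(lam, mu, c)[0][0]),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-9 / scale},
        )
        if float(_expsat_profile(lam, mu, float(res.x))[0][0]) <= sses[i]:
            c_best = float(res.x)
    sse, a, b = _expsat_profile(lam, mu, c_best)
    return np.array([a[0], b[0], c_best])


def fit_form(points, form_id: str) -> tuple:
    """Least-squares fit of one candidate form.

    Returns ``(CandidateForm, rms_deviation)`` with
    ``rms = sqrt(mean squared residual)``.  Deterministic.  Raises on a
    degenerate design (all lambda equal) or too few points
    (fewer than n_parameters + 1).
    """
    if form_id not in FORM_N_PARAMS:
        raise ValueError(f"unknown form {form_id!r}")
    lam, mu = _as_arrays(points)
    if np.ptp(lam) == 0:
        raise ValueError("no environmental contrast (all lambda equal)")
    if lam.size < FORM_N_PARAMS[form_id] + 1:
        raise ValueError(
            f"{form_id} needs at least {FORM_N_PARAMS[form_id] + 1} points"
        )
    if form_id == "constant":
        params = np.array([mu.mean()])
    elif form_id == "linear":
        params = _fit_poly(lam, mu, 1)
    elif form_id == "quadratic":
        params = _fit_poly(lam, mu, 2)
    else:
        params = _fit_expsat(lam, mu)
    form = CandidateForm(form_id, params)
    resid = mu - form(lam)
    rms = float(np.sqrt(np.mean(resid**2)))
    return form, rms


def adaptive_force(form: CandidateForm, lam_range: Sequence[float]) -> dict:
    """Force report for a fitted form: ``f = -d(mu)/d(lambda)``.

    Linear forms give a constant force; nonlinear forms report the mean
    derivative over the observed lambda range (equal to the chord slope)
    as the headline force, alongside the derivative description.
    """
    lo, hi = float(min(lam_range)), float(max(lam_range))
    if form.form_id == "constant":
        force = 0.0
    elif form.form_id == "linear":
        force = -float(form.parameters[1])
    else:
        if hi == lo:
            raise ValueError("degenerate lambda range")
        force = -float((form(hi) - form(lo)) / (hi - lo))
    return {
        "force": force,
        "derivative": form.describe(),
        "lam_range": (lo, hi),
    }


def select_and_flag(
    points,
    forms: Sequence[str] = DEFAULT_FORMS,
    *,
    snp_id: str = "",
    target: str = "snp",
    parameter_name: str = "",
    rms_threshold: float = DEFAULT_RMS_THRESHOLD,
    monotone_required: bool | None = None,
) -> ScanResult:
    """Fit all admissible forms, pick the best, apply the flagging rule.

    Admissible forms have at least one more point than parameters and — for
    allelic targets — a derivative that does not change sign over the
    observed lambda range.  The best form minimizes the relative RMS
    (RMS residual / observed max-minus-min potential); ties favour fewer
    parameters.  Flagged iff relative RMS <= threshold.
    """
    pts = [
        p if isinstance(p, ScanPoint) else ScanPoint("", p[0], p[1], False)
        for p in points
    ]
    lam, mu = _as_arrays(pts)
    if monotone_required is None:
        monotone_required = target in ("allele_major", "allele_minor")
    prange = float(np.ptp(mu))
    base = dict(
        snp_id=snp_id,
        target=target,
        parameter_name=parameter_name,
        per_population_points=pts,
    )
    if prange == 0.0:
        return ScanResult(
            best_form=None,
            rms_deviation=0.0,
            potential_range=0.0,
            relative_rms=math.inf,
            flagged=False,
            adaptive_force_linear=0.0,
            adaptive_force=0.0,
            adaptive_force_curve="",
            reason="no variation",
            **base,
        )
    lo, hi = float(lam.min()), float(lam.max())
    candidates = []
    for form_id in forms:
        if lam.size < FORM_N_PARAMS[form_id] + 1:
            continue
        try:
            form, rms = fit_form(pts, form_id)
        except ValueError as exc:
            logger.debug("fit %s failed for %s/%s: %s", form_id, snp_id, target, exc)
            continue
        if monotone_required and not form.is_monotone(lo, hi):
            continue
        form.monotone_required = monotone_required
        candidates.append((rms / prange, form.n_parameters, form, rms))
    if not candidates:
        return ScanResult(
            best_form=None,
            rms_deviation=math.nan,
            potential_range=prange,
            relative_rms=math.inf,
            flagged=False,
            adaptive_force_linear=math.nan,
            adaptive_force=math.nan,
            adaptive_force_curve="",
            reason="no admissible form",
            **base,
        )
    candidates.sort(key=lambda c: (round(c[0], 12), c[1]))
    rel_rms, _, best, rms = candidates[0]
    report = adaptive_force(best, (lo, hi))
    try:
        lin_form, _ = fit_form(pts, "linear")
        force_linear = -float(lin_form.parameters[1])
    except ValueError:
        force_linear = math.nan
    return ScanResult(
        best_form=best,
        rms_deviation=rms,
        potential_range=prange,
        relative_rms=rel_rms,
        flagged=rel_rms <= rms_threshold,
        adaptive_force_linear=force_linear,
        adaptive_force=report["force"],
        adaptive_force_curve=report["derivative"],
        **base,
    )


# ---------------------------------------------------------------------------
# assembling points from a potential table
# ---------------------------------------------------------------------------


def assemble_scan_points(
    potentials: pd.DataFrame,
    env_series: Mapping[str, float],
    snp_id: str,
    target: str,
    *,
    min_populations: int = 3,
) -> list:
    """Per-population (lambda, potential) pairs for one SNP and target.

    ``target`` is ``allele_major``, ``allele_minor`` or ``snp``.  Where the
    SNP is linked (in a block) in a population the distributed potential is
    used, otherwise the marginal one; each point carries its linked flag.
    Non-finite potentials (absent alleles) and populations without an
    environmental value are dropped.  Raises if fewer than
    ``min_populations`` usable points remain.
    """
    sub = potentials[potentials["snp_id"] == snp_id]
    if sub.empty:
        raise ValueError(f"SNP {snp_id!r} absent from potential table")
    if target == "snp":
        rows = sub.drop_duplicates(subset=["population"])
        col_linked, col_plain = "mu_snp_distributed", "mu_snp"
    elif target in ("allele_major", "allele_minor"):
        role = target.split("_")[1]
        rows = sub[sub["role"] == role]
        col_linked, col_plain = "mu_allele_distributed", "mu_allele"
    else:
        raise ValueError(f"unknown target {target!r}")
    points = []
    for pop, linked, mu_linked, mu_plain in zip(
        rows["population"], rows["linked"], rows[col_linked], rows[col_plain]
    ):
        if pop not in env_series:
            continue
        linked = bool(linked)
        mu = float(mu_linked if linked else mu_plain)
        if not math.isfinite(mu):
            continue
        points.append(ScanPoint(pop, float(env_series[pop]), mu, linked))
    if len(points) < min_populations:
        raise ValueError(
            f"{snp_id}/{target}: only {len(points)} usable populations "
            f"(need {min_populations})"
        )
    return points


def scan_all(
    potentials: pd.DataFrame,
    env_table,
    *,
    forms: Sequence[str] = DEFAULT_FORMS,
    rms_threshold: float = DEFAULT_RMS_THRESHOLD,
    targets: Sequence[str] = ("allele_major", "allele_minor", "snp"),
    parameters: Sequence[str] | None = None,
) -> list:
    """Scan every SNP x parameter x target; failures are logged, not fatal."""
    results = []
    params = list(parameters) if parameters is not None else list(env_table.parameters)
    snp_ids = list(dict.fromkeys(potentials["snp_id"]))
    by_snp = {sid: grp for sid, grp in potentials.groupby("snp_id", sort=False)}
    for param in params:
        series = env_table.series(param)
        for snp_id in snp_ids:
            for target in targets:
                try:
                    pts = assemble_scan_points(by_snp[snp_id], series, snp_id, target)
                    res = select_and_flag(
                        pts,
                        forms,
                        snp_id=snp_id,
                        target=target,
                        parameter_name=param,
                        rms_threshold=rms_threshold,
                    )
                except ValueError as exc:
                    logger.info("scan skipped for %s/%s/%s: %s", snp_id, target, param, exc)
                    continue
                results.append(res)
    return results


def flag_fraction(results: Iterable[ScanResult]) -> float:
    results = list(results)
    if not results:
        return 0.0
    return sum(r.flagged for r in results) / len(results)


def results_to_frame(results: Iterable[ScanResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "snp_id": r.snp_id,
                "target": r.target,
                "parameter": r.parameter_name,
                "best_form": r.best_form.form_id if r.best_form else "",
                "parameters": json.dumps(
                    list(np.round(r.best_form.parameters, 12))
                )
                if r.best_form
                else "",
                "rms_deviation": r.rms_deviation,
                "potential_range": r.potential_range,
                "relative_rms": r.relative_rms,
                "flagged": r.flagged,
                "adaptive_force": r.adaptive_force,
                "adaptive_force_linear": r.adaptive_force_linear,
                "n_points": len(r.per_population_points),
                "n_linked": sum(p.linked for p in r.per_population_points),
                "reason": r.reason,
            }
        )
    return pd.DataFrame(rows)


def plot_scan(result: ScanResult, path) -> None:
    """Potential vs lambda plot with the fitted curve; linked points in red."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for p in result.per_population_points:
        ax.plot(
            p.lam,
            p.mu,
            "o",
            color="red" if p.linked else "tab:blue",
        )
        ax.annotate(p.population, (p.lam, p.mu), fontsize=7)
    if result.best_form is not None:
        lams = [p.lam for p in result.per_population_points]
        grid = np.linspace(min(lams), max(lams), 200)
        ax.plot(grid, result.best_form(grid), "-", color="black", lw=1)
    ax.set_xlabel(result.parameter_name)
    ax.set_ylabel(f"{result.snp_id} {result.target} potential (GEU)")
    ax.set_title(
        f"rel RMS {result.relative_rms:.3g}; force {result.adaptive_force:.3g}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
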